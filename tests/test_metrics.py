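"""Normalization and error metrics: resampling, rescaling, magnitude and
shape errors, participant summaries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from ames import (
    DomainError,
    magnitude_error,
    rescale_unit,
    resample_unit,
    sample_template,
    shape_error,
    summarize_participants,
    template_profile,
)
from ames.metrics import DegenerateUnitError, NormalizedUnit
from ames.segment import segment_trace

from conftest import FS
from oracles import linear_resample


def test_resample_length_and_endpoints(template_11):
    unit = segment_trace(sample_template(template_11, FS, 5.0)).units[0]
    nu = resample_unit(unit)
    assert nu.values.shape == (50,)
    assert nu.values[0] == unit.samples[0]
    assert nu.values[-1] == unit.samples[-1]
    assert not nu.rescaled


def test_resample_is_identity_on_uniform_50_point_unit(rng):
    y = rng.normal(size=50)
    assert np.allclose(resample_unit(y).values, y, atol=1e-12)


def test_resample_matches_dense_grid_oracle(template_11):
    """Linear interpolation of a sampled sine cycle: the hand-rolled
    two-point-line oracle and the implementation must agree, and both must
    track the analytic curve within the linear-interpolation error bound."""
    unit = segment_trace(sample_template(template_11, FS, 5.0)).units[1]
    got = resample_unit(unit).values
    want = np.array(linear_resample(list(unit.samples), 50))
    assert np.allclose(got, want, atol=1e-12)
    grid = np.linspace(0.0, 1.0, 50)
    analytic = template_11.cycle(grid * (len(unit.samples) - 1) / FS / unit.duration_s * unit.duration_s)
    # second-derivative bound for linear interpolation on the unit's grid
    h = 1.0 / FS
    bound = 4.0 * (2 * np.pi) ** 2 / 2 * h**2 / 4 + 1e-9
    assert np.max(np.abs(got - template_11.cycle(grid))) <= bound + 0.05


def test_too_short_unit_rejected():
    with pytest.raises(DomainError):
        resample_unit(np.array([0.0, 1.0, 0.5]))


@pytest.mark.parametrize(
    "samples,target,expected",
    [
        (np.array([0.0, 2.0, 4.0, 2.0, 0.0]), 4.0, 0.0),
        (np.array([0.0, 1.5, 3.0, 1.5, 0.0]), 4.0, 1.0),
        (np.array([1.0, 3.0, 6.0, 3.0, 1.0]), 4.0, 1.0),
    ],
)
def test_magnitude_error_peak_to_trough(samples, target, expected):
    assert magnitude_error(samples, target) == pytest.approx(expected)


def test_magnitude_error_on_clean_template_within_discretization(template_11):
    """Noise-free units err only by sampling: each extremum can sit half a
    sample off its true position, so peak-to-trough is short by at most
    twice the per-extremum bound A*(1-cos(pi*f/fs))/2."""
    seg = segment_trace(sample_template(template_11, FS, 10.0))
    bound = 4.0 * (1.0 - np.cos(np.pi * 1.0 / FS)) / 2.0
    for u in seg.units:
        assert magnitude_error(u) <= 2.0 * bound + 1e-12


def test_rescale_affine_map_and_idempotence():
    nu = NormalizedUnit(np.array([0.0, 2.0, 4.0]))
    out = rescale_unit(nu)
    assert np.allclose(out.values, [0.0, 0.5, 1.0])
    assert out.rescaled
    again = rescale_unit(out)
    assert np.allclose(again.values, out.values)
    assert out.values.min() == 0.0 and out.values.max() == 1.0


def test_rescale_constant_unit_is_degenerate():
    with pytest.raises(DegenerateUnitError):
        rescale_unit(NormalizedUnit(np.full(50, 2.0)))


def test_shape_error_zero_against_itself(template_21):
    prof = template_profile(template_21, 50)
    nu = NormalizedUnit(prof, rescaled=True)
    assert shape_error(nu, template_21) == 0.0


def test_shape_error_between_session_templates(template_11, template_21):
    """A perfect simple-session unit scored against the complicated
    template equals the grid-mean squared difference of the two rescaled
    analytic curves, and is strictly positive."""
    p11 = template_profile(template_11, 50)
    p21 = template_profile(template_21, 50)
    expected = float(np.mean((p11 - p21) ** 2))
    nu = NormalizedUnit(p11, rescaled=True)
    assert expected > 0.01
    assert shape_error(nu, template_21) == pytest.approx(expected)


@settings(max_examples=40, derandomize=True)
@given(scale=st.floats(0.1, 10.0), offset=st.floats(-50.0, 50.0))
def test_shape_error_invariant_under_affine_displacement(scale, offset):
    tpl = __import__("ames").complicated_template()
    base = sample_template(tpl, FS, 6.0)
    unit = segment_trace(base).units[2]
    raw = rescale_unit(resample_unit(unit))
    transformed = rescale_unit(resample_unit(scale * unit.samples + offset))
    assert shape_error(transformed, tpl) == pytest.approx(shape_error(raw, tpl), abs=1e-9)


def test_magnitude_error_translation_invariant_and_scales(template_11):
    u = np.array([0.0, 2.0, 4.0, 2.0, 0.0])
    assert magnitude_error(u + 7.0) == magnitude_error(u)
    # doubling amplitude about the target: |2*4 - 4| = 4
    assert magnitude_error(2.0 * u) == pytest.approx(4.0)


def test_shape_error_requires_rescaled_input(template_11):
    with pytest.raises(DomainError):
        shape_error(NormalizedUnit(np.linspace(0, 4, 50), rescaled=False), template_11)


def test_summarize_participants_matches_brute_force():
    rows = []
    rng = np.random.default_rng(9)
    for pid in ("c01", "c02"):
        for phase in ("pre_test", "post_test"):
            for k in range(5):
                rows.append(
                    {
                        "participant": pid,
                        "group": "concurrent_vf",
                        "session": "simple",
                        "phase": phase,
                        "magnitude_error_mm": float(rng.uniform(0, 2)),
                        "shape_error": float(rng.uniform(0, 0.1)),
                    }
                )
    table = pd.DataFrame(rows)
    out = summarize_participants(table)
    for _, r in out.iterrows():
        manual_m = manual_s = 0.0
        n = 0
        for row in rows:
            if row["participant"] == r["participant"] and row["phase"] == r["phase"]:
                manual_m += row["magnitude_error_mm"]
                manual_s += row["shape_error"]
                n += 1
        assert r["mean_magnitude_error_mm"] == pytest.approx(manual_m / n)
        assert r["mean_shape_error"] == pytest.approx(manual_s / n)


def test_summary_of_single_unit_equals_that_unit():
    table = pd.DataFrame(
        [
            {
                "participant": "p01",
                "group": "post_trial_vf",
                "session": "simple",
                "phase": "pre_test",
                "magnitude_error_mm": 1.25,
                "shape_error": 0.03,
            }
        ]
    )
    out = summarize_participants(table)
    assert out.loc[0, "mean_magnitude_error_mm"] == 1.25
    assert out.loc[0, "mean_shape_error"] == 0.03
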