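"""Synthetic learner-motion generator: determinism, degenerate cases,
amplitude-error calibration, spectral confinement, study tree shape."""

import numpy as np
import pytest

from ames import (
    DomainError,
    LearningCurve,
    SimulationParams,
    StudyDesign,
    default_params_by_group,
    post_trial_vf_params,
    sample_template,
    simulate_study,
    simulate_trial,
)
from ames.segment import segment_trace
from ames.simulate import PHASES, phase_time

from conftest import FS, flat_params, zero_params


def test_noise_free_simulation_is_identity_on_template(template_11, template_21):
    for tpl in (template_11, template_21):
        trace = simulate_trial(tpl, zero_params(), "trial_4", seed=7)
        ref = sample_template(tpl, FS, 20.0)
        assert np.array_equal(trace.displacement_mm, ref.displacement_mm)


def test_same_seed_gives_identical_trace(template_11):
    p = flat_params(magnitude=0.8, shape=0.5)
    a = simulate_trial(template_11, p, "pre_test", seed=99)
    b = simulate_trial(template_11, p, "pre_test", seed=99)
    assert np.array_equal(a.displacement_mm, b.displacement_mm)
    c = simulate_trial(template_11, p, "pre_test", seed=100)
    assert not np.array_equal(a.displacement_mm, c.displacement_mm)


def test_too_short_trial_rejected(template_11):
    with pytest.raises(DomainError):
        simulate_trial(template_11, zero_params(), "pre_test", seed=0, duration_s=2.0)


def test_learning_curve_closed_form_and_schedule():
    lc = LearningCurve(initial=1.2, asymptote=0.25, tau=2.5)
    assert lc.value(0) == pytest.approx(1.2)
    assert lc.value(1) == pytest.approx(0.25 + 0.95 * np.exp(-1 / 2.5))
    # schedule across phases is monotone non-increasing when E0 >= E_inf
    sched = [lc.value(phase_time(ph)) for ph in PHASES]
    assert all(a >= b for a, b in zip(sched, sched[1:]))
    assert phase_time("pre_test") == 0 and phase_time("post_test") == 8


def test_default_post_trial_error_decays_over_trials():
    p = post_trial_vf_params()
    assert p.magnitude.value(1) > p.magnitude.value(8)
    assert p.shape.value(1) > p.shape.value(8)


def test_amplitude_error_monte_carlo_matches_expectation(template_11):
    """Per-unit peak-to-trough deviation from 4 mm: each cycle's amplitude
    is 4 + d with d ~ N(0, s), so the mean |deviation| estimates
    s*sqrt(2/pi); check the Monte-Carlo mean over 200 seeds against the
    closed form within 3 standard errors."""
    s = 1.0
    p = flat_params(magnitude=s, shape=0.0, drift=0.0, noise=0.0)
    means = []
    for seed in range(200):
        trace = simulate_trial(template_11, p, "pre_test", seed=seed, duration_s=10.0)
        seg = segment_trace(trace)
        devs = [abs(np.ptp(u.samples) - 4.0) for u in seg.units]
        means.append(np.mean(devs))
    expected = s * np.sqrt(2.0 / np.pi)
    se = np.std(means, ddof=1) / np.sqrt(len(means))
    assert abs(np.mean(means) - expected) < 3.0 * se + 0.01


def test_drift_and_jitter_are_spectrally_confined(template_11):
    """Drift-only residual must live below 0.2 Hz and jitter-only residual
    above 5 Hz, so the band-pass can remove them by construction."""
    ref = sample_template(template_11, FS, 20.0).displacement_mm
    window = np.hanning(len(ref))  # tame rectangular-window leakage
    freqs = np.fft.rfftfreq(len(ref), 1.0 / FS)

    drift_only = flat_params(drift=0.5, noise=0.0)
    resid = simulate_trial(template_11, drift_only, "pre_test", seed=3).displacement_mm - ref
    power = np.abs(np.fft.rfft(resid * window)) ** 2
    assert freqs[np.argmax(power)] < 0.2
    assert power[freqs >= 0.2].sum() < 0.02 * power.sum()

    noise_only = flat_params(drift=0.0, noise=0.5)
    resid = simulate_trial(template_11, noise_only, "pre_test", seed=3).displacement_mm - ref
    power = np.abs(np.fft.rfft(resid * window)) ** 2
    assert freqs[np.argmax(power)] > 5.0
    assert power[freqs <= 5.0].sum() < 0.02 * power.sum()


def test_invalid_simulation_params_rejected():
    with pytest.raises(DomainError):
        SimulationParams(
            magnitude=LearningCurve(0.2, 0.5, 1.0),  # E0 < E_inf
            shape=LearningCurve(0.0, 0.0, 1.0),
        )
    with pytest.raises(DomainError):
        SimulationParams(
            magnitude=LearningCurve(0, 0, 1),
            shape=LearningCurve(0, 0, 1),
            drift_freq_hz=0.3,  # inside the passband
        )
    with pytest.raises(DomainError):
        SimulationParams(
            magnitude=LearningCurve(0, 0, 1),
            shape=LearningCurve(0, 0, 1),
            noise_band_hz=(3.0, 10.0),  # below the 5 Hz cut
        )


def test_study_tree_shape_and_determinism():
    design = StudyDesign(trial_duration_s=5.0)
    ds = simulate_study(design, default_params_by_group(), seed=42)
    assert len(ds) == 21 * 2 * 10  # participants x sessions x phases
    assert len({r.participant for r in ds}) == 21
    for rec in ds:
        assert rec.trace.meta["phase"] == rec.phase
        assert len(rec.trace) == int(5.0 * FS)
    per_participant = {}
    for r in ds:
        per_participant.setdefault(r.participant, []).append((r.session, r.phase))
    assert all(len(v) == 20 for v in per_participant.values())

    ds2 = simulate_study(design, default_params_by_group(), seed=42)
    for a, b in zip(ds, ds2):
        assert np.array_equal(a.trace.displacement_mm, b.trace.displacement_mm)


def test_study_subsets_reproducible_independently():
    """Per-trace seeding from (seed, group, participant, session, phase)
    means a smaller design regenerates the shared traces bitwise."""
    big = simulate_study(StudyDesign(trial_duration_s=5.0), seed=5)
    small = simulate_study(
        StudyDesign(n_per_group={"concurrent_vf": 2, "post_trial_vf": 2}, trial_duration_s=5.0),
        seed=5,
    )
    big_map = {(r.participant, r.session, r.phase): r.trace for r in big}
    for r in small:
        ref = big_map[(r.participant, r.session, r.phase)]
        assert np.array_equal(r.trace.displacement_mm, ref.displacement_mm)
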