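"""Duration/amplitude normalisation and the two error measures.

Each motion unit is compared to the training template through two numbers,
computed in a fixed order:

* **magnitude error** (mm) — the absolute deviation of the unit's
  peak-to-trough displacement from the 4-mm target, computed *before* any
  rescaling. A pointwise variant (mean absolute deviation from the template
  evaluated on the normalised-time grid, in mm) is available behind the
  ``method`` switch.
* **shape error** (dimensionless MSE) — after resampling the unit to 50
  points on normalised time [0, 1] and min-max rescaling it to [0, 1], the
  mean squared difference to the identically resampled-and-rescaled
  template cycle. Both curves start at the trough by the shared phase
  convention, so no alignment search is needed.

Per-participant summaries are arithmetic means of the per-unit values
within each (participant, session, phase) cell.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline

from .segment import MotionUnit
from .templates import MotionTemplate, template_profile
from .trace import DomainError

N_RESAMPLE = 50
TARGET_MM = 4.0


class DegenerateUnitError(DomainError):
    """A constant unit cannot be min-max rescaled."""


@dataclass(frozen=True)
class NormalizedUnit:
    """A motion unit on the fixed normalised-time grid.

    ``values`` holds exactly ``n_resample`` displacement values; after
    ``rescale_unit`` they span [0, 1] exactly and ``rescaled`` is True.
    ``source`` carries (participant, session, phase, unit index) labels
    where known.
    """

    values: np.ndarray
    rescaled: bool = False
    source: tuple = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))


def resample_unit(
    unit: MotionUnit | np.ndarray,
    n_resample: int = N_RESAMPLE,
    interp: str = "linear",
    source: tuple = (),
) -> NormalizedUnit:
    """Interpolate a unit at ``n_resample`` equally spaced points on [0, 1].

    Both endpoints are included, so the first/last output values equal the
    unit's endpoint samples. Linear interpolation by default; ``interp=
    "cubic"`` uses a natural cubic spline.
    """
    y = unit.samples if isinstance(unit, MotionUnit) else np.asarray(unit, dtype=float)
    if y.size < 4:
        raise DomainError(f"unit of {y.size} samples is too short to resample")
    x = np.linspace(0.0, 1.0, y.size)
    grid = np.linspace(0.0, 1.0, n_resample)
    if interp == "linear":
        v = np.interp(grid, x, y)
    elif interp == "cubic":
        v = CubicSpline(x, y, bc_type="natural")(grid)
    else:
        raise DomainError(f"unknown interpolation method: {interp}")
    return NormalizedUnit(values=v, rescaled=False, source=source)


def magnitude_error(
    unit: MotionUnit | np.ndarray,
    target_mm: float = TARGET_MM,
    method: str = "peak_to_trough",
    template: MotionTemplate | None = None,
) -> float:
    """Deviation of a unit's movement magnitude from the target, in mm.

    ``peak_to_trough`` (default): ``|max - min - target_mm|``.
    ``pointwise``: mean absolute difference between the resampled unit and
    the unrescaled template cycle (both in mm, trough-anchored at 0);
    requires ``template``.
    """
    y = unit.samples if isinstance(unit, MotionUnit) else np.asarray(unit, dtype=float)
    if method == "peak_to_trough":
        return float(abs(np.ptp(y) - target_mm))
    if method == "pointwise":
        if template is None:
            raise DomainError("pointwise magnitude error needs the template")
        v = resample_unit(y).values
        prof = template_profile(template, v.size, rescaled=False)
        return float(np.mean(np.abs((v - v.min()) - prof)))
    raise DomainError(f"unknown magnitude-error method: {method}")


def rescale_unit(unit: NormalizedUnit) -> NormalizedUnit:
    """Min-max rescale to [0, 1]; exact 0 minimum and 1 maximum.

    Raises
    ------
    DegenerateUnitError
        If the unit is constant (max == min); callers exclude such units
        upstream with a logged warning.
    """
    v = unit.values
    lo, hi = float(v.min()), float(v.max())
    if hi == lo:
        raise DegenerateUnitError("constant unit cannot be rescaled")
    return NormalizedUnit(values=(v - lo) / (hi - lo), rescaled=True, source=unit.source)


def shape_error(unit: NormalizedUnit, template: MotionTemplate) -> float:
    """Mean squared difference between a rescaled unit and the template.

    The template's one cycle is evaluated on the same normalised-time grid
    and identically min-max rescaled; both curves start at the trough.
    """
    if not unit.rescaled:
        raise DomainError("shape_error requires a rescaled unit")
    v = unit.values
    prof = template_profile(template, v.size, rescaled=True)
    return float(np.mean((v - prof) ** 2))


def unit_errors(
    units: Sequence[MotionUnit],
    template: MotionTemplate,
    target_mm: float = TARGET_MM,
    n_resample: int = N_RESAMPLE,
    magnitude_method: str = "peak_to_trough",
    interp: str = "linear",
    source: tuple = (),
):
    """Per-unit magnitude and shape errors for one trace.

    Returns ``(magnitude_errors, shape_errors, excluded)`` where
    ``excluded`` lists (unit index, reason) for degenerate units dropped at
    the rescaling step. Magnitude error is computed before rescaling,
    shape error after, mirroring the processing order of the pipeline.
    """
    mags, shapes, excluded = [], [], []
    for i, u in enumerate(units):
        m = magnitude_error(u, target_mm, method=magnitude_method, template=template)
        try:
            nu = rescale_unit(resample_unit(u, n_resample, interp=interp, source=(*source, i)))
        except DegenerateUnitError:
            excluded.append((i, "degenerate_rescale"))
            continue
        mags.append(m)
        shapes.append(shape_error(nu, template))
    return np.asarray(mags), np.asarray(shapes), excluded


@dataclass(frozen=True)
class TrialErrors:
    """Per-unit errors of one trace plus their means."""

    magnitude_errors_mm: np.ndarray
    shape_errors: np.ndarray

    @property
    def mean_magnitude_error_mm(self) -> float:
        return float(np.mean(self.magnitude_errors_mm))

    @property
    def mean_shape_error(self) -> float:
        return float(np.mean(self.shape_errors))


def summarize_participants(unit_table: pd.DataFrame) -> pd.DataFrame:
    """Per-participant phase means from the tidy per-unit error table.

    Expects columns participant, group, session, phase,
    magnitude_error_mm, shape_error; returns one row per
    (participant, group, session, phase) with the arithmetic means.
    """
    required = {"participant", "group", "session", "phase", "magnitude_error_mm", "shape_error"}
    missing = required - set(unit_table.columns)
    if missing:
        raise DomainError(f"unit table missing columns: {sorted(missing)}")
    out = (
        unit_table.groupby(["participant", "group", "session", "phase"], sort=True)[
            ["magnitude_error_mm", "shape_error"]
        ]
        .mean()
        .reset_index()
        .rename(
            columns={
                "magnitude_error_mm": "mean_magnitude_error_mm",
                "shape_error": "mean_shape_error",
            }
        )
    )
    return out
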