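"""Smoothed motion-pattern response curves.

Visualises what a participant's typical cycle looks like: all rescaled
motion units of one participant-phase are pooled on the shared 50-point
normalised-time grid and smoothed with a penalized cubic smoothing spline
(second-derivative penalty, smoothing parameter chosen by generalized
cross-validation). The group-level curve is the pointwise mean of the
participant curves.

This two-stage estimator (per-participant smooth, then average) targets the
same mean response as a mixed-model smooth with participant as a random
effect; it serves the qualitative pre/post contrast and plotting, not
formal inference on the smooth terms.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.interpolate import make_smoothing_spline

from .metrics import NormalizedUnit
from .templates import MotionTemplate, template_profile
from .trace import DomainError

N_GRID = 50


class InsufficientDataError(DomainError):
    """Fewer units or curves than the estimator needs."""


@dataclass(frozen=True)
class ResponseCurve:
    """A smoothed rescaled-displacement curve on the shared grid."""

    grid: np.ndarray
    fitted: np.ndarray
    level: str  # "participant" | "group"
    n_units: int = 0
    lam: float | None = None  # GCV-selected smoothing parameter

    def __post_init__(self) -> None:
        object.__setattr__(self, "grid", np.asarray(self.grid, dtype=float))
        object.__setattr__(self, "fitted", np.asarray(self.fitted, dtype=float))
        if self.grid.shape != self.fitted.shape:
            raise DomainError("grid and fitted must have equal length")
        if not np.all(np.diff(self.grid) > 0):
            raise DomainError("grid must be strictly increasing")
        if not np.all(np.isfinite(self.fitted)):
            raise DomainError("fitted values must be finite")


def fit_participant_curve(
    units: Sequence[NormalizedUnit], n_grid: int = N_GRID
) -> ResponseCurve:
    """Penalized-spline smooth of one participant-phase's pooled units.

    The units share the normalised-time grid, so the penalized
    least-squares fit on the pooled points equals a fit to the pointwise
    mean curve with uniform weights; lambda is picked by GCV.
    """
    if len(units) < 2:
        raise InsufficientDataError(f"need >= 2 units, got {len(units)}")
    vals = []
    for u in units:
        if not u.rescaled:
            raise DomainError("participant curves are fit on rescaled units")
        if u.values.size != n_grid:
            raise DomainError("all units must be on the shared grid")
        vals.append(u.values)
    grid = np.linspace(0.0, 1.0, n_grid)
    mean = np.mean(vals, axis=0)
    spline = make_smoothing_spline(grid, mean, lam=None)
    return ResponseCurve(
        grid=grid,
        fitted=spline(grid),
        level="participant",
        n_units=len(units),
    )


def fit_group_curve(participant_curves: Sequence[ResponseCurve]) -> ResponseCurve:
    """Pointwise mean of participant curves on the shared grid."""
    if len(participant_curves) < 2:
        raise InsufficientDataError(
            f"need >= 2 participant curves, got {len(participant_curves)}"
        )
    grid = participant_curves[0].grid
    for c in participant_curves[1:]:
        if c.grid.shape != grid.shape or not np.allclose(c.grid, grid):
            raise DomainError("participant curves are on mixed grids")
    fitted = np.mean([c.fitted for c in participant_curves], axis=0)
    return ResponseCurve(
        grid=grid,
        fitted=fitted,
        level="group",
        n_units=int(sum(c.n_units for c in participant_curves)),
    )


def curve_template_distance(curve: ResponseCurve, template: MotionTemplate) -> float:
    """Grid-mean squared distance from a curve to the rescaled template."""
    prof = template_profile(template, curve.grid.size, rescaled=True)
    return float(np.mean((curve.fitted - prof) ** 2))
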