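"""Uniformly sampled needle-displacement time series.

The displacement convention throughout the package: larger values mean the
needle is thrust deeper; the trough (minimum) is the most-lifted position.
Time starts at 0 for every trace; sample k sits at ``k / sampling_rate_hz``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np


class DomainError(ValueError):
    """An argument violates a stated precondition."""


@dataclass(frozen=True)
class MotionTrace:
    """A needle-displacement recording with acquisition metadata.

    Parameters
    ----------
    displacement_mm :
        Displacement samples in millimetres (1-D).
    sampling_rate_hz :
        Uniform sampling rate; the study apparatus records at 80.3 Hz.
    meta :
        Free-form string metadata (participant, group, session, phase, role).
    """

    displacement_mm: np.ndarray
    sampling_rate_hz: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        x = np.asarray(self.displacement_mm, dtype=float)
        if x.ndim != 1:
            raise DomainError("displacement_mm must be one-dimensional")
        if self.sampling_rate_hz <= 0:
            raise DomainError("sampling_rate_hz must be positive")
        object.__setattr__(self, "displacement_mm", x)

    def __len__(self) -> int:
        return self.displacement_mm.size

    @property
    def duration_s(self) -> float:
        return len(self) / self.sampling_rate_hz

    @property
    def time_s(self) -> np.ndarray:
        return np.arange(len(self)) / self.sampling_rate_hz

    def with_displacement(self, x: np.ndarray) -> "MotionTrace":
        """Same metadata and rate, new samples (used by the filter)."""
        return replace(self, displacement_mm=np.asarray(x, dtype=float))
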