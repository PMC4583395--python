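"""Segmentation of a filtered trace into repeated motion units.

One motion unit is one lifting/thrusting cycle, delimited trough-to-trough:
the relatively lower points of the recording. Troughs are operationalised
as local minima with (i) topographic prominence at least ``prominence_frac``
of the trace's peak-to-trough range and (ii) spacing of at least
``min_sep_frac`` of the expected cycle period. Units whose duration falls
outside plausibility bounds (default half to twice the expected period) are
excluded and reported, not silently dropped: an unbounded unit would corrupt
the fixed-length resampling downstream.

Because cycles start at the trough by the package-wide phase convention, a
recording that begins at the most-lifted position begins a cycle at its
very first sample, where no left neighborhood exists. The first sample is
therefore accepted as a delimiter when it sits at trough level (within
``boundary_tol_frac`` of the trace range of the first interior delimiter)
and respects the spacing constraint. The trailing partial cycle after the
last delimiter is always discarded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .trace import DomainError, MotionTrace

PROMINENCE_FRAC = 0.25
MIN_SEP_FRAC = 0.5
DURATION_BOUNDS_FRAC = (0.5, 2.0)
BOUNDARY_TOL_FRAC = 0.1


class NoCompleteUnitError(DomainError):
    """Fewer than two delimiters: the trace contains no complete cycle."""


@dataclass(frozen=True)
class MotionUnit:
    """One trough-to-trough movement cycle.

    ``start_index``/``end_index`` give the half-open ``[start, end)`` range
    in the parent trace, so consecutive units tile the delimited span with
    no overlap; ``samples`` nevertheless includes the closing trough
    (``x[start..end]`` inclusive) so the stored cycle begins and ends at a
    local minimum, which the resampling step relies on.
    """

    samples: np.ndarray
    start_index: int
    end_index: int
    duration_s: float

    def __len__(self) -> int:
        return self.samples.size


@dataclass
class SegmentationResult:
    units: list
    n_delimiters: int
    excluded: list = field(default_factory=list)  # (start, end, reason)

    @property
    def n_detected(self) -> int:
        """Candidate units between consecutive delimiters."""
        return max(self.n_delimiters - 1, 0)

    @property
    def n_excluded(self) -> int:
        return len(self.excluded)


def find_delimiters(
    trace: MotionTrace,
    expected_freq_hz: float,
    prominence_frac: float = PROMINENCE_FRAC,
    min_sep_frac: float = MIN_SEP_FRAC,
    boundary_tol_frac: float = BOUNDARY_TOL_FRAC,
) -> np.ndarray:
    """Indices of the trough delimiters, strictly increasing.

    Interior troughs come from prominence- and spacing-constrained local
    minima; the first sample joins them when it lies at trough level (see
    module docstring).

    Raises
    ------
    NoCompleteUnitError
        If fewer than two qualifying troughs exist.
    """
    if expected_freq_hz <= 0:
        raise DomainError("expected_freq_hz must be positive")
    x = trace.displacement_mm
    span = float(np.ptp(x))
    if span == 0.0:
        raise NoCompleteUnitError("constant trace has no troughs")
    distance = max(1, int(round(min_sep_frac * trace.sampling_rate_hz / expected_freq_hz)))
    idx, _ = signal.find_peaks(-x, prominence=prominence_frac * span, distance=distance)
    if idx.size > 0 and idx[0] >= distance and x[0] <= x[idx[0]] + boundary_tol_frac * span:
        idx = np.concatenate(([0], idx))
    if idx.size < 2:
        raise NoCompleteUnitError(
            f"only {idx.size} delimiter(s) found; no complete motion unit"
        )
    return idx


def extract_units(
    trace: MotionTrace,
    delimiters: np.ndarray,
    expected_freq_hz: float = 1.0,
    duration_bounds_frac: tuple = DURATION_BOUNDS_FRAC,
) -> SegmentationResult:
    """One unit per consecutive delimiter pair, duration-filtered.

    Partial cycles before the first and after the last delimiter are
    discarded. Units with implausible duration (outside
    ``duration_bounds_frac / expected_freq_hz``) go to ``excluded`` with a
    reason code.
    """
    delimiters = np.asarray(delimiters, dtype=int)
    if delimiters.size < 2:
        raise NoCompleteUnitError("need at least 2 delimiters")
    lo = duration_bounds_frac[0] / expected_freq_hz
    hi = duration_bounds_frac[1] / expected_freq_hz
    fs = trace.sampling_rate_hz
    units, excluded = [], []
    for s, e in zip(delimiters[:-1], delimiters[1:]):
        dur = (e - s) / fs
        if not lo <= dur <= hi:
            excluded.append((int(s), int(e), "duration_out_of_bounds"))
            continue
        units.append(
            MotionUnit(
                samples=trace.displacement_mm[s : e + 1].copy(),
                start_index=int(s),
                end_index=int(e),
                duration_s=dur,
            )
        )
    return SegmentationResult(units=units, n_delimiters=int(delimiters.size), excluded=excluded)


def segment_trace(
    trace: MotionTrace,
    expected_freq_hz: float = 1.0,
    prominence_frac: float = PROMINENCE_FRAC,
    min_sep_frac: float = MIN_SEP_FRAC,
    duration_bounds_frac: tuple = DURATION_BOUNDS_FRAC,
) -> SegmentationResult:
    """find_delimiters + extract_units in one call."""
    delims = find_delimiters(trace, expected_freq_hz, prominence_frac, min_sep_frac)
    return extract_units(trace, delims, expected_freq_hz, duration_bounds_frac)
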