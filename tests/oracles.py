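"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately written with plain Python loops and first
principles (direct neighborhood scans, exhaustive enumeration), not with
the library calls the implementation uses.
"""

from __future__ import annotations

import itertools
import math
from typing import List, Sequence


def local_minima(x: Sequence[float]) -> List[int]:
    """Interior local minima by direct neighborhood comparison; a flat
    plateau bounded by higher samples on both sides counts once, at its
    middle sample."""
    mins = []
    n = len(x)
    i = 1
    while i < n - 1:
        if x[i] < x[i - 1]:
            j = i
            while j < n - 1 and x[j + 1] == x[i]:
                j += 1
            if j < n - 1 and x[j + 1] > x[i]:
                mins.append((i + j) // 2)
            i = j + 1
        else:
            i += 1
    return mins


def trough_prominence(x: Sequence[float], p: int) -> float:
    """Topographic prominence of the trough at index p: walk outward in
    each direction until a sample lower than x[p] (or the border), take
    the highest sample seen on each side, and measure the drop from the
    lower of the two heights."""
    left_max = x[p]
    i = p - 1
    while i >= 0 and x[i] >= x[p]:
        left_max = max(left_max, x[i])
        i -= 1
    right_max = x[p]
    i = p + 1
    while i < len(x) and x[i] >= x[p]:
        right_max = max(right_max, x[i])
        i += 1
    return min(left_max, right_max) - x[p]


def brute_force_delimiters(
    x: Sequence[float],
    sampling_rate_hz: float,
    expected_freq_hz: float,
    prominence_frac: float = 0.25,
    min_sep_frac: float = 0.5,
    boundary_tol_frac: float = 0.1,
) -> List[int]:
    """Trough delimiters by exhaustive scan: every sample is examined,
    interior minima are kept in depth-priority order subject to the
    spacing rule, then filtered by prominence; the first sample joins if
    it sits at trough level and respects the spacing."""
    x = list(float(v) for v in x)
    span = max(x) - min(x)
    if span == 0:
        return []
    distance = max(1, round(min_sep_frac * sampling_rate_hz / expected_freq_hz))
    cands = local_minima(x)
    # spacing: deepest troughs claim their neighborhood first
    keep = [True] * len(cands)
    order = sorted(range(len(cands)), key=lambda k: (x[cands[k]], cands[k]))
    for oi in order:
        if not keep[oi]:
            continue
        for oj in range(len(cands)):
            if oj != oi and keep[oj] and abs(cands[oj] - cands[oi]) < distance:
                keep[oj] = False
    survivors = [c for c, k in zip(cands, keep) if k]
    out = [c for c in survivors if trough_prominence(x, c) >= prominence_frac * span]
    if out and out[0] >= distance and x[0] <= x[out[0]] + boundary_tol_frac * span:
        out = [0] + out
    return out


def rank_average(values: Sequence[float]) -> List[float]:
    """Average ranks (1-based), ties shared, by explicit sorting."""
    n = len(values)
    order = sorted(range(n), key=lambda i: values[i])
    ranks = [0.0] * n
    i = 0
    while i < n:
        j = i
        while j + 1 < n and values[order[j + 1]] == values[order[i]]:
            j += 1
        r = (i + j) / 2.0 + 1.0
        for k in range(i, j + 1):
            ranks[order[k]] = r
        i = j + 1
    return ranks


def wilcoxon_enumeration_p(diffs: Sequence[float]) -> tuple[float, float]:
    """Exact two-sided signed-rank p by enumerating every sign pattern.

    Returns (W+, p). Zero differences are dropped; ties share average
    ranks. Two-sided p = min(1, 2*min(P(W<=w), P(W>=w))) over the uniform
    distribution on all 2^n sign assignments.
    """
    d = [v for v in diffs if v != 0]
    n = len(d)
    ranks = rank_average([abs(v) for v in d])
    w_obs = sum(r for r, v in zip(ranks, d) if v > 0)
    total = 0
    n_le = 0
    n_ge = 0
    eps = 1e-9
    for signs in itertools.product((0, 1), repeat=n):
        w = sum(r for r, s in zip(ranks, signs) if s)
        total += 1
        if w <= w_obs + eps:
            n_le += 1
        if w >= w_obs - eps:
            n_ge += 1
    p = min(1.0, 2.0 * min(n_le / total, n_ge / total))
    return w_obs, p


def paired_t_closed_form(diffs: Sequence[float]) -> float:
    """t statistic from the definition, with explicit sums."""
    n = len(diffs)
    mean = sum(diffs) / n
    var = sum((v - mean) ** 2 for v in diffs) / (n - 1)
    return mean / math.sqrt(var / n)


def linear_resample(samples: Sequence[float], n_out: int) -> List[float]:
    """Piecewise-linear interpolation at n_out equally spaced points on
    [0, 1], written from the two-point line formula."""
    n_in = len(samples)
    out = []
    for k in range(n_out):
        pos = k / (n_out - 1) * (n_in - 1)
        i = min(int(pos), n_in - 2)
        frac = pos - i
        out.append(samples[i] * (1 - frac) + samples[i + 1] * frac)
    return out
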