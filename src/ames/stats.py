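"""Paired pre/post comparisons with normality-based test selection.

The study design yields one value per participant per phase; the question
is always whether the post-training value changed from the pre-training
value within a group. Normality of the paired differences is assessed with
the Shapiro-Wilk test; if it is rejected at alpha the comparison uses the
Wilcoxon signed-rank test, otherwise a paired t-test. Both tests are
two-sided. No multiple-testing correction is applied by default; a Holm
adjustment helper is provided for reuse on families of comparisons.

The Wilcoxon signed-rank p-value is exact for n <= 12 (full enumeration of
the 2^n sign assignments, with average ranks for tied absolute
differences); beyond that, a tie-corrected normal approximation with
continuity correction is used. Zero differences are dropped before
ranking, following Wilcoxon's original prescription.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps

from .trace import DomainError

ALPHA = 0.05
EXACT_N_MAX = 12


class DegenerateDataError(DomainError):
    """Zero-variance (or all-zero-difference) input; the test is undefined."""


@dataclass(frozen=True)
class PairedComparison:
    """Matched pre/post values for one group x session x metric cell."""

    pre: np.ndarray
    post: np.ndarray
    metric: str = ""
    alpha: float = ALPHA

    def __post_init__(self) -> None:
        pre = np.asarray(self.pre, dtype=float)
        post = np.asarray(self.post, dtype=float)
        if pre.shape != post.shape or pre.ndim != 1:
            raise DomainError("pre and post must be matched 1-D arrays")
        if pre.size < 3:
            raise DomainError("need at least 3 matched pairs")
        object.__setattr__(self, "pre", pre)
        object.__setattr__(self, "post", post)


@dataclass(frozen=True)
class TestResult:
    test_used: str  # "paired_t" | "wilcoxon_signed_rank"
    statistic: float
    p_value: float
    n: int
    direction: int  # sign of mean(pre - post): +1 means the value decreased
    normality_p: float | None = None


def shapiro_wilk(values: Sequence[float]) -> tuple[float, float]:
    """Shapiro-Wilk W and p for a sample of 3..50 values.

    Raises on n outside the supported coefficient range and on
    zero-variance samples (W undefined).
    """
    x = np.asarray(values, dtype=float)
    if not 3 <= x.size <= 50:
        raise DomainError(f"Shapiro-Wilk supported for 3 <= n <= 50, got {x.size}")
    if np.ptp(x) == 0:
        raise DegenerateDataError("zero-variance sample")
    w, p = sps.shapiro(x)
    return float(w), float(p)


def paired_t(pre: Sequence[float], post: Sequence[float]) -> TestResult:
    """Two-sided paired t-test on d = pre - post."""
    d = np.asarray(pre, dtype=float) - np.asarray(post, dtype=float)
    n = d.size
    if n < 2:
        raise DomainError("paired t needs n >= 2")
    sd = d.std(ddof=1)
    if sd == 0:
        raise DegenerateDataError("differences have zero variance")
    t = d.mean() / (sd / np.sqrt(n))
    p = 2.0 * sps.t.sf(abs(t), df=n - 1)
    return TestResult(
        test_used="paired_t",
        statistic=float(t),
        p_value=float(p),
        n=int(n),
        direction=int(np.sign(d.mean())),
    )


def _signed_ranks(d: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Drop zeros, rank |d| with average ranks; return (ranks, signs)."""
    d = d[d != 0.0]
    if d.size < 3:
        raise DegenerateDataError(
            f"only {d.size} nonzero difference(s); signed-rank test undefined"
        )
    return sps.rankdata(np.abs(d)), np.sign(d)


def _wilcoxon_exact_p(ranks: np.ndarray, w_plus: float) -> float:
    """Exact two-sided p by enumerating all 2^n sign assignments.

    Every assignment of +/- to the fixed ranks is equally likely under the
    null of symmetric differences; p = min(1, 2*min(P(W<=w), P(W>=w))).
    """
    n = ranks.size
    # bit-matrix of all sign patterns; row s has bit j = sign of rank j
    patterns = (np.arange(2**n)[:, None] >> np.arange(n)) & 1
    w_all = patterns @ ranks
    eps = 1e-9
    p_le = np.mean(w_all <= w_plus + eps)
    p_ge = np.mean(w_all >= w_plus - eps)
    return float(min(1.0, 2.0 * min(p_le, p_ge)))


def _wilcoxon_normal_p(ranks: np.ndarray, w_plus: float) -> float:
    """Tie-corrected normal approximation with continuity correction."""
    n = ranks.size
    mu = n * (n + 1) / 4.0
    _, counts = np.unique(ranks, return_counts=True)
    tie_term = np.sum(counts**3 - counts) / 48.0
    sigma = np.sqrt(n * (n + 1) * (2 * n + 1) / 24.0 - tie_term)
    if sigma == 0:
        raise DegenerateDataError("all absolute differences tied at one value")
    shift = w_plus - mu
    z = (shift - 0.5 * np.sign(shift)) / sigma
    return float(2.0 * sps.norm.sf(abs(z)))


def wilcoxon_signed_rank(pre: Sequence[float], post: Sequence[float]) -> TestResult:
    """Two-sided Wilcoxon signed-rank test on d = pre - post.

    The statistic is W+, the sum of ranks of the positive differences.
    Exact p for n <= 12 nonzero differences, normal approximation with tie
    and continuity corrections otherwise.
    """
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    d = pre - post
    ranks, signs = _signed_ranks(d)
    w_plus = float(ranks[signs > 0].sum())
    n = ranks.size
    if n <= EXACT_N_MAX:
        p = _wilcoxon_exact_p(ranks, w_plus)
    else:
        p = _wilcoxon_normal_p(ranks, w_plus)
    med = float(np.median(d[d != 0]))
    return TestResult(
        test_used="wilcoxon_signed_rank",
        statistic=w_plus,
        p_value=p,
        n=int(n),
        direction=int(np.sign(med)),
    )


def compare_pre_post(comparison: PairedComparison) -> TestResult:
    """Route a paired comparison by Shapiro-Wilk normality of differences.

    Normality is assessed on d = pre - post (the quantity the t-test
    assumes normal); if its Shapiro-Wilk p < alpha the Wilcoxon signed-rank
    test is used, otherwise the paired t-test. The result carries the
    routing p-value.
    """
    d = comparison.pre - comparison.post
    if np.ptp(d) == 0:
        raise DegenerateDataError("pre and post differ by a constant; no test run")
    _, norm_p = shapiro_wilk(d)
    if norm_p < comparison.alpha:
        res = wilcoxon_signed_rank(comparison.pre, comparison.post)
    else:
        res = paired_t(comparison.pre, comparison.post)
    return TestResult(
        test_used=res.test_used,
        statistic=res.statistic,
        p_value=res.p_value,
        n=res.n,
        direction=res.direction,
        normality_p=float(norm_p),
    )


def holm_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Holm step-down adjusted p-values (optional, off by default)."""
    p = np.asarray(p_values, dtype=float)
    order = np.argsort(p)
    m = p.size
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(1.0, running)
    return adj
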