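"""Paired testing layer: Shapiro-Wilk routing, paired t, exact Wilcoxon."""

import numpy as np
import pytest

from ames import (
    PairedComparison,
    compare_pre_post,
    holm_adjust,
    paired_t,
    shapiro_wilk,
    wilcoxon_signed_rank,
)
from ames.stats import DegenerateDataError, _signed_ranks, _wilcoxon_exact_p
from ames.trace import DomainError

from oracles import paired_t_closed_form, wilcoxon_enumeration_p


class TestShapiroWilk:
    def test_deterministic_and_permutation_invariant(self, rng):
        x = rng.normal(size=12)
        w1, p1 = shapiro_wilk(x)
        w2, p2 = shapiro_wilk(rng.permutation(x))
        assert (w1, p1) == (w2, p2)
        assert 0 < w1 <= 1

    def test_symmetric_three_point_sample(self):
        w, p = shapiro_wilk([-1.0, 0.0, 1.0])
        assert 0 < w <= 1 and 0 <= p <= 1

    def test_domain_errors(self):
        with pytest.raises(DomainError):
            shapiro_wilk([1.0, 2.0])
        with pytest.raises(DegenerateDataError):
            shapiro_wilk([1.0] * 5)

    def test_rejection_rate_calibrated_under_normality(self):
        """n = 10 standard-normal samples: rejection at alpha = 0.05 should
        happen about 5% of the time (Monte-Carlo, 1000 seeds)."""
        rng = np.random.default_rng(7)
        rejections = sum(shapiro_wilk(rng.normal(size=10))[1] < 0.05 for _ in range(1000))
        assert 0.03 <= rejections / 1000 <= 0.07


class TestPairedT:
    def test_closed_form_example(self):
        res = paired_t([2.0, 3.0, 4.0], [1.0, 1.0, 1.0])  # d = [1, 2, 3]
        assert res.statistic == pytest.approx(3.4641, abs=1e-4)
        assert res.n == 3
        assert res.test_used == "paired_t"
        assert res.statistic == pytest.approx(paired_t_closed_form([1.0, 2.0, 3.0]))

    def test_zero_variance_differences_degenerate(self):
        with pytest.raises(DegenerateDataError):
            paired_t([1.0, 2.0, 3.0], [0.0, 1.0, 2.0])

    def test_sign_flip_negates_t_preserves_p(self, rng):
        pre = rng.normal(size=10)
        post = rng.normal(size=10)
        a = paired_t(pre, post)
        b = paired_t(post, pre)
        assert a.statistic == pytest.approx(-b.statistic)
        assert a.p_value == pytest.approx(b.p_value)
        assert a.direction == -b.direction


class TestWilcoxon:
    def test_enumerated_three_point_example(self):
        res = wilcoxon_signed_rank([2.0, 3.0, 4.0], [1.0, 1.0, 1.0])  # d = [1, 2, 3]
        assert res.statistic == 6.0
        assert res.p_value == pytest.approx(0.25)

    def test_sign_symmetry(self, rng):
        pre = rng.normal(size=9)
        post = rng.normal(size=9)
        assert wilcoxon_signed_rank(pre, post).p_value == pytest.approx(
            wilcoxon_signed_rank(post, pre).p_value
        )

    @pytest.mark.parametrize("n", [4, 6, 8, 10, 12])
    def test_exact_p_matches_enumeration_oracle(self, n):
        """Exact small-sample p equals the full 2^n sign-pattern oracle,
        with and without ties."""
        rng = np.random.default_rng(n)
        for rep in range(8):
            d = rng.normal(size=n)
            if rep % 2 == 0:
                d = np.round(d, 1)  # induce ties in |d|
            d = d[d != 0.0]
            if d.size < 3:
                continue
            res = wilcoxon_signed_rank(d, np.zeros_like(d))
            w_or, p_or = wilcoxon_enumeration_p(list(d))
            assert res.statistic == pytest.approx(w_or)
            assert res.p_value == pytest.approx(p_or, abs=1e-12)

    def test_normal_approximation_close_to_enumeration_at_n15(self):
        """n = 15 with ties: the tie-corrected normal approximation must sit
        within 0.01 of the exhaustive 2^15 oracle across a spread of
        effect locations."""
        rng = np.random.default_rng(0)
        for rep in range(30):
            d = np.round(rng.normal(loc=rng.uniform(-1, 1), size=15), 1)
            d[d == 0] = 0.1
            res = wilcoxon_signed_rank(d, np.zeros_like(d))
            _, p_or = wilcoxon_enumeration_p(list(d))
            assert res.n == 15
            assert abs(res.p_value - p_or) < 0.01

    def test_zero_differences_dropped_and_all_zero_degenerate(self):
        res = wilcoxon_signed_rank([1.0, 2.0, 3.0, 5.0], [1.0, 1.0, 1.0, 1.0])
        assert res.n == 3  # the zero difference is dropped
        with pytest.raises(DegenerateDataError):
            wilcoxon_signed_rank([1.0, 1.0, 1.0], [1.0, 1.0, 1.0])


class TestRouting:
    def test_deterministic_routing_and_fields(self, rng):
        pre = rng.normal(loc=1.0, size=10)
        post = rng.normal(size=10)
        comp = PairedComparison(pre=pre, post=post, metric="magnitude_error")
        a = compare_pre_post(comp)
        b = compare_pre_post(comp)
        assert (a.test_used, a.statistic, a.p_value, a.normality_p) == (
            b.test_used,
            b.statistic,
            b.p_value,
            b.normality_p,
        )
        assert a.normality_p is not None
        expected = "wilcoxon_signed_rank" if a.normality_p < 0.05 else "paired_t"
        assert a.test_used == expected

    def test_normal_differences_route_to_t(self):
        """Standard-normal differences, n = 10: the paired t-test should be
        chosen in at least 90% of runs (Shapiro-Wilk size is 5%)."""
        rng = np.random.default_rng(11)
        n_t = 0
        for _ in range(500):
            pre = rng.normal(size=10)
            post = pre - rng.normal(size=10)
            res = compare_pre_post(PairedComparison(pre=pre, post=post))
            n_t += res.test_used == "paired_t"
        assert n_t / 500 >= 0.9

    def test_heavy_tailed_differences_route_to_wilcoxon(self):
        """Cauchy-like differences, n = 11: normality is usually rejected."""
        rng = np.random.default_rng(12)
        n_w = 0
        for _ in range(500):
            pre = rng.normal(size=11)
            post = pre - rng.standard_cauchy(size=11)
            res = compare_pre_post(PairedComparison(pre=pre, post=post))
            n_w += res.test_used == "wilcoxon_signed_rank"
        assert n_w / 500 > 0.5

    def test_constant_shift_is_degenerate(self):
        with pytest.raises(DegenerateDataError):
            compare_pre_post(
                PairedComparison(pre=np.array([1.0, 2.0, 3.0]), post=np.array([0.0, 1.0, 2.0]))
            )

    def test_comparison_validation(self):
        with pytest.raises(DomainError):
            PairedComparison(pre=np.array([1.0, 2.0]), post=np.array([1.0]))


def test_holm_adjustment_monotone_and_bounded():
    p = [0.01, 0.04, 0.03, 0.5]
    adj = holm_adjust(p)
    assert np.all(adj >= np.asarray(p) - 1e-15)
    assert np.all(adj <= 1.0)
    assert adj[0] == pytest.approx(0.04)  # 4 * 0.01


def test_signed_ranks_use_average_ranks():
    ranks, signs = _signed_ranks(np.array([1.0, -1.0, 2.0]))
    assert sorted(ranks) == [1.5, 1.5, 3.0]
    w = float(ranks[signs > 0].sum())
    assert _wilcoxon_exact_p(ranks, w) <= 1.0
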