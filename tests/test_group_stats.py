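"""Rank-based tests, chi-square, Spearman and the boxplot summary."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from coordx.group_stats import (
    boxplot_summary,
    chi_square_prevalence,
    kruskal_wallis,
    mann_whitney_u,
    spearman,
)
from oracles import exact_mwu_p, rank_pearson


class TestMannWhitney:
    def test_fully_separated_samples(self):
        res = mann_whitney_u([1, 2, 3], [4, 5, 6], method="exact")
        assert res.statistic == 0.0
        # exact enumeration over all 20 rank assignments gives p = 2/20
        assert res.p_value == pytest.approx(0.1)
        assert res.effect_direction == -1

    def test_identical_samples_are_null(self):
        res = mann_whitney_u([1, 2, 3], [1, 2, 3])
        assert res.p_value > 0.95
        assert res.effect_direction == 0

    def test_all_ties_midrank_u(self):
        res = mann_whitney_u([1, 1, 1], [1, 1, 1])
        assert res.statistic == pytest.approx(4.5)
        assert res.p_value == 1.0

    def test_swap_symmetry(self, rng):
        x, y = rng.normal(0, 1, 20), rng.normal(0.5, 1, 25)
        a, b = mann_whitney_u(x, y), mann_whitney_u(y, x)
        assert a.p_value == pytest.approx(b.p_value)
        assert a.effect_direction == -b.effect_direction

    def test_empty_sample_raises(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1.0])

    def test_exact_p_matches_enumeration_oracle(self, rng):
        for _ in range(20):
            x = list(rng.normal(size=int(rng.integers(3, 6))))
            y = list(rng.normal(size=int(rng.integers(3, 6))))
            u, p = exact_mwu_p(x, y)
            res = mann_whitney_u(x, y, method="exact")
            assert res.statistic == pytest.approx(u)
            assert res.p_value == pytest.approx(p, abs=1e-12)

    def test_asymptotic_close_to_exact_for_small_n(self, rng):
        for _ in range(30):
            x = list(rng.normal(size=6))
            y = list(rng.normal(size=6))
            _, p_exact = exact_mwu_p(x, y)
            p_approx = mann_whitney_u(x, y, method="asymptotic").p_value
            assert abs(p_approx - p_exact) <= 0.03


class TestKruskalWallis:
    def test_identical_groups_null(self):
        res = kruskal_wallis([[1, 2, 3], [1, 2, 3], [1, 2, 3]])
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_constant_data_null(self):
        res = kruskal_wallis([[5, 5], [5, 5], [5]])
        assert (res.statistic, res.p_value) == (0.0, 1.0)

    def test_hand_computed_h(self):
        # no ties: H = 12/(N(N+1)) * sum(R_i^2/n_i) - 3(N+1)
        res = kruskal_wallis([[1, 2, 3], [4, 5, 6], [7, 8, 9]])
        assert res.statistic == pytest.approx(7.2)

    def test_fewer_than_two_groups_raises(self):
        with pytest.raises(ValueError):
            kruskal_wallis([[1, 2, 3]])

    def test_label_permutation_preserves_null_distribution(self, rng):
        # Monte-Carlo: H on permuted labels has the same null law as on the
        # original grouping when there is no effect
        pooled = rng.normal(size=30)
        h_orig = [
            kruskal_wallis(np.split(rng.permutation(pooled), [10, 20])).statistic
            for _ in range(200)
        ]
        from scipy.stats import chi2, kstest

        # under H0, H ~ chi2(2) approximately
        assert kstest(h_orig, chi2(df=2).cdf).pvalue > 0.01


class TestChiSquare:
    def test_homogeneous_table_is_null(self):
        res = chi_square_prevalence([[10, 10], [10, 10]])
        assert (res.statistic, res.p_value) == (0.0, 1.0)

    def test_pearson_formula(self):
        # all expected counts 15; sum (O-E)^2/E = 4 * 25/15 = 20/3
        res = chi_square_prevalence([[20, 10], [10, 20]])
        assert res.statistic == pytest.approx(20.0 / 3.0)

    def test_one_by_two_table_raises(self):
        with pytest.raises(ValueError, match="2x2"):
            chi_square_prevalence([[5, 5]])

    def test_zero_marginal_raises(self):
        with pytest.raises(ValueError, match="marginal"):
            chi_square_prevalence([[0, 10], [0, 20]])

    def test_permutation_invariance(self, rng):
        t = rng.integers(1, 50, size=(3, 2))
        base = chi_square_prevalence(t).statistic
        assert chi_square_prevalence(t[::-1]).statistic == pytest.approx(base)
        assert chi_square_prevalence(t[:, ::-1]).statistic == pytest.approx(base)


class TestSpearman:
    def test_perfect_monotone(self):
        x = [1.0, 2.0, 5.0, 9.0]
        assert spearman(x, [v**3 for v in x]).rho == pytest.approx(1.0)
        assert spearman(x, [-v for v in x]).rho == pytest.approx(-1.0)

    def test_constant_vector_flagged(self):
        res = spearman([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        assert res.constant_input
        assert np.isnan(res.rho)

    def test_matches_midrank_pearson_oracle(self, rng):
        x = list(rng.integers(0, 20, size=50).astype(float))  # ties likely
        y = list(rng.integers(0, 20, size=50).astype(float))
        assert spearman(x, y).rho == pytest.approx(rank_pearson(x, y), abs=1e-12)


class TestBoxplotSummary:
    def test_even_n_median_midpoint(self):
        assert boxplot_summary(range(1, 9)).median == pytest.approx(4.5)

    def test_constant_vector_collapses(self):
        s = boxplot_summary([7.0] * 10)
        assert s.median == s.q25 == s.q75 == s.whisker_low == s.whisker_high == 7.0

    def test_linear_interpolation_convention(self):
        # type-7 percentile of 1..1000 at 25%: 1 + 999*0.25 = 250.75
        s = boxplot_summary(range(1, 1001))
        assert s.q25 == pytest.approx(250.75)
        assert s.whisker_low == pytest.approx(1 + 999 * 0.125)
        assert s.whisker_high == pytest.approx(1 + 999 * 0.875)

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            boxplot_summary([])

    def test_ordering_invariant(self):
        s = boxplot_summary([5, 1, 9, 3, 7, 2, 8])
        assert s.whisker_low <= s.q25 <= s.median <= s.q75 <= s.whisker_high


class TestMonotoneInvariance:
    """Rank-based tests must not change under strictly monotone transforms."""

    @given(shift=st.floats(-2, 2), data=st.data())
    @settings(max_examples=40, derandomize=True, deadline=None)
    def test_mwu_invariant_under_exp(self, shift, data):
        rng = np.random.default_rng(data.draw(st.integers(0, 10_000)))
        x = rng.normal(shift, 1, 12)
        y = rng.normal(0, 1, 15)
        a = mann_whitney_u(x, y)
        b = mann_whitney_u(np.exp(x), np.exp(y))
        assert a.statistic == pytest.approx(b.statistic)
        assert a.p_value == pytest.approx(b.p_value)

    def test_kruskal_invariant_under_exp(self, rng):
        groups = [rng.normal(m, 1, 10) for m in (0, 0.5, 1.0)]
        a = kruskal_wallis(groups)
        b = kruskal_wallis([np.exp(g) for g in groups])
        assert a.statistic == pytest.approx(b.statistic)

    def test_spearman_invariant_under_monotone_maps(self, rng):
        x, y = rng.normal(size=40), rng.normal(size=40)
        assert spearman(x, y).rho == pytest.approx(spearman(np.exp(x), y**3).rho)
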