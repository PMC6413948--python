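from itertools import permutations

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from gatabind.stats import (PUBLISHED_UNIVERSE, ContingencyTable,
                            chi_square_independence, chi_square_upper_tail,
                            contingency, rank_sum, set_enrichment)


def make_table(rows, index=None, columns=None) -> ContingencyTable:
    return ContingencyTable(pd.DataFrame(rows, index=index, columns=columns))


class TestContingency:
    def test_joint_counts(self):
        a = pd.Series(["X", "X", "Y", "Y"], index=list("abcd"))
        b = pd.Series([1, 1, 2, 2], index=list("abcd"))
        table = contingency(a, b)
        assert table.observed.tolist() == [[2, 0], [0, 2]]

    def test_published_bound_by_nitrogen_reconstruction(self):
        """Bound (212/325/732) vs unbound rows against the printed class
        sizes (754 NCR, 928 revNCR, 4116 unaffected; 1269 bound)."""
        table = make_table([[212, 325, 732], [542, 603, 3384]],
                           index=["bound", "unbound"],
                           columns=["NCR", "revNCR", "unaffected"])
        assert table.row_totals.tolist() == [1269, 4529]
        assert table.col_totals.tolist() == [754, 928, 4116]
        assert table.total == PUBLISHED_UNIVERSE

    def test_universe_mismatch_rejected(self):
        a = pd.Series(["X"], index=["a"])
        b = pd.Series(["Y"], index=["b"])
        with pytest.raises(ValueError, match="symmetric"):
            contingency(a, b)
        with pytest.raises(ValueError, match="empty"):
            contingency(a.iloc[:0], b.iloc[:0])


class TestChiSquare:
    def test_perfect_independence(self):
        result = chi_square_independence(make_table([[10, 10], [10, 10]]))
        assert result.statistic == 0.0 and result.p_value == 1.0

    def test_closed_form_case(self):
        result = chi_square_independence(make_table([[20, 10], [10, 20]]))
        assert result.statistic == pytest.approx(20 / 3)
        assert result.df == 1
        assert result.p_value == pytest.approx(0.009823, abs=1e-5)

    def test_matches_scipy_on_random_tables(self, rng):
        for _ in range(25):
            shape = rng.integers(2, 5, size=2)
            obs = rng.integers(5, 80, size=shape)
            ours = chi_square_independence(ContingencyTable(pd.DataFrame(obs)))
            ref = sps.chi2_contingency(obs, correction=False)
            assert ours.statistic == pytest.approx(ref.statistic)
            assert ours.p_value == pytest.approx(ref.pvalue)
            assert ours.df == ref.dof

    def test_permutation_invariance(self, rng):
        obs = rng.integers(1, 50, size=(3, 4))
        base = chi_square_independence(ContingencyTable(pd.DataFrame(obs)))
        for perm in permutations(range(3)):
            shuffled = chi_square_independence(
                ContingencyTable(pd.DataFrame(obs[list(perm)])))
            assert shuffled.statistic == pytest.approx(base.statistic)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError, match="margin"):
            chi_square_independence(make_table([[0, 0], [5, 5]]))

    def test_small_expected_warns_not_fails(self):
        result = chi_square_independence(make_table([[1, 2], [2, 1]]))
        assert result.warnings and result.p_value <= 1.0

    def test_yates_correction_shrinks_statistic(self):
        table = make_table([[20, 10], [10, 20]])
        plain = chi_square_independence(table)
        corrected = chi_square_independence(table, yates=True)
        assert corrected.statistic < plain.statistic
        ref = sps.chi2_contingency(table.observed, correction=True)
        assert corrected.statistic == pytest.approx(ref.statistic)

    def test_upper_tail_matches_quadrature(self):
        """Regularized upper incomplete gamma vs direct quadrature of the
        chi-square density, to 1e-10 relative accuracy."""
        from scipy.integrate import quad

        for df in range(1, 11):
            for stat in (0.5, 3.0, 12.0, 40.0, 90.0, 150.0, 200.0):
                ours = chi_square_upper_tail(stat, df)
                ref, _err = quad(lambda x: sps.chi2.pdf(x, df), stat, np.inf,
                                 epsabs=0, epsrel=1e-13, limit=300)
                assert ours == pytest.approx(ref, rel=1e-10)

    def test_type_one_error_calibration(self):
        """Under shuffled labels the chi-square test rejects at ~alpha.

        10,000 null 2x3 tables with all expected cells >= 10 (n chosen well
        into the asymptotic regime; at n ~ 200 the discreteness of the
        statistic visibly inflates the rate for any implementation); the
        rejection rate at alpha=0.05 must sit within 3-sigma binomial error.
        """
        rng = np.random.default_rng(0)
        n, n_sim, alpha = 1200, 10_000, 0.05
        a = np.repeat([0, 1], n // 2)
        b = np.repeat([0, 1, 2], n // 3)
        rejected = 0
        for _ in range(n_sim):
            rng.shuffle(b)
            obs = np.zeros((2, 3))
            np.add.at(obs, (a, b), 1)
            stat_table = ContingencyTable(pd.DataFrame(obs))
            result = chi_square_independence(stat_table)
            rejected += result.p_value <= alpha
        rate = rejected / n_sim
        tol = 3 * np.sqrt(alpha * (1 - alpha) / n_sim)
        assert abs(rate - alpha) < tol


class TestRankSum:
    def test_identical_samples_p_one(self):
        assert rank_sum([1, 2, 3], [1, 2, 3]).p_value == 1.0

    def test_separated_samples_exact_p(self):
        result = rank_sum([1, 2, 3], [4, 5, 6])
        assert result.p_value == pytest.approx(0.1)
        assert result.method == "wilcoxon_rank_sum_exact"

    def test_scaling_invariance(self, rng):
        x = rng.lognormal(0, 1, 6)
        y = rng.lognormal(1, 1, 7)
        assert rank_sum(x, y).p_value == rank_sum(10 * x, 10 * y).p_value

    def test_exact_matches_scipy(self, rng):
        for _ in range(10):
            x = rng.normal(0, 1, int(rng.integers(2, 8)))
            y = rng.normal(0.5, 1, int(rng.integers(2, 8)))
            ours = rank_sum(x, y)
            ref = sps.mannwhitneyu(x, y, alternative="two-sided",
                                   method="exact")
            assert ours.p_value == pytest.approx(ref.pvalue)

    def test_exact_with_ties_matches_permutation(self):
        """Midrank exact p agrees with full permutation enumeration."""
        x, y = [1.0, 2.0, 2.0], [2.0, 3.0, 4.0]
        ours = rank_sum(x, y).p_value
        ref = sps.mannwhitneyu(
            x, y, alternative="two-sided",
            method=sps.PermutationMethod(n_resamples=100_000)).pvalue
        assert ours == pytest.approx(ref)

    def test_normal_approximation_matches_scipy(self, rng):
        x = rng.normal(0, 1, 30)
        y = np.round(rng.normal(0.4, 1, 25), 1)  # induces ties
        ours = rank_sum(x, y)
        ref = sps.mannwhitneyu(x, y, alternative="two-sided",
                               method="asymptotic", use_continuity=False)
        assert ours.method == "wilcoxon_rank_sum_normal"
        assert ours.p_value == pytest.approx(ref.pvalue)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            rank_sum([], [1.0])


class TestSetEnrichment:
    def test_published_chip_overlap(self):
        """103 of 205 known nitrogen-regulated genes among 1269 bound."""
        table, result = set_enrichment(103, 205, 1269, PUBLISHED_UNIVERSE)
        assert result.extra["expected_hits"] == pytest.approx(44.9, abs=0.1)
        assert result.p_value < 0.001
        assert table.observed.sum() == PUBLISHED_UNIVERSE

    def test_hits_at_expectation_give_zero_statistic(self):
        # 50 of 500 in-list vs 1000 of 10000 overall: exactly independent
        _table, result = set_enrichment(50, 500, 1000, 10_000)
        assert result.statistic == pytest.approx(0.0)
        assert result.extra["fold_enrichment"] == pytest.approx(1.0)

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ValueError, match="inconsistent"):
            set_enrichment(50, 40, 100, 1000)
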