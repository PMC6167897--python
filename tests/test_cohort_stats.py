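import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from tmeprox import (
    chi_square,
    density_adjusted_proximity,
    mann_whitney,
    quartile_stratify,
)
from tmeprox.cohort_stats import benjamini_hochberg


def exact_mw_p(a, b):
    """Enumeration oracle: two-sided exact Mann-Whitney p over all
    C(n_a+n_b, n_a) group-label assignments of the pooled sample."""
    pooled = np.concatenate([a, b])
    n_a = len(a)

    def u_stat(ix_a):
        aa = pooled[list(ix_a)]
        bb = np.delete(pooled, list(ix_a))
        return sum((x > y) + 0.5 * (x == y) for x in aa for y in bb)

    observed = u_stat(range(n_a))
    n = len(pooled)
    mu = n_a * (n - n_a) / 2
    us = [u_stat(c) for c in itertools.combinations(range(n), n_a)]
    extreme = sum(abs(u - mu) >= abs(observed - mu) - 1e-12 for u in us)
    return extreme / len(us)


class TestMannWhitney:
    def test_separated_groups_exact_p(self):
        res = mann_whitney([1, 2, 3], [4, 5, 6])
        assert res.statistic == 0.0
        # full enumeration over C(6,3)=20 assignments gives 2/20
        assert res.p_value == pytest.approx(0.1)
        assert res.p_value == pytest.approx(exact_mw_p([1, 2, 3], [4, 5, 6]))

    def test_exact_matches_enumeration_on_random_small_samples(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            a = rng.normal(size=4)
            b = rng.normal(size=5)
            res = mann_whitney(a, b)
            assert res.p_value == pytest.approx(exact_mw_p(a, b))
            assert res.note == "method=exact"

    def test_symmetric_in_group_order(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(size=8), rng.normal(1.0, size=8)
        assert mann_whitney(a, b).p_value == mann_whitney(b, a).p_value

    def test_exact_vs_asymptotic_agree_for_n8_vs_8(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            a, b = rng.normal(size=8), rng.normal(size=8)
            exact = sps.mannwhitneyu(a, b, alternative="two-sided", method="exact")
            asym = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
            assert abs(exact.pvalue - asym.pvalue) <= 0.02

    def test_null_rejection_rate_calibrated(self):
        rng = np.random.default_rng(3)
        rejections = sum(
            mann_whitney(rng.normal(size=8), rng.normal(size=8)).p_value < 0.05
            for _ in range(1000)
        )
        assert 0.03 <= rejections / 1000 <= 0.07

    def test_ties_fall_back_to_corrected_normal_approximation(self):
        res = mann_whitney([1, 1, 2, 2], [2, 3, 3, 4])
        assert res.note == "method=asymptotic"
        assert 0.0 <= res.p_value <= 1.0

    def test_group_summaries_report_median_and_range(self):
        res = mann_whitney([1.0, 2.0, 9.0], [4.0, 5.0, 6.0])
        assert res.summaries["a"]["median"] == 2.0
        assert res.summaries["a"]["min"] == 1.0
        assert res.summaries["a"]["max"] == 9.0
        assert res.summaries["b"]["n"] == 3

    def test_empty_group_is_error(self):
        with pytest.raises(ValueError, match="non-empty"):
            mann_whitney([], [1.0])


class TestChiSquare:
    def test_independent_table_statistic_zero(self):
        res = chi_square([[10, 10], [10, 10]])
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_perfect_association_hand_computed(self):
        # [[20,0],[0,20]]: every expected count is 10, X^2 = 4 * 10 = 40
        res = chi_square([[20, 0], [0, 20]], yates=False)
        assert res.statistic == pytest.approx(40.0)
        assert res.summaries["dof"] == 1

    def test_yates_correction_shrinks_statistic(self):
        uncorr = chi_square([[12, 5], [6, 14]], yates=False)
        corr = chi_square([[12, 5], [6, 14]], yates=True)
        assert corr.statistic < uncorr.statistic

    def test_invariant_under_row_swap(self):
        t = [[12, 5, 3], [6, 14, 9]]
        assert chi_square(t).statistic == pytest.approx(chi_square(t[::-1]).statistic)

    def test_degenerate_table_is_error(self):
        with pytest.raises(ValueError, match="degenerate"):
            chi_square([[0, 0], [5, 5]])


class TestQuartileStratify:
    def cohort(self, values, responders):
        return pd.DataFrame(
            {
                "specimen_id": [f"s{i}" for i in range(len(values))],
                "metric": values,
                "responder": responders,
            }
        )

    def test_rank_quartiles_on_one_to_eight(self):
        df = self.cohort(list(range(1, 9)), [False] * 8)
        q = quartile_stratify(df, "metric")
        top = q.assignments.loc[q.assignments["quartile"] == 4, "specimen_id"]
        assert sorted(top) == ["s6", "s7"]  # values 7 and 8

    def test_all_responders_in_top_quartile(self):
        df = self.cohort([1, 2, 3, 4, 5, 6, 7, 8], [False] * 6 + [True] * 2)
        q = quartile_stratify(df, "metric")
        assert q.fraction(4) == 1.0
        assert q.fraction(1) == 0.0

    def test_sizes_differ_by_at_most_one_without_ties(self):
        rng = np.random.default_rng(4)
        for n in (16, 17, 25, 26):
            df = self.cohort(list(rng.permutation(n).astype(float)), [False] * n)
            sizes = quartile_stratify(df, "metric").assignments["quartile"].value_counts()
            assert sizes.max() - sizes.min() <= 1
            assert sizes.sum() == n

    def test_ties_assigned_to_lower_quartile(self):
        df = self.cohort([1, 2, 2, 2, 5, 6, 7, 8], [False] * 8)
        q = quartile_stratify(df, "metric").assignments.set_index("specimen_id")
        # the three tied 2s share the min rank (2) -> all in Q1
        assert (q.loc[["s1", "s2", "s3"], "quartile"] == 1).all()

    def test_missing_values_dropped_and_small_n_errors(self):
        df = self.cohort([1.0, 2.0, np.nan, 4.0], [False] * 4)
        with pytest.raises(ValueError, match=">= 4"):
            quartile_stratify(df, "metric")

    def test_simulated_cohort_pd1_gradient(self):
        from tmeprox.synthetic import simulate_cohort

        df = simulate_cohort(8, 8, seed=7)
        q = quartile_stratify(df, "pd1_density_total")
        assert q.fraction(4) > q.fraction(1)


class TestDensityAdjustedProximity:
    def records(self, n, rng, independent_signal=0.0):
        # marginal densities deliberately NOT separated by group, so any
        # responder signal in proximity is beyond the densities by design
        responder = np.arange(n) < n // 2
        pd1 = rng.lognormal(3.0, 0.6, n)
        pdl1 = rng.lognormal(5.5, 0.6, n)
        prox = 0.5 * pd1 * (1 + 0.1 * rng.normal(size=n))
        prox *= 1 + independent_signal * responder
        return pd.DataFrame(
            {
                "specimen_id": [f"s{i}" for i in range(n)],
                "responder": responder,
                "pd1_density_total": pd1,
                "pdl1_density_total": pdl1,
                "pd1_near_pdl1_density": prox,
            }
        )

    def test_perfect_mediation_gives_null_result(self):
        # proximity exactly proportional to PD-1 density: nothing left
        rng = np.random.default_rng(5)
        df = self.records(24, rng)
        df["pd1_near_pdl1_density"] = 0.7 * df["pd1_density_total"]
        res = density_adjusted_proximity(df)
        assert res.p_value > 0.4

    def test_independent_signal_detected_with_power(self):
        rng = np.random.default_rng(6)
        hits = sum(
            density_adjusted_proximity(
                self.records(24, rng, independent_signal=0.8)
            ).p_value
            < 0.05
            for _ in range(200)
        )
        assert hits / 200 >= 0.8

    def test_permuted_labels_give_calibrated_null_p(self):
        # under label permutation the adjusted p must behave like a valid
        # p-value: never anti-conservative, and at most mildly conservative
        # (the continuity correction shifts the asymptotic p slightly up,
        # so exact uniformity is not expected)
        rng = np.random.default_rng(7)
        df = self.records(24, rng)
        ps = np.array([
            density_adjusted_proximity(
                df.assign(responder=rng.permutation(df["responder"].to_numpy()))
            ).p_value
            for _ in range(500)
        ])
        for alpha in (0.05, 0.1, 0.2):
            rate = (ps <= alpha).mean()
            se = np.sqrt(alpha * (1 - alpha) / 500)
            assert rate <= alpha + 3 * se
            assert rate >= alpha / 2
        ks = sps.kstest(ps, "uniform")
        assert ks.statistic < 0.12  # gross departures from uniformity

    def test_small_n_is_error(self):
        rng = np.random.default_rng(8)
        with pytest.raises(ValueError, match="n = 6"):
            density_adjusted_proximity(self.records(4, rng))


def test_benjamini_hochberg_monotone_and_bounded():
    p = np.array([0.001, 0.01, 0.02, 0.5, 0.9])
    adj = benjamini_hochberg(p)
    assert np.all(adj >= p)
    assert np.all(adj <= 1.0)
    assert np.all(np.diff(adj[np.argsort(p)]) >= 0)
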