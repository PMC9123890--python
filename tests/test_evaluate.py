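"""Unit tests for the disentanglement / association statistics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from sparekit.evaluate import (
    accuracy_sens_eq_spec,
    bh_adjust,
    cohens_d,
    compare_correlations,
    corr_pair,
    nested_lrt,
    select_evaluation_scan,
    spearman_cell,
    spearman_table,
)


class TestCorrPair:
    def test_perfect_affine_relation(self):
        x = np.arange(10.0)
        r, n = corr_pair(x, 2 * x + 1)
        assert r == pytest.approx(1.0)
        assert n == 10

    def test_hand_computed_value(self):
        # cov/sd computation by hand gives r = 0.6
        r, n = corr_pair([1, 2, 3, 4], [2, 1, 4, 3])
        assert r == pytest.approx(0.6, abs=1e-12)

    def test_complete_pairs_only(self):
        x = pd.Series([1, 2, 3, 4, np.nan, 6.0])
        y = pd.Series([2, 4, 6, 8, 10, np.nan])
        r, n = corr_pair(x, y)
        assert n == 4
        assert r == pytest.approx(1.0)

    def test_independent_normals_are_weakly_correlated(self):
        rng = np.random.default_rng(42)
        r, _ = corr_pair(rng.normal(size=10000), rng.normal(size=10000))
        assert abs(r) < 0.04

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            corr_pair([1, 1, 1, 1], [1, 2, 3, 4])

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError, match="at least 4"):
            corr_pair([1, 2, 3], [3, 2, 1])


class TestCompareCorrelations:
    def test_equal_coefficients_give_null_result(self):
        stat, p = compare_correlations(0.4, 100, 0.4, 250)
        assert stat == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_matches_direct_fisher_z_computation(self):
        # independent oracle: recompute from atanh and the chi-squared tail
        stat, p = compare_correlations(0.5, 1000, 0.3, 1000)
        z1, z2 = np.arctanh(0.5), np.arctanh(0.3)
        expected_stat = (z1 - z2) ** 2 / (1 / 997 + 1 / 997)
        expected_p = stats.chi2.sf(expected_stat, 1)
        assert stat == pytest.approx(expected_stat, abs=1e-10)
        assert p == pytest.approx(expected_p, abs=1e-10)
        assert stat == pytest.approx(28.67, abs=0.05)

    def test_symmetric_in_arguments(self):
        s1, p1 = compare_correlations(0.6, 80, 0.2, 120)
        s2, p2 = compare_correlations(0.2, 120, 0.6, 80)
        assert s1 == pytest.approx(s2)
        assert p1 == pytest.approx(p2)

    def test_type_one_error_rate_under_null(self):
        # both samples drawn from one bivariate normal with r = 0.4
        rng = np.random.default_rng(7)
        n, reps, rejections = 500, 2000, 0
        cov = np.array([[1.0, 0.4], [0.4, 1.0]])
        L = np.linalg.cholesky(cov)
        for _ in range(reps):
            a = rng.standard_normal((n, 2)) @ L.T
            b = rng.standard_normal((n, 2)) @ L.T
            r1 = np.corrcoef(a[:, 0], a[:, 1])[0, 1]
            r2 = np.corrcoef(b[:, 0], b[:, 1])[0, 1]
            _, p = compare_correlations(r1, n, r2, n)
            rejections += p < 0.05
        assert 0.03 <= rejections / reps <= 0.07

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            compare_correlations(1.0, 100, 0.3, 100)
        with pytest.raises(ValueError):
            compare_correlations(0.5, 3, 0.3, 100)


class TestAccuracySensEqSpec:
    def test_perfectly_separated_groups(self):
        scores = np.r_[np.zeros(50), np.ones(50)]
        labels = np.r_[np.zeros(50, int), np.ones(50, int)]
        _, acc = accuracy_sens_eq_spec(scores, labels)
        assert acc == pytest.approx(1.0)

    def test_two_normals_match_analytic_value(self):
        # populations N(0,1) and N(2,1): crossing at t=1, accuracy Phi(1)
        rng = np.random.default_rng(11)
        n = 50000
        scores = np.r_[rng.normal(0, 1, n), rng.normal(2, 1, n)]
        labels = np.r_[np.zeros(n, int), np.ones(n, int)]
        thr, acc = accuracy_sens_eq_spec(scores, labels)
        assert 100 * acc == pytest.approx(100 * stats.norm.cdf(1.0), abs=0.7)
        assert thr == pytest.approx(1.0, abs=0.05)

    def test_uninformative_scores_near_chance(self):
        rng = np.random.default_rng(3)
        scores = rng.normal(size=10000)
        labels = np.r_[np.zeros(5000, int), np.ones(5000, int)]
        _, acc = accuracy_sens_eq_spec(scores, labels)
        assert 100 * acc == pytest.approx(50.0, abs=2.0)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            accuracy_sens_eq_spec([1.0, 2.0], [1, 1])


class TestCohensD:
    def test_identical_groups(self):
        with pytest.raises(ValueError):
            cohens_d([1, 1, 1], [1, 1, 1])  # zero pooled SD
        assert cohens_d([1, 2, 3], [1, 2, 3]) == pytest.approx(0.0)

    def test_hand_computed_value(self):
        assert cohens_d([1, 2, 3], [3, 4, 5]) == pytest.approx(-2.0)

    def test_antisymmetry(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(size=20), rng.normal(1.0, 1.0, size=20)
        assert cohens_d(a, b) == pytest.approx(-cohens_d(b, a))


class TestBHAdjust:
    def test_single_p_unchanged(self):
        assert bh_adjust([0.031])[0] == pytest.approx(0.031)

    def test_step_up_by_hand(self):
        out = bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(out, [0.04, 0.04, 0.04, 0.04])

    def test_monotone_in_ranks_and_idempotent(self):
        rng = np.random.default_rng(5)
        p = rng.uniform(size=40)
        adj = bh_adjust(p)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-12)
        assert np.all(adj >= p - 1e-12)
        # re-adjusting already-adjusted values never lowers them
        assert np.all(bh_adjust(adj) >= adj - 1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.2, 1.4])


class TestSpearman:
    def test_monotone_transform_gives_one(self):
        x = np.arange(12.0)
        rho, _, _ = spearman_cell(x, np.exp(x))
        assert rho == pytest.approx(1.0)

    def test_hand_computed_value(self):
        # sum of squared rank differences = 2 -> rho = 1 - 12/60 = 0.8
        rho, _, _ = spearman_cell([1, 2, 3, 4], [1, 3, 2, 4], min_n=4)
        assert rho == pytest.approx(0.8)

    def test_all_tied_flagged(self):
        with pytest.raises(ValueError, match="all-tied"):
            spearman_cell([1] * 12, np.arange(12))

    def test_table_adjusts_across_cells(self):
        rng = np.random.default_rng(9)
        n = 60
        scores = pd.DataFrame(
            {"S1": rng.normal(size=n), "S2": rng.normal(size=n)},
            index=[f"s{i}" for i in range(n)],
        )
        variables = pd.DataFrame(
            {"v1": scores["S1"] * 2 + rng.normal(scale=0.1, size=n),
             "v2": rng.normal(size=n)},
            index=scores.index,
        )
        table = spearman_table(scores, variables)
        assert len(table) == 4
        assert (table["p_adj"] >= table["p"] - 1e-12).all()
        strong = table[(table.variable == "v1") & (table.score == "S1")]
        assert strong["rho"].iloc[0] > 0.9


class TestNestedLRT:
    @staticmethod
    def _frame(n, rng):
        return pd.DataFrame(
            {"x1": rng.normal(size=n), "x2": rng.normal(size=n)},
            index=range(n),
        )

    def test_redundant_predictor_gives_null(self):
        rng = np.random.default_rng(2)
        X = self._frame(200, rng)
        X["dup"] = X["x1"]
        y = 2 * X["x1"] + rng.normal(size=200)
        lr, df, p = nested_lrt(y, X[["x1", "x2", "dup"]], X[["x1", "x2"]])
        assert df == 1
        assert lr == pytest.approx(0.0, abs=1e-6)
        assert p == pytest.approx(1.0, abs=1e-3)

    def test_strong_predictor_detected(self):
        rng = np.random.default_rng(4)
        X = self._frame(500, rng)
        y = 2 * X["x1"] + rng.normal(size=500)
        lr, df, p = nested_lrt(y, X, X[["x2"]])
        assert p < 1e-10

    def test_non_nested_rejected(self):
        rng = np.random.default_rng(0)
        X = self._frame(50, rng)
        with pytest.raises(ValueError):
            nested_lrt(X["x1"], X[["x1"]], X[["x2"]])

    def test_type_one_error_rate_under_null(self):
        rng = np.random.default_rng(8)
        n, reps, rej = 100, 2000, 0
        for _ in range(reps):
            X = self._frame(n, rng)
            y = 1.5 * X["x1"] + rng.normal(size=n)  # x2 truly null
            _, _, p = nested_lrt(y, X, X[["x1"]])
            rej += p < 0.05
        assert 0.03 <= rej / reps <= 0.07


class TestSelectEvaluationScan:
    @staticmethod
    def _pheno():
        return pd.DataFrame(
            {
                "participant_id": ["p1", "p1", "p1", "p2"],
                "scan_id": ["a", "b", "c", "d"],
                "clinical_dx": ["CN", "MCI", "AD", "CN"],
            }
        )

    def test_most_advanced_label_wins(self):
        chosen = select_evaluation_scan(self._pheno(), seed=0)
        assert "c" in chosen  # the AD scan of p1
        assert "d" in chosen

    def test_deterministic_under_seed(self):
        ph = pd.DataFrame(
            {
                "participant_id": ["p"] * 5,
                "scan_id": list("abcde"),
                "clinical_dx": ["MCI"] * 5,
            }
        )
        assert select_evaluation_scan(ph, seed=3) == select_evaluation_scan(ph, seed=3)


class TestBHPropertiesHypothesis:
    """Property-based checks of the step-up adjustment."""

    from hypothesis import given, settings
    from hypothesis import strategies as st

    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=60))
    @settings(deadline=None, derandomize=True, max_examples=60)
    def test_adjusted_values_bounded_monotone(self, pvals):
        p = np.asarray(pvals)
        adj = bh_adjust(p)
        assert np.all((adj >= 0) & (adj <= 1))
        assert np.all(adj >= p - 1e-12)
        order = np.argsort(p, kind="stable")
        assert np.all(np.diff(adj[order]) >= -1e-12)
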