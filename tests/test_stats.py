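"""Group statistics: routing, effect sizes, FDR, nodewise and EEG tests."""

import numpy as np
import pandas as pd
import pytest

from comagraph import (
    adjusted_group_difference,
    cohens_d,
    compare_groups,
    eeg_category_tests,
    fdr_adjust,
    metric_correlations,
    nodewise_outcome_correlation,
)


class TestCompareGroups:
    def test_identical_samples_mann_whitney_p_one(self, rng):
        # heavy-tailed draw routes to Mann-Whitney; identical groups -> p ~ 1
        g = rng.standard_cauchy(30)
        res = compare_groups(g, g)
        assert res.test == "mann_whitney"
        assert res.p_raw == pytest.approx(1.0, abs=0.02)

    def test_u_statistic_matches_rank_enumeration(self):
        res = compare_groups([1.0, 2, 3], [4.0, 5, 6])
        # brute force: U = number of (a, b) pairs with a > b
        u_brute = sum(a > b for a in [1, 2, 3] for b in [4, 5, 6])
        if res.test == "mann_whitney":
            assert res.statistic == u_brute == 0
        else:  # tiny normal-looking samples may route to t; force MW path
            from scipy.stats import mannwhitneyu

            assert mannwhitneyu([1, 2, 3], [4, 5, 6]).statistic == u_brute

    def test_chi_square_closed_form(self):
        # (ad-bc)^2 * n / (r1 r2 c1 c2) with no continuity correction
        res = compare_groups([10, 0], [0, 10], variable_kind="categorical")
        assert res.test == "chi_square"
        assert res.statistic == pytest.approx((10 * 10) ** 2 * 20 / (10 * 10 * 10 * 10))

    def test_small_expected_counts_use_fisher(self):
        res = compare_groups([3, 1], [1, 3], variable_kind="categorical")
        assert res.test == "fisher_exact"

    def test_normal_groups_route_to_t(self, rng):
        a = rng.normal(0, 1, 40)
        b = rng.normal(0.2, 1, 40)
        assert compare_groups(a, b).test == "t"

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            compare_groups([], [1.0, 2])


class TestCohensD:
    def test_identical_means_zero(self):
        assert cohens_d([1.0, 2, 3], [3.0, 2, 1]) == pytest.approx(0.0)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            cohens_d([0.0, 0, 0, 0], [1.0, 1, 1, 1])

    def test_hand_pooled_sd(self):
        # groups (1,2,3) vs (3,4,5): pooled SD = 1, d = -2
        assert cohens_d([1.0, 2, 3], [3.0, 4, 5]) == pytest.approx(-2.0)


class TestAdjustedGroupDifference:
    @staticmethod
    def _covariates(rng, n):
        return pd.DataFrame({
            "arrest_to_mri_hours": rng.normal(60, 20, n),
            "hospital": rng.choice(list("ABC"), n),
            "comatose_during_mri": rng.integers(0, 2, n).astype(float),
        })

    def test_null_calibration(self, rng):
        """Independent metric rejects at ~ alpha over replicates."""
        rejections = 0
        n_rep = 200
        for _ in range(n_rep):
            n = 60
            y = rng.integers(0, 2, n).astype(float)
            if y.min() == y.max():
                continue
            metric = rng.standard_normal(n)
            try:
                _, p = adjusted_group_difference(metric, y, self._covariates(rng, n))
            except ValueError:
                continue
            rejections += p < 0.05
        assert 0.02 <= rejections / n_rep <= 0.09

    def test_collinear_metric_raises(self, rng):
        n = 40
        cov = self._covariates(rng, n)
        y = rng.integers(0, 2, n).astype(float)
        y[0], y[1] = 0, 1
        with pytest.raises(ValueError, match="collinear"):
            adjusted_group_difference(cov["arrest_to_mri_hours"].to_numpy(), y, cov)

    def test_strong_effect_detected(self, rng):
        n = 80
        y = np.repeat([0.0, 1.0], n // 2)
        metric = y * 2 + rng.standard_normal(n)
        _, p = adjusted_group_difference(metric, y, self._covariates(rng, n))
        assert p < 0.01


class TestFdrAdjust:
    def test_single_p_unchanged(self):
        assert fdr_adjust([0.04])[0] == pytest.approx(0.04)

    def test_hand_bh_stepup(self):
        np.testing.assert_allclose(fdr_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_adjusted_dominates_raw(self, rng):
        p = rng.random(25)
        assert (fdr_adjust(p) >= p - 1e-12).all()

    def test_readjustment_fixed_points(self, rng):
        # step-up adjustment leaves flat (tied) adjusted vectors unchanged
        flat = fdr_adjust([0.01, 0.02, 0.03])  # -> (0.03, 0.03, 0.03)
        np.testing.assert_allclose(fdr_adjust(flat), flat, atol=1e-12)
        # and re-adjustment never lowers any value
        p = np.sort(rng.random(10))
        adj = fdr_adjust(p)
        assert (fdr_adjust(adj) >= adj - 1e-12).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            fdr_adjust([0.5, 1.2])


class TestNodewiseOutcomeCorrelation:
    def test_constant_node_recorded_missing(self, rng):
        M = rng.standard_normal((10, 3))
        M[:, 1] = 0.5
        y = np.tile([1, 0], 5)
        results, counts = nodewise_outcome_correlation(M, y)
        assert np.isnan(results[1].r)
        assert all(np.isfinite(results[j].r) for j in (0, 2))

    def test_indicator_node_perfect_correlation(self, rng):
        y = np.tile([1.0, 0.0], 8)
        M = np.column_stack([y, rng.standard_normal(16)])
        results, counts = nodewise_outcome_correlation(M, y)
        assert results[0].r == pytest.approx(1.0)
        assert counts[0.05] >= 1

    def test_null_nodes_pass_at_alpha_rate(self, rng):
        hits, total = 0, 0
        for _ in range(40):
            M = rng.standard_normal((30, 50))
            y = np.tile([1, 0], 15)
            _, counts = nodewise_outcome_correlation(M, y)
            hits += counts[0.05]
            total += 50
        assert 0.025 <= hits / total <= 0.08

    def test_string_outcomes_good_coded_positive(self):
        M = np.array([[1.0], [1.0], [0.0], [0.0]]) + np.arange(4)[:, None] * 1e-3
        results, _ = nodewise_outcome_correlation(
            M, np.array(["good", "good", "poor", "poor"])
        )
        assert results[0].r > 0.99


class TestEegCategoryTests:
    def test_shifted_category_detected(self, rng):
        cats = {
            1: rng.normal(0, 1, 15),
            2: rng.normal(0, 1, 15),
            3: rng.normal(4, 1, 15),
        }
        res = eeg_category_tests(cats)
        assert res["kruskal_p"] < 0.05
        sig = {tuple(p["categories"]): p["p_fdr"] for p in res["pairwise"]}
        assert sig[(1, 3)] < 0.05 and sig[(2, 3)] < 0.05

    def test_pairwise_suppressed_when_omnibus_null(self, rng):
        cats = {c: rng.normal(0, 1, 20) for c in range(4)}
        res = eeg_category_tests(cats)
        if res["kruskal_p"] >= 0.05:
            assert res["pairwise"] == []

    def test_identical_categories_pairwise_p_near_one(self):
        g = np.arange(10.0)
        res = eeg_category_tests({1: g, 2: g, 3: g + 30})
        pair = {tuple(p["categories"]): p["p_raw"] for p in res["pairwise"]}
        assert pair[(1, 2)] == pytest.approx(1.0, abs=0.05)

    def test_small_category_excluded_with_warning(self, rng):
        with pytest.warns(UserWarning, match="excluded"):
            eeg_category_tests({1: rng.normal(0, 1, 10), 2: [1.0], 3: rng.normal(1, 1, 10)})


class TestMetricCorrelations:
    def test_self_correlation_unity_and_linearity(self, rng):
        fc = rng.random(12)
        df = pd.DataFrame({"FC": fc, "C": 2 * fc, "GE": rng.random(12)})
        r, p = metric_correlations(df)
        assert r.loc["FC", "FC"] == 1.0
        assert r.loc["FC", "C"] == pytest.approx(1.0)

    def test_matches_direct_formula(self, rng):
        df = pd.DataFrame(rng.random((5, 2)), columns=["a", "b"])
        r, p = metric_correlations(df)
        a, b = df["a"].to_numpy(), df["b"].to_numpy()
        expect = np.corrcoef(a, b)[0, 1]
        assert r.loc["a", "b"] == pytest.approx(expect, abs=1e-12)

    def test_constant_column_missing(self, rng):
        df = pd.DataFrame({"a": rng.random(6), "b": np.ones(6)})
        r, _ = metric_correlations(df)
        assert np.isnan(r.loc["a", "b"])
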