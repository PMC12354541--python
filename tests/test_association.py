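"""Correlations, group comparison, stepwise-AIC selection, commonality."""

import itertools

import numpy as np
import pandas as pd
import pytest

from lt2lab.association import (
    aic_ols,
    commonality,
    correlate,
    group_compare,
    ols_fit,
    stepwise_aic,
)


class TestCorrelate:
    def test_exact_linear_pearson(self):
        x = np.arange(10.0)
        res = correlate(x, 2 * x + 1, "pearson")
        assert res.coefficient == pytest.approx(1.0)
        assert res.interpretation == "very_high"

    def test_monotone_transform_spearman(self):
        x = np.linspace(0, 5, 20)
        assert correlate(x, np.exp(x), "spearman").coefficient == pytest.approx(1.0)
        assert correlate(x, np.exp(x), "pearson").coefficient < 1.0

    def test_sampling_accuracy_on_known_correlation(self):
        rng = np.random.default_rng(5)
        cov = [[1, 0.5], [0.5, 1]]
        xy = rng.multivariate_normal([0, 0], cov, size=10000)
        res = correlate(xy[:, 0], xy[:, 1], "pearson")
        assert res.coefficient == pytest.approx(0.5, abs=0.03)
        assert res.interpretation == "moderate"

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            correlate(np.ones(10), np.arange(10.0))


class TestGroupCompare:
    def test_separated_groups_significant(self):
        rng = np.random.default_rng(2)
        v = np.concatenate([rng.normal(0, 1, 30), rng.normal(10, 1, 30)])
        g = np.repeat(["a", "b"], 30)
        for normal in (True, False):
            assert group_compare(v, g, normal).p < 0.001

    def test_null_groups_not_significant(self):
        rng = np.random.default_rng(3)
        v = rng.normal(0, 1, 400)
        g = np.repeat(["a", "b"], 200)
        assert group_compare(v, g, True).p > 0.001

    def test_dispatch_to_rank_sum(self):
        v = np.arange(20.0)
        g = np.repeat(["a", "b"], 10)
        assert group_compare(v, g, normal=False).test_name == "wilcoxon-rank-sum"
        assert group_compare(v, g, normal=True).test_name == "t-test"


class TestStepwiseAIC:
    def test_exact_signal_selected(self):
        rng = np.random.default_rng(11)
        X = pd.DataFrame({"x1": rng.normal(0, 1, 50),
                          "x2": rng.normal(0, 1, 50),
                          "x3": rng.normal(0, 1, 50)})
        y = 3.0 * X["x1"].to_numpy() + 1.0
        res = stepwise_aic(y, X)
        names = [t.name for t in res.terms[1:]]
        assert names == ["x1"]
        assert res.r2 == pytest.approx(1.0, abs=1e-12)

    def test_pure_noise_never_beats_intercept_only(self):
        rng = np.random.default_rng(13)
        X = pd.DataFrame({f"x{i}": rng.normal(0, 1, 100) for i in range(3)})
        y = rng.normal(0, 1, 100)
        res = stepwise_aic(y, X)
        start_aic = res.step_trace[0][2]
        assert res.aic <= start_aic
        aics = [a for _, _, a in res.step_trace]
        assert all(b <= a for a, b in zip(aics, aics[1:]))

    def test_final_aic_matches_exhaustive_subsets(self):
        rng = np.random.default_rng(17)
        X = pd.DataFrame({"x1": rng.normal(0, 1, 40),
                          "x2": rng.normal(0, 1, 40),
                          "x3": rng.normal(0, 1, 40)})
        y = (1.5 * X["x1"] + 0.8 * X["x2"] + rng.normal(0, 1, 40)).to_numpy()
        res = stepwise_aic(y, X)
        best = min(
            aic_ols(y, np.column_stack(
                [np.ones(40)] + [X[c].to_numpy() for c in combo]))
            for k in range(4) for combo in itertools.combinations(X.columns, k)
        )
        assert res.aic == pytest.approx(best, abs=1e-10)

    def test_rank_deficiency_rejected(self):
        x = np.arange(20.0)
        X = pd.DataFrame({"x1": x, "x2": 2 * x})
        with pytest.raises(ValueError, match="rank"):
            stepwise_aic(np.random.default_rng(0).normal(size=20), X)

    def test_ols_report_matches_statsmodels(self):
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(19)
        X = pd.DataFrame({"x1": rng.normal(0, 1, 60),
                          "x2": rng.normal(0, 1, 60)})
        y = 2 * X["x1"].to_numpy() - X["x2"].to_numpy() + rng.normal(0, 1, 60)
        res = ols_fit(y, X, ["x1", "x2"])
        ref = sm.OLS(y, sm.add_constant(X[["x1", "x2"]])).fit()
        assert np.allclose([t.beta for t in res.terms], ref.params, atol=1e-10)
        assert np.allclose([t.se for t in res.terms], ref.bse, atol=1e-10)
        assert np.allclose([t.p for t in res.terms], ref.pvalues, atol=1e-10)
        assert res.r2 == pytest.approx(ref.rsquared, abs=1e-12)
        assert res.adj_r2 == pytest.approx(ref.rsquared_adj, abs=1e-12)
        assert res.f == pytest.approx(ref.fvalue, abs=1e-8)


class TestCommonality:
    def test_orthogonal_predictors_have_zero_commons(self):
        rng = np.random.default_rng(23)
        Q, _ = np.linalg.qr(rng.normal(0, 1, (60, 3)))
        Q -= Q.mean(axis=0)  # keep orthogonality to the intercept
        Q, _ = np.linalg.qr(Q)
        x1, x2, x3 = Q.T
        y = 2 * x1 + 1 * x2 + 0.5 * x3 + rng.normal(0, 0.3, 60)
        res = commonality(y, x1, x2, x3)
        for comp, val in res.components.items():
            if len(comp) > 1:
                assert abs(val) < 1e-10
        # uniques equal squared marginal correlations
        for xi, comp in zip((x1, x2, x3), (("x1",), ("x2",), ("x3",))):
            r = np.corrcoef(xi, y)[0, 1]
            assert res.components[comp] == pytest.approx(r**2, abs=1e-10)

    def test_collinear_pair_shares_variance(self):
        rng = np.random.default_rng(29)
        x1 = rng.normal(0, 1, 80)
        x2 = rng.normal(0, 1, 80)
        x3 = x2 + rng.normal(0, 1e-4, 80)
        y = x2 + rng.normal(0, 0.5, 80)
        res = commonality(y, x1, x2, x3)
        assert abs(res.components[("x3",)]) < 1e-3
        r2_x2 = np.corrcoef(x2, y)[0, 1] ** 2
        assert res.components[("x2", "x3")] == pytest.approx(r2_x2, abs=1e-2)

    def test_conservation_on_random_data(self):
        rng = np.random.default_rng(31)
        for _ in range(5):
            x = rng.normal(0, 1, (40, 3))
            y = rng.normal(0, 1, 40)
            res = commonality(y, x[:, 0], x[:, 1], x[:, 2])
            assert sum(res.components.values()) == pytest.approx(
                res.total_r2, abs=1e-10)
            assert sum(res.percent_of_total.values()) == pytest.approx(
                100.0, abs=1e-6)

    def test_suppression_yields_negative_common(self):
        # classic suppression: x2 correlates with x1 but not with y
        rng = np.random.default_rng(37)
        x2 = rng.normal(0, 1, 200)
        e = rng.normal(0, 1, 200)
        x1 = x2 + e
        y = e + rng.normal(0, 0.2, 200)  # y relates to x1 only via e
        x3 = rng.normal(0, 1, 200)
        res = commonality(y, x1, x2, x3)
        assert res.components[("x1", "x2")] < 0
        assert sum(res.components.values()) == pytest.approx(res.total_r2,
                                                             abs=1e-10)
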