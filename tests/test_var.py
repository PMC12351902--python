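"""VAR estimation, lag selection, VIF, recursive residuals."""

import numpy as np
import pytest

from tycausal.panel import AnnualPanel
from tycausal.synthetic import SyntheticTruth, gen_var_panel
from tycausal.var import (
    VarError,
    build_lag_design,
    fit_var,
    recursive_residuals,
    select_lag,
    vif_pair,
)


def _panel(values, names=None):
    values = np.atleast_2d(np.asarray(values, float))
    names = names or tuple(f"v{i}" for i in range(values.shape[0]))
    years = tuple(range(2000, 2000 + values.shape[1]))
    return AnnualPanel(years, names, values)


class TestFitVar:
    def test_noiseless_ar1_recovered_exactly(self):
        y = 2.0 * 0.5 ** np.arange(30)
        fit = fit_var(_panel(y), lag_order=1)
        assert fit.coefs[0, 1] == pytest.approx(0.5, abs=1e-10)
        assert np.max(np.abs(fit.residuals)) < 1e-10

    def test_equals_brute_force_normal_equations(self, rng):
        """fit_var must agree with an explicit normal-equations solve."""
        Y = rng.standard_normal((3, 10))
        panel = _panel(Y)
        fit = fit_var(panel, lag_order=2)
        X, Z = build_lag_design(Y, 2)
        B = np.linalg.solve(X.T @ X, X.T @ Z.T)  # independent solve
        np.testing.assert_allclose(fit.coefs, B.T, atol=1e-10)

    def test_residuals_orthogonal_to_regressors(self, bivariate_panel):
        fit = fit_var(bivariate_panel, lag_order=2)
        inner = fit.design.T @ fit.residuals.T
        scale = np.abs(fit.design).max() * np.abs(fit.targets).max()
        assert np.max(np.abs(inner)) < 1e-8 * scale

    def test_known_coefficients_recovered_within_3_se(self):
        hits, total = 0, 0
        for seed in range(40):
            truth = SyntheticTruth(
                variables=("X", "Y"), edges=(("X", "Y", 1, 0.4),),
                ar={"X": 0.5, "Y": 0.3}, n=500, seed=seed,
            )
            fit = fit_var(gen_var_panel(truth), lag_order=1)
            true_b = {("Y", "X"): 0.4, ("Y", "Y"): 0.3, ("X", "X"): 0.5, ("X", "Y"): 0.0}
            for (eq, src), b in true_b.items():
                i, j = fit.equation(eq), fit.coef_index(src, 1)
                se = np.sqrt(fit.cov_params[i][j, j])
                hits += abs(fit.coefs[i, j] - b) < 3 * se
                total += 1
        assert hits / total >= 0.97

    def test_too_few_observations(self):
        with pytest.raises(VarError, match="too few"):
            fit_var(_panel(np.arange(5.0) ** 2), lag_order=3)

    def test_collinear_regressors(self):
        x = np.random.default_rng(0).standard_normal(20)
        with pytest.raises(VarError, match="collinear"):
            fit_var(_panel(np.vstack([x, 2 * x])), lag_order=1)


class TestSelectLag:
    def test_var2_dgp_prefers_p2(self):
        hits = 0
        for seed in range(50):
            truth = SyntheticTruth(
                variables=("X", "Y"),
                edges=(("X", "Y", 2, 0.5), ("Y", "X", 2, -0.3)),
                ar={"X": 0.3, "Y": 0.3}, n=300, seed=seed,
            )
            sel = select_lag(gen_var_panel(truth), max_p=5, cap=5)
            hits += sel.chosen == 2
        assert hits >= 30  # >= 60% of seeds

    def test_cap_rule_fires_when_argmin_exceeds_cap(self):
        truth = SyntheticTruth(
            variables=("X", "Y"), edges=(("X", "Y", 5, 0.7),),
            ar={"X": 0.3, "Y": 0.2}, n=400, seed=1,
        )
        panel = gen_var_panel(truth)
        sel = select_lag(panel, max_p=6, cap=3)
        assert sel.argmin == 5
        assert sel.cap_applied and sel.chosen == 3

    def test_aic_invariant_to_variable_ordering(self, trivariate_panel):
        a = select_lag(trivariate_panel, max_p=4)
        b = select_lag(trivariate_panel.subset(("Y", "X", "M")), max_p=4)
        for p in a.values:
            assert a.values[p] == pytest.approx(b.values[p], abs=1e-10)
        assert a.chosen == b.chosen


class TestVif:
    def test_orthogonal_series_give_one(self):
        x = np.array([1.0, 1.0, -1.0, -1.0])
        y = np.array([1.0, -1.0, 1.0, -1.0])
        assert abs(np.corrcoef(x, y)[0, 1]) < 1e-12
        assert vif_pair(x, y) == pytest.approx(1.0)

    def test_near_collinear_blows_up(self, rng):
        x = rng.standard_normal(100)
        y = x + 1e-6 * rng.standard_normal(100)
        assert vif_pair(x, y) > 1e4

    def test_matches_closed_form(self, rng):
        x = rng.standard_normal(50)
        y = 0.7 * x + rng.standard_normal(50)
        r2 = np.corrcoef(x, y)[0, 1] ** 2
        assert vif_pair(x, y) == pytest.approx(1.0 / (1.0 - r2))
        assert vif_pair(x, y) == pytest.approx(vif_pair(y, x))

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            vif_pair(np.ones(10), np.arange(10.0))


class TestRecursiveResiduals:
    def test_exact_linear_data_gives_zeros(self):
        x = np.arange(30.0)
        y = 2.0 + 3.0 * x
        w = recursive_residuals(y, np.column_stack([np.ones(30), x]))
        assert w.size == 28
        np.testing.assert_allclose(w, 0.0, atol=1e-8)

    def test_unit_variance_under_stable_model(self):
        ok = 0
        for seed in range(60):
            rng = np.random.default_rng(seed)
            X = np.column_stack([np.ones(200), rng.standard_normal((200, 2))])
            y = X @ np.array([1.0, 0.5, -0.3]) + rng.standard_normal(200)
            w = recursive_residuals(y, X)
            ok += 0.8 <= w.var() <= 1.2
        assert ok >= 54  # >= 90% of seeds

    def test_mean_shift_pushes_post_break_residuals_up(self):
        rng = np.random.default_rng(5)
        X = np.column_stack([np.ones(100)])
        y = rng.standard_normal(100)
        y[50:] += 3.0
        w = recursive_residuals(y, X)
        assert w[49:].mean() > 0

    def test_matches_statsmodels_on_fixture(self, rng):
        import statsmodels.api as sm
        from statsmodels.stats.diagnostic import recursive_olsresiduals

        X = np.column_stack([np.ones(40), rng.standard_normal(40)])
        y = X @ np.array([0.5, 1.0]) + rng.standard_normal(40)
        w = recursive_residuals(y, X)
        res = sm.OLS(y, X).fit()
        rresid = recursive_olsresiduals(res, skip=2)[4]  # scaled recursive residuals
        np.testing.assert_allclose(w, rresid[2:], atol=1e-8)
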