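"""Lag-augmented Wald causality tests."""

import numpy as np
import pytest

from tycausal.causality import TYSpec, run_hypothesis_battery, ty_joint_with_submodels, ty_test
from tycausal.synthetic import SyntheticTruth, gen_var_panel
from tycausal.var import build_lag_design


def _wald_oracle(panel, outcome, causes, p, dmax):
    """Brute-force quadratic form (R b)' [R V R']^{-1} (R b), assembled
    explicitly from the lagged design — independent of the tested path."""
    names = (outcome, *causes)
    Y = np.vstack([panel.series(n) for n in names])
    k = p + dmax
    X, Z = build_lag_design(Y, k)
    y = Z[0]
    beta = np.linalg.solve(X.T @ X, X.T @ y)
    resid = y - X @ beta
    s2 = resid @ resid / (len(y) - X.shape[1])
    V = s2 * np.linalg.inv(X.T @ X)
    m = len(names)
    idx = [1 + (lag - 1) * m + names.index(c) for c in causes for lag in range(1, p + 1)]
    R = np.zeros((len(idx), len(beta)))
    for row, j in enumerate(idx):
        R[row, j] = 1.0
    rb = R @ beta
    return float(rb @ np.linalg.solve(R @ V @ R.T, rb)), len(idx)


class TestTyTest:
    def test_matches_matrix_algebra_oracle_on_fixture(self, bivariate_panel):
        res = ty_test(bivariate_panel, TYSpec(outcome="Y", cause_blocks=(("X",),), p=2, dmax=1))
        w, df = _wald_oracle(bivariate_panel, "Y", ("X",), p=2, dmax=1)
        assert res.chi2 == pytest.approx(w, abs=1e-8)
        assert res.df == df == 2

    def test_df_is_p_times_restricted_variables(self, trivariate_panel):
        res = ty_test(trivariate_panel, TYSpec(outcome="Y", cause_blocks=(("X", "M"),), p=3, dmax=1))
        assert res.df == 6

    def test_zero_restricted_coefficients_give_zero_statistic(self, rng):
        # construct the cause so its lag column is orthogonal (in sample) to
        # the intercept, the outcome's own lag, and the outcome target: the
        # restricted OLS coefficient is then exactly zero, hence W = 0, p = 1
        n = 40
        y = rng.standard_normal(n)
        others = np.column_stack([np.ones(n - 1), y[:-1], y[1:]])
        raw = rng.standard_normal(n - 1)
        x_lag = raw - others @ np.linalg.lstsq(others, raw, rcond=None)[0]
        x = np.append(x_lag, 0.0)
        from tycausal.panel import AnnualPanel

        panel = AnnualPanel(tuple(range(2000, 2000 + n)), ("Y", "X"), np.vstack([y, x]))
        res = ty_test(panel, TYSpec(outcome="Y", cause_blocks=(("X",),), p=1, dmax=0))
        assert res.chi2 == pytest.approx(0.0, abs=1e-8)
        assert res.p_value == pytest.approx(1.0)

    def test_dmax0_equals_granger_wald_from_statsmodels(self, bivariate_panel):
        """Augmentation off: the statistic reduces to the standard
        Granger-Wald test (independent implementation)."""
        from statsmodels.tsa.api import VAR

        res = ty_test(bivariate_panel, TYSpec(outcome="Y", cause_blocks=(("X",),), p=2, dmax=0))
        sm_fit = VAR(bivariate_panel.to_frame()).fit(2, trend="c")
        sm_res = sm_fit.test_causality("Y", ["X"], kind="wald")
        assert res.chi2 == pytest.approx(float(sm_res.test_statistic), abs=1e-8)

    def test_augmentation_lags_never_restricted(self, bivariate_panel):
        """df depends on p only, not dmax, and the statistic changes when
        augmentation enters the fit."""
        r0 = ty_test(bivariate_panel, TYSpec(outcome="Y", cause_blocks=(("X",),), p=2, dmax=0))
        r1 = ty_test(bivariate_panel, TYSpec(outcome="Y", cause_blocks=(("X",),), p=2, dmax=1))
        assert r0.df == r1.df == 2
        assert r0.chi2 != pytest.approx(r1.chi2)

    def test_power_on_strong_link(self):
        hits = 0
        for seed in range(50):
            truth = SyntheticTruth(
                variables=("X", "Y"), edges=(("X", "Y", 1, 0.8),),
                ar={"X": 0.5, "Y": 0.1}, n=100, seed=seed,
            )
            panel = gen_var_panel(truth)
            res = ty_test(panel, TYSpec(outcome="Y", cause_blocks=(("X",),)), cap=3)
            hits += res.reject
        assert hits >= 45  # >= 90%


class TestJointWithSubmodels:
    def test_single_cause_degenerates_to_simple_test(self, bivariate_panel):
        trio = ty_joint_with_submodels(bivariate_panel, "Y", ("X",), p=2, dmax=1)
        simple = ty_test(bivariate_panel, TYSpec(outcome="Y", cause_blocks=(("X",),), p=2, dmax=1))
        assert trio["joint"].chi2 == pytest.approx(simple.chi2, abs=1e-10)
        assert trio["sub_X"].chi2 == pytest.approx(simple.chi2, abs=1e-10)

    def test_all_three_share_one_fitted_var(self, trivariate_panel):
        trio = ty_joint_with_submodels(trivariate_panel, "Y", ("X", "M"), p=2, dmax=0)
        assert trio["joint"].fit is trio["sub_X"].fit is trio["sub_M"].fit
        assert trio["joint"].df == 4
        assert trio["sub_X"].df == trio["sub_M"].df == 2

    def test_joint_matches_oracle(self, trivariate_panel):
        trio = ty_joint_with_submodels(trivariate_panel, "Y", ("X", "M"), p=2, dmax=1)
        w, df = _wald_oracle(trivariate_panel, "Y", ("X", "M"), p=2, dmax=1)
        assert trio["joint"].chi2 == pytest.approx(w, abs=1e-8)

    def test_only_x_drives_outcome(self):
        """DGP with X -> Y only: joint and X-submodel reject, Z-submodel
        keeps approximately nominal size."""
        joint_hits = sub_x_hits = sub_z_hits = 0
        n_seeds = 40
        for seed in range(n_seeds):
            truth = SyntheticTruth(
                variables=("X", "Z", "Y"), edges=(("X", "Y", 1, 0.8),),
                ar={"X": 0.5, "Z": 0.5, "Y": 0.1}, n=150, seed=seed,
            )
            panel = gen_var_panel(truth)
            trio = ty_joint_with_submodels(panel, "Y", ("X", "Z"), cap=3)
            joint_hits += trio["joint"].reject
            sub_x_hits += trio["sub_X"].reject
            sub_z_hits += trio["sub_Z"].reject
        assert joint_hits / n_seeds >= 0.8
        assert sub_x_hits / n_seeds >= 0.8
        assert sub_z_hits / n_seeds <= 0.15


class TestBattery:
    def test_results_follow_registry_order(self, trivariate_panel):
        registry = [
            TYSpec(outcome="M", cause_blocks=(("X",),), name="a"),
            TYSpec(outcome="Y", cause_blocks=(("M",),), name="b"),
        ]
        results = run_hypothesis_battery(trivariate_panel, registry)
        assert [r.spec.name for r in results] == ["a", "b"]
        assert all(r.error is None for r in results)

    def test_per_spec_failure_recorded_and_battery_continues(self, bivariate_panel):
        registry = [
            TYSpec(outcome="Y", cause_blocks=(("X",),), p=1, dmax=0),
            TYSpec(outcome="Y", cause_blocks=(("missing",),), p=1, dmax=0),
        ]
        results = run_hypothesis_battery(bivariate_panel, registry)
        assert results[0].error is None
        assert results[1].error is not None and np.isnan(results[1].chi2)

    def test_empty_registry_is_an_error(self, bivariate_panel):
        with pytest.raises(ValueError, match="empty"):
            run_hypothesis_battery(bivariate_panel, [])


class TestSpecValidation:
    def test_outcome_cannot_be_a_cause(self):
        with pytest.raises(ValueError):
            TYSpec(outcome="Y", cause_blocks=(("Y",),))

    def test_p_must_be_positive(self):
        with pytest.raises(ValueError):
            TYSpec(outcome="Y", cause_blocks=(("X",),), p=0)
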