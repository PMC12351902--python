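"""Structural-break and CUSUM stability tests."""

import itertools

import numpy as np
import pytest

from tycausal.stability import bai_perron, cusum_test
from tycausal.synthetic import gen_break_regression
from tycausal.var import VarError


def _brute_force_single_break(y, X, h):
    """Enumerate every admissible single-break partition; return min SSR."""

    def ssr(i, j):
        Xs, ys = X[i : j + 1], y[i : j + 1]
        b, *_ = np.linalg.lstsq(Xs, ys, rcond=None)
        r = ys - Xs @ b
        return float(r @ r)

    n = len(y)
    best = np.inf
    best_split = None
    for s in range(h - 1, n - h):
        v = ssr(0, s) + ssr(s + 1, n - 1)
        if v < best:
            best, best_split = v, s
    return best, best_split


class TestBaiPerron:
    def test_chosen_partition_beats_every_enumerated_alternative(self):
        """Oracle equivalence on n <= 25: the DP single-break partition has
        the SSR of the brute-force enumeration, exactly."""
        for seed in range(5):
            y, X, _ = gen_break_regression(24, 12, 3.0, seed=seed)
            h = max(int(np.ceil(0.15 * 24)), X.shape[1] + 1)
            report = bai_perron(y, X, max_breaks=1, trim=0.15)
            best_ssr, best_split = _brute_force_single_break(y, X, h)
            if report.n_breaks == 1:
                assert report.ssr == pytest.approx(best_ssr, abs=1e-9)
                assert report.break_indices[0] == best_split

    def test_noiseless_stable_data_has_zero_supf_and_no_breaks(self):
        x = np.linspace(-1, 1, 60)
        y = 1.0 + 2.0 * x
        X = np.column_stack([np.ones(60), x])
        report = bai_perron(y, X, max_breaks=2)
        assert report.n_breaks == 0
        assert report.supf.get(1, 0.0) == 0.0

    def test_planted_5sigma_break_localized(self):
        hits = 0
        for seed in range(40):
            y, X, _ = gen_break_regression(100, 50, 5.0, seed=seed)
            report = bai_perron(y, X, max_breaks=2)
            ok = report.n_breaks >= 1 and any(abs(b - 49) <= 2 for b in report.break_indices)
            hits += ok
        assert hits / 40 >= 0.8

    def test_no_shift_keeps_nominal_size(self):
        false_alarms = 0
        for seed in range(40):
            y, X, _ = gen_break_regression(100, 50, 0.0, seed=seed)
            false_alarms += bai_perron(y, X, max_breaks=2, alpha=0.10).n_breaks > 0
        assert false_alarms / 40 <= 0.25  # 10% nominal + Monte Carlo slack

    def test_break_years_mapped_through_calendar(self):
        y, X, _ = gen_break_regression(40, 20, 6.0, seed=3)
        years = list(range(1983, 2023))
        report = bai_perron(y, X, max_breaks=1, years=years)
        if report.n_breaks:
            assert report.break_years[0] == years[report.break_indices[0]]

    def test_infeasible_trimming_rejected(self):
        y, X, _ = gen_break_regression(30, 15, 1.0, seed=0)
        with pytest.raises(VarError, match="infeasible"):
            bai_perron(y, X, max_breaks=8, trim=0.15)

    def test_two_breaks_found_when_planted(self):
        rng = np.random.default_rng(7)
        n = 150
        x = rng.standard_normal(n)
        b = np.where(np.arange(n) < 50, 1.0, np.where(np.arange(n) < 100, 6.0, 1.0))
        y = b * x + rng.standard_normal(n)
        X = np.column_stack([np.ones(n), x])
        report = bai_perron(y, X, max_breaks=3)
        assert report.n_breaks == 2


class TestCusum:
    def test_final_cusum_point_is_scaled_residual_sum(self):
        """Closed form: the last path value equals sum(w)/sd(w)."""
        rng = np.random.default_rng(1)
        X = np.column_stack([np.ones(80), rng.standard_normal(80)])
        y = X @ np.array([1.0, 0.5]) + rng.standard_normal(80)
        from tycausal.var import recursive_residuals

        w = recursive_residuals(y, X)
        report = cusum_test(y, X, variant="CUSUM")
        assert report.path[-1] == pytest.approx(w.sum() / np.std(w, ddof=1), abs=1e-10)

    def test_noiseless_exact_fit_path_is_null_and_not_crossed(self):
        x = np.arange(50.0)
        y = 3.0 + 0.5 * x
        X = np.column_stack([np.ones(50), x])
        for variant in ("CUSUM", "CUSUM-SQ"):
            report = cusum_test(y, X, variant=variant)
            assert not report.crossed
            assert report.p_value == pytest.approx(1.0)
        sq = cusum_test(y, X, variant="CUSUM-SQ")
        np.testing.assert_allclose(sq.path, np.arange(1, 49) / 48)

    def test_crossed_iff_path_outside_bounds(self):
        rng = np.random.default_rng(9)
        X = np.column_stack([np.ones(100), rng.standard_normal(100)])
        y = X @ np.array([0.0, 1.0]) + rng.standard_normal(100)
        y[60:] += 4.0
        for variant in ("CUSUM", "CUSUM-SQ"):
            r = cusum_test(y, X, variant=variant)
            outside = bool(np.any((r.path < r.lower) | (r.path > r.upper)))
            assert r.crossed == outside

    def test_stable_model_keeps_size(self):
        crossings = 0
        n_seeds = 100
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            X = np.column_stack([np.ones(200), rng.standard_normal(200)])
            y = X @ np.array([1.0, 0.5]) + rng.standard_normal(200)
            crossings += cusum_test(y, X, variant="CUSUM", level=0.05).crossed
        assert crossings / n_seeds <= 0.10

    def test_variance_doubling_detected_by_cusum_sq(self):
        hits = 0
        n_seeds = 40
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            X = np.column_stack([np.ones(200), rng.standard_normal(200)])
            noise = rng.standard_normal(200)
            noise[100:] *= 2.0  # variance quadruples; sd doubles
            y = X @ np.array([1.0, 0.5]) + noise
            hits += cusum_test(y, X, variant="CUSUM-SQ", level=0.05).crossed
        assert hits / n_seeds >= 0.8

    def test_unknown_variant_rejected(self):
        with pytest.raises(ValueError, match="variant"):
            cusum_test(np.arange(30.0), np.ones((30, 1)), variant="MOSUM")
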