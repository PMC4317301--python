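"""Two-segment model, breakpoint scan, selection rule and segment fits."""

import numpy as np
import pytest

from memnet.segmented import (
    BreakpointScanResult,
    candidate_grid,
    fit_segment_regressions,
    fit_two_segment,
    scan_breakpoints,
    select_breakpoint,
)


def _hinge_data(rng, n=90, psi=-0.3, slope=1.0, noise=0.0):
    x = rng.standard_normal(n)
    y = slope * np.minimum(x - psi, 0.0) + noise * rng.standard_normal(n)
    return x, y


class TestTwoSegment:
    def test_pure_linear_data_gives_zero_delta(self, rng):
        x = rng.standard_normal(80)
        y = 2.0 + 1.5 * x
        for psi in (-0.5, 0.0, 0.5):
            fit = fit_two_segment(x, y, psi)
            assert fit.delta == pytest.approx(0.0, abs=1e-9)

    def test_perfect_hinge_recovered_exactly(self, rng):
        x, y = _hinge_data(rng, psi=-0.3, slope=1.0, noise=0.0)
        fit = fit_two_segment(x, y, -0.3)
        assert fit.beta1 == pytest.approx(1.0, abs=1e-9)
        assert fit.delta == pytest.approx(-1.0, abs=1e-9)
        X = np.column_stack([np.ones(x.size), x, np.maximum(x + 0.3, 0)])
        rss = ((y - X @ [fit.beta0, fit.beta1, fit.delta]) ** 2).sum()
        assert rss == pytest.approx(0.0, abs=1e-12)
        assert fit.p_delta == pytest.approx(0.0, abs=1e-12)

    def test_twelve_point_toy_matches_normal_equations(self):
        rng = np.random.default_rng(11)
        x = np.linspace(-2, 2, 12)
        y = rng.standard_normal(12)
        psi = 0.1
        fit = fit_two_segment(x, y, psi, min_seg=3)
        X = np.column_stack([np.ones(12), x, np.maximum(x - psi, 0)])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        assert (fit.beta0, fit.beta1, fit.delta) == pytest.approx(tuple(beta), rel=1e-10)

    def test_short_side_rejected(self, rng):
        x = rng.standard_normal(30)
        with pytest.raises(ValueError, match="need >= 10"):
            fit_two_segment(x, x, np.sort(x)[2])


class TestScan:
    def test_default_grid_has_120_candidates(self, rng):
        x, y = _hinge_data(rng, noise=1.0)
        scan = scan_breakpoints(x, y)
        assert scan.candidates.size == 120
        assert scan.slope_diff_p.size == 120
        assert np.all(scan.n_low + scan.n_high == 90)
        assert np.all(scan.n_low >= 10) and np.all(scan.n_high >= 10)

    def test_grid_feasible_with_heavy_ties(self):
        x = np.repeat([0.0, 1, 2, 3, 4, 5], 15)  # 90 values, 6 distinct
        grid = candidate_grid(x, 120, 10)
        for psi in grid:
            assert np.sum(x <= psi) >= 10 and np.sum(x > psi) >= 10

    def test_infeasible_scan_errors(self, rng):
        with pytest.raises(ValueError, match="min_seg"):
            scan_breakpoints(rng.standard_normal(15), rng.standard_normal(15))

    def test_p_profile_invariant_to_affine_y(self, rng):
        x, y = _hinge_data(rng, noise=0.7)
        a = scan_breakpoints(x, y)
        b = scan_breakpoints(x, 3.5 * y - 200.0)
        assert np.allclose(a.slope_diff_p, b.slope_diff_p, atol=1e-10)

    def test_null_data_rarely_yields_selection(self):
        hits = 0
        for seed in range(40):
            rng = np.random.default_rng(seed)
            x = rng.standard_normal(90)
            y = 0.5 * x + rng.standard_normal(90)  # pure linear, no break
            if select_breakpoint(scan_breakpoints(x, y)) is not None:
                hits += 1
        # 120 correlated tests inflate the family-wise rate above .05, but
        # a selection should still be the minority outcome
        assert hits < 20

    def test_free_lines_model_available(self, rng):
        x, y = _hinge_data(rng, noise=0.7)
        scan = scan_breakpoints(x, y, model="free")
        assert scan.model == "free"
        assert scan.candidates.size == 120


class TestSelect:
    def _scan(self, psis, pvals, n_low, n_total=90, alpha=0.05):
        n_low = np.asarray(n_low)
        return BreakpointScanResult(
            np.asarray(psis, dtype=float),
            np.asarray(pvals),
            n_low,
            n_total - n_low,
            alpha,
            "hinge",
        )

    def test_most_even_split_wins(self):
        scan = self._scan([-1.0, 0.0, 0.5], [0.01, 0.02, 0.03], [20, 40, 44])
        assert select_breakpoint(scan).psi == 0.5

    def test_empty_significant_set_returns_none(self):
        scan = self._scan([-1.0, 0.0], [0.3, 0.9], [30, 45])
        assert select_breakpoint(scan) is None

    def test_ties_broken_by_smaller_p_then_lower_psi(self):
        scan = self._scan([-0.2, 0.4], [0.04, 0.01], [44, 46])
        assert select_breakpoint(scan).psi == 0.4
        scan = self._scan([-0.2, 0.4], [0.01, 0.01], [44, 46])
        assert select_breakpoint(scan).psi == -0.2

    def test_insignificant_candidates_ignored(self):
        scan = self._scan([-1.0, 0.0], [0.01, 0.3], [25, 45])
        assert select_breakpoint(scan).psi == -1.0


class TestSegmentFits:
    def test_hinge_free_null_gives_small_segment_r2(self, rng):
        x = rng.standard_normal(120)
        y = rng.standard_normal(120)
        low, high, comp = fit_segment_regressions(x, y, float(np.median(x)))
        assert low.r_squared < 0.15 and high.r_squared < 0.15
        assert abs(comp.z_stat) < 2.5

    def test_perfect_low_side_hinge(self, rng):
        x, y = _hinge_data(rng, psi=0.0, slope=1.0, noise=0.0)
        low, high, comp = fit_segment_regressions(x, y, 0.0)
        assert low.r_squared == pytest.approx(1.0)
        assert high.r_squared == pytest.approx(0.0, abs=1e-12)
        assert low.slope == pytest.approx(1.0)

    def test_toy_matches_per_subset_ols_oracle(self):
        rng = np.random.default_rng(3)
        x = np.sort(rng.standard_normal(30))
        y = 0.8 * np.minimum(x, 0) + 0.3 * rng.standard_normal(30)
        low, high, comp = fit_segment_regressions(x, y, 0.0, min_seg=5)
        for fit, mask in ((low, x <= 0), (high, x > 0)):
            X = np.column_stack([np.ones(mask.sum()), x[mask]])
            b = np.linalg.solve(X.T @ X, X.T @ y[mask])
            assert fit.intercept == pytest.approx(b[0], rel=1e-10)
            assert fit.slope == pytest.approx(b[1], rel=1e-10)
            assert fit.n == int(mask.sum())
            assert (fit.df1, fit.df2) == (1, fit.n - 2)
            assert fit.r_squared == pytest.approx(fit.r_signed**2, abs=1e-12)

    def test_segment_f_matches_r2(self, rng):
        x, y = _hinge_data(rng, noise=0.8)
        low, _, _ = fit_segment_regressions(x, y, -0.3)
        expected_f = low.r_squared / (1 - low.r_squared) * low.df2
        assert low.f_stat == pytest.approx(expected_f, rel=1e-10)
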