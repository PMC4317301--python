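"""Stepwise hierarchical regression: entry order and nested fits."""

import numpy as np
import pandas as pd
import pytest

from memnet.association import CorrelationResult
from memnet.hierarchy import fit_hierarchical, order_predictors


def _corr(var, r):
    return CorrelationResult("mem_immediate_z", var, r, 88, 0.01)


class TestOrder:
    def test_largest_magnitude_first(self):
        order = order_predictors(
            [
                _corr("resid_vol_l_dlpfc", 0.23),
                _corr("splenium_fa", 0.28),
                _corr("resid_vol_r_hipp", 0.25),
            ]
        )
        assert order == ["splenium_fa", "resid_vol_r_hipp", "resid_vol_l_dlpfc"]

    def test_negative_correlations_ordered_by_magnitude(self):
        order = order_predictors([_corr("a", -0.5), _corr("b", 0.3)])
        assert order == ["a", "b"]

    def test_ties_broken_alphabetically(self):
        order = order_predictors([_corr("b", 0.3), _corr("a", 0.3), _corr("c", 0.3)])
        assert order == ["a", "b", "c"]

    def test_single_predictor(self):
        assert order_predictors([_corr("splenium_fa", 0.28)]) == ["splenium_fa"]

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            order_predictors([])


def _frame(**cols):
    return pd.DataFrame(cols)


class TestFit:
    def test_single_standardized_predictor_identity(self, rng):
        x = rng.standard_normal(40)
        y = 0.6 * x + 0.8 * rng.standard_normal(40)
        df = _frame(y=y, x=x)
        fit = fit_hierarchical(df, "y", ["x"])
        r = np.corrcoef(x, y)[0, 1]
        step = fit.steps[0]
        assert step.betas[0] == pytest.approx(r, abs=1e-10)
        assert step.r_squared == pytest.approx(r**2, abs=1e-10)
        assert (step.df_model, step.df_resid) == (1, 38)

    def test_orthogonal_predictors_add_r_squared(self, rng):
        n = 64
        # centered, exactly orthogonal predictors via Gram-Schmidt
        x1 = rng.standard_normal(n)
        x1 = x1 - x1.mean()
        x2 = rng.standard_normal(n)
        x2 = x2 - x2.mean()
        x2 = x2 - (x1 @ x2) / (x1 @ x1) * x1
        y = 3 * x1 + 1 * x2 + 0.5 * rng.standard_normal(n)
        y = y - y.mean()
        df = _frame(y=y, a=x1, b=x2)
        fit = fit_hierarchical(df, "y", ["a", "b"])
        r1 = np.corrcoef(df.a, y)[0, 1]
        r2 = np.corrcoef(df.b, y)[0, 1]
        assert fit.steps[1].r_squared == pytest.approx(r1**2 + r2**2, abs=1e-6)

    def test_ten_row_toy_matches_normal_equations(self):
        rng = np.random.default_rng(5)
        x1 = rng.standard_normal(10)
        x2 = rng.standard_normal(10)
        y = 1.0 + 0.5 * x1 - 0.3 * x2 + 0.2 * rng.standard_normal(10)
        df = _frame(y=y, x1=x1, x2=x2)
        fit = fit_hierarchical(df, "y", ["x1", "x2"])

        def z(v):
            return (v - v.mean()) / v.std(ddof=1)

        X = np.column_stack([np.ones(10), z(x1), z(x2)])
        beta = np.linalg.solve(X.T @ X, X.T @ z(y))
        assert fit.steps[1].betas == pytest.approx(tuple(beta[1:]), abs=1e-10)
        yhat = X @ beta
        zy = z(y)
        r2 = 1 - ((zy - yhat) ** 2).sum() / ((zy - zy.mean()) ** 2).sum()
        assert fit.steps[1].r_squared == pytest.approx(r2, abs=1e-10)

    def test_final_r_squared_invariant_to_entry_order(self, paper_matrix):
        preds = ["splenium_fa", "resid_vol_r_hipp", "resid_vol_l_dlpfc"]
        a = fit_hierarchical(paper_matrix, "mem_immediate_z", preds, sample="listwise")
        b = fit_hierarchical(
            paper_matrix, "mem_immediate_z", preds[::-1], sample="listwise"
        )
        assert a.steps[-1].r_squared == pytest.approx(b.steps[-1].r_squared, abs=1e-10)

    def test_listwise_delta_r_squared_nonnegative(self, paper_matrix):
        preds = ["splenium_fa", "resid_vol_r_hipp", "resid_vol_l_dlpfc"]
        fit = fit_hierarchical(paper_matrix, "mem_immediate_z", preds, sample="listwise")
        assert all(s.delta_r_squared >= -1e-12 for s in fit.steps)
        r2s = [s.r_squared for s in fit.steps]
        assert r2s == sorted(r2s)

    def test_per_step_df_trajectory_tracks_block_ns(self, paper_matrix):
        """Entering splenium FA, then right hippocampus, then left DLPFC
        shrinks the per-step complete-case sample with each QC block."""
        preds = ["splenium_fa", "resid_vol_r_hipp", "resid_vol_l_dlpfc"]
        fit = fit_hierarchical(paper_matrix, "mem_immediate_z", preds, sample="per_step")
        ns = [s.n for s in fit.steps]
        assert ns[0] >= ns[1] >= ns[2]
        for step, k in zip(fit.steps, range(1, 4)):
            assert (step.df_model, step.df_resid) == (k, step.n - k - 1)

    def test_collinear_predictors_rejected(self, rng):
        x = rng.standard_normal(20)
        df = _frame(y=rng.standard_normal(20), a=x, b=2 * x)
        with pytest.raises(ValueError, match="collinear"):
            fit_hierarchical(df, "y", ["a", "b"])


def test_final_immediate_r2_band_across_seeds():
    """Across 200 synthetic cohorts at default effects, the final-step R^2
    for Immediate recall falls in a band around the emulated value (.16
    +/- .10) in at least 60% of seeds."""
    from memnet import preprocess
    from memnet.association import correlation_screen
    from memnet.synthetic import make_fixture

    candidates = ("splenium_fa", "resid_vol_r_hipp", "resid_vol_l_dlpfc")
    in_band = total = 0
    for seed in range(200):
        matrix, _ = preprocess.build_analysis_matrix(
            make_fixture("paper_like", seed=seed)
        )
        sig = [
            c
            for c in correlation_screen(matrix, outcomes=("mem_immediate_z",))
            if c.var_y in candidates and c.error is None and c.p < 0.05
        ]
        if not sig:
            continue
        fit = fit_hierarchical(matrix, "mem_immediate_z", order_predictors(sig))
        total += 1
        in_band += 0.06 < fit.steps[-1].r_squared < 0.26
    assert total > 150
    assert in_band / total >= 0.60
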