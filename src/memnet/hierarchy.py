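"""Hierarchical stepwise regression of memory composites on network variables.

Predictors enter in order of their group-level correlation magnitude
(largest first); each step refits OLS with one more predictor and reports
standardized betas, model F with its df pair, R-squared and the increment
over the previous step.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from memnet.association import CorrelationResult
from memnet.preprocess import zscore


@dataclass
class HierarchicalStep:
    predictors: tuple[str, ...]
    betas: tuple[float, ...]  # standardized
    f_stat: float
    df_model: int
    df_resid: int
    r_squared: float
    delta_r_squared: float
    p: float
    n: int


@dataclass
class HierarchicalFit:
    outcome: str
    entry_order: tuple[str, ...]
    steps: list[HierarchicalStep]
    sample: str  # "per_step" or "listwise"


def order_predictors(correlations: list[CorrelationResult]) -> list[str]:
    """Entry order: |r| descending, ties broken alphabetically by label."""
    if not correlations:
        raise ValueError("no predictors to order")
    return [
        c.var_y
        for c in sorted(correlations, key=lambda c: (-abs(c.r), c.var_y))
    ]


def fit_hierarchical(
    matrix: pd.DataFrame,
    outcome: str,
    predictors: list[str],
    sample: str = "per_step",
) -> HierarchicalFit:
    """Fit the stepwise hierarchy of nested OLS models.

    ``sample="per_step"`` uses, at each step, the cases complete on the
    outcome and the predictors entered so far (the sample shrinks as
    predictors with more QC exclusions enter); ``"listwise"`` restricts every
    step to the cases complete on all predictors.
    """
    if sample not in ("per_step", "listwise"):
        raise ValueError(f"unknown sample mode {sample!r}")
    if not predictors:
        raise ValueError("need at least one predictor")

    listwise = matrix[[outcome, *predictors]].dropna()
    steps: list[HierarchicalStep] = []
    prev_r2 = 0.0
    for k in range(1, len(predictors) + 1):
        entered = predictors[:k]
        if sample == "per_step":
            sub = matrix[[outcome, *entered]].dropna()
        else:
            sub = listwise[[outcome, *entered]]
        n = len(sub)
        if n < k + 2:
            raise ValueError(f"step {k}: need >= {k + 2} complete rows, got {n}")
        y = zscore(sub[outcome].to_numpy(float))
        X = np.column_stack([zscore(sub[c].to_numpy(float)) for c in entered])
        if np.linalg.matrix_rank(X) < k:
            raise ValueError(f"collinear predictors among {entered}")
        fit = sm.OLS(y, sm.add_constant(X)).fit()
        steps.append(
            HierarchicalStep(
                predictors=tuple(entered),
                betas=tuple(float(b) for b in fit.params[1:]),
                f_stat=float(fit.fvalue),
                df_model=int(fit.df_model),
                df_resid=int(fit.df_resid),
                r_squared=float(fit.rsquared),
                delta_r_squared=float(fit.rsquared - prev_r2),
                p=float(fit.f_pvalue),
                n=n,
            )
        )
        prev_r2 = float(fit.rsquared)
    return HierarchicalFit(outcome, tuple(predictors), steps, sample)


def hierarchy_to_frame(fit: HierarchicalFit) -> pd.DataFrame:
    """Table mirroring the stepwise layout (betas, F, df, R^2, dR^2, p)."""
    rows = []
    for step in fit.steps:
        row = {"outcome": fit.outcome, "model": " + ".join(step.predictors)}
        for i, b in enumerate(step.betas, start=1):
            row[f"beta{i}"] = b
        row.update(
            F=step.f_stat,
            df=f"{step.df_model}, {step.df_resid}",
            R2=step.r_squared,
            dR2=step.delta_r_squared,
            p=step.p,
            n=step.n,
        )
        rows.append(row)
    return pd.DataFrame(rows)
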