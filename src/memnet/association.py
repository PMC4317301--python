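"""Correlation screen and correlation-comparison tests.

Two comparison procedures are provided: Williams' t (df = n - 3) for two
dependent correlations sharing one variable — used for the lateralization
questions (is the memory association stronger on the left DLPFC than the
right? stronger in the splenium than the genu?) — and Fisher's r-to-z for
correlations from disjoint subgroups, used to compare segment-level
associations on either side of a breakpoint.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from memnet.preprocess import MEMORY_COMPOSITES, MRI_VARIABLES


@dataclass
class CorrelationResult:
    var_x: str
    var_y: str
    r: float
    n: int
    p: float
    trend: bool = False  # .05 < p < .08
    error: str | None = None


@dataclass
class DependentComparison:
    r_jk: float
    r_jh: float
    r_kh: float
    n: int
    t_stat: float
    df: int
    p: float
    label: str = ""


@dataclass
class IndependentComparison:
    r1: float
    n1: int
    r2: float
    n2: int
    z_stat: float
    p: float


def pearson_with_p(
    x: np.ndarray, y: np.ndarray, var_x: str = "x", var_y: str = "y"
) -> CorrelationResult:
    """Pairwise-complete Pearson correlation with a two-sided t-based p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    n = int(ok.sum())
    if n < 3:
        raise ValueError(f"need >= 3 complete pairs for {var_x} ~ {var_y}, got {n}")
    if np.ptp(x[ok]) == 0 or np.ptp(y[ok]) == 0:
        raise ValueError(f"constant input in {var_x} ~ {var_y}")
    r, p = stats.pearsonr(x[ok], y[ok])
    return CorrelationResult(
        var_x, var_y, float(r), n, float(p), trend=bool(0.05 < p < 0.08)
    )


def williams_dependent_test(
    r_jk: float, r_jh: float, r_kh: float, n: int, label: str = ""
) -> DependentComparison:
    """Williams' t for two dependent correlations sharing variable j.

    t = (r_jk - r_jh) * sqrt[ (n-1)(1 + r_kh) /
        ( 2 |R| (n-1)/(n-3) + rbar^2 (1 - r_kh)^3 ) ],   df = n - 3,

    where |R| is the determinant of the 3x3 correlation matrix and
    rbar = (r_jk + r_jh)/2.
    """
    for name, r in (("r_jk", r_jk), ("r_jh", r_jh), ("r_kh", r_kh)):
        if not abs(r) < 1:
            raise ValueError(f"|{name}| must be < 1, got {r}")
    if n < 4:
        raise ValueError(f"need n >= 4, got {n}")
    det = 1 - r_jk**2 - r_jh**2 - r_kh**2 + 2 * r_jk * r_jh * r_kh
    if det < -1e-12:
        raise ValueError(
            f"correlation triple not positive semi-definite (determinant {det:.6g})"
        )
    det = max(det, 0.0)
    rbar = (r_jk + r_jh) / 2
    denom = 2 * det * (n - 1) / (n - 3) + rbar**2 * (1 - r_kh) ** 3
    t = (r_jk - r_jh) * np.sqrt((n - 1) * (1 + r_kh) / denom)
    df = n - 3
    p = 2 * stats.t.sf(abs(t), df)
    return DependentComparison(r_jk, r_jh, r_kh, n, float(t), df, float(p), label)


def fisher_independent_test(r1: float, n1: int, r2: float, n2: int) -> IndependentComparison:
    """Fisher r-to-z comparison of correlations from two independent samples.

    z = (atanh r1 - atanh r2) / sqrt(1/(n1-3) + 1/(n2-3)), two-sided p.
    """
    for name, r in (("r1", r1), ("r2", r2)):
        if not abs(r) < 1:
            raise ValueError(f"|{name}| must be < 1 (infinite transform), got {r}")
    if n1 < 4 or n2 < 4:
        raise ValueError("both samples need n >= 4")
    z = (np.arctanh(r1) - np.arctanh(r2)) / np.sqrt(1 / (n1 - 3) + 1 / (n2 - 3))
    p = 2 * stats.norm.sf(abs(z))
    return IndependentComparison(r1, n1, r2, n2, float(z), float(p))


def correlation_screen(
    matrix: pd.DataFrame,
    outcomes: tuple[str, ...] = MEMORY_COMPOSITES,
    mri_vars: tuple[str, ...] = MRI_VARIABLES,
) -> list[CorrelationResult]:
    """The 2 x 10 grid of memory composites against MRI variables.

    Pairwise complete per cell; a failing cell (constant column, too few
    pairs) is reported with its error message and does not abort the rest.
    """
    results = []
    for outcome in outcomes:
        for var in mri_vars:
            try:
                results.append(
                    pearson_with_p(
                        matrix[outcome].to_numpy(float),
                        matrix[var].to_numpy(float),
                        var_x=outcome,
                        var_y=var,
                    )
                )
            except ValueError as exc:
                results.append(
                    CorrelationResult(outcome, var, np.nan, 0, np.nan, error=str(exc))
                )
    return results


def _joint_complete(matrix: pd.DataFrame, cols: list[str]) -> pd.DataFrame:
    return matrix[cols].dropna()


def lateralization_tests(matrix: pd.DataFrame) -> list[DependentComparison]:
    """Dependent-correlation comparisons of homotopic / homologous measures.

    For each memory composite: left vs right DLPFC residual volume, right vs
    left hippocampus residual volume, and splenium vs genu FA and MD.  Each
    comparison uses the participants jointly complete on the memory composite
    and both compared variables, so the df bookkeeping follows each block's
    own complete-case count.
    """
    pairs = [
        ("dlpfc_l_vs_r", "resid_vol_l_dlpfc", "resid_vol_r_dlpfc"),
        ("hipp_r_vs_l", "resid_vol_r_hipp", "resid_vol_l_hipp"),
        ("fa_splenium_vs_genu", "splenium_fa", "genu_fa"),
        ("md_splenium_vs_genu", "splenium_md", "genu_md"),
    ]
    out = []
    for outcome in MEMORY_COMPOSITES:
        for name, var_k, var_h in pairs:
            sub = _joint_complete(matrix, [outcome, var_k, var_h])
            n = len(sub)
            r_jk = float(np.corrcoef(sub[outcome], sub[var_k])[0, 1])
            r_jh = float(np.corrcoef(sub[outcome], sub[var_h])[0, 1])
            r_kh = float(np.corrcoef(sub[var_k], sub[var_h])[0, 1])
            out.append(
                williams_dependent_test(r_jk, r_jh, r_kh, n, label=f"{outcome}:{name}")
            )
    return out


def screen_to_frame(results: list[CorrelationResult]) -> pd.DataFrame:
    """Tidy frame of screen results (round-trips exactly through TSV)."""
    return pd.DataFrame(
        [
            {
                "var_x": c.var_x,
                "var_y": c.var_y,
                "r": c.r,
                "n": c.n,
                "p": c.p,
                "trend": c.trend,
                "error": c.error or "",
            }
            for c in results
        ]
    )
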