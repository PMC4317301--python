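"""Memory-network integrity composite and low/high performer comparisons.

Each MRI variable significantly associated with memory at the group level
(by default splenium FA, right hippocampus and left DLPFC residual volumes)
is standardized to mean 100, SD 15 — an affine transform, so FA and mm^3
become directly comparable and every downstream t-test is identical to one
on plain z-scores — and averaged per participant.  Participants on either
side of a selected memory breakpoint are then compared with Welch's
unequal-variance t-test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_COMPONENTS = ("splenium_fa", "resid_vol_r_hipp", "resid_vol_l_dlpfc")


@dataclass
class CompositeScore:
    components: tuple[str, ...]
    standardized: pd.DataFrame  # one column per component, mean 100 / SD 15
    composite: pd.Series  # row-mean over available components


@dataclass
class WelchResult:
    mean_low: float
    mean_high: float
    n_low: int
    n_high: int
    t_stat: float  # sign follows mean_low - mean_high
    df: float  # Welch-Satterthwaite, fractional
    p: float


def standardize_100_15(x: np.ndarray) -> np.ndarray:
    """Linear transform to sample mean 100 and SD 15 (n-1) on complete cases."""
    x = np.asarray(x, dtype=float)
    ok = ~np.isnan(x)
    if ok.sum() < 2:
        raise ValueError("need >= 2 non-missing values")
    sd = x[ok].std(ddof=1)
    if sd == 0:
        raise ValueError("constant input cannot be standardized")
    out = np.full_like(x, np.nan)
    out[ok] = 100 + 15 * (x[ok] - x[ok].mean()) / sd
    return out


def composite_network(
    matrix: pd.DataFrame, components: tuple[str, ...] = DEFAULT_COMPONENTS
) -> CompositeScore:
    """Row-mean of the standardized components over those available per row."""
    for label in components:
        if label not in matrix.columns:
            raise ValueError(f"unknown component label {label!r}")
    standardized = pd.DataFrame(
        {c: standardize_100_15(matrix[c].to_numpy(float)) for c in components},
        index=matrix.index,
    )
    composite = standardized.mean(axis=1, skipna=True)
    return CompositeScore(tuple(components), standardized, composite)


def welch_compare(values: np.ndarray, low_mask: np.ndarray) -> WelchResult:
    """Welch's t comparing low (mask True) vs high groups on `values`."""
    values = np.asarray(values, dtype=float)
    low_mask = np.asarray(low_mask, dtype=bool)
    low = values[low_mask & ~np.isnan(values)]
    high = values[~low_mask & ~np.isnan(values)]
    if low.size < 2 or high.size < 2:
        raise ValueError(f"both groups need >= 2 values, got {low.size}/{high.size}")
    v1, v2 = low.var(ddof=1), high.var(ddof=1)
    n1, n2 = low.size, high.size
    se2 = v1 / n1 + v2 / n2
    t = (low.mean() - high.mean()) / np.sqrt(se2)
    df = se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
    p = 2 * stats.t.sf(abs(t), df)
    return WelchResult(
        float(low.mean()), float(high.mean()), n1, n2, float(t), float(df), float(p)
    )


def component_breakdown(
    score: CompositeScore, low_mask: np.ndarray
) -> dict[str, WelchResult]:
    """Welch comparison per standardized component (which region drives the
    composite difference?)."""
    return {
        label: welch_compare(score.standardized[label].to_numpy(float), low_mask)
        for label in score.components
    }
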