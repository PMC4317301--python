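"""Rater-agreement utilities for the manual volumetry.

Intra-class correlation (two-way, absolute agreement, single measures —
McGraw & Wong's ICC(A,1)) and Bland-Altman limits of agreement for repeated
parcellations of the same hemispheres.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class ReliabilityResult:
    icc_agreement: float
    ba_mean: float
    ba_limits: tuple[float, float]
    n_pairs: int


def _as_pairs(ratings: np.ndarray) -> np.ndarray:
    arr = np.asarray(ratings, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("ratings must be an (n, 2) table of paired measurements")
    arr = arr[~np.isnan(arr).any(axis=1)]
    if arr.shape[0] < 3:
        raise ValueError(f"need >= 3 complete rating pairs, got {arr.shape[0]}")
    return arr


def icc_agreement(ratings: np.ndarray) -> float:
    """ICC(A,1) from the two-way mean-squares decomposition.

    ICC = (MSR - MSE) / (MSR + (k-1) MSE + (k/n)(MSC - MSE)) with k = 2
    raters/occasions; absolute agreement, so a constant offset between the
    two columns is penalized.
    """
    arr = _as_pairs(ratings)
    n, k = arr.shape
    grand = arr.mean()
    row_means = arr.mean(axis=1)
    col_means = arr.mean(axis=0)
    ss_total = ((arr - grand) ** 2).sum()
    ss_rows = k * ((row_means - grand) ** 2).sum()
    ss_cols = n * ((col_means - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols
    if ss_total == 0:
        raise ValueError("zero total variance; ICC undefined")
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    return float((msr - mse) / (msr + (k - 1) * mse + k / n * (msc - mse)))


def bland_altman(ratings: np.ndarray) -> tuple[float, tuple[float, float]]:
    """Mean difference and limits of agreement (mean +/- 1.96 SD of diffs)."""
    arr = _as_pairs(ratings)
    diffs = arr[:, 0] - arr[:, 1]
    mean = float(diffs.mean())
    sd = float(diffs.std(ddof=1))
    return mean, (mean - 1.96 * sd, mean + 1.96 * sd)


def reliability_report(ratings: np.ndarray) -> ReliabilityResult:
    arr = _as_pairs(ratings)
    mean, limits = bland_altman(arr)
    return ReliabilityResult(icc_agreement(arr), mean, limits, arr.shape[0])
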