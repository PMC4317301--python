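"""Segmented (breakpoint) regression on the memory axis.

The scan fits, at each of ``grid_size`` candidate breakpoints psi along the
memory z-score axis, a two-segment linear model of residualized volume on
memory and tests whether the slopes of the two segments differ.  The default
model is the continuous hinge parameterization

    y = b0 + b1 * x + delta * (x - psi)_+ + e,

in which ``delta`` is exactly the difference in slope between the segments
joined at psi, and its t-test is the slope-difference test.  A free-lines
variant (two unconstrained lines, Welch-style slope comparison) is available
behind ``model="free"``.  Among candidates with a significant slope
difference, the breakpoint dividing the sample most evenly is selected, and
separate per-segment regressions quantify the association on each side.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from memnet.association import IndependentComparison, fisher_independent_test

DEFAULT_GRID_SIZE = 120
DEFAULT_ALPHA = 0.05
DEFAULT_MIN_SEG = 10


@dataclass
class TwoSegmentModel:
    beta0: float
    beta1: float  # slope below psi
    delta: float  # slope change at psi (slope above = beta1 + delta)
    psi: float
    t_delta: float
    p_delta: float
    n: int


@dataclass
class BreakpointScanResult:
    candidates: np.ndarray
    slope_diff_p: np.ndarray
    n_low: np.ndarray
    n_high: np.ndarray
    alpha: float
    model: str

    @property
    def significant_mask(self) -> np.ndarray:
        return self.slope_diff_p < self.alpha

    @property
    def significant_set(self) -> np.ndarray:
        return self.candidates[self.significant_mask]


@dataclass
class SelectedBreakpoint:
    psi: float
    p: float
    n_low: int
    n_high: int


@dataclass
class SegmentFit:
    side: str  # "low" | "high"
    slope: float
    intercept: float
    r_signed: float
    r_squared: float
    f_stat: float
    df1: int
    df2: int
    p: float
    n: int


def _complete(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    return x[ok], y[ok]


def _side_counts(x: np.ndarray, psi: float) -> tuple[int, int]:
    return int(np.sum(x <= psi)), int(np.sum(x > psi))


def fit_two_segment(
    x: np.ndarray, y: np.ndarray, psi: float, min_seg: int = DEFAULT_MIN_SEG
) -> TwoSegmentModel:
    """OLS on the hinge design {1, x, (x - psi)_+}; tests delta = 0."""
    x, y = _complete(x, y)
    n_low, n_high = _side_counts(x, psi)
    if n_low < min_seg or n_high < min_seg:
        raise ValueError(
            f"breakpoint {psi} leaves segments of {n_low}/{n_high} rows; "
            f"need >= {min_seg} on each side"
        )
    n = x.size
    X = np.column_stack([np.ones(n), x, np.maximum(x - psi, 0.0)])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    df = n - 3
    sigma2 = resid @ resid / df
    cov = sigma2 * np.linalg.inv(X.T @ X)
    se_delta = np.sqrt(cov[2, 2])
    t = beta[2] / se_delta if se_delta > 0 else np.inf * np.sign(beta[2] or 1)
    p = 2 * stats.t.sf(abs(t), df)
    return TwoSegmentModel(
        float(beta[0]), float(beta[1]), float(beta[2]), float(psi), float(t), float(p), n
    )


def _free_lines_p(x: np.ndarray, y: np.ndarray, psi: float) -> float:
    """Slope-difference test with two unconstrained lines (Welch df)."""
    lo = x <= psi
    res_l = stats.linregress(x[lo], y[lo])
    res_h = stats.linregress(x[~lo], y[~lo])
    se2 = res_l.stderr**2 + res_h.stderr**2
    if se2 == 0:
        return 0.0 if res_l.slope != res_h.slope else 1.0
    t = (res_l.slope - res_h.slope) / np.sqrt(se2)
    df = se2**2 / (
        res_l.stderr**4 / (lo.sum() - 2) + res_h.stderr**4 / ((~lo).sum() - 2)
    )
    return float(2 * stats.t.sf(abs(t), df))


def candidate_grid(x: np.ndarray, grid_size: int, min_seg: int) -> np.ndarray:
    """``grid_size`` evenly spaced quantiles of x between its min_seg-th
    smallest and min_seg-th largest values.

    Sides are low: x <= psi, high: x > psi.  Candidates are clamped into
    [x_(min_seg), x_(n-min_seg+1)) — just below the upper order statistic —
    which guarantees at least min_seg rows strictly on each side even when x
    carries ties (composites of integer test scores do).
    """
    x = np.sort(x[~np.isnan(x)])
    n = x.size
    if n < 2 * min_seg:
        raise ValueError(
            f"only {n} complete rows; a scan with min_seg={min_seg} needs >= "
            f"{2 * min_seg} (max feasible grid_size is 0)"
        )
    lo = x[min_seg - 1]
    hi = x[n - min_seg]
    if not lo < hi:
        raise ValueError(
            f"values between the min_seg-th smallest and largest are all tied "
            f"({lo}); no feasible candidate exists (max feasible grid_size is 0)"
        )
    positions = np.linspace(min_seg - 1, n - min_seg, grid_size)
    candidates = np.interp(positions, np.arange(n), x)
    return np.clip(candidates, lo, np.nextafter(hi, lo))


def scan_breakpoints(
    x: np.ndarray,
    y: np.ndarray,
    grid_size: int = DEFAULT_GRID_SIZE,
    alpha: float = DEFAULT_ALPHA,
    min_seg: int = DEFAULT_MIN_SEG,
    model: str = "hinge",
) -> BreakpointScanResult:
    """Profile the slope-difference p-value across candidate breakpoints."""
    if model not in ("hinge", "free"):
        raise ValueError(f"unknown model {model!r}")
    x, y = _complete(x, y)
    candidates = candidate_grid(x, grid_size, min_seg)
    pvals = np.empty(grid_size)
    n_low = np.empty(grid_size, dtype=int)
    n_high = np.empty(grid_size, dtype=int)
    for i, psi in enumerate(candidates):
        n_low[i], n_high[i] = _side_counts(x, psi)
        if model == "hinge":
            pvals[i] = fit_two_segment(x, y, psi, min_seg=min_seg).p_delta
        else:
            pvals[i] = _free_lines_p(x, y, psi)
    return BreakpointScanResult(candidates, pvals, n_low, n_high, alpha, model)


def select_breakpoint(scan: BreakpointScanResult) -> SelectedBreakpoint | None:
    """Among significant candidates, the one dividing the sample most evenly.

    Ties broken by smaller slope-difference p, then lower psi.  Returns
    ``None`` when no candidate is significant — a legitimate outcome (the
    expected one for a region without a differential association), not an
    error.
    """
    mask = scan.significant_mask
    if not mask.any():
        return None
    idx = np.flatnonzero(mask)
    best = min(
        idx,
        key=lambda i: (
            abs(int(scan.n_low[i]) - int(scan.n_high[i])),
            scan.slope_diff_p[i],
            scan.candidates[i],
        ),
    )
    return SelectedBreakpoint(
        float(scan.candidates[best]),
        float(scan.slope_diff_p[best]),
        int(scan.n_low[best]),
        int(scan.n_high[best]),
    )


def _simple_fit(x: np.ndarray, y: np.ndarray, side: str) -> SegmentFit:
    n = x.size
    if np.ptp(x) == 0:
        raise ValueError(f"{side} segment has constant memory scores")
    if np.ptp(y) == 0:
        # a flat response: zero slope, zero variance explained
        return SegmentFit(side, 0.0, float(y[0]), 0.0, 0.0, 0.0, 1, n - 2, 1.0, n)
    res = stats.linregress(x, y)
    r = float(res.rvalue)
    r2 = r * r
    df2 = n - 2
    f = r2 / (1 - r2) * df2 if r2 < 1 else np.inf
    return SegmentFit(
        side,
        float(res.slope),
        float(res.intercept),
        r,
        r2,
        float(f),
        1,
        df2,
        float(res.pvalue),
        n,
    )


def fit_segment_regressions(
    x: np.ndarray, y: np.ndarray, psi: float, min_seg: int = DEFAULT_MIN_SEG
) -> tuple[SegmentFit, SegmentFit, IndependentComparison]:
    """Separate simple regressions within x <= psi and x > psi, plus a
    Fisher r-to-z comparison of the signed segment correlations."""
    x, y = _complete(x, y)
    lo = x <= psi
    n_low, n_high = int(lo.sum()), int((~lo).sum())
    if n_low < min_seg or n_high < min_seg:
        raise ValueError(
            f"breakpoint {psi} leaves segments of {n_low}/{n_high} rows; "
            f"need >= {min_seg} on each side"
        )
    fit_low = _simple_fit(x[lo], y[lo], "low")
    fit_high = _simple_fit(x[~lo], y[~lo], "high")
    if abs(fit_low.r_signed) >= 1 or abs(fit_high.r_signed) >= 1:
        # a noise-free segment makes the r-to-z transform infinite; report
        # the comparison as maximally significant rather than erroring
        sign = 1.0 if fit_low.r_signed >= fit_high.r_signed else -1.0
        comparison = IndependentComparison(
            fit_low.r_signed, n_low, fit_high.r_signed, n_high, sign * np.inf, 0.0
        )
    else:
        comparison = fisher_independent_test(
            fit_low.r_signed, n_low, fit_high.r_signed, n_high
        )
    return fit_low, fit_high, comparison
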