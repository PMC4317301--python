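"""Cohort table -> analysis matrix.

ICV residualization of regional volumes, +/-3 SD winsorization, composite
memory z-scores with a single-test fallback, and per-block complete-case
bookkeeping.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from memnet.synthetic import REGION_LABELS, TRACT_LABELS

MEMORY_COMPOSITES = ("mem_immediate_z", "mem_delayed_z")
MRI_VARIABLES = tuple(f"resid_vol_{r}" for r in REGION_LABELS) + TRACT_LABELS


def residualize_on_icv(volume: np.ndarray, icv: np.ndarray) -> np.ndarray:
    """Unstandardized residuals of OLS ``volume ~ 1 + ICV`` on complete pairs.

    Missing inputs propagate to missing outputs.  The residuals represent a
    region's size relative to its expected size given maximal healthy brain
    size, i.e. the atrophy-sensitive part of the raw volume.
    """
    volume = np.asarray(volume, dtype=float)
    icv = np.asarray(icv, dtype=float)
    ok = ~(np.isnan(volume) | np.isnan(icv))
    if ok.sum() < 3:
        raise ValueError(f"need >= 3 complete (volume, ICV) pairs, got {int(ok.sum())}")
    if np.ptp(icv[ok]) == 0:
        raise ValueError("ICV is constant on complete cases; cannot residualize")
    slope, intercept = np.polyfit(icv[ok], volume[ok], 1)
    out = np.full_like(volume, np.nan)
    out[ok] = volume[ok] - (intercept + slope * icv[ok])
    return out


def winsorize_3sd(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Replace values beyond mean +/- 3 SD with the boundary value.

    Clipping is repeated until the +/-3 SD band (mean and n-1 SD of the
    current non-missing values) is stable, i.e. until no value lies strictly
    outside it.  This makes the operation a projection — applying it twice
    equals applying it once exactly — while for the marginal outliers it is
    meant for (a clipped cell barely moves the moments) the result coincides
    with a single clipping pass to within a small fraction of an SD.  Returns
    the winsorized vector and a boolean flag per replaced cell; the number of
    values is preserved.
    """
    x = np.asarray(x, dtype=float)
    ok = ~np.isnan(x)
    if ok.sum() < 3:
        raise ValueError(f"need >= 3 non-missing values, got {int(ok.sum())}")
    out = x.copy()
    flags = np.zeros(x.shape, dtype=bool)
    for _ in range(100):
        mean = out[ok].mean()
        sd = out[ok].std(ddof=1)
        lo, hi = mean - 3 * sd, mean + 3 * sd
        outside = ok & ((out < lo) | (out > hi))
        if not outside.any():
            break
        flags |= outside
        out[outside] = np.clip(out[outside], lo, hi)
    return out, flags


def zscore(x: np.ndarray) -> np.ndarray:
    """Sample z-scores (n-1 SD) on non-missing values; NaN passes through."""
    x = np.asarray(x, dtype=float)
    ok = ~np.isnan(x)
    if ok.sum() < 2:
        raise ValueError("need >= 2 non-missing values to z-score")
    sd = x[ok].std(ddof=1)
    if sd == 0:
        raise ValueError("constant vector cannot be z-scored")
    out = np.full_like(x, np.nan)
    out[ok] = (x[ok] - x[ok].mean()) / sd
    return out


def composite_memory(lm_z: np.ndarray, vpa_z: np.ndarray) -> np.ndarray:
    """Mean of the two test z-scores; where exactly one is missing, the
    available score is used alone; both missing -> missing."""
    lm_z = np.asarray(lm_z, dtype=float)
    vpa_z = np.asarray(vpa_z, dtype=float)
    stacked = np.vstack([lm_z, vpa_z])
    both_missing = np.isnan(stacked).all(axis=0)
    out = np.full(lm_z.shape, np.nan)
    if not both_missing.all():
        out[~both_missing] = np.nanmean(stacked[:, ~both_missing], axis=0)
    return out


def build_analysis_matrix(
    cohort: pd.DataFrame, winsorize_order: str = "resid_then_winsor"
) -> tuple[pd.DataFrame, dict]:
    """Derive the per-participant analysis matrix from a cohort table.

    Steps: z-score the four raw memory tests on the analysis sample and
    average into Immediate (LM I + VPA I) and Delayed (LM II + VPA II)
    composites; residualize each regional volume on ICV per-region on that
    region's complete cases; winsorize the residualized volumes and tract
    values at +/-3 SD.  ``winsorize_order`` switches to winsorizing raw
    volumes before residualization (``"winsor_then_resid"``).

    Returns the matrix and a provenance dict recording fitted ICV slopes and
    winsorized cells.
    """
    if winsorize_order not in ("resid_then_winsor", "winsor_then_resid"):
        raise ValueError(f"unknown winsorize_order {winsorize_order!r}")
    provenance: dict = {"winsorize_order": winsorize_order, "icv_fits": {}, "winsorized": {}}

    out = pd.DataFrame({"participant_id": cohort["participant_id"]})
    z = {t: zscore(cohort[t].to_numpy(float)) for t in ("lm1", "lm2", "vpa1", "vpa2")}
    out["mem_immediate_z"] = composite_memory(z["lm1"], z["vpa1"])
    out["mem_delayed_z"] = composite_memory(z["lm2"], z["vpa2"])

    icv = cohort["icv"].to_numpy(float)
    for region in REGION_LABELS:
        vol = cohort[f"vol_{region}"].to_numpy(float)
        if winsorize_order == "winsor_then_resid":
            vol, pre_flags = winsorize_3sd(vol)
            resid = residualize_on_icv(vol, icv)
            flags = pre_flags
        else:
            resid = residualize_on_icv(vol, icv)
            resid, flags = winsorize_3sd(resid)
        ok = ~(np.isnan(vol) | np.isnan(icv))
        slope, intercept = np.polyfit(icv[ok], cohort[f"vol_{region}"].to_numpy(float)[ok], 1) if ok.sum() >= 3 else (np.nan, np.nan)
        provenance["icv_fits"][region] = {"slope": float(slope), "intercept": float(intercept)}
        out[f"resid_vol_{region}"] = resid
        out[f"win_resid_vol_{region}"] = flags
        if flags.any():
            provenance["winsorized"][f"resid_vol_{region}"] = np.flatnonzero(flags).tolist()
    for tract in TRACT_LABELS:
        vals, flags = winsorize_3sd(cohort[tract].to_numpy(float))
        out[tract] = vals
        out[f"win_{tract}"] = flags
        if flags.any():
            provenance["winsorized"][tract] = np.flatnonzero(flags).tolist()

    out["left_handed"] = cohort["left_handed"].to_numpy(bool)
    for block in ("frontal", "hipp", "genu", "splenium", "vpa"):
        col = f"qc_fail_{block}"
        if col in cohort.columns:
            out[col] = cohort[col].to_numpy(bool)
    return out, provenance
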