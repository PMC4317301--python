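"""Calibrated synthetic cohort generator.

Emulates the tabular structure of a male cohort of ~90 community-dwelling
adults in their early seventies: four verbal memory test scores (Logical
Memory I/II, Verbal Paired Associates I/II), intracranial volume (ICV), six
manually-parcellated regional volumes (left/right DLPFC, IFG, hippocampus),
four callosal diffusion parameters (genu/splenium FA and MD), handedness, and
per-block quality-control flags.

The generative model is latent-factor based rather than a raw 15x15
covariance: one standard-normal memory factor ``M`` drives all four test
z-scores with equal loadings (so every test pair correlates at
``intertest_r``), and one ICV factor carries a configurable fraction
(``icv_loading``) of each regional volume's variance.  "Network" variables
(splenium FA, right hippocampus, left DLPFC) load on ``M`` so that their
population correlation with both the Immediate and the Delayed memory
composite equals ``network_effect_r``.  The right DLPFC instead relates to
the continuous Immediate memory composite through a hinge: a positive slope
below the breakpoint ``hinge_psi_true`` — calibrated via truncated-normal
moments so the below-hinge correlation equals ``hinge_r_low`` — and zero
slope above it.  The right IFG carries no memory effect at all.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml
from scipy import stats

REGION_LABELS = ("l_dlpfc", "r_dlpfc", "l_ifg", "r_ifg", "l_hipp", "r_hipp")
TRACT_LABELS = ("genu_fa", "genu_md", "splenium_fa", "splenium_md")
TEST_LABELS = ("lm1", "lm2", "vpa1", "vpa2")

#: variables loaded on the memory factor at ``network_effect_r``
NETWORK_VARIABLES = ("splenium_fa", "vol_r_hipp", "vol_l_dlpfc")

QC_BLOCKS = {
    "frontal": ["vol_l_dlpfc", "vol_r_dlpfc", "vol_l_ifg", "vol_r_ifg"],
    "hipp": ["vol_l_hipp", "vol_r_hipp"],
    "genu": ["genu_fa", "genu_md"],
    "splenium": ["splenium_fa", "splenium_md"],
    "vpa": ["vpa1", "vpa2"],
}

COHORT_COLUMNS = (
    ["participant_id"]
    + list(TEST_LABELS)
    + ["icv"]
    + [f"vol_{r}" for r in REGION_LABELS]
    + list(TRACT_LABELS)
    + ["left_handed"]
    + [f"qc_fail_{b}" for b in QC_BLOCKS]
)


@dataclass
class CohortParams:
    """Parameters of the synthetic cohort.

    Defaults reproduce the descriptive moments of the emulated study sample
    (e.g. ICV 1,545,481 (113,685) mm^3) and its reported effect-size targets.
    """

    n_participants: int = 90
    icv_mean: float = 1_545_481.0
    icv_sd: float = 113_685.0
    region_means: dict[str, float] = field(
        default_factory=lambda: {
            "l_dlpfc": 25_064.0,
            "r_dlpfc": 24_477.0,
            "l_ifg": 16_238.0,
            "r_ifg": 15_715.0,
            "l_hipp": 3_079.0,
            "r_hipp": 3_376.0,
        }
    )
    region_sds: dict[str, float] = field(
        default_factory=lambda: {
            "l_dlpfc": 5_644.0,
            "r_dlpfc": 5_410.0,
            "l_ifg": 2_946.0,
            "r_ifg": 3_110.0,
            "l_hipp": 392.0,
            "r_hipp": 412.0,
        }
    )
    tract_means: dict[str, float] = field(
        default_factory=lambda: {
            "genu_fa": 0.40,
            "genu_md": 789.18,
            "splenium_fa": 0.49,
            "splenium_md": 979.63,
        }
    )
    tract_sds: dict[str, float] = field(
        default_factory=lambda: {
            "genu_fa": 0.05,
            "genu_md": 79.14,
            "splenium_fa": 0.07,
            "splenium_md": 183.73,
        }
    )
    # fraction of each regional volume's variance explained by ICV
    icv_loading: float = 0.25
    # (mean, sd, max score) per raw test
    memory_test_moments: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: {
            "lm1": (44.37, 11.43, 75),
            "lm2": (27.62, 8.82, 50),
            "vpa1": (19.88, 7.76, 32),
            "vpa2": (6.09, 2.26, 8),
        }
    )
    intertest_r: float = 0.53
    network_effect_r: float = 0.28
    hinge_psi_true: float = -0.3
    hinge_r_low: float = 0.45
    n_left_handed: int = 8
    missingness_spec: dict[str, int] = field(
        default_factory=lambda: {"frontal": 2, "hipp": 1, "genu": 7, "splenium": 4, "vpa": 1}
    )
    # optional test-retest attenuation (reliability per test), off by default
    measurement_reliability: dict[str, float] | None = None
    seed: int = 0

    def validate(self) -> None:
        if self.n_participants < 1:
            raise ValueError("n_participants must be positive")
        for name, sd in [("icv_sd", self.icv_sd), *self.region_sds.items(), *self.tract_sds.items()]:
            if sd <= 0:
                raise ValueError(f"SD for {name!r} must be > 0")
        if not 0 <= self.icv_loading < 1:
            raise ValueError("icv_loading must be in [0, 1)")
        if not 0 <= self.intertest_r < 1:
            raise ValueError("intertest_r must be in [0, 1) for a common-factor model")
        for name, r in [
            ("network_effect_r", self.network_effect_r),
            ("hinge_r_low", self.hinge_r_low),
        ]:
            if not abs(r) < 1:
                raise ValueError(f"|{name}| must be < 1")
        if self.n_left_handed > self.n_participants:
            raise ValueError("n_left_handed cannot exceed n_participants")
        for block, count in self.missingness_spec.items():
            if block not in QC_BLOCKS:
                raise ValueError(f"unknown missingness block {block!r}")
            if count > self.n_participants:
                raise ValueError(f"missingness count for {block!r} exceeds n_participants")
        # the factor loading required on M so that the memory *composites*
        # correlate with a network variable at network_effect_r
        if abs(self._factor_loading()) >= 1:
            raise ValueError(
                "implied covariance not positive definite: network_effect_r "
                f"({self.network_effect_r}) is unattainable at intertest_r "
                f"({self.intertest_r}); the required factor loading is >= 1"
            )

    # corr(M, composite): composite = mean of two test z-scores
    def _composite_factor_corr(self) -> float:
        lam = self.intertest_r
        return float(np.sqrt(2 * lam / (1 + lam)))

    def _factor_loading(self) -> float:
        return self.network_effect_r / self._composite_factor_corr()

    def composite_sd(self) -> float:
        """Population SD of a two-test composite of unit-variance scores."""
        return float(np.sqrt((1 + self.intertest_r) / 2))


def _hinge_moments(psi: float, s: float) -> tuple[float, float, float]:
    """Population moments of t = (C - psi) * 1[C < psi] for C ~ N(0, s^2).

    Returns (E[t], Var[t], Var[C | C < psi]).
    """
    a = psi / s
    phi, Phi = stats.norm.pdf(a), stats.norm.cdf(a)
    if Phi <= 0:
        raise ValueError("hinge_psi_true is too far below the memory distribution")
    mean_t = s * (-phi - a * Phi)
    ex2 = s**2 * (Phi * (1 + a**2) + a * phi)
    var_t = ex2 - mean_t**2
    var_low = s**2 * (1 - a * phi / Phi - (phi / Phi) ** 2)
    return mean_t, var_t, var_low


def _hinge_slope(params: CohortParams) -> tuple[float, float]:
    """Slope b and residual SD so that, below the hinge, corr(u, C) equals
    hinge_r_low while u keeps unit marginal variance."""
    s = params.composite_sd()
    _, v_all, v_low = _hinge_moments(params.hinge_psi_true, s)
    r = params.hinge_r_low
    denom = v_low * (1 - r**2) + r**2 * v_all
    if denom <= 0:
        raise ValueError(
            "implied covariance not positive definite: hinge_r_low "
            f"({r}) incompatible with hinge_psi_true ({params.hinge_psi_true})"
        )
    b = r / np.sqrt(denom)
    resid_var = 1 - b**2 * v_all
    if resid_var <= 0:
        raise ValueError(
            "implied covariance not positive definite: hinge_r_low "
            f"({r}) with hinge_psi_true ({params.hinge_psi_true}) requires "
            "more than the available unit variance"
        )
    return float(b), float(np.sqrt(resid_var))


def generate_cohort(params: CohortParams) -> pd.DataFrame:
    """Draw one cohort table (no missingness; see :func:`inject_missingness`).

    Deterministic given ``params.seed``.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    n = params.n_participants
    lam = params.intertest_r

    memory_factor = rng.standard_normal(n)
    test_z: dict[str, np.ndarray] = {}
    for test in TEST_LABELS:
        noise = rng.standard_normal(n)
        z = np.sqrt(lam) * memory_factor + np.sqrt(1 - lam) * noise
        if params.measurement_reliability:
            rel = params.measurement_reliability.get(test, 1.0)
            z = np.sqrt(rel) * z + np.sqrt(1 - rel) * rng.standard_normal(n)
        test_z[test] = z
    # continuous Immediate composite drives the hinge (abscissa of the scan)
    comp_imm = 0.5 * (test_z["lm1"] + test_z["vpa1"])

    z_icv = rng.standard_normal(n)
    icv = params.icv_mean + params.icv_sd * z_icv

    loading = params._factor_loading()
    b_hinge, sd_hinge_resid = _hinge_slope(params)
    mean_t, _, _ = _hinge_moments(params.hinge_psi_true, params.composite_sd())

    def network_component() -> np.ndarray:
        return loading * memory_factor + np.sqrt(1 - loading**2) * rng.standard_normal(n)

    residual_parts: dict[str, np.ndarray] = {}
    for region in REGION_LABELS:
        col = f"vol_{region}"
        if col in NETWORK_VARIABLES:
            u = network_component()
        elif region == "r_dlpfc":
            t = np.where(comp_imm < params.hinge_psi_true, comp_imm - params.hinge_psi_true, 0.0)
            u = b_hinge * (t - mean_t) + sd_hinge_resid * rng.standard_normal(n)
        else:
            u = rng.standard_normal(n)
        residual_parts[region] = u

    data: dict[str, object] = {"participant_id": [f"P{i + 1:03d}" for i in range(n)]}
    for test in TEST_LABELS:
        mean, sd, max_score = params.memory_test_moments[test]
        raw = np.rint(mean + sd * test_z[test])
        data[test] = np.clip(raw, 0, max_score)
    data["icv"] = icv
    sqrt_load = np.sqrt(params.icv_loading)
    sqrt_rest = np.sqrt(1 - params.icv_loading)
    for region in REGION_LABELS:
        vol = params.region_means[region] + params.region_sds[region] * (
            sqrt_load * z_icv + sqrt_rest * residual_parts[region]
        )
        data[f"vol_{region}"] = np.maximum(vol, 1.0)
    for tract in TRACT_LABELS:
        if tract in NETWORK_VARIABLES:
            u = network_component()
        else:
            u = rng.standard_normal(n)
        vals = params.tract_means[tract] + params.tract_sds[tract] * u
        if tract.endswith("_fa"):
            vals = np.clip(vals, 1e-3, 1 - 1e-3)
        else:
            vals = np.maximum(vals, 1.0)
        data[tract] = vals

    left = np.zeros(n, dtype=bool)
    left[rng.choice(n, size=params.n_left_handed, replace=False)] = True
    data["left_handed"] = left
    for block in QC_BLOCKS:
        data[f"qc_fail_{block}"] = np.zeros(n, dtype=bool)
    return pd.DataFrame(data, columns=list(COHORT_COLUMNS))


def inject_missingness(
    table: pd.DataFrame, spec: dict[str, int], seed: int = 0
) -> pd.DataFrame:
    """Blank a seeded-random subset of rows per variable block and set the
    matching QC flag.  Block names: frontal, hipp, genu, splenium, vpa."""
    out = table.copy()
    n = len(out)
    rng = np.random.default_rng(seed)
    for block, count in spec.items():
        if block not in QC_BLOCKS:
            raise ValueError(f"unknown missingness block {block!r}")
        if count > n:
            raise ValueError(f"missingness count {count} for {block!r} exceeds {n} rows")
        if count == 0:
            continue
        rows = rng.choice(n, size=count, replace=False)
        for col in QC_BLOCKS[block]:
            out.iloc[rows, out.columns.get_loc(col)] = np.nan
        out.iloc[rows, out.columns.get_loc(f"qc_fail_{block}")] = True
    return out


def make_fixture(scale: str, seed: int = 1) -> pd.DataFrame:
    """Canonical test cohorts.

    ``tiny``: 12 rows, no missingness, 2 left-handers — small enough to check
    by hand.  ``paper_like``: the default 90-row cohort with 8 left-handers
    and block missingness leaving complete-case counts 88/89/83/86.
    """
    if scale == "tiny":
        params = replace(
            CohortParams(),
            n_participants=12,
            n_left_handed=2,
            missingness_spec={},
            seed=seed,
        )
        return generate_cohort(params)
    if scale == "paper_like":
        params = replace(CohortParams(), seed=seed)
        table = generate_cohort(params)
        return inject_missingness(table, params.missingness_spec, seed=seed + 1)
    raise ValueError(f"unknown fixture scale {scale!r}; use 'tiny' or 'paper_like'")


def write_cohort_csv(table: pd.DataFrame, path: str | io.IOBase) -> None:
    """Write the cohort with the fixed documented header; missing cells empty."""
    table.to_csv(path, index=False, na_rep="")


def read_cohort_csv(path: str | io.IOBase) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cohort CSV missing columns: {missing}")
    for col in df.columns:
        if col.startswith("qc_fail_") or col == "left_handed":
            df[col] = df[col].astype(bool)
    return df


def params_from_config(path: str) -> CohortParams:
    """Load :class:`CohortParams` from a YAML/JSON mapping; seed is mandatory."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ValueError("cohort config must be a mapping")
    if "seed" not in raw:
        raise ValueError("cohort config must set an explicit seed")
    if "memory_test_moments" in raw:
        raw["memory_test_moments"] = {
            k: tuple(v) for k, v in raw["memory_test_moments"].items()
        }
    params = CohortParams(**raw)
    params.validate()
    return params
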