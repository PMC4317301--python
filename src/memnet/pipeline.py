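"""End-to-end pipeline: simulate/load -> preprocess -> associate -> model ->
segment -> composite, with artifact persistence and sensitivity re-runs.

Every stage writes a tidy TSV (plus a JSON report collecting the headline
numbers), so a report can be regenerated from the persisted artifacts
without recomputation and every reported value is traceable to a file.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from memnet import association, hierarchy, network, preprocess, segmented, synthetic


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    Either ``input_csv`` (a cohort table on disk) or ``cohort_params``
    (simulate) must be provided.  ``seed`` drives simulation and missingness
    and is mandatory for any stochastic step.
    """

    input_csv: str | None = None
    cohort_params: synthetic.CohortParams | None = None
    outcomes: tuple[str, ...] = preprocess.MEMORY_COMPOSITES
    scan_targets: tuple[str, ...] = ("resid_vol_r_dlpfc", "resid_vol_r_ifg")
    grid_size: int = segmented.DEFAULT_GRID_SIZE
    alpha: float = segmented.DEFAULT_ALPHA
    min_seg: int = segmented.DEFAULT_MIN_SEG
    scan_model: str = "hinge"
    winsorize_order: str = "resid_then_winsor"
    hierarchy_sample: str = "per_step"
    network_candidates: tuple[str, ...] = network.DEFAULT_COMPONENTS
    drop_left_handed: bool = False
    seed: int = 0
    out_dir: str | None = None

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if not isinstance(raw, dict):
            raise ValueError("run config must be a mapping")
        if "cohort_params" in raw and raw["cohort_params"] is not None:
            cp = dict(raw["cohort_params"])
            if "memory_test_moments" in cp:
                cp["memory_test_moments"] = {
                    k: tuple(v) for k, v in cp["memory_test_moments"].items()
                }
            raw["cohort_params"] = synthetic.CohortParams(**cp)
        for key in ("outcomes", "scan_targets", "network_candidates"):
            if key in raw:
                raw[key] = tuple(raw[key])
        if "seed" not in raw:
            raise ValueError("run config must set an explicit seed")
        return cls(**raw)


@dataclass
class ScanOutcome:
    target: str
    outcome: str
    scan: segmented.BreakpointScanResult
    selected: segmented.SelectedBreakpoint | None
    segment_low: segmented.SegmentFit | None = None
    segment_high: segmented.SegmentFit | None = None
    magnitude: association.IndependentComparison | None = None


@dataclass
class NetworkOutcome:
    outcome: str
    psi: float
    overall: network.WelchResult
    breakdown: dict[str, network.WelchResult]


@dataclass
class RunReport:
    config: RunConfig
    n_rows: int
    screen: list[association.CorrelationResult]
    lateralization: list[association.DependentComparison]
    hierarchies: dict[str, hierarchy.HierarchicalFit]
    scans: dict[tuple[str, str], ScanOutcome]
    network: dict[str, NetworkOutcome]
    skipped: list[str] = field(default_factory=list)


def _load_cohort(config: RunConfig) -> pd.DataFrame:
    if config.input_csv is not None:
        return synthetic.read_cohort_csv(config.input_csv)
    params = config.cohort_params or synthetic.CohortParams()
    params = dataclasses.replace(params, seed=config.seed)
    table = synthetic.generate_cohort(params)
    return synthetic.inject_missingness(table, params.missingness_spec, seed=config.seed + 1)


def _check_columns(matrix: pd.DataFrame, config: RunConfig) -> None:
    referenced = list(config.outcomes) + list(config.scan_targets) + list(
        config.network_candidates
    )
    for col in referenced:
        if col not in matrix.columns:
            raise ValueError(f"column {col!r} referenced by the config is absent from the data")


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute all stages in order; stages downstream of breakpoint selection
    are skipped (and recorded as skipped) when no significant breakpoint
    exists for their target."""
    cohort = _load_cohort(config)
    if config.drop_left_handed:
        cohort = cohort.loc[~cohort["left_handed"]].reset_index(drop=True)
    matrix, provenance = preprocess.build_analysis_matrix(
        cohort, winsorize_order=config.winsorize_order
    )
    _check_columns(matrix, config)

    screen = association.correlation_screen(matrix, outcomes=config.outcomes)
    lateral = association.lateralization_tests(matrix)

    hierarchies: dict[str, hierarchy.HierarchicalFit] = {}
    for outcome in config.outcomes:
        sig = [
            c
            for c in screen
            if c.var_x == outcome
            and c.error is None
            and c.var_y in config.network_candidates
            and c.p < 0.05
        ]
        if not sig:
            continue
        order = hierarchy.order_predictors(sig)
        hierarchies[outcome] = hierarchy.fit_hierarchical(
            matrix, outcome, order, sample=config.hierarchy_sample
        )

    skipped: list[str] = []
    scans: dict[tuple[str, str], ScanOutcome] = {}
    net: dict[str, NetworkOutcome] = {}
    primary_target = config.scan_targets[0] if config.scan_targets else None
    for target in config.scan_targets:
        for outcome in config.outcomes:
            sub = matrix[[outcome, target]].dropna()
            x = sub[outcome].to_numpy(float)
            y = sub[target].to_numpy(float)
            try:
                scan = segmented.scan_breakpoints(
                    x,
                    y,
                    grid_size=config.grid_size,
                    alpha=config.alpha,
                    min_seg=config.min_seg,
                    model=config.scan_model,
                )
            except ValueError as exc:
                skipped.append(f"scan {target} ~ {outcome}: {exc}")
                continue
            selected = segmented.select_breakpoint(scan)
            result = ScanOutcome(target, outcome, scan, selected)
            if selected is None:
                skipped.append(
                    f"segments {target} ~ {outcome}: no significant breakpoint"
                )
            else:
                low, high, comp = segmented.fit_segment_regressions(
                    x, y, selected.psi, min_seg=config.min_seg
                )
                result.segment_low, result.segment_high, result.magnitude = low, high, comp
            scans[(target, outcome)] = result
            # the network comparison splits on the primary target's breakpoint
            if target == primary_target and selected is not None:
                score = network.composite_network(matrix, config.network_candidates)
                mem = matrix[outcome].to_numpy(float)
                usable = ~(np.isnan(mem) | score.composite.isna().to_numpy())
                low_mask = usable & (mem <= selected.psi)
                values = score.composite.to_numpy(float)
                overall = network.welch_compare(values[usable], low_mask[usable])
                breakdown = network.component_breakdown(
                    network.CompositeScore(
                        score.components,
                        score.standardized.loc[usable],
                        score.composite.loc[usable],
                    ),
                    low_mask[usable],
                )
                net[outcome] = NetworkOutcome(outcome, selected.psi, overall, breakdown)

    report = RunReport(
        config=config,
        n_rows=len(cohort),
        screen=screen,
        lateralization=lateral,
        hierarchies=hierarchies,
        scans=scans,
        network=net,
        skipped=skipped,
    )
    if config.out_dir is not None:
        persist_report(report, cohort, matrix, provenance)
    return report


# ---------------------------------------------------------------------------
# persistence

def _scan_frame(outcome: ScanOutcome) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "psi": outcome.scan.candidates,
            "p_delta": outcome.scan.slope_diff_p,
            "n_low": outcome.scan.n_low,
            "n_high": outcome.scan.n_high,
            "significant": outcome.scan.significant_mask,
        }
    )


def _builtin(obj):
    """Recursively convert numpy scalars/arrays for JSON emission."""
    if isinstance(obj, dict):
        return {k: _builtin(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_builtin(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, np.generic):
        return obj.item()
    if isinstance(obj, float) and not np.isfinite(obj):
        return None if np.isnan(obj) else ("inf" if obj > 0 else "-inf")
    return obj


def report_summary(report: RunReport) -> dict:
    """JSON-serializable headline numbers, traceable to the TSV artifacts."""
    summary: dict = {
        "n_rows": report.n_rows,
        "flags": {
            "winsorize_order": report.config.winsorize_order,
            "scan_model": report.config.scan_model,
            "hierarchy_sample": report.config.hierarchy_sample,
            "grid_size": report.config.grid_size,
            "alpha": report.config.alpha,
            "min_seg": report.config.min_seg,
            "drop_left_handed": report.config.drop_left_handed,
            "seed": report.config.seed,
        },
        "screen": [dataclasses.asdict(c) for c in report.screen],
        "lateralization": [dataclasses.asdict(c) for c in report.lateralization],
        "hierarchy": {
            outcome: [dataclasses.asdict(s) for s in fit.steps]
            for outcome, fit in report.hierarchies.items()
        },
        "scans": {},
        "network": {},
        "skipped": report.skipped,
    }
    for (target, outcome), sc in report.scans.items():
        entry: dict = {
            "n_candidates": int(sc.scan.candidates.size),
            "n_significant": int(sc.scan.significant_mask.sum()),
            "selected": dataclasses.asdict(sc.selected) if sc.selected else None,
        }
        if sc.segment_low is not None:
            entry["segment_low"] = dataclasses.asdict(sc.segment_low)
            entry["segment_high"] = dataclasses.asdict(sc.segment_high)
            entry["magnitude"] = dataclasses.asdict(sc.magnitude)
        summary["scans"][f"{target}~{outcome}"] = entry
    for outcome, no in report.network.items():
        summary["network"][outcome] = {
            "psi": no.psi,
            "overall": dataclasses.asdict(no.overall),
            "breakdown": {k: dataclasses.asdict(v) for k, v in no.breakdown.items()},
        }
    return _builtin(summary)


def persist_report(
    report: RunReport,
    cohort: pd.DataFrame,
    matrix: pd.DataFrame,
    provenance: dict,
) -> Path:
    out = Path(report.config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    synthetic.write_cohort_csv(cohort, str(out / "cohort.csv"))
    matrix.to_csv(out / "analysis_matrix.csv", index=False)
    association.screen_to_frame(report.screen).to_csv(
        out / "screen.tsv", sep="\t", index=False
    )
    pd.DataFrame([dataclasses.asdict(c) for c in report.lateralization]).to_csv(
        out / "lateralization.tsv", sep="\t", index=False
    )
    for outcome, fit in report.hierarchies.items():
        hierarchy.hierarchy_to_frame(fit).to_csv(
            out / f"hierarchy_{outcome}.tsv", sep="\t", index=False
        )
    for (target, outcome), sc in report.scans.items():
        _scan_frame(sc).to_csv(
            out / f"scan_{target}__{outcome}.tsv", sep="\t", index=False
        )
    with open(out / "provenance.json", "w") as fh:
        json.dump(provenance, fh, indent=2)
    with open(out / "report.json", "w") as fh:
        json.dump(report_summary(report), fh, indent=2)
    return out


def load_report_summary(out_dir: str) -> dict:
    """Regenerate the report view from persisted artifacts (no recomputation)."""
    with open(Path(out_dir) / "report.json") as fh:
        return json.load(fh)


# ---------------------------------------------------------------------------
# sensitivity

def sensitivity_rerun(config: RunConfig, keep=None) -> dict:
    """Full re-run on a filtered sample, reported side by side with the
    original.

    ``keep`` is a predicate on cohort rows (returns a boolean mask given the
    cohort frame); the default drops left-handed participants.  Returns a
    dict with both reports and a delta summary flagging qualitative changes
    (breakpoints appearing/disappearing, significance flips).
    """
    base = run_pipeline(dataclasses.replace(config, out_dir=None))
    if keep is None:
        filtered_cfg = dataclasses.replace(config, drop_left_handed=True, out_dir=None)
        filtered = run_pipeline(filtered_cfg)
    else:
        cohort = _load_cohort(config)
        cohort = cohort.loc[np.asarray(keep(cohort), dtype=bool)].reset_index(drop=True)
        tmp = dataclasses.replace(config, out_dir=None)
        filtered = _run_on_cohort(tmp, cohort)

    delta: dict = {"screen_r_delta": {}, "breakpoint_changes": {}, "significance_flips": {}}
    base_screen = {(c.var_x, c.var_y): c for c in base.screen}
    for c in filtered.screen:
        b = base_screen.get((c.var_x, c.var_y))
        if b is None or b.error or c.error:
            continue
        delta["screen_r_delta"][f"{c.var_x}~{c.var_y}"] = c.r - b.r
        if (b.p < 0.05) != (c.p < 0.05):
            delta["significance_flips"][f"{c.var_x}~{c.var_y}"] = {
                "base_p": b.p,
                "filtered_p": c.p,
            }
    for key in set(base.scans) | set(filtered.scans):
        b = base.scans.get(key)
        f = filtered.scans.get(key)
        had = b is not None and b.selected is not None
        has = f is not None and f.selected is not None
        if had != has:
            delta["breakpoint_changes"]["~".join(key)] = (
                "disappeared" if had else "appeared"
            )
    return {"base": base, "filtered": filtered, "delta": delta}


def _run_on_cohort(config: RunConfig, cohort: pd.DataFrame) -> RunReport:
    """Run the post-ingestion stages on an already-loaded cohort table."""
    import tempfile

    with tempfile.NamedTemporaryFile("w", suffix=".csv", delete=False) as fh:
        synthetic.write_cohort_csv(cohort, fh.name)
        path = fh.name
    try:
        return run_pipeline(dataclasses.replace(config, input_csv=path, cohort_params=None))
    finally:
        Path(path).unlink(missing_ok=True)
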