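#!/usr/bin/env python
"""Memory-network integrity composite: low vs high performers.

Standardizes the three network components (splenium FA, right hippocampus,
left DLPFC residual volumes) to mean 100 / SD 15, averages them per
participant, splits the sample at each selected breakpoint from the scan
stage, and compares groups with Welch's t — overall and per component.
"""

import argparse
import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd

from memnet.network import component_breakdown, composite_network, welch_compare


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--results", type=Path, default=Path("results"))
    args = parser.parse_args()

    matrix = pd.read_csv(args.results / "analysis_matrix.csv")
    segments = pd.read_csv(args.results / "segments.tsv", sep="\t")
    score = composite_network(matrix)
    score.standardized.assign(composite=score.composite).to_csv(
        args.results / "network_scores.tsv", sep="\t", index=False
    )

    rows = []
    psis = (
        segments.loc[segments.target == "resid_vol_r_dlpfc", ["outcome", "psi"]]
        .drop_duplicates()
        .itertuples(index=False)
    )
    for outcome, psi in psis:
        mem = matrix[outcome].to_numpy(float)
        usable = ~(np.isnan(mem) | score.composite.isna().to_numpy())
        low = (mem <= psi) & usable
        overall = welch_compare(score.composite.to_numpy(float)[usable], low[usable])
        trimmed = composite_network(matrix.loc[usable])
        breakdown = component_breakdown(trimmed, low[usable])
        print(f"{outcome} split at psi={psi:+.2f}: "
              f"low mean {overall.mean_low:.1f} vs high {overall.mean_high:.1f}, "
              f"t({overall.df:.2f})={overall.t_stat:+.2f}, p={overall.p:.3f}")
        for comp_name, res in breakdown.items():
            print(f"    {comp_name}: t({res.df:.1f})={res.t_stat:+.2f}, p={res.p:.3f}")
            rows.append({"outcome": outcome, "psi": psi, "component": comp_name,
                         **dataclasses.asdict(res)})
        rows.append({"outcome": outcome, "psi": psi, "component": "composite",
                     **dataclasses.asdict(overall)})
    if rows:
        pd.DataFrame(rows).to_csv(args.results / "network_comparison.tsv", sep="\t", index=False)
        print(f"wrote {args.results/'network_comparison.tsv'}")
    else:
        print("no breakpoints available; run 05_breakpoint_scan.py first")


if __name__ == "__main__":
    main()
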