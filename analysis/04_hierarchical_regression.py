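#!/usr/bin/env python
"""Hierarchical stepwise regression of memory on network variables.

For each memory composite, the group-level-significant network variables
(splenium FA, right hippocampus, left DLPFC residual volumes) enter a
stepwise OLS hierarchy ordered by correlation magnitude (largest first);
each step reports standardized betas, F with its df pair, R² and the
increment over the previous step.
"""

import argparse
from pathlib import Path

import pandas as pd

from memnet.association import correlation_screen
from memnet.hierarchy import fit_hierarchical, hierarchy_to_frame, order_predictors
from memnet.network import DEFAULT_COMPONENTS


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--results", type=Path, default=Path("results"))
    parser.add_argument("--sample", choices=["per_step", "listwise"], default="per_step")
    args = parser.parse_args()

    matrix = pd.read_csv(args.results / "analysis_matrix.csv")
    frames = []
    for outcome in ("mem_immediate_z", "mem_delayed_z"):
        screen = correlation_screen(matrix, outcomes=(outcome,))
        sig = [
            c for c in screen
            if c.error is None and c.var_y in DEFAULT_COMPONENTS and c.p < 0.05
        ]
        if not sig:
            print(f"{outcome}: no group-level-significant network predictors")
            continue
        fit = fit_hierarchical(matrix, outcome, order_predictors(sig), sample=args.sample)
        frames.append(hierarchy_to_frame(fit))
        final = fit.steps[-1]
        print(f"{outcome}: entry order {' -> '.join(fit.entry_order)}")
        print(
            f"  final model R²={final.r_squared:.3f}, "
            f"F({final.df_model},{final.df_resid})={final.f_stat:.2f}, p={final.p:.4f}"
        )
    if frames:
        pd.concat(frames).to_csv(args.results / "hierarchy.tsv", sep="\t", index=False)
        print(f"wrote {args.results/'hierarchy.tsv'}")


if __name__ == "__main__":
    main()
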