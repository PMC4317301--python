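#!/usr/bin/env python
"""Correlation screen and lateralization tests.

Correlates both memory composites with the ten MRI variables (pairwise
complete), flags trends (.05 < p < .08), and runs Williams' dependent-
correlation tests asking whether the memory associations are lateralized
(left vs right DLPFC, right vs left hippocampus) or regionally specific
within the callosum (splenium vs genu FA and MD).
"""

import argparse
import dataclasses
from pathlib import Path

import pandas as pd

from memnet.association import correlation_screen, lateralization_tests, screen_to_frame


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--results", type=Path, default=Path("results"))
    args = parser.parse_args()

    matrix = pd.read_csv(args.results / "analysis_matrix.csv")
    screen = correlation_screen(matrix)
    screen_to_frame(screen).to_csv(args.results / "screen.tsv", sep="\t", index=False)
    lateral = lateralization_tests(matrix)
    pd.DataFrame([dataclasses.asdict(c) for c in lateral]).to_csv(
        args.results / "lateralization.tsv", sep="\t", index=False
    )

    sig = [c for c in screen if c.error is None and c.p < 0.05]
    print(f"screen: {len(screen)} cells, {len(sig)} significant at p<.05")
    for c in sorted(sig, key=lambda c: -abs(c.r)):
        print(f"  {c.var_x} ~ {c.var_y}: r={c.r:+.3f} (n={c.n}, p={c.p:.3f})")
    print("lateralization (Williams t, df = n-3):")
    for c in lateral:
        mark = "*" if c.p < 0.05 else " "
        print(f" {mark}{c.label}: t({c.df})={c.t_stat:+.2f}, p={c.p:.3f}")


if __name__ == "__main__":
    main()
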