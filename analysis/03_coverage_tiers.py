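#!/usr/bin/env python
"""Tiered coverage of species ranges and the 30% adequacy cascade.

Reads the unbiased world's coverage table (written by 02_null_model.py's
pipeline run), reports how many species reach 30% cumulative coverage at
each successive land-designation tier — the question of whether adequate
protection is achievable on existing public land or requires private
land — and draws the mean-coverage-by-class bar chart
(results/class_coverage.png).
"""

import os
import sys

sys.path.insert(0, os.path.join(os.path.dirname(__file__), "..", "src"))

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from gapcover.coverage import TIER_ORDER

HERE = os.path.dirname(__file__)
RES = os.path.join(HERE, "..", "results", "worlds", "unbiased", "results")


def main() -> None:
    cov = pd.read_csv(os.path.join(RES, "coverage.csv"))
    cascade = pd.read_csv(os.path.join(RES, "adequacy_cascade.csv"))
    n = len(cov)
    print(f"{n} species; species with >=30% of range covered, cumulatively by tier:")
    for _, row in cascade.iterrows():
        print(f"  through {row.through_tier:<22s} {row.n_adequate:4d} "
              f"({100.0 * row.n_adequate / n:.0f}%)")

    summary = pd.read_csv(os.path.join(RES, "class_summary.csv"))
    pivot = summary.pivot(index="tetrapod_class", columns="tier_id", values="mean_pct")
    pivot = pivot[list(TIER_ORDER)]
    ax = pivot.plot.bar(stacked=True, figsize=(8, 5), colormap="viridis")
    ax.axhline(30.0, color="red", lw=1.5, label="30% adequacy threshold")
    ax.set_ylabel("mean % of range")
    ax.set_title("Mean percent of species ranges by land designation tier")
    ax.legend(fontsize=7, bbox_to_anchor=(1.02, 1.0), loc="upper left")
    out = os.path.join(HERE, "..", "results", "class_coverage.png")
    plt.tight_layout()
    plt.savefig(out, dpi=150)
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
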