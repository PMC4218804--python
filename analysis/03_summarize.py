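#!/usr/bin/env python
"""Condense the study report: growth effects versus the planted design,
flux-capacity shifts per subsystem, gene-category mix of the down-regulated
genes, and where those genes sit in the centrality rankings.

Writes results/study/summary.tsv.
"""

import json
import math
import os
import sys

import pandas as pd

ROOT = os.path.dirname(os.path.dirname(os.path.abspath(__file__)))
DATA_DIR = os.path.join(ROOT, "scratch", "study_data")
RESULTS_DIR = os.path.join(ROOT, "results", "study")


def main():
    with open(os.path.join(RESULTS_DIR, "report.json")) as fh:
        reports = json.load(fh)
    with open(os.path.join(DATA_DIR, "study.json")) as fh:
        study = json.load(fh)
    design = {c["label"]: c for c in study["conditions"]}

    rows = []
    for r in reports:
        d = design[r["label"]]
        expected = d["expected_growth_ratio"]
        dev = (
            abs(math.log2(r["growth_ratio"]) - math.log2(expected))
            if r["growth_ratio"] > 0 and expected > 0
            else float("nan")
        )
        top_hits = sum(1 for members in r["centrality_top_flags"].values() if members)
        rows.append(
            {
                "condition": r["label"],
                "planted_genes": ",".join(d["planted_model_genes"]) or "(none)",
                "planted_fc": d["planted_fc"],
                "expected_ratio": round(expected, 4),
                "realized_ratio": round(r["growth_ratio"], 4),
                "abs_log2_deviation": round(dev, 3),
                "n_down_in_model": len(r["down_genes_in_model"]),
                "n_constrained": r["n_constrained_reactions"],
                "n_subsystems_up": len(r["increased_subsystems"]),
                "n_subsystems_down": len(r["decreased_subsystems"]),
                "pct_essential": round(r["percent_essential"], 1),
                "pct_blocked": round(r["category_percentages"]["blocked"], 1),
                "n_indices_flagging_down_genes": top_hits,
            }
        )
    frame = pd.DataFrame(rows)
    out = os.path.join(RESULTS_DIR, "summary.tsv")
    frame.to_csv(out, sep="\t", index=False)
    print(frame.to_string(index=False))
    tracked = frame[(frame["expected_ratio"] < 1.0) & (frame["n_constrained"] > 0)]
    missed = frame[(frame["expected_ratio"] < 1.0) & (frame["n_constrained"] == 0)]
    print(
        f"\n{len(tracked)} conditions throttle a unique-route step; their realized "
        f"growth ratios deviate from 2**FC by at most "
        f"{tracked['abs_log2_deviation'].max():.3f} log2 units (fold-change "
        "estimation noise)."
    )
    if len(missed):
        print(
            f"{len(missed)} condition(s) planted a weak fold change the t-test did "
            f"not recover at alpha 0.01 ({', '.join(missed['condition'])}); with no "
            "constraint applied their growth stays at the WT optimum."
        )
    print(f"wrote {out}")
    return 0


if __name__ == "__main__":
    sys.exit(main())
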