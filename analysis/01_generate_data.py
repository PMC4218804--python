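#!/usr/bin/env python
"""Generate the synthetic study inputs: the branched core model (SBML) and
nine WT-vs-mutant expression bundles with planted down-regulated genes.

Inputs are regenerable from the seed, so they go under scratch/ (not
versioned); the study manifest is echoed here for the record.
"""

import json
import os
import sys

from valveflux.synthetic import STUDY_CONDITIONS, make_study

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 7
ROOT = os.path.dirname(os.path.dirname(os.path.abspath(__file__)))
DATA_DIR = os.path.join(ROOT, "scratch", "study_data")


def main():
    record = make_study(DATA_DIR, seed=SEED)
    print(f"wrote model + {len(record['conditions'])} expression bundles to {DATA_DIR}")
    print(f"core model optimum (analytic): {record['wt_optimum']}")
    print("\ncondition           planted genes        FC    expected growth ratio")
    for (label, genes, fc, ratio), cond in zip(STUDY_CONDITIONS, record["conditions"]):
        print(f"{label:22s} {','.join(genes) or '(none)':18s} {fc:5.1f}  {ratio:.4f}")
    print("\nexpected ratios assume exact fold-change recovery; the realized")
    print("values in 02_run_study.py scatter around them with array noise.")
    return 0


if __name__ == "__main__":
    sys.exit(main())
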