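#!/usr/bin/env python
"""Recompute the reference study's headline numbers from its printed counts.

Runs the same operations the synthetic analyses use, but on the published
summary data packaged with liquidbx: the nine-gene tumor/ctDNA agreement
tables, the cohort mutation-overlap counts, and the Youden operating points
with the group sizes. Writes results/reference_recomputation.json.
"""

import argparse
import json
import subprocess
import sys
from pathlib import Path

ROOT = Path(__file__).resolve().parent.parent


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    args = ap.parse_args()
    out = ROOT / "results" / "reference_recomputation.json"
    subprocess.run(
        [sys.executable, str(ROOT / "scripts" / "acceptance.py"),
         "--seed", str(args.seed), "--out", str(out)],
        check=True,
    )
    doc = json.loads(out.read_text())
    labels = {
        "t1": "pooled diagnostic accuracy (%)",
        "t2": "pooled PPV (%)",
        "t3": "pooled NPV (%)",
        "t4": "pooled printed sensitivity, tn/(tn+fp) (%)",
        "t5": "pooled printed specificity, tp/(tp+fn) (%)",
        "t6": "Cohen's kappa",
        "t7": "TP53 gene accuracy (%)",
        "t8": "mutation-level concordance (%)",
        "t9": "crude OR, cfDNA cutoff, CCA vs normal",
        "t10": "crude OR, cfDNA cutoff, CCA vs BBD",
        "t11": "positive LR, cfDNA cutoff, CCA vs normal",
    }
    print(f"{'quantity':50s} value")
    for k, v in doc.items():
        print(f"{labels.get(k, k):50s} {v['value']}")


if __name__ == "__main__":
    main()
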