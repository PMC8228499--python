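#!/usr/bin/env python
"""Tumor-vs-ctDNA concordance of the filtered synthetic calls.

Compares each patient's kept plasma mutations against the kept tumor
mutations: mutation-level overlap and rate, patient categories
(concordant / partially concordant / discordant), per-gene 2x2 tables with
tissue as reference, pooled diagnostics and Cohen's kappa. Writes the gene
table and a JSON summary under results/concordance/.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from liquidbx import io as lio
from liquidbx.concordance import (
    PatientCallPair, cohens_kappa, diagnostic_metrics, gene_confusion,
    pool_confusions, summarize_cohort,
)

ROOT = Path(__file__).resolve().parent.parent


def main() -> None:
    argparse.ArgumentParser().parse_args()
    src = ROOT / "results" / "filtered"
    out = ROOT / "results" / "concordance"
    out.mkdir(parents=True, exist_ok=True)

    def load(assay):
        return {
            p.name.split(".")[0]: {v.key for v in lio.read_variants(p)}
            for p in sorted(src.glob(f"*.{assay}.kept.vcf"))
        }

    tumor, plasma = load("tumor"), load("plasma")
    pairs = [PatientCallPair(pid, tumor.get(pid, set()), plasma.get(pid, set()))
             for pid in sorted(set(tumor) | set(plasma))]
    s = summarize_cohort(pairs)
    print(f"mutation-level concordance: {s.n_shared}/{s.n_total} "
          f"= {100 * s.concordance_rate:.2f}% "
          f"(tumor-only {s.n_tumor_only}, ctDNA-only {s.n_ctdna_only})")
    cats = {}
    for c in s.patient_categories.values():
        cats[c.value] = cats.get(c.value, 0) + 1
    print("patient categories:", cats)

    genes = sorted({m.gene for p in pairs
                    for m in set(p.tumor_mutations) | set(p.ctdna_mutations)})
    rows, tables = [], []
    for g in genes:
        t = gene_confusion(pairs, g)
        tables.append(t)
        m = diagnostic_metrics(t)
        rows.append({"gene": g, "tp": t.tp, "fp": t.fp, "fn": t.fn, "tn": t.tn,
                     "accuracy_pct": round(100 * m.accuracy, 2)})
    pooled = pool_confusions(tables)
    pm = diagnostic_metrics(pooled)
    kappa = cohens_kappa(pooled)
    rows.append({"gene": "Total", "tp": pooled.tp, "fp": pooled.fp,
                 "fn": pooled.fn, "tn": pooled.tn,
                 "accuracy_pct": round(100 * pm.accuracy, 2)})
    pd.DataFrame(rows).to_csv(out / "gene_table.csv", index=False)
    print(f"pooled over {len(genes)} genes: accuracy {100 * pm.accuracy:.1f}%, "
          f"kappa {kappa:.3f}")

    (out / "summary.json").write_text(json.dumps({
        "concordance_rate": s.concordance_rate,
        "categories": cats,
        "kappa": kappa,
    }, indent=1, sort_keys=True))
    print(f"outputs in {out}")


if __name__ == "__main__":
    main()
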