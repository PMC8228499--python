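#!/usr/bin/env python
"""Cutoff-based diagnostics of plasma cfDNA level on the synthetic cohort.

For each group comparison (CCA vs control, CCA vs BBD, BBD vs control):
ROC/AUC with 95% CI, Youden-optimal cutoff with sensitivity/specificity
and positive LR, and the crude odds ratio at that cutoff. Also runs the
rank-based group comparisons (Kruskal-Wallis with Dunn post hoc,
Mann-Whitney by nodal status), the cfDNA-vs-tumor-size Spearman
correlation, and detection rates at the clinical cutoffs. Writes
results/biomarkers/.
"""

import argparse
import json
from pathlib import Path

import numpy as np
import pandas as pd

from liquidbx import io as lio
from liquidbx.diagnostics import (
    LabeledValues, crude_odds_ratio, detection_rates, dunn_posthoc,
    empirical_roc, rank_tests, spearman_correlation, youden_cutoff,
)
from liquidbx.reference import CA19_9_CLINICAL_CUTOFF, CEA_CLINICAL_CUTOFF

ROOT = Path(__file__).resolve().parent.parent


def main() -> None:
    argparse.ArgumentParser().parse_args()
    cohort = lio.read_cohort(ROOT / "results" / "synthetic" / "cohort.csv")
    out = ROOT / "results" / "biomarkers"
    out.mkdir(parents=True, exist_ok=True)

    rows = []
    for case, control in (("CCA", "NORMAL"), ("CCA", "BBD"), ("BBD", "NORMAL")):
        vals, labels = [], []
        for r in cohort:
            if r.group in (case, control):
                vals.append(r.cfdna_level)
                labels.append(r.group == case)
        data = LabeledValues(vals, labels)
        curve = empirical_roc(data)
        rep = youden_cutoff(curve, data)
        orr = crude_odds_ratio(rep.table)
        rows.append({
            "comparison": f"{case} vs {control}",
            "cutoff_ng_ul": round(rep.cutoff, 4),
            "auc": round(curve.auc, 4),
            "auc_95ci": f"{curve.auc_ci_low:.3f}-{curve.auc_ci_high:.3f}",
            "youden_j": round(rep.youden_j, 2),
            "sn_pct": round(100 * rep.sensitivity, 2),
            "sp_pct": round(100 * rep.specificity, 2),
            "lr": None if rep.positive_lr is None else round(rep.positive_lr, 2),
            "crude_or": None if orr.odds_ratio is None else round(orr.odds_ratio, 2),
        })
    df = pd.DataFrame(rows)
    df.to_csv(out / "roc_performance.csv", index=False)
    print(df.to_string(index=False))

    by_group = {g: [r.cfdna_level for r in cohort if r.group == g]
                for g in ("CCA", "BBD", "NORMAL")}
    h, p = rank_tests(list(by_group.values()), mode="kruskal_wallis")
    print(f"\nKruskal-Wallis over the three groups: H={h:.1f}, p={p:.3g}")
    for r in dunn_posthoc(list(by_group.values())):
        gi, gj = list(by_group)[r["group_i"]], list(by_group)[r["group_j"]]
        print(f"  Dunn {gi} vs {gj}: z={r['z']:+.2f}, "
              f"p(bonf)={r['p_bonferroni']:.3g}")

    cca = [r for r in cohort if r.group == "CCA"]
    node_pos = [r.cfdna_level for r in cca if r.node_positive]
    node_neg = [r.cfdna_level for r in cca if not r.node_positive]
    _, p_node = rank_tests([node_pos, node_neg], mode="mann_whitney")
    rho, p_rho = spearman_correlation(
        [r.tumor_size_cm for r in cca], [r.cfdna_level for r in cca])
    print(f"node-positive vs node-negative cfDNA: Mann-Whitney p={p_node:.3g}")
    print(f"cfDNA vs tumor size: Spearman r={rho:.2f}, p={p_rho:.3g}")

    cutoff_cca_normal = rows[0]["cutoff_ng_ul"]
    rates = detection_rates(
        {
            "cfdna_level": [r.cfdna_level for r in cca],
            "ca19_9": [r.ca19_9 for r in cca],
            "cea": [r.cea for r in cca],
        },
        {
            "cfdna_level": cutoff_cca_normal,
            "ca19_9": CA19_9_CLINICAL_CUTOFF,
            "cea": CEA_CLINICAL_CUTOFF,
        },
    )
    print("positive detection rates among CCA cases:",
          {k: (None if v is None else f"{100 * v:.1f}%") for k, v in rates.items()})
    (out / "detection_rates.json").write_text(json.dumps(rates, indent=1))
    print(f"outputs in {out}")


if __name__ == "__main__":
    main()
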