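#!/usr/bin/env python
"""Run the somatic filter chain over the simulated plasma and tumor calls.

Reads the VCFs written by 01_simulate_study.py, applies the post-calling
filters (functional class; strand/support/depth/VAF; one-sided Fisher
somatic p; dbSNP-unless-COSMIC; >30% cohort recurrence) and reports how
well the kept calls recover the planted truth. Writes kept-variant VCFs
and the rejection audit under results/filtered/.
"""

import argparse
from pathlib import Path

import pandas as pd

from liquidbx import io as lio
from liquidbx.filters import apply_filter_chain, kept_mutations

ROOT = Path(__file__).resolve().parent.parent


def main() -> None:
    argparse.ArgumentParser().parse_args()
    src = ROOT / "results" / "synthetic"
    out = ROOT / "results" / "filtered"
    out.mkdir(parents=True, exist_ok=True)
    truth = lio.read_truth(src / "truth.json")

    audit = []
    for assay in ("plasma", "tumor"):
        calls = {
            p.name.split(".")[0]: lio.read_variants(p)
            for p in sorted((src / "vcf").glob(f"*.{assay}.vcf"))
        }
        outcomes = apply_filter_chain(calls)
        kept = kept_mutations(outcomes)
        for pid, outs in outcomes.items():
            lio.write_variants([o.variant for o in outs if o.kept],
                               out / f"{pid}.{assay}.kept.vcf",
                               sample=assay.upper())
            for o in outs:
                if not o.kept:
                    audit.append({
                        "patient": pid, "assay": assay, "gene": o.variant.gene,
                        "chrom": o.variant.chrom, "pos": o.variant.pos,
                        "ref": o.variant.ref, "alt": o.variant.alt,
                        "reasons": ";".join(r.value for r in o.reason_codes),
                    })
        n_total = sum(len(v) for v in calls.values())
        n_kept = sum(len(k) for k in kept.values())
        print(f"{assay}: kept {n_kept}/{n_total} candidate variants")
        if assay == "plasma":
            som = {m.key for muts in truth.somatic.values() for m in muts
                   if m.detected_in_plasma}
            kept_all = {k for ks in kept.values() for k in ks}
            germ = {k for ks in truth.germline.values() for k in ks}
            print(f"  recovered {len(som & kept_all)}/{len(som)} detectable "
                  f"planted somatic mutations; "
                  f"{len(germ & kept_all)} germline leaked (expect 0)")
    pd.DataFrame(audit).to_csv(out / "rejection_audit.csv", index=False)
    print(f"outputs in {out}")


if __name__ == "__main__":
    main()
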