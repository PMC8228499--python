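"""End-to-end orchestration: simulate -> filter -> concordance -> diagnostics.

``run_pipeline`` ties the stages into one deterministic run over a seeded
synthetic study (or pre-existing inputs), persisting every intermediate
artifact — cohort table, per-patient VCFs, kept-variant VCFs, a rejection
audit table — plus report tables as CSV and a machine-readable JSON summary
with a provenance block (config hash, seed). Every number in the reports is
computed by the underlying library operation on the persisted intermediates;
the report layer does no arithmetic of its own.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd

from . import io as lio
from .concordance import (
    ConfusionTable,
    PatientCallPair,
    cohens_kappa,
    diagnostic_metrics,
    gene_confusion,
    pool_confusions,
    summarize_cohort,
)
from .diagnostics import (
    LabeledValues,
    crude_odds_ratio,
    empirical_roc,
    youden_cutoff,
)
from .filters import FilterConfig, apply_filter_chain, kept_mutations
from .synthetic import (
    CohortConfig,
    PanelSimConfig,
    simulate_cohort,
    simulate_panel,
)

logger = logging.getLogger("liquidbx")


@dataclass
class RunConfig:
    """One pipeline run: either simulate inputs (default) or point at
    existing ones."""

    out_dir: Path
    seed: int = 0
    cohort_path: Optional[Path] = None     # simulate if None
    vcf_dir: Optional[Path] = None         # simulate if None
    truth_path: Optional[Path] = None
    cohort_config: CohortConfig = field(default_factory=CohortConfig)
    panel_config: PanelSimConfig = field(default_factory=PanelSimConfig)
    filter_config: FilterConfig = field(default_factory=FilterConfig)

    def __post_init__(self) -> None:
        if self.seed < 0:
            raise ValueError("seed must be a non-negative integer")
        self.out_dir = Path(self.out_dir)


@dataclass
class ReportBundle:
    marker_performance: pd.DataFrame   # marker, cutoff, AUC, CI, YI, SN, SP, LR
    odds_ratios: pd.DataFrame          # comparison, OR, CI, p
    gene_table: pd.DataFrame           # per-gene 2x2 rows + Total
    category_counts: dict[str, int]
    kappa: Optional[float]
    concordance_rate: Optional[float]
    provenance: dict


def _config_hash(cfg: RunConfig) -> str:
    def default(o):
        if dataclasses.is_dataclass(o):
            return dataclasses.asdict(o)
        if isinstance(o, (Path, frozenset, tuple, set)):
            return sorted(o) if isinstance(o, (set, frozenset)) else str(o)
        return str(o)

    doc = dataclasses.asdict(cfg)
    doc.pop("out_dir", None)  # output location is not part of the analysis
    blob = json.dumps(doc, default=default, sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _pct(x: Optional[float]) -> Optional[float]:
    return None if x is None else round(100.0 * x, 2)


def run_pipeline(config: RunConfig) -> ReportBundle:
    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)
    logger.info("run config hash=%s seed=%d", _config_hash(config), config.seed)

    # --- stage 1: cohort ---------------------------------------------------
    if config.cohort_path is None:
        cc = dataclasses.replace(config.cohort_config, seed=config.seed)
        cohort = simulate_cohort(cc)
        lio.write_cohort(cohort, out / "cohort.csv")
    else:
        cohort = lio.read_cohort(config.cohort_path)
    logger.info("cohort: %d subjects", len(cohort))

    # --- stage 2: panel ----------------------------------------------------
    if config.vcf_dir is None:
        pc = dataclasses.replace(config.panel_config, seed=config.seed)
        tables, truth = simulate_panel(pc)
        vcf_dir = out / "vcf"
        vcf_dir.mkdir(exist_ok=True)
        for pid, samples in tables.items():
            for sample, variants in samples.items():
                lio.write_variants(
                    variants, vcf_dir / f"{pid}.{sample}.vcf", sample=sample.upper()
                )
        lio.write_truth(truth, out / "truth.json")
        plasma = {pid: s["plasma"] for pid, s in tables.items()}
        tumor = {pid: s["tumor"] for pid, s in tables.items()}
    else:
        vcf_dir = Path(config.vcf_dir)
        plasma, tumor = {}, {}
        for p in sorted(vcf_dir.glob("*.plasma.vcf")):
            plasma[p.name.split(".")[0]] = lio.read_variants(p)
        for p in sorted(vcf_dir.glob("*.tumor.vcf")):
            tumor[p.name.split(".")[0]] = lio.read_variants(p)

    # --- stage 3: filter chain ---------------------------------------------
    kept_dir = out / "kept"
    kept_dir.mkdir(exist_ok=True)
    audit_rows = []
    kept = {}
    for label, calls in (("plasma", plasma), ("tumor", tumor)):
        outcomes = apply_filter_chain(calls, config.filter_config)
        kept[label] = kept_mutations(outcomes)
        for pid, outs in outcomes.items():
            n_kept = sum(o.kept for o in outs)
            logger.info("%s %s: %d/%d variants kept", label, pid, n_kept, len(outs))
            kept_vars = [o.variant for o in outs if o.kept]
            lio.write_variants(
                kept_vars, kept_dir / f"{pid}.{label}.kept.vcf", sample=label.upper()
            )
            for o in outs:
                if not o.kept:
                    audit_rows.append({
                        "patient": pid,
                        "assay": label,
                        "gene": o.variant.gene,
                        "chrom": o.variant.chrom,
                        "pos": o.variant.pos,
                        "ref": o.variant.ref,
                        "alt": o.variant.alt,
                        "reasons": ";".join(r.value for r in o.reason_codes),
                        "error": o.error or "",
                    })
    pd.DataFrame(audit_rows).to_csv(out / "rejection_audit.csv", index=False)

    # --- stage 4: concordance ----------------------------------------------
    pairs = [
        PatientCallPair(
            patient_id=pid,
            tumor_mutations=kept["tumor"].get(pid, set()),
            ctdna_mutations=kept["plasma"].get(pid, set()),
        )
        for pid in sorted(set(kept["tumor"]) | set(kept["plasma"]))
    ]
    summary = summarize_cohort(pairs)
    genes = sorted({m.gene for p in pairs for m in (set(p.tumor_mutations) | set(p.ctdna_mutations))})
    gene_rows = []
    gene_tables = []
    for gene in genes:
        t = gene_confusion(pairs, gene)
        gene_tables.append(t)
        m = diagnostic_metrics(t)
        gene_rows.append({
            "gene": gene, "tp": t.tp, "fp": t.fp, "fn": t.fn, "tn": t.tn,
            "sensitivity_pct": _pct(m.sensitivity),
            "specificity_pct": _pct(m.specificity),
            "ppv_pct": _pct(m.ppv), "npv_pct": _pct(m.npv),
            "accuracy_pct": _pct(m.accuracy),
        })
    if gene_tables:
        pooled = pool_confusions(gene_tables)
    else:
        pooled = ConfusionTable(0, 0, 0, len(pairs))
    pm = diagnostic_metrics(pooled) if pooled.n else None
    gene_rows.append({
        "gene": "Total", "tp": pooled.tp, "fp": pooled.fp,
        "fn": pooled.fn, "tn": pooled.tn,
        "sensitivity_pct": _pct(pm.sensitivity) if pm else None,
        "specificity_pct": _pct(pm.specificity) if pm else None,
        "ppv_pct": _pct(pm.ppv) if pm else None,
        "npv_pct": _pct(pm.npv) if pm else None,
        "accuracy_pct": _pct(pm.accuracy) if pm else None,
    })
    gene_df = pd.DataFrame(gene_rows)
    kappa = cohens_kappa(pooled) if pooled.n else None
    cat_counts: dict[str, int] = {}
    for cat in summary.patient_categories.values():
        cat_counts[cat.value] = cat_counts.get(cat.value, 0) + 1

    # --- stage 5: biomarker diagnostics ------------------------------------
    marker_rows, or_rows = [], []
    comparisons = [("CCA", "NORMAL"), ("CCA", "BBD"), ("BBD", "NORMAL")]
    for case_group, control_group in comparisons:
        values, labels = [], []
        for r in cohort:
            if r.group == case_group:
                values.append(r.cfdna_level)
                labels.append(True)
            elif r.group == control_group:
                values.append(r.cfdna_level)
                labels.append(False)
        if not any(labels) or all(labels):
            continue
        data = LabeledValues(values, labels)
        curve = empirical_roc(data)
        rep = youden_cutoff(curve, data)
        or_res = crude_odds_ratio(rep.table)
        name = f"{case_group}_vs_{control_group}"
        marker_rows.append({
            "comparison": name, "marker": "cfdna_level",
            "cutoff": round(rep.cutoff, 4),
            "auc": round(curve.auc, 4),
            "auc_ci_low": round(curve.auc_ci_low, 4),
            "auc_ci_high": round(curve.auc_ci_high, 4),
            "youden_j": round(rep.youden_j, 4),
            "sensitivity_pct": _pct(rep.sensitivity),
            "specificity_pct": _pct(rep.specificity),
            "positive_lr": None if rep.positive_lr is None else round(rep.positive_lr, 2),
        })
        or_rows.append({
            "comparison": name, "marker": "cfdna_level",
            "odds_ratio": None if or_res.odds_ratio is None else round(or_res.odds_ratio, 2),
            "ci_low": None if or_res.ci_low is None else round(or_res.ci_low, 2),
            "ci_high": None if or_res.ci_high is None else round(or_res.ci_high, 2),
            "p_value": or_res.p_value,
            "haldane_corrected": or_res.haldane_corrected,
        })
    marker_df = pd.DataFrame(marker_rows)
    or_df = pd.DataFrame(or_rows)

    # --- persist reports -----------------------------------------------------
    marker_df.to_csv(out / "marker_performance.csv", index=False)
    or_df.to_csv(out / "odds_ratios.csv", index=False)
    gene_df.to_csv(out / "gene_concordance.csv", index=False)
    bundle = ReportBundle(
        marker_performance=marker_df,
        odds_ratios=or_df,
        gene_table=gene_df,
        category_counts=cat_counts,
        kappa=kappa,
        concordance_rate=summary.concordance_rate,
        provenance={
            "config_hash": _config_hash(config),
            "seed": config.seed,
            "n_subjects": len(cohort),
            "n_sequenced": len(pairs),
        },
    )
    summary_doc = {
        "provenance": bundle.provenance,
        "concordance_rate": bundle.concordance_rate,
        "kappa": bundle.kappa,
        "category_counts": bundle.category_counts,
        "marker_performance": marker_rows,
        "odds_ratios": or_rows,
        "gene_table": gene_rows,
    }
    (out / "summary.json").write_text(json.dumps(summary_doc, indent=1, sort_keys=True))
    return bundle
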