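"""Tumor-vs-ctDNA concordance and gene-level diagnostic agreement.

Somatic mutations called from plasma ctDNA are compared against matched
tumor-tissue calls in three complementary ways:

* **mutation level** — exact-identity set overlap of mutations across the
  cohort; the concordance rate is shared / (shared + tumor-only + ctDNA-only);
* **patient level** — each patient classified concordant (every mutation in
  the union seen by both assays), partially concordant (some but not all), or
  discordant (no overlap);
* **gene level** — per-gene 2x2 tables with tumor tissue as the reference
  assay and ctDNA as the test assay, one count per patient, from which
  sensitivity/specificity/PPV/NPV/accuracy and Cohen's kappa follow.

A patient with no mutation in either assay counts as agreement (a true
negative at gene level, and "concordant" at patient level by default).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Optional


@dataclass(frozen=True, order=True)
class MutationKey:
    """Identity of a mutation for set comparison: exact field-wise match."""

    gene: str
    chrom: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be 1-based positive, got {self.pos}")


class ConcordanceCategory(str, Enum):
    CONCORDANT = "concordant"
    PARTIALLY_CONCORDANT = "partially_concordant"
    DISCORDANT = "discordant"
    NO_CALL = "no_call"


@dataclass
class PatientCallPair:
    """One patient's tumor and ctDNA somatic mutation call sets."""

    patient_id: str
    tumor_mutations: frozenset[MutationKey] | set[MutationKey]
    ctdna_mutations: frozenset[MutationKey] | set[MutationKey]
    stage: Optional[str] = None
    subtype: Optional[str] = None


@dataclass(frozen=True)
class ConfusionTable:
    """2x2 agreement counts.

    Orientation is explicit: the reference (truth) axis is the tumor-tissue
    assay and the test axis is ctDNA, so ``tp`` = positive in both, ``fp`` =
    ctDNA-positive only, ``fn`` = tumor-positive only, ``tn`` = negative in
    both.
    """

    tp: int
    fp: int
    fn: int
    tn: int
    orientation: str = "reference=tumor,test=ctdna"

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "fn", "tn"):
            v = getattr(self, name)
            if v < 0 or v != int(v):
                raise ValueError(f"{name} must be a non-negative integer, got {v}")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def transposed(self) -> "ConfusionTable":
        """Relabel the positive and negative classes (tp<->tn, fp<->fn).

        Under this view sensitivity and specificity exchange, as do PPV and
        NPV, while accuracy and kappa are invariant.
        """
        return ConfusionTable(
            tp=self.tn, fp=self.fn, fn=self.fp, tn=self.tp,
            orientation=self.orientation + ",classes_swapped",
        )


@dataclass
class DiagnosticMetrics:
    """Standard 2x2 diagnostic metrics; ratios with a zero denominator are
    reported as None (missing), never coerced to 0."""

    sensitivity: Optional[float]
    specificity: Optional[float]
    ppv: Optional[float]
    npv: Optional[float]
    accuracy: Optional[float]
    false_positive_rate: Optional[float]
    false_negative_rate: Optional[float]
    labeling: str = "reference=tumor"


@dataclass
class ConcordanceSummary:
    n_shared: int
    n_tumor_only: int
    n_ctdna_only: int
    concordance_rate: Optional[float]
    patient_categories: dict[str, ConcordanceCategory] = field(default_factory=dict)

    @property
    def n_total(self) -> int:
        return self.n_shared + self.n_tumor_only + self.n_ctdna_only


def mutation_overlap(
    pair: PatientCallPair,
) -> tuple[set[MutationKey], set[MutationKey], set[MutationKey]]:
    """Partition the union of the two call sets into (shared, tumor_only,
    ctdna_only)."""
    tumor = set(pair.tumor_mutations)
    ctdna = set(pair.ctdna_mutations)
    return tumor & ctdna, tumor - ctdna, ctdna - tumor


def classify_patient(
    pair: PatientCallPair, *, empty_is_concordant: bool = True
) -> ConcordanceCategory:
    """Patient-level concordance category.

    Concordant: all mutations in the union were seen by both assays (a
    double-negative patient counts as concordant unless
    ``empty_is_concordant=False``, in which case it is ``NO_CALL``).
    Partially concordant: some but not all. Discordant: none.
    """
    shared, tumor_only, ctdna_only = mutation_overlap(pair)
    union = len(shared) + len(tumor_only) + len(ctdna_only)
    if union == 0:
        return (
            ConcordanceCategory.CONCORDANT
            if empty_is_concordant
            else ConcordanceCategory.NO_CALL
        )
    if len(shared) == union:
        return ConcordanceCategory.CONCORDANT
    if len(shared) == 0:
        return ConcordanceCategory.DISCORDANT
    return ConcordanceCategory.PARTIALLY_CONCORDANT


def summarize_cohort(
    cohort: Iterable[PatientCallPair], *, empty_is_concordant: bool = True
) -> ConcordanceSummary:
    """Cohort-wide mutation-level overlap counts and per-patient categories."""
    n_shared = n_tumor = n_ctdna = 0
    categories: dict[str, ConcordanceCategory] = {}
    for pair in cohort:
        shared, tumor_only, ctdna_only = mutation_overlap(pair)
        n_shared += len(shared)
        n_tumor += len(tumor_only)
        n_ctdna += len(ctdna_only)
        categories[pair.patient_id] = classify_patient(
            pair, empty_is_concordant=empty_is_concordant
        )
    total = n_shared + n_tumor + n_ctdna
    rate = n_shared / total if total > 0 else None
    return ConcordanceSummary(n_shared, n_tumor, n_ctdna, rate, categories)


def gene_confusion(cohort: list[PatientCallPair], gene: str) -> ConfusionTable:
    """Per-gene 2x2 table, one count per patient.

    A patient is gene-positive in an assay if that assay called at least one
    mutation in the gene, irrespective of how many distinct mutations.
    """
    if not cohort:
        raise ValueError("gene_confusion requires a non-empty cohort")
    tp = fp = fn = tn = 0
    for pair in cohort:
        in_tumor = any(m.gene == gene for m in pair.tumor_mutations)
        in_ctdna = any(m.gene == gene for m in pair.ctdna_mutations)
        if in_tumor and in_ctdna:
            tp += 1
        elif in_tumor:
            fn += 1
        elif in_ctdna:
            fp += 1
        else:
            tn += 1
    return ConfusionTable(tp=tp, fp=fp, fn=fn, tn=tn)


def pool_confusions(tables: Iterable[ConfusionTable]) -> ConfusionTable:
    """Element-wise sum of 2x2 tables sharing one orientation."""
    tables = list(tables)
    if not tables:
        raise ValueError("cannot pool an empty list of tables")
    orientations = {t.orientation for t in tables}
    if len(orientations) > 1:
        raise ValueError(f"mixed table orientations: {sorted(orientations)}")
    return ConfusionTable(
        tp=sum(t.tp for t in tables),
        fp=sum(t.fp for t in tables),
        fn=sum(t.fn for t in tables),
        tn=sum(t.tn for t in tables),
        orientation=tables[0].orientation,
    )


def _ratio(num: int, den: int) -> Optional[float]:
    return num / den if den > 0 else None


def diagnostic_metrics(
    table: ConfusionTable, *, labels: str = "reference=tumor"
) -> DiagnosticMetrics:
    """Sensitivity, specificity, PPV, NPV, accuracy and error rates.

    ``labels="reference=tumor"`` (default) uses the declared orientation:
    sensitivity = tp/(tp+fn) against the tissue reference.
    ``labels="transposed"`` reports the same table with the axes swapped
    (sensitivity and specificity exchange, as do PPV and NPV) — the labeling
    convention under which the reference study prints its per-gene columns.
    """
    if table.n == 0:
        raise ValueError("diagnostic metrics need n > 0")
    if labels == "transposed":
        m = diagnostic_metrics(table.transposed())
        m.labeling = "transposed"
        return m
    if labels != "reference=tumor":
        raise ValueError(f"unknown labeling {labels!r}")
    sens = _ratio(table.tp, table.tp + table.fn)
    spec = _ratio(table.tn, table.tn + table.fp)
    return DiagnosticMetrics(
        sensitivity=sens,
        specificity=spec,
        ppv=_ratio(table.tp, table.tp + table.fp),
        npv=_ratio(table.tn, table.tn + table.fn),
        accuracy=(table.tp + table.tn) / table.n,
        false_positive_rate=None if spec is None else 1.0 - spec,
        false_negative_rate=None if sens is None else 1.0 - sens,
    )


def cohens_kappa(table: ConfusionTable) -> Optional[float]:
    """Chance-corrected agreement between the two assays.

    kappa = (p_o - p_e) / (1 - p_e) with observed agreement
    p_o = (tp+tn)/n and chance agreement
    p_e = [(tp+fp)(tp+fn) + (fn+tn)(fp+tn)] / n^2.  Returns None when the
    marginals are degenerate (p_e = 1, e.g. both assays always positive).
    """
    n = table.n
    if n == 0:
        raise ValueError("kappa needs n > 0")
    p_o = (table.tp + table.tn) / n
    p_e = (
        (table.tp + table.fp) * (table.tp + table.fn)
        + (table.fn + table.tn) * (table.fp + table.tn)
    ) / (n * n)
    if math.isclose(p_e, 1.0, abs_tol=1e-12):
        return None
    return (p_o - p_e) / (1.0 - p_e)
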