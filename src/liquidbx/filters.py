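"""Somatic variant statistic and the post-calling filter chain.

Candidate variants from deep targeted sequencing of plasma cfDNA (or tumor
DNA) with a matched germline sample are reduced to reportable somatic
mutations by a fixed sequence of rules:

0. functional-class exclusion — silent SNVs and non-frameshifting indels
   are dropped (no clinical significance);
1. read support — alt reads on both strands, >= 2 supporting reads, site
   depth >= 200 and variant allele frequency >= 0.1;
2. somatic evidence — one-sided Fisher exact p < 0.05 for alt-allele
   enrichment in the tumor/plasma sample over the germline sample;
3. germline polymorphisms — dbSNP-annotated variants are dropped unless
   also catalogued in COSMIC;
4. recurrent artifacts — variants seen in more than 30% of the cohort's
   patients and absent from COSMIC are dropped in every carrier.

Every rule that fails is recorded (evaluation does not short-circuit), so a
rejected variant carries the full list of reasons. A COSMIC annotation
exempts a variant from rules 3 and 4 but from nothing else.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Mapping, Optional, Sequence

from scipy.stats import hypergeom

from .concordance import MutationKey

FUNC_CLASSES = {
    "nonsynonymous_snv",
    "stopgain",
    "stoploss",
    "frameshift_indel",
    "nonframeshift_indel",
    "synonymous_snv",
    "splicing",
    "other",
}


@dataclass
class AnnotatedVariant:
    """One candidate variant with paired tumor/germline allele counts.

    ``tumor_*`` fields refer to the assayed (tumor or plasma) sample;
    ``normal_*`` to the matched germline sample. Counts are per strand for
    the assayed sample (forward/reverse), pooled for the germline.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str
    func_class: str
    tumor_alt_fwd: Optional[int] = None
    tumor_alt_rev: Optional[int] = None
    tumor_ref_fwd: Optional[int] = None
    tumor_ref_rev: Optional[int] = None
    normal_alt: Optional[int] = None
    normal_ref: Optional[int] = None
    depth: Optional[int] = None
    vaf: Optional[float] = None
    dbsnp_id: Optional[str] = None
    cosmic_id: Optional[str] = None
    somatic_p: Optional[float] = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be 1-based positive, got {self.pos}")
        if self.func_class not in FUNC_CLASSES:
            raise ValueError(f"unknown func_class {self.func_class!r}")
        if self.vaf is not None and not (0.0 <= self.vaf <= 1.0):
            raise ValueError(f"vaf out of [0,1]: {self.vaf}")

    @property
    def key(self) -> MutationKey:
        return MutationKey(self.gene, self.chrom, self.pos, self.ref, self.alt)

    @property
    def tumor_alt(self) -> Optional[int]:
        if self.tumor_alt_fwd is None or self.tumor_alt_rev is None:
            return None
        return self.tumor_alt_fwd + self.tumor_alt_rev

    @property
    def tumor_ref(self) -> Optional[int]:
        if self.tumor_ref_fwd is None or self.tumor_ref_rev is None:
            return None
        return self.tumor_ref_fwd + self.tumor_ref_rev

    def effective_depth(self) -> Optional[int]:
        if self.depth is not None:
            return self.depth
        if self.tumor_alt is not None and self.tumor_ref is not None:
            return self.tumor_alt + self.tumor_ref
        return None

    def effective_vaf(self) -> Optional[float]:
        if self.vaf is not None:
            return self.vaf
        d = self.effective_depth()
        if d is not None and self.tumor_alt is not None:
            return compute_vaf(self.tumor_alt, d)
        return None


class Reason(str, Enum):
    FUNC_CLASS = "FUNC_CLASS"
    STRAND = "STRAND"
    SUPPORT = "SUPPORT"
    DEPTH = "DEPTH"
    VAF = "VAF"
    SOMATIC_P = "SOMATIC_P"
    DBSNP = "DBSNP"
    RECURRENT_NON_COSMIC = "RECURRENT_NON_COSMIC"


@dataclass
class FilterConfig:
    """Thresholds of the filter chain; defaults are the study settings."""

    min_supporting_reads: int = 2
    require_both_strands: bool = True
    min_depth: int = 200
    min_vaf: float = 0.1
    max_somatic_p: float = 0.05
    recurrence_fraction: float = 0.30
    excluded_func_classes: frozenset[str] = frozenset(
        {"synonymous_snv", "nonframeshift_indel"}
    )
    # Base quality is applied upstream when alleles are counted; recorded
    # here as provenance metadata only.
    min_base_quality: int = 15

    def __post_init__(self) -> None:
        if not (0.0 < self.min_vaf <= 1.0):
            raise ValueError(f"min_vaf must be in (0,1], got {self.min_vaf}")
        if not (0.0 < self.recurrence_fraction < 1.0):
            raise ValueError(
                f"recurrence_fraction must be in (0,1), got {self.recurrence_fraction}"
            )
        unknown = set(self.excluded_func_classes) - FUNC_CLASSES
        if unknown:
            raise ValueError(f"unknown excluded func classes: {sorted(unknown)}")


@dataclass
class FilterOutcome:
    """Filter verdict for one variant: kept iff no reasons and no error."""

    variant: AnnotatedVariant
    kept: bool
    reason_codes: list[Reason] = field(default_factory=list)
    error: Optional[str] = None


def compute_vaf(alt_reads: int, depth: int) -> float:
    """Variant allele frequency: alt-supporting reads over total depth.

    Returns 0.0 at zero depth by convention.
    """
    if depth < 0 or alt_reads < 0:
        raise ValueError("read counts must be non-negative")
    if alt_reads > depth:
        raise ValueError(f"alt_reads ({alt_reads}) exceeds depth ({depth})")
    if depth == 0:
        return 0.0
    return alt_reads / depth


def somatic_fisher_test(
    tumor_alt: int, tumor_ref: int, normal_alt: int, normal_ref: int
) -> float:
    """One-sided Fisher exact test for alt enrichment in the tumor sample.

    The 2x2 table (tumor vs germline) x (alt vs ref) is tested against the
    alternative that the tumor sample carries proportionally more alt reads;
    the p-value is the hypergeometric tail over tables at least as extreme
    in the tumor-alt direction. This is the somatic-calling convention of
    paired tumor/normal callers.
    """
    for name, v in (
        ("tumor_alt", tumor_alt),
        ("tumor_ref", tumor_ref),
        ("normal_alt", normal_alt),
        ("normal_ref", normal_ref),
    ):
        if v < 0 or v != int(v):
            raise ValueError(f"{name} must be a non-negative integer, got {v}")
    total = tumor_alt + tumor_ref + normal_alt + normal_ref
    if total == 0:
        raise ValueError("all-zero 2x2 table")
    # P(X >= tumor_alt) for X ~ Hypergeom(N=total, K=alt total, n=tumor total)
    return float(
        hypergeom.sf(
            tumor_alt - 1, total, tumor_alt + normal_alt, tumor_alt + tumor_ref
        )
    )


def _per_variant_reasons(
    v: AnnotatedVariant, config: FilterConfig
) -> tuple[list[Reason], Optional[str]]:
    reasons: list[Reason] = []

    if v.func_class in config.excluded_func_classes:
        reasons.append(Reason.FUNC_CLASS)

    if config.require_both_strands:
        if v.tumor_alt_fwd is None or v.tumor_alt_rev is None:
            return reasons, "per-strand alt counts absent; strand rule not evaluable"
        if v.tumor_alt_fwd < 1 or v.tumor_alt_rev < 1:
            reasons.append(Reason.STRAND)

    alt = v.tumor_alt
    if alt is None:
        return reasons, "alt read counts absent; support rule not evaluable"
    if alt < config.min_supporting_reads:
        reasons.append(Reason.SUPPORT)

    depth = v.effective_depth()
    if depth is None:
        return reasons, "depth absent and not derivable from counts"
    if depth < config.min_depth:
        reasons.append(Reason.DEPTH)

    vaf = v.effective_vaf()
    if vaf is None:
        return reasons, "vaf absent and not derivable from counts"
    if vaf < config.min_vaf:
        reasons.append(Reason.VAF)

    p = v.somatic_p
    if p is None:
        if (
            v.tumor_ref is None
            or v.normal_alt is None
            or v.normal_ref is None
        ):
            return reasons, "somatic p unset and paired counts absent"
        p = somatic_fisher_test(alt, v.tumor_ref, v.normal_alt, v.normal_ref)
    if not (p < config.max_somatic_p):
        reasons.append(Reason.SOMATIC_P)

    # dbSNP polymorphisms are germline unless COSMIC vouches for them.
    if v.dbsnp_id is not None and v.cosmic_id is None:
        reasons.append(Reason.DBSNP)

    return reasons, None


def apply_filter_chain(
    cohort: Mapping[str, Sequence[AnnotatedVariant]],
    config: FilterConfig | None = None,
) -> dict[str, list[FilterOutcome]]:
    """Run the full filter chain over a patient -> variant-list mapping.

    The cohort mapping must cover every patient of the run because the
    recurrence rule counts carriers across it: a mutation key carried by
    strictly more than ``recurrence_fraction`` of patients and lacking a
    COSMIC annotation is removed from all carriers. A patient is counted
    once per key regardless of duplicate records.
    """
    if config is None:
        config = FilterConfig()
    n_patients = len(cohort)
    if n_patients == 0:
        raise ValueError("empty cohort")

    carriers: dict[MutationKey, set[str]] = {}
    for patient, variants in cohort.items():
        for v in variants:
            carriers.setdefault(v.key, set()).add(patient)
    recurrent = {
        key
        for key, pats in carriers.items()
        if len(pats) / n_patients > config.recurrence_fraction
    }

    results: dict[str, list[FilterOutcome]] = {}
    for patient, variants in cohort.items():
        outcomes = []
        for v in variants:
            reasons, error = _per_variant_reasons(v, config)
            if v.key in recurrent and v.cosmic_id is None:
                reasons = reasons + [Reason.RECURRENT_NON_COSMIC]
            kept = not reasons and error is None
            outcomes.append(
                FilterOutcome(variant=v, kept=kept, reason_codes=reasons, error=error)
            )
        results[patient] = outcomes
    return results


def kept_mutations(
    outcomes: Mapping[str, Sequence[FilterOutcome]]
) -> dict[str, set[MutationKey]]:
    """Per-patient set of mutation keys that survived the chain."""
    return {
        patient: {o.variant.key for o in outs if o.kept}
        for patient, outs in outcomes.items()
    }


def decompose_multiallelic(
    chrom: str,
    pos: int,
    ref: str,
    alts: Sequence[str],
    template: AnnotatedVariant | None = None,
    **fields,
) -> list[AnnotatedVariant]:
    """Split a multi-allelic site into one record per alt allele."""
    out = []
    for alt in alts:
        if template is not None:
            out.append(replace(template, chrom=chrom, pos=pos, ref=ref, alt=alt))
        else:
            out.append(AnnotatedVariant(chrom=chrom, pos=pos, ref=ref, alt=alt, **fields))
    return out
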