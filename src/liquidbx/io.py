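"""File formats: cohort tables (CSV), variant tables (VCF v4.2), truth JSON.

Cohort tables are comma-separated UTF-8 with a header row and "." for
missing values. Variant tables are VCF v4.2 with 1-based coordinates, INFO
keys GENE / FCLASS / DBSNP / COSMIC, and per-strand allele counts in the
ADF/ADR FORMAT convention (Number=R: ref first, then each alt). Each VCF
carries the assayed sample first and, when paired counts exist, a second
sample named NORMAL holding the germline counts. Multi-allelic records are
decomposed into one variant per alt allele on read.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd
import pysam

from .concordance import MutationKey
from .filters import AnnotatedVariant
from .synthetic import PlantedMutation, SimulatedTruth, SubjectRecord

MISSING = "."

_COHORT_COLUMNS = [
    "subject_id", "group", "age", "sex", "cfdna_level", "ca19_9", "cea",
    "stage", "node_positive", "tumor_size_cm",
]


class ParseError(ValueError):
    pass


# --------------------------------------------------------------------------
# cohort tables
# --------------------------------------------------------------------------

def write_cohort(records: Sequence[SubjectRecord], path: str | Path) -> None:
    rows = []
    for r in records:
        d = dataclasses.asdict(r)
        row = {}
        for col in _COHORT_COLUMNS:
            v = d[col]
            if v is None:
                row[col] = MISSING
            elif col == "node_positive":
                row[col] = "yes" if v else "no"
            elif isinstance(v, float):
                row[col] = repr(v)
            else:
                row[col] = str(v)
        rows.append(row)
    pd.DataFrame(rows, columns=_COHORT_COLUMNS).to_csv(path, index=False)


def read_cohort(path: str | Path) -> list[SubjectRecord]:
    """Parse a cohort table into typed records; malformed rows raise a
    ParseError naming the row and column."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    unknown = set(df.columns) - set(_COHORT_COLUMNS)
    if unknown:
        raise ParseError(f"unknown columns: {sorted(unknown)}")
    missing_cols = set(_COHORT_COLUMNS) - set(df.columns)
    if missing_cols:
        raise ParseError(f"missing columns: {sorted(missing_cols)}")

    def num(row_idx: int, col: str, raw: str) -> Optional[float]:
        if raw == MISSING or raw == "":
            return None
        try:
            return float(raw)
        except ValueError:
            raise ParseError(f"row {row_idx + 2}: non-numeric {col} value {raw!r}")

    records = []
    for idx, row in df.iterrows():
        group = row["group"]
        if group not in ("CCA", "BBD", "NORMAL"):
            raise ParseError(f"row {idx + 2}: unknown group {group!r}")
        level = num(idx, "cfdna_level", row["cfdna_level"])
        if level is None:
            level = float("nan")
        node_raw = row["node_positive"]
        records.append(SubjectRecord(
            subject_id=row["subject_id"],
            group=group,
            age=num(idx, "age", row["age"]) or 0.0,
            sex=row["sex"],
            cfdna_level=level,
            ca19_9=num(idx, "ca19_9", row["ca19_9"]),
            cea=num(idx, "cea", row["cea"]),
            stage=None if row["stage"] == MISSING else row["stage"],
            node_positive=None if node_raw == MISSING else node_raw == "yes",
            tumor_size_cm=num(idx, "tumor_size_cm", row["tumor_size_cm"]),
        ))
    return records


# --------------------------------------------------------------------------
# variant tables (VCF)
# --------------------------------------------------------------------------

def _vcf_header(sample: str, paired: bool) -> pysam.VariantHeader:
    h = pysam.VariantHeader()
    for i in range(1, 23):
        h.contigs.add(f"chr{i}", length=250_000_000)
    h.info.add("GENE", 1, "String", "Panel gene symbol")
    h.info.add("FCLASS", 1, "String", "Functional class of the variant")
    h.info.add("DBSNP", 1, "String", "dbSNP identifier, if annotated")
    h.info.add("COSMIC", 1, "String", "COSMIC identifier, if annotated")
    h.formats.add("ADF", "R", "Integer", "Forward-strand allele depths (ref, alt...)")
    h.formats.add("ADR", "R", "Integer", "Reverse-strand allele depths (ref, alt...)")
    h.formats.add("DP", 1, "Integer", "Total read depth")
    h.add_sample(sample)
    if paired:
        h.add_sample("NORMAL")
    return h


def write_variants(
    variants: Sequence[AnnotatedVariant], path: str | Path, sample: str = "SAMPLE"
) -> None:
    """Write annotated variants as an uncompressed single-patient VCF.

    The assayed sample's per-strand counts go in its ADF/ADR fields; when a
    variant carries germline counts a NORMAL sample is emitted with the
    (unstranded) germline counts split evenly across ADF/ADR.
    """
    paired = any(v.normal_alt is not None for v in variants)
    header = _vcf_header(sample, paired)
    path = Path(path)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for v in sorted(variants, key=lambda x: (x.chrom, x.pos, x.ref, x.alt)):
            rec = out.new_record(
                contig=v.chrom, start=v.pos - 1, stop=v.pos - 1 + len(v.ref),
                alleles=(v.ref, v.alt),
            )
            rec.info["GENE"] = v.gene
            rec.info["FCLASS"] = v.func_class
            if v.dbsnp_id:
                rec.info["DBSNP"] = v.dbsnp_id
                rec.id = v.dbsnp_id
            if v.cosmic_id:
                rec.info["COSMIC"] = v.cosmic_id
            s = rec.samples[sample]
            s["ADF"] = (v.tumor_ref_fwd, v.tumor_alt_fwd)
            s["ADR"] = (v.tumor_ref_rev, v.tumor_alt_rev)
            if v.depth is not None:
                s["DP"] = v.depth
            if paired and v.normal_alt is not None and v.normal_ref is not None:
                nf = v.normal_ref // 2
                af = v.normal_alt // 2
                n = rec.samples["NORMAL"]
                n["ADF"] = (nf, af)
                n["ADR"] = (v.normal_ref - nf, v.normal_alt - af)
                n["DP"] = v.normal_ref + v.normal_alt
            out.write(rec)


def read_variants(path: str | Path) -> list[AnnotatedVariant]:
    """Read a VCF back into annotated variants (one per alt allele).

    The first sample is the assayed one; a sample named NORMAL, if present,
    supplies the pooled germline counts. A missing ADF/ADR FORMAT on the
    assayed sample is a parse error naming the record.
    """
    out: list[AnnotatedVariant] = []
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        if not samples:
            raise ParseError(f"{path}: VCF has no samples")
        assay = samples[0]
        normal = "NORMAL" if "NORMAL" in samples[1:] else None
        for rec in vcf:
            s = rec.samples[assay]
            adf, adr = s.get("ADF"), s.get("ADR")
            if adf is None or adr is None or adf[0] is None:
                raise ParseError(
                    f"{path}: record {rec.contig}:{rec.pos} lacks ADF/ADR for {assay}"
                )
            n_alt = n_ref = None
            if normal is not None:
                ns = rec.samples[normal]
                nadf, nadr = ns.get("ADF"), ns.get("ADR")
                if nadf is not None and nadf[0] is not None:
                    n_ref = nadf[0] + nadr[0]
            info = dict(rec.info)
            for ai, alt in enumerate(rec.alts or (), start=1):
                alt_f, alt_r = adf[ai], adr[ai]
                ref_f, ref_r = adf[0], adr[0]
                if normal is not None and n_ref is not None:
                    n_alt = nadf[ai] + nadr[ai]
                depth = alt_f + alt_r + ref_f + ref_r
                out.append(AnnotatedVariant(
                    chrom=rec.contig, pos=rec.pos, ref=rec.ref, alt=alt,
                    gene=info.get("GENE", ""),
                    func_class=info.get("FCLASS", "other"),
                    tumor_alt_fwd=alt_f, tumor_alt_rev=alt_r,
                    tumor_ref_fwd=ref_f, tumor_ref_rev=ref_r,
                    normal_alt=n_alt, normal_ref=n_ref,
                    depth=depth,
                    vaf=(alt_f + alt_r) / depth if depth else 0.0,
                    dbsnp_id=info.get("DBSNP"),
                    cosmic_id=info.get("COSMIC"),
                ))
    return out


# --------------------------------------------------------------------------
# truth sidecar
# --------------------------------------------------------------------------

def _key_to_dict(k: MutationKey) -> dict:
    return {"gene": k.gene, "chrom": k.chrom, "pos": k.pos, "ref": k.ref, "alt": k.alt}


def _key_from_dict(d: dict) -> MutationKey:
    return MutationKey(d["gene"], d["chrom"], d["pos"], d["ref"], d["alt"])


def write_truth(truth: SimulatedTruth, path: str | Path) -> None:
    doc = {
        "stages": truth.stages,
        "artifact_keys": [_key_to_dict(k) for k in truth.artifact_keys],
        "somatic": {
            pid: [
                {
                    "key": _key_to_dict(m.key),
                    "truth_vaf": m.truth_vaf,
                    "tumor_vaf": m.tumor_vaf,
                    "detected_in_plasma": m.detected_in_plasma,
                    "cosmic_id": m.cosmic_id,
                }
                for m in muts
            ]
            for pid, muts in truth.somatic.items()
        },
        "germline": {
            pid: [_key_to_dict(k) for k in keys]
            for pid, keys in truth.germline.items()
        },
        "artifacts": {
            pid: [_key_to_dict(k) for k in keys]
            for pid, keys in truth.artifacts.items()
        },
    }
    Path(path).write_text(json.dumps(doc, indent=1, sort_keys=True))


def read_truth(path: str | Path) -> SimulatedTruth:
    doc = json.loads(Path(path).read_text())
    return SimulatedTruth(
        somatic={
            pid: [
                PlantedMutation(
                    key=_key_from_dict(m["key"]),
                    truth_vaf=m["truth_vaf"],
                    tumor_vaf=m["tumor_vaf"],
                    detected_in_plasma=m["detected_in_plasma"],
                    cosmic_id=m["cosmic_id"],
                )
                for m in muts
            ]
            for pid, muts in doc["somatic"].items()
        },
        germline={
            pid: [_key_from_dict(k) for k in keys]
            for pid, keys in doc["germline"].items()
        },
        artifacts={
            pid: [_key_from_dict(k) for k in keys]
            for pid, keys in doc["artifacts"].items()
        },
        stages=doc["stages"],
        artifact_keys=[_key_from_dict(k) for k in doc["artifact_keys"]],
    )
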