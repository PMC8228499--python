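"""Packaged reference data from the CCA liquid-biopsy study this package models.

Two kinds of constants live here:

* the 60-gene targeted sequencing panel used for mutation profiling of
  cholangiocarcinoma (CCA) plasma and tissue samples, and
* the published summary counts of the reference cohort (62 CCA / 33 benign
  biliary disease / 30 healthy controls for the biomarker arm; 10 CCA
  patients with paired tumor/plasma sequencing for the concordance arm).

The summary counts let the worked examples and the acceptance script
recompute the study's headline diagnostic numbers exactly — per-gene 2x2
agreement tables, the pooled nine-gene table, the mutation-level overlap,
and the ROC operating points from which the odds ratios are reconstructed.
"""

from __future__ import annotations

from .concordance import ConfusionTable

#: 60-gene CCA targeted panel (recurrently mutated / therapeutically
#: actionable genes in biliary tract cancer).
PANEL_GENES: tuple[str, ...] = (
    "TP53", "ARID1A", "KRAS", "SMAD4", "BAP1", "APC", "PBRM1", "ELF3",
    "ARID2", "STK11", "RNF43", "SF3B1", "ACVR2A", "RASA1", "BRCA2", "FBXW7",
    "IDH1", "BRAF", "RB1", "PIK3R1", "PTEN", "TGFBR2", "NRAS", "MAP2K4",
    "NCOR1", "CTNNB1", "IDH2", "GNAS", "KMT2C", "ATM", "PIK3CA", "ERBB2",
    "CDKN2A", "ERBB4", "FGFR2", "NF1", "ROS1", "BRCA1", "EGFR", "ROBO2",
    "ATRX", "GNAQ", "EPHA2", "FGFR1", "HRAS", "EZH2", "FGFR3", "ALK",
    "MYC", "MDM2", "TERT", "MAP2K1", "MAP2K2", "CDH1", "CDK4", "CDK6",
    "CDK12", "MLH1", "MTOR", "FGFR4",
)

#: Reference cohort group sizes (biomarker arm).
N_CCA = 62
N_BBD = 33
N_NORMAL = 30

#: Number of patients in the paired tumor/ctDNA sequencing arm.
N_SEQUENCED = 10

#: Per-gene tumor-vs-ctDNA agreement counts over the 10 sequenced patients,
#: for the nine recurrently mutated genes.  Orientation: tumor tissue is the
#: reference assay, ctDNA the test assay (tp = mutated in both, fp = ctDNA
#: only, fn = tumor only, tn = neither).
GENE_CONFUSIONS: dict[str, ConfusionTable] = {
    "ARID1A": ConfusionTable(tp=3, fp=0, fn=0, tn=7),
    "PBRM1": ConfusionTable(tp=3, fp=0, fn=0, tn=7),
    "NCOR1": ConfusionTable(tp=2, fp=0, fn=0, tn=8),
    "MTOR": ConfusionTable(tp=3, fp=0, fn=1, tn=6),
    "EZH2": ConfusionTable(tp=2, fp=0, fn=1, tn=7),
    "PTEN": ConfusionTable(tp=2, fp=0, fn=1, tn=7),
    "FGFR3": ConfusionTable(tp=2, fp=1, fn=0, tn=7),
    "RASA1": ConfusionTable(tp=1, fp=0, fn=2, tn=7),
    "TP53": ConfusionTable(tp=1, fp=1, fn=2, tn=6),
}

#: Cohort-wide mutation-level overlap between tumor and ctDNA call sets
#: (71 distinct somatic mutations across the 10 sequenced patients).
MUTATION_OVERLAP_SHARED = 40
MUTATION_OVERLAP_TUMOR_ONLY = 25
MUTATION_OVERLAP_CTDNA_ONLY = 6

#: Patient-level concordance category counts over the 10 sequenced patients.
PATIENT_CATEGORY_COUNTS = {"concordant": 2, "partially_concordant": 6, "discordant": 2}

#: ROC operating points (Youden-optimal cutoffs) for plasma cfDNA level,
#: with the case/control sample sizes that realize them.  Sensitivities and
#: specificities are fractions; cutoffs in ng/uL.
CFDNA_OPERATING_POINTS = {
    # comparison: (cutoff, sensitivity, specificity, n_case, n_control)
    "cca_vs_normal": (0.2175, 0.8871, 0.9667, N_CCA, N_NORMAL),
    "cca_vs_bbd": (0.3388, 0.8226, 0.5758, N_CCA, N_BBD),
    "bbd_vs_normal": (0.0897, 0.9091, 0.8000, N_BBD, N_NORMAL),
}

#: Clinical positivity cutoffs for the serum protein markers (upper limit
#: of the normal range): CA19-9 in U/mL, CEA in ng/mL.
CA19_9_CLINICAL_CUTOFF = 37.0
CEA_CLINICAL_CUTOFF = 2.5
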