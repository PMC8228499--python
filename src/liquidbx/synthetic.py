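"""Seeded synthetic cohorts and paired variant call sets with known truth.

Two generators make every downstream stage testable without access to the
study's raw sequencing:

* :func:`simulate_cohort` draws a three-group biomarker cohort
  (cholangiocarcinoma / benign biliary disease / healthy controls). Plasma
  cfDNA level is log-normal per group — the right-skewed, strictly positive
  shape such fluorometric measurements show — with multiplicative
  stage/node/size effects for the cancer group applied on the log scale.
  The covariate effects are centered so the configured group-level mean
  exp(mu + sigma^2/2) is preserved exactly; they redistribute levels within
  the group (stage IV above stage I, node-positive above node-negative)
  without moving the group mean.

* :func:`simulate_panel` plants somatic mutations, germline dbSNP
  polymorphisms and recurrent cross-patient artifacts over the 60-gene
  panel and renders them as paired tumor/germline/plasma call tables with
  Poisson depths, binomial alt counts at the truth VAF, and a binomial
  strand split — exactly the fields the filter chain consumes. Ground
  truth is returned alongside so filter recovery is checkable.

Randomness is hierarchical: one global integer seed plus stable per-record
stream keys, so enlarging a group appends subjects without perturbing the
ones already drawn.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .concordance import MutationKey
from .filters import AnnotatedVariant
from .reference import PANEL_GENES

STAGES = ("I", "II", "III", "IV")

_BASES = ("A", "C", "G", "T")


# --------------------------------------------------------------------------
# cohort simulation
# --------------------------------------------------------------------------

@dataclass
class GroupLevelParams:
    """Log-normal parameters of one group's cfDNA level (ng/uL):
    level = exp(N(mu, sigma^2)), mean = exp(mu + sigma^2/2)."""

    mu: float
    sigma: float


@dataclass
class MarkerParams:
    """Log-normal serum marker model with missing-at-random rate;
    ``missing_rate = 1`` means the marker is not assayed in that group."""

    mu: float = 0.0
    sigma: float = 1.0
    missing_rate: float = 0.0


@dataclass
class CohortConfig:
    """Study conditions for the biomarker cohort.

    Defaults reproduce the reference cohort: 62 CCA / 33 BBD / 30 controls;
    group mean cfDNA levels 1.89 / 0.57 / 0.08 ng/uL with heavy right
    tails; CCA stage distribution 6:8:12:36, ~53% node-positive, tumor
    size centered at 5 cm; CA19-9 and CEA partially missing, unmeasured in
    controls.
    """

    n_cca: int = 62
    n_bbd: int = 33
    n_normal: int = 30
    level_params: dict[str, GroupLevelParams] = field(default_factory=lambda: {
        # mu = ln(target mean) - sigma^2/2
        "CCA": GroupLevelParams(mu=math.log(1.89) - 1.4**2 / 2, sigma=1.4),
        "BBD": GroupLevelParams(mu=math.log(0.57) - 1.1**2 / 2, sigma=1.1),
        "NORMAL": GroupLevelParams(mu=math.log(0.08) - 0.9**2 / 2, sigma=0.9),
    })
    stage_probs: tuple[float, float, float, float] = (6 / 62, 8 / 62, 12 / 62, 36 / 62)
    # raw multiplicative level shifts per stage (centered before use)
    stage_effect: dict[str, float] = field(default_factory=lambda: {
        "I": 0.15, "II": 0.21, "III": 0.65, "IV": 1.46,
    })
    node_positive_prob: float = 33 / 62
    node_effect: float = 3.8
    size_effect_per_cm: float = 1.15
    size_gamma_shape: float = 6.25   # tumor size ~ Gamma: mean 5 cm, sd 2 cm
    size_gamma_scale: float = 0.8
    age_params: dict[str, tuple[float, float]] = field(default_factory=lambda: {
        "CCA": (64, 8), "BBD": (60, 10), "NORMAL": (41, 11),
    })
    male_prob: dict[str, float] = field(default_factory=lambda: {
        "CCA": 43 / 62, "BBD": 18 / 33, "NORMAL": 15 / 30,
    })
    marker_params: dict[str, dict[str, MarkerParams]] = field(default_factory=lambda: {
        "ca19_9": {
            "CCA": MarkerParams(mu=math.log(271.4) - 1.8**2 / 2, sigma=1.8,
                                missing_rate=8 / 62),
            "BBD": MarkerParams(mu=math.log(139.4) - 1.8**2 / 2, sigma=1.8,
                                missing_rate=4 / 33),
            "NORMAL": MarkerParams(missing_rate=1.0),
        },
        "cea": {
            "CCA": MarkerParams(mu=math.log(22.0) - 1.5**2 / 2, sigma=1.5,
                                missing_rate=21 / 62),
            "BBD": MarkerParams(mu=math.log(62.0) - 2.0**2 / 2, sigma=2.0,
                                missing_rate=8 / 33),
            "NORMAL": MarkerParams(missing_rate=1.0),
        },
    })
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_cca", "n_bbd", "n_normal"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if abs(sum(self.stage_probs) - 1.0) > 1e-9:
            raise ValueError("stage_probs must sum to 1")
        for g, p in self.level_params.items():
            if p.sigma <= 0:
                raise ValueError(f"level_params[{g}].sigma must be > 0")
        for e in list(self.stage_effect.values()) + [
            self.node_effect, self.size_effect_per_cm,
            self.size_gamma_shape, self.size_gamma_scale,
        ]:
            if e <= 0:
                raise ValueError("effect and scale parameters must be > 0")
        if math.log(self.size_effect_per_cm) >= 1.0 / self.size_gamma_scale:
            raise ValueError("size_effect_per_cm too large for the size distribution")


@dataclass
class SubjectRecord:
    subject_id: str
    group: str  # CCA | BBD | NORMAL
    age: float
    sex: str  # male | female
    cfdna_level: float
    ca19_9: Optional[float] = None
    cea: Optional[float] = None
    stage: Optional[str] = None
    node_positive: Optional[bool] = None
    tumor_size_cm: Optional[float] = None


def _effect_normalizer(config: CohortConfig) -> float:
    """E[e^shift] of the combined stage/node/size log shift, in closed form
    (stage: finite mixture; node: Bernoulli; size: Gamma MGF)."""
    stage_part = sum(
        p * config.stage_effect[s] for p, s in zip(config.stage_probs, STAGES)
    )
    node_part = (
        config.node_positive_prob * config.node_effect
        + (1.0 - config.node_positive_prob)
    )
    beta = math.log(config.size_effect_per_cm)
    size_part = (1.0 - config.size_gamma_scale * beta) ** (-config.size_gamma_shape)
    return stage_part * node_part * size_part


def analytic_group_mean(config: CohortConfig, group: str) -> float:
    """Closed-form expected cfDNA level of a group under the configured
    model (covariate effects are centered, so this is exp(mu+sigma^2/2))."""
    p = config.level_params[group]
    return math.exp(p.mu + p.sigma**2 / 2)


def _subject_rng(seed: int, group_idx: int, i: int) -> np.random.Generator:
    return np.random.default_rng([seed, 7, group_idx, i])


def simulate_cohort(config: CohortConfig) -> list[SubjectRecord]:
    """Draw the configured cohort; identical config + seed reproduce
    identical records."""
    config.validate()
    records: list[SubjectRecord] = []
    log_norm = math.log(_effect_normalizer(config))
    groups = [("CCA", config.n_cca), ("BBD", config.n_bbd), ("NORMAL", config.n_normal)]
    for gi, (group, n) in enumerate(groups):
        lp = config.level_params[group]
        for i in range(n):
            rng = _subject_rng(config.seed, gi, i)
            age_mu, age_sd = config.age_params[group]
            age = float(np.clip(rng.normal(age_mu, age_sd), 20, 90))
            sex = "male" if rng.random() < config.male_prob[group] else "female"

            log_level = rng.normal(lp.mu, lp.sigma)
            stage = node = size = None
            if group == "CCA":
                stage = STAGES[rng.choice(4, p=config.stage_probs)]
                node = bool(rng.random() < config.node_positive_prob)
                size = float(rng.gamma(config.size_gamma_shape, config.size_gamma_scale))
                size = max(size, 0.3)
                shift = math.log(config.stage_effect[stage])
                if node:
                    shift += math.log(config.node_effect)
                shift += math.log(config.size_effect_per_cm) * size
                log_level += shift - log_norm
            level = math.exp(log_level)

            markers: dict[str, Optional[float]] = {}
            for marker in ("ca19_9", "cea"):
                mp = config.marker_params[marker][group]
                if rng.random() < mp.missing_rate:
                    markers[marker] = None
                else:
                    markers[marker] = float(math.exp(rng.normal(mp.mu, mp.sigma)))

            records.append(SubjectRecord(
                subject_id=f"{group}{i + 1:04d}",
                group=group,
                age=round(age, 1),
                sex=sex,
                cfdna_level=level,
                ca19_9=markers["ca19_9"],
                cea=markers["cea"],
                stage=stage,
                node_positive=node,
                tumor_size_cm=None if size is None else round(size, 2),
            ))
    return records


# --------------------------------------------------------------------------
# panel simulation
# --------------------------------------------------------------------------

@dataclass
class PanelSimConfig:
    """Study conditions for the paired tumor/germline/plasma sequencing arm.

    Defaults emulate the 10-patient sequencing cohort: ~4.5 somatic
    mutations per tumor (range 1-10), stage-dependent plasma detection so
    ctDNA averages ~2.6 mutations per patient, truth VAF rising with stage
    (0.14 / 0.15 / 0.17 / 0.19 means), mean depths near 2500x (tumor),
    1450x (germline) and 1600x (plasma), a few dbSNP germline
    polymorphisms per patient, and recurrent non-COSMIC artifacts shared
    across patients.
    """

    n_patients: int = 10
    panel_genes: tuple[str, ...] = PANEL_GENES
    # P(k somatic mutations per tumor), k = 1..10 (truncated Poisson(4.5))
    n_somatic_per_patient: dict[int, float] = field(default_factory=lambda: (
        _truncated_poisson(4.5, 1, 10)
    ))
    stage_probs: tuple[float, float, float, float] = (0.1, 0.3, 0.0, 0.6)
    ctdna_detection_prob_by_stage: dict[str, float] = field(default_factory=lambda: {
        "I": 0.35, "II": 0.45, "III": 0.55, "IV": 0.70,
    })
    depth_params: dict[str, float] = field(default_factory=lambda: {
        "tumor": 2500.0, "plasma": 1600.0, "germline": 1450.0,
    })
    # truth VAF ~ Normal(mean, sd) clipped to [0.02, 0.95], per stage
    vaf_params: dict[str, tuple[float, float]] = field(default_factory=lambda: {
        "I": (0.14, 0.04), "II": (0.15, 0.05), "III": (0.17, 0.08), "IV": (0.19, 0.11),
    })
    tumor_vaf_params: tuple[float, float] = (0.28, 0.10)
    germline_snp_rate: float = 3.0       # expected dbSNP variants per patient
    artifact_rate: float = 2.0           # expected recurrent artifacts cohort-wide
    artifact_carrier_prob: float = 0.5   # P(an artifact shows in a patient's plasma)
    noise_rate: float = 2.0              # expected sub-threshold noise records/plasma
    cosmic_prob: float = 0.7             # P(a somatic mutation has a COSMIC id)
    germline_error_rate: float = 5e-4    # alt-read error rate at somatic sites
    force_single_strand_noise: bool = True
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients < 0:
            raise ValueError("n_patients must be >= 0")
        if not self.panel_genes:
            raise ValueError("panel_genes must be non-empty")
        if len(set(self.panel_genes)) != len(self.panel_genes):
            raise ValueError("panel_genes must be unique")
        for s, p in self.ctdna_detection_prob_by_stage.items():
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"ctdna_detection_prob_by_stage[{s}] out of [0,1]")
        for k, d in self.depth_params.items():
            if d <= 0:
                raise ValueError(f"depth_params[{k}] must be > 0")
        if abs(sum(self.stage_probs) - 1.0) > 1e-9:
            raise ValueError("stage_probs must sum to 1")
        total = sum(self.n_somatic_per_patient.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError("n_somatic_per_patient must sum to 1")


def _truncated_poisson(lam: float, lo: int, hi: int) -> dict[int, float]:
    ks = range(lo, hi + 1)
    weights = {k: math.exp(-lam) * lam**k / math.factorial(k) for k in ks}
    z = sum(weights.values())
    return {k: w / z for k, w in weights.items()}


@dataclass
class PlantedMutation:
    key: MutationKey
    truth_vaf: float           # plasma truth VAF
    tumor_vaf: float
    detected_in_plasma: bool
    cosmic_id: Optional[str]


@dataclass
class SimulatedTruth:
    """Ground truth of one panel simulation: per-patient planted somatic
    mutations, germline polymorphisms and shared artifacts (pairwise
    disjoint per patient), plus each patient's stage."""

    somatic: dict[str, list[PlantedMutation]]
    germline: dict[str, list[MutationKey]]
    artifacts: dict[str, list[MutationKey]]
    stages: dict[str, str]
    artifact_keys: list[MutationKey] = field(default_factory=list)


def _gene_locus(gene: str, panel: Sequence[str]) -> tuple[str, int]:
    idx = panel.index(gene)
    return f"chr{1 + idx % 22}", 1_000_000 * (1 + idx // 22) + 50_000 * (idx % 22)


def _random_site(rng: np.random.Generator, gene: str, panel: Sequence[str]) -> MutationKey:
    chrom, base = _gene_locus(gene, panel)
    pos = int(base + rng.integers(0, 5000))
    ref = _BASES[rng.integers(0, 4)]
    alt = _BASES[(_BASES.index(ref) + 1 + rng.integers(0, 3)) % 4]
    return MutationKey(gene, chrom, pos, ref, alt)


def _counts(
    rng: np.random.Generator, mean_depth: float, vaf: float,
    single_strand: bool = False,
) -> tuple[int, int, int, int]:
    """(alt_fwd, alt_rev, ref_fwd, ref_rev) with depth ~ Poisson, alt ~
    Binomial(depth, vaf), strand split ~ Binomial(alt, 1/2)."""
    depth = max(int(rng.poisson(mean_depth)), 1)
    alt = int(rng.binomial(depth, min(max(vaf, 0.0), 1.0)))
    ref = depth - alt
    if single_strand:
        alt_f, alt_r = alt, 0
    else:
        alt_f = int(rng.binomial(alt, 0.5))
        alt_r = alt - alt_f
    ref_f = int(rng.binomial(ref, 0.5))
    return alt_f, alt_r, ref_f, ref - ref_f


def _variant(
    key: MutationKey,
    rng: np.random.Generator,
    sample_depth: float,
    germ_depth: float,
    vaf: float,
    germ_vaf: float,
    func_class: str,
    dbsnp_id: Optional[str],
    cosmic_id: Optional[str],
    single_strand: bool = False,
) -> AnnotatedVariant:
    af, ar, rf, rr = _counts(rng, sample_depth, vaf, single_strand)
    g_depth = max(int(rng.poisson(germ_depth)), 1)
    g_alt = int(rng.binomial(g_depth, min(max(germ_vaf, 0.0), 1.0)))
    depth = af + ar + rf + rr
    return AnnotatedVariant(
        chrom=key.chrom, pos=key.pos, ref=key.ref, alt=key.alt, gene=key.gene,
        func_class=func_class,
        tumor_alt_fwd=af, tumor_alt_rev=ar, tumor_ref_fwd=rf, tumor_ref_rev=rr,
        normal_alt=g_alt, normal_ref=g_depth - g_alt,
        depth=depth, vaf=(af + ar) / depth if depth else 0.0,
        dbsnp_id=dbsnp_id, cosmic_id=cosmic_id,
    )


_SOMATIC_CLASSES = ("nonsynonymous_snv", "stopgain", "frameshift_indel", "splicing")
_NOISE_CLASSES = ("nonsynonymous_snv", "synonymous_snv", "nonframeshift_indel")


def simulate_panel(
    config: PanelSimConfig,
) -> tuple[dict[str, dict[str, list[AnnotatedVariant]]], SimulatedTruth]:
    """Generate per-patient tumor/germline/plasma call tables plus truth.

    Returns ``(tables, truth)`` where ``tables[patient_id]`` maps
    ``"tumor" | "germline" | "plasma"`` to lists of annotated variants.
    """
    config.validate()
    seed = config.seed
    panel = list(config.panel_genes)

    # cohort-wide artifact sites (recurrent, never COSMIC-annotated)
    art_rng = np.random.default_rng([seed, 11])
    n_art = int(art_rng.poisson(config.artifact_rate))
    artifact_keys = [
        _random_site(art_rng, panel[int(art_rng.integers(0, len(panel)))], panel)
        for _ in range(n_art)
    ]

    ks = sorted(config.n_somatic_per_patient)
    kp = np.array([config.n_somatic_per_patient[k] for k in ks])

    tables: dict[str, dict[str, list[AnnotatedVariant]]] = {}
    truth = SimulatedTruth(
        somatic={}, germline={}, artifacts={}, stages={},
        artifact_keys=artifact_keys,
    )

    for i in range(config.n_patients):
        pid = f"P{i + 1:03d}"
        rng = np.random.default_rng([seed, 13, i])
        stage = STAGES[rng.choice(4, p=config.stage_probs)]
        truth.stages[pid] = stage
        tumor: list[AnnotatedVariant] = []
        germline: list[AnnotatedVariant] = []
        plasma: list[AnnotatedVariant] = []

        used_sites: set[tuple[str, int]] = set()

        def fresh_site(gene_pool: Sequence[str]) -> MutationKey:
            while True:
                gene = gene_pool[int(rng.integers(0, len(gene_pool)))]
                key = _random_site(rng, gene, panel)
                if (key.chrom, key.pos) not in used_sites:
                    used_sites.add((key.chrom, key.pos))
                    return key

        # --- planted somatic mutations ---------------------------------
        n_som = int(rng.choice(ks, p=kp))
        detect_p = config.ctdna_detection_prob_by_stage[stage]
        vaf_mu, vaf_sd = config.vaf_params[stage]
        t_mu, t_sd = config.tumor_vaf_params
        planted: list[PlantedMutation] = []
        for _ in range(n_som):
            key = fresh_site(panel)
            plasma_vaf = float(np.clip(rng.normal(vaf_mu, vaf_sd), 0.02, 0.95))
            tumor_vaf = float(np.clip(rng.normal(t_mu, t_sd), 0.05, 0.95))
            cosmic = (
                f"COSM{rng.integers(10_000, 999_999)}"
                if rng.random() < config.cosmic_prob else None
            )
            func = _SOMATIC_CLASSES[int(rng.integers(0, len(_SOMATIC_CLASSES)))]
            detected = bool(rng.random() < detect_p)
            planted.append(PlantedMutation(key, plasma_vaf, tumor_vaf, detected, cosmic))

            tumor.append(_variant(
                key, rng, config.depth_params["tumor"],
                config.depth_params["germline"], tumor_vaf,
                config.germline_error_rate, func, None, cosmic,
            ))
            if detected:
                plasma.append(_variant(
                    key, rng, config.depth_params["plasma"],
                    config.depth_params["germline"], plasma_vaf,
                    config.germline_error_rate, func, None, cosmic,
                ))
        truth.somatic[pid] = planted

        # --- germline dbSNP polymorphisms (all three samples) -----------
        n_germ = int(rng.poisson(config.germline_snp_rate))
        germ_keys: list[MutationKey] = []
        for _ in range(n_germ):
            key = fresh_site(panel)
            germ_vaf = 1.0 if rng.random() < 0.3 else 0.5
            rsid = f"rs{rng.integers(1_000_000, 99_999_999)}"
            germ_keys.append(key)
            for sample, dest in (("tumor", tumor), ("plasma", plasma), ("germline", germline)):
                dest.append(_variant(
                    key, rng, config.depth_params[sample],
                    config.depth_params["germline"], germ_vaf, germ_vaf,
                    "nonsynonymous_snv", rsid, None,
                ))
        truth.germline[pid] = germ_keys

        # --- recurrent cross-patient artifacts (plasma only) -------------
        carried: list[MutationKey] = []
        for key in artifact_keys:
            if rng.random() < config.artifact_carrier_prob:
                carried.append(key)
                vaf = float(rng.uniform(0.12, 0.25))
                plasma.append(_variant(
                    key, rng, config.depth_params["plasma"],
                    config.depth_params["germline"], vaf,
                    config.germline_error_rate, "nonsynonymous_snv", None, None,
                ))
        truth.artifacts[pid] = carried

        # --- sub-threshold noise records (plasma only) --------------------
        n_noise = int(rng.poisson(config.noise_rate))
        for _ in range(n_noise):
            key = fresh_site(panel)
            vaf = float(rng.uniform(0.01, 0.08))
            single = config.force_single_strand_noise and rng.random() < 0.5
            func = _NOISE_CLASSES[int(rng.integers(0, len(_NOISE_CLASSES)))]
            plasma.append(_variant(
                key, rng, config.depth_params["plasma"],
                config.depth_params["germline"], vaf,
                config.germline_error_rate, func, None, None,
                single_strand=single,
            ))

        tables[pid] = {"tumor": tumor, "germline": germline, "plasma": plasma}

    return tables, truth
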