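# Methods

## Scope and data model

The package evaluates two liquid-biopsy questions for cholangiocarcinoma
(CCA): how well the plasma cfDNA *level* separates CCA from benign biliary
disease (BBD) and healthy controls, and how faithfully somatic mutations
called from plasma ctDNA reproduce the matched tumor tissue profile over a
60-gene panel. The pipeline starts from per-site allele counts: upstream
base calling, alignment, deduplication and functional annotation are taken
as given, with annotation (functional class, dbSNP id, COSMIC id) carried
as input fields on each variant. The 60-gene panel ships as a constant and
can be overridden.

## Somatic filter chain

A candidate variant carries per-strand alt/ref counts for the assayed
sample (plasma or tumor) and pooled counts for the matched germline. The
rules, applied in order with all failures recorded (no short-circuit):

1. **Functional class** — silent SNVs and non-frameshifting indels are
   excluded (configurable set).
2. **Read support** — alt reads ≥ 2 in total with ≥ 1 on each strand;
   site depth ≥ 200; VAF = alt/depth ≥ 0.1. The support wording "reads
   from both strands, with ≥2 supporting reads" is read as the weakest
   interpretation consistent with both clauses (≥2 total, ≥1 per strand);
   the stricter ≥2-per-strand reading is reachable via configuration.
3. **Somatic evidence** — one-sided Fisher exact p < 0.05 on the 2×2 table
   (sample vs germline) × (alt vs ref), alternative: sample enriched for
   alt. This is the paired-caller convention; the tail is the
   hypergeometric survival function. If the p-value is not supplied it is
   computed from the counts; if neither is available the variant gets an
   explicit error outcome, never a silent pass.
4. **Polymorphisms** — dbSNP-annotated variants are removed unless they
   also carry a COSMIC id.
5. **Recurrent artifacts** — a mutation key carried by strictly more than
   30% of the patients in the supplied run cohort, and lacking a COSMIC
   id, is removed from every carrier. Each patient counts once per key.
   The denominator is the cohort of the same run; note that in a
   one-patient run every non-COSMIC variant is trivially "recurrent",
   which is the faithful consequence of using the run cohort.

A COSMIC id exempts a variant from rules 4 and 5 only. The base-quality
threshold (default 15) is provenance metadata: counts are assumed to be
pre-thresholded upstream. Manual review is representable as user-supplied
allow/deny lists rather than a computation. Multi-allelic records are
decomposed into one variant per alt allele at parse time.

## Concordance and gene-level diagnostics

Mutation identity is the exact tuple (gene, chrom, pos, ref, alt); no
fuzzy matching of nearby indels, since no tolerance rule is defined for
one. Mutation-level concordance is shared/(shared + tumor-only +
ctDNA-only) over the cohort. Patients are concordant when both assays saw
the entire mutation union (a double-negative patient counts as agreement;
a separate no-call category is available), partially concordant when some
but not all of the union is shared, discordant when none is.

Gene-level tables count one unit per patient — a gene is positive in an
assay if the assay called ≥ 1 mutation in it — with tumor tissue as the
reference axis, so tp+fp+fn+tn equals the number of patients per gene and
pooling over genes is element-wise addition. Ratios with zero denominators
are reported as missing, never as 0. Cohen's κ uses
p_e = [(tp+fp)(tp+fn) + (fn+tn)(fp+tn)]/n² and is missing when p_e = 1.

Published gene tables in this field sometimes print the class-swapped
labeling (the "sensitivity" column holding tn/(tn+fp)); metrics are
therefore available in both labelings via an explicit `transposed` view
(tp↔tn, fp↔fn), under which sensitivity↔specificity and PPV↔NPV exchange
while accuracy and κ are invariant. The default follows the standard
tumor-as-truth convention, and no guess is made about which labeling an
external table intended.

## Cutoff-based biomarker diagnostics

Markers are evaluated as "higher is disease". Candidate cutoffs are the
midpoints between consecutive distinct observed values plus sentinels
outside the range, and positivity is strictly greater than the cutoff, so
every achievable empirical operating point is visited. The trapezoidal AUC
over this curve equals the tie-corrected Mann–Whitney statistic U/(n₁n₀)
(property-tested against brute-force pair enumeration). The AUC 95% CI
uses the Hanley–McNeil standard error with bounds clipped to [0, 1]; a
one-point distribution yields AUC 0.5 with a degenerate-curve flag.

The Youden cutoff maximizes J = SN + SP − 1; ties are broken toward the
lowest qualifying cutoff, which maximizes sensitivity at equal J. The
positive likelihood ratio SN/(1−SP) is missing at perfect specificity.
`reconstruct_two_by_two` recovers integer 2×2 tables from printed
sensitivity/specificity and group sizes by rounding tp = sens·n_case and
tn = spec·n_control, enabling exact recomputation of odds and likelihood
ratios from published operating points.

Crude odds ratios use the cross-product with Woolf (log-normal) 95% CIs;
when any cell is zero the Haldane–Anscombe +0.5 correction is applied to
all cells and flagged, and a zero diagonal is reported missing. Logistic
regression is fit by Newton/IRLS (convergence: max |score| < 1e-8, cap 50
iterations); complete separation is detected — diverging coefficients or
fully saturated fitted probabilities that perfectly classify — and flagged
instead of being reported as a converged fit. For a single dichotomous
predictor the fitted exp(coefficient) equals the cross-product odds ratio
(tested property). Adjusted models encode sex as binary and, by default,
age dichotomized at the cohort median, since no encoding is canonical.

Rank-based comparisons delegate to the standard tie-corrected
implementations (Mann–Whitney with exact small-sample null when n₁+n₂ ≤ 12
and no ties; Kruskal–Wallis against χ²_{k−1}); Dunn's post hoc test is
computed from pooled rank means with tie correction and reports both
unadjusted and Bonferroni-adjusted p-values, as no single adjustment is
canonical. All p-values are two-sided except the somatic Fisher test.
Detection rates exclude subjects missing a marker from that marker's
denominator; clinical positivity cutoffs default to 37 U/mL (CA19-9) and
2.5 ng/mL (CEA), distinct from any ROC-derived cutoff.

## Synthetic study generators

The cohort generator draws per-group cfDNA levels from log-normals —
right-skewed, strictly positive, matching the heavy upper tails such
fluorometric measurements show (group means near 1.89 / 0.57 / 0.08 ng/µL
with observed maxima an order of magnitude above the mean). Only group
means and ranges are published, not log-scale spreads, so the default
sigmas (1.4 / 1.1 / 0.9) are a packaged choice that reproduces both the
means (via mu = ln(mean) − sigma²/2) and plausible ranges at the study's
sample sizes; they are a modeling decision, not an estimate of the
study's data.

Within the CCA group, stage, nodal status and tumor size shift the level
multiplicatively on the log scale (stage multipliers 0.15/0.21/0.65/1.46,
node ×3.8, ×1.15 per cm). These shifts are *centered*: the combined
multiplier is divided by its closed-form expectation (finite stage
mixture × Bernoulli node × Gamma moment-generating function for size), so
the group mean stays exactly exp(mu + sigma²/2) while subgroups separate.
Tumor size uses a Gamma (mean 5 cm, sd 2 cm) precisely because its MGF
gives that normalizer in closed form. CA19-9 and CEA are log-normal with
missing-at-random rates matching the published availability (8/62 and
21/62 missing among CCA; unmeasured in controls). Covariates are drawn
independently of one another, which real cohorts violate (stage, node and
size co-vary); tests passing on this generator show the pipeline's
arithmetic is right, not that real cfDNA data meet the model.

The panel generator plants 1–10 somatic mutations per tumor (truncated
Poisson, mean 4.5), each detectable in plasma with a stage-dependent
probability (0.35/0.45/0.55/0.70) chosen so plasma averages roughly 2.6
detectable mutations per patient; plasma truth VAFs rise with stage
(means 0.14–0.19). Read counts are depth ~ Poisson (tumor 2500×, plasma
1600×, germline 1450×), alt ~ Binomial(depth, VAF), strand split ~
Binomial(alt, ½), with an option to force single-strand support on noise
records to exercise the strand rule. Germline polymorphisms (VAF 0.5 or
1.0, dbSNP-tagged) appear in all three samples; cohort-wide artifact
sites appear in each patient's plasma with probability 0.5, so they
usually — not always — exceed the 30% recurrence cutoff, and the truth
sidecar lets tests condition on the realized carrier count. No read-level
errors, alignment artifacts or base-quality structure are simulated.

Randomness is hierarchical: a single integer seed plus fixed per-subject
and per-patient stream keys, so enlarging one group appends new subjects
without perturbing existing ones.

## Validation against the reference study

The study's headline ctDNA-vs-tissue numbers are exactly recomputable
from its printed per-gene 2×2 counts, and its odds/likelihood ratios from
printed operating points and group sizes; `scripts/acceptance.py` and the
acceptance tests do exactly that through the package's operations.
Quantities that would need the patient-level data (the real-cohort AUCs,
group means, VAF-by-stage means, covariate-adjusted odds ratios) are
covered instead by property checks on synthetic data: AUC ≡ U-statistic on
random fixtures; the somatic Fisher tail against an independent
log-factorial enumeration for every 2×2 with both row margins ≤ 50;
filter-chain truth recovery on a seeded panel; κ = 1 with all patients
concordant under perfect detection; empirical AUC within 0.02 of the
closed-form log-normal AUC Φ(Δμ/√(σ₁²+σ₀²)) at 5000 per group (covariate
effects off); and Kruskal–Wallis type-I error ≈ 5% over 1000 null
replicates. One published inconsistency is deliberately not reproduced:
the BBD-vs-control crude odds ratio cannot be recovered from the printed
sensitivity/specificity and group sizes (reconstruction gives a different
integer table), so it is excluded from the recomputation set.

Problem sizes in the test suite (5000 per group for calibration checks,
1000 replicates for the type-I-error check, 10-patient panels) keep the
whole suite under a minute while leaving Monte-Carlo error well inside
the asserted tolerances.

## Known limitations

- The filter chain assumes counts are already base-quality-filtered and
  deduplicated; it cannot detect upstream artifacts that mimic clean
  strand-balanced support.
- Mutation matching is exact; representation differences (indel
  left-alignment, MNV decomposition) would appear as discordance.
- The recurrence rule's denominator is the run cohort, so results depend
  on which patients are co-analyzed.
- The logistic module fits plain maximum likelihood; no penalization, so
  quasi-separated designs yield large, honest Wald intervals rather than
  shrunken estimates.
- No survival or prognosis modeling, no tumor-fraction or clonality
  estimation, and no read-level (FASTQ/BAM) handling.
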