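# Methods

`cnvassoc` implements a candidate-locus copy-number association analysis:
copy numbers at a biallelic-dosage CNV locus (the "E2" amplicon near exon 2
of *LEPR*, shared with *LEPROT*) are quantified from QMPSF peak heights,
dichotomized into low (1X) and high (2X) classes by sex-stratified medians,
and tested for association with metabolic traits, type 2 diabetes status,
and transcript abundance. Because the underlying cohort data are not
public, the package ships a synthetic-data generator whose defaults encode
the study conditions, so every stage is validated by parameter recovery.

## Copy-number model and QMPSF calling

Each multiplex reaction amplifies three loci: the E2 target (1 or 2 copies
per genome depending on genotype), the X-linked Factor VIII reference
(1 copy in males, 2 in females) and the autosomal invariant CN2-2 reference
(always 2 copies). The expected peak height of amplicon *a* is
*k<sub>a</sub>* · *c<sub>a</sub>*, an amplicon-specific efficiency constant
times the template copy count, with multiplicative log-normal noise per
reaction.

Relative copy number is the **mean over replicate reactions of the
per-reaction ratio** height(target)/height(reference). Mean-of-ratios
(rather than ratio of mean heights) is robust to per-reaction intensity
scaling; reactions with a zero reference peak are excluded, and a subject
with no usable reaction is a calling error. With 3 rounds × 2 duplicates
and a per-reaction ratio CV of ~7.3%, the subject-level estimate has a
relative SE of ~3%, so the 1-copy and 2-copy classes (a 2× separation) are
~16 within-subject SEs apart — which is why dichotomized calls recover the
true genotype essentially always at the default noise level.

Dichotomization is strictly **within sex**: the cutoff is the median
relative CN of the non-diabetic reference subjects of that sex, and a
subject is low (1X) iff strictly below it. The strict-less-than rule makes
an even stratum of distinct values split exactly in half (287/287 for 574
men) and sends the median-valued subject of an odd stratum to the high
class (246/247 for 493 women). The same cutoffs are reused for diabetic
subjects. Degenerate strata (all values equal) call everything high, with
a warning.

The dual references give a QC cross-check: the per-subject FVIII/CN2-2
ratio is split into two clusters by an exhaustive 1-D two-class split
minimizing within-cluster variance (O(n log n) after sorting); the lower
cluster is inferred male. If the cluster separation is below twice the
pooled within-cluster SD the distribution is declared degenerate and no sex
is assigned. The per-reaction CN2-2/FVIII ratio CV, computed within sex,
is the calibration statistic for the invariant reference (~7.3% at
defaults).

## CNV-region detection

From a probe × subject matrix of real-valued CN estimates, the per-probe
sample standard deviation (n−1 denominator) across subjects is the
dispersion statistic. CNV regions are maximal runs of consecutive probes
with dispersion **> 0.25** (the published cutoff); runs shorter than
`min_probes` (default 3) are discarded and up to `merge_gap` (default 0)
sub-threshold probes may be bridged. Minimum-run and gap rules are not in
the source analysis, which only states the cutoff — they are needed to
produce well-defined regions and are exposed as CLI flags. Region bounds
are the first and last probe positions (1-based, inclusive), and runs never
cross chromosomes.

Copy-number-invariant windows (the CN2-2 analogue) are selected by a
sliding window minimizing mean per-probe dispersion, ties to the leftmost.
Individual profiles are median-smoothed (default window 5, centred,
truncated at the edges) and rounded to integer states; exact .5 ties round
away from the diploid baseline 2, so 1.5 → 1 and 2.5 → 3.

## Association statistics

Per trait and sex stratum: a two-sided pooled-variance Student's *t*
between the low and high classes (accepting raw samples or (mean, sd, n)
summaries, which are equivalent by construction); a covariate-adjusted
p-value from OLS of the trait on {group indicator, age, BMI} (normal-theory
two-sided test of the group coefficient); and Bonferroni correction
p_corrected = min(1, m·p) with **m = 29**, the number of tabulated traits
excluding the two covariates. Because the table is sex-stratified, sex
drops out of the adjustment. Traits missing for more than 20% of subjects
are skipped with a warning.

The nested case-control layer reports the 2×2 odds ratio OR = ad/bc with
the **Woolf** 95% interval exp(ln OR ± 1.96·√(1/a+1/b+1/c+1/d)) and the
Pearson χ² p (df = 1, no continuity correction) — from the published
counts (86, 49, 123, 135) these reproduce the printed 1.92, 1.26~2.96 and
0.003. A zero cell triggers the Haldane–Anscombe +0.5 correction, flagged.
The covariate-controlled odds ratio comes from a logistic regression fitted
by iteratively reweighted least squares (convergence max |Δβ| < 1e-8 within
50 iterations; |β| > 15 is treated as separation), with Wald p-values. On a
saturated 2×2 design the IRLS coefficient equals ln(ad/bc) and its SE the
Woolf SE, which the tests verify to 1e-6; conditional (matched-set)
logistic regression is deliberately not implemented.

## Dosage–expression stage

Relative expression uses the comparative-Ct method with perfect doubling
per cycle: per experiment ΔCt = mean Ct(target) − mean Ct(GAPDH), level =
2^(−ΔCt), averaged over the three experiments. The dosage–expression
relationship is an OLS fit of level on relative DNA copy number (R², slope
t-test on n−2 df, slope sign). Correlation is computed on the linear
2^(−ΔCt) scale by default, with a log2 option, since either scale is
defensible for such data.

## Synthetic-data generator

The generator's defaults are the study conditions:

- **Cohort**: 574 men and 493 women; each trait drawn independently per
  (sex, genotype) cell from the published non-diabetic group summaries
  (mean ± SD). Exactly round(n·low_cn_fraction) subjects per sex carry the
  low-CN genotype (default fraction 0.5, shuffled positions): the published
  groups are exactly balanced, and a fixed-count draw keeps the median
  cutoff consistent with the generating fraction, which an iid Bernoulli
  draw would not. HOMA-IR is derived as fasting insulin × fasting
  glucose / 405 so the identity holds subject-by-subject; its group moments
  follow from the insulin and glucose parameters and sit close to (not
  exactly at) the tabulated HOMA-IR row.
- **Peaks**: 3 rounds × 2 duplicates; per-amplicon log-normal noise with
  CV 0.073/√2 ≈ 0.0516, chosen because the ratio of two independent equal-CV
  log-normals has CV ≈ CV·√2, reproducing the reported 7.3% reference-ratio
  CV.
- **Diabetes**: WHO OGTT rule, fasting ≥ 126 mg/dL or 2-h ≥ 200 mg/dL
  (≥ convention at the boundary); the source cites WHO criteria without
  numbers, so the standard values are the defaults.
- **Case-control arms**: 137 cases with low-CN fraction 0.637 (the observed
  86/135) and diabetic-range OGTT glucose (fasting ~N(155, 25), 2-h
  ~N(230, 45) mg/dL); an 8,000-subject non-diabetic control pool represents
  the wider source cohort from which nested controls are drawn — without it,
  1:2 matching at the tight BMI ± 0.1 kg/m² tolerance would drop roughly half
  the cases instead of a handful. Matching is greedy and reproducible:
  cases in ascending id order, same sex, age ± 1 y, BMI ± 0.1, nearest BMI
  first, ties by ascending control id, without replacement; infeasible
  cases are dropped and logged.
- **CN matrix**: 200 probes × 90 subjects, background N(2, 0.1); probes
  40–60 carry a per-subject integer state from {1, 2, 3} (equifrequent by
  default, population SD √(2/3) ≈ 0.816 ≫ 0.25) plus N(0, 0.1) noise.
- **Expression**: 32 lines; log2 relative expression = intercept +
  slope·relative CN + N(0, 0.3), slope −1.0 for LEPR and +0.5 for LEPROT.
  With the default relative-CN spread these give R² around 0.4 and 0.15 —
  the magnitudes reported for the real LCL panel — but only the pair of
  correlation signs is a validation target, since the printed R² values
  require the original cell lines.

Determinism: every artefact is a pure function of the configuration seed
(independent salted streams per artefact), so identical configurations give
byte-identical outputs.

What the generator does **not** emulate: trait–trait correlation (only
marginal group summaries are published, so traits are independent given sex
and genotype — adjusted p-values are therefore slightly conservative
relative to real data where age/BMI correlate with outcomes);
physiological nonnegativity (plain Gaussians can produce negative CRP or
insulin in the tails); longitudinal follow-up (the multi-wave design is
collapsed to one diabetes flag); linkage structure; electropherogram-level
artefacts (peak calling from raw traces is out of scope). Passing
recovery tests therefore demonstrates correctness of the statistical
machinery under the assumed generative model, not robustness to real-data
pathologies.

## Numerical choices and degenerate inputs

- Sample (n−1) standard deviations throughout.
- Dispersion cutoff comparisons are strict (> 0.25), as is the low-call
  rule (< median).
- Zero-height reference reactions are excluded, not imputed.
- χ² p-values are computed from the original (uncorrected) counts even when
  the OR needs the Haldane correction.
- IRLS starts from β = 0; a singular weighted information matrix or
  diverging coefficients raise a separation error rather than returning
  garbage.
- Two-cluster sex inference refuses to assign sex when separation < 2×
  pooled within-cluster SD.

## Validation problem sizes

The test-suite and acceptance-script simulations use: the full published
cohort size (1,067) for genotype/sex recovery; 100 seeds for CNV-region
boundary recovery and for fasting-glucose power at the published effect
size; 20 null cohorts (580 null tests) for type-I error; 200 seeds at
n = 32 for expression-sign recovery; 200 random 2×2 tables for the
IRLS/closed-form agreement property.

One power result deserves a note: at the published fasting-glucose effect
in men (3.7 mg/dL, SDs 7.5/6.5, n = 287 + 287) the noncentrality is ≈ 6.32
while the Bonferroni-corrected 10⁻⁴ threshold needs |t| > 4.69, so the
per-seed probability of a corrected p < 10⁻⁴ is ≈ 0.95 exactly — a
knife-edge quantity whose observed rate over any finite seed set fluctuates
around 95%.

## Known limitations

- Matched sets are analyzed with unconditional logistic regression (the
  matching variables are included as covariates); a conditional likelihood
  would be the strictly correct treatment of matched strata.
- The per-probe dispersion scan assumes a cohort-level matrix; the
  single-sample reference-genome comparison modes of array CNV callers are
  not reimplemented.
- qPCR efficiency is fixed at 2.0 per cycle; no standard-curve calibration.
- The trinucleotide-deletion variant that shifts the target amplicon from
  242 to 245 bp is carried as metadata only and never genotyped.
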