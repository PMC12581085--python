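# Methods

## Scope and data model

`mrmediate` implements summary-statistics Mendelian randomisation: all
inference uses per-variant GWAS association records (effect size, SE,
alleles, allele frequency, p, sample size) for one exposure, a panel of
outcomes and a panel of candidate mediators. A `SummaryStats` holds one
trait's records (pandas-backed, unique variant ids, validated on load); a
`HarmonisedSet` holds exposure/outcome effect pairs aligned to a common
effect allele and is the input to every univariable estimator. Continuous
traits are assumed standardised (effects per SD); binary traits are on the
log-odds scale.

## Instrument selection and harmonisation

Instruments are genome-wide-significant variants (default p < 5×10⁻⁸)
pruned to mutual independence by greedy clumping: candidates are visited in
ascending p (ties broken lexicographically by variant id, which makes the
output invariant to input row order), and a candidate is retained iff its
r² with every already-retained variant within the window (default
±10,000 kb, boundary inclusive) is below the threshold (default 0.001).
When no LD matrix is supplied, pruning falls back to distance only —
retained variants on a chromosome must be more than one window apart — since
reference-panel LD computation is out of scope. Instrument strength is the
mean per-SNP F = (β̂/σ)²; instruments are flagged weak unless mean F
strictly exceeds 10.

Harmonisation aligns the outcome's effect to the exposure's effect allele:
swapped labels flip the sign and complement the frequency; strand flips
resolve by base complement; palindromic (A/T, C/G) variants are aligned by
allele frequency and dropped when either trait's frequency lies in
(0.40, 0.60) or is missing — a conventional, configurable policy. Every
decision is recorded per SNP (`unchanged`, `allele_flipped`,
`dropped_palindromic`, `dropped_missing`, `dropped_incompatible`);
irreconcilable allele pairs warn rather than abort.

## Estimators

* **Wald ratio** — β̂_Y/β̂_X; first-order SE σ_Y/|β̂_X| by default, with a
  second-order option adding the exposure-noise term
  β̂_Y²σ_X²/β̂_X⁴. First-order weights are the classical choice and keep
  IVW equal to the textbook weighted mean.
* **IVW** — fixed-effect weighted mean of Wald ratios; the headline model
  is multiplicative random effects, inflating the SE by
  max(1, √(Q/(n−1))). The floor at 1 means the random model can never claim
  more precision than the fixed one.
* **MR-Egger** — weighted regression with free intercept after orienting
  all SNPs to positive exposure effect; SEs use the same multiplicative
  inflation floored at 1; inference uses t with n−2 df. The intercept is
  the directional-pleiotropy diagnostic.
* **Weighted median** — value at cumulative normalised weight 0.5 with
  linear interpolation between the centred cumulative weights of adjacent
  order statistics.
* **Weighted mode** — maximiser of the inverse-variance-weighted normal
  kernel density over Wald ratios on a 2048-point grid spanning the ratio
  range ±3 bandwidths. The bandwidth is 0.9·min(SD, normalised MAD)·n^(−1/5)
  times a user factor; the MAD term keeps a single outlier from inflating
  the bandwidth; a zero-spread ratio set short-circuits to the common value.
* **Bootstrap SEs** (median, mode) — seeded parametric bootstrap of the
  per-SNP betas. Outcome-side noise is drawn in antithetic pairs (+z, −z),
  which halves Monte-Carlo variance and makes the SE exactly invariant
  under negating all outcome effects (a symmetry the point estimators obey
  by construction). A seed is mandatory; there is no hidden global RNG.
* **p-values** — two-sided normal for all estimators except Egger (t,
  n−2 df), clamped to ≥1e-300 so they remain valid probabilities.
  Intervals use the fixed multiplier 1.96 to match 95% reporting.

## MR-PRESSO

The observed residual sum of squares is Σ_j (β̂_Yj − β̂₍₋j₎β̂_Xj)² with
β̂₍₋j₎ the leave-one-out fixed-IVW slope. The null distribution comes from
seeded parametric draws (exposure betas resampled about their observed
values, outcome betas about the leave-one-out fit), with the empirical
p-value continuity-corrected (+1 in numerator and denominator), so the
global p is bounded below by 1/(n_sim+1). Per-SNP outlier p-values compare
each observed squared residual with its simulated distribution and are
Bonferroni-adjusted across instruments (flag threshold 0.05). The corrected
estimate is IVW after removing flagged SNPs (same model as the headline
fit); the distortion test compares the observed slope shift against the
distribution of shifts from removing an equally sized random subset of
non-flagged instruments. Defaults: n_sim = 1000, configurable.

## Multivariable MR and mediation

The MVMR design pools genome-wide-significant variants across exposures,
prunes the union with greedy priority by each variant's minimum p across
exposures, harmonises every trait to the first exposure's allele coding and
intersects with the outcome. The fit is no-intercept weighted least squares
(weights 1/σ_Y²) with the same multiplicative SE inflation floored at 1;
a rank-deficient exposure matrix raises an error naming the collinear
exposures, except that an all-zero exposure column (no instrument signal)
is assigned a zero coefficient and infinite SE while leaving the other
coefficients untouched.

The pipeline default adjusts each mediator *pairwise* with the exposure
(exposure + one mediator as the two MVMR exposures), matching the
definition of β₂ as the mediator's effect conditional on the exposure;
joint multi-mediator decomposition is out of scope.

Mediation: indirect = β₁β₂ with delta-method SE √(β₁²se₂² + β₂²se₁²)
(first order, cross-term omitted; the Monte-Carlo-validated exact product
SE exceeds it by the √(se₁²se₂²) term, negligible when either coefficient
is well estimated). The proportion mediated has two reporting modes:

* `exact` — unrounded indirect/total, delta-method variance with both
  ratio terms. The scientific default for new analyses.
* `table2_convention` — the indirect effect (and its CI bounds) is first
  rounded to two decimals, then divided by the total point estimate and
  expressed as a percentage rounded to two decimals, ties to even. This is
  the convention that exactly reproduces published two-step MR tables whose
  coefficients are printed at two decimals, and is the default in the
  report pipeline so printed tables are internally consistent. Percentage
  CIs in this mode divide the rounded indirect-effect CI bounds by the
  total, treating the total as fixed; displayed upper bounds cap at 100%.

Qualification requires all three criteria with strict inequalities:
β₁'s p below the mediator layer (default 0.05/24), β₂'s p below the
mediator-outcome layer (default 0.05/96; the pipeline recomputes this
denominator from the number of step-2 tests actually performed), and sign
agreement between β₁β₂ and the total effect.

The overlap-SNP sensitivity re-runs the whole decomposition after removing
every variant genome-wide significant for *both* the exposure and the
mediator from all instrument sets, reporting the excluded count; if the
exclusion empties an instrument set the result is returned flagged
non-estimable rather than raising.

## Synthetic GWAS generator

`simulate_triad` emulates the study conditions entirely on the summary
level. Per instrument j: MAF ~ U(maf_range); the exposure effect γ_j is
normal with variance h²/(n_snps·2·maf(1−maf)), so the instruments jointly
explain h² of exposure variance; the mediator's true effect is
θ_xm·γ_j plus its own instruments' effects γm_j (variance
mediator_h2/(n_med_snps·2·maf(1−maf))); the outcome's true effect is
θ_direct·γ_j + θ_my·(mediator effect) + α_j with pleiotropy
α_j ~ N(pleiotropy_mean, pleiotropy_sd²) on exposure instruments. Observed
betas add noise with the GWAS standard-error profile
σ = 1/√(2·n·maf(1−maf)), using the effective size 4/(1/n_case+1/n_control)
for binary traits whose effects are generated directly on the log-OR scale.
Null background SNPs have no true effects, so their p-values are uniform.

The mediator needs instruments of its own because a mediator whose only
genetic signal is θ_xm·γ would make the MVMR design exactly collinear;
identifiability of β₂ in two-step designs rests on mediator-specific
variants.

Defaults are one realistic study condition, fixed once: 100 exposure
instruments with h² = 0.02 in a 298,142-sample exposure GWAS (expected mean
instrument F = 1 + n·h²/n_snps ≈ 60, comfortably past the weak-instrument
threshold of 10), a 450,243-sample continuous mediator with 100 instruments
(h² = 0.04), a binary outcome with 8,125 cases / 381,977 controls, and a
causal chain θ_xm = 0.47, θ_my = 0.22, total = 0.38 (true mediated
proportion 27.2%). Ten percent of emitted records are allele-swapped so
harmonisation is always exercised. Variants sit 20 Mb apart across 22
chromosomes — more than one pruning window — so distance-only clumping
treats them as independent; `simulate_ld_block` provides correlated
variants (r² decaying geometrically, 100 kb spacing) for testing the
clumping rule itself.

What the simulator does **not** model: real LD structure from reference
panels, sample overlap between the exposure and outcome GWAS (the
two-sample design is assumed exactly), covariate adjustment of the exposure
GWAS, population stratification, or individual-level binary-trait
generation (log-OR effects with effective-n SEs stand in for a logistic
model). Passing simulation tests therefore validates the estimators under
clean two-sample assumptions, not robustness to those real-data artefacts.

## Pipeline and reproducibility

`run_study` executes the funnel: exposure instrument selection → per-outcome
total effects (screened at 0.05/n_outcomes) → step-1 effects
(0.05/n_mediators) → step-2 MVMR only for screened (outcome, mediator)
pairs → qualification → mediation table (qualified pairs only, matching the
published-table shape) → sensitivity block → Sankey edge list (plain TSV;
rendering is external). Per-pair failures are logged with a reason code and
the run continues. Bonferroni thresholds use strict inequality and are also
reported rounded to four decimals for display.

All stochastic steps derive their seeds deterministically from the study
seed and the pair label (CRC32 mix, kept below 2³¹), so report files are
byte-identical across reruns; the human-readable `run.log` carries a
wall-clock timestamp and is the one file exempt from byte identity. Display
strings round to two decimals half-away-from-zero; the table-convention
percentage rounds ties to even (see above).

## Validation problem sizes

The simulation-based checks run at sizes chosen to keep the whole suite in
the low minutes while leaving Monte-Carlo error well inside the asserted
bands: 2,000 replicates for IVW coverage and Egger type-I error (binomial
SE ≈ 0.5%), 100 replicates for MR-PRESSO outlier recovery, 500 replicates
per true proportion for mediation recovery, 50–60 instruments per
replicate. Coverage is checked under the default case/control outcome,
where the exposure GWAS is roughly ten times larger on the effective scale
than the outcome GWAS — the regime in which first-order Wald weights (which
neglect exposure-side noise) are calibrated; with a same-size continuous
outcome and a large causal effect, first-order IVW intervals undercover by
design (≈92–93%), which is a known property of the weighting, not an
implementation artefact.

## Known limitations

No conditional F-statistics, Steiger direction filtering, MVMR-Egger,
contamination mixture, RAPS, non-linear MR, or counterfactual
natural-effect mediation. The proportion-mediated CI ignores the covariance
between the indirect and total estimates (both use the exposure's
instruments), as is standard when only summary statistics are available.
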