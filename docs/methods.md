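# Methods

## The problem and the model

`targetmr` implements drug-target Mendelian randomisation (MR) from GWAS
summary statistics.  The exposure is the genetically proxied activity of a
drug's protein target; the instruments are cis SNPs near the encoding gene
that associate strongly with the exposure; the outcome is a disease (the
bundled worked example: ovarian cancer).  Under the instrumental-variable
assumptions (relevance, independence from confounders, and effect on the
outcome only through the exposure), the ratio of a SNP's outcome effect to
its exposure effect estimates the causal effect of pharmacologically
modulating the target.

Per SNP *j* the inputs are the exposure association β̂ₓⱼ (SE σₓⱼ) and the
outcome association β̂ᵧⱼ (SE σᵧⱼ), harmonised to a common effect allele.
The estimators:

* **Wald ratio** — β̂ᵧⱼ/β̂ₓⱼ with first-order SE σᵧⱼ/|β̂ₓⱼ| (exposure
  uncertainty ignored; adequate because the F ≥ 10 filter guarantees
  strong instruments).
* **IVW** — the weighted regression of β̂ᵧ on β̂ₓ through the origin with
  weights 1/σᵧ², i.e. the inverse-variance meta-analysis of the Wald
  ratios: β̂ = Σβ̂ₓβ̂ᵧ/σᵧ² ÷ Σβ̂ₓ²/σᵧ².
* **MR-Egger** — the same weighted regression with a free intercept; the
  intercept estimates the average directional pleiotropy, the slope a
  pleiotropy-adjusted causal effect.
* **Weighted median** — the weighted median of the Wald ratios with
  weights β̂ₓ²/σᵧ²; consistent when instruments carrying at least half the
  weight are valid.

## Variance conventions (what pins the reported numbers)

The exact variance convention determines the reported p-values, so it is
fixed deliberately:

* The IVW default is **multiplicative random effects floored at the
  fixed-effect SE** (`mre_floor`): with Cochran's
  Q = Σwⱼ(β̂ᵧⱼ/β̂ₓⱼ − β̂)², wⱼ = β̂ₓⱼ²/σᵧⱼ², the fixed-effect SE
  (Σβ̂ₓ²/σᵧ²)^(−1/2) is multiplied by max(1, √(Q/(L−1))).  Under
  homogeneity this is the fixed-effect SE; under heterogeneity the
  multiplicative random-effects SE.  This is the convention under which
  the bundled reference results reproduce exactly, verified for every
  target before implementation.  `fixed` and `mre` (no floor) are
  available as modes.
* MR-Egger mirrors the same floor: coefficient SEs are the unscaled
  (XᵀWX)^(−1/2) diagonal times max(1, σ̂), with σ̂² the weighted residual
  mean square on L−2 degrees of freedom.  This keeps IVW and Egger
  uncertainties comparable.
* p-values are two-sided standard normal for all methods (matches the
  reference results exactly; a t reference would not).
* The default 95% CI multiplier is **1.96 exactly**, not the exact normal
  quantile 1.959963985.  This is the convention of standard MR reporting
  tools, and it is the only multiplier that reproduces the bundled
  reference CI endpoints to the printed precision (the implied multiplier
  backed out of those endpoints is 1.9600000 on both sides).  Other
  confidence levels use the exact quantile.
* The weighted median uses the cumulative-weight rule: sort ratios
  ascending, give value *i* cumulative position (Σ₁..ᵢwₖ − wᵢ/2)/Σw, and
  interpolate linearly where the position crosses ½.  Its SE is a seeded
  parametric bootstrap (default 10,000 resamples of β̂ₓ*, β̂ᵧ* normal
  around the observed values with the observed SEs).

## Instrument selection

* **cis window**: gene body ± `window_bp` (default 100 kb), closed on both
  boundaries, read as symmetric flanks on the region's chromosome.
* **Significance**: exposure p < 5×10⁻⁸, strict inequality.
* **LD clumping**: greedy over ascending p-value (ties broken
  lexicographically by snp_id, so output is deterministic and independent
  of input order); a SNP is kept iff its squared Pearson correlation with
  every already-kept SNP's dosage column in the user-supplied reference
  matrix is below `r2_threshold` (default 0.3).  No remote LD service is
  ever queried.
* **Strength**: two F conventions are implemented.  The default derives F
  from the per-SNP variance explained, R² = 2β̂ₓ²·EAF·(1−EAF) under a
  unit-variance exposure, as F = R²(n−k−1)/(k(1−R²)); the companion
  convention is the squared Wald ratio (β̂ₓ/σₓ)².  The R²-based form is
  the default because the bundled table's tabulated F values are
  consistent with it (at a per-target constant implied n — e.g. inverting
  the strongest CASP1 instrument's (R², F) pair gives n ≈ 3934 — and not
  with (β̂ₓ/σₓ)²).  Instruments with F < `f_min` (default 10) are
  filtered.

## The bundled instrument table

The package ships a 77-row harmonised instrument table covering 11
ovarian-cancer drug targets (CASP1, CASP3, CCND1, FNTA, FNTB, HMGCR,
HSPA5, ITGAL, NEU1, PLA2G4A, PTGS1), used by the test-suite and the
worked example.  Notes on its interpretation:

* The rows are treated as **pre-harmonised**: the outcome beta already
  refers to the exposure's effect allele.  This is the only reading under
  which the reference odds ratios are reproducible.
* Each target carries an outcome-cohort label (`ieu-a-1120`, a dedicated
  ovarian-cancer case/control GWAS, or `ieu-b-4963`, a biobank GWAS with
  linear-probability-scale effects).  The per-target assignment is
  inferred from how the reference results were grouped, not stated
  row-by-row; the outcome-beta magnitudes suggest the grouping may not be
  exact for four targets, but the label affects no computed number.
* One CASP3 row (rs2171835) has F = 0.185 < 10 although the reference
  analysis describes all 77 instruments as having F > 10.  The row is kept
  — it is required to reproduce the reference CASP3 estimate — and the
  contradiction is documented here rather than resolved.
* Three of the reference summary numbers are internally inconsistent and
  are treated as transcription typos in the source, not as targets: the
  CASP3 point odds ratio (its own CI midpoint and p-value both imply
  0.999272957, which this package computes, rather than the separately
  printed 0.999417702); the ITGAL "p-value" 0.000579236 (it equals the SE
  implied by the ITGAL CI; the CI itself is exactly consistent with the
  mre-floored p of 0.0196 computed here); and the HMGCR CI upper bound
  (printed identical to the lower bound; the computed lower bound matches
  the printed 1.027776107 exactly, the computed upper bound is 1.2453).
* Re-running MR-PRESSO on the bundled CASP1 rows flags rs61751523 (an
  instrument whose outcome effect is 3.4 SEs from the pooled fit), even
  though the reference analysis reports no outliers anywhere.  The claim
  is asserted in tests only for synthetic homogeneous data and for FNTA,
  where it holds.

## Sensitivity diagnostics

* **Cochran's Q** around the IVW fit (df L−1) or the Egger fit (df L−2),
  upper-tail chi-square p.  The IVW-flavour Q is the same computation that
  scales the IVW SE — a single code path, asserted by test.
* **Egger intercept test**: intercept ≠ 0 at α = 0.05 flags directional
  pleiotropy.
* **MR-PRESSO** (re-implemented from its published algorithmic
  description): observed statistic RSS = Σ(β̂ᵧⱼ − β̂ₓⱼ·β̂₍₋ⱼ₎)²/σᵧⱼ² with
  β̂₍₋ⱼ₎ the IVW slope excluding SNP j; the null is simulated
  parametrically (β̂ₓ* ~ N(β̂ₓ, σₓ), β̂ᵧ* ~ N(β̂ₓβ̂₍₋ⱼ₎, σᵧ), default
  1,000 draws — a desk-scale default, adjustable via `n_sim`).
  Monte-Carlo p-values use the add-one estimator
  (1 + #exceedances)/(1 + n_sim), which never returns exactly zero and
  keeps the finite-simulation outlier test from over-flagging.  Per-SNP
  outlier p-values are Bonferroni-corrected across instruments.  The
  distortion test is not implemented in this version.
* **Leave-one-out**: the default IVW re-fitted with each instrument
  removed, in input order.

## The synthetic generator

`synthetic_data` simulates the causal model MR assumes, end to end:

* **Genotypes**: two haplotypes per individual from a first-order Markov
  chain along SNPs with marginal frequencies `mafs` (default U(0.1, 0.5))
  and adjacent-haplotype correlation `ld_rho`; dosage = haplotype sum.
  One parameter controls LD — deliberately simpler than a full correlation
  matrix, and sufficient to exercise the clumper on both sides of any
  r² threshold.
* **Phenotypes**: exposure X = Gγ + N(0,1); binary outcome from a
  logistic model with linear predictor c + θX + Gα, the intercept c
  solved by Brent's method so the expected case fraction equals
  `outcome_prevalence` (default 0.1).  θ is the causal effect; a non-zero
  α injects pleiotropy.
* **Summary statistics**: per-SNP simple linear regression for the
  exposure; per-SNP logistic regression (two-parameter Newton iterations,
  batched across SNPs) or a linear-probability model for the outcome.
  Monomorphic SNPs yield flagged degenerate records (β=0, SE=∞, p=1)
  that all downstream filters exclude.
* `simulate_mr_dataset` draws **two independent cohorts** (exposure and
  outcome), making the summary statistics a genuine two-sample pair.

Default conditions for calibration experiments: cohorts of 20,000,
20 strong instruments (γ alternating in sign, |γ| from 0.08 to 0.15,
giving per-SNP F well above 30), prevalence 0.1.  The directional
pleiotropy magnitude used in detection experiments is α = 0.04 per
allele, chosen by an a-priori power calculation (Egger intercept SE ≈
0.008 under these conditions, so the expected detection rate is near 1).

What the generator does **not** emulate: realistic human LD structure,
population stratification, relatedness, sample overlap between the two
cohorts, imputation noise, and winner's-curse selection of instruments.
Passing calibration tests therefore demonstrate correctness of the
estimators under the assumed model, not robustness to those
complications.

## Calibration experiments (problem sizes)

The acceptance-level calibration tests run the full pipeline (simulate
both cohorts → GWAS → harmonise → estimate) at the reference conditions:

* type-I error of the IVW test under θ=0: 2,000 replicates, expected in
  [0.04, 0.06];
* 95% CI coverage under θ=0.3: 200 replicates, expected in [0.92, 0.97];
* Egger-intercept flag rate under α=0.04 directional pleiotropy:
  200 replicates, expected above 0.5;
* MR-PRESSO detection of a 10-SE planted outlier: 100 replicates,
  expected ≥ 90 detections; and an empty outlier list on homogeneous
  data: 100 replicates, expected ≥ 95.

The type-I and coverage checks evaluate the **fixed-effect** IVW
variance, which is the correctly calibrated variant when the instruments
are genuinely homogeneous; the `mre_floor` default is conservative by
construction (its SE is never smaller), so its rejection rate under the
null sits below the nominal level.  Smaller-scale versions of these
experiments (summary-level generators, fewer replicates, wider binomial
tolerances) run in the per-module unit tests.

## Numerical and degenerate-input choices

* Coordinates are 0-based half-open internally; BED is read natively and
  1-based inputs must be converted at the boundary.
* Summary TSVs are parsed with Python's correctly rounded float parser,
  so write-then-read round-trips are bit-exact.
* Palindromic SNPs (A/T, C/G) are dropped by default during
  harmonisation; `keep` and `freq-infer` (EAF-based orientation with an
  ambiguity band of 0.42–0.58) are available.
* A zero exposure effect makes the Wald ratio undefined (error); a zero
  outcome SE makes an inverse-variance weight infinite (error).
* Exact (noise-free) Egger fits have zero residual scale; the floor then
  leaves the unscaled coefficient SEs, which remain positive.
* Multiple-testing across targets is **not** part of the primary
  procedure; the report includes a clearly labelled Bonferroni column as
  a convenience only.

## Known limitations

* The weighted-median bootstrap resamples β̂ₓ and β̂ᵧ independently; any
  exposure/outcome correlation from sample overlap is not modelled.
* MR-PRESSO's distortion test, robust/penalised median variants,
  mode-based estimators, multivariable MR, and Steiger filtering are out
  of scope.
* The LD reference must be user-supplied (or simulated); no remote panel
  lookup exists by design.
* Implied per-target exposure sample sizes recovered from (R², F) pairs
  are diagnostic only; they are not stated inputs.
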