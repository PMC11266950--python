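# Methods

## Model and estimators

`mrkit` implements the summary-statistics form of two-sample Mendelian
randomization. The causal parameter is the log odds ratio of a binary
outcome per unit of the exposure; each genetic instrument supplies one Wald
ratio `θ_i = β_yi / β_xi` with first-order delta-method standard error
`σ_yi / |β_xi|`. The first-order SE ignores exposure-side sampling error;
a second-order option adds `θ_i² σ_xi² / β_xi²` in quadrature but is not the
default, because published per-SNP confidence intervals in the reference
application are consistent with first-order (the packaged reproduction would
not close otherwise). Exposure-side noise is the textbook source of
weak-instrument bias; the simulator makes that regime reachable rather than
the SE pretending to absorb it.

Pooling is inverse-variance weighting. Three modes:

* `fixed` — `θ̂ = Σw_iθ_i/Σw_i`, `se = (Σw_i)^(-1/2)`, `w_i = 1/se_i²`.
* `multiplicative_random` (default) — same `θ̂`, SE inflated by
  `φ = max(1, √(Q/(k−1)))`. The floor at 1 means under-dispersed sets fall
  back to the fixed-effect SE. This flavour was chosen because it is the
  default of the widely used TwoSampleMR tooling and because it is the only
  flavour that reproduces all three published CI pairs of the reference
  analysis: the CAD interval requires φ = 1.213 > 1 and the stroke/T2D
  intervals require the floor.
* `additive_random` — DerSimonian–Laird: `τ² = max(0, (Q−df)/c)` with
  `c = Σw − Σw²/Σw`, re-weighting by `1/(se_i²+τ²)`. Provided for
  comparison; cross-checked in tests against the statsmodels
  meta-analysis routines.

Cochran's `Q = Σw_i(θ_i−θ̂)²` is referred to χ²(k−1). With a single
estimate the "pooled" result is the estimate itself and Q is reported
absent; leave-one-out therefore degrades gracefully at k = 2. CIs and
p-values use the normal reference distribution throughout (z = 1.959964 at
95%), matching standard MR practice; no t-correction is applied because the
inputs are themselves large-sample GWAS estimates.

The instrument-strength statistic is `F = (R²/(1−R²))·(n−k−1)/k`. The
sample size `n` is an explicit argument: the conventional choice is the
exposure-GWAS n, but the reference analysis computed per-outcome F values
from the outcome-GWAS sample sizes, and the packaged reproduction follows
that convention (it is the only reading that reproduces 558.5 / 65.4 /
1732.1 from R² = 0.0147 and k = 4). Both uses are plain function calls; the
result object records which n produced it.

## Harmonization

Exposure/outcome records are matched by rsid only. Allele reconciliation
tries, in order: identical pairs (kept as-is), swapped pairs (outcome beta
negated, EAF reflected), and the same two cases after strand
complementation. Palindromic variants (A/T, C/G) cannot be resolved by
complementation, so orientation is taken from allele frequency; when either
study's EAF lies within 0.08 of 0.5 — or is missing — the variant is
dropped rather than guessed. The window is configurable; 0.08 is a common
two-sample default, and with the reference instruments (all non-palindromic)
nothing hinges on it. Irreconcilable alleles are dropped as mismatches, and
every action is recorded on the pair so filtering is auditable.

A weight stated for a variant's other allele is re-expressed on the dosage
allele by negation. Reflecting the dosage column instead (g → 2−g) changes
any weighted score by a per-variant constant only, so association z-scores
are invariant to the convention; tests pin both facts.

## Scale conversion

Linear-mixed-model GWAS of case/control status (BOLT-LMM style) report
effects on the 0/1 scale; dividing the effect and SE by `μ(1−μ)`, with μ the
case fraction, converts to approximate log odds ratios. The approximation is
first-order and is validated in tests by simulating binary traits, fitting
per-variant linear models, converting, and comparing against directly
fitted logistic slopes (agreement within 3 logistic SEs; SEs within 10%).
Printed OR confidence intervals are turned back into log-scale SEs via
`(ln U − ln L)/(2z)`, which is exact for symmetric normal-theory intervals
and is what lets published tables serve as analysis inputs.

## Pleiotropy scan

Each variant and the weighted GRS are regressed against a trait panel —
ordinary least squares for continuous traits, logistic regression for
binary ones, optional covariates — and `z = β/se` is aligned so that
positive values mean "associated with higher genetically predicted
exposure": a variant whose exposure weight is negative has its z negated;
the GRS is aligned by construction. Benjamini–Hochberg FDR is applied
across all predictor × trait cells jointly by default (the conservative,
reproducible family; per-predictor is available) and flags are exactly
`q < α`. Non-convergent or degenerate cells (zero-variance predictor,
constant trait, separation) become missing values excluded from the FDR
family, never zeros.

## Synthetic data generator

The generator emulates the study design the estimators assume:

* **Genotypes** — independent variants in Hardy–Weinberg equilibrium,
  dosage = Binomial(2, EAF). Defaults: 4 variants, EAFs (0.1, 0.2, 0.3,
  0.4), equal variance shares. No LD, no stratification — by design, since
  the estimators assume independent instruments.
* **Exposure** — per-variant effects scaled so
  `Σ 2·eaf_i(1−eaf_i)·β_i² = R²` on the unit-variance latent scale
  (default R² = 0.0147, the reference instrument set's variance explained),
  Gaussian residual, then rank-based inverse normal transformation (Blom
  offset 3/8, average ranks for ties), mirroring how hormone phenotypes are
  GWAS-ed. Effects are per-unit-INT thereafter.
* **Outcome** — logistic model `P(y=1) = expit(α + θ·x + c·u)` with the
  intercept solved by Brent's method so the expected case fraction equals
  the target prevalence (tolerance 1e-10). Default prevalence 0.267 and
  n = 17,541 match the smallest (stroke-like) outcome study; the default
  causal effect is zero.
* **Two-sample structure** — one pooled population; the exposure GWAS takes
  the first `n_exposure` individuals (default 7,049, the exposure-GWAS
  size) and the outcome GWAS the last `n_outcome`, so `overlap_fraction`
  of the outcome sample is shared (default 0: the reference design had no
  exposure/outcome overlap for its largest outcome source). An optional
  shared confounder (`confounder_strength`, default 0) loads equally on
  the exposure and the outcome linear predictor; it exists to demonstrate
  the weak-instrument sample-overlap bias mechanism and is off otherwise.

Because the outcome model conditions on the exposure, marginal per-variant
logistic slopes are mildly attenuated by non-collapsibility; at the default
effect sizes and prevalences this is well inside Monte-Carlo error of the
recovery tests, and the null-calibration results do not depend on it.

What passing tests on these data do **not** show: robustness to LD between
instruments, population stratification, assay artefacts, phenotype
misclassification, or horizontal pleiotropy of real variants — none of
which the generator produces.

## Verification scales and numerical choices

* Published-value reproduction is deterministic desk-scale arithmetic:
  per-SNP SEs from printed CIs (rounded to 2 dp in print), hence tolerances
  of ±0.01 on ORs and CI bounds, ±0.05 on Q, ±0.1 on F in the packaged
  checker — input rounding dominates.
* Null calibration: 500 full-pipeline replicates at n = 5,000/5,000,
  prevalence 0.3, R² = 0.0147; type-I error and 95% CI coverage asserted
  within 3 binomial SEs of 0.05/0.95.
* Causal recovery: 40 replicates at n = 20,000/20,000, θ = 0.3, prevalence
  0.1; mean within 3 SEMs.
* Overlap bias: 300 paired replicates per arm at n = 600/600 with a
  confounder of 0.6–0.8; with F ≈ 2–3 the Wald ratios are heavy-tailed, so
  the arms are compared by median and only the direction is asserted.
* Extreme Wald ratios (near-zero exposure beta) produce `inf` odds ratios
  rather than exceptions, keeping weak-instrument simulations runnable;
  `β_x = 0` itself is a hard error.
* Ordering is everywhere the caller's input order; no tie-breaking is
  needed. All generators accept integer seeds and echo them in their truth
  records; fixed seed implies byte-identical outputs.

## Known limitations

MR-Egger, weighted-median and MR-PRESSO estimators are deliberately absent:
they are not identifiable or not meaningful with as few as four instruments,
which is the regime this package's reference application occupies. The
harmonizer does not search proxies, lift positions over builds, or query
remote catalogs. The F-statistic is the approximation from R², n and k, not
a re-fit first-stage F; when R² comes from a discovery sample it can
overstate strength in the analysis sample.
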