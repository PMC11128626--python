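# Methods

## Design

The pipeline implements a two-sample, two-step Mendelian randomization (MR)
design with a drug-target exposure.  Genetic variants serve as instruments
under the three usual conditions: association with the exposure, no
association with confounders, and no effect on the outcome except through
the exposure.  "Two-sample" means exposure and outcome effects come from
non-overlapping GWAS; "two-step" means the mediator is handled by two
further univariable MR fits whose product estimates the indirect effect.

Stages, in fixed order:

1. **Colocalization gate.**  Drug-target (cis) instruments are only trusted
   if gene expression and the validating biomarker share a causal variant at
   the locus (posterior of the shared-variant hypothesis H4 above 0.70).
2. **Instrument selection.**  Significance filter, greedy LD clumping, weak
   instrument exclusion, confounder screen — in that order, with every
   removal logged.
3. **Estimation.**  Five-estimator panel plus sensitivity suite per outcome.
4. **Mediation.**  Product of coefficients and mediated proportion.

## Harmonization

Outcome effects are aligned to the exposure's effect allele.  Swapped allele
labels flip the outcome beta sign and replace the frequency by its
complement; strand flips are resolved by nucleotide complementing.
Palindromic variants (A/T, C/G) cannot be oriented by labels; under the
default `infer` policy they are oriented by allele frequency and dropped when
either frequency lies in [0.42, 0.58] (too close to 0.5 to call the strand)
or is missing.  Harmonization is idempotent on its survivors and every drop
carries a recorded reason.

## Instrument selection

- Significance thresholds follow the design: genome-wide 5e-8 for the
  mediator GWAS, locus-wide 1e-4 for the cis exposure set.
- Clumping is greedy: repeatedly take the smallest-p remaining variant as an
  index and discard variants with r² above the threshold against it.  Both
  thresholds are interpreted on the r² scale (0.001 genome-wide, 0.8 within
  the cis locus), the convention of standard clumping tools; p-value ties
  break by variant id so the result is order-invariant.
- Instrument strength is F = (β/σ)², the squared z-score, requiring only the
  printed summary columns; variants with F < 10 are excluded as weak.  The
  variance-explained form (n−2)R²/(1−R²) is available as
  `f_statistic_from_r2`.
- The confounder screen removes variants annotated to blocked traits
  (defaults: low-density lipoprotein, coronary artery disease) from a local
  two-column annotation table; no web service is queried.

## Colocalization

Per-variant evidence is the Wakefield approximate Bayes factor: with
z = β/σ, V = σ² and prior effect variance W,

    log ABF = ½ [ log(1 − r) + r z² ],   r = W/(W + V).

Prior effect SDs default to 0.15 (quantitative traits) and 0.20 (binary);
hypothesis priors default to p1 = p2 = 1e-4, p12 = 1e-5.  The five hypothesis
sums (H0 none, H1/H2 one trait, H3 distinct variants, H4 shared variant) are
accumulated in log space with log-sum-exp; H3's cross term is the product of
the single-trait sums minus the same-variant sum.  The gate requires
PP(H4) strictly greater than 0.70.

## Estimators

All estimates are on the log-odds scale for binary outcomes; odds ratios are
exp-transformed with 95% CIs.

- **IVW**: weighted regression of β̂_Y on β̂_X through the origin, weights
  σ_Y⁻².  Default is multiplicative random effects — the fixed-effect SE
  inflated by max(1, √(Q/(J−1))) — reducing to fixed effects in homogeneous
  data.  One instrument degrades to the Wald ratio.
- **MR-Egger**: the same regression with a free intercept after orienting
  every instrument to a positive exposure effect; solved by explicit weighted
  normal equations.  The residual variance scale is floored at 1 (never
  tighter than fixed effects).  A nonzero intercept estimates the average
  directional pleiotropy; its two-sided test is the pleiotropy diagnostic.
- **Weighted median**: Wald ratios ordered, weights (β_X/σ_Y)² normalized;
  the estimate interpolates the cumulative weight function (evaluated at
  observation midpoints) at 0.5.
- **Mode estimators**: normal-kernel density over the Wald ratios with
  bandwidth φ × 0.9·min(sd, MAD)·J^(−1/5) (modified Silverman; φ defaults
  to 1), argmax taken on a 2048-point grid spanning the ratios ± 3
  bandwidths.  When the robust scale is zero (tied ratios) the h→0 limit —
  the discrete weighted mode — is returned.  The weighted variant weights
  each ratio by (β_X/σ_Y)².
- Median and mode SEs come from a parametric bootstrap (effects redrawn from
  their reported normals; 5,000 draws by default, seed required), p-values
  from the normal reference.  Estimator p-values are two-sided normal;
  heterogeneity p-values are upper-tail chi-square.

### Sensitivity suite

- **Cochran's Q** over Wald ratios with first-order weights (β_X/σ_Y)²,
  referenced to the fixed-effect IVW estimate; χ²(J−1).
- **Leave-one-out**: IVW re-fitted J times omitting one variant.
- **MR-PRESSO**: the observed statistic is the weighted residual sum of
  squares in which each variant's prediction uses the IVW slope fitted
  without it.  The null distribution comes from parametric simulations
  (default 5,000, ≥ 1,000 required) with exposure effects redrawn around
  their observed values and outcome effects generated from the full-sample
  IVW slope.  Centring each variant's simulated outcome on its own
  leave-one-out slope — a superficially natural choice — plants artificial
  between-variant heterogeneity in the null draws and makes the global test
  severely conservative (empirical size ~0.005 at nominal 0.05); with the
  single generating slope the size is ~0.03 and a +10σ outlier is flagged
  essentially always.  Outlier p-values are per-residual tail probabilities
  with Bonferroni correction across instruments; the distortion test
  compares the estimate with and without outliers against the distortion
  from removing random subsets of the same size.

## Mediation

The indirect effect is β₁β₂ (product of coefficients).  Intervals:

- **delta**: SE = √(β₁²σ₂² + β₂²σ₁²), symmetric normal CI;
- **monte-carlo** (default): (b₁, b₂) drawn from independent normals,
  empirical 2.5/97.5 percentiles of b₁b₂.  The product of normals is
  skewed when either coefficient is imprecise, so the percentile interval
  is asymmetric — consistent with the asymmetric published interval, whose
  exact construction (and the SEs behind it) is not recoverable from the
  printed table; exact reproduction of that CI is therefore not claimed,
  while the point estimates and ratios reproduce exactly.

The mediated proportion is 100·β₁β₂/β_total with a delta or Monte-Carlo
ratio interval (default Monte-Carlo, 100,000 draws; the delta method for
ratios is fragile when the total effect is small).  β₂ comes from the
univariable mediator→outcome fit, which assumes the mediator's instruments
reach the outcome only through the mediator; variants acting through the
exposure pathway must be screened out via the annotation mechanism, which is
the role the confounder screen plays in the design.

## Synthetic data

Summary statistics are simulated directly at the summary level: each
variant's observed effect is a normal draw around its true marginal effect
with the analytic SE

    σ = 1/√(2·maf·(1−maf)·n)            (quantitative, standardized scale)
    σ = 1/√(2·maf·(1−maf)·n·v·(1−v))    (binary, log-odds, case fraction v).

This matches two-sample MR theory (estimators consume only summary
statistics), keeps ground truth exact, and is orders of magnitude faster
than genotype-level simulation.  The causal graph places direct exposure
effects γⱼ and direct mediator effects δⱼ on disjoint variant sets, giving
marginal effects γⱼ, θ_EM γⱼ + δⱼ and (θ_direct + θ_MO θ_EM)γⱼ + θ_MO δⱼ
(+ optional pleiotropy αⱼ) on exposure, mediator and outcome.  LD blocks,
when configured, propagate both true effects and sampling noise through the
block correlation matrix.  Defaults mirror the motivating study: θ_EM =
−0.0502, θ_MO = 0.0304, total effect −0.0171; VTE-like mediator
(12,240/484,598 cases) and rare cardiac-death-like outcome (1,597/361,194
cases); MAF uniform on [0.05, 0.5]; per-allele exposure effects of SD 0.02
(HbA1c scale) and mediator log-odds effects of SD 0.10.

The study-shaped fixture engineers the published instrument accounting: 13
genome-wide-significant mediator variants of which 9 are clump indices, 4
are satellites at r = 0.6 to an index, and 2 indices carry LDL/CAD
annotations, so the selection pipeline keeps exactly 7; the exposure is a
6-variant cis set.  Background z-scores are clipped at |z| = 3 so the counts
hold for every seed; the noise around planted signals is deliberately small
(a tenth of the SE), which makes the fixture's heterogeneity statistics
unrealistically clean — it validates structure and plumbing, not dispersion.

What the generator does not emulate: realistic genome-wide LD, winner's
curse from discovery-stage selection, sample overlap between the two
samples, MAF-dependent effect-size architecture, and non-collapsibility of
the odds ratio (binary traits enter only through the SE scaling).  Passing
recovery and calibration tests therefore demonstrates correctness of the
estimators under the stated model, not robustness to those real-data
features.

## Test and experiment sizes

Recovery experiments use 200 replicates of 50 strong instruments (per-allele
effect SD 0.15 at n = 10⁶, so mean F is in the thousands and the 1/F Wald
dilution is negligible), selected by true strength to avoid winner's curse;
acceptance checks compare each estimator's mean to truth within 3 Monte-Carlo
SEs.  Calibration uses 500 null replicates for IVW and the Egger intercept
and 200 for MR-PRESSO (1,000 simulations each), requiring empirical size in
[0.02, 0.09] at nominal 0.05.  Colocalization gate behaviour is measured
over 100 simulated loci per scenario.  These sizes give stable Monte-Carlo
estimates while keeping the full suite fast on a laptop.

## Numerical choices and degenerate inputs

- Posterior sums and ABF accumulation in log space; posteriors sum to 1
  within 1e-9.
- p-values are clamped to the smallest positive double rather than 0, so the
  (0,1] invariant holds even for extreme z-scores.
- Clump ties broken lexicographically by variant id; mode grid of 2048
  points; bootstrap and Monte-Carlo draws all flow from explicit seeds —
  identical seeds give bit-identical results.
- Degenerate cases raise typed errors: zero exposure effect (Wald ratio),
  fewer than 3 instruments (Egger, median, mode), fewer than 4 (MR-PRESSO),
  zero total effect (mediated proportion), irreconcilable alleles (dropped,
  never silently kept).

## Known limitations

- Univariable β₂ (no multivariable adjustment): mediation assumes the
  mediator's instruments are exposure-independent after screening.
- The clumping window is purely LD-matrix based; without a matrix variants
  are assumed uncorrelated.
- No Steiger filtering, MR-RAPS, CAUSE, SuSiE colocalization or
  multivariable MR — out of scope by design.
- Real-data ORs/CIs for the secondary outcomes (cardiac arrest, CHD) depend
  on external GWAS accessions and are not reproducible at desk scale; the
  pipeline reproduces the design and arithmetic, and all statistical claims
  are validated on synthetic data with known truth.
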