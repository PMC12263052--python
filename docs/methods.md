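# Methods

This note documents the models, numerical choices and known limitations of
`mrchain`. Nothing here reports an empirical result the test suite or
`scripts/acceptance.py` does not itself compute.

## Study design

The package implements a four-component screening design over GWAS summary
statistics: (1) bidirectional MR between each exposure in a panel and one
outcome; (2) classification of each pair as forward-only, reverse-only,
bidirectional or null, with bidirectional pairs barred from mediation;
(3) forward MR of exposures on candidate mediators and of mediators on the
outcome; (4) two-step mediation quantifying the proportion of each total
effect carried by each gated mediator. The motivating application is the
lipid-species → immune/inflammatory-trait → endometriosis causal chain, but
nothing in the code is specific to those traits.

## Harmonization

Exposure and outcome effects are aligned to the exposure's effect allele.
Swapped allele labels negate the outcome beta; strand flips (A↔T, C↔G
complements) are recognized; palindromic variants (A/T, C/G) are aligned by
label first and then by effect-allele-frequency concordance, and dropped as
ambiguous when either frequency is missing or falls inside the window
(0.42, 0.58). The window is a conservative standard default; it and the
drop-on-missing rule are explicit package choices, since summary-data
conventions differ between sources. Every overlap variant is accounted for
exactly once: retained, or dropped with one of `allele_mismatch`,
`palindromic_ambiguous`, `missing_in_outcome`, `duplicate`.

## Instrument selection

Defaults: association `p < 5×10⁻⁵` (strict), confounder exclusion by a
static variant-id list, greedy LD clumping, and a strict per-variant
`F = (β/se)² > 10`. Choices worth noting:

* The F statistic is the squared Wald z — the summary-data approximation
  that needs no sample size or variance explained. It equals the
  single-SNP regression F at large n.
* Clumping prunes a variant only when **both** its r² with a better-ranked
  index exceeds `clump_r2` (default 0.001) **and** it lies within
  `clump_window_kb` (default 10,000 kb) on the same chromosome. Ties on p
  break lexicographically by variant id, making the result deterministic.
  The LD matrix is caller-supplied (long-format pairs or square TSV);
  without one, variants are treated as independent. Computing LD from a
  reference panel is out of scope.
* The same criteria apply in reverse-direction MR by default; the reverse
  p-threshold is a separate config knob because the appropriate choice for
  a disease-as-exposure screen is genuinely debatable.

## Estimators

All p-values are two-sided normal (summary-data convention; documented
because k is sometimes small). Confidence intervals use z = 1.959964, and
odds-ratio reporting is `OR = exp(β)` with log-symmetric CIs.

* **IVW**: weights `1/se_y²`, regression through the origin. The headline
  flavor is multiplicative random effects: SE inflated by `√(Q/(k−1))`
  only when `Q/(k−1) > 1`, so it never undercuts the fixed-effect SE and
  reduces to it for homogeneous ratios. Cochran's Q uses first-order ratio
  weights `(bx/se_y)²`; with k = 1 the Q test is undefined (df 0, p NaN).
* **MR-Egger**: variants oriented to `bx ≥ 0` (estimates are invariant to
  joint per-variant reorientation), weighted regression with intercept,
  SEs scaled by `max(1, √(RSS_w/(k−2)))`. Requires k ≥ 3.
* **Weighted median**: ratios sorted, normalized inverse-variance weights,
  cumulative weight midpoints `S_{j−1} + w_j/2`, linear interpolation at
  0.5. SE by parametric bootstrap: (bx, by) redrawn from normals centered
  on the observed effects with the observed SEs, n_boot = 1000 by default,
  seed mandatory.
* **Weighted mode**: Gaussian kernel density over the ratios with weights
  `1/ratio_se²`, bandwidth `φ × 0.9·min(sd, MAD)·k^(−1/5)` (MAD normalized;
  sd substitutes when MAD is 0; φ defaults to 1), evaluated on a 512-point
  grid spanning the ratio range; the estimate is the grid argmax. Same
  bootstrap as the median.
* **Multivariable IVW**: weighted regression of `by` on m exposure-effect
  columns without intercept, SEs scaled by `max(1, √(RSS_w/(k−m)))`;
  rank-deficient designs raise a collinearity error. With m = 1 it equals
  univariable random-effects IVW.
* Wald-ratio SEs are first-order delta (`se_y/|bx|`); the second-order
  variant adding `by²se_x²/bx⁴` is available behind a flag.

## Mediation

The product method is primary: `indirect = β_{X→M}·β_{M→Y}` with
delta-method SE `√(β_my²se_xm² + β_xm²se_my²)`; the difference method
(`indirect = β_total − β_direct`, direct from multivariable IVW with
exposure and mediator jointly modeled) is computed alongside. Cross-estimate
covariances are set to zero, reflecting the three-sample design; possible
cohort overlap in real applications is not modeled. Proportions outside
[0, 1] and indirect effects whose sign opposes the total are flagged, never
truncated. A triplet is quantified only when both the X→M and M→Y IVW
p-values pass the significance level (nominal 0.05 by default, matching the
screening convention; a BH-FDR column is emitted for users who want it).

Two design points deserve emphasis, both discovered analytically and
verified by simulation:

* **Step-2 instrument exclusion.** When instrumenting the mediator against
  the outcome, variants that are QC-passing instruments of the upstream
  exposure are excluded by default. Such variants act on the outcome
  through the exposure's direct path, so their Wald ratio for the mediator
  is `θ_total/θ_xm` rather than `θ_my`; leaving them in biases the mediated
  proportion upward (in the recovery simulations below, from a median of
  ~0.40 to ~0.48). This is the in-silico analogue of screening mediator
  instruments against a variant–phenotype database for upstream-trait
  associations.
* **Reverse-MR instrument exclusion.** In the study pipeline's reverse
  panel, the disease's instrument set excludes each tested trait's own
  forward instruments: a strong forward effect otherwise leaks those
  variants into the disease GWAS's significance set, where their reverse
  Wald ratio is exactly `1/θ_total`, and every strongly forward-causal
  pair would be misclassified bidirectional. The forward direction needs
  no such guard: contamination there creates two ratio clusters whose
  Cochran-Q inflation of the random-effects SE keeps forward IVW
  non-significant. Neither exclusion is Steiger filtering (which is out of
  scope); both reuse the ordinary exclusion-list mechanism.

## Synthetic data generator

The generator emulates three summary-level GWAS linked by a linear
structural model with parameters `θ_xm`, `θ_my`, `θ_direct` and optional
reverse effect `r`; per-SNP true effects solve the simultaneous system
`(I−B)⁻¹e` exactly, so feedback loops are handled consistently. Each trait
owns a disjoint block of `n_snps` instruments (the disease block always
exists; it feeds back into the exposure only when `r ≠ 0`), which keeps
two-sample and no-sample-overlap assumptions clean and makes reverse MR
meaningful even under pure forward causation. Observed effects add noise
with `se = 1/√(2·maf·(1−maf)·n)` — the standardized-trait approximation,
also used for the binary outcome's log-odds (a documented simplification).
Horizontal pleiotropy attaches direct SNP→outcome effects to the exposure's
instruments, defined relative to the exposure-increasing allele (otherwise
reorientation would cancel any directional component by symmetry): none,
balanced `N(0, scale²)`, or directional `N(scale, scale²)`. All randomness
flows from one seed through named SeedSequence spawns.

Defaults mirror the motivating data sources: exposure GWAS n = 7174,
mediator n = 3757, outcome n = 100,000, 100 instruments explaining 5% of
exposure variance, MAF ~ U(0.05, 0.5). What the generator does **not**
emulate: LD structure (clump tests use hand-written LD fixtures), allele
miscoding or strand errors in the wild, sample overlap between cohorts,
case–control ascertainment, and winner's-curse selection in discovery
GWAS. Passing tests therefore demonstrate correctness of the estimators and
the screening logic under clean two-sample assumptions, not robustness to
those real-data pathologies.

## Validation problem sizes

The calibration and recovery studies (in `tests/test_acceptance.py` and
`scripts/acceptance.py`) use deliberately well-powered configurations so
that estimator properties, not GWAS power, drive the outcomes:

* null calibration and Egger-intercept calibration: 100 instruments,
  n = 200,000 per trait, 500 replicates;
* parameter recovery at `(θ_direct, θ_xm, θ_my) = (0.3, 0.4, 0.5)`:
  n = 500,000, 200 replicates — the scale at which median instrument F
  comfortably exceeds 10 and regression-dilution bias in IVW is below 1%;
* direction classification at `θ_direct = 0.3`, `r = 0.2`: n = 200,000,
  100 replicates.

These sizes were chosen once, from power considerations, as the package's
standard validation conditions.

## Known limitations

* No MR-PRESSO outlier removal, Steiger directionality filtering, or
  robust adjusted profile score; no correlated-instrument IVW.
* The Egger SE treatment (multiplicative scaling, normal p) is the common
  summary-data convention, not the t-based small-sample variant.
* The bootstrap SEs for median/mode estimators assume normal sampling of
  (bx, by); with very weak instruments the ratio distribution is heavy-
  tailed and the bootstrap SE can be unstable.
* Mediation SEs ignore the covariance between the total and indirect
  estimates when both derive from the same exposure GWAS; the reported
  proportion SE is therefore approximate (conservative in the difference
  method).
* Multi-allelic variants, VCF input, and genome-build liftover are out of
  scope; coordinates are 1-based and alleles uppercased on read.
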