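# mrchain

Two-sample Mendelian randomization (MR) for causal-chain questions:
does an exposure X (here, a circulating lipid species) causally affect a
disease Y (endometriosis), and how much of that effect flows through an
intermediate trait M (an immune-cell or inflammatory-protein phenotype)?

`mrchain` is aimed at analysts working with GWAS summary statistics who want
a reproducible, scriptable version of the familiar screening design:
instrument selection → harmonization → an estimator battery with sensitivity
tests → bidirectional screening → two-step mediation. Everything runs from
plain TSV summary tables; a built-in generator simulates whole studies with
known causal structure so every stage can be validated end to end.

## The statistics

For a harmonized variant set with exposure effects `bx_j ± se_x_j` and
outcome effects `by_j ± se_y_j`, each variant's Wald ratio is
`β̂_j = by_j / bx_j` with first-order SE `se_y_j / |bx_j|`. The estimators:

* **IVW** (primary): `β̂ = Σ bx_j by_j / se_y_j² ÷ Σ bx_j² / se_y_j²`, i.e.
  weighted least squares of `by` on `bx` through the origin. Cochran's
  `Q = Σ w_j (β̂_j − β̂)²` with `w_j = (bx_j/se_y_j)²` tests heterogeneity;
  the multiplicative random-effects SE inflates by `√(Q/(k−1))` when
  `Q/(k−1) > 1`.
* **MR-Egger**: the same regression with an intercept after orienting
  `bx_j ≥ 0`; a nonzero intercept indicates directional horizontal
  pleiotropy, and the slope remains consistent under the InSIDE assumption.
* **Weighted median**: interpolated 50% point of the inverse-variance-
  weighted ratio distribution; consistent when valid instruments carry a
  majority of the weight. SE by parametric bootstrap.
* **Weighted mode**: mode of the weighted kernel density of the ratios
  (modified Silverman bandwidth); consistent under the ZEMPA assumption.
* **Multivariable IVW**: joint weighted regression of `by` on several
  exposures' effects, giving the exposure's *direct* effect adjusted for the
  mediator.

Instrument QC follows the screening design defaults: association
`p < 5×10⁻⁵`, greedy LD clumping at `r² > 0.001` within 10,000 kb,
confounder exclusion lists, and per-variant `F = (β/se)² > 10`.

Two-step mediation decomposes the total effect `β_total` into an indirect
component via the mediator and a direct remainder:

* product of coefficients: `indirect = β_{X→M} · β_{M→Y}`,
* difference method: `indirect = β_total − β_direct(MVMR)`,

with the proportion mediated `indirect / β_total`. Pairs whose reverse MR
(disease as exposure) is also significant are labelled *bidirectional* and
excluded from mediation.

## Worked example

Simulate a study in which the exposure's total effect is
`0.3 (direct) + 0.4 × 0.5 (via the mediator) = 0.5`, then run the full MR
battery on the exposure–outcome pair:

```bash
mrchain simulate --seed 5 --n-x 200000 --n-m 200000 --n-y 200000 \
    --theta-direct 0.3 --theta-xm 0.4 --theta-my 0.5 --out-dir sim/
mrchain mr --exposure sim/X.tsv --outcome sim/Y.tsv --seed 1 --n-boot 200
```

which prints:

```
ivw_fixed       k=67    beta=0.477986   se=0.0100309    OR=1.613 (1.581-1.645)  p=0.000
ivw_random      k=67    beta=0.477986   se=0.0112214    OR=1.613 (1.578-1.649)  p=0.000
egger           k=67    beta=0.505257   se=0.0232776    OR=1.657 (1.583-1.735)  p=0.000
weighted_median k=67    beta=0.478159   se=0.0165815    OR=1.613 (1.562-1.666)  p=0.000
weighted_mode   k=67    beta=0.489273   se=0.0190939    OR=1.631 (1.571-1.693)  p=0.000
cochran_q       Q=82.6  df=66   p=0.081
egger_intercept -0.00140247     se=0.00105067   p=0.182
```

All four estimators agree on the simulated truth of 0.5 within their SEs
(the outcome is binary, so `beta` is a log-odds ratio and `OR = exp(beta)`);
Cochran's Q finds no heterogeneity and the Egger intercept no directional
pleiotropy — as expected, since the generator injected neither. A full
four-component study (forward panel, reverse panel, direction
classification, mediation) runs from a YAML config via `mrchain mediate
--config study.yaml` and writes results TSVs, a QC/drops log, a run
manifest, and a plain-text report.

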