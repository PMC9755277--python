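# mddineq

Survey-weighted measurement and decomposition of socio-economic inequality in
**minimum dietary diversity (MDD)** among children aged 6–23 months.

MDD is the WHO/UNICEF infant-and-young-child-feeding indicator: a child meets
it when they consumed foods from at least 5 of 8 defined food groups
(breastfeeding; grains/roots/tubers; legumes/nuts; dairy; flesh foods; eggs;
vitamin-A-rich fruits/vegetables; other fruits/vegetables) on the previous
day. Public-health analysts working with DHS-style household surveys use this
package to ask not just *how common* MDD is, but *how unequally* it is
distributed across wealth and maternal education, and *which factors drive*
that inequality.

## What it computes

**Concentration index (convenient covariance approach).** With sampling
weights, outcome h (MDD), weighted mean μ, and each child's weighted
fractional rank r in the distribution of a living-standards variable
(wealth quintile or mother's education; ties share the midpoint rank),

    CIX = (2 / μ) · cov_w(h, r),    CIX ∈ [−1, 1]

Positive values mean MDD is concentrated among the better-off. The companion
**concentration curve** plots the cumulative weighted share of MDD against
the cumulative weighted population share ranked poorest → richest; twice the
signed area between the curve and the 45° line of equality reproduces the
index exactly under the midpoint-rank convention. Inference comes from the
convenient-regression equivalence with heteroskedasticity-robust and
cluster-robust (PSU-level) standard errors.

**Regression-based decomposition.** Fitting the linear probability model
h = α + Σₖ βₖxₖ + ε by weighted least squares on dummy-coded covariates
splits the index exactly:

    CIX = Σₖ (βₖ·x̄ₖ/μ) · Cₖ + GC_ε/μ

where βₖ·x̄ₖ/μ is the elasticity of MDD with respect to dummy k, Cₖ is that
dummy's concentration index against the *same* rank vector, and GC_ε/μ is the
unexplained residual term. The package reports per-category and per-variable
contributions, percentage shares, and enforces the identity
explained + residual = overall to 1e-10.

Also included: the staged cohort filter (age 6–23 months, complete food-group
responses, complete covariates), covariate recodes (media exposure, antenatal
visits dichotomized at 4, parity bands), weighted descriptive tables, an
asset-based wealth index (weighted first principal component cut into
weighted quintiles), per-food-group and per-age-band index sweeps, an
arithmetic verifier for published decomposition tables, and a synthetic
DHS-style survey generator with a closed-form decomposition oracle so every
stage is testable without restricted microdata.

## Worked example

Simulate a survey of 8,000 children under the default study conditions
(calibrated 37.5% target prevalence, positive wealth and education gradients
in food-group consumption, unequal lognormal weights, 160 clusters) and run
the full pipeline:

```bash
mddineq run --n 8000 --seed 42 --out-dir mdd_demo
```

prints

```
CIX(wealth_quintile) = 0.1375 (p 6.31e-13)
CIX(mother_education) = 0.1128 (p 1.18e-08)
weighted MDD prevalence: 34.88%
artifacts in mdd_demo
```

The cohort surviving the filter cascade (~2,100 children aged 6–23 months)
shows MDD significantly concentrated among the wealthy (CIX 0.14) and the
educated (CIX 0.11); the weighted prevalence sits near the calibrated target,
within sampling noise at this cohort size. `mdd_demo/` then contains the
filter-cascade report, descriptives, curve points and plots, per-food-group
and per-age-band index tables, both decomposition tables with percentage
bar charts, and a run manifest. The wealth-ranked decomposition totals
(`decomposition_wealth_quintile_totals.csv`) attribute 78.0% of the measured
inequality to wealth status itself and 20.3% to mother's education — the two
gradients the generator injected — with everything else near zero.

The same stages are available piecewise (`mddineq simulate | prep | cix |
decompose | verify-tables`) and as library functions (see
`mddineq.concentration`, `mddineq.decomposition`).

## Documentation

`docs/methods.md` describes the statistical model, the synthetic-data
generator's design and its limits, numerical conventions and known
limitations.
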