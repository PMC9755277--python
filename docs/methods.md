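# Methods

## Scope and model

`mddineq` measures socio-economic inequality in a binary child-nutrition
indicator (minimum dietary diversity, MDD) over a weighted household survey,
and attributes that inequality to covariates. The analysis chain is:

1. **Cohort construction.** Children aged 6–23 months (closed interval on
   both ends — the indicator is defined for exactly this window), then
   deletion of rows with any missing food-group response, then deletion of
   rows missing any modelled covariate. Deletion order is fixed
   (age → outcome missingness → covariate missingness) so stage counts are
   interpretable; the per-stage report is part of the output contract.
   No imputation: missing food responses are treated as uninformative
   non-response and dropped.
2. **Outcome.** MDD = 1 iff the count of distinct food groups consumed
   (0–8) is at least 5.
3. **Ranking.** Weighted fractional ranks of the living-standards variable.
   For grouped ordinal rankers (wealth quintiles, education levels) each tie
   group receives the shared midpoint rank: cumulative weight of strictly
   lower groups plus half its own weight. The weighted mean of the ranks is
   0.5 by construction.
4. **Concentration index.** CIX = (2/μ)·cov_w(h, r) with normalised weights
   and the population covariance convention. Under this convention the
   formula is exact: it equals the brute-force weighted sum expansion, and
   twice the signed area between the concentration curve (one vertex per tie
   group, trapezoid integration) and the diagonal.
5. **Inference.** The index equals the slope of the "convenient regression"
   of 2σ²_r·(h/μ) on r, fitted by weighted least squares. Standard errors
   are sandwich estimates: HC1 by default, cluster-robust at the primary
   sampling unit when cluster identifiers are present (p-values then use a
   t distribution with G−1 degrees of freedom, the usual small-G
   correction). Survey-design strata are not used in variance estimation.
6. **Decomposition.** Linear probability model (weighted least squares of
   the binary outcome on dummy-coded covariates, one omitted reference
   category per variable), then per-dummy contribution
   (βₖx̄ₖ/μ)·Cₖ with Cₖ computed against the *same* rank vector as the
   overall index — the convention under which the identity
   explained + residual = overall holds exactly. The residual GC_ε/μ is
   computed directly from the residuals and cross-checked against
   overall − explained; a discrepancy above 1e-8 raises an error rather
   than being absorbed.

### Assumptions

- Weights are design weights: strictly positive, treated as fixed
  constants; all moments use normalised weights.
- The binary outcome's attainable index range is [μ−1, 1−μ]; the package
  reports the plain (unnormalised) index. Wagstaff and Erreygers
  binary-outcome normalisations are available behind an explicit flag and
  are never applied by default.
- The linear probability model is taken at face value: elasticities are
  evaluated at weighted means, and no probit/logit marginal-effect variant
  is offered.
- Ranking defaults to the categorical quintile/education variable (not a
  continuous wealth score), matching the categorical treatment of the same
  variables inside the decomposition.

## Synthetic survey generator

The generator emulates a DHS-style child recode so the whole chain is
testable without restricted microdata. Design, with defaults:

- **Survey structure.** 16 strata (8 divisions × urban/rural, shares from a
  published national survey's background table), 160 clusters allocated
  proportionally, children assigned uniformly to clusters. Sampling weights
  are cluster-level lognormal with coefficient of variation 0.5 (unequal
  but not extreme, as in two-stage designs), rescaled to mean 1.
- **Wealth.** A latent household score = cluster effect (30% of variance) +
  household noise + an urban shift, cut into *exact weighted quintiles*
  (boundary observation goes to the lower quintile). Six asset indicators
  load on the latent score (two binarised) so the principal-component
  wealth-index module can be exercised against known structure; one
  household per child.
- **Education.** Drawn from a configurable P(education | quintile) matrix;
  the default has a mild positive association whose marginals match the
  survey table, and an exact-independence matrix is provided for tests.
- **Food groups.** Eight independent Bernoulli flags per child with
  probability clip(b_g + W[q,g] + E[e,g], 0, 1). Baselines b_g range from
  0.25 (legumes) to 0.85 (breastfeeding). The default per-quintile and
  per-education offsets are scaled so the implied MDD gradient tracks the
  published per-quintile prevalences (≈26% poorest → ≈52% richest), with
  the breastfeeding column reversed against wealth (breastfeeding is
  pro-poor) and flat in education. A single additive shift on the logit of
  the baselines, solved by bisection over the analytic grid, calibrates the
  population MDD prevalence to the default target 0.3747.
- **Other covariates** (mother's age group, partner education, work status,
  post-natal visit, antenatal visits, child sex, parity, media sources) are
  drawn independently with realistic marginals; they carry no gradient, so
  their true decomposition contributions are zero.
- **Missingness** is MCAR at rate 0.01 per missable field — sufficient to
  exercise the deletion cascade, which is the only consumer of missingness.

Because the data-generating process lives on a finite (quintile × education)
grid, the asymptotic decomposition is available in closed form:
`true_decomposition` computes the population WLS coefficients, component
indices and contributions by exact expectation over the 20 cells. It refuses
configurations where the probability clipping binds, since the cell
probabilities then stop being the stated additive ones.

**What the generator does not emulate** — and hence what passing tests do
not establish about real surveys: probability-proportional-to-size cluster
selection and calibration of weights to frames; within-household correlation
of siblings; informative (non-MCAR) missingness; age-dependent feeding
gradients; correlation between the non-SES covariates and wealth (e.g. ANC
visits are independent of wealth here, unlike in any real population, so
synthetic decompositions attribute essentially everything to wealth and
education). Parameter recovery on this generator validates the estimator
algebra and its sampling behaviour, not substantive conclusions about any
real population.

## Numerical conventions

- Weighted covariance: population convention, weights normalised to sum 1.
- Fractional ranks: stable sort; tie groups detected by exact value
  equality; refusal (not silent coercion) for ranking variables without a
  declared order.
- Quintile cuts: weighted empirical CDF, boundary to the lower quintile,
  with a 1e-9 epsilon guarding cumulative-sum round-off at exact 0.2k
  boundaries.
- Wealth index: indicators standardized to weighted mean 0/variance 1;
  constant columns dropped with a warning; first eigenvector of the
  weighted correlation matrix; the sign is fixed against a required
  "affluence anchor" column (PCA sign is otherwise arbitrary); fewer than
  five distinct scores is an error.
- Collinear dummy designs are rejected with the aliased columns named (rank
  check plus pivoted QR), not silently dropped.
- Degenerate subgroups: a subgroup with zero outcome mean is flagged and
  excluded from comparisons; a single observation has rank 0.5 and index 0
  with undefined standard error.
- Report rounding: index quantities to 4 decimals, percentages to 2, full
  precision retained internally.
- Published-table verification uses interval arithmetic: every printed
  number stands for ± half an ulp at its printed precision, and a row is
  consistent iff the printed output's interval overlaps the recomputed
  interval (for percentages, the hull of the rounded-contribution and
  unrounded-product readings, since a table printer may use either).
  Inconsistent rows are reported as findings, never "corrected".

## Design choices that were genuinely open

- **Inference method.** Sources in this literature often report p-values
  without a formula. The convenient-regression sandwich route was chosen
  because it reduces to the classical variance without clustering and
  extends naturally to PSU clustering; strata are ignored (conservative).
- **Weighted regression.** The decomposition regression is survey-weighted
  by default (disableable), so that a single weighting convention governs
  μ, the ranks, the coefficients and the component indices; this is also
  what makes the decomposition identity exact.
- **Residual term size.** When the ranking variable's own categories are
  included as regressors, the rank vector is a linear function of those
  dummies and weighted-least-squares orthogonality forces the residual term
  to zero in this package's convention. Published tables computed under
  other conventions (unweighted regression, different rank handling) show
  small nonzero residuals; the verifier checks their internal arithmetic,
  not this package's convention.
- **Reference categories** default to the conventional base levels
  (poorest, no education, rural, male, first division alphabetically) to
  reproduce familiar table layouts; fully configurable.

## Problem sizes used in the checks

Parameter recovery uses one survey of 200,000 children (ages confined to
6–23 months, missingness off) with 20 cluster-bootstrap replicates for
Monte-Carlo standard errors; the null-size experiment uses 500 replicate
surveys of 1,000 children in 50 clusters; convergence checks use 100,000
children. These sizes put Monte-Carlo error well below the effects being
checked while keeping the default suite quick on a single CPU.

## Known limitations

- No dominance *testing* between concentration curves (dominance is
  reported as a flag from pointwise comparison, as in visual assessment).
- No Oaxaca-Blinder between-group or two-survey change decomposition.
- No urban/rural split-sample composite wealth index.
- The linear probability model can fit outside [0, 1]; contributions remain
  well-defined (the identity is algebraic) but elasticities inherit LPM
  limitations.
- Percentage contributions are unstable when the overall index is near
  zero; the operation refuses an exactly-zero overall index but cannot
  rescue a nearly-zero one.
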