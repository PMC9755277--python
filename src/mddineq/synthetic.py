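"""Synthetic DHS-style child-recode generator with known inequality structure.

Emulates a child-level survey table for children of reproductive-age women in
a two-stage cluster design: strata (division x residence), clusters, unequal
lognormal sampling weights, a latent household wealth score cut into exact
weighted quintiles, maternal education drawn jointly with wealth, and eight
binary food-group indicators whose consumption probabilities carry
configurable wealth and education gradients:

    P(group g | quintile q, education e) = clip(b_g + W[q, g] + E[e, g], 0, 1)

where ``b_g`` are baseline probabilities (optionally shifted on the logit
scale so the analytic MDD prevalence hits a target) and W, E are the
per-quintile / per-education offset matrices.  Because the data-generating
process is a finite covariate grid, the asymptotic concentration index and
its regression-based decomposition are available in closed form
(:func:`true_decomposition`), giving an exact oracle for parameter-recovery
tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .cohort import FOOD_COLUMNS, FOOD_GROUPS

# ---------------------------------------------------------------------------
# default study conditions
# ---------------------------------------------------------------------------

#: Baseline per-food-group consumption probabilities (breastfeeding, grains,
#: legumes, dairy, flesh, eggs, vitamin-A fruit/veg, other fruit/veg).
DEFAULT_BASE_GROUP_PROBS = (0.85, 0.80, 0.25, 0.40, 0.60, 0.35, 0.55, 0.45)

# Per-quintile offsets applied to all food groups except breastfeeding, which
# runs the other way (breastfeeding is concentrated among the poor).
_WEALTH_OFFSETS = np.array([-0.050, -0.012, 0.000, 0.010, 0.062])
_EDU_OFFSETS = np.array([-0.040, -0.018, 0.002, 0.037])


def _default_wealth_gradient() -> np.ndarray:
    g = np.tile(_WEALTH_OFFSETS[:, None], (1, len(FOOD_GROUPS)))
    g[:, 0] = -0.6 * _WEALTH_OFFSETS  # breastfeeding decreases with wealth
    return g


def _default_education_gradient() -> np.ndarray:
    g = np.tile(_EDU_OFFSETS[:, None], (1, len(FOOD_GROUPS)))
    g[:, 0] = 0.0  # breastfeeding carries no education gradient
    return g


#: P(mother education | wealth quintile): mild positive association whose
#: marginals track a typical DHS education distribution.
DEFAULT_EDUCATION_GIVEN_WEALTH = np.array([
    [0.14, 0.40, 0.41, 0.05],
    [0.09, 0.33, 0.48, 0.10],
    [0.05, 0.28, 0.52, 0.15],
    [0.02, 0.22, 0.55, 0.21],
    [0.01, 0.12, 0.48, 0.39],
])

DIVISIONS = ["Barisal", "Chittagong", "Dhaka", "Khulna",
             "Mymensingh", "Rajshahi", "Rangpur", "Sylhet"]
DIVISION_SHARES = np.array([0.0582, 0.2026, 0.2558, 0.0886,
                            0.0857, 0.1152, 0.1140, 0.0798])
URBAN_SHARE = 0.26

MOTHER_AGE_GROUPS = ["15-19", "20-24", "25-29", "30-49"]
MOTHER_AGE_PROBS = np.array([0.1917, 0.3521, 0.2483, 0.2079])
PARTNER_EDU_PROBS = np.array([0.1355, 0.3529, 0.3242, 0.1874])

MDD_THRESHOLD = 5


def independent_education_given_wealth(marginal=None) -> np.ndarray:
    """A joint matrix making education independent of wealth (for tests)."""
    m = DEFAULT_EDUCATION_GIVEN_WEALTH.mean(axis=0) if marginal is None else np.asarray(marginal, float)
    return np.tile(m / m.sum(), (5, 1))


@dataclass
class GeneratorConfig:
    """Study conditions for one synthetic survey draw.

    Gradients may be given per level (length 5 / 4, broadcast over the eight
    food groups) or as full (levels x 8) matrices for per-group structure.
    ``target_prevalence`` if set shifts the baseline probabilities on the
    logit scale (solved by bisection over the analytic grid) so the weighted
    MDD prevalence matches; set it to None to use the baselines as given.
    """

    n_children: int = 8000
    seed: int = 0
    wealth_gradient: np.ndarray = field(default_factory=_default_wealth_gradient)
    education_gradient: np.ndarray = field(default_factory=_default_education_gradient)
    base_group_probs: tuple = DEFAULT_BASE_GROUP_PROBS
    weight_dispersion: float = 0.5
    target_prevalence: float | None = 0.3747
    missing_rate: float = 0.01
    n_clusters: int = 160
    n_strata: int = 16
    age_range: tuple = (0, 59)
    education_given_wealth: np.ndarray = field(
        default_factory=lambda: DEFAULT_EDUCATION_GIVEN_WEALTH.copy())
    n_asset_indicators: int = 6

    def __post_init__(self):
        if not (isinstance(self.n_children, (int, np.integer)) and self.n_children >= 1):
            raise ValueError("n_children: must be a positive integer")
        base = np.asarray(self.base_group_probs, dtype=float)
        if base.shape != (8,):
            raise ValueError("base_group_probs: must have exactly 8 entries")
        if not np.all(np.isfinite(base)) or np.any(base < 0) or np.any(base > 1):
            raise ValueError("base_group_probs: probabilities must lie in [0, 1]")
        self.base_group_probs = tuple(float(x) for x in base)
        self.wealth_gradient = self._expand_gradient(self.wealth_gradient, 5, "wealth_gradient")
        self.education_gradient = self._expand_gradient(self.education_gradient, 4, "education_gradient")
        if not np.isfinite(self.weight_dispersion) or self.weight_dispersion < 0:
            raise ValueError("weight_dispersion: must be a finite non-negative number")
        if self.target_prevalence is not None and not (0 < self.target_prevalence < 1):
            raise ValueError("target_prevalence: must lie in (0, 1)")
        if not (0 <= self.missing_rate < 1):
            raise ValueError("missing_rate: must lie in [0, 1)")
        if self.n_clusters < 1:
            raise ValueError("n_clusters: must be positive")
        if self.n_strata != 16:
            # strata are the 8 divisions x urban/rural by construction
            raise ValueError("n_strata: the generator's design has exactly 16 strata")
        ejw = np.asarray(self.education_given_wealth, dtype=float)
        if ejw.shape != (5, 4) or np.any(ejw < 0) or not np.allclose(ejw.sum(axis=1), 1.0):
            raise ValueError("education_given_wealth: must be a 5x4 row-stochastic matrix")
        self.education_given_wealth = ejw
        lo, hi = self.age_range
        if not (0 <= lo <= hi <= 59):
            raise ValueError("age_range: must satisfy 0 <= lo <= hi <= 59")

    @staticmethod
    def _expand_gradient(g, n_levels: int, name: str) -> np.ndarray:
        arr = np.asarray(g, dtype=float)
        if arr.ndim == 1:
            if arr.shape != (n_levels,):
                raise ValueError(f"{name}: expected {n_levels} per-level offsets")
            arr = np.tile(arr[:, None], (1, 8))
        if arr.shape != (n_levels, 8):
            raise ValueError(f"{name}: expected shape ({n_levels},) or ({n_levels}, 8)")
        if not np.all(np.isfinite(arr)):
            raise ValueError(f"{name}: offsets must be finite")
        return arr


# ---------------------------------------------------------------------------
# analytic grid machinery
# ---------------------------------------------------------------------------

def _group_prob_grid(config: GeneratorConfig, logit_shift: float = 0.0):
    """(clipped, raw) pair of (5, 4, 8) per-cell food-group probabilities."""
    base = expit(logit(np.clip(np.asarray(config.base_group_probs), 1e-9, 1 - 1e-9)) + logit_shift)
    raw = base[None, None, :] + config.wealth_gradient[:, None, :] + config.education_gradient[None, :, :]
    return np.clip(raw, 0.0, 1.0), raw


def poisson_binomial_tail(probs: np.ndarray, k: int = MDD_THRESHOLD) -> np.ndarray:
    """P(sum of independent Bernoullis >= k) along the last axis."""
    probs = np.asarray(probs, dtype=float)
    m = probs.shape[-1]
    pmf = np.zeros(probs.shape[:-1] + (m + 1,))
    pmf[..., 0] = 1.0
    for j in range(m):
        p = probs[..., j : j + 1]
        shifted = np.concatenate([np.zeros(probs.shape[:-1] + (1,)), pmf[..., :-1]], axis=-1)
        pmf = pmf * (1 - p) + shifted * p
    return pmf[..., k:].sum(axis=-1)


def _joint_cell_probs(config: GeneratorConfig) -> np.ndarray:
    """(5, 4) joint probability of (wealth quintile, education)."""
    return 0.2 * config.education_given_wealth


def analytic_prevalence(config: GeneratorConfig, logit_shift: float = 0.0) -> float:
    """Exact population MDD prevalence implied by the generator grid."""
    probs, _ = _group_prob_grid(config, logit_shift)
    cell = poisson_binomial_tail(probs)
    return float((_joint_cell_probs(config) * cell).sum())


def _solve_logit_shift(config: GeneratorConfig) -> float:
    """Bisection for the logit shift hitting the target prevalence."""
    if config.target_prevalence is None:
        return 0.0
    target = config.target_prevalence
    lo, hi = -8.0, 8.0
    flo = analytic_prevalence(config, lo) - target
    fhi = analytic_prevalence(config, hi) - target
    if flo > 0 or fhi < 0:
        raise ValueError("target_prevalence unreachable by a logit shift of the baselines")
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if analytic_prevalence(config, mid) < target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


# ---------------------------------------------------------------------------
# survey generation
# ---------------------------------------------------------------------------

def _weighted_quintiles(score: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Exact weighted quintiles; a boundary observation goes to the lower
    quintile."""
    order = np.argsort(score, kind="stable")
    w = weights[order] / weights.sum()
    cum_incl = np.cumsum(w)
    # epsilon guards cumulative-sum round-off at exact 0.2k boundaries
    q_sorted = np.digitize(cum_incl - 1e-9, [0.2, 0.4, 0.6, 0.8], right=True) + 1
    q = np.empty(len(score), dtype=int)
    q[order] = q_sorted
    return q


def generate_survey(config: GeneratorConfig) -> pd.DataFrame:
    """Draw one schema-complete child-level survey table.

    Deterministic given ``config.seed``.  Weights are lognormal with the
    requested coefficient of variation, rescaled to mean 1; wealth quintiles
    are exact weighted quintiles of the latent household score; food-group
    flags are independent Bernoullis on the configured probability grid.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_children

    # strata = division x residence; clusters allocated proportionally
    strat_probs = np.outer(DIVISION_SHARES / DIVISION_SHARES.sum(),
                           [1 - URBAN_SHARE, URBAN_SHARE]).ravel()
    cluster_stratum = rng.choice(len(strat_probs), size=config.n_clusters, p=strat_probs)
    cluster_of_child = rng.integers(0, config.n_clusters, size=n)
    stratum = cluster_stratum[cluster_of_child]
    division = np.array(DIVISIONS)[stratum // 2]
    residence = np.where(stratum % 2 == 1, "urban", "rural")

    # sampling weights: cluster-level lognormal, mean 1
    if config.weight_dispersion > 0:
        sigma2 = np.log1p(config.weight_dispersion ** 2)
        wc = rng.lognormal(mean=-sigma2 / 2, sigma=np.sqrt(sigma2), size=config.n_clusters)
    else:
        wc = np.ones(config.n_clusters)
    weight = wc[cluster_of_child]
    weight = weight / weight.mean()

    # latent household wealth: cluster effect + household noise + urban shift
    u_cluster = rng.normal(0, 1, size=config.n_clusters)
    latent = (np.sqrt(0.3) * u_cluster[cluster_of_child]
              + np.sqrt(0.7) * rng.normal(0, 1, size=n)
              + 0.5 * (residence == "urban"))
    quintile = _weighted_quintiles(latent, weight)

    # asset indicators (household level; one household per child here)
    loadings = np.array([0.9, 0.8, 0.7, 0.6, 0.5, 0.4])[: config.n_asset_indicators]
    assets = (loadings[None, :] * latent[:, None]
              + np.sqrt(1 - loadings**2)[None, :] * rng.normal(0, 1, size=(n, len(loadings))))
    if len(loadings) >= 5:
        assets[:, 4] = (assets[:, 4] > 0).astype(float)  # e.g. improved floor
    if len(loadings) >= 6:
        assets[:, 5] = (assets[:, 5] > 0).astype(float)  # e.g. owns television

    # education jointly with wealth
    edu_cum = np.cumsum(config.education_given_wealth, axis=1)
    education = (rng.random(n)[:, None] > edu_cum[quintile - 1]).sum(axis=1)

    # remaining covariates: independent draws with DHS-like marginals
    mother_age_group = rng.choice(MOTHER_AGE_GROUPS, size=n, p=MOTHER_AGE_PROBS)
    partner_education = rng.choice(4, size=n, p=PARTNER_EDU_PROBS)
    currently_working = (rng.random(n) < 0.368).astype(float)
    postnatal_visited = (rng.random(n) < 0.6528).astype(float)
    anc_ge4 = rng.random(n) < 0.4661
    anc_visits = np.where(anc_ge4, 4 + rng.poisson(1.2, size=n), rng.integers(0, 4, size=n)).astype(float)
    child_sex = np.where(rng.random(n) < 0.5181, "male", "female")
    kid_cat = rng.choice(3, size=n, p=[0.3919, 0.3483, 0.2598])
    living_children = np.where(kid_cat < 2, kid_cat + 1, 3 + rng.poisson(0.8, size=n)).astype(float)
    media_newspaper = (rng.random(n) < 0.08).astype(float)
    media_tv = (rng.random(n) < 0.50).astype(float)
    media_radio = (rng.random(n) < 0.05).astype(float)
    age = rng.integers(config.age_range[0], config.age_range[1] + 1, size=n)

    # food-group flags on the calibrated probability grid
    shift = _solve_logit_shift(config)
    prob_grid, _ = _group_prob_grid(config, shift)
    p_child = prob_grid[quintile - 1, education, :]
    flags = (rng.random((n, 8)) < p_child).astype(float)

    table = pd.DataFrame({
        "child_id": np.arange(n),
        "household_id": np.arange(n),
        "cluster_id": cluster_of_child,
        "stratum_id": stratum,
        "division": division,
        "residence": residence,
        "weight": weight,
        "child_age_months": age,
        "child_sex": child_sex,
        "mother_age_group": mother_age_group,
        "mother_education": education.astype(float),
        "partner_education": partner_education.astype(float),
        "currently_working": currently_working,
        "postnatal_visited": postnatal_visited,
        "anc_visits": anc_visits,
        "living_children": living_children,
        "media_newspaper_weekly": media_newspaper,
        "media_tv_weekly": media_tv,
        "media_radio_weekly": media_radio,
        "wealth_quintile": quintile.astype(float),
    })
    for j in range(assets.shape[1]):
        table[f"asset_{j + 1}"] = assets[:, j]
    for col, j in zip(FOOD_COLUMNS, range(8)):
        table[col] = flags[:, j]

    if config.missing_rate > 0:
        missable = FOOD_COLUMNS + [
            "mother_education", "partner_education", "anc_visits",
            "living_children", "currently_working", "postnatal_visited",
            "media_newspaper_weekly", "media_tv_weekly", "media_radio_weekly",
        ]
        for col in missable:
            mask = rng.random(n) < config.missing_rate
            table.loc[mask, col] = np.nan

    return table


# ---------------------------------------------------------------------------
# closed-form decomposition oracle
# ---------------------------------------------------------------------------

def _grid_midpoint_ranks(marginal: np.ndarray) -> np.ndarray:
    cum = np.concatenate([[0.0], np.cumsum(marginal)[:-1]])
    return cum + marginal / 2.0


def true_decomposition(config: GeneratorConfig, ranking: str = "wealth_quintile") -> dict:
    """Asymptotic decomposition implied by the generator, by exact grid
    expectation.

    Fits the population linear probability model of MDD on wealth-quintile
    and education dummies over the 5 x 4 covariate grid and returns the
    per-variable contributions (elasticity x component index), the residual
    term, the overall concentration index, and percentage shares.  Refuses
    configurations where probability clipping binds, since the grid
    probabilities are then no longer the stated additive ones.
    """
    if ranking not in ("wealth_quintile", "mother_education"):
        raise ValueError("ranking must be 'wealth_quintile' or 'mother_education'")
    shift = _solve_logit_shift(config)
    probs, raw = _group_prob_grid(config, shift)
    if np.any(raw < 0) or np.any(raw > 1):
        raise ValueError("unsupported config: probability clipping distorts additivity")

    pi = _joint_cell_probs(config)            # (5, 4)
    p_cell = poisson_binomial_tail(probs)      # (5, 4)
    mu = float((pi * p_cell).sum())

    # ranks constant within levels of the ranking variable
    if ranking == "wealth_quintile":
        r_level = _grid_midpoint_ranks(pi.sum(axis=1))
        r_cell = np.tile(r_level[:, None], (1, 4))
    else:
        r_level = _grid_midpoint_ranks(pi.sum(axis=0))
        r_cell = np.tile(r_level[None, :], (5, 1))

    # population WLS of p on additive dummies (reference: q1, e0)
    cells = [(q, e) for q in range(5) for e in range(4)]
    X = np.zeros((20, 8))
    X[:, 0] = 1.0
    names = ["const"] + [f"wealth_quintile={q + 1}" for q in range(1, 5)] \
        + [f"mother_education={e}" for e in range(1, 4)]
    for i, (q, e) in enumerate(cells):
        if q >= 1:
            X[i, q] = 1.0
        if e >= 1:
            X[i, 4 + e] = 1.0
    wcell = np.array([pi[q, e] for q, e in cells])
    ycell = np.array([p_cell[q, e] for q, e in cells])
    rcell = np.array([r_cell[q, e] for q, e in cells])
    XtWX = X.T @ (wcell[:, None] * X)
    beta = np.linalg.solve(XtWX, X.T @ (wcell * ycell))

    rbar = float(wcell @ rcell)
    overall = 2.0 / mu * float(wcell @ ((ycell - mu) * (rcell - rbar)))

    rows = []
    for k in range(1, 8):
        xk = X[:, k]
        xbar = float(wcell @ xk)
        cov_xr = float(wcell @ ((xk - xbar) * (rcell - rbar)))
        ck = 2.0 / xbar * cov_xr if xbar > 0 else np.nan
        elasticity = beta[k] * xbar / mu
        rows.append({"dummy": names[k], "elasticity": elasticity,
                     "component_cix": ck, "contribution": elasticity * ck})
    contributions = {
        "wealth_quintile": sum(r["contribution"] for r in rows if r["dummy"].startswith("wealth")),
        "mother_education": sum(r["contribution"] for r in rows if r["dummy"].startswith("mother")),
    }
    explained = sum(contributions.values())
    residual = overall - explained
    shares = {k: 100.0 * v / overall for k, v in contributions.items()} if overall != 0 else {}
    return {
        "overall_cix": overall,
        "mu": mu,
        "rows": rows,
        "contributions": contributions,
        "explained": explained,
        "residual": residual,
        "pct_shares": shares,
    }


def null_config(**overrides) -> GeneratorConfig:
    """A gradient-free configuration (no injected inequality)."""
    base = dict(
        wealth_gradient=np.zeros((5, 8)),
        education_gradient=np.zeros((4, 8)),
        target_prevalence=None,
        missing_rate=0.0,
    )
    base.update(overrides)
    return GeneratorConfig(**base)
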