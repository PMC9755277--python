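"""Concentration curves and concentration indices for survey-weighted outcomes.

The concentration index (CIX) measures socio-economic inequality in a health
indicator ``h`` across a living-standards ranking (wealth, education, ...).
It is computed by the convenient covariance approach,

    CIX = (2 / mu) * cov_w(h, r),

where ``mu`` is the weighted mean of ``h`` and ``r`` is the weighted
fractional rank of each individual in the distribution of the ranking
variable.  CIX lies in [-1, 1]; positive values mean the indicator is
concentrated among the better-off.  For a binary indicator the attainable
range shrinks to [mu - 1, 1 - mu].

Weighted covariances use normalised weights and the population (not n-1)
convention throughout; under that convention the covariance formula is exact
and equals twice the signed area between the concentration curve and the
diagonal of equality.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


# ---------------------------------------------------------------------------
# weighted moments (population convention, normalised weights)
# ---------------------------------------------------------------------------

def normalised_weights(weights) -> np.ndarray:
    w = np.asarray(weights, dtype=float)
    if w.ndim != 1:
        raise ValueError("weights must be one-dimensional")
    if not np.all(np.isfinite(w)) or np.any(w <= 0):
        raise ValueError("weights must be finite and strictly positive")
    return w / w.sum()


def weighted_mean(x, weights) -> float:
    w = normalised_weights(weights)
    return float(np.dot(w, np.asarray(x, dtype=float)))


def weighted_cov(x, y, weights) -> float:
    """Population-convention weighted covariance with normalised weights."""
    w = normalised_weights(weights)
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xbar = np.dot(w, x)
    ybar = np.dot(w, y)
    return float(np.dot(w, (x - xbar) * (y - ybar)))


def weighted_var(x, weights) -> float:
    return weighted_cov(x, x, weights)


# ---------------------------------------------------------------------------
# fractional ranks
# ---------------------------------------------------------------------------

@dataclass
class FractionalRankVector:
    """Weighted fractional ranks of individuals in a ranking variable.

    Ties share the midpoint rank of their weight block: a tie group with
    cumulative weight ``c`` strictly below it and own weight ``g`` receives
    rank ``c + g / 2``.  The weighted mean of the ranks is 0.5 by
    construction.
    """

    ranks: np.ndarray
    ranking_variable: str
    tie_group_ranks: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.ranks)


def _ordinal_codes(values, name: str) -> np.ndarray:
    """Map a ranking variable to sortable numeric codes, or refuse."""
    if isinstance(values, pd.Series):
        if isinstance(values.dtype, pd.CategoricalDtype):
            if not values.dtype.ordered:
                raise TypeError(
                    f"ranking variable {name!r} is categorical without a "
                    "declared order; declare an ordered categorical"
                )
            codes = values.cat.codes.to_numpy()
            if np.any(codes < 0):
                raise ValueError(f"ranking variable {name!r} contains missing values")
            return codes.astype(float)
        values = values.to_numpy()
    arr = np.asarray(values)
    if arr.dtype.kind not in "ifub":
        raise TypeError(
            f"ranking variable {name!r} is not numeric and carries no "
            "declared order; pass an ordered categorical instead"
        )
    arr = arr.astype(float)
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"ranking variable {name!r} contains missing values")
    return arr


def weighted_fractional_rank(values, weights, name: str = "ranking") -> FractionalRankVector:
    """Weighted fractional ranks with tie groups sharing the midpoint rank."""
    codes = _ordinal_codes(values, name)
    w = normalised_weights(weights)
    if len(codes) != len(w):
        raise ValueError("ranking values and weights differ in length")

    uniq, inverse = np.unique(codes, return_inverse=True)
    group_w = np.bincount(inverse, weights=w, minlength=len(uniq))
    cum_below = np.concatenate([[0.0], np.cumsum(group_w)[:-1]])
    group_rank = cum_below + group_w / 2.0
    ranks = group_rank[inverse]
    tie_map = {u: r for u, r in zip(uniq.tolist(), group_rank.tolist())}
    return FractionalRankVector(ranks=ranks, ranking_variable=name, tie_group_ranks=tie_map)


# ---------------------------------------------------------------------------
# concentration index with inference
# ---------------------------------------------------------------------------

@dataclass
class CIXEstimate:
    value: float
    mu: float
    se: float
    p_value: float
    n: int
    ranking_variable: str

    def significant(self, alpha: float = 0.05) -> bool:
        return bool(np.isfinite(self.p_value) and self.p_value < alpha)


def _convenient_regression(y, r, w, clusters):
    """WLS of y on [1, r] with robust sandwich variance for the slope.

    Heteroskedasticity-robust (HC1) by default; cluster-robust when cluster
    identifiers are supplied (p-value then uses a t with G-1 dof, the usual
    small-G correction for survey clusters).
    """
    n = len(y)
    X = np.column_stack([np.ones(n), r])
    W = w  # already normalised
    XtWX = X.T @ (W[:, None] * X)
    XtWy = X.T @ (W * y)
    beta = np.linalg.solve(XtWX, XtWy)
    resid = y - X @ beta
    bread = np.linalg.inv(XtWX)

    k = X.shape[1]
    if clusters is None:
        we = (W * resid)[:, None] * X
        meat = we.T @ we
        correction = n / max(n - k, 1)
        dof = max(n - k, 1)
    else:
        codes, _ = pd.factorize(np.asarray(clusters))
        G = codes.max() + 1
        sx = np.zeros((G, k))
        for j in range(k):
            sx[:, j] = np.bincount(codes, weights=W * resid * X[:, j], minlength=G)
        meat = sx.T @ sx
        correction = (G / max(G - 1, 1)) * ((n - 1) / max(n - k, 1))
        dof = max(G - 1, 1)

    V = bread @ (correction * meat) @ bread
    se = float(np.sqrt(max(V[1, 1], 0.0)))
    return float(beta[1]), se, dof


def concentration_index(
    h,
    ranks: FractionalRankVector,
    weights,
    clusters=None,
    normalization: str | None = None,
) -> CIXEstimate:
    """Concentration index by the convenient covariance approach.

    ``normalization`` optionally applies a binary-outcome correction —
    ``"wagstaff"`` (divide by 1 - mu) or ``"erreygers"`` (multiply by
    4 mu / 1) — neither is the default, plain-index convention.
    """
    h = np.asarray(h, dtype=float)
    if not np.all(np.isfinite(h)):
        raise ValueError("outcome contains missing values; run the filter cascade first")
    r = ranks.ranks if isinstance(ranks, FractionalRankVector) else np.asarray(ranks, float)
    w = normalised_weights(weights)
    if not (len(h) == len(r) == len(w)):
        raise ValueError("outcome, ranks and weights differ in length")

    mu = float(np.dot(w, h))
    if mu <= 0:
        raise ValueError("concentration index undefined: weighted mean of outcome is zero")

    value = 2.0 / mu * weighted_cov(h, r, w)

    var_r = weighted_var(r, w)
    if var_r <= 0 or len(h) < 3:
        se, p = float("nan"), float("nan")
    else:
        # convenient regression: slope of 2*var(r)*(h/mu) on r equals CIX
        ystar = 2.0 * var_r * h / mu
        slope, se, dof = _convenient_regression(ystar, r, w, clusters)
        if se > 0:
            p = float(2.0 * stats.t.sf(abs(slope) / se, dof))
        else:
            p = float("nan") if abs(slope) < 1e-14 else 0.0

    if normalization == "wagstaff":
        if mu >= 1:
            raise ValueError("Wagstaff normalization undefined when mu = 1")
        value, se = value / (1 - mu), se / (1 - mu)
    elif normalization == "erreygers":
        value, se = 4 * mu * value, 4 * mu * se
    elif normalization is not None:
        raise ValueError(f"unknown normalization {normalization!r}")

    name = ranks.ranking_variable if isinstance(ranks, FractionalRankVector) else "ranking"
    return CIXEstimate(value=float(value), mu=mu, se=se, p_value=p, n=len(h), ranking_variable=name)


def cix_brute_force(h, ranks, weights) -> float:
    """Independent expansion 2/mu * (sum w_i h_i r_i - mu * rbar): oracle form."""
    w = normalised_weights(weights)
    h = np.asarray(h, dtype=float)
    r = ranks.ranks if isinstance(ranks, FractionalRankVector) else np.asarray(ranks, float)
    mu = float(np.dot(w, h))
    rbar = float(np.dot(w, r))
    return 2.0 / mu * (float(np.dot(w, h * r)) - mu * rbar)


# ---------------------------------------------------------------------------
# concentration curves
# ---------------------------------------------------------------------------

@dataclass
class CurvePoints:
    """A concentration curve: cumulative population share vs outcome share.

    Anchored at (0, 0) and (1, 1) with one interior point per tie group of
    the ranking variable.  ``dominance`` summarises the position relative to
    the 45-degree line of equality: "below" (pro-rich), "above" (pro-poor),
    "equal", or "crosses".
    """

    points: np.ndarray
    ranking_variable: str
    dominance: str

    @property
    def population_share(self) -> np.ndarray:
        return self.points[:, 0]

    @property
    def outcome_share(self) -> np.ndarray:
        return self.points[:, 1]

    def area_index(self) -> float:
        """Twice the signed area between diagonal and curve (= CIX exactly
        for midpoint-ranked grouped data)."""
        p, L = self.points[:, 0], self.points[:, 1]
        return float(2.0 * np.trapezoid(p - L, p))


def concentration_curve(h, ranking_values, weights, name: str = "ranking") -> CurvePoints:
    codes = _ordinal_codes(ranking_values, name)
    w = normalised_weights(weights)
    h = np.asarray(h, dtype=float)
    if not np.all(np.isfinite(h)):
        raise ValueError("outcome contains missing values; run the filter cascade first")
    total = float(np.dot(w, h))
    if total <= 0:
        raise ValueError("concentration curve undefined: weighted outcome total is zero")

    uniq, inverse = np.unique(codes, return_inverse=True)
    gw = np.bincount(inverse, weights=w, minlength=len(uniq))
    gh = np.bincount(inverse, weights=w * h, minlength=len(uniq))
    pop = np.concatenate([[0.0], np.cumsum(gw)])
    out = np.concatenate([[0.0], np.cumsum(gh) / total])
    pop[-1], out[-1] = 1.0, 1.0  # exact endpoints

    interior_pop, interior_out = pop[1:-1], out[1:-1]
    tol = 1e-12
    below = interior_out <= interior_pop + tol
    above = interior_out >= interior_pop - tol
    strict_below = np.any(interior_out < interior_pop - tol)
    strict_above = np.any(interior_out > interior_pop + tol)
    if below.all() and strict_below:
        dominance = "below"
    elif above.all() and strict_above:
        dominance = "above"
    elif not strict_below and not strict_above:
        dominance = "equal"
    else:
        dominance = "crosses"
    return CurvePoints(points=np.column_stack([pop, out]), ranking_variable=name, dominance=dominance)


# ---------------------------------------------------------------------------
# sweeps
# ---------------------------------------------------------------------------

def subgroup_cix(
    table: pd.DataFrame,
    outcome,
    ranking_variable: str,
    subgroup_variable: str,
    weight_col: str = "weight",
    cluster_col: str | None = "cluster_id",
):
    """Concentration index within each level of a subgroup variable.

    Ranks are recomputed inside every subgroup.  Returns
    ``(estimates, comparator)`` where ``estimates`` maps subgroup level to a
    CIXEstimate and ``comparator`` names the largest and smallest indices
    (degenerate subgroups with mu = 0 are flagged and excluded).
    """
    h = np.asarray(outcome, dtype=float)
    estimates: dict = {}
    excluded: list = []
    for level, idx in table.groupby(subgroup_variable, observed=True).indices.items():
        sub = table.iloc[idx]
        hs = h[idx]
        if len(idx) == 0:
            continue
        if weighted_mean(hs, sub[weight_col]) <= 0:
            excluded.append(level)
            continue
        ranks = weighted_fractional_rank(sub[ranking_variable], sub[weight_col], name=ranking_variable)
        clusters = sub[cluster_col] if cluster_col and cluster_col in sub else None
        estimates[level] = concentration_index(hs, ranks, sub[weight_col], clusters=clusters)
    if not estimates:
        raise ValueError("no subgroup with positive outcome mean")
    largest = max(estimates, key=lambda k: estimates[k].value)
    smallest = min(estimates, key=lambda k: estimates[k].value)
    comparator = {"largest": largest, "smallest": smallest, "excluded_mu_zero": excluded}
    return estimates, comparator


def component_cix(
    table: pd.DataFrame,
    ranking_variable: str,
    food_columns,
    weight_col: str = "weight",
    cluster_col: str | None = "cluster_id",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-food-group concentration indices against one ranking variable.

    Returns a frame with value/se/p per component plus a direction label:
    "pro-rich" (significantly positive), "pro-poor" (significantly
    negative), or "none".  Components with zero variance (never or always
    consumed) get a zero or undefined index flag.
    """
    ranks = weighted_fractional_rank(table[ranking_variable], table[weight_col], name=ranking_variable)
    clusters = table[cluster_col] if cluster_col and cluster_col in table else None
    rows = []
    for col in food_columns:
        hc = np.asarray(table[col], dtype=float)
        mu = weighted_mean(hc, table[weight_col])
        if mu == 0:
            rows.append({"food_group": col, "value": np.nan, "se": np.nan,
                         "p_value": np.nan, "mu": 0.0, "flag": "never-consumed"})
            continue
        est = concentration_index(hc, ranks, table[weight_col], clusters=clusters)
        sig = est.significant(alpha)
        direction = "pro-rich" if (sig and est.value > 0) else "pro-poor" if (sig and est.value < 0) else "none"
        rows.append({"food_group": col, "value": est.value, "se": est.se,
                     "p_value": est.p_value, "mu": est.mu, "flag": direction})
    return pd.DataFrame(rows)
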