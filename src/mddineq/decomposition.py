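"""Regression-based decomposition of the concentration index.

For a binary outcome ``h`` with weighted mean ``mu`` and a linear probability
model ``h = alpha + sum_k beta_k x_k + eps`` fitted by survey-weighted least
squares on dummy-coded covariates, the concentration index splits exactly as

    CIX = sum_k (beta_k * xbar_k / mu) * C_k  +  GC_eps / mu,

where ``C_k = (2 / xbar_k) * cov_w(x_k, r)`` is the component concentration
index of dummy ``k`` against the SAME fractional rank vector ``r`` used for
the overall index, ``beta_k * xbar_k / mu`` is the elasticity of the outcome
with respect to the dummy, and ``GC_eps = 2 * cov_w(eps, r)`` is the
generalized concentration index of the residuals.  Because weighted
least-squares residuals are exactly orthogonal decompositions of ``h``, the
identity explained + residual = overall holds to machine precision.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg as sla

from .concentration import (
    CIXEstimate,
    FractionalRankVector,
    normalised_weights,
    weighted_cov,
)

#: Reference category per modelled covariate (matches the conventional
#: poorest / no-education / male / rural / Barisal base rows).
DEFAULT_REFERENCES = {
    "mother_age_group": "15-19",
    "mother_education": 0.0,
    "wealth_quintile": 1.0,
    "partner_education": 0.0,
    "residence": "rural",
    "media_exposure": 0.0,
    "currently_working": 0.0,
    "postnatal_visited": 0.0,
    "anc_category": "<4",
    "child_sex": "male",
    "living_children_category": "1",
    "division": "Barisal",
}


class CollinearDesignError(ValueError):
    def __init__(self, aliased):
        self.aliased = list(aliased)
        super().__init__(f"collinear dummy design; aliased columns: {self.aliased}")


class InternalConsistencyError(RuntimeError):
    pass


@dataclass
class RegressionFit:
    """Weighted linear-probability-model fit on a dummy design."""

    alpha: float
    beta: pd.Series                 # indexed by "variable=category"
    xbar: pd.Series                 # weighted dummy means, same index
    residuals: np.ndarray
    mu: float
    design: pd.DataFrame            # columns (variable, category, dummy)
    dummies: pd.DataFrame           # the 0/1 design matrix (no intercept)
    fitted: np.ndarray


def build_design(
    table: pd.DataFrame,
    variables: list[str],
    references: dict | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Dummy-code the covariates, omitting each variable's reference category.

    Returns ``(X, info)`` where X holds one 0/1 column per non-reference
    category named ``variable=category`` and info maps columns back to
    (variable, category, reference).
    """
    references = {**DEFAULT_REFERENCES, **(references or {})}
    cols, info = {}, []
    for var in variables:
        values = table[var]
        if values.isna().any():
            raise ValueError(f"covariate {var!r} has missing values; run the filter cascade first")
        levels = sorted(pd.unique(values).tolist(), key=lambda v: (isinstance(v, str), v))
        ref = references.get(var, levels[0])
        if ref not in levels:
            raise ValueError(f"reference category {ref!r} absent from {var!r} (levels: {levels})")
        for lev in levels:
            if lev == ref:
                continue
            name = f"{var}={lev}"
            cols[name] = (values == lev).to_numpy(dtype=float)
            info.append({"dummy": name, "variable": var, "category": lev, "reference": ref})
    X = pd.DataFrame(cols, index=table.index)
    return X, pd.DataFrame(info)


def _find_aliased(A: np.ndarray, names: list[str]) -> list[str]:
    """Columns not pivotal in a rank-revealing QR (candidate aliases)."""
    _, R, piv = sla.qr(A, pivoting=True, mode="economic")
    diag = np.abs(np.diag(R))
    tol = diag.max() * max(A.shape) * np.finfo(float).eps if diag.size else 0.0
    rank = int((diag > tol).sum())
    return [names[i] for i in sorted(piv[rank:])]


def fit_lpm(
    outcome,
    table: pd.DataFrame,
    weights,
    variables: list[str],
    references: dict | None = None,
) -> RegressionFit:
    """Survey-weighted least squares of the binary outcome on dummy-coded
    covariates (the linear probability model feeding the decomposition)."""
    h = np.asarray(getattr(outcome, "mdd", outcome), dtype=float)
    w = normalised_weights(weights)
    X, info = build_design(table, variables, references)
    A = np.column_stack([np.ones(len(h)), X.to_numpy()])
    names = ["const"] + list(X.columns)

    sw = np.sqrt(w)
    rank = np.linalg.matrix_rank(sw[:, None] * A)
    if rank < A.shape[1]:
        raise CollinearDesignError(_find_aliased(sw[:, None] * A, names))

    AtWA = A.T @ (w[:, None] * A)
    coef = np.linalg.solve(AtWA, A.T @ (w * h))
    fitted = A @ coef
    resid = h - fitted

    mu = float(w @ h)
    if mu <= 0:
        raise ValueError("outcome weighted mean is zero; model undefined")
    xbar = pd.Series(w @ X.to_numpy(), index=X.columns)
    return RegressionFit(
        alpha=float(coef[0]),
        beta=pd.Series(coef[1:], index=X.columns),
        xbar=xbar,
        residuals=resid,
        mu=mu,
        design=info,
        dummies=X,
        fitted=fitted,
    )


@dataclass
class DecompositionTable:
    rows: pd.DataFrame              # variable, category, elasticity, component_cix, contribution, pct
    variable_totals: pd.DataFrame   # variable, contribution, pct
    explained: float
    residual: float
    overall: float
    mu: float
    ranking_variable: str
    excluded_dummies: list = field(default_factory=list)

    def to_report(self, decimals_value: int = 4, decimals_pct: int = 2) -> pd.DataFrame:
        """Publication-style rounding: 4 dp for index quantities, 2 dp for
        percentages (full precision is kept on the table itself)."""
        rep = self.rows.copy()
        for c in ("elasticity", "component_cix", "contribution"):
            rep[c] = rep[c].round(decimals_value)
        rep["pct"] = rep["pct"].round(decimals_pct)
        return rep


def decompose(
    fit: RegressionFit,
    ranks: FractionalRankVector,
    weights,
    overall: CIXEstimate,
) -> DecompositionTable:
    """Split the overall concentration index into per-dummy contributions.

    Component indices use the same rank vector as the overall index.  The
    residual term is computed directly from the regression residuals and
    cross-checked against ``overall - explained``; a gap above 1e-8 raises
    an internal-consistency error.
    """
    w = normalised_weights(weights)
    r = ranks.ranks
    if len(r) != len(fit.residuals):
        raise ValueError("ranks and regression rows are inconsistent")
    mu = fit.mu

    rows, excluded = [], []
    meta = fit.design.set_index("dummy")
    for dummy in fit.beta.index:
        xbar = float(fit.xbar[dummy])
        if xbar == 0:
            warnings.warn(f"dummy {dummy!r} has zero weighted mean; excluded from the table",
                          stacklevel=2)
            excluded.append(dummy)
            continue
        xk = fit.dummies[dummy].to_numpy(dtype=float)
        ck = 2.0 / xbar * weighted_cov(xk, r, w)
        elasticity = float(fit.beta[dummy]) * xbar / mu
        rows.append({
            "variable": meta.loc[dummy, "variable"],
            "category": meta.loc[dummy, "category"],
            "dummy": dummy,
            "elasticity": elasticity,
            "component_cix": ck,
            "contribution": elasticity * ck,
        })
    rows = pd.DataFrame(rows)

    explained = float(rows["contribution"].sum())
    residual_direct = 2.0 * weighted_cov(fit.residuals, r, w) / mu
    residual_identity = overall.value - explained
    if abs(residual_direct - residual_identity) > 1e-8:
        raise InternalConsistencyError(
            f"residual term mismatch: direct {residual_direct:.3e} vs "
            f"identity {residual_identity:.3e}")

    totals = (rows.groupby("variable", sort=False)["contribution"]
              .sum().rename("contribution").reset_index())
    table = DecompositionTable(
        rows=rows,
        variable_totals=totals,
        explained=explained,
        residual=residual_direct,
        overall=overall.value,
        mu=mu,
        ranking_variable=ranks.ranking_variable,
        excluded_dummies=excluded,
    )
    return percentage_contributions(table)


def percentage_contributions(table: DecompositionTable) -> DecompositionTable:
    """Finalize the percentage-of-overall columns.

    Negative percentages are meaningful and kept as printed: a negative
    share marks a factor that pulls the concentration index down.
    """
    if table.overall == 0:
        raise ValueError("percentage contributions undefined: overall CIX is zero")
    table.rows = table.rows.copy()
    table.rows["pct"] = 100.0 * table.rows["contribution"] / table.overall
    table.variable_totals = table.variable_totals.copy()
    table.variable_totals["pct"] = 100.0 * table.variable_totals["contribution"] / table.overall
    return table
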