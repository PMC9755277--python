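"""Household wealth index from asset indicators.

DHS-style construction: standardize the asset indicators (weighted mean 0,
variance 1), take the first principal component of the weighted correlation
structure as the continuous wealth score, orient its sign against a declared
affluence anchor column, and cut the score into weighted quintiles
(poorest ... richest).  Households are the unit; children inherit the score
of their household.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .concentration import normalised_weights

QUINTILE_LABELS = ["poorest", "poorer", "middle", "richer", "richest"]


@dataclass
class WealthScore:
    score: np.ndarray
    quintile: np.ndarray          # 1..5, non-decreasing in score
    loadings: pd.Series           # first-PC loadings per retained indicator
    explained_variance: float     # leading eigenvalue share
    dropped_columns: list


def weighted_quintile_cut(score: np.ndarray, weights) -> np.ndarray:
    """Weighted empirical-CDF quintiles; an observation sitting exactly on a
    0.2k boundary goes to the lower quintile."""
    w = normalised_weights(weights)
    order = np.argsort(score, kind="stable")
    cum_incl = np.cumsum(w[order])
    # epsilon guards cumulative-sum round-off at exact 0.2k boundaries
    q_sorted = np.digitize(cum_incl - 1e-9, [0.2, 0.4, 0.6, 0.8], right=True) + 1
    q = np.empty(len(score), dtype=int)
    q[order] = q_sorted
    return q


def compute_wealth_scores(
    assets: pd.DataFrame,
    weights,
    anchor: str,
) -> WealthScore:
    """First-principal-component wealth score and weighted quintiles.

    ``anchor`` names an indicator that rises with affluence; the score's
    sign is fixed so it correlates positively with that column (the PC sign
    is otherwise arbitrary).  Constant columns are dropped with a warning;
    fewer than two usable columns, or fewer than five distinct scores, is an
    error.
    """
    if not isinstance(assets, pd.DataFrame):
        assets = pd.DataFrame(np.asarray(assets, dtype=float))
        assets.columns = [f"col_{i}" for i in range(assets.shape[1])]
    if anchor not in assets.columns:
        raise KeyError(f"anchor column {anchor!r} not among the asset indicators")
    w = normalised_weights(weights)
    if len(w) != len(assets):
        raise ValueError("weights and asset table differ in length")

    X = assets.to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValueError("asset indicators contain missing values")
    means = w @ X
    var = w @ (X - means) ** 2
    keep = var > 1e-14
    dropped = [c for c, k in zip(assets.columns, keep) if not k]
    if dropped:
        warnings.warn(f"dropping constant asset indicators: {dropped}", stacklevel=2)
    cols = [c for c, k in zip(assets.columns, keep) if k]
    if len(cols) < 2:
        raise ValueError("need at least two non-constant asset indicators")
    Z = (X[:, keep] - means[keep]) / np.sqrt(var[keep])

    # weighted correlation matrix of the standardized indicators
    R = Z.T @ (w[:, None] * Z)
    eigvals, eigvecs = np.linalg.eigh(R)
    v = eigvecs[:, -1]
    score = Z @ v

    if anchor in cols:
        anchor_std = Z[:, cols.index(anchor)]
    else:  # anchor was constant: orientation is undefined
        raise ValueError(f"anchor column {anchor!r} is constant; cannot orient the score")
    if float(w @ (score * anchor_std)) < 0:
        v, score = -v, -score

    if len(np.unique(np.round(score, 12))) < 5:
        raise ValueError("fewer than five distinct wealth scores; quintiles undefined")
    quintile = weighted_quintile_cut(score, w)

    return WealthScore(
        score=score,
        quintile=quintile,
        loadings=pd.Series(v, index=cols),
        explained_variance=float(eigvals[-1] / eigvals.sum()),
        dropped_columns=dropped,
    )


def attach_wealth_index(
    table: pd.DataFrame,
    asset_columns: list[str],
    anchor: str,
    weight_col: str = "weight",
    household_col: str = "household_id",
) -> pd.DataFrame:
    """Compute the index at household level and merge scores/quintiles back
    onto the child-level table (children inherit their household's score)."""
    hh = table.drop_duplicates(subset=[household_col])
    ws = compute_wealth_scores(hh[asset_columns], hh[weight_col], anchor=anchor)
    mapping = pd.DataFrame({
        household_col: hh[household_col].to_numpy(),
        "wealth_score": ws.score,
        "wealth_quintile": ws.quintile.astype(float),
    })
    out = table.drop(columns=[c for c in ("wealth_score", "wealth_quintile") if c in table])
    return out.merge(mapping, on=household_col, how="left")
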