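"""Simulation-based validation: parameter recovery and test size.

Two experiments tie the pipeline back to the generator's known truth:

* :func:`recovery_experiment` — one large synthetic draw, decompose the
  wealth-ranked concentration index on the generating covariates, and compare
  each variable's contribution with the closed-form grid oracle; the
  Monte-Carlo standard error of each contribution is estimated by a cluster
  bootstrap (resampling primary sampling units, the level at which the
  generator induces dependence).

* :func:`null_rejection_rate` — under a gradient-free generator the true
  concentration index is zero, so the cluster-robust test should reject at
  its nominal size; the experiment measures the rejection rate over many
  replicate surveys.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .cohort import FOOD_COLUMNS, compute_mdd
from .concentration import concentration_index, weighted_fractional_rank
from .decomposition import decompose, fit_lpm
from .synthetic import GeneratorConfig, generate_survey, null_config, true_decomposition

GENERATING_COVARIATES = ["wealth_quintile", "mother_education"]


def _contributions(table: pd.DataFrame, ranking: str) -> dict:
    h = compute_mdd(table[FOOD_COLUMNS])
    w = table["weight"].to_numpy()
    ranks = weighted_fractional_rank(table[ranking], w, name=ranking)
    overall = concentration_index(h.mdd, ranks, w, clusters=table["cluster_id"])
    fit = fit_lpm(h, table, w, GENERATING_COVARIATES,
                  references={"wealth_quintile": 1.0, "mother_education": 0.0})
    tab = decompose(fit, ranks, w, overall)
    by_var = dict(zip(tab.variable_totals["variable"], tab.variable_totals["contribution"]))
    by_var["__overall__"] = overall.value
    return by_var


def recovery_experiment(
    config: GeneratorConfig | None = None,
    n_children: int = 200_000,
    seed: int = 2024,
    n_boot: int = 20,
    ranking: str = "wealth_quintile",
) -> pd.DataFrame:
    """Decomposition contributions vs the generator's analytic truth.

    Returns one row per generating covariate (plus the overall index) with
    the estimate, the oracle value, the cluster-bootstrap Monte-Carlo SE and
    the standardized gap ``z = (estimate - truth) / se``.
    """
    if config is None:
        config = GeneratorConfig(n_children=n_children, seed=seed,
                                 age_range=(6, 23), missing_rate=0.0)
    else:
        config = dataclasses.replace(config, n_children=n_children, seed=seed,
                                     age_range=(6, 23), missing_rate=0.0)
    table = generate_survey(config)
    point = _contributions(table, ranking)
    oracle = true_decomposition(config, ranking=ranking)
    truth = dict(oracle["contributions"])
    truth["__overall__"] = oracle["overall_cix"]

    rng = np.random.default_rng(seed + 1)
    cluster_groups = table.groupby("cluster_id").indices
    cluster_ids = sorted(cluster_groups)
    boots: list[dict] = []
    for _ in range(n_boot):
        chosen = rng.choice(cluster_ids, size=len(cluster_ids), replace=True)
        idx = np.concatenate([cluster_groups[c] for c in chosen])
        resampled = table.iloc[idx].reset_index(drop=True)
        # re-label duplicated clusters so they count as distinct PSUs
        resampled["cluster_id"] = np.repeat(
            np.arange(len(chosen)), [len(cluster_groups[c]) for c in chosen])
        boots.append(_contributions(resampled, ranking))

    rows = []
    for key in point:
        bvals = np.array([b[key] for b in boots])
        se = float(bvals.std(ddof=1))
        rows.append({
            "quantity": key, "estimate": point[key], "truth": truth.get(key, np.nan),
            "mc_se": se,
            "z": (point[key] - truth.get(key, np.nan)) / se if se > 0 else np.nan,
        })
    return pd.DataFrame(rows)


def null_rejection_rate(
    n_reps: int = 500,
    n_children: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
    ranking: str = "wealth_quintile",
) -> float:
    """Share of gradient-free replicate surveys whose concentration index is
    (spuriously) significant at level ``alpha``."""
    seeds = np.random.default_rng(seed).integers(0, 2**31 - 1, size=n_reps)
    rejections = 0
    for s in seeds:
        cfg = null_config(n_children=n_children, seed=int(s),
                          age_range=(6, 23), n_clusters=50)
        table = generate_survey(cfg)
        h = compute_mdd(table[FOOD_COLUMNS])
        w = table["weight"].to_numpy()
        ranks = weighted_fractional_rank(table[ranking], w, name=ranking)
        est = concentration_index(h.mdd, ranks, w, clusters=table["cluster_id"])
        rejections += est.p_value < alpha
    return rejections / n_reps
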