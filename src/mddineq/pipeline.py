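"""End-to-end pipeline: data in, inequality report out.

Chains the stages — simulate or load a child-level survey table, recode
covariates, run the filter cascade, (optionally) rebuild the wealth index
from raw assets, compute descriptives, concentration curves and indices per
ranking variable, subgroup and food-group sweeps, and the regression-based
decomposition — writing CSV tables, figures and a machine-readable run
manifest to an output directory.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import (
    MODELLED_COVARIATES,
    apply_filter_cascade,
    compute_mdd,
    recode_covariates,
    weighted_descriptives,
    FOOD_COLUMNS,
)
from .concentration import (
    component_cix,
    concentration_curve,
    concentration_index,
    subgroup_cix,
    weighted_fractional_rank,
)
from .decomposition import decompose, fit_lpm
from .published import verify_all
from .synthetic import GeneratorConfig, generate_survey
from .wealth import attach_wealth_index

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """One reproducible run: input, rankings, references, outputs, seed."""

    output_dir: str = "mddineq_out"
    input_csv: str | None = None
    generator: GeneratorConfig | None = None
    seed: int | None = None
    ranking_variables: tuple = ("wealth_quintile", "mother_education")
    subgroup_variable: str = "child_age_band"
    references: dict | None = None
    use_asset_index: bool = False
    asset_columns: tuple = ()
    asset_anchor: str | None = None
    weighted_regression: bool = True
    normalization: str | None = None

    def resolved_generator(self) -> GeneratorConfig:
        gen = self.generator or GeneratorConfig()
        if self.seed is not None:
            gen = dataclasses.replace(gen, seed=self.seed)
        return gen


def _plain(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, np.generic):
        return obj.item()
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    return obj


def _config_to_dict(config: PipelineConfig) -> dict:
    return _plain(dataclasses.asdict(config))


def _plot_curve(curve, path: Path) -> None:
    fig, ax = plt.subplots(figsize=(5, 5))
    ax.plot([0, 1], [0, 1], "k--", lw=1, label="line of equality")
    ax.plot(curve.population_share, curve.outcome_share, "-o", ms=3,
            label="concentration curve")
    ax.set_xlabel(f"cumulative population share ({curve.ranking_variable})")
    ax.set_ylabel("cumulative MDD share")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _plot_contributions(table, path: Path) -> None:
    totals = table.variable_totals.sort_values("pct")
    fig, ax = plt.subplots(figsize=(7, 5))
    ax.barh(totals["variable"], totals["pct"])
    ax.axvline(0, color="k", lw=0.8)
    ax.set_xlabel(f"% contribution to CIX ({table.ranking_variable})")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def load_or_generate(config: PipelineConfig) -> pd.DataFrame:
    if config.input_csv:
        return pd.read_csv(config.input_csv)
    return generate_survey(config.resolved_generator())


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage and write the artifact bundle.

    Returns a dict of in-memory results (cohort, report, estimates,
    decompositions) mirroring what lands in ``output_dir``.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    table = load_or_generate(config)
    table = recode_covariates(table)

    # schema validation before any computation on the cohort
    needed = set(config.ranking_variables) | {config.subgroup_variable, "weight"}
    missing = sorted(c for c in needed if c not in table.columns)
    if missing:
        raise KeyError(f"configured columns absent from input schema: {missing}")

    if config.use_asset_index:
        if not config.asset_columns or config.asset_anchor is None:
            raise ValueError("use_asset_index requires asset_columns and asset_anchor")
        table = attach_wealth_index(table, list(config.asset_columns), config.asset_anchor)

    cohort, report = apply_filter_cascade(table)
    (out / "filter_cascade.jsonl").write_text(report.to_json_lines() + "\n")

    outcome = compute_mdd(cohort[FOOD_COLUMNS])
    desc, prevalence = weighted_descriptives(cohort, outcome)
    desc.to_csv(out / "descriptives.csv", index=False)

    weights = cohort["weight"].to_numpy()
    clusters = cohort["cluster_id"] if "cluster_id" in cohort else None
    results: dict = {
        "cohort": cohort, "cascade": report, "outcome": outcome,
        "prevalence": prevalence, "cix": {}, "curves": {},
        "decompositions": {}, "subgroup": {}, "components": {},
    }

    estimates_rows = []
    for ranking in config.ranking_variables:
        ranks = weighted_fractional_rank(cohort[ranking], weights, name=ranking)
        est = concentration_index(outcome.mdd, ranks, weights, clusters=clusters,
                                  normalization=config.normalization)
        curve = concentration_curve(outcome.mdd, cohort[ranking], weights, name=ranking)
        results["cix"][ranking] = est
        results["curves"][ranking] = curve
        estimates_rows.append({"ranking_variable": ranking, "subgroup": "all",
                               "value": est.value, "se": est.se, "p": est.p_value,
                               "mu": est.mu, "n": est.n})
        pd.DataFrame(curve.points, columns=["population_share", "outcome_share"]) \
            .to_csv(out / f"curve_{ranking}.csv", index=False)
        _plot_curve(curve, out / f"curve_{ranking}.png")

        reg_weights = weights if config.weighted_regression else np.ones(len(cohort))
        covariates = [c for c in MODELLED_COVARIATES]
        fit = fit_lpm(outcome, cohort, reg_weights, covariates, config.references)
        decomp = decompose(fit, ranks, reg_weights, est)
        results["decompositions"][ranking] = decomp
        decomp.rows.drop(columns=["dummy"]).to_csv(out / f"decomposition_{ranking}.csv", index=False)
        decomp.variable_totals.to_csv(out / f"decomposition_{ranking}_totals.csv", index=False)
        _plot_contributions(decomp, out / f"decomposition_{ranking}_pct.png")

        sub_est, comparator = subgroup_cix(cohort, outcome.mdd, ranking,
                                           config.subgroup_variable)
        results["subgroup"][ranking] = (sub_est, comparator)
        for level, e in sub_est.items():
            estimates_rows.append({"ranking_variable": ranking, "subgroup": str(level),
                                   "value": e.value, "se": e.se, "p": e.p_value,
                                   "mu": e.mu, "n": e.n})

        comp = component_cix(cohort, ranking, FOOD_COLUMNS)
        comp.to_csv(out / f"component_cix_{ranking}.csv", index=False)
        results["components"][ranking] = comp

    pd.DataFrame(estimates_rows).to_csv(out / "cix_estimates.csv", index=False)

    verification = verify_all()
    ver_json = {
        name: {
            "overall": res["overall"],
            "rows_checked": int(res["rows"]["contribution_ok"].notna().sum()),
            "contribution_ok": int(res["rows"]["contribution_ok"].eq(True).sum()),
            "pct_ok": int(res["rows"]["pct_ok"].eq(True).sum()),
            "findings": res["findings"],
        }
        for name, res in verification.items()
    }
    (out / "published_verification.json").write_text(json.dumps(ver_json, indent=2))
    results["verification"] = verification

    manifest = {
        "package_version": __version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "config": _config_to_dict(config),
        "rows_input": int(len(table)),
        "rows_cohort": int(len(cohort)),
        "weighted_n": report.final_weighted_n,
        "prevalence": prevalence,
        "cix": {k: v.value for k, v in results["cix"].items()},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    (out / "config.yaml").write_text(yaml.safe_dump(_config_to_dict(config)))
    logger.info("pipeline complete: %s", json.dumps(
        {k: v for k, v in manifest.items() if k not in ("config",)}))
    return results
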