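"""Cohort construction for child dietary-diversity analyses.

Builds the analysis cohort from a DHS-style child-level table: the staged
filter cascade (age window, complete food-group responses, complete modelled
covariates), the minimum-dietary-diversity (MDD) outcome — a child aged
6-23 months who consumed at least 5 of the 8 IYCF food groups on the
previous day — covariate recodes, and survey-weighted descriptive tables.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: The eight IYCF food groups, in conventional order.
FOOD_GROUPS = [
    "breastfeeding",
    "grains_roots_tubers",
    "legumes_nuts",
    "dairy",
    "flesh_foods",
    "eggs",
    "vitamin_a_fruit_veg",
    "other_fruit_veg",
]

#: Column names carrying the binary food-group flags.
FOOD_COLUMNS = [f"fg_{g}" for g in FOOD_GROUPS]

#: Covariates entering the decomposition model (post-recode names).
MODELLED_COVARIATES = [
    "mother_age_group",
    "mother_education",
    "wealth_quintile",
    "partner_education",
    "residence",
    "media_exposure",
    "currently_working",
    "postnatal_visited",
    "anc_category",
    "child_sex",
    "living_children_category",
    "division",
]

MDD_THRESHOLD = 5
AGE_WINDOW = (6, 23)  # closed interval, months


class EmptyCohortError(ValueError):
    """Raised when a cascade stage leaves no children."""

    def __init__(self, stage: str):
        self.stage = stage
        super().__init__(f"cohort empty after filter stage {stage!r}")


@dataclass
class StageRecord:
    stage_name: str
    rows_in: int
    rows_dropped: int
    rows_out: int


@dataclass
class FilterCascadeReport:
    stages: list[StageRecord] = field(default_factory=list)
    final_unweighted_n: int = 0
    final_weighted_n: float = 0.0

    def add(self, name: str, rows_in: int, rows_out: int) -> None:
        self.stages.append(StageRecord(name, rows_in, rows_in - rows_out, rows_out))

    def to_json_lines(self) -> str:
        lines = [json.dumps(vars(s)) for s in self.stages]
        lines.append(json.dumps({
            "final_unweighted_n": self.final_unweighted_n,
            "final_weighted_n": self.final_weighted_n,
        }))
        return "\n".join(lines)


def apply_filter_cascade(
    table: pd.DataFrame,
    covariates: list[str] | None = None,
) -> tuple[pd.DataFrame, FilterCascadeReport]:
    """Staged cohort filter: age 6-23 months, then complete food-group
    responses, then complete modelled covariates.

    Returns the surviving rows and a per-stage report.  Raises
    :class:`EmptyCohortError` naming the first stage that empties the table.
    """
    covariates = MODELLED_COVARIATES if covariates is None else covariates
    report = FilterCascadeReport()

    n0 = len(table)
    age = pd.to_numeric(table["child_age_months"], errors="coerce")
    stage1 = table[(age >= AGE_WINDOW[0]) & (age <= AGE_WINDOW[1])]
    report.add("age_6_23_months", n0, len(stage1))
    if stage1.empty:
        raise EmptyCohortError("age_6_23_months")

    stage2 = stage1.dropna(subset=[c for c in FOOD_COLUMNS if c in stage1.columns])
    report.add("complete_food_groups", len(stage1), len(stage2))
    if stage2.empty:
        raise EmptyCohortError("complete_food_groups")

    present = [c for c in covariates if c in stage2.columns]
    missing_cols = sorted(set(covariates) - set(present))
    if missing_cols:
        raise KeyError(f"modelled covariates absent from table: {missing_cols}")
    stage3 = stage2.dropna(subset=present)
    report.add("complete_covariates", len(stage2), len(stage3))
    if stage3.empty:
        raise EmptyCohortError("complete_covariates")

    report.final_unweighted_n = len(stage3)
    report.final_weighted_n = float(stage3["weight"].sum())
    logger.info("filter cascade:\n%s", report.to_json_lines())
    return stage3.reset_index(drop=True), report


@dataclass
class OutcomeVector:
    """Per-child MDD indicator and food-group count (0-8)."""

    mdd: np.ndarray
    n_groups: np.ndarray

    def __len__(self) -> int:
        return len(self.mdd)


def compute_mdd(food_flags) -> OutcomeVector:
    """MDD = 1 iff the child consumed at least 5 of the 8 food groups.

    Refuses missing flags: the filter cascade must run first.
    """
    if isinstance(food_flags, pd.DataFrame):
        arr = food_flags.to_numpy(dtype=float)
    else:
        arr = np.asarray(food_flags, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != len(FOOD_GROUPS):
        raise ValueError(f"expected an n x {len(FOOD_GROUPS)} array of food-group flags")
    if np.isnan(arr).any():
        raise ValueError("food-group flags contain missing values; apply the filter cascade first")
    if not np.isin(arr, (0.0, 1.0)).all():
        raise ValueError("food-group flags must be binary")
    counts = arr.sum(axis=1).astype(int)
    return OutcomeVector(mdd=(counts >= MDD_THRESHOLD).astype(int), n_groups=counts)


def recode_covariates(table: pd.DataFrame) -> pd.DataFrame:
    """Derive the modelled categorical covariates from raw survey fields.

    media_exposure: 1 if the mother reads a newspaper/magazine, watches
    television, or listens to the radio at least once a week; anc_category:
    antenatal visits dichotomised at 4 (4 visits falls in ">=4");
    living_children_category: 1 / 2 / >=3; child_age_band: 6-12 / 13-18 /
    19-23 months.  Unknown raw codes are logged and treated as missing.
    """
    out = table.copy()

    media_raw = ["media_newspaper_weekly", "media_tv_weekly", "media_radio_weekly"]
    flags = []
    for col in media_raw:
        v = pd.to_numeric(out[col], errors="coerce")
        bad = v.notna() & ~v.isin([0, 1])
        if bad.any():
            logger.warning("unknown codes in %s treated as missing (%d rows)", col, int(bad.sum()))
            v[bad] = np.nan
        flags.append(v)
    any_yes = (flags[0] == 1) | (flags[1] == 1) | (flags[2] == 1)
    all_known_no = (flags[0] == 0) & (flags[1] == 0) & (flags[2] == 0)
    media = pd.Series(np.nan, index=out.index)
    media[any_yes] = 1.0
    media[all_known_no] = 0.0
    out["media_exposure"] = media

    anc = pd.to_numeric(out["anc_visits"], errors="coerce")
    bad = anc.notna() & (anc < 0)
    if bad.any():
        logger.warning("negative anc_visits treated as missing (%d rows)", int(bad.sum()))
        anc[bad] = np.nan
    out["anc_category"] = pd.Series(np.nan, index=out.index, dtype=object)
    out.loc[anc >= 4, "anc_category"] = ">=4"
    out.loc[(anc >= 0) & (anc < 4), "anc_category"] = "<4"

    kids = pd.to_numeric(out["living_children"], errors="coerce")
    bad = kids.notna() & (kids < 1)
    if bad.any():
        logger.warning("living_children < 1 treated as missing (%d rows)", int(bad.sum()))
        kids[bad] = np.nan
    cat = pd.Series(np.nan, index=out.index, dtype=object)
    cat[kids == 1] = "1"
    cat[kids == 2] = "2"
    cat[kids >= 3] = ">=3"
    out["living_children_category"] = cat

    age = pd.to_numeric(out["child_age_months"], errors="coerce")
    band = pd.Series(np.nan, index=out.index, dtype=object)
    band[(age >= 6) & (age <= 12)] = "6-12"
    band[(age >= 13) & (age <= 18)] = "13-18"
    band[(age >= 19) & (age <= 23)] = "19-23"
    out["child_age_band"] = band

    return out


def weighted_descriptives(
    table: pd.DataFrame,
    outcome,
    variables: list[str] | None = None,
    weight_col: str = "weight",
) -> tuple[pd.DataFrame, float]:
    """Per-category weighted counts, column percentages and MDD prevalence.

    Mirrors a background-characteristics table: for every category of every
    variable the weighted N, its weighted share of the column (percent), and
    the weighted percentage having MDD; plus the overall weighted prevalence.
    Percentages within each variable sum to 100 before rounding.
    """
    variables = MODELLED_COVARIATES if variables is None else variables
    h = np.asarray(outcome.mdd if isinstance(outcome, OutcomeVector) else outcome, dtype=float)
    w = table[weight_col].to_numpy(dtype=float)
    total_w = w.sum()
    overall = float(np.dot(w, h) / total_w)

    rows = []
    for var in variables:
        grouped = pd.DataFrame({"w": w, "wh": w * h, "cat": table[var].to_numpy()})
        agg = grouped.groupby("cat", dropna=False, observed=True)[["w", "wh"]].sum()
        for cat, rec in agg.iterrows():
            rows.append({
                "variable": var,
                "category": cat,
                "weighted_n": rec["w"],
                "pct": 100.0 * rec["w"] / total_w,
                "mdd_pct": 100.0 * rec["wh"] / rec["w"] if rec["w"] > 0 else 0.0,
            })
    return pd.DataFrame(rows), overall
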