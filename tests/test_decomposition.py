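"""Linear probability model fit and the exact decomposition identity."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from mddineq.cohort import MODELLED_COVARIATES
from mddineq.concentration import concentration_index, weighted_fractional_rank
from mddineq.decomposition import (
    CollinearDesignError,
    DecompositionTable,
    build_design,
    decompose,
    fit_lpm,
    percentage_contributions,
)


def test_perfect_fit_single_dummy():
    t = pd.DataFrame({"x": [0.0, 0.0, 1.0, 1.0, 1.0]})
    y = t["x"].to_numpy()
    fit = fit_lpm(y, t, np.ones(5), ["x"], references={"x": 0.0})
    assert fit.alpha == pytest.approx(0.0, abs=1e-12)
    assert fit.beta["x=1.0"] == pytest.approx(1.0)
    np.testing.assert_allclose(fit.residuals, 0.0, atol=1e-12)


def test_coefficients_equal_weighted_group_mean_differences(rng):
    """One categorical regressor: the LPM is saturated, so each coefficient
    must equal the weighted outcome-mean difference from the reference
    (brute-force group-means oracle)."""
    n = 400
    cat = rng.integers(0, 4, size=n).astype(float)
    w = rng.uniform(0.5, 2.0, size=n)
    y = (rng.random(n) < 0.2 + 0.15 * cat).astype(float)
    t = pd.DataFrame({"v": cat})
    fit = fit_lpm(y, t, w, ["v"], references={"v": 0.0})

    def wmean(mask):
        return np.dot(w[mask], y[mask]) / w[mask].sum()

    base = wmean(cat == 0)
    for k in (1, 2, 3):
        assert fit.beta[f"v={float(k)}"] == pytest.approx(wmean(cat == k) - base, abs=1e-10)
    assert fit.alpha == pytest.approx(base, abs=1e-10)


def test_fitted_plus_residual_reproduces_outcome(default_cohort, cohort_outcome):
    cohort, _ = default_cohort
    w = cohort["weight"].to_numpy()
    fit = fit_lpm(cohort_outcome, cohort, w, MODELLED_COVARIATES)
    np.testing.assert_allclose(fit.fitted + fit.residuals, cohort_outcome.mdd, atol=1e-12)


def test_matches_statsmodels_wls(default_cohort, cohort_outcome):
    cohort, _ = default_cohort
    w = cohort["weight"].to_numpy()
    fit = fit_lpm(cohort_outcome, cohort, w, MODELLED_COVARIATES)
    X, _ = build_design(cohort, MODELLED_COVARIATES)
    sm_fit = sm.WLS(cohort_outcome.mdd.astype(float), sm.add_constant(X.to_numpy()),
                    weights=w).fit()
    np.testing.assert_allclose(
        np.concatenate([[fit.alpha], fit.beta.to_numpy()]), sm_fit.params, atol=1e-10)


def test_collinear_design_raises_naming_alias():
    t = pd.DataFrame({"a": [0.0, 1.0, 0.0, 1.0], "b": ["n", "y", "n", "y"]})
    with pytest.raises(CollinearDesignError, match="b=y"):
        fit_lpm(np.array([0, 1, 1, 0.0]), t, np.ones(4), ["a", "b"],
                references={"a": 0.0, "b": "n"})


def test_single_covariate_perfect_fit_attributes_everything(rng):
    n = 200
    x = rng.integers(0, 2, size=n).astype(float)
    w = rng.uniform(0.5, 2.0, size=n)
    t = pd.DataFrame({"x": x})
    fr = weighted_fractional_rank(x, w, name="x")
    overall = concentration_index(x, fr, w)
    fit = fit_lpm(x, t, w, ["x"], references={"x": 0.0})
    table = decompose(fit, fr, w, overall)
    assert table.rows["contribution"].iloc[0] == pytest.approx(overall.value, abs=1e-12)
    assert table.residual == pytest.approx(0.0, abs=1e-12)


@pytest.mark.parametrize("ranking", ["wealth_quintile", "mother_education"])
def test_identity_explained_plus_residual(default_cohort, cohort_outcome, ranking):
    cohort, _ = default_cohort
    w = cohort["weight"].to_numpy()
    fr = weighted_fractional_rank(cohort[ranking], w, name=ranking)
    overall = concentration_index(cohort_outcome.mdd, fr, w)
    fit = fit_lpm(cohort_outcome, cohort, w, MODELLED_COVARIATES)
    table = decompose(fit, fr, w, overall)
    assert table.explained + table.residual == pytest.approx(overall.value, abs=1e-10)
    # per-row product identity and percentage closure
    np.testing.assert_allclose(
        table.rows["contribution"],
        table.rows["elasticity"] * table.rows["component_cix"], atol=1e-12)
    total_pct = table.rows["pct"].sum() + 100.0 * table.residual / table.overall
    assert total_pct == pytest.approx(100.0, abs=1e-8)
    # sum of per-variable totals + residual = overall
    assert table.variable_totals["contribution"].sum() + table.residual == \
        pytest.approx(overall.value, abs=1e-10)


def test_identity_survives_omitting_a_generating_covariate(default_cohort, cohort_outcome):
    cohort, _ = default_cohort
    w = cohort["weight"].to_numpy()
    fr = weighted_fractional_rank(cohort["wealth_quintile"], w, name="wealth_quintile")
    overall = concentration_index(cohort_outcome.mdd, fr, w)
    reduced = [c for c in MODELLED_COVARIATES if c != "mother_education"]
    fit = fit_lpm(cohort_outcome, cohort, w, reduced)
    table = decompose(fit, fr, w, overall)
    assert table.explained + table.residual == pytest.approx(overall.value, abs=1e-10)


def test_percentage_contribution_published_arithmetic():
    """The percentage operation reproduces the printed worked examples:
    0.0134 / 0.1211 -> 11.07%; 0.0731 x 0.8079 -> 0.0591 (48.77%);
    -0.0081 / 0.1211 -> -6.69%."""
    rows = pd.DataFrame({
        "variable": ["media_exposure", "wealth_quintile", "postnatal_visited"],
        "category": ["Yes", "Highest", "Yes"],
        "dummy": ["m", "w", "p"],
        "elasticity": [-0.03654, 0.0731, 0.1327],
        "component_cix": [-0.3669, 0.8079, -0.0610],
    })
    # the postnatal percentage is computed from the contribution as printed
    # (-0.0081), matching table conventions
    rows["contribution"] = [rows["elasticity"][0] * rows["component_cix"][0],
                            rows["elasticity"][1] * rows["component_cix"][1],
                            -0.0081]
    totals = rows.groupby("variable", sort=False)["contribution"].sum().reset_index()
    table = DecompositionTable(
        rows=rows, variable_totals=totals,
        explained=float(rows["contribution"].sum()),
        residual=0.0, overall=0.1211, mu=0.3747, ranking_variable="wealth_quintile")
    table = percentage_contributions(table)
    rep = table.to_report()
    assert rep.loc[0, "contribution"] == pytest.approx(0.0134)
    assert rep.loc[0, "pct"] == pytest.approx(11.07)
    assert rep.loc[1, "contribution"] == pytest.approx(0.0591)
    assert rep.loc[1, "pct"] == pytest.approx(48.77)
    assert rep.loc[2, "pct"] == pytest.approx(-6.69)


def test_zero_overall_percentages_error():
    rows = pd.DataFrame({"variable": ["v"], "category": ["c"], "dummy": ["d"],
                         "elasticity": [0.0], "component_cix": [0.0], "contribution": [0.0]})
    table = DecompositionTable(rows=rows, variable_totals=rows[["variable", "contribution"]],
                               explained=0.0, residual=0.0, overall=0.0, mu=0.5,
                               ranking_variable="x")
    with pytest.raises(ValueError, match="overall"):
        percentage_contributions(table)
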