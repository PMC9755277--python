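"""Ranks, concentration index, curves: hand examples and exact invariants."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mddineq.cohort import FOOD_COLUMNS
from mddineq.concentration import (
    cix_brute_force,
    component_cix,
    concentration_curve,
    concentration_index,
    subgroup_cix,
    weighted_fractional_rank,
)

# ---------------------------------------------------------------------------
# fractional ranks
# ---------------------------------------------------------------------------

def test_equal_weights_distinct_values_midpoint_ranks():
    fr = weighted_fractional_rank([10, 20, 30, 40], np.ones(4))
    np.testing.assert_allclose(fr.ranks, [0.125, 0.375, 0.625, 0.875])


def test_single_tie_group_all_half():
    fr = weighted_fractional_rank([3, 3, 3], [1.0, 2.0, 5.0])
    np.testing.assert_allclose(fr.ranks, 0.5)


def test_two_groups_weights_one_three():
    fr = weighted_fractional_rank([0, 1], [1.0, 3.0])
    np.testing.assert_allclose(fr.ranks, [0.125, 0.625])


def test_unordered_categorical_refused():
    s = pd.Series(pd.Categorical(["a", "b", "a"], ordered=False))
    with pytest.raises(TypeError, match="order"):
        weighted_fractional_rank(s, np.ones(3))
    with pytest.raises(TypeError, match="order"):
        weighted_fractional_rank(["x", "y", "z"], np.ones(3))


@settings(deadline=None, max_examples=60)
@given(
    st.lists(st.integers(min_value=0, max_value=5), min_size=2, max_size=40),
    st.integers(0, 2**31 - 1),
)
def test_rank_mean_is_half_and_ties_monotone(values, seed):
    w = np.random.default_rng(seed).uniform(0.1, 5.0, size=len(values))
    fr = weighted_fractional_rank(values, w)
    wn = w / w.sum()
    assert float(wn @ fr.ranks) == pytest.approx(0.5, abs=1e-12)
    ordered = [fr.tie_group_ranks[v] for v in sorted(set(values))]
    assert all(a < b for a, b in zip(ordered, ordered[1:]))


# ---------------------------------------------------------------------------
# concentration index
# ---------------------------------------------------------------------------

def test_hand_example_reaches_binary_upper_bound():
    h = np.array([0, 0, 1, 1])
    w = np.ones(4)
    fr = weighted_fractional_rank([1, 2, 3, 4], w)
    est = concentration_index(h, fr, w)
    assert est.mu == pytest.approx(0.5)
    assert est.value == pytest.approx(0.5)        # = 1 - mu, the binary bound
    assert est.value == pytest.approx(1 - est.mu)


def test_constant_outcome_gives_zero_index():
    fr = weighted_fractional_rank([1, 2, 3, 4], np.ones(4))
    est = concentration_index(np.ones(4), fr, np.ones(4))
    assert est.value == pytest.approx(0.0, abs=1e-15)


def test_zero_mean_outcome_is_an_error():
    fr = weighted_fractional_rank([1, 2], np.ones(2))
    with pytest.raises(ValueError, match="mean"):
        concentration_index(np.zeros(2), fr, np.ones(2))


@settings(deadline=None, max_examples=40)
@given(st.integers(0, 2**31 - 1), st.integers(5, 60))
def test_covariance_formula_equals_brute_force_sum(seed, n):
    r = np.random.default_rng(seed)
    h = r.integers(0, 2, size=n).astype(float)
    if h.sum() == 0:
        h[0] = 1.0
    vals = r.integers(0, 5, size=n)
    w = r.uniform(0.2, 3.0, size=n)
    fr = weighted_fractional_rank(vals, w)
    est = concentration_index(h, fr, w)
    assert est.value == pytest.approx(cix_brute_force(h, fr, w), abs=1e-12)


def test_antisymmetry_under_rank_reversal(default_cohort, cohort_outcome):
    cohort, _ = default_cohort
    w = cohort["weight"].to_numpy()
    fr = weighted_fractional_rank(cohort["wealth_quintile"], w)
    fr_rev = weighted_fractional_rank(-cohort["wealth_quintile"], w)
    a = concentration_index(cohort_outcome.mdd, fr, w).value
    b = concentration_index(cohort_outcome.mdd, fr_rev, w).value
    assert a == pytest.approx(-b, abs=1e-14)


def test_scale_invariance(default_cohort, cohort_outcome):
    cohort, _ = default_cohort
    w = cohort["weight"].to_numpy()
    fr = weighted_fractional_rank(cohort["wealth_quintile"], w)
    h = cohort_outcome.n_groups.astype(float)  # non-degenerate count outcome
    a = concentration_index(h, fr, w).value
    b = concentration_index(7.3 * h, fr, w).value
    assert a == pytest.approx(b, rel=1e-12)


def test_binary_bound_holds(default_cohort, cohort_outcome):
    cohort, _ = default_cohort
    w = cohort["weight"].to_numpy()
    for var in ("wealth_quintile", "mother_education"):
        fr = weighted_fractional_rank(cohort[var], w)
        est = concentration_index(cohort_outcome.mdd, fr, w)
        assert est.mu - 1 - 1e-12 <= est.value <= 1 - est.mu + 1e-12


def test_cluster_robust_se_differs_from_iid(default_cohort, cohort_outcome):
    cohort, _ = default_cohort
    w = cohort["weight"].to_numpy()
    fr = weighted_fractional_rank(cohort["wealth_quintile"], w)
    plain = concentration_index(cohort_outcome.mdd, fr, w)
    clustered = concentration_index(cohort_outcome.mdd, fr, w, clusters=cohort["cluster_id"])
    assert plain.value == pytest.approx(clustered.value)
    assert plain.se != clustered.se


# ---------------------------------------------------------------------------
# curves
# ---------------------------------------------------------------------------

def test_equality_curve_lies_on_diagonal():
    w = np.ones(10)
    curve = concentration_curve(np.ones(10), np.arange(10), w)
    np.testing.assert_allclose(curve.outcome_share, curve.population_share, atol=1e-15)
    assert curve.dominance == "equal"
    mid = curve.points[len(curve.points) // 2]
    assert mid[0] == pytest.approx(mid[1])


def test_all_outcome_in_top_quintile():
    quintile = np.repeat([1, 2, 3, 4, 5], 4)
    h = (quintile == 5).astype(float)
    curve = concentration_curve(h, quintile, np.ones(20))
    np.testing.assert_allclose(curve.points[-2], [0.8, 0.0], atol=1e-15)
    np.testing.assert_allclose(curve.points[-1], [1.0, 1.0])
    assert curve.dominance == "below"


@settings(deadline=None, max_examples=40)
@given(st.integers(0, 2**31 - 1))
def test_curve_area_reproduces_index(seed):
    r = np.random.default_rng(seed)
    n = r.integers(6, 80)
    h = r.integers(0, 2, size=n).astype(float)
    if h.sum() == 0:
        h[0] = 1.0
    vals = r.integers(0, 6, size=n)
    w = r.uniform(0.2, 3.0, size=n)
    curve = concentration_curve(h, vals, w)
    fr = weighted_fractional_rank(vals, w)
    est = concentration_index(h, fr, w)
    assert curve.area_index() == pytest.approx(est.value, abs=1e-10)
    assert np.all(np.diff(curve.population_share) >= -1e-15)
    assert np.all(np.diff(curve.outcome_share) >= -1e-15)


# ---------------------------------------------------------------------------
# sweeps
# ---------------------------------------------------------------------------

def test_subgroup_recovers_band_specific_gradient(rng):
    """Inequality injected only in one band must give that band the largest
    index."""
    n = 6000
    band = np.where(rng.random(n) < 0.5, "A", "B")
    quintile = rng.integers(1, 6, size=n)
    p = np.where(band == "A", 0.15 + 0.12 * (quintile - 1), 0.4)
    table = pd.DataFrame({
        "band": band, "wealth_quintile": quintile.astype(float),
        "weight": rng.uniform(0.5, 1.5, size=n),
        "cluster_id": rng.integers(0, 40, size=n),
    })
    h = (rng.random(n) < p).astype(float)
    est, comparator = subgroup_cix(table, h, "wealth_quintile", "band")
    assert comparator["largest"] == "A"
    assert est["A"].value > est["B"].value + 0.05


def test_exchangeable_age_bands_have_similar_cix(default_cohort, cohort_outcome):
    """The generator's food probabilities do not depend on child age, so the
    per-age-band indices agree within sampling error."""
    cohort, _ = default_cohort
    est, _ = subgroup_cix(cohort, cohort_outcome.mdd, "wealth_quintile", "child_age_band")
    vals = list(est.values())
    for a in vals:
        for b in vals:
            assert abs(a.value - b.value) <= 3 * np.hypot(a.se, b.se)


def test_single_row_subgroup_degenerates_to_zero():
    table = pd.DataFrame({
        "g": ["x", "y", "y", "y"], "wealth_quintile": [3.0, 1.0, 2.0, 3.0],
        "weight": np.ones(4), "cluster_id": [0, 0, 1, 1],
    })
    est, _ = subgroup_cix(table, np.array([1, 1, 0, 1]), "wealth_quintile", "g")
    assert est["x"].value == pytest.approx(0.0, abs=1e-15)


def test_component_cix_signs_follow_injected_gradients():
    from mddineq.synthetic import GeneratorConfig, generate_survey

    cfg = GeneratorConfig(n_children=40000, seed=21, age_range=(6, 23), missing_rate=0.0)
    table = generate_survey(cfg)
    comp = component_cix(table, "wealth_quintile", FOOD_COLUMNS)
    by_group = comp.set_index("food_group")
    # breastfeeding probability falls with wealth; dairy and legumes rise
    assert by_group.loc["fg_breastfeeding", "value"] < 0
    assert by_group.loc["fg_breastfeeding", "flag"] == "pro-poor"
    assert by_group.loc["fg_dairy", "flag"] == "pro-rich"
    assert by_group.loc["fg_legumes_nuts", "value"] > 0


def test_component_consumed_by_everyone_is_zero():
    table = pd.DataFrame({
        "wealth_quintile": [1.0, 2.0, 3.0, 4.0, 5.0],
        "weight": np.ones(5),
        "fg_all": np.ones(5),
    })
    comp = component_cix(table, "wealth_quintile", ["fg_all"], cluster_col=None)
    assert comp["value"].iloc[0] == pytest.approx(0.0, abs=1e-15)


def test_component_never_consumed_is_flagged():
    table = pd.DataFrame({
        "wealth_quintile": [1.0, 2.0, 3.0],
        "weight": np.ones(3),
        "fg_none": np.zeros(3),
    })
    comp = component_cix(table, "wealth_quintile", ["fg_none"], cluster_col=None)
    assert comp["flag"].iloc[0] == "never-consumed"
    assert np.isnan(comp["value"].iloc[0])
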