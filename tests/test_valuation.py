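import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from pollivalue import (
    align_panels,
    corrected_price,
    index_to_base,
    pollination_benefit,
    price_signal,
    scenario_bounds,
    staple_baseline,
    weighted_quantity,
)
from pollivalue.valuation import ValuationSeries

from conftest import brute_force_benefit, random_panel


def _aligned_single_country():
    """One country, two crops, one year: hand-checkable numbers."""
    production = pd.DataFrame(
        {"country_id": ["A", "A"], "crop_id": ["c1", "c2"], "year": [2000, 2000], "quantity": [50.0, 10.0]}
    )
    prices = production.assign(price_nominal=[200.0, 100.0]).drop(columns="quantity")
    corrections = pd.DataFrame(
        {"country_id": ["A"], "year": [2000], "inflation_factor": [1.0], "ppp_factor": [1.0]}
    )
    dependency = pd.DataFrame(
        {
            "crop_id": ["c1", "c2"],
            "dr_lower": [0.65, 0.05],
            "dr_median": [0.65, 0.05],
            "dr_upper": [0.65, 0.05],
            "is_staple": [False, False],
        }
    )
    return align_panels(production, prices, corrections, dependency)


def test_corrected_price_products():
    assert corrected_price(100, 1.2, 1.5) == pytest.approx(180)
    assert corrected_price(100, 1, 1) == 100
    assert corrected_price(0, 2.3, 0.7) == 0
    with pytest.raises(ValueError):
        corrected_price(-1, 1, 1)


def test_benefit_hand_sum():
    al = _aligned_single_country()
    v = pollination_benefit(al)
    # 200*50*0.65 + 100*10*0.05 = 6500 + 50
    assert v.values.loc[2000, "global"] == pytest.approx(6550)


def test_benefit_zero_dependency_is_zero():
    al = _aligned_single_country()
    al.table[["dr_lower", "dr_median", "dr_upper"]] = 0.0
    v = pollination_benefit(al)
    assert (v.values.to_numpy() == 0).all()


def test_benefit_matches_brute_force_triple_loop():
    production, prices, corrections, dependency = random_panel(11)
    al = align_panels(production, prices, corrections, dependency)
    v = pollination_benefit(al)
    oracle = brute_force_benefit(production, prices, corrections, dependency)
    for year, val in oracle.items():
        assert v.values.loc[year, "global"] == pytest.approx(val, rel=1e-9)


def test_benefit_errors():
    al = _aligned_single_country()
    with pytest.raises(ValueError, match="scenario"):
        pollination_benefit(al, scenario="middle")
    with pytest.raises(ValueError, match="empty"):
        pollination_benefit(al.table.iloc[:0])


def test_weighted_quantity_hand_and_limits():
    al = _aligned_single_country()
    q = weighted_quantity(al)
    assert q.values.loc[2000, "global"] == pytest.approx(50 * 0.65 + 10 * 0.05)  # 33
    al.table[["dr_lower", "dr_median", "dr_upper"]] = 1.0
    q1 = weighted_quantity(al)
    assert q1.values.loc[2000, "global"] == pytest.approx(60)  # total tonnage


def test_weighted_quantity_brute_force_and_corrections_flag():
    production, prices, corrections, dependency = random_panel(12)
    al = align_panels(production, prices, corrections, dependency)
    q = weighted_quantity(al)
    t = al.complete
    expected = (t["quantity"] * t["dr_median"]).groupby(t["year"]).sum()
    np.testing.assert_allclose(q.values["global"].to_numpy(), expected.to_numpy(), rtol=1e-9)
    qc = weighted_quantity(al, monetary_corrections_on_quantity=True)
    exp_c = (t["quantity"] * t["dr_median"] * t["inflation_factor"] * t["ppp_factor"]).groupby(t["year"]).sum()
    np.testing.assert_allclose(qc.values["global"].to_numpy(), exp_c.to_numpy(), rtol=1e-9)


def test_price_signal_division_and_identity():
    al = _aligned_single_country()
    v, q = pollination_benefit(al), weighted_quantity(al)
    p = price_signal(v, q)
    assert p.values.loc[2000, "global"] == pytest.approx(6550 / 33)
    np.testing.assert_allclose((p.values * q.values).to_numpy(), v.values.to_numpy(), rtol=1e-12)


def test_price_signal_uniform_price_limit():
    production, prices, corrections, dependency = random_panel(13)
    prices["price_nominal"] = 180.0
    corrections[["inflation_factor", "ppp_factor"]] = 1.0
    al = align_panels(production, prices, corrections, dependency)
    p = price_signal(pollination_benefit(al), weighted_quantity(al))
    np.testing.assert_allclose(p.values.to_numpy(), 180.0, rtol=1e-12)


def test_price_signal_zero_quantity_flagged_not_dropped():
    years = [2000, 2001]
    vals = pd.DataFrame({"global": [10.0, 5.0]}, index=pd.Index(years, name="year"))
    qvals = pd.DataFrame({"global": [2.0, 0.0]}, index=pd.Index(years, name="year"))
    v = ValuationSeries("benefit", "median", "global", vals)
    q = ValuationSeries("weighted_quantity", "median", "global", qvals)
    p = price_signal(v, q)
    assert p.values.loc[2000, "global"] == 5.0
    assert np.isnan(p.values.loc[2001, "global"])
    assert bool(p.undefined.loc[2001, "global"])
    assert 2001 in p.values.index  # reported, not dropped


def test_staple_baseline_hand_values(small_aligned):
    production = pd.DataFrame(
        {"country_id": ["A"], "crop_id": ["maize"], "year": [2000], "quantity": [20.0]}
    )
    prices = production.assign(price_nominal=150.0).drop(columns="quantity")
    corrections = pd.DataFrame(
        {"country_id": ["A"], "year": [2000], "inflation_factor": [1.0], "ppp_factor": [1.0]}
    )
    dependency = pd.DataFrame(
        {"crop_id": ["maize"], "dr_lower": [0.0], "dr_median": [0.0], "dr_upper": [0.0], "is_staple": [True]}
    )
    al = align_panels(production, prices, corrections, dependency)
    qty, val, price = staple_baseline(al)
    assert val.values.loc[2000, "global"] == pytest.approx(3000)
    assert price.values.loc[2000, "global"] == pytest.approx(150)
    assert qty.values.loc[2000, "global"] == pytest.approx(20)


def test_staple_baseline_equals_benefit_with_unit_dependency(small_aligned):
    staples = set(small_aligned.table.loc[small_aligned.table["is_staple"].astype(bool), "crop_id"])
    qty, val, price = staple_baseline(small_aligned)
    forced = small_aligned.complete.copy()
    forced = forced[forced["crop_id"].isin(staples)]
    forced[["dr_lower", "dr_median", "dr_upper"]] = 1.0
    v1 = pollination_benefit(forced.assign(complete=True))
    np.testing.assert_allclose(val.values.to_numpy(), v1.values.to_numpy(), rtol=1e-9)


def test_staple_baseline_requires_staple_rows():
    al = _aligned_single_country()
    with pytest.raises(ValueError, match="staple"):
        staple_baseline(al)


def test_index_to_base_normalization_and_idempotence():
    vals = pd.DataFrame({"global": [2.0, 4.0, 6.0]}, index=pd.Index([1993, 1994, 1995], name="year"))
    s = ValuationSeries("benefit", "median", "global", vals)
    idx = index_to_base(s)
    np.testing.assert_allclose(idx.values["global"].to_numpy(), [1, 2, 3])
    assert idx.values.loc[1993, "global"] == 1.0
    twice = index_to_base(idx)
    pd.testing.assert_frame_equal(twice.values, idx.values)


def test_index_to_base_errors():
    vals = pd.DataFrame({"global": [0.0, 4.0]}, index=pd.Index([1993, 1994], name="year"))
    s = ValuationSeries("benefit", "median", "global", vals)
    with pytest.raises(ValueError, match="zero or undefined"):
        index_to_base(s)
    with pytest.raises(ValueError, match="not present"):
        index_to_base(s, base_year=1890)


def test_scenario_bounds_ordering_and_collapse():
    production, prices, corrections, dependency = random_panel(14)
    al = align_panels(production, prices, corrections, dependency)
    b = scenario_bounds(al, grouping="country")
    assert (b["lower"].values.to_numpy() <= b["median"].values.to_numpy() + 1e-12).all()
    assert (b["median"].values.to_numpy() <= b["upper"].values.to_numpy() + 1e-12).all()
    collapsed = dependency.assign(dr_lower=dependency["dr_median"], dr_upper=dependency["dr_median"])
    al2 = align_panels(production, prices, corrections, collapsed)
    b2 = scenario_bounds(al2)
    pd.testing.assert_frame_equal(b2["lower"].values, b2["upper"].values)
    zeroed = dependency.assign(dr_lower=0.0)
    al3 = align_panels(production, prices, corrections, zeroed)
    assert (scenario_bounds(al3)["lower"].values.to_numpy() == 0).all()


@pytest.mark.parametrize("grouping", ["global", "country", "crop"])
@pytest.mark.parametrize("scenario", ["lower", "median", "upper"])
def test_decomposition_identity_everywhere(small_aligned, grouping, scenario):
    v = pollination_benefit(small_aligned, scenario=scenario, grouping=grouping)
    q = weighted_quantity(small_aligned, scenario=scenario, grouping=grouping)
    p = price_signal(v, q)
    defined = ~p.undefined.to_numpy()
    recon = (p.values * q.values).to_numpy()
    np.testing.assert_allclose(recon[defined], v.values.to_numpy()[defined], rtol=1e-9)
    # where the signal is undefined the quantity (hence the benefit) is zero
    assert (v.values.to_numpy()[~defined] == 0).all()


def test_linearity_over_disjoint_country_sets(small_aligned):
    countries = sorted(small_aligned.table["country_id"].unique())
    half = len(countries) // 2
    t = small_aligned.table
    va = pollination_benefit(t[t["country_id"].isin(countries[:half])])
    vb = pollination_benefit(t[t["country_id"].isin(countries[half:])])
    vall = pollination_benefit(t)
    np.testing.assert_allclose(
        (va.values + vb.values).to_numpy(), vall.values.to_numpy(), rtol=1e-12
    )


def test_disabling_ppp_equals_unit_ppp_factors(small_aligned):
    v_off = pollination_benefit(small_aligned, ppp_enabled=False)
    forced = small_aligned.table.copy()
    forced["ppp_factor"] = 1.0
    v_unit = pollination_benefit(forced)
    np.testing.assert_allclose(v_off.values.to_numpy(), v_unit.values.to_numpy(), rtol=0, atol=0)


def test_row_permutation_leaves_sums_stable(small_aligned):
    v0 = pollination_benefit(small_aligned)
    shuffled = small_aligned.table.sample(frac=1.0, random_state=5)
    v1 = pollination_benefit(shuffled)
    np.testing.assert_allclose(v0.values.to_numpy(), v1.values.to_numpy(), rtol=1e-9)


@settings(deadline=None, max_examples=25, derandomize=True)
@given(
    bump=st.floats(min_value=0.0, max_value=0.3, allow_nan=False),
    crop_i=st.integers(min_value=0, max_value=7),
)
def test_increasing_dependency_weakly_increases_value_and_quantity(bump, crop_i):
    production, prices, corrections, dependency = random_panel(21)
    al = align_panels(production, prices, corrections, dependency)
    v0, q0 = pollination_benefit(al), weighted_quantity(al)
    bumped = al.table.copy()
    crop = sorted(dependency["crop_id"])[crop_i]
    sel = bumped["crop_id"] == crop
    bumped.loc[sel, "dr_median"] = np.minimum(bumped.loc[sel, "dr_median"] + bump, 1.0)
    v1, q1 = pollination_benefit(bumped), weighted_quantity(bumped)
    assert (v1.values.to_numpy() >= v0.values.to_numpy() - 1e-12).all()
    assert (q1.values.to_numpy() >= q0.values.to_numpy() - 1e-12).all()
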