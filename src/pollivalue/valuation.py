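"""Monetary valuation of the pollination-attributable share of crop production.

For crops *i*, countries *j* and years *t* the pollination benefit is

    V_t = sum_ij  pp_ijt * pq_ijt * dr_i * inf_jt * ppp_jt        ($, corrected)

and its physical twin, the pollination-weighted production quantity,

    Q_t = sum_ij  pq_ijt * dr_i                                    (tons)

where ``pp`` is the nominal producer price ($/ton), ``pq`` the
production quantity (tons), ``dr`` the crop's pollination dependency
ratio, and ``inf``/``ppp`` the inflation (to the reference year 2009)
and purchasing-power-parity correction factors.  The price signal
P_t = V_t / Q_t is the implicit average corrected price of
pollination-dependent output; V = P * Q holds by construction.

The same machinery with dr replaced by 1 and restricted to
pollination-independent staple crops (maize, rice, wheat, rye, yams,
sorghum, taro) gives the staple baseline used for comparison, and
base-year indexing (default 1993) makes the series' relative trends
directly comparable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from pollivalue.data_model import AlignedPanel

#: pollination-independent staple crops used for the baseline comparison
STAPLE_CROPS = ("maize", "rice", "wheat", "rye", "yams", "sorghum", "taro")

SCENARIOS = {"lower": "dr_lower", "median": "dr_median", "upper": "dr_upper"}

_GROUPINGS = {
    "global": None,
    "country": "country_id",
    "per-country": "country_id",
    "crop": "crop_id",
    "per-crop": "crop_id",
}

_KINDS = {"benefit", "weighted_quantity", "price_signal", "production_value", "production_quantity"}


@dataclass
class ValuationSeries:
    """A year-indexed valuation series for one grouping and scenario.

    ``values`` is a DataFrame indexed by year; columns are group labels
    (a single ``"global"`` column for the global grouping, country or
    crop identifiers otherwise).  ``undefined`` marks entries where the
    quantity is not defined (e.g. a zero-quantity year in a price
    signal); such entries hold NaN in ``values`` and are reported, never
    silently dropped.
    """

    kind: str
    scenario: str
    grouping: str
    values: pd.DataFrame
    undefined: pd.DataFrame | None = field(default=None, repr=False)

    def __post_init__(self):
        if self.kind not in _KINDS:
            raise ValueError(f"unknown series kind {self.kind!r}")
        mask = self.undefined.to_numpy() if self.undefined is not None else False
        vals = self.values.to_numpy(dtype=float)
        ok = np.isfinite(vals) | mask
        if not ok.all():
            raise ValueError(f"{self.kind} series contains non-finite values outside the undefined mask")
        if self.kind in {"benefit", "weighted_quantity", "production_value", "production_quantity"}:
            if (vals[np.isfinite(vals)] < 0).any():
                raise ValueError(f"{self.kind} series contains negative values")

    @property
    def years(self) -> np.ndarray:
        return self.values.index.to_numpy()

    def to_frame(self) -> pd.DataFrame:
        """Long-form (group, year, scenario, kind, value) table for CSV output."""
        long = self.values.stack().rename("value").reset_index()
        long.columns = ["year", "group", "value"]
        long["scenario"] = self.scenario
        long["kind"] = self.kind
        return long[["group", "year", "scenario", "kind", "value"]]


def corrected_price(price_nominal, inflation_factor, ppp_factor):
    """Producer price corrected to reference-year purchasing-power dollars.

    Element-wise ``price_nominal * inflation_factor * ppp_factor``;
    inputs must be non-negative.
    """
    p = np.asarray(price_nominal, dtype=float)
    f1 = np.asarray(inflation_factor, dtype=float)
    f2 = np.asarray(ppp_factor, dtype=float)
    if (p < 0).any() or (f1 < 0).any() or (f2 < 0).any():
        raise ValueError("corrected_price requires non-negative inputs")
    out = p * f1 * f2
    return float(out) if out.ndim == 0 else out


def _as_table(aligned) -> pd.DataFrame:
    if isinstance(aligned, AlignedPanel):
        return aligned.complete
    return aligned[aligned["complete"]] if "complete" in aligned.columns else aligned


def _group_col(grouping: str) -> str | None:
    if grouping not in _GROUPINGS:
        raise ValueError(f"unknown grouping {grouping!r}; expected one of {sorted(_GROUPINGS)}")
    return _GROUPINGS[grouping]


def _dr_col(scenario: str) -> str:
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}; expected one of {sorted(SCENARIOS)}")
    return SCENARIOS[scenario]


def _grouped_sum(t: pd.DataFrame, contrib: np.ndarray, grouping: str) -> pd.DataFrame:
    gcol = _group_col(grouping)
    s = pd.Series(contrib, index=t.index, name="value")
    if gcol is None:
        out = s.groupby(t["year"]).sum().to_frame(name="global")
    else:
        out = s.groupby([t["year"], t[gcol]]).sum().unstack(fill_value=0.0)
    out.index.name = "year"
    return out.sort_index()


def pollination_benefit(
    aligned,
    scenario: str = "median",
    grouping: str = "global",
    ppp_enabled: bool = True,
) -> ValuationSeries:
    """Pollination benefit V = sum pp*pq*dr*inf*ppp per group and year.

    ``ppp_enabled=False`` replaces every ppp factor by 1, reproducing the
    PPP-uncorrected variant of the valuation.
    """
    t = _as_table(aligned)
    if len(t) == 0:
        raise ValueError("empty aligned table")
    dr = t[_dr_col(scenario)].to_numpy(float)
    ppp = t["ppp_factor"].to_numpy(float) if ppp_enabled else 1.0
    contrib = (
        t["price_nominal"].to_numpy(float)
        * t["quantity"].to_numpy(float)
        * dr
        * t["inflation_factor"].to_numpy(float)
        * ppp
    )
    return ValuationSeries("benefit", scenario, grouping, _grouped_sum(t, contrib, grouping))


def weighted_quantity(
    aligned,
    scenario: str = "median",
    grouping: str = "global",
    monetary_corrections_on_quantity: bool = False,
) -> ValuationSeries:
    """Pollination-weighted production quantity Q = sum pq*dr per group and year.

    With ``monetary_corrections_on_quantity=True`` each term is further
    multiplied by inf*ppp (a documented variant; the default keeps Q in
    plain tons so that the price signal V/Q stays in $/ton).
    """
    t = _as_table(aligned)
    if len(t) == 0:
        raise ValueError("empty aligned table")
    contrib = t["quantity"].to_numpy(float) * t[_dr_col(scenario)].to_numpy(float)
    if monetary_corrections_on_quantity:
        contrib = contrib * t["inflation_factor"].to_numpy(float) * t["ppp_factor"].to_numpy(float)
    return ValuationSeries("weighted_quantity", scenario, grouping, _grouped_sum(t, contrib, grouping))


def price_signal(benefit: ValuationSeries, quantity: ValuationSeries) -> ValuationSeries:
    """Implicit average corrected price P = V / Q, per group and year.

    Years (or groups) with Q = 0 get an undefined flag and NaN value;
    they are reported in the result's ``undefined`` mask rather than
    dropped.  V = P * Q holds exactly wherever P is defined.
    """
    if benefit.grouping != quantity.grouping or benefit.scenario != quantity.scenario:
        raise ValueError("benefit and quantity series must share grouping and scenario")
    if not benefit.values.index.equals(quantity.values.index) or not benefit.values.columns.equals(
        quantity.values.columns
    ):
        raise ValueError("benefit and quantity series must share year and group coverage")
    q = quantity.values.to_numpy(float)
    v = benefit.values.to_numpy(float)
    undefined = q == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(undefined, np.nan, v / np.where(undefined, 1.0, q))
    vals = pd.DataFrame(p, index=benefit.values.index, columns=benefit.values.columns)
    und = pd.DataFrame(undefined, index=vals.index, columns=vals.columns)
    return ValuationSeries("price_signal", benefit.scenario, benefit.grouping, vals, undefined=und)


def staple_baseline(
    aligned,
    staples: set | None = None,
    grouping: str = "global",
) -> tuple[ValuationSeries, ValuationSeries, ValuationSeries]:
    """Quantity, value and price series for pollination-independent staples.

    The valuation machinery with dr replaced by 1, restricted to the
    staple crop set (rows flagged ``is_staple`` by default):
    quantity = sum pq, value = sum pp*pq*inf*ppp, price = value/quantity.

    Returns ``(production_quantity, production_value, price)`` series.
    """
    t = _as_table(aligned)
    if staples is None:
        t = t[t["is_staple"].astype(bool)]
    else:
        if not staples:
            raise ValueError("staple set must be non-empty")
        t = t[t["crop_id"].isin(staples)]
    if len(t) == 0:
        raise ValueError("no staple rows in the aligned table")
    qty = _grouped_sum(t, t["quantity"].to_numpy(float), grouping)
    val = _grouped_sum(
        t,
        t["price_nominal"].to_numpy(float)
        * t["quantity"].to_numpy(float)
        * t["inflation_factor"].to_numpy(float)
        * t["ppp_factor"].to_numpy(float),
        grouping,
    )
    q_series = ValuationSeries("production_quantity", "median", grouping, qty)
    v_series = ValuationSeries("production_value", "median", grouping, val)
    q = qty.to_numpy(float)
    undefined = q == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(undefined, np.nan, val.to_numpy(float) / np.where(undefined, 1.0, q))
    p_series = ValuationSeries(
        "price_signal",
        "median",
        grouping,
        pd.DataFrame(p, index=qty.index, columns=qty.columns),
        undefined=pd.DataFrame(undefined, index=qty.index, columns=qty.columns),
    )
    return q_series, v_series, p_series


def index_to_base(series: ValuationSeries, base_year: int = 1993) -> ValuationSeries:
    """Scale every column so its value in ``base_year`` is exactly 1.

    Idempotent; raises if the base year is absent or any group's base
    value is zero or undefined.
    """
    if base_year not in series.values.index:
        raise ValueError(f"base year {base_year} not present in series")
    base = series.values.loc[base_year]
    if (base == 0).any() or base.isna().any():
        bad = base.index[(base == 0) | base.isna()].tolist()
        raise ValueError(f"base-year value zero or undefined for group(s) {bad}")
    vals = series.values.div(base, axis=1)
    return ValuationSeries(series.kind, series.scenario, series.grouping, vals, undefined=series.undefined)


def scenario_bounds(aligned, grouping: str = "global", ppp_enabled: bool = True) -> dict[str, ValuationSeries]:
    """Benefit series under the lower, median and upper dependency bounds.

    Because dr_lower <= dr_median <= dr_upper crop-wise, the returned
    series satisfy lower <= median <= upper at every group and year.
    """
    return {
        s: pollination_benefit(aligned, scenario=s, grouping=grouping, ppp_enabled=ppp_enabled)
        for s in ("lower", "median", "upper")
    }
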