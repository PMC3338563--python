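"""National vulnerability to pollinator decline, trends and trend comparisons.

Two indicators quantify how exposed an economy is to a loss of
pollination services:

* ``gdp_dependency`` — pollination benefit as a share of a country's GDP;
* ``ag_gdp_dependency`` — benefit as a share of the agricultural GDP
  (GDP times the agricultural share).

Ratios above 1 are possible when the underlying agricultural and
macroeconomic statistics disagree; they are flagged as
data-inconsistency signals rather than rejected.  Per-country linear
trends over the analysis window (ordinary least squares of value on
calendar year), Pearson correlations between trend vectors (e.g.
benefit trends vs. beehive-count trends), relative changes between two
anchor years and a change-on-change regression complete the toolkit.
Outlier handling is always an explicit exclusion list, never automatic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm


@dataclass
class FlaggedRatio:
    """A dependency ratio with its data-quality flags."""

    value: float
    inconsistent: bool = False  # ratio > 1: benefit exceeds the (ag-)GDP it is part of
    undefined: bool = False  # zero denominator


@dataclass
class TrendRecord:
    """OLS slope/intercept of a series on calendar year."""

    slope: float
    intercept: float
    n_years: int


@dataclass
class TrendCorrelation:
    r: float
    n: int
    excluded: tuple
    undefined: bool = False


@dataclass
class FlaggedChange:
    """Relative change value(y1)/value(y0) - 1; undefined when value(y0) = 0."""

    value: float
    undefined: bool = False


@dataclass
class ChangeRegression:
    """OLS fit of benefit changes on production changes across countries."""

    r_squared: float
    r_squared_excluded: float
    n: int
    n_excluded: int
    table: pd.DataFrame


def gdp_dependency(benefit: float, gdp: float) -> FlaggedRatio:
    """Share of GDP attributable to pollination: benefit / gdp.

    A ratio above 1 sets ``inconsistent`` (the benefit cannot really
    exceed the GDP it is part of; such values indicate incompatibilities
    between the agricultural and macroeconomic sources).  A zero GDP
    yields an undefined-flagged record.
    """
    if gdp == 0:
        return FlaggedRatio(np.nan, undefined=True)
    r = benefit / gdp
    return FlaggedRatio(r, inconsistent=r > 1)


def ag_gdp_dependency(benefit: float, gdp: float, ag_share: float) -> FlaggedRatio:
    """Share of agricultural GDP attributable to pollination: benefit / (gdp * ag_share)."""
    denom = gdp * ag_share
    if denom == 0:
        return FlaggedRatio(np.nan, undefined=True)
    r = benefit / denom
    return FlaggedRatio(r, inconsistent=r > 1)


def vulnerability_table(benefit_by_country: pd.DataFrame, macro: pd.DataFrame) -> pd.DataFrame:
    """Both indicators for every country-year.

    Parameters
    ----------
    benefit_by_country
        Year-indexed DataFrame of per-country benefits (the ``values``
        of a per-country benefit series).
    macro
        Validated macro panel with country_id, year, gdp, ag_share.

    Returns
    -------
    DataFrame with country_id, year, gdp_dependency, ag_gdp_dependency,
    inconsistent and undefined flags.
    """
    long = benefit_by_country.stack().rename("benefit").reset_index()
    long.columns = ["year", "country_id", "benefit"]
    t = long.merge(macro[["country_id", "year", "gdp", "ag_share"]], on=["country_id", "year"], how="inner")
    gdp = t["gdp"].to_numpy(float)
    ag = gdp * t["ag_share"].to_numpy(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        t["gdp_dependency"] = np.where(gdp == 0, np.nan, t["benefit"] / np.where(gdp == 0, 1, gdp))
        t["ag_gdp_dependency"] = np.where(ag == 0, np.nan, t["benefit"] / np.where(ag == 0, 1, ag))
    t["undefined"] = (gdp == 0) | (ag == 0)
    t["inconsistent"] = (t["gdp_dependency"] > 1) | (t["ag_gdp_dependency"] > 1)
    return t[["country_id", "year", "gdp_dependency", "ag_gdp_dependency", "inconsistent", "undefined"]]


def global_dependency(benefit_by_country: pd.DataFrame, macro: pd.DataFrame) -> pd.DataFrame:
    """Global indicators per year as ratio of sums.

    Sum of national benefits divided by the sum of (ag-)GDP over the
    countries contributing a benefit that year — a ratio of sums, not a
    mean of national ratios, so large economies carry their economic
    weight.
    """
    long = benefit_by_country.stack().rename("benefit").reset_index()
    long.columns = ["year", "country_id", "benefit"]
    t = long.merge(macro[["country_id", "year", "gdp", "ag_share"]], on=["country_id", "year"], how="inner")
    t["ag_gdp"] = t["gdp"] * t["ag_share"]
    g = t.groupby("year")[["benefit", "gdp", "ag_gdp"]].sum()
    out = pd.DataFrame(index=g.index)
    out["gdp_dependency"] = g["benefit"] / g["gdp"]
    out["ag_gdp_dependency"] = g["benefit"] / g["ag_gdp"]
    return out


def linear_trend(series) -> TrendRecord:
    """OLS slope and intercept of value on calendar year.

    ``series`` is a mapping year -> value or a pandas Series indexed by
    year; NaN values are dropped.  Requires at least two distinct years.
    """
    s = pd.Series(dict(series)) if not isinstance(series, pd.Series) else series.dropna()
    s = s.dropna()
    years = s.index.to_numpy(float)
    if len(s) < 2:
        raise ValueError("linear_trend requires at least 2 observations")
    if np.ptp(years) == 0:
        raise ValueError("linear_trend requires at least 2 distinct years")
    fit = stats.linregress(years, s.to_numpy(float))
    return TrendRecord(slope=float(fit.slope), intercept=float(fit.intercept), n_years=len(s))


def linear_trends(values: pd.DataFrame) -> pd.DataFrame:
    """Per-column (per-country) linear trends of a year-indexed DataFrame.

    Columns observed for only part of the window get trends over their
    available years, with n_years reported.
    """
    rows = {}
    for col in values.columns:
        s = values[col].dropna()
        if len(s) >= 2 and np.ptp(s.index.to_numpy(float)) > 0:
            t = linear_trend(s)
            rows[col] = (t.slope, t.intercept, t.n_years)
    out = pd.DataFrame.from_dict(rows, orient="index", columns=["slope", "intercept", "n_years"])
    out.index.name = "country_id"
    return out


def trend_correlation(trends_a, trends_b, exclude=()) -> TrendCorrelation:
    """Pearson correlation between two country -> slope vectors.

    Computed over the intersection of countries after removing the
    explicit ``exclude`` list; reports n and the applied exclusions.
    Zero variance in either vector yields an undefined-flagged result.
    """
    a = pd.Series(dict(trends_a)) if not isinstance(trends_a, pd.Series) else trends_a
    b = pd.Series(dict(trends_b)) if not isinstance(trends_b, pd.Series) else trends_b
    common = a.index.intersection(b.index).difference(pd.Index(list(exclude)))
    a, b = a[common].astype(float), b[common].astype(float)
    mask = a.notna() & b.notna()
    a, b = a[mask], b[mask]
    if len(a) < 3:
        raise ValueError(f"trend_correlation requires >= 3 common countries, got {len(a)}")
    if np.std(a.to_numpy()) == 0 or np.std(b.to_numpy()) == 0:
        return TrendCorrelation(np.nan, len(a), tuple(exclude), undefined=True)
    r = stats.pearsonr(a.to_numpy(), b.to_numpy()).statistic
    return TrendCorrelation(float(r), len(a), tuple(exclude))


def relative_change(series, y0: int = 1993, y1: int = 2009) -> FlaggedChange:
    """Relative change value(y1)/value(y0) - 1 between two anchor years.

    A value of 1 means the series doubled.  A zero base-year value makes
    the change undefined (flagged, to be excluded from comparisons
    rather than plotted as infinite).
    """
    s = pd.Series(dict(series)) if not isinstance(series, pd.Series) else series
    if y0 not in s.index or y1 not in s.index:
        raise ValueError(f"years {y0} and {y1} must both be present")
    v0, v1 = float(s[y0]), float(s[y1])
    if v0 == 0:
        return FlaggedChange(np.nan, undefined=True)
    return FlaggedChange(v1 / v0 - 1.0)


def change_regression(x, y, weights=None, exclude=()) -> ChangeRegression:
    """OLS R-squared of benefit changes on agricultural-production changes.

    ``x`` and ``y`` map country -> relative change; ``weights`` (e.g.
    agricultural economy size) ride along into the plot-ready table but
    do not enter the fit.  ``exclude`` names countries dropped in the
    second fit (``r_squared_excluded``); both fits are reported.
    """
    xs = pd.Series(dict(x)) if not isinstance(x, pd.Series) else x
    ys = pd.Series(dict(y)) if not isinstance(y, pd.Series) else y
    common = xs.index.intersection(ys.index)
    table = pd.DataFrame(
        {
            "change_x": xs[common].astype(float),
            "change_y": ys[common].astype(float),
            "weight": (pd.Series(dict(weights)) if weights is not None else pd.Series(1.0, index=common))[
                common
            ].astype(float),
        }
    ).dropna(subset=["change_x", "change_y"])
    table.index.name = "country_id"
    if len(table) < 3:
        raise ValueError("change_regression requires >= 3 countries")

    def _r2(tab):
        X = sm.add_constant(tab["change_x"].to_numpy())
        return float(sm.OLS(tab["change_y"].to_numpy(), X).fit().rsquared)

    r2_all = _r2(table)
    kept = table.drop(index=[c for c in exclude if c in table.index])
    r2_ex = _r2(kept) if len(kept) >= 3 else np.nan
    return ChangeRegression(
        r_squared=r2_all,
        r_squared_excluded=r2_ex,
        n=len(table),
        n_excluded=len(table) - len(kept),
        table=table,
    )
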