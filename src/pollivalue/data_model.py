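"""Tabular domain model: CSV schemas, validation and panel alignment.

Five CSV panels drive the valuation pipeline:

========== =============================================================
schema     columns
========== =============================================================
production country_id, crop_id, year, quantity            (tons)
price      country_id, crop_id, year, price_nominal       ($/ton)
corrections country_id, year, inflation_factor, ppp_factor
macro      country_id, year, gdp, ag_share[, beehives]
dependency crop_id, dr_lower, dr_median, dr_upper, is_staple
========== =============================================================

All files are UTF-8 CSV with a header row.  Extra columns are ignored
with a warning; key uniqueness and range invariants are enforced on
read.  ``align_panels`` inner-joins production with prices, correction
factors and dependency ratios into the analysis table consumed by the
valuation stage, flagging and counting rows that lack a price or a
correction factor (FAO-style gaps).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


class SchemaError(ValueError):
    """A required column is missing or the schema name is unknown."""


class ValidationError(ValueError):
    """A table violates a documented invariant (duplicate keys, bad ranges)."""


#: schema name -> (key columns, numeric columns, optional columns)
SCHEMAS: dict[str, dict] = {
    "production": {
        "keys": ["country_id", "crop_id", "year"],
        "numeric": ["year", "quantity"],
        "optional": [],
    },
    "price": {
        "keys": ["country_id", "crop_id", "year"],
        "numeric": ["year", "price_nominal"],
        "optional": [],
    },
    "corrections": {
        "keys": ["country_id", "year"],
        "numeric": ["year", "inflation_factor", "ppp_factor"],
        "optional": [],
    },
    "macro": {
        "keys": ["country_id", "year"],
        "numeric": ["year", "gdp", "ag_share"],
        "optional": ["beehives"],
    },
    "dependency": {
        "keys": ["crop_id"],
        "numeric": ["dr_lower", "dr_median", "dr_upper"],
        "optional": [],
    },
}

_NONNEG = {
    "quantity",
    "price_nominal",
    "gdp",
    "beehives",
    "dr_lower",
    "dr_median",
    "dr_upper",
}
_POSITIVE = {"inflation_factor", "ppp_factor"}
_UNIT_INTERVAL = {"ag_share", "dr_lower", "dr_median", "dr_upper"}


def _required_columns(schema: str) -> list[str]:
    spec = SCHEMAS[schema]
    cols = list(dict.fromkeys(spec["keys"] + spec["numeric"]))
    if schema == "dependency":
        cols.append("is_staple")
    return cols


def validate_panel(df: pd.DataFrame, schema: str) -> pd.DataFrame:
    """Check a table against its schema invariants; return the clean table.

    Raises
    ------
    SchemaError
        If ``schema`` is unknown or a required column is absent.
    ValidationError
        On duplicate keys, out-of-range or non-finite values, or a
        dependency table with ``dr_lower > dr_upper`` (or any violation
        of the lower <= median <= upper ordering), or a staple crop with
        nonzero median dependency.
    """
    if schema not in SCHEMAS:
        raise SchemaError(f"unknown schema {schema!r}; expected one of {sorted(SCHEMAS)}")
    spec = SCHEMAS[schema]
    required = _required_columns(schema)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{schema} table missing required column(s): {missing}")

    known = set(required) | set(spec["optional"])
    extra = [c for c in df.columns if c not in known]
    if extra:
        warnings.warn(f"{schema} table: ignoring extra column(s) {extra}", stacklevel=2)
        df = df.drop(columns=extra)

    df = df.copy()
    numeric = spec["numeric"] + [c for c in spec["optional"] if c in df.columns]
    for col in numeric:
        df[col] = pd.to_numeric(df[col], errors="coerce")

    # reject rows whose numerics failed to parse, with row-numbered diagnostics
    core_numeric = [c for c in spec["numeric"]]
    bad = df[core_numeric].isna().any(axis=1)
    if bad.any():
        rows = (np.flatnonzero(bad.to_numpy()) + 2).tolist()  # 1-based incl. header
        warnings.warn(
            f"{schema} table: rejected {int(bad.sum())} row(s) with unparseable "
            f"numerics at file line(s) {rows[:20]}",
            stacklevel=2,
        )
        df = df[~bad]

    keys = spec["keys"]
    dup = df.duplicated(subset=keys, keep=False)
    if dup.any():
        offenders = df.loc[dup, keys].drop_duplicates().to_records(index=False).tolist()
        raise ValidationError(f"{schema} table: duplicate key(s) {offenders[:10]}")

    for col in numeric:
        vals = df[col].to_numpy(dtype=float)
        finite = np.isfinite(vals) | np.isnan(vals)
        if not finite.all():
            raise ValidationError(f"{schema} table: non-finite values in {col!r}")
        checkable = vals[~np.isnan(vals)]
        if col in _NONNEG and (checkable < 0).any():
            raise ValidationError(f"{schema} table: negative values in {col!r}")
        if col in _POSITIVE and (checkable <= 0).any():
            raise ValidationError(f"{schema} table: non-positive values in {col!r}")
        if col in _UNIT_INTERVAL and ((checkable < 0) | (checkable > 1)).any():
            raise ValidationError(f"{schema} table: values outside [0, 1] in {col!r}")

    if schema == "dependency":
        df["is_staple"] = df["is_staple"].map(_parse_bool)
        lo, md, up = (df[c].to_numpy(dtype=float) for c in ("dr_lower", "dr_median", "dr_upper"))
        bad_order = (lo > md) | (md > up)
        if bad_order.any():
            crops = df.loc[bad_order, "crop_id"].tolist()
            raise ValidationError(
                f"dependency table: dr_lower <= dr_median <= dr_upper violated for {crops}"
            )
        staple_dep = df["is_staple"].to_numpy(bool) & (md != 0)
        if staple_dep.any():
            crops = df.loc[staple_dep, "crop_id"].tolist()
            raise ValidationError(
                f"dependency table: staple crop(s) with nonzero median dependency: {crops}"
            )

    if schema == "corrections":
        # reference-country / reference-year conventions: warn, don't fail,
        # so that country subsets without the reference country still load
        by_country = df.groupby("country_id")["ppp_factor"]
        if not (by_country.apply(lambda s: np.allclose(s, 1.0))).any():
            warnings.warn(
                "corrections table: no country has ppp_factor == 1 in all years "
                "(reference-country convention)",
                stacklevel=2,
            )
        by_year = df.groupby("year")["inflation_factor"]
        if not (by_year.apply(lambda s: np.allclose(s, 1.0))).any():
            warnings.warn(
                "corrections table: no year has inflation_factor == 1 for all countries "
                "(reference-year convention)",
                stacklevel=2,
            )

    if "year" in df.columns:
        df["year"] = df["year"].astype(int)
    return df.reset_index(drop=True)


def _parse_bool(x) -> bool:
    if isinstance(x, (bool, np.bool_)):
        return bool(x)
    if isinstance(x, (int, np.integer, float)):
        return bool(int(x))
    s = str(x).strip().lower()
    if s in {"true", "t", "1", "yes"}:
        return True
    if s in {"false", "f", "0", "no"}:
        return False
    raise ValidationError(f"cannot parse boolean value {x!r} in is_staple")


def read_panel(path, schema: str) -> pd.DataFrame:
    """Read and validate one of the five CSV panels."""
    if schema not in SCHEMAS:
        raise SchemaError(f"unknown schema {schema!r}; expected one of {sorted(SCHEMAS)}")
    df = pd.read_csv(path)
    return validate_panel(df, schema)


def write_panel(df: pd.DataFrame, path, schema: str) -> None:
    """Validate and write a panel; ``read_panel`` round-trips it value-identically."""
    df = validate_panel(df, schema)
    df.to_csv(path, index=False)


@dataclass
class AlignedPanel:
    """Production joined with prices, corrections and dependency ratios.

    ``table`` has one row per (country, crop, year) present in the
    production panel.  Rows lacking a price or a correction factor are
    kept with ``complete == False`` and excluded from all valuation
    sums; ``n_excluded`` counts them and ``coverage`` is the complete
    fraction.
    """

    table: pd.DataFrame
    n_excluded: int
    coverage: float
    excluded_keys: pd.DataFrame = field(repr=False, default=None)

    @property
    def complete(self) -> pd.DataFrame:
        """Rows usable in valuation sums."""
        return self.table[self.table["complete"]]


def align_panels(
    production: pd.DataFrame,
    prices: pd.DataFrame,
    corrections: pd.DataFrame,
    dependency: pd.DataFrame,
    impute: str = "none",
) -> AlignedPanel:
    """Join the four panels into the analysis table.

    Parameters
    ----------
    impute
        ``"none"`` (default) leaves gaps excluded; ``"country-mean"``
        fills a missing producer price with that country x crop's mean
        price over the years where it is observed.

    Raises
    ------
    ValidationError
        If production shares no year with the price or correction panels.
    """
    if impute not in {"none", "country-mean"}:
        raise ValueError(f"impute must be 'none' or 'country-mean', got {impute!r}")
    production = validate_panel(production, "production")
    prices = validate_panel(prices, "price")
    corrections = validate_panel(corrections, "corrections")
    dependency = validate_panel(dependency, "dependency")

    prod_years = set(production["year"])
    if not (prod_years & set(prices["year"])) or not (prod_years & set(corrections["year"])):
        raise ValidationError("empty intersection of years between production and price/correction panels")

    t = production.merge(prices, on=["country_id", "crop_id", "year"], how="left")
    t = t.merge(corrections, on=["country_id", "year"], how="left")
    t = t.merge(dependency, on="crop_id", how="left")
    missing_dep = t["dr_median"].isna()
    if missing_dep.any():
        crops = sorted(t.loc[missing_dep, "crop_id"].unique())
        raise ValidationError(f"crops present in production but absent from dependency table: {crops}")

    if impute == "country-mean":
        means = t.groupby(["country_id", "crop_id"])["price_nominal"].transform("mean")
        t["price_nominal"] = t["price_nominal"].fillna(means)

    t["complete"] = t[["price_nominal", "inflation_factor", "ppp_factor"]].notna().all(axis=1)
    n_excluded = int((~t["complete"]).sum())
    coverage = 1.0 - n_excluded / len(t) if len(t) else 1.0
    excluded = t.loc[~t["complete"], ["country_id", "crop_id", "year"]].reset_index(drop=True)
    return AlignedPanel(table=t, n_excluded=n_excluded, coverage=coverage, excluded_keys=excluded)
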