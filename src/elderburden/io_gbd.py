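"""Reading, writing and summarising GBD-results-dialect burden panels.

The central container is :class:`BurdenPanel`, a validated long-format table
of annual burden observations for the population aged 70 years and over,
keyed by (measure, location, sex, age band, year).  Each observation carries
a rate per 100,000 person-years and/or an absolute count, both with 95%
uncertainty bounds when available.

The CSV dialect is the one emitted by the IHME GBD Results tool: one row per
(stratum, year, metric) with columns ``measure_name, location_name,
sex_name, age_name, cause_name, rei_name, metric_name, year, val, upper,
lower`` and ``metric_name`` in {"Rate", "Number"}.  Rate and Number rows for
the same stratum-year are merged into a single observation on read.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import (
    AggregationError,
    CompletenessError,
    ConfigurationError,
    DomainError,
    FormatError,
    IntegrityError,
    JoinError,
    ParseError,
)

#: Persons per rate unit: all rates in this package are per 100,000.
RATE_SCALE = 100_000.0

#: The six accepted 5-year age bands, in order, plus the 70+ aggregate label.
AGE_BANDS: tuple[str, ...] = ("70-74", "75-79", "80-84", "85-89", "90-94", "95+")
AGGREGATE_BAND = "70+"

SEXES: tuple[str, ...] = ("Male", "Female", "Both")
MEASURES: tuple[str, ...] = ("Deaths", "DALYs")

#: Location labels recognised as SDI quintile groupings.
SDI_LABELS: dict[str, str] = {
    "Low SDI": "low",
    "Low-middle SDI": "low-middle",
    "Middle SDI": "middle",
    "High-middle SDI": "high-middle",
    "High SDI": "high",
}

KEY_COLUMNS = ["measure", "location", "sex", "age_band"]
GBD_COLUMNS = [
    "measure_name",
    "location_name",
    "sex_name",
    "age_name",
    "cause_name",
    "rei_name",
    "metric_name",
    "year",
    "val",
    "upper",
    "lower",
]

_MEASURE_ALIASES = {
    "Deaths": "Deaths",
    "DALYs": "DALYs",
    "DALYs (Disability-Adjusted Life Years)": "DALYs",
}


def _age_name_to_band(name: str) -> str:
    """Map a GBD ``age_name`` string ("70-74 years") to an internal band."""
    s = name.strip()
    if s.endswith("years"):
        s = s[: -len("years")].strip()
    if s in ("70+", "70 plus", "70plus-aggregate", "All ages 70+"):
        return AGGREGATE_BAND
    return s


def sdi_group_for_location(location: str) -> str:
    """SDI quintile label for a location, or ``"none"`` for countries/Global."""
    return SDI_LABELS.get(location, "none")


@dataclass
class BurdenPanel:
    """Long-format annual burden observations with uncertainty bounds.

    ``data`` columns: measure, location, sdi_group, sex, age_band, year,
    rate, rate_lower, rate_upper, count, count_lower, count_upper.
    Missing metrics are NaN.
    """

    data: pd.DataFrame
    source: str = "unspecified"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = self.data.reset_index(drop=True)
        if "sdi_group" not in self.data.columns:
            self.data["sdi_group"] = self.data["location"].map(sdi_group_for_location)
        self.validate()

    # -- validation ---------------------------------------------------------

    def validate(self) -> None:
        df = self.data
        required = KEY_COLUMNS + ["year", "rate", "count"]
        for col in required:
            if col not in df.columns:
                raise FormatError(f"panel is missing required column {col!r}")
        dup = df.duplicated(subset=KEY_COLUMNS + ["year"])
        if dup.any():
            keys = df.loc[dup, KEY_COLUMNS + ["year"]].iloc[0].tolist()
            raise IntegrityError(f"duplicate observation for key {keys}")
        for stratum, grp in df.groupby(KEY_COLUMNS, observed=True, sort=False):
            years = np.sort(grp["year"].to_numpy())
            if len(years) > 1 and not np.array_equal(
                years, np.arange(years[0], years[-1] + 1)
            ):
                raise IntegrityError(f"year sequence has gaps for stratum {stratum}")
        for val, lo, hi in (("rate", "rate_lower", "rate_upper"),
                            ("count", "count_lower", "count_upper")):
            if lo in df.columns and hi in df.columns:
                have = df[[val, lo, hi]].notna().all(axis=1)
                bad = have & ~((df[lo] <= df[val] + 1e-9) & (df[val] <= df[hi] + 1e-9))
                if bad.any():
                    raise IntegrityError(
                        f"{val} bounds do not bracket the point value in "
                        f"{int(bad.sum())} rows"
                    )

    # -- access helpers -----------------------------------------------------

    def strata(self) -> pd.DataFrame:
        """Distinct (measure, location, sex, age_band) keys."""
        return self.data[KEY_COLUMNS].drop_duplicates().reset_index(drop=True)

    def get_series(
        self,
        measure: str,
        location: str,
        sex: str,
        age_band: str,
        years: tuple[int, int] | None = None,
    ) -> pd.DataFrame:
        """One stratum's annual series, sorted by year."""
        df = self.data
        m = (
            (df["measure"] == measure)
            & (df["location"] == location)
            & (df["sex"] == sex)
            & (df["age_band"] == age_band)
        )
        out = df.loc[m].sort_values("year").reset_index(drop=True)
        if years is not None:
            out = out[(out["year"] >= years[0]) & (out["year"] <= years[1])]
            out = out.reset_index(drop=True)
        return out

    def years(self) -> tuple[int, int]:
        return int(self.data["year"].min()), int(self.data["year"].max())


# ---------------------------------------------------------------------------
# CSV ingestion
# ---------------------------------------------------------------------------

def read_gbd_csv(path, strict: bool = True, source: str | None = None) -> BurdenPanel:
    """Read a GBD Results tool CSV extract into a :class:`BurdenPanel`.

    Parameters
    ----------
    path : str or path-like
        CSV file in the GBD results dialect.
    strict : bool
        If True (default), an age band outside the six 70+ bands (or the
        70+ aggregate) is an error; if False such rows are dropped with a
        warning.
    """
    raw = pd.read_csv(path, dtype=str)
    for col in GBD_COLUMNS:
        if col not in raw.columns:
            raise FormatError(f"missing mandatory column {col!r} in {path}")

    for col in ("val", "upper", "lower"):
        parsed = pd.to_numeric(raw[col], errors="coerce")
        bad = parsed.isna() & raw[col].notna()
        if bad.any():
            idx = int(np.flatnonzero(bad.to_numpy())[0])
            raise ParseError(f"non-numeric {col!r} at data row {idx}: {raw[col].iloc[idx]!r}")
        raw[col] = parsed
    raw["year"] = pd.to_numeric(raw["year"], errors="coerce")
    if raw["year"].isna().any():
        idx = int(np.flatnonzero(raw["year"].isna().to_numpy())[0])
        raise ParseError(f"non-numeric year at data row {idx}")
    raw["year"] = raw["year"].astype(int)

    raw["measure"] = raw["measure_name"].map(_MEASURE_ALIASES)
    if raw["measure"].isna().any():
        bad = raw.loc[raw["measure"].isna(), "measure_name"].unique().tolist()
        raise FormatError(f"unrecognised measure_name values: {bad}")
    raw["age_band"] = raw["age_name"].map(_age_name_to_band)
    known = set(AGE_BANDS) | {AGGREGATE_BAND}
    unknown = ~raw["age_band"].isin(known)
    if unknown.any():
        bands = sorted(raw.loc[unknown, "age_name"].unique().tolist())
        if strict:
            raise FormatError(
                f"age band(s) outside the 70+ scope: {bands} (strict mode)"
            )
        warnings.warn(f"dropping rows with out-of-scope age bands: {bands}")
        raw = raw[~unknown]

    if not raw["metric_name"].isin(["Rate", "Number"]).all():
        bad = sorted(set(raw["metric_name"]) - {"Rate", "Number"})
        raise FormatError(f"unrecognised metric_name values: {bad}")

    raw = raw.rename(columns={"location_name": "location", "sex_name": "sex"})
    keycols = KEY_COLUMNS + ["year", "metric_name"]
    dup = raw.duplicated(subset=keycols)
    if dup.any():
        keys = raw.loc[dup, keycols].iloc[0].tolist()
        raise IntegrityError(f"duplicate (key, year, metric) row: {keys}")

    wide = raw.pivot_table(
        index=KEY_COLUMNS + ["year"],
        columns="metric_name",
        values=["val", "lower", "upper"],
        aggfunc="first",
        observed=True,
    )
    wide.columns = [f"{v}_{m}" for v, m in wide.columns]
    wide = wide.reset_index()
    rename = {
        "val_Rate": "rate", "lower_Rate": "rate_lower", "upper_Rate": "rate_upper",
        "val_Number": "count", "lower_Number": "count_lower",
        "upper_Number": "count_upper",
    }
    wide = wide.rename(columns=rename)
    for col in rename.values():
        if col not in wide.columns:
            wide[col] = np.nan

    meta = {
        "has_rate": bool(wide["rate"].notna().any()),
        "has_count": bool(wide["count"].notna().any()),
    }
    return BurdenPanel(wide, source=source or str(path), metadata=meta)


# ---------------------------------------------------------------------------
# Population reconstruction and aggregation
# ---------------------------------------------------------------------------

def reconstruct_population(rate, count):
    """Population implied by a rate (per 100,000) and a count.

    ``population = count / rate * 100000``.  Accepts scalars or arrays.
    """
    rate = np.asarray(rate, dtype=float)
    count = np.asarray(count, dtype=float)
    if np.any(rate <= 0):
        raise DomainError("rate must be > 0 to reconstruct a population")
    if np.any(count < 0):
        raise DomainError("count must be >= 0")
    out = count / rate * RATE_SCALE
    return float(out) if out.ndim == 0 else out


def _with_population(df: pd.DataFrame, context: str) -> pd.DataFrame:
    missing = df["rate"].isna() | df["count"].isna() | (df["rate"] <= 0)
    if missing.any():
        rows = df.loc[missing, KEY_COLUMNS + ["year"]]
        raise AggregationError(
            f"{context}: rate and count required for population reconstruction; "
            f"offending stratum-years:\n{rows.to_string(index=False)}"
        )
    df = df.copy()
    df["population"] = df["count"] / df["rate"] * RATE_SCALE
    return df


def aggregate_strata(
    panel: BurdenPanel, collapse: Iterable[str] = ("sex", "age_band")
) -> BurdenPanel:
    """Collapse sex and/or age-band strata by summing counts and populations.

    The aggregated rate is total count / total reconstructed population x
    100,000 (a population-weighted mean of stratum rates).  Uncertainty
    bounds are summed on the count scale and divided by the total
    population — a conservative approximation, since draw-level correlation
    information is not available in results-tool extracts.
    """
    collapse = set(collapse)
    if not collapse or not collapse <= {"sex", "age_band"}:
        raise ConfigurationError(
            f"collapse must be a non-empty subset of {{'sex','age_band'}}, got {collapse}"
        )
    return _aggregate(panel, collapse)


def _aggregate(panel: BurdenPanel, collapse: set[str]) -> BurdenPanel:
    df = panel.data
    if "sex" in collapse:
        # Aggregate over the primary sexes; a pre-existing "Both" is used
        # only for the ±0.5% consistency check.
        both = df[df["sex"] == "Both"]
        df = df[df["sex"].isin(["Male", "Female"])]
        if df.empty:
            raise AggregationError("no Male/Female rows to collapse over sex")
    else:
        both = None
    if "age_band" in collapse:
        df = df[df["age_band"] != AGGREGATE_BAND]
        if df.empty:
            raise AggregationError("no 5-year age-band rows to collapse")

    df = _with_population(df, "aggregate_strata")
    group_keys = [c for c in KEY_COLUMNS if c not in collapse] + ["year"]
    agg = df.groupby(group_keys, observed=True, as_index=False).agg(
        count=("count", "sum"),
        population=("population", "sum"),
        count_lower=("count_lower", "sum"),
        count_upper=("count_upper", "sum"),
    )
    agg["rate"] = agg["count"] / agg["population"] * RATE_SCALE
    agg["rate_lower"] = agg["count_lower"] / agg["population"] * RATE_SCALE
    agg["rate_upper"] = agg["count_upper"] / agg["population"] * RATE_SCALE
    if "sex" in collapse:
        agg["sex"] = "Both"
    if "age_band" in collapse:
        agg["age_band"] = AGGREGATE_BAND

    if both is not None and not both.empty and "age_band" not in collapse:
        _check_both_consistency(agg, both)

    cols = KEY_COLUMNS + [
        "year", "rate", "rate_lower", "rate_upper",
        "count", "count_lower", "count_upper", "population",
    ]
    out = agg[[c for c in cols if c in agg.columns]]
    return BurdenPanel(out.copy(), source=panel.source,
                       metadata={**panel.metadata, "aggregated_over": sorted(collapse)})


def _check_both_consistency(agg: pd.DataFrame, both: pd.DataFrame) -> None:
    merged = agg.merge(
        both[KEY_COLUMNS + ["year", "count"]],
        on=[c for c in KEY_COLUMNS if c != "sex"] + ["year"],
        suffixes=("", "_reported"),
    )
    if merged.empty:
        return
    rel = np.abs(merged["count"] - merged["count_reported"]) / merged["count_reported"]
    if (rel > 0.005).any():
        worst = float(rel.max())
        warnings.warn(
            "aggregated Male+Female counts disagree with reported Both-sex counts "
            f"by up to {worst:.2%} (tolerance 0.5%)"
        )


# ---------------------------------------------------------------------------
# Summaries: PAF and DALY-to-death ratio
# ---------------------------------------------------------------------------

def compute_paf(
    attributable: BurdenPanel, total_cause: BurdenPanel, on: str = "count"
) -> pd.DataFrame:
    """Population-attributable fraction (%) = attributable / total-cause x 100.

    Computed on counts by default; ``on="rate"`` is equivalent when the two
    panels describe exactly the same strata (same denominators).
    """
    if on not in ("count", "rate"):
        raise DomainError("on must be 'count' or 'rate'")
    keys = KEY_COLUMNS + ["year"]
    a = attributable.data[keys + [on]].rename(columns={on: "attributable"})
    t = total_cause.data[keys + [on]].rename(columns={on: "total"})
    merged = a.merge(t, on=keys, how="outer", indicator=True)
    unmatched = merged["_merge"] != "both"
    if unmatched.any():
        rows = merged.loc[unmatched, keys]
        raise JoinError(
            f"panels do not share keys; unmatched rows:\n{rows.to_string(index=False)}"
        )
    bad = (merged["total"] <= 0) & (merged["attributable"] > 0)
    if bad.any():
        raise DomainError("total-cause value is 0 where attributable burden is > 0")
    merged["paf"] = np.where(
        merged["total"] > 0, merged["attributable"] / merged["total"] * 100.0, 0.0
    )
    return merged[keys + ["paf"]]


def daly_death_ratio(panel: BurdenPanel, age_band: str = AGGREGATE_BAND) -> tuple[pd.DataFrame, float]:
    """Per-location DALY-rate / death-rate ratio and its unweighted mean.

    Locations with a zero death rate are excluded from the mean with a
    warning.  Uses each location's 70+ aggregate rates by default.
    """
    df = panel.data
    sel = df[(df["age_band"] == age_band) & (df["sex"] == "Both")]
    if sel.empty:
        sel = df[df["age_band"] == age_band]
    year = int(sel["year"].max())
    sel = sel[sel["year"] == year]
    deaths = sel[sel["measure"] == "Deaths"][["location", "rate"]]
    dalys = sel[sel["measure"] == "DALYs"][["location", "rate"]]
    merged = deaths.merge(dalys, on="location", suffixes=("_death", "_daly"))
    if merged.empty:
        raise CompletenessError(
            "panel must contain both Deaths and DALYs rates per location "
            f"for the {age_band} aggregate"
        )
    zero = merged["rate_death"] <= 0
    if zero.any():
        warnings.warn(
            f"excluding {int(zero.sum())} location(s) with zero death rate from the mean"
        )
    merged["ratio"] = np.where(zero, np.nan, merged["rate_daly"] / merged["rate_death"])
    mean_ratio = float(merged["ratio"].mean())
    return merged[["location", "ratio"]], mean_ratio
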