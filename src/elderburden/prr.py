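"""Descriptive period rate ratios (PRRs) over 5-year calendar bins.

Calendar years are grouped into consecutive periods (1990-1994, 1995-1999,
..., with a possibly shorter terminal bin such as 2020-2021).  The PRR for
a period is its mean annual point rate divided by the mean point rate of
the reference (first) period.  The accompanying bounds divide the period's
mean lower/upper estimates by the reference period's POINT mean — they are
descriptive envelopes inherited from the input uncertainty ribbons, not
inferential confidence intervals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DomainError

__all__ = ["PRRTable", "period_rate_ratios", "period_rate_ratios_panel"]


@dataclass
class PRRTable:
    """Rows of (period label, mean rate, prr, prr_low, prr_high)."""

    table: pd.DataFrame
    reference_period: str


def _period_label(start: int, end: int) -> str:
    return f"{start}-{end}"


def period_rate_ratios(
    series: pd.DataFrame,
    period_length: int = 5,
    min_coverage: float = 0.0,
) -> PRRTable:
    """Period rate ratios for one stratum's series.

    Parameters
    ----------
    series : DataFrame
        Columns ``year`` and ``rate``; optional ``rate_lower`` and
        ``rate_upper`` for the descriptive bounds.
    period_length : int
        Calendar bin width in years (default 5); the terminal bin may be
        shorter and is labelled by its actual span.
    min_coverage : float
        Drop bins whose observed-year fraction is below this threshold
        (0 keeps everything, 0.5 drops bins less than half covered).
    """
    if period_length < 1:
        raise ConfigurationError("period_length must be >= 1")
    df = series.sort_values("year").reset_index(drop=True)
    if df.empty:
        raise ConfigurationError("empty series")
    if (df["rate"] <= 0).any():
        raise DomainError("all rates must be > 0 for PRR computation")
    y0, y1 = int(df["year"].min()), int(df["year"].max())
    has_bounds = {"rate_lower", "rate_upper"} <= set(df.columns)

    rows = []
    for start in range(y0, y1 + 1, period_length):
        end = min(start + period_length - 1, y1)
        sub = df[(df["year"] >= start) & (df["year"] <= end)]
        # coverage relative to the nominal bin width, so a short terminal
        # bin can be dropped by the flag even though it is fully observed
        coverage = len(sub) / period_length
        if sub.empty or coverage < min_coverage:
            continue
        row = {
            "period": _period_label(start, end),
            "n_years": len(sub),
            "mean_rate": float(sub["rate"].mean()),
        }
        if has_bounds:
            row["mean_lower"] = float(sub["rate_lower"].mean())
            row["mean_upper"] = float(sub["rate_upper"].mean())
        rows.append(row)
    if not rows:
        raise ConfigurationError("no periods survive the coverage threshold")
    table = pd.DataFrame(rows)

    first = df[(df["year"] >= y0) & (df["year"] <= y0 + period_length - 1)]
    if first.empty:
        raise ConfigurationError("reference period is empty")
    ref_mean = float(first["rate"].mean())
    ref_label = table["period"].iloc[0]

    table["prr"] = table["mean_rate"] / ref_mean
    if has_bounds:
        table["prr_low"] = table["mean_lower"] / ref_mean
        table["prr_high"] = table["mean_upper"] / ref_mean
    return PRRTable(table=table, reference_period=ref_label)


def period_rate_ratios_panel(
    panel, measure: str = "DALYs", period_length: int = 5, min_coverage: float = 0.0
) -> pd.DataFrame:
    """PRR tables for every (location, sex) stratum of one measure's
    aggregate or band series in a panel, stacked into one frame."""
    df = panel.data[panel.data["measure"] == measure]
    out = []
    for (loc, sex, band), grp in df.groupby(
        ["location", "sex", "age_band"], observed=True, sort=False
    ):
        res = period_rate_ratios(grp, period_length=period_length,
                                 min_coverage=min_coverage)
        t = res.table.copy()
        t.insert(0, "age_band", band)
        t.insert(0, "sex", sex)
        t.insert(0, "location", loc)
        t.insert(0, "measure", measure)
        out.append(t)
    return pd.concat(out, ignore_index=True)
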