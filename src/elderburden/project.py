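"""Empirical age-specific log-linear extrapolation of rates and populations.

For each age x sex stratum, two independent OLS fits on the log scale —
one to the rate series, one to the reconstructed population series — over
a training window (2000-2021 by default).  Projected counts combine the
two point paths; 95% prediction intervals for the rate come from the
classical t-based out-of-sample interval on the log scale, exponentiated,
and are propagated to counts by multiplying by the (point) population
path.  Populations are projected as point paths without intervals, so
count uncertainty reflects rate uncertainty only.  Aggregated bounds are
sums of stratum bounds (perfect dependence, conservative);
``bounds="independent"`` combines half-widths root-sum-square instead.

The fitted (in-sample) state at the training window's last year — the
"model-fitted baseline" — is emitted alongside the projections so that the
decomposition of projected change can be anchored to the model rather
than to the observed value, keeping forecasting and decomposition
internally consistent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import AggregationError, CompletenessError, ConfigurationError, DomainError
from .decompose import DemographicState
from .io_gbd import AGE_BANDS, RATE_SCALE, BurdenPanel

__all__ = [
    "LogLinearFit",
    "ProjectionResult",
    "fit_loglinear",
    "fit_rate_and_pop",
    "project_stratum",
    "project_aggregate",
]


@dataclass(frozen=True)
class LogLinearFit:
    """Closed-form OLS fit of ln(value) on year, with the design moments
    needed for t-based prediction intervals."""

    intercept: float
    slope: float
    sigma2: float          # residual variance, ddof = 2
    n: int
    t_mean: float
    sxx: float
    window: tuple[int, int]

    def predict(self, years) -> np.ndarray:
        years = np.asarray(years, dtype=float)
        return np.exp(self.intercept + self.slope * years)

    def predict_interval(self, years, alpha: float = 0.05):
        """(point, lower, upper) on the natural scale for new observations."""
        years = np.asarray(years, dtype=float)
        mean_log = self.intercept + self.slope * years
        if self.sigma2 <= 0 or self.n <= 2:
            point = np.exp(mean_log)
            return point, point.copy(), point.copy()
        se_pred = np.sqrt(
            self.sigma2 * (1.0 + 1.0 / self.n + (years - self.t_mean) ** 2 / self.sxx)
        )
        tq = stats.t.ppf(1.0 - alpha / 2.0, self.n - 2)
        return (
            np.exp(mean_log),
            np.exp(mean_log - tq * se_pred),
            np.exp(mean_log + tq * se_pred),
        )


@dataclass
class ProjectionResult:
    """Per-stratum and aggregated projections over a horizon."""

    strata: pd.DataFrame       # sex, age_band, year, rate, rate_lo/hi, pop, count, count_lo/hi
    aggregate: pd.DataFrame    # year, count, count_lo/hi, population, rate, rate_lo/hi
    anchor_year: int
    anchor_state: DemographicState            # both-sex, sex x age cells
    anchor_states_by_sex: dict[str, DemographicState]
    horizon: tuple[int, int]
    window: tuple[int, int]


def fit_loglinear(years, values, window: tuple[int, int] | None = None) -> LogLinearFit:
    """Closed-form OLS of ln(value) on year over an (optional) window."""
    years = np.asarray(years, dtype=float)
    values = np.asarray(values, dtype=float)
    if window is not None:
        m = (years >= window[0]) & (years <= window[1])
        years, values = years[m], values[m]
        expected = window[1] - window[0] + 1
        if len(years) != expected:
            raise CompletenessError(
                f"window {window} requires {expected} observations, found {len(years)}"
            )
    else:
        window = (int(years.min()), int(years.max()))
    if len(years) < 5:
        raise CompletenessError("training window must contain at least 5 years")
    if np.any(values <= 0):
        raise DomainError("all values must be > 0 for log-linear fitting")
    ly = np.log(values)
    t_mean = years.mean()
    sxx = float(np.sum((years - t_mean) ** 2))
    slope = float(np.sum((years - t_mean) * (ly - ly.mean())) / sxx)
    intercept = float(ly.mean() - slope * t_mean)
    resid = ly - (intercept + slope * years)
    n = len(years)
    sigma2 = float(resid @ resid / (n - 2))
    return LogLinearFit(intercept, slope, sigma2, n, float(t_mean), sxx, tuple(window))


def fit_rate_and_pop(
    panel: BurdenPanel,
    stratum: dict,
    window: tuple[int, int] = (2000, 2021),
) -> tuple[LogLinearFit, LogLinearFit]:
    """Fit the rate and reconstructed-population series of one stratum."""
    series = panel.get_series(
        stratum.get("measure", "Deaths"),
        stratum.get("location", "Global"),
        stratum["sex"],
        stratum["age_band"],
    )
    if series.empty:
        raise CompletenessError(f"no observations for stratum {stratum}")
    sub = series[(series["year"] >= window[0]) & (series["year"] <= window[1])]
    if sub[["rate", "count"]].isna().any(axis=None) or (sub["rate"] <= 0).any():
        raise DomainError(
            f"stratum {stratum}: positive rate and count required across {window}"
        )
    years = sub["year"].to_numpy()
    pop = sub["count"].to_numpy() / sub["rate"].to_numpy() * RATE_SCALE
    rate_fit = fit_loglinear(years, sub["rate"].to_numpy(), window)
    pop_fit = fit_loglinear(years, pop, window)
    return rate_fit, pop_fit


def project_stratum(
    rate_fit: LogLinearFit,
    pop_fit: LogLinearFit,
    horizon: tuple[int, int] = (2022, 2044),
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-year projected rate (with PI), population, and count (with
    rate-driven bounds) for one stratum."""
    if horizon[1] < horizon[0]:
        raise ConfigurationError("horizon must be an increasing (first, last) pair")
    years = np.arange(horizon[0], horizon[1] + 1)
    rate, rate_lo, rate_hi = rate_fit.predict_interval(years, alpha=alpha)
    pop = pop_fit.predict(years)
    return pd.DataFrame({
        "year": years,
        "rate": rate, "rate_lower": rate_lo, "rate_upper": rate_hi,
        "population": pop,
        "count": rate * pop / RATE_SCALE,
        "count_lower": rate_lo * pop / RATE_SCALE,
        "count_upper": rate_hi * pop / RATE_SCALE,
    })


def _anchor_state(
    fits: dict[tuple[str, str], tuple[LogLinearFit, LogLinearFit]],
    cells: list[tuple[str, str]],
    anchor_year: int,
    labels_with_sex: bool,
) -> DemographicState:
    pops, rates, labels = [], [], []
    for sex, band in cells:
        rate_fit, pop_fit = fits[(sex, band)]
        pops.append(float(pop_fit.predict([anchor_year])[0]))
        rates.append(float(rate_fit.predict([anchor_year])[0]) / RATE_SCALE)
        labels.append(f"{sex}|{band}" if labels_with_sex else band)
    pops = np.asarray(pops)
    return DemographicState(
        year=anchor_year, n_total=float(pops.sum()), shares=pops / pops.sum(),
        rates=np.asarray(rates), labels=tuple(labels),
    )


def project_aggregate(
    panel: BurdenPanel,
    measure: str = "Deaths",
    location: str = "Global",
    sexes: tuple[str, ...] = ("Male", "Female"),
    bands: tuple[str, ...] = AGE_BANDS,
    window: tuple[int, int] = (2000, 2021),
    horizon: tuple[int, int] = (2022, 2044),
    bounds: str = "sum",
) -> ProjectionResult:
    """Project every age x sex stratum and aggregate to totals.

    ``bounds="sum"`` adds stratum count bounds (perfect dependence);
    ``bounds="independent"`` combines half-widths root-sum-square.
    """
    if bounds not in ("sum", "independent"):
        raise ConfigurationError("bounds must be 'sum' or 'independent'")
    cells = [(s, b) for s in sexes for b in bands]
    fits, paths, failures = {}, [], []
    for sex, band in cells:
        stratum = {"measure": measure, "location": location,
                   "sex": sex, "age_band": band}
        try:
            fits[(sex, band)] = fit_rate_and_pop(panel, stratum, window)
        except (CompletenessError, DomainError) as exc:
            failures.append(f"{sex}/{band}: {exc}")
            continue
        path = project_stratum(*fits[(sex, band)], horizon=horizon)
        path.insert(0, "age_band", band)
        path.insert(0, "sex", sex)
        paths.append(path)
    if failures:
        raise AggregationError("unfittable strata: " + "; ".join(failures))

    strata = pd.concat(paths, ignore_index=True)
    grouped = strata.groupby("year", as_index=False)
    agg = grouped.agg(
        count=("count", "sum"),
        population=("population", "sum"),
        count_lower=("count_lower", "sum"),
        count_upper=("count_upper", "sum"),
    )
    if bounds == "independent":
        lo_hw = strata.assign(hw=strata["count"] - strata["count_lower"])
        hi_hw = strata.assign(hw=strata["count_upper"] - strata["count"])
        rss = lambda df: df.groupby("year")["hw"].apply(
            lambda s: float(np.sqrt(np.sum(s.to_numpy() ** 2)))
        ).to_numpy()
        agg["count_lower"] = agg["count"] - rss(lo_hw)
        agg["count_upper"] = agg["count"] + rss(hi_hw)
    agg["rate"] = agg["count"] / agg["population"] * RATE_SCALE
    agg["rate_lower"] = agg["count_lower"] / agg["population"] * RATE_SCALE
    agg["rate_upper"] = agg["count_upper"] / agg["population"] * RATE_SCALE

    anchor_year = window[1]
    anchor_both = _anchor_state(fits, cells, anchor_year, labels_with_sex=True)
    by_sex = {
        sex: _anchor_state(fits, [(sex, b) for b in bands], anchor_year,
                           labels_with_sex=False)
        for sex in sexes
    }
    return ProjectionResult(
        strata=strata, aggregate=agg, anchor_year=anchor_year,
        anchor_state=anchor_both, anchor_states_by_sex=by_sex,
        horizon=tuple(horizon), window=tuple(window),
    )
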