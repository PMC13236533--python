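"""Hindcasting validation and multi-model robustness of the projections.

``hindcast`` refits the primary log-linear model on an early window
(2000-2014 by default), forecasts the held-out years (2015-2021) with 95%
prediction intervals, and reports MAPE, MAE, RMSE and interval coverage.

``compare_models`` contrasts the primary log-linear forecast of an
aggregated rate series with two alternatives fitted on the log of the
series (for positivity and comparability; ``scale="natural"`` is
available): an unobserved-components model with a local linear trend, and
an ARIMA model with its order selected by AIC over p, q in {0, 1, 2} and
d in {0, 1}.  Differences are summarised by the mean absolute percentage
difference (MAPD) over the horizon — directional, with the primary path
as denominator — and the percentage difference in the final horizon year.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import CompletenessError, ConfigurationError, DomainError
from .project import LogLinearFit, fit_loglinear

__all__ = [
    "HindcastReport",
    "ModelForecast",
    "ModelComparison",
    "hindcast",
    "compare_models",
    "error_metrics",
]


@dataclass
class HindcastReport:
    """Out-of-sample error metrics for one series."""

    mape: float      # percent
    mae: float       # units of the series
    rmse: float
    coverage: float  # percent of test years inside the 95% PI
    train_window: tuple[int, int]
    test_window: tuple[int, int]
    predictions: np.ndarray
    pi_lower: np.ndarray
    pi_upper: np.ndarray
    observed: np.ndarray
    test_years: np.ndarray


@dataclass
class ModelForecast:
    name: str
    path: np.ndarray
    mapd: float | None
    pct_diff_at_horizon: float | None
    order: tuple | None = None
    converged: bool = True


@dataclass
class ModelComparison:
    horizon_years: np.ndarray
    primary: np.ndarray
    models: dict[str, ModelForecast] = field(default_factory=dict)


def error_metrics(observed, predicted) -> tuple[float, float, float]:
    """(MAPE %, MAE, RMSE).  MAPE = mean(|obs - pred| / obs) x 100."""
    observed = np.asarray(observed, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if np.any(observed <= 0):
        raise DomainError("MAPE requires strictly positive observations")
    err = observed - predicted
    mape = float(np.mean(np.abs(err) / observed) * 100.0)
    mae = float(np.mean(np.abs(err)))
    rmse = float(np.sqrt(np.mean(err ** 2)))
    return mape, mae, rmse


def hindcast(
    years,
    rates,
    train: tuple[int, int] = (2000, 2014),
    test: tuple[int, int] = (2015, 2021),
    alpha: float = 0.05,
) -> HindcastReport:
    """Train the primary log-linear model on ``train`` and score it on
    ``test`` with 95% prediction intervals."""
    if train[1] >= test[0]:
        raise ConfigurationError(
            f"train window {train} overlaps test window {test}"
        )
    years = np.asarray(years, dtype=float)
    rates = np.asarray(rates, dtype=float)
    test_mask = (years >= test[0]) & (years <= test[1])
    if test_mask.sum() != test[1] - test[0] + 1:
        raise CompletenessError(f"test window {test} not fully observed")

    fit = fit_loglinear(years, rates, window=train)
    test_years = years[test_mask]
    observed = rates[test_mask]
    pred, lo, hi = fit.predict_interval(test_years, alpha=alpha)
    mape, mae, rmse = error_metrics(observed, pred)
    covered = (observed >= lo) & (observed <= hi)
    return HindcastReport(
        mape=mape, mae=mae, rmse=rmse,
        coverage=float(covered.mean() * 100.0),
        train_window=tuple(train), test_window=tuple(test),
        predictions=pred, pi_lower=lo, pi_upper=hi,
        observed=observed, test_years=test_years,
    )


# ---------------------------------------------------------------------------
# Alternative-model robustness
# ---------------------------------------------------------------------------

def _fit_ucm(y: np.ndarray, steps: int):
    from statsmodels.tsa.statespace.structural import UnobservedComponents

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = UnobservedComponents(y, level="local linear trend")
        res = model.fit(disp=0)
        converged = bool(res.mle_retvals.get("converged", True))
        return np.asarray(res.forecast(steps)), None, converged


def _fit_arima_aic(y: np.ndarray, steps: int,
                   p_grid=(0, 1, 2), d_grid=(0, 1), q_grid=(0, 1, 2)):
    from statsmodels.tsa.arima.model import ARIMA

    best = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for p, d, q in itertools.product(p_grid, d_grid, q_grid):
            trend = "t" if d >= 1 else "c"
            try:
                res = ARIMA(y, order=(p, d, q), trend=trend,
                            concentrate_scale=True).fit()
            except Exception:
                continue
            aic = res.aic
            if not np.isfinite(aic):
                continue
            if best is None or aic < best[0]:
                converged = bool(getattr(res, "mle_retvals", {}).get("converged", True))
                best = (aic, (p, d, q), np.asarray(res.forecast(steps)), converged)
    if best is None:
        raise DomainError("no ARIMA candidate could be fitted")
    return best[2], best[1], best[3]


def compare_models(
    years,
    rates,
    horizon: tuple[int, int] = (2022, 2044),
    train: tuple[int, int] | None = None,
    scale: str = "log",
) -> ModelComparison:
    """Compare the primary log-linear forecast with UCM and AIC-selected
    ARIMA alternatives over a horizon."""
    if scale not in ("log", "natural"):
        raise ConfigurationError("scale must be 'log' or 'natural'")
    years = np.asarray(years, dtype=float)
    rates = np.asarray(rates, dtype=float)
    if train is None:
        train = (int(years.min()), int(years.max()))
    if horizon[0] <= train[1]:
        raise ConfigurationError("horizon must start after the last observation")
    m = (years >= train[0]) & (years <= train[1])
    fit = fit_loglinear(years[m], rates[m])
    hyears = np.arange(horizon[0], horizon[1] + 1)
    primary = fit.predict(hyears)
    steps = len(hyears)

    endog = np.log(rates[m]) if scale == "log" else rates[m]
    back = (lambda f: np.exp(f)) if scale == "log" else (lambda f: f)

    comparison = ModelComparison(horizon_years=hyears, primary=primary)
    for name, fitter in (("UCM", _fit_ucm), ("ARIMA", _fit_arima_aic)):
        try:
            fc, order, converged = fitter(endog, steps)
        except Exception as exc:  # state-space non-convergence and kin
            warnings.warn(f"{name} fit failed and was skipped: {exc}")
            comparison.models[name] = ModelForecast(
                name=name, path=np.full(steps, np.nan),
                mapd=None, pct_diff_at_horizon=None, converged=False,
            )
            continue
        path = back(fc)
        mapd = float(np.mean(np.abs(path - primary) / primary) * 100.0)
        pct = float((path[-1] - primary[-1]) / primary[-1] * 100.0)
        comparison.models[name] = ModelForecast(
            name=name, path=path, mapd=mapd, pct_diff_at_horizon=pct,
            order=order, converged=converged,
        )
    return comparison
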