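"""Log-linear and segmented (joinpoint-style) trend estimation.

Two estimators, both scikit-learn compatible:

``LogLinearTrend``
    OLS of ln(rate) on calendar year with Newey–West (HAC, Bartlett kernel,
    maxlag 1) slope inference.  The annual percent change (APC) is
    (exp(beta) - 1) x 100; its 95% CI is the exp-transform of
    beta +/- 1.96 x SE.

``SegmentedTrend``
    Continuous piecewise log-linear regression with 1..max_segments
    segments, breakpoints constrained to integer years with a minimum
    knot-to-knot spacing, fitted by exhaustive search over admissible
    breakpoint sets (with at most ~30 annual observations the search space
    is small and the minimiser exact).  The segment count is selected by
    BIC; ties are broken toward fewer segments.  The full-period average
    annual percent change (AAPC) comes from a separate single log-linear
    fit over the whole series, never from averaging segment APCs.

Module-level functions ``fit_loglinear_apc``, ``fit_segmented`` and
``age_specific_apc`` are thin wrappers over the estimators.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.base import BaseEstimator, RegressorMixin

from .errors import CompletenessError, DomainError
from .io_gbd import AGE_BANDS, BurdenPanel

__all__ = [
    "ApcEstimate",
    "SegmentedFit",
    "LogLinearTrend",
    "SegmentedTrend",
    "fit_loglinear_apc",
    "fit_segmented",
    "age_specific_apc",
]

#: Numerical floor applied to RSS (per observation) inside the BIC so that a
#: noiseless series does not drive n·ln(RSS/n) to -inf for every candidate;
#: with the floor all interpolating candidates tie and parsimony wins.
_RSS_FLOOR_PER_OBS = 1e-20

_Z975 = 1.959963984540054


@dataclass(frozen=True)
class ApcEstimate:
    """Annual percent change with HAC-based 95% CI.

    ``apc = (exp(slope) - 1) x 100`` exactly; the CI is the same transform
    of ``slope +/- 1.96 x se``.
    """

    apc: float
    ci_low: float
    ci_high: float
    slope: float
    se: float

    @staticmethod
    def from_slope(slope: float, se: float) -> "ApcEstimate":
        to_apc = lambda b: float((np.exp(b) - 1.0) * 100.0)
        return ApcEstimate(
            apc=to_apc(slope),
            ci_low=to_apc(slope - _Z975 * se),
            ci_high=to_apc(slope + _Z975 * se),
            slope=float(slope),
            se=float(se),
        )


@dataclass
class SegmentedFit:
    """Selected piecewise log-linear model for one stratum's series."""

    breakpoints: tuple[int, ...]
    n_segments: int
    segment_slopes: tuple[float, ...]
    segment_ses: tuple[float, ...]
    segment_apcs: tuple[ApcEstimate, ...]
    bic: float
    aapc: ApcEstimate
    fitted_log_rates: np.ndarray
    years: np.ndarray
    note: str | None = None


def _validate_series(years, rates, min_points: int = 3):
    years = np.asarray(years, dtype=float)
    rates = np.asarray(rates, dtype=float)
    if years.ndim == 2 and years.shape[1] == 1:
        years = years.ravel()
    if years.shape != rates.shape or years.ndim != 1:
        raise DomainError("years and rates must be 1-d arrays of equal length")
    if len(years) < min_points:
        raise CompletenessError(f"need at least {min_points} observations, got {len(years)}")
    if np.any(rates <= 0) or not np.all(np.isfinite(rates)):
        raise DomainError("all rates must be finite and > 0 for log-linear fitting")
    order = np.argsort(years)
    return years[order], rates[order]


def _hac_slope_se(years: np.ndarray, log_rates: np.ndarray) -> tuple[float, float, float]:
    """(intercept, slope, HAC se of slope) from statsmodels OLS."""
    X = sm.add_constant(years)
    res = sm.OLS(log_rates, X).fit(cov_type="HAC", cov_kwds={"maxlags": 1})
    return float(res.params[0]), float(res.params[1]), float(res.bse[1])


class LogLinearTrend(BaseEstimator, RegressorMixin):
    """OLS log-linear trend with Newey–West slope inference.

    Parameters
    ----------
    maxlags : int
        Bartlett-kernel truncation lag for the HAC covariance (default 1).

    Attributes
    ----------
    intercept_, slope_ : float
        Coefficients of ln(rate) = intercept + slope x year.
    se_ : float
        HAC standard error of the slope.
    apc_ : ApcEstimate
        Annual percent change with 95% CI.
    """

    def __init__(self, maxlags: int = 1):
        self.maxlags = maxlags

    def fit(self, X, y):
        years, rates = _validate_series(X, y)
        ly = np.log(rates)
        Xd = sm.add_constant(years)
        res = sm.OLS(ly, Xd).fit(cov_type="HAC", cov_kwds={"maxlags": self.maxlags})
        self.intercept_ = float(res.params[0])
        self.slope_ = float(res.params[1])
        self.se_ = float(res.bse[1])
        self.apc_ = ApcEstimate.from_slope(self.slope_, self.se_)
        self.n_ = len(years)
        return self

    def predict(self, X):
        years = np.asarray(X, dtype=float)
        if years.ndim == 2:
            years = years.ravel()
        return np.exp(self.intercept_ + self.slope_ * years)


# ---------------------------------------------------------------------------
# Segmented fitting
# ---------------------------------------------------------------------------

def _hinge_design(years: np.ndarray, breakpoints: tuple[int, ...]) -> np.ndarray:
    cols = [np.ones_like(years), years - years[0]]
    for b in breakpoints:
        cols.append(np.maximum(years - b, 0.0))
    return np.column_stack(cols)


def _piecewise_rss(years, log_rates, breakpoints):
    X = _hinge_design(years, breakpoints)
    coef, _, _, _ = np.linalg.lstsq(X, log_rates, rcond=None)
    resid = log_rates - X @ coef
    return float(resid @ resid), coef, X


def _admissible_breakpoints(y0: int, y1: int, k: int, min_len: int):
    """All ordered (k-1)-tuples of integer interior years with knot spacing
    >= min_len on (y0, b1, ..., b_{k-1}, y1)."""
    if k == 1:
        yield ()
        return
    lo, hi = y0 + min_len, y1 - min_len
    for combo in itertools.combinations(range(lo, hi + 1), k - 1):
        knots = (y0, *combo, y1)
        if all(b - a >= min_len for a, b in zip(knots, knots[1:])):
            yield combo


def _bic(rss: float, n: int, n_segments: int) -> float:
    # p = (#slopes) + (#breakpoints) + 1 intercept = 2 * n_segments
    rss = max(rss, n * _RSS_FLOOR_PER_OBS)
    p = 2 * n_segments
    return n * np.log(rss / n) + p * np.log(n)


class SegmentedTrend(BaseEstimator, RegressorMixin):
    """BIC-selected continuous piecewise log-linear trend.

    Parameters
    ----------
    max_segments : int
        Largest candidate segment count (default 6).
    min_segment_len : int
        Minimum knot-to-knot spacing in calendar years (default 5).

    Attributes
    ----------
    breakpoints_ : tuple of int
    n_segments_ : int
    segment_apcs_ : tuple of ApcEstimate
        Point APCs from the constrained piecewise fit; SEs from HAC
        refits on each segment's own years.
    aapc_ : ApcEstimate
        From a separate full-period log-linear fit.
    bic_ : float
    result_ : SegmentedFit
    """

    def __init__(self, max_segments: int = 6, min_segment_len: int = 5):
        self.max_segments = max_segments
        self.min_segment_len = min_segment_len

    def fit(self, X, y):
        years, rates = _validate_series(X, y)
        if not np.allclose(years, np.round(years)):
            raise DomainError("segmented fitting requires integer calendar years")
        years_i = years.astype(int)
        log_rates = np.log(rates)
        y0, y1 = int(years_i[0]), int(years_i[-1])
        span = y1 - y0
        n = len(years)

        note = None
        max_k = self.max_segments
        if span < 2 * self.min_segment_len and max_k > 1:
            note = (
                f"series spans only {span} years; multi-segment candidates "
                f"infeasible, returning the single-segment fit"
            )
            warnings.warn(note)
            max_k = 1

        best = None  # (bic, k, breakpoints, coef)
        for k in range(1, max_k + 1):
            best_k = None
            for bps in _admissible_breakpoints(y0, y1, k, self.min_segment_len):
                rss, coef, _ = _piecewise_rss(years, log_rates, bps)
                if best_k is None or rss < best_k[0]:
                    best_k = (rss, bps, coef)
            if best_k is None:
                continue
            bic = _bic(best_k[0], n, k)
            if best is None or bic < best[0]:  # strict: ties keep fewer segments
                best = (bic, k, best_k[1], best_k[2])

        bic, k, bps, coef = best
        slopes = tuple(np.cumsum(coef[1:]).tolist())
        X_best = _hinge_design(years, bps)
        fitted = X_best @ coef

        # HAC SEs from per-segment refits (segments share their knot year)
        knots = (y0, *bps, y1)
        ses = []
        apcs = []
        for i in range(k):
            lo, hi = knots[i], knots[i + 1]
            m = (years_i >= lo) & (years_i <= hi)
            _, _, se = _hac_slope_se(years[m], log_rates[m])
            ses.append(se)
            apcs.append(ApcEstimate.from_slope(slopes[i], se))

        aapc_est = LogLinearTrend().fit(years, rates).apc_

        self.breakpoints_ = tuple(int(b) for b in bps)
        self.n_segments_ = k
        self.segment_slopes_ = slopes
        self.segment_ses_ = tuple(ses)
        self.segment_apcs_ = tuple(apcs)
        self.bic_ = float(bic)
        self.aapc_ = aapc_est
        self.coef_ = coef
        self.years_ = years_i
        self.result_ = SegmentedFit(
            breakpoints=self.breakpoints_,
            n_segments=k,
            segment_slopes=slopes,
            segment_ses=tuple(ses),
            segment_apcs=tuple(apcs),
            bic=float(bic),
            aapc=aapc_est,
            fitted_log_rates=fitted,
            years=years_i,
            note=note,
        )
        return self

    def predict(self, X):
        years = np.asarray(X, dtype=float)
        if years.ndim == 2:
            years = years.ravel()
        Xd = np.column_stack(
            [np.ones_like(years), years - self.years_[0]]
            + [np.maximum(years - b, 0.0) for b in self.breakpoints_]
        )
        return np.exp(Xd @ self.coef_)


# ---------------------------------------------------------------------------
# Module-level wrappers
# ---------------------------------------------------------------------------

def fit_loglinear_apc(years, rates) -> ApcEstimate:
    """APC from an OLS log-linear fit with HAC (maxlag 1) inference."""
    return LogLinearTrend().fit(years, rates).apc_


def fit_segmented(years, rates, max_segments: int = 6, min_segment_len: int = 5) -> SegmentedFit:
    """BIC-selected segmented log-linear fit (see :class:`SegmentedTrend`)."""
    est = SegmentedTrend(max_segments=max_segments, min_segment_len=min_segment_len)
    return est.fit(years, rates).result_


def age_specific_apc(
    panel: BurdenPanel,
    measure: str = "DALYs",
    years: tuple[int, int] | None = None,
) -> pd.DataFrame:
    """One APC per (location/SDI group, sex, age band) stratum.

    Strata with missing years are skipped and listed in the returned
    frame's ``attrs['incomplete']`` completeness report.
    """
    df = panel.data[panel.data["measure"] == measure]
    if df.empty:
        raise CompletenessError(f"panel has no {measure!r} observations")
    if years is None:
        years = (int(df["year"].min()), int(df["year"].max()))
    expected = years[1] - years[0] + 1

    rows, incomplete = [], []
    keys = ["location", "sdi_group", "sex", "age_band"]
    for (loc, sdi, sex, band), grp in df.groupby(keys, observed=True, sort=False):
        if band not in AGE_BANDS:
            continue
        grp = grp[(grp["year"] >= years[0]) & (grp["year"] <= years[1])]
        if len(grp) < expected:
            missing = sorted(set(range(years[0], years[1] + 1)) - set(grp["year"]))
            incomplete.append({"location": loc, "sex": sex, "age_band": band,
                               "missing_years": missing})
            continue
        grp = grp.sort_values("year")
        est = fit_loglinear_apc(grp["year"].to_numpy(), grp["rate"].to_numpy())
        rows.append({
            "location": loc, "sdi_group": sdi, "sex": sex, "age_band": band,
            "apc": est.apc, "ci_low": est.ci_low, "ci_high": est.ci_high,
            "slope": est.slope, "se": est.se,
        })
    out = pd.DataFrame(rows)
    out.attrs["incomplete"] = incomplete
    return out
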