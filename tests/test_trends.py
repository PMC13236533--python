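"""Log-linear APC and segmented trend fitting against independent oracles."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from elderburden.errors import CompletenessError, DomainError
from elderburden.synth import StratumSpec, SyntheticSpec, generate_panel
from elderburden.trends import (
    ApcEstimate,
    LogLinearTrend,
    SegmentedTrend,
    age_specific_apc,
    fit_loglinear_apc,
    fit_segmented,
)

# ---------------------------------------------------------------------------
# Independent oracles
# ---------------------------------------------------------------------------

def ols_newey_west(years, log_rates, maxlag=1):
    """Closed-form OLS slope with Bartlett-kernel HAC SE (no small-sample
    correction), written from the sandwich formula directly."""
    X = np.column_stack([np.ones_like(years), years])
    beta = np.linalg.solve(X.T @ X, X.T @ log_rates)
    e = log_rates - X @ beta
    Xe = X * e[:, None]
    S = Xe.T @ Xe
    for lag in range(1, maxlag + 1):
        w = 1.0 - lag / (maxlag + 1.0)
        G = Xe[lag:].T @ Xe[:-lag]
        S += w * (G + G.T)
    XtXi = np.linalg.inv(X.T @ X)
    V = XtXi @ S @ XtXi
    return beta, np.sqrt(np.diag(V))


def hat_basis_best_rss(years, log_rates, k, min_len=5):
    """Brute-force best continuous piecewise-linear RSS with k segments:
    naive loop over all admissible integer breakpoint tuples, least squares
    in the hat-function (knot-value) basis."""
    y0, y1 = int(years[0]), int(years[-1])
    best = (np.inf, None)
    for combo in itertools.combinations(range(y0 + min_len, y1 - min_len + 1), k - 1):
        knots = np.array([y0, *combo, y1], dtype=float)
        if np.any(np.diff(knots) < min_len):
            continue
        # hat functions: value-at-knot parameterisation of a continuous
        # piecewise-linear function
        B = np.zeros((len(years), len(knots)))
        for j in range(len(knots)):
            B[:, j] = np.interp(years, knots,
                                np.eye(len(knots))[j])
        coef, _, _, _ = np.linalg.lstsq(B, log_rates, rcond=None)
        rss = float(np.sum((log_rates - B @ coef) ** 2))
        if rss < best[0]:
            best = (rss, combo)
    return best


# ---------------------------------------------------------------------------
# APC estimation
# ---------------------------------------------------------------------------

class TestLogLinearApc:
    def test_noiseless_exponential_analytic_apc(self):
        years = np.arange(1990, 2022)
        rates = 100.0 * np.exp(-0.02 * (years - 1990))
        est = fit_loglinear_apc(years, rates)
        assert est.apc == pytest.approx((np.exp(-0.02) - 1) * 100, abs=1e-10)
        assert est.slope == pytest.approx(-0.02, abs=1e-12)

    def test_constant_series_zero_apc_ci_spans_zero(self):
        years = np.arange(2000, 2011)
        est = fit_loglinear_apc(years, np.full(11, 7.5))
        assert est.apc == pytest.approx(0.0, abs=1e-10)
        assert est.ci_low <= 0.0 <= est.ci_high

    def test_matches_hand_newey_west_oracle(self):
        rng = np.random.default_rng(42)
        years = np.arange(1990, 2022, dtype=float)
        rates = 50.0 * np.exp(0.01 * (years - 1990) + rng.normal(0, 0.01, 32))
        est = fit_loglinear_apc(years, rates)
        beta, se = ols_newey_west(years, np.log(rates))
        assert est.slope == pytest.approx(beta[1], abs=1e-10)
        assert est.se == pytest.approx(se[1], abs=1e-10)
        assert est.apc == pytest.approx((np.exp(beta[1]) - 1) * 100, abs=1e-10)

    def test_domain_errors(self):
        with pytest.raises(DomainError):
            fit_loglinear_apc([2000, 2001, 2002], [1.0, 0.0, 2.0])
        with pytest.raises(CompletenessError):
            fit_loglinear_apc([2000, 2001], [1.0, 2.0])

    @given(st.floats(min_value=-0.2, max_value=0.2),
           st.floats(min_value=1e-4, max_value=0.1))
    @settings(max_examples=100, derandomize=True, deadline=None)
    def test_apc_slope_bijection(self, slope, se):
        est = ApcEstimate.from_slope(slope, se)
        assert np.log1p(est.apc / 100.0) == pytest.approx(slope, abs=1e-12)
        assert est.ci_low <= est.apc <= est.ci_high


# ---------------------------------------------------------------------------
# Segmented fitting
# ---------------------------------------------------------------------------

class TestSegmented:
    years = np.arange(1990, 2022)

    def test_noiseless_single_segment_selected(self):
        rates = 40.0 * np.exp(-0.015 * (self.years - 1990))
        fit = fit_segmented(self.years, rates)
        assert fit.n_segments == 1
        assert fit.breakpoints == ()
        apc = fit_loglinear_apc(self.years, rates)
        assert fit.segment_apcs[0].apc == pytest.approx(apc.apc, abs=1e-8)
        # AAPC of a single-exponential series equals its single-segment APC
        assert fit.aapc.apc == pytest.approx(apc.apc, abs=1e-12)

    def test_noiseless_two_segment_exact_recovery(self):
        lr = np.where(self.years <= 2005,
                      np.log(30.0) - 0.01 * (self.years - 1990),
                      np.log(30.0) - 0.01 * 15 + 0.02 * (self.years - 2005))
        fit = fit_segmented(self.years, np.exp(lr))
        assert fit.breakpoints == (2005,)
        np.testing.assert_allclose(fit.segment_slopes, (-0.01, 0.02), atol=1e-8)

    def test_rss_matches_hat_basis_brute_force(self):
        rng = np.random.default_rng(5)
        rates = 20.0 * np.exp(-0.01 * (self.years - 1990)
                              + rng.normal(0, 0.03, len(self.years)))
        lr = np.log(rates)
        est = SegmentedTrend(max_segments=3).fit(self.years, rates)
        # same RSS as the naive hat-basis search at the selected k
        rss_fit = float(np.sum((lr - est.result_.fitted_log_rates) ** 2))
        rss_oracle, _ = hat_basis_best_rss(self.years.astype(float), lr,
                                           est.n_segments_)
        assert rss_fit == pytest.approx(rss_oracle, abs=1e-9)

    def test_best_rss_monotone_in_segment_count(self):
        rng = np.random.default_rng(9)
        lr = np.log(15.0) - 0.01 * (self.years - 1990) + rng.normal(0, 0.05, 32)
        rss = [hat_basis_best_rss(self.years.astype(float), lr, k)[0]
               for k in (1, 2, 3)]
        assert rss[0] >= rss[1] - 1e-12 >= rss[2] - 2e-12

    def test_short_series_falls_back_to_one_segment(self):
        years = np.arange(2000, 2008)
        rates = 10.0 * np.exp(-0.01 * (years - 2000))
        with pytest.warns(UserWarning, match="single-segment"):
            fit = fit_segmented(years, rates)
        assert fit.n_segments == 1
        assert fit.note is not None

    def test_segment_cis_contain_point_apcs(self):
        rng = np.random.default_rng(3)
        lr = np.where(self.years <= 2004,
                      np.log(25.0) + 0.005 * (self.years - 1990),
                      np.log(25.0) + 0.005 * 14 - 0.02 * (self.years - 2004))
        fit = fit_segmented(self.years, np.exp(lr + rng.normal(0, 0.01, 32)))
        for seg in fit.segment_apcs:
            assert seg.ci_low <= seg.apc <= seg.ci_high


class TestAgeSpecificApc:
    def test_table_bookkeeping_and_sign_pattern(self):
        strata = []
        bands = ("70-74", "75-79", "80-84", "85-89", "90-94", "95+")
        for sex in ("Male", "Female"):
            for band in bands:
                slope = 0.005 if band == "95+" else -0.01
                strata.append(StratumSpec(sex=sex, age_band=band,
                                          rate_log_slopes=(slope,)))
        spec = SyntheticSpec(strata=tuple(strata), measure="DALYs",
                             noise_sigma=0.0, seed=0)
        panel, _ = generate_panel(spec)
        table = age_specific_apc(panel, measure="DALYs")
        assert len(table) == 2 * 6  # sexes x bands for one location
        pos = table[table["apc"] > 0]
        assert set(pos["age_band"]) == {"95+"}
        assert table.attrs["incomplete"] == []

    def test_shared_series_gives_identical_apcs(self, single_stratum_spec):
        spec = single_stratum_spec(noise_sigma=0.0, rate_log_slopes=(-0.013,))
        panel, _ = generate_panel(spec)
        table = age_specific_apc(panel, measure="Deaths")
        assert table["apc"].iloc[0] == pytest.approx((np.exp(-0.013) - 1) * 100,
                                                     abs=1e-10)
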