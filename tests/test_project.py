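"""Age-specific log-linear projection: exactness and aggregation."""

import numpy as np
import pytest

from elderburden.errors import AggregationError, DomainError
from elderburden.io_gbd import RATE_SCALE
from elderburden.project import (
    fit_loglinear,
    fit_rate_and_pop,
    project_aggregate,
    project_stratum,
)
from elderburden.synth import (
    StratumSpec,
    SyntheticSpec,
    default_global_spec,
    generate_panel,
)


def closed_form_ols(x, y):
    xm, ym = x.mean(), y.mean()
    slope = np.sum((x - xm) * (y - ym)) / np.sum((x - xm) ** 2)
    return ym - slope * xm, slope


class TestFits:
    def test_noiseless_slopes_exact(self, single_stratum_spec):
        spec = single_stratum_spec(rate_log_slopes=(np.log(0.98),),
                                   pop_log_growth=0.0, noise_sigma=0.0,
                                   years=(2000, 2021))
        panel, _ = generate_panel(spec)
        rate_fit, pop_fit = fit_rate_and_pop(
            panel, {"sex": "Female", "age_band": "70-74"}, window=(2000, 2021))
        assert rate_fit.slope == pytest.approx(np.log(0.98), abs=1e-12)
        assert pop_fit.slope == pytest.approx(0.0, abs=1e-12)

    def test_matches_closed_form_ols_oracle(self):
        rng = np.random.default_rng(8)
        years = np.arange(2000, 2022, dtype=float)
        vals = 30.0 * np.exp(-0.01 * (years - 2000) + rng.normal(0, 0.02, 22))
        fit = fit_loglinear(years, vals)
        intercept, slope = closed_form_ols(years, np.log(vals))
        assert fit.slope == pytest.approx(slope, abs=1e-10)
        assert fit.intercept == pytest.approx(intercept, abs=1e-8)

    def test_nonpositive_values_rejected(self):
        with pytest.raises(DomainError):
            fit_loglinear(np.arange(2000, 2010), np.r_[np.ones(9), 0.0])


class TestProjectStratum:
    def test_point_path_continues_exponential_and_bounds_collapse(
            self, single_stratum_spec):
        spec = single_stratum_spec(rate_baseline=12.0,
                                   rate_log_slopes=(-0.02,),
                                   pop_log_growth=0.03, noise_sigma=0.0,
                                   years=(2000, 2021))
        panel, _ = generate_panel(spec)
        fits = fit_rate_and_pop(panel, {"sex": "Female", "age_band": "70-74"},
                                window=(2000, 2021))
        path = project_stratum(*fits, horizon=(2022, 2044))
        expected = 12.0 * np.exp(-0.02 * (path["year"] - 2000))
        np.testing.assert_allclose(path["rate"], expected, rtol=1e-10)
        np.testing.assert_allclose(path["rate_lower"], path["rate"], rtol=1e-8)
        np.testing.assert_allclose(path["rate_upper"], path["rate"], rtol=1e-8)
        # counts = rate x pop / 1e5 to machine precision
        np.testing.assert_allclose(
            path["count"], path["rate"] * path["population"] / RATE_SCALE,
            rtol=1e-14)

    def test_rates_down_numbers_up_single_stratum(self, single_stratum_spec):
        spec = single_stratum_spec(rate_log_slopes=(np.log(0.99),),
                                   pop_log_growth=np.log(1.03),
                                   noise_sigma=0.0, years=(2000, 2021))
        panel, _ = generate_panel(spec)
        fits = fit_rate_and_pop(panel, {"sex": "Female", "age_band": "70-74"},
                                window=(2000, 2021))
        path = project_stratum(*fits, horizon=(2022, 2044))
        growth = path["count"].to_numpy()[1:] / path["count"].to_numpy()[:-1]
        np.testing.assert_allclose(growth, np.exp(np.log(0.99) + np.log(1.03)),
                                   rtol=1e-10)

    def test_fitted_anchor_differs_from_observed_under_noise(self):
        spec = default_global_spec(seed=5, noise_sigma=0.05)
        panel, _ = generate_panel(spec)
        fits = fit_rate_and_pop(panel, {"sex": "Female", "age_band": "70-74"},
                                window=(2000, 2021))
        fitted_2021 = float(fits[0].predict([2021])[0])
        observed_2021 = panel.get_series("Deaths", "Global", "Female", "70-74")
        observed_2021 = float(
            observed_2021.loc[observed_2021["year"] == 2021, "rate"].iloc[0])
        assert fitted_2021 == pytest.approx(
            np.exp(fits[0].intercept + fits[0].slope * 2021), rel=1e-12)
        assert fitted_2021 != pytest.approx(observed_2021, rel=1e-6)


class TestAggregate:
    def test_two_identical_strata_double_the_totals(self):
        strata = tuple(
            StratumSpec(sex=sex, age_band="70-74", rate_baseline=10.0,
                        rate_log_slopes=(-0.01,), pop_baseline=1e6,
                        pop_log_growth=0.02)
            for sex in ("Male", "Female"))
        spec = SyntheticSpec(strata=strata, noise_sigma=0.0, seed=0)
        panel, _ = generate_panel(spec)
        single = project_aggregate(panel, sexes=("Male",), bands=("70-74",))
        both = project_aggregate(panel, sexes=("Male", "Female"), bands=("70-74",))
        np.testing.assert_allclose(both.aggregate["count"],
                                   2 * single.aggregate["count"], rtol=1e-12)

    def test_aggregate_count_is_analytic_sum_of_exponential_paths(
            self, default_panel):
        panel, truth = default_panel
        res = project_aggregate(panel, window=(2000, 2021), horizon=(2022, 2044))
        agg = res.aggregate
        # per-stratum analytic path from each stratum's own fitted parameters
        years = agg["year"].to_numpy()
        total = np.zeros(len(years))
        for _, row in res.strata.groupby(["sex", "age_band"], observed=True):
            total += row.sort_values("year")["count"].to_numpy()
        np.testing.assert_allclose(agg["count"], total, rtol=1e-6)
        np.testing.assert_allclose(
            agg["rate"], agg["count"] / agg["population"] * RATE_SCALE, rtol=1e-12)

    def test_anchor_state_matches_fitted_values(self, default_panel):
        panel, _ = default_panel
        res = project_aggregate(panel)
        st = res.anchor_state
        assert st.year == 2021
        assert len(st.labels) == 12
        assert st.shares.sum() == pytest.approx(1.0, abs=1e-12)
        # fitted anchor deaths stay near the observed 2021 total
        observed = panel.data[panel.data["year"] == 2021]["count"].sum()
        assert st.deaths == pytest.approx(observed, rel=0.1)

    def test_unfittable_stratum_is_aggregate_error(self, default_panel):
        panel, _ = default_panel
        df = panel.data
        pruned = panel.__class__(
            df[~((df["sex"] == "Male") & (df["age_band"] == "95+")
                 & (df["year"] > 2010))].copy())
        with pytest.raises(AggregationError, match="Male/95"):
            project_aggregate(pruned)

    def test_independent_bounds_are_narrower_than_summed(self, default_panel):
        panel, _ = default_panel
        summed = project_aggregate(panel, bounds="sum").aggregate
        indep = project_aggregate(panel, bounds="independent").aggregate
        assert (indep["count_upper"] <= summed["count_upper"] + 1e-9).all()
        assert (indep["count_lower"] >= summed["count_lower"] - 1e-9).all()
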