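"""Synthetic GBD-shaped burden panels with known ground truth.

Each stratum's death (or DALY) rate follows a piecewise log-linear trend:
segments of constant log-scale annual change joined continuously at integer
breakpoint years, perturbed by multiplicative lognormal noise.  Populations
grow exponentially and are noiseless — in results-tool extracts the
population is only ever seen implicitly as count/rate, so it is treated as
a deterministic denominator.  Counts are rate x population / 100,000 and
inherit the rate noise.  Uncertainty bounds are symmetric relative bands
around the realised value, a deliberate simplification of draw-based
uncertainty intervals.

Seeding: one root seed; each stratum draws from a child generator derived
by stable hashing of its key, so adding or removing a stratum never
perturbs the noise of the others.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io_gbd import AGE_BANDS, GBD_COLUMNS, RATE_SCALE, BurdenPanel

__all__ = [
    "StratumSpec",
    "SyntheticSpec",
    "GroundTruth",
    "generate_panel",
    "write_gbd_csv",
    "default_global_spec",
]


@dataclass(frozen=True)
class StratumSpec:
    """Ground-truth parameters for one (sex, age band, location) stratum."""

    sex: str
    age_band: str
    location: str = "Global"
    rate_baseline: float = 10.0          # per 100,000 at the first year
    rate_breakpoints: tuple[int, ...] = ()
    rate_log_slopes: tuple[float, ...] = (-0.01,)
    pop_baseline: float = 1e6            # persons at the first year
    pop_log_growth: float = 0.02         # log-scale annual growth

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.location, self.sex, self.age_band)


@dataclass(frozen=True)
class SyntheticSpec:
    """Full specification of a synthetic burden panel.

    ``noise_sigma`` is the standard deviation of the Normal log-scale noise
    applied to rates; ``ui_halfwidth`` the relative half-width of the
    synthetic 95% bounds (bounds = value x (1 -/+ ui_halfwidth)).
    """

    strata: tuple[StratumSpec, ...]
    years: tuple[int, int] = (1990, 2021)
    measure: str = "Deaths"
    noise_sigma: float = 0.01
    ui_halfwidth: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sigma < 0:
            raise ValidationError("noise_sigma must be >= 0")
        if not 0 <= self.ui_halfwidth < 1:
            raise ValidationError("ui_halfwidth must be in [0, 1)")
        if self.years[1] <= self.years[0]:
            raise ValidationError("years must be an increasing (first, last) pair")
        if not self.strata:
            raise ValidationError("strata must be non-empty")
        y0, y1 = self.years
        for s in self.strata:
            if s.rate_baseline <= 0:
                raise ValidationError(f"rate_baseline must be > 0 in stratum {s.key}")
            if s.pop_baseline <= 0:
                raise ValidationError(f"pop_baseline must be > 0 in stratum {s.key}")
            bp = tuple(s.rate_breakpoints)
            if len(s.rate_log_slopes) != len(bp) + 1:
                raise ValidationError(
                    f"rate_log_slopes must have len(rate_breakpoints)+1 entries "
                    f"in stratum {s.key}"
                )
            knots = (y0, *bp, y1)
            if any(b2 - b1 < 5 for b1, b2 in zip(knots, knots[1:])):
                raise ValidationError(
                    f"breakpoints must lie strictly inside the year range with "
                    f">=5-year spacing in stratum {s.key}"
                )


@dataclass
class GroundTruth:
    """Noiseless paths and true trend parameters, keyed per stratum."""

    years: np.ndarray
    rates: dict = field(default_factory=dict)        # key -> noiseless rate path
    populations: dict = field(default_factory=dict)  # key -> population path
    counts: dict = field(default_factory=dict)       # key -> noiseless count path
    breakpoints: dict = field(default_factory=dict)  # key -> tuple of years
    segment_slopes: dict = field(default_factory=dict)
    segment_apcs: dict = field(default_factory=dict)


def _child_rng(seed: int, measure: str, stratum: StratumSpec) -> np.random.Generator:
    tag = "|".join((measure, *stratum.key))
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), zlib.crc32(tag.encode())])
    )


def _noiseless_log_rate(spec: SyntheticSpec, s: StratumSpec) -> np.ndarray:
    """Cumulative piecewise-linear log-rate path over the year range."""
    y0, y1 = spec.years
    years = np.arange(y0, y1 + 1)
    knots = (y0, *s.rate_breakpoints, y1)
    log_rate = np.empty_like(years, dtype=float)
    log_rate[0] = np.log(s.rate_baseline)
    # annual increments: the step leaving a breakpoint year already uses the
    # next segment's slope, so the kink sits exactly at the breakpoint
    for i in range(1, len(years)):
        t_prev = years[i - 1]
        seg = np.searchsorted(np.asarray(s.rate_breakpoints), t_prev, side="right")
        seg = min(seg, len(s.rate_log_slopes) - 1)
        log_rate[i] = log_rate[i - 1] + s.rate_log_slopes[seg]
    return log_rate


def generate_panel(spec: SyntheticSpec) -> tuple[BurdenPanel, GroundTruth]:
    """Realise a panel (and its ground truth) from a synthetic specification."""
    y0, y1 = spec.years
    years = np.arange(y0, y1 + 1)
    truth = GroundTruth(years=years)
    rows = []
    for s in spec.strata:
        rng = _child_rng(spec.seed, spec.measure, s)
        log_rate = _noiseless_log_rate(spec, s)
        clean_rate = np.exp(log_rate)
        eps = rng.normal(0.0, spec.noise_sigma, size=len(years)) if spec.noise_sigma > 0 else np.zeros(len(years))
        rate = clean_rate * np.exp(eps)
        pop = s.pop_baseline * np.exp(s.pop_log_growth * (years - y0))
        count = rate * pop / RATE_SCALE

        truth.rates[s.key] = clean_rate
        truth.populations[s.key] = pop
        truth.counts[s.key] = clean_rate * pop / RATE_SCALE
        truth.breakpoints[s.key] = tuple(s.rate_breakpoints)
        truth.segment_slopes[s.key] = tuple(s.rate_log_slopes)
        truth.segment_apcs[s.key] = tuple(
            (np.exp(b) - 1.0) * 100.0 for b in s.rate_log_slopes
        )

        rows.append(pd.DataFrame({
            "measure": spec.measure,
            "location": s.location,
            "sex": s.sex,
            "age_band": s.age_band,
            "year": years,
            "rate": rate,
            "rate_lower": rate * (1 - spec.ui_halfwidth),
            "rate_upper": rate * (1 + spec.ui_halfwidth),
            "count": count,
            "count_lower": count * (1 - spec.ui_halfwidth),
            "count_upper": count * (1 + spec.ui_halfwidth),
        }))
    data = pd.concat(rows, ignore_index=True)
    panel = BurdenPanel(data, source="synthetic", metadata={"seed": spec.seed})
    return panel, truth


def write_gbd_csv(panel: BurdenPanel, path) -> None:
    """Write a panel in the GBD results dialect (one Rate + one Number row
    per observation).  Values carry enough digits to round-trip to <1e-6
    relative error."""
    df = panel.data
    out = []
    for metric, val, lo, hi in (
        ("Rate", "rate", "rate_lower", "rate_upper"),
        ("Number", "count", "count_lower", "count_upper"),
    ):
        sub = df[df[val].notna()]
        if sub.empty:
            continue
        out.append(pd.DataFrame({
            "measure_name": sub["measure"],
            "location_name": sub["location"],
            "sex_name": sub["sex"],
            "age_name": sub["age_band"].map(lambda b: f"{b} years"),
            "cause_name": "Ischemic stroke",
            "rei_name": "High body-mass index",
            "metric_name": metric,
            "year": sub["year"],
            "val": sub[val],
            "upper": sub[hi],
            "lower": sub[lo],
        }))
    table = pd.concat(out, ignore_index=True)
    table.to_csv(path, index=False, float_format="%.10g", columns=GBD_COLUMNS)


# ---------------------------------------------------------------------------
# Default study conditions
# ---------------------------------------------------------------------------

# Global-scale defaults for attributable ischemic-stroke deaths in the 70+
# population: rate baselines (per 100,000, 1990) rise steeply with age;
# population baselines (persons, 1990) shrink with age but older bands grow
# faster, so the age structure shifts upward over time.
_BAND_RATE_1990 = {"70-74": 5.0, "75-79": 9.0, "80-84": 15.0,
                   "85-89": 23.0, "90-94": 33.0, "95+": 46.0}
_BAND_POP_1990 = {"70-74": 80e6, "75-79": 55e6, "80-84": 35e6,
                  "85-89": 17e6, "90-94": 6e6, "95+": 1.5e6}
_BAND_POP_GROWTH = {"70-74": 0.022, "75-79": 0.024, "80-84": 0.027,
                    "85-89": 0.030, "90-94": 0.033, "95+": 0.036}
_SEX_RATE_FACTOR = {"Male": 0.92, "Female": 1.08}
_SEX_POP_SHARE = {"Male": 0.45, "Female": 0.55}


def default_global_spec(
    seed: int = 0,
    noise_sigma: float = 0.01,
    measure: str = "Deaths",
    years: tuple[int, int] = (1990, 2021),
) -> SyntheticSpec:
    """Default 12-stratum (2 sexes x 6 age bands) global specification.

    Rate trends are two-segment declines (near-flat through 2004, then a
    sustained fall); population growth outpaces the rate decline in every
    band, so aggregate counts rise while aggregate rates fall.
    """
    strata = []
    for sex in ("Male", "Female"):
        for band in AGE_BANDS:
            strata.append(StratumSpec(
                sex=sex,
                age_band=band,
                location="Global",
                rate_baseline=_BAND_RATE_1990[band] * _SEX_RATE_FACTOR[sex],
                rate_breakpoints=(2004,),
                rate_log_slopes=(0.002, -0.014),
                pop_baseline=_BAND_POP_1990[band] * _SEX_POP_SHARE[sex],
                pop_log_growth=_BAND_POP_GROWTH[band],
            ))
    return SyntheticSpec(
        strata=tuple(strata), years=years, measure=measure,
        noise_sigma=noise_sigma, ui_halfwidth=0.8, seed=seed,
    )
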