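"""Shapley three-factor decomposition of change in death counts.

The death count in a demographic state is factorised as

    D = N x sum_a c_a m_a

where ``N`` is the total population aged >= 70 in the stratum, ``c`` the
vector of age-band population shares (summing to one) and ``m`` the vector
of age-specific death rates per person-year.  The change in deaths between
a base and a final state is attributed to the three factors — population
growth (N), population aging / age structure (c), and age-specific rate
change (m) — by the Shapley rule: each factor's contribution is the
average, over all 3! orders of switching factors from base to final, of
the marginal change in deaths when that factor switches.  By construction
the three contributions add up exactly to the total change and do not
depend on any ordering of the factors, and a factor identical in both
states contributes exactly zero.

The permutation enumeration is the implementation; the closed-form
three-factor Shapley expression is used only as an independent oracle in
the test suite.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .errors import CompletenessError, DomainError
from .io_gbd import AGE_BANDS, RATE_SCALE, BurdenPanel

__all__ = [
    "DemographicState",
    "DecompositionResult",
    "state_from_panel",
    "counterfactual_deaths",
    "shapley_decompose",
    "offset_fraction",
]

_FACTORS = ("N", "c", "m")


@dataclass(frozen=True)
class DemographicState:
    """Population size, age structure and age-specific rates at one year.

    ``rates`` are deaths per person-year (the per-100,000 rates divided by
    100,000).  ``shares`` must sum to 1.
    """

    year: int
    n_total: float
    shares: np.ndarray
    rates: np.ndarray
    labels: tuple[str, ...]

    def __post_init__(self):
        shares = np.asarray(self.shares, dtype=float)
        rates = np.asarray(self.rates, dtype=float)
        object.__setattr__(self, "shares", shares)
        object.__setattr__(self, "rates", rates)
        if shares.shape != rates.shape or shares.ndim != 1:
            raise DomainError("shares and rates must be 1-d arrays of equal length")
        if len(self.labels) != len(shares):
            raise DomainError("labels must match the share/rate vectors")
        if np.any(shares < -1e-12) or abs(shares.sum() - 1.0) > 1e-9:
            raise DomainError("shares must be non-negative and sum to 1")
        if np.any(rates < 0):
            raise DomainError("rates must be non-negative")
        if self.n_total < 0:
            raise DomainError("total population must be non-negative")

    @property
    def deaths(self) -> float:
        return float(self.n_total * np.dot(self.shares, self.rates))


@dataclass
class DecompositionResult:
    """Additive contributions of the three factors to a change in deaths."""

    delta_total: float
    contrib_growth: float
    contrib_aging: float
    contrib_rate: float
    baseline_mode: str = "descriptive"
    sex: str = "Both"
    years: tuple[int, int] = (0, 0)

    @property
    def contributions(self) -> dict[str, float]:
        return {
            "growth": self.contrib_growth,
            "aging": self.contrib_aging,
            "rate": self.contrib_rate,
        }


def counterfactual_deaths(n_total: float, shares, rates) -> float:
    """Deaths implied by mixing N, c and m from (possibly different) states:
    ``N x sum_a c_a m_a``."""
    shares = np.asarray(shares, dtype=float)
    rates = np.asarray(rates, dtype=float)
    if shares.shape != rates.shape:
        raise DomainError("share and rate vectors must have the same age-band support")
    return float(n_total * np.dot(shares, rates))


def state_from_panel(
    panel: BurdenPanel,
    year: int,
    sex: str = "Both",
    measure: str = "Deaths",
    location: str = "Global",
    structure: str = "age_sex",
) -> DemographicState:
    """Build a :class:`DemographicState` from a panel's rates and counts.

    For ``sex="Both"`` the default ``structure="age_sex"`` uses the twelve
    sex x age cells of the Male and Female rows, so the "aging" factor
    captures shifts in both age and sex composition.  ``structure="age"``
    instead uses pre-pooled Both-sex rows (six age cells).
    """
    df = panel.data
    df = df[(df["measure"] == measure) & (df["location"] == location)
            & (df["year"] == year)]
    if sex == "Both" and structure == "age_sex":
        cells = [(s, b) for s in ("Male", "Female") for b in AGE_BANDS]
        sel = df[df["sex"].isin(["Male", "Female"])]
    else:
        cells = [(sex, b) for b in AGE_BANDS]
        sel = df[df["sex"] == sex]

    pops, rates, labels = [], [], []
    for s, b in cells:
        row = sel[(sel["sex"] == s) & (sel["age_band"] == b)]
        if len(row) != 1 or row[["rate", "count"]].isna().any(axis=None):
            raise CompletenessError(
                f"missing rate/count for band {b!r} (sex {s!r}) in {year}"
            )
        rate = float(row["rate"].iloc[0])
        count = float(row["count"].iloc[0])
        if rate <= 0:
            raise DomainError(f"non-positive rate for band {b!r} in {year}")
        pops.append(count / rate * RATE_SCALE)
        rates.append(rate / RATE_SCALE)
        labels.append(f"{s}|{b}" if sex == "Both" and structure == "age_sex" else b)

    pops = np.asarray(pops)
    n_total = float(pops.sum())
    return DemographicState(
        year=int(year), n_total=n_total, shares=pops / n_total,
        rates=np.asarray(rates), labels=tuple(labels),
    )


def shapley_decompose(
    base: DemographicState,
    final: DemographicState,
    baseline_mode: str = "descriptive",
    sex: str = "Both",
) -> DecompositionResult:
    """Shapley decomposition of ``final.deaths - base.deaths`` into the
    population-growth, aging and rate-change factors (permutation
    enumeration over all 3! switching orders)."""
    if base.labels != final.labels:
        raise DomainError("states must share the same age-band support")

    values = {
        "N": (base.n_total, final.n_total),
        "c": (base.shares, final.shares),
        "m": (base.rates, final.rates),
    }

    def deaths(switched: frozenset[str]) -> float:
        n = values["N"][1] if "N" in switched else values["N"][0]
        c = values["c"][1] if "c" in switched else values["c"][0]
        m = values["m"][1] if "m" in switched else values["m"][0]
        return counterfactual_deaths(n, c, m)

    contrib = dict.fromkeys(_FACTORS, 0.0)
    perms = list(itertools.permutations(_FACTORS))
    for perm in perms:
        switched: frozenset[str] = frozenset()
        for f in perm:
            before = deaths(switched)
            switched = switched | {f}
            contrib[f] += deaths(switched) - before
    for f in _FACTORS:
        contrib[f] /= len(perms)

    return DecompositionResult(
        delta_total=final.deaths - base.deaths,
        contrib_growth=contrib["N"],
        contrib_aging=contrib["c"],
        contrib_rate=contrib["m"],
        baseline_mode=baseline_mode,
        sex=sex,
        years=(base.year, final.year),
    )


def offset_fraction(result: DecompositionResult) -> float:
    """Share (%) of the demographic-driven increase offset by rate decline:
    ``|contrib_rate| / (contrib_growth + contrib_aging) x 100``.

    Defined only when the demographic contribution is positive and the
    rate contribution is non-positive.
    """
    demographic = result.contrib_growth + result.contrib_aging
    if demographic <= 0:
        raise DomainError(
            "offset fraction undefined: demographic contribution is not positive"
        )
    if result.contrib_rate > 0:
        raise DomainError(
            "offset fraction undefined: rate contribution is positive, not offsetting"
        )
    return abs(result.contrib_rate) / demographic * 100.0
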