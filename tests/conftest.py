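import numpy as np
import pytest

from elderburden.synth import (
    StratumSpec,
    SyntheticSpec,
    default_global_spec,
    generate_panel,
)


@pytest.fixture(scope="session")
def default_panel():
    """The default 12-stratum global panel at a fixed seed, with truth."""
    panel, truth = generate_panel(default_global_spec(seed=7))
    return panel, truth


@pytest.fixture()
def single_stratum_spec():
    """Factory for one-stratum specs with overridable parameters."""

    def make(**kw):
        stratum_keys = {
            "sex", "age_band", "location", "rate_baseline", "rate_breakpoints",
            "rate_log_slopes", "pop_baseline", "pop_log_growth",
        }
        s_kw = {k: kw.pop(k) for k in list(kw) if k in stratum_keys}
        s_kw.setdefault("sex", "Female")
        s_kw.setdefault("age_band", "70-74")
        stratum = StratumSpec(**s_kw)
        kw.setdefault("noise_sigma", 0.0)
        kw.setdefault("seed", 0)
        return SyntheticSpec(strata=(stratum,), **kw)

    return make


def exp_series(years, baseline, slope):
    years = np.asarray(years)
    return baseline * np.exp(slope * (years - years[0]))
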