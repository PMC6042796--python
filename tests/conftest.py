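import numpy as np
import pytest

from merkelsim import default_config, run_simulation


@pytest.fixture(scope="session")
def wt_high_bundle():
    """Wildtype (with USI) run at the high default stimulus."""
    return run_simulation(default_config(genotype="wildtype_with_USI", magnitude="high"))


@pytest.fixture(scope="session")
def wt_low_bundle():
    return run_simulation(default_config(genotype="wildtype_with_USI", magnitude="low"))


@pytest.fixture(scope="session")
def no_usi_high_bundle():
    return run_simulation(default_config(genotype="wildtype_no_USI", magnitude="high"))


@pytest.fixture(scope="session")
def atoh1_high_bundle():
    return run_simulation(default_config(genotype="atoh1_cko", magnitude="high"))


def smoothed_iff_at(bundle, t):
    """Smoothed IFF interpolated at time t (flat extrapolation)."""
    sm = bundle.iff_smooth
    return float(np.interp(t, sm.time_s, sm.iff_hz))


def decline_fraction(bundle, t0=2.0, t1=5.0):
    """Fractional drop of the smoothed IFF between two hold times."""
    i0 = smoothed_iff_at(bundle, t0)
    i1 = smoothed_iff_at(bundle, t1)
    return (i0 - i1) / i0
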