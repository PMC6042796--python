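"""Parameter presets and packaged measurement tables.

All physiological constants (generator-kernel parameters per genotype, LIF
constants, skin material properties, stimulus and analysis defaults) are
stored in ``data/presets.yaml`` and loaded here.  Fitted time-constant and
peak/steady-ratio datasets used to derive the kernel parameters ship as CSV
fixtures in ``data/``.
"""

from __future__ import annotations

import functools
from importlib import resources

import pandas as pd
import yaml

_FIXTURES = {
    "tau_ri": "tau_ri_fits_ms.csv",
    "tau_si": "tau_si_fits_ms.csv",
    "k_si_peak": "k_si_peak_ratios.csv",
}


@functools.lru_cache(maxsize=1)
def load_presets() -> dict:
    """Return the full preset tree as a plain dict."""
    ref = resources.files("merkelsim.data").joinpath("presets.yaml")
    with ref.open("r") as fh:
        return yaml.safe_load(fh)


def generator_preset_names() -> list[str]:
    return list(load_presets()["generator"])


def load_fixture_table(name: str) -> pd.DataFrame:
    """Load a packaged measurement table.

    Parameters
    ----------
    name:
        One of ``"tau_ri"`` (fitted RI decay time constants, ms),
        ``"tau_si"`` (fitted SI decay time constants, ms) or
        ``"k_si_peak"`` (peak fraction of Merkel-cell potential traces).

    Returns
    -------
    DataFrame with columns ``fiber``, ``run``, ``value``.
    """
    try:
        fname = _FIXTURES[name]
    except KeyError:
        raise KeyError(
            f"unknown fixture {name!r}; choose from {sorted(_FIXTURES)}"
        ) from None
    ref = resources.files("merkelsim.data").joinpath(fname)
    with ref.open("r") as fh:
        return pd.read_csv(fh)
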