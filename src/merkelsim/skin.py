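"""One-dimensional quasi-linear viscoelastic (QLV) skin surrogate.

Converts the probe displacement into a compressive-stress history interior
to the skin.  The instantaneous (elastic) response follows a one-term Ogden
law for uniaxial compression of a slab of the given thickness; the
time-dependent response filters that elastic stress through a reduced
relaxation function

    G(t) = Ginf + G1*exp(-t/tau1) + G2*exp(-t/tau2),

a two-term Prony series with G(0) = G1 + G2 + Ginf = 1.  The convolution
``sigma(t) = int_0^t G(t-s) d(sigma_e)/ds ds`` is evaluated with recursive
exponential filters that are exact for piecewise-linear elastic stress,
so the scheme has no numerical-diffusion error on the uniform grid.

Compressive stress is represented positive.  An externally computed stress
history (e.g. from a finite-element skin model) can be substituted through
:func:`load_stress_csv`.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .presets import load_presets
from .stimulus import StimulusTrace

__all__ = [
    "SkinParams",
    "StressTrace",
    "skin_preset",
    "elastic_stress",
    "qlv_stress",
    "prony_relax",
    "load_stress_csv",
]


@dataclass(frozen=True)
class SkinParams:
    """Material parameters of the skin surrogate.

    ``mu_kpa`` (kPa) and ``alpha`` are the Ogden shear modulus and strain
    exponent; ``tau1_s < tau2_s`` are the Prony relaxation times with
    weights ``g1``, ``g2`` and long-time ratio ``ginf``.  ``stress_scale``
    is a dimensionless calibration factor mapping surrogate stress onto the
    scale expected by the generator-current coefficients (pA/Pa).
    """

    mu_kpa: float
    alpha: float
    tau1_s: float
    tau2_s: float
    g1: float
    g2: float
    ginf: float
    thickness_um: float
    stress_scale: float = 1.0

    def __post_init__(self) -> None:
        if min(self.mu_kpa, self.alpha, self.tau1_s, self.tau2_s) <= 0:
            raise ValueError("moduli and relaxation times must be positive")
        if not self.tau1_s < self.tau2_s:
            raise ValueError("need tau1_s < tau2_s")
        if self.thickness_um <= 0:
            raise ValueError("thickness_um must be positive")
        if min(self.g1, self.g2, self.ginf) < 0:
            raise ValueError("Prony weights must be non-negative")

    @property
    def prony_sum(self) -> float:
        return self.g1 + self.g2 + self.ginf

    def with_ginf(self, ginf: float) -> "SkinParams":
        """Return a copy at a new long-time ratio.

        The transient weights g1, g2 are rescaled proportionally so the
        instantaneous modulus stays normalised (g1+g2+ginf = 1).
        """
        if not 0 <= ginf < 1:
            raise ValueError("ginf must lie in [0, 1)")
        scale = (1.0 - ginf) / (self.g1 + self.g2)
        return replace(self, g1=self.g1 * scale, g2=self.g2 * scale, ginf=ginf)


def skin_preset(name: str = "default_380um") -> SkinParams:
    """Load a named skin preset (``default_380um`` or ``s4_418um``)."""
    presets = load_presets()["skin"]
    try:
        block = presets[name]
    except KeyError:
        raise KeyError(f"unknown skin preset {name!r}; choose from {sorted(presets)}") from None
    return SkinParams(**block)


@dataclass(frozen=True)
class StressTrace:
    """Compressive stress (Pa, positive) on the stimulus time grid."""

    time_s: np.ndarray
    stress_pa: np.ndarray

    @property
    def dt_s(self) -> float:
        return float(self.time_s[1] - self.time_s[0])

    def to_csv(self, path) -> None:
        pd.DataFrame({"time_s": self.time_s, "stress_pa": self.stress_pa}).to_csv(
            path, index=False
        )


def _check_uniform(time_s: np.ndarray) -> float:
    dt = np.diff(time_s)
    if dt.size == 0 or not np.allclose(dt, dt[0], rtol=1e-6, atol=0.0):
        raise ValueError("trace must be sampled on a uniform time grid")
    return float(dt[0])


def elastic_stress(displacement_um, params: SkinParams):
    """Instantaneous compressive stress (Pa) for a given indentation depth.

    One-term Ogden uniaxial compression with stretch
    ``lambda = 1 - d/thickness``:

        sigma_e = -(2*mu/alpha) * (lambda**(alpha-1) - lambda**(-alpha/2-1))

    sign-flipped to compressive-positive and multiplied by ``stress_scale``.
    """
    d = np.asarray(displacement_um, float)
    if np.any(d < 0):
        raise ValueError("displacement must be non-negative")
    if np.any(d >= params.thickness_um):
        raise ValueError("displacement reaches full skin compression")
    lam = 1.0 - d / params.thickness_um
    mu_pa = params.mu_kpa * 1e3
    sigma = -(2.0 * mu_pa / params.alpha) * (
        lam ** (params.alpha - 1.0) - lam ** (-params.alpha / 2.0 - 1.0)
    )
    return params.stress_scale * sigma


def qlv_stress(stimulus: StimulusTrace, params: SkinParams) -> StressTrace:
    """Viscoelastic stress response to a displacement stimulus.

    The elastic stress is treated as piecewise linear between grid points;
    each Prony branch ``h_i`` then obeys the exact per-step recursion

        h_i[k] = h_i[k-1]*E_i + g_i * (tau_i/dt) * (1 - E_i) * d_sigma_e[k]

    with ``E_i = exp(-dt/tau_i)``, implemented as a first-order IIR filter.
    The total stress ``ginf*sigma_e + sum_i h_i`` is clamped at zero to
    guard against interpolation undershoot.
    """
    dt = _check_uniform(stimulus.time_s)
    sig_e = elastic_stress(stimulus.displacement_um, params)
    out = prony_relax(sig_e, dt, params)
    return StressTrace(time_s=stimulus.time_s.copy(), stress_pa=out)


def prony_relax(sig_e: np.ndarray, dt: float, params: SkinParams) -> np.ndarray:
    """Filter an elastic-stress history through the reduced relaxation G(t).

    ``sig_e`` is piecewise linear between samples; a non-zero first sample
    is treated as a pre-existing step applied at t = 0.  Output is clamped
    at zero.
    """
    sig_e = np.asarray(sig_e, float)
    d_sig = np.diff(sig_e, prepend=0.0)
    d_sig[0] = 0.0
    out = params.ginf * sig_e.copy()
    k = np.arange(sig_e.size)
    for g, tau in ((params.g1, params.tau1_s), (params.g2, params.tau2_s)):
        if g == 0:
            continue
        e = np.exp(-dt / tau)
        coef = g * (tau / dt) * (1.0 - e)
        branch = lfilter([coef], [1.0, -e], d_sig)
        if sig_e[0] != 0.0:
            branch += g * sig_e[0] * e**k
        out += branch
    np.clip(out, 0.0, None, out=out)
    return out


def load_stress_csv(path, time_s: np.ndarray | None = None) -> StressTrace:
    """Read a two-column stress CSV (time_s, stress_pa).

    If ``time_s`` is given the trace is linearly resampled onto that grid;
    otherwise the file's own (uniform) grid is kept.  Time must be strictly
    increasing and stress non-negative.
    """
    df = pd.read_csv(path)
    cols = [c.strip().lower() for c in df.columns]
    df.columns = cols
    if not {"time_s", "stress_pa"} <= set(cols):
        raise ValueError("stress CSV needs columns time_s, stress_pa")
    t = df["time_s"].to_numpy(float)
    s = df["stress_pa"].to_numpy(float)
    if np.any(np.diff(t) <= 0):
        raise ValueError("time column must be strictly increasing")
    if np.any(s < 0):
        raise ValueError("stress must be non-negative (compressive positive)")
    if time_s is None:
        _check_uniform(t)
        return StressTrace(time_s=t, stress_pa=s)
    out = np.interp(time_s, t, s, left=s[0], right=s[-1])
    np.clip(out, 0.0, None, out=out)
    return StressTrace(time_s=np.asarray(time_s, float), stress_pa=out)
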