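"""Generator-current model of a single Merkel cell-neurite complex.

The receptor (generator) current produced by one complex is the convolution
of the time derivative of compressive skin stress with the sum of three
exponential kernels, one per current component:

* RI  — rapidly inactivating neurite current:      ``a * exp(-t/tau_RI)``
* SI  — slowly inactivating Merkel-cell current:
        ``b * (K_SI_peak * exp(-t/tau_SI) + K_SI_steady)``
* USI — ultra-slowly inactivating neurite current: ``c * exp(-t/tau_USI)``

so that a step increase in stress evokes an instantaneous current jump
proportional to the step, followed by exponential decay; the SI kernel does
not decay to zero but retains the fraction ``K_SI_steady`` of its jump
(``K_SI_peak + K_SI_steady = 1``).  The coefficients a, b, c (pA/Pa) set the
relative magnitudes of the three components.  The summed current uses zero
as its mathematical baseline and is clamped there whenever the convolution
goes negative.

Genotype presets select which components exist: the Atoh1 knockout lacks
Merkel cells, so its SI component is removed (b = 0) while RI and USI, both
positioned in the neurite, are retained.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .presets import load_presets
from .skin import StressTrace, _check_uniform

__all__ = [
    "GeneratorParams",
    "CurrentTrace",
    "generator_preset",
    "kernel_RI",
    "kernel_SI",
    "kernel_USI",
    "generator_current",
    "sweep_parameter",
]

GENOTYPES = (
    "wildtype_with_USI",
    "wildtype_no_USI_long_SI",
    "wildtype_no_USI",
    "atoh1_cko",
)


@dataclass(frozen=True)
class GeneratorParams:
    """Kernel parameters for one genotype.

    Time constants are in milliseconds, coefficients in pA/Pa.  A component
    is disabled by setting its coefficient (and time constant) to ``None``:
    ``b is None`` removes the SI current (Atoh1 knockout), ``c is None``
    removes the USI current.
    """

    tau_ri_ms: float
    a: float
    tau_si_ms: float | None = None
    k_si_peak: float | None = None
    k_si_steady: float | None = None
    b: float | None = None
    tau_usi_ms: float | None = None
    c: float | None = None
    genotype: str = "wildtype_with_USI"

    def __post_init__(self) -> None:
        if self.genotype not in GENOTYPES:
            raise ValueError(f"unknown genotype {self.genotype!r}")
        if self.tau_ri_ms <= 0:
            raise ValueError("tau_ri_ms must be positive")
        if self.a < 0:
            raise ValueError("coefficient a must be non-negative")
        if self.genotype == "atoh1_cko" and self.si_active:
            raise ValueError("atoh1_cko has no Merkel cells: SI must be disabled")
        if self.si_active:
            if self.tau_si_ms is None or self.tau_si_ms <= 0:
                raise ValueError("active SI needs a positive tau_si_ms")
            if self.k_si_peak is None or self.k_si_steady is None:
                raise ValueError("active SI needs both K fractions")
            if abs(self.k_si_peak + self.k_si_steady - 1.0) > 1e-9:
                raise ValueError("K_SI_peak + K_SI_steady must equal 1")
            if self.b < 0:
                raise ValueError("coefficient b must be non-negative")
        if self.usi_active:
            if self.tau_usi_ms is None or self.tau_usi_ms <= 0:
                raise ValueError("active USI needs a positive tau_usi_ms")
            if self.c < 0:
                raise ValueError("coefficient c must be non-negative")

    @property
    def si_active(self) -> bool:
        return self.b is not None

    @property
    def usi_active(self) -> bool:
        return self.c is not None

    def coefficient_sum(self) -> float:
        """Instantaneous pA/Pa response to a stress step: a + b + c."""
        return self.a + (self.b or 0.0) + (self.c or 0.0)


def generator_preset(name: str = "wildtype_with_USI") -> GeneratorParams:
    """Load a genotype preset by name."""
    presets = load_presets()["generator"]
    try:
        block = presets[name]
    except KeyError:
        raise KeyError(
            f"unknown generator preset {name!r}; choose from {sorted(presets)}"
        ) from None
    return GeneratorParams(
        tau_ri_ms=block["tau_ri_ms"],
        a=block["a_pa_per_pa"],
        tau_si_ms=block["tau_si_ms"],
        k_si_peak=block["k_si_peak"],
        k_si_steady=block["k_si_steady"],
        b=block["b_pa_per_pa"],
        tau_usi_ms=block["tau_usi_ms"],
        c=block["c_pa_per_pa"],
        genotype=name,
    )


def _t_since(t_since_s) -> np.ndarray:
    t = np.asarray(t_since_s, float)
    if np.any(t < 0):
        raise ValueError("kernel lag must be non-negative")
    return t


def kernel_RI(t_since_s, params: GeneratorParams):
    """RI kernel weight ``a * exp(-t/tau_RI)`` at lag ``t_since_s`` (s)."""
    t = _t_since(t_since_s)
    return params.a * np.exp(-t / (params.tau_ri_ms * 1e-3))


def kernel_SI(t_since_s, params: GeneratorParams):
    """SI kernel ``b*(K_peak*exp(-t/tau_SI) + K_steady)``; 0 if SI disabled.

    Note the kernel floor: it decays to ``b*K_SI_steady``, not to zero, which
    is what sustains the current through a static hold.
    """
    t = _t_since(t_since_s)
    if not params.si_active:
        return np.zeros_like(t) if t.ndim else 0.0
    return params.b * (
        params.k_si_peak * np.exp(-t / (params.tau_si_ms * 1e-3)) + params.k_si_steady
    )


def kernel_USI(t_since_s, params: GeneratorParams):
    """USI kernel ``c * exp(-t/tau_USI)``; 0 if USI disabled."""
    t = _t_since(t_since_s)
    if not params.usi_active:
        return np.zeros_like(t) if t.ndim else 0.0
    return params.c * np.exp(-t / (params.tau_usi_ms * 1e-3))


@dataclass(frozen=True)
class CurrentTrace:
    """Per-component and total generator current for one complex (pA)."""

    time_s: np.ndarray
    i_ri_pa: np.ndarray
    i_si_pa: np.ndarray
    i_usi_pa: np.ndarray
    i_total_pa: np.ndarray

    @property
    def dt_s(self) -> float:
        return float(self.time_s[1] - self.time_s[0])

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {
                "time_s": self.time_s,
                "I_RI_pA": self.i_ri_pa,
                "I_SI_pA": self.i_si_pa,
                "I_USI_pA": self.i_usi_pa,
                "I_total_pA": self.i_total_pa,
            }
        ).to_csv(path, index=False)


def _exp_component(d_sig: np.ndarray, coef: float, tau_s: float, dt: float) -> np.ndarray:
    """Convolve stress increments with ``coef * exp(-t/tau)``.

    Per-step recursion ``y_k = y_{k-1} * exp(-dt/tau) + coef * d_sig_k`` —
    exact when the stress history is a staircase of increments applied at
    the sample times.
    """
    e = np.exp(-dt / tau_s)
    return lfilter([coef], [1.0, -e], d_sig)


def generator_current(stress: StressTrace, params: GeneratorParams) -> CurrentTrace:
    """Generator current of one complex in response to a stress history.

    The convolution of each kernel with ``d(sigma)/dt`` is evaluated by
    treating the sampled stress as a staircase of per-step increments
    ``d_sigma_k`` and updating each exponential term recursively (O(n),
    exact for that discretisation).  The non-decaying SI floor integrates
    to ``b * K_SI_steady * sigma(t)`` because the stress starts at zero.
    The summed current is clamped at zero; components are reported
    unclamped.
    """
    dt = _check_uniform(stress.time_s)
    sig = np.asarray(stress.stress_pa, float)
    if np.any(~np.isfinite(sig)):
        raise ValueError("stress trace contains NaN or infinite values")
    d_sig = np.diff(sig, prepend=0.0)  # sigma[0] = 0 for a stimulus from rest

    i_ri = _exp_component(d_sig, params.a, params.tau_ri_ms * 1e-3, dt)
    if params.si_active:
        i_si = _exp_component(
            d_sig, params.b * params.k_si_peak, params.tau_si_ms * 1e-3, dt
        )
        i_si += params.b * params.k_si_steady * sig
    else:
        i_si = np.zeros_like(sig)
    if params.usi_active:
        i_usi = _exp_component(d_sig, params.c, params.tau_usi_ms * 1e-3, dt)
    else:
        i_usi = np.zeros_like(sig)

    total = np.clip(i_ri + i_si + i_usi, 0.0, None)
    return CurrentTrace(
        time_s=stress.time_s.copy(),
        i_ri_pa=i_ri,
        i_si_pa=i_si,
        i_usi_pa=i_usi,
        i_total_pa=total,
    )


_SWEEPABLE = ("tau_ri_ms", "tau_si_ms", "k_si_peak")


def sweep_parameter(
    name: str,
    values: Iterable[float],
    stress: StressTrace,
    base_params: GeneratorParams,
) -> list[CurrentTrace]:
    """Recompute the generator current across a one-parameter sweep.

    ``name`` is one of ``tau_ri_ms``, ``tau_si_ms`` or ``k_si_peak``; all
    other parameters stay at their base values.  Sweeping ``k_si_peak``
    co-updates ``k_si_steady = 1 - k_si_peak`` to preserve the unit sum.
    """
    if name not in _SWEEPABLE:
        raise ValueError(f"sweepable parameters are {_SWEEPABLE}")
    if name in ("tau_si_ms", "k_si_peak") and not base_params.si_active:
        raise ValueError("cannot sweep SI parameters of an SI-less genotype")
    out = []
    for v in values:
        if name == "k_si_peak":
            p = replace(base_params, k_si_peak=v, k_si_steady=1.0 - v)
        else:
            p = replace(base_params, **{name: v})
        out.append(generator_current(stress, p))
    return out
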