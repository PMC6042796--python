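"""Synthetic electrophysiology-style traces for testing the fitting layer.

Real patch-clamp recordings behind the packaged time-constant tables are
not distributable, so decaying traces with known ground truth are generated
here: a single exponential (optionally plus a constant offset) with additive
Gaussian noise, reproducible under a seed.
"""

from __future__ import annotations

import numpy as np

from .fitting import DecayTrace

__all__ = ["make_synthetic_decay_traces"]


def make_synthetic_decay_traces(
    n: int,
    true_tau_s: float,
    amplitude: float = 1.0,
    offset: float = 0.0,
    noise_sd: float = 0.0,
    duration_s: float | None = None,
    dt_s: float = 1e-4,
    seed: int = 0,
    modality: str = "voltage_clamp_current",
) -> list[DecayTrace]:
    """Generate ``n`` noisy exponential-decay traces with known parameters.

    Each trace is ``amplitude * exp(-t/true_tau_s) + offset`` over five time
    constants (unless ``duration_s`` overrides), sampled at ``dt_s``, with
    i.i.d. Gaussian noise of standard deviation ``noise_sd`` added.  The
    same seed always yields the same traces.
    """
    if n < 0:
        raise ValueError("n must be non-negative")
    if true_tau_s <= 0 or dt_s <= 0:
        raise ValueError("true_tau_s and dt_s must be positive")
    rng = np.random.default_rng(seed)
    duration = duration_s if duration_s is not None else 5.0 * true_tau_s
    t = np.arange(0.0, duration + dt_s / 2, dt_s)
    clean = amplitude * np.exp(-t / true_tau_s) + offset
    traces = []
    for _ in range(n):
        noise = rng.normal(0.0, noise_sd, t.size) if noise_sd > 0 else 0.0
        traces.append(DecayTrace(time_s=t.copy(), value=clean + noise, modality=modality))
    return traces
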