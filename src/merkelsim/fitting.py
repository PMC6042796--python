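"""Parameter derivation and fitting.

Two layers mirror how the model's parameters were obtained:

1. *Biologically derived* kernel parameters come from exponential-decay fits
   of electrophysiology-style traces: voltage-clamp current decays give the
   RI time constant (form ``y = a*exp(-x/tau)``), current-clamp Merkel-cell
   potential decays give the SI time constant and peak/steady fractions
   (form ``y = a*exp(-x/tau) + b``).
2. *Free* coefficients (a, b, c, in pA/Pa) are fitted in the context of the
   whole end organ: reference spike trains at two stimulus magnitudes are
   reduced to smoothed, log-sampled instantaneous firing frequencies, and
   Levenberg-Marquardt least squares drives the model's firing toward them
   (equivalently, maximises the coefficient of determination).  The final
   coefficients average the two per-magnitude fits.

The recordings behind the published coefficients are not distributable, so
the second layer is exercised against synthetic references produced by the
forward model itself (parameter recovery); user-supplied spike-time CSVs
slot in the same way.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy.optimize import curve_fit, least_squares

from .analysis import IFFTrace, compute_iff, log_sample, smooth_iff
from .end_organ import SpikeTrain
from .pipeline import RunConfig, run_simulation

__all__ = [
    "DecayTrace",
    "ExpFitResult",
    "FreeParamFit",
    "fit_exponential",
    "peak_steady_ratio",
    "summarize_table_fits",
    "fit_free_parameters",
]

_PENALTY = 1e3  # residual magnitude when a candidate model barely fires


@dataclass(frozen=True)
class DecayTrace:
    """A decaying electrophysiology-style trace on a uniform grid.

    ``modality`` records whether values are voltage-clamp currents (pA) or
    current-clamp membrane potentials (mV); the fitting code treats both
    identically.
    """

    time_s: np.ndarray
    value: np.ndarray
    modality: str = "voltage_clamp_current"

    def __post_init__(self) -> None:
        if self.modality not in ("voltage_clamp_current", "current_clamp_potential"):
            raise ValueError(f"unknown modality {self.modality!r}")
        if self.time_s.size != self.value.size:
            raise ValueError("time and value must have equal length")


@dataclass(frozen=True)
class ExpFitResult:
    """Result of a single exponential-decay fit."""

    tau_s: float
    amplitude: float
    offset: float
    r_squared: float
    form: str
    converged: bool = True
    message: str = ""


def _r_squared(y: np.ndarray, y_hat: np.ndarray) -> float:
    ss_res = float(np.sum((y - y_hat) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        return 1.0 if ss_res == 0 else 0.0
    return 1.0 - ss_res / ss_tot


def fit_exponential(trace: DecayTrace, form: str = "a_exp") -> ExpFitResult:
    """Fit a decaying exponential to the trace from its maximum onward.

    ``form="a_exp"`` fits ``y = a*exp(-x/tau)``; ``form="a_exp_plus_b"``
    adds a constant offset.  Nonlinear least squares; a fit that fails to
    converge, or converges to a non-positive time constant, is returned
    flagged rather than raised.
    """
    if form not in ("a_exp", "a_exp_plus_b"):
        raise ValueError("form must be 'a_exp' or 'a_exp_plus_b'")
    k0 = int(np.argmax(trace.value))
    x = trace.time_s[k0:] - trace.time_s[k0]
    y = trace.value[k0:].astype(float)
    if x.size < 5:
        raise ValueError("need at least 5 samples in the decaying segment")

    span = x[-1] - x[0]
    y0, y_end = y[0], float(np.mean(y[-max(1, y.size // 10):]))
    if form == "a_exp":
        model = lambda x, a, tau: a * np.exp(-x / tau)
        p0 = (y0, max(span / 5.0, 1e-6))
    else:
        model = lambda x, a, tau, b: a * np.exp(-x / tau) + b
        p0 = (y0 - y_end, max(span / 5.0, 1e-6), y_end)

    try:
        popt, _ = curve_fit(model, x, y, p0=p0, maxfev=10000)
    except RuntimeError as exc:
        return ExpFitResult(
            tau_s=np.nan, amplitude=np.nan, offset=np.nan, r_squared=0.0,
            form=form, converged=False, message=str(exc),
        )
    tau = float(popt[1])
    if tau <= 0:
        return ExpFitResult(
            tau_s=tau, amplitude=float(popt[0]),
            offset=float(popt[2]) if form == "a_exp_plus_b" else 0.0,
            r_squared=0.0, form=form, converged=False,
            message="rejected: non-positive time constant",
        )
    y_hat = model(x, *popt)
    return ExpFitResult(
        tau_s=tau,
        amplitude=float(popt[0]),
        offset=float(popt[2]) if form == "a_exp_plus_b" else 0.0,
        r_squared=_r_squared(y, y_hat),
        form=form,
    )


def peak_steady_ratio(trace: DecayTrace) -> tuple[float, float]:
    """Peak and steady fractions of a decaying trace.

    Steady value = mean of the final 10 % of the trace; peak = maximum.
    Returns ``(K_peak, K_steady)`` with ``K_steady = steady/peak`` and
    ``K_peak = 1 - K_steady``, the convention used for the SI kernel.
    """
    y = trace.value.astype(float)
    peak = float(y.max())
    if peak <= 0:
        raise ValueError("trace peak must be positive")
    tail = y[-max(1, y.size // 10):]
    k_steady = float(np.mean(tail)) / peak
    return 1.0 - k_steady, k_steady


def summarize_table_fits(
    results: Sequence[ExpFitResult] | Sequence[float],
) -> tuple[float, float]:
    """Arithmetic mean and sample standard deviation of fitted time constants.

    Accepts either `ExpFitResult` objects (their ``tau_s`` is used) or bare
    numbers; at least two entries are required for a sample deviation.
    """
    vals = np.asarray(
        [r.tau_s if isinstance(r, ExpFitResult) else float(r) for r in results],
        dtype=float,
    )
    if vals.size < 2:
        raise ValueError("need at least 2 fits to summarise")
    return float(vals.mean()), float(vals.std(ddof=1))


@dataclass(frozen=True)
class FreeParamFit:
    """Fitted generator coefficients and per-magnitude diagnostics."""

    a: float
    b: float
    c: float
    r_squared: dict[str, float]
    per_magnitude: dict[str, tuple[float, float, float]]


def _reference_curve(
    spikes: SpikeTrain, window: int, n_samples: int
) -> IFFTrace:
    return log_sample(smooth_iff(compute_iff(spikes), window), n_samples)


def _model_iff(config: RunConfig, abc: np.ndarray) -> IFFTrace:
    gen = config.generator
    if not (gen.si_active and gen.usi_active):
        raise ValueError("free-parameter fitting expects all three components active")
    a, b, c = (float(max(v, 0.0)) for v in abc)
    cfg = replace(config, generator=replace(gen, a=a, b=b, c=c))
    bundle = run_simulation(cfg)
    if len(bundle.spikes) < 2:
        return IFFTrace(time_s=np.empty(0), iff_hz=np.empty(0))
    return smooth_iff(bundle.iff, config.smooth_window)


def fit_free_parameters(
    references: dict[str, SpikeTrain],
    configs: dict[str, RunConfig],
    x0: tuple[float, float, float] | None = None,
) -> FreeParamFit:
    """Fit (a, b, c) so modelled firing matches reference spike trains.

    ``references`` maps magnitude labels (e.g. ``"low"``, ``"high"``) to
    recorded or synthetic spike trains; ``configs`` supplies the matching
    forward-model configuration per label.  For each label the reference is
    reduced to a smoothed, 50-point log-sampled IFF curve; the residual
    vector is the difference between that curve and the model's smoothed
    IFF linearly interpolated at the same times, minimised by
    Levenberg-Marquardt.  A candidate that produces fewer than two spikes
    contributes large penalty residuals.  The reported coefficients are the
    mean of the per-label fits.

    The default start point follows the design heuristic that a single
    complex should contribute a 10-20 pA peak (afferent currents up to
    ~250 pA shared by 17 complexes), apportioned like the preset ratios.
    """
    if set(references) != set(configs):
        raise ValueError("references and configs must share magnitude labels")
    if not references:
        raise ValueError("need at least one reference spike train")
    x0 = np.asarray(x0 if x0 is not None else (0.8, 0.3, 0.1), float)

    per: dict[str, tuple[float, float, float]] = {}
    r2: dict[str, float] = {}
    for label, spikes in references.items():
        config = configs[label]
        ref = _reference_curve(spikes, config.smooth_window, config.n_log_samples)

        def residuals(abc: np.ndarray) -> np.ndarray:
            model = _model_iff(config, abc)
            if len(model) < 2:
                return np.full(len(ref), _PENALTY)
            y_hat = np.interp(ref.time_s, model.time_s, model.iff_hz)
            return ref.iff_hz - y_hat

        # spike times are quantised to the simulation step, so the
        # finite-difference step must be coarse enough to move spikes
        sol = least_squares(
            residuals, x0, method="lm", diff_step=0.05, xtol=1e-10, ftol=1e-10
        )
        abc = tuple(float(max(v, 0.0)) for v in sol.x)
        per[label] = abc
        r2[label] = _r_squared(ref.iff_hz, ref.iff_hz - sol.fun)

    mean = np.mean(list(per.values()), axis=0)
    return FreeParamFit(
        a=float(mean[0]), b=float(mean[1]), c=float(mean[2]),
        r_squared=r2, per_magnitude=per,
    )
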