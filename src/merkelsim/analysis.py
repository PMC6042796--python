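"""Spike-train analysis: instantaneous firing frequency and phase rates.

The instantaneous firing frequency (IFF) is the reciprocal of each
inter-spike interval, timestamped at the latter spike of the pair.  For
fitting and display the IFF is smoothed with a short centred moving average
and, where the early response should carry extra weight, resampled at
logarithmically spaced time points.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .end_organ import SpikeTrain

__all__ = [
    "IFFTrace",
    "PhaseWindows",
    "compute_iff",
    "smooth_iff",
    "log_sample",
    "phase_rates",
]


@dataclass(frozen=True)
class IFFTrace:
    """Instantaneous firing frequencies (Hz) at the latter spike of each pair."""

    time_s: np.ndarray
    iff_hz: np.ndarray

    def __len__(self) -> int:
        return int(self.time_s.size)

    def to_csv(self, path) -> None:
        pd.DataFrame({"time_s": self.time_s, "iff_hz": self.iff_hz}).to_csv(
            path, index=False
        )


@dataclass(frozen=True)
class PhaseWindows:
    """Time windows (s) of the three stimulus phases.

    ramp = [0, ramp_end]; early hold = [ramp_end, ramp_end + 0.5 s];
    late hold = [2, 5] s by default.
    """

    ramp_end_s: float = 0.2
    early_hold_s: float = 0.5
    late_hold_start_s: float = 2.0
    late_hold_end_s: float = 5.0

    def __post_init__(self) -> None:
        if not 0 < self.ramp_end_s:
            raise ValueError("ramp_end_s must be positive")
        if self.early_hold_s <= 0:
            raise ValueError("early_hold_s must be positive")
        if not self.ramp_end_s + self.early_hold_s <= self.late_hold_start_s:
            raise ValueError("late hold must start after the early hold ends")
        if not self.late_hold_start_s < self.late_hold_end_s:
            raise ValueError("late hold window must have positive length")

    @property
    def windows(self) -> dict[str, tuple[float, float]]:
        return {
            "ramp": (0.0, self.ramp_end_s),
            "early_hold": (self.ramp_end_s, self.ramp_end_s + self.early_hold_s),
            "late_hold": (self.late_hold_start_s, self.late_hold_end_s),
        }


def compute_iff(spikes: SpikeTrain) -> IFFTrace:
    """Reciprocal inter-spike intervals; empty (with a warning) if < 2 spikes."""
    t = spikes.spike_times_s
    if t.size < 2:
        warnings.warn("fewer than 2 spikes: IFF trace is empty", stacklevel=2)
        return IFFTrace(time_s=np.empty(0), iff_hz=np.empty(0))
    isi = np.diff(t)
    return IFFTrace(time_s=t[1:].copy(), iff_hz=1.0 / isi)


def smooth_iff(iff: IFFTrace, window: int = 5) -> IFFTrace:
    """Centred moving average; edge windows shrink to the available samples."""
    if window < 1:
        raise ValueError("window must be >= 1")
    if len(iff) == 0 or window == 1:
        return IFFTrace(time_s=iff.time_s.copy(), iff_hz=iff.iff_hz.copy())
    sm = (
        pd.Series(iff.iff_hz)
        .rolling(window, center=True, min_periods=1)
        .mean()
        .to_numpy()
    )
    return IFFTrace(time_s=iff.time_s.copy(), iff_hz=sm)


def log_sample(iff: IFFTrace, n: int = 50) -> IFFTrace:
    """Resample an IFF trace at ``n`` log-spaced times.

    Sample times run logarithmically from the first to the last timestamp,
    weighting the early response more densely; each sample is the nearest
    existing (time, frequency) pair (selection, not interpolation), so every
    reported point occurs in the input trace.
    """
    if n < 2:
        raise ValueError("need at least 2 sample points")
    if len(iff) < 2:
        raise ValueError("need an IFF trace with at least 2 points")
    t0, t1 = iff.time_s[0], iff.time_s[-1]
    if t0 <= 0:
        raise ValueError("log sampling requires positive timestamps")
    t_new = np.geomspace(t0, t1, n)
    # nearest-neighbour lookup on the sorted timestamps
    idx = np.searchsorted(iff.time_s, t_new)
    idx = np.clip(idx, 1, len(iff) - 1)
    left_closer = (t_new - iff.time_s[idx - 1]) <= (iff.time_s[idx] - t_new)
    idx = idx - left_closer
    return IFFTrace(time_s=iff.time_s[idx], iff_hz=iff.iff_hz[idx])


def phase_rates(
    spikes: SpikeTrain, windows: PhaseWindows | None = None
) -> dict[str, float]:
    """Mean firing rate (Hz) in the ramp, early-hold and late-hold windows.

    The rate is the mean IFF of intervals ending inside the window; if the
    window contains spikes but no complete interval, the spike count divided
    by the window length is used; windows without spikes report 0.
    """
    windows = windows or PhaseWindows()
    t = spikes.spike_times_s
    iff = compute_iff(spikes) if t.size >= 2 else None
    out: dict[str, float] = {}
    for name, (w0, w1) in windows.windows.items():
        if iff is not None and len(iff):
            sel = (iff.time_s >= w0) & (iff.time_s <= w1)
            if sel.any():
                out[name] = float(iff.iff_hz[sel].mean())
                continue
        n_spikes = int(((t >= w0) & (t <= w1)).sum())
        out[name] = n_spikes / (w1 - w0) if n_spikes else 0.0
    return out
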