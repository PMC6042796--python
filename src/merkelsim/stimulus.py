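"""Ramp-and-hold displacement stimuli.

The model is displacement-clamped: the probe indents the skin along a ramp
whose velocity decreases linearly from ``2*D/Tr`` to zero (constant negative
acceleration), then holds at the final depth ``D``.  The displacement profile
over the ramp is therefore quadratic,

    d(t) = D * (2*t/Tr - (t/Tr)**2),   0 <= t <= Tr,

and ``d(t) = D`` for the remainder of the hold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["StimulusParams", "StimulusTrace", "make_ramp_and_hold"]


@dataclass(frozen=True)
class StimulusParams:
    """Parameters of a ramp-and-hold displacement command.

    Attributes
    ----------
    final_displacement_um:
        Indentation depth D at the end of the ramp (µm); must be positive.
    ramp_s:
        Ramp duration Tr (s).
    total_s:
        Total stimulus duration including the hold (s).
    dt_s:
        Sampling interval (s).
    magnitude_label:
        ``"low"`` or ``"high"``; bookkeeping only.
    """

    final_displacement_um: float
    ramp_s: float = 0.2
    total_s: float = 5.0
    dt_s: float = 1e-4
    magnitude_label: str = "high"

    def __post_init__(self) -> None:
        if self.final_displacement_um <= 0:
            raise ValueError("final_displacement_um must be positive")
        if not (0 < self.ramp_s < self.total_s):
            raise ValueError("need 0 < ramp_s < total_s")
        if self.dt_s <= 0:
            raise ValueError("dt_s must be positive")
        for name in ("ramp_s", "total_s"):
            dur = getattr(self, name)
            n = dur / self.dt_s
            if abs(n - round(n)) > 1e-6 * max(1.0, n):
                raise ValueError(f"dt_s must divide {name} to within one step")
        if self.magnitude_label not in ("low", "high"):
            raise ValueError("magnitude_label must be 'low' or 'high'")


@dataclass(frozen=True)
class StimulusTrace:
    """Sampled displacement command; ``time_s`` is a uniform grid from 0."""

    time_s: np.ndarray
    displacement_um: np.ndarray
    params: StimulusParams | None = field(default=None, compare=False)

    @property
    def dt_s(self) -> float:
        return float(self.time_s[1] - self.time_s[0])

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {"time_s": self.time_s, "displacement_um": self.displacement_um}
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "StimulusTrace":
        df = pd.read_csv(path)
        return cls(
            time_s=df["time_s"].to_numpy(float),
            displacement_um=df["displacement_um"].to_numpy(float),
        )


def ramp_profile(t: np.ndarray, depth_um: float, ramp_s: float) -> np.ndarray:
    """Quadratic (linearly decelerating) ramp evaluated at times ``t``."""
    u = np.clip(np.asarray(t, float) / ramp_s, 0.0, 1.0)
    return depth_um * (2.0 * u - u * u)


def make_ramp_and_hold(params: StimulusParams) -> StimulusTrace:
    """Build the displacement trace for a ramp-and-hold command.

    The ramp starts at velocity ``2*D/Tr`` and decelerates linearly to zero
    at ``t = Tr``; the hold keeps the displacement at ``D`` until
    ``total_s``.
    """
    n = int(round(params.total_s / params.dt_s)) + 1
    t = np.arange(n) * params.dt_s
    d = ramp_profile(t, params.final_displacement_um, params.ramp_s)
    return StimulusTrace(time_s=t, displacement_um=d, params=params)
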