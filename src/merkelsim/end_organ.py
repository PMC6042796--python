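"""Whole end-organ spike generation.

An SAI afferent's end organ is a set of heminodes, each fed by a cluster of
Merkel cell-neurite complexes (default architecture {8, 5, 3, 1}, i.e. 17
complexes in total).  All complexes see the same skin stress, so each
cluster's input current is the per-complex generator current times the
cluster size.  Every heminode is a leaky integrate-and-fire (LIF) unit

    C dV/dt = -V/R + I(t)

integrated by forward Euler from V = 0.  When any heminode reaches the
firing threshold it emits a spike into the shared axon and the potentials
of *all* heminodes are reset to baseline; a 1 ms absolute refractory period
then holds every potential at baseline.  The model is deterministic — no
spike-timing noise — so inter-spike intervals are regular.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .generator import CurrentTrace
from .presets import load_presets
from .skin import _check_uniform

__all__ = [
    "LIFParams",
    "EndOrganConfig",
    "SpikeTrain",
    "end_organ_preset",
    "heminode_currents",
    "simulate_spikes",
    "lif_rheobase_pa",
    "lif_first_spike_time_s",
]


@dataclass(frozen=True)
class LIFParams:
    """Leaky integrate-and-fire constants, shared by all heminodes.

    With R in GΩ, C in pF and I in pA, the products R*C (ms) and I*R (mV)
    come out in convenient units; the membrane time constant is R*C = 150 ms
    at the defaults.
    """

    r_gohm: float = 5.0
    c_pf: float = 30.0
    v_threshold_mv: float = 30.0
    refractory_ms: float = 1.0

    def __post_init__(self) -> None:
        if min(self.r_gohm, self.c_pf, self.v_threshold_mv, self.refractory_ms) <= 0:
            raise ValueError("all LIF parameters must be positive")

    @property
    def tau_s(self) -> float:
        return self.r_gohm * self.c_pf * 1e-3


@dataclass(frozen=True)
class EndOrganConfig:
    cluster_sizes: tuple[int, ...] = (8, 5, 3, 1)
    lif: LIFParams = field(default_factory=LIFParams)
    refractory_scope: str = "global"  # or "per_heminode"

    def __post_init__(self) -> None:
        if not self.cluster_sizes or any(s < 1 for s in self.cluster_sizes):
            raise ValueError("every cluster needs at least one complex")
        if self.refractory_scope not in ("global", "per_heminode"):
            raise ValueError("refractory_scope must be 'global' or 'per_heminode'")

    @property
    def n_complexes(self) -> int:
        return int(sum(self.cluster_sizes))


def end_organ_preset() -> EndOrganConfig:
    """Default end-organ architecture and LIF constants from the presets."""
    block = load_presets()["end_organ"]
    lif = block["lif"]
    return EndOrganConfig(
        cluster_sizes=tuple(block["cluster_sizes"]),
        lif=LIFParams(
            r_gohm=lif["r_gohm"],
            c_pf=lif["c_pf"],
            v_threshold_mv=lif["v_threshold_mv"],
            refractory_ms=lif["refractory_ms"],
        ),
        refractory_scope=block.get("refractory_scope", "global"),
    )


@dataclass(frozen=True)
class SpikeTrain:
    """Afferent spike times (s) and the heminode that fired each spike."""

    spike_times_s: np.ndarray
    heminode_ids: np.ndarray

    def __len__(self) -> int:
        return int(self.spike_times_s.size)

    def to_csv(self, path, include_heminode: bool = True) -> None:
        df = pd.DataFrame({"spike_time_s": self.spike_times_s})
        if include_heminode:
            df["heminode_id"] = self.heminode_ids
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "SpikeTrain":
        df = pd.read_csv(path, float_precision="round_trip")
        t = df["spike_time_s"].to_numpy(float)
        if np.any(np.diff(t) <= 0):
            raise ValueError("spike times must be strictly increasing")
        ids = (
            df["heminode_id"].to_numpy(int)
            if "heminode_id" in df.columns
            else np.zeros(t.size, dtype=int)
        )
        return cls(spike_times_s=t, heminode_ids=ids)


def heminode_currents(
    complex_current: CurrentTrace, config: EndOrganConfig
) -> list[np.ndarray]:
    """Total current entering each heminode: cluster size x per-complex current."""
    return [size * complex_current.i_total_pa for size in config.cluster_sizes]


def simulate_spikes(
    currents: list[np.ndarray],
    time_s: np.ndarray,
    config: EndOrganConfig,
) -> SpikeTrain:
    """Run the multi-heminode LIF stage over per-cluster current traces.

    Forward Euler at the trace time step, threshold checked after each step.
    At most one spike is emitted per step: if several heminodes cross
    threshold simultaneously, the one with the largest instantaneous input
    current wins (lowest index on exact ties).  Any spike resets all
    potentials to baseline; with the default global refractory scope no
    heminode may fire within the refractory period of any spike and all
    potentials are held at baseline during it.
    """
    dt = _check_uniform(time_s)
    n = time_s.size
    currents = [np.asarray(c, float) for c in currents]
    if len(currents) != len(config.cluster_sizes):
        raise ValueError("one current trace per cluster required")
    if any(c.size != n for c in currents):
        raise ValueError("cluster currents must share the simulation time grid")

    lif = config.lif
    tau = lif.tau_s
    r = lif.r_gohm
    v_th = lif.v_threshold_mv
    refrac = lif.refractory_ms * 1e-3
    per_heminode = config.refractory_scope == "per_heminode"

    i_mat = np.vstack(currents)  # (n_clusters, n_samples), pA
    v = np.zeros(len(currents))
    a = dt / tau
    spike_t: list[float] = []
    spike_id: list[int] = []
    last_spike = -np.inf
    last_spike_per = np.full(len(currents), -np.inf)

    for k in range(1, n):
        t = time_s[k]
        if per_heminode:
            blocked = (t - last_spike_per) < refrac
            v[blocked] = 0.0
            v += a * (r * i_mat[:, k - 1] - v)
            v[blocked] = 0.0
            eligible = (v >= v_th) & ~blocked
        else:
            if (t - last_spike) < refrac:
                v[:] = 0.0
                continue
            v += a * (r * i_mat[:, k - 1] - v)
            eligible = v >= v_th
        if eligible.any():
            idx = np.flatnonzero(eligible)
            winner = idx[np.argmax(i_mat[idx, k])]
            spike_t.append(float(t))
            spike_id.append(int(winner))
            v[:] = 0.0
            last_spike = t
            last_spike_per[winner] = t

    return SpikeTrain(
        spike_times_s=np.asarray(spike_t, float),
        heminode_ids=np.asarray(spike_id, int),
    )


def lif_rheobase_pa(lif: LIFParams) -> float:
    """Minimum constant current that ever reaches threshold: V_th / R."""
    return lif.v_threshold_mv / lif.r_gohm


def lif_first_spike_time_s(i_pa: float, lif: LIFParams) -> float:
    """Closed-form charging time to threshold under constant current.

    ``t = R*C * ln(I*R / (I*R - V_th))``; infinite below rheobase.
    """
    ir = i_pa * lif.r_gohm
    if ir <= lif.v_threshold_mv:
        return np.inf
    return lif.tau_s * np.log(ir / (ir - lif.v_threshold_mv))
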