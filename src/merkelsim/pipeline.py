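"""End-to-end simulation pipeline: stimulus -> skin -> generator -> spikes -> IFF.

`RunConfig` bundles the parameters of every stage; `run_simulation` executes
the stages in order and returns (optionally writes) all intermediate traces.
`run_s4_sweep` repeats the no-USI simulation across the biologically
observed range of the skin's long-time relaxation ratio Ginf, the
numerical experiment showing that skin viscoelasticity alone cannot
reproduce the slow adaptation of the sustained response.
"""

from __future__ import annotations

import json
import logging

import numpy as np
from dataclasses import dataclass, field, replace
from pathlib import Path

from . import __version__
from .analysis import IFFTrace, PhaseWindows, compute_iff, phase_rates, smooth_iff
from .end_organ import EndOrganConfig, SpikeTrain, end_organ_preset, heminode_currents, simulate_spikes
from .generator import CurrentTrace, GeneratorParams, generator_current, generator_preset
from .presets import load_presets
from .skin import SkinParams, StressTrace, load_stress_csv, qlv_stress, skin_preset
from .stimulus import StimulusParams, StimulusTrace, make_ramp_and_hold

__all__ = ["RunConfig", "SimulationBundle", "default_config", "run_simulation", "run_s4_sweep"]

logger = logging.getLogger("merkelsim")


@dataclass(frozen=True)
class RunConfig:
    """Complete configuration of one end-organ simulation."""

    stimulus: StimulusParams
    skin: SkinParams
    generator: GeneratorParams
    end_organ: EndOrganConfig
    smooth_window: int = 5
    n_log_samples: int = 50
    seed: int = 0
    stress_csv: str | None = None  # optional externally computed stress

    def phase_windows(self) -> PhaseWindows:
        blk = load_presets()["analysis"]
        end = min(blk["late_hold_end_s"], self.stimulus.total_s)
        start = blk["late_hold_start_s"]
        if start >= end:
            # stimulus shorter than the standard protocol: late hold is
            # whatever remains after the early hold
            start = self.stimulus.ramp_s + blk["early_hold_s"]
        return PhaseWindows(
            ramp_end_s=self.stimulus.ramp_s,
            early_hold_s=blk["early_hold_s"],
            late_hold_start_s=start,
            late_hold_end_s=end,
        )


def default_config(
    genotype: str = "wildtype_with_USI",
    magnitude: str = "high",
    skin_name: str = "default_380um",
    seed: int = 0,
    dt_s: float | None = None,
) -> RunConfig:
    """Assemble a RunConfig from the packaged presets.

    ``magnitude`` selects the high reference displacement or the low
    fraction of it used as the second stimulus level.
    """
    blk = load_presets()
    stim = blk["stimulus"]
    depth = stim["reference_displacement_um"]
    if magnitude == "low":
        depth *= stim["low_fraction"]
    elif magnitude != "high":
        raise ValueError("magnitude must be 'low' or 'high'")
    params = StimulusParams(
        final_displacement_um=depth,
        ramp_s=stim["ramp_s"],
        total_s=stim["total_s"],
        dt_s=dt_s if dt_s is not None else stim["dt_s"],
        magnitude_label=magnitude,
    )
    return RunConfig(
        stimulus=params,
        skin=skin_preset(skin_name),
        generator=generator_preset(genotype),
        end_organ=end_organ_preset(),
        smooth_window=blk["analysis"]["smooth_window"],
        n_log_samples=blk["analysis"]["n_log_samples"],
        seed=seed,
    )


@dataclass
class SimulationBundle:
    """All traces produced by one pipeline run."""

    config: RunConfig
    stimulus: StimulusTrace
    stress: StressTrace
    current: CurrentTrace
    spikes: SpikeTrain
    iff: IFFTrace
    iff_smooth: IFFTrace
    rates: dict[str, float]
    manifest: dict = field(default_factory=dict)

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.stimulus.to_csv(outdir / "stimulus.csv")
        self.stress.to_csv(outdir / "stress.csv")
        self.current.to_csv(outdir / "current.csv")
        self.spikes.to_csv(outdir / "spikes.csv")
        self.iff.to_csv(outdir / "iff.csv")
        self.iff_smooth.to_csv(outdir / "iff_smooth.csv")
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(self.manifest, fh, indent=2)


def _summ(name: str, x) -> None:
    if len(x):
        logger.info(
            "%s: n=%d min=%.4g max=%.4g", name, len(x), float(min(x)), float(max(x))
        )
    else:
        logger.info("%s: empty", name)


def run_simulation(config: RunConfig, outdir=None) -> SimulationBundle:
    """Execute the full pipeline for one configuration.

    Deterministic: the seed is recorded in the manifest but only synthetic
    trace generation elsewhere consumes randomness.
    """
    try:
        stim = make_ramp_and_hold(config.stimulus)
        _summ("stimulus displacement_um", stim.displacement_um)
    except Exception as exc:
        raise RuntimeError(f"stimulus stage failed: {exc}") from exc
    try:
        if config.stress_csv is not None:
            stress = load_stress_csv(config.stress_csv, time_s=stim.time_s)
        else:
            stress = qlv_stress(stim, config.skin)
        _summ("stress_pa", stress.stress_pa)
    except Exception as exc:
        raise RuntimeError(f"skin stage failed: {exc}") from exc
    try:
        current = generator_current(stress, config.generator)
        _summ("I_total_pA", current.i_total_pa)
    except Exception as exc:
        raise RuntimeError(f"generator stage failed: {exc}") from exc
    try:
        cluster = heminode_currents(current, config.end_organ)
        spikes = simulate_spikes(cluster, current.time_s, config.end_organ)
        _summ("spike_times_s", spikes.spike_times_s)
    except Exception as exc:
        raise RuntimeError(f"end-organ stage failed: {exc}") from exc
    try:
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            iff = compute_iff(spikes)
        iff_smooth = smooth_iff(iff, config.smooth_window)
        rates = phase_rates(spikes, config.phase_windows())
    except Exception as exc:
        raise RuntimeError(f"analysis stage failed: {exc}") from exc

    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "genotype": config.generator.genotype,
        "magnitude": config.stimulus.magnitude_label,
        "final_displacement_um": config.stimulus.final_displacement_um,
        "skin_ginf": config.skin.ginf,
        "n_spikes": len(spikes),
        "phase_rates_hz": rates,
    }
    bundle = SimulationBundle(
        config=config,
        stimulus=stim,
        stress=stress,
        current=current,
        spikes=spikes,
        iff=iff,
        iff_smooth=iff_smooth,
        rates=rates,
        manifest=manifest,
    )
    if outdir is not None:
        bundle.write(outdir)
    return bundle


def run_ri_only_normalized(config: RunConfig | None = None) -> SpikeTrain:
    """Knockout thought experiment: RI current alone, amplitude-matched.

    Runs the Atoh1-knockout model (USI + RI), then rescales the RI
    component so its peak equals the peak of the knockout's total current
    and feeds that RI-only current through the end organ.  Because the RI
    kernel decays within ~8 ms the rescaled current delivers far less
    charge, and the afferent fires only at stimulus onset — the argument
    that a rapidly inactivating current cannot carry the knockout response.
    """
    if config is None:
        config = default_config(genotype="atoh1_cko", magnitude="low")
    if config.generator.si_active:
        raise ValueError("RI-only experiment expects an SI-less (knockout) genotype")
    bundle = run_simulation(config)
    cur = bundle.current
    peak_ri = cur.i_ri_pa.max()
    if peak_ri <= 0:
        raise ValueError("RI current never rises above zero")
    scale = cur.i_total_pa.max() / peak_ri
    total = np.clip(cur.i_ri_pa * scale, 0.0, None)
    zeros = np.zeros_like(total)
    ri_only = CurrentTrace(
        time_s=cur.time_s.copy(),
        i_ri_pa=cur.i_ri_pa * scale,
        i_si_pa=zeros,
        i_usi_pa=zeros.copy(),
        i_total_pa=total,
    )
    cluster = heminode_currents(ri_only, config.end_organ)
    return simulate_spikes(cluster, ri_only.time_s, config.end_organ)


def run_s4_sweep(
    config: RunConfig | None = None, outdir=None
) -> list[SimulationBundle]:
    """No-USI simulations across the observed range of skin relaxation.

    Runs the thicker-skin preset at each Ginf value (maximum, median,
    minimum residual stress ratio) with the USI current disabled, so the
    hold-phase IFF decay reflects skin viscoelasticity alone.
    """
    blk = load_presets()
    ginf_values = blk["s4_ginf_values"]
    if config is None:
        config = default_config(
            genotype="wildtype_no_USI", magnitude="low", skin_name="s4_418um"
        )
    bundles = []
    for ginf in ginf_values:
        cfg = replace(config, skin=config.skin.with_ginf(ginf))
        sub = Path(outdir) / f"ginf_{ginf:.2f}" if outdir is not None else None
        b = run_simulation(cfg, outdir=sub)
        b.manifest["ginf"] = ginf
        bundles.append(b)
    return bundles
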