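# Versioned parameter presets for the Merkel cell-neurite complex model.
# All physiological constants live here, never hard-coded in logic.

stimulus:
  reference_displacement_um: 100.0   # "high" magnitude; "low" is low_fraction of it
  low_fraction: 0.75
  ramp_s: 0.2
  total_s: 5.0
  dt_s: 1.0e-4

skin:
  # Uniaxial Ogden + two-term Prony quasi-linear viscoelastic surrogate.
  # stress_scale calibrates surrogate stress so the wildtype per-complex
  # generator current peaks at ~15 pA (mid-range of the 10-20 pA design target).
  default_380um:
    mu_kpa: 1.3
    alpha: 7.9
    tau1_s: 0.08
    tau2_s: 1.2
    g1: 0.59
    g2: 0.10
    ginf: 0.31
    thickness_um: 380.0
    stress_scale: 0.069
  s4_418um:
    mu_kpa: 1.3
    alpha: 7.9
    tau1_s: 0.08
    tau2_s: 1.21
    g1: 0.557
    g2: 0.093
    ginf: 0.35
    thickness_um: 418.0
    stress_scale: 0.069

# Ginf values spanning the biologically observed relaxation range
# (maximum, median, minimum residual stress ratio).
s4_ginf_values: [0.81, 0.35, 0.10]

generator:
  wildtype_with_USI:
    tau_ri_ms: 8.0
    tau_si_ms: 200.0
    tau_usi_ms: 1744.6
    k_si_peak: 0.87
    k_si_steady: 0.13
    a_pa_per_pa: 0.74
    b_pa_per_pa: 0.24
    c_pa_per_pa: 0.07
  wildtype_no_USI_long_SI:
    tau_ri_ms: 8.3
    tau_si_ms: 569.8
    tau_usi_ms: null
    k_si_peak: 0.82
    k_si_steady: 0.18
    a_pa_per_pa: 0.99
    b_pa_per_pa: 0.26
    c_pa_per_pa: null
  wildtype_no_USI:
    tau_ri_ms: 8.0
    tau_si_ms: 200.0
    tau_usi_ms: null
    k_si_peak: 0.81
    k_si_steady: 0.19
    a_pa_per_pa: 0.74
    b_pa_per_pa: 0.36
    c_pa_per_pa: null
  atoh1_cko:
    tau_ri_ms: 8.0
    tau_si_ms: null
    tau_usi_ms: 1744.6
    k_si_peak: null
    k_si_steady: null
    a_pa_per_pa: 0.74
    b_pa_per_pa: null
    c_pa_per_pa: 0.07

end_organ:
  cluster_sizes: [8, 5, 3, 1]
  lif:
    r_gohm: 5.0
    c_pf: 30.0
    v_threshold_mv: 30.0
    refractory_ms: 1.0
  refractory_scope: global   # or per_heminode

analysis:
  smooth_window: 5
  n_log_samples: 50
  early_hold_s: 0.5          # early hold = [ramp end, ramp end + this]
  late_hold_start_s: 2.0
  late_hold_end_s: 5.0
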