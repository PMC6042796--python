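# Methods

This note records the model as implemented, the parameter choices that
matter, the numerical schemes, and what the packaged tests do and do not
demonstrate.

## Model structure and assumptions

The pipeline is strictly feed-forward: displacement → interior compressive
stress → per-complex generator current → per-cluster heminode current →
spikes → instantaneous firing frequency (IFF).  Three assumptions shape
everything downstream:

* **Linearity of transduction.** The generator current is a linear
  time-invariant functional of the stress history: a convolution of dσ/dt
  with a sum of decaying exponential kernels.  A step increase in stress
  evokes an instantaneous current jump proportional to the step, followed
  by exponential decay; superposition carries the stimulus history forward.
  Ion-channel gating, synaptic transfer from Merkel cell to neurite, and
  downstream conductances are all absorbed into the kernels.
* **Identical complexes.** All 17 complexes see the same stress and
  produce the same current; a cluster's heminode input is simply the
  per-complex current times the cluster size ({8, 5, 3, 1}).
* **Determinism.** Spike-timing noise is deliberately absent, so
  inter-spike intervals are regular; the model targets mean firing
  patterns, not interval variability.

The total current uses zero as its mathematical baseline and is clamped
there when the convolution goes negative (components are reported
unclamped; the clamp applies to the sum).

## Parameters

| parameter | value | units | origin |
|---|---|---|---|
| τ_RI | 8 (sweep 1–15) | ms | mean of 44 exponential fits to voltage-clamp current decays (packaged table) |
| τ_SI | 200 (sweep 50–350) | ms | printed mean of 12 fits to Merkel-cell potential decays (packaged table) |
| τ_USI | 1744.6 | ms | model-fit around the ~1.7 s literature value |
| K_SI_peak / K_SI_steady | 0.87 / 0.13 | — | peak/steady fractions of Merkel-cell traces, constrained to sum to 1 |
| a, b, c | 0.74, 0.24, 0.07 | pA/Pa | whole-end-organ fit (see below); knockout preset sets b absent |
| R, C, V_th, refractory | 5, 30, 30, 1 | GΩ, pF, mV, ms | standard LIF constants for this end organ |
| μ, α | 1.3, 7.9 | kPa, — | Ogden uniaxial law for mouse skin |
| G₁, G₂, G_∞, τ₁, τ₂ | 0.59, 0.10, 0.31, 0.08 s, 1.2 s | — | two-term Prony relaxation, 380 µm skin |
| thick-skin preset | G_∞ = 0.35, τ₂ = 1.21 s, 418 µm | — | used for the relaxation sweep G_∞ ∈ {0.81, 0.35, 0.10} |

Notes on the packaged tables: the 44 RI time constants average 7.63 ms,
which rounds to the 8 ms used for τ_RI.  The 12 SI time constants have an
arithmetic mean of ≈160 ms, not the printed 200 ms that the τ_SI preset
uses; the discrepancy is inherited from the source data's own summary and
no test or reported number is anchored to the 200 ms being the arithmetic
mean.  The relaxation-sweep preset does not specify transient Prony
weights, so `SkinParams.with_ginf` rescales G₁ and G₂ proportionally to
keep G₁+G₂+G_∞ = 1.

## The skin surrogate and its calibration

The full finite-element skin model is replaced by a one-dimensional
surrogate: Ogden elastic stress of the compressed slab filtered through
the Prony relaxation function.  Its fidelity claim is limited to the
*shape* of interior stress over time (ramp rise, then viscoelastic decay
toward the G_∞ plateau); it has no spatial fields, contact mechanics, or
tip-size effects.  Because the absolute stress scale of the surrogate
cannot match the finite-element model that the pA/Pa coefficients
presuppose, a single dimensionless factor `stress_scale = 0.069`
calibrates it: chosen once so the wildtype per-complex current peaks at
15 pA under the reference stimulus, the midpoint of the 10–20 pA design
window (typical whole-afferent currents of ~250 pA shared by 17
complexes).  Users substituting true finite-element stress output via
`load_stress_csv` bypass the surrogate and its calibration entirely.

## Stimulus magnitudes

The reference (high) stimulus indents 100 µm of the 380 µm skin over a
0.2 s decelerating ramp and holds to 5 s, sampled at 0.1 ms.  The low
magnitude is 75 % of the reference.  Both are config values.  The 75 %
fraction is a deliberate design choice: the Ogden law is strongly convex,
so a half-depth indentation produces only ~37 % of the stress, which at
the 10–20 pA calibration leaves every genotype silent during the hold.
At 75 % the low stimulus behaves like the weaker of two levels used in
SAI experiments — wildtype firing persists into the late hold, the
knockout truncates near 0.8 s, and the amplitude-matched RI-only current
(below) elicits exactly one spike.

## Numerical schemes

* **QLV convolution.** Elastic stress is piecewise linear between samples;
  each Prony branch uses the exact per-step recursion
  h[k] = h[k−1]·e^(−Δt/τ) + g·(τ/Δt)(1−e^(−Δt/τ))·Δσ_e, implemented as a
  first-order IIR filter (O(n), no quadrature error for that
  interpolation).  A non-zero initial elastic stress is treated as a
  pre-existing step so an ideal step input reproduces G(t) exactly.
* **Generator convolution.** Stress is treated as a staircase of
  per-sample increments Δσ_k (matching the step-construction reading of
  the model); each exponential term updates as
  y[k] = y[k−1]·e^(−Δt/τ) + coef·Δσ_k, exact for that discretisation,
  and the non-decaying SI floor integrates to b·K_SI_steady·σ(t) because
  the stimulus starts from rest.  The tests verify equality with a direct
  O(n²) discrete convolution to < 10⁻⁶ and < 0.1 % peak-current drift
  under Δt halving/doubling.
* **LIF integration.** Forward Euler at the trace Δt with the threshold
  checked after each step; at most one spike per step, ties broken by the
  largest instantaneous input current, then by lowest cluster index.  The
  refractory period is global — all heminodes share one axon, so no spike
  may follow another within 1 ms regardless of origin, and potentials are
  held at baseline throughout it (a per-heminode scope is available as a
  config toggle).  Euler introduces an O(Δt) period bias (~0.03 % at
  0.1 ms against the closed-form charging time); spike times are
  reproducible bit-for-bit given a config.
* **Exponential fitting.** Decay fits run from the trace maximum onward
  via nonlinear least squares; non-convergent or non-positive-τ fits are
  returned flagged, never silently accepted.  The steady-state window for
  peak/steady ratios is the final 10 % of the trace.
* **Free-parameter fitting.** References (recorded or synthetic spike
  trains at two magnitudes) are reduced to IFF → 5-point moving average →
  50 log-spaced samples; log sampling *selects* the nearest existing
  sample rather than interpolating, so each reference point is a real
  (time, rate) pair.  Levenberg–Marquardt minimises the residuals between
  reference samples and the model's smoothed IFF interpolated at the same
  times (equivalent to maximising R² for a fixed reference variance).
  Because spike times are quantised to the simulation step, the
  finite-difference step is set to 5 % of each parameter; candidates that
  produce fewer than two spikes receive large penalty residuals.  The two
  per-magnitude fits are averaged.

## The knockout RI-only experiment

To show that a rapidly inactivating current alone cannot carry the
knockout response, `run_ri_only_normalized` rescales the knockout's RI
component so its *peak* matches the peak of the knockout's USI+RI current
and feeds it through the end organ.  The amplitude-matched RI current
delivers far less charge (it decays within ~8 ms of each stress
increment), and at the default low stimulus the afferent emits exactly
one spike at onset.

## What the synthetic data does and does not show

Synthetic decay traces are single exponentials (± offset) with i.i.d.
Gaussian noise — adequate for validating estimator correctness and bias
(exact recovery without noise; < 10 % mean bias at 10 % amplitude noise
over 100 seeded replicates), but free of the baseline drift, stimulus
artefacts, and correlated noise of real patch-clamp recordings.
Likewise, the free-parameter recovery study fits references generated by
the forward model itself: it demonstrates that the pipeline is a
well-posed estimator of (a, b, c) under the model's own assumptions, not
that those values are correct for any particular animal.  Refitting to
real data requires user-supplied spike-time CSVs via `fit-endorgan`.

## Problem sizes

Default simulations use Δt = 0.1 ms over 5 s (50 001 samples).  The
convolution-oracle comparisons run on 1 s traces; the O(n²) oracle uses
Δt = 1 ms (1 001 samples) and the QLV quadrature oracle checks 40 output
times of a Δt = 0.1 ms trace.  The recovery studies use 100 noisy traces
of 401 samples and two full-pipeline LM fits (~25–60 forward simulations).

## Known limitations

* No spatial skin mechanics; the surrogate cannot reproduce absolute
  stress magnitudes or indenter-geometry effects.
* No spike-timing noise, so simulated inter-spike intervals are far more
  regular than recorded SAI trains.
* All complexes are identical; chains, heterogeneous sensitivities, and
  architectural remodelling are out of scope.
* The mechanistic origin of the USI kernel is deliberately agnostic — it
  is a phenomenological current, not an ion-channel model.
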