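import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from merkelsim.generator import (
    GeneratorParams,
    generator_current,
    generator_preset,
    kernel_RI,
    kernel_SI,
    kernel_USI,
    sweep_parameter,
)
from merkelsim.skin import StressTrace, qlv_stress, skin_preset
from merkelsim.stimulus import StimulusParams, make_ramp_and_hold


@pytest.fixture(scope="module")
def wt():
    return generator_preset("wildtype_with_USI")


@pytest.fixture(scope="module")
def cko():
    return generator_preset("atoh1_cko")


def step_stress(step_pa, t_step_s=0.0, total_s=1.0, dt=1e-3):
    t = np.arange(0.0, total_s + dt / 2, dt)
    s = np.where(t >= t_step_s, step_pa, 0.0)
    return StressTrace(time_s=t, stress_pa=s)


class TestKernels:
    def test_ri_kernel_values(self, wt):
        assert kernel_RI(0.0, wt) == pytest.approx(0.74)
        assert kernel_RI(8e-3, wt) == pytest.approx(0.74 / np.e)
        assert kernel_RI(80e-3, wt) < 1e-4 * 0.74

    def test_si_kernel_floor(self, wt):
        # the SI kernel never decays to zero: its floor is b*K_SI_steady
        assert kernel_SI(0.0, wt) == pytest.approx(wt.b)  # K's sum to 1
        assert kernel_SI(1e3, wt) == pytest.approx(0.24 * 0.13)
        assert kernel_SI(1e3, wt) == pytest.approx(0.0312)

    def test_usi_kernel_values(self, wt):
        assert kernel_USI(0.0, wt) == pytest.approx(0.07)
        assert kernel_USI(1.7446, wt) == pytest.approx(0.07 / np.e)

    def test_disabled_components_are_zero(self, cko):
        assert kernel_SI(0.1, cko) == 0.0
        no_usi = generator_preset("wildtype_no_USI")
        assert kernel_USI(0.1, no_usi) == 0.0

    def test_negative_lag_rejected(self, wt):
        with pytest.raises(ValueError):
            kernel_RI(-1e-3, wt)


class TestPresets:
    def test_wildtype_row(self, wt):
        assert (wt.tau_ri_ms, wt.tau_si_ms, wt.tau_usi_ms) == (8.0, 200.0, 1744.6)
        assert (wt.k_si_peak, wt.k_si_steady) == (0.87, 0.13)
        assert (wt.a, wt.b, wt.c) == (0.74, 0.24, 0.07)

    def test_k_fractions_sum_to_one(self):
        for name in ("wildtype_with_USI", "wildtype_no_USI_long_SI", "wildtype_no_USI"):
            p = generator_preset(name)
            assert p.k_si_peak + p.k_si_steady == pytest.approx(1.0)

    def test_knockout_has_no_si(self, cko):
        assert not cko.si_active
        assert cko.usi_active

    def test_invalid_k_sum_rejected(self):
        with pytest.raises(ValueError, match="equal 1"):
            GeneratorParams(
                tau_ri_ms=8.0, a=0.74, tau_si_ms=200.0,
                k_si_peak=0.9, k_si_steady=0.2, b=0.24,
            )


class TestStepResponse:
    def test_instantaneous_jump_is_coefficient_sum(self, wt):
        trace = generator_current(step_stress(10.0, t_step_s=0.1), wt)
        k = int(round(0.1 / 1e-3))
        assert trace.i_total_pa[k] == pytest.approx(10.5)  # (a+b+c)*10

    def test_decay_matches_analytic_kernels(self, wt):
        """One second after a 10 Pa step the components equal the kernels at lag."""
        trace = generator_current(step_stress(10.0, t_step_s=0.1, total_s=1.5), wt)
        k = int(round(1.1 / 1e-3))
        assert trace.i_ri_pa[k] == pytest.approx(10 * 0.74 * np.exp(-1.0 / 8e-3), abs=1e-12)
        assert trace.i_si_pa[k] == pytest.approx(
            10 * 0.24 * (0.87 * np.exp(-5.0) + 0.13), rel=1e-9
        )
        assert trace.i_usi_pa[k] == pytest.approx(
            10 * 0.07 * np.exp(-1.0 / 1.7446), rel=1e-9
        )
        assert trace.i_total_pa[k] == pytest.approx(0.72, abs=5e-3)

    def test_step_decrease_drops_current_immediately(self, wt):
        t = np.arange(0.0, 1.0, 1e-3)
        sig = np.full(t.size, 50.0)
        sig[0] = 0.0
        sig[t >= 0.5] = 49.0
        trace = generator_current(StressTrace(time_s=t, stress_pa=sig), wt)
        k = int(round(0.5 / 1e-3))
        drop = trace.i_total_pa[k - 1] - trace.i_total_pa[k]
        # immediate decrease ~ (a+b+c)*|d_sigma| (plus one step of kernel decay),
        # then the slower decay resumes
        assert drop == pytest.approx(wt.coefficient_sum() * 1.0, rel=0.01)
        after = np.abs(np.diff(trace.i_total_pa[k : k + 50]))
        assert np.all(after < drop / 10)

    def test_constant_hold_asymptote_is_si_floor(self, wt):
        """With stress clamped at S, current settles at b*K_SI_steady*S (+USI tail)."""
        trace = generator_current(step_stress(100.0, total_s=30.0, dt=1e-2), wt)
        expected = 0.24 * 0.13 * 100.0
        assert trace.i_total_pa[-1] == pytest.approx(expected, rel=0.01)


def _oracle_convolution(stress, params):
    """Direct double-loop discrete convolution of the kernel sum with d(sigma)."""
    t = stress.time_s
    d_sig = np.diff(stress.stress_pa, prepend=0.0)
    n = t.size
    out = np.zeros(n)
    for i in range(n):
        lag = t[i] - t[: i + 1]
        k = kernel_RI(lag, params) + kernel_SI(lag, params) + kernel_USI(lag, params)
        out[i] = np.dot(k, d_sig[: i + 1])
    return np.clip(out, 0.0, None)


def test_recursive_filter_matches_bruteforce_oracle(wt):
    """O(n) recursive updates equal the O(n^2) discrete convolution."""
    stim = make_ramp_and_hold(
        StimulusParams(final_displacement_um=100.0, ramp_s=0.2, total_s=1.0, dt_s=1e-3)
    )
    stress = qlv_stress(stim, skin_preset("default_380um"))
    fast = generator_current(stress, wt).i_total_pa
    slow = _oracle_convolution(stress, wt)
    assert np.max(np.abs(fast - slow)) / slow.max() < 1e-6


@settings(deadline=None, max_examples=20, derandomize=True)
@given(k=st.floats(0.0, 20.0))
def test_linearity_in_stress(k):
    """Superposition: scaling the stress scales every component linearly."""
    wt = generator_preset("wildtype_with_USI")
    t = np.arange(0.0, 0.5, 1e-3)
    base = 30.0 * np.sin(2 * np.pi * t) ** 2
    base[0] = 0.0
    a = generator_current(StressTrace(time_s=t, stress_pa=base), wt)
    b = generator_current(StressTrace(time_s=t, stress_pa=k * base), wt)
    np.testing.assert_allclose(b.i_ri_pa, k * a.i_ri_pa, rtol=1e-9, atol=1e-12)
    np.testing.assert_allclose(b.i_si_pa, k * a.i_si_pa, rtol=1e-9, atol=1e-12)
    np.testing.assert_allclose(b.i_total_pa, k * a.i_total_pa, rtol=1e-9, atol=1e-12)


class TestGenotypes:
    def test_knockout_is_ri_plus_usi(self, cko):
        stim = make_ramp_and_hold(
            StimulusParams(final_displacement_um=100.0, ramp_s=0.2, total_s=1.0, dt_s=1e-3)
        )
        stress = qlv_stress(stim, skin_preset("default_380um"))
        tr = generator_current(stress, cko)
        assert np.all(tr.i_si_pa == 0.0)
        np.testing.assert_allclose(
            tr.i_total_pa, np.clip(tr.i_ri_pa + tr.i_usi_pa, 0, None)
        )

    def test_component_peak_ordering_at_default(self, wt_high_bundle):
        """SI and USI currents both exceed the RI current in peak amplitude."""
        cur = wt_high_bundle.current
        assert cur.i_si_pa.max() > cur.i_ri_pa.max()
        assert cur.i_usi_pa.max() > cur.i_ri_pa.max()


class TestSweeps:
    @pytest.fixture(scope="class")
    @staticmethod
    def stress():
        stim = make_ramp_and_hold(
            StimulusParams(final_displacement_um=75.0, ramp_s=0.2, total_s=2.0, dt_s=1e-4)
        )
        return qlv_stress(stim, skin_preset("default_380um"))

    def test_tau_ri_sweep_raises_ramp_peak(self, stress, wt):
        traces = sweep_parameter("tau_ri_ms", [1.0, 8.0, 15.0], stress, wt)
        ramp = stress.time_s <= 0.2
        peaks = [tr.i_total_pa[ramp].max() for tr in traces]
        assert peaks[0] < peaks[1] < peaks[2]

    def test_tau_si_sweep_raises_early_hold(self, stress, wt):
        traces = sweep_parameter("tau_si_ms", [50.0, 200.0, 350.0], stress, wt)
        early = (stress.time_s >= 0.2) & (stress.time_s <= 0.7)
        peaks = [tr.i_total_pa[early].max() for tr in traces]
        assert peaks[0] < peaks[1] < peaks[2]

    def test_k_si_peak_identity_sweep(self, stress, wt):
        (trace,) = sweep_parameter("k_si_peak", [wt.k_si_peak], stress, wt)
        base = generator_current(stress, wt)
        np.testing.assert_array_equal(trace.i_total_pa, base.i_total_pa)

    def test_k_si_peak_sweep_coupdates_steady(self, stress, wt):
        traces = sweep_parameter("k_si_peak", [0.5, 0.87, 0.95], stress, wt)
        # higher steady fraction (lower peak fraction) -> more late current
        late = stress.time_s >= 1.5
        lates = [tr.i_total_pa[late].mean() for tr in traces]
        assert lates[0] > lates[1] > lates[2]

    def test_unknown_parameter_rejected(self, stress, wt):
        with pytest.raises(ValueError):
            sweep_parameter("a", [0.5], stress, wt)


def test_dt_convergence(wt):
    """Peak current changes < 0.1 % when the time step is halved or doubled."""
    peaks = {}
    for dt in (2e-4, 1e-4, 5e-5):
        stim = make_ramp_and_hold(
            StimulusParams(final_displacement_um=100.0, ramp_s=0.2, total_s=1.0, dt_s=dt)
        )
        stress = qlv_stress(stim, skin_preset("default_380um"))
        peaks[dt] = generator_current(stress, wt).i_total_pa.max()
    ref = peaks[1e-4]
    assert abs(peaks[2e-4] - ref) / ref < 1e-3
    assert abs(peaks[5e-5] - ref) / ref < 1e-3


def test_nan_stress_rejected(wt):
    t = np.arange(0.0, 0.1, 1e-3)
    s = np.zeros_like(t)
    s[5] = np.nan
    with pytest.raises(ValueError, match="NaN"):
        generator_current(StressTrace(time_s=t, stress_pa=s), wt)
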