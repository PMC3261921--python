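import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ipsense.model_core import (ap_duration_baseline, boltzmann_steady_state,
                                detect_spikes, resting_potential, simulate)
from ipsense.params import (AP_MODELS, GateKinetics, InvalidParameterError,
                            MembraneParams, NoiseParams, NoisePopulation,
                            sodium_template, standard_noise)

from conftest import MAP_DT


class TestBoltzmann:
    def test_midpoint(self):
        g = GateKinetics(-30.0, 5.0, 1.0)
        assert boltzmann_steady_state(-30.0, g) == pytest.approx(0.5)

    def test_efold_point(self):
        # V_half + k*ln(9) puts an activation gate at 0.9 exactly
        g = GateKinetics(-30.0, 5.0, 1.0)
        V = -30.0 + 5.0 * math.log(9.0)
        assert boltzmann_steady_state(V, g) == pytest.approx(0.9, abs=1e-12)

    def test_against_high_precision_oracle(self):
        # frozen from sympy: (1/(1+exp(-(-50-(-30))/5))).evalf(30)
        expected = 0.0179862099620915
        g = GateKinetics(-30.0, 5.0, 1.0)
        assert boltzmann_steady_state(-50.0, g) == pytest.approx(
            expected, rel=1e-12)

    def test_zero_slope_rejected(self):
        with pytest.raises(InvalidParameterError):
            GateKinetics(-30.0, 0.0, 1.0)

    @given(vh=st.floats(-90, -10), k=st.floats(0.5, 20),
           v1=st.floats(-120, 40), v2=st.floats(-120, 40))
    @settings(max_examples=200, deadline=None)
    def test_monotone_and_bounded(self, vh, k, v1, v2):
        g = GateKinetics(vh, k, 1.0)
        y1 = boltzmann_steady_state(v1, g)
        y2 = boltzmann_steady_state(v2, g)
        assert 0.0 <= y1 <= 1.0
        if v1 < v2:
            assert y1 <= y2

    @given(vh=st.floats(-90, -10), k=st.floats(0.5, 20),
           v1=st.floats(-120, 40), v2=st.floats(-120, 40))
    @settings(max_examples=100, deadline=None)
    def test_inactivation_sign_decreasing(self, vh, k, v1, v2):
        g = GateKinetics(vh, -k, 1.0)
        if v1 < v2:
            assert (boltzmann_steady_state(v1, g)
                    >= boltzmann_steady_state(v2, g))


class TestSimulate:
    def test_rest_no_spikes(self, membrane):
        tr = simulate(membrane, None, I=0.0, duration=1000.0)
        assert tr.n_spikes == 0
        # relaxed to a fixed point near E_L
        assert abs(tr.V[-1] - tr.V[-2]) < 1e-6
        assert abs(tr.V[-1] - membrane.E_L) < 5.0

    def test_rheobase_stable_under_dt_refinement(self, membrane):
        from ipsense.sensitivity import measure_threshold
        th1 = measure_threshold(membrane, None, dt=0.02, resolution=5e-4)
        th2 = measure_threshold(membrane, None, dt=0.005, resolution=5e-4)
        assert th2 > 0
        assert abs(th1 - th2) / th2 < 0.01

    def test_inward_subthreshold_x_raises_rate(self, membrane):
        I = 0.5  # above the bare rheobase (~0.16)
        base = simulate(membrane, None, I=I, duration=2000.0,
                        record_every=100)
        x = sodium_template(gmax=2e-3)
        boosted = simulate(membrane, x, I=I, duration=2000.0,
                           record_every=100)
        assert boosted.n_spikes > base.n_spikes

    def test_gating_variables_confined(self, membrane):
        x = sodium_template(-50.0, 2.0, gmax=0.05)
        tr = simulate(membrane, x, I=2.0, duration=500.0)
        for name, series in tr.gates.items():
            assert np.all(series >= 0.0), name
            assert np.all(series <= 1.0), name

    def test_dt_halving_frequency_convergence(self, membrane, std_template):
        x = std_template.with_gmax(1e-3)
        rates = []
        for dt in (0.02, 0.01):
            tr = simulate(membrane, x, I=1.0, duration=3000.0, dt=dt,
                          record_every=1000)
            st_ = tr.spike_times
            rates.append((len(st_) - 1) / (st_[-1] - st_[0]) * 1000.0)
        assert abs(rates[0] - rates[1]) / rates[1] < 0.01

    def test_noise_reproducible_given_seed(self, membrane):
        noise = standard_noise(seed=7)
        a = simulate(membrane, None, I=0.0, noise=noise, duration=2000.0,
                     record_every=50)
        b = simulate(membrane, None, I=0.0, noise=noise, duration=2000.0,
                     record_every=50)
        assert np.array_equal(a.V, b.V)
        assert np.array_equal(a.spike_times, b.spike_times)

    def test_noise_free_reproducible_bitwise(self, membrane):
        a = simulate(membrane, None, I=0.3, duration=1000.0, record_every=10)
        b = simulate(membrane, None, I=0.3, duration=1000.0, record_every=10)
        assert np.array_equal(a.V, b.V)

    def test_vanishing_noise_matches_noise_free(self, membrane):
        """E_syn at E_L and g_unit -> 0: mean V within 0.5 mV of silent run."""
        quiet = NoiseParams(
            excitatory=NoisePopulation(100, 10, 10.0, 1e-9, 3.0,
                                       membrane.E_L),
            inhibitory=NoisePopulation(50, 10, 10.0, 1e-9, 10.0,
                                       membrane.E_L),
            seed=3)
        a = simulate(membrane, None, I=0.0, noise=quiet, duration=2000.0,
                     record_every=10)
        b = simulate(membrane, None, I=0.0, duration=2000.0, record_every=10)
        assert abs(a.V[500:].mean() - b.V[500:].mean()) < 0.5

    def test_current_conservation_at_rest(self, membrane):
        """At the numerical fixed point all membrane currents cancel."""
        from ipsense.iaf_theory import steady_state_current
        v_rest = resting_potential(membrane)
        assert abs(steady_state_current(membrane, v_rest)[0]) < 1e-4


class TestDetectSpikes:
    def test_subthreshold_series_empty(self):
        t = np.arange(0, 100, 0.01)
        V = -65.0 + 2.0 * np.sin(t / 5.0)
        times, durs = detect_spikes(t, V)
        assert len(times) == 0

    def test_three_synthetic_aps(self):
        dt = 0.01
        t = np.arange(0, 300, dt)
        V = np.full_like(t, -65.0)
        centers = [50.0, 150.0, 250.0]
        for c in centers:
            mask = np.abs(t - c) < 1.0
            V[mask] = -65.0 + 100.0 * np.cos((t[mask] - c) * np.pi / 2.0)
        times, durs = detect_spikes(t, V)
        assert len(times) == 3
        for found, c in zip(times, centers):
            assert abs(found - c) < 1.0

    def test_ap_duration_in_band(self, membrane):
        d = ap_duration_baseline(membrane, None, I=1.0, dt=MAP_DT)
        assert 1.8 * 0.75 <= d <= 1.8 * 1.25

    def test_refractory_guard(self):
        # two crossings 1 ms apart collapse into one event
        t = np.arange(0, 10, 0.01)
        V = np.full_like(t, -65.0)
        for c in (4.0, 5.0):
            V[np.abs(t - c) < 0.3] = 20.0
        times, _ = detect_spikes(t, V)
        assert len(times) == 1
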