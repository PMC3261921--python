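import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ipsense.iaf_theory import (IAFParams, NoSpikeError,
                                barrier_threshold_potential,
                                effective_threshold, iaf_inverse_gain,
                                iaf_isi_duration, iaf_threshold_current,
                                iaf_trajectory, iso_sensitivity_lines,
                                s_E_analytic, s_theta_analytic, standard_iaf)
from ipsense.params import (GateKinetics, InvalidParameterError,
                            MembraneParams, XConductance, potassium_template,
                            sodium_template)

from conftest import MAP_DT


class TestSThetaAnalytic:
    def test_zero_activation_at_threshold(self, iaf):
        x = sodium_template(-10.0, 1.0)  # x_inf(V_theta) ~ 0
        assert abs(s_theta_analytic(x, iaf)) < 1e-6

    def test_zero_driving_force(self, iaf):
        x = sodium_template(-70.0, 2.0).replace(E_X=iaf.V_theta)
        assert s_theta_analytic(x, iaf) == pytest.approx(0.0, abs=1e-12)

    def test_inward_subthreshold_negative(self, iaf):
        assert s_theta_analytic(sodium_template(-70.0, 2.0), iaf) < -50.0

    def test_depends_only_on_activation_at_threshold(self, iaf):
        """Different (V_half, k) with equal x_inf(V_theta) share S_theta."""
        a = GateKinetics(-62.0, 4.0, 5.0)
        level = 1.0 / (1.0 + math.exp(-(iaf.V_theta - a.V_half) / a.k))
        k2 = 8.0
        vh2 = iaf.V_theta - k2 * math.log(level / (1.0 - level))
        b = GateKinetics(vh2, k2, 5.0)
        xa = XConductance(0.0, 1, a, 55.0)
        xb = XConductance(0.0, 1, b, 55.0)
        assert s_theta_analytic(xa, iaf) == pytest.approx(
            s_theta_analytic(xb, iaf), rel=1e-9)


class TestIsoLines:
    def test_half_level_vertical_intercept(self):
        lines = iso_sensitivity_lines([0.5], V_theta=-50.0, p=1)
        intercept, slope = lines[0.5]
        assert intercept == -50.0
        assert slope == pytest.approx(0.0, abs=1e-12)

    def test_closed_form_point(self):
        lines = iso_sensitivity_lines([0.9], V_theta=-50.0, p=1)
        intercept, slope = lines[0.9]
        assert intercept + slope * 5.0 == pytest.approx(
            -50.0 - 5.0 * math.log(9.0))

    @given(c1=st.floats(0.05, 0.95), c2=st.floats(0.05, 0.95),
           p=st.sampled_from([1, 2, 3, 4]))
    @settings(max_examples=50, deadline=None)
    def test_all_lines_meet_at_central_point(self, c1, c2, p):
        lines = iso_sensitivity_lines([c1, c2], V_theta=-52.0, p=p)
        for c in (c1, c2):
            intercept, slope = lines[c]
            assert intercept + slope * 0.0 == pytest.approx(-52.0)

    def test_invalid_level(self):
        with pytest.raises(InvalidParameterError):
            iso_sensitivity_lines([1.5], V_theta=-50.0)


class TestEffectiveThreshold:
    def test_phase_min_matches_barrier(self, membrane, iaf):
        assert iaf.V_theta == pytest.approx(
            barrier_threshold_potential(membrane), abs=1.0)

    def test_ordering_invariant(self, iaf):
        assert iaf.V_r < iaf.V_theta <= iaf.V_s

    def test_dt_refinement_stability(self, membrane):
        a = effective_threshold(membrane, None, dt=0.02)
        b = effective_threshold(membrane, None, dt=0.01)
        assert abs(a.V_theta - b.V_theta) < 0.5

    def test_probe_gmax_stability(self, membrane, iaf):
        weak = sodium_template(gmax=1e-5)
        est = effective_threshold(membrane, weak, dt=MAP_DT)
        assert abs(est.V_theta - iaf.V_theta) < 1.0

    def test_invalid_ordering_rejected(self, membrane):
        with pytest.raises(InvalidParameterError):
            IAFParams(V_r=-50.0, V_s=-55.0, V_theta=-52.0,
                      membrane=membrane)


class TestTrajectories:
    def test_pure_leak_matches_closed_form(self, iaf):
        """gmax = 0: ISI equals the textbook leaky charging time."""
        mem = iaf.membrane
        x = sodium_template(gmax=0.0)
        I = 2.5
        T = iaf_isi_duration("threshold", x, iaf, I)
        tau_m = mem.capacitance / mem.g_L
        Vinf = mem.E_L + I / mem.g_L
        expected = tau_m * math.log((Vinf - iaf.V_r) / (Vinf - iaf.V_s))
        assert T == pytest.approx(expected, rel=1e-3)

    def test_below_threshold_no_spike(self, iaf):
        x = sodium_template(gmax=0.0)
        with pytest.raises(NoSpikeError):
            iaf_trajectory("threshold", x, iaf, I=0.0)

    def test_isi_decreasing_in_current(self, iaf):
        x = sodium_template(gmax=2e-3)
        Is = np.linspace(2.2, 6.0, 6)
        Ts = [iaf_isi_duration("prepost", x, iaf, I) for I in Is]
        assert all(np.isfinite(Ts))
        assert np.all(np.diff(Ts) < 0)

    def test_trajectory_spans_reset_to_threshold(self, iaf):
        t, V, xs, T, f = iaf_trajectory("prepost",
                                        sodium_template(gmax=1e-3), iaf, 3.0)
        assert V[0] == pytest.approx(iaf.V_r)
        assert V[-1] >= iaf.V_s - 0.5
        assert f == pytest.approx(1000.0 / T)

    def test_spike_duration_bias_small_below_100hz(self, iaf):
        """|1/T - 1/(T+T_spike)| stays a small relative error up to 100 Hz."""
        T = 10.0  # ms -> 100 Hz
        rel = abs(1.0 / T - 1.0 / (T + iaf.T_spike)) * T
        assert rel < 0.16  # bounded by T_spike/T


class TestSEAnalytic:
    def test_inert_conductance_zero(self, iaf):
        # never activates anywhere, including during the AP excursion
        x = sodium_template(60.0, 1.0)
        assert abs(s_E_analytic(x, iaf, "prepost")) < 1e-3

    def test_supra_sodium_negative(self, iaf):
        x = sodium_template(-35.0, 2.0)
        assert s_E_analytic(x, iaf, "prepost") < 0.0

    def test_potassium_sign_flip(self, iaf):
        na = sodium_template(-35.0, 2.0)
        k = potassium_template(-35.0, 2.0)
        se_na = s_E_analytic(na, iaf, "prepost")
        se_k = s_E_analytic(k, iaf, "prepost")
        assert se_na < 0.0 < se_k

    def test_prepost_reduces_to_pre_for_fast_kinetics(self, iaf):
        """With tau << ISI the spike loading is forgotten instantly and the
        pre/post theory degenerates to the pre-spike one."""
        x = sodium_template(-45.0, 3.0, tau=0.1)
        se_pre = s_E_analytic(x, iaf, "pre")
        se_pp = s_E_analytic(x, iaf, "prepost")
        assert se_pp == pytest.approx(se_pre, rel=0.12, abs=1e-3)

    def test_unknown_theory_rejected(self, iaf):
        with pytest.raises(ValueError):
            s_E_analytic(sodium_template(), iaf, "sideways")

    def test_deterministic(self, iaf):
        x = sodium_template(-40.0, 3.0)
        assert s_E_analytic(x, iaf, "prepost") == s_E_analytic(
            x, iaf, "prepost")


class TestThresholdCurrent:
    def test_matches_leak_only_value(self, iaf):
        mem = iaf.membrane
        x = sodium_template(gmax=0.0)
        expected = mem.g_L * (iaf.V_s - mem.E_L)
        assert iaf_threshold_current(x, iaf) == pytest.approx(expected,
                                                              rel=1e-6)

    def test_lowered_by_inward_conductance(self, iaf):
        x0 = sodium_template(-70.0, 3.0, gmax=0.0)
        x1 = x0.with_gmax(5e-3)
        assert iaf_threshold_current(x1, iaf) < iaf_threshold_current(x0, iaf)
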