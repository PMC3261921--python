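import numpy as np
import pytest

from ipsense.params import MembraneParams, XConductance, GateKinetics, \
    sodium_template
from ipsense.sensitivity import (AdmissibilityVerdict, DegenerateStartError,
                                 admissibility_check, compute_map,
                                 estimate_sensitivities, gmax_progression,
                                 measure_threshold, select_g1)

from conftest import MAP_DT


class TestProgression:
    def test_pass_all_stub_geometric(self, membrane, baseline, monkeypatch):
        """With admissibility stubbed to always pass, the progression is the
        full geometric sequence."""
        import ipsense.sensitivity as S

        def fake_check(mem, x, bl, dt=0.01, **kw):
            return AdmissibilityVerdict("pass"), 0.1, None

        monkeypatch.setattr(S, "admissibility_check", fake_check)
        gs, ths, Es, As, trunc = S.gmax_progression(
            membrane, sodium_template(), baseline, g1=1e-4, ratio=2.0,
            max_steps=10, measure="theta")
        assert len(gs) == 10
        np.testing.assert_allclose(gs, 1e-4 * 2.0 ** np.arange(10))
        assert trunc == ""

    def test_bad_ratio_rejected(self, membrane, baseline):
        with pytest.raises(ValueError):
            gmax_progression(membrane, sodium_template(), baseline,
                             ratio=1.0)

    def test_g1_leaves_threshold_unchanged(self, membrane, baseline):
        g1 = select_g1(membrane, sodium_template(), baseline, dt=MAP_DT)
        th = measure_threshold(membrane, sodium_template(gmax=g1),
                               dt=MAP_DT, hint=baseline.I_theta)
        assert abs(th - baseline.I_theta) < 0.005 * baseline.I_theta + 2e-4


class TestAdmissibility:
    def test_baseline_passes(self, membrane, baseline, std_template):
        verdict, th, fi = admissibility_check(
            membrane, std_template.with_gmax(0.0), baseline, dt=MAP_DT)
        assert verdict.passed

    def test_strong_outward_is_high_threshold(self, membrane, baseline):
        # massive potassium leak-like conductance silences the neuron
        x = XConductance(20.0, 1, GateKinetics(-90.0, 4.0, 5.0), -90.0)
        verdict, _, _ = admissibility_check(membrane, x, baseline, dt=MAP_DT,
                                            measure="theta")
        assert verdict.category == "high_threshold"

    def test_strong_inward_is_spontaneous(self, membrane, baseline):
        x = sodium_template(-70.0, 2.0, gmax=0.05)
        verdict, _, _ = admissibility_check(membrane, x, baseline, dt=MAP_DT,
                                            measure="theta")
        assert verdict.category == "spontaneous"

    def test_degenerate_start_raises(self, membrane, baseline):
        with pytest.raises(DegenerateStartError):
            gmax_progression(membrane, sodium_template(-70.0, 2.0), baseline,
                             g1=0.05, dt=MAP_DT, measure="theta")


class TestEstimates:
    def test_leak_duplicate_oracle(self, membrane, baseline, iaf):
        """X duplicating the leak: S_theta equals the closed-form shift
        (V_theta - E_L) of the rheobase barrier."""
        leak_x = XConductance(0.0, 1, GateKinetics(-120.0, 4.0, 5.0),
                              membrane.E_L)
        from ipsense.sensitivity import gmax_progression
        from ipsense.excitability import model_I_regression
        # restrict to the small-g regime: at large added leak the barrier
        # potential itself drifts and I_theta(g) becomes convex
        gs, ths, _, _, _ = gmax_progression(membrane, leak_x, baseline,
                                         g1=1e-4, max_steps=7, dt=MAP_DT,
                                         measure="theta")
        slope = model_I_regression(np.concatenate([[0.0], gs]),
                                   np.concatenate([[baseline.I_theta],
                                                   ths])).slope
        expected = iaf.V_theta - membrane.E_L
        assert slope == pytest.approx(expected, rel=0.10)

    def test_subthreshold_signs(self, est_std):
        assert est_std.S_theta < -20.0
        # inverse gain essentially untouched relative to threshold action
        assert abs(est_std.S_E) / abs(est_std.S_theta) < 0.05
        assert est_std.fit_theta.r2 > 0.99

    def test_suprathreshold_signs(self, est_supra):
        assert est_supra.S_E < 0.0
        assert abs(est_supra.S_theta) < 1.0

    def test_decreasing_thresholds_with_gmax(self, membrane, baseline):
        est = estimate_sensitivities(membrane, sodium_template(-60.0, 4.0),
                                     baseline=baseline, dt=MAP_DT,
                                     measure="theta")
        assert np.all(np.diff(est.I_theta_list) < 1e-4)

    def test_sensitivity_independent_of_g1(self, membrane, baseline):
        tpl = sodium_template(-60.0, 4.0)
        e1 = estimate_sensitivities(membrane, tpl, baseline=baseline,
                                    g1=1e-5, dt=MAP_DT, measure="theta")
        e2 = estimate_sensitivities(membrane, tpl, baseline=baseline,
                                    g1=2e-5, dt=MAP_DT, measure="theta")
        assert e1.S_theta == pytest.approx(e2.S_theta, rel=0.05)


class TestMap:
    def test_tiny_map_with_stub(self, membrane, monkeypatch, std_template):
        """3x3 grid with a stubbed estimator: all cells populated."""
        import ipsense.sensitivity as S

        def fake_estimate(mem, node, baseline=None, dt=0.01, **kw):
            vh = node.activation.V_half
            fit = S.model_I_regression([0, 1, 2], [0.0, vh, 2 * vh])
            return S.SensitivityEstimate(
                S_theta=vh, S_E=node.activation.k, gmax_list=np.array(
                    [1e-4, 2e-4, 4e-4]),
                fit_theta=fit, fit_E=fit, linear=True)

        def fake_baseline(mem, template=None, dt=0.01, **kw):
            return S.Baseline(0.16, 0.043, 23.0, 1.8)

        monkeypatch.setattr(S, "estimate_sensitivities", fake_estimate)
        monkeypatch.setattr(S, "compute_baseline", fake_baseline)
        vg = np.array([-70.0, -60.0, -50.0])
        kg = np.array([2.0, 4.0, 8.0])
        smap = compute_map(membrane, std_template, vg, kg)
        assert smap.S_theta.shape == (3, 3)
        assert np.all(np.isfinite(smap.S_theta))
        np.testing.assert_allclose(smap.S_theta[0], vg)
        np.testing.assert_allclose(smap.S_E[:, 0], kg)
        assert smap.ap_model == membrane.ap_model

    def test_checkpoint_resume(self, membrane, monkeypatch, std_template,
                               tmp_path):
        import ipsense.sensitivity as S
        calls = {"n": 0}

        def fake_estimate(mem, node, baseline=None, dt=0.01, **kw):
            calls["n"] += 1
            fit = S.model_I_regression([0, 1, 2], [0.0, 1.0, 2.0])
            return S.SensitivityEstimate(
                S_theta=-1.0, S_E=0.5, gmax_list=np.array([1e-4, 2e-4,
                                                           4e-4]),
                fit_theta=fit, fit_E=fit, linear=True)

        def fake_baseline(mem, template=None, dt=0.01, **kw):
            return S.Baseline(0.16, 0.043, 23.0, 1.8)

        monkeypatch.setattr(S, "estimate_sensitivities", fake_estimate)
        monkeypatch.setattr(S, "compute_baseline", fake_baseline)
        ck = str(tmp_path / "ck.csv")
        vg = np.array([-60.0, -50.0])
        kg = np.array([2.0, 4.0])
        compute_map(membrane, std_template, vg, kg, checkpoint_path=ck)
        assert calls["n"] == 4
        smap = compute_map(membrane, std_template, vg, kg,
                           checkpoint_path=ck)
        assert calls["n"] == 4  # all nodes loaded from the checkpoint
        assert np.all(np.isfinite(smap.S_theta))
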