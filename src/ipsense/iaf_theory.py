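"""Integrate-and-fire sensitivity theories.

The reduced model keeps only the leak and the X conductance and integrates
the membrane equation across one ISI from the reset potential V_r to the
phenomenological spike threshold V_s.  Four activation treatments are
available:

``threshold``
    instantaneous activation; yields the closed-form threshold sensitivity
    S_theta = (V_theta - E_X) * x_inf(V_theta)^p evaluated at the effective
    AP-threshold potential V_theta.
``pre``
    activation builds up from its reset-level steady state during the ISI.
``post``
    activation is loaded by the AP excursion and relaxes as a pure function
    of time toward its ISI-level steady state.
``prepost``
    AP loading followed by relaxation early in the ISI and buildup near
    threshold (the general case; reduces to ``pre`` for vanishing spike
    loading and to ``post`` for fast sub-threshold kinetics).
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from . import _kernels as K
from .excitability import current_for_rate, fit_fi, model_I_regression
from .model_core import DEFAULT_DT, boltzmann_steady_state, simulate
from .params import (GateKinetics, InvalidParameterError, MembraneParams,
                     XConductance)

THEORY_CODES = {"threshold": 0, "pre": 1, "post": 2, "prepost": 3}

IAF_DT = 0.01


class NoThresholdError(RuntimeError):
    """The model does not fire at the probe current."""


class NoSpikeError(RuntimeError):
    """Current below the theory's threshold current."""


@dataclass(frozen=True, eq=False)
class IAFParams:
    """Reduced-model potentials plus the membrane it derives from.

    ``ap_waveform`` is the stereotyped AP excursion (t, V arrays from the
    threshold crossing through the AHP back to V_r) used to load the X
    activation across the un-integrated spike; when absent a rectangular
    pulse of ``T_spike`` ms at ``V_peak`` is assumed.
    """

    V_r: float                  # reset/resting potential, mV
    V_s: float                  # phenomenological spike threshold, mV
    V_theta: float              # effective AP-threshold potential, mV
    membrane: MembraneParams
    T_spike: float = 1.8        # ms, AP excursion seen by the activation
    V_peak: float = 20.0        # mV, effective potential during the AP
    ap_waveform: Optional[tuple] = None   # (t ms, V mV) arrays

    def __post_init__(self):
        if not (self.V_r < self.V_theta <= self.V_s):
            raise InvalidParameterError(
                f"require V_r < V_theta <= V_s, got "
                f"{self.V_r}, {self.V_theta}, {self.V_s}")


@dataclass
class ThresholdEstimate:
    V_theta: float
    V_s: float
    V_r: float
    criterion: str
    n_spikes: int


def steady_state_current(membrane: MembraneParams, V) -> np.ndarray:
    """Steady-state membrane current of the full AP model at potential V
    (µA/cm²): the current needed to hold V in steady state."""
    V = np.atleast_1d(np.asarray(V, float))
    out = np.empty_like(V)
    for i, v in enumerate(V):
        m = K._m_inf(v)
        ah, bh = K._h_rates(v)
        an, bn = K._n_rates(v)
        h = ah / (ah + bh)
        n = an / (an + bn)
        ap = membrane.ap
        out[i] = (membrane.g_L * (v - membrane.E_L)
                  + ap.g_Na * m ** 3 * h * (v - ap.E_Na)
                  + ap.g_K * n ** 4 * (v - ap.E_K))
    return out


def barrier_threshold_potential(membrane: MembraneParams,
                                V_lo: float = -75.0, V_hi: float = -40.0,
                                dv: float = 0.01) -> float:
    """V at the maximum of the steady-state I-V barrier (saddle point of
    the rheobase crossing); deterministic counterpart of the trace-based
    estimators."""
    V = np.arange(V_lo, V_hi, dv)
    return float(V[np.argmax(steady_state_current(membrane, V))])


def effective_threshold(membrane: MembraneParams,
                        x: Optional[XConductance] = None,
                        criterion: str = "phase_min",
                        dt: float = DEFAULT_DT,
                        I_probe: Optional[float] = None) -> ThresholdEstimate:
    """Estimate V_theta (and V_s, V_r) from an HH trace.

    ``criterion="phase_min"``: V at the minimum of dV/dt over the
    inter-spike crawl (the barrier crossing), the default.
    ``criterion="dvdt"``: V at which dV/dt first exceeds 10 mV/ms on the
    AP upstroke; this more depolarized value is reported as V_s in both
    modes.
    """
    from .sensitivity import measure_threshold  # local import, no cycle
    if I_probe is None:
        I_th = measure_threshold(membrane, x, dt=dt)
        I_probe = 1.1 * I_th + 0.005
    tr = simulate(membrane, x, I=I_probe, duration=20_000.0,
                  stop_after_spikes=12, dt=dt)
    st = tr.spike_times
    if len(st) < 3:
        raise NoThresholdError(f"no repetitive firing at I = {I_probe}")
    V = tr.V
    t = tr.t
    dV = np.gradient(V, t)
    v_theta_vals, v_s_vals, v_r_vals = [], [], []
    for a, b in zip(st[1:-1], st[2:]):
        i0 = int(a / tr.dt)
        i1 = int(b / tr.dt)
        seg = slice(i0, i1)
        # reset level: trough after the spike
        v_r_vals.append(V[seg].min())
        # barrier: minimum positive dV/dt in the central part of the ISI
        lo = i0 + (i1 - i0) // 5
        hi = i1 - (i1 - i0) // 10
        j = lo + int(np.argmin(dV[lo:hi]))
        v_theta_vals.append(V[j])
        # upstroke: first crossing of 10 mV/ms after the crawl
        ks = np.nonzero(dV[j:i1] >= 10.0)[0]
        if len(ks):
            v_s_vals.append(V[j + ks[0]])
    v_s = float(np.mean(v_s_vals)) if v_s_vals else math.nan
    v_theta = v_s if criterion == "dvdt" else float(np.mean(v_theta_vals))
    return ThresholdEstimate(V_theta=v_theta, V_s=v_s,
                             V_r=float(np.mean(v_r_vals)),
                             criterion=criterion, n_spikes=len(st))


def ap_excursion_waveform(membrane: MembraneParams, V_theta: float,
                          V_r: float, dt: float = 0.01, I: float = 1.0):
    """Stereotyped AP excursion of the bare model.

    Returns (t, V) from the upward V_theta crossing through the peak down
    to the AHP trough (the reset point); the last steady spike of a short
    repetitive-firing run is used.
    """
    tr = simulate(membrane, None, I=I, duration=10_000.0,
                  stop_after_spikes=8, dt=dt)
    V = tr.V
    up = np.nonzero((V[:-1] < V_theta) & (V[1:] >= V_theta))[0]
    if len(up) < 3:
        raise NoThresholdError("could not capture an AP waveform")
    i, nxt = up[-2], up[-1]
    j = i + 1 + int(np.argmin(V[i + 1:nxt]))   # AHP trough
    seg = V[i:j + 1].copy()
    t = np.arange(len(seg)) * tr.dt
    return t, seg


def activation_loading(iaf: IAFParams, gate: GateKinetics):
    """Affine map of the activation across the AP excursion.

    x after the excursion = A + B * (x at threshold), for first-order
    kinetics driven by the excursion waveform:
    B = exp(-T/tau), A = (1/tau) ∫ x_inf(V(s)) exp(-(T-s)/tau) ds.
    """
    tau = 1e-4 if gate.is_instantaneous else float(gate.tau)
    if iaf.ap_waveform is None:
        B = math.exp(-iaf.T_spike / tau)
        A = boltzmann_steady_state(iaf.V_peak, gate) * (1.0 - B)
        return A, B
    t, V = iaf.ap_waveform
    T = t[-1]
    B = math.exp(-T / tau)
    xinf = boltzmann_steady_state(V, gate)
    w = np.exp(-(T - t) / tau) / tau
    A = float(np.trapezoid(xinf * w, t))
    return A, B


def standard_iaf(membrane: Optional[MembraneParams] = None,
                 dt: float = DEFAULT_DT) -> IAFParams:
    """IAF potentials measured once from the bare AP model.

    V_r is the reset potential (AHP trough) and V_s is tied to the
    effective threshold, so the reduced ISI spans the whole recovery from
    the trough up to the saddle crossing and the spike excursion proper
    (threshold -> peak -> trough) is folded into the activation loading.
    """
    membrane = membrane or MembraneParams()
    est = effective_threshold(membrane, None, dt=dt)
    wave = ap_excursion_waveform(membrane, est.V_theta, est.V_r, dt=dt)
    return IAFParams(V_r=est.V_r, V_s=est.V_theta, V_theta=est.V_theta,
                     membrane=membrane, ap_waveform=wave)


# -- threshold theory -------------------------------------------------------

def s_theta_analytic(x: XConductance, iaf: IAFParams) -> float:
    """Closed-form threshold sensitivity.

    S_theta = (V_theta - E_X) * x_inf(V_theta)^p, times the inactivation
    steady state at V_theta when the conductance inactivates.
    """
    act = boltzmann_steady_state(iaf.V_theta, x.activation) ** x.p
    if x.inactivation is not None:
        act *= boltzmann_steady_state(iaf.V_theta, x.inactivation)
    return (iaf.V_theta - x.E_X) * act


def iso_sensitivity_lines(levels: Sequence[float], V_theta: float, p: int = 1):
    """Iso-activation straight lines in the (V_half, k) plane.

    Level c maps to V_half = V_theta - k * ln(c^(1/p) / (1 - c^(1/p))):
    all lines pass through the central point O = (V_theta, 0).  Returns
    ``{c: (intercept, slope)}`` with V_half = intercept + slope * k.
    """
    out = {}
    for c in levels:
        if not 0.0 < c < 1.0:
            raise InvalidParameterError(f"iso level {c} outside (0, 1)")
        a = c ** (1.0 / p)
        out[c] = (V_theta, -math.log(a / (1.0 - a)))
    return out


# -- dynamic theories -------------------------------------------------------

def _theory_args(x: XConductance, iaf: IAFParams):
    if x.activation.is_instantaneous:
        tau = 1e-4
    else:
        tau = float(x.activation.tau)
    mem = iaf.membrane
    return (mem.capacitance, mem.g_L, mem.E_L, x.gmax, int(x.p),
            x.activation.V_half, x.activation.k, tau, x.E_X)


def iaf_threshold_current(x: XConductance, iaf: IAFParams,
                          dv: float = 0.01) -> float:
    """Smallest current able to push V from V_r to V_s: the maximum of
    the quasi-static current barrier over [V_r, V_s]."""
    mem = iaf.membrane
    V = np.append(np.arange(iaf.V_r, iaf.V_s, dv), iaf.V_s)
    xinf = boltzmann_steady_state(V, x.activation) ** x.p
    barrier = mem.g_L * (V - mem.E_L) + x.gmax * xinf * (V - x.E_X)
    return float(barrier.max())


def iaf_isi_duration(theory: str, x: XConductance, iaf: IAFParams, I: float,
                     dt: float = IAF_DT, max_ms: float = 2000.0) -> float:
    """Steady-state ISI duration T(I) in ms (inf if the model stays silent)."""
    code = THEORY_CODES[theory]
    C, gL, EL, gx, p, vh, kk, tau, ex = _theory_args(x, iaf)
    A, B = activation_loading(iaf, x.activation)
    return float(K.iaf_isi(code, C, gL, EL, gx, p, vh, kk, tau, ex, I,
                           iaf.V_r, iaf.V_s, A, B, dt, max_ms, 30))


def iaf_rate_fn(theory: str, x: XConductance, iaf: IAFParams,
                dt: float = IAF_DT):
    def rate(I: float) -> float:
        T = iaf_isi_duration(theory, x, iaf, I, dt=dt)
        return 0.0 if not np.isfinite(T) else 1000.0 / T
    return rate


def iaf_trajectory(theory: str, x: XConductance, iaf: IAFParams, I: float,
                   dt: float = IAF_DT, max_ms: float = 2000.0):
    """Analytic-model ISI trajectory: (t, V, x_series, T, f)."""
    code = THEORY_CODES[theory]
    C, gL, EL, gx, p, vh, kk, tau, ex = _theory_args(x, iaf)
    A, B = activation_loading(iaf, x.activation)
    t, V, xs = K.iaf_trajectory_kernel(code, C, gL, EL, gx, p, vh, kk, tau,
                                       ex, I, iaf.V_r, iaf.V_s, A, B,
                                       dt, max_ms)
    if len(t) == 0:
        raise NoSpikeError(f"I = {I} below the {theory} threshold current")
    T = float(t[-1])
    return t, V, xs, T, 1000.0 / T


def _barrier_at_level(x: XConductance, iaf: IAFParams, level: float,
                      dv: float = 0.02) -> float:
    """Quasi-static current barrier with the activation clamped at level."""
    mem = iaf.membrane
    V = np.append(np.arange(iaf.V_r, iaf.V_s, dv), iaf.V_s)
    barrier = (mem.g_L * (V - mem.E_L)
               + x.gmax * level ** x.p * (V - x.E_X))
    return float(barrier.max())


def iaf_inverse_gain(theory: str, x: XConductance, iaf: IAFParams,
                     F_low: float = 40.0, F_high: float = 120.0,
                     n_points: int = 30, dt: float = IAF_DT) -> float:
    """Inverse gain of the reduced model: linear regression of f over the
    [F_low, F_high] window, like the HH pipeline.

    The default window sits above the reduced model's f-I foot, which is
    much steeper than the HH one (logarithmic divergence of the leaky
    charging time); fitting inside the foot makes E numerically unstable.
    The exact threshold current depends on the theory's activation
    dynamics, so the window search starts from a current that is silent
    under every activation hypothesis (clamped levels 0 and 1 bracket it).
    """
    rate = iaf_rate_fn(theory, x, iaf, dt=dt)
    b0 = _barrier_at_level(x, iaf, 0.0)
    b1 = _barrier_at_level(x, iaf, 1.0)
    bq = iaf_threshold_current(x, iaf)
    I_silent = min(b0, b1, bq) - 0.05
    I_cap = max(b0, b1, bq) + 10.0
    fi = fit_fi(rate, F_low=F_low, F_high=F_high, n_points=n_points,
                I_theta=I_silent, I_max=I_cap, bound_rel_tol=1e-4)
    return fi.E


def s_E_analytic(x: XConductance, iaf: IAFParams, theory: str = "prepost",
                 g_probe: Optional[Sequence[float]] = None,
                 dt: float = IAF_DT) -> float:
    """Inverse-gain sensitivity of the chosen IAF theory.

    E(gmax) is linear, so S_E is the regression slope of E over a small
    gmax probe set anchored at 0 (deterministic by construction).
    """
    if theory not in THEORY_CODES:
        raise ValueError(f"unknown theory {theory!r}")
    if g_probe is None:
        gl = iaf.membrane.g_L
        g_probe = [0.0, 0.01 * gl, 0.02 * gl, 0.04 * gl]
    Es = [iaf_inverse_gain(theory, x.with_gmax(g), iaf, dt=dt)
          for g in g_probe]
    return model_I_regression(g_probe, Es).slope


def theory_map(theory: str, template: XConductance, iaf: IAFParams,
               V_half_grid, k_grid, dt: float = IAF_DT):
    """Deterministic analytic sensitivity map on the (V_half, k) lattice.

    Returns (S_theta_map, S_E_map); S_E is only evaluated for the dynamic
    theories (None for ``threshold``).
    """
    V_half_grid = np.asarray(V_half_grid, float)
    k_grid = np.asarray(k_grid, float)
    St = np.empty((len(k_grid), len(V_half_grid)))
    Se = np.full_like(St, np.nan)
    for j, kk in enumerate(k_grid):
        for i, vh in enumerate(V_half_grid):
            act = GateKinetics(vh, kk, template.activation.tau)
            node = template.replace(activation=act)
            St[j, i] = s_theta_analytic(node, iaf)
            if theory != "threshold":
                Se[j, i] = s_E_analytic(node, iaf, theory=theory, dt=dt)
    return St, (None if theory == "threshold" else Se)
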