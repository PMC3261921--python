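"""Homeostatic plasticity loop.

A high-threshold calcium current translates spiking into intracellular
calcium; calcium drives a kinase/phosphatase cycle setting the
phosphorylated (functional) fraction f_phi of the X conductance; the
effective maximal conductance is g_sup * f_phi.  With an inward X
conductance the regulation is homeostatic: activity raises calcium, which
lowers f_phi and excitability.

Two engines are provided: full HH co-integration, and a rate-based model
where the f-I line with a plastic threshold replaces the membrane
equations.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

from . import _kernels as K
from .excitability import model_I_regression
from .model_core import (DEFAULT_DT, IntegrationBlowupError,
                         build_param_vector, gate_tables)
from .params import (GateKinetics, InvalidParameterError, MembraneParams,
                     XConductance)

FARADAY = 96485.332  # C/mol

LOOP_DT = 0.02
DEFAULT_HORIZON_MS = 150_000.0


@dataclass(frozen=True)
class CalciumParams:
    """High-threshold calcium source and single-shell buffering."""

    g_CaL: float = 0.15          # mS/cm²
    activation: GateKinetics = GateKinetics(-20.0, 5.0, 2.0)
    E_Ca: float = 120.0          # mV
    Ca_b: float = 0.1            # µM, basal concentration
    tau_Ca: float = 200.0        # ms, buffering time constant
    soma_radius: float = 10.0    # µm
    shell_thickness: float = 1.0  # µm

    def __post_init__(self):
        if not 0 < self.shell_thickness < self.soma_radius:
            raise InvalidParameterError("require 0 < thickness < radius")

    @property
    def surface_to_volume(self) -> float:
        """Shell surface-to-volume ratio (1/m) for a spherical soma."""
        r, d = self.soma_radius, self.shell_thickness
        return 3.0 * r ** 2 / (r ** 3 - (r - d) ** 3) * 1e6

    @property
    def influx_factor(self) -> float:
        """µM/ms of free calcium per µA/cm² of inward calcium current."""
        return self.surface_to_volume * 1e-2 / (2.0 * FARADAY)


@dataclass(frozen=True)
class AKPParams:
    """Activity-dependent kinase/phosphatase cycle constants.

    The kinase (half-activation K_K, below K_P) dominates at basal calcium
    so the functional fraction creeps up in silence; the faster phosphatase
    takes over at elevated calcium, closing the homeostatic loop.
    """

    v_K: float = 0.015    # ms⁻¹
    v_P: float = 0.075    # ms⁻¹
    K_K: float = 0.35     # µM
    K_P: float = 1.2      # µM
    n_H: float = 4.0
    g_sup: float = 0.01   # mS/cm², superior physiological conductance

    def __post_init__(self):
        for name in ("v_K", "v_P", "K_K", "K_P", "n_H"):
            if getattr(self, name) <= 0:
                raise InvalidParameterError(f"{name} must be > 0")
        if self.g_sup < 0:
            raise InvalidParameterError("g_sup must be >= 0")


@dataclass
class LoopTrajectory:
    t: np.ndarray             # ms
    V: Optional[np.ndarray]   # mV (HH engine) or None
    rate: Optional[np.ndarray]  # Hz (rate engine) or None
    Ca: np.ndarray            # µM
    f_phi: np.ndarray
    gmax: np.ndarray          # mS/cm², = g_sup * f_phi
    spike_times: np.ndarray
    steady_frequency: float   # Hz; 0 when silent
    fired: bool
    stationary: bool


def akp_dynamics(Ca: float, f_phi: float, akp: AKPParams):
    """Cycle derivative and closed-form steady state.

    Returns ``(df_phi/dt, f_star, tau)`` with
    f* = R_K / (R_K + R_P) and tau = 1 / (R_K + R_P).
    """
    if Ca < 0:
        raise InvalidParameterError("Ca must be >= 0")
    cK = (Ca / akp.K_K) ** akp.n_H
    cP = (Ca / akp.K_P) ** akp.n_H
    RK = akp.v_K * cK / (1.0 + cK)
    RP = akp.v_P * cP / (1.0 + cP)
    total = RK + RP
    dfdt = RK * (1.0 - f_phi) - RP * f_phi
    f_star = RK / total if total > 0 else f_phi
    tau = 1.0 / total if total > 0 else math.inf
    return dfdt, f_star, tau


def _loop_param_vector(membrane: MembraneParams, template: XConductance,
                       cal: CalciumParams, akp: AKPParams) -> np.ndarray:
    P = build_param_vector(membrane, template.with_gmax(0.0), I=0.0)
    P[K.P_USE_LOOP] = 1.0
    P[K.P_GCAL] = cal.g_CaL
    P[K.P_UVH] = cal.activation.V_half
    P[K.P_UK] = cal.activation.k
    P[K.P_UTAU] = float(cal.activation.tau)
    P[K.P_ECA] = cal.E_Ca
    P[K.P_CAB] = cal.Ca_b
    P[K.P_TAUCA] = cal.tau_Ca
    P[K.P_CAFAC] = cal.influx_factor
    P[K.P_VK] = akp.v_K
    P[K.P_VP] = akp.v_P
    P[K.P_KK] = akp.K_K
    P[K.P_KP] = akp.K_P
    P[K.P_NH] = akp.n_H
    P[K.P_GSUP] = akp.g_sup
    return P


def _steady_rate(spike_times: np.ndarray, horizon: float, window_frac=0.2):
    """Rate over the trailing window plus a two-half stationarity check."""
    w0 = horizon * (1.0 - window_frac)
    tail = spike_times[spike_times >= w0]
    rate = len(tail) / (horizon - w0) * 1000.0
    half = 0.5 * (horizon + w0)
    r1 = len(tail[tail < half]) / (half - w0) * 1000.0
    r2 = len(tail[tail >= half]) / (horizon - half) * 1000.0
    if rate == 0.0:
        return 0.0, True
    stationary = abs(r2 - r1) <= 0.02 * max(rate, 1.0) + 2000.0 / (horizon - w0)
    return rate, bool(stationary)


def simulate_loop_hh(membrane: MembraneParams, template: XConductance,
                     cal: CalciumParams, akp: AKPParams,
                     duration: float = DEFAULT_HORIZON_MS,
                     dt: float = LOOP_DT, f_phi0: float = 0.0,
                     record_ms: float = 5.0) -> LoopTrajectory:
    """Co-integrate membrane, calcium and f_phi with no injected current
    and no synaptic drive; classify the outcome at the horizon."""
    P = _loop_param_vector(membrane, template, cal, akp)
    rec_every = max(1, int(round(record_ms / dt)))
    n_steps = int(round(duration / dt))
    cap = int(duration / 4) + 16
    rec, spikes, n_spk, status, t_end, _ = K.run_model(
        P, gate_tables(P), dt, n_steps, membrane.E_L, f_phi0, 0,
        rec_every, 0, cap)
    if status == 2:
        raise IntegrationBlowupError(t_end)
    t = np.arange(rec.shape[0]) * dt * rec_every
    f_phi = rec[:, 6]
    rate, stationary = _steady_rate(spikes, duration)
    return LoopTrajectory(t=t, V=rec[:, 0], rate=None, Ca=rec[:, 5],
                          f_phi=f_phi, gmax=akp.g_sup * f_phi,
                          spike_times=spikes,
                          steady_frequency=rate, fired=bool(rate > 0.0),
                          stationary=stationary)


def fit_ca_frequency_slope(membrane: MembraneParams, cal: CalciumParams,
                           currents=(0.5, 1.0, 1.5, 2.0, 2.5),
                           dt: float = LOOP_DT, settle_ms: float = 3000.0):
    """Slope of the near-linear steady calcium vs firing-rate relation
    (µM per Hz), fitted from HH runs with the plasticity frozen off."""
    akp_off = AKPParams(v_K=1e-12, v_P=1e-12, g_sup=0.0)
    template = XConductance(0.0, 1, GateKinetics(-60.0, 4.0, 5.0), 55.0)
    P = _loop_param_vector(membrane, template, cal, akp_off)
    rates, cas = [], []
    for I in currents:
        P2 = P.copy()
        P2[K.P_I] = I
        n_steps = int(round(settle_ms / dt))
        rec, spikes, n_spk, status, _, _ = K.run_model(
            P2, gate_tables(P2), dt, n_steps, membrane.E_L, 0.0, 0,
            max(1, int(1.0 / dt)), 0, int(settle_ms / 4) + 16)
        tail = spikes[spikes > settle_ms / 2]
        rates.append(len(tail) / (settle_ms / 2) * 1000.0)
        m = rec.shape[0]
        cas.append(float(rec[3 * m // 4:, 5].mean()))
    fit = model_I_regression(rates, cas)
    return fit.slope, fit


def simulate_loop_rate(I_theta0: float, E0: float, S_theta: float,
                       akp: AKPParams, cal: CalciumParams,
                       ca_slope: float,
                       duration: float = DEFAULT_HORIZON_MS,
                       dt: float = 10.0, f_phi0: float = 0.0,
                       I_ext: float = 0.0) -> LoopTrajectory:
    """Rate-based loop: f = H(I - I_theta) (I - I_theta) / E0 with
    I_theta = I_theta0 + S_theta * g_sup * f_phi, and the linearized
    calcium relation Ca = Ca_b + ca_slope * f."""
    n = int(round(duration / dt)) + 1
    t = np.arange(n) * dt
    f_phi = np.empty(n)
    rate = np.empty(n)
    Ca = np.empty(n)
    f = f_phi0
    for i in range(n):
        g = akp.g_sup * f
        I_theta = I_theta0 + S_theta * g
        drive = I_ext - I_theta
        r = max(0.0, drive) / E0      # Heaviside gate on the drive
        ca = cal.Ca_b + ca_slope * r
        f_phi[i] = f
        rate[i] = r
        Ca[i] = ca
        dfdt, _, _ = akp_dynamics(ca, f, akp)
        f = min(1.0, max(0.0, f + dt * dfdt))
    tail = rate[int(0.8 * n):]
    steady = float(tail.mean())
    fired = steady > 1e-3
    stationary = abs(tail[-1] - tail[0]) <= 0.02 * max(steady, 1.0)
    return LoopTrajectory(t=t, V=None, rate=rate, Ca=Ca, f_phi=f_phi,
                          gmax=akp.g_sup * f_phi,
                          spike_times=np.array([]),
                          steady_frequency=steady if fired else 0.0,
                          fired=bool(fired), stationary=bool(stationary))


def spontaneous_border_predicted(I_theta0: float, S_theta: float,
                                 g_sup: float) -> bool:
    """A priori criterion: firing possible iff I_theta0 + S_theta*g_sup <= 0."""
    return I_theta0 + S_theta * g_sup <= 0.0


def spontaneous_map(membrane: MembraneParams, template: XConductance,
                    cal: CalciumParams, akp: AKPParams,
                    V_half_grid, k_grid, engine: str = "hh",
                    duration: float = DEFAULT_HORIZON_MS,
                    dt: float = LOOP_DT,
                    rate_inputs: Optional[dict] = None,
                    iaf=None, progress=None):
    """Steady spontaneous frequency over the (V_half, k) lattice.

    ``engine="hh"`` runs the full loop per cell; ``engine="rate"`` needs
    ``rate_inputs`` with keys I_theta0, E0, ca_slope and an ``iaf`` for the
    analytic per-cell S_theta.  Also returns the a priori border map from
    I_theta0 + S_theta * g_sup <= 0.
    """
    from .iaf_theory import s_theta_analytic
    V_half_grid = np.asarray(V_half_grid, float)
    k_grid = np.asarray(k_grid, float)
    freq = np.full((len(k_grid), len(V_half_grid)), np.nan)
    predicted = np.zeros_like(freq, dtype=bool)
    failures = {}
    for j, kk in enumerate(k_grid):
        for i, vh in enumerate(V_half_grid):
            act = GateKinetics(vh, kk, template.activation.tau)
            node = template.replace(activation=act)
            if iaf is not None:
                st = s_theta_analytic(node, iaf)
                base_th = (rate_inputs or {}).get("I_theta0")
                if base_th is not None:
                    predicted[j, i] = spontaneous_border_predicted(
                        base_th, st, akp.g_sup)
            try:
                if engine == "hh":
                    tr = simulate_loop_hh(membrane, node, cal, akp,
                                          duration=duration, dt=dt)
                elif engine == "rate":
                    ri = rate_inputs or {}
                    st = s_theta_analytic(node, iaf)
                    tr = simulate_loop_rate(ri["I_theta0"], ri["E0"], st,
                                            akp, cal, ri["ca_slope"],
                                            duration=duration)
                else:
                    raise ValueError(f"unknown engine {engine!r}")
                freq[j, i] = tr.steady_frequency
            except Exception as exc:  # per-node failures are not fatal
                failures[(vh, kk)] = repr(exc)
            if progress:
                progress(f"loop node ({vh:g}, {kk:g}) -> {freq[j, i]:.2f} Hz")
    return freq, predicted, failures
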