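"""Conductance-based single-compartment neuron: simulation and spike tools.

The membrane carries a leak current, fast AP currents (instantaneous
sodium activation ``m_inf^3 h`` and a delayed rectifier ``n^4``), a generic
plastic X conductance with Boltzmann gating, and optionally a stochastic
background synaptic drive made of superposed Poisson conductance trains.
Integration is fixed-step Runge-Kutta 4.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from . import _kernels as K
from .params import (AP_MODELS, GateKinetics, InvalidParameterError,
                     MembraneParams, NoiseParams, XConductance)

DEFAULT_DT = 0.01  # ms

AP_DURATION_LEVEL = -20.0  # mV, duration measured at this level
AP_DURATION_TARGET = 1.8   # ms
AP_DURATION_TOL = 0.25     # relative band half-width


class IntegrationBlowupError(RuntimeError):
    def __init__(self, t: float):
        super().__init__(f"non-finite membrane state at t = {t:.3f} ms")
        self.t = t


class SimulationTimeoutError(RuntimeError):
    pass


def boltzmann_steady_state(V, gate: GateKinetics):
    """Steady-state fraction of a Boltzmann gate at potential ``V``.

    Increasing in V for ``k > 0`` (activation), decreasing for ``k < 0``
    (inactivation).  Accepts scalars or arrays.
    """
    if gate.k == 0:
        raise InvalidParameterError("k must be non-zero")
    z = (np.asarray(V, dtype=float) - gate.V_half) / gate.k
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    if np.isscalar(V) or np.ndim(V) == 0:
        return float(out)
    return out


@dataclass
class Trace:
    """Recorded simulation output on a uniform time grid."""

    t: np.ndarray
    V: np.ndarray
    gates: dict                     # name -> series (x, h, n, xi[, Ca, f_phi])
    spike_times: np.ndarray         # ms
    ap_durations: np.ndarray        # ms, at the -20 mV level
    dt: float
    status: str = "completed"       # or "stopped_at_spike_count"

    @property
    def n_spikes(self) -> int:
        return len(self.spike_times)


def build_param_vector(membrane: MembraneParams, x: Optional[XConductance],
                       I: float = 0.0,
                       noise: Optional[NoiseParams] = None) -> np.ndarray:
    P = np.zeros(K.NPARAMS)
    P[K.P_C] = membrane.capacitance
    P[K.P_GL] = membrane.g_L
    P[K.P_EL] = membrane.E_L
    ap = membrane.ap
    P[K.P_GNA], P[K.P_ENA] = ap.g_Na, ap.E_Na
    P[K.P_GK], P[K.P_EK] = ap.g_K, ap.E_K
    P[K.P_PHI] = ap.phi

    if x is None:
        x = XConductance(0.0, 1, GateKinetics(-60.0, 4.0, 5.0), 55.0)
    P[K.P_GX] = x.gmax
    P[K.P_XP] = float(x.p)
    P[K.P_XVH] = x.activation.V_half
    P[K.P_XK] = x.activation.k
    P[K.P_XTAU] = 1.0 if x.activation.is_instantaneous else float(x.activation.tau)
    P[K.P_XINST] = 1.0 if x.activation.is_instantaneous else 0.0
    if x.inactivation is not None:
        P[K.P_HASINACT] = 1.0
        P[K.P_XIVH] = x.inactivation.V_half
        P[K.P_XIK] = x.inactivation.k
        P[K.P_XITAU] = float(x.inactivation.tau)
    P[K.P_EX] = x.E_X
    P[K.P_I] = I

    if noise is not None:
        e, i = noise.excitatory, noise.inhibitory
        P[K.P_RATE_E] = e.total_rate_per_ms
        P[K.P_JUMP_E] = e.jump
        P[K.P_TAU_E] = e.tau_syn
        P[K.P_E_E] = e.E_syn
        P[K.P_RATE_I] = i.total_rate_per_ms
        P[K.P_JUMP_I] = i.jump
        P[K.P_TAU_I] = i.tau_syn
        P[K.P_E_I] = i.E_syn
        P[K.P_USE_NOISE] = 1.0
    # calcium/aKP block left zeroed; the plasticity loop fills it in ip_loop
    P[K.P_TAUCA] = 1.0
    P[K.P_XITAU] = max(P[K.P_XITAU], 1.0)
    P[K.P_UTAU] = 1.0
    P[K.P_UK] = 1.0
    P[K.P_KK] = 1.0
    P[K.P_KP] = 1.0
    P[K.P_NH] = 1.0
    return P


_TABLE_CACHE: dict = {}


def gate_tables(P: np.ndarray) -> np.ndarray:
    """Cached voltage-grid tables of all gate curves for ``P``."""
    key = (P[K.P_PHI], P[K.P_XVH], P[K.P_XK], P[K.P_HASINACT],
           P[K.P_XIVH], P[K.P_XIK], P[K.P_UVH], P[K.P_UK])
    tab = _TABLE_CACHE.get(key)
    if tab is None:
        tab = K.build_tables(P)
        if len(_TABLE_CACHE) > 32:
            _TABLE_CACHE.clear()
        _TABLE_CACHE[key] = tab
    return tab


def resting_potential(membrane: MembraneParams,
                      x: Optional[XConductance] = None,
                      settle_ms: float = 500.0, dt: float = DEFAULT_DT) -> float:
    """Relax the model at I = 0 without noise and return the final V."""
    tr = simulate(membrane, x, I=0.0, noise=None, duration=settle_ms, dt=dt,
                  record_every=100)
    return float(tr.V[-1])


def simulate(membrane: MembraneParams, x: Optional[XConductance],
             I: float = 0.0, noise: Optional[NoiseParams] = None,
             duration: Optional[float] = None,
             stop_after_spikes: Optional[int] = None,
             dt: float = DEFAULT_DT, V0: Optional[float] = None,
             record_every: int = 1, max_wall_ms: float = 120_000.0) -> Trace:
    """Integrate the model and return a :class:`Trace`.

    Exactly one stopping rule applies: a ``duration`` in ms, or
    ``stop_after_spikes`` (with ``duration`` as a hard wall, defaulting to
    ``max_wall_ms``).  Gating variables start at their steady state for the
    initial voltage; with ``noise`` the run is reproducible given the seed.
    """
    if duration is None and stop_after_spikes is None:
        raise ValueError("provide duration and/or stop_after_spikes")
    wall = duration if duration is not None else max_wall_ms
    n_steps = int(round(wall / dt))
    P = build_param_vector(membrane, x, I=I, noise=noise)
    if V0 is None:
        V0 = membrane.E_L
    seed = 0 if noise is None else noise.seed
    max_spk = 0 if stop_after_spikes is None else int(stop_after_spikes)
    cap = max(max_spk + 4, int(wall / 4) + 16)  # generous spike buffer
    rec, spikes, n_spk, status, t_end, _ = K.run_model(
        P, gate_tables(P), dt, n_steps, V0, 0.0, seed, record_every,
        max_spk, cap)
    if status == 2:
        raise IntegrationBlowupError(t_end)
    if max_spk > 0 and n_spk < max_spk and duration is None:
        # explicit duration doubles as a legitimate stopping rule; only a
        # pure spike-count stop that exhausts the hard wall is an error
        raise SimulationTimeoutError(
            f"only {n_spk}/{max_spk} spikes within {wall:.0f} ms wall")
    t = np.arange(rec.shape[0]) * dt * record_every
    V = rec[:, 0]
    gates = {"x": rec[:, 1], "h": rec[:, 2], "n": rec[:, 3], "xi": rec[:, 4]}
    # AP durations from the recorded trace (full resolution runs only give
    # meaningful durations; decimated traces interpolate coarsely)
    durations = _ap_durations(t, V, spikes)
    return Trace(t=t, V=V, gates=gates, spike_times=spikes,
                 ap_durations=durations, dt=dt * record_every,
                 status="stopped_at_spike_count" if status == 1 else "completed")


def detect_spikes(t: np.ndarray, V: np.ndarray,
                  detect_level: float = K.SPIKE_DETECT_V,
                  refractory: float = K.REFRACTORY_MS,
                  duration_level: float = AP_DURATION_LEVEL):
    """Spike times and AP durations from a raw uniformly sampled V series.

    One event per upward crossing of ``detect_level`` separated by at least
    ``refractory`` ms; durations are measured at ``duration_level`` with
    linear interpolation.
    """
    t = np.asarray(t, float)
    V = np.asarray(V, float)
    up = np.nonzero((V[:-1] < detect_level) & (V[1:] >= detect_level))[0]
    times = []
    last = -np.inf
    for i in up:
        ts = t[i] + (t[i + 1] - t[i]) * (detect_level - V[i]) / (V[i + 1] - V[i])
        if ts - last > refractory:
            times.append(ts)
            last = ts
    times = np.asarray(times)
    return times, _ap_durations(t, V, times, level=duration_level)


def _ap_durations(t, V, spike_times, level: float = AP_DURATION_LEVEL):
    """Width of each AP at ``level``, linearly interpolated."""
    out = []
    if len(spike_times) == 0 or len(t) < 3:
        return np.asarray(out)
    dtg = t[1] - t[0]
    for ts in spike_times:
        i = int(ts / dtg)
        # walk back to the upward crossing of `level`
        j = i
        while j > 0 and V[j] > level:
            j -= 1
        if V[j] > level:
            continue
        t_up = t[j] + dtg * (level - V[j]) / (V[j + 1] - V[j])
        j = i
        while j < len(V) - 1 and V[j + 1] > level:
            j += 1
        if j >= len(V) - 1:
            continue
        t_dn = t[j] + dtg * (V[j] - level) / (V[j] - V[j + 1])
        out.append(t_dn - t_up)
    return np.asarray(out)


def ap_duration_baseline(membrane: MembraneParams,
                         x: Optional[XConductance], I: float,
                         dt: float = DEFAULT_DT) -> float:
    """Mean AP duration (ms at -20 mV) over ~10 spikes at current ``I``."""
    tr = simulate(membrane, x, I=I, duration=3000.0,
                  stop_after_spikes=12, dt=dt)
    if len(tr.ap_durations) == 0:
        return np.nan
    return float(np.mean(tr.ap_durations[1:]))
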