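"""f-I curve construction: threshold current, gain and inverse gain.

A *model closure* here is any callable ``rate_fn(I) -> Hz`` returning the
mean firing frequency at injected current ``I``.  :func:`make_rate_fn`
builds one from a simulation scenario; the analysis functions are agnostic
of where the rates come from, which keeps them testable against synthetic
generators.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np
from scipy import stats

from .model_core import DEFAULT_DT, simulate, SimulationTimeoutError
from .params import MembraneParams, NoiseParams, XConductance

DEFAULT_F_LOW = 5.0    # Hz, lower bound of the linear fitting window
DEFAULT_F_HIGH = 60.0  # Hz, upper bound (avoids saturation shoulder)
DEFAULT_N_ISI = 30


class NoSpikingError(RuntimeError):
    """Scan never elicited firing (admissibility category: high threshold)."""


class SpontaneousFiringError(RuntimeError):
    """Model fires at the lowest scanned current (category: spontaneous)."""


class SaturationError(RuntimeError):
    """Frequency saturates below the requested fitting window top."""


class DiscontinuousOnsetError(RuntimeError):
    """f jumps across the whole fitting window: effectively infinite gain."""


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    r: float
    t_statistic: float
    p_value: float
    n: int

    @property
    def r2(self) -> float:
        return self.r * self.r


@dataclass
class FICurve:
    currents: np.ndarray     # µA/cm²
    frequencies: np.ndarray  # Hz
    n_isi: int
    I_theta: float           # µA/cm², from the first-spiking-current rule
    E: float                 # µA/cm² per Hz (inverse gain)
    gain: float              # Hz per µA/cm²
    fit: RegressionResult
    poor_linearity: bool = False


def mean_frequency(spike_times, n_isi: int = DEFAULT_N_ISI) -> float:
    """Mean rate over the first ``n_isi`` inter-spike intervals (Hz).

    Returns ``n_isi / (t[n_isi] - t[0])``; 0 if fewer than 2 spikes.  When
    fewer than ``n_isi`` ISIs are available, all of them are used.
    """
    if n_isi < 1:
        raise ValueError("n_isi must be >= 1")
    st = np.asarray(spike_times, float)
    if len(st) < 2:
        return 0.0
    m = min(n_isi, len(st) - 1)
    return 1000.0 * m / (st[m] - st[0])


def model_I_regression(xs, ys) -> RegressionResult:
    """Ordinary least squares with the correlation-coefficient test
    (t = r sqrt((n-2)/(1-r^2)), n-2 degrees of freedom)."""
    xs = np.asarray(xs, float)
    ys = np.asarray(ys, float)
    n = len(xs)
    if n < 3:
        raise ValueError("need at least 3 points")
    if np.ptp(xs) == 0:
        raise ValueError("zero variance in x")
    res = stats.linregress(xs, ys)
    r = float(res.rvalue)
    if abs(r) >= 1.0:
        t = math.inf
        p = 0.0
    else:
        t = r * math.sqrt((n - 2) / (1.0 - r * r))
        p = 2.0 * stats.t.sf(abs(t), n - 2)
    return RegressionResult(slope=float(res.slope),
                            intercept=float(res.intercept), r=r,
                            t_statistic=t, p_value=p, n=n)


def make_rate_fn(membrane: MembraneParams, x: Optional[XConductance],
                 noise: Optional[NoiseParams] = None,
                 n_isi: int = DEFAULT_N_ISI, dt: float = DEFAULT_DT,
                 probe_ms: Optional[float] = None) -> Callable[[float], float]:
    """Closure measuring the mean rate at current I from simulations.

    Runs until ``n_isi + 1`` spikes are collected, with a hard wall at
    ``probe_ms`` (default: generous enough for ~4 Hz and the requested ISI
    count); fewer spikes simply yield the rate over the available ISIs.
    """
    if probe_ms is None:
        probe_ms = max(2000.0, (n_isi + 1) * 250.0)

    def rate_fn(I: float) -> float:
        try:
            tr = simulate(membrane, x, I=I, noise=noise, duration=probe_ms,
                          stop_after_spikes=n_isi + 1, dt=dt,
                          record_every=1_000_000)
        except SimulationTimeoutError:
            tr = simulate(membrane, x, I=I, noise=noise, duration=probe_ms,
                          dt=dt, record_every=1_000_000)
        return mean_frequency(tr.spike_times, n_isi)

    return rate_fn


def find_current_threshold(rate_fn: Callable[[float], float],
                           I_min: float = 0.0, I_max: float = 30.0,
                           n_scan: int = 100, n_bisect: int = 8) -> float:
    """Smallest current eliciting a non-null mean firing frequency.

    Scans ``n_scan`` currents uniformly, then refines by bisection between
    the last silent and first firing current.
    """
    grid = np.linspace(I_min, I_max, n_scan + 1)
    fired = None
    for i, I in enumerate(grid):
        if rate_fn(I) > 0.0:
            fired = i
            break
    if fired is None:
        raise NoSpikingError(f"no discharge up to I = {I_max} µA/cm²")
    if fired == 0:
        raise SpontaneousFiringError(f"fires at lowest current I = {grid[0]}")
    lo, hi = grid[fired - 1], grid[fired]
    for _ in range(n_bisect):
        mid = 0.5 * (lo + hi)
        if rate_fn(mid) > 0.0:
            hi = mid
        else:
            lo = mid
    return hi


def current_for_rate(rate_fn: Callable[[float], float], target: float,
                     I_lo: float, I_hi: float, rel_tol: float = 0.02,
                     max_iter: int = 30) -> float:
    """Current producing ``target`` Hz, by regula falsi with bisection
    fallback (f(I) is close to linear, so this converges in a few probes)."""
    f_lo = rate_fn(I_lo)
    f_hi = rate_fn(I_hi)
    if f_hi < target:
        raise SaturationError(
            f"max rate {f_hi:.1f} Hz at I = {I_hi} below target {target} Hz")
    if f_lo >= target:
        return I_lo
    lo, hi = I_lo, I_hi
    for _ in range(max_iter):
        if f_hi > f_lo:
            mid = lo + (hi - lo) * (target - f_lo) / (f_hi - f_lo)
            # keep strictly inside the bracket
            mid = min(max(mid, lo + 0.05 * (hi - lo)), hi - 0.05 * (hi - lo))
        else:
            mid = 0.5 * (lo + hi)
        f_mid = rate_fn(mid)
        if abs(f_mid - target) <= rel_tol * target:
            return mid
        if f_mid < target:
            lo, f_lo = mid, f_mid
        else:
            hi, f_hi = mid, f_mid
    return 0.5 * (lo + hi)


def fit_fi(rate_fn: Callable[[float], float],
           F_low: float = DEFAULT_F_LOW, F_high: float = DEFAULT_F_HIGH,
           n_points: int = 30, I_theta: Optional[float] = None,
           I_max: float = 30.0, n_isi: int = DEFAULT_N_ISI,
           bound_rel_tol: float = 0.02) -> FICurve:
    """Linear f-I fit over currents spanning [F_low, F_high] Hz.

    The gain is the regression slope of frequency on current and E its
    reciprocal.  ``I_theta`` is the first-spiking current (computed here if
    not supplied) rather than the regression intercept, which would be
    biased by gain changes.
    """
    if n_points < 3:
        raise ValueError("n_points must be >= 3")
    if I_theta is None:
        I_theta = find_current_threshold(rate_fn, I_max=I_max)
    I_lo = current_for_rate(rate_fn, F_low, I_theta, I_max,
                            rel_tol=bound_rel_tol)
    I_hi = current_for_rate(rate_fn, F_high, I_lo, I_max,
                            rel_tol=bound_rel_tol)
    if I_hi - I_lo < 1e-6:
        raise DiscontinuousOnsetError(
            f"f rises from {F_low} to {F_high} Hz within <1e-6 µA/cm²")
    currents = np.linspace(I_lo, I_hi, n_points)
    freqs = np.array([rate_fn(I) for I in currents])
    fit = model_I_regression(currents, freqs)
    gain = fit.slope
    E = 1.0 / gain if gain != 0 else math.inf
    return FICurve(currents=currents, frequencies=freqs, n_isi=n_isi,
                   I_theta=float(I_theta), E=E, gain=gain, fit=fit,
                   poor_linearity=bool(fit.p_value >= 0.05))
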