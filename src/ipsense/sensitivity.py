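"""Threshold (S_theta) and inverse-gain (S_E) sensitivity estimation.

I_theta and E depend linearly on the maximal conductance gmax, so the
sensitivities are regression slopes of I_theta(gmax) and E(gmax) taken over
a geometric gmax progression restricted by an admissibility filter that
rejects unphysiological regimes (absurd thresholds, gains, saturation,
distorted action potentials).
"""
from __future__ import annotations

import csv
import math
import os
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np

from .excitability import (DEFAULT_F_HIGH, DEFAULT_F_LOW, DiscontinuousOnsetError, FICurve,
                           NoSpikingError, RegressionResult, SaturationError,
                           SpontaneousFiringError, current_for_rate,
                           find_current_threshold, fit_fi, make_rate_fn,
                           model_I_regression)
from .model_core import (AP_DURATION_TARGET, AP_DURATION_TOL, DEFAULT_DT,
                         ap_duration_baseline, simulate)
from .params import MembraneParams, XConductance

CATEGORY_PASS = "pass"
CATEGORIES = ("pass", "high_threshold", "spontaneous", "low_gain",
              "high_gain", "saturation", "short_AP", "long_AP")

GAIN_BOUND_FACTOR = 2.5
TEST_CURRENT = 30.0       # µA/cm², category-1 probe
G1_DEFAULT_FRACTION = 1e-3  # g1 = g_L / 1000
G1_TOLERANCE = 0.005        # relative no-effect tolerance at g1
DEFAULT_RATIO = 2.0
MAX_PROGRESSION = 15


class DegenerateStartError(RuntimeError):
    """The first progression point already fails admissibility."""


class InsufficientRangeError(RuntimeError):
    """Fewer than 3 admissible gmax values."""


@dataclass
class AdmissibilityVerdict:
    category: str
    detail: float = math.nan

    @property
    def passed(self) -> bool:
        return self.category == CATEGORY_PASS


@dataclass
class Baseline:
    """gmax = 0 reference quantities shared by a whole map."""
    I_theta: float
    E: float
    gain: float
    ap_duration: float
    fi: Optional[FICurve] = None


@dataclass
class SensitivityEstimate:
    S_theta: float                     # µA/cm² per mS/cm² (≡ mV)
    S_E: float                         # µA/cm²·s per mS/cm²
    gmax_list: np.ndarray
    fit_theta: Optional[RegressionResult]
    fit_E: Optional[RegressionResult]
    linear: bool
    I_theta_list: np.ndarray = field(default_factory=lambda: np.array([]))
    E_list: np.ndarray = field(default_factory=lambda: np.array([]))
    truncated_by: str = ""
    # linear-description threshold: slope of the fitted-line current
    # intercept a(gmax).  Without background noise the first-spiking
    # threshold shifts faster with gmax than the fitted line does, so the
    # frequency-decomposition identity must use S_a, not S_theta.
    S_a: float = math.nan
    fit_a: Optional[RegressionResult] = None
    a_list: np.ndarray = field(default_factory=lambda: np.array([]))


@dataclass
class SensitivityMap:
    V_half: np.ndarray                 # grid axis, mV
    k: np.ndarray                      # grid axis, mV
    S_theta: np.ndarray                # (len(k), len(V_half))
    S_E: np.ndarray
    r2_theta: np.ndarray
    r2_E: np.ndarray
    n_gmax: np.ndarray
    fail_category: np.ndarray          # object array of strings
    template: Optional[XConductance] = None
    ap_model: str = ""
    seed: int = 0


def _fires(membrane, x, I, dt, probe_ms=1000.0) -> bool:
    tr = simulate(membrane, x, I=I, duration=probe_ms, stop_after_spikes=3,
                  dt=dt, record_every=1_000_000)
    return tr.n_spikes >= 2


def measure_threshold(membrane: MembraneParams, x: Optional[XConductance],
                      dt: float = DEFAULT_DT, I_max: float = TEST_CURRENT,
                      hint: Optional[float] = None,
                      resolution: float = 1e-4) -> float:
    """Rheobase by bracket expansion + bisection on a cheap firing probe.

    Bisects down to a fixed absolute current ``resolution`` so thresholds
    measured at different gmax are directly comparable.  Raises
    :class:`SpontaneousFiringError` if the model fires at I = 0 and
    :class:`NoSpikingError` if it stays silent up to ``I_max``.
    """
    if _fires(membrane, x, 0.0, dt):
        raise SpontaneousFiringError("fires at I = 0")
    hi = min(I_max, max(2.0 * hint, 0.25)) if hint is not None else I_max
    while not _fires(membrane, x, hi, dt):
        if hi >= I_max:
            raise NoSpikingError(f"no discharge up to I = {I_max} µA/cm²")
        hi = min(I_max, 2.0 * hi)
    lo = 0.0
    while hi - lo > resolution:
        mid = 0.5 * (lo + hi)
        if _fires(membrane, x, mid, dt):
            hi = mid
        else:
            lo = mid
    return hi


def compute_baseline(membrane: MembraneParams,
                     template: Optional[XConductance] = None,
                     dt: float = DEFAULT_DT, F_low: float = DEFAULT_F_LOW,
                     F_high: float = DEFAULT_F_HIGH,
                     full: bool = True, n_points: int = 30) -> Baseline:
    """Baseline excitability at gmax = 0 (template kinetics irrelevant).

    ``n_points`` must match the per-gmax f-I fits it anchors: the fitted E
    carries a small sampling-dependent bias, so mixing point counts between
    the baseline and the progression corrupts the S_E regression.
    """
    x0 = template.with_gmax(0.0) if template is not None else None
    I_theta = measure_threshold(membrane, x0, dt=dt)
    if full:
        rate_fn = make_rate_fn(membrane, x0, dt=dt)
        fi = fit_fi(rate_fn, F_low=F_low, F_high=F_high, I_theta=I_theta,
                    n_points=n_points, bound_rel_tol=5e-4)
        I_mid = float(np.median(fi.currents))
        dur = ap_duration_baseline(membrane, x0, I=I_mid, dt=dt)
        return Baseline(I_theta=I_theta, E=fi.E, gain=fi.gain,
                        ap_duration=dur, fi=fi)
    dur = ap_duration_baseline(membrane, x0, I=max(2.0 * I_theta, 1.0), dt=dt)
    return Baseline(I_theta=I_theta, E=math.nan, gain=math.nan,
                    ap_duration=dur)


def admissibility_check(membrane: MembraneParams, x: XConductance,
                        baseline: Baseline, dt: float = DEFAULT_DT,
                        F_low: float = DEFAULT_F_LOW,
                        F_high: float = DEFAULT_F_HIGH,
                        measure: str = "both", n_points: int = 30):
    """Classify one gmax value and measure (I_theta, E) if admissible.

    Returns ``(verdict, I_theta, fi_or_None)``.  Categories follow the
    fixed order: high_threshold, spontaneous, gain bounds, saturation,
    AP-duration band.  With ``measure="theta"`` the gain/saturation
    categories are skipped (used for threshold-only maps).
    """
    if not _fires(membrane, x, TEST_CURRENT, dt):
        return AdmissibilityVerdict("high_threshold", TEST_CURRENT), math.nan, None
    if _fires(membrane, x, 0.0, dt):
        return AdmissibilityVerdict("spontaneous", 0.0), math.nan, None
    I_theta = measure_threshold(membrane, x, dt=dt, hint=baseline.I_theta)

    fi = None
    if measure == "both":
        rate_fn = make_rate_fn(membrane, x, dt=dt)
        try:
            # tight window-bound tolerance: E differences along the gmax
            # progression are small, and bound jitter aliases into S_E
            fi = fit_fi(rate_fn, F_low=F_low, F_high=F_high,
                        I_theta=I_theta, n_points=n_points,
                        bound_rel_tol=5e-4)
        except SaturationError:
            return AdmissibilityVerdict("saturation", math.nan), I_theta, None
        except DiscontinuousOnsetError:
            return AdmissibilityVerdict("high_gain", math.inf), I_theta, None
        if fi.gain < baseline.gain / GAIN_BOUND_FACTOR:
            return AdmissibilityVerdict("low_gain", fi.gain), I_theta, fi
        if fi.gain > baseline.gain * GAIN_BOUND_FACTOR:
            return AdmissibilityVerdict("high_gain", fi.gain), I_theta, fi
        I_dur = float(np.median(fi.currents))
    else:
        I_dur = max(2.0 * I_theta, 1.0)
    dur = ap_duration_baseline(membrane, x, I=I_dur, dt=dt)
    lo = AP_DURATION_TARGET * (1.0 - AP_DURATION_TOL)
    hi = AP_DURATION_TARGET * (1.0 + AP_DURATION_TOL)
    if np.isfinite(dur):
        if dur < lo:
            return AdmissibilityVerdict("short_AP", dur), I_theta, fi
        if dur > hi:
            return AdmissibilityVerdict("long_AP", dur), I_theta, fi
    return AdmissibilityVerdict(CATEGORY_PASS, dur), I_theta, fi


def select_g1(membrane: MembraneParams, template: XConductance,
              baseline: Baseline, dt: float = DEFAULT_DT,
              g1: Optional[float] = None, max_halvings: int = 6) -> float:
    """First progression point: small enough to leave I_theta unchanged."""
    if g1 is None:
        g1 = membrane.g_L * G1_DEFAULT_FRACTION
    for _ in range(max_halvings + 1):
        th = measure_threshold(membrane, template.with_gmax(g1), dt=dt,
                               hint=baseline.I_theta)
        if abs(th - baseline.I_theta) < G1_TOLERANCE * abs(baseline.I_theta):
            return g1
        g1 *= 0.5
    return g1


def gmax_progression(membrane: MembraneParams, template: XConductance,
                     baseline: Baseline, g1: Optional[float] = None,
                     ratio: float = DEFAULT_RATIO,
                     max_steps: int = MAX_PROGRESSION,
                     dt: float = DEFAULT_DT, measure: str = "both",
                     F_low: float = DEFAULT_F_LOW,
                     F_high: float = DEFAULT_F_HIGH,
                     n_points: int = 30):
    """Longest admissible geometric prefix g1, g1*ratio, g1*ratio^2, ...

    Returns ``(gmax_list, I_theta_list, E_list, a_list, truncated_by)``
    where ``a`` is the fitted-line current intercept; E and a entries are
    NaN in threshold-only mode.
    """
    if ratio <= 1.0:
        raise ValueError("ratio must be > 1")
    if g1 is None:
        g1 = select_g1(membrane, template, baseline, dt=dt)
    gs, ths, Es, As = [], [], [], []
    truncated_by = ""
    for i in range(max_steps):
        g = g1 * ratio ** i
        verdict, th, fi = admissibility_check(
            membrane, template.with_gmax(g), baseline, dt=dt,
            measure=measure, F_low=F_low, F_high=F_high, n_points=n_points)
        if not verdict.passed:
            truncated_by = verdict.category
            if i == 0:
                raise DegenerateStartError(
                    f"g1 = {g1:g} fails admissibility: {verdict.category}")
            break
        gs.append(g)
        ths.append(th)
        Es.append(fi.E if fi is not None else math.nan)
        As.append(-fi.fit.intercept / fi.fit.slope
                  if fi is not None else math.nan)
    return (np.asarray(gs), np.asarray(ths), np.asarray(Es),
            np.asarray(As), truncated_by)


def estimate_sensitivities(membrane: MembraneParams, template: XConductance,
                           baseline: Optional[Baseline] = None,
                           g1: Optional[float] = None,
                           ratio: float = DEFAULT_RATIO,
                           dt: float = DEFAULT_DT, measure: str = "both",
                           r2_linear: float = 0.99,
                           F_low: float = DEFAULT_F_LOW,
                           F_high: float = DEFAULT_F_HIGH,
                           n_points: int = 30) -> SensitivityEstimate:
    """Model-I regression slopes of I_theta(gmax) and E(gmax).

    The gmax = 0 baseline is included as the regression anchor point.
    """
    if baseline is None:
        baseline = compute_baseline(membrane, template, dt=dt,
                                    full=(measure == "both"),
                                    F_low=F_low, F_high=F_high,
                                    n_points=n_points)
    gs, ths, Es, As, trunc = gmax_progression(membrane, template, baseline,
                                              g1=g1, ratio=ratio, dt=dt,
                                              measure=measure, F_low=F_low,
                                              F_high=F_high,
                                              n_points=n_points)
    if len(gs) < 3:
        raise InsufficientRangeError(
            f"only {len(gs)} admissible gmax values (truncated by {trunc})")
    g_all = np.concatenate([[0.0], gs])
    th_all = np.concatenate([[baseline.I_theta], ths])
    fit_theta = model_I_regression(g_all, th_all)
    fit_E = None
    fit_a = None
    S_E = math.nan
    S_a = math.nan
    E_all = np.array([])
    a_all = np.array([])
    if measure == "both":
        E_all = np.concatenate([[baseline.E], Es])
        fit_E = model_I_regression(g_all, E_all)
        S_E = fit_E.slope  # µA/cm² per Hz, per mS/cm²
        a0 = -baseline.fi.fit.intercept / baseline.fi.fit.slope
        a_all = np.concatenate([[a0], As])
        fit_a = model_I_regression(g_all, a_all)
        S_a = fit_a.slope
    linear = fit_theta.r2 > r2_linear and (fit_E is None or fit_E.r2 > r2_linear)
    return SensitivityEstimate(
        S_theta=fit_theta.slope, S_E=S_E, gmax_list=gs, fit_theta=fit_theta,
        fit_E=fit_E, linear=bool(linear), I_theta_list=th_all,
        E_list=E_all, truncated_by=trunc, S_a=S_a, fit_a=fit_a,
        a_list=a_all)


def default_grid(n_vhalf: int = 9, n_k: int = 9):
    """Desk-scale (V_half, k) lattice within the physiological window."""
    return np.linspace(-80.0, -40.0, n_vhalf), np.linspace(1.0, 15.0, n_k)


def compute_map(membrane: MembraneParams, template: XConductance,
                V_half_grid: Optional[Sequence[float]] = None,
                k_grid: Optional[Sequence[float]] = None,
                dt: float = DEFAULT_DT, measure: str = "both",
                seed: int = 0, checkpoint_path: Optional[str] = None,
                ratio: float = DEFAULT_RATIO,
                F_low: float = DEFAULT_F_LOW, F_high: float = DEFAULT_F_HIGH,
                n_points: int = 30,
                progress: Optional[Callable[[str], None]] = None) -> SensitivityMap:
    """Per-node sensitivity estimates over the (V_half, k) lattice.

    Node failures are recorded in ``fail_category`` and leave NaN cells.
    With ``checkpoint_path`` finished nodes are appended to a CSV and
    skipped on re-run, making long sweeps resumable.
    """
    if V_half_grid is None or k_grid is None:
        dv, dk = default_grid()
        V_half_grid = dv if V_half_grid is None else np.asarray(V_half_grid)
        k_grid = dk if k_grid is None else np.asarray(k_grid)
    V_half_grid = np.asarray(V_half_grid, float)
    k_grid = np.asarray(k_grid, float)

    nk, nv = len(k_grid), len(V_half_grid)
    S_theta = np.full((nk, nv), np.nan)
    S_E = np.full((nk, nv), np.nan)
    r2t = np.full((nk, nv), np.nan)
    r2e = np.full((nk, nv), np.nan)
    ng = np.zeros((nk, nv), dtype=int)
    fail = np.full((nk, nv), "", dtype=object)

    done = {}
    if checkpoint_path and os.path.exists(checkpoint_path):
        with open(checkpoint_path) as fh:
            for row in csv.DictReader(fh):
                done[(float(row["V_half"]), float(row["k"]))] = row

    ck = None
    if checkpoint_path:
        new_file = not os.path.exists(checkpoint_path)
        ck = open(checkpoint_path, "a", newline="")
        writer = csv.writer(ck)
        if new_file:
            writer.writerow(["V_half", "k", "S_theta", "S_E", "r2_theta",
                            "r2_E", "n_gmax", "fail_category"])

    baseline = compute_baseline(membrane, template, dt=dt,
                                full=(measure == "both"),
                                F_low=F_low, F_high=F_high,
                                n_points=n_points)
    try:
        for j, k in enumerate(k_grid):
            for i, vh in enumerate(V_half_grid):
                key = (float(vh), float(k))
                if key in done:
                    row = done[key]
                    S_theta[j, i] = float(row["S_theta"])
                    S_E[j, i] = float(row["S_E"])
                    r2t[j, i] = float(row["r2_theta"])
                    r2e[j, i] = float(row["r2_E"])
                    ng[j, i] = int(row["n_gmax"])
                    fail[j, i] = row["fail_category"]
                    continue
                act = template.activation
                tau = act.tau
                node = template.replace(activation=type(act)(vh, k, tau))
                try:
                    est = estimate_sensitivities(membrane, node,
                                                 baseline=baseline, dt=dt,
                                                 measure=measure,
                                                 ratio=ratio, F_low=F_low,
                                                 F_high=F_high,
                                                 n_points=n_points)
                    S_theta[j, i] = est.S_theta
                    S_E[j, i] = est.S_E
                    r2t[j, i] = est.fit_theta.r2
                    r2e[j, i] = est.fit_E.r2 if est.fit_E else np.nan
                    ng[j, i] = len(est.gmax_list)
                except (InsufficientRangeError, DegenerateStartError,
                        NoSpikingError, SpontaneousFiringError) as exc:
                    fail[j, i] = type(exc).__name__
                if progress:
                    progress(f"node V_half={vh:g} k={k:g} "
                             f"S_theta={S_theta[j, i]:.4g} S_E={S_E[j, i]:.4g}")
                if ck:
                    writer.writerow([vh, k, S_theta[j, i], S_E[j, i],
                                     r2t[j, i], r2e[j, i], ng[j, i],
                                     fail[j, i]])
                    ck.flush()
    finally:
        if ck:
            ck.close()
    return SensitivityMap(V_half=V_half_grid, k=k_grid, S_theta=S_theta,
                          S_E=S_E, r2_theta=r2t, r2_E=r2e, n_gmax=ng,
                          fail_category=fail, template=template,
                          ap_model=membrane.ap_model, seed=seed)
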