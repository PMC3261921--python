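"""Sensitivities of threshold and inverse gain to kinetic parameters.

For a parameter q of the X conductance, the chain rule gives
dI_theta/dq = S_theta * dgmax/dq + gmax * dS_theta/dq (and analogously for
E).  With independent plasticity of q (gmax fixed) the first term drops,
so the kinetic-parameter sensitivities scale with gmax and the partial
derivatives of the analytic sensitivity expressions.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np

from .iaf_theory import IAFParams, s_E_analytic, s_theta_analytic
from .model_core import boltzmann_steady_state
from .params import GateKinetics, XConductance

SUPPORTED = ("V_half", "k", "E_X", "tau")


class UnsupportedParameterError(ValueError):
    pass


class StepTooLargeError(RuntimeError):
    """Admissibility lost at the perturbed parameter value."""


@dataclass
class ParameterSensitivity:
    parameter: str
    dI_theta_dq: float
    dE_dq: float
    method: str          # "analytic" | "finite_difference"
    gmax: float
    non_smooth: bool = False   # Richardson self-check flag (FD only)


def _perturb(x: XConductance, q: str, value: float) -> XConductance:
    a = x.activation
    if q == "V_half":
        return x.replace(activation=GateKinetics(value, a.k, a.tau))
    if q == "k":
        return x.replace(activation=GateKinetics(a.V_half, value, a.tau))
    if q == "tau":
        return x.replace(activation=GateKinetics(a.V_half, a.k, value))
    if q == "E_X":
        return x.replace(E_X=value)
    raise UnsupportedParameterError(f"unsupported parameter {q!r}")


def _q_value(x: XConductance, q: str) -> float:
    if q in ("V_half", "k", "tau"):
        return float(getattr(x.activation, q))
    if q == "E_X":
        return x.E_X
    raise UnsupportedParameterError(f"unsupported parameter {q!r}")


def ds_theta_dq(q: str, x: XConductance, iaf: IAFParams) -> float:
    """Hand-derived partial derivatives of the closed-form S_theta.

    With s = x_inf(V_theta):
      dS/dV_half = -(V_theta - E_X) p s^p (1 - s) / k
      dS/dk      = -(V_theta - E_X) p s^p (1 - s) (V_theta - V_half) / k²
      dS/dE_X    = -s^p
      dS/dtau    = 0  (steady activation does not involve tau)
    """
    a = x.activation
    s = boltzmann_steady_state(iaf.V_theta, a)
    drive = iaf.V_theta - x.E_X
    if q == "V_half":
        return -drive * x.p * s ** x.p * (1.0 - s) / a.k
    if q == "k":
        return (-drive * x.p * s ** x.p * (1.0 - s)
                * (iaf.V_theta - a.V_half) / a.k ** 2)
    if q == "E_X":
        return -(s ** x.p)
    if q == "tau":
        return 0.0
    raise UnsupportedParameterError(f"unsupported parameter {q!r}")


def ds_E_dq(q: str, x: XConductance, iaf: IAFParams,
            theory: str = "prepost", rel_step: float = 0.02) -> float:
    """dS_E/dq by central differencing of the analytic S_E (the expression
    is evaluated through the reduced-model pipeline, so the step is kept
    large enough to dominate the solver tolerance)."""
    q0 = _q_value(x, q)
    h = max(abs(q0) * rel_step, rel_step)
    sp = s_E_analytic(_perturb(x, q, q0 + h), iaf, theory=theory)
    sm = s_E_analytic(_perturb(x, q, q0 - h), iaf, theory=theory)
    return (sp - sm) / (2.0 * h)


def sensitivity_to_parameter(q: str, x: XConductance, iaf: IAFParams,
                             coupling: str = "independent",
                             dgmax_dq: float = 0.0,
                             S_theta: Optional[float] = None,
                             S_E: Optional[float] = None,
                             theory: str = "prepost") -> ParameterSensitivity:
    """Analytic kinetic-parameter sensitivities at fixed gmax.

    ``coupling="independent"``: dI_theta/dq = gmax * dS_theta/dq.
    ``coupling="coupled"``: adds the cross term S_theta * dgmax/dq
    (requires ``dgmax_dq``).
    """
    if q not in SUPPORTED:
        raise UnsupportedParameterError(f"unsupported parameter {q!r}")
    dI = x.gmax * ds_theta_dq(q, x, iaf)
    dE = x.gmax * (ds_E_dq(q, x, iaf, theory=theory) if x.gmax != 0 else 0.0)
    if coupling == "coupled":
        st = s_theta_analytic(x, iaf) if S_theta is None else S_theta
        se = s_E_analytic(x, iaf, theory=theory) if S_E is None else S_E
        dI += st * dgmax_dq
        dE += se * dgmax_dq
    elif coupling != "independent":
        raise ValueError(f"unknown coupling {coupling!r}")
    return ParameterSensitivity(parameter=q, dI_theta_dq=dI, dE_dq=dE,
                                method="analytic", gmax=x.gmax)


def finite_difference_oracle(q: str, x: XConductance,
                             measure: Callable[[XConductance], tuple],
                             step: float,
                             richardson_tol: float = 0.2) -> ParameterSensitivity:
    """Central-difference sensitivities from a measurement closure.

    ``measure(x) -> (I_theta, E)`` is evaluated at q ± step and q ± step/2;
    the half-step (Richardson) pair flags non-smoothness when the two
    estimates disagree by more than ``richardson_tol`` relatively.
    """
    if q not in SUPPORTED:
        raise UnsupportedParameterError(f"unsupported parameter {q!r}")
    q0 = _q_value(x, q)

    def central(h):
        try:
            Ip, Ep = measure(_perturb(x, q, q0 + h))
            Im, Em = measure(_perturb(x, q, q0 - h))
        except Exception as exc:
            raise StepTooLargeError(
                f"measurement failed at {q} = {q0} ± {h}: {exc!r}") from exc
        return (Ip - Im) / (2.0 * h), (Ep - Em) / (2.0 * h)

    dI, dE = central(step)
    dI2, dE2 = central(step / 2.0)
    non_smooth = False
    for full, half in ((dI, dI2), (dE, dE2)):
        scale = max(abs(full), abs(half))
        if scale > 0 and math.isfinite(scale):
            if abs(full - half) > richardson_tol * scale:
                non_smooth = True
    return ParameterSensitivity(parameter=q, dI_theta_dq=dI2, dE_dq=dE2,
                                method="finite_difference", gmax=x.gmax,
                                non_smooth=non_smooth)
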