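"""Parameter containers for the conductance-based neuron model.

Units used project-wide: mV, ms, µA/cm², mS/cm², µF/cm², µM.
"""
from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np

INSTANTANEOUS = "instantaneous"


class InvalidParameterError(ValueError):
    """Raised when a parameter violates a model invariant."""


@dataclass(frozen=True)
class GateKinetics:
    """First-order Boltzmann gate.

    ``k`` is the e-fold slope in mV; its sign encodes the gating direction
    (positive: activation increasing with V, negative: inactivation).
    ``tau`` is the time constant in ms, or the string ``"instantaneous"``.
    """

    V_half: float
    k: float
    tau: float | str = 1.0

    def __post_init__(self):
        if self.k == 0:
            raise InvalidParameterError("gate e-fold slope k must be non-zero")
        if not self.is_instantaneous and self.tau <= 0:
            raise InvalidParameterError("gate time constant tau must be > 0")

    @property
    def is_instantaneous(self) -> bool:
        return isinstance(self.tau, str) and self.tau == INSTANTANEOUS


@dataclass(frozen=True)
class XConductance:
    """Generic plastic voltage-gated conductance.

    The gating product is ``x^p * xi`` where ``x`` is the activation variable
    and ``xi`` the (optional) inactivation variable; with ``inactivation``
    set to None the product reduces to ``x^p``.
    """

    gmax: float
    p: int
    activation: GateKinetics
    E_X: float
    inactivation: Optional[GateKinetics] = None

    def __post_init__(self):
        if self.gmax < 0:
            raise InvalidParameterError("gmax must be >= 0")
        if self.p not in (1, 2, 3, 4):
            raise InvalidParameterError("activation power p must be in {1,2,3,4}")

    def with_gmax(self, gmax: float) -> "XConductance":
        return XConductance(gmax, self.p, self.activation, self.E_X, self.inactivation)

    def replace(self, **kw) -> "XConductance":
        d = dict(gmax=self.gmax, p=self.p, activation=self.activation,
                 E_X=self.E_X, inactivation=self.inactivation)
        d.update(kw)
        return XConductance(**d)


# ---------------------------------------------------------------------------
# Action-potential current parameter sets.
#
# The AP machinery is a fast (instantaneous) sodium activation m_inf^3 * h
# plus a delayed-rectifier n^4, in the classical rate-function form of
# type I excitability single-compartment models.  Parameter sets are named
# and swappable; `rs_default` is tuned so the baseline AP duration measured
# at -20 mV falls in the 1.8 ms +/- 25% admissibility band while preserving
# continuous (type I) f-I onset.
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class APModel:
    name: str
    g_Na: float
    E_Na: float
    g_K: float
    E_K: float
    phi: float  # temperature-like factor scaling h and n kinetics


AP_MODELS = {
    # slowed repolarization -> ~1.8 ms AP at the -20 mV measurement level
    "rs_default": APModel("rs_default", g_Na=35.0, E_Na=55.0, g_K=9.0,
                          E_K=-90.0, phi=1.2),
    # the classical fast-kinetics variant, kept for robustness checks
    "rs_fast": APModel("rs_fast", g_Na=35.0, E_Na=55.0, g_K=9.0,
                       E_K=-90.0, phi=5.0),
}


@dataclass(frozen=True)
class MembraneParams:
    capacitance: float = 1.0    # µF/cm²
    g_L: float = 0.1            # mS/cm²
    E_L: float = -65.0          # mV
    ap_model: str = "rs_default"

    def __post_init__(self):
        if self.capacitance <= 0:
            raise InvalidParameterError("capacitance must be > 0")
        if self.g_L < 0:
            raise InvalidParameterError("g_L must be >= 0")
        if self.ap_model not in AP_MODELS:
            raise InvalidParameterError(
                f"unknown AP model {self.ap_model!r}; known: {sorted(AP_MODELS)}")

    @property
    def ap(self) -> APModel:
        return AP_MODELS[self.ap_model]


@dataclass(frozen=True)
class NoisePopulation:
    """One population of background Poisson conductance trains."""

    n_trains: int
    n_sync: int
    rate: float       # Hz, per train
    g_unit: float     # mS/cm², unitary conductance
    tau_syn: float    # ms
    E_syn: float      # mV

    def __post_init__(self):
        if self.n_trains < 0 or self.n_sync < 0:
            raise InvalidParameterError("counts must be >= 0")
        if self.rate < 0:
            raise InvalidParameterError("rate must be >= 0")

    @property
    def total_rate_per_ms(self) -> float:
        # superposition of independent Poisson trains is Poisson
        return self.n_trains * self.rate * 1e-3

    @property
    def jump(self) -> float:
        return self.g_unit * self.n_sync


@dataclass(frozen=True)
class NoiseParams:
    excitatory: NoisePopulation
    inhibitory: NoisePopulation
    seed: int = 0


def standard_noise(seed: int = 0) -> NoiseParams:
    """Background synaptic drive calibrated to ~15 Hz spontaneous firing.

    The excitatory unitary conductance was calibrated against the standard
    membrane (gmax of X = 0, I = 0) to reproduce a 15 Hz mean spontaneous
    rate; other values are typical AMPA/GABA-like figures.
    """
    return NoiseParams(
        excitatory=NoisePopulation(n_trains=100, n_sync=10, rate=10.0,
                                   g_unit=2.65e-4, tau_syn=3.0, E_syn=0.0),
        inhibitory=NoisePopulation(n_trains=50, n_sync=10, rate=10.0,
                                   g_unit=2.0e-4, tau_syn=10.0, E_syn=-80.0),
        seed=seed,
    )


# Standard X-conductance templates -----------------------------------------

def sodium_template(V_half: float = -60.0, k: float = 4.0, *,
                    gmax: float = 0.0, p: int = 1, tau: float | str = 5.0,
                    inactivation: Optional[GateKinetics] = None) -> XConductance:
    """Inward (sodium-type) non-inactivating template, E_X = E_Na."""
    return XConductance(gmax=gmax, p=p,
                        activation=GateKinetics(V_half, k, tau),
                        E_X=55.0, inactivation=inactivation)


def potassium_template(V_half: float = -40.0, k: float = 4.0, *,
                       gmax: float = 0.0, p: int = 1,
                       tau: float | str = 5.0) -> XConductance:
    return XConductance(gmax=gmax, p=p,
                        activation=GateKinetics(V_half, k, tau),
                        E_X=-90.0, inactivation=None)


def calcium_template(V_half: float = -40.0, k: float = 4.0, *,
                     gmax: float = 0.0, p: int = 1,
                     tau: float | str = 5.0) -> XConductance:
    return XConductance(gmax=gmax, p=p,
                        activation=GateKinetics(V_half, k, tau),
                        E_X=120.0, inactivation=None)
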