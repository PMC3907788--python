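"""Voltage- and calcium-gated channel primitives.

All four cell types share one small library of Hodgkin-Huxley-style mechanisms:
fast sodium (Na), delayed-rectifier potassium (Kdr), A-type potassium (KA),
slow non-inactivating potassium (Kslow), slowly inactivating D-type potassium
(KD), N- and T-type calcium (CaN, CaT), the hyperpolarization-activated cation
current (H), and a fast calcium-activated potassium current (fAHP).  Each gate
is a Boltzmann steady state with either a constant or a bell-shaped voltage
dependence of its time constant; the fAHP carries an instantaneous saturating
calcium factor instead of a voltage gate.  Somatic compartments carry a single
first-order buffered calcium pool fed by the calcium currents.

Units: voltage mV, time ms, conductance density S/cm2, current density mA/cm2,
calcium mM.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np

CHANNEL_KINDS = ("Na", "Kdr", "KA", "Kslow", "KD", "CaN", "CaT", "H", "fAHP")

#: gates whose steady state *decreases* with voltage carry a negative slope k
TAU_FORMS = ("constant", "bell")


@dataclass
class GatingScheme:
    """One activation or inactivation variable of a channel.

    Steady state is the Boltzmann sigmoid ``1 / (1 + exp((vhalf - v)/k))``
    (``k < 0`` yields an inactivation curve).  The time constant is either a
    constant ``tau_min`` or the bell
    ``tau_min + tau_amp / (exp((v - tau_vmax)/tau_sig1) + exp(-(v - tau_vmax)/tau_sig2))``.
    """

    role: str  # "activation" | "inactivation"
    exponent: int = 1
    vhalf: float = -40.0
    k: float = 6.0
    tau_form: str = "constant"
    tau_min: float = 1.0  # ms; the constant value when tau_form == "constant"
    tau_amp: float = 0.0
    tau_vmax: float = -40.0
    tau_sig1: float = 15.0
    tau_sig2: float = 15.0

    def steady_state(self, v: float) -> float:
        return 1.0 / (1.0 + math.exp((self.vhalf - v) / self.k))

    def time_constant(self, v: float) -> float:
        if self.tau_form == "constant":
            return self.tau_min
        u = v - self.tau_vmax
        return self.tau_min + self.tau_amp / (
            math.exp(u / self.tau_sig1) + math.exp(-u / self.tau_sig2)
        )


def evaluate_steady_state(scheme: GatingScheme, v: float) -> float:
    """Steady-state open fraction at voltage ``v``, clamped to [0, 1]."""
    if not np.isfinite(v):
        raise ValueError(f"non-finite voltage: {v!r}")
    return min(1.0, max(0.0, scheme.steady_state(v)))


def advance_gate(scheme: GatingScheme, x: float, v: float, dt: float) -> float:
    """Exact exponential relaxation of gate ``x`` toward its steady state.

    ``x(t+dt) = x_inf + (x - x_inf) * exp(-dt / tau(v))`` for voltage held at
    ``v`` over the step.  Exact for constant voltage, hence it composes: two
    half steps equal one full step.
    """
    if dt < 0:
        raise ValueError(f"negative dt: {dt!r}")
    if not np.isfinite(v):
        raise ValueError(f"non-finite voltage: {v!r}")
    xinf = evaluate_steady_state(scheme, v)
    x_new = xinf + (x - xinf) * math.exp(-dt / scheme.time_constant(v))
    return min(1.0, max(0.0, x_new))


@dataclass
class ChannelSpec:
    """A conductance density of one mechanism on one compartment."""

    kind: str
    gbar: float  # S/cm2
    reversal: float  # mV
    gates: list[GatingScheme] = field(default_factory=list)
    calcium_dependent: bool = False  # True only for fAHP
    ca_kd: float = 5e-4  # mM; half-activation of the fAHP calcium factor
    is_calcium_source: bool = False  # current feeds the calcium pool

    def __post_init__(self):
        if self.kind not in CHANNEL_KINDS:
            raise ValueError(f"unknown channel kind {self.kind!r}")
        if self.gbar < 0:
            raise ValueError("gbar must be >= 0")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ChannelSpec":
        d = dict(d)
        d["gates"] = [GatingScheme(**g) for g in d.get("gates", [])]
        return cls(**d)


def channel_current(
    spec: ChannelSpec, gate_values, v: float, ca: float = 0.0
) -> float:
    """Ohmic channel current density, positive outward (mA/cm2).

    ``gbar * prod(x_i ** p_i) * (v - reversal)``, multiplied by the saturating
    calcium factor ``ca / (ca + ca_kd)`` for calcium-dependent channels.
    """
    gate_values = list(gate_values)
    if len(gate_values) != len(spec.gates):
        raise ValueError(
            f"expected {len(spec.gates)} gate values, got {len(gate_values)}"
        )
    g = spec.gbar
    for x, scheme in zip(gate_values, spec.gates):
        if not (0.0 <= x <= 1.0):
            raise ValueError(f"gate value out of [0,1]: {x!r}")
        g *= x**scheme.exponent
    if spec.calcium_dependent:
        g *= ca / (ca + spec.ca_kd)
    return g * (v - spec.reversal)


@dataclass
class CalciumPool:
    """First-order buffered intracellular calcium pool.

    ``dCa/dt = -influx_factor * i_ca - (Ca - rest) / decay_tau`` with ``i_ca``
    the (inward-negative) calcium current density in mA/cm2 and concentrations
    in mM.
    """

    concentration: float = 5e-5
    rest_concentration: float = 5e-5
    decay_tau: float = 20.0  # ms
    influx_factor: float = 0.1  # mM per (mA/cm2 * ms)

    def to_dict(self) -> dict:
        return asdict(self)


def advance_calcium(pool: CalciumPool, i_ca: float, dt: float) -> CalciumPool:
    """Advance the pool analytically over ``dt`` under constant ``i_ca``.

    The linear ODE has fixed point ``rest - influx_factor * i_ca * decay_tau``
    and relaxes toward it with time constant ``decay_tau``.
    """
    if dt < 0:
        raise ValueError(f"negative dt: {dt!r}")
    fixed = pool.rest_concentration - pool.influx_factor * i_ca * pool.decay_tau
    ca = fixed + (pool.concentration - fixed) * math.exp(-dt / pool.decay_tau)
    return CalciumPool(
        concentration=max(0.0, ca),
        rest_concentration=pool.rest_concentration,
        decay_tau=pool.decay_tau,
        influx_factor=pool.influx_factor,
    )
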