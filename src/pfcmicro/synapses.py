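"""Synaptic mechanisms: AMPA, NMDA (voltage-dependent magnesium block),
GABA_A and GABA_B, their ratio-based scaling, and the voltage-clamp
validation protocols.

Conductances are peak-normalized differences of exponentials; an activation
event of weight w contributes a transient whose peak conductance is w.  The
NMDA conductance is multiplied by the standard sigmoidal magnesium-unblock
factor.  GABA_B is modelled as a slow delayed double-exponential conductance
with a potassium reversal (a simplification of the metabotropic cascade).

NMDA-to-AMPA ratios are defined operationally as peak-conductance ratios;
the clamp-based measurement reconstructs peak conductances from clamp
currents via the driving force and the known magnesium unblock at the
holding potential.  The GABA_B-to-GABA_A ratio is defined on unitary
somatic IPSP amplitudes (see ``GABAB_IPSP_SCALE``): the slow conductance is
not attenuated by membrane filtering, so matching IPSP amplitudes requires
far less GABA_B peak conductance than GABA_A.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np

from . import engine
from .engine import (AMPA, GABAA, GABAB, NMDA, CompiledNetwork,
                     SimulationConfig, integrate)
from .cells import CellModel, build_cell

MG_ETA = 0.28  # [Mg2+] = 1 mM divided by 3.57 mM
MG_GAMMA = 0.062  # 1/mV

#: default receptor kinetics (rise tau ms, decay tau ms, reversal mV)
RECEPTOR_DEFAULTS = {
    "AMPA": (0.5, 3.0, 0.0),
    "NMDA": (5.0, 150.0, 0.0),
    "GABAA": (0.5, 8.0, -75.0),
    "GABAB": (50.0, 150.0, -90.0),
}

RECEPTOR_INDEX = {"AMPA": AMPA, "NMDA": NMDA, "GABAA": GABAA, "GABAB": GABAB}

#: conductance scale giving GABA_B the same unitary somatic IPSP amplitude as
#: GABA_A on the resting pyramidal model (calibrated once); the
#: GABA_B-to-GABA_A ratio is defined on unitary IPSP amplitudes, so a synapse
#: of GABA_A weight g carries a GABA_B weight ratio * GABAB_IPSP_SCALE * g
GABAB_IPSP_SCALE = 0.085

#: FS autaptic IPSC transient amplitude (reported as "0.35 mA" in the source
#: literature, which is dimensionally implausible for a single synapse; read
#: as nA and exposed as a config constant)
FS_AUTAPSE_IPSC_NA = 0.35
#: holding potential at which that amplitude is defined
FS_AUTAPSE_HOLD_MV = -55.0


@dataclass
class SynapseKinetics:
    """Kinetic template of one receptor class."""

    receptor: str
    rise_tau: float
    decay_tau: float
    reversal: float
    gmax: float = 1e-3  # uS

    def __post_init__(self):
        if self.receptor not in RECEPTOR_INDEX:
            raise ValueError(f"unknown receptor {self.receptor!r}")
        if not (self.decay_tau > self.rise_tau > 0):
            raise ValueError("need decay_tau > rise_tau > 0")

    @classmethod
    def default(cls, receptor: str, gmax: float = 1e-3) -> "SynapseKinetics":
        r, d, e = RECEPTOR_DEFAULTS[receptor]
        return cls(receptor, r, d, e, gmax)

    def peak_time(self) -> float:
        tr, td = self.rise_tau, self.decay_tau
        return tr * td / (td - tr) * math.log(td / tr)

    def unit_conductance(self, t: np.ndarray) -> np.ndarray:
        """Peak-normalized conductance transient for one event at t = 0."""
        t = np.asarray(t, dtype=float)
        tp = self.peak_time()
        norm = 1.0 / (math.exp(-tp / self.decay_tau) - math.exp(-tp / self.rise_tau))
        g = norm * (np.exp(-t / self.decay_tau) - np.exp(-t / self.rise_tau))
        return np.where(t >= 0, g, 0.0)


@dataclass
class RatioConfig:
    """Receptor-balance parameters of the microcircuit (control state)."""

    nmda_ampa_pyr: float = 1.25
    nmda_ampa_fs: float = 0.5
    nmda_ampa_rs: float = 0.8
    nmda_ampa_is: float = 1.0  # smallest grid ratio at which IS fires during the stimulus
    gabab_gabaa: float = 0.2
    rs_pyr_gabaa_scale: float = 0.1  # relative to FS->Pyr GABA_A
    is_pyr_gabaa_scale: float = 0.1  # relative to RS->Pyr GABA_A

    def __post_init__(self):
        for name, value in asdict(self).items():
            if value < 0:
                raise ValueError(f"{name} must be >= 0")

    def nmda_ampa(self, post_type: str) -> float:
        return {
            "PYR": self.nmda_ampa_pyr,
            "FS": self.nmda_ampa_fs,
            "RS": self.nmda_ampa_rs,
            "IS": self.nmda_ampa_is,
        }[post_type]


@dataclass
class SynapseInstance:
    """One anatomical synapse: presynaptic cell, target compartment, and a
    receptor mix given as ``{receptor name: peak conductance uS}``."""

    pre: int
    post: int
    post_compartment: str
    receptor_weights: dict[str, float]
    latency: float
    is_autapse: bool = False

    def __post_init__(self):
        if self.latency <= 0:
            raise ValueError("latency must be positive")
        kinds = set(self.receptor_weights)
        if not (kinds <= {"AMPA", "NMDA"} or kinds <= {"GABAA", "GABAB"}):
            raise ValueError(f"inconsistent receptor mix {kinds}")


def mg_block_factor(v: float) -> float:
    """Fraction of NMDA conductance unblocked at voltage ``v`` (mV)."""
    if not np.isfinite(v):
        raise ValueError(f"non-finite voltage: {v!r}")
    return 1.0 / (1.0 + MG_ETA * math.exp(-MG_GAMMA * v))


def mg_half_unblock_voltage() -> float:
    """Voltage at which the magnesium block factor equals 1/2."""
    return math.log(MG_ETA) / MG_GAMMA


def synaptic_current(
    instance: SynapseInstance,
    spike_times,
    v_post: float,
    t: float,
) -> float:
    """Closed-form synaptic current (nA) at time ``t`` for a fixed
    postsynaptic voltage, summing over activation events at
    ``spike_times + latency``.  Positive = outward."""
    total = 0.0
    for rec, w in instance.receptor_weights.items():
        kin = SynapseKinetics.default(rec, w)
        g = 0.0
        for ts in spike_times:
            dt = t - (ts + instance.latency)
            if dt >= 0:
                g += w * float(kin.unit_conductance(np.array([dt]))[0])
        if rec == "NMDA":
            g *= mg_block_factor(v_post)
        total += g * (v_post - kin.reversal)
    return total


# ---------------------------------------------------------------------------
# calibration / validation protocols


def _epsp_peak(pyr: CellModel, gmax: float, compartment: str = "basal") -> float:
    """Peak somatic depolarization (mV) from one AMPA event of weight gmax."""
    net = CompiledNetwork.from_cells([pyr], names=["pyr"])
    comp = net.comp(0, compartment)
    net.add_events([200.0], [comp], [AMPA], [gmax])
    cfg = SimulationConfig(dt=0.025, duration=300.0)
    traces, _ = integrate(net, cfg)
    v = traces.voltage("pyr.soma")
    base = v[int(199.0 / traces.dt)]
    return float(v[int(200.0 / traces.dt):].max() - base)


def calibrate_unitary_ampa(
    pyr: CellModel | None = None,
    target_mv: float = 0.1,
    compartment: str = "basal",
    lo: float = 1e-5,
    hi: float = 0.05,
    tol: float = 1e-3,
) -> float:
    """Single-synapse AMPA peak conductance (uS) on the basal dendrite that
    gives a ``target_mv`` somatic EPSP; deterministic bisection."""
    pyr = pyr or build_cell("PYR")
    f_lo = _epsp_peak(pyr, lo, compartment) - target_mv
    f_hi = _epsp_peak(pyr, hi, compartment) - target_mv
    if f_lo > 0 or f_hi < 0:
        raise ValueError("bisection bounds do not bracket the target EPSP")
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if _epsp_peak(pyr, mid, compartment) > target_mv:
            hi = mid
        else:
            lo = mid
        if (hi - lo) / hi < tol:
            break
    return 0.5 * (lo + hi)


def voltage_clamp_pair(
    pre_type: str,
    post_type: str,
    hold: float,
    ampa_gmax: float = 1e-3,
    nmda_ampa_ratio: float | None = None,
    receptors: tuple[str, ...] = ("AMPA", "NMDA"),
    post_compartment: str = "dendrite",
    duration: float = 400.0,
    passive_post: bool = True,
):
    """Somatic voltage clamp of the postsynaptic model while the presynaptic
    model fires once; returns ``(time, clamp_current)`` in (ms, nA).

    The synapse is placed on ``post_compartment`` of the postsynaptic cell
    (''basal'' for pyramidal targets).  Positive current = outward.  With
    ``passive_post`` the postsynaptic cell's voltage-gated channels are
    removed, mimicking the pharmacological isolation used in the recordings
    these protocols replicate (the drifting standing currents of an active
    cell held far from rest would otherwise swamp the synaptic current).
    """
    ratios = RatioConfig()
    if nmda_ampa_ratio is None:
        nmda_ampa_ratio = ratios.nmda_ampa(post_type)
    pre = build_cell(pre_type)
    post = build_cell(post_type)
    if passive_post:
        post.channels = {c.name: [] for c in post.compartments}
        post.e_leak = {c.name: post.v_rest_target for c in post.compartments}
    if post_type == "PYR" and post_compartment == "dendrite":
        post_compartment = "basal"
    net = CompiledNetwork.from_cells([pre, post], names=["pre", "post"])
    weights = {"AMPA": ampa_gmax, "NMDA": ampa_gmax * nmda_ampa_ratio}
    comps, recs, ws, delays, pres = [], [], [], [], []
    for rec in receptors:
        comps.append(net.comp(1, post_compartment))
        recs.append(RECEPTOR_INDEX[rec])
        ws.append(weights[rec])
        delays.append(1.7)
        pres.append(0)
    net.set_synapses(pres, comps, recs, ws, delays)
    # one presynaptic spike via a brief strong somatic pulse
    net.add_injection(net.comp(0, "soma"), 100.0, 103.0, 1.0)
    # perfect space clamp: every compartment of the postsynaptic cell is held
    for comp in post.ordered_compartments():
        net.add_clamp(net.comp(1, comp.name), hold, g_series=20.0)
    cfg = SimulationConfig(dt=0.025, duration=duration, record_voltages=False)
    traces, spikes = integrate(net, cfg)
    if len(spikes.trains[0]) < 1:
        raise RuntimeError("presynaptic cell did not fire")
    # amplifier current = summed membrane current (outward positive); an
    # inward synaptic current appears as a negative deflection
    i_total = sum(
        traces.clamp_currents[f"post.{c.name}"] for c in post.ordered_compartments()
    )
    base = np.median(i_total[int(95.0 / traces.dt): int(101.0 / traces.dt)])
    return traces.time, i_total - base


def nmda_ampa_peak_ratio(pre_type: str, post_type: str,
                         nmda_ampa_ratio: float | None = None) -> float:
    """Peak-conductance NMDA/AMPA ratio recovered from the two-hold clamp
    protocol (AMPA at -70 mV, NMDA at +60 mV), correcting each peak current
    for driving force and magnesium unblock."""
    t, i_ampa = voltage_clamp_pair(pre_type, post_type, -70.0,
                                   nmda_ampa_ratio=nmda_ampa_ratio,
                                   receptors=("AMPA",))
    t, i_nmda = voltage_clamp_pair(pre_type, post_type, +60.0,
                                   nmda_ampa_ratio=nmda_ampa_ratio,
                                   receptors=("NMDA",))
    win = t >= 101.0  # response window: after the presynaptic spike
    g_ampa = np.abs(i_ampa[win]).max() / abs(-70.0 - 0.0)
    g_nmda = np.abs(i_nmda[win]).max() / abs(60.0 - 0.0) / mg_block_factor(60.0)
    return float(g_nmda / g_ampa)


def fs_autapse_gmax(
    ipsc_na: float = FS_AUTAPSE_IPSC_NA, hold: float = FS_AUTAPSE_HOLD_MV
) -> float:
    """GABA_A peak conductance (uS) of the FS somatic autapse, set so one
    activation evokes an IPSC of ``ipsc_na`` at the reference holding
    potential."""
    e_gabaa = RECEPTOR_DEFAULTS["GABAA"][2]
    return ipsc_na / abs(hold - e_gabaa)


def fs_autapse(fs_index: int, latency: float = 1.0) -> SynapseInstance:
    """The single somatic inhibitory autapse of an FS cell (fast GABA_A
    transient, matching the validated autaptic IPSC)."""
    g = fs_autapse_gmax()
    return SynapseInstance(
        pre=fs_index,
        post=fs_index,
        post_compartment="soma",
        receptor_weights={"GABAA": g},
        latency=latency,
        is_autapse=True,
    )
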