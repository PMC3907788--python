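"""Assembly of the 20-neuron microcircuit and its manipulated variants.

The control network holds 16 pyramidal cells, 2 fast-spiking (FS), 1
regular-spiking (RS) and 1 irregular-spiking (IS) interneuron (interneuron
fraction 20%, half the inhibitory input from FS).  Pyramidal cells are fully
recurrently connected on their basal dendrites; FS cells project to every
pyramidal soma, RS and IS to every distal apical dendrite, IS additionally to
the RS dendrite (disinhibition); pyramidal cells carry basal autapses and
each FS cell one somatic autapse.  Synaptic latencies are Gaussian
(mean 1.7 ms, sd 0.9 ms), truncated at 0.1 ms for causality.

Manipulations: interneuron knock-outs (cell plus all its synapses), graded
removal of FS->pyramidal synapses, retargeting the FS projection onto a
dendritic compartment (D0 basal / D1 proximal / D2 distal), and "reverse"
networks in which two RS (or IS) models provide the somatic projection with
the FS count while one FS cell projects distally with the RS count.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .cells import CellModel, build_cell
from .engine import RECEPTOR_NAMES, CompiledNetwork
from .synapses import (GABAB_IPSP_SCALE, RECEPTOR_INDEX, RatioConfig,
                       SynapseInstance, fs_autapse_gmax)

#: NMDA saturation ceiling per synapse, in units of its single-event peak
#: conductance: closely spaced activations cannot raise the open conductance
#: of one synapse above this multiple of a unitary transient
NMDA_SAT_FACTOR = 3.25

LATENCY_MEAN = 1.7  # ms
LATENCY_SD = 0.9  # ms
LATENCY_MIN = 0.1  # ms truncation; Gaussian admits negatives, causality does not

POPULATIONS = ("PYR", "FS", "RS", "IS")

MANIPULATION_MODES = (
    "control", "fs_ko", "rs_ko", "is_ko",
    "fs_scale", "fs_retarget", "reverse_rs", "reverse_is",
)

RETARGET_SITES = {"D0": "basal", "D1": "proximal", "D2": "distal"}


@dataclass
class ConnectionRule:
    source_pop: str
    target_pop: str
    target_compartment: str
    n_synapses_per_pair: int
    receptor_class: str  # "excitatory" | "inhibitory"
    autapse: bool = False

    def __post_init__(self):
        if self.receptor_class not in ("excitatory", "inhibitory"):
            raise ValueError(f"bad receptor class {self.receptor_class!r}")
        if self.n_synapses_per_pair < 0:
            raise ValueError("synapse count must be >= 0")


def control_rules() -> list[ConnectionRule]:
    """The published control wiring (synapse counts per connected pair)."""
    return [
        ConnectionRule("PYR", "PYR", "basal", 24, "excitatory"),
        ConnectionRule("PYR", "PYR", "basal", 8, "excitatory", autapse=True),
        ConnectionRule("PYR", "FS", "dendrite", 12, "excitatory"),
        ConnectionRule("PYR", "RS", "dendrite", 14, "excitatory"),
        ConnectionRule("PYR", "IS", "dendrite", 7, "excitatory"),
        ConnectionRule("FS", "FS", "soma", 1, "inhibitory", autapse=True),
        ConnectionRule("FS", "PYR", "soma", 15, "inhibitory"),
        ConnectionRule("RS", "PYR", "distal", 12, "inhibitory"),
        ConnectionRule("IS", "PYR", "distal", 10, "inhibitory"),
        ConnectionRule("IS", "RS", "dendrite", 2, "inhibitory"),
    ]


@dataclass
class UnitaryConductances:
    """Peak conductances (uS) of single synapses per connection class.

    ``pyr_pyr`` is the unitary AMPA weight calibrated to a 0.1 mV somatic
    EPSP; inhibitory weights follow the published scaling chain
    (RS->Pyr = 0.1 x FS->Pyr, IS->Pyr = 0.1 x RS->Pyr); the FS autapse weight
    reproduces the published autaptic IPSC amplitude.
    """

    pyr_pyr: float = 7.38e-5
    pyr_fs: float = 5.0e-5
    pyr_rs: float = 1.0e-4
    pyr_is: float = 2.0e-4
    fs_pyr: float = 2.7e-3
    is_rs: float = 5.0e-4
    fs_autapse: float = field(default_factory=fs_autapse_gmax)

    def excitatory(self, target_pop: str) -> float:
        return {"PYR": self.pyr_pyr, "FS": self.pyr_fs,
                "RS": self.pyr_rs, "IS": self.pyr_is}[target_pop]

    def inhibitory(self, source_pop: str, target_pop: str,
                   ratios: RatioConfig, autapse: bool = False) -> float:
        if autapse:
            return self.fs_autapse
        if (source_pop, target_pop) == ("FS", "PYR"):
            return self.fs_pyr
        if (source_pop, target_pop) == ("RS", "PYR"):
            return self.fs_pyr * ratios.rs_pyr_gabaa_scale
        if (source_pop, target_pop) == ("IS", "PYR"):
            return self.fs_pyr * ratios.rs_pyr_gabaa_scale * ratios.is_pyr_gabaa_scale
        if (source_pop, target_pop) == ("IS", "RS"):
            return self.is_rs
        raise KeyError((source_pop, target_pop))


@dataclass
class NoiseConfig:
    """Background somatic noise: Poisson-timed brief current transients.

    The published rate is 0.02 (0.035 for the IS model); its unit as printed
    (Hz) yields essentially no events per trial, so the interpretation is
    selectable: "hz" (events/s, as printed) or "per_ms" (events/ms).
    """

    rate: float = 0.02
    rate_is: float = 0.035
    interpretation: str = "per_ms"
    amplitude: float = 0.05  # nA per event
    decay_tau: float = 2.0  # ms

    def rate_per_ms(self, cell_type: str) -> float:
        r = self.rate_is if cell_type == "IS" else self.rate
        return r * 1e-3 if self.interpretation == "hz" else r


@dataclass
class ManipulationSpec:
    mode: str = "control"
    fs_fraction: float = 1.0  # fs_scale only
    retarget_site: str = "D2"  # fs_retarget only

    def __post_init__(self):
        if self.mode not in MANIPULATION_MODES:
            raise ValueError(f"unknown manipulation {self.mode!r}")
        if not (0.0 <= self.fs_fraction <= 1.0):
            raise ValueError("fs_fraction must lie in [0, 1]")
        if self.retarget_site not in RETARGET_SITES:
            raise ValueError(f"unknown retarget site {self.retarget_site!r}")


@dataclass
class NetworkSpec:
    n_pyr: int = 16
    n_fs: int = 2
    n_rs: int = 1
    n_is: int = 1
    rules: list[ConnectionRule] = field(default_factory=control_rules)
    ratios: RatioConfig = field(default_factory=RatioConfig)
    unitary: UnitaryConductances = field(default_factory=UnitaryConductances)
    noise: NoiseConfig = field(default_factory=NoiseConfig)
    manipulation: ManipulationSpec = field(default_factory=ManipulationSpec)
    seed: int = 0
    #: optional per-cell-type parameter overrides, e.g. {"PYR": {...}}
    cell_overrides: dict = field(default_factory=dict)

    def cell_types(self) -> list[str]:
        return (["PYR"] * self.n_pyr + ["FS"] * self.n_fs
                + ["RS"] * self.n_rs + ["IS"] * self.n_is)


@dataclass
class Network:
    """A built network: cells, typed indices, explicit synapse list."""

    spec: NetworkSpec
    cells: list[CellModel]
    cell_types: list[str]
    synapses: list[SynapseInstance]

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def indices(self, pop: str) -> list[int]:
        return [i for i, t in enumerate(self.cell_types) if t == pop]

    @property
    def pyramidal(self) -> list[int]:
        return self.indices("PYR")

    def manifest(self) -> pd.DataFrame:
        """Edge list for audit and diffing between manipulations."""
        rows = []
        for s in self.synapses:
            for rec, w in sorted(s.receptor_weights.items()):
                rows.append(
                    dict(pre=s.pre, post=s.post,
                         pre_type=self.cell_types[s.pre],
                         post_type=self.cell_types[s.post],
                         compartment=s.post_compartment, receptor=rec,
                         weight=w, latency=s.latency,
                         autapse=s.is_autapse)
                )
        return pd.DataFrame(rows)

    def compile(self) -> CompiledNetwork:
        """Flatten to engine arrays; pyramidal compartments are flagged for
        the summed synaptic-current recording."""
        names = [f"{t.lower()}{i}" for i, t in enumerate(self.cell_types)]
        net = CompiledNetwork.from_cells(self.cells, names=names)
        pre, comp, rec, w, delay = [], [], [], [], []
        for s in self.synapses:
            gcomp = net.comp(s.post, s.post_compartment)
            for rname, weight in s.receptor_weights.items():
                if weight <= 0:
                    continue
                pre.append(s.pre)
                comp.append(gcomp)
                rec.append(RECEPTOR_INDEX[rname])
                w.append(weight)
                delay.append(s.latency)
        if pre:
            net.set_synapses(pre, comp, rec, w, delay)
        # NMDA saturation ceiling: NMDA_SAT_FACTOR peak-units per anatomical
        # synapse, aggregated per target compartment
        for gcomp, rname, weight in zip(comp, (RECEPTOR_NAMES[r] for r in rec), w):
            if rname == "NMDA":
                net.nmda_sat[gcomp] += NMDA_SAT_FACTOR * weight
        for ci in self.pyramidal:
            for c in self.cells[ci].compartments:
                net.is_current_flagged[net.comp(ci, c.name)] = 1
        return net


def draw_latencies(n: int, rng: np.random.Generator | int) -> np.ndarray:
    """``n`` i.i.d. Gaussian(1.7, 0.9) latencies, resampled below 0.1 ms."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    out = rng.normal(LATENCY_MEAN, LATENCY_SD, size=n)
    bad = out <= LATENCY_MIN
    while bad.any():
        out[bad] = rng.normal(LATENCY_MEAN, LATENCY_SD, size=int(bad.sum()))
        bad = out <= LATENCY_MIN
    return out


def _excitatory_weights(ratios: RatioConfig, ampa: float, post_type: str) -> dict:
    return {"AMPA": ampa, "NMDA": ampa * ratios.nmda_ampa(post_type)}


def _inhibitory_weights(ratios: RatioConfig, gabaa: float) -> dict:
    # the GABA_B-to-GABA_A ratio is defined on unitary IPSP amplitudes;
    # GABAB_IPSP_SCALE converts it to a peak-conductance weight
    return {"GABAA": gabaa,
            "GABAB": gabaa * ratios.gabab_gabaa * GABAB_IPSP_SCALE}


def build_network(spec: NetworkSpec) -> Network:
    """Instantiate cells and synapses from the spec; deterministic per seed."""
    types = spec.cell_types()
    cells = [build_cell(t, spec.cell_overrides.get(t)) for t in types]
    by_pop = {p: [i for i, t in enumerate(types) if t == p] for p in POPULATIONS}
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0x5EED]))
    synapses: list[SynapseInstance] = []
    for rule in spec.rules:
        sources = by_pop[rule.source_pop]
        targets = by_pop[rule.target_pop]
        for i in sources:
            for j in targets:
                if rule.autapse != (i == j):
                    continue
                lat = draw_latencies(rule.n_synapses_per_pair, rng)
                for k in range(rule.n_synapses_per_pair):
                    if rule.receptor_class == "excitatory":
                        wdict = _excitatory_weights(
                            spec.ratios, spec.unitary.excitatory(rule.target_pop),
                            rule.target_pop)
                    else:
                        g = spec.unitary.inhibitory(
                            rule.source_pop, rule.target_pop, spec.ratios,
                            autapse=rule.autapse)
                        if rule.autapse:
                            # autaptic IPSCs are the validated fast GABA_A
                            # transients; no slow component
                            wdict = {"GABAA": g}
                        else:
                            wdict = _inhibitory_weights(spec.ratios, g)
                    synapses.append(SynapseInstance(
                        pre=i, post=j,
                        post_compartment=rule.target_compartment,
                        receptor_weights=wdict,
                        latency=float(lat[k]),
                        is_autapse=rule.autapse,
                    ))
    net = Network(spec=spec, cells=cells, cell_types=types, synapses=synapses)
    _audit_inhibitory_fraction(net)
    return net


def _audit_inhibitory_fraction(net: Network, limit: float = 0.13) -> None:
    """Inhibitory synapses onto each pyramidal cell must not exceed ``limit``
    of its excitatory synapse count (thalamocortical inputs included)."""
    n_stim = 120  # thalamocortical synapses delivered by the stimulus
    for j in net.pyramidal:
        exc = sum(1 for s in net.synapses
                  if s.post == j and "AMPA" in s.receptor_weights) + n_stim
        inh = sum(1 for s in net.synapses
                  if s.post == j and "GABAA" in s.receptor_weights)
        if inh > limit * exc:
            raise ValueError(
                f"inhibitory fraction {inh}/{exc} on pyramidal {j} exceeds {limit}"
            )


def background_noise_sources(
    net: Network, seed: int, duration: float
) -> list[np.ndarray]:
    """Per-neuron Poisson event-time arrays over ``[0, duration)`` ms."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xB6]))
    out = []
    for t in net.cell_types:
        rate = net.spec.noise.rate_per_ms(t)
        n = rng.poisson(rate * duration)
        out.append(np.sort(rng.uniform(0.0, duration, size=n)))
    return out


# ---------------------------------------------------------------------------
# manipulations


def apply_manipulation(net: Network, m: ManipulationSpec) -> Network:
    """Derive a manipulated network from a control network (pure; the input
    is never modified)."""
    if net.spec.manipulation.mode != "control":
        raise ValueError("manipulation applied twice")
    if m.mode == "control":
        out = copy.deepcopy(net)
        out.spec = replace(out.spec, manipulation=m)
        return out
    if m.mode in ("fs_ko", "rs_ko", "is_ko"):
        return _knockout(net, m)
    if m.mode == "fs_scale":
        return _fs_scale(net, m)
    if m.mode == "fs_retarget":
        return _fs_retarget(net, m)
    if m.mode in ("reverse_rs", "reverse_is"):
        return _reverse(net, m)
    raise ValueError(f"unknown manipulation {m.mode!r}")


def _knockout(net: Network, m: ManipulationSpec) -> Network:
    pop = {"fs_ko": "FS", "rs_ko": "RS", "is_ko": "IS"}[m.mode]
    keep = [i for i, t in enumerate(net.cell_types) if t != pop]
    remap = {old: new for new, old in enumerate(keep)}
    cells = [copy.deepcopy(net.cells[i]) for i in keep]
    types = [net.cell_types[i] for i in keep]
    synapses = []
    for s in net.synapses:
        if s.pre in remap and s.post in remap:
            synapses.append(replace(copy.deepcopy(s), pre=remap[s.pre],
                                    post=remap[s.post]))
    spec = replace(
        net.spec, manipulation=m,
        n_pyr=types.count("PYR"), n_fs=types.count("FS"),
        n_rs=types.count("RS"), n_is=types.count("IS"),
    )
    return Network(spec=spec, cells=cells, cell_types=types, synapses=synapses)


def _fs_scale(net: Network, m: ManipulationSpec) -> Network:
    """Keep round(fraction * 15) FS->Pyr synapses per pair, selected
    uniformly without replacement, reproducibly by the network seed."""
    rng = np.random.default_rng(
        np.random.SeedSequence([net.spec.seed, 0xF5, int(round(m.fs_fraction * 1000))])
    )
    out_syn = []
    pairs: dict[tuple[int, int], list[SynapseInstance]] = {}
    for s in net.synapses:
        if (net.cell_types[s.pre] == "FS" and net.cell_types[s.post] == "PYR"
                and not s.is_autapse):
            pairs.setdefault((s.pre, s.post), []).append(s)
        else:
            out_syn.append(copy.deepcopy(s))
    for key in sorted(pairs):
        group = pairs[key]
        n_keep = int(round(m.fs_fraction * len(group)))
        idx = rng.choice(len(group), size=n_keep, replace=False)
        for k in sorted(idx):
            out_syn.append(copy.deepcopy(group[k]))
    return Network(spec=replace(net.spec, manipulation=m),
                   cells=copy.deepcopy(net.cells),
                   cell_types=list(net.cell_types), synapses=out_syn)


def _fs_retarget(net: Network, m: ManipulationSpec) -> Network:
    """Move every FS->Pyr synapse to the chosen dendritic compartment."""
    target = RETARGET_SITES[m.retarget_site]
    synapses = []
    for s in net.synapses:
        s = copy.deepcopy(s)
        if (net.cell_types[s.pre] == "FS" and net.cell_types[s.post] == "PYR"
                and not s.is_autapse):
            s.post_compartment = target
        synapses.append(s)
    return Network(spec=replace(net.spec, manipulation=m),
                   cells=copy.deepcopy(net.cells),
                   cell_types=list(net.cell_types), synapses=synapses)


def _reverse(net: Network, m: ManipulationSpec) -> Network:
    """Swap the somatic role: 2 RS (or IS) cells project to every pyramidal
    soma with the FS synapse count, while 1 FS cell projects to the distal
    dendrite with the RS count.  Each interneuron keeps its own unitary
    conductance; synapse counts follow the ROLE."""
    swap_pop = "RS" if m.mode == "reverse_rs" else "IS"
    base = net.spec
    if swap_pop == "RS":
        n_fs, n_rs, n_is = 1, 2, base.n_is
    else:
        n_fs, n_rs, n_is = 1, base.n_rs, 2
    rules = []
    for rule in base.rules:
        rule = copy.deepcopy(rule)
        if rule.source_pop == "FS" and rule.target_pop == "PYR":
            # somatic role taken over by the swapped population
            rules.append(ConnectionRule(swap_pop, "PYR", "soma",
                                        rule.n_synapses_per_pair, "inhibitory"))
        elif rule.source_pop == swap_pop and rule.target_pop == "PYR":
            # distal role taken over by the remaining FS cell
            rules.append(ConnectionRule("FS", "PYR", rule.target_compartment,
                                        rule.n_synapses_per_pair, "inhibitory"))
        else:
            rules.append(rule)
    spec = replace(base, manipulation=m, n_fs=n_fs, n_rs=n_rs, n_is=n_is,
                   rules=rules)
    built = build_network(replace(spec, manipulation=ManipulationSpec()))
    built.spec = spec
    return built
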