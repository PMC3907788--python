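"""The four validated cell models: pyramidal (PYR), fast-spiking (FS),
regular-spiking (RS) and irregular-spiking (IS).

Channel *densities* and passive properties of the three interneurons are the
published table values; channel placement follows the same tables (somatic
calcium pool, N-/T-type calcium, D-type and slow potassium, H and fAHP only
where listed; axonal sodium 10x somatic for FS/RS/IS).  Gating kinetics and
compartment dimensions are calibrated constants: kinetics were pinned so the
assembled cells reproduce the published validation numbers (FS: 6 spikes at
0.05 nA / 500 ms, 100 Hz at 0.2 nA, input resistance 250 MOhm; RS: 15 spikes,
60 Hz, 487 MOhm; IS: initial cluster of 2-6 spikes then irregular firing) and
geometry was chosen so total membrane area together with the published R_M
reproduces the published input resistances.  The pyramidal cell is a
4-compartment regular-spiking-with-adaptation model calibrated to a 91.3 MOhm
input resistance.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field

import numpy as np

from .kinetics import CalciumPool, ChannelSpec, GatingScheme, channel_current
from . import engine
from .engine import CompiledNetwork, SimulationConfig, integrate

CELL_TYPES = ("PYR", "FS", "RS", "IS")

E_NA = 55.0
E_K = -90.0
E_CA = 120.0
E_H = -30.0


@dataclass
class CompartmentGeometry:
    """A cylinder in the compartment tree (lengths/diameters in um)."""

    name: str
    length: float
    diameter: float
    parent: str | None = None

    def __post_init__(self):
        if self.length <= 0 or self.diameter <= 0:
            raise ValueError("length and diameter must be positive")

    def area(self) -> float:
        """Lateral membrane area in um2."""
        return math.pi * self.diameter * self.length


@dataclass
class PassiveProperties:
    cm: float = 1.2  # uF/cm2
    ra: float = 150.0  # ohm*cm
    rm: float = 10.0  # kOhm*cm2
    e_leak: float = -70.0  # overridden per compartment at build time

    def __post_init__(self):
        if min(self.cm, self.ra, self.rm) <= 0:
            raise ValueError("passive properties must be positive")


@dataclass
class CellModel:
    cell_type: str
    compartments: list[CompartmentGeometry]
    passive: PassiveProperties
    channels: dict[str, list[ChannelSpec]]
    calcium: dict[str, CalciumPool]
    v_rest_target: float
    e_leak: dict[str, float] = field(default_factory=dict)

    def compartment(self, name: str) -> CompartmentGeometry:
        for c in self.compartments:
            if c.name == name:
                return c
        raise KeyError(name)

    def ordered_compartments(self) -> list[CompartmentGeometry]:
        """Compartments ordered parents-before-children (soma first)."""
        out, seen = [], set()
        pending = list(self.compartments)
        while pending:
            progressed = False
            for c in list(pending):
                if c.parent is None or c.parent in seen:
                    out.append(c)
                    seen.add(c.name)
                    pending.remove(c)
                    progressed = True
            if not progressed:
                raise ValueError("compartment graph is not a tree rooted at soma")
        return out

    def total_area(self) -> float:
        return sum(c.area() for c in self.compartments)


# ---------------------------------------------------------------------------
# calibrated gating-kinetics library (shared across cell types, with
# per-cell-type overrides in the default tables below)

KINETICS: dict[str, dict[str, dict]] = {
    "Na": {
        "m": dict(role="activation", exponent=3, vhalf=-40.0, k=6.0,
                  tau_form="bell", tau_min=0.04, tau_amp=0.12,
                  tau_vmax=-40.0, tau_sig1=15.0, tau_sig2=15.0),
        "h": dict(role="inactivation", exponent=1, vhalf=-62.0, k=-6.0,
                  tau_form="bell", tau_min=0.25, tau_amp=3.5,
                  tau_vmax=-60.0, tau_sig1=12.0, tau_sig2=12.0),
    },
    "Kdr": {
        "n": dict(role="activation", exponent=4, vhalf=-35.0, k=8.0,
                  tau_form="bell", tau_min=0.4, tau_amp=3.0,
                  tau_vmax=-40.0, tau_sig1=20.0, tau_sig2=20.0),
    },
    "KA": {
        "a": dict(role="activation", exponent=4, vhalf=-45.0, k=12.0,
                  tau_form="constant", tau_min=1.0),
        "b": dict(role="inactivation", exponent=1, vhalf=-72.0, k=-8.0,
                  tau_form="constant", tau_min=20.0),
    },
    "Kslow": {
        "m": dict(role="activation", exponent=1, vhalf=-38.0, k=6.0,
                  tau_form="constant", tau_min=75.0),
    },
    "KD": {
        "a": dict(role="activation", exponent=1, vhalf=-50.0, k=9.0,
                  tau_form="constant", tau_min=1.5),
        "b": dict(role="inactivation", exponent=1, vhalf=-75.0, k=-9.0,
                  tau_form="constant", tau_min=250.0),
    },
    "CaN": {
        "m": dict(role="activation", exponent=2, vhalf=-22.0, k=7.0,
                  tau_form="constant", tau_min=1.5),
        "h": dict(role="inactivation", exponent=1, vhalf=-45.0, k=-12.0,
                  tau_form="constant", tau_min=80.0),
    },
    "CaT": {
        "m": dict(role="activation", exponent=2, vhalf=-52.0, k=5.0,
                  tau_form="constant", tau_min=2.0),
        "h": dict(role="inactivation", exponent=1, vhalf=-72.0, k=-5.0,
                  tau_form="constant", tau_min=25.0),
    },
    "H": {
        "m": dict(role="activation", exponent=1, vhalf=-82.0, k=-7.0,
                  tau_form="constant", tau_min=120.0),
    },
    "fAHP": {},  # calcium factor only, no voltage gate
}

REVERSALS = {"Na": E_NA, "Kdr": E_K, "KA": E_K, "Kslow": E_K, "KD": E_K,
             "CaN": E_CA, "CaT": E_CA, "H": E_H, "fAHP": E_K}

CA_SOURCE_KINDS = {"CaN", "CaT"}


# per-cell defaults: geometry, passive, densities, kinetics overrides,
# calcium-pool constants, resting potential
CELL_DEFAULTS: dict[str, dict] = {
    "FS": {
        "v_rest": -73.0,
        "passive": {"cm": 1.2, "ra": 150.0, "rm": 10.0},
        "geometry": [
            ("soma", 20.0, 20.0, None),
            ("dendrite", 475.0, 1.95, "soma"),
            ("axon", 100.0, 0.8, "soma"),
        ],
        "channels": {
            "soma": {"Na": 0.135, "Kdr": 0.036, "CaN": 0.0003, "KD": 0.0000725,
                     "H": 0.00001, "KA": 0.0032, "fAHP": 0.0001},
            "axon": {"Na": 1.35, "Kdr": 0.018},
            "dendrite": {"Na": 0.09, "Kdr": 0.0075, "KA": 0.032},
        },
        "calcium": {"soma": {"rest": 5e-5, "tau": 10.0, "phi": 0.1}},
        "kinetics": {
            "Na": {"m": {"vhalf": -40.3}, "h": {"vhalf": -68.0, "tau_amp": 5.0}},
            "Kdr": {"n": {"vhalf": -32.0, "tau_min": 3.0, "tau_amp": 18.0}},
            "KA": {"a": {"vhalf": -36.0}, "b": {"tau_min": 10.0}},
            "KD": {"b": {"tau_min": 500.0}},
        },
        "ca_kd": 5e-4,
    },
    "RS": {
        "v_rest": -64.0,
        "passive": {"cm": 1.2, "ra": 150.0, "rm": 40.0},
        "geometry": [
            ("soma", 20.0, 20.0, None),
            ("dendrite", 716.0, 4.4, "soma"),
            ("axon", 100.0, 0.8, "soma"),
        ],
        "channels": {
            "soma": {"Na": 0.075, "Kdr": 0.018, "CaT": 0.003, "H": 0.000002,
                     "KA": 0.035},
            "axon": {"Na": 0.75, "Kdr": 0.009},
            "dendrite": {"Na": 0.018, "Kdr": 0.009, "KA": 0.00875},
        },
        "calcium": {"soma": {"rest": 5e-5, "tau": 20.0, "phi": 0.1}},
        "kinetics": {
            "Na": {"m": {"vhalf": -36.1, "k": 8.0},
                   "h": {"vhalf": -58.0, "k": -7.0, "tau_min": 0.5,
                         "tau_amp": 3.5}},
            "Kdr": {"n": {"vhalf": -41.0, "k": 12.0, "tau_min": 4.0,
                          "tau_amp": 12.0}},
            "KA": {"a": {"tau_min": 2.4}, "b": {"tau_min": 400.0}},
            "CaT": {"h": {"tau_min": 15.0}},
        },
        "ca_kd": 5e-4,
    },
    "IS": {
        "v_rest": -70.0,
        "passive": {"cm": 1.2, "ra": 150.0, "rm": 20.0},
        "geometry": [
            ("soma", 15.0, 15.0, None),
            ("dendrite", 280.0, 1.6, "soma"),
            ("dendrite2", 280.0, 1.6, "soma"),
            ("axon", 100.0, 1.2, "soma"),
        ],
        "channels": {
            "soma": {"Na": 0.015, "Kdr": 0.018, "KD": 0.000725, "CaN": 0.001,
                     "fAHP": 0.00003},
            "axon": {"Na": 0.15, "Kdr": 0.009},
            "dendrite": {"Na": 0.075, "Kdr": 0.009},
            "dendrite2": {"Na": 0.075, "Kdr": 0.009},
        },
        "calcium": {"soma": {"rest": 5e-5, "tau": 20.0, "phi": 0.1}},
        "kinetics": {
            "Na": {"m": {"vhalf": -44.0}, "h": {"vhalf": -60.0}},
            "Kdr": {"n": {"vhalf": -35.0, "tau_min": 1.2}},
            "KD": {"a": {"vhalf": -38.0, "k": 6.0, "tau_min": 200.0},
                   "b": {"vhalf": 0.0}},
            "CaN": {"m": {"vhalf": -45.0},
                    "h": {"vhalf": -48.0, "tau_min": 200.0}},
        },
        "ca_kd": 5e-4,
    },
    "PYR": {
        "v_rest": -66.0,
        "passive": {"cm": 1.2, "ra": 150.0, "rm": 10.8},
        "geometry": [
            ("soma", 25.0, 25.0, None),
            ("basal", 315.0, 2.5, "soma"),
            ("proximal", 150.0, 4.0, "soma"),
            ("distal", 300.0, 4.5, "proximal"),
        ],
        "channels": {
            "soma": {"Na": 0.15, "Kdr": 0.05, "KA": 0.003, "Kslow": 0.0005,
                     "CaN": 0.001, "fAHP": 0.0004, "H": 0.00001},
            "basal": {"Na": 0.02, "Kdr": 0.005, "KA": 0.01},
            "proximal": {"Na": 0.02, "Kdr": 0.005, "KA": 0.01},
            "distal": {"Na": 0.02, "Kdr": 0.005, "KA": 0.01},
        },
        "calcium": {"soma": {"rest": 5e-5, "tau": 36.0, "phi": 0.1}},
        "kinetics": {
            "Na": {"m": {"vhalf": -41.0}},
            "Kdr": {"n": {"vhalf": -38.0}},
            "Kslow": {"m": {"vhalf": -42.0, "tau_min": 300.0}},
        },
        "ca_kd": 5e-4,
    },
}


def _apply_overrides(defaults: dict, overrides: dict) -> dict:
    """Apply flat dotted-key overrides to a nested defaults copy."""
    d = copy.deepcopy(defaults)
    for key, value in (overrides or {}).items():
        parts = key.split(".")
        node = d
        try:
            if parts[0] == "geometry":
                # geometry.<comp>.<length|diameter>
                name, attr = parts[1], parts[2]
                rows = [list(r) for r in node["geometry"]]
                idx = {"length": 1, "diameter": 2}[attr]
                hit = False
                for r in rows:
                    if r[0] == name:
                        r[idx] = value
                        hit = True
                if not hit:
                    raise KeyError(name)
                node["geometry"] = [tuple(r) for r in rows]
            elif parts[0] == "kinetics":
                # kinetics.<kind>.<gate>.<param>
                kind, gate, param = parts[1], parts[2], parts[3]
                base = copy.deepcopy(KINETICS[kind][gate])
                base.update(node["kinetics"].get(kind, {}).get(gate, {}))
                if param not in base:
                    raise KeyError(param)
                node["kinetics"].setdefault(kind, {}).setdefault(gate, {})[param] = value
            elif parts[0] == "channels":
                comp, kind, param = parts[1], parts[2], parts[3]
                if param != "gbar" or kind not in node["channels"][comp]:
                    raise KeyError(key)
                node["channels"][comp][kind] = value
            elif parts[0] == "passive":
                if parts[1] not in node["passive"]:
                    raise KeyError(parts[1])
                node["passive"][parts[1]] = value
            elif parts[0] == "calcium":
                comp, param = parts[1], parts[2]
                if param not in node["calcium"][comp]:
                    raise KeyError(param)
                node["calcium"][comp][param] = value
            elif key == "v_rest":
                node["v_rest"] = value
            elif key == "ca_kd":
                node["ca_kd"] = value
            else:
                raise KeyError(key)
        except (KeyError, IndexError) as exc:
            raise KeyError(f"unknown override {key!r}") from exc
    return d


def _make_gates(kind: str, kin_overrides: dict) -> list[GatingScheme]:
    gates = []
    for gate_name, params in KINETICS[kind].items():
        p = dict(params)
        p.update(kin_overrides.get(kind, {}).get(gate_name, {}))
        gates.append(GatingScheme(**p))
    return gates


def build_cell(cell_type: str, overrides: dict | None = None) -> CellModel:
    """Assemble a cell from the default tables, with optional overrides.

    The leak reversal of each compartment is solved analytically so that the
    assembled cell is exactly at rest at its target potential (all gates at
    steady state, calcium at rest, no axial current).
    """
    if cell_type not in CELL_TYPES:
        raise ValueError(f"unknown cell type {cell_type!r}")
    d = _apply_overrides(CELL_DEFAULTS[cell_type], overrides or {})
    passive = PassiveProperties(**d["passive"])
    comps = [CompartmentGeometry(n, L, diam, par) for n, L, diam, par in d["geometry"]]
    channels: dict[str, list[ChannelSpec]] = {}
    for comp_name, dens in d["channels"].items():
        specs = []
        for kind, gbar in dens.items():
            if gbar == 0:
                continue
            specs.append(
                ChannelSpec(
                    kind=kind,
                    gbar=gbar,
                    reversal=REVERSALS[kind],
                    gates=_make_gates(kind, d["kinetics"]),
                    calcium_dependent=(kind == "fAHP"),
                    ca_kd=d["ca_kd"],
                    is_calcium_source=(kind in CA_SOURCE_KINDS),
                )
            )
        channels[comp_name] = specs
    calcium = {
        comp: CalciumPool(
            concentration=p["rest"], rest_concentration=p["rest"],
            decay_tau=p["tau"], influx_factor=p["phi"],
        )
        for comp, p in d["calcium"].items()
    }
    v_rest = d["v_rest"]
    e_leak = {}
    for comp in comps:
        i_total = 0.0  # mA/cm2 at v_rest with gates at steady state
        ca0 = calcium.get(comp.name, CalciumPool()).rest_concentration
        for spec in channels.get(comp.name, []):
            x = [g.steady_state(v_rest) for g in spec.gates]
            i_total += channel_current(spec, x, v_rest, ca0)
        # leak density: (v - e)/rm in mV/kOhm.cm2 = 1e-3 mA/cm2
        e_leak[comp.name] = v_rest + passive.rm * 1e3 * i_total
    return CellModel(
        cell_type=cell_type,
        compartments=comps,
        passive=passive,
        channels=channels,
        calcium=calcium,
        v_rest_target=v_rest,
        e_leak=e_leak,
    )


# ---------------------------------------------------------------------------
# single-cell protocols


def _single_cell_net(cell: CellModel) -> CompiledNetwork:
    net = CompiledNetwork.from_cells([cell], names=[cell.cell_type.lower()])
    net.record_comps = net.soma_idx.copy()
    return net


def current_step_response(
    cell: CellModel,
    amplitude: float,
    duration: float = 500.0,
    onset: float = 100.0,
    settle: float = 200.0,
    dt: float = 0.025,
):
    """Somatic current step from rest.

    Returns ``(spike_times, traces)`` where spike times are measured from step
    onset and restricted to the step window.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    net = _single_cell_net(cell)
    net.add_injection(0, settle + onset, settle + onset + duration, amplitude)
    cfg = SimulationConfig(dt=dt, duration=settle + onset + duration + 100.0)
    traces, spikes = integrate(net, cfg)
    t0 = settle + onset
    st = spikes.trains[0]
    st = st[(st >= t0) & (st < t0 + duration)] - t0
    return st, traces


def measure_input_resistance(cell: CellModel, i_step: float = -0.005) -> float:
    """Input resistance (MOhm) from a small somatic current step.

    The steady-state somatic deflection (mean over the last 100 ms of a
    1000 ms step) divided by the injected current.
    """
    spikes, traces = current_step_response(cell, i_step, duration=1000.0)
    if spikes.size:
        raise ValueError(
            f"current step {i_step} nA elicited spikes; use a smaller step"
        )
    v = traces.voltage(f"{cell.cell_type.lower()}.soma")
    dt = traces.dt
    i0 = int(round((200.0 + 100.0) / dt))  # sample just before onset
    i1 = int(round((200.0 + 100.0 + 900.0) / dt))
    i2 = int(round((200.0 + 100.0 + 1000.0) / dt))
    v_base = v[i0 - 1]
    v_ss = float(np.mean(v[i1:i2]))
    return (v_ss - v_base) / i_step  # mV / nA = MOhm


def f_i_point(cell: CellModel, amplitude: float, duration: float = 500.0) -> float:
    """Firing rate in Hz: spike count over the step divided by its duration."""
    if amplitude < 0:
        raise ValueError("amplitude must be >= 0")
    spikes, _ = current_step_response(cell, amplitude, duration=duration)
    return len(spikes) / (duration * 1e-3)


def spike_threshold_voltage(cell: CellModel, amplitude: float,
                            dvdt_crit: float = 20.0) -> float:
    """Voltage at the first point where dV/dt exceeds ``dvdt_crit`` mV/ms
    before the first spike (conventional threshold estimate)."""
    spikes, traces = current_step_response(cell, amplitude)
    if not spikes.size:
        raise ValueError("no spike elicited")
    v = traces.voltage(f"{cell.cell_type.lower()}.soma")
    dt = traces.dt
    i_end = int((spikes[0] + 300.0) / dt)
    dvdt = np.diff(v[:i_end]) / dt
    idx = np.nonzero(dvdt > dvdt_crit)[0]
    return float(v[idx[0]]) if idx.size else float("nan")


def classify_discharge(
    spike_times: np.ndarray, cv_threshold: float = 0.2
) -> tuple[int, bool | None]:
    """Initial-cluster size and irregularity flag from a spike-time list.

    The initial cluster ends at the first interspike interval longer than
    twice the first one; the flag is the coefficient of variation of the
    post-cluster intervals exceeding ``cv_threshold`` (None if inconclusive).
    """
    st = np.asarray(spike_times, dtype=float)
    if st.size < 3:
        return st.size, None
    isi = np.diff(st)
    cluster = 1
    for i in range(len(isi)):
        if isi[i] > 2.0 * isi[0]:
            break
        cluster += 1
    # no break found: the train has no cluster structure; judge regularity
    # from all intervals
    post = isi[cluster - 1:] if cluster <= len(isi) else isi
    if post.size < 3:
        return cluster, None
    cv = float(np.std(post) / np.mean(post))
    return cluster, bool(cv > cv_threshold)


def is_discharge_signature(
    cell: CellModel, amplitude: float, duration: float = 500.0
) -> tuple[int, bool | None]:
    """Cluster/irregularity signature of the IS model's step response."""
    if cell.cell_type != "IS":
        raise ValueError("discharge signature is defined for the IS model")
    spikes, _ = current_step_response(cell, amplitude, duration=duration)
    return classify_discharge(spikes)
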