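"""Time-stepping engine for branched compartmental cells coupled by synapses.

The engine flattens an arbitrary collection of cells, synapses, current
injections, voltage clamps, stimulus events and noise events into plain
arrays and advances them with a semi-implicit (linearized backward-Euler)
update: gating variables are advanced exactly over the step at the held
voltage, ionic and synaptic conductances are then frozen and the resulting
linear cable system is solved per cell by Hines elimination (parents are
ordered before children, so one backward sweep + one forward sweep).  The
scheme is unconditionally stable at the default dt = 0.025 ms.

Internal units: mV, ms, nA, uS, nF, mM; geometry um; densities S/cm2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import math
import numpy as np
from numba import njit

from .kinetics import GatingScheme

# receptor class indices used throughout the package
AMPA, NMDA, GABAA, GABAB = 0, 1, 2, 3
RECEPTOR_NAMES = ("AMPA", "NMDA", "GABAA", "GABAB")
N_REC = 4

SPIKE_THRESHOLD = 0.0  # mV, upward crossing
SPIKE_LOCKOUT = 2.0  # ms

# default receptor kinetics by class index (AMPA, NMDA, GABAA, GABAB)
REC_TAU_RISE = (0.5, 5.0, 0.5, 50.0)
REC_TAU_DECAY = (3.0, 150.0, 8.0, 150.0)
REC_EREV = (0.0, 0.0, -75.0, -90.0)


@dataclass
class SimulationConfig:
    """Integration settings.  ``record_currents`` enables the per-receptor
    summed synaptic-current streams over the flagged (pyramidal) cells."""

    dt: float = 0.025
    duration: float = 500.0
    seed: int = 0
    record_voltages: bool = True
    record_currents: bool = False
    record_every: int = 1

    def __post_init__(self):
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.duration <= 0:
            raise ValueError("duration must be positive")


@dataclass
class TraceSet:
    """Recorded traces on a uniform time base."""

    dt: float
    time: np.ndarray
    voltages: dict[str, np.ndarray]  # label -> mV trace
    receptor_currents: np.ndarray | None = None  # (n_samples, 4) nA, summed
    clamp_currents: dict[str, np.ndarray] = field(default_factory=dict)

    def voltage(self, label: str) -> np.ndarray:
        return self.voltages[label]


@dataclass
class SpikeTrainSet:
    """Per-neuron ordered spike times for one trial."""

    trains: list[np.ndarray]
    duration: float
    condition: str = ""
    seed: int = 0

    def __post_init__(self):
        self.trains = [np.asarray(t, dtype=float) for t in self.trains]
        for t in self.trains:
            if t.size and (np.any(np.diff(t) <= 0) or t[0] < 0 or t[-1] > self.duration):
                raise ValueError("spike times must be increasing within [0, duration]")

    @property
    def n_neurons(self) -> int:
        return len(self.trains)

    def restricted(self, t0: float, t1: float) -> "SpikeTrainSet":
        out = [t[(t >= t0) & (t < t1)] for t in self.trains]
        return SpikeTrainSet(out, self.duration, self.condition, self.seed)


def detect_spikes(
    trace: np.ndarray,
    dt: float,
    threshold: float = SPIKE_THRESHOLD,
    lockout: float = SPIKE_LOCKOUT,
) -> np.ndarray:
    """Upward threshold crossings with a refractory lockout.

    Crossing times are linearly interpolated between the samples that bracket
    the threshold.
    """
    v = np.asarray(trace, dtype=float)
    above = v >= threshold
    idx = np.nonzero(~above[:-1] & above[1:])[0]
    times = []
    last = -np.inf
    for i in idx:
        frac = (threshold - v[i]) / (v[i + 1] - v[i])
        t = (i + frac) * dt
        if t - last >= lockout:
            times.append(t)
            last = t
    return np.asarray(times, dtype=float)


# ---------------------------------------------------------------------------
# flattened network description


class CompiledNetwork:
    """Flat-array form of a set of cells plus everything that drives them.

    Built via :meth:`from_cells`; synapses, injections, clamps, stimulus
    events and noise events are then attached before :func:`integrate`.
    """

    def __init__(self):
        # compartments
        self.c = None  # nF
        self.gl = None  # uS
        self.el = None  # mV
        self.parent = None  # global parent index, -1 at cell roots
        self.gax = None  # uS coupling to parent
        self.cell_of = None
        self.area = None  # um2
        self.labels: list[str] = []  # "cellname.compname"
        self.soma_idx = None  # per cell
        self.v0 = None  # initial voltages
        self.is_current_flagged = None  # bool per comp: included in summed currents
        # channels (CSR gates)
        self.ch_comp = np.zeros(0, dtype=np.int64)
        self.ch_g = np.zeros(0)
        self.ch_erev = np.zeros(0)
        self.ch_cadep = np.zeros(0, dtype=np.int64)
        self.ch_cakd = np.zeros(0)
        self.ch_casrc = np.zeros(0, dtype=np.int64)
        self.ch_gate_ptr = np.zeros(1, dtype=np.int64)
        # gates
        self.g_vhalf = np.zeros(0)
        self.g_k = np.zeros(0)
        self.g_tauform = np.zeros(0, dtype=np.int64)
        self.g_taumin = np.zeros(0)
        self.g_tauamp = np.zeros(0)
        self.g_tauvmax = np.zeros(0)
        self.g_sig1 = np.zeros(0)
        self.g_sig2 = np.zeros(0)
        self.g_exp = np.zeros(0, dtype=np.int64)
        # calcium pools
        self.ca_has = None
        self.ca_rest = None
        self.ca_tau = None
        self.ca_phi = None
        # synapses, CSR by presynaptic neuron
        self.syn_ptr = np.zeros(1, dtype=np.int64)
        self.syn_comp = np.zeros(0, dtype=np.int64)
        self.syn_rec = np.zeros(0, dtype=np.int64)
        self.syn_w = np.zeros(0)
        self.syn_delay = np.zeros(0)  # ms
        # receptor kinetics (tau_rise, tau_decay, erev) indexed by class
        self.rec_tau_r = np.array(REC_TAU_RISE)
        self.rec_tau_d = np.array(REC_TAU_DECAY)
        self.rec_erev = np.array(REC_EREV)
        self.mg_eta = 0.28  # [Mg]=1 mM / 3.57
        self.mg_gamma = 0.062  # 1/mV
        # per-compartment NMDA conductance ceiling (uS); receptor saturation
        # is modelled as a concave soft cap g_eff = S (1 - exp(-g/S)); 0 = off
        self.nmda_sat = None  # set when compartments are known
        # external synaptic events (sorted by time)
        self.ev_t = np.zeros(0)
        self.ev_comp = np.zeros(0, dtype=np.int64)
        self.ev_rec = np.zeros(0, dtype=np.int64)
        self.ev_w = np.zeros(0)
        # noise current events (sorted by time)
        self.noise_t = np.zeros(0)
        self.noise_comp = np.zeros(0, dtype=np.int64)
        self.noise_amp = np.zeros(0)
        self.noise_tau = 2.0  # ms decay of each noise transient
        # step current injections
        self.inj_comp = np.zeros(0, dtype=np.int64)
        self.inj_t0 = np.zeros(0)
        self.inj_t1 = np.zeros(0)
        self.inj_amp = np.zeros(0)
        # voltage clamps
        self.clamp_comp = np.zeros(0, dtype=np.int64)
        self.clamp_v = np.zeros(0)
        self.clamp_g = np.zeros(0)  # uS series conductance
        # recording selection (compartment indices)
        self.record_comps = None

    # -- construction -------------------------------------------------------

    @classmethod
    def from_cells(cls, cells, names=None):
        """Flatten ``cells`` (list of ``cell_models.CellModel``)."""
        self = cls()
        names = names or [f"cell{i}" for i in range(len(cells))]
        comp_index: dict[tuple[int, str], int] = {}
        c, gl, el, parent, gax, cell_of, area, v0 = [], [], [], [], [], [], [], []
        ca_has, ca_rest, ca_tau, ca_phi = [], [], [], []
        soma_idx = []
        ch_rows = []  # (comp, g_uS, erev, cadep, cakd, casrc, gates)
        for ci, cell in enumerate(cells):
            order = cell.ordered_compartments()
            soma_idx.append(len(c))
            for comp in order:
                gi = len(c)
                comp_index[(ci, comp.name)] = gi
                a = comp.area()  # um2
                c.append(cell.passive.cm * a * 1e-5)  # nF
                gl.append(a * 1e-5 / cell.passive.rm)  # uS
                el.append(cell.e_leak[comp.name])
                cell_of.append(ci)
                area.append(a)
                v0.append(cell.v_rest_target)
                self.labels.append(f"{names[ci]}.{comp.name}")
                if comp.parent is None:
                    parent.append(-1)
                    gax.append(0.0)
                else:
                    pi = comp_index[(ci, comp.parent)]
                    parent.append(pi)
                    pc = cell.compartment(comp.parent)
                    # axial: two half-cylinder resistances in series (ohm)
                    def half_r(g):
                        ax_area = math.pi * (g.diameter * 1e-4) ** 2 / 4.0  # cm2
                        return cell.passive.ra * (g.length * 1e-4 / 2.0) / ax_area

                    r = half_r(comp) + half_r(pc)
                    gax.append(1e6 / r)  # uS
                pooled = cell.calcium.get(comp.name)
                if pooled is not None:
                    ca_has.append(1)
                    ca_rest.append(pooled.rest_concentration)
                    ca_tau.append(pooled.decay_tau)
                    ca_phi.append(pooled.influx_factor)
                else:
                    ca_has.append(0)
                    ca_rest.append(0.0)
                    ca_tau.append(1.0)
                    ca_phi.append(0.0)
                for spec in cell.channels.get(comp.name, []):
                    g_us = spec.gbar * a * 1e-2  # S/cm2 * um2 -> uS
                    ch_rows.append(
                        (
                            gi,
                            g_us,
                            spec.reversal,
                            1 if spec.calcium_dependent else 0,
                            spec.ca_kd,
                            1 if spec.is_calcium_source else 0,
                            spec.gates,
                        )
                    )
        self.c = np.array(c)
        self.gl = np.array(gl)
        self.el = np.array(el)
        self.parent = np.array(parent, dtype=np.int64)
        self.gax = np.array(gax)
        self.cell_of = np.array(cell_of, dtype=np.int64)
        self.area = np.array(area)
        self.v0 = np.array(v0)
        self.soma_idx = np.array(soma_idx, dtype=np.int64)
        self.ca_has = np.array(ca_has, dtype=np.int64)
        self.ca_rest = np.array(ca_rest)
        self.ca_tau = np.array(ca_tau)
        self.ca_phi = np.array(ca_phi)
        self.is_current_flagged = np.zeros(len(c), dtype=np.int64)
        self.nmda_sat = np.zeros(len(c))
        self._comp_index = comp_index
        self._set_channels(ch_rows)
        self.record_comps = self.soma_idx.copy()
        self.syn_ptr = np.zeros(self.n_cells + 1, dtype=np.int64)
        return self

    def _set_channels(self, rows):
        n = len(rows)
        self.ch_comp = np.zeros(n, dtype=np.int64)
        self.ch_g = np.zeros(n)
        self.ch_erev = np.zeros(n)
        self.ch_cadep = np.zeros(n, dtype=np.int64)
        self.ch_cakd = np.zeros(n)
        self.ch_casrc = np.zeros(n, dtype=np.int64)
        ptr = [0]
        gates: list[GatingScheme] = []
        for i, (gi, g, erev, cadep, cakd, casrc, gs) in enumerate(rows):
            self.ch_comp[i] = gi
            self.ch_g[i] = g
            self.ch_erev[i] = erev
            self.ch_cadep[i] = cadep
            self.ch_cakd[i] = cakd
            self.ch_casrc[i] = casrc
            gates.extend(gs)
            ptr.append(len(gates))
        self.ch_gate_ptr = np.array(ptr, dtype=np.int64)
        m = len(gates)
        self.g_vhalf = np.array([g.vhalf for g in gates]) if m else np.zeros(0)
        self.g_k = np.array([g.k for g in gates]) if m else np.zeros(0)
        self.g_tauform = np.array(
            [0 if g.tau_form == "constant" else 1 for g in gates], dtype=np.int64
        )
        self.g_taumin = np.array([g.tau_min for g in gates]) if m else np.zeros(0)
        self.g_tauamp = np.array([g.tau_amp for g in gates]) if m else np.zeros(0)
        self.g_tauvmax = np.array([g.tau_vmax for g in gates]) if m else np.zeros(0)
        self.g_sig1 = np.array([g.tau_sig1 for g in gates]) if m else np.zeros(0)
        self.g_sig2 = np.array([g.tau_sig2 for g in gates]) if m else np.zeros(0)
        self.g_exp = np.array([g.exponent for g in gates], dtype=np.int64)

    def comp(self, cell_index: int, comp_name: str) -> int:
        return self._comp_index[(cell_index, comp_name)]

    @property
    def n_comp(self) -> int:
        return len(self.c)

    @property
    def n_cells(self) -> int:
        return len(self.soma_idx)

    # -- drive attachment ---------------------------------------------------

    def set_synapses(self, pre_neuron, comp, rec, weight, delay):
        """Attach spike-triggered synapses, CSR-grouped by presynaptic cell."""
        pre = np.asarray(pre_neuron, dtype=np.int64)
        order = np.argsort(pre, kind="stable")
        pre = pre[order]
        self.syn_comp = np.asarray(comp, dtype=np.int64)[order]
        self.syn_rec = np.asarray(rec, dtype=np.int64)[order]
        self.syn_w = np.asarray(weight, dtype=float)[order]
        self.syn_delay = np.asarray(delay, dtype=float)[order]
        if np.any(self.syn_delay <= 0):
            raise ValueError("synaptic delays must be positive")
        ptr = np.zeros(self.n_cells + 1, dtype=np.int64)
        np.add.at(ptr, pre + 1, 1)
        self.syn_ptr = np.cumsum(ptr)

    def add_events(self, t, comp, rec, weight):
        self.ev_t = np.concatenate([self.ev_t, np.asarray(t, dtype=float)])
        self.ev_comp = np.concatenate([self.ev_comp, np.asarray(comp, dtype=np.int64)])
        self.ev_rec = np.concatenate([self.ev_rec, np.asarray(rec, dtype=np.int64)])
        self.ev_w = np.concatenate([self.ev_w, np.asarray(weight, dtype=float)])
        order = np.argsort(self.ev_t, kind="stable")
        self.ev_t = self.ev_t[order]
        self.ev_comp = self.ev_comp[order]
        self.ev_rec = self.ev_rec[order]
        self.ev_w = self.ev_w[order]

    def add_noise_events(self, t, comp, amp):
        self.noise_t = np.concatenate([self.noise_t, np.asarray(t, dtype=float)])
        self.noise_comp = np.concatenate(
            [self.noise_comp, np.asarray(comp, dtype=np.int64)]
        )
        self.noise_amp = np.concatenate([self.noise_amp, np.asarray(amp, dtype=float)])
        order = np.argsort(self.noise_t, kind="stable")
        self.noise_t = self.noise_t[order]
        self.noise_comp = self.noise_comp[order]
        self.noise_amp = self.noise_amp[order]

    def add_injection(self, comp, t0, t1, amp):
        self.inj_comp = np.append(self.inj_comp, comp)
        self.inj_t0 = np.append(self.inj_t0, t0)
        self.inj_t1 = np.append(self.inj_t1, t1)
        self.inj_amp = np.append(self.inj_amp, amp)

    def add_clamp(self, comp, v_hold, g_series=10.0):
        self.clamp_comp = np.append(self.clamp_comp, comp).astype(np.int64)
        self.clamp_v = np.append(self.clamp_v, v_hold)
        self.clamp_g = np.append(self.clamp_g, g_series)


# ---------------------------------------------------------------------------
# numba kernel


@njit(cache=True)
def _kernel(
    dt, n_steps, rec_every,
    c, gl, el, parent, gax, cell_of, area, v_init, soma_idx, flagged,
    ch_comp, ch_g, ch_erev, ch_cadep, ch_cakd, ch_casrc, ch_gate_ptr,
    g_vhalf, g_k, g_tauform, g_taumin, g_tauamp, g_tauvmax, g_sig1, g_sig2, g_exp,
    ca_has, ca_rest, ca_tau, ca_phi,
    syn_ptr, syn_comp, syn_rec, syn_w, syn_delay,
    rec_tau_r, rec_tau_d, rec_erev, mg_eta, mg_gamma, nmda_sat,
    ev_t, ev_comp, ev_rec, ev_w,
    noise_t, noise_comp, noise_amp, noise_tau,
    inj_comp, inj_t0, inj_t1, inj_amp,
    clamp_comp, clamp_v, clamp_g,
    record_comps, do_record_v, do_record_cur,
):
    n_comp = c.shape[0]
    n_cells = soma_idx.shape[0]
    n_chan = ch_comp.shape[0]
    n_gate = g_vhalf.shape[0]

    v = v_init.copy()
    gate_x = np.zeros(n_gate)
    # gates start at steady state for the initial voltage
    for ch in range(n_chan):
        vv = v[ch_comp[ch]]
        for gi in range(ch_gate_ptr[ch], ch_gate_ptr[ch + 1]):
            gate_x[gi] = 1.0 / (1.0 + math.exp((g_vhalf[gi] - vv) / g_k[gi]))
    ca = ca_rest.copy()

    # receptor state: difference-of-exponentials per compartment per class
    syn_r = np.zeros((n_comp, N_REC))
    syn_d = np.zeros((n_comp, N_REC))
    fr = np.empty(N_REC)
    fd = np.empty(N_REC)
    norm = np.empty(N_REC)
    for k in range(N_REC):
        fr[k] = math.exp(-dt / rec_tau_r[k])
        fd[k] = math.exp(-dt / rec_tau_d[k])
        tr = rec_tau_r[k]
        td = rec_tau_d[k]
        tpk = tr * td / (td - tr) * math.log(td / tr)
        norm[k] = 1.0 / (math.exp(-tpk / td) - math.exp(-tpk / tr))

    # ring buffer for delayed synaptic activations
    max_delay = 0.0
    for i in range(syn_delay.shape[0]):
        if syn_delay[i] > max_delay:
            max_delay = syn_delay[i]
    L = int(max_delay / dt) + 2
    buf = np.zeros((L, n_comp, N_REC))

    noise_state = np.zeros(n_comp)
    f_noise = math.exp(-dt / noise_tau)

    any_record = do_record_v or do_record_cur or clamp_comp.shape[0] > 0
    n_rec_samples = (n_steps + rec_every - 1) // rec_every if any_record else 0
    v_out = np.zeros((n_rec_samples, record_comps.shape[0])) if do_record_v else np.zeros((0, 0))
    cur_out = np.zeros((n_rec_samples, N_REC)) if do_record_cur else np.zeros((0, 0))
    clamp_out = np.zeros((n_rec_samples, clamp_comp.shape[0])) if clamp_comp.shape[0] > 0 else np.zeros((0, 0))

    max_spikes = 400000
    spike_cell = np.zeros(max_spikes, dtype=np.int64)
    spike_time = np.zeros(max_spikes)
    n_spikes = 0
    last_spike = np.full(n_cells, -1e9)
    prev_soma = np.empty(n_cells)
    for ci in range(n_cells):
        prev_soma[ci] = v[soma_idx[ci]]

    G = np.zeros(n_comp)
    GE = np.zeros(n_comp)
    Iext = np.zeros(n_comp)
    diag = np.zeros(n_comp)
    rhs = np.zeros(n_comp)

    ev_i = 0
    noise_i = 0
    n_ev = ev_t.shape[0]
    n_noise = noise_t.shape[0]

    rec_cur = np.zeros(N_REC)

    for s in range(n_steps):
        t = s * dt
        # receptor states: decay, then deliver this step's events
        slot = s % L
        for i in range(n_comp):
            for k in range(N_REC):
                syn_r[i, k] = syn_r[i, k] * fr[k] + buf[slot, i, k]
                syn_d[i, k] = syn_d[i, k] * fd[k] + buf[slot, i, k]
                buf[slot, i, k] = 0.0
        while ev_i < n_ev and ev_t[ev_i] <= t + 1e-9:
            i = ev_comp[ev_i]
            k = ev_rec[ev_i]
            syn_r[i, k] += ev_w[ev_i]
            syn_d[i, k] += ev_w[ev_i]
            ev_i += 1
        while noise_i < n_noise and noise_t[noise_i] <= t + 1e-9:
            noise_state[noise_comp[noise_i]] += noise_amp[noise_i]
            noise_i += 1

        # gating variables: exact exponential relaxation at the held voltage
        for ch in range(n_chan):
            vv = v[ch_comp[ch]]
            for gi in range(ch_gate_ptr[ch], ch_gate_ptr[ch + 1]):
                xinf = 1.0 / (1.0 + math.exp((g_vhalf[gi] - vv) / g_k[gi]))
                if g_tauform[gi] == 0:
                    tau = g_taumin[gi]
                else:
                    u = vv - g_tauvmax[gi]
                    tau = g_taumin[gi] + g_tauamp[gi] / (
                        math.exp(u / g_sig1[gi]) + math.exp(-u / g_sig2[gi])
                    )
                gate_x[gi] = xinf + (gate_x[gi] - xinf) * math.exp(-dt / tau)

        # ionic conductances
        for i in range(n_comp):
            G[i] = 0.0
            GE[i] = 0.0
            Iext[i] = 0.0
        i_ca_density = np.zeros(n_comp)
        for ch in range(n_chan):
            i = ch_comp[ch]
            g = ch_g[ch]
            for gi in range(ch_gate_ptr[ch], ch_gate_ptr[ch + 1]):
                x = gate_x[gi]
                p = g_exp[gi]
                for _ in range(p):
                    g *= x
            if ch_cadep[ch] == 1:
                g *= ca[i] / (ca[i] + ch_cakd[ch])
            G[i] += g
            GE[i] += g * ch_erev[ch]
            if ch_casrc[ch] == 1:
                # density mA/cm2 = nA / (um2 * 1e-8 cm2/um2) * 1e-6
                i_ca_density[i] += g * (v[i] - ch_erev[ch]) / area[i] * 1e2
        # calcium pools (analytic first-order update)
        for i in range(n_comp):
            if ca_has[i] == 1:
                fixed = ca_rest[i] - ca_phi[i] * i_ca_density[i] * ca_tau[i]
                cc = fixed + (ca[i] - fixed) * math.exp(-dt / ca_tau[i])
                ca[i] = cc if cc > 0.0 else 0.0

        # synaptic conductances (NMDA magnesium block at the held voltage)
        for k in range(N_REC):
            rec_cur[k] = 0.0
        for i in range(n_comp):
            for k in range(N_REC):
                g = norm[k] * (syn_d[i, k] - syn_r[i, k])
                if g <= 0.0:
                    continue
                if k == NMDA:
                    if nmda_sat[i] > 0.0:
                        g = nmda_sat[i] * (1.0 - math.exp(-g / nmda_sat[i]))
                    g *= 1.0 / (1.0 + mg_eta * math.exp(-mg_gamma * v[i]))
                G[i] += g
                GE[i] += g * rec_erev[k]
                if flagged[i] == 1:
                    rec_cur[k] += g * (v[i] - rec_erev[k])

        # injections and noise
        for j in range(inj_comp.shape[0]):
            if inj_t0[j] <= t < inj_t1[j]:
                Iext[inj_comp[j]] += inj_amp[j]
        for i in range(n_comp):
            noise_state[i] *= f_noise
            Iext[i] += noise_state[i]

        # voltage clamps as stiff series conductances
        for j in range(clamp_comp.shape[0]):
            i = clamp_comp[j]
            G[i] += clamp_g[j]
            GE[i] += clamp_g[j] * clamp_v[j]

        # assemble and solve the per-cell tree systems (Hines)
        for i in range(n_comp):
            diag[i] = c[i] / dt + gl[i] + G[i]
            rhs[i] = c[i] / dt * v[i] + gl[i] * el[i] + GE[i] + Iext[i]
        for i in range(n_comp):
            p = parent[i]
            if p >= 0:
                diag[i] += gax[i]
                diag[p] += gax[i]
        for i in range(n_comp - 1, -1, -1):
            p = parent[i]
            if p >= 0:
                f = gax[i] / diag[i]
                diag[p] -= f * gax[i]
                rhs[p] += f * rhs[i]
        for i in range(n_comp):
            p = parent[i]
            if p < 0:
                v[i] = rhs[i] / diag[i]
            else:
                v[i] = (rhs[i] + gax[i] * v[p]) / diag[i]
            if not np.isfinite(v[i]):
                return (
                    v_out, cur_out, clamp_out,
                    spike_cell[:n_spikes], spike_time[:n_spikes],
                    -1, t, i,
                )

        # spike detection on somata; propagate through the synapse table
        for ci in range(n_cells):
            vs = v[soma_idx[ci]]
            if vs >= SPIKE_THRESHOLD and prev_soma[ci] < SPIKE_THRESHOLD:
                frac = (SPIKE_THRESHOLD - prev_soma[ci]) / (vs - prev_soma[ci])
                t_sp = t + frac * dt
                if t_sp - last_spike[ci] >= SPIKE_LOCKOUT:
                    last_spike[ci] = t_sp
                    if n_spikes < max_spikes:
                        spike_cell[n_spikes] = ci
                        spike_time[n_spikes] = t_sp
                        n_spikes += 1
                    for sy in range(syn_ptr[ci], syn_ptr[ci + 1]):
                        dstep = int(syn_delay[sy] / dt + 0.5)
                        if dstep < 1:
                            dstep = 1
                        tgt = (s + dstep) % L
                        buf[tgt, syn_comp[sy], syn_rec[sy]] += syn_w[sy]
            prev_soma[ci] = vs

        # recording
        if (do_record_v or do_record_cur or clamp_comp.shape[0] > 0) and s % rec_every == 0:
            r = s // rec_every
            if do_record_v:
                for j in range(record_comps.shape[0]):
                    v_out[r, j] = v[record_comps[j]]
            if do_record_cur:
                for k in range(N_REC):
                    cur_out[r, k] = rec_cur[k]
            for j in range(clamp_comp.shape[0]):
                clamp_out[r, j] = clamp_g[j] * (clamp_v[j] - v[clamp_comp[j]])

    return v_out, cur_out, clamp_out, spike_cell[:n_spikes], spike_time[:n_spikes], 0, n_steps * dt, -1


def integrate(net: CompiledNetwork, config: SimulationConfig):
    """Run the semi-implicit integration; returns ``(TraceSet, SpikeTrainSet)``."""
    n_steps = int(round(config.duration / config.dt))
    out = _kernel(
        config.dt, n_steps, config.record_every,
        net.c, net.gl, net.el, net.parent, net.gax, net.cell_of, net.area,
        net.v0, net.soma_idx, net.is_current_flagged,
        net.ch_comp, net.ch_g, net.ch_erev, net.ch_cadep, net.ch_cakd,
        net.ch_casrc, net.ch_gate_ptr,
        net.g_vhalf, net.g_k, net.g_tauform, net.g_taumin, net.g_tauamp,
        net.g_tauvmax, net.g_sig1, net.g_sig2, net.g_exp,
        net.ca_has, net.ca_rest, net.ca_tau, net.ca_phi,
        net.syn_ptr, net.syn_comp, net.syn_rec, net.syn_w, net.syn_delay,
        net.rec_tau_r, net.rec_tau_d, net.rec_erev, net.mg_eta, net.mg_gamma,
        net.nmda_sat,
        net.ev_t, net.ev_comp, net.ev_rec, net.ev_w,
        net.noise_t, net.noise_comp, net.noise_amp, net.noise_tau,
        net.inj_comp.astype(np.int64), net.inj_t0, net.inj_t1, net.inj_amp,
        net.clamp_comp, net.clamp_v, net.clamp_g,
        net.record_comps, config.record_voltages, config.record_currents,
    )
    v_out, cur_out, clamp_out, spike_cell, spike_time, status, t_last, bad_comp = out
    if status != 0:
        label = net.labels[bad_comp] if 0 <= bad_comp < len(net.labels) else "?"
        raise RuntimeError(
            f"integration diverged at t = {t_last:.3f} ms in compartment {label}; "
            f"n_comp={net.n_comp} dt={config.dt}"
        )
    dt_rec = config.dt * config.record_every
    n_samples = v_out.shape[0] if config.record_voltages else (
        cur_out.shape[0] if config.record_currents else clamp_out.shape[0]
    )
    time = np.arange(n_samples) * dt_rec
    voltages = {}
    if config.record_voltages:
        for j, gi in enumerate(net.record_comps):
            voltages[net.labels[gi]] = v_out[:, j]
    clamp_currents = {}
    for j, gi in enumerate(net.clamp_comp):
        clamp_currents[net.labels[gi]] = clamp_out[:, j]
    traces = TraceSet(
        dt=dt_rec,
        time=time,
        voltages=voltages,
        receptor_currents=cur_out if config.record_currents else None,
        clamp_currents=clamp_currents,
    )
    trains = [spike_time[spike_cell == ci] for ci in range(net.n_cells)]
    spikes = SpikeTrainSet(trains, duration=config.duration, seed=config.seed)
    return traces, spikes
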