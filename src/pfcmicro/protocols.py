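"""Persistent-activity induction: stimulus delivery, trial classification,
and probability maps over receptor-ratio grids.

A trial delivers the thalamocortical stimulus -- 120 AMPA+NMDA synapses on
the proximal apical dendrite of every pyramidal cell, activated as 10 volleys
at 20 Hz -- on top of background somatic noise, and classifies the outcome
from the pyramidal spike trains alone: the trial counts as induced when at
least ``min_fraction`` of the pyramidal cells fire above ``min_rate`` inside
a window of the delay period (defaults: 1-4 s after stimulus end, 2 Hz, 75%).
The induction criterion is an operational definition chosen so that delay
firing at 8-17 Hz that outlasts the stimulus by seconds classifies as
induced and a silent network does not.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .engine import AMPA, NMDA, SimulationConfig, SpikeTrainSet, TraceSet, integrate
from .network import (ManipulationSpec, Network, NetworkSpec, apply_manipulation,
                      background_noise_sources, build_network, draw_latencies)


@dataclass
class StimulusSpec:
    """Thalamocortical stimulation of all pyramidal cells (identical drive)."""

    n_synapses: int = 120
    target: str = "proximal"
    pulses: int = 10
    rate: float = 20.0  # Hz; the 40 Hz variant is the same protocol faster
    onset: float = 200.0  # ms
    ampa_gmax: float = 1.5e-4  # uS per synapse (thalamocortical unitary weight)
    #: sd (ms) of the per-synapse activation jitter around each volley;
    #: thalamocortical afferents do not fire in lockstep
    jitter_sd: float = 0.9

    @property
    def period(self) -> float:
        return 1000.0 / self.rate

    @property
    def end(self) -> float:
        return self.onset + self.pulses * self.period


@dataclass
class InductionCriterion:
    window_start: float = 1000.0  # ms after stimulus end
    window_length: float = 3000.0  # ms
    min_rate: float = 2.0  # Hz
    min_fraction_of_pyr: float = 0.75

    def __post_init__(self):
        if min(self.window_start, self.window_length, self.min_rate,
               self.min_fraction_of_pyr) <= 0:
            raise ValueError("criterion fields must be positive")


@dataclass
class InductionResult:
    outcomes: list[bool]
    condition: dict
    seeds: list[int]

    @property
    def probability(self) -> float:
        return float(np.mean(self.outcomes)) if self.outcomes else float("nan")

    @property
    def n_trials(self) -> int:
        return len(self.outcomes)

    def wilson_ci(self, z: float = 1.96) -> tuple[float, float]:
        n, p = self.n_trials, self.probability
        if n == 0:
            return (float("nan"), float("nan"))
        den = 1 + z * z / n
        mid = (p + z * z / (2 * n)) / den
        half = z * np.sqrt(p * (1 - p) / n + z * z / (4 * n * n)) / den
        return (max(0.0, mid - half), min(1.0, mid + half))


def classify_induction(
    spikes: SpikeTrainSet, pyr_indices, stim_end: float, crit: InductionCriterion
) -> bool:
    """Apply the induction criterion to the pyramidal trains of one trial."""
    t0 = stim_end + crit.window_start
    t1 = t0 + crit.window_length
    rates = []
    for i in pyr_indices:
        st = spikes.trains[i]
        rates.append(np.sum((st >= t0) & (st < t1)) / (crit.window_length * 1e-3))
    ok = np.asarray(rates) >= crit.min_rate
    return bool(np.mean(ok) >= crit.min_fraction_of_pyr)


def run_induction_trial(
    net: Network,
    stim: StimulusSpec | None = None,
    crit: InductionCriterion | None = None,
    seed: int = 0,
    duration: float | None = None,
    record_currents: bool = True,
    record_voltages: bool = False,
) -> tuple[bool, SpikeTrainSet, TraceSet]:
    """One seeded trial: stimulus + noise, integration, classification.

    The seed drives the per-trial entropy (stimulus synapse latencies and
    background-noise event times); the network itself is fixed.
    """
    stim = stim or StimulusSpec()
    crit = crit or InductionCriterion()
    if duration is None:
        duration = stim.end + crit.window_start + crit.window_length + 300.0
    if duration < stim.end + crit.window_start + crit.window_length:
        raise ValueError("trial too short for the induction window")
    cnet = net.compile()
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x57EB]))
    # stimulus events: per-synapse latency jitter, identical volley times
    from .network import NMDA_SAT_FACTOR

    ev_t, ev_c, ev_r, ev_w = [], [], [], []
    ratios = net.spec.ratios
    for j in net.pyramidal:
        comp = cnet.comp(j, stim.target)
        cnet.nmda_sat[comp] += (NMDA_SAT_FACTOR * stim.n_synapses
                                * stim.ampa_gmax * ratios.nmda_ampa_pyr)
        lat = draw_latencies(stim.n_synapses, rng)
        if stim.jitter_sd > 0.9:
            lat = lat + np.abs(rng.normal(0.0, stim.jitter_sd,
                                          size=stim.n_synapses))
        for p in range(stim.pulses):
            t_pulse = stim.onset + p * stim.period
            for k in range(stim.n_synapses):
                ev_t.append(t_pulse + lat[k])
                ev_c.append(comp)
                ev_r.append(AMPA)
                ev_w.append(stim.ampa_gmax)
                ev_t.append(t_pulse + lat[k])
                ev_c.append(comp)
                ev_r.append(NMDA)
                ev_w.append(stim.ampa_gmax * ratios.nmda_ampa_pyr)
    if ev_t:
        cnet.add_events(ev_t, ev_c, ev_r, ev_w)
    noise = background_noise_sources(net, seed, duration)
    nt, nc, na = [], [], []
    for ci, events in enumerate(noise):
        soma = cnet.comp(ci, "soma")
        for t in events:
            nt.append(t)
            nc.append(soma)
            na.append(net.spec.noise.amplitude)
    if nt:
        cnet.add_noise_events(nt, nc, na)
    cfg = SimulationConfig(duration=duration, seed=seed,
                           record_voltages=record_voltages,
                           record_currents=record_currents)
    traces, spikes = integrate(cnet, cfg)
    spikes.condition = net.spec.manipulation.mode
    spikes.seed = seed
    induced = classify_induction(spikes, net.pyramidal, stim.end, crit)
    return induced, spikes, traces


def run_trials(
    net: Network,
    n_trials: int,
    base_seed: int = 0,
    stim: StimulusSpec | None = None,
    crit: InductionCriterion | None = None,
    **kwargs,
) -> InductionResult:
    seeds = [base_seed + 1000 * k for k in range(n_trials)]
    outcomes = [
        run_induction_trial(net, stim, crit, seed=s, record_currents=False,
                            **kwargs)[0]
        for s in seeds
    ]
    return InductionResult(
        outcomes=outcomes,
        condition=dict(manipulation=net.spec.manipulation.mode,
                       nmda_ampa=net.spec.ratios.nmda_ampa_pyr,
                       gabab_gabaa=net.spec.ratios.gabab_gabaa),
        seeds=seeds,
    )


DEFAULT_NMDA_GRID = (0.5, 0.875, 1.25, 1.625, 2.0)
DEFAULT_GABAB_GRID = (0.0, 0.1, 0.2, 0.3, 0.4)


def induction_probability_grid(
    template: NetworkSpec,
    nmda_ampa_grid=DEFAULT_NMDA_GRID,
    gabab_gabaa_grid=DEFAULT_GABAB_GRID,
    n_trials: int = 10,
    base_seed: int = 0,
    manipulation: ManipulationSpec | None = None,
    stim: StimulusSpec | None = None,
    crit: InductionCriterion | None = None,
) -> pd.DataFrame:
    """Induction probability over a (NMDA/AMPA x GABA_B/GABA_A) grid.

    Ratios are applied to the pyramidal connections; each grid point runs
    ``n_trials`` independently seeded trials.  Returns a long-format frame
    with Wilson confidence bounds per point.
    """
    if n_trials < 1 or not len(nmda_ampa_grid) or not len(gabab_gabaa_grid):
        raise ValueError("grid and trial count must be non-empty")
    rows = []
    for na in nmda_ampa_grid:
        for gg in gabab_gabaa_grid:
            ratios = replace(template.ratios, nmda_ampa_pyr=na, gabab_gabaa=gg)
            spec = replace(template, ratios=ratios)
            net = build_network(spec)
            if manipulation is not None and manipulation.mode != "control":
                net = apply_manipulation(net, manipulation)
            res = run_trials(net, n_trials, base_seed=base_seed, stim=stim,
                             crit=crit)
            lo, hi = res.wilson_ci()
            rows.append(dict(nmda_ampa=na, gabab_gabaa=gg,
                             probability=res.probability, n_trials=n_trials,
                             ci_lo=lo, ci_hi=hi))
    return pd.DataFrame(rows)


def persistent_mean_isi(
    spikes: SpikeTrainSet, pyr_indices, stim_end: float,
    epoch_start_offset: float = 500.0, bin_width: float = 500.0,
) -> float:
    """Population-mean pyramidal ISI (ms) over 500 ms bins of the
    persistent-activity epoch (stimulus end + offset to trial end)."""
    from .analysis import binned_isi_cv

    sub = SpikeTrainSet([spikes.trains[i] for i in pyr_indices],
                        spikes.duration, spikes.condition, spikes.seed)
    summary = binned_isi_cv(sub, (stim_end + epoch_start_offset,
                                  spikes.duration), bin_width=bin_width)
    means = summary.population_mean_isi
    means = means[~np.isnan(means)]
    return float(np.mean(means)) if means.size else float("nan")


def nmda_modulation_experiment(
    target_pop: str,
    ratio_list,
    template: NetworkSpec | None = None,
    n_trials: int = 5,
    base_seed: int = 0,
    stim: StimulusSpec | None = None,
    crit: InductionCriterion | None = None,
) -> pd.DataFrame:
    """Sweep the NMDA-to-AMPA ratio on pyramidal or FS connections.

    Reports per ratio the induction probability and the mean pyramidal ISI
    during persistent activity (NaN when nothing persisted).
    """
    if target_pop not in ("PYR", "FS"):
        raise ValueError("target must be PYR or FS")
    template = template or NetworkSpec()
    stim = stim or StimulusSpec()
    crit = crit or InductionCriterion()
    field_name = "nmda_ampa_pyr" if target_pop == "PYR" else "nmda_ampa_fs"
    rows = []
    for r in ratio_list:
        if r < 0:
            raise ValueError("ratios must be >= 0")
        ratios = replace(template.ratios, **{field_name: r})
        net = build_network(replace(template, ratios=ratios))
        outcomes, isis = [], []
        for k in range(n_trials):
            seed = base_seed + 1000 * k
            induced, spikes, _ = run_induction_trial(
                net, stim, crit, seed=seed, record_currents=False)
            outcomes.append(induced)
            if induced:
                isis.append(persistent_mean_isi(spikes, net.pyramidal, stim.end))
        rows.append(dict(target=target_pop, ratio=r,
                         probability=float(np.mean(outcomes)),
                         n_trials=n_trials,
                         mean_isi=float(np.mean(isis)) if isis else float("nan")))
    return pd.DataFrame(rows)
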