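"""Experiment manifests: reproducible, resumable trial bundles.

A manifest fully describes one experiment (network variant, receptor ratios,
stimulus, induction criterion, trial count, base seed); running it produces a
bundle directory holding a copy of the manifest, one spike-train table per
trial, a results table, optional voltage/current traces (HDF5), and a log.
Re-running an archived manifest reproduces the spike tables byte-for-byte;
interrupted runs resume at the first missing trial.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .engine import SpikeTrainSet, TraceSet
from .network import ManipulationSpec, NetworkSpec, apply_manipulation, build_network
from .protocols import (InductionCriterion, StimulusSpec, classify_induction,
                        run_induction_trial)


@dataclass
class ExperimentManifest:
    name: str = "experiment"
    manipulation: ManipulationSpec = field(default_factory=ManipulationSpec)
    nmda_ampa_pyr: float = 1.25
    nmda_ampa_fs: float = 0.5
    gabab_gabaa: float = 0.2
    stimulus: StimulusSpec = field(default_factory=StimulusSpec)
    criterion: InductionCriterion = field(default_factory=InductionCriterion)
    n_trials: int = 10
    base_seed: int = 0
    network_seed: int = 0
    save_traces: bool = False

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentManifest":
        d = dict(d)
        d["manipulation"] = ManipulationSpec(**d.get("manipulation", {}))
        d["stimulus"] = StimulusSpec(**d.get("stimulus", {}))
        d["criterion"] = InductionCriterion(**d.get("criterion", {}))
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "ExperimentManifest":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    def network_spec(self) -> NetworkSpec:
        spec = NetworkSpec(seed=self.network_seed)
        ratios = replace(spec.ratios, nmda_ampa_pyr=self.nmda_ampa_pyr,
                         nmda_ampa_fs=self.nmda_ampa_fs,
                         gabab_gabaa=self.gabab_gabaa)
        return replace(spec, ratios=ratios)

    def trial_seeds(self) -> list[int]:
        return [self.base_seed + 1000 * k for k in range(self.n_trials)]


# -- delimited / binary persistence -----------------------------------------


def save_spike_trains(spikes: SpikeTrainSet, path) -> None:
    """Spike trains as a delimited table (neuron id, spike time in ms)."""
    with open(path, "w") as fh:
        fh.write(f"# duration_ms={spikes.duration} condition={spikes.condition} "
                 f"seed={spikes.seed} n_neurons={spikes.n_neurons}\n")
        fh.write("neuron\ttime_ms\n")
        for i, train in enumerate(spikes.trains):
            for t in train:
                fh.write(f"{i}\t{t:.6f}\n")


def load_spike_trains(path) -> SpikeTrainSet:
    with open(path) as fh:
        header = fh.readline().lstrip("# ").split()
        meta = dict(kv.split("=", 1) for kv in header)
        df = pd.read_csv(fh, sep="\t")
    n = int(meta["n_neurons"])
    trains = [df.loc[df["neuron"] == i, "time_ms"].to_numpy() for i in range(n)]
    return SpikeTrainSet(trains, duration=float(meta["duration_ms"]),
                         condition=meta.get("condition", ""),
                         seed=int(meta.get("seed", 0)))


def save_traces(traces: TraceSet, path) -> None:
    """Traces in a chunked HDF5 container with embedded metadata."""
    import h5py

    with h5py.File(path, "w") as h5:
        h5.attrs["dt"] = traces.dt
        h5.create_dataset("time", data=traces.time, chunks=True)
        g = h5.create_group("voltages")
        for label, v in traces.voltages.items():
            g.create_dataset(label, data=v, chunks=True)
        if traces.receptor_currents is not None:
            h5.create_dataset("receptor_currents",
                              data=traces.receptor_currents, chunks=True)


def load_traces(path) -> TraceSet:
    import h5py

    with h5py.File(path, "r") as h5:
        voltages = {k: v[...] for k, v in h5["voltages"].items()}
        rc = h5["receptor_currents"][...] if "receptor_currents" in h5 else None
        return TraceSet(dt=float(h5.attrs["dt"]), time=h5["time"][...],
                        voltages=voltages, receptor_currents=rc)


# -- execution ---------------------------------------------------------------


def run_manifest(manifest: ExperimentManifest, out_dir) -> pd.DataFrame:
    """Execute all trials of a manifest into a bundle directory.

    Trials whose spike-train files already exist are not recomputed, so a
    partially written bundle resumes where it stopped.  Returns the results
    table (one row per trial).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest.to_yaml(out / "manifest.yaml")
    net = build_network(manifest.network_spec())
    if manifest.manipulation.mode != "control":
        net = apply_manipulation(net, manifest.manipulation)
    rows = []
    log_lines = [f"pfcmicro {__version__}", f"manifest {manifest.name}"]
    for k, seed in enumerate(manifest.trial_seeds()):
        spike_path = out / f"trial_{seed:06d}.spikes.tsv"
        if spike_path.exists():
            spikes = load_spike_trains(spike_path)
            log_lines.append(f"trial {k} seed {seed}: reused")
        else:
            _, spikes, traces = run_induction_trial(
                net, manifest.stimulus, manifest.criterion, seed=seed,
                record_currents=manifest.save_traces)
            save_spike_trains(spikes, spike_path)
            if manifest.save_traces:
                save_traces(traces, out / f"trial_{seed:06d}.traces.h5")
            log_lines.append(f"trial {k} seed {seed}: simulated")
        induced = classify_induction(spikes, net.pyramidal,
                                     manifest.stimulus.end, manifest.criterion)
        window = (manifest.stimulus.end, spikes.duration)
        n_spk = sum(np.sum((t >= window[0]) & (t < window[1]))
                    for t in [spikes.trains[i] for i in net.pyramidal])
        mean_rate = n_spk / len(net.pyramidal) / ((window[1] - window[0]) * 1e-3)
        rows.append(dict(trial=k, seed=seed, induced=bool(induced),
                         mean_delay_rate_hz=float(mean_rate)))
    results = pd.DataFrame(rows)
    results.to_csv(out / "results.csv", index=False)
    (out / "log.txt").write_text("\n".join(log_lines) + "\n")
    return results
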