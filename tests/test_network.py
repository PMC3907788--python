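"""Microcircuit assembly: Table-style connectivity audit, latency statistics,
background noise, and every manipulated variant."""

import numpy as np
import pytest
from scipy import stats

from pfcmicro.network import (LATENCY_MEAN, LATENCY_MIN, LATENCY_SD,
                              ManipulationSpec, NetworkSpec, NoiseConfig,
                              apply_manipulation, background_noise_sources,
                              build_network, draw_latencies)

# expected synapse counts per connected pair, transcribed from the published
# wiring table (hard-coded adjacency audit)
EXPECTED_COUNTS = {
    ("PYR", "PYR", "basal", False): 24,
    ("PYR", "PYR", "basal", True): 8,
    ("PYR", "FS", "dendrite", False): 12,
    ("PYR", "RS", "dendrite", False): 14,
    ("PYR", "IS", "dendrite", False): 7,
    ("FS", "FS", "soma", True): 1,
    ("FS", "PYR", "soma", False): 15,
    ("RS", "PYR", "distal", False): 12,
    ("IS", "PYR", "distal", False): 10,
    ("IS", "RS", "dendrite", False): 2,
}


def pair_counts(net):
    out = {}
    for s in net.synapses:
        key = (net.cell_types[s.pre], net.cell_types[s.post],
               s.post_compartment, s.is_autapse, s.pre, s.post)
        out[key] = out.get(key, 0) + 1
    return out


class TestControlWiring:
    def test_population_composition(self, control_network):
        types = control_network.cell_types
        assert types.count("PYR") == 16
        assert types.count("FS") == 2
        assert types.count("RS") == 1
        assert types.count("IS") == 1
        # interneuron fraction 20%
        assert (types.count("FS") + types.count("RS") + types.count("IS")) == 4

    def test_adjacency_matches_published_table(self, control_network):
        counts = pair_counts(control_network)
        for (pre_t, post_t, comp, aut, pre, post), n in counts.items():
            assert EXPECTED_COUNTS[(pre_t, post_t, comp, aut)] == n
        # full recurrent pyramidal connectivity: every ordered pair present
        pyr_pairs = {(k[4], k[5]) for k in counts
                     if k[:4] == ("PYR", "PYR", "basal", False)}
        assert len(pyr_pairs) == 16 * 15

    def test_every_pyramidal_receives_fifteen_somatic_fs_synapses(self, control_network):
        counts = pair_counts(control_network)
        for fs in control_network.indices("FS"):
            for pyr in control_network.pyramidal:
                assert counts[("FS", "PYR", "soma", False, fs, pyr)] == 15

    def test_same_seed_builds_identical_networks(self):
        a = build_network(NetworkSpec(seed=11))
        b = build_network(NetworkSpec(seed=11))
        assert len(a.synapses) == len(b.synapses)
        assert all(x.latency == y.latency and x.pre == y.pre and x.post == y.post
                   for x, y in zip(a.synapses, b.synapses))

    def test_inhibitory_fraction_within_limit(self, control_network):
        n_stim = 120
        for j in control_network.pyramidal:
            exc = sum(1 for s in control_network.synapses
                      if s.post == j and "AMPA" in s.receptor_weights) + n_stim
            inh = sum(1 for s in control_network.synapses
                      if s.post == j and "GABAA" in s.receptor_weights)
            assert inh <= 0.13 * exc

    def test_manifest_exports_every_edge(self, control_network):
        mf = control_network.manifest()
        # one row per (synapse, receptor); excitatory and inhibitory both have 2
        # receptors except the GABA_A-only autapses
        n_aut = sum(1 for s in control_network.synapses
                    if s.is_autapse and "GABAA" in s.receptor_weights)
        assert len(mf) == 2 * len(control_network.synapses) - n_aut


class TestLatencies:
    def test_moments_match_truncated_normal_oracle(self):
        lat = draw_latencies(100_000, 123)
        ref = stats.truncnorm((LATENCY_MIN - LATENCY_MEAN) / LATENCY_SD, np.inf,
                              loc=LATENCY_MEAN, scale=LATENCY_SD)
        assert lat.mean() == pytest.approx(ref.mean(), abs=0.02)
        assert lat.std() == pytest.approx(ref.std(), abs=0.02)
        # mean close to the published 1.7 ms; the offset is the truncation
        # correction (~0.077 ms for sd 0.9 truncated at 0.1 ms)
        assert lat.mean() == pytest.approx(1.7, abs=0.1)

    def test_all_latencies_positive_after_truncation(self):
        lat = draw_latencies(50_000, 5)
        assert np.all(lat > LATENCY_MIN)

    def test_at_least_one_sample_required(self):
        with pytest.raises(ValueError):
            draw_latencies(0, 1)


class TestBackgroundNoise:
    def test_event_counts_are_poisson_dispersed(self, control_network):
        events = background_noise_sources(control_network, seed=2,
                                          duration=50_000.0)
        counts = []
        for train in events:
            edges = np.arange(0, 50_000.0 + 50.0, 50.0)
            counts.extend(np.histogram(train, bins=edges)[0])
        counts = np.asarray(counts, dtype=float)
        dispersion = counts.var() / counts.mean()
        assert dispersion == pytest.approx(1.0, abs=0.1)

    def test_zero_rate_yields_no_events(self, control_network):
        from dataclasses import replace

        silent = replace(control_network.spec,
                         noise=NoiseConfig(rate=0.0, rate_is=0.0))
        net = build_network(silent)
        events = background_noise_sources(net, seed=3, duration=10_000.0)
        assert all(t.size == 0 for t in events)

    def test_is_cell_uses_larger_rate(self, control_network):
        cfg = control_network.spec.noise
        assert cfg.rate_per_ms("IS") > cfg.rate_per_ms("PYR")


class TestManipulations:
    def test_fs_ko_removes_population_and_synapses(self, control_network,
                                                   fs_ko_network):
        assert fs_ko_network.n_cells == 18
        assert "FS" not in fs_ko_network.cell_types
        for j in fs_ko_network.pyramidal:
            somatic_inh = [s for s in fs_ko_network.synapses
                           if s.post == j and s.post_compartment == "soma"
                           and "GABAA" in s.receptor_weights]
            assert somatic_inh == []
        # source network untouched (purity)
        assert control_network.n_cells == 20

    def test_fs_scale_full_fraction_is_identity(self, control_network):
        scaled = apply_manipulation(control_network,
                                    ManipulationSpec(mode="fs_scale",
                                                     fs_fraction=1.0))
        assert len(scaled.synapses) == len(control_network.synapses)

    def test_fs_scale_keeps_rounded_fraction_per_pair(self, control_network):
        scaled = apply_manipulation(control_network,
                                    ManipulationSpec(mode="fs_scale",
                                                     fs_fraction=0.4))
        counts = pair_counts(scaled)
        for fs in scaled.indices("FS"):
            for pyr in scaled.pyramidal:
                assert counts[("FS", "PYR", "soma", False, fs, pyr)] == 6

    def test_fs_scale_synapse_conservation(self, control_network):
        f = 0.4
        scaled = apply_manipulation(control_network,
                                    ManipulationSpec(mode="fs_scale",
                                                     fs_fraction=f))
        removed = 2 * 16 * (15 - round(f * 15))
        assert len(scaled.synapses) == len(control_network.synapses) - removed

    @pytest.mark.parametrize("site,comp", [("D0", "basal"), ("D1", "proximal"),
                                           ("D2", "distal")])
    def test_fs_retarget_moves_projection(self, control_network, site, comp):
        moved = apply_manipulation(control_network,
                                   ManipulationSpec(mode="fs_retarget",
                                                    retarget_site=site))
        fs_syn = [s for s in moved.synapses
                  if moved.cell_types[s.pre] == "FS"
                  and moved.cell_types[s.post] == "PYR" and not s.is_autapse]
        assert len(fs_syn) == 2 * 16 * 15  # counts unchanged
        assert all(s.post_compartment == comp for s in fs_syn)

    def test_reverse_rs_swaps_roles_and_counts(self, control_network):
        rev = apply_manipulation(control_network,
                                 ManipulationSpec(mode="reverse_rs"))
        types = rev.cell_types
        assert (types.count("PYR"), types.count("FS"),
                types.count("RS"), types.count("IS")) == (16, 1, 2, 1)
        counts = pair_counts(rev)
        for rs in rev.indices("RS"):
            for pyr in rev.pyramidal:
                assert counts[("RS", "PYR", "soma", False, rs, pyr)] == 15
        fs = rev.indices("FS")[0]
        for pyr in rev.pyramidal:
            assert counts[("FS", "PYR", "distal", False, fs, pyr)] == 12

    def test_double_manipulation_rejected(self, fs_ko_network):
        with pytest.raises(ValueError):
            apply_manipulation(fs_ko_network, ManipulationSpec(mode="rs_ko"))

    def test_invalid_manipulation_parameters(self):
        with pytest.raises(ValueError):
            ManipulationSpec(mode="fs_scale", fs_fraction=1.5)
        with pytest.raises(ValueError):
            ManipulationSpec(mode="gap_junction_ko")
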