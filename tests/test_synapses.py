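"""Receptor models and the synaptic validation protocols: magnesium block,
bi-exponential transients, unitary-EPSP calibration and the two-hold
voltage-clamp ratio measurements."""

import math

import numpy as np
import pytest

from pfcmicro.cells import build_cell
from pfcmicro.engine import AMPA, GABAA, CompiledNetwork, SimulationConfig, integrate
from pfcmicro.synapses import (FS_AUTAPSE_HOLD_MV, FS_AUTAPSE_IPSC_NA,
                               RECEPTOR_DEFAULTS, RatioConfig, SynapseInstance,
                               SynapseKinetics, _epsp_peak,
                               calibrate_unitary_ampa, fs_autapse,
                               fs_autapse_gmax, mg_block_factor,
                               mg_half_unblock_voltage, nmda_ampa_peak_ratio,
                               synaptic_current, voltage_clamp_pair)


class TestMgBlock:
    def test_blocked_when_hyperpolarized(self):
        assert mg_block_factor(-120.0) < 0.05

    def test_unblocked_when_depolarized(self):
        assert mg_block_factor(60.0) > 0.9

    def test_half_unblock_voltage_closed_form(self):
        v_half = mg_half_unblock_voltage()
        assert mg_block_factor(v_half) == pytest.approx(0.5, abs=1e-12)

    def test_monotone_nondecreasing(self):
        vs = np.linspace(-120, 60, 200)
        bs = [mg_block_factor(float(v)) for v in vs]
        assert np.all(np.diff(bs) >= 0)
        assert all(0 < b < 1 for b in bs)


class TestKinetics:
    def test_decay_must_exceed_rise(self):
        with pytest.raises(ValueError):
            SynapseKinetics("AMPA", rise_tau=3.0, decay_tau=1.0, reversal=0.0)

    def test_ordering_of_default_time_constants(self):
        assert RECEPTOR_DEFAULTS["NMDA"][1] > RECEPTOR_DEFAULTS["AMPA"][1]
        assert RECEPTOR_DEFAULTS["GABAB"][1] > RECEPTOR_DEFAULTS["GABAA"][1]

    def test_unit_conductance_peaks_at_one_at_peak_time(self):
        kin = SynapseKinetics.default("AMPA")
        tp = kin.peak_time()
        assert kin.unit_conductance(np.array([tp]))[0] == pytest.approx(1.0, abs=1e-9)
        # independent closed form for the peak time of a bi-exponential
        tr, td = kin.rise_tau, kin.decay_tau
        assert tp == pytest.approx(tr * td / (td - tr) * math.log(td / tr))


class TestSynapticCurrent:
    @pytest.fixture
    def ampa_instance(self):
        return SynapseInstance(pre=0, post=1, post_compartment="basal",
                               receptor_weights={"AMPA": 1e-3}, latency=1.7)

    def test_silent_before_any_spike(self, ampa_instance):
        assert synaptic_current(ampa_instance, [], -70.0, 50.0) == 0.0
        assert synaptic_current(ampa_instance, [100.0], -70.0, 50.0) == 0.0

    def test_zero_at_reversal(self, ampa_instance):
        assert synaptic_current(ampa_instance, [10.0], 0.0, 20.0) == 0.0

    def test_peak_current_matches_bi_exponential_closed_form(self, ampa_instance):
        kin = SynapseKinetics.default("AMPA")
        t_peak = 10.0 + 1.7 + kin.peak_time()
        i = synaptic_current(ampa_instance, [10.0], -70.0, t_peak)
        assert i == pytest.approx(1e-3 * (-70.0 - 0.0), rel=0.02)

    def test_nmda_scaling_is_linear_in_ratio(self):
        base = SynapseInstance(pre=0, post=1, post_compartment="basal",
                               receptor_weights={"NMDA": 1e-3}, latency=1.0)
        doubled = SynapseInstance(pre=0, post=1, post_compartment="basal",
                                  receptor_weights={"NMDA": 2e-3}, latency=1.0)
        t = 1.0 + 1.0 + 20.0
        i1 = synaptic_current(base, [1.0], -30.0, t)
        i2 = synaptic_current(doubled, [1.0], -30.0, t)
        assert i2 == pytest.approx(2 * i1)

    def test_mixed_receptor_classes_rejected(self):
        with pytest.raises(ValueError):
            SynapseInstance(pre=0, post=1, post_compartment="soma",
                            receptor_weights={"AMPA": 1e-3, "GABAA": 1e-3},
                            latency=1.0)


class TestRatioConfig:
    def test_control_defaults(self):
        r = RatioConfig()
        assert r.nmda_ampa_pyr == 1.25
        assert r.gabab_gabaa == 0.2
        assert r.nmda_ampa_fs == 0.5
        assert r.nmda_ampa_rs == 0.8

    def test_negative_ratio_rejected(self):
        with pytest.raises(ValueError):
            RatioConfig(gabab_gabaa=-0.1)


class TestUnitaryCalibration:
    def test_calibrated_weight_gives_tenth_millivolt_epsp(self, cells):
        g = calibrate_unitary_ampa(cells["PYR"])
        peak = _epsp_peak(cells["PYR"], g)
        assert peak == pytest.approx(0.1, rel=0.05)

    def test_doubled_weight_sublinear_or_linear(self, cells):
        g = calibrate_unitary_ampa(cells["PYR"])
        peak2 = _epsp_peak(cells["PYR"], 2 * g)
        assert 0.1 < peak2 <= 0.2 * 1.01

    def test_zero_weight_zero_deflection(self, cells):
        # bounded only by the slow-gate numerical drift of the resting cell
        assert _epsp_peak(cells["PYR"], 0.0) == pytest.approx(0.0, abs=1e-3)

    def test_non_bracketing_bounds_rejected(self, cells):
        with pytest.raises(ValueError):
            calibrate_unitary_ampa(cells["PYR"], lo=0.01, hi=0.05)


class TestVoltageClamp:
    def test_pyr_pair_inward_at_minus70_with_small_nmda_share(self):
        t, i_both = voltage_clamp_pair("PYR", "PYR", -70.0)
        t, i_nmda = voltage_clamp_pair("PYR", "PYR", -70.0, receptors=("NMDA",))
        win = t >= 101.0
        assert i_both[win].min() < 0  # inward EPSC
        share = np.abs(i_nmda[win]).max() / np.abs(i_both[win]).max()
        assert share < 0.10

    def test_pyr_pair_outward_nmda_dominated_at_plus60(self):
        t, i = voltage_clamp_pair("PYR", "PYR", 60.0)
        t, i_nmda = voltage_clamp_pair("PYR", "PYR", 60.0, receptors=("NMDA",))
        win = t >= 101.0
        assert i[win].max() > 0
        assert i_nmda[win].max() / i[win].max() > 0.5

    @pytest.mark.parametrize("post,target", [("FS", 0.5), ("RS", 0.8)])
    def test_recovered_nmda_ampa_ratio(self, post, target):
        assert nmda_ampa_peak_ratio("PYR", post) == pytest.approx(target, rel=0.10)


class TestFsAutapse:
    def test_single_somatic_gabaa_autapse(self):
        syn = fs_autapse(3)
        assert syn.pre == syn.post == 3
        assert syn.is_autapse
        assert syn.post_compartment == "soma"
        assert set(syn.receptor_weights) == {"GABAA"}

    def test_weight_reproduces_reference_ipsc_amplitude(self):
        g = fs_autapse_gmax()
        e_gabaa = RECEPTOR_DEFAULTS["GABAA"][2]
        assert g * abs(FS_AUTAPSE_HOLD_MV - e_gabaa) == pytest.approx(
            FS_AUTAPSE_IPSC_NA)

    def test_removing_autapse_cannot_reduce_excitability(self):
        counts = {}
        for weight in (fs_autapse_gmax(), 0.0):
            fs = build_cell("FS")
            net = CompiledNetwork.from_cells([fs])
            if weight > 0:
                net.set_synapses([0], [net.comp(0, "soma")], [GABAA],
                                 [weight], [1.0])
            net.add_injection(0, 100.0, 600.0, 0.2)
            _, spikes = integrate(net, SimulationConfig(duration=700.0))
            counts[weight] = len(spikes.trains[0])
        assert counts[0.0] >= counts[fs_autapse_gmax()]
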