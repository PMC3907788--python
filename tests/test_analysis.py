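"""Analysis procedures: binned ISI/CV, SPIKE-distance (against a brute-force
oracle), discrete-time rate, and the decimated periodogram."""

import numpy as np
import pytest

from conftest import poisson_train
from pfcmicro.analysis import (binned_isi_cv, discrete_time_rate,
                               spike_distance_index, summed_current,
                               synaptic_current_spectrum)
from pfcmicro.engine import SpikeTrainSet, TraceSet


def trains(list_of_lists, duration):
    return SpikeTrainSet([np.asarray(t, float) for t in list_of_lists], duration)


# ---------------------------------------------------------------------------
# independent brute-force SPIKE-distance oracle (dense evaluation of the
# definition, integrated by trapezoid over a grid containing all corners)


def _nearest(t, train):
    i = np.searchsorted(train, t)
    c = []
    if i > 0:
        c.append(abs(t - train[i - 1]))
    if i < len(train):
        c.append(abs(train[i] - t))
    return min(c)


def oracle_pair_average(t1, t2, t0, t_end, n_fine=20000):
    a = np.concatenate([[t0], t1, [t_end]])
    b = np.concatenate([[t0], t2, [t_end]])
    grid = np.unique(np.concatenate([a, b, np.linspace(t0, t_end, n_fine)]))

    def S(t):
        vals = []
        for own, other in ((a, b), (b, a)):
            ip = np.searchsorted(own, t, side="right") - 1
            tp = own[max(ip, 0)]
            if_ = np.searchsorted(own, t, side="left")
            tf = own[min(if_, len(own) - 1)]
            if tf <= tp:  # exactly on a spike: distance contribution is local
                tf = own[min(if_ + 1, len(own) - 1)] if if_ + 1 < len(own) else tp
            x = max(tf - tp, 1e-12)
            dp, df = _nearest(tp, other), _nearest(tf, other)
            vals.append(((dp * (tf - t) + df * (t - tp)) / x, x))
        (s1, x1), (s2, x2) = vals
        mean_isi = 0.5 * (x1 + x2)
        return (s1 * x2 + s2 * x1) / (2 * mean_isi**2)

    mids = 0.5 * (grid[:-1] + grid[1:])
    widths = np.diff(grid)
    return float(np.sum([S(m) * w for m, w in zip(mids, widths)]) / (t_end - t0))


class TestSpikeDistance:
    def test_identical_trains_give_zero(self):
        base = np.arange(100.0, 900.0, 100.0)
        st = trains([base, base, base], 1000.0)
        assert spike_distance_index(st, (0.0, 1000.0)).index == pytest.approx(0.0, abs=1e-12)

    def test_offset_pair_matches_bruteforce_oracle(self):
        t1 = np.arange(100.0, 901.0, 100.0)
        t2 = t1 + 20.0
        st = trains([t1, t2], 1000.0)
        mine = spike_distance_index(st, (0.0, 1000.0)).index
        ref = oracle_pair_average(t1, t2, 0.0, 1000.0)
        assert mine == pytest.approx(ref, abs=1e-6)

    def test_random_pair_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(12)
        t1 = poisson_train(8.0, 1000.0, rng)
        t2 = poisson_train(8.0, 1000.0, rng)
        st = trains([t1, t2], 1000.0)
        mine = spike_distance_index(st, (0.0, 1000.0)).index
        ref = oracle_pair_average(t1, t2, 0.0, 1000.0)
        assert mine == pytest.approx(ref, abs=1e-6)

    def test_invariant_under_train_permutation(self):
        rng = np.random.default_rng(4)
        ts = [poisson_train(10.0, 800.0, rng) for _ in range(4)]
        a = spike_distance_index(trains(ts, 800.0), (0.0, 800.0)).index
        b = spike_distance_index(trains(ts[::-1], 800.0), (0.0, 800.0)).index
        assert a == pytest.approx(b, abs=1e-12)

    def test_invariant_under_global_time_shift(self):
        t1 = np.arange(100.0, 900.0, 95.0)
        t2 = np.arange(120.0, 900.0, 105.0)
        a = spike_distance_index(trains([t1, t2], 1000.0), (50.0, 950.0)).index
        b = spike_distance_index(trains([t1 + 500, t2 + 500], 1500.0),
                                 (550.0, 1450.0)).index
        assert a == pytest.approx(b, abs=1e-9)

    def test_fewer_than_two_nonempty_trains_rejected(self):
        st = trains([[100.0], []], 1000.0)
        with pytest.raises(ValueError):
            spike_distance_index(st, (0.0, 1000.0))

    def test_asynchronous_exceeds_synchronous(self):
        sync = trains([np.arange(50.0, 950.0, 50.0)] * 3, 1000.0)
        rng = np.random.default_rng(9)
        async_ = trains([poisson_train(20.0, 1000.0, rng) for _ in range(3)], 1000.0)
        assert (spike_distance_index(async_, (0, 1000)).index
                > spike_distance_index(sync, (0, 1000)).index)


class TestBinnedIsiCv:
    def test_regular_train_has_flat_profile(self):
        st = trains([np.arange(0.0, 2000.0, 100.0)], 2000.0)
        out = binned_isi_cv(st, (0.0, 2000.0), bin_width=500.0)
        valid = ~np.isnan(out.mean_isi[:, 0])
        assert np.all(out.mean_isi[valid, 0] == pytest.approx(100.0))
        assert np.all(out.cv_isi[valid, 0] == pytest.approx(0.0, abs=1e-12))

    def test_poisson_train_cv_near_one(self):
        rng = np.random.default_rng(21)
        st = trains([poisson_train(20.0, 200_000.0, rng)], 200_000.0)
        out = binned_isi_cv(st, (0.0, 200_000.0), bin_width=200_000.0)
        assert out.cv_isi[0, 0] == pytest.approx(1.0, abs=0.05)

    def test_sparse_bins_reported_missing(self):
        st = trains([[100.0, 150.0]], 2000.0)
        out = binned_isi_cv(st, (0.0, 2000.0), bin_width=500.0)
        assert np.isnan(out.mean_isi[1:, 0]).all()

    def test_empty_spike_set_not_an_error(self):
        out = binned_isi_cv(trains([[]], 1000.0), (0.0, 1000.0))
        assert np.isnan(out.mean_isi).all()

    def test_shift_invariance(self):
        t = np.sort(np.random.default_rng(8).uniform(0, 1000, 40))
        a = binned_isi_cv(trains([t], 1000.0), (0.0, 1000.0))
        b = binned_isi_cv(trains([t + 300.0], 1300.0), (300.0, 1300.0))
        assert np.allclose(a.mean_isi, b.mean_isi, equal_nan=True)


class TestDiscreteTimeRate:
    def test_empty_trains_all_zero(self):
        out = discrete_time_rate(trains([[], []], 1000.0), (0.0, 1000.0))
        assert out.total == 0

    def test_coincident_population_spike_in_single_bin(self):
        st = trains([[500.0]] * 20, 1000.0)
        out = discrete_time_rate(st, (0.0, 1000.0))
        assert out.counts.max() == 20
        assert out.total == 20

    def test_histogram_conserves_total_count(self):
        rng = np.random.default_rng(30)
        ts = [poisson_train(15.0, 900.0, rng) for _ in range(5)]
        out = discrete_time_rate(trains(ts, 900.0), (0.0, 900.0))
        assert out.total == sum(len(t) for t in ts)


def synthetic_traces(signal, dt=0.025):
    """Wrap a 1-D signal as the AMPA stream of a TraceSet."""
    n = signal.size
    rc = np.zeros((n, 4))
    rc[:, 0] = signal
    return TraceSet(dt=dt, time=np.arange(n) * dt, voltages={},
                    receptor_currents=rc)


class TestSpectrum:
    def test_pure_sinusoid_peaks_at_its_frequency(self):
        t = np.arange(0, 1000.0, 0.025)  # 1 s at the simulation rate
        tr = synthetic_traces(np.sin(2 * np.pi * 20.0 * t * 1e-3))
        sp = synaptic_current_spectrum([tr], (0.0, 1000.0))
        assert sp.dominant_frequency() == pytest.approx(20.0, abs=1.0)

    def test_white_noise_spectrum_is_flat(self):
        # single-trial periodogram bins are exponential (max/median ~ log n),
        # so flatness is asserted on the ten-trial average the procedure is
        # designed to produce
        rng = np.random.default_rng(17)
        trs = [synthetic_traces(rng.normal(size=40_000)) for _ in range(10)]
        sp = synaptic_current_spectrum(trs, (0.0, 1000.0))
        body = sp.power[(sp.frequencies > 2)]
        assert body.max() < 5 * np.median(body)

    def test_parseval_total_power_matches_variance(self):
        from scipy import signal as ss

        rng = np.random.default_rng(5)
        x = rng.normal(size=40_000)
        tr = synthetic_traces(x)
        sp = synaptic_current_spectrum([tr], (0.0, 1000.0))
        # variance of the decimated, demeaned signal (same preprocessing)
        y = x - x.mean()
        for q in (8, 5):
            y = ss.decimate(y, q, ftype="fir", zero_phase=True)
        total = np.sum(sp.power) * (sp.frequencies[1] - sp.frequencies[0])
        assert total == pytest.approx(np.var(y), rel=0.01)

    def test_window_outside_recording_rejected(self):
        tr = synthetic_traces(np.zeros(1000))
        with pytest.raises(ValueError):
            synaptic_current_spectrum([tr], (0.0, 10_000.0))

    def test_summed_current_excludes_gabab(self):
        rc = np.ones((100, 4))
        tr = TraceSet(dt=1.0, time=np.arange(100.0), voltages={},
                      receptor_currents=rc)
        assert np.all(summed_current(tr) == 3.0)
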