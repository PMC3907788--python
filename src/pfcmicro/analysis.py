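"""Spike-train and spectral analysis of microcircuit trials.

Four procedures: interspike-interval means and coefficients of variation in
500 ms bins; a desynchronization index based on the time-averaged
multivariate SPIKE-distance (Kreuz et al.); the discrete-time firing-rate
histogram (population spike counts in 1 ms bins); and the trial-averaged
mean-square periodogram of the summed synaptic currents (AMPA + NMDA +
GABA_A over the pyramidal population), decimated to 1 kHz first.

The SPIKE-distance profile of a pair of trains is piecewise linear between
the merged spike times, so its time average is computed exactly by
trapezoidal integration over those corners; the multivariate index is the
average over all train pairs.  Zero for identical trains; larger values mean
more asynchronous firing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .engine import SpikeTrainSet, TraceSet


# ---------------------------------------------------------------------------
# binned ISI / CV


@dataclass
class ISISummary:
    bin_edges: np.ndarray  # (n_bins + 1,)
    mean_isi: np.ndarray  # (n_bins, n_neurons), NaN where < 2 ISIs
    cv_isi: np.ndarray  # (n_bins, n_neurons)
    epoch: tuple[float, float]

    @property
    def population_mean_isi(self) -> np.ndarray:
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.mean_isi, axis=1)

    @property
    def population_cv(self) -> np.ndarray:
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.cv_isi, axis=1)


def binned_isi_cv(
    spikes: SpikeTrainSet, epoch: tuple[float, float], bin_width: float = 500.0
) -> ISISummary:
    """Per-neuron ISI mean and CV in ``bin_width`` bins tiling the epoch.

    An interval is assigned to the bin containing its terminating spike.
    Bins holding fewer than two intervals are reported as NaN ("missing"),
    not zero.
    """
    t0, t1 = epoch
    if not (t1 > t0):
        raise ValueError("epoch end must exceed start")
    n_bins = int(np.ceil((t1 - t0) / bin_width))
    edges = t0 + bin_width * np.arange(n_bins + 1)
    n = spikes.n_neurons
    mean = np.full((n_bins, n), np.nan)
    cv = np.full((n_bins, n), np.nan)
    for j, st in enumerate(spikes.trains):
        st = st[(st >= t0) & (st < t1)]
        if st.size < 2:
            continue
        isi = np.diff(st)
        term = st[1:]  # terminating spike of each interval
        which = np.clip(((term - t0) // bin_width).astype(int), 0, n_bins - 1)
        for b in range(n_bins):
            vals = isi[which == b]
            if vals.size >= 2:
                mean[b, j] = vals.mean()
                cv[b, j] = vals.std() / vals.mean()
    return ISISummary(bin_edges=edges, mean_isi=mean, cv_isi=cv, epoch=(t0, t1))


# ---------------------------------------------------------------------------
# SPIKE-distance


@dataclass
class SynchronyResult:
    index: float  # time-averaged multivariate SPIKE-distance
    epoch: tuple[float, float]
    neurons_included: list[int]


def _nearest_distance(t: float, train: np.ndarray) -> float:
    i = np.searchsorted(train, t)
    best = np.inf
    if i > 0:
        best = min(best, abs(t - train[i - 1]))
    if i < train.size:
        best = min(best, abs(train[i] - t))
    return best


def _pair_average(t1: np.ndarray, t2: np.ndarray, t0: float, t_end: float) -> float:
    """Exact time average of the bivariate SPIKE-distance profile.

    Auxiliary spikes at the epoch edges bound the interval structure (the
    standard edge correction).  Within each interval between merged spike
    times the profile is linear, so trapezoids over one-sided limits at the
    corners integrate it exactly.
    """
    a = np.concatenate([[t0], t1, [t_end]])
    b = np.concatenate([[t0], t2, [t_end]])
    corners = np.unique(np.concatenate([a, b]))

    def eval_limits(lo: float, hi: float) -> tuple[float, float]:
        # brackets are constant on the open interval (lo, hi)
        out = []
        comps = []
        for own, other in ((a, b), (b, a)):
            tp = own[np.searchsorted(own, lo, side="right") - 1]
            tf = own[np.searchsorted(own, hi, side="left")]
            x_isi = max(tf - tp, 1e-12)
            dp = _nearest_distance(tp, other)
            df = _nearest_distance(tf, other)
            comps.append((tp, tf, x_isi, dp, df))
        vals = []
        for t in (lo, hi):
            s_n = []
            for tp, tf, x_isi, dp, df in comps:
                xp = t - tp
                xf = tf - t
                s_n.append((dp * xf + df * xp) / x_isi)
            isi1, isi2 = comps[0][2], comps[1][2]
            mean_isi = 0.5 * (isi1 + isi2)
            vals.append((s_n[0] * isi2 + s_n[1] * isi1) / (2.0 * mean_isi**2))
        return vals[0], vals[1]

    total = 0.0
    for lo, hi in zip(corners[:-1], corners[1:]):
        if hi <= lo:
            continue
        s_lo, s_hi = eval_limits(lo, hi)
        total += 0.5 * (s_lo + s_hi) * (hi - lo)
    return total / (t_end - t0)


def spike_distance_index(
    spikes: SpikeTrainSet, epoch: tuple[float, float]
) -> SynchronyResult:
    """Time-averaged multivariate SPIKE-distance over the epoch.

    Neurons without spikes in the epoch are excluded; fewer than two
    remaining trains leave the index undefined.
    """
    t0, t1 = epoch
    trains = []
    included = []
    for i, st in enumerate(spikes.trains):
        st = st[(st >= t0) & (st <= t1)]
        if st.size:
            trains.append(st)
            included.append(i)
    if len(trains) < 2:
        raise ValueError("SPIKE-distance needs >= 2 non-empty spike trains")
    total = 0.0
    n_pairs = 0
    for i in range(len(trains)):
        for j in range(i + 1, len(trains)):
            total += _pair_average(trains[i], trains[j], t0, t1)
            n_pairs += 1
    return SynchronyResult(index=total / n_pairs, epoch=(t0, t1),
                           neurons_included=included)


# ---------------------------------------------------------------------------
# discrete-time firing rate


@dataclass
class FiringRateHistogram:
    bin_edges: np.ndarray
    counts: np.ndarray  # spikes summed over neurons per 1 ms bin

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def discrete_time_rate(
    spikes: SpikeTrainSet, epoch: tuple[float, float], bin_width: float = 1.0
) -> FiringRateHistogram:
    """Total spike count per ``bin_width`` (default 1 ms) bin, neurons summed."""
    t0, t1 = epoch
    n_bins = int(np.ceil((t1 - t0) / bin_width))
    edges = t0 + bin_width * np.arange(n_bins + 1)
    counts = np.zeros(n_bins, dtype=int)
    for st in spikes.trains:
        st = st[(st >= t0) & (st < edges[-1])]
        idx = ((st - t0) // bin_width).astype(int)
        np.add.at(counts, idx, 1)
    return FiringRateHistogram(bin_edges=edges, counts=counts)


# ---------------------------------------------------------------------------
# periodogram of summed synaptic currents


@dataclass
class SpectrumResult:
    frequencies: np.ndarray  # Hz
    power: np.ndarray  # mean-square power per frequency bin
    n_trials: int

    def dominant_frequency(self, f_min: float = 5.0) -> float:
        mask = self.frequencies >= f_min
        return float(self.frequencies[mask][np.argmax(self.power[mask])])


def summed_current(traces: TraceSet, receptors=(0, 1, 2)) -> np.ndarray:
    """Summed synaptic current over the flagged (pyramidal) population.

    Default receptors: AMPA, NMDA and GABA_A (GABA_B excluded)."""
    if traces.receptor_currents is None:
        raise ValueError("trial was recorded without receptor currents")
    return traces.receptor_currents[:, list(receptors)].sum(axis=1)


def synaptic_current_spectrum(
    trials: list[TraceSet],
    window: tuple[float, float],
    decimate_to: float = 1000.0,
) -> SpectrumResult:
    """Trial-averaged mean-square periodogram of the summed synaptic currents.

    Each trial's summed current is windowed, mean-subtracted, decimated to
    ``decimate_to`` Hz with FIR anti-alias filtering, and transformed with a
    plain (untapered) periodogram; spectra are averaged across trials.
    """
    if not trials:
        raise ValueError("no trials given")
    psds = []
    freqs = None
    for tr in trials:
        fs = 1000.0 / tr.dt  # Hz
        i0 = int(round(window[0] / tr.dt))
        i1 = int(round(window[1] / tr.dt))
        if i0 < 0 or i1 > tr.time.size:
            raise ValueError("window extends past the recording")
        x = summed_current(tr)[i0:i1]
        x = x - x.mean()
        q = int(round(fs / decimate_to))
        if q > 1:
            # factor q into small steps (scipy recommends q <= 13 per pass)
            for f in _factorize(q):
                x = signal.decimate(x, f, ftype="fir", zero_phase=True)
        f, p = signal.periodogram(x, fs=decimate_to, window="boxcar",
                                  detrend="constant")
        freqs = f
        psds.append(p)
    return SpectrumResult(frequencies=freqs, power=np.mean(psds, axis=0),
                          n_trials=len(trials))


def _factorize(q: int) -> list[int]:
    out = []
    for f in (13, 11, 10, 8, 7, 5, 4, 3, 2):
        while q % f == 0 and q > 1:
            out.append(f)
            q //= f
    if q > 1:
        out.append(q)
    return out
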