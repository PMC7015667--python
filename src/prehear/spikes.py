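"""Spike-train burst analysis for spiral ganglion neuron (SGN) recordings.

Before hearing onset, SGNs fire high-frequency bursts of action potentials
driven by inner-hair-cell Ca2+ spikes.  Bursts are identified from the
interspike-interval (ISI) sequence: each interval is classified as a
*burst interval* (30 ms - 1 s, matching the preferred IHC Ca2+-spike rate),
a *mini-burst interval* (< 30 ms, very fast doublets/triplets riding on a
burst), or a *non-burst interval* (> 1 s).  A burst is a maximal cluster of
consecutive burst intervals, at least ten of them, where mini-burst
intervals neither break the cluster nor count toward the ten, but their
spikes do count toward the burst's spike total.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import signal

__all__ = [
    "SpikeTrain",
    "ISIClassification",
    "Burst",
    "BurstMetrics",
    "MINI_BURST_MAX_S",
    "BURST_MAX_S",
    "detect_spikes",
    "classify_isis",
    "detect_bursts",
    "burst_metrics",
    "isi_log_histogram",
    "bin_firing_rate",
]

#: Upper edge of the mini-burst ISI class (exclusive).
MINI_BURST_MAX_S = 0.030
#: Upper edge of the burst ISI class (inclusive); longer intervals are non-burst.
BURST_MAX_S = 1.000

NON_BURST, BURST_IVL, MINI_BURST = "non_burst", "burst", "mini_burst"


@dataclass(frozen=True)
class SpikeTrain:
    """Ordered spike times (s) within a recording of known duration."""

    times: np.ndarray
    duration: float
    source_id: str = ""

    def __post_init__(self):
        times = np.asarray(self.times, dtype=float)
        object.__setattr__(self, "times", times)
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if times.size and (times.min() < 0 or times.max() >= self.duration):
            raise ValueError("spike times must lie in [0, duration)")
        if times.size > 1 and np.any(np.diff(times) <= 0):
            raise ValueError("spike times must be strictly increasing")

    def __len__(self) -> int:
        return int(self.times.size)

    @property
    def isis(self) -> np.ndarray:
        return np.diff(self.times)

    def shifted(self, dt: float) -> "SpikeTrain":
        """Translate all spikes by ``dt`` (duration grows to fit)."""
        times = self.times + dt
        dur = max(self.duration + dt, (times.max() + 1e-9) if times.size else 1e-9)
        return SpikeTrain(times, dur, self.source_id)


@dataclass(frozen=True)
class ISIClassification:
    """Per-interval labels for a spike train (one label per consecutive pair)."""

    times: np.ndarray
    intervals: np.ndarray
    labels: np.ndarray  # array of {non_burst, burst, mini_burst}

    def __post_init__(self):
        if len(self.labels) != len(self.intervals):
            raise ValueError("one label required per interval")
        if len(self.times) and len(self.intervals) != len(self.times) - 1:
            raise ValueError("n_intervals must equal n_spikes - 1")


@dataclass(frozen=True)
class Burst:
    start: float  # time of first spike in the burst (s)
    end: float  # time of last spike (s)
    n_spikes: int

    @property
    def duration(self) -> float:
        return self.end - self.start


@dataclass(frozen=True)
class BurstMetrics:
    burst_freq: float  # bursts per minute
    mean_duration: float | None  # s; None when no bursts
    mean_spikes_per_burst: float | None
    mean_ap_freq: float  # Hz, total spikes over the analysis window
    isi_cv: float | None  # SD/mean over all ISIs in the window


def detect_spikes(
    samples: np.ndarray,
    rate_hz: float,
    highpass_hz: float = 10.0,
    threshold_k: float = 5.0,
    refractory_s: float = 0.001,
    polarity: str = "pos",
) -> SpikeTrain:
    """Detect action potentials in a juxtacellular voltage/current trace.

    The raw trace is zero-phase high-pass filtered (2nd-order Butterworth)
    to remove baseline drift, and spikes are identified by an amplitude
    threshold of ``threshold_k`` times the robust noise SD
    (1.4826 x median absolute deviation) of the filtered trace.  One spike
    is reported per suprathreshold excursion, at its peak, with a minimal
    separation of ``refractory_s``.  ``polarity`` selects the deflection
    sign to detect on ("pos", "neg", or "both" via the absolute trace; the
    default assumes positive-going juxtacellular spikes).
    """
    samples = np.asarray(samples, dtype=float)
    if samples.size == 0:
        raise ValueError("empty trace")
    if rate_hz <= 2 * highpass_hz:
        raise ValueError("sampling rate must exceed twice the high-pass cutoff")
    sos = signal.butter(2, highpass_hz, btype="highpass", fs=rate_hz, output="sos")
    filt = signal.sosfiltfilt(sos, samples)
    if polarity == "neg":
        det = -filt
    elif polarity == "pos":
        det = filt
    else:
        det = np.abs(filt)
    mad = np.median(np.abs(filt - np.median(filt)))
    noise_sd = 1.4826 * mad
    if noise_sd == 0:
        # noiseless trace: any nonzero excursion counts
        thresh = 0.0
        if not np.any(det > 0):
            return SpikeTrain(np.empty(0), samples.size / rate_hz)
        thresh = det.max() * 0.5
    else:
        thresh = threshold_k * noise_sd
    distance = max(1, int(round(refractory_s * rate_hz)))
    peaks, _ = signal.find_peaks(det, height=thresh, distance=distance)
    return SpikeTrain(peaks / rate_hz, samples.size / rate_hz)


def classify_isis(train: SpikeTrain) -> ISIClassification:
    """Label every interspike interval as non_burst, burst, or mini_burst.

    Burst intervals are the closed range [30 ms, 1 s]; shorter intervals are
    mini-burst intervals and longer ones non-burst intervals, so the three
    classes partition the positive reals.
    """
    isis = train.isis
    labels = np.full(isis.shape, BURST_IVL, dtype=object)
    labels[isis < MINI_BURST_MAX_S] = MINI_BURST
    labels[isis > BURST_MAX_S] = NON_BURST
    return ISIClassification(train.times, isis, labels)


def detect_bursts(cls: ISIClassification, min_burst_intervals: int = 10) -> list[Burst]:
    """Group classified intervals into bursts.

    A candidate run is a maximal stretch of consecutive burst/mini-burst
    intervals (any non-burst interval terminates it).  The run qualifies as
    a burst iff it contains at least ``min_burst_intervals`` burst-labelled
    intervals; mini-burst intervals do not count toward that minimum but do
    not break the run, and the spikes they contribute are included in the
    burst's spike count and span.
    """
    labels = np.asarray(cls.labels, dtype=object)
    n = len(labels)
    bursts: list[Burst] = []
    i = 0
    while i < n:
        if labels[i] == NON_BURST:
            i += 1
            continue
        j = i
        while j < n and labels[j] != NON_BURST:
            j += 1
        run = labels[i:j]
        if int(np.sum(run == BURST_IVL)) >= min_burst_intervals:
            # run covers intervals i..j-1, hence spikes i..j
            bursts.append(Burst(float(cls.times[i]), float(cls.times[j]), j - i + 1))
        i = j
    return bursts


def burst_metrics(
    bursts: Sequence[Burst], train: SpikeTrain, window: float
) -> BurstMetrics:
    """Summary statistics over an analysis window of length ``window`` s.

    ``burst_freq`` is bursts/min; ``mean_ap_freq`` counts every spike in the
    train over the window; ``isi_cv`` is computed over all ISIs in the
    window, not only those inside bursts.  Burst-derived means are None
    when no bursts were detected.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    burst_freq = len(bursts) / window * 60.0
    if bursts:
        mean_dur = float(np.mean([b.duration for b in bursts]))
        mean_spb = float(np.mean([b.n_spikes for b in bursts]))
    else:
        mean_dur = mean_spb = None
    mean_ap_freq = len(train) / window
    isis = train.isis
    if isis.size >= 2 and isis.mean() > 0:
        isi_cv = float(isis.std(ddof=0) / isis.mean())
    elif isis.size:
        isi_cv = 0.0
    else:
        isi_cv = None
    return BurstMetrics(burst_freq, mean_dur, mean_spb, mean_ap_freq, isi_cv)


def isi_log_histogram(
    train: SpikeTrain,
    bins_per_decade: int = 10,
    isi_range: tuple[float, float] = (0.001, 10.0),
) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of ISIs with geometrically spaced bin edges.

    Returns ``(counts, edges)``; counts sum to the number of ISIs inside
    ``isi_range``.
    """
    lo, hi = isi_range
    if lo <= 0 or hi <= lo:
        raise ValueError("isi_range must be positive and increasing")
    n_decades = np.log10(hi / lo)
    n_bins = max(1, int(np.ceil(n_decades * bins_per_decade)))
    edges = np.geomspace(lo, hi, n_bins + 1)
    isis = train.isis
    isis = isis[(isis >= lo) & (isis <= hi)]
    counts, edges = np.histogram(isis, bins=edges)
    return counts, edges


def bin_firing_rate(train: SpikeTrain, bin_s: float = 1.0) -> np.ndarray:
    """Firing rate (Hz) in consecutive bins of ``bin_s`` seconds."""
    if bin_s <= 0:
        raise ValueError("bin must be positive")
    n_bins = int(np.ceil(train.duration / bin_s))
    if n_bins == 0:
        return np.empty(0)
    edges = np.arange(n_bins + 1) * bin_s
    counts, _ = np.histogram(train.times, bins=edges)
    return counts / bin_s
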