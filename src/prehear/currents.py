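"""Voltage-clamp current analysis for inner supporting cells and hair cells.

Spontaneous ATP-mediated events appear as transient inward (negative)
current deflections on a slowly drifting baseline.  This module detects
those events against a running-median baseline, summarizes holding current
per measurement period as a 95th-percentile statistic (robust to the brief
inward transients), and extracts tail-current series from voltage-step
sweeps used to index extracellular K+ changes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CurrentTrace",
    "CurrentEvent",
    "TailSeries",
    "detect_current_events",
    "holding_current_change",
    "tail_current_series",
]


@dataclass
class CurrentTrace:
    """Uniformly sampled current recording.

    samples are in pA; ``epochs`` maps a name (e.g. ``baseline``, ``drug``)
    to a (start_s, stop_s) window within the trace.
    """

    samples: np.ndarray
    rate_hz: float
    epochs: dict[str, tuple[float, float]] = field(default_factory=dict)
    holding_potential_mv: float | None = None

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.rate_hz <= 0:
            raise ValueError("rate_hz must be positive")
        dur = self.duration
        spans = []
        for name, (a, b) in self.epochs.items():
            if not (0 <= a < b <= dur + 1e-9):
                raise ValueError(f"epoch {name!r} outside trace span")
            spans.append((a, b, name))
        spans.sort()
        for (a0, b0, n0), (a1, b1, n1) in zip(spans, spans[1:]):
            if a1 < b0:
                raise ValueError(f"epochs {n0!r} and {n1!r} overlap")

    @property
    def duration(self) -> float:
        return self.samples.size / self.rate_hz

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.samples.size) / self.rate_hz

    def window(self, start: float, stop: float) -> np.ndarray:
        i0 = max(0, int(np.floor(start * self.rate_hz)))
        i1 = min(self.samples.size, int(np.ceil(stop * self.rate_hz)))
        if i1 <= i0:
            raise ValueError("empty window")
        return self.samples[i0:i1]


@dataclass(frozen=True)
class CurrentEvent:
    onset: float  # s, threshold crossing
    peak_time: float  # s
    peak_amp: float  # pA, negative for inward events
    integral: float  # pC, signed charge transfer over the event extent
    extent: tuple[float, float] = (0.0, 0.0)  # (start_s, stop_s)


@dataclass(frozen=True)
class TailSeries:
    sweep_times: np.ndarray  # s, one per sweep
    tail_amp: np.ndarray  # pA, baseline-normalized


def _running_baseline(samples: np.ndarray, rate_hz: float, window_s: float) -> np.ndarray:
    win = max(3, int(round(window_s * rate_hz)) | 1)
    ser = pd.Series(samples)
    base = ser.rolling(win, center=True, min_periods=1).median().to_numpy()
    return base


def detect_current_events(
    trace: CurrentTrace,
    threshold_k: float = 5.0,
    min_separation: float = 0.2,
    baseline_window_s: float = 10.0,
    smooth_s: float = 0.02,
) -> tuple[list[CurrentEvent], pd.DataFrame]:
    """Detect spontaneous inward current events.

    Events are negative-going excursions that drop more than
    ``threshold_k`` x noise SD below a 10 s rolling-median baseline; the
    crossing test runs on a lightly smoothed (``smooth_s`` moving-average)
    residual so noise cannot fragment one slow decay into several events,
    and crossings closer than ``min_separation`` are merged.  The noise SD
    is the robust (1.4826 x MAD) spread of the smoothed residual.  Each
    event's extent runs from the threshold crossing to the first return
    within one noise SD of baseline; the charge transfer is the integral
    of the raw baseline-subtracted current over that extent (pA*s = pC,
    negative for inward events, matching the amplitude sign).

    Returns the event list plus a per-epoch summary frame with columns
    ``epoch, n_events, frequency_per_min, mean_amp_pa, mean_integral_pc``.
    If the trace declares no epochs the whole trace is one epoch ``all``.
    """
    x = trace.samples
    base = _running_baseline(x, trace.rate_hz, baseline_window_s)
    resid = x - base
    win = max(1, int(round(smooth_s * trace.rate_hz)))
    sm = np.convolve(resid, np.ones(win) / win, mode="same") if win > 1 else resid
    mad = np.median(np.abs(sm - np.median(sm)))
    noise_sd = 1.4826 * mad
    if noise_sd == 0:
        noise_sd = max(np.max(np.abs(sm)) * 1e-3, 1e-12)
    below = sm < -threshold_k * noise_sd
    n = x.size
    dt = 1.0 / trace.rate_hz
    min_gap = max(1, int(round(min_separation * trace.rate_hz)))
    # connected sub-threshold runs, merged across gaps < min_separation
    runs: list[list[int]] = []
    i = 0
    while i < n:
        if not below[i]:
            i += 1
            continue
        j = i
        while j < n and below[j]:
            j += 1
        if runs and i - runs[-1][1] < min_gap:
            runs[-1][1] = j
        else:
            runs.append([i, j])
        i = j
    events: list[CurrentEvent] = []
    prev_end = -1
    for i, j in runs:
        if i < prev_end:  # swallowed by the previous event's extent
            continue
        # extend to the first sustained return within 1 noise SD of baseline
        while j < n and sm[j] < -noise_sd:
            j += 1
        seg = slice(i, j)
        k = i + int(np.argmin(resid[seg]))
        events.append(
            CurrentEvent(
                onset=i * dt,
                peak_time=k * dt,
                peak_amp=float(resid[k]),
                integral=float(np.sum(resid[seg]) * dt),
                extent=(i * dt, j * dt),
            )
        )
        prev_end = j
    epochs = trace.epochs or {"all": (0.0, trace.duration)}
    rows = []
    for name, (a, b) in epochs.items():
        if b - a < min_separation:
            raise ValueError(f"epoch {name!r} shorter than min_separation")
        evs = [e for e in events if a <= e.onset < b]
        rows.append(
            {
                "epoch": name,
                "n_events": len(evs),
                "frequency_per_min": len(evs) / (b - a) * 60.0,
                "mean_amp_pa": np.mean([e.peak_amp for e in evs]) if evs else np.nan,
                "mean_integral_pc": np.mean([e.integral for e in evs]) if evs else np.nan,
            }
        )
    return events, pd.DataFrame(rows)


def holding_current_change(
    trace: CurrentTrace,
    period_a: tuple[float, float],
    period_b: tuple[float, float],
    percentile: float = 95.0,
) -> tuple[float, float, float]:
    """Holding-current statistic per period and its change.

    The holding current of a period is the 95th-percentile sample value in
    that window — for a cell held below reversal (inward events are
    negative), this tracks the standing baseline while ignoring the brief
    inward transients.  Returns ``(value_a, value_b, change_b_minus_a)``.
    """
    for p in (period_a, period_b):
        if p[1] - p[0] < 10.0:
            raise ValueError("measurement periods must be at least 10 s")
    a = float(np.percentile(trace.window(*period_a), percentile))
    b = float(np.percentile(trace.window(*period_b), percentile))
    return a, b, b - a


def tail_current_series(
    sweeps: list[CurrentTrace],
    measure_window: tuple[float, float],
    sweep_times: np.ndarray | None = None,
    baseline_sweeps: slice | list[int] = slice(0, 5),
    statistic: str = "mean",
) -> TailSeries:
    """Tail-current amplitude per sweep, normalized to the baseline sweeps.

    Each sweep is one repetition of the K+-accumulation voltage protocol
    (hyperpolarizing step, depolarizing step, then a step to -70 mV whose
    'tail' current reports the K+ driving force).  The tail amplitude is the
    mean (or min, via ``statistic='peak'``) of the current in
    ``measure_window`` within the sweep; the series is shifted so the mean
    amplitude over ``baseline_sweeps`` is 0 pA.
    """
    if not sweeps:
        raise ValueError("no sweeps")
    amps = []
    for s in sweeps:
        w = s.window(*measure_window)
        amps.append(float(np.min(w)) if statistic == "peak" else float(np.mean(w)))
    amps = np.asarray(amps)
    idx = np.arange(len(amps))[baseline_sweeps] if isinstance(baseline_sweeps, slice) else np.asarray(baseline_sweeps)
    if idx.size == 0:
        raise ValueError("no baseline sweeps designated")
    amps = amps - amps[idx].mean()
    if sweep_times is None:
        sweep_times = np.arange(len(amps), dtype=float)
    return TailSeries(np.asarray(sweep_times, dtype=float), amps)
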