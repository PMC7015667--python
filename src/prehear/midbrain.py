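"""In vivo widefield midbrain analysis.

Inferior colliculus (IC): detection of spontaneous calcium events on
per-lobe mean dF/F traces with a fixed 2% threshold, greedy matching of
simultaneous left/right events into bilateral pairs with a weak/strong
amplitude ratio, a rotated-rectangle line scan along the tonotopic axis
with regional-maxima band detection, spatial histograms with a
medial/lateral split, and exclusion of global (whole-surface) events.

Superior colliculus (SC): retinal-wave detection — downsampled dF/F
pixels are active above mean + 3 SD (after per-frame mean subtraction), and
a wave is any period longer than 1 s during which more than five pixels are
simultaneously active.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.feature import peak_local_max

from .movie import DFFMovie, MovieStack, dff, find_peaks_threshold
from .rois import ROISet

__all__ = [
    "ICEvent",
    "BilateralPair",
    "TonotopicScan",
    "RetinalWave",
    "detect_ic_events",
    "match_bilateral",
    "tonotopic_linescan",
    "detect_band_peaks",
    "spatial_event_histogram",
    "exclude_global_events",
    "detect_retinal_waves",
]


@dataclass(frozen=True)
class ICEvent:
    time: float  # s, at peak
    lobe: str  # left | right
    amplitude: float  # % dF/F, baseline-subtracted peak
    half_width: float  # s, full width at half amplitude
    matched_id: int | None = None


@dataclass(frozen=True)
class BilateralPair:
    strong_amp: float  # % dF/F
    weak_amp: float
    ratio: float  # weak/strong, in (0, 1]
    dominant_lobe: str
    time: float


@dataclass
class TonotopicScan:
    """% dF/F over (position along the tonotopic axis, time).

    ``values`` has shape (n_positions, n_frames); the position axis starts
    at the lateral edge of the sampling rectangle.
    """

    values: np.ndarray
    positions_um: np.ndarray
    frame_rate: float
    anchor: tuple[float, float]
    angle_deg: float


@dataclass(frozen=True)
class RetinalWave:
    start: float  # s
    duration: float  # s
    lobe: str


def _local_baseline(trace: np.ndarray, peak_idx: int, rate_hz: float, lookback_s: float = 5.0) -> float:
    i0 = max(0, peak_idx - int(round(lookback_s * rate_hz)))
    seg = trace[i0:peak_idx] if peak_idx > i0 else trace[: peak_idx + 1]
    return float(np.median(seg))


def _half_width(trace: np.ndarray, peak_idx: int, baseline: float, rate_hz: float) -> float:
    half = baseline + 0.5 * (trace[peak_idx] - baseline)
    i = peak_idx
    while i > 0 and trace[i - 1] > half:
        i -= 1
    # linear interpolation to the crossing
    if i > 0:
        left = (i - 1) + (half - trace[i - 1]) / (trace[i] - trace[i - 1])
    else:
        left = 0.0
    j = peak_idx
    n = trace.size
    while j < n - 1 and trace[j + 1] > half:
        j += 1
    if j < n - 1:
        right = j + (trace[j] - half) / (trace[j] - trace[j + 1])
    else:
        right = float(n - 1)
    return (right - left) / rate_hz


def detect_ic_events(
    dffm: DFFMovie,
    lobe_rois: ROISet,
    threshold_pct: float = 2.0,
    min_sep_s: float = 2.0,
) -> list[ICEvent]:
    """Detect spontaneous events on each IC lobe's mean dF/F trace.

    Fluorescence is already normalized, so a fixed threshold (default 2%
    dF/F) is applied across conditions.  Amplitude is the baseline-
    subtracted peak (% dF/F, local baseline = median of the preceding 5 s);
    half-width is the full width at half that amplitude.
    """
    shape = dffm.dff.shape[1:]
    events: list[ICEvent] = []
    lobes = [r for r in lobe_rois if r.compartment in ("left", "right")] or list(lobe_rois)
    if len(lobes) < 2:
        raise ValueError("need left and right lobe ROIs")
    for r in lobes:
        m = r.mask(shape)
        tr = dffm.dff[:, m].mean(axis=1) * 100.0  # % dF/F
        peaks = find_peaks_threshold(tr, threshold_pct, min_sep_s, dffm.frame_rate)
        for p in peaks:
            base = _local_baseline(tr, p, dffm.frame_rate)
            events.append(
                ICEvent(
                    time=p / dffm.frame_rate,
                    lobe=r.compartment if r.compartment in ("left", "right") else r.name,
                    amplitude=float(tr[p] - base),
                    half_width=_half_width(tr, p, base, dffm.frame_rate),
                )
            )
    events.sort(key=lambda e: e.time)
    return events


def match_bilateral(
    events: list[ICEvent], window: float = 0.5
) -> tuple[list[BilateralPair], list[ICEvent]]:
    """Pair simultaneous left/right events and compute amplitude ratios.

    Candidate pairs within ±``window`` seconds are matched greedily by
    minimal time difference (ties to the earlier pair); each event is used
    at most once.  The ratio is weak/strong amplitude, so 1 indicates
    complete synchrony between lobes and values near 0 complete asymmetry.
    Returns (pairs, unmatched_events).
    """
    left = [e for e in events if e.lobe == "left"]
    right = [e for e in events if e.lobe == "right"]
    cands = []
    for i, el in enumerate(left):
        for j, er in enumerate(right):
            d = abs(el.time - er.time)
            if d <= window:
                cands.append((d, min(el.time, er.time), i, j))
    cands.sort()
    used_l: set[int] = set()
    used_r: set[int] = set()
    pairs: list[BilateralPair] = []
    for d, _, i, j in cands:
        if i in used_l or j in used_r:
            continue
        used_l.add(i)
        used_r.add(j)
        el, er = left[i], right[j]
        strong, weak = (el, er) if el.amplitude >= er.amplitude else (er, el)
        pairs.append(
            BilateralPair(
                strong_amp=strong.amplitude,
                weak_amp=weak.amplitude,
                ratio=weak.amplitude / strong.amplitude,
                dominant_lobe=strong.lobe,
                time=min(el.time, er.time),
            )
        )
    unmatched = [e for i, e in enumerate(left) if i not in used_l]
    unmatched += [e for j, e in enumerate(right) if j not in used_r]
    unmatched.sort(key=lambda e: e.time)
    return pairs, unmatched


def tonotopic_linescan(
    dffm: DFFMovie,
    anchor: tuple[float, float],
    angle_deg: float,
    length_px: int = 125,
    width_px: int = 50,
) -> TonotopicScan:
    """Average a rotated rectangle across its width into a line scan.

    A ``length_px`` x ``width_px`` rectangle centered on ``anchor``
    (col, row) and rotated by ``angle_deg`` lies perpendicular to the IC's
    isofrequency bands, i.e. along the tonotopic axis.  Each frame is
    sampled over the rectangle with bilinear interpolation and averaged
    over the width, giving one ``length_px``-sample profile per frame
    (in % dF/F).  Position 0 is the lateral end of the rectangle.
    """
    T, H, W = dffm.dff.shape
    th = np.deg2rad(angle_deg)
    u = np.array([np.cos(th), np.sin(th)])  # (dcol, drow) along the axis
    v = np.array([-np.sin(th), np.cos(th)])  # across
    s = np.arange(length_px) - (length_px - 1) / 2.0
    t = np.arange(width_px) - (width_px - 1) / 2.0
    S, Tt = np.meshgrid(s, t, indexing="ij")
    cols = anchor[0] + S * u[0] + Tt * v[0]
    rows = anchor[1] + S * u[1] + Tt * v[1]
    if rows.min() < 0 or rows.max() > H - 1 or cols.min() < 0 or cols.max() > W - 1:
        raise ValueError("sampling rectangle extends outside the frame")
    coords = np.stack([rows.ravel(), cols.ravel()])
    out = np.empty((length_px, T), dtype=float)
    for k in range(T):
        samp = ndimage.map_coordinates(dffm.dff[k], coords, order=1, mode="nearest")
        out[:, k] = samp.reshape(length_px, width_px).mean(axis=1)
    positions = np.arange(length_px) * dffm.um_per_px
    return TonotopicScan(out * 100.0, positions, dffm.frame_rate, anchor, angle_deg)


def detect_band_peaks(
    scan: TonotopicScan, threshold_pct: float = 3.0, min_distance: int = 3
) -> pd.DataFrame:
    """Regional maxima of the (position x time) scan above a fixed threshold.

    Returns a frame with ``position_um, time_s, amplitude_pct`` per peak.
    """
    xy = peak_local_max(
        scan.values, min_distance=min_distance, threshold_abs=threshold_pct,
        exclude_border=False,
    )
    rows = [
        {
            "position_um": float(scan.positions_um[i]),
            "time_s": float(j / scan.frame_rate),
            "amplitude_pct": float(scan.values[i, j]),
        }
        for i, j in xy
    ]
    rows.sort(key=lambda r: r["time_s"])
    return pd.DataFrame(rows, columns=["position_um", "time_s", "amplitude_pct"])


def spatial_event_histogram(
    peaks: pd.DataFrame,
    split_um: float,
    duration_min: float,
    bin_um: float = 25.0,
    axis_range_um: tuple[float, float] | None = None,
    exclusion_center_um: float | None = None,
    exclusion_half_width_um: float = 50.0,
) -> dict:
    """Histogram of band events along the tonotopic axis.

    Events are counted in ``bin_um`` bins; positions below ``split_um``
    count as lateral, above as medial (events at exactly the split count as
    medial by convention of the strict < lateral rule).  An optional
    exclusion zone of ±``exclusion_half_width_um`` around the single-band
    locus removes bifurcation-edge events from the medial/lateral tallies.
    Returns a dict with ``counts, edges, lateral_per_min, medial_per_min,
    n_excluded``.
    """
    pos = peaks["position_um"].to_numpy(dtype=float) if len(peaks) else np.empty(0)
    if axis_range_um is None:
        hi = max(float(pos.max()) if pos.size else 0.0, split_um) + bin_um
        axis_range_um = (0.0, hi)
    edges = np.arange(axis_range_um[0], axis_range_um[1] + bin_um, bin_um)
    keep = np.ones(pos.shape, dtype=bool)
    if exclusion_center_um is not None:
        keep = np.abs(pos - exclusion_center_um) > exclusion_half_width_um
    counts, edges = np.histogram(pos[keep], bins=edges)
    lateral = int(np.sum(pos[keep] < split_um))
    medial = int(np.sum(pos[keep] >= split_um))
    return {
        "counts": counts,
        "edges": edges,
        "lateral_count": lateral,
        "medial_count": medial,
        "lateral_per_min": lateral / duration_min,
        "medial_per_min": medial / duration_min,
        "n_excluded": int(np.sum(~keep)),
    }


def exclude_global_events(
    events: list[ICEvent],
    dffm: DFFMovie,
    lobe_rois: ROISet,
    coverage_frac: float = 0.8,
    threshold_pct: float = 2.0,
) -> list[ICEvent]:
    """Drop events that broadly activate the entire IC surface.

    Cortical or SC events bleed into the IC as near-uniform fluorescence
    increases; an event is excluded when more than ``coverage_frac`` of its
    lobe's ROI pixels exceed ``threshold_pct`` dF/F at the peak frame
    (strictly greater: an event exactly at the threshold is retained).
    """
    if not (0 < coverage_frac <= 1):
        raise ValueError("coverage_frac must be in (0, 1]")
    shape = dffm.dff.shape[1:]
    masks = {}
    for r in lobe_rois:
        key = r.compartment if r.compartment in ("left", "right") else r.name
        masks[key] = r.mask(shape)
    kept = []
    for e in events:
        m = masks[e.lobe]
        k = int(round(e.time * dffm.frame_rate))
        k = min(max(k, 0), dffm.n_frames - 1)
        frac = float(np.mean(dffm.dff[k][m] * 100.0 > threshold_pct))
        if frac <= coverage_frac:
            kept.append(e)
    return kept


def detect_retinal_waves(
    movie: MovieStack,
    sc_rois: ROISet,
    downsample: int = 5,
    threshold_k: float = 3.0,
    min_active_px: int = 5,
    min_duration_s: float = 1.0,
) -> tuple[list[RetinalWave], dict]:
    """Detect retinal waves in superior-colliculus lobes.

    Per lobe: crop the ROI (expected 200 x 150 px), block-mean downsample
    by ``downsample``, normalize to dF/F with a per-pixel 5th-percentile
    baseline, subtract each frame's all-pixel mean to remove periodic
    whole-sample fluorescence changes, and mark a pixel active when it
    exceeds its own temporal mean + ``threshold_k`` SD.  A retinal wave is
    a maximal run strictly longer than ``min_duration_s`` during which
    strictly more than ``min_active_px`` pixels are active simultaneously;
    its duration is the run length.

    Returns (waves, summary) where summary holds per-lobe frequency
    (waves/min) and mean duration.
    """
    waves: list[RetinalWave] = []
    summary: dict[str, dict] = {}
    duration_min = movie.duration / 60.0
    for r in sc_rois:
        x0, y0, x1, y1 = (int(round(b)) for b in r.bounds())
        if (y1 - y0) < 150 or (x1 - x0) < 200:
            raise ValueError(f"SC ROI {r.name!r} smaller than 200 x 150 px")
        crop = movie.data[:, y0:y1, x0:x1].astype(float)
        T, h, w = crop.shape
        h2, w2 = h // downsample, w // downsample
        crop = crop[:, : h2 * downsample, : w2 * downsample]
        ds = crop.reshape(T, h2, downsample, w2, downsample).mean(axis=(2, 4))
        f0 = np.percentile(ds, 5, axis=0)
        if np.any(f0 <= 0):
            raise ValueError("non-positive baseline in SC ROI; offset the movie")
        d = (ds - f0) / f0
        d = d - d.mean(axis=(1, 2), keepdims=True)
        mu = d.mean(axis=0)
        sd = d.std(axis=0)
        active = d > mu + threshold_k * sd
        active[:, sd == 0] = False
        n_active = active.sum(axis=(1, 2))
        hot = n_active > min_active_px
        lobe_waves = []
        i = 0
        while i < T:
            if not hot[i]:
                i += 1
                continue
            j = i
            while j < T and hot[j]:
                j += 1
            dur = (j - i) / movie.frame_rate
            if dur > min_duration_s:
                lobe_waves.append(RetinalWave(i / movie.frame_rate, dur, r.name))
            i = j
        waves.extend(lobe_waves)
        durs = [wv.duration for wv in lobe_waves]
        summary[r.name] = {
            "n_waves": len(lobe_waves),
            "frequency_per_min": len(lobe_waves) / duration_min,
            "mean_duration_s": float(np.mean(durs)) if durs else float("nan"),
        }
    waves.sort(key=lambda wv: wv.start)
    return waves, summary
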