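"""Cochlear explant imaging analysis.

Three pipelines: crenation (supporting-cell shrinkage) statistics from
transmitted-light difference movies, Ca2+ transient frequency and area per
cellular compartment (ISC / IHC / SGN) from GCaMP movies, and pairwise
correlation of inner-hair-cell activity with a nearest-four-neighbour
summary.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .movie import (
    DetectionConfig,
    DFFMovie,
    MovieStack,
    difference_movie,
    find_peaks_threshold,
    region_areas,
    threshold_mask,
)
from .rois import ROISet

__all__ = [
    "CorrelationResult",
    "crenation_stats",
    "calcium_event_stats",
    "roi_traces",
    "ihc_correlation",
]


@dataclass
class CorrelationResult:
    matrix: np.ndarray  # pairwise Pearson coefficients, unit diagonal
    mean_nearest4: np.ndarray  # per-cell mean over its <=4 nearest IHCs
    group_mean: float
    names: list[str]


def crenation_stats(
    movie: MovieStack, cfg: DetectionConfig | None = None
) -> pd.DataFrame:
    """Crenation frequency and per-event area from a transmitted-light movie.

    Pipeline: difference movie (default 5 s lag) -> global mean+3SD
    threshold mask -> peaks in the per-frame count of suprathreshold pixels
    (the whole field acting as one ROI) give event times; the mask at each
    event frame is Gaussian-smoothed and its connected regions measured in
    µm².  Returns one row per event with columns ``time_s, area_um2,
    n_regions, frequency_per_min`` (frequency repeated per row; an empty
    frame carries a ``frequency_per_min`` attribute of 0).
    """
    cfg = cfg or DetectionConfig()
    if movie.duration < 2 * cfg.diff_lag:
        raise ValueError("movie shorter than twice the difference lag")
    diff = difference_movie(movie, cfg.diff_lag)
    mask = threshold_mask(diff, cfg.threshold_k)
    counts = mask.sum(axis=(1, 2)).astype(float)
    if counts.std() == 0:
        out = pd.DataFrame(columns=["time_s", "area_um2", "n_regions", "frequency_per_min"])
        out.attrs["frequency_per_min"] = 0.0
        return out
    # smooth the whole-field count trace over ~1 s so noise cannot split a
    # single slow event into several peaks
    win = max(1, int(round(movie.frame_rate)))
    smooth = np.convolve(counts, np.ones(win) / win, mode="same")
    # events are sparse, so threshold against the robust baseline of the
    # count trace rather than its event-inflated global SD
    mad = np.median(np.abs(smooth - np.median(smooth)))
    thr = np.median(smooth) + cfg.threshold_k * 1.4826 * max(mad, 1.0)
    peaks = find_peaks_threshold(
        smooth, thr, max(cfg.min_peak_sep, cfg.diff_lag), movie.frame_rate
    )
    rows = []
    freq = len(peaks) / movie.duration * 60.0
    for p in peaks:
        regions = region_areas(mask[p], cfg.gauss_sigma, movie.um_per_px)
        total_area = sum(r["area_um2"] for r in regions)
        rows.append(
            {
                "time_s": p / movie.frame_rate,
                "area_um2": total_area,
                "n_regions": len(regions),
                "frequency_per_min": freq,
            }
        )
    out = pd.DataFrame(rows, columns=["time_s", "area_um2", "n_regions", "frequency_per_min"])
    out.attrs["frequency_per_min"] = freq
    return out


def roi_traces(dffm: DFFMovie, rois: ROISet) -> pd.DataFrame:
    """Mean dF/F trace within each ROI; columns are ROI names."""
    shape = dffm.dff.shape[1:]
    rois.validate(shape)
    cols = {}
    for r in rois:
        m = r.mask(shape)
        if not m.any():
            raise ValueError(f"ROI {r.name!r} rasterizes to an empty mask")
        cols[r.name] = dffm.dff[:, m].mean(axis=1)
    return pd.DataFrame(cols, index=dffm.times)


def calcium_event_stats(
    dffm: DFFMovie, rois: ROISet, cfg: DetectionConfig | None = None
) -> pd.DataFrame:
    """Per-compartment Ca2+ transient statistics.

    Each ROI's mean-dF/F trace is thresholded at its own mean + k*SD and
    peaks counted (min separation ``cfg.min_peak_sep``); event area is
    measured by thresholding the dF/F frame at the peak time and measuring
    smoothed connected regions restricted to the ROI.  Returns one row per
    event with ``roi, compartment, time_s, amplitude_dff, area_um2`` plus a
    per-ROI ``frequency_per_min`` column.
    """
    cfg = cfg or DetectionConfig()
    traces = roi_traces(dffm, rois)
    shape = dffm.dff.shape[1:]
    frame_mask = threshold_mask(dffm, cfg.threshold_k)
    rows = []
    for r in rois:
        tr = traces[r.name].to_numpy()
        thr = tr.mean() + cfg.threshold_k * tr.std()
        if tr.std() == 0:
            continue
        peaks = find_peaks_threshold(tr, thr, cfg.min_peak_sep, dffm.frame_rate)
        freq = len(peaks) / (dffm.n_frames / dffm.frame_rate) * 60.0
        roi_px = r.mask(shape)
        for p in peaks:
            regions = region_areas(
                frame_mask[p] & roi_px, cfg.gauss_sigma, dffm.um_per_px
            )
            rows.append(
                {
                    "roi": r.name,
                    "compartment": r.compartment,
                    "time_s": p / dffm.frame_rate,
                    "amplitude_dff": float(tr[p]),
                    "area_um2": sum(g["area_um2"] for g in regions),
                    "frequency_per_min": freq,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["roi", "compartment", "time_s", "amplitude_dff", "area_um2", "frequency_per_min"],
    )


def ihc_correlation(dffm: DFFMovie, ihc_rois: ROISet) -> CorrelationResult:
    """Pairwise Pearson correlation of inner-hair-cell activity.

    Correlations are computed between the raw mean-dF/F traces of every
    IHC pair.  Each cell is also summarized by the mean coefficient with
    its four nearest IHCs (centroid Euclidean distance, ties broken by ROI
    index; edge cells with fewer than four neighbours use all available),
    and ``group_mean`` averages that over cells.  A zero-variance trace
    yields NaN coefficients for its pairs, which are excluded from the
    neighbour means.
    """
    cells = ihc_rois.by_compartment("IHC") or list(ihc_rois)
    if len(cells) < 5:
        raise ValueError("need at least 5 IHC ROIs")
    traces = roi_traces(dffm, ROISet(list(cells)))
    x = traces.to_numpy().T  # cells x time
    sd = x.std(axis=1)
    n = len(cells)
    with np.errstate(invalid="ignore", divide="ignore"):
        mat = np.corrcoef(x)
    mat[sd == 0, :] = np.nan
    mat[:, sd == 0] = np.nan
    np.fill_diagonal(mat, 1.0)
    centroids = np.array([c.centroid_px for c in cells])
    mean_n4 = np.full(n, np.nan)
    for i in range(n):
        d = np.linalg.norm(centroids - centroids[i], axis=1)
        d[i] = np.inf
        order = np.lexsort((np.arange(n), d))  # stable: index order breaks ties
        nbrs = [j for j in order[: min(4, n - 1)] if np.isfinite(d[j])]
        vals = np.array([mat[i, j] for j in nbrs])
        vals = vals[np.isfinite(vals)]
        if vals.size:
            mean_n4[i] = vals.mean()
    finite = mean_n4[np.isfinite(mean_n4)]
    group = float(finite.mean()) if finite.size else float("nan")
    return CorrelationResult(mat, mean_n4, group, [c.name for c in cells])
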