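"""Shared image-processing primitives for time-series movies.

Containers and operations used by every imaging pipeline in the package:
per-pixel dF/F0 normalization against a 5th-percentile baseline,
single-exponential photobleaching correction, lagged difference movies for
transmittance (crenation) imaging, global SD thresholding, Gaussian-smoothed
region area measurement, and thresholded 1-D peak detection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, optimize, signal
from skimage import measure

__all__ = [
    "MovieStack",
    "DFFMovie",
    "DetectionConfig",
    "dff",
    "bleach_correct",
    "difference_movie",
    "threshold_mask",
    "region_areas",
    "find_peaks_threshold",
]


@dataclass
class MovieStack:
    """T x H x W intensity stack with acquisition metadata."""

    data: np.ndarray
    frame_rate: float  # Hz
    um_per_px: float

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("movie data must be T x H x W")
        if self.frame_rate <= 0 or self.um_per_px <= 0:
            raise ValueError("frame_rate and um_per_px must be positive")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def duration(self) -> float:
        return self.n_frames / self.frame_rate

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.frame_rate


@dataclass
class DFFMovie:
    """dF/F0 movie (dimensionless) with its per-pixel baseline map."""

    dff: np.ndarray
    f0: np.ndarray
    frame_rate: float
    um_per_px: float

    @property
    def n_frames(self) -> int:
        return self.dff.shape[0]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.frame_rate


@dataclass
class DetectionConfig:
    """Constants shared by the transmittance and Ca2+ event pipelines."""

    threshold_k: float = 3.0  # SD multiplier for activity thresholds
    gauss_sigma: float = 2.0  # px, smoothing before border detection
    diff_lag: float = 5.0  # s, difference-movie lag
    min_peak_sep: float = 2.0  # s, minimal separation between detected peaks

    def __post_init__(self):
        if min(self.threshold_k, self.gauss_sigma, self.diff_lag, self.min_peak_sep) <= 0:
            raise ValueError("all detection constants must be positive")


def dff(movie: MovieStack, percentile: float = 5.0) -> DFFMovie:
    """Normalize a movie to dF/F0 with a per-pixel percentile baseline.

    F0 is the 5th-percentile value of each pixel's trace over time
    (linear interpolation between order statistics); dF/F0 = (F - F0)/F0.
    Raises if any pixel baseline is non-positive, which would make the
    ratio meaningless — offset the movie first.
    """
    data = np.asarray(movie.data, dtype=float)
    f0 = np.percentile(data, percentile, axis=0)
    if np.any(f0 <= 0):
        raise ValueError(
            "non-positive F0 baseline; add a constant offset to the movie "
            "before dF/F normalization"
        )
    out = (data - f0) / f0
    return DFFMovie(out, f0, movie.frame_rate, movie.um_per_px)


def _exp_model(t, a, b, tau):
    return a + b * np.exp(-t / tau)


def bleach_correct(movie: MovieStack) -> MovieStack:
    """Remove photobleaching by subtracting a fitted exponential decay.

    The frame-mean trace is fit with m(t) = a + b*exp(-t/tau); the decaying
    component m(t) - m(0) is subtracted from every pixel of frame t, so the
    corrected movie is flat at the initial brightness a + b (anchoring at
    the asymptote a instead would drive movies that bleach toward zero to a
    non-positive baseline and break subsequent dF/F normalization).  A
    non-decaying or unfittable trace leaves the movie unchanged (with a
    warning).
    """
    if movie.n_frames < 20:
        raise ValueError("need at least 20 frames to fit a bleaching curve")
    t = movie.times
    m = movie.data.mean(axis=(1, 2)).astype(float)
    b0 = m[0] - m[-1]
    if b0 <= 0:
        warnings.warn("frame-mean trace does not decay; skipping bleach correction")
        return MovieStack(movie.data.astype(float).copy(), movie.frame_rate, movie.um_per_px)
    p0 = (m[-1], b0, max(t[-1] / 3.0, t[1]))
    try:
        popt, _ = optimize.curve_fit(
            _exp_model, t, m, p0=p0, maxfev=10000,
            bounds=([0.0, 0.0, t[1]], [np.inf, np.inf, np.inf]),
        )
    except (RuntimeError, ValueError):
        warnings.warn("bleaching fit failed; movie returned unchanged")
        return MovieStack(movie.data.astype(float).copy(), movie.frame_rate, movie.um_per_px)
    a, b, tau = popt
    trend = _exp_model(t, a, b, tau) - (a + b)  # decay relative to t = 0
    out = movie.data.astype(float) - trend[:, None, None]
    return MovieStack(out, movie.frame_rate, movie.um_per_px)


def difference_movie(movie: MovieStack, lag: float = 5.0) -> MovieStack:
    """Lagged frame-difference movie: out[k] = frame[k + lagframes] - frame[k].

    Used on transmitted-light recordings as an index of transmittance change
    over time; crenation events appear as localized intensity deviations.
    """
    lagframes = int(round(lag * movie.frame_rate))
    if lagframes < 1:
        raise ValueError("lag must span at least one frame")
    if movie.n_frames <= lagframes:
        raise ValueError("movie shorter than the difference lag")
    data = movie.data.astype(float)
    out = data[lagframes:] - data[:-lagframes]
    return MovieStack(out, movie.frame_rate, movie.um_per_px)


def threshold_mask(
    data: np.ndarray | MovieStack | DFFMovie,
    threshold_k: float = 3.0,
    per_pixel: bool = False,
) -> np.ndarray:
    """Binary activity mask: values above mean + k*SD.

    By default the mean and SD are computed globally over all pixels and
    frames; ``per_pixel=True`` instead thresholds each pixel against its own
    temporal mean and SD.  A zero-variance input yields an empty mask.
    """
    if isinstance(data, MovieStack):
        x = np.asarray(data.data, dtype=float)
    elif isinstance(data, DFFMovie):
        x = np.asarray(data.dff, dtype=float)
    else:
        x = np.asarray(data, dtype=float)
    if x.size == 0:
        raise ValueError("empty input")
    if per_pixel:
        mu = x.mean(axis=0)
        sd = x.std(axis=0)
        mask = x > mu + threshold_k * sd
        mask[:, sd == 0] = False
        return mask
    mu = float(x.mean())
    sd = float(x.std())
    if sd == 0:
        return np.zeros_like(x, dtype=bool)
    return x > mu + threshold_k * sd


def region_areas(
    mask_frame: np.ndarray,
    gauss_sigma: float = 2.0,
    um_per_px: float = 1.0,
) -> list[dict]:
    """Measure smoothed connected-region areas in a binary frame.

    The binary mask is Gaussian-smoothed (sigma in px), re-binarized at 0.5,
    and labelled with 8-connectivity; each region's area is its pixel count
    times (um_per_px)^2.  Returns one dict per region with keys
    ``label, area_um2, area_px, centroid`` (row, col).
    """
    mask = np.asarray(mask_frame, dtype=bool)
    if mask.ndim != 2:
        raise ValueError("mask_frame must be 2-D")
    if gauss_sigma > 0:
        smooth = ndimage.gaussian_filter(mask.astype(float), gauss_sigma)
        binary = smooth > 0.5
    else:
        binary = mask
    labels = measure.label(binary, connectivity=2)
    out = []
    for rp in measure.regionprops(labels):
        out.append(
            {
                "label": rp.label,
                "area_px": int(rp.area),
                "area_um2": float(rp.area) * um_per_px**2,
                "centroid": tuple(rp.centroid),
            }
        )
    return out


def find_peaks_threshold(
    trace: np.ndarray,
    threshold: float,
    min_sep: float = 0.0,
    rate_hz: float = 1.0,
) -> np.ndarray:
    """Indices of local maxima above a fixed threshold.

    Peaks closer than ``min_sep`` seconds are resolved greedily in favour of
    the larger peak.  Returns sample indices; divide by ``rate_hz`` for
    times.
    """
    x = np.asarray(trace, dtype=float)
    distance = max(1, int(round(min_sep * rate_hz)))
    peaks, _ = signal.find_peaks(x, height=threshold, distance=distance)
    # find_peaks misses a first/last sample plateau; acceptable for traces
    return peaks
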