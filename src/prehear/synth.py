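"""Synthetic recordings with known ground truth.

Every analysis stage in this package is exercised against data generated
here: bursty SGN spike trains (intra-burst ISIs concentrated near
75-125 ms over tonic Poisson firing), voltage-clamp traces with transient
inward events on a drifting baseline, transmitted-light movies with slow
local crenation events, widefield midbrain movies with bilateral
tonotopically-banded events under photobleaching, superior-colliculus
movies with propagating retinal waves, and cochlear explant movies with
coordinated ISC/IHC/SGN events of configurable hair-cell pairwise
correlation.

Each generator consumes an explicit ``seed`` and an independent random
stream, renders a deterministic noiseless signal from its event schedule,
adds noise last, and returns a :class:`GroundTruthLog` listing every
simulated event so parameter-recovery tests can compare detector output
against truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .currents import CurrentTrace
from .movie import MovieStack
from .rois import ROI, ROISet
from .spikes import SpikeTrain

__all__ = [
    "SpikeGenSpec",
    "MovieEvent",
    "MovieGenSpec",
    "GroundTruthLog",
    "gen_spike_train",
    "render_spike_trace",
    "gen_current_trace",
    "gen_widefield_movie",
    "default_lobe_geometry",
    "cochlea_layout",
    "schedule_ic_events",
    "schedule_sc_waves",
    "schedule_crenations",
]


@dataclass
class GroundTruthLog:
    """Generator-side record of every simulated event plus parameters."""

    events: list[dict] = field(default_factory=list)
    params: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.events)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.events)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps({"params": self.params, "events": self.events}, indent=2)
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruthLog":
        d = json.loads(Path(path).read_text())
        return cls(events=d["events"], params=d["params"])


# ---------------------------------------------------------------------------
# spike trains
# ---------------------------------------------------------------------------

@dataclass
class SpikeGenSpec:
    """Parameters of a bursty SGN-like spike train.

    Bursts arrive as a renewal process with mean rate ``burst_rate``
    (bursts/min); each contains roughly ``spikes_per_burst`` spikes with
    intra-burst ISIs drawn uniformly from ``intra_burst_isi`` (defaults to
    the 75-125 ms range typical of IHC Ca2+-spike-driven firing).  With
    probability ``mini_burst_prob`` per intra-burst interval an extra spike
    is inserted 8-25 ms after a burst spike, producing a mini-burst
    interval.  Tonic background firing is homogeneous Poisson at
    ``tonic_rate`` Hz.
    """

    duration: float = 600.0  # s
    burst_rate: float = 2.0  # bursts/min
    spikes_per_burst: int = 15  # mean spike count per burst
    intra_burst_isi: tuple[float, float] = (0.075, 0.125)  # s
    tonic_rate: float = 0.1  # Hz
    mini_burst_prob: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if min(self.burst_rate, self.tonic_rate) < 0 or self.spikes_per_burst < 0:
            raise ValueError("rates must be non-negative")
        lo, hi = self.intra_burst_isi
        if not (0.030 <= lo <= hi <= 1.0):
            raise ValueError("intra_burst_isi must lie within the burst-interval class")


def gen_spike_train(spec: SpikeGenSpec) -> tuple[SpikeTrain, GroundTruthLog]:
    """Simulate a spike train; ground truth lists each burst's span and count."""
    rng = np.random.default_rng(spec.seed)
    log = GroundTruthLog(params=vars(spec).copy())
    burst_spikes: list[np.ndarray] = []
    lo, hi = spec.intra_burst_isi
    mean_isi = 0.5 * (lo + hi)
    if spec.burst_rate > 0 and spec.spikes_per_burst > 0:
        exp_span = (spec.spikes_per_burst - 1) * mean_isi
        dead = exp_span + 1.2  # refractory gap so bursts never merge
        mean_gap = max(60.0 / spec.burst_rate - dead, 0.1)
        t = float(rng.exponential(mean_gap)) + 0.5
        while True:
            n = max(12, int(rng.poisson(spec.spikes_per_burst)))
            isis = rng.uniform(lo, hi, size=n - 1)
            times = t + np.concatenate([[0.0], np.cumsum(isis)])
            if spec.mini_burst_prob > 0:
                ins = rng.random(n - 1) < spec.mini_burst_prob
                extra = times[:-1][ins] + rng.uniform(0.008, 0.025, size=int(ins.sum()))
                times = np.sort(np.concatenate([times, extra]))
            if times[-1] >= spec.duration - 0.5:
                break
            burst_spikes.append(times)
            log.events.append(
                {
                    "kind": "burst",
                    "start": float(times[0]),
                    "end": float(times[-1]),
                    "n_spikes": int(times.size),
                }
            )
            t += dead + float(rng.exponential(mean_gap))
    tonic = np.empty(0)
    if spec.tonic_rate > 0:
        n_tonic = rng.poisson(spec.tonic_rate * spec.duration)
        tonic = rng.uniform(0, spec.duration, size=n_tonic)
    allspk = np.sort(np.concatenate(burst_spikes + [tonic])) if (burst_spikes or tonic.size) else np.empty(0)
    if allspk.size:
        # enforce strict ordering with a 0.5 ms floor between spikes
        keep = np.concatenate([[True], np.diff(allspk) > 5e-4])
        allspk = allspk[keep]
        allspk = allspk[allspk < spec.duration]
    return SpikeTrain(allspk, spec.duration), log


def render_spike_trace(
    train: SpikeTrain,
    rate_hz: float = 10000.0,
    amp: float = 1.0,
    width_s: float = 0.001,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> np.ndarray:
    """Render a juxtacellular-style trace with a biphasic spike at each time.

    Used to exercise threshold-based spike detection: each spike is a short
    positive-then-negative transient of peak ``amp`` and total width
    ``width_s`` on a flat baseline plus optional Gaussian noise.
    """
    n = int(round(train.duration * rate_hz))
    x = np.zeros(n)
    half = max(2, int(round(width_s * rate_hz / 2)))
    tt = np.arange(-half, 3 * half + 1)
    # dominant positive deflection with a small afterhyperpolarization
    wave = amp * np.exp(-((tt / (half / 1.5)) ** 2))
    wave -= 0.25 * amp * np.exp(-(((tt - 2 * half) / (2 * half)) ** 2))
    k = int(np.argmax(wave))
    for t in train.times:
        i = int(round(t * rate_hz))
        lo = i - k
        hi = lo + wave.size
        a, b = max(lo, 0), min(hi, n)
        if a < b:
            x[a:b] += wave[a - lo : b - lo]
    if noise_sd > 0:
        x += np.random.default_rng(seed).normal(0, noise_sd, size=n)
    return x


# ---------------------------------------------------------------------------
# voltage-clamp current traces
# ---------------------------------------------------------------------------

def gen_current_trace(
    event_rate: float,
    amp_mean: float = 100.0,
    tau_decay: float = 0.5,
    noise_sd: float = 2.0,
    drift: float = 0.0,
    duration: float = 600.0,
    rate_hz: float = 500.0,
    seed: int = 0,
    baseline_pa: float = -50.0,
    amp_sigma: float = 0.4,
) -> tuple[CurrentTrace, GroundTruthLog]:
    """Simulate a voltage-clamp trace with transient inward events.

    Events arrive as a Poisson process at ``event_rate`` per minute; each is
    an instantaneous-onset, single-exponential-decay inward deflection whose
    peak magnitude is drawn log-normal with mean ``amp_mean`` pA (shape
    ``amp_sigma``), mimicking the heavy-tailed sizes of spontaneous
    ATP-mediated currents.  ``drift`` adds a linear baseline trend (pA/s);
    Gaussian noise of ``noise_sd`` pA is added last.
    """
    if duration <= 0 or rate_hz <= 0:
        raise ValueError("duration and rate_hz must be positive")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    rng = np.random.default_rng(seed)
    n = int(round(duration * rate_hz))
    t = np.arange(n) / rate_hz
    x = baseline_pa + drift * t
    log = GroundTruthLog(
        params=dict(
            event_rate=event_rate, amp_mean=amp_mean, tau_decay=tau_decay,
            noise_sd=noise_sd, drift=drift, duration=duration, rate_hz=rate_hz,
            seed=seed, baseline_pa=baseline_pa,
        )
    )
    if event_rate > 0:
        # renewal process with a dead time (events individually resolvable)
        # whose mean inter-event interval equals 60/event_rate exactly
        min_gap = max(3 * tau_decay, 0.5)
        mean_extra = max(60.0 / event_rate - min_gap, 0.05)
        kept = []
        o = float(rng.exponential(mean_extra))
        while o < duration - 5 * tau_decay:
            kept.append(o)
            o += min_gap + float(rng.exponential(mean_extra))
        mu = np.log(amp_mean) - amp_sigma**2 / 2.0
        for o in kept:
            amp = float(rng.lognormal(mu, amp_sigma))
            i0 = int(round(o * rate_hz))
            m = min(n - i0, int(round(8 * tau_decay * rate_hz)))
            if m <= 0:
                continue
            tt = np.arange(m) / rate_hz
            x[i0 : i0 + m] -= amp * np.exp(-tt / tau_decay)
            log.events.append({"kind": "current_event", "onset": float(o), "amp_pa": amp})
    if noise_sd > 0:
        x += rng.normal(0, noise_sd, size=n)
    return CurrentTrace(x, rate_hz), log


# ---------------------------------------------------------------------------
# movies
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MovieEvent:
    """One scheduled movie event.

    ``position`` is mode-dependent: µm along the tonotopic axis for IC
    bands, (row, col) pixel coordinates for SC waves and crenations, and
    unused for cochlea events.  ``extent`` is a band width (µm) for IC, a
    disk radius (px) otherwise.  ``amplitude`` is fractional dF/F for
    fluorescence modes and intensity counts for crenation mode.
    """

    time: float
    amplitude: float
    duration: float
    lobe: str = ""
    position: float | tuple[float, float] = 0.0
    extent: float = 10.0


@dataclass
class MovieGenSpec:
    shape: tuple[int, int, int]  # frames x rows x cols
    frame_rate: float = 10.0  # Hz
    um_per_px: float = 8.0
    event_schedule: list[MovieEvent] = field(default_factory=list)
    bleach_tau: float = 0.0  # s; 0 disables photobleaching
    noise_sd: float = 0.0  # intensity counts
    bilateral_ratio: float = 1.0  # weak/strong amplitude for IC events
    baseline: float = 1000.0  # resting intensity counts
    corr_target: float | None = None  # cochlea mode: IHC pairwise correlation
    n_ihc: int = 12  # cochlea mode
    axis_len_px: int = 125  # IC mode tonotopic-axis length
    axis_width_px: int = 50
    seed: int = 0

    def __post_init__(self):
        T = self.shape[0]
        dur = T / self.frame_rate
        for ev in self.event_schedule:
            if ev.amplitude <= 0:
                raise ValueError("event amplitudes must be positive")
            if not (0 <= ev.time <= dur):
                raise ValueError(f"event at t={ev.time} outside the movie span")
        if not (0 <= self.bilateral_ratio <= 1):
            raise ValueError("bilateral_ratio must lie in [0, 1]")


def default_lobe_geometry(
    shape_hw: tuple[int, int], angle_deg: float = 55.0
) -> dict[str, dict]:
    """Anchor and tonotopic-axis angle for the two IC lobes.

    The left lobe's axis is rotated +``angle_deg`` from the image x axis,
    the right lobe mirrored at -``angle_deg``; anchors sit at the lobe
    centers (quarter points of the frame width).
    """
    h, w = shape_hw
    return {
        "left": {"anchor": (w / 4.0, h / 2.0), "angle_deg": angle_deg},
        "right": {"anchor": (3 * w / 4.0, h / 2.0), "angle_deg": -angle_deg},
    }


def lobe_rois(shape_hw: tuple[int, int]) -> ROISet:
    """Rectangular left/right lobe ROIs splitting the frame in half."""
    h, w = shape_hw
    return ROISet(
        [
            ROI("left", "rect", {"x": 0, "y": 0, "w": w // 2, "h": h}, "left"),
            ROI("right", "rect", {"x": w // 2, "y": 0, "w": w - w // 2, "h": h}, "right"),
        ]
    )


def _lobe_coords(shape_hw, geom):
    """Per-pixel coordinates (s, t) px along/across a lobe's tonotopic axis."""
    h, w = shape_hw
    rows, cols = np.mgrid[0:h, 0:w]
    cx, cy = geom["anchor"]
    th = np.deg2rad(geom["angle_deg"])
    dx = cols - cx
    dy = rows - cy
    s = dx * np.cos(th) + dy * np.sin(th)
    t = -dx * np.sin(th) + dy * np.cos(th)
    return s, t


def _alpha_kernel(tt: np.ndarray, tau: float) -> np.ndarray:
    a = np.where(tt > 0, (tt / tau) * np.exp(1 - tt / tau), 0.0)
    return a


def gen_widefield_movie(
    spec: MovieGenSpec, mode: str
) -> tuple[MovieStack, GroundTruthLog]:
    """Render a synthetic movie for one of four imaging preparations.

    mode="ic": stationary Gaussian bands along the tonotopic axis of two
    IC lobes (temporal alpha-function envelope); each scheduled event on its
    strong lobe is paired with a contralateral copy scaled by
    ``bilateral_ratio``.
    mode="sc": retinal-wave-like disks of elevated fluorescence that drift
    slowly while active for exactly their scheduled duration.
    mode="crenation": slow local transmittance changes (Hann time course,
    hard-edged disk footprint) on a transmitted-light background.
    mode="cochlea": coordinated ISC/IHC/SGN events; see
    :func:`cochlea_layout` for geometry.  When ``corr_target`` is set,
    per-IHC noise is calibrated so hair-cell trace pairs correlate at that
    level.

    Photobleaching is applied multiplicatively (exp(-t/bleach_tau)) to the
    fluorescence signal before additive Gaussian noise.
    """
    if mode not in {"ic", "sc", "cochlea", "crenation"}:
        raise ValueError(f"unknown mode {mode!r}")
    T, H, W = spec.shape
    rng = np.random.default_rng(spec.seed)
    times = np.arange(T) / spec.frame_rate
    log = GroundTruthLog(params={"mode": mode, **{k: v for k, v in vars(spec).items() if k != "event_schedule"}})
    signal = np.zeros((T, H, W), dtype=np.float32)

    if mode == "ic":
        geom = default_lobe_geometry((H, W))
        coords = {lobe: _lobe_coords((H, W), g) for lobe, g in geom.items()}
        L, Wd = spec.axis_len_px, spec.axis_width_px
        for ev in spec.event_schedule:
            strong = ev.lobe or "left"
            weak = "right" if strong == "left" else "left"
            tau = max(ev.duration / 3.0, 1.0 / spec.frame_rate)
            tmask = (times >= ev.time) & (times <= ev.time + 6 * tau)
            env = _alpha_kernel(times[tmask] - ev.time, tau).astype(np.float32)
            sides = [(strong, ev.amplitude)]
            if spec.bilateral_ratio > 0:
                sides.append((weak, ev.amplitude * spec.bilateral_ratio))
            for lobe, amp in sides:
                s, t = coords[lobe]
                pos_um = (s + L / 2.0) * spec.um_per_px  # 0 at the lateral end
                sigma_um = float(ev.extent)
                along = np.exp(-((pos_um - float(ev.position)) ** 2) / (2 * sigma_um**2))
                across = np.exp(-np.clip(np.abs(t) - Wd / 2.0, 0, None) ** 2 / (2 * 5.0**2))
                inside = (s >= -L / 2.0) & (s <= L / 2.0)
                spatial = (along * across * inside).astype(np.float32)
                signal[tmask] += amp * env[:, None, None] * spatial[None]
            log.events.append(
                {
                    "kind": "ic_event",
                    "time": ev.time,
                    "lobe": strong,
                    "amplitude": ev.amplitude,
                    "weak_amplitude": ev.amplitude * spec.bilateral_ratio,
                    "position_um": float(ev.position),
                    "width_um": float(ev.extent),
                    "duration": ev.duration,
                }
            )

    elif mode == "sc":
        rows, cols = np.mgrid[0:H, 0:W]
        for ev in spec.event_schedule:
            r0, c0 = ev.position if isinstance(ev.position, tuple) else (H / 2, W / 2)
            tmask = (times >= ev.time) & (times < ev.time + ev.duration)
            idx = np.nonzero(tmask)[0]
            drift_px_s = 2.0
            ang = rng.uniform(0, 2 * np.pi)
            for k, fi in enumerate(idx):
                dt = k / spec.frame_rate
                rc = np.clip(r0 + drift_px_s * dt * np.sin(ang), ev.extent, H - ev.extent)
                cc = np.clip(c0 + drift_px_s * dt * np.cos(ang), ev.extent, W - ev.extent)
                disk = (rows - rc) ** 2 + (cols - cc) ** 2 <= ev.extent**2
                signal[fi][disk] += ev.amplitude
            log.events.append(
                {
                    "kind": "sc_wave",
                    "time": ev.time,
                    "lobe": ev.lobe or "left",
                    "duration": ev.duration,
                    "position": (float(r0), float(c0)),
                    "radius_px": float(ev.extent),
                    "amplitude": ev.amplitude,
                }
            )

    elif mode == "crenation":
        rows, cols = np.mgrid[0:H, 0:W]
        for ev in spec.event_schedule:
            r0, c0 = ev.position if isinstance(ev.position, tuple) else (H / 2, W / 2)
            disk = (rows - r0) ** 2 + (cols - c0) ** 2 <= ev.extent**2
            tmask = (times >= ev.time) & (times < ev.time + ev.duration)
            tt = times[tmask] - ev.time
            env = 0.5 * (1 - np.cos(2 * np.pi * tt / ev.duration))  # Hann
            signal[tmask] += (
                ev.amplitude * env[:, None, None].astype(np.float32) * disk[None]
            )
            log.events.append(
                {
                    "kind": "crenation",
                    "time": ev.time,
                    "peak_time": ev.time + ev.duration / 2.0,
                    "duration": ev.duration,
                    "position": (float(r0), float(c0)),
                    "radius_px": float(ev.extent),
                    "amplitude": ev.amplitude,
                }
            )

    elif mode == "cochlea":
        layout = cochlea_layout((H, W), spec.n_ihc)
        masks = {r.name: r.mask((H, W)) for r in layout}
        comp_gain = {"ISC": 1.0, "IHC": 0.8, "SGN": 0.6}
        envelope = np.zeros(T, dtype=np.float64)
        for ev in spec.event_schedule:
            tau = max(ev.duration / 3.0, 1.0 / spec.frame_rate)
            tmask = (times >= ev.time) & (times <= ev.time + 6 * tau)
            env = _alpha_kernel(times[tmask] - ev.time, tau)
            envelope[tmask] += ev.amplitude * env
            log.events.append(
                {"kind": "cochlea_event", "time": ev.time,
                 "amplitude": ev.amplitude, "duration": ev.duration}
            )
        for r in layout:
            gain = comp_gain.get(r.compartment, 1.0)
            signal += (
                gain
                * envelope[:, None, None].astype(np.float32)
                * masks[r.name][None].astype(np.float32)
            )
        if spec.corr_target is not None and spec.event_schedule:
            # per-IHC independent noise sized so trace pairs correlate at target
            rho = spec.corr_target
            if not (0 < rho <= 1):
                raise ValueError("corr_target must lie in (0, 1]")
            sig_sd = float(np.std(comp_gain["IHC"] * envelope))
            eps_sd = sig_sd * np.sqrt(1.0 / rho - 1.0)
            for r in layout:
                if r.compartment == "IHC":
                    noise = rng.normal(0, eps_sd, size=T).astype(np.float32)
                    signal += noise[:, None, None] * masks[r.name][None].astype(np.float32)
        log.params["ihc_noise_model"] = "independent per-cell, correlation-calibrated"

    movie = spec.baseline * (1.0 + signal)
    if spec.bleach_tau > 0:
        movie *= np.exp(-times / spec.bleach_tau)[:, None, None].astype(np.float32)
    if spec.noise_sd > 0:
        movie = movie + rng.normal(0, spec.noise_sd, size=movie.shape).astype(np.float32)
    return MovieStack(movie.astype(np.float32), spec.frame_rate, spec.um_per_px), log


def cochlea_layout(shape_hw: tuple[int, int], n_ihc: int = 12) -> ROISet:
    """Deterministic explant geometry: ISC band, a row of IHCs, SGN region.

    The top 40% of the frame is the ISC (Kölliker's organ) band, a single
    row of elliptical IHCs sits below it, and the bottom third holds the
    SGN somata region — a flattened stand-in for the merged two-plane
    recordings of real explants.
    """
    h, w = shape_hw
    rois = [
        ROI("ISC", "rect", {"x": 0, "y": 0, "w": w, "h": int(0.4 * h)}, "ISC"),
        ROI("SGN", "rect", {"x": 0, "y": int(0.7 * h), "w": w, "h": h - int(0.7 * h)}, "SGN"),
    ]
    cy = int(0.55 * h)
    rx = max(2, w // (3 * n_ihc))
    ry = max(2, int(0.05 * h))
    for i in range(n_ihc):
        cx = (i + 0.5) * w / n_ihc
        rois.append(
            ROI(f"IHC_{i:02d}", "ellipse", {"cx": cx, "cy": cy, "rx": rx, "ry": ry}, "IHC")
        )
    return ROISet(rois)


# ---------------------------------------------------------------------------
# schedule builders
# ---------------------------------------------------------------------------

def schedule_ic_events(
    n_events: int,
    duration: float,
    positions_um: np.ndarray | list[float],
    rng: np.random.Generator,
    amp_range: tuple[float, float] = (0.25, 0.6),
    width_um: float = 100.0,
    event_duration: float = 1.5,
    min_gap: float = 4.0,
    lobes: list[str] | None = None,
) -> list[MovieEvent]:
    """Evenly spread, jittered IC band events with the given axis positions."""
    base = np.linspace(min_gap, duration - 2 * event_duration - min_gap, n_events)
    jitter = rng.uniform(-min_gap / 4, min_gap / 4, size=n_events)
    times = np.sort(base + jitter)
    positions = np.asarray(positions_um, dtype=float)
    evs = []
    for i, t in enumerate(times):
        evs.append(
            MovieEvent(
                time=float(t),
                amplitude=float(rng.uniform(*amp_range)),
                duration=event_duration,
                lobe=(lobes[i] if lobes else ("left" if rng.random() < 0.5 else "right")),
                position=float(positions[i % positions.size]),
                extent=width_um,
            )
        )
    return evs


def schedule_sc_waves(
    n_waves: int,
    duration: float,
    shape_hw: tuple[int, int],
    rng: np.random.Generator,
    dur_range: tuple[float, float] = (1.2, 3.0),
    radius_px: float = 16.0,
    amplitude: float = 0.5,
    gap: float = 2.0,
) -> list[MovieEvent]:
    """Non-overlapping waves with random onsets and durations > 1 s."""
    h, w = shape_hw
    durs = rng.uniform(*dur_range, size=n_waves)
    total = durs.sum() + gap * (n_waves + 1)
    if total > duration:
        raise ValueError("schedule does not fit in the movie duration")
    slack = duration - total
    gaps = rng.dirichlet(np.ones(n_waves)) * slack + gap
    t = gap
    evs = []
    for d, g in zip(durs, gaps):
        r0 = rng.uniform(radius_px + 2, h - radius_px - 2)
        c0 = rng.uniform(radius_px + 2, w - radius_px - 2)
        evs.append(
            MovieEvent(
                time=float(t), amplitude=amplitude, duration=float(d),
                lobe="left", position=(float(r0), float(c0)), extent=radius_px,
            )
        )
        t += d + g
    return evs


def schedule_crenations(
    n_events: int,
    duration: float,
    shape_hw: tuple[int, int],
    rng: np.random.Generator,
    radius_px: float = 12.0,
    amplitude: float = 50.0,
    event_duration: float = 8.0,
) -> list[MovieEvent]:
    """Evenly spaced crenation events at random positions."""
    h, w = shape_hw
    times = np.linspace(event_duration, duration - 2 * event_duration, n_events)
    evs = []
    for t in times:
        r0 = rng.uniform(radius_px + 3, h - radius_px - 3)
        c0 = rng.uniform(radius_px + 3, w - radius_px - 3)
        evs.append(
            MovieEvent(
                time=float(t), amplitude=amplitude, duration=event_duration,
                position=(float(r0), float(c0)), extent=radius_px,
            )
        )
    return evs
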