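"""Readers and writers for the package's on-disk formats.

Movies travel as multi-frame TIFF with a JSON metadata sidecar
(``<path>.meta.json`` holding frame_rate and um_per_px); traces and spike
times as two-column CSV (comma-separated, header row, UTF-8); event tables
as CSV sorted by time; ROI geometry as the JSON format of
:mod:`prehear.rois`.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .currents import CurrentTrace
from .movie import MovieStack
from .rois import ROISet
from .spikes import SpikeTrain

__all__ = [
    "read_movie",
    "write_movie",
    "read_trace",
    "write_trace",
    "read_spikes",
    "write_spikes",
    "read_events",
    "write_events",
    "read_rois",
]


def _sidecar(path: str | Path) -> Path:
    return Path(str(path) + ".meta.json")


def write_movie(stack: MovieStack, path: str | Path) -> None:
    tifffile.imwrite(str(path), stack.data, photometric="minisblack")
    _sidecar(path).write_text(
        json.dumps({"frame_rate": stack.frame_rate, "um_per_px": stack.um_per_px})
    )


def read_movie(path: str | Path) -> MovieStack:
    side = _sidecar(path)
    if not side.exists():
        raise FileNotFoundError(f"missing metadata sidecar {side}")
    meta = json.loads(side.read_text())
    for key in ("frame_rate", "um_per_px"):
        if key not in meta:
            raise ValueError(f"metadata sidecar missing required field {key!r}")
    data = tifffile.imread(str(path))
    if data.ndim == 2:
        data = data[None]
    return MovieStack(data, float(meta["frame_rate"]), float(meta["um_per_px"]))


def write_trace(trace: CurrentTrace, path: str | Path) -> None:
    df = pd.DataFrame({"time_s": trace.times, "value": trace.samples})
    df.to_csv(path, index=False)
    meta = {"rate_hz": trace.rate_hz, "epochs": trace.epochs,
            "holding_potential_mv": trace.holding_potential_mv}
    _sidecar(path).write_text(json.dumps(meta))


def read_trace(path: str | Path) -> CurrentTrace:
    df = _read_csv(path)
    if "value" not in df.columns or "time_s" not in df.columns:
        raise ValueError("trace CSV must have columns time_s,value")
    side = _sidecar(path)
    if side.exists():
        meta = json.loads(side.read_text())
        rate = float(meta["rate_hz"])
        epochs = {k: tuple(v) for k, v in meta.get("epochs", {}).items()}
        hp = meta.get("holding_potential_mv")
    else:
        t = df["time_s"].to_numpy()
        if t.size < 2:
            raise ValueError("cannot infer sampling rate from a single sample")
        rate = 1.0 / float(np.median(np.diff(t)))
        epochs, hp = {}, None
    return CurrentTrace(df["value"].to_numpy(float), rate, epochs, hp)


def write_spikes(train: SpikeTrain, path: str | Path) -> None:
    pd.DataFrame({"time_s": train.times}).to_csv(path, index=False)
    _sidecar(path).write_text(json.dumps({"duration": train.duration}))


def read_spikes(path: str | Path, duration: float | None = None) -> SpikeTrain:
    df = _read_csv(path)
    times = np.sort(df["time_s"].to_numpy(float))
    side = _sidecar(path)
    if duration is None:
        if side.exists():
            duration = float(json.loads(side.read_text())["duration"])
        else:
            duration = float(times[-1]) + 1.0 if times.size else 1.0
    return SpikeTrain(times, duration)


def write_events(events: pd.DataFrame, path: str | Path) -> None:
    df = events.copy()
    for cand in ("time_s", "onset", "time"):
        if cand in df.columns:
            df = df.sort_values(cand, kind="stable")
            break
    df.to_csv(path, index=False)


def read_events(path: str | Path) -> pd.DataFrame:
    df = _read_csv(path)
    for cand in ("time_s", "onset", "time"):
        if cand in df.columns:
            df = df.sort_values(cand, kind="stable").reset_index(drop=True)
            break
    return df


def read_rois(path: str | Path, image_shape: tuple[int, int] | None = None) -> ROISet:
    return ROISet.from_json(path, image_shape)


def _read_csv(path: str | Path) -> pd.DataFrame:
    try:
        return pd.read_csv(path)
    except pd.errors.ParserError as err:
        raise ValueError(f"malformed CSV {path}: {err}") from err
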