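"""Reproducible multi-stage runs driven by a plain-text (YAML) config.

A run config selects stages, carries every tunable constant of the other
modules, and names a seed and output directory.  The exact config used is
copied into the run directory alongside the stage outputs so reruns are
diffable and, for deterministic stages, byte-identical.
"""

from __future__ import annotations

import json
import platform
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, io, synth
from .cochlea import calcium_event_stats, crenation_stats, ihc_correlation
from .midbrain import detect_ic_events, detect_retinal_waves, match_bilateral
from .movie import DetectionConfig, dff
from .spikes import burst_metrics, classify_isis, detect_bursts
from .synth import (
    MovieGenSpec,
    SpikeGenSpec,
    gen_current_trace,
    gen_spike_train,
    gen_widefield_movie,
    lobe_rois,
    schedule_crenations,
    schedule_sc_waves,
)
from .currents import detect_current_events

VALID_STAGES = [
    "synth_spikes",
    "spike_bursts",
    "synth_currents",
    "current_events",
    "synth_crenation",
    "crenation",
    "synth_cochlea",
    "cochlea_events",
    "synth_ic",
    "ic_events",
    "synth_sc",
    "sc_waves",
]


def load_config(path: str | Path) -> dict:
    cfg = yaml.safe_load(Path(path).read_text())
    if not isinstance(cfg, dict):
        raise ValueError("config must be a YAML mapping")
    return cfg


def run_pipeline(config: dict, outdir: str | Path) -> dict:
    """Execute the selected stages in order and write a result bundle.

    ``config`` keys: ``stages`` (list), ``seed`` (int), plus optional
    per-stage parameter mappings keyed by stage name.  Stage outputs (CSV
    tables, generated inputs) land in ``outdir`` together with the exact
    config (``config.yaml``) and a ``summary.json``.  A failing stage
    aborts the run but leaves earlier outputs in place.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stages = config.get("stages", [])
    unknown = [s for s in stages if s not in VALID_STAGES]
    if unknown:
        raise ValueError(f"unknown stage(s) {unknown}; valid stages: {VALID_STAGES}")
    seed = int(config.get("seed", 0))
    (outdir / "config.yaml").write_text(yaml.safe_dump(config, sort_keys=True))
    summary: dict = {
        "prehear_version": __version__,
        "python": platform.python_version(),
        "seed": seed,
        "stages": {},
    }
    state: dict = {}
    for stage in stages:
        params = config.get(stage, {}) or {}
        result = _run_stage(stage, params, seed, state, outdir)
        summary["stages"][stage] = result
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2, default=str))
    return summary


def _run_stage(stage: str, params: dict, seed: int, state: dict, outdir: Path) -> dict:
    rng = np.random.default_rng(seed)
    if stage == "synth_spikes":
        spec = SpikeGenSpec(seed=seed, **params)
        train, log = gen_spike_train(spec)
        io.write_spikes(train, outdir / "spikes.csv")
        log.to_json(outdir / "spikes_truth.json")
        state["spike_train"] = train
        return {"n_spikes": len(train), "n_true_bursts": len(log)}
    if stage == "spike_bursts":
        train = state.get("spike_train") or io.read_spikes(outdir / "spikes.csv")
        bursts = detect_bursts(classify_isis(train))
        m = burst_metrics(bursts, train, train.duration)
        rows = [{"start": b.start, "end": b.end, "n_spikes": b.n_spikes,
                 "duration": b.duration} for b in bursts]
        io.write_events(pd.DataFrame(rows), outdir / "bursts.csv")
        return {"n_bursts": len(bursts), "burst_freq_per_min": m.burst_freq,
                "isi_cv": m.isi_cv}
    if stage == "synth_currents":
        trace, log = gen_current_trace(seed=seed, **params)
        io.write_trace(trace, outdir / "trace.csv")
        log.to_json(outdir / "trace_truth.json")
        state["trace"] = trace
        return {"n_true_events": len(log)}
    if stage == "current_events":
        trace = state.get("trace") or io.read_trace(outdir / "trace.csv")
        events, per_epoch = detect_current_events(trace, **params)
        per_epoch.to_csv(outdir / "current_events_summary.csv", index=False)
        return {"n_events": len(events)}
    if stage in ("synth_crenation", "synth_cochlea", "synth_ic", "synth_sc"):
        mode = stage.split("_", 1)[1]
        mode = {"crenation": "crenation", "cochlea": "cochlea", "ic": "ic", "sc": "sc"}[mode]
        default_shape = (600, 160, 210) if mode == "sc" else (300, 96, 96)
        shape = tuple(params.pop("shape", default_shape))
        frame_rate = params.pop("frame_rate", 10.0)
        n_events = params.pop("n_events", 6)
        dur = shape[0] / frame_rate
        if mode == "crenation":
            sched = schedule_crenations(n_events, dur, shape[1:], rng)
        elif mode == "sc":
            sched = schedule_sc_waves(n_events, dur, shape[1:], rng)
        elif mode == "ic":
            sched = synth.schedule_ic_events(
                n_events, dur, params.pop("positions_um", [300.0, 700.0]), rng
            )
        else:
            times = np.linspace(5, dur - 10, n_events)
            sched = [synth.MovieEvent(time=float(t), amplitude=0.5, duration=2.0)
                     for t in times]
        spec = MovieGenSpec(
            shape=shape, frame_rate=frame_rate, event_schedule=sched,
            seed=seed, **params,
        )
        stack, log = gen_widefield_movie(spec, mode)
        io.write_movie(stack, outdir / f"{mode}.tif")
        log.to_json(outdir / f"{mode}_truth.json")
        state[f"movie_{mode}"] = stack
        return {"n_true_events": len(log)}
    if stage == "crenation":
        stack = state.get("movie_crenation") or io.read_movie(outdir / "crenation.tif")
        table = crenation_stats(stack, DetectionConfig(**params))
        io.write_events(table, outdir / "crenations.csv")
        return {"n_events": len(table),
                "frequency_per_min": table.attrs.get("frequency_per_min", 0.0)}
    if stage == "cochlea_events":
        stack = state.get("movie_cochlea") or io.read_movie(outdir / "cochlea.tif")
        layout = synth.cochlea_layout(stack.data.shape[1:])
        d = dff(stack)
        table = calcium_event_stats(d, layout, DetectionConfig(**params))
        io.write_events(table, outdir / "cochlea_events.csv")
        corr = ihc_correlation(d, layout)
        return {"n_events": len(table), "ihc_group_mean_corr": corr.group_mean}
    if stage == "ic_events":
        stack = state.get("movie_ic") or io.read_movie(outdir / "ic.tif")
        d = dff(stack)
        events = detect_ic_events(d, lobe_rois(stack.data.shape[1:]), **params)
        pairs, unmatched = match_bilateral(events)
        rows = [asdict(e) for e in events]
        io.write_events(pd.DataFrame(rows), outdir / "ic_events.csv")
        ratios = [p.ratio for p in pairs]
        return {"n_events": len(events), "n_pairs": len(pairs),
                "mean_bilateral_ratio": float(np.mean(ratios)) if ratios else None}
    if stage == "sc_waves":
        stack = state.get("movie_sc") or io.read_movie(outdir / "sc.tif")
        from .rois import ROI, ROISet
        h, w = stack.data.shape[1:]
        roi = ROISet([ROI("left", "rect", {"x": 0, "y": 0, "w": w, "h": h}, "left")])
        waves, summary = detect_retinal_waves(stack, roi, **params)
        rows = [asdict(wv) for wv in waves]
        io.write_events(pd.DataFrame(rows), outdir / "sc_waves.csv")
        return summary
    raise ValueError(f"unknown stage {stage!r}")
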