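"""File readers/writers for session inputs and stage outputs.

Formats
-------
- spikes:  CSV with columns ``unit_id, time_s`` (sorted within unit)
- events:  CSV with columns ``kind, time_s[, duration_s]``
- timeline: JSON with ``baseline_start, lickspout_time, food_time,
  session_end[, phase]``
- trace:   flat binary little-endian int16, channel-interleaved, with a
  sidecar JSON holding ``fs``, ``channel_ids``, ``uv_per_count`` and ``t0``
- results: one CSV per result family plus a JSON run manifest carrying the
  config hash and seed
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .types import EventKind, EventSeries, RawTrace, SchemaError, SessionTimeline, SpikeTrain

log = logging.getLogger("arcpipe.io")


# ---------------------------------------------------------------------------
# spike tables
# ---------------------------------------------------------------------------

def read_spikes(path: str | Path) -> List[SpikeTrain]:
    """Read a spike-time table into one SpikeTrain per unit."""
    df = pd.read_csv(path)
    for col in ("unit_id", "time_s"):
        if col not in df.columns:
            raise SchemaError(f"{path}: missing column {col!r}")
    trains = []
    for unit_id, grp in df.groupby("unit_id", sort=True):
        times = grp["time_s"].to_numpy(dtype=float)
        if np.any(np.diff(times) <= 0):
            bad = int(np.argmax(np.diff(times) <= 0)) + 1
            raise SchemaError(
                f"{path}: unit {unit_id} times not strictly increasing "
                f"at row {grp.index[bad]}"
            )
        trains.append(SpikeTrain(str(unit_id), times))
    return trains


def write_spikes(trains: List[SpikeTrain], path: str | Path) -> None:
    frames = [
        pd.DataFrame({"unit_id": t.unit_id, "time_s": t.times}) for t in trains
    ]
    out = (pd.concat(frames, ignore_index=True) if frames
           else pd.DataFrame(columns=["unit_id", "time_s"]))
    out.to_csv(path, index=False, float_format="%.6f")


# ---------------------------------------------------------------------------
# event tables
# ---------------------------------------------------------------------------

def read_events(path: str | Path) -> List[EventSeries]:
    """Read an event table into one EventSeries per kind."""
    df = pd.read_csv(path)
    for col in ("kind", "time_s"):
        if col not in df.columns:
            raise SchemaError(f"{path}: missing column {col!r}")
    series = []
    for kind, grp in df.groupby("kind", sort=True):
        times = grp["time_s"].to_numpy(dtype=float)
        dec = np.nonzero(np.diff(times) < 0)[0]
        if dec.size:
            raise SchemaError(
                f"{path}: {kind} times decrease at row {grp.index[dec[0] + 1]}"
            )
        durations = None
        if "duration_s" in grp.columns and grp["duration_s"].notna().all():
            durations = grp["duration_s"].to_numpy(dtype=float)
        try:
            series.append(EventSeries(EventKind(kind), times, durations))
        except ValueError as exc:
            raise SchemaError(f"{path}: unknown event kind {kind!r}") from exc
    return series


def write_events(series: List[EventSeries], path: str | Path) -> None:
    frames = []
    for s in series:
        frame = pd.DataFrame({"kind": s.kind.value, "time_s": s.times})
        frame["duration_s"] = s.durations if s.durations is not None else np.nan
        frames.append(frame)
    out = (pd.concat(frames, ignore_index=True) if frames
           else pd.DataFrame(columns=["kind", "time_s", "duration_s"]))
    out.to_csv(path, index=False, float_format="%.6f")


def events_by_kind(series: List[EventSeries]) -> Dict[EventKind, EventSeries]:
    return {s.kind: s for s in series}


# ---------------------------------------------------------------------------
# timeline
# ---------------------------------------------------------------------------

def read_timeline(path: str | Path) -> SessionTimeline:
    with open(path) as fh:
        raw = json.load(fh)
    required = ("baseline_start", "lickspout_time", "food_time", "session_end")
    missing = [k for k in required if k not in raw]
    if missing:
        raise SchemaError(f"{path}: missing timeline keys {missing}")
    return SessionTimeline(
        baseline_start=float(raw["baseline_start"]),
        lickspout_time=float(raw["lickspout_time"]),
        food_time=float(raw["food_time"]),
        session_end=float(raw["session_end"]),
        phase=raw.get("phase"),
    )


def write_timeline(timeline: SessionTimeline, path: str | Path) -> None:
    payload = {
        "baseline_start": timeline.baseline_start,
        "lickspout_time": timeline.lickspout_time,
        "food_time": timeline.food_time,
        "session_end": timeline.session_end,
    }
    if timeline.phase is not None:
        payload["phase"] = timeline.phase
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


# ---------------------------------------------------------------------------
# raw traces: flat binary int16, channel-interleaved, JSON sidecar
# ---------------------------------------------------------------------------

def read_trace(bin_path: str | Path, sidecar_path: str | Path) -> RawTrace:
    with open(sidecar_path) as fh:
        meta = json.load(fh)
    for key in ("fs", "channel_ids", "uv_per_count"):
        if key not in meta:
            raise SchemaError(f"{sidecar_path}: missing key {key!r}")
    fs = float(meta["fs"])
    if fs <= 0:
        raise SchemaError(f"{sidecar_path}: fs must be > 0, got {fs}")
    channel_ids = list(meta["channel_ids"])
    n_channels = len(channel_ids)
    counts = np.fromfile(bin_path, dtype="<i2")
    if counts.size % n_channels:
        raise SchemaError(
            f"{bin_path}: {counts.size} samples not divisible by "
            f"{n_channels} channels"
        )
    samples = counts.reshape(-1, n_channels).T * float(meta["uv_per_count"])
    return RawTrace(samples, fs, channel_ids, t0=float(meta.get("t0", 0.0)))


def write_trace(trace: RawTrace, bin_path: str | Path,
                sidecar_path: str | Path, uv_per_count: float = 0.25) -> None:
    counts = np.round(trace.samples / uv_per_count)
    counts = np.clip(counts, -32768, 32767).astype("<i2")
    counts.T.tofile(bin_path)  # channel-interleaved
    meta = {
        "fs": trace.fs,
        "channel_ids": list(trace.channel_ids),
        "uv_per_count": uv_per_count,
        "t0": trace.t0,
    }
    with open(sidecar_path, "w") as fh:
        json.dump(meta, fh, indent=1)


# ---------------------------------------------------------------------------
# session assembly and result writing
# ---------------------------------------------------------------------------

def read_session(session_dir: str | Path, config: Optional[PipelineConfig] = None):
    """Read a session directory into validated domain objects.

    Expects ``spikes.csv``, ``events.csv`` and ``timeline.json``; a raw trace
    (``trace.bin`` + ``trace.json``) is optional.  Returns
    ``(spike_trains, event_series, timeline, trace_or_None)``.
    """
    session_dir = Path(session_dir)
    spikes = read_spikes(session_dir / "spikes.csv")
    events = read_events(session_dir / "events.csv")
    timeline = read_timeline(session_dir / "timeline.json")
    trace = None
    if (session_dir / "trace.bin").exists():
        trace = read_trace(session_dir / "trace.bin", session_dir / "trace.json")
    log.info("read session %s: %d units, %d event series",
             session_dir, len(spikes), len(events))
    return spikes, events, timeline, trace


def write_results(tables: Dict[str, pd.DataFrame], out_dir: str | Path,
                  config: Optional[PipelineConfig] = None) -> dict:
    """Write one CSV per result family plus a JSON run manifest.

    Returns the manifest dict (also written to ``manifest.json``).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    config = config or PipelineConfig()
    manifest: dict = {
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "tables": {},
    }
    for name, table in tables.items():
        path = out_dir / f"{name}.csv"
        table.to_csv(path, index=False, float_format="%.10g")
        manifest["tables"][name] = {"file": path.name, "rows": int(len(table))}
        log.info("wrote %s: %d rows", path, len(table))
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
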