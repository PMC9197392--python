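"""Readers and writers for the plain tabular and image-stack formats.

Formats
-------
spikes.csv      unit_id,region,spike_time_s
events.csv      onset_s,pulse_duration_s,kind
footprints.csv  idx,x_cm,y_cm,side
trajectory.csv  t_s,x_cm,y_cm
scores.csv      rater_id,block,score
frames/         directory of 8-bit grayscale PNGs plus manifest.json
                ({width,height,n_frames,fps,px_per_cm}), or a .raw binary
                stack next to the same manifest.

Floats are written with 17 significant digits so a read-back reproduces
them bit-exactly.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .types import (
    BehaviorScoreSeries,
    FootprintSequence,
    FormatError,
    SpikeTrain,
    StimProtocol,
    Trajectory,
)

_FLOAT_FMT = "%.17g"


def _require_columns(df: pd.DataFrame, cols, path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")


# ---------------------------------------------------------------------------
# Spike trains
# ---------------------------------------------------------------------------

def read_spike_trains(path, t_start: float | None = None,
                      t_end: float | None = None) -> list[SpikeTrain]:
    """Read one :class:`SpikeTrain` per ``unit_id`` from ``spikes.csv``.

    The recording interval defaults to ``[0, max spike time + 1e-9)`` when
    not given.  Duplicate timestamps within a unit are dropped with a
    warning; an unknown region label is an error naming the offending row.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, ["unit_id", "region", "spike_time_s"], path)
    if len(df) and not np.all(np.isfinite(df["spike_time_s"].to_numpy(float))):
        raise FormatError(f"{path}: non-finite spike_time_s")
    trains = []
    if t_end is None and len(df):
        t_end = float(df["spike_time_s"].max()) + 1e-9
    t_start = 0.0 if t_start is None else t_start
    for unit_id, grp in df.groupby("unit_id", sort=True):
        region = str(grp["region"].iloc[0])
        if region not in ("DN", "VAL", "CL", "M1", "DLS"):
            row = int(grp.index[0]) + 2  # 1-based with header line
            raise FormatError(
                f"{path}: unknown region {region!r} for unit "
                f"{unit_id!r} (first at file line {row})"
            )
        times = np.sort(grp["spike_time_s"].to_numpy(float))
        uniq = np.unique(times)
        if uniq.size != times.size:
            warnings.warn(
                f"unit {unit_id!r}: dropped {times.size - uniq.size} "
                "duplicate spike timestamps",
                stacklevel=2,
            )
        trains.append(SpikeTrain(str(unit_id), region, uniq,
                                 t_start, float(t_end)))
    return trains


def write_spike_trains(trains, path) -> None:
    rows = [
        {"unit_id": tr.unit_id, "region": tr.region, "spike_time_s": t}
        for tr in trains
        for t in tr.spike_times
    ]
    df = pd.DataFrame(rows, columns=["unit_id", "region", "spike_time_s"])
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


# ---------------------------------------------------------------------------
# Stimulation events
# ---------------------------------------------------------------------------

def read_events(path) -> StimProtocol:
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, ["onset_s", "pulse_duration_s", "kind"], path)
    if df.empty:
        raise FormatError(f"{path}: no stimulation events")
    durations = df["pulse_duration_s"].unique()
    if durations.size != 1:
        raise FormatError(
            f"{path}: expected a single pulse duration, found {durations}"
        )
    kinds = df["kind"].unique()
    if kinds.size != 1:
        raise FormatError(f"{path}: mixed protocol kinds {kinds}")
    onsets = df["onset_s"].to_numpy(float)
    if np.any(np.diff(onsets) < 0):
        warnings.warn(f"{path}: onsets out of order; re-sorting", stacklevel=2)
        onsets = np.sort(onsets)
    return StimProtocol(onsets, float(durations[0]), str(kinds[0]))


def write_events(protocol: StimProtocol, path) -> None:
    df = pd.DataFrame({
        "onset_s": protocol.onsets,
        "pulse_duration_s": protocol.pulse_duration,
        "kind": protocol.kind,
    })
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


# ---------------------------------------------------------------------------
# Footprints / trajectory / scores
# ---------------------------------------------------------------------------

def read_footprints(path) -> FootprintSequence:
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, ["idx", "x_cm", "y_cm", "side"], path)
    df = df.sort_values("idx")
    return FootprintSequence(df["x_cm"].to_numpy(float),
                             df["y_cm"].to_numpy(float),
                             df["side"].to_numpy())


def write_footprints(fp: FootprintSequence, path) -> None:
    df = pd.DataFrame({
        "idx": np.arange(fp.n_prints),
        "x_cm": fp.x,
        "y_cm": fp.y,
        "side": fp.sides,
    })
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_trajectory(path, arena_center=(0.0, 0.0), arena_radius=19.0,
                    px_per_cm=1.0) -> Trajectory:
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, ["t_s", "x_cm", "y_cm"], path)
    pos = df[["x_cm", "y_cm"]].to_numpy(float)
    return Trajectory(df["t_s"].to_numpy(float), pos,
                      arena_center=tuple(arena_center),
                      arena_radius=arena_radius, px_per_cm=px_per_cm)


def write_trajectory(traj: Trajectory, path) -> None:
    df = pd.DataFrame({
        "t_s": traj.timestamps,
        "x_cm": traj.positions[:, 0],
        "y_cm": traj.positions[:, 1],
    })
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_scores(path) -> BehaviorScoreSeries:
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, ["rater_id", "block", "score"], path)
    if len(df) and not np.all(np.isin(df["score"], [0, 1, 2, 3, 4])):
        bad = df.loc[~df["score"].isin([0, 1, 2, 3, 4])].iloc[0]
        raise FormatError(
            f"{path}: invalid score {bad['score']} for rater "
            f"{bad['rater_id']!r} block {bad['block']}"
        )
    table = df.pivot(index="rater_id", columns="block", values="score")
    if table.isna().any().any():
        raise FormatError(f"{path}: missing blocks for some raters")
    return BehaviorScoreSeries(table.to_numpy(int), tuple(table.index))


def write_scores(series: BehaviorScoreSeries, path) -> None:
    rows = [
        {"rater_id": rid, "block": b, "score": int(series.block_scores[i, b])}
        for i, rid in enumerate(series.rater_ids)
        for b in range(series.n_blocks)
    ]
    pd.DataFrame(rows, columns=["rater_id", "block", "score"]).to_csv(
        path, index=False)


# ---------------------------------------------------------------------------
# Frame stacks
# ---------------------------------------------------------------------------

def read_frame_stack(path):
    """Iterate ``(frame_index, 2-D uint8 array)`` over a frame stack.

    ``path`` is a directory containing either numbered 8-bit grayscale PNGs
    or a ``frames.raw`` binary stack, plus ``manifest.json``.  Frames of
    mismatched size raise at the offending index.
    """
    path = Path(path)
    manifest = json.loads((path / "manifest.json").read_text())
    h, w, n = manifest["height"], manifest["width"], manifest["n_frames"]
    raw = path / "frames.raw"
    if raw.exists():
        data = np.fromfile(raw, dtype=np.uint8)
        if data.size != n * h * w:
            raise FormatError(
                f"{raw}: expected {n * h * w} bytes, found {data.size}"
            )
        for i in range(n):
            yield i, data[i * h * w:(i + 1) * h * w].reshape(h, w)
        return
    pngs = sorted(path.glob("*.png"))
    if len(pngs) != n:
        raise FormatError(
            f"{path}: manifest promises {n} frames, found {len(pngs)} PNGs"
        )
    for i, png in enumerate(pngs):
        frame = np.asarray(Image.open(png).convert("L"))
        if frame.shape != (h, w):
            raise FormatError(
                f"frame {i} ({png.name}): size {frame.shape} != ({h}, {w})"
            )
        yield i, frame


def write_frame_stack(frames, path, fps: float, px_per_cm: float) -> None:
    """Write frames as a raw binary stack plus JSON manifest."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    frames = [np.asarray(f, dtype=np.uint8) for f in frames]
    if frames:
        h, w = frames[0].shape
        for i, f in enumerate(frames):
            if f.shape != (h, w):
                raise FormatError(f"frame {i}: size {f.shape} != ({h}, {w})")
    else:
        h = w = 0
    np.concatenate([f.ravel() for f in frames] or [np.empty(0, np.uint8)]
                   ).tofile(path / "frames.raw")
    (path / "manifest.json").write_text(json.dumps({
        "width": w, "height": h, "n_frames": len(frames),
        "fps": fps, "px_per_cm": px_per_cm,
    }))


# ---------------------------------------------------------------------------
# Generic report writer
# ---------------------------------------------------------------------------

def _to_record(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        rec = {}
        for f in dataclasses.fields(obj):
            v = getattr(obj, f.name)
            if isinstance(v, np.ndarray) and v.ndim > 0:
                continue  # array fields stay out of flat tables
            if isinstance(v, np.generic):
                v = v.item()
            rec[f.name] = v
        return rec
    if isinstance(obj, dict):
        return obj
    raise TypeError(f"cannot tabulate {type(obj).__name__}")


def write_report(results, path) -> None:
    """Write stage output as a tidy CSV plus a JSON summary.

    ``results`` is a dataclass instance, a dict, or a list of either.  The
    CSV round-trips bit-exactly for integers and strings and to full float
    precision; an empty list writes a header-only CSV when the element
    schema cannot be inferred (an empty frame).
    """
    path = Path(path)
    items = results if isinstance(results, list) else [results]
    records = [_to_record(x) for x in items]
    df = pd.DataFrame(records)
    df.to_csv(path.with_suffix(".csv"), index=False, float_format=_FLOAT_FMT)
    path.with_suffix(".json").write_text(
        json.dumps(records, indent=2, default=_json_default))


def _json_default(v):
    if isinstance(v, np.generic):
        return v.item()
    if isinstance(v, np.ndarray):
        return v.tolist()
    raise TypeError(f"not JSON serializable: {type(v).__name__}")
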