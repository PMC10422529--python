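"""Readers and writers for the package's on-disk sequence layout.

A sequence directory holds:

``frames.csv``
    Long-format sparse table ``time_s,row,col,pressure_mmHg`` listing only
    nonzero cells, so file size scales with contact area, not grid size.
``meta.json``
    Geometry and acquisition metadata: shape, pitch, frequency, floor,
    ceiling, mattress model tag, subject id.
``labels.csv``
    Per-frame posture ground truth: ``frame_index,time_s,posture``.
``events.csv``
    Ground-truth postural-change instants: ``event_time_s``.

Floats are written with 17 significant digits so a write/read round-trip is
bit-exact.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .frames import FrameSequence, PressureFrame, ValidationError

_FRAMES_CSV = "frames.csv"
_META_JSON = "meta.json"
_LABELS_CSV = "labels.csv"
_EVENTS_CSV = "events.csv"


def write_sequence(seq: FrameSequence, path: str | Path) -> None:
    """Write ``seq`` to directory ``path`` in the sparse long-format layout.

    Only nonzero cells appear in ``frames.csv``; an all-zero frame
    contributes no data rows and is reconstructed from ``meta.json`` alone.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)

    times = seq.times()
    stacked = seq.pressures()
    t_idx, r_idx, c_idx = np.nonzero(stacked)
    frames_df = pd.DataFrame(
        {
            "time_s": times[t_idx],
            "row": r_idx,
            "col": c_idx,
            "pressure_mmHg": stacked[t_idx, r_idx, c_idx],
        }
    )
    frames_df.to_csv(path / _FRAMES_CSV, index=False, lineterminator="\n", float_format="%.17g")

    rows, cols = seq.shape
    meta = {
        "rows": rows,
        "cols": cols,
        "pitch_mm": seq.pitch,
        "frequency_hz": seq.frequency,
        "floor_mmHg": seq.frames[0].floor,
        "ceiling_mmHg": seq.frames[0].ceiling,
        "floored": seq.frames[0].floored,
        "n_frames": len(seq),
        "mattress": seq.mattress,
        "subject": seq.subject,
    }
    (path / _META_JSON).write_text(json.dumps(meta, indent=2) + "\n")

    labels_df = pd.DataFrame(
        {
            "frame_index": np.arange(len(seq)),
            "time_s": times,
            "posture": list(seq.posture_labels),
        }
    )
    labels_df.to_csv(path / _LABELS_CSV, index=False, lineterminator="\n", float_format="%.17g")

    events_df = pd.DataFrame({"event_time_s": list(seq.event_times)})
    events_df.to_csv(path / _EVENTS_CSV, index=False, lineterminator="\n", float_format="%.17g")


def read_sequence(path: str | Path) -> FrameSequence:
    """Read a sequence directory written by :func:`write_sequence`.

    Cells absent from ``frames.csv`` are 0.  Validates the sensor-range
    invariants; duplicate ``(time, row, col)`` entries and out-of-range
    pressures are errors.
    """
    path = Path(path)
    meta_path = path / _META_JSON
    if not meta_path.exists():
        raise FileNotFoundError(f"missing {meta_path}")
    meta = json.loads(meta_path.read_text())
    rows, cols = int(meta["rows"]), int(meta["cols"])
    n_frames = int(meta["n_frames"])
    frequency = float(meta["frequency_hz"])
    pitch = float(meta["pitch_mm"])
    floor = float(meta["floor_mmHg"])
    ceiling = float(meta["ceiling_mmHg"])
    floored = bool(meta.get("floored", True))

    frames_df = pd.read_csv(path / _FRAMES_CSV, float_precision="round_trip")
    dupes = frames_df.duplicated(subset=["time_s", "row", "col"], keep=False)
    if dupes.any():
        first = frames_df[dupes].iloc[0]
        raise ValidationError(
            f"duplicate cell entry at time={first['time_s']} "
            f"row={int(first['row'])} col={int(first['col'])}"
        )

    labels_df = pd.read_csv(path / _LABELS_CSV)
    if len(labels_df) != n_frames:
        raise ValidationError(
            f"labels.csv has {len(labels_df)} rows, meta declares {n_frames} frames"
        )
    labels = tuple(labels_df.sort_values("frame_index")["posture"])

    events_df = pd.read_csv(path / _EVENTS_CSV, float_precision="round_trip")
    event_times = tuple(float(t) for t in events_df["event_time_s"])

    grids = np.zeros((n_frames, rows, cols))
    if len(frames_df):
        idx = np.rint(frames_df["time_s"].to_numpy() * frequency).astype(int)
        if np.any((idx < 0) | (idx >= n_frames)):
            raise ValidationError("frame time outside the declared sequence span")
        r = frames_df["row"].to_numpy(dtype=int)
        c = frames_df["col"].to_numpy(dtype=int)
        if np.any((r < 0) | (r >= rows) | (c < 0) | (c >= cols)):
            raise ValidationError("cell index outside the declared grid")
        grids[idx, r, c] = frames_df["pressure_mmHg"].to_numpy()

    frames = tuple(
        PressureFrame(g, pitch=pitch, floor=floor, ceiling=ceiling, floored=floored)
        for g in grids
    )
    return FrameSequence(
        frames=frames,
        frequency=frequency,
        posture_labels=labels,
        event_times=event_times,
        mattress=str(meta.get("mattress", "foam")),
        subject=str(meta.get("subject", "s00")),
    )


def write_cohort(
    cohort: list[FrameSequence], root: str | Path, manifest_name: str = "manifest.csv"
) -> Path:
    """Write each sequence of a cohort to ``root/<subject>`` and a manifest
    CSV (``subject,mattress,path``) at ``root/manifest_name``.

    Returns the manifest path.
    """
    root = Path(root)
    root.mkdir(parents=True, exist_ok=True)
    rows = []
    for seq in cohort:
        sub_dir = root / seq.subject
        write_sequence(seq, sub_dir)
        rows.append({"subject": seq.subject, "mattress": seq.mattress, "path": seq.subject})
    manifest = root / manifest_name
    pd.DataFrame(rows).to_csv(manifest, index=False, lineterminator="\n")
    return manifest


def read_cohort(manifest: str | Path) -> list[FrameSequence]:
    """Read every sequence listed in a cohort manifest CSV."""
    manifest = Path(manifest)
    df = pd.read_csv(manifest)
    return [read_sequence(manifest.parent / p) for p in df["path"]]
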