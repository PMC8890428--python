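"""Readers and writers for the pipeline's on-disk formats.

Movies travel as channel-interleaved multi-page 16-bit TIFF with a JSON
event-log and ground-truth sidecar; masks as multi-page 16-bit TIFF; traces,
peaks, rates and fits as CSV; region calls and comparison reports as JSON.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile
from Bio import SeqIO

from .domains import DeletionConstruct
from .quantify import LabelMask, NuclearTrace, _region_table
from .simulate import (Cycle, CyclePlan, GroundTruth, ImagingMovie,
                       PhotoswitchEvent)

MOVIE_SCALE = 16.0  # intensity units -> uint16 counts


def write_movie(path: Path, movie: ImagingMovie, *, scale: float = MOVIE_SCALE) -> None:
    """Write a movie as channel-interleaved multi-page uint16 TIFF.

    Sidecars ``<stem>.events.json`` and (when ground truth is embedded)
    ``<stem>.truth.json`` are written next to it.
    """
    path = Path(path)
    T, C, H, W = movie.frames.shape
    data = np.clip(movie.frames * scale, 0, 65535).astype(np.uint16)
    tifffile.imwrite(path, data.reshape(T * C, H, W),
                     metadata={"axes": "QYX"}, photometric="minisblack")
    meta = {
        "n_frames": T,
        "n_channels": C,
        "frame_interval_s": movie.frame_interval_s,
        "pixel_size_um": movie.pixel_size_um,
        "start_time_min": movie.start_time_min,
        "intensity_scale": scale,
        "events": [{"time": e.time, "action": e.action} for e in movie.event_log],
    }
    path.with_suffix(".events.json").write_text(_dumps(meta))
    if movie.ground_truth is not None:
        path.with_suffix(".truth.json").write_text(_dumps(_truth_dict(movie.ground_truth)))


def read_movie(path: Path) -> ImagingMovie:
    """Read a movie written by :func:`write_movie` (ground truth not reloaded)."""
    path = Path(path)
    meta = json.loads(path.with_suffix(".events.json").read_text())
    data = tifffile.imread(path).astype(np.float64) / meta["intensity_scale"]
    T, C = meta["n_frames"], meta["n_channels"]
    frames = data.reshape(T, C, *data.shape[-2:])
    events = [PhotoswitchEvent(e["time"], e["action"]) for e in meta["events"]]
    return ImagingMovie(frames=frames, frame_interval_s=meta["frame_interval_s"],
                        pixel_size_um=meta["pixel_size_um"], event_log=events,
                        start_time_min=meta["start_time_min"])


def _truth_dict(gt: GroundTruth) -> dict:
    return {
        "plan": {
            "cycles": [{"index": c.index, "nef_time": c.nef_time,
                        "neb_time": c.neb_time} for c in gt.plan.cycles],
            "end_time": gt.plan.end_time,
        },
        "nuclear_radius_px": gt.nuclear_radius_px,
        "centers_by_cycle": {str(k): v.tolist() for k, v in gt.centers_by_cycle.items()},
        "trajectory": {
            "time": gt.trajectory.time.tolist(),
            "L": gt.trajectory.L.tolist(),
            "D": gt.trajectory.D.tolist(),
            "k": gt.trajectory.k.tolist(),
        },
    }


def read_plan(path: Path) -> CyclePlan:
    d = json.loads(Path(path).read_text())["plan"]
    cycles = tuple(Cycle(c["index"], c["nef_time"], c["neb_time"]) for c in d["cycles"])
    return CyclePlan(cycles=cycles, end_time=d["end_time"])


def write_masks(path: Path, masks: Sequence[LabelMask]) -> None:
    stack = np.stack([m.labels.astype(np.uint16) for m in masks])
    tifffile.imwrite(Path(path), stack, photometric="minisblack")


def read_masks(path: Path) -> list[LabelMask]:
    stack = tifffile.imread(Path(path))
    if stack.ndim == 2:
        stack = stack[None]
    return [LabelMask(fr.astype(np.int32), _region_table(fr.astype(np.int32)))
            for fr in stack]


def write_trace(path: Path, trace: NuclearTrace) -> None:
    trace.to_frame().to_csv(Path(path), index=False)


def read_trace(path: Path) -> NuclearTrace:
    return NuclearTrace.from_frame(pd.read_csv(Path(path)))


def read_events(path: Path) -> list[PhotoswitchEvent]:
    meta = json.loads(Path(path).read_text())
    events = meta["events"] if isinstance(meta, dict) else meta
    return [PhotoswitchEvent(e["time"], e["action"]) for e in events]


def read_constructs(path: Path) -> list[DeletionConstruct]:
    """Constructs CSV: name, start, end, phenotype[, note]."""
    df = pd.read_csv(Path(path))
    required = {"name", "start", "end", "phenotype"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"constructs CSV missing columns: {sorted(missing)}")
    out = []
    for row in df.itertuples(index=False):
        note = getattr(row, "note", "")
        out.append(DeletionConstruct(name=str(row.name), start=int(row.start),
                                     end=int(row.end), phenotype=str(row.phenotype),
                                     note="" if pd.isna(note) else str(note)))
    return out


def read_fasta_single(path: Path) -> str:
    """First record of a FASTA file as an upper-case sequence string."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return str(records[0].seq).upper()


def _dumps(obj) -> str:
    return json.dumps(obj, indent=1, sort_keys=True)


def write_json(path: Path, obj) -> None:
    Path(path).write_text(_dumps(obj))


def sha256_file(path: Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()
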