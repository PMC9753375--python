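"""File formats: pose CSV/HDF5, trajectory TSV, ground-truth TSV, kernels.

Pose CSV schema (wide, one row per frame)::

    # frame_rate: 30.0
    # animal_id: M0001
    # sex: male
    t_s,nose_x,nose_y,nose_z,left_ear_x,...

All coordinates in cm, times in seconds, frames 0-based, intervals
half-open.  Isolated missing pose values (gaps of at most 3 consecutive
frames) are filled by linear interpolation at ingest; longer gaps are a
data-quality error naming the frames.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .dtak import KernelMatrix
from .errors import DataQualityError, SchemaError
from .skeleton import LANDMARKS, N_LANDMARKS, SkeletonSeries

log = logging.getLogger("loomkit")

MAX_GAP_FRAMES = 3


def _pose_columns(names=LANDMARKS) -> list[str]:
    return [f"{n}_{ax}" for n in names for ax in ("x", "y", "z")]


def write_pose_csv(series: SkeletonSeries, path) -> None:
    path = Path(path)
    cols = _pose_columns(series.landmark_names)
    flat = series.coords.reshape(series.n_frames, -1)
    df = pd.DataFrame(flat, columns=cols)
    df.insert(0, "t_s", series.times)
    with open(path, "w") as fh:
        fh.write(f"# frame_rate: {series.frame_rate}\n")
        fh.write(f"# animal_id: {series.animal_id}\n")
        fh.write(f"# sex: {series.sex}\n")
        df.to_csv(fh, index=False)


def read_pose_csv(path) -> SkeletonSeries:
    """Read a pose CSV, validating the schema and interpolating short gaps."""
    path = Path(path)
    meta: dict[str, str] = {}
    with open(path) as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            key, _, val = line[1:].partition(":")
            meta[key.strip()] = val.strip()
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        df = pd.read_csv(fh)
    return _series_from_frame(df, meta, str(path))


def _series_from_frame(df: pd.DataFrame, meta: dict, origin: str) -> SkeletonSeries:
    cols = [c for c in df.columns if c != "t_s"]
    if len(cols) % 3 != 0 or len(cols) // 3 != N_LANDMARKS:
        raise SchemaError(
            f"{origin}: expected {N_LANDMARKS} landmarks x 3 coords, got {len(cols)} columns"
        )
    names = tuple(c[:-2] for c in cols[::3])
    flat = df[cols].to_numpy(dtype=float)
    flat = _interpolate_gaps(flat, origin)
    coords = flat.reshape(len(df), N_LANDMARKS, 3)
    return SkeletonSeries(
        coords=coords,
        frame_rate=float(meta.get("frame_rate", 30.0)),
        landmark_names=names,
        animal_id=meta.get("animal_id", ""),
        sex=meta.get("sex", "unspecified") or "unspecified",
    )


def _interpolate_gaps(flat: np.ndarray, origin: str) -> np.ndarray:
    """Linear interpolation of missing frames, at most MAX_GAP_FRAMES long."""
    missing = ~np.isfinite(flat).all(axis=1)
    if not missing.any():
        return flat
    padded = np.concatenate([[False], missing, [False]])
    edges = np.flatnonzero(np.diff(padded.astype(int)))
    gaps = [(int(edges[i]), int(edges[i + 1])) for i in range(0, len(edges), 2)]
    for s, e in gaps:
        if e - s > MAX_GAP_FRAMES:
            raise DataQualityError(f"{origin}: missing-data gap of {e - s} frames at {s}..{e - 1}")
        if s == 0 or e == len(flat):
            raise DataQualityError(f"{origin}: missing data at the series boundary ({s}..{e - 1})")
    filled = pd.DataFrame(flat).interpolate(method="linear", axis=0).to_numpy()
    log.info("interpolated %d missing frame(s): %s", missing.sum(), [g for g in gaps])
    return filled


def write_pose_h5(series: SkeletonSeries, path) -> None:
    with h5py.File(path, "w") as f:
        d = f.create_dataset("coords", data=series.coords)
        d.attrs["frame_rate"] = series.frame_rate
        d.attrs["animal_id"] = series.animal_id
        d.attrs["sex"] = series.sex
        f.create_dataset("landmark_names", data=np.array(series.landmark_names, dtype="S"))


def read_pose_h5(path) -> SkeletonSeries:
    with h5py.File(path, "r") as f:
        d = f["coords"]
        coords = d[...]
        if coords.ndim != 3 or coords.shape[1] != N_LANDMARKS:
            raise SchemaError(f"{path}: coords must be (frames, {N_LANDMARKS}, 3)")
        names = tuple(n.decode() for n in f["landmark_names"][...])
        return SkeletonSeries(
            coords=coords,
            frame_rate=float(d.attrs["frame_rate"]),
            landmark_names=names,
            animal_id=str(d.attrs.get("animal_id", "")),
            sex=str(d.attrs.get("sex", "unspecified")),
        )


def write_trajectory(traj: pd.DataFrame, path) -> None:
    traj.to_csv(path, sep="\t", index=False)


def read_trajectory(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"t_s", "x_cm", "y_cm"}
    if not required.issubset(df.columns):
        raise SchemaError(f"{path}: trajectory TSV needs columns {sorted(required)}")
    return df


def write_ground_truth(gt, path_events, path_labels) -> None:
    """Events TSV (name, t_start_s, t_end_s) + per-frame label TSV."""
    rows = []
    for name, t in (
        ("stimulus_onset", gt.stimulus_onset),
        ("flight_onset", gt.flight_onset),
        ("refuge_entry", gt.refuge_entry),
        ("refuge_exit", gt.refuge_exit),
    ):
        if t is not None:
            rows.append({"name": name, "t_start_s": t, "t_end_s": ""})
    for s, e in gt.freezing_bouts:
        rows.append({"name": "freezing_bout", "t_start_s": s, "t_end_s": e})
    rows.append({"name": "group", "t_start_s": "", "t_end_s": gt.group})
    pd.DataFrame(rows).to_csv(path_events, sep="\t", index=False)
    pd.DataFrame({"frame": np.arange(len(gt.labels)), "label": gt.labels}).to_csv(
        path_labels, sep="\t", index=False
    )


def write_segments_tsv(segments, path) -> None:
    rows = [
        {
            "trial_id": s.trial_id,
            "start_frame": s.start_frame,
            "end_frame": s.end_frame,
            "mean_speed": s.mean_speed,
        }
        for s in segments
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_kernel_h5(kernel: KernelMatrix, path) -> None:
    with h5py.File(path, "w") as f:
        d = f.create_dataset("values", data=kernel.values)
        d.attrs["sigma"] = kernel.sigma
        d.attrs["normalized"] = kernel.normalized
        f.create_dataset("segment_ids", data=np.array(kernel.segment_ids, dtype="S"))


def read_kernel_h5(path) -> KernelMatrix:
    with h5py.File(path, "r") as f:
        d = f["values"]
        return KernelMatrix(
            values=d[...],
            segment_ids=[s.decode() for s in f["segment_ids"][...]],
            sigma=float(d.attrs["sigma"]),
            normalized=bool(d.attrs["normalized"]),
        )


def write_behavior_map_tsv(bmap, path) -> None:
    df = pd.DataFrame(
        {
            "segment_id": bmap.segment_ids or np.arange(len(bmap.umap1)),
            "umap1": bmap.umap1,
            "umap2": bmap.umap2,
            "loco": bmap.loco,
            "phenotype_id": bmap.phenotype_id,
        }
    )
    if bmap.movement is not None:
        df["movement"] = bmap.movement
    df.to_csv(path, sep="\t", index=False)


def write_ethogram_tsv(etho, path) -> None:
    rows = [
        {"trial_id": etho.trial_id, "label": b.label, "t_start_s": b.start_s, "t_end_s": b.end_s}
        for b in etho.bouts()
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_label_mapping_json(mapping, path) -> None:
    Path(path).write_text(json.dumps(mapping.to_dict(), indent=2))


def read_label_mapping_json(path):
    from .behavior_map import LabelMapping

    return LabelMapping.from_dict(json.loads(Path(path).read_text()))
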