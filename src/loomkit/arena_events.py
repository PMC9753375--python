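"""Assay-event detection and per-trial defensive metrics.

Works on 2D centroid trajectories in arena coordinates (the tracking
modality): detects the stimulus trigger (first entry into the central
circle), refuge entry/exit transitions, and computes the trajectory-level
defensive metrics — responsive latency, return time, mean return speed,
refuge time, acclimation occupancy ratios and the initial distance to the
refuge entrance.

Conventions: times in seconds, frame 0 at t = 0; the trigger circle is open
(boundary counts as outside) while the refuge rectangle is closed; an animal
starting inside the refuge is an entry at t = 0.  ``refuge_outside_ratio``
follows the refuge-to-outside wording; ``refuge_fraction`` (refuge/total) is
exported alongside.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import ArenaGeometry
from .errors import EventError


def _traj_arrays(traj) -> tuple[np.ndarray, np.ndarray]:
    """(t, xy) from a DataFrame with t_s/x_cm/y_cm or a (t, x, y) array."""
    if hasattr(traj, "columns"):
        t = traj["t_s"].to_numpy(dtype=float)
        xy = traj[["x_cm", "y_cm"]].to_numpy(dtype=float)
    else:
        arr = np.asarray(traj, dtype=float)
        t, xy = arr[:, 0], arr[:, 1:3]
    if len(t) < 2:
        raise ValueError("trajectory needs at least 2 samples")
    return t, xy


def detect_center_entry(traj, arena: ArenaGeometry, after: float = 0.0) -> float | None:
    """First time >= ``after`` strictly inside the trigger circle, else None."""
    if after < 0:
        raise ValueError("after must be >= 0")
    t, xy = _traj_arrays(traj)
    inside = arena.in_trigger(xy) & (t >= after)
    idx = np.flatnonzero(inside)
    return float(t[idx[0]]) if idx.size else None


def detect_refuge_transitions(traj, arena: ArenaGeometry) -> list[tuple[float, float | None]]:
    """Ordered (entry, exit) time pairs for the refuge rectangle.

    Entry is the first frame inside after >= 1 frame outside (or frame 0 if
    the trajectory starts inside); the matching exit is the next frame
    outside, or ``None`` if the animal never leaves again.
    """
    t, xy = _traj_arrays(traj)
    inside = arena.in_refuge(xy)
    pairs: list[tuple[float, float | None]] = []
    padded = np.concatenate([[False], inside, [False]])
    edges = np.flatnonzero(np.diff(padded.astype(int)))
    for i in range(0, len(edges), 2):
        s = int(edges[i])
        e = int(edges[i + 1])
        pairs.append((float(t[s]), float(t[e]) if e < len(t) else None))
    return pairs


@dataclass
class TrialMetrics:
    """The nine trajectory-level defensive metrics of one looming trial."""

    escaped: bool
    responsive_latency: float | None  # s, flight onset - trigger
    return_time: float | None  # s, first refuge entry - trigger
    mean_return_speed: float | None  # cm/s, path length / return time
    refuge_time: float | None  # s, dwell from that entry to the next exit
    center_ratio: float  # time in trigger circle / acclimation duration
    refuge_outside_ratio: float  # refuge / non-refuge time in acclimation (nan if undefined)
    refuge_fraction: float  # refuge / total time in acclimation
    acclimation_mean_speed: float  # cm/s over the acclimation window
    initial_distance: float  # cm, position at trigger -> entrance midpoint

    def __post_init__(self) -> None:
        if not 0.0 <= self.center_ratio <= 1.0:
            raise ValueError("center_ratio must lie in [0, 1]")
        if (
            self.return_time is not None
            and self.responsive_latency is not None
            and self.return_time < self.responsive_latency - 1e-9
        ):
            raise ValueError("return_time cannot precede responsive_latency")


def _path_length(xy: np.ndarray, i0: int, i1: int) -> float:
    """Arc length of the polyline between frames i0 and i1 (inclusive)."""
    if i1 <= i0:
        return 0.0
    seg = np.diff(xy[i0 : i1 + 1], axis=0)
    return float(np.linalg.norm(seg, axis=1).sum())


def compute_trial_metrics(
    traj,
    trigger: float | None,
    flight_onset: float | None,
    transitions: list[tuple[float, float | None]],
    acclimation_window: tuple[float, float],
    arena: ArenaGeometry,
    escape_timeout: float = 30.0,
) -> TrialMetrics:
    """Compute :class:`TrialMetrics` from a trajectory and detected events.

    ``escaped`` requires a flight onset and a refuge entry within
    ``escape_timeout`` seconds of the trigger; the escape-dependent metrics
    (return time, return speed, refuge time) are ``None`` otherwise.
    ``refuge_outside_ratio`` is ``nan`` (a sentinel, not an exception) when
    the animal spent the whole acclimation inside the refuge.
    """
    if trigger is None:
        raise EventError("no stimulus trigger detected; trial metrics undefined")
    t, xy = _traj_arrays(traj)
    a0, a1 = acclimation_window
    if a1 > trigger + 1e-9:
        raise ValueError("acclimation window must precede the trigger")

    trig_idx = int(np.searchsorted(t, trigger - 1e-12))

    # escape chain: first refuge entry at/after the trigger
    entry = exit_ = None
    for s, e in transitions:
        if s >= trigger - 1e-12:
            entry, exit_ = s, e
            break

    responsive_latency = None if flight_onset is None else float(flight_onset - trigger)
    return_time = mean_return_speed = refuge_time = None
    if entry is not None:
        return_time = float(entry - trigger)
        entry_idx = int(np.searchsorted(t, entry - 1e-12))
        if return_time > 0:
            mean_return_speed = _path_length(xy, trig_idx, entry_idx) / return_time
        refuge_end = exit_ if exit_ is not None else float(t[-1])
        refuge_time = float(refuge_end - entry)
    escaped = flight_onset is not None and entry is not None and (entry - trigger) <= escape_timeout
    if not escaped:
        return_time = mean_return_speed = refuge_time = None

    # acclimation-window occupancy
    acc = (t >= a0) & (t < a1)
    n_acc = int(acc.sum())
    if n_acc == 0:
        raise ValueError("empty acclimation window")
    in_center = arena.in_trigger(xy[acc])
    in_ref = arena.in_refuge(xy[acc])
    center_ratio = float(in_center.mean())
    refuge_frames = int(in_ref.sum())
    outside_frames = n_acc - refuge_frames
    refuge_outside_ratio = refuge_frames / outside_frames if outside_frames > 0 else math.nan
    refuge_fraction = refuge_frames / n_acc
    acc_idx = np.flatnonzero(acc)
    duration = float(t[acc_idx[-1]] - t[acc_idx[0]])
    acclimation_mean_speed = (
        _path_length(xy, int(acc_idx[0]), int(acc_idx[-1])) / duration if duration > 0 else 0.0
    )

    initial_distance = float(arena.distance_to_entrance(xy[trig_idx]))
    return TrialMetrics(
        escaped=escaped,
        responsive_latency=responsive_latency,
        return_time=return_time,
        mean_return_speed=mean_return_speed,
        refuge_time=refuge_time,
        center_ratio=center_ratio,
        refuge_outside_ratio=refuge_outside_ratio,
        refuge_fraction=refuge_fraction,
        acclimation_mean_speed=acclimation_mean_speed,
        initial_distance=initial_distance,
    )


def metrics_table(per_animal: dict[str, TrialMetrics]) -> pd.DataFrame:
    """One-row-per-animal metrics table (columns as in the trial figures)."""
    rows = []
    for animal_id, m in per_animal.items():
        rows.append(
            {
                "animal_id": animal_id,
                "escaped": m.escaped,
                "responsive_latency_s": m.responsive_latency,
                "return_time_s": m.return_time,
                "mean_return_speed_cms": m.mean_return_speed,
                "refuge_time_s": m.refuge_time,
                "center_ratio": m.center_ratio,
                "refuge_outside_ratio": m.refuge_outside_ratio,
                "refuge_fraction": m.refuge_fraction,
                "acclimation_mean_speed_cms": m.acclimation_mean_speed,
                "initial_distance_cm": m.initial_distance,
            }
        )
    return pd.DataFrame(rows)
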