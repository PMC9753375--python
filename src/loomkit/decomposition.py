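"""Parallel motion decomposition: locomotion vs non-locomotor movement.

Mammalian behavior mixes locomotion (torso translation, captured by centroid
velocity) with non-locomotor movement (limb/head/organ motion with the torso
in place).  This module splits a skeleton series into those two channels:

* :func:`egocentric_align` removes translation and heading rotation, leaving
  pose features that are invariant to where and which way the animal moved;
* :func:`compute_locomotion` extracts the smoothed centroid speed;
* :func:`segment_nm` cuts the aligned pose stream into short segments — the
  unit of kernel comparison — and :func:`zscore_velocity` normalises the
  per-segment speeds into the locomotion dimension of the behavior map
  (negative z-scores are clipped to zero; only positive normalised velocity
  is used).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import uniform_filter1d

from .errors import AlignmentError
from .skeleton import BODY_AXIS, NECK, TAIL_BASE, SkeletonSeries

#: features per frame: 16 aligned landmarks x 3 coords, plus their deltas
N_FEATURES = 96


@dataclass
class AlignedPose:
    """Egocentrically aligned pose features.

    ``features`` is ``(n_frames, 96)``: the 48 aligned coordinates (centroid
    at the origin, body axis along +x, z unchanged) followed by their
    frame-to-frame deltas (first frame's deltas are zero).
    """

    features: np.ndarray
    heading: np.ndarray
    centroid: np.ndarray
    frame_rate: float
    trial_id: str = ""

    @property
    def n_frames(self) -> int:
        return self.features.shape[0]

    def coords(self) -> np.ndarray:
        """Aligned landmark coordinates, ``(n_frames, 16, 3)``."""
        return self.features[:, :48].reshape(-1, 16, 3)

    def deltas(self) -> np.ndarray:
        """Frame-to-frame landmark displacements, ``(n_frames, 16, 3)``."""
        return self.features[:, 48:].reshape(-1, 16, 3)


@dataclass
class NMSegment:
    """A contiguous block of aligned non-locomotor pose features."""

    start_frame: int
    end_frame: int  # half-open
    features: np.ndarray
    mean_speed: float = 0.0
    trial_id: str = ""

    def __post_init__(self) -> None:
        if self.end_frame <= self.start_frame:
            raise ValueError("end_frame must exceed start_frame")

    @property
    def n_frames(self) -> int:
        return self.end_frame - self.start_frame

    @property
    def segment_id(self) -> str:
        return f"{self.trial_id}:{self.start_frame}-{self.end_frame}"


def egocentric_align(
    series: SkeletonSeries,
    trial_id: str = "",
    delta_smooth: int = 3,
    delta_scale: float = 3.0,
) -> AlignedPose:
    """Remove translation and heading rotation from a skeleton series.

    Per frame: translate the body-axis centroid to the origin and rotate
    about the vertical axis so the tail-base→neck vector points along +x.
    Heights (z) are kept as-is.  Features are the aligned coordinates plus
    frame-to-frame deltas.

    Deltas are computed on coordinates pre-smoothed with a ``delta_smooth``-
    frame boxcar (landmark noise would otherwise swamp sub-centimetre gait
    dynamics) and multiplied by ``delta_scale`` so that pose *dynamics*
    carry weight comparable to static posture in downstream frame
    distances; motifs that share a posture but differ in movement (walking
    vs freezing) are separable only through this block.

    Raises
    ------
    AlignmentError
        If the body axis is degenerate (zero length) in any frame; the
        message names the first offending frame.
    """
    coords = series.coords
    centroid = coords[:, BODY_AXIS, :2].mean(axis=1)
    axis = coords[:, NECK, :2] - coords[:, TAIL_BASE, :2]
    norm = np.linalg.norm(axis, axis=1)
    bad = np.flatnonzero(norm < 1e-8)
    if bad.size:
        raise AlignmentError(f"degenerate body axis (zero length) at frame {int(bad[0])}")
    heading = np.arctan2(axis[:, 1], axis[:, 0])

    rel = coords.copy()
    rel[:, :, :2] -= centroid[:, None, :]
    c, s = np.cos(-heading), np.sin(-heading)
    x, y = rel[:, :, 0].copy(), rel[:, :, 1].copy()
    rel[:, :, 0] = c[:, None] * x - s[:, None] * y
    rel[:, :, 1] = s[:, None] * x + c[:, None] * y

    flat = rel.reshape(len(coords), -1)
    base = flat
    if delta_smooth > 1 and len(flat) > 2:
        base = uniform_filter1d(flat, size=delta_smooth, axis=0, mode="nearest")
    deltas = np.zeros_like(base)
    deltas[1:] = np.diff(base, axis=0)
    features = np.hstack([flat, delta_scale * deltas])
    return AlignedPose(
        features=features,
        heading=heading,
        centroid=centroid,
        frame_rate=series.frame_rate,
        trial_id=trial_id,
    )


def compute_locomotion(series: SkeletonSeries, smooth_window: int = 5) -> np.ndarray:
    """Per-frame centroid speed (cm/s), boxcar-smoothed.

    Uses a centered finite difference of the body-axis centroid (one-sided at
    the edges) followed by a boxcar of ``smooth_window`` frames.  Output
    length equals the frame count.
    """
    if series.n_frames < 2:
        raise ValueError("need at least 2 frames to compute locomotion")
    centroid = series.centroid()
    vel = np.gradient(centroid, axis=0) * series.frame_rate
    speed = np.linalg.norm(vel, axis=1)
    if smooth_window > 1:
        speed = uniform_filter1d(speed, size=smooth_window, mode="nearest")
    return speed


def trajectory_speed(
    xy: np.ndarray,
    frame_rate: float,
    position_window: int = 1,
    speed_window: int = 5,
) -> np.ndarray:
    """Speed of a 2D trajectory with optional position pre-smoothing.

    Position smoothing (a boxcar over ``position_window`` frames) suppresses
    tracking/landmark noise before differentiation, at the cost of blurring
    speed transitions over about half the window; detectors choose the
    trade-off per event type.
    """
    xy = np.asarray(xy, dtype=float)
    if position_window > 1:
        xy = uniform_filter1d(xy, size=position_window, axis=0, mode="nearest")
    vel = np.gradient(xy, axis=0) * frame_rate
    speed = np.linalg.norm(vel, axis=1)
    if speed_window > 1:
        speed = uniform_filter1d(speed, size=speed_window, mode="nearest")
    return speed


def segment_nm(
    aligned: AlignedPose,
    window_frames: int = 12,
    merge_threshold: float = 0.0,
    speeds: np.ndarray | None = None,
) -> list[NMSegment]:
    """Partition an aligned pose stream into fixed-length segments.

    Non-overlapping windows of ``window_frames`` (the last may be shorter)
    that together cover every frame.  When ``merge_threshold > 0``, adjacent
    windows whose mean-feature Euclidean distance falls below the threshold
    are merged.  ``speeds`` (per-frame cm/s, e.g. from
    :func:`compute_locomotion`) fills each segment's ``mean_speed``.
    """
    if window_frames < 2:
        raise ValueError("window_frames must be >= 2")
    n = aligned.n_frames
    bounds = list(range(0, n, window_frames)) + [n]
    windows = [(bounds[i], bounds[i + 1]) for i in range(len(bounds) - 1)]

    if merge_threshold > 0 and len(windows) > 1:
        merged: list[tuple[int, int]] = [windows[0]]
        for s, e in windows[1:]:
            ps, pe = merged[-1]
            prev_mean = aligned.features[ps:pe].mean(axis=0)
            cur_mean = aligned.features[s:e].mean(axis=0)
            if np.linalg.norm(prev_mean - cur_mean) < merge_threshold:
                merged[-1] = (ps, e)
            else:
                merged.append((s, e))
        windows = merged

    segments = []
    for s, e in windows:
        mean_speed = float(np.mean(speeds[s:e])) if speeds is not None else 0.0
        segments.append(
            NMSegment(
                start_frame=s,
                end_frame=e,
                features=aligned.features[s:e],
                mean_speed=mean_speed,
                trial_id=aligned.trial_id,
            )
        )
    return segments


def zscore_velocity(segment_speeds) -> np.ndarray:
    """Z-score segment speeds across the cohort and clip negatives to zero.

    The locomotion dimension of the behavior map; only non-negative
    normalised velocity is used.  A zero-variance input yields all zeros
    with a warning rather than an exception.
    """
    speeds = np.asarray(segment_speeds, dtype=float)
    if speeds.size < 2:
        raise ValueError("need at least 2 segment speeds to z-score")
    sd = speeds.std()
    if sd == 0:
        warnings.warn("segment speeds have zero variance; locomotion set to 0", stacklevel=2)
        return np.zeros_like(speeds)
    z = (speeds - speeds.mean()) / sd
    return np.clip(z, 0.0, None)
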