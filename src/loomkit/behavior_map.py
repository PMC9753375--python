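"""The 3D behavioral feature space and movement phenotypes.

The non-locomotor pose segments are embedded into two dimensions (UMAP1,
UMAP2) from their DTAK dissimilarities, the z-scored (clipped) locomotion
speed supplies the third dimension, and unsupervised clustering of that 3D
space yields movement phenotypes.  Phenotypes are then designated as named
movements through a label mapping; the default table reproduces the
reference 40-phenotype → 12-movement designation.  Two classical defensive
movements — flight and freezing — are detected separately by explicit
kinematic rules, since they are defined by the stimulus context rather than
by pose shape alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import ArenaGeometry, DEFENSIVE_MOVEMENTS, MOVEMENT_VOCABULARY
from .decomposition import NMSegment, trajectory_speed
from .dtak import KernelMatrix
from .errors import AggregationError, EventError, MappingError
from .skeleton import SkeletonSeries


def embed_nm(
    kernel: KernelMatrix,
    n_neighbors: int = 15,
    min_dist: float = 0.1,
    seed: int = 0,
) -> np.ndarray:
    """2D UMAP embedding of the DTAK dissimilarity d = sqrt(2 - 2 k).

    Requires a normalised kernel and at least ``n_neighbors + 1`` segments;
    deterministic given ``seed`` (single-threaded exact mode).
    Returns an ``(S, 2)`` array of (UMAP1, UMAP2) coordinates.
    """
    if not kernel.normalized:
        raise ValueError("embed_nm requires a normalised kernel")
    if kernel.n < n_neighbors + 1:
        raise ValueError(f"need at least n_neighbors+1={n_neighbors + 1} segments, got {kernel.n}")
    import umap  # deferred: numba compilation makes this import expensive

    reducer = umap.UMAP(
        n_components=2,
        n_neighbors=n_neighbors,
        min_dist=min_dist,
        metric="precomputed",
        random_state=seed,
        force_approximation_algorithm=False,
    )
    return np.asarray(reducer.fit_transform(kernel.dissimilarity()), dtype=float)


def build_feature_space(embedding: np.ndarray, loco: np.ndarray) -> np.ndarray:
    """Column-bind (UMAP1, UMAP2, loco) into the 3D behavioral feature space.

    ``loco`` must already be the z-scored, non-negative locomotion values.
    """
    embedding = np.asarray(embedding, dtype=float)
    loco = np.asarray(loco, dtype=float)
    if embedding.ndim != 2 or embedding.shape[1] != 2:
        raise ValueError("embedding must be (S, 2)")
    if loco.shape != (embedding.shape[0],):
        raise ValueError("loco length must match embedding rows")
    if (loco < 0).any():
        raise ValueError("loco values must be non-negative (z-scored and clipped)")
    return np.column_stack([embedding, loco])


def cluster_phenotypes(
    points: np.ndarray,
    k: int = 40,
    method: str = "ward",
    seed: int = 0,
    **kwargs,
) -> np.ndarray:
    """Hard-cluster the 3D feature space into movement phenotypes.

    ``method`` is ``"ward"`` (agglomerative, deterministic; the default),
    ``"kmeans"``, or ``"dbscan"`` (density mode; ``k`` is ignored and noise
    points join the nearest cluster).  Cluster IDs are relabeled 1..k by
    descending cluster size, so phenotype 1 is always the most common.
    """
    points = np.asarray(points, dtype=float)
    S = points.shape[0]
    if method != "dbscan":
        if k < 2:
            raise ValueError("k must be >= 2")
        if S <= k:
            raise ValueError(f"need more points ({S}) than clusters ({k})")
    if method == "ward":
        from sklearn.cluster import AgglomerativeClustering

        raw = AgglomerativeClustering(n_clusters=k, linkage="ward").fit_predict(points)
    elif method == "kmeans":
        from sklearn.cluster import KMeans

        raw = KMeans(n_clusters=k, random_state=seed, n_init=10).fit_predict(points)
    elif method == "dbscan":
        from sklearn.cluster import DBSCAN
        from sklearn.neighbors import NearestNeighbors

        raw = DBSCAN(**kwargs).fit_predict(points)
        if (raw == -1).any():
            core = raw != -1
            if not core.any():
                raise ValueError("dbscan found no clusters; adjust eps/min_samples")
            nn = NearestNeighbors(n_neighbors=1).fit(points[core])
            _, idx = nn.kneighbors(points[~core])
            raw[~core] = raw[core][idx[:, 0]]
    else:
        raise ValueError(f"unknown clustering method {method!r}")

    # relabel by descending size, 1-based
    labels, counts = np.unique(raw, return_counts=True)
    order = labels[np.argsort(-counts, kind="stable")]
    remap = {old: new + 1 for new, old in enumerate(order)}
    return np.array([remap[r] for r in raw], dtype=int)


@dataclass
class LabelMapping:
    """Phenotype-ID → movement-name designation table.

    ``movements`` maps each of the 12 movement names to the phenotype IDs it
    covers; flight and freezing are listed separately as the defensive
    movements (they are detected kinematically, not via phenotypes).
    """

    movements: dict[str, list[int]]
    defensive: tuple[str, ...] = DEFENSIVE_MOVEMENTS

    def __post_init__(self) -> None:
        lookup: dict[int, str] = {}
        for name, ids in self.movements.items():
            if name not in MOVEMENT_VOCABULARY:
                raise MappingError(f"movement name {name!r} not in the 12-name vocabulary")
            for pid in ids:
                if pid in lookup:
                    raise MappingError(f"phenotype {pid} mapped to both {lookup[pid]!r} and {name!r}")
                lookup[pid] = name
        self._lookup = lookup

    def phenotype_ids(self) -> set[int]:
        return set(self._lookup)

    def __getitem__(self, phenotype_id: int) -> str:
        return self._lookup[phenotype_id]

    def to_dict(self) -> dict:
        return {"movements": self.movements, "defensive": list(self.defensive)}

    @classmethod
    def from_dict(cls, d: dict) -> "LabelMapping":
        return cls(movements={k: list(v) for k, v in d["movements"].items()},
                   defensive=tuple(d.get("defensive", DEFENSIVE_MOVEMENTS)))


#: the reference designation of the 40 phenotypes into 12 movements
DEFAULT_LABEL_MAPPING = LabelMapping(
    movements={
        "left turning": [30, 36, 37],
        "right turning": [9, 10, 24, 27, 33, 34],
        "looking up": [3, 4, 11, 12, 17, 25],
        "stretching up": [31],
        "stepping": [26, 39],
        "hunching": [7],
        "sniffing": [8, 18, 32, 38],
        "trotting": [19, 23, 35],
        "running": [1, 2, 21, 28, 29],
        "walking": [5, 6, 20, 22],
        "rearing": [14, 15, 16, 40],
        "grooming": [13],
    }
)


def apply_label_mapping(phenotype_ids, mapping: LabelMapping) -> np.ndarray:
    """Relabel phenotype IDs as movement names; unmapped IDs are an error."""
    ids = np.asarray(phenotype_ids, dtype=int)
    missing = sorted(set(ids.tolist()) - mapping.phenotype_ids())
    if missing:
        raise MappingError(f"phenotype IDs with no movement designation: {missing}")
    return np.array([mapping[i] for i in ids], dtype=object)


@dataclass
class BehaviorMap:
    """Per-segment behavior-space rows: embedding, locomotion, phenotype."""

    umap1: np.ndarray
    umap2: np.ndarray
    loco: np.ndarray
    phenotype_id: np.ndarray
    k: int
    segment_ids: list[str] = field(default_factory=list)
    movement: np.ndarray | None = None

    def __post_init__(self) -> None:
        n = len(self.umap1)
        for name in ("umap2", "loco", "phenotype_id"):
            if len(getattr(self, name)) != n:
                raise ValueError("all BehaviorMap columns must have equal length")
        if (np.asarray(self.loco) < 0).any():
            raise ValueError("loco must be non-negative")
        pid = np.asarray(self.phenotype_id)
        if pid.min() < 1 or pid.max() > self.k:
            raise ValueError("phenotype_id must lie in [1, k]")


@dataclass
class PhenotypeSummary:
    """Mean pose and normalised moving intensity of one phenotype."""

    phenotype_id: int
    mean_pose: np.ndarray  # (16, 3), egocentric cm
    mi: float  # in [0, 1]; max over phenotypes is 1


def compute_moving_intensity(
    segments: list[NMSegment],
    phenotype_ids,
) -> list[PhenotypeSummary]:
    """Normalised moving intensity (MI) and mean skeleton per phenotype.

    MI is the mean per-frame landmark displacement (from the aligned-feature
    deltas) within each phenotype, divided by the maximum over phenotypes,
    so the most vigorous phenotype scores exactly 1.
    """
    ids = np.asarray(phenotype_ids, dtype=int)
    if len(segments) != len(ids):
        raise ValueError("one phenotype id per segment required")
    out: list[PhenotypeSummary] = []
    raw: list[tuple[int, np.ndarray, float]] = []
    for pid in np.unique(ids):
        members = [segments[i] for i in np.flatnonzero(ids == pid)]
        if not members:
            raise AggregationError(f"phenotype {pid} has no segments")
        feats = np.vstack([m.features for m in members])
        coords = feats[:, :48].reshape(-1, 16, 3)
        deltas = feats[:, 48:].reshape(-1, 16, 3)
        disp = float(np.linalg.norm(deltas, axis=2).mean())
        raw.append((int(pid), coords.mean(axis=0), disp))
    max_disp = max(d for _, _, d in raw)
    if max_disp == 0:
        max_disp = 1.0
    for pid, pose, disp in raw:
        out.append(PhenotypeSummary(phenotype_id=pid, mean_pose=pose, mi=disp / max_disp))
    return out


# ---------------------------------------------------------------------------
# defensive-movement detectors
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DefensiveThresholds:
    """Kinematic rules for the two defensive movements (package definitions).

    flight: sustained centroid speed >= ``flight_speed_min`` for at least
    ``flight_min_s`` after stimulus onset, with net displacement toward the
    refuge entrance.  freezing: centroid speed <= ``freeze_speed_max`` and
    mean landmark motion <= ``freeze_pose_max`` for >= ``freeze_min_s``.
    Position smoothing windows control the noise/latency trade-off of each
    speed channel: flight onsets need frame accuracy (light smoothing),
    freezing needs a stable near-zero baseline (heavy smoothing).
    """

    flight_speed_min: float = 20.0  # cm/s
    flight_min_s: float = 0.2
    freeze_speed_max: float = 1.0  # cm/s
    freeze_pose_max: float = 8.0  # mean landmark speed, cm/s
    freeze_min_s: float = 0.5
    flight_pos_window: int = 1
    flight_speed_window: int = 3
    freeze_pos_window: int = 15
    pose_smooth_window: int = 9


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, end) index runs of True values."""
    padded = np.concatenate([[False], mask, [False]])
    edges = np.flatnonzero(np.diff(padded.astype(int)))
    return [(int(edges[i]), int(edges[i + 1])) for i in range(0, len(edges), 2)]


def landmark_motion(series: SkeletonSeries, smooth_window: int = 9) -> np.ndarray:
    """Mean landmark speed per frame (cm/s) after position smoothing."""
    from scipy.ndimage import uniform_filter1d

    coords = series.coords
    if smooth_window > 1:
        coords = uniform_filter1d(coords, size=smooth_window, axis=0, mode="nearest")
    disp = np.zeros(series.n_frames)
    step = np.linalg.norm(np.diff(coords, axis=0), axis=2).mean(axis=1)
    disp[1:] = step * series.frame_rate
    disp[0] = disp[1] if series.n_frames > 1 else 0.0
    return disp


def detect_defensive(
    series: SkeletonSeries | None,
    trajectory,
    stimulus_onset: float | None,
    arena: ArenaGeometry,
    thresholds: DefensiveThresholds = DefensiveThresholds(),
) -> tuple[tuple[float, float] | None, list[tuple[float, float]]]:
    """Detect the flight interval and freezing bouts of a trial.

    Parameters
    ----------
    series
        Noisy skeleton series; may be ``None``, in which case the freezing
        pose criterion is skipped (trajectory-only mode).
    trajectory
        DataFrame with ``t_s, x_cm, y_cm`` or an ``(n, 2)`` array (frames at
        the series frame rate).
    stimulus_onset
        Stimulus time in seconds; required (:class:`EventError` if ``None``).

    Returns
    -------
    (flight, freezing_bouts)
        ``flight`` is a half-open ``(start_s, end_s)`` interval or ``None``;
        ``freezing_bouts`` is a list of half-open intervals in seconds.
    """
    if stimulus_onset is None:
        raise EventError("stimulus onset is required for defensive detection")
    th = thresholds
    if hasattr(trajectory, "columns"):
        xy = trajectory[["x_cm", "y_cm"]].to_numpy()
        t = trajectory["t_s"].to_numpy()
        frame_rate = 1.0 / float(np.median(np.diff(t))) if len(t) > 1 else 30.0
    else:
        xy = np.asarray(trajectory, dtype=float)
        frame_rate = series.frame_rate if series is not None else 30.0
    n = xy.shape[0]
    dt = 1.0 / frame_rate
    onset_frame = int(round(stimulus_onset * frame_rate))

    # ---- flight: fast channel -------------------------------------------
    speed_fast = trajectory_speed(
        xy, frame_rate, position_window=th.flight_pos_window, speed_window=th.flight_speed_window
    )
    flight = None
    mask = speed_fast >= th.flight_speed_min
    mask[:onset_frame] = False
    min_frames = max(int(round(th.flight_min_s * frame_rate)), 1)
    for s, e in _runs(mask):
        if e - s < min_frames:
            continue
        d_start = float(arena.distance_to_entrance(xy[s]))
        d_end = float(arena.distance_to_entrance(xy[e - 1]))
        if d_end < d_start:  # net displacement toward the refuge
            flight = (s * dt, e * dt)
            break

    # ---- freezing: slow channel -----------------------------------------
    speed_slow = trajectory_speed(xy, frame_rate, position_window=th.freeze_pos_window, speed_window=1)
    quiet = speed_slow <= th.freeze_speed_max
    if series is not None:
        pose_motion = landmark_motion(series, smooth_window=th.pose_smooth_window)
        if len(pose_motion) == n:
            quiet &= pose_motion <= th.freeze_pose_max
    # bout edges found on the smoothed channel are blurred by ~half the
    # position window; refine them against the raw speed so durations are
    # accurate to a frame or two
    speed_raw = trajectory_speed(xy, frame_rate, position_window=1, speed_window=1)
    quiet_raw = speed_raw <= th.freeze_speed_max
    min_freeze = max(int(round(th.freeze_min_s * frame_rate)), 1)
    freezing = []
    prev_end = 0
    for s, e in _runs(quiet):
        while s > prev_end and quiet_raw[s - 1]:
            s -= 1
        while s < e and not quiet_raw[s]:
            s += 1
        while e < n and quiet_raw[e]:
            e += 1
        while e > s and not quiet_raw[e - 1]:
            e -= 1
        if e - s >= min_freeze and (not freezing or s * dt >= freezing[-1][1]):
            freezing.append((s * dt, e * dt))
            prev_end = e
    return flight, freezing
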