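"""Dynamic time alignment kernel (DTAK) between pose segments.

DTAK scores the similarity of two variable-length multivariate time series
by dynamic programming over monotone frame alignments.  With a Gaussian
local kernel kappa(x, y) = exp(-||x-y||^2 / (2 sigma^2)), the table is

    G(1,1) = 2 kappa(x1, y1)
    G(i,j) = max( G(i-1,j)   +   kappa(xi, yj),
                  G(i-1,j-1) + 2 kappa(xi, yj),
                  G(i,j-1)   +   kappa(xi, yj) )

and the kernel value is G(n,m)/(n+m), so a perfect diagonal self-alignment
scores exactly 1.  This is the canonical max-formulation with diagonal
weight 2 and path-length normalisation; segments of unequal length are
compared directly without resampling.

DTAK matrices are not guaranteed positive semidefinite, so downstream
embedding works on the dissimilarity d = sqrt(2 - 2 k) of the normalised
kernel rather than on an eigendecomposition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist, pdist

from .decomposition import NMSegment


def _as_matrix(seg) -> np.ndarray:
    feats = seg.features if isinstance(seg, NMSegment) else np.asarray(seg, dtype=float)
    feats = np.atleast_2d(feats)
    if feats.size == 0:
        raise ValueError("empty segment")
    return feats


def local_kernel(frame_a: np.ndarray, frame_b: np.ndarray, sigma: float) -> float:
    """Gaussian frame similarity exp(-||a-b||^2 / (2 sigma^2)), in (0, 1]."""
    a = np.asarray(frame_a, dtype=float)
    b = np.asarray(frame_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"feature dimension mismatch: {a.shape} vs {b.shape}")
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    d2 = float(np.sum((a - b) ** 2))
    return float(np.exp(-d2 / (2.0 * sigma**2)))


def _dp(K: np.ndarray) -> float:
    """Run the DTAK recursion on a precomputed local-kernel table."""
    n, m = K.shape
    G = np.empty((n, m))
    G[0, 0] = 2.0 * K[0, 0]
    for j in range(1, m):
        G[0, j] = G[0, j - 1] + K[0, j]
    for i in range(1, n):
        G[i, 0] = G[i - 1, 0] + K[i, 0]
        row = G[i]
        prev = G[i - 1]
        Ki = K[i]
        for j in range(1, m):
            k = Ki[j]
            row[j] = max(prev[j] + k, prev[j - 1] + 2.0 * k, row[j - 1] + k)
    return float(G[n - 1, m - 1] / (n + m))


def _local_table(X: np.ndarray, Y: np.ndarray, sigma: float) -> np.ndarray:
    d2 = cdist(X, Y, metric="sqeuclidean")
    return np.exp(-d2 / (2.0 * sigma**2))


def dtak(X, Y, sigma: float) -> float:
    """Unnormalised DTAK value G(n,m)/(n+m) between two segments."""
    Xm, Ym = _as_matrix(X), _as_matrix(Y)
    if Xm.shape[1] != Ym.shape[1]:
        raise ValueError("segments must share a feature dimension")
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    return _dp(_local_table(Xm, Ym, sigma))


def dtak_normalized(X, Y, sigma: float) -> float:
    """Cosine-normalised DTAK: k(X,Y) / sqrt(k(X,X) k(Y,Y)); 1 for X = Y."""
    kxy = dtak(X, Y, sigma)
    kxx = dtak(X, X, sigma)
    kyy = dtak(Y, Y, sigma)
    return kxy / np.sqrt(kxx * kyy)


def median_sigma(segments, rng: np.random.Generator | None = None, max_frames: int = 500) -> float:
    """Median heuristic bandwidth: median pairwise frame-feature distance.

    Computed over a subsample of at most ``max_frames`` frames pooled from
    all segments.
    """
    frames = np.vstack([_as_matrix(s) for s in segments])
    if frames.shape[0] > max_frames:
        rng = rng or np.random.default_rng(0)
        idx = rng.choice(frames.shape[0], size=max_frames, replace=False)
        frames = frames[idx]
    d = pdist(frames)
    d = d[d > 0]
    if d.size == 0:
        return 1.0
    return float(np.median(d))


@dataclass
class KernelMatrix:
    """Pairwise DTAK similarities over a segment list."""

    values: np.ndarray
    segment_ids: list[str]
    sigma: float
    normalized: bool

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("kernel matrix must be square")
        if not np.allclose(v, v.T, atol=1e-10):
            raise ValueError("kernel matrix must be symmetric")
        if self.normalized and not np.allclose(np.diag(v), 1.0, atol=1e-10):
            raise ValueError("normalized kernel must have unit diagonal")
        if not (v > 0).all():
            raise ValueError("kernel values must be positive")
        self.values = v

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def dissimilarity(self) -> np.ndarray:
        """d = sqrt(2 - 2 k), zero on the diagonal for a normalised kernel."""
        return np.sqrt(np.clip(2.0 - 2.0 * self.values, 0.0, None))


def kernel_matrix(segments, sigma: float | None = None, normalized: bool = True) -> KernelMatrix:
    """All pairwise DTAK values over a segment list.

    ``sigma=None`` selects the median-heuristic bandwidth.  Each pair is
    computed once and mirrored, so the result is exactly symmetric; with
    ``normalized=True`` the diagonal is exactly 1.
    """
    if len(segments) < 2:
        raise ValueError("need at least 2 segments")
    mats = [_as_matrix(s) for s in segments]
    if sigma is None:
        sigma = median_sigma(mats)
    S = len(mats)
    raw_self = np.array([_dp(_local_table(m, m, sigma)) for m in mats])
    values = np.empty((S, S))
    for i in range(S):
        values[i, i] = 1.0 if normalized else raw_self[i]
        for j in range(i + 1, S):
            v = _dp(_local_table(mats[i], mats[j], sigma))
            if normalized:
                v = v / np.sqrt(raw_self[i] * raw_self[j])
            values[i, j] = values[j, i] = v
    ids = [s.segment_id if isinstance(s, NMSegment) else f"seg{i}" for i, s in enumerate(segments)]
    return KernelMatrix(values=values, segment_ids=ids, sigma=float(sigma), normalized=normalized)
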