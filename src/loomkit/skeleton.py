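"""The 16-landmark skeleton container.

loomkit fixes a 16-point landmark roster (the upstream pose-estimation step is
out of scope, so the roster is a package convention, not a measured one):

==  ===================  =========================================
 #  name                 description
==  ===================  =========================================
 0  nose                 tip of the snout
 1  left_ear             left ear base
 2  right_ear            right ear base
 3  neck                 base of the skull / start of the spine
 4  spine1               anterior trunk
 5  spine2               mid trunk
 6  spine3               posterior trunk
 7  tail_base            root of the tail
 8  left_front_limb      left shoulder/elbow point
 9  right_front_limb     right shoulder/elbow point
10  left_hind_limb       left hip/knee point
11  right_hind_limb      right hip/knee point
12  left_front_paw       left fore paw
13  right_front_paw      right fore paw
14  left_hind_paw        left hind paw
15  right_hind_paw       right hind paw
==  ===================  =========================================

Coordinates are centimetres; x/y span the horizontal arena plane and z is
height above the floor.  The body-axis landmarks (neck, spine1-3, tail_base)
define the animal's centroid and heading; limbs and head move relative to
that axis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

LANDMARKS: tuple[str, ...] = (
    "nose",
    "left_ear",
    "right_ear",
    "neck",
    "spine1",
    "spine2",
    "spine3",
    "tail_base",
    "left_front_limb",
    "right_front_limb",
    "left_hind_limb",
    "right_hind_limb",
    "left_front_paw",
    "right_front_paw",
    "left_hind_paw",
    "right_hind_paw",
)

N_LANDMARKS = len(LANDMARKS)

#: indices of the torso landmarks used for centroid and heading
BODY_AXIS = tuple(LANDMARKS.index(n) for n in ("neck", "spine1", "spine2", "spine3", "tail_base"))
NOSE = LANDMARKS.index("nose")
NECK = LANDMARKS.index("neck")
TAIL_BASE = LANDMARKS.index("tail_base")


@dataclass
class SkeletonSeries:
    """Per-frame 3D coordinates of the 16 landmarks for one animal.

    Parameters
    ----------
    coords
        Array of shape ``(n_frames, 16, 3)``, centimetres.
    frame_rate
        Capture rate in Hz (> 0).
    landmark_names
        Ordered landmark roster; defaults to :data:`LANDMARKS`.
    animal_id, sex
        Trial metadata; ``sex`` is ``male``, ``female`` or ``unspecified``.
    """

    coords: np.ndarray
    frame_rate: float
    landmark_names: tuple[str, ...] = LANDMARKS
    animal_id: str = ""
    sex: str = "unspecified"

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[1] != N_LANDMARKS or self.coords.shape[2] != 3:
            raise ValueError(
                f"coords must have shape (n_frames, {N_LANDMARKS}, 3), got {self.coords.shape}"
            )
        if len(self.landmark_names) != N_LANDMARKS:
            raise ValueError(f"expected {N_LANDMARKS} landmark names")
        if not np.isfinite(self.coords).all():
            raise ValueError("coords contain missing/non-finite values")
        if not self.frame_rate > 0:
            raise ValueError("frame_rate must be positive")
        if self.sex not in ("male", "female", "unspecified"):
            raise ValueError(f"invalid sex {self.sex!r}")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def times(self) -> np.ndarray:
        """Frame timestamps in seconds (frame 0 at t = 0)."""
        return np.arange(self.n_frames) / self.frame_rate

    def centroid(self) -> np.ndarray:
        """``(n_frames, 2)`` horizontal centroid: mean of the body-axis landmarks."""
        return self.coords[:, BODY_AXIS, :2].mean(axis=1)

    def slice(self, start: int, stop: int) -> "SkeletonSeries":
        """Sub-series over the half-open frame interval [start, stop)."""
        return SkeletonSeries(
            coords=self.coords[start:stop],
            frame_rate=self.frame_rate,
            landmark_names=self.landmark_names,
            animal_id=self.animal_id,
            sex=self.sex,
        )
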