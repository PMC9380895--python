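"""Skeleton schema and core sequence containers.

The keypoint layout follows the OpenPose BODY_25 convention: 25 body
keypoints per frame, each with pixel coordinates (x, y) and an optional
detection confidence in [0, 1].  MidHip (index 8) serves as the origin of
the body-centred coordinate system used throughout feature construction,
and is removed once sequences are translated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: BODY_25 keypoint index -> label.
BODY_25_LABELS: dict[int, str] = {
    0: "Nose", 1: "Neck", 2: "RShoulder", 3: "RElbow", 4: "RWrist",
    5: "LShoulder", 6: "LElbow", 7: "LWrist", 8: "MidHip", 9: "RHip",
    10: "RKnee", 11: "RAnkle", 12: "LHip", 13: "LKnee", 14: "LAnkle",
    15: "REye", 16: "LEye", 17: "REar", 18: "LEar", 19: "LBigToe",
    20: "LSmallToe", 21: "LHeel", 22: "RBigToe", 23: "RSmallToe", 24: "RHeel",
}

N_KEYPOINTS = 25
MIDHIP = 8
#: The 24 keypoints that survive translation to the MidHip origin.
KEYPOINTS_24: tuple[int, ...] = tuple(i for i in range(N_KEYPOINTS) if i != MIDHIP)

DEFAULT_FRAME_COUNT = 75


class GaitError(ValueError):
    """Base class for gait-pipeline input errors."""


class SchemaError(GaitError):
    """Input does not conform to the BODY_25 / file-format contract."""


class InsufficientFramesError(GaitError):
    """Sequence has fewer frames than the analysis window requires."""


class UnrecoverableTrackError(GaitError):
    """A keypoint is invalid in every frame and cannot be interpolated."""


@dataclass
class GaitSequence:
    """A per-subject sequence of BODY_25 skeleton frames in image coordinates.

    Attributes
    ----------
    subject_id : str
        Identifier of the walker.
    xy : ndarray of shape (n_frames, 25, 2)
        Pixel coordinates, frame-major, BODY_25 keypoint order.
    confidence : ndarray of shape (n_frames, 25), optional
        Per-keypoint detection confidence in [0, 1]; ``None`` when the
        source format carries no confidence.
    """

    subject_id: str
    xy: np.ndarray
    confidence: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.xy = np.asarray(self.xy, dtype=float)
        if self.xy.ndim != 3 or self.xy.shape[1:] != (N_KEYPOINTS, 2):
            raise SchemaError(
                f"expected coordinates of shape (n_frames, {N_KEYPOINTS}, 2), "
                f"got {self.xy.shape}"
            )
        if self.xy.shape[0] < 1:
            raise SchemaError("a gait sequence needs at least one frame")
        if self.confidence is not None:
            self.confidence = np.asarray(self.confidence, dtype=float)
            if self.confidence.shape != self.xy.shape[:2]:
                raise SchemaError(
                    f"confidence shape {self.confidence.shape} does not match "
                    f"frame layout {self.xy.shape[:2]}"
                )

    @property
    def n_frames(self) -> int:
        return self.xy.shape[0]

    @property
    def frame_indices(self) -> np.ndarray:
        """1-based frame numbers."""
        return np.arange(1, self.n_frames + 1)


@dataclass
class TranslatedSequence:
    """A gait sequence in MidHip-origin coordinates, MidHip removed.

    ``xy`` holds 24 keypoints per frame in :data:`KEYPOINTS_24` order
    (BODY_25 indices 0..24 with 8 skipped).  ``frame_indices`` keeps the
    1-based frame numbers of the source sequence so odd/even splits retain
    their provenance.
    """

    subject_id: str
    xy: np.ndarray
    frame_indices: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.xy = np.asarray(self.xy, dtype=float)
        if self.xy.ndim != 3 or self.xy.shape[1:] != (len(KEYPOINTS_24), 2):
            raise SchemaError(
                f"expected shape (n_frames, {len(KEYPOINTS_24)}, 2), got {self.xy.shape}"
            )
        if self.frame_indices is None:
            self.frame_indices = np.arange(1, self.xy.shape[0] + 1)
        else:
            self.frame_indices = np.asarray(self.frame_indices, dtype=int)
            if self.frame_indices.shape != (self.xy.shape[0],):
                raise SchemaError("frame_indices length must equal the frame count")
        if not np.all(np.isfinite(self.xy)):
            raise SchemaError("translated coordinates must be finite")

    @property
    def n_frames(self) -> int:
        return self.xy.shape[0]

    def series(self, keypoint: int, axis: int) -> np.ndarray:
        """Coordinate series of one keypoint (BODY_25 index) along one axis."""
        if keypoint == MIDHIP:
            raise KeyError("MidHip is the coordinate origin and was eliminated")
        return self.xy[:, KEYPOINTS_24.index(keypoint), axis]
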