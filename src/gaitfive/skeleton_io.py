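"""Read, write and window BODY_25 keypoint sequences.

Two on-disk dialects are supported: a directory of OpenPose per-frame JSON
files (``people[i].pose_keypoints_2d`` as 75 floats, x/y/confidence per
keypoint) and a flat CSV with columns ``frame,keypoint,x,y[,confidence]``
(1-based frames, 0-based keypoint indices).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .schema import (
    DEFAULT_FRAME_COUNT,
    N_KEYPOINTS,
    GaitSequence,
    InsufficientFramesError,
    SchemaError,
    UnrecoverableTrackError,
)

DEFAULT_CONF_THRESHOLD = 0.1


def read_openpose_frames(path: str | Path, subject_id: str | None = None) -> GaitSequence:
    """Load a directory of OpenPose BODY_25 JSON files, one file per frame.

    Files are consumed in lexicographic order.  When a frame contains
    several detected people, the entry with the highest summed keypoint
    confidence is kept (one walker per video is assumed).
    """
    path = Path(path)
    files = sorted(p for p in path.iterdir() if p.suffix == ".json")
    if not files:
        raise SchemaError(f"no JSON frame files found in {path}")
    xy = np.empty((len(files), N_KEYPOINTS, 2))
    conf = np.empty((len(files), N_KEYPOINTS))
    for t, fp in enumerate(files):
        try:
            payload = json.loads(fp.read_text())
        except json.JSONDecodeError as exc:
            raise SchemaError(f"malformed JSON in {fp}: {exc}") from exc
        people = payload.get("people", [])
        if not people:
            raise SchemaError(f"no people detected in {fp}")
        best = None
        best_score = -np.inf
        for person in people:
            kp = np.asarray(person.get("pose_keypoints_2d", []), dtype=float)
            if kp.size != 3 * N_KEYPOINTS:
                raise SchemaError(
                    f"{fp}: pose_keypoints_2d has {kp.size} floats, "
                    f"expected {3 * N_KEYPOINTS} (x,y,confidence x {N_KEYPOINTS})"
                )
            score = kp[2::3].sum()
            if score > best_score:
                best, best_score = kp.reshape(N_KEYPOINTS, 3), score
        xy[t] = best[:, :2]
        conf[t] = best[:, 2]
    return GaitSequence(subject_id or path.name, xy, conf)


def read_keypoint_csv(path: str | Path, subject_id: str | None = None) -> GaitSequence:
    """Load a ``frame,keypoint,x,y[,confidence]`` CSV into a sequence."""
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    required = {"frame", "keypoint", "x", "y"}
    if not required.issubset(df.columns):
        raise SchemaError(f"{path}: missing columns {sorted(required - set(df.columns))}")
    for col in ("x", "y"):
        if not np.issubdtype(df[col].dtype, np.number):
            raise SchemaError(f"{path}: non-numeric values in column {col!r}")
    frames = sorted(df["frame"].unique())
    n = len(frames)
    xy = np.full((n, N_KEYPOINTS, 2), np.nan)
    has_conf = "confidence" in df.columns
    conf = np.full((n, N_KEYPOINTS), np.nan) if has_conf else None
    frame_pos = {f: t for t, f in enumerate(frames)}
    for f, group in df.groupby("frame"):
        kps = set(group["keypoint"].astype(int))
        missing = sorted(set(range(N_KEYPOINTS)) - kps)
        if missing:
            raise SchemaError(f"{path}: frame {f} is missing keypoint(s) {missing}")
        t = frame_pos[f]
        idx = group["keypoint"].to_numpy(dtype=int)
        xy[t, idx, 0] = group["x"].to_numpy(dtype=float)
        xy[t, idx, 1] = group["y"].to_numpy(dtype=float)
        if has_conf:
            conf[t, idx] = group["confidence"].to_numpy(dtype=float)
    return GaitSequence(subject_id or path.stem, xy, conf)


def write_sequence(seq: GaitSequence, path: str | Path) -> None:
    """Write a sequence as a keypoint CSV; round-trips coordinates exactly."""
    path = Path(path)
    n, k = seq.xy.shape[:2]
    frame = np.repeat(np.arange(1, n + 1), k)
    keypoint = np.tile(np.arange(k), n)
    data = {
        "frame": frame,
        "keypoint": keypoint,
        "x": seq.xy[:, :, 0].ravel(),
        "y": seq.xy[:, :, 1].ravel(),
    }
    if seq.confidence is not None:
        data["confidence"] = seq.confidence.ravel()
    # repr-precision floats so read_keypoint_csv restores them bit-exactly
    pd.DataFrame(data).to_csv(path, index=False, float_format=None)


def interpolate_missing(
    seq: GaitSequence, conf_threshold: float = DEFAULT_CONF_THRESHOLD
) -> GaitSequence:
    """Fill dropped keypoint detections by linear interpolation over frames.

    A sample is invalid when its confidence falls below ``conf_threshold``
    or when it is the OpenPose null detection (0, 0) with zero confidence.
    Interior gaps are linearly interpolated per coordinate; runs at either
    end copy the nearest valid value.  Valid samples are never altered.
    """
    xy = seq.xy.copy()
    if seq.confidence is None:
        conf = np.ones(xy.shape[:2])
    else:
        conf = seq.confidence
    null_det = (xy[:, :, 0] == 0) & (xy[:, :, 1] == 0) & (conf == 0)
    valid = (conf >= conf_threshold) & ~null_det
    t = np.arange(xy.shape[0])
    for k in range(xy.shape[1]):
        mask = valid[:, k]
        if mask.all():
            continue
        if not mask.any():
            raise UnrecoverableTrackError(
                f"keypoint {k} has no valid detection in any frame"
            )
        for axis in (0, 1):
            xy[~mask, k, axis] = np.interp(t[~mask], t[mask], xy[mask, k, axis])
    new_conf = None if seq.confidence is None else np.where(valid, conf, conf_threshold)
    return GaitSequence(seq.subject_id, xy, new_conf)


def unify_frames(seq: GaitSequence, n: int = DEFAULT_FRAME_COUNT) -> GaitSequence:
    """Crop a sequence to a contiguous window of exactly ``n`` frames.

    The window with the highest mean keypoint confidence is kept (earliest
    window on ties); sequences shorter than ``n`` are rejected rather than
    resampled, so the temporal sampling downstream features assume is
    preserved.
    """
    total = seq.n_frames
    if total < n:
        raise InsufficientFramesError(
            f"sequence has {total} frames, need at least {n}"
        )
    if seq.confidence is None:
        start = 0
    else:
        frame_conf = seq.confidence.mean(axis=1)
        csum = np.concatenate([[0.0], np.cumsum(frame_conf)])
        window_means = (csum[n:] - csum[:-n]) / n
        start = int(np.argmax(np.round(window_means, 12)))  # ties -> earliest
    stop = start + n
    conf = None if seq.confidence is None else seq.confidence[start:stop]
    return GaitSequence(seq.subject_id, seq.xy[start:stop], conf)
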