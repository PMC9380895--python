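"""Body-centred coordinates, smoothing, and odd/even frame splitting.

Translation re-expresses every keypoint relative to MidHip per frame
(x'_i = x_i - x_8, y'_i = y_i - y_8), removing global position and leaving
the periodic limb motion; MidHip itself becomes the origin and is dropped.
Smoothing applies the binomial kernel [1, 4, 6, 4, 1]/16 along frames to
suppress high-frequency jitter from the pose estimator.
"""

from __future__ import annotations

import numpy as np
from scipy.ndimage import convolve1d

from .schema import (
    KEYPOINTS_24,
    MIDHIP,
    GaitError,
    GaitSequence,
    TranslatedSequence,
)

SMOOTHING_KERNEL = np.array([1.0, 4.0, 6.0, 4.0, 1.0]) / 16.0


def translate_to_midhip(seq: GaitSequence) -> TranslatedSequence:
    """Shift every frame so MidHip is the origin, then drop MidHip."""
    origin = seq.xy[:, MIDHIP : MIDHIP + 1, :]
    shifted = seq.xy - origin
    kept = shifted[:, list(KEYPOINTS_24), :]
    return TranslatedSequence(seq.subject_id, kept, seq.frame_indices)


def smooth_series(series: np.ndarray) -> np.ndarray:
    """Smooth one coordinate series with the 5-tap binomial kernel.

    Boundaries use symmetric (reflect) extension, so output length equals
    input length and constant series pass through unchanged.
    """
    series = np.asarray(series, dtype=float)
    if series.ndim != 1:
        raise GaitError("smooth_series expects a one-dimensional series")
    if series.size < 5:
        raise GaitError(f"series of length {series.size} is too short to smooth (need >= 5)")
    return convolve1d(series, SMOOTHING_KERNEL, mode="reflect")


def smooth_sequence(seq: TranslatedSequence) -> TranslatedSequence:
    """Smooth all 48 coordinate series (24 keypoints x two axes) independently."""
    if seq.n_frames < 5:
        raise GaitError("need at least 5 frames to smooth")
    smoothed = convolve1d(seq.xy, SMOOTHING_KERNEL, axis=0, mode="reflect")
    return TranslatedSequence(seq.subject_id, smoothed, seq.frame_indices)


def split_odd_even(seq: TranslatedSequence) -> tuple[TranslatedSequence, TranslatedSequence]:
    """Split a 75-frame sequence into odd and even halves of the first 74 frames.

    Frame numbering is 1-based: the odd half is frames 1, 3, ..., 73 and the
    even half frames 2, 4, ..., 74 (37 frames each); frame 75 is unused.
    """
    if seq.n_frames != 75:
        raise GaitError(f"odd/even split requires exactly 75 frames, got {seq.n_frames}")
    odd_pos = np.arange(0, 74, 2)   # frames 1,3,...,73
    even_pos = np.arange(1, 74, 2)  # frames 2,4,...,74
    odd = TranslatedSequence(seq.subject_id, seq.xy[odd_pos], seq.frame_indices[odd_pos])
    even = TranslatedSequence(seq.subject_id, seq.xy[even_pos], seq.frame_indices[even_pos])
    return odd, even


def preprocess_sequence(seq: GaitSequence, smooth: bool = True) -> TranslatedSequence:
    """Convenience composition: translate to MidHip origin, then smooth."""
    translated = translate_to_midhip(seq)
    return smooth_sequence(translated) if smooth else translated
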