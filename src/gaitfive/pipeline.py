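"""End-to-end composition helpers: raw sequences to per-stream feature tables."""

from __future__ import annotations

from typing import Iterable

import pandas as pd

from .features import extract_feature_vector
from .preprocess import preprocess_sequence, split_odd_even
from .schema import DEFAULT_FRAME_COUNT, GaitSequence, TranslatedSequence
from .skeleton_io import DEFAULT_CONF_THRESHOLD, interpolate_missing, unify_frames


def prepare_sequence(
    seq: GaitSequence,
    n_frames: int = DEFAULT_FRAME_COUNT,
    conf_threshold: float = DEFAULT_CONF_THRESHOLD,
    smooth: bool = True,
) -> TranslatedSequence:
    """Interpolate drops, window to ``n_frames``, translate and smooth."""
    seq = interpolate_missing(seq, conf_threshold=conf_threshold)
    seq = unify_frames(seq, n=n_frames)
    return preprocess_sequence(seq, smooth=smooth)


def feature_streams(
    sequences: Iterable[GaitSequence],
    conf_threshold: float = DEFAULT_CONF_THRESHOLD,
    smooth: bool = True,
    halves: bool = True,
) -> dict[str, pd.DataFrame]:
    """Per-stream feature matrices for a cohort.

    Returns a mapping of stream name (``all`` and, when ``halves``,
    ``odd``/``even``) to a DataFrame indexed by subject_id with the 2472
    feature columns, rows aligned across streams.
    """
    rows: dict[str, dict[str, pd.Series]] = {"all": {}}
    if halves:
        rows["odd"] = {}
        rows["even"] = {}
    for seq in sequences:
        prepared = prepare_sequence(seq, conf_threshold=conf_threshold, smooth=smooth)
        rows["all"][seq.subject_id] = extract_feature_vector(prepared)
        if halves:
            odd, even = split_odd_even(prepared)
            rows["odd"][seq.subject_id] = extract_feature_vector(odd)
            rows["even"][seq.subject_id] = extract_feature_vector(even)
    subject_ids = list(rows["all"])
    return {
        stream: pd.DataFrame([per_subj[s] for s in subject_ids], index=subject_ids)
        for stream, per_subj in rows.items()
    }
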