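"""Time-frequency gait feature construction.

From a translated, smoothed sequence the feature data pool collects 132
named time series:

* 48 coordinate series ``coord_<k>_<axis>`` (24 keypoints x x/y),
* 48 forward interframe-difference series ``diff_<k>_<axis>``,
* 26 axis-wise joint distance series ``dist_<a>_<b>_<axis>`` (13 pairs),
* 10 joint angle series ``angle_<a>_<b>_<c>`` (degrees at the middle joint),

plus, for each coordinate series, a 5-level haar wavelet decomposition into
detail bands D1..D5 and approximation A5.

Ten time-domain statistics over each of the 132 series give 1320 features;
four statistics over each of the 48 x 6 wavelet coefficient arrays give
1152 frequency-domain features, for a fixed 2472-dimensional vector whose
names and order are identical for full (75-frame) and half (37-frame)
inputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import pywt

from .schema import KEYPOINTS_24, GaitError, TranslatedSequence

logger = logging.getLogger(__name__)

AXES = ("x", "y")

#: Joint pairs whose axis-wise separations describe limb swing, head swing
#: and stride (label pairs (a, b) -> series dist_a_b_x / dist_a_b_y).
DISTANCE_PAIRS: tuple[tuple[int, int], ...] = (
    (1, 0),    # head swing
    (3, 2),    # upper arm swing (right)
    (4, 2),    # arm swing (right)
    (6, 5),    # upper arm swing (left)
    (7, 5),    # arm swing (left)
    (6, 3),    # relative swing of both elbows
    (7, 4),    # relative swing of both hands
    (10, 9),   # thigh swing (right)
    (11, 9),   # leg swing (right)
    (13, 12),  # thigh swing (left)
    (14, 12),  # leg swing (left)
    (13, 10),  # relative swing of both knees
    (14, 11),  # relative swing of both feet
)

#: Joint triples (a, b, c): the angle is at vertex b between rays b->a, b->c.
ANGLE_TRIPLES: tuple[tuple[int, int, int], ...] = (
    (0, 1, 2),     # neck angle (right)
    (0, 1, 5),     # neck angle (left)
    (1, 2, 3),     # shoulder angle (right)
    (1, 5, 6),     # shoulder angle (left)
    (2, 3, 4),     # elbow angle (right)
    (5, 6, 7),     # elbow angle (left)
    (12, 9, 10),   # hip angle (right)
    (9, 12, 13),   # hip angle (left)
    (9, 10, 11),   # knee angle (right)
    (12, 13, 14),  # knee angle (left)
)

WAVELET = "haar"
WAVELET_LEVEL = 5
WAVELET_MODE = "symmetric"
MIN_WAVELET_LENGTH = 2 ** WAVELET_LEVEL
WAVELET_BANDS = ("D1", "D2", "D3", "D4", "D5", "A5")

TIME_DOMAIN_FUNCTIONS = (
    "maximum", "minimum", "mean", "median", "variance",
    "root_mean_square", "skewness", "kurtosis", "abs_energy",
    "variation_coefficient",
)
FREQUENCY_DOMAIN_STATS = ("abs_max", "mean", "variance", "abs_energy")

N_TIME_SERIES = 132
N_TIME_FEATURES = 1320
N_FREQ_FEATURES = 1152
N_FEATURES = N_TIME_FEATURES + N_FREQ_FEATURES


# ---------------------------------------------------------------------------
# series construction
# ---------------------------------------------------------------------------

def interframe_difference(series: np.ndarray) -> np.ndarray:
    """Forward difference Δf_j = f_{j+1} - f_j (length n-1)."""
    series = np.asarray(series, dtype=float)
    if series.size < 2:
        raise GaitError("interframe difference needs at least 2 frames")
    return np.diff(series)


def coordinate_series(seq: TranslatedSequence) -> dict[str, np.ndarray]:
    """The 48 named coordinate series in canonical order."""
    out: dict[str, np.ndarray] = {}
    for k in KEYPOINTS_24:
        for a, axis in enumerate(AXES):
            out[f"coord_{k}_{axis}"] = seq.series(k, a)
    return out


def joint_distance_series(
    seq: TranslatedSequence, signed: bool = False
) -> dict[str, np.ndarray]:
    """Axis-wise distances for the 13 joint pairs (26 series).

    Distances are absolute separations by default — swings are magnitudes;
    ``signed=True`` keeps the raw coordinate differences instead.
    """
    out: dict[str, np.ndarray] = {}
    for a, b in DISTANCE_PAIRS:
        for ax, axis in enumerate(AXES):
            d = seq.series(a, ax) - seq.series(b, ax)
            out[f"dist_{a}_{b}_{axis}"] = d if signed else np.abs(d)
    return out


def joint_angle_series(seq: TranslatedSequence) -> dict[str, np.ndarray]:
    """Angles ∠abc in degrees at vertex b for the 10 joint triples.

    The cosine is clipped to [-1, 1] before arccos; a zero-length ray makes
    the angle 0 for that frame (logged once per series).
    """
    out: dict[str, np.ndarray] = {}
    for a, b, c in ANGLE_TRIPLES:
        pa = np.stack([seq.series(a, 0), seq.series(a, 1)], axis=1)
        pb = np.stack([seq.series(b, 0), seq.series(b, 1)], axis=1)
        pc = np.stack([seq.series(c, 0), seq.series(c, 1)], axis=1)
        u = pa - pb
        v = pc - pb
        nu = np.linalg.norm(u, axis=1)
        nv = np.linalg.norm(v, axis=1)
        degenerate = (nu == 0) | (nv == 0)
        denom = np.where(degenerate, 1.0, nu * nv)
        cos = np.clip((u * v).sum(axis=1) / denom, -1.0, 1.0)
        ang = np.degrees(np.arccos(cos))
        if degenerate.any():
            logger.warning(
                "angle_%d_%d_%d: zero-length ray in %d frame(s); angle set to 0",
                a, b, c, int(degenerate.sum()),
            )
            ang = np.where(degenerate, 0.0, ang)
        out[f"angle_{a}_{b}_{c}"] = ang
    return out


def wavelet_decompose(series: np.ndarray) -> dict[str, np.ndarray]:
    """5-level haar decomposition into coefficient arrays D1..D5, A5."""
    series = np.asarray(series, dtype=float)
    if series.size < MIN_WAVELET_LENGTH:
        raise GaitError(
            f"series of length {series.size} cannot support a "
            f"{WAVELET_LEVEL}-level decomposition (need >= {MIN_WAVELET_LENGTH})"
        )
    coeffs = pywt.wavedec(series, WAVELET, mode=WAVELET_MODE, level=WAVELET_LEVEL)
    a5, d5, d4, d3, d2, d1 = coeffs
    return {"D1": d1, "D2": d2, "D3": d3, "D4": d4, "D5": d5, "A5": a5}


def reconstruct_band_signals(
    bands: dict[str, np.ndarray], length: int
) -> dict[str, np.ndarray]:
    """Per-band time-domain signals whose sum reconstructs the input.

    Each band is inverted with every other band zeroed, so the six returned
    signals satisfy the additive multiresolution identity
    X = D1 + D2 + D3 + D4 + D5 + A5.
    """
    order = ["A5", "D5", "D4", "D3", "D2", "D1"]
    out: dict[str, np.ndarray] = {}
    for band in bands:
        coeffs = [
            bands[name] if name == band else np.zeros_like(bands[name])
            for name in order
        ]
        out[band] = pywt.waverec(coeffs, WAVELET, mode=WAVELET_MODE)[:length]
    return out


# ---------------------------------------------------------------------------
# feature pool
# ---------------------------------------------------------------------------

@dataclass
class FeaturePool:
    """Named time series plus wavelet bands for the coordinate series."""

    series: dict[str, np.ndarray]
    wavelet_bands: dict[str, dict[str, np.ndarray]]

    def __post_init__(self) -> None:
        if len(self.series) != N_TIME_SERIES:
            raise GaitError(
                f"feature pool must hold {N_TIME_SERIES} series, got {len(self.series)}"
            )


def build_feature_pool(seq: TranslatedSequence, signed_distances: bool = False) -> FeaturePool:
    """Assemble the full feature data pool for one preprocessed sequence.

    Wavelet bands are computed for the 48 coordinate series only.
    """
    coords = coordinate_series(seq)
    series: dict[str, np.ndarray] = dict(coords)
    for name, s in coords.items():
        series[name.replace("coord_", "diff_", 1)] = interframe_difference(s)
    series.update(joint_distance_series(seq, signed=signed_distances))
    series.update(joint_angle_series(seq))
    bands = {name: wavelet_decompose(s) for name, s in coords.items()}
    return FeaturePool(series, bands)


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------

def time_domain_summary(series: np.ndarray) -> dict[str, float]:
    """Ten time-domain statistics of one series.

    Variance, skewness and kurtosis are population moment estimators;
    kurtosis is excess (Fisher).  Degenerate cases are made finite:
    skewness/kurtosis of a constant series are 0, and the variation
    coefficient is 0 when the mean is 0.
    """
    x = np.asarray(series, dtype=float)
    if x.size < 2:
        raise GaitError("time-domain summary needs at least 2 samples")
    mean = float(x.mean())
    var = float(x.var())
    std = np.sqrt(var)
    abs_energy = float(np.dot(x, x))
    if std > 0:
        centred = x - mean
        skew = float((centred**3).mean()) / std**3
        kurt = float((centred**4).mean()) / var**2 - 3.0
    else:
        skew = kurt = 0.0
    if mean == 0.0:
        logger.debug("variation coefficient of a zero-mean series set to 0")
        vc = 0.0
    else:
        vc = std / mean
    return {
        "maximum": float(x.max()),
        "minimum": float(x.min()),
        "mean": mean,
        "median": float(np.median(x)),
        "variance": var,
        "root_mean_square": float(np.sqrt(abs_energy / x.size)),
        "skewness": skew,
        "kurtosis": kurt,
        "abs_energy": abs_energy,
        "variation_coefficient": vc,
    }


def frequency_domain_summary(bands: dict[str, np.ndarray]) -> dict[str, float]:
    """Absolute maximum, mean, population variance and absolute energy per band."""
    out: dict[str, float] = {}
    for band in WAVELET_BANDS:
        c = np.asarray(bands[band], dtype=float)
        if c.size == 0:
            raise GaitError(f"wavelet band {band} is empty")
        out[f"{band}__abs_max"] = float(np.abs(c).max())
        out[f"{band}__mean"] = float(c.mean())
        out[f"{band}__variance"] = float(c.var())
        out[f"{band}__abs_energy"] = float(np.dot(c, c))
    return out


# ---------------------------------------------------------------------------
# feature vector
# ---------------------------------------------------------------------------

def feature_names() -> list[str]:
    """Canonical ordered names of all 2472 features (data-independent)."""
    names: list[str] = []
    series_names: list[str] = []
    coord_names: list[str] = []
    for k in KEYPOINTS_24:
        for axis in AXES:
            coord_names.append(f"coord_{k}_{axis}")
    series_names.extend(coord_names)
    series_names.extend(n.replace("coord_", "diff_", 1) for n in coord_names)
    for a, b in DISTANCE_PAIRS:
        for axis in AXES:
            series_names.append(f"dist_{a}_{b}_{axis}")
    for a, b, c in ANGLE_TRIPLES:
        series_names.append(f"angle_{a}_{b}_{c}")
    for sname in series_names:
        for fn in TIME_DOMAIN_FUNCTIONS:
            names.append(f"{sname}__{fn}")
    for cname in coord_names:
        for band in WAVELET_BANDS:
            for stat in FREQUENCY_DOMAIN_STATS:
                names.append(f"{cname}__{band}__{stat}")
    return names


_FEATURE_NAMES = feature_names()


def extract_feature_vector(
    seq: TranslatedSequence, signed_distances: bool = False
) -> pd.Series:
    """Extract the ordered 2472-dimensional time-frequency feature vector.

    Works on full 75-frame sequences and 37-frame odd/even halves alike;
    the name set and order are identical, only the values differ.
    """
    pool = build_feature_pool(seq, signed_distances=signed_distances)
    values: dict[str, float] = {}
    for name, s in pool.series.items():
        for fn, v in time_domain_summary(s).items():
            values[f"{name}__{fn}"] = v
    for cname, bands in pool.wavelet_bands.items():
        for key, v in frequency_domain_summary(bands).items():
            values[f"{cname}__{key}"] = v
    vec = pd.Series([values[n] for n in _FEATURE_NAMES], index=_FEATURE_NAMES, dtype=float)
    if len(vec) != N_FEATURES:
        raise GaitError(f"expected {N_FEATURES} features, built {len(vec)}")
    if not np.all(np.isfinite(vec.to_numpy())):
        bad = vec.index[~np.isfinite(vec.to_numpy())].tolist()
        raise GaitError(f"non-finite feature values: {bad[:5]}")
    return vec


def extract_feature_table(
    sequences: list[TranslatedSequence],
    halves: tuple[list[TranslatedSequence], list[TranslatedSequence]] | None = None,
) -> pd.DataFrame:
    """Feature rows for a cohort: one row per subject per stream.

    Columns are ``subject_id``, ``stream`` (all/odd/even) and the 2472
    feature names.
    """
    rows = []
    streams: list[tuple[str, list[TranslatedSequence]]] = [("all", sequences)]
    if halves is not None:
        streams += [("odd", halves[0]), ("even", halves[1])]
    for stream, seqs in streams:
        for seq in seqs:
            vec = extract_feature_vector(seq)
            row = {"subject_id": seq.subject_id, "stream": stream}
            row.update(vec.to_dict())
            rows.append(row)
    return pd.DataFrame(rows, columns=["subject_id", "stream", *_FEATURE_NAMES])
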