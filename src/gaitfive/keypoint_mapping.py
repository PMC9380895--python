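"""Map selected model features back onto body keypoints.

Feature construction is invertible at the level of bookkeeping: every
feature name records which keypoints entered it.  A coordinate,
interframe-difference or wavelet feature of keypoint k charges k with
weight 1; a joint-distance feature splits its weight 1/2 + 1/2 over the
pair; a joint-angle feature splits 1/3 + 1/3 + 1/3 over the triple.

Because selection operates on principal components rather than raw
features, each selected component first distributes one unit of mass over
the 2472 raw features in proportion to its absolute PCA loadings (an
alternative squared-loading rule is available), and that mass then flows
to keypoints through the construction weights.  Total mass is conserved:
it always equals the number of selected components.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .features import feature_names
from .schema import BODY_25_LABELS, KEYPOINTS_24, MIDHIP
from .modeling import TraitRegressor


def feature_keypoint_weights(feature_name: str) -> dict[int, float]:
    """Keypoint -> construction weight for one feature name."""
    base = feature_name.split("__", 1)[0]
    parts = base.split("_")
    kind = parts[0]
    if kind in ("coord", "diff") and len(parts) == 3:
        return {int(parts[1]): 1.0}
    if kind == "dist" and len(parts) == 4:
        a, b = int(parts[1]), int(parts[2])
        return {a: 0.5, b: 0.5}
    if kind == "angle" and len(parts) == 4:
        a, b, c = int(parts[1]), int(parts[2]), int(parts[3])
        return {a: 1 / 3, b: 1 / 3, c: 1 / 3}
    raise ValueError(f"unparseable feature name {feature_name!r}")


def construction_weight_matrix(names: list[str] | None = None) -> pd.DataFrame:
    """(n_features, 24) matrix of construction weights, rows summing to 1."""
    names = names if names is not None else feature_names()
    mat = np.zeros((len(names), len(KEYPOINTS_24)))
    col = {k: i for i, k in enumerate(KEYPOINTS_24)}
    for i, name in enumerate(names):
        for k, w in feature_keypoint_weights(name).items():
            if k == MIDHIP:
                raise ValueError("MidHip cannot carry feature weight")
            mat[i, col[k]] = w
    return pd.DataFrame(mat, index=names, columns=list(KEYPOINTS_24))


@dataclass
class KeypointStats:
    """Contribution weights over the 24 keypoints, with ranks.

    ``weights`` is indexed by BODY_25 keypoint index (MidHip absent) and
    sums to the number of selected components.
    """

    weights: pd.Series

    def __post_init__(self) -> None:
        if MIDHIP in self.weights.index:
            raise ValueError("MidHip must not appear in keypoint statistics")
        if (self.weights < 0).any():
            raise ValueError("keypoint weights must be non-negative")

    @property
    def total_mass(self) -> float:
        return float(self.weights.sum())

    def ranking(self) -> pd.DataFrame:
        """Keypoints sorted by weight (ties -> lower index first)."""
        order = np.lexsort((self.weights.index.to_numpy(), -self.weights.to_numpy()))
        ranked = self.weights.iloc[order]
        return pd.DataFrame(
            {
                "keypoint": ranked.index,
                "label": [BODY_25_LABELS[k] for k in ranked.index],
                "weight": ranked.to_numpy(),
                "rank": np.arange(1, len(ranked) + 1),
            }
        ).set_index("keypoint")

    def top_fraction(self, fraction: float = 0.5) -> list[int]:
        """The top ``ceil(24 * fraction)`` keypoints by weight."""
        m = int(np.ceil(len(self.weights) * fraction))
        return self.ranking().index[:m].tolist()


def keypoint_contribution_stats(
    model: TraitRegressor, loading_rule: str = "abs"
) -> KeypointStats:
    """Propagate each selected component's mass to keypoints.

    ``loading_rule`` chooses how a component spreads its unit of mass over
    raw features: ``"abs"`` (proportional to absolute loadings, default)
    or ``"squared"`` (proportional to squared loadings).
    """
    if not hasattr(model, "selected_"):
        raise ValueError("model must be fitted before mapping keypoints")
    loadings = model.pca_.components_[model.selected_]  # (k, n_features)
    if loading_rule == "abs":
        w = np.abs(loadings)
    elif loading_rule == "squared":
        w = loadings**2
    else:
        raise ValueError(f"unknown loading rule {loading_rule!r}")
    w = w / w.sum(axis=1, keepdims=True)
    feature_mass = w.sum(axis=0)  # (n_features,), sums to k
    cw = construction_weight_matrix()
    kp_mass = feature_mass @ cw.to_numpy()
    return KeypointStats(pd.Series(kp_mass, index=list(KEYPOINTS_24)))


def top_half_intersection(
    stats_a: KeypointStats, stats_b: KeypointStats, fraction: float = 0.5
) -> list[int]:
    """Keypoints in the top ``fraction`` of both contribution rankings."""
    top_a = set(stats_a.top_fraction(fraction))
    top_b = set(stats_b.top_fraction(fraction))
    return sorted(top_a & top_b)
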