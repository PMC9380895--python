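"""Psychometric evaluation of trait models.

Treats a fitted model like a questionnaire: criterion validity r1 is the
Pearson correlation between out-of-fold model predictions and scale
scores, odd-even split-half reliability r2 correlates predictions obtained
from the odd-frame and even-frame halves of the same videos, and the
multitrait-multimethod (MTMM) matrix arranges model- and scale-measured
traits into one 10x10 correlation matrix whose blocks separate convergent
(same trait, different method) from discriminant (different trait)
structure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .modeling import TRAITS, PredictionSet

SIGNIFICANCE_FLAG_P = 1e-3


def pearson_r(u, v) -> tuple[float, float]:
    """Pearson correlation and its two-sided p-value (t with n-2 df)."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape or u.ndim != 1:
        raise ValueError("pearson_r expects two equal-length vectors")
    if u.size < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(u) == 0 or np.ptp(v) == 0:
        raise ValueError("correlation is undefined for a constant vector")
    r, p = stats.pearsonr(u, v)
    return float(r), float(p)


def rmse(predicted, actual) -> float:
    """Root mean squared error between prediction and scale scores."""
    predicted = np.asarray(predicted, dtype=float)
    actual = np.asarray(actual, dtype=float)
    if predicted.shape != actual.shape:
        raise ValueError("length mismatch between predicted and actual")
    return float(np.sqrt(np.mean((predicted - actual) ** 2)))


def criterion_validity_table(
    predictions: dict[str, PredictionSet], scores: pd.DataFrame
) -> pd.DataFrame:
    """Per-trait RMSE, criterion validity r1 and split-half reliability r2.

    ``predictions`` maps trait name -> :class:`PredictionSet`; ``scores``
    holds one column per trait.  Rows are the five traits plus a ``mean``
    row averaging each column.  r2 columns are NaN when a prediction set
    lacks odd/even streams.
    """
    rows = {}
    for trait in TRAITS:
        if trait not in predictions:
            continue
        pset = predictions[trait]
        agg = pset.aggregated
        actual = scores[trait].to_numpy(dtype=float)
        r1, r1_p = pearson_r(agg["all"], actual)
        row = {
            "rmse": rmse(agg["all"], actual),
            "r1": r1,
            "r1_p": r1_p,
            "r2": np.nan,
            "r2_p": np.nan,
        }
        if "odd" in agg and "even" in agg:
            r2, r2_p = pearson_r(agg["odd"], agg["even"])
            row["r2"], row["r2_p"] = r2, r2_p
        rows[trait] = row
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.loc["mean"] = table.mean()
    return table


def split_half_reliability(predictions: dict[str, PredictionSet]) -> pd.Series:
    """Odd-even split-half reliability r2 per trait."""
    out = {}
    for trait, pset in predictions.items():
        agg = pset.aggregated
        out[trait] = pearson_r(agg["odd"], agg["even"])[0]
    return pd.Series(out, name="r2")


def per_repetition_r1(pset: PredictionSet, actual) -> np.ndarray:
    """Criterion validity computed separately for each CV repetition."""
    actual = np.asarray(actual, dtype=float)
    return np.array(
        [pearson_r(rep_pred, actual)[0] for rep_pred in pset.per_repetition["all"]]
    )


# ---------------------------------------------------------------------------
# multitrait-multimethod matrix
# ---------------------------------------------------------------------------

@dataclass
class MTMMMatrix:
    """10x10 trait-by-method Pearson matrix with its underlying score data.

    Rows/columns are ordered model traits then scale traits.  The raw
    per-subject score matrices are retained so permutation tests can
    re-correlate under shuffled subject labels.
    """

    matrix: pd.DataFrame
    model_scores: pd.DataFrame
    scale_scores: pd.DataFrame

    @property
    def n_subjects(self) -> int:
        return len(self.model_scores)

    def convergent(self) -> pd.Series:
        """Mono-trait hetero-method correlations (the validity diagonal)."""
        return pd.Series(
            {t: self.matrix.loc[f"model_{t}", f"scale_{t}"] for t in TRAITS}
        )

    def _block_off_diagonal(self, prefix: str) -> pd.Series:
        vals = {}
        for i, a in enumerate(TRAITS):
            for b in TRAITS[i + 1:]:
                vals[(a, b)] = self.matrix.loc[f"{prefix}_{a}", f"{prefix}_{b}"]
        return pd.Series(vals)

    def model_discriminant(self) -> pd.Series:
        """Hetero-trait mono-method correlations within the model block."""
        return self._block_off_diagonal("model")

    def scale_discriminant(self) -> pd.Series:
        """Hetero-trait mono-method correlations within the scale block."""
        return self._block_off_diagonal("scale")

    def hetero_trait_hetero_method(self) -> pd.Series:
        """Different trait measured by different methods (20 entries)."""
        vals = {}
        for a in TRAITS:
            for b in TRAITS:
                if a != b:
                    vals[(a, b)] = self.matrix.loc[f"model_{a}", f"scale_{b}"]
        return pd.Series(vals)


def _cross_method_matrix(model: np.ndarray, scale: np.ndarray) -> np.ndarray:
    both = np.corrcoef(np.hstack([model, scale]), rowvar=False)
    return both


def mtmm_matrix(model_scores: pd.DataFrame, scale_scores: pd.DataFrame) -> MTMMMatrix:
    """Build the 10x10 MTMM Pearson matrix from per-subject trait scores.

    ``model_scores`` holds aggregated all-frames predictions per trait and
    ``scale_scores`` the questionnaire subscale sums, over the same
    subjects in the same order.
    """
    model = model_scores[list(TRAITS)].to_numpy(dtype=float)
    scale = scale_scores[list(TRAITS)].to_numpy(dtype=float)
    if model.shape != scale.shape:
        raise ValueError("model and scale score tables must cover the same subjects")
    labels = [f"model_{t}" for t in TRAITS] + [f"scale_{t}" for t in TRAITS]
    corr = _cross_method_matrix(model, scale)
    matrix = pd.DataFrame(corr, index=labels, columns=labels)
    return MTMMMatrix(matrix, model_scores[list(TRAITS)], scale_scores[list(TRAITS)])


def validity_summary(
    mtmm: MTMMMatrix, n_permutations: int = 500, seed: int = 0
) -> dict:
    """Convergent/discriminant summary statistics of an MTMM matrix.

    Reports the mean convergent correlation, the mean absolute
    discriminant correlations within each method block, and a permutation
    test of whether convergent entries exceed the hetero-trait
    hetero-method entries sharing their row or column: subject labels of
    the model block are shuffled, the cross-method block re-correlated,
    and the observed mean paired difference compared with the null
    distribution.  Off-diagonal entries whose n-2 df p-value is >= 0.001
    are listed under ``weak_entries``.
    """
    conv = mtmm.convergent()
    out = {
        "mean_convergent_r": float(conv.mean()),
        "mean_abs_model_discriminant": float(mtmm.model_discriminant().abs().mean()),
        "mean_abs_scale_discriminant": float(mtmm.scale_discriminant().abs().mean()),
    }

    model = mtmm.model_scores.to_numpy(dtype=float)
    scale = mtmm.scale_scores.to_numpy(dtype=float)
    n = model.shape[0]

    def paired_stat(cross: np.ndarray) -> float:
        # cross[i, j] = corr(model trait i, scale trait j)
        diffs = []
        for i in range(len(TRAITS)):
            for j in range(len(TRAITS)):
                if i != j:
                    diffs.append(abs(cross[i, i]) - abs(cross[i, j]))
                    diffs.append(abs(cross[j, j]) - abs(cross[i, j]))
        return float(np.mean(diffs))

    cross_obs = _cross_method_matrix(model, scale)[:5, 5:]
    observed = paired_stat(cross_obs)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_permutations):
        perm = rng.permutation(n)
        cross = _cross_method_matrix(model[perm], scale)[:5, 5:]
        if paired_stat(cross) >= observed:
            exceed += 1
    out["convergent_exceeds_htm_stat"] = observed
    out["convergent_exceeds_htm_p"] = (exceed + 1) / (n_permutations + 1)

    weak = []
    labels = mtmm.matrix.index
    for i, a in enumerate(labels):
        for b in labels[i + 1:]:
            r = float(mtmm.matrix.loc[a, b])
            p = stats.pearsonr(
                _label_scores(mtmm, a), _label_scores(mtmm, b)
            )[1]
            if p >= SIGNIFICANCE_FLAG_P:
                weak.append((a, b, r))
    out["weak_entries"] = weak
    return out


def _label_scores(mtmm: MTMMMatrix, label: str) -> np.ndarray:
    method, trait = label.split("_", 1)
    table = mtmm.model_scores if method == "model" else mtmm.scale_scores
    return table[trait].to_numpy(dtype=float)


def evaluation_report(
    predictions: dict[str, PredictionSet], scores: pd.DataFrame
) -> dict:
    """JSON-ready evaluation report: per-trait rmse/r1/r2 plus means."""
    table = criterion_validity_table(predictions, scores)
    report = {
        trait: {
            k: (None if pd.isna(v) else float(v)) for k, v in row.items()
        }
        for trait, row in table.iterrows()
        if trait != "mean"
    }
    report["means"] = {
        k: (None if pd.isna(v) else float(v)) for k, v in table.loc["mean"].items()
    }
    return report
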