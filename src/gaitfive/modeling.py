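"""Trait regression: standardize -> PCA -> sequential forward selection -> regressor.

The 2472-dimensional feature vectors vastly outnumber subjects, so each
trait model standardizes features, projects them onto at most n-1 principal
components, greedily selects 40 components by inner cross-validated RMSE
(sequential forward selection, SFS), and fits one of seven regressors on
the selected components: Gaussian process regression (GPR), linear
regression (LR), random forest regression (RFR), and support vector
regression with linear/poly/rbf/sigmoid kernels.

Model quality is measured by 10x10 repeated cross-validation.  Within each
training fold the full stack (standardizer, PCA, SFS, regressor) is refit
from scratch, then applied unchanged to the held-out subjects' all-frames,
odd-frames and even-frames feature vectors — so the odd/even predictions
measure the reliability of one fixed model, not of refitted ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import linalg
from sklearn.base import BaseEstimator, RegressorMixin, clone
from sklearn.decomposition import PCA
from sklearn.ensemble import RandomForestRegressor
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import RBF, WhiteKernel
from sklearn.linear_model import LinearRegression
from sklearn.model_selection import KFold
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVR
from sklearn.utils.validation import check_is_fitted, validate_data

TRAITS = ("extraversion", "agreeableness", "conscientiousness", "neuroticism", "openness")

ALGORITHMS = ("gpr", "lr", "rfr", "svr-linear", "svr-poly", "svr-rbf", "svr-sigmoid")

DEFAULT_N_SELECT = 40
DEFAULT_INNER_CV = 5
_MOD31 = 2**31 - 1


def make_regressor(algorithm: str, seed: int = 0) -> BaseEstimator:
    """Instantiate one of the seven supported regression algorithms."""
    if algorithm == "gpr":
        return GaussianProcessRegressor(
            kernel=RBF() + WhiteKernel(),
            n_restarts_optimizer=3,
            normalize_y=True,
            random_state=seed % _MOD31,
        )
    if algorithm == "lr":
        return LinearRegression()
    if algorithm == "rfr":
        return RandomForestRegressor(n_estimators=100, random_state=seed % _MOD31)
    if algorithm.startswith("svr-"):
        kernel = algorithm.split("-", 1)[1]
        if kernel in ("linear", "poly", "rbf", "sigmoid"):
            return SVR(kernel=kernel)
    raise ValueError(f"unknown algorithm {algorithm!r}; choose from {ALGORITHMS}")


# ---------------------------------------------------------------------------
# sequential forward selection
# ---------------------------------------------------------------------------

def _ols_fold_cache(Z, y, splits):
    """Per-fold centred Gram matrices for the closed-form OLS scoring path."""
    cache = []
    for tr, te in splits:
        Xtr = Z[tr]
        mu = Xtr.mean(axis=0)
        Xc = Xtr - mu
        ym = y[tr].mean()
        yc = y[tr] - ym
        cache.append(
            {
                "gram": Xc.T @ Xc,
                "xty": Xc.T @ yc,
                "Xte": Z[te] - mu,  # centred with training means
                "yte": y[te] - ym,
            }
        )
    return cache


def _ols_stage_rmse(selected, remaining, cache):
    """RMSE of OLS-with-intercept for every candidate extension, per fold mean.

    For a fixed selected set S and each remaining column j, the model on
    S + [j] is scored in closed form: the candidate column is
    orthogonalized against the selected block in the training inner
    product, so its coefficient and the updated predictions follow from
    the base fit without re-solving per candidate.  Exact OLS, vectorized
    over candidates.
    """
    S = np.asarray(selected, dtype=int)
    R = np.asarray(remaining, dtype=int)
    total = np.zeros(R.size)
    for f in cache:
        G, b, Xte, yte = f["gram"], f["xty"], f["Xte"], f["yte"]
        if S.size:
            GSS = G[np.ix_(S, S)]
            GSR = G[np.ix_(S, R)]
            try:
                c_and_lower = linalg.cho_factor(GSS)
                beta_s = linalg.cho_solve(c_and_lower, b[S])
                A = linalg.cho_solve(c_and_lower, GSR)
            except linalg.LinAlgError:
                beta_s = np.linalg.lstsq(GSS, b[S], rcond=None)[0]
                A = np.linalg.lstsq(GSS, GSR, rcond=None)[0]
            denom = G[R, R] - np.einsum("ij,ij->j", GSR, A)
            numer = b[R] - GSR.T @ beta_s
            base = Xte[:, S] @ beta_s
            V = Xte[:, R] - Xte[:, S] @ A
        else:
            denom = G[R, R].copy()
            numer = b[R].copy()
            base = np.zeros(Xte.shape[0])
            V = Xte[:, R]
        ok = denom > 1e-10 * np.maximum(G[R, R], 1.0)
        coef = np.where(ok, numer / np.where(ok, denom, 1.0), 0.0)
        resid = (base[:, None] + V * coef[None, :]) - yte[:, None]
        total += np.sqrt(np.mean(resid**2, axis=0))
    return total / len(cache)


def _generic_cv_neg_rmse(cols, estimator, Z, y, splits):
    idx = list(cols)
    total = 0.0
    for tr, te in splits:
        est = clone(estimator)
        est.fit(Z[np.ix_(tr, idx)], y[tr])
        pred = est.predict(Z[np.ix_(te, idx)])
        total += float(np.sqrt(np.mean((pred - y[te]) ** 2)))
    return -total / len(splits)


def sequential_forward_selection(
    Z: np.ndarray,
    y: np.ndarray,
    estimator: BaseEstimator,
    k: int = DEFAULT_N_SELECT,
    cv_folds: int = DEFAULT_INNER_CV,
    seed: int = 0,
) -> list[int]:
    """Greedily select ``k`` columns of ``Z`` maximizing inner-CV score.

    At each of the ``k`` stages every remaining column is tried; the one
    whose addition maximizes the mean negative RMSE of ``estimator`` under
    seeded ``cv_folds``-fold cross-validation is kept (ties break to the
    lowest column index).  Returns the selection path in order of addition.

    Linear regression is scored through a closed-form OLS path (centred
    normal equations per fold), numerically equivalent to fitting the
    estimator but fast enough to refit the selection inside every outer
    cross-validation fold.
    """
    Z = np.asarray(Z, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = Z.shape
    if k > p:
        raise ValueError(f"cannot select {k} components from {p}")
    kf = KFold(n_splits=cv_folds, shuffle=True, random_state=seed % _MOD31)
    splits = list(kf.split(Z))
    fast = isinstance(estimator, LinearRegression) and estimator.fit_intercept
    cache = _ols_fold_cache(Z, y, splits) if fast else None

    selected: list[int] = []
    remaining = list(range(p))
    for _ in range(k):
        if fast:
            mean_rmse = _ols_stage_rmse(selected, remaining, cache)
            best_j = remaining[int(np.argmin(mean_rmse))]  # ties -> lowest index
        else:
            best_j = None
            best_score = -np.inf
            for j in remaining:
                score = _generic_cv_neg_rmse(selected + [j], estimator, Z, y, splits)
                if score > best_score:
                    best_score, best_j = score, j
        selected.append(best_j)
        remaining.remove(best_j)
    return selected


# ---------------------------------------------------------------------------
# the per-trait estimator
# ---------------------------------------------------------------------------

class TraitRegressor(RegressorMixin, BaseEstimator):
    """Standardize -> PCA -> SFS -> regressor, as one sklearn estimator.

    Parameters
    ----------
    algorithm : str, default "lr"
        One of :data:`ALGORITHMS`.
    n_select : int, default 40
        Number of principal components chosen by sequential forward
        selection.
    inner_cv : int, default 5
        Folds of the inner cross-validation that scores SFS candidates.
    random_state : int, default 0
        Seeds the inner CV shuffling and any stochastic regressor.

    Attributes
    ----------
    scaler_ : StandardScaler
        Per-feature standardizer (zero-variance features scaled by 1).
    pca_ : PCA
        Full-rank basis, ``min(n_samples - 1, n_features)`` components.
    selected_ : list of int
        SFS-chosen component indices, in order of addition.
    regressor_ : fitted estimator
        The algorithm refit on the selected components.
    """

    def __init__(
        self,
        algorithm: str = "lr",
        n_select: int = DEFAULT_N_SELECT,
        inner_cv: int = DEFAULT_INNER_CV,
        random_state: int = 0,
    ) -> None:
        self.algorithm = algorithm
        self.n_select = n_select
        self.inner_cv = inner_cv
        self.random_state = random_state

    def fit(self, X, y):
        X, y = validate_data(self, X, y, dtype=float)
        n, p = X.shape
        self.scaler_ = StandardScaler().fit(X)
        Xs = self.scaler_.transform(X)
        n_components = min(n - 1, p)
        if n_components < self.n_select:
            raise ValueError(
                f"only {n_components} principal components available, "
                f"cannot select {self.n_select}"
            )
        self.pca_ = PCA(n_components=n_components, svd_solver="full").fit(Xs)
        Z = self.pca_.transform(Xs)
        estimator = make_regressor(self.algorithm, seed=self.random_state)
        self.selected_ = sequential_forward_selection(
            Z, y, estimator, k=self.n_select, cv_folds=self.inner_cv,
            seed=self.random_state,
        )
        self.regressor_ = clone(estimator).fit(Z[:, self.selected_], y)
        return self

    def transform(self, X) -> np.ndarray:
        """Project feature vectors onto the SFS-selected components."""
        check_is_fitted(self, "selected_")
        X = validate_data(self, X, reset=False, dtype=float)
        Z = self.pca_.transform(self.scaler_.transform(X))
        return Z[:, self.selected_]

    def predict(self, X) -> np.ndarray:
        return self.regressor_.predict(self.transform(X))


def fit_transform_stack(
    X_all: np.ndarray,
    y: np.ndarray,
    algorithm: str = "lr",
    k: int = DEFAULT_N_SELECT,
    seed: int = 0,
) -> TraitRegressor:
    """Fit the standardize/PCA/SFS stack (plus regressor) on all-frames features."""
    return TraitRegressor(
        algorithm=algorithm, n_select=k, random_state=seed
    ).fit(X_all, y)


def fit_trait_model(
    features_all: np.ndarray,
    scores: np.ndarray,
    trait: str,
    algorithm: str = "lr",
    seed: int = 0,
    n_select: int = DEFAULT_N_SELECT,
) -> TraitRegressor:
    """Fit one trait's model; ``trait`` must be a Big Five subscale name."""
    if trait not in TRAITS:
        raise ValueError(f"unknown trait {trait!r}; choose from {TRAITS}")
    return fit_transform_stack(features_all, scores, algorithm=algorithm, k=n_select, seed=seed)


# ---------------------------------------------------------------------------
# repeated cross-validated prediction
# ---------------------------------------------------------------------------

@dataclass
class PredictionSet:
    """Out-of-fold predictions per stream, per repetition, plus aggregates.

    ``per_repetition[stream]`` has shape (repeats, n_subjects): each subject
    is predicted exactly once per repetition per stream.  ``aggregated`` is
    the mean over repetitions.
    """

    per_repetition: dict[str, np.ndarray]
    subject_index: np.ndarray = field(default=None)  # type: ignore[assignment]

    @property
    def aggregated(self) -> dict[str, np.ndarray]:
        return {s: arr.mean(axis=0) for s, arr in self.per_repetition.items()}

    @property
    def streams(self) -> tuple[str, ...]:
        return tuple(self.per_repetition)


def repeated_cv_predict(
    features: Mapping[str, np.ndarray],
    y: Sequence[float],
    algorithm: str = "lr",
    repeats: int = 10,
    folds: int = 10,
    seed: int = 0,
    n_select: int = DEFAULT_N_SELECT,
    inner_cv: int = DEFAULT_INNER_CV,
    refit_stack_per_fold: bool = True,
) -> PredictionSet:
    """Repeated k-fold out-of-fold prediction with per-fold stack refitting.

    ``features`` maps stream name -> (n_subjects, n_features) matrix; the
    ``"all"`` stream is mandatory and is the only one models are trained
    on.  Additional streams (``"odd"``, ``"even"``) are predicted through
    the identical fitted stack.

    With ``refit_stack_per_fold=False`` the standardize/PCA/SFS stack is
    fitted once on the full all-frames matrix and only the regressor is
    refit per fold; this leaks the held-out subjects into the transforms
    and exists for comparison with the leakage-free default.
    """
    if "all" not in features:
        raise ValueError('features must contain the "all" stream')
    X_all = np.asarray(features["all"], dtype=float)
    y = np.asarray(y, dtype=float)
    n = X_all.shape[0]
    if n < folds:
        raise ValueError(f"need at least {folds} subjects for {folds}-fold CV")
    mats = {s: np.asarray(m, dtype=float) for s, m in features.items()}
    for s, m in mats.items():
        if m.shape != X_all.shape:
            raise ValueError(f"stream {s!r} shape {m.shape} != all-frames {X_all.shape}")

    global_stack = None
    if not refit_stack_per_fold:
        global_stack = TraitRegressor(
            algorithm=algorithm, n_select=n_select, inner_cv=inner_cv,
            random_state=seed,
        ).fit(X_all, y)
        Z = {s: global_stack.transform(m) for s, m in mats.items()}

    preds = {s: np.full((repeats, n), np.nan) for s in mats}
    for rep in range(repeats):
        rep_seed = (seed + 1_000_003 * rep) % _MOD31
        kf = KFold(n_splits=folds, shuffle=True, random_state=rep_seed)
        for fold_i, (tr, te) in enumerate(kf.split(X_all)):
            if refit_stack_per_fold:
                model = TraitRegressor(
                    algorithm=algorithm, n_select=n_select, inner_cv=inner_cv,
                    random_state=(rep_seed + fold_i) % _MOD31,
                ).fit(X_all[tr], y[tr])
                for s, m in mats.items():
                    preds[s][rep, te] = model.predict(m[te])
            else:
                reg = make_regressor(algorithm, seed=(rep_seed + fold_i) % _MOD31)
                reg.fit(Z["all"][tr], y[tr])
                for s in mats:
                    preds[s][rep, te] = reg.predict(Z[s][te])
    for s, arr in preds.items():
        if not np.all(np.isfinite(arr)):
            raise RuntimeError(f"non-finite predictions in stream {s!r}")
    return PredictionSet(preds, subject_index=np.arange(n))
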