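"""Shared multivariate SVR machinery for lesion-symptom mapping.

Both the voxel-level and the edge-level analyses fit an epsilon-insensitive
support vector regression of a behavioral residual score on a subjects x
features matrix, back-project the dual solution onto feature space to get a
weight ("beta") map, average that map over k cross-validation folds, and
score the true map against a Monte-Carlo permutation null built by
shuffling the behavioral vector across subjects:

    z_j = (w_true,j - mean_null,j) / sd_null,j

Back-projection uses the linear sensitivity map w = X^T alpha over support
vectors.  For a linear kernel this is the primal weight vector exactly; for
the Gaussian kernel it is the convention of published SVR-LSM toolboxes and
keeps the map kernel-agnostic and reproducible.

Performance note: the kernel depends only on the feature matrix, which the
permutation loop never touches.  The Gram matrix is therefore computed once
and every fold/permutation fit runs libsvm on a precomputed-kernel slice,
which keeps 10,000-permutation runs tractable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from sklearn.metrics.pairwise import linear_kernel, rbf_kernel
from sklearn.svm import SVR

logger = logging.getLogger("svrlsm")

__all__ = [
    "SvrConfig",
    "WeightMap",
    "SvrModel",
    "fit_svr",
    "feature_weights",
    "crossval_weight_map",
    "permutation_zscores",
    "zscore_against_null",
]

_KERNELS = ("gaussian", "linear")


@dataclass
class SvrConfig:
    """Hyperparameters for the SVR mapping engine.

    kernel_scale is the Gaussian kernel bandwidth sigma in
    K(x, y) = exp(-||x - y||^2 / sigma^2); the default of 1 matches the
    convention of MATLAB's fitrsvm KernelScale.  epsilon_tube defaults to
    0.1 * sd(target), which is 0.1 after target standardization.
    """

    kernel: str = "gaussian"
    kernel_scale: float = 1.0
    box_constraint: float = 1.0
    epsilon_tube: Optional[float] = None
    n_folds: int = 5
    n_permutations: int = 10000
    seed: int = 0
    standardize_target: bool = True

    def __post_init__(self) -> None:
        if self.kernel not in _KERNELS:
            raise ValueError(f"kernel must be one of {_KERNELS}, got {self.kernel!r}")
        if self.kernel_scale <= 0:
            raise ValueError("kernel_scale must be > 0")
        if self.box_constraint <= 0:
            raise ValueError("box_constraint must be > 0")
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if self.n_permutations < 100:
            raise ValueError("n_permutations must be >= 100")

    def with_(self, **kwargs) -> "SvrConfig":
        return replace(self, **kwargs)


@dataclass
class WeightMap:
    """Back-projected feature weights, optionally with permutation z-scores."""

    feature_ids: list
    weights: np.ndarray
    z_scores: Optional[np.ndarray] = None
    null_mean: Optional[np.ndarray] = None
    null_sd: Optional[np.ndarray] = None
    degenerate: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if len(self.feature_ids) != self.weights.shape[0]:
            raise ValueError("feature_ids and weights lengths differ")
        for name in ("z_scores", "null_mean", "null_sd", "degenerate"):
            arr = getattr(self, name)
            if arr is not None and np.asarray(arr).shape[0] != self.weights.shape[0]:
                raise ValueError(f"{name} length does not match weights")


@dataclass
class SvrModel:
    """Fitted SVR handle exposing the dual solution.

    dual_vector holds the signed dual coefficient alpha_i for every training
    row (zero for non-support rows), so w = X^T @ dual_vector.
    """

    features: np.ndarray
    dual_vector: np.ndarray
    support_rows: np.ndarray
    config: SvrConfig
    target_mean: float
    target_sd: float


def _validate_features_target(features, target):
    X = np.asarray(features, dtype=float)
    y = np.asarray(target, dtype=float)
    if X.ndim != 2:
        raise ValueError("features must be a 2-D subjects x features matrix")
    if y.shape != (X.shape[0],):
        raise ValueError(
            f"target shape {y.shape} does not match {X.shape[0]} feature rows"
        )
    if X.shape[0] < 5:
        raise ValueError("need at least 5 subjects")
    if not np.all(np.isfinite(X)):
        raise ValueError("features contain non-finite values")
    if not np.all(np.isfinite(y)):
        raise ValueError("target contains non-finite values")
    return X, y


def _standardize(y: np.ndarray, config: SvrConfig):
    mean = float(y.mean())
    sd = float(y.std())
    if config.standardize_target and sd > 0:
        return (y - mean) / sd, mean, sd
    return y.copy(), 0.0, 1.0


def _epsilon(y: np.ndarray, config: SvrConfig) -> float:
    if config.epsilon_tube is not None:
        return float(config.epsilon_tube)
    sd = float(y.std())
    return 0.1 * sd if sd > 0 else 0.1


def _gram(X: np.ndarray, config: SvrConfig) -> np.ndarray:
    if config.kernel == "linear":
        return linear_kernel(X)
    gamma = 1.0 / (config.kernel_scale ** 2)
    return rbf_kernel(X, gamma=gamma)


def _fit_dual(K_train: np.ndarray, y_train: np.ndarray, config: SvrConfig,
              epsilon: float) -> tuple[np.ndarray, np.ndarray]:
    """Fit on a precomputed-kernel block; return (dual vector, support idx)."""
    svr = SVR(kernel="precomputed", C=config.box_constraint, epsilon=epsilon)
    svr.fit(K_train, y_train)
    dual = np.zeros(K_train.shape[0])
    dual[svr.support_] = svr.dual_coef_[0]
    return dual, svr.support_


def fit_svr(features, target, config: SvrConfig) -> SvrModel:
    """Fit a single epsilon-insensitive SVR on all subjects."""
    X, y = _validate_features_target(features, target)
    y_std, mean, sd = _standardize(y, config)
    eps = _epsilon(y_std, config)
    K = _gram(X, config)
    dual, support = _fit_dual(K, y_std, config, eps)
    return SvrModel(
        features=X, dual_vector=dual, support_rows=support,
        config=config, target_mean=mean, target_sd=sd,
    )


def feature_weights(model: SvrModel, features=None) -> np.ndarray:
    """Back-project dual coefficients onto feature space: w = X^T alpha."""
    if model.dual_vector is None:  # pragma: no cover - defensive
        raise ValueError("model is not fitted")
    X = model.features if features is None else np.asarray(features, dtype=float)
    if X.shape != model.features.shape:
        raise ValueError("features do not match the matrix the model was fitted on")
    return X.T @ model.dual_vector


def _fold_assignment(n: int, n_folds: int, rng: np.random.Generator) -> list[np.ndarray]:
    order = rng.permutation(n)
    folds = np.array_split(order, n_folds)
    if min(len(f) for f in folds) < 2 or n - max(len(f) for f in folds) < 2:
        raise ValueError(
            f"cross-validation fold with fewer than 2 subjects "
            f"(n={n}, n_folds={n_folds})"
        )
    return folds


def _cv_dual_vector(K: np.ndarray, y: np.ndarray, folds, config: SvrConfig,
                    epsilon: float) -> np.ndarray:
    """Average the fold-wise dual solutions into one length-n vector.

    The fold-averaged weight map mean_k X_k^T alpha_k equals X^T a where
    a gathers each fold's dual coefficients (zero on its test rows) divided
    by the number of folds, so only this n-vector needs to be carried.
    """
    n = K.shape[0]
    combined = np.zeros(n)
    for fold in folds:
        train = np.setdiff1d(np.arange(n), fold, assume_unique=False)
        dual, _ = _fit_dual(K[np.ix_(train, train)], y[train], config, epsilon)
        combined[train] += dual
    return combined / len(folds)


def crossval_weight_map(features, target, config: SvrConfig,
                        feature_ids=None) -> WeightMap:
    """K-fold averaged back-projected weight map.

    Subjects are partitioned into n_folds disjoint folds (seeded); each fold
    map is fitted on the complementary 80% and the final map is the mean of
    the fold maps.
    """
    X, y = _validate_features_target(features, target)
    if X.shape[0] < config.n_folds:
        raise ValueError("fewer subjects than folds")
    y_std, _, _ = _standardize(y, config)
    eps = _epsilon(y_std, config)
    K = _gram(X, config)
    rng = np.random.default_rng(config.seed)
    folds = _fold_assignment(X.shape[0], config.n_folds, rng)
    a = _cv_dual_vector(K, y_std, folds, config, eps)
    if feature_ids is None:
        feature_ids = list(range(X.shape[1]))
    return WeightMap(feature_ids=list(feature_ids), weights=X.T @ a)


def zscore_against_null(w_true: np.ndarray, null_mean: np.ndarray,
                        null_sd: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """z = (w_true - null_mean) / null_sd; degenerate (sd == 0) features get z = 0."""
    w_true = np.asarray(w_true, dtype=float)
    null_mean = np.asarray(null_mean, dtype=float)
    null_sd = np.asarray(null_sd, dtype=float)
    degenerate = null_sd <= 0
    safe_sd = np.where(degenerate, 1.0, null_sd)
    z = (w_true - null_mean) / safe_sd
    z[degenerate] = 0.0
    return z, degenerate


def permutation_zscores(features, target, config: SvrConfig,
                        feature_ids=None) -> WeightMap:
    """Monte-Carlo permutation z-scores for the cross-validated weight map.

    For each permutation the target vector is shuffled across subjects, the
    fold assignment is re-randomized (so the null variance includes fold
    variance), and the full cross-validated map is recomputed.  The true map
    is then z-scored feature-wise against the null mean and SD.
    """
    X, y = _validate_features_target(features, target)
    if X.shape[0] < config.n_folds:
        raise ValueError("fewer subjects than folds")
    n, n_feat = X.shape
    y_std, _, _ = _standardize(y, config)
    eps = _epsilon(y_std, config)
    K = _gram(X, config)
    rng = np.random.default_rng(config.seed)

    folds = _fold_assignment(n, config.n_folds, rng)
    a_true = _cv_dual_vector(K, y_std, folds, config, eps)
    w_true = X.T @ a_true

    # Streamed first/second moments of the null weight maps.
    s1 = np.zeros(n_feat)
    s2 = np.zeros(n_feat)
    n_perm = config.n_permutations
    logger.debug("permutation null: %d iterations, n=%d, features=%d",
                 n_perm, n, n_feat)
    for _ in range(n_perm):
        perm = rng.permutation(n)
        folds_p = _fold_assignment(n, config.n_folds, rng)
        a_p = _cv_dual_vector(K, y_std[perm], folds_p, config, eps)
        w_p = X.T @ a_p
        s1 += w_p
        s2 += w_p * w_p

    null_mean = s1 / n_perm
    # Sample variance (ddof=1), clipped at zero against round-off.
    var = np.maximum((s2 - n_perm * null_mean ** 2) / (n_perm - 1), 0.0)
    null_sd = np.sqrt(var)
    z, degenerate = zscore_against_null(w_true, null_mean, null_sd)
    if degenerate.any():
        logger.warning("%d feature(s) with degenerate permutation null (sd=0)",
                       int(degenerate.sum()))
    if feature_ids is None:
        feature_ids = list(range(n_feat))
    return WeightMap(
        feature_ids=list(feature_ids), weights=w_true, z_scores=z,
        null_mean=null_mean, null_sd=null_sd, degenerate=degenerate,
    )
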