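"""Multilabel classifiers: binary relevance, classifier chains and ML-kNN.

Base learners are a closed-form ridge regression on {0,1} targets, a
K-nearest-neighbour voter, and a linear support vector machine (delegated
to scikit-learn; the multilabel wrappers, selection and evaluation around
it are local).  ML-kNN is used standalone.

Features are standardized with training-fold statistics before any
distance or fit; kNN and ML-kNN scores are in [0, 1] and thresholded at
0.5 (``>=``), ridge scores are the raw linear output thresholded at 0.5,
and the SVM uses its native sign rule with decision values as ranking
scores.  Everything is deterministic: kNN distance ties are broken by
training index.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.svm import SVC

# Hyperparameter search grids used in model selection.
RIDGE_LAMBDA_GRID = tuple(np.arange(0.25, 2.01, 0.25))
KNN_K_GRID = tuple(range(5, 35, 5))
SVM_C_GRID = tuple(np.round(np.arange(0.2, 2.01, 0.2), 10))
MLKNN_K = 15

BASES = ("ridge", "knn", "svm")


@dataclass(frozen=True)
class ModelConfig:
    """One point of the model grid."""

    strategy: str  # "BR" | "CC" | "MLKNN"
    base: str | None = None  # for BR/CC
    params: dict = field(default_factory=dict)
    selection: str = "MLMIM"
    n_features: int = 10
    chain_order: tuple[int, ...] | None = None

    @property
    def name(self) -> str:
        if self.strategy == "MLKNN":
            return "ML-KNN"
        return f"{self.base.upper().replace('RIDGE', 'RR')}-{self.strategy}"


#: The configuration that won model selection in the reference study:
#: KNN under binary relevance with K=20 and 10 MLMIM-selected features.
BEST_CONFIG = ModelConfig("BR", "knn", {"K": 20}, "MLMIM", 10)


@dataclass
class Standardizer:
    mean: np.ndarray
    scale: np.ndarray

    @classmethod
    def fit(cls, X: np.ndarray) -> "Standardizer":
        mean = X.mean(axis=0)
        scale = X.std(axis=0)
        scale = np.where(scale > 0, scale, 1.0)
        return cls(mean, scale)

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.mean) / self.scale


# ---------------------------------------------------------------------------
# Base learners (binary targets)
# ---------------------------------------------------------------------------

class _ConstantBase:
    """Degenerate scorer for constant label columns."""

    def __init__(self, value: float):
        self.value = float(value)

    def scores(self, X: np.ndarray) -> np.ndarray:
        return np.full(len(X), self.value)

    def predict(self, X: np.ndarray, threshold: float = 0.5) -> np.ndarray:
        return (self.scores(X) >= threshold).astype(np.int8)


class RidgeScorer:
    """Closed-form ridge regression with an (optional) unpenalized intercept.

    beta = (Xc'Xc + lambda I)^-1 Xc'yc on centred data; the ranking score
    is the raw linear output.
    """

    def __init__(self, X: np.ndarray, y: np.ndarray, lam: float,
                 fit_intercept: bool = True):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        x_mean = X.mean(axis=0) if fit_intercept else np.zeros(X.shape[1])
        y_mean = y.mean() if fit_intercept else 0.0
        Xc = X - x_mean
        A = Xc.T @ Xc + lam * np.eye(X.shape[1])
        self.beta = np.linalg.solve(A, Xc.T @ (y - y_mean))
        self.intercept = float(y_mean - x_mean @ self.beta)

    def scores(self, X: np.ndarray) -> np.ndarray:
        return X @ self.beta + self.intercept

    def predict(self, X: np.ndarray, threshold: float = 0.5) -> np.ndarray:
        return (self.scores(X) >= threshold).astype(np.int8)


def _knn_indices(Xtr: np.ndarray, Xq: np.ndarray, k: int) -> np.ndarray:
    """Indices of the k nearest training rows per query, ties by index."""
    # Quadratic expansion keeps memory at O(nq * ntr); identical rows still
    # produce identical distances, so stable argsort breaks ties by index.
    d2 = (
        (Xq**2).sum(axis=1)[:, None]
        + (Xtr**2).sum(axis=1)[None, :]
        - 2.0 * (Xq @ Xtr.T)
    )
    return np.argsort(d2, axis=1, kind="stable")[:, :k]


class _KNNBase:
    """K-nearest-neighbour positive-vote fraction."""

    def __init__(self, X: np.ndarray, y: np.ndarray, k: int):
        self.X, self.y, self.k = X, y.astype(float), int(k)

    def scores(self, X: np.ndarray) -> np.ndarray:
        if len(X) == 0:
            return np.zeros(0)
        nbrs = _knn_indices(self.X, np.asarray(X, dtype=float), self.k)
        return self.y[nbrs].mean(axis=1)

    def predict(self, X: np.ndarray, threshold: float = 0.5) -> np.ndarray:
        return (self.scores(X) >= threshold).astype(np.int8)


class _SVMBase:
    """Linear-kernel SVM; decision values as ranking scores, sign rule."""

    def __init__(self, X: np.ndarray, y: np.ndarray, C: float):
        self.clf = SVC(kernel="linear", C=C)
        self.clf.fit(X, y)

    def scores(self, X: np.ndarray) -> np.ndarray:
        if len(X) == 0:
            return np.zeros(0)
        return self.clf.decision_function(X)

    def predict(self, X: np.ndarray, threshold: float = 0.5) -> np.ndarray:
        if len(X) == 0:
            return np.zeros(0, dtype=np.int8)
        return (self.scores(X) >= 0.0).astype(np.int8)


def _fit_base(base: str, X: np.ndarray, y: np.ndarray, params: dict):
    if len(np.unique(y)) < 2:
        warnings.warn(f"constant label column; {base} base degenerates to a constant")
        return _ConstantBase(y[0] if len(y) else 0.0)
    if base == "ridge":
        return RidgeScorer(X, y, float(params.get("lambda", 1.0)))
    if base == "knn":
        return _KNNBase(X, y, int(params.get("K", 20)))
    if base == "svm":
        return _SVMBase(X, y, float(params.get("C", 1.0)))
    raise ValueError(f"unknown base learner {base!r}")


# ---------------------------------------------------------------------------
# Multilabel strategies
# ---------------------------------------------------------------------------

@dataclass
class TrainedModel:
    strategy: str
    bases: list
    standardizer: Standardizer
    n_labels: int
    chain_order: tuple[int, ...] | None = None
    feature_names: list[str] | None = None

    def scores(self, X: np.ndarray) -> np.ndarray:
        Xs = self.standardizer.transform(X)
        if self.strategy == "BR":
            if len(Xs) == 0:
                return np.zeros((0, self.n_labels))
            return np.column_stack([b.scores(Xs) for b in self.bases])
        if self.strategy == "CC":
            return self._chain(Xs)[0]
        raise ValueError(self.strategy)

    def predict(self, X: np.ndarray, threshold: float = 0.5) -> np.ndarray:
        Xs = self.standardizer.transform(X)
        if len(Xs) == 0:
            return np.zeros((0, self.n_labels), dtype=np.int8)
        if self.strategy == "BR":
            return np.column_stack(
                [b.predict(Xs, threshold) for b in self.bases]
            )
        return self._chain(Xs, threshold)[1]

    def _chain(self, Xs: np.ndarray, threshold: float = 0.5):
        n = len(Xs)
        scores = np.zeros((n, self.n_labels))
        preds = np.zeros((n, self.n_labels), dtype=np.int8)
        if n == 0:
            return scores, preds
        augment = Xs
        for pos, label in enumerate(self.chain_order):
            base = self.bases[pos]
            scores[:, label] = base.scores(augment)
            preds[:, label] = base.predict(augment, threshold)
            augment = np.column_stack([augment, preds[:, label].astype(float)])
        return scores, preds


def fit_binary_relevance(
    X: np.ndarray, Y: np.ndarray, base: str = "knn", params: dict | None = None,
    feature_names: list[str] | None = None,
) -> TrainedModel:
    """One independent base model per label."""
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y)
    std = Standardizer.fit(X)
    Xs = std.transform(X)
    bases = [_fit_base(base, Xs, Y[:, l], params or {}) for l in range(Y.shape[1])]
    return TrainedModel("BR", bases, std, Y.shape[1], feature_names=feature_names)


def fit_classifier_chain(
    X: np.ndarray, Y: np.ndarray, base: str = "knn", params: dict | None = None,
    order: tuple[int, ...] | None = None,
    feature_names: list[str] | None = None,
) -> TrainedModel:
    """Chained models: label i sees the true earlier labels at train time
    and the predicted ones at inference (default chain order = AOI order)."""
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y)
    L = Y.shape[1]
    order = tuple(order) if order is not None else tuple(range(L))
    if sorted(order) != list(range(L)):
        raise ValueError(f"chain order {order} is not a permutation of 0..{L - 1}")
    std = Standardizer.fit(X)
    augment = std.transform(X)
    bases = []
    for label in order:
        bases.append(_fit_base(base, augment, Y[:, label], params or {}))
        augment = np.column_stack([augment, Y[:, label].astype(float)])
    return TrainedModel("CC", bases, std, L, chain_order=order, feature_names=feature_names)


# ---------------------------------------------------------------------------
# ML-kNN
# ---------------------------------------------------------------------------

@dataclass
class MLkNNModel:
    strategy: str
    Xtr: np.ndarray
    k: int
    prior: np.ndarray  # P(H_l), Laplace-smoothed
    lik_pos: np.ndarray  # P(c | H_l), shape (L, k+1)
    lik_neg: np.ndarray  # P(c | not H_l)
    Ytr: np.ndarray
    standardizer: Standardizer
    feature_names: list[str] | None = None

    @property
    def n_labels(self) -> int:
        return self.Ytr.shape[1]

    def scores(self, X: np.ndarray) -> np.ndarray:
        Xs = self.standardizer.transform(X)
        if len(Xs) == 0:
            return np.zeros((0, self.n_labels))
        nbrs = _knn_indices(self.Xtr, Xs, self.k)
        counts = self.Ytr[nbrs].sum(axis=1)  # (n, L)
        out = np.zeros((len(Xs), self.n_labels))
        for l in range(self.n_labels):
            c = counts[:, l].astype(int)
            num = self.prior[l] * self.lik_pos[l, c]
            den = num + (1.0 - self.prior[l]) * self.lik_neg[l, c]
            out[:, l] = num / den
        return out

    def predict(self, X: np.ndarray, threshold: float = 0.5) -> np.ndarray:
        return (self.scores(X) >= threshold).astype(np.int8)


def fit_mlknn(
    X: np.ndarray, Y: np.ndarray, k: int = MLKNN_K, s: float = 1.0,
    feature_names: list[str] | None = None,
) -> MLkNNModel:
    """Standard ML-kNN: smoothed label priors plus per-label likelihoods of
    observing c of k active neighbours, combined by Bayes' rule."""
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y)
    m, L = Y.shape
    if k >= m:
        raise ValueError(f"k={k} must be below the number of training instances {m}")
    std = Standardizer.fit(X)
    Xs = std.transform(X)
    prior = (s + Y.sum(axis=0)) / (2.0 * s + m)
    # Neighbours of each training point, self excluded.
    nbrs = _knn_indices(Xs, Xs, k + 1)
    counts = np.zeros((m, L), dtype=int)
    for i in range(m):
        row = [j for j in nbrs[i] if j != i][:k]
        counts[i] = Y[row].sum(axis=0)
    lik_pos = np.zeros((L, k + 1))
    lik_neg = np.zeros((L, k + 1))
    for l in range(L):
        kj_pos = np.bincount(counts[Y[:, l] == 1, l], minlength=k + 1)
        kj_neg = np.bincount(counts[Y[:, l] == 0, l], minlength=k + 1)
        lik_pos[l] = (s + kj_pos) / (s * (k + 1) + kj_pos.sum())
        lik_neg[l] = (s + kj_neg) / (s * (k + 1) + kj_neg.sum())
    return MLkNNModel("MLKNN", Xs, k, prior, lik_pos, lik_neg, Y.copy(), std,
                      feature_names=feature_names)


def fit_model(config: ModelConfig, X: np.ndarray, Y: np.ndarray,
              feature_names: list[str] | None = None):
    """Dispatch on a :class:`ModelConfig`."""
    if config.strategy == "BR":
        return fit_binary_relevance(X, Y, config.base, config.params, feature_names)
    if config.strategy == "CC":
        return fit_classifier_chain(
            X, Y, config.base, config.params, config.chain_order, feature_names
        )
    if config.strategy == "MLKNN":
        return fit_mlknn(X, Y, int(config.params.get("k", MLKNN_K)),
                         feature_names=feature_names)
    raise ValueError(f"unknown strategy {config.strategy!r}")


def score(model, X: np.ndarray) -> np.ndarray:
    """Ranking scores, shape (n, L)."""
    return model.scores(X)


def predict(model, X: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Hard predictions, shape (n, L)."""
    return model.predict(X, threshold)
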