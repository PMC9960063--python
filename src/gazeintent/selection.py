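"""Mutual-information-based multilabel feature selection.

Features are discretized (floor by default, optionally equal-width bins —
flooring pixel-scale features yields very large alphabets) and scored
against the binary labels with empirical mutual information in bits.
Multilabel relevance is the sum of per-label MI.  Four greedy forward
rankers are provided:

* ``MLMIM`` — relevance only;
* ``MLMRMR`` — relevance minus mean redundancy (MI with already-selected);
* ``MLJMI`` — mean joint MI of the candidate paired with each selected
  feature against the labels;
* ``FSCORE`` — per-label ANOVA F statistic summed over labels.

``MIFS`` and ``RFS`` are accepted as strategy names for interface
compatibility but are not implemented.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
from sklearn.feature_selection import f_classif
from sklearn.metrics import mutual_info_score

METHODS = ("MLMIM", "MLJMI", "MLMRMR", "FSCORE")
UNIMPLEMENTED = ("MIFS", "RFS")

#: Grid of feature-set sizes scanned during model search (5:5:40).
N_FEATURES_GRID = tuple(range(5, 45, 5))


def discretize(x: np.ndarray, scheme: str = "floor", bins: int = 10) -> np.ndarray:
    """Map a numeric column to integer codes (``floor`` or ``equal_width``)."""
    x = np.asarray(x, dtype=float)
    if scheme == "floor":
        return np.floor(x).astype(np.int64)
    if scheme == "equal_width":
        lo, hi = x.min(), x.max()
        if hi <= lo:
            return np.zeros(len(x), dtype=np.int64)
        edges = np.linspace(lo, hi, bins + 1)
        return np.clip(np.digitize(x, edges[1:-1]), 0, bins - 1)
    raise ValueError(f"unknown discretization scheme {scheme!r}")


def discretized_mi(
    x: np.ndarray, y: np.ndarray, scheme: str = "floor", bins: int = 10
) -> float:
    """Empirical mutual information of discretized ``x`` vs ``y`` in bits.

    Nonnegative and bounded by ``min(H(X), H(Y))``; zero for a constant
    column.
    """
    xd = discretize(x, scheme, bins)
    return float(mutual_info_score(xd, np.asarray(y)) / np.log(2.0))


def _joint_mi(xd_a: np.ndarray, xd_b: np.ndarray, y: np.ndarray) -> float:
    """I((A, B); Y) in bits, with the pair encoded as one discrete variable."""
    _, pair = np.unique(np.column_stack([xd_a, xd_b]), axis=0, return_inverse=True)
    return float(mutual_info_score(pair, y) / np.log(2.0))


def select_features(
    X: np.ndarray,
    Y: np.ndarray,
    method: str = "MLMIM",
    n_features: int = 10,
    scheme: str = "floor",
    bins: int = 10,
) -> list[int]:
    """Greedy forward ranking of feature indices (ties broken by index)."""
    method = method.upper()
    if method in UNIMPLEMENTED:
        raise NotImplementedError(
            f"{method} selection is not implemented; available: {', '.join(METHODS)}"
        )
    if method not in METHODS:
        raise ValueError(f"unknown selection method {method!r}")
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y)
    p = X.shape[1]
    if n_features > p:
        raise ValueError(f"n_features={n_features} exceeds feature count {p}")

    if method == "FSCORE":
        scores = np.zeros(p)
        for l in range(Y.shape[1]):
            if len(np.unique(Y[:, l])) < 2:
                continue
            with np.errstate(divide="ignore", invalid="ignore"):
                f, _ = f_classif(X, Y[:, l])
            # A perfectly separating feature has zero within-class variance
            # and an infinite F; cap it at a huge finite value so it ranks
            # first instead of being dropped.
            scores += np.nan_to_num(f, nan=0.0, posinf=1e300)
        order = np.argsort(-scores, kind="stable")
        return [int(i) for i in order[:n_features]]

    Xd = [discretize(X[:, j], scheme, bins) for j in range(p)]
    relevance = np.array(
        [
            sum(
                mutual_info_score(Xd[j], Y[:, l]) / np.log(2.0)
                for l in range(Y.shape[1])
            )
            for j in range(p)
        ]
    )
    if method == "MLMIM":
        order = np.argsort(-relevance, kind="stable")
        return [int(i) for i in order[:n_features]]

    selected: list[int] = [int(np.argmax(relevance))]
    remaining = [j for j in range(p) if j != selected[0]]
    mi_ff: dict[tuple[int, int], float] = {}

    def redundancy(a: int, b: int) -> float:
        key = (min(a, b), max(a, b))
        if key not in mi_ff:
            mi_ff[key] = float(mutual_info_score(Xd[a], Xd[b]) / np.log(2.0))
        return mi_ff[key]

    jmi_cache: dict[tuple[int, int], float] = {}

    def joint(a: int, b: int) -> float:
        key = (min(a, b), max(a, b))
        if key not in jmi_cache:
            jmi_cache[key] = sum(
                _joint_mi(Xd[a], Xd[b], Y[:, l]) for l in range(Y.shape[1])
            )
        return jmi_cache[key]

    while len(selected) < n_features:
        best_j, best_score = -1, -np.inf
        for j in remaining:
            if method == "MLMRMR":
                score = relevance[j] - np.mean([redundancy(j, s) for s in selected])
            else:  # MLJMI
                score = np.mean([joint(j, s) for s in selected])
            if score > best_score + 1e-15:
                best_j, best_score = j, score
        selected.append(best_j)
        remaining.remove(best_j)
    return selected


def selection_report(
    X: np.ndarray,
    Y: np.ndarray,
    method: str,
    n_features: int,
    feature_names: list[str] | None = None,
    scheme: str = "floor",
    bins: int = 10,
) -> dict:
    """Selection summary with per-feature MI scores (Fig.-6-style data)."""
    order = select_features(X, Y, method, n_features, scheme, bins)
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y)
    mi = {
        j: sum(
            discretized_mi(X[:, j], Y[:, l], scheme, bins) for l in range(Y.shape[1])
        )
        for j in order
    }
    names = feature_names or [f"f{j}" for j in range(X.shape[1])]
    return {
        "method": method,
        "n_features": n_features,
        "selected": [
            {"index": j, "name": names[j], "mi_bits": mi[j]} for j in order
        ],
    }


def save_selection_report(report: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report, indent=1), encoding="utf-8")
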