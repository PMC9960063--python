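"""MLSMOTE: multilabel synthetic minority oversampling.

Training folds of the visit-intention problem are imbalanced — label
vectors involving the pop-up AOI are rare.  MLSMOTE treats each label whose
imbalance ratio (IRLbl) exceeds the mean ratio (MeanIR) as a minority
seed set: every instance bearing the label spawns one synthetic instance
interpolated toward one of its k nearest minority neighbours, with the
synthetic label vector decided by majority vote over seed + neighbours.
Test folds are never balanced.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class ImbalanceProfile:
    """Per-label imbalance ratios.  IRLbl_l = max count / count_l (>= 1)."""

    irlbl: np.ndarray
    mean_ir: float

    @classmethod
    def from_labels(cls, Y: np.ndarray) -> "ImbalanceProfile":
        counts = np.asarray(Y).sum(axis=0).astype(float)
        max_count = counts.max() if counts.size else 0.0
        with np.errstate(divide="ignore"):
            irlbl = np.where(counts > 0, max_count / np.maximum(counts, 1e-300), np.inf)
        finite = irlbl[np.isfinite(irlbl)]
        mean_ir = float(finite.mean()) if finite.size else np.inf
        return cls(irlbl, mean_ir)

    def minority_labels(self) -> list[int]:
        return [l for l in range(len(self.irlbl)) if self.irlbl[l] > self.mean_ir]


def _binary_columns(X: np.ndarray) -> np.ndarray:
    return np.array([np.isin(X[:, j], (0.0, 1.0)).all() for j in range(X.shape[1])])


def mlsmote(
    X: np.ndarray,
    Y: np.ndarray,
    k_neighbors: int = 5,
    seed: int | np.random.Generator = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Oversample minority-label instances by neighbour interpolation.

    One pass over the labels with ``IRLbl > MeanIR`` (both computed on the
    input): each seed instance bearing the label produces one synthetic
    row, its numeric features uniformly interpolated between the seed and a
    randomly chosen one of its ``k_neighbors`` nearest neighbours within
    the minority bag, its labels set where active in more than half of
    seed + neighbours.  Binary feature columns are rounded back to {0, 1}.
    Originals are returned unchanged, synthetics appended after them;
    deterministic given ``seed``.  Labels whose bag has fewer than two
    instances are skipped with a warning.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y)
    profile = ImbalanceProfile.from_labels(Y)
    binary = _binary_columns(X)
    new_X: list[np.ndarray] = []
    new_Y: list[np.ndarray] = []
    for label in profile.minority_labels():
        bag = np.flatnonzero(Y[:, label] == 1)
        if len(bag) < 2:
            warnings.warn(
                f"MLSMOTE: label {label} has {len(bag)} minority instance(s); skipped"
            )
            continue
        Xb, Yb = X[bag], Y[bag]
        # All-pairs distances within the bag (bags are small by definition).
        d2 = ((Xb[:, None, :] - Xb[None, :, :]) ** 2).sum(axis=2)
        np.fill_diagonal(d2, np.inf)
        k = min(k_neighbors, len(bag) - 1)
        for i in range(len(bag)):
            nbrs = np.argsort(d2[i], kind="stable")[:k]
            ref = nbrs[rng.integers(len(nbrs))]
            frac = rng.random()
            synth = Xb[i] + frac * (Xb[ref] - Xb[i])
            synth[binary] = np.round(synth[binary])
            votes = Yb[nbrs].sum(axis=0) + Yb[i]
            new_X.append(synth)
            new_Y.append((votes > (k + 1) / 2).astype(Y.dtype))
    if not new_X:
        return X.copy(), Y.copy()
    return np.vstack([X, np.vstack(new_X)]), np.vstack([Y, np.vstack(new_Y)])
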