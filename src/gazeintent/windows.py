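"""Window segmentation, visit-intention labels and balanced fold assignment.

A recording of length ``T`` seconds is cut into ``floor(T / tau)``
contiguous windows of ``tau`` seconds; the trailing remainder is discarded.
The prediction target for window ``t`` is the binary vector over AOIs
saying which of them receive at least one (filtered) fixation during the
window.

Users are split into K cross-validation folds so that no fold shares a
user and the total window counts per fold are as even as possible; the
assignment is an exact mixed-integer program minimising the sum of
absolute deviations of per-fold window sums from their mean.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import LinearConstraint, milp
from scipy.optimize import Bounds

from .gaze_io import GazeRecording
from .layout import Layout, LayoutState, hit_test

DEFAULT_TAU_S = 5.0
DEFAULT_K_FOLDS = 10


@dataclass(frozen=True)
class TimeWindow:
    index: int  # 1-based window index t
    to_ms: float
    tf_ms: float


def segment_windows(duration_ms: float, tau_s: float) -> list[TimeWindow]:
    """Tile ``[0, floor(T/tau)*tau)`` with tau-second windows."""
    if tau_s <= 0:
        raise ValueError("tau_s must be positive")
    tau_ms = tau_s * 1000.0
    n = int(duration_ms // tau_ms)
    return [TimeWindow(t + 1, t * tau_ms, (t + 1) * tau_ms) for t in range(n)]


def fixation_hits(
    recording: GazeRecording, layout: Layout, layout_state: LayoutState
) -> list[tuple[str, int | None]]:
    """Hit-test each fixation's centroid at its onset time.

    Attribution at onset is deliberate: the pop-up can open or close while
    a fixation is in progress, and the onset is when the visit decision
    materialises.
    """
    return [
        hit_test((f.cx, f.cy), f.onset_ms, layout, layout_state)
        for f in recording.fixations
    ]


def label_windows(
    recording: GazeRecording,
    layout: Layout,
    layout_state: LayoutState,
    tau_s: float = DEFAULT_TAU_S,
    hits: Sequence[tuple[str, int | None]] | None = None,
) -> np.ndarray:
    """Visit-intention matrix, shape ``(floor(T/tau), n_aois)``, dtype int8.

    A fixation counts toward every window its ``[onset, offset)`` span
    overlaps (fixations can be interrupted by window transitions), with the
    AOI resolved at its onset.
    """
    windows = segment_windows(recording.duration_ms, tau_s)
    n = layout.n_aois
    labels = np.zeros((len(windows), n), dtype=np.int8)
    if not windows:
        return labels
    if hits is None:
        hits = fixation_hits(recording, layout, layout_state)
    tau_ms = tau_s * 1000.0
    horizon = windows[-1].tf_ms
    for f, (_, aoi) in zip(recording.fixations, hits):
        if aoi is None or f.onset_ms >= horizon:
            continue
        first = int(f.onset_ms // tau_ms)
        last = int(min(np.nextafter(f.offset_ms, -np.inf), horizon - 1e-9) // tau_ms)
        labels[first : last + 1, aoi - 1] = 1
    return labels


def majority_class_ratio(
    labelsets: Sequence[np.ndarray],
) -> tuple[list[tuple[int, float]], tuple[tuple[int, ...], float]]:
    """Per-AOI majority class and ratio, plus the whole-vector majority.

    Returns ``(per_aoi, (modal_vector, ratio))`` where ``per_aoi[j]`` is
    ``(class, ratio)``.  Ties at 0.5 report class 1.  The whole-vector
    majority is the empirical frequency of the modal label vector.
    """
    stacked = np.vstack([ls for ls in labelsets if len(ls)])
    if stacked.size == 0:
        raise ValueError("no label rows to compute majority class from")
    m = stacked.shape[0]
    per_aoi = []
    for j in range(stacked.shape[1]):
        p1 = float(stacked[:, j].mean())
        cls = 1 if p1 >= 0.5 else 0
        per_aoi.append((cls, max(p1, 1.0 - p1)))
    vecs, counts = np.unique(stacked, axis=0, return_counts=True)
    # Deterministic tie-break: np.unique sorts rows, argmax takes the first.
    best = int(np.argmax(counts))
    modal = tuple(int(v) for v in vecs[best])
    return per_aoi, (modal, float(counts[best]) / m)


# ---------------------------------------------------------------------------
# Fold assignment MILP
# ---------------------------------------------------------------------------

@dataclass
class FoldAssignment:
    users: list[str]
    n_folds: int
    fold_of: dict[str, int]  # user -> fold in 0..K-1
    fold_sums: np.ndarray
    objective: float

    def users_in_fold(self, k: int) -> list[str]:
        return [u for u in self.users if self.fold_of[u] == k]


def assign_folds(window_counts: Mapping[str, int], n_folds: int = DEFAULT_K_FOLDS) -> FoldAssignment:
    """Assign each user to exactly one fold, balancing window totals.

    Solves ``min sum_k U_k`` with ``U_k >= +-(x_k - xbar)``, where
    ``x_k = sum_{u in fold k} P_u`` and ``xbar = sum_u P_u / K`` — the
    linearised sum of absolute deviations.  Exact HiGHS solve.
    """
    users = list(window_counts.keys())
    P = np.array([window_counts[u] for u in users], dtype=float)
    N, K = len(users), int(n_folds)
    if K < 2:
        raise ValueError("need at least 2 folds")
    if K > N:
        raise ValueError(f"infeasible: {K} folds for {N} users")
    if np.any(P < 0):
        raise ValueError("window counts must be nonnegative")
    xbar = P.sum() / K

    ny = N * K
    nvar = ny + K
    c = np.concatenate([np.zeros(ny), np.ones(K)])

    constraints = []
    # (1b) each user in exactly one fold
    A_assign = np.zeros((N, nvar))
    for u in range(N):
        A_assign[u, u * K : (u + 1) * K] = 1.0
    constraints.append(LinearConstraint(A_assign, 1.0, 1.0))
    # U_k - (x_k - xbar) >= 0  and  U_k + (x_k - xbar) >= 0
    A_pos = np.zeros((K, nvar))
    A_neg = np.zeros((K, nvar))
    for k in range(K):
        for u in range(N):
            A_pos[k, u * K + k] = -P[u]
            A_neg[k, u * K + k] = P[u]
        A_pos[k, ny + k] = 1.0
        A_neg[k, ny + k] = 1.0
    constraints.append(LinearConstraint(A_pos, -xbar, np.inf))
    constraints.append(LinearConstraint(A_neg, xbar, np.inf))

    integrality = np.concatenate([np.ones(ny), np.zeros(K)])
    bounds = Bounds(
        lb=np.concatenate([np.zeros(ny), np.zeros(K)]),
        ub=np.concatenate([np.ones(ny), np.full(K, np.inf)]),
    )
    res = milp(c, constraints=constraints, integrality=integrality, bounds=bounds)
    if not res.success:
        raise RuntimeError(f"fold-assignment MILP failed: {res.message}")
    y = np.round(res.x[:ny]).reshape(N, K)
    fold_of = {users[u]: int(np.argmax(y[u])) for u in range(N)}
    fold_sums = np.array([sum(P[u] for u in range(N) if np.argmax(y[u]) == k) for k in range(K)])
    objective = float(np.abs(fold_sums - xbar).sum())
    return FoldAssignment(users, K, fold_of, fold_sums, objective)


def enumerate_folds_oracle(
    window_counts: Mapping[str, int], n_folds: int, cap: int = 3**10
) -> tuple[float, dict[str, int]]:
    """Brute-force optimum of the fold-balance objective (test oracle)."""
    users = list(window_counts.keys())
    P = np.array([window_counts[u] for u in users], dtype=float)
    N, K = len(users), int(n_folds)
    if K**N > cap:
        raise ValueError(f"enumeration size {K}^{N} exceeds cap {cap}")
    xbar = P.sum() / K
    best_obj, best_assign = np.inf, None
    for assign in itertools.product(range(K), repeat=N):
        sums = np.zeros(K)
        for u, k in enumerate(assign):
            sums[k] += P[u]
        obj = float(np.abs(sums - xbar).sum())
        if obj < best_obj - 1e-12:
            best_obj, best_assign = obj, assign
    return best_obj, {u: k for u, k in zip(users, best_assign)}
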