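"""Window-level feature extraction for visit-intention prediction.

Three feature families are computed for every window instance ``t >= 2``
(features describe the past, so the first window has no usable history):

* **fixation history** — per-AOI recency/lag indicators, per-component
  visit statistics, and the population-level ``Heat_AOI`` visit
  frequencies taken from training-fold users at the same window index;
* **visual kinematics** — position, velocity and acceleration statistics
  of the raw gaze signal over the previous window (derivatives via finite
  differences on valid-sample chains);
* **oculomotor statistics** — counts and duration/amplitude summaries of
  all fixations and saccades completed before the window starts.

Causality contract: no feature of instance ``(user, t)`` reads any data of
that user at or after the window start ``To(t)``, and only training-fold
users ever contribute to ``Heat_AOI``.

Units: ``*_tslv`` in seconds; ``*_atv``/``*_atbv`` and fixation-duration
statistics in milliseconds; positions px, velocities px/s, accelerations
px/s^2; saccade amplitudes px.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .gaze_io import GazeRecording, valid_sample_chains
from .layout import Layout, LayoutState
from .windows import FoldAssignment, fixation_hits, label_windows, segment_windows

KINEMATIC_NAMES = [
    f"{stat}{axis}"
    for axis in ("X", "Y")
    for stat in ("coord", "Mean", "Std", "Vel", "MeanVel", "StdVel", "Acl", "MeanAcl", "StdAcl")
]
OCULOMOTOR_NAMES = [
    "NFix", "TPromFix", "TMaxFix", "TMinFix",
    "NSac", "APromSac", "AMaxSac", "AMinSac",
]


def component_id_map(layout: Layout) -> dict[str, int]:
    """Stable 1-based integer ids for components, in layout order."""
    return {c.id: i + 1 for i, c in enumerate(layout.components)}


def feature_registry(layout: Layout) -> list[str]:
    """Ordered column names of the design matrix (persisted with models)."""
    n = layout.n_aois
    names: list[str] = []
    for fam in ("tslv", "r1", "r2", "r3", "end_r1"):
        names += [f"AOI_{j}_{fam}" for j in range(1, n + 1)]
    names.append("End_r1")
    comps = [c.id for c in layout.components]
    for fam in ("his", "end_r1", "tslv", "atv", "atbv"):
        names += [f"{c}_{fam}" for c in comps]
    names.append("Component_end")
    names += [f"Heat_AOI_{j}" for j in range(1, n + 1)]
    names += KINEMATIC_NAMES
    names += OCULOMOTOR_NAMES
    return names


def feature_families(layout: Layout) -> dict[str, str]:
    """Family tag per registry column (for reports and ablations)."""
    fams = {}
    for name in feature_registry(layout):
        if name.startswith("Heat_AOI"):
            fams[name] = "heat"
        elif name in KINEMATIC_NAMES:
            fams[name] = "kinematics"
        elif name in OCULOMOTOR_NAMES:
            fams[name] = "oculomotor"
        else:
            fams[name] = "fixation_history"
    return fams


# ---------------------------------------------------------------------------
# Family extractors
# ---------------------------------------------------------------------------

def aoi_history_features(
    labels: np.ndarray,
    fix_spans: Sequence[tuple[float, float, int | None]],
    t: int,
    tau_s: float,
    n_aois: int,
) -> dict[str, float]:
    """Per-AOI recency and lag features for window ``t`` (1-based).

    ``labels`` holds rows for windows before ``t`` (at least ``t-1`` rows);
    ``fix_spans`` are ``(onset_ms, offset_ms, aoi_index_or_None)`` per
    fixation.  ``tslv`` is the gap in seconds between the window start and
    the onset of the last fixation in the AOI (0 if never visited); lag
    flags ``r1..r3`` echo the label of windows ``t-1..t-3`` (0 before the
    recording starts); ``end_r1`` one-hot marks the AOI holding the last
    fixation of the previous window, summarised by the indicator
    ``End_r1 = sum_j j * end_r1_j``.
    """
    to_ms = (t - 1) * tau_s * 1000.0
    prev_lo, prev_hi = to_ms - tau_s * 1000.0, to_ms
    out: dict[str, float] = {}
    last_onset = [None] * n_aois
    last_prev_fix: tuple[float, int] | None = None  # (onset, aoi) in window t-1
    for onset, offset, aoi in fix_spans:
        if aoi is None or onset >= to_ms:
            continue
        j = aoi - 1
        if last_onset[j] is None or onset > last_onset[j]:
            last_onset[j] = onset
        if offset > prev_lo and onset < prev_hi:
            if last_prev_fix is None or onset > last_prev_fix[0]:
                last_prev_fix = (onset, aoi)
    # "Last fixation of the previous window" considers all fixations there,
    # whitespace included — a window ending on whitespace one-hots nothing.
    for onset, offset, aoi in fix_spans:
        if aoi is None and offset > prev_lo and onset < prev_hi and onset < to_ms:
            if last_prev_fix is not None and onset > last_prev_fix[0]:
                last_prev_fix = (onset, 0)
    for j in range(1, n_aois + 1):
        out[f"AOI_{j}_tslv"] = (
            0.0 if last_onset[j - 1] is None else (to_ms - last_onset[j - 1]) / 1000.0
        )
        for q in (1, 2, 3):
            tq = t - q
            out[f"AOI_{j}_r{q}"] = float(labels[tq - 1, j - 1]) if tq >= 1 else 0.0
        out[f"AOI_{j}_end_r1"] = float(
            last_prev_fix is not None and last_prev_fix[1] == j
        )
    out["End_r1"] = float(
        sum(j * out[f"AOI_{j}_end_r1"] for j in range(1, n_aois + 1))
    )
    return out


def component_history_features(
    fix_comp_spans: Sequence[tuple[float, float, str | None]],
    t: int,
    tau_s: float,
    comp_ids: Mapping[str, int],
) -> dict[str, float]:
    """Per-component visit history for window ``t``.

    ``his`` flags any past fixation on the component; ``tslv`` mirrors the
    AOI version; ``atv`` is the mean fixation duration on the component so
    far (ms); ``atbv`` the mean gap between consecutive visits (ms,
    offset-to-next-onset); ``Component_end`` is the integer id of the last
    component fixated in the previous window (0 if none), with a one-hot
    ``{c}_end_r1`` companion.
    """
    to_ms = (t - 1) * tau_s * 1000.0
    prev_lo = to_ms - tau_s * 1000.0
    visits: dict[str, list[tuple[float, float]]] = {c: [] for c in comp_ids}
    last_prev: tuple[float, str] | None = None
    for onset, offset, comp in fix_comp_spans:
        if onset >= to_ms:
            continue
        if comp in visits:
            visits[comp].append((onset, offset))
            if offset > prev_lo and onset < to_ms:
                if last_prev is None or onset > last_prev[0]:
                    last_prev = (onset, comp)
    out: dict[str, float] = {}
    end_comp = last_prev[1] if last_prev is not None else None
    for comp, cid in comp_ids.items():
        vs = sorted(visits[comp])
        out[f"{comp}_his"] = float(bool(vs))
        out[f"{comp}_end_r1"] = float(comp == end_comp)
        out[f"{comp}_tslv"] = (to_ms - vs[-1][0]) / 1000.0 if vs else 0.0
        out[f"{comp}_atv"] = float(np.mean([b - a for a, b in vs])) if vs else 0.0
        gaps = [vs[i + 1][0] - vs[i][1] for i in range(len(vs) - 1)]
        out[f"{comp}_atbv"] = float(np.mean(gaps)) if gaps else 0.0
    out["Component_end"] = float(comp_ids[end_comp]) if end_comp is not None else 0.0
    return out


def heat_aoi(
    train_labelsets: Sequence[np.ndarray], t: int, n_aois: int
) -> np.ndarray:
    """Population visit frequency per AOI at window index ``t``.

    Mean of the visit-intention labels at window ``t`` across training-fold
    recordings long enough to contain that window; zeros when none are.
    Never touches test-fold users — the caller passes training labels only.
    """
    rows = [ls[t - 1] for ls in train_labelsets if len(ls) >= t]
    if not rows:
        return np.zeros(n_aois)
    return np.mean(rows, axis=0).astype(float)


def kinematics_features(
    samples: pd.DataFrame, lo_ms: float, hi_ms: float
) -> dict[str, float]:
    """Position/velocity/acceleration statistics over ``[lo_ms, hi_ms)``.

    Derivatives use ``np.gradient`` per valid-sample chain (central
    differences inside, second-order one-sided at the edges — exact for
    quadratic trajectories); chains broken by track-loss gaps never mix.
    ``coord``/``Vel``/``Acl`` take the last available value in the window;
    ``Mean``/``Std`` aggregate over it.  Degenerate windows yield zeros.
    """
    t_ms = samples["t_ms"].to_numpy(dtype=float)
    mask = (t_ms >= lo_ms) & (t_ms < hi_ms)
    win = samples.loc[mask]
    out = {name: 0.0 for name in KINEMATIC_NAMES}
    chains = valid_sample_chains(win.reset_index(drop=True))
    if not chains:
        return out
    tw = win["t_ms"].to_numpy(dtype=float) / 1000.0
    for axis, col in (("X", "x_px"), ("Y", "y_px")):
        pos_all: list[np.ndarray] = []
        vel_all: list[np.ndarray] = []
        acl_all: list[np.ndarray] = []
        xs = win[col].to_numpy(dtype=float)
        for chain in chains:
            p, ts = xs[chain], tw[chain]
            pos_all.append(p)
            if len(chain) >= 2:
                v = np.gradient(p, ts, edge_order=2 if len(chain) >= 3 else 1)
                vel_all.append(v)
                if len(chain) >= 3:
                    acl_all.append(np.gradient(v, ts, edge_order=2))
        pos = np.concatenate(pos_all)
        out[f"coord{axis}"] = float(pos[-1])
        out[f"Mean{axis}"] = float(pos.mean())
        out[f"Std{axis}"] = float(pos.std())
        if vel_all:
            vel = np.concatenate(vel_all)
            out[f"Vel{axis}"] = float(vel[-1])
            out[f"MeanVel{axis}"] = float(vel.mean())
            out[f"StdVel{axis}"] = float(vel.std())
        if acl_all:
            acl = np.concatenate(acl_all)
            out[f"Acl{axis}"] = float(acl[-1])
            out[f"MeanAcl{axis}"] = float(acl.mean())
            out[f"StdAcl{axis}"] = float(acl.std())
    return out


def oculomotor_features(rec: GazeRecording, to_ms: float) -> dict[str, float]:
    """Fixation/saccade count and summary statistics before ``to_ms``.

    Only fixations fully completed (offset <= window start) count — the
    duration of a fixation still in progress is not observable at
    prediction time.  A saccade counts once its landing fixation has begun.
    """
    durs = [f.duration_ms for f in rec.fixations if f.offset_ms <= to_ms]
    amps = [
        s.amplitude_px
        for s in rec.saccades
        if rec.fixations[s.to_fix].onset_ms < to_ms
    ]
    return {
        "NFix": float(len(durs)),
        "TPromFix": float(np.mean(durs)) if durs else 0.0,
        "TMaxFix": float(np.max(durs)) if durs else 0.0,
        "TMinFix": float(np.min(durs)) if durs else 0.0,
        "NSac": float(len(amps)),
        "APromSac": float(np.mean(amps)) if amps else 0.0,
        "AMaxSac": float(np.max(amps)) if amps else 0.0,
        "AMinSac": float(np.min(amps)) if amps else 0.0,
    }


# ---------------------------------------------------------------------------
# Per-recording extraction and fold assembly
# ---------------------------------------------------------------------------

def window_features(
    rec: GazeRecording,
    layout: Layout,
    layout_state: LayoutState,
    t: int,
    tau_s: float,
    hits: Sequence[tuple[str, int | None]] | None = None,
) -> dict[str, float]:
    """Base feature row (everything except ``Heat_AOI``) for window ``t``.

    Works from history alone, so it is well defined even on a recording
    truncated exactly at the window start.
    """
    if t < 2:
        raise ValueError("features need a previous window: t must be >= 2")
    if hits is None:
        hits = fixation_hits(rec, layout, layout_state)
    to_ms = (t - 1) * tau_s * 1000.0
    aoi_spans = [
        (f.onset_ms, f.offset_ms, aoi) for f, (_, aoi) in zip(rec.fixations, hits)
    ]
    comp_spans = [
        (f.onset_ms, f.offset_ms, comp if comp != "whitespace" else None)
        for f, (comp, _aoi) in zip(rec.fixations, hits)
    ]
    # Label history for the lag features, from fixations before the window.
    past = _history_labels(aoi_spans, t, tau_s, layout.n_aois)
    row: dict[str, float] = {}
    row.update(aoi_history_features(past, aoi_spans, t, tau_s, layout.n_aois))
    row.update(component_history_features(comp_spans, t, tau_s, component_id_map(layout)))
    row.update(kinematics_features(rec.samples, to_ms - tau_s * 1000.0, to_ms))
    row.update(oculomotor_features(rec, to_ms))
    return row


def _history_labels(
    aoi_spans: Sequence[tuple[float, float, int | None]],
    t: int,
    tau_s: float,
    n_aois: int,
) -> np.ndarray:
    """Visit labels of windows ``1..t-1`` from onset-attributed fixations."""
    tau_ms = tau_s * 1000.0
    horizon = (t - 1) * tau_ms
    labels = np.zeros((t - 1, n_aois), dtype=np.int8)
    for onset, offset, aoi in aoi_spans:
        if aoi is None or onset >= horizon:
            continue
        first = int(onset // tau_ms)
        last = int(min(np.nextafter(offset, -np.inf), horizon - 1e-9) // tau_ms)
        labels[first : last + 1, aoi - 1] = 1
    return labels


@dataclass
class RecordingInstances:
    """Base features and labels of one recording at a fixed tau."""

    user_id: str
    session_id: str
    features: pd.DataFrame  # index = window t (>= 2), base columns
    labels: np.ndarray  # all windows, shape (floor(T/tau), n_aois)


def extract_instances(
    rec: GazeRecording, layout: Layout, tau_s: float,
    layout_state: LayoutState | None = None,
) -> RecordingInstances:
    """Compute base features for every window ``t >= 2`` of a recording."""
    state = layout_state or LayoutState.from_events(rec.events, rec.duration_ms)
    hits = fixation_hits(rec, layout, state)
    labels = label_windows(rec, layout, state, tau_s, hits=hits)
    n_windows = len(segment_windows(rec.duration_ms, tau_s))
    rows = {
        t: window_features(rec, layout, state, t, tau_s, hits=hits)
        for t in range(2, n_windows + 1)
    }
    base_cols = [c for c in feature_registry(layout) if not c.startswith("Heat_AOI")]
    df = pd.DataFrame.from_dict(rows, orient="index")
    df = df.reindex(columns=base_cols) if len(df) else pd.DataFrame(columns=base_cols)
    return RecordingInstances(rec.user_id, rec.session_id, df, labels)


@dataclass
class FoldData:
    """Train/test design matrices of one cross-validation fold."""

    train_X: pd.DataFrame
    train_Y: np.ndarray
    test_X: pd.DataFrame
    test_Y: np.ndarray
    train_keys: list[tuple[str, str, int]]
    test_keys: list[tuple[str, str, int]]


def build_design_matrix(
    instances: Sequence[RecordingInstances],
    layout: Layout,
    fold_assignment: FoldAssignment,
    fold: int,
) -> FoldData:
    """Assemble train/test matrices for one fold.

    ``Heat_AOI`` columns are computed from training-fold recordings only
    and appended to both sides with an identical column registry.
    """
    n = layout.n_aois
    train_insts = [
        ri for ri in instances if fold_assignment.fold_of[ri.user_id] != fold
    ]
    test_insts = [
        ri for ri in instances if fold_assignment.fold_of[ri.user_id] == fold
    ]
    train_labelsets = [ri.labels for ri in train_insts]

    def assemble(insts: Sequence[RecordingInstances]):
        frames, ys, keys = [], [], []
        for ri in insts:
            if len(ri.features) == 0:
                continue
            df = ri.features.copy()
            heat = np.array(
                [heat_aoi(train_labelsets, int(t), n) for t in df.index]
            )
            for j in range(1, n + 1):
                df[f"Heat_AOI_{j}"] = heat[:, j - 1]
            frames.append(df)
            ys.append(ri.labels[df.index.to_numpy() - 1])
            keys += [(ri.user_id, ri.session_id, int(t)) for t in df.index]
        registry = feature_registry(layout)
        if not frames:
            empty = pd.DataFrame(columns=registry)
            return empty, np.zeros((0, n), dtype=np.int8), []
        X = pd.concat(frames, ignore_index=True)[registry]
        return X, np.vstack(ys), keys

    train_X, train_Y, train_keys = assemble(train_insts)
    test_X, test_Y, test_keys = assemble(test_insts)
    return FoldData(train_X, train_Y, test_X, test_Y, train_keys, test_keys)
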