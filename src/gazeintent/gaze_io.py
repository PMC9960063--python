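"""Gaze, fixation and event log I/O plus fixation/saccade derivation.

A recording is the raw signal of one user browsing one page: gaze samples at
a nominal 120 Hz, fixations (either imported from the tracker software or
detected here with a dispersion-threshold algorithm), the saccades between
them, and the interaction events (scroll, pop-up open/close, click) that
drive the dynamic layout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: Nominal sample spacing of the eye tracker (120 Hz).
SAMPLE_PERIOD_MS = 1000.0 / 120.0

#: Fixations shorter than this are discarded as noise before any analysis.
MIN_FIXATION_MS = 100.0

EVENT_KINDS = frozenset({"scroll", "popup_open", "popup_close", "click"})


@dataclass(frozen=True)
class Fixation:
    """A quasi-stationary gaze interval with its centroid in screen pixels."""

    onset_ms: float
    offset_ms: float
    cx: float
    cy: float

    @property
    def duration_ms(self) -> float:
        return self.offset_ms - self.onset_ms

    def __post_init__(self) -> None:
        if self.offset_ms <= self.onset_ms:
            raise ValueError(
                f"fixation duration must be positive: [{self.onset_ms}, {self.offset_ms})"
            )


@dataclass(frozen=True)
class Saccade:
    """Ballistic movement between two consecutive fixations."""

    from_fix: int
    to_fix: int
    duration_ms: float
    amplitude_px: float


@dataclass(frozen=True)
class InteractionEvent:
    """Timestamped browsing event.

    ``payload`` is the new vertical scroll offset in px for ``scroll``, the
    clicked component id for ``click``, and unused otherwise.
    """

    t_ms: float
    kind: str
    payload: object = None

    def __post_init__(self) -> None:
        if self.kind not in EVENT_KINDS:
            raise ValueError(f"unknown event kind {self.kind!r}")
        if self.kind == "scroll" and float(self.payload) < 0:
            raise ValueError("scroll offsets must be >= 0")


@dataclass
class GazeRecording:
    """One user x session visual record.

    ``samples`` is a DataFrame with columns ``t_ms, x_px, y_px, valid``,
    sorted by strictly increasing ``t_ms``.  Invalid samples (blinks, track
    loss) are retained but flagged.
    """

    user_id: str
    session_id: str
    samples: pd.DataFrame
    fixations: list[Fixation] = field(default_factory=list)
    saccades: list[Saccade] = field(default_factory=list)
    events: list[InteractionEvent] = field(default_factory=list)
    duration_ms: float = 0.0
    fixation_source: str = "none"  # "imported" | "idt" | "none"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        t = self.samples["t_ms"].to_numpy(dtype=float)
        if len(t) and np.any(np.diff(t) <= 0):
            bad = int(np.argmax(np.diff(t) <= 0)) + 1
            raise ValueError(f"non-monotone sample timestamps at row {bad}")
        if len(t):
            self.duration_ms = max(self.duration_ms, float(t[-1]))

    def valid_samples(self) -> pd.DataFrame:
        return self.samples[self.samples["valid"]]


# ---------------------------------------------------------------------------
# CSV I/O.  Formats: gaze `t_ms,x_px,y_px,valid`; fixation
# `onset_ms,offset_ms,cx_px,cy_px`; event `t_ms,kind,payload`.
# ---------------------------------------------------------------------------

def read_gaze_log(
    path: str | Path,
    *,
    user_id: str = "",
    session_id: str = "",
    fixation_path: str | Path | None = None,
    event_path: str | Path | None = None,
) -> GazeRecording:
    """Read a gaze sample CSV (and optional fixation / event CSVs).

    Raises ``ValueError`` naming the offending line for malformed rows and
    for non-monotone timestamps.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str)
    expected = ["t_ms", "x_px", "y_px", "valid"]
    if list(df.columns) != expected:
        raise ValueError(f"{path}: expected header {expected}, got {list(df.columns)}")
    out = {}
    for col in ("t_ms", "x_px", "y_px"):
        vals = np.empty(len(df), dtype=float)
        for i, raw in enumerate(df[col]):
            try:
                # float() round-trips repr() output exactly, unlike the fast
                # csv parsers, which keeps write->read lossless.
                vals[i] = float(raw)
            except (TypeError, ValueError):
                # +2: one for the header line, one for 1-based numbering
                raise ValueError(f"{path}: non-numeric {col} at line {i + 2}") from None
        out[col] = vals
    valid = df["valid"].str.strip().str.lower().isin(["1", "true", "t", "yes"])
    samples = pd.DataFrame(
        {"t_ms": out["t_ms"], "x_px": out["x_px"], "y_px": out["y_px"], "valid": valid.to_numpy()}
    )
    rec = GazeRecording(user_id=user_id, session_id=session_id, samples=samples)
    if fixation_path is not None:
        rec.fixations = read_fixation_log(fixation_path)
        rec.fixation_source = "imported"
    if event_path is not None:
        rec.events = read_event_log(event_path)
    return rec


def read_fixation_log(path: str | Path) -> list[Fixation]:
    df = pd.read_csv(path, dtype=str)
    return [
        Fixation(float(r.onset_ms), float(r.offset_ms), float(r.cx_px), float(r.cy_px))
        for r in df.itertuples()
    ]


def read_event_log(path: str | Path) -> list[InteractionEvent]:
    df = pd.read_csv(path, dtype=str)
    events = []
    for r in df.itertuples():
        payload: object = r.payload
        if r.kind == "scroll":
            payload = float(payload)
        events.append(InteractionEvent(float(r.t_ms), str(r.kind), payload))
    return events


def _fmt(x: float) -> str:
    # Fixed decimal formatting keeps round-trips exact and files byte-stable.
    return repr(float(x))


def write_gaze_log(rec: GazeRecording, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("t_ms,x_px,y_px,valid\n")
        for t, x, y, v in rec.samples.itertuples(index=False):
            fh.write(f"{_fmt(t)},{_fmt(x)},{_fmt(y)},{1 if v else 0}\n")


def write_fixation_log(fixations: Sequence[Fixation], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("onset_ms,offset_ms,cx_px,cy_px\n")
        for f in fixations:
            fh.write(f"{_fmt(f.onset_ms)},{_fmt(f.offset_ms)},{_fmt(f.cx)},{_fmt(f.cy)}\n")


def write_event_log(events: Sequence[InteractionEvent], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("t_ms,kind,payload\n")
        for e in events:
            payload = "" if e.payload is None else (
                _fmt(e.payload) if e.kind == "scroll" else str(e.payload)
            )
            fh.write(f"{_fmt(e.t_ms)},{e.kind},{payload}\n")


# ---------------------------------------------------------------------------
# Fixation detection and kinematic derivation
# ---------------------------------------------------------------------------

def valid_sample_chains(
    samples: pd.DataFrame, max_gap_ms: float = 2.0 * SAMPLE_PERIOD_MS
) -> list[np.ndarray]:
    """Split valid samples into runs of near-contiguous indices.

    Gaps longer than ``max_gap_ms`` (default two nominal sample intervals)
    break the chain, so difference-based quantities never straddle track
    loss.
    """
    idx = np.flatnonzero(samples["valid"].to_numpy())
    if len(idx) == 0:
        return []
    t = samples["t_ms"].to_numpy(dtype=float)[idx]
    breaks = np.flatnonzero(np.diff(t) > max_gap_ms + 1e-9)
    return [np.asarray(c) for c in np.split(idx, breaks + 1)]


def detect_fixations_idt(
    recording: GazeRecording,
    dispersion_px: float = 50.0,
    min_duration_ms: float = MIN_FIXATION_MS,
) -> list[Fixation]:
    """Dispersion-threshold (I-DT) fixation detection.

    Grows maximal windows of valid samples whose dispersion
    ``(max-min x) + (max-min y)`` stays within ``dispersion_px`` and whose
    span reaches ``min_duration_ms``.  Centroid is the mean of member
    samples.  Empty / all-invalid recordings yield an empty list.
    """
    if dispersion_px <= 0:
        raise ValueError("dispersion_px must be positive")
    fixations: list[Fixation] = []
    t_all = recording.samples["t_ms"].to_numpy(dtype=float)
    x_all = recording.samples["x_px"].to_numpy(dtype=float)
    y_all = recording.samples["y_px"].to_numpy(dtype=float)
    for chain in valid_sample_chains(recording.samples):
        t, x, y = t_all[chain], x_all[chain], y_all[chain]
        i, n = 0, len(chain)
        while i < n:
            j = i + 1
            while j < n and t[j] - t[i] < min_duration_ms:
                j += 1
            if j >= n:
                break
            win = slice(i, j + 1)
            if _dispersion(x[win], y[win]) > dispersion_px:
                i += 1
                continue
            while j + 1 < n and _dispersion(x[i : j + 2], y[i : j + 2]) <= dispersion_px:
                j += 1
            fixations.append(
                Fixation(
                    onset_ms=float(t[i]),
                    offset_ms=float(t[j]),
                    cx=float(np.mean(x[i : j + 1])),
                    cy=float(np.mean(y[i : j + 1])),
                )
            )
            i = j + 1
    return fixations


def _dispersion(x: np.ndarray, y: np.ndarray) -> float:
    return float((x.max() - x.min()) + (y.max() - y.min()))


def filter_short_fixations(
    fixations: Iterable[Fixation], min_duration_ms: float = MIN_FIXATION_MS
) -> list[Fixation]:
    """Drop fixations with duration strictly below ``min_duration_ms``.

    The boundary duration is kept: the filter removes durations < 100 ms,
    so exactly 100 ms survives.
    """
    return [f for f in fixations if f.duration_ms >= min_duration_ms]


def derive_saccades(fixations: Sequence[Fixation]) -> list[Saccade]:
    """One saccade per consecutive fixation pair.

    Amplitude is the Euclidean distance between centroids (the eye does not
    necessarily travel a straight line, but amplitude is defined endpoint to
    endpoint); duration is the gap between the first fixation's offset and
    the next one's onset.
    """
    out = []
    for i in range(len(fixations) - 1):
        a, b = fixations[i], fixations[i + 1]
        out.append(
            Saccade(
                from_fix=i,
                to_fix=i + 1,
                duration_ms=max(0.0, b.onset_ms - a.offset_ms),
                amplitude_px=math.hypot(b.cx - a.cx, b.cy - a.cy),
            )
        )
    return out


def prepare_recording(
    rec: GazeRecording,
    *,
    dispersion_px: float = 50.0,
    min_duration_ms: float = MIN_FIXATION_MS,
) -> GazeRecording:
    """Ensure a recording has filtered fixations and saccades.

    Imported fixations are preferred (mirroring tracker-software pipelines);
    the I-DT detector is the fallback when none are present.  Short
    fixations are filtered either way and saccades rebuilt.
    """
    if rec.fixations:
        fixations = rec.fixations
        source = rec.fixation_source if rec.fixation_source != "none" else "imported"
    else:
        fixations = detect_fixations_idt(rec, dispersion_px, min_duration_ms)
        source = "idt"
    fixations = filter_short_fixations(fixations, min_duration_ms)
    rec.fixations = sorted(fixations, key=lambda f: f.onset_ms)
    rec.saccades = derive_saccades(rec.fixations)
    rec.fixation_source = source
    return rec
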