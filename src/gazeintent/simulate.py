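"""Synthetic browsing cohorts with the statistical structure the method assumes.

The generator emulates users freely browsing a one-page news layout in
front of a 120 Hz eye tracker: a semi-Markov walk over six AOIs plus an
explicit whitespace state (so windows with no active AOI occur), with
per-visit fixation dwells drawn from a truncated log-normal, 30-80 ms
saccade gaps, viewport scrolling that keeps page-fixed targets visible,
and occasional registration pop-up episodes that occlude the page content
below.  Per-user transition matrices are Dirichlet perturbations of a
shared population matrix, and all users enter the page at the top — the
cross-user regularity that makes the population-level ``Heat_AOI``
feature informative.

Real gaze data this deliberately does not reproduce: saliency-driven
content effects, reading-order microstructure within a news item,
drift/calibration error, and pupil signals.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .gaze_io import (
    Fixation,
    GazeRecording,
    InteractionEvent,
    write_event_log,
    write_fixation_log,
    write_gaze_log,
)
from .layout import Component, AOIDefinition, Layout

# State indexing: 0 = whitespace, 1..6 = AOIs.
N_STATES = 7
WHITESPACE_STATE = 0
POPUP_STATE = 6

#: Fixation dwell bounds (ms): the short-fixation filter floor and the
#: longest fixation observed in the reference cohort.
DWELL_BOUNDS_MS = (100.0, 3273.0)


def study_layout() -> Layout:
    """A layout shaped like the study stimulus: sticky menu bar (AOI 1),
    two news blocks (AOIs 2-3), two advertising columns (AOIs 4-5) and a
    registration pop-up (AOI 6) that occludes the page while open."""
    comps = [
        Component("Logo", (0, 0, 200, 80), sticky=True),
        Component("Bar_Menu", (200, 0, 1280, 80), sticky=True),
        Component("Title", (250, 85, 700, 115)),
        Component("Sub_Butt", (860, 85, 1040, 115)),
        Component("Num_Pag", (40, 1150, 200, 1190)),
    ]
    aoi2, aoi3 = [], []
    for i in range(1, 4):  # first news block: three items
        y = 120 + 140 * (i - 1)
        comps += [
            Component(f"Img_{i}", (40, y, 240, y + 120)),
            Component(f"New_{i}", (250, y, 820, y + 120)),
        ]
        aoi2 += [f"Img_{i}", f"New_{i}"]
    for i in range(4, 8):  # second news block: four items
        y = 560 + 140 * (i - 4)
        comps += [
            Component(f"Img_{i}", (40, y, 240, y + 120)),
            Component(f"New_{i}", (250, y, 820, y + 120)),
        ]
        aoi3 += [f"Img_{i}", f"New_{i}"]
    for i in range(1, 5):  # advertising banners
        y = 120 + 310 * (i - 1)
        comps.append(Component(f"Banner_{i}", (860, y, 1240, y + 280)))
    comps.append(Component("Popup", (340, 200, 940, 700), sticky=True))
    aois = [
        AOIDefinition(1, ("Logo", "Bar_Menu"), dynamic=True),
        AOIDefinition(2, tuple(aoi2)),
        AOIDefinition(3, tuple(aoi3)),
        AOIDefinition(4, ("Banner_1", "Banner_2")),
        AOIDefinition(5, ("Banner_3", "Banner_4")),
        AOIDefinition(6, ("Popup",), dynamic=True, occludes_below=True),
    ]
    return Layout(screen=(1280, 1024), components=comps, aois=aois)


#: Page rectangle guaranteed free of components, used for whitespace dwells.
WHITESPACE_RECT = (300.0, 1250.0, 800.0, 2000.0)
PAGE_HEIGHT = 2048.0


def population_transition_matrix(
    persistence: np.ndarray | None = None,
    popup_entry: float = 0.008,
) -> np.ndarray:
    """Sticky population-level transition matrix over whitespace + 6 AOIs.

    High self-persistence keeps users in one semantic area for several
    seconds (reading a news block spans many consecutive fixations), so
    window labels are sparse and strongly autocorrelated — the lag-1
    structure the recency features exploit; pop-up entries are rare by
    default so AOI 6 stays a strongly minority label.
    """
    if persistence is None:
        persistence = np.array([0.35, 0.80, 0.93, 0.93, 0.90, 0.90, 0.85])
    attract = np.array([0.10, 0.06, 0.10, 0.10, 0.06, 0.06, popup_entry])
    T = np.zeros((N_STATES, N_STATES))
    for i in range(N_STATES):
        w = attract.copy()
        w[i] = 0.0
        T[i] = (1.0 - persistence[i]) * w / w.sum()
        T[i, i] = persistence[i]
    return T


@dataclass
class UserProfile:
    """Per-user semi-Markov parameters."""

    transition: np.ndarray  # (7, 7), rows sum to 1
    dwell_mean_ms: np.ndarray  # per state
    dwell_sigma: float = 0.45
    scroll_propensity: float = 0.05
    noise_sd: float = 8.0
    initial: np.ndarray = field(
        default_factory=lambda: np.array([0.15, 0.60, 0.25, 0, 0, 0, 0], dtype=float)
    )


@dataclass
class PopulationConfig:
    n_users: int = 51
    sessions_per_user: int = 3
    rate_hz: float = 120.0
    perturbation_scale: float = 1.0  # 0 => every user shares the population matrix
    noise_sd: float = 8.0
    scroll_propensity: float = 0.05
    popup_entry: float = 0.008
    mean_duration_s: float = 78.8
    sd_duration_s: float = 51.9
    duration_bounds_s: tuple[float, float] = (16.5, 399.0)
    fixed_duration_s: float | None = None


@dataclass
class PopulationModel:
    config: PopulationConfig
    layout: Layout
    transition: np.ndarray
    profiles: list[UserProfile]


def sample_population(
    config: PopulationConfig | None = None, seed: int | np.random.Generator = 0
) -> PopulationModel:
    """Draw user profiles around the population transition tendencies."""
    config = config or PopulationConfig()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if config.n_users < 2:
        raise ValueError("need at least 2 users")
    T_pop = population_transition_matrix(popup_entry=config.popup_entry)
    dwell_means = np.array([250.0, 220.0, 240.0, 240.0, 230.0, 230.0, 260.0])
    profiles = []
    for _ in range(config.n_users):
        if config.perturbation_scale == 0:
            T = T_pop.copy()
        else:
            conc = 60.0 / config.perturbation_scale
            T = np.vstack([rng.dirichlet(np.maximum(row, 1e-6) * conc) for row in T_pop])
        profiles.append(
            UserProfile(
                transition=T,
                dwell_mean_ms=dwell_means * rng.uniform(0.85, 1.15),
                scroll_propensity=config.scroll_propensity,
                noise_sd=config.noise_sd,
            )
        )
    return PopulationModel(config, study_layout(), T_pop, profiles)


def _draw_dwell(rng: np.random.Generator, mean_ms: float, sigma: float) -> float:
    lo, hi = DWELL_BOUNDS_MS
    mu = np.log(mean_ms) - sigma**2 / 2.0
    for _ in range(100):
        d = float(rng.lognormal(mu, sigma))
        if lo <= d <= hi:
            return d
    return float(np.clip(d, lo, hi))


def _state_target(
    state: int, layout: Layout, rng: np.random.Generator
) -> tuple[float, float, bool, str | None]:
    """Pick a dwell point: (x, y, is_screen_space, component_id)."""
    if state == WHITESPACE_STATE:
        x0, y0, x1, y1 = WHITESPACE_RECT
        return (rng.uniform(x0, x1 - 1), rng.uniform(y0, y1 - 1), False, None)
    aoi = layout.aois[state - 1]
    cid = aoi.components[rng.integers(len(aoi.components))]
    comp = layout.component(cid)
    x0, y0, x1, y1 = comp.rect
    x = rng.uniform(x0 + 0.5, x1 - 0.5)
    y = rng.uniform(y0 + 0.5, y1 - 0.5)
    return (x, y, comp.sticky, cid)


def simulate_recording(
    profile: UserProfile,
    layout: Layout,
    duration_s: float,
    rate_hz: float = 120.0,
    seed: int | np.random.Generator = 0,
    user_id: str = "u00",
    session_id: str = "s1",
) -> GazeRecording:
    """Simulate one browsing session.

    Ground truth is attached in ``meta``: per fixation the generating state
    and, for zero-noise round-trip checks, its exact screen-space point.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    duration_ms = duration_s * 1000.0
    screen_h = layout.screen[1]
    max_scroll = PAGE_HEIGHT - screen_h

    fixations: list[Fixation] = []
    events: list[InteractionEvent] = []
    truth: list[dict] = []
    scroll_dy = 0.0
    popup_open = False
    state = int(rng.choice(N_STATES, p=profile.initial / profile.initial.sum()))
    t = 0.0
    while t < duration_ms:
        # Pop-up bookkeeping at the moment of transition.
        if state == POPUP_STATE and not popup_open:
            events.append(InteractionEvent(t, "click", "Sub_Butt"))
            events.append(InteractionEvent(t, "popup_open"))
            popup_open = True
        elif state != POPUP_STATE and popup_open:
            events.append(InteractionEvent(t, "popup_close"))
            popup_open = False

        x, y, is_screen, cid = _state_target(state, layout, rng)
        if not is_screen:
            # Scroll so the page-fixed target is visible (plus idle drift).
            sy = y - scroll_dy
            if not (80.0 <= sy < screen_h) or rng.random() < profile.scroll_propensity:
                scroll_dy = float(np.clip(round(y - screen_h / 2.0), 0.0, max_scroll))
                events.append(InteractionEvent(t, "scroll", scroll_dy))
            sx, sy = x, y - scroll_dy
        else:
            sx, sy = x, y

        dwell = _draw_dwell(rng, profile.dwell_mean_ms[state], profile.dwell_sigma)
        offset = min(t + dwell, duration_ms)
        if offset > t:
            fixations.append(Fixation(t, offset, sx, sy))
            truth.append(
                {"onset_ms": t, "offset_ms": offset, "state": state,
                 "screen_x": sx, "screen_y": sy, "component": cid}
            )
        t = offset + rng.uniform(30.0, 80.0)  # saccade gap
        state = int(rng.choice(N_STATES, p=profile.transition[state]))
    if popup_open:
        events.append(InteractionEvent(duration_ms, "popup_close"))

    samples = _render_samples(fixations, duration_ms, rate_hz, profile.noise_sd, rng)
    rec = GazeRecording(
        user_id=user_id,
        session_id=session_id,
        samples=samples,
        fixations=list(fixations),
        events=events,
        duration_ms=duration_ms,
        fixation_source="imported",
        meta={"true_fixations": truth},
    )
    return rec


def _render_samples(
    fixations: list[Fixation],
    duration_ms: float,
    rate_hz: float,
    noise_sd: float,
    rng: np.random.Generator,
) -> pd.DataFrame:
    ts = np.arange(0.0, duration_ms, 1000.0 / rate_hz)
    xs = np.zeros(len(ts))
    ys = np.zeros(len(ts))
    fi = 0
    for i, t in enumerate(ts):
        while fi < len(fixations) - 1 and t >= fixations[fi + 1].onset_ms:
            fi += 1
        f = fixations[fi]
        if f.onset_ms <= t < f.offset_ms or fi == len(fixations) - 1:
            xs[i], ys[i] = f.cx, f.cy
        elif t < f.onset_ms:
            xs[i], ys[i] = f.cx, f.cy
        else:  # saccade gap: linear sweep toward the next fixation
            g = fixations[fi + 1]
            frac = (t - f.offset_ms) / max(g.onset_ms - f.offset_ms, 1e-9)
            xs[i] = f.cx + frac * (g.cx - f.cx)
            ys[i] = f.cy + frac * (g.cy - f.cy)
    if noise_sd > 0:
        xs = xs + rng.normal(0.0, noise_sd, len(ts))
        ys = ys + rng.normal(0.0, noise_sd, len(ts))
    return pd.DataFrame(
        {"t_ms": ts, "x_px": xs, "y_px": ys, "valid": np.ones(len(ts), dtype=bool)}
    )


def _draw_duration(config: PopulationConfig, rng: np.random.Generator) -> float:
    if config.fixed_duration_s is not None:
        return config.fixed_duration_s
    cv2 = (config.sd_duration_s / config.mean_duration_s) ** 2
    sigma = float(np.sqrt(np.log1p(cv2)))
    mu = float(np.log(config.mean_duration_s) - sigma**2 / 2.0)
    lo, hi = config.duration_bounds_s
    for _ in range(100):
        d = float(rng.lognormal(mu, sigma))
        if lo <= d <= hi:
            return d
    return float(np.clip(d, lo, hi))


def simulate_cohort(
    population: PopulationModel, seed: int | np.random.Generator = 0
) -> list[GazeRecording]:
    """All user x session recordings of a population, in memory."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    cfg = population.config
    recordings = []
    for u, profile in enumerate(population.profiles, start=1):
        for s in range(1, cfg.sessions_per_user + 1):
            duration = _draw_duration(cfg, rng)
            recordings.append(
                simulate_recording(
                    profile,
                    population.layout,
                    duration,
                    cfg.rate_hz,
                    rng,
                    user_id=f"u{u:02d}",
                    session_id=f"s{s}",
                )
            )
    return recordings


def generate_cohort(
    population: PopulationModel, seed: int, out_dir: str | Path
) -> list[GazeRecording]:
    """Write a cohort to disk: per-recording gaze/fixation/event CSVs, the
    layout JSON and a manifest with ground-truth parameters.  Byte-identical
    across runs with the same seed."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    recordings = simulate_cohort(population, seed)
    population.layout.save(out / "layout.json")
    manifest: dict = {
        "seed": int(seed),
        "config": asdict(population.config),
        "population_transition": population.transition.tolist(),
        "user_transitions": {
            f"u{u:02d}": p.transition.tolist()
            for u, p in enumerate(population.profiles, start=1)
        },
        "recordings": [],
    }
    for rec in recordings:
        stem = f"{rec.user_id}_{rec.session_id}"
        write_gaze_log(rec, out / f"{stem}_gaze.csv")
        write_fixation_log(rec.fixations, out / f"{stem}_fixations.csv")
        write_event_log(rec.events, out / f"{stem}_events.csv")
        manifest["recordings"].append(
            {"user": rec.user_id, "session": rec.session_id,
             "duration_ms": rec.duration_ms}
        )
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True), encoding="utf-8"
    )
    return recordings
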