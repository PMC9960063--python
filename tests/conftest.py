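import numpy as np
import pandas as pd
import pytest

from gazeintent.gaze_io import GazeRecording
from gazeintent.simulate import (
    PopulationConfig,
    sample_population,
    simulate_cohort,
    study_layout,
)


@pytest.fixture(scope="session")
def layout():
    return study_layout()


def make_recording(samples=None, fixations=None, events=None, duration_ms=None,
                   user="u01", session="s1"):
    """Small hand-built recording for unit tests."""
    if samples is None:
        samples = pd.DataFrame(
            {"t_ms": [0.0], "x_px": [0.0], "y_px": [0.0], "valid": [True]}
        )
    rec = GazeRecording(
        user_id=user,
        session_id=session,
        samples=samples,
        fixations=list(fixations or []),
        events=list(events or []),
        duration_ms=duration_ms or 0.0,
    )
    return rec


def sampled_signal(points, rate_hz=120.0):
    """Samples visiting (t_start_ms, t_end_ms, x, y) segments at a fixed rate."""
    ts, xs, ys = [], [], []
    for t0, t1, x, y in points:
        t = t0
        while t < t1:
            ts.append(t)
            xs.append(x)
            ys.append(y)
            t += 1000.0 / rate_hz
    return pd.DataFrame(
        {"t_ms": ts, "x_px": xs, "y_px": ys, "valid": [True] * len(ts)}
    )


@pytest.fixture(scope="session")
def small_cohort():
    """10 users x 2 sessions x 60 s, zero gaze noise (exact geometry)."""
    cfg = PopulationConfig(
        n_users=10, sessions_per_user=2, fixed_duration_s=60.0, noise_sd=0.0
    )
    pop = sample_population(cfg, seed=11)
    return pop, simulate_cohort(pop, seed=11)
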