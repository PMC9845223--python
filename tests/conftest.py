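import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import fsmotion as fm

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def small_dataset() -> fm.TrackingDataset:
    """Compact synthetic match for unit tests (4 outfield + GK, 2 x 120 s)."""
    cfg = fm.GeneratorConfig(
        n_outfield=4, n_segments=2, segment_duration=120.0, seed=7
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return fm.generate_dataset(cfg)


@pytest.fixture(scope="session")
def study_dataset() -> fm.TrackingDataset:
    """Full study-scale synthetic match: 20 outfield players, 6 x 600 s
    segments (60 min), sprint state alpha = 1.3 1/s, vmax = 8 m/s, noise
    sigma = 0.5 m, fixed seed."""
    cfg = fm.GeneratorConfig(seed=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return fm.generate_dataset(cfg)


@pytest.fixture()
def simple_segment() -> fm.PlaySegment:
    """Two hand-built players on a 0.1 s grid: uniform motion and stationary."""
    dt = 0.1
    t = np.round(np.arange(0, 30.0 + dt / 2, dt), 9)
    rows = []
    for pid, role, fx, fy in [
        ("mover", "OUT", lambda s: 2.0 * s, lambda s: np.zeros_like(s)),
        ("sitter", "OUT", lambda s: np.full_like(s, 5.0), lambda s: np.full_like(s, -3.0)),
    ]:
        rows.append(
            pd.DataFrame(
                {
                    "segment_id": "S1",
                    "time_s": t,
                    "player_id": pid,
                    "team": "A",
                    "role": role,
                    "x_m": fx(t),
                    "y_m": fy(t),
                }
            )
        )
    return fm.PlaySegment("S1", pd.concat(rows, ignore_index=True), dt)
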