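import numpy as np
import pandas as pd
import pytest

from flockwake import (
    FlockDataset,
    SimConfig,
    Trajectory,
    all_pairs_relative,
    build_rulebase,
    simulate,
)


@pytest.fixture(scope="session")
def base():
    """Default in-wake rule base."""
    return build_rulebase()


@pytest.fixture
def rng():
    return np.random.default_rng(20230215)


def straight_trajectory(bird_id, start, velocity, n=20, dt=0.2, z=50.0):
    """Constant-velocity track; start/velocity are (x, y) metres / m/s."""
    t = np.arange(n) * dt
    x = start[0] + velocity[0] * t
    y = start[1] + velocity[1] * t
    return Trajectory(bird_id, t, np.column_stack([x, y, np.full(n, z)]), dt=dt)


@pytest.fixture
def echelon_flock():
    """Two birds on parallel northward tracks, B in A's wake station."""
    a = straight_trajectory("A", (0.0, 0.0), (0.0, 10.0))
    b = straight_trajectory("B", (1.3, -0.5), (0.0, 10.0))
    return FlockDataset({"A": a, "B": b}, rate_hz=5.0)


@pytest.fixture(scope="session")
def noisy_v_run():
    """A simulated V flock with realistic noise, scored end to end."""
    from flockwake import assign_all, score_table

    cfg = SimConfig(n_birds=6, duration_s=60.0, template="v", noise_sd=0.05, seed=11)
    flock, truth = simulate(cfg)
    rels = all_pairs_relative(flock)
    scored = score_table(rels, build_rulebase())
    assignments = assign_all(scored)
    return flock, truth, rels, scored, assignments


def make_assignments(rows):
    """Assignment frame from (follower, timestamp, state, leader) tuples."""
    df = pd.DataFrame(rows, columns=["follower", "timestamp", "state", "leader"])
    df["ew"] = 0.0
    df["ns"] = 0.0
    df["ud"] = 0.0
    df["output"] = np.where(df["state"] == "in_wake", 1.0, 0.0)
    return df
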