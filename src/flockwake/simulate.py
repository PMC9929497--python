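"""Synthetic flock trajectories with planted wake structure.

The generator emulates the geometry the in-wake model consumes: a flock
sharing a smoothly wandering heading in which each planted follower holds
a wake-optimal station behind its current leader (lateral offset near
±1.3 m, slightly behind, co-planar) plus Gaussian positional noise.  It is
deliberately kinematic — followers are placed at their station rather than
flown there by a behavioural or aerodynamic controller — which is
sufficient to produce the spatial statistics the fuzzy model and the FNN
baseline consume, together with exact ground truth.

Templates
---------
``echelon``   a single diagonal line, every bird on the same side;
``v``         two diagonal branches behind an apex bird;
``line``      a zig-zag chain, sides alternating;
``cluster``   a loose 3D blob with no planted wake structure;
``none``      independent parallel tracks far apart.

Solo birds (``solo_fraction``) fly with the flock heading but far outside
any wake region.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ConfigError
from .frames import FlockDataset, Trajectory
from .wake_model import IN_WAKE

__all__ = ["SimConfig", "simulate", "make_null_preference", "recovery_score"]

TEMPLATES = ("echelon", "v", "line", "cluster", "none")


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one synthetic flight.

    Distances in metres, durations in seconds, angles in radians.
    """

    n_birds: int = 6
    duration_s: float = 60.0
    rate_hz: float = 5.0
    speed: float = 10.0            # cruise speed, m/s
    heading_sd: float = 0.01       # heading random-walk step sd, rad/sample
    template: str = "echelon"
    ew_offset: float = 1.3         # planted lateral station (one side)
    ns_offset: float = -1.0        # planted anteroposterior station
    ud_offset: float = 0.0         # planted vertical station
    noise_sd: float = 0.05         # white positional noise per axis, m
    ar1_rho: float = 0.0           # >0 gives AR(1) noise mimicking GNSS smoothness
    leader_switch_prob: float = 0.0  # per follower per sample
    solo_fraction: float = 0.0
    null_bout_mean_s: float = 1.0  # mean bout length in the null generator
    altitude: float = 50.0
    seed: int = 0

    def __post_init__(self):
        if self.n_birds < 2:
            raise ConfigError("need at least 2 birds")
        if self.template not in TEMPLATES:
            raise ConfigError(f"template must be one of {TEMPLATES}")
        if self.noise_sd < 0 or self.heading_sd < 0:
            raise ConfigError("noise and heading sds must be >= 0")
        if not (0.0 <= self.leader_switch_prob <= 1.0):
            raise ConfigError("leader_switch_prob must lie in [0, 1]")
        if not (0.0 <= self.solo_fraction <= 1.0):
            raise ConfigError("solo_fraction must lie in [0, 1]")
        if not (0.0 <= self.ar1_rho < 1.0):
            raise ConfigError("ar1_rho must lie in [0, 1)")
        if not (self.ns_offset < 0):
            raise ConfigError("planted ns offset must be behind the leader (< 0)")
        if self.seed is None:
            raise ConfigError("seed is mandatory")

    @property
    def dt(self) -> float:
        return 1.0 / self.rate_hz

    @property
    def n_steps(self) -> int:
        return int(round(self.duration_s * self.rate_hz)) + 1


def _bird_ids(n: int) -> list[str]:
    return [f"b{i:02d}" for i in range(n)]


def _lead_path(cfg: SimConfig, rng: np.random.Generator):
    """Lead bird's track: heading random walk at constant speed."""
    steps = rng.normal(0.0, cfg.heading_sd, size=cfg.n_steps - 1)
    gamma0 = rng.uniform(-np.pi, np.pi)
    gamma = gamma0 + np.concatenate([[0.0], np.cumsum(steps)])
    step = cfg.speed * cfg.dt
    xy = np.zeros((cfg.n_steps, 2))
    xy[1:, 0] = np.cumsum(step * np.cos(gamma[:-1]))
    xy[1:, 1] = np.cumsum(step * np.sin(gamma[:-1]))
    return xy, gamma


def _station_offsets(cfg: SimConfig, n_followers: int, rng: np.random.Generator):
    """Parent index and local-frame station for each planted follower.

    Index 0 is the lead bird; followers are 1..n_followers.  Parents are
    expressed as bird indices strictly smaller than the follower's, so
    positions can be computed in one forward pass.
    """
    parents = np.zeros(n_followers + 1, dtype=int)
    stations = np.zeros((n_followers + 1, 3))
    for j in range(1, n_followers + 1):
        if cfg.template == "echelon":
            parent, side = j - 1, +1.0
        elif cfg.template == "v":
            if j <= 2:
                parent, side = 0, (-1.0 if j == 1 else +1.0)
            else:
                parent, side = j - 2, (-1.0 if j % 2 == 1 else +1.0)
        elif cfg.template == "line":
            parent, side = j - 1, (-1.0 if j % 2 == 1 else +1.0)
        else:
            raise ConfigError(f"template {cfg.template!r} has no wake stations")
        parents[j] = parent
        stations[j] = (side * cfg.ew_offset, cfg.ns_offset, cfg.ud_offset)
    return parents, stations


def _noise(cfg: SimConfig, rng: np.random.Generator, shape) -> np.ndarray:
    white = rng.normal(0.0, cfg.noise_sd, size=shape)
    if cfg.ar1_rho == 0.0 or cfg.noise_sd == 0.0:
        return white
    out = np.empty_like(white)
    scale = np.sqrt(1.0 - cfg.ar1_rho**2)  # keeps the marginal sd at noise_sd
    out[0] = white[0]
    for t in range(1, shape[0]):
        out[t] = cfg.ar1_rho * out[t - 1] + scale * white[t]
    return out


def _offset_to_xy(station, gamma):
    """Local (ew, ns) station rotated into the absolute frame at heading gamma."""
    ew, ns = station[..., 0], station[..., 1]
    dx = np.sin(gamma) * ew + np.cos(gamma) * ns
    dy = -np.cos(gamma) * ew + np.sin(gamma) * ns
    return np.stack([dx, dy], axis=-1)


def simulate(cfg: SimConfig) -> tuple[FlockDataset, pd.DataFrame]:
    """Generate one synthetic flight and its planted ground truth.

    Returns ``(flock, truth)`` where ``truth`` has one row per follower
    per timestamp with the planted leader id (``None`` for birds with no
    wake station).  Fully deterministic given the config seed.
    """
    rng = np.random.default_rng(cfg.seed)
    ids = _bird_ids(cfg.n_birds)
    n_solo = int(round(cfg.solo_fraction * (cfg.n_birds - 1)))
    n_planted = cfg.n_birds - 1 - n_solo

    lead_xy, gamma = _lead_path(cfg, rng)
    t = np.arange(cfg.n_steps) * cfg.dt
    pos = np.zeros((cfg.n_steps, cfg.n_birds, 3))
    pos[:, 0, :2] = lead_xy
    pos[:, 0, 2] = cfg.altitude

    parent_of = np.full((cfg.n_steps, cfg.n_birds), -1, dtype=int)

    if cfg.template in ("echelon", "v", "line"):
        parents, stations = _station_offsets(cfg, n_planted, rng)
        sides = np.sign(stations[:, 0])
        for j in range(1, n_planted + 1):
            parent_of[:, j] = parents[j]
        # leader switching: redraw among the planted birds (not self)
        if cfg.leader_switch_prob > 0:
            for j in range(1, n_planted + 1):
                cur = parents[j]
                for s in range(cfg.n_steps):
                    if rng.random() < cfg.leader_switch_prob:
                        choices = [k for k in range(n_planted + 1) if k != j]
                        cur = choices[rng.integers(len(choices))]
                    parent_of[s, j] = cur
        noise = _noise(cfg, rng, (cfg.n_steps, n_planted, 3))
        for s in range(cfg.n_steps):
            for j in range(1, n_planted + 1):
                p = parent_of[s, j]
                station = np.array([sides[j] * cfg.ew_offset, cfg.ns_offset, cfg.ud_offset])
                if p < j:
                    ppos = pos[s, p]
                elif s > 0:
                    # parent not yet placed this step: advance its previous
                    # position by the lead bird's step (the flock moves together)
                    ppos = pos[s - 1, p] + (pos[s, 0] - pos[s - 1, 0])
                else:
                    ppos = pos[0, 0]
                dxy = _offset_to_xy(station, gamma[s])
                pos[s, j, :2] = ppos[:2] + dxy
                pos[s, j, 2] = ppos[2] - station[2]
                pos[s, j] += noise[s, j - 1]
    elif cfg.template == "cluster":
        radius = max(3.0, cfg.n_birds)
        blob = rng.uniform(-radius, radius, size=(cfg.n_birds - 1 - n_solo, 3))
        blob[:, 2] *= 0.2
        noise = _noise(cfg, rng, (cfg.n_steps, n_planted, 3))
        for j in range(1, n_planted + 1):
            off = np.tile(blob[j - 1], (cfg.n_steps, 1))
            pos[:, j, :2] = lead_xy + _offset_to_xy(off, gamma)
            pos[:, j, 2] = cfg.altitude + blob[j - 1, 2]
            pos[:, j] += noise[:, j - 1]
    else:  # "none": independent parallel tracks
        noise = _noise(cfg, rng, (cfg.n_steps, n_planted, 3))
        for j in range(1, n_planted + 1):
            off = np.tile([10.0 * j, 0.0, 0.0], (cfg.n_steps, 1))
            pos[:, j, :2] = lead_xy + _offset_to_xy(off, gamma)
            pos[:, j, 2] = cfg.altitude
            pos[:, j] += noise[:, j - 1]

    # solo birds: with the flock's heading, far outside any wake region
    for k in range(n_solo):
        j = cfg.n_birds - 1 - k
        off = np.tile([25.0 + 15.0 * k, 5.0 + 3.0 * k, 0.0], (cfg.n_steps, 1))
        pos[:, j, :2] = lead_xy + _offset_to_xy(off, gamma)
        pos[:, j, 2] = cfg.altitude
        pos[:, j] += _noise(cfg, rng, (cfg.n_steps, 3))

    trajs = {
        ids[i]: Trajectory(ids[i], t, pos[:, i, :], dt=cfg.dt)
        for i in range(cfg.n_birds)
    }
    flock = FlockDataset(trajs, rate_hz=cfg.rate_hz)

    truth_rows = []
    for j in range(1, cfg.n_birds):
        planted = parent_of[:, j] >= 0
        leaders = np.where(planted, parent_of[:, j], -1)
        truth_rows.append(
            pd.DataFrame(
                {
                    "follower": ids[j],
                    "timestamp": t,
                    "leader": [ids[p] if p >= 0 else None for p in leaders],
                }
            )
        )
    truth = pd.concat(truth_rows, ignore_index=True)
    return flock, truth


def make_null_preference(cfg: SimConfig) -> tuple[FlockDataset, pd.DataFrame]:
    """Flock in which every follower redraws its leader at every bout.

    Bout lengths are geometric with mean ``null_bout_mean_s``; the leader
    of each bout is uniform over the other birds, so no leader is
    preferred in expectation.  Followers pursue the wake station of their
    current leader with a first-order controller, which keeps tracks
    continuous through switches.
    """
    if cfg.n_birds < 3:
        raise ConfigError("a preference null needs at least 3 birds")
    rng = np.random.default_rng(cfg.seed)
    ids = _bird_ids(cfg.n_birds)
    lead_xy, gamma = _lead_path(cfg, rng)
    t = np.arange(cfg.n_steps) * cfg.dt

    p_end = 1.0 / max(cfg.null_bout_mean_s * cfg.rate_hz, 1.0)
    leader_seq = np.zeros((cfg.n_steps, cfg.n_birds), dtype=int)
    for j in range(1, cfg.n_birds):
        others = [k for k in range(cfg.n_birds) if k != j]
        s = 0
        while s < cfg.n_steps:
            length = rng.geometric(p_end)
            leader_seq[s : s + length, j] = others[rng.integers(len(others))]
            s += length
    sides = rng.choice([-1.0, 1.0], size=cfg.n_birds)

    pos = np.zeros((cfg.n_steps, cfg.n_birds, 3))
    pos[:, 0, :2] = lead_xy
    pos[:, 0, 2] = cfg.altitude
    # scatter initial positions around the lead bird
    init = rng.uniform(-3, 3, size=(cfg.n_birds - 1, 2))
    pos[0, 1:, :2] = lead_xy[0] + init
    pos[0, 1:, 2] = cfg.altitude
    noise = _noise(cfg, rng, (cfg.n_steps, cfg.n_birds, 3))
    blend = 0.35  # first-order pursuit gain per sample
    for s in range(1, cfg.n_steps):
        lead_step = np.concatenate([lead_xy[s] - lead_xy[s - 1], [0.0]])
        for j in range(1, cfg.n_birds):
            L = leader_seq[s, j]
            station = np.array([sides[j] * cfg.ew_offset, cfg.ns_offset, cfg.ud_offset])
            dxy = _offset_to_xy(station, gamma[s])
            target = pos[s - 1, L] + lead_step + np.array([dxy[0], dxy[1], -station[2]])
            pos[s, j] = pos[s - 1, j] + lead_step + blend * (target - (pos[s - 1, j] + lead_step))
            pos[s, j] += noise[s, j]

    trajs = {
        ids[i]: Trajectory(ids[i], t, pos[:, i, :], dt=cfg.dt)
        for i in range(cfg.n_birds)
    }
    flock = FlockDataset(trajs, rate_hz=cfg.rate_hz)
    truth = pd.concat(
        [
            pd.DataFrame(
                {
                    "follower": ids[j],
                    "timestamp": t,
                    "leader": [ids[k] for k in leader_seq[:, j]],
                }
            )
            for j in range(1, cfg.n_birds)
        ],
        ignore_index=True,
    )
    return flock, truth


def truth_to_assignments(truth: pd.DataFrame) -> pd.DataFrame:
    """Planted ground truth rendered as an assignment stream.

    Snapshots with a planted leader become in-wake rows; the positional
    columns are filled with the nominal station (unused by the bout /
    preference analytics).  Useful for exercising the flock-level
    analytics on a known truth without running the inference.
    """
    out = truth.copy()
    has = out["leader"].notna()
    out["state"] = np.where(has, IN_WAKE, "alone_no_front")
    out["leader"] = out["leader"].where(has, None)
    out[["ew", "ns", "ud"]] = 0.0
    out["output"] = np.where(has, 1.0, 0.0)
    return out


def recovery_score(assignments: pd.DataFrame, truth: pd.DataFrame) -> float:
    """Fraction of planted-leader snapshots the model recovered.

    Only snapshots where the ground truth plants a leader and the model
    produced an assignment row enter the denominator.
    """
    planted = truth[truth["leader"].notna()]
    merged = planted.merge(
        assignments,
        on=["follower", "timestamp"],
        how="inner",
        suffixes=("_true", ""),
    )
    if len(merged) == 0:
        return float("nan")
    hit = (merged["state"] == IN_WAKE) & (merged["leader"] == merged["leader_true"])
    return float(hit.mean())
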