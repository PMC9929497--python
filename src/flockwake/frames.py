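"""Leader-relative coordinate frames for flock trajectories.

Absolute 3D tracks (metres, shared local tangent frame, fixed sampling
rate) are converted into pairwise follower-in-leader's-frame coordinates:

* ``ew`` — lateral offset, positive when the follower sits to the right of
  the leader's track;
* ``ns`` — anteroposterior offset, positive when the follower is ahead;
* ``ud`` — vertical offset, computed as ``z_leader − z_follower`` (the sign
  convention is documented here once; every downstream consumer of the
  vertical channel is symmetric in its sign).

The leader's instantaneous flight direction is smoothed over three
consecutive fixes: the heading of the displacement into the fix (``alpha``)
and out of the fix (``beta``) are combined by a circular mean (sum of unit
vectors, then arctangent) to give ``gamma``.  The horizontal plane is then
rotated so ``gamma`` maps onto the +y axis; the vertical channel never
enters the rotation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import (
    BoundaryTimestampError,
    DegenerateHeadingError,
    InsufficientDataError,
    MissingSnapshotError,
    TrajectoryError,
)

#: Tolerance (seconds) when snapping timestamps onto the nominal grid.
SNAP_TOL = 1e-3

#: Relative tolerance on the sampling interval.
RATE_TOL = 0.01


@dataclass(frozen=True)
class HeadingEstimate:
    """Smoothed flight direction at one fix, angles in radians, (−π, π]."""

    alpha: float
    beta: float
    gamma: float


@dataclass(frozen=True)
class RelativePosition:
    """Position of ``follower`` in ``leader``'s flight frame at time ``t``."""

    follower_id: str
    leader_id: str
    t: float
    ew: float
    ns: float
    ud: float

    @property
    def dist_3d(self) -> float:
        return float(np.sqrt(self.ew**2 + self.ns**2 + self.ud**2))


class Trajectory:
    """One bird's time-stamped 3D track on a fixed sampling grid.

    Parameters
    ----------
    bird_id:
        Unique identifier.
    t:
        Timestamps in seconds, strictly increasing.  Gaps are allowed but
        every interval must be an integer multiple of the sampling period.
    xyz:
        ``(n, 3)`` array of metres east / north / up.
    dt:
        Sampling period in seconds.  Inferred from the smallest interval
        when omitted.
    """

    def __init__(self, bird_id, t, xyz, dt: float | None = None):
        self.bird_id = str(bird_id)
        self.t = np.asarray(t, dtype=float)
        self.xyz = np.asarray(xyz, dtype=float)
        if self.t.ndim != 1 or self.xyz.shape != (self.t.size, 3):
            raise TrajectoryError(
                f"bird {bird_id}: expected t (n,) and xyz (n, 3), got "
                f"{self.t.shape} and {self.xyz.shape}"
            )
        if self.t.size < 2:
            raise TrajectoryError(f"bird {bird_id}: need at least 2 samples")
        if not np.isfinite(self.t).all() or not np.isfinite(self.xyz).all():
            raise TrajectoryError(f"bird {bird_id}: non-finite coordinate or timestamp")
        diffs = np.diff(self.t)
        if (diffs <= 0).any():
            raise TrajectoryError(f"bird {bird_id}: timestamps not strictly increasing")
        self.dt = float(dt) if dt is not None else float(diffs.min())
        # every interval must sit on the nominal grid (gaps = integer multiples)
        mult = diffs / self.dt
        if (np.abs(mult - np.round(mult)) > RATE_TOL).any():
            raise TrajectoryError(
                f"bird {bird_id}: sample interval not constant (dt={self.dt:g} s)"
            )
        self.ticks = snap_to_grid(self.t, self.dt)
        if np.unique(self.ticks).size != self.ticks.size:
            raise TrajectoryError(f"bird {bird_id}: duplicate timestamps after snapping")
        self._tick_index = {int(k): i for i, k in enumerate(self.ticks)}

    def __len__(self) -> int:
        return self.t.size

    def index_at(self, t: float) -> int:
        """Index of the sample at time ``t`` (snap tolerance applies)."""
        tick = int(round(t / self.dt))
        if abs(t - tick * self.dt) > SNAP_TOL or tick not in self._tick_index:
            raise MissingSnapshotError(f"bird {self.bird_id} has no sample at t={t!r}")
        return self._tick_index[tick]


def snap_to_grid(t: np.ndarray, dt: float) -> np.ndarray:
    """Snap timestamps to integer ticks of the nominal period ``dt``."""
    ticks = np.round(np.asarray(t, dtype=float) / dt).astype(np.int64)
    off = np.abs(t - ticks * dt)
    if (off > SNAP_TOL).any():
        i = int(np.argmax(off > SNAP_TOL))
        raise TrajectoryError(
            f"timestamp {t[i]!r} is {off[i]:.4g} s off the {dt:g} s grid"
        )
    return ticks


@dataclass
class FlockDataset:
    """A set of simultaneously recorded trajectories at one sampling rate."""

    trajectories: dict[str, Trajectory]
    rate_hz: float = 5.0

    def __post_init__(self):
        if len(self.trajectories) < 2:
            raise TrajectoryError("a flock needs at least 2 birds")

    @property
    def n_birds(self) -> int:
        return len(self.trajectories)

    @property
    def bird_ids(self) -> list[str]:
        return sorted(self.trajectories)

    @property
    def dt(self) -> float:
        return 1.0 / self.rate_hz

    @classmethod
    def from_frame(cls, df: pd.DataFrame, rate_hz: float = 5.0) -> "FlockDataset":
        """Build from a long-format frame with bird_id, timestamp, x, y, z."""
        dt = 1.0 / rate_hz
        trajs = {}
        for bird, sub in df.groupby("bird_id", sort=True):
            sub = sub.sort_values("timestamp")
            trajs[str(bird)] = Trajectory(
                bird, sub["timestamp"].to_numpy(), sub[["x", "y", "z"]].to_numpy(), dt=dt
            )
        return cls(trajs, rate_hz=rate_hz)

    def to_frame(self) -> pd.DataFrame:
        parts = []
        for bird in self.bird_ids:
            tr = self.trajectories[bird]
            parts.append(
                pd.DataFrame(
                    {
                        "bird_id": bird,
                        "timestamp": tr.t,
                        "x": tr.xyz[:, 0],
                        "y": tr.xyz[:, 1],
                        "z": tr.xyz[:, 2],
                    }
                )
            )
        return pd.concat(parts, ignore_index=True)


# ---------------------------------------------------------------------------
# heading and rotation


def _circular_mean(alpha: float | np.ndarray, beta: float | np.ndarray):
    """Mean direction of two angles via summed unit vectors."""
    s = np.sin(alpha) + np.sin(beta)
    c = np.cos(alpha) + np.cos(beta)
    return np.arctan2(s, c), np.hypot(s, c)


def mean_heading(traj: Trajectory, t: float) -> HeadingEstimate:
    """Three-fix smoothed heading of ``traj`` at time ``t``.

    ``alpha`` is the direction of the horizontal displacement into the fix,
    ``beta`` the direction out of it, both as mathematical angles
    (``atan2(dy, dx)``); ``gamma`` is their circular mean.

    Raises
    ------
    BoundaryTimestampError
        If the fix has no immediate predecessor or successor on the grid.
    DegenerateHeadingError
        If either displacement has zero horizontal length, or the two
        directions are exactly antiparallel.
    """
    i = traj.index_at(t)
    tick = traj.ticks[i]
    prev = traj._tick_index.get(int(tick) - 1)
    nxt = traj._tick_index.get(int(tick) + 1)
    if prev is None or nxt is None:
        raise BoundaryTimestampError(
            f"bird {traj.bird_id}: t={t!r} lacks a neighbouring sample"
        )
    d1 = traj.xyz[i, :2] - traj.xyz[prev, :2]
    d2 = traj.xyz[nxt, :2] - traj.xyz[i, :2]
    if np.hypot(*d1) == 0.0 or np.hypot(*d2) == 0.0:
        raise DegenerateHeadingError(
            f"bird {traj.bird_id}: zero horizontal displacement at t={t!r}"
        )
    alpha = float(np.arctan2(d1[1], d1[0]))
    beta = float(np.arctan2(d2[1], d2[0]))
    gamma, r = _circular_mean(alpha, beta)
    if r < 1e-12:
        raise DegenerateHeadingError(
            f"bird {traj.bird_id}: antiparallel displacements at t={t!r}"
        )
    return HeadingEstimate(alpha=alpha, beta=beta, gamma=float(gamma))


def rotate_to_track(dx, dy, gamma):
    """Rotate horizontal offsets so the direction ``gamma`` maps onto +y.

    Returns ``(ew, ns)``; works element-wise on arrays.
    """
    sg, cg = np.sin(gamma), np.cos(gamma)
    ew = sg * dx - cg * dy
    ns = cg * dx + sg * dy
    return ew, ns


def relative_position(leader: Trajectory, follower: Trajectory, t: float) -> RelativePosition:
    """Follower's position in the leader's flight frame at time ``t``."""
    li = leader.index_at(t)
    fi = follower.index_at(t)
    gamma = mean_heading(leader, t).gamma
    d = follower.xyz[fi] - leader.xyz[li]
    ew, ns = rotate_to_track(d[0], d[1], gamma)
    ud = leader.xyz[li, 2] - follower.xyz[fi, 2]
    return RelativePosition(
        follower_id=follower.bird_id,
        leader_id=leader.bird_id,
        t=float(t),
        ew=float(ew),
        ns=float(ns),
        ud=float(ud),
    )


def _interior_mask(traj: Trajectory) -> np.ndarray:
    """Samples with both grid neighbours present (heading is defined there)."""
    m = np.zeros(len(traj), dtype=bool)
    if len(traj) >= 3:
        has_prev = np.diff(traj.ticks) == 1
        m[1:-1] = has_prev[:-1] & has_prev[1:]
    return m


def heading_table(traj: Trajectory) -> pd.DataFrame:
    """Vectorised smoothed headings at every interior fix of one bird.

    Fixes with a degenerate (zero-length or antiparallel) displacement are
    silently dropped; callers treat them as 'heading undefined'.
    """
    m = _interior_mask(traj)
    idx = np.nonzero(m)[0]
    if idx.size == 0:
        return pd.DataFrame({"tick": [], "gamma": []})
    d1 = traj.xyz[idx, :2] - traj.xyz[idx - 1, :2]
    d2 = traj.xyz[idx + 1, :2] - traj.xyz[idx, :2]
    ok = (np.hypot(d1[:, 0], d1[:, 1]) > 0) & (np.hypot(d2[:, 0], d2[:, 1]) > 0)
    alpha = np.arctan2(d1[:, 1], d1[:, 0])
    beta = np.arctan2(d2[:, 1], d2[:, 0])
    gamma, r = _circular_mean(alpha, beta)
    ok &= r > 1e-12
    return pd.DataFrame({"tick": traj.ticks[idx[ok]], "gamma": gamma[ok]})


def all_pairs_relative(flock: FlockDataset) -> pd.DataFrame:
    """Relative positions for every ordered dyad at every usable snapshot.

    Rows are emitted where the leader has a defined smoothed heading and
    both birds are at interior fixes (first and last fix of each bird, and
    fixes flanking a gap, are dropped — no extrapolation).

    Returns a frame with columns
    ``follower, leader, timestamp, ew, ns, ud, dist3d``.
    """
    birds = flock.bird_ids
    # per-bird caches
    headings = {}
    interiors = {}
    for b in birds:
        tr = flock.trajectories[b]
        ht = heading_table(tr)
        headings[b] = dict(zip(ht["tick"].astype(int), ht["gamma"]))
        interiors[b] = set(tr.ticks[_interior_mask(tr)].tolist())

    parts = []
    for leader in birds:
        ltr = flock.trajectories[leader]
        lg = headings[leader]
        for follower in birds:
            if follower == leader:
                continue
            ftr = flock.trajectories[follower]
            common = sorted(set(lg) & interiors[follower])
            if not common:
                continue
            ticks = np.array(common, dtype=np.int64)
            li = np.array([ltr._tick_index[k] for k in common])
            fi = np.array([ftr._tick_index[k] for k in common])
            gamma = np.array([lg[k] for k in common])
            d = ftr.xyz[fi] - ltr.xyz[li]
            ew, ns = rotate_to_track(d[:, 0], d[:, 1], gamma)
            ud = ltr.xyz[li, 2] - ftr.xyz[fi, 2]
            parts.append(
                pd.DataFrame(
                    {
                        "follower": follower,
                        "leader": leader,
                        "timestamp": ticks * ltr.dt,
                        "ew": ew,
                        "ns": ns,
                        "ud": ud,
                        "dist3d": np.sqrt(ew**2 + ns**2 + ud**2),
                    }
                )
            )
    if not parts:
        raise InsufficientDataError("no dyad shares 3 or more usable snapshots")
    out = pd.concat(parts, ignore_index=True)
    return out.sort_values(["follower", "timestamp", "leader"], ignore_index=True)
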