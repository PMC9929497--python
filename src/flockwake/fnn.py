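"""Frontal-nearest-neighbour (FNN) baseline leader assignment.

The conventional proximity heuristic: the presumed upwash provider of a
bird is the nearest individual that (i) is in front (ns > 0 in the
follower's flight frame), (ii) is co-planar (|ud| strictly inside half a
wingspan) and (iii) lies within 6 m horizontal range.  Unlike the fuzzy
model it ignores where the wingtip vortices actually are, so it will
happily pick a bird directly ahead in the downwash.

Candidates are ranked by horizontal (ew, ns) distance, consistent with the
horizontal range condition; 3D ranking is available via the config.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigError

__all__ = ["FNNConfig", "fnn", "fnn_table", "FNN_LEADER", "FNN_NONE"]

FNN_LEADER = "fnn_leader"
FNN_NONE = "no_front_neighbour"


@dataclass(frozen=True)
class FNNConfig:
    coplanar_halfwidth: float = 0.75  # m, half a wingspan
    max_range: float = 6.0            # m, horizontal
    metric: str = "2d"                # candidate ranking: "2d" or "3d"

    def __post_init__(self):
        if self.coplanar_halfwidth <= 0 or self.max_range <= 0:
            raise ConfigError("FNN thresholds must be positive")
        if self.metric not in ("2d", "3d"):
            raise ConfigError("metric must be '2d' or '3d'")


def _eligible(df: pd.DataFrame, cfg: FNNConfig) -> pd.Series:
    horiz = np.hypot(df["ns"], df["ew"])
    return (
        (df["ns"] > 0)
        & (df["ud"].abs() < cfg.coplanar_halfwidth)
        & (horiz <= cfg.max_range)
    )


def _rank_key(df: pd.DataFrame, cfg: FNNConfig) -> pd.Series:
    if cfg.metric == "2d":
        return np.hypot(df["ns"], df["ew"])
    return df["dist3d"]


def fnn(cands: pd.DataFrame, cfg: FNNConfig | None = None):
    """FNN of one bird at one snapshot.

    ``cands`` holds the other birds' positions in the bird-of-interest's
    flight frame (columns at least ``candidate, ew, ns, ud, dist3d``; see
    :func:`flockwake.wake_model.front_candidates`).  Returns
    ``(leader_id, row)`` or ``(None, None)`` when no candidate qualifies.
    """
    cfg = cfg or FNNConfig()
    cand = cands[_eligible(cands, cfg)].copy()
    if len(cand) == 0:
        return None, None
    cand["_key"] = _rank_key(cand, cfg)
    best = cand.sort_values(["_key", "candidate"]).iloc[0]
    return str(best["candidate"]), best.drop("_key")


def fnn_table(rels: pd.DataFrame, cfg: FNNConfig | None = None) -> pd.DataFrame:
    """Vectorised FNN over a full all-pairs relative-position table.

    ``rels`` is the follower-in-leader's-frame table from
    :func:`flockwake.frames.all_pairs_relative`; internally it is
    re-oriented so each bird sees the others in its own frame.  One row
    per (follower, timestamp) with columns
    ``follower, timestamp, state, leader, ew, ns, ud, output`` matching the
    fuzzy assignment schema (``output`` is NaN — the FNN is not graded).
    """
    from .wake_model import front_candidates

    cfg = cfg or FNNConfig()
    df = front_candidates(rels)
    df["_ok"] = _eligible(df, cfg)
    df["_key"] = _rank_key(df, cfg)
    cand = df[df["_ok"]].sort_values(
        ["bird", "timestamp", "_key", "candidate"], kind="mergesort"
    )
    best = cand.drop_duplicates(["bird", "timestamp"], keep="first")
    best = best.set_index(["bird", "timestamp"])

    snaps = df[["bird", "timestamp"]].drop_duplicates().set_index(["bird", "timestamp"])
    out = pd.DataFrame(index=snaps.index)
    out["state"] = FNN_NONE
    out["leader"] = None
    out[["ew", "ns", "ud"]] = 0.0
    hit = out.index.intersection(best.index)
    out.loc[hit, "state"] = FNN_LEADER
    out.loc[hit, "leader"] = best.loc[hit, "candidate"]
    for col in ("ew", "ns", "ud"):
        out.loc[hit, col] = best.loc[hit, col]
    out["output"] = np.nan
    out.index.names = ["follower", "timestamp"]
    return out.reset_index().sort_values(["follower", "timestamp"], ignore_index=True)
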