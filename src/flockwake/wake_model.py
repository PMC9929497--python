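"""The in-wake flight fuzzy model and per-snapshot leader assignment.

A trailing bird gains upwash from a leader's wingtip vortex only when it
sits laterally offset (one wingtip overlapping the leader's vortex region),
slightly behind, and co-planar.  Three linguistic variables capture this:

* ``bird_ew`` — lateral displacement.  ``wingtip_aligned`` peaks at
  ±1.3 m (a 20 cm wingtip overlap for a 1.5 m wingspan), falls to zero at
  ±1.8 m (wingtips fully separated) and is zero for |ew| ≤ 0.8 m, the
  downwash corridor directly behind the leader's body.
  ``wingtip_misaligned`` is its pointwise complement.
* ``bird_ns`` — anteroposterior distance.  ``close`` rises from 0 at the
  leader to a peak 0.1 m behind, then decays to zero 5 m back; ``too_close``
  is a narrow spike inside the last 0.1 m (collision risk); ``distant``
  ramps up as ``close`` decays and saturates beyond 5 m.  All three are
  zero for a bird flying ahead (ns ≥ 0).
* ``bird_plane`` — vertical offset.  ``same_plane`` peaks at 0 and reaches
  zero at ±0.75 m (half a wingspan); ``different_plane`` is its complement.

Five rules map these onto the crisp outputs in_wake = 1 / not_in_wake = 0;
the defuzzified 0-order Takagi–Sugeno output is the degree of in-wake
flying.  A follower exploits at most one upwash at a time, so per snapshot
the candidate leader with the highest output wins; if even the winner's
output does not exceed the decision threshold the bird is not in wake, and
the record falls back to the nearest bird in front (or zeros when nobody
is in front).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .errors import ConfigError
from .frames import RelativePosition
from .fuzzy import FuzzyRule, LinguisticVariable, MembershipFunction, RuleBase

__all__ = [
    "WakeModelConfig",
    "DyadScore",
    "WakeAssignment",
    "build_rulebase",
    "score_dyad",
    "score_table",
    "front_candidates",
    "assign_leaders",
    "assign_all",
    "response_grid",
    "IN_WAKE",
    "NOT_IN_WAKE_FRONT",
    "ALONE_NO_FRONT",
]

IN_WAKE = "in_wake"
NOT_IN_WAKE_FRONT = "not_in_wake_front_bird"
ALONE_NO_FRONT = "alone_no_front"

RULE_COLUMNS = ["r1", "r2", "r3", "r4", "r5"]


@dataclass(frozen=True)
class WakeModelConfig:
    """Anchor geometry and decision parameters of the in-wake model.

    All distances in metres.  Defaults encode the knowledge-based values
    for the northern bald ibis (wingspan ≈ 1.5 m).
    """

    ew_inner_zero: float = 0.8    # downwash corridor half-width
    ew_peak: float = 1.3          # optimal lateral displacement
    ew_outer_zero: float = 1.8    # wingtips fully misaligned
    ew_peak_halfwidth: float = 0.0  # >0 turns the point peak into a plateau
    ns_peak: float = -0.1         # optimal distance behind the leader
    ns_far_zero: float = -5.0     # beyond this the wake is spent
    too_close_peak: float = -0.05  # apex of the collision-risk spike
    plane_zero: float = 0.75      # half a wingspan
    in_wake_value: float = 1.0
    not_in_wake_value: float = 0.0
    tau: float = 0.0              # in-wake iff winning output > tau
    wingspan: float = 1.5
    and_op: str = "min"

    def __post_init__(self):
        if not (0.0 < self.ew_inner_zero < self.ew_peak < self.ew_outer_zero):
            raise ConfigError("need 0 < ew_inner_zero < ew_peak < ew_outer_zero")
        if self.ew_peak_halfwidth < 0:
            raise ConfigError("ew_peak_halfwidth must be >= 0")
        if not (self.ns_far_zero < self.ns_peak < 0.0):
            raise ConfigError("need ns_far_zero < ns_peak < 0")
        if not (self.ns_peak < self.too_close_peak < 0.0):
            raise ConfigError("too_close_peak must lie between ns_peak and 0")
        if self.plane_zero <= 0:
            raise ConfigError("plane_zero must be positive")
        if not (0.0 <= self.tau < 1.0):
            raise ConfigError("tau must lie in [0, 1)")
        if self.in_wake_value == self.not_in_wake_value:
            raise ConfigError("consequent values must be distinct")

    @property
    def wingtip_overlap(self) -> float:
        """Wingtip overlap (m) implied by the alignment peak."""
        return self.wingspan - self.ew_peak


@dataclass(frozen=True)
class DyadScore:
    """FIS evaluation of one (follower, leader) dyad at one snapshot."""

    follower_id: str
    leader_id: str
    t: float
    rule_strengths: tuple[float, ...]
    output: float
    zero_fire: bool


@dataclass(frozen=True)
class WakeAssignment:
    """Resolved per-follower state at one snapshot."""

    follower_id: str
    t: float
    state: str
    leader_id: str | None
    ew: float
    ns: float
    ud: float
    output: float


def _aligned_mf(cfg: WakeModelConfig) -> MembershipFunction:
    h = cfg.ew_peak_halfwidth
    if h == 0.0:
        pos = [(cfg.ew_inner_zero, 0.0), (cfg.ew_peak, 1.0), (cfg.ew_outer_zero, 0.0)]
    else:
        if not (cfg.ew_inner_zero < cfg.ew_peak - h and cfg.ew_peak + h < cfg.ew_outer_zero):
            raise ConfigError("peak plateau exceeds the zero anchors")
        pos = [
            (cfg.ew_inner_zero, 0.0),
            (cfg.ew_peak - h, 1.0),
            (cfg.ew_peak + h, 1.0),
            (cfg.ew_outer_zero, 0.0),
        ]
    neg = [(-x, m) for x, m in reversed(pos)]
    return MembershipFunction(anchors=tuple(neg + pos), left_plateau=0.0, right_plateau=0.0)


def build_rulebase(cfg: WakeModelConfig | None = None) -> RuleBase:
    """Construct the five-rule in-wake rule base from its configuration."""
    cfg = cfg or WakeModelConfig()

    aligned = _aligned_mf(cfg)
    misaligned = aligned.complement()

    close = MembershipFunction(
        anchors=((cfg.ns_far_zero, 0.0), (cfg.ns_peak, 1.0), (0.0, 0.0)),
        left_plateau=0.0,
        right_plateau=0.0,
    )
    too_close = MembershipFunction(
        anchors=((cfg.ns_peak, 0.0), (cfg.too_close_peak, 1.0), (0.0, 0.0)),
        left_plateau=0.0,
        right_plateau=0.0,
    )
    # complement of `close` on the decaying limb; saturates beyond the far zero
    distant = MembershipFunction(
        anchors=((cfg.ns_far_zero, 1.0), (cfg.ns_peak, 0.0)),
        left_plateau=1.0,
        right_plateau=0.0,
    )

    same_plane = MembershipFunction(
        anchors=((-cfg.plane_zero, 0.0), (0.0, 1.0), (cfg.plane_zero, 0.0)),
        left_plateau=0.0,
        right_plateau=0.0,
    )
    different_plane = same_plane.complement()

    variables = [
        LinguisticVariable(
            "bird_ew",
            {"wingtip_aligned": aligned, "wingtip_misaligned": misaligned},
            universe=(-cfg.ew_outer_zero - 1, cfg.ew_outer_zero + 1),
            units="m",
        ),
        LinguisticVariable(
            "bird_ns",
            {"too_close": too_close, "close": close, "distant": distant},
            universe=(cfg.ns_far_zero - 1, 1.0),
            units="m",
        ),
        LinguisticVariable(
            "bird_plane",
            {"same_plane": same_plane, "different_plane": different_plane},
            universe=(-cfg.plane_zero - 1, cfg.plane_zero + 1),
            units="m",
        ),
    ]
    rules = [
        FuzzyRule(
            antecedent=(
                ("bird_ew", "wingtip_aligned"),
                ("bird_ns", "close"),
                ("bird_plane", "same_plane"),
            ),
            consequent_label="in_wake",
            consequent_value=cfg.in_wake_value,
        ),
        FuzzyRule(
            antecedent=(("bird_ew", "wingtip_misaligned"),),
            consequent_label="not_in_wake",
            consequent_value=cfg.not_in_wake_value,
        ),
        FuzzyRule(
            antecedent=(("bird_ns", "too_close"),),
            consequent_label="not_in_wake",
            consequent_value=cfg.not_in_wake_value,
        ),
        FuzzyRule(
            antecedent=(("bird_ns", "distant"),),
            consequent_label="not_in_wake",
            consequent_value=cfg.not_in_wake_value,
        ),
        FuzzyRule(
            antecedent=(("bird_plane", "different_plane"),),
            consequent_label="not_in_wake",
            consequent_value=cfg.not_in_wake_value,
        ),
    ]
    return RuleBase(
        variables,
        rules,
        zero_strength_output=cfg.not_in_wake_value,
        and_op=cfg.and_op,
    )


def score_dyad(rel: RelativePosition, base: RuleBase) -> DyadScore:
    """Degree of in-wake flying for one dyad at one snapshot."""
    inputs = {"bird_ew": rel.ew, "bird_ns": rel.ns, "bird_plane": rel.ud}
    out, w, zero = base.defuzzify(inputs)
    return DyadScore(
        follower_id=rel.follower_id,
        leader_id=rel.leader_id,
        t=rel.t,
        rule_strengths=tuple(float(s) for s in w),
        output=out,
        zero_fire=zero,
    )


def score_table(rels: pd.DataFrame, base: RuleBase) -> pd.DataFrame:
    """Vectorised :func:`score_dyad` over a relative-position table.

    Adds rule-strength columns ``r1..r5``, the defuzzified ``output`` and
    the ``zero_fire`` flag to a copy of ``rels``.
    """
    inputs = {
        "bird_ew": rels["ew"].to_numpy(),
        "bird_ns": rels["ns"].to_numpy(),
        "bird_plane": rels["ud"].to_numpy(),
    }
    out, w, zero = base.defuzzify(inputs)
    scored = rels.copy()
    for i, col in enumerate(RULE_COLUMNS[: len(base.rules)]):
        scored[col] = w[i]
    scored["output"] = np.asarray(out, dtype=float)
    scored["zero_fire"] = np.asarray(zero, dtype=bool)
    return scored


def front_candidates(rels: pd.DataFrame) -> pd.DataFrame:
    """Candidates expressed in the bird-of-interest's own flight frame.

    In the all-pairs table a row (follower=j, leader=k) gives bird j's
    coordinates in bird k's frame; from bird k's point of view those are
    exactly 'the relative coordinates of bird j'.  This helper relabels the
    table accordingly (``bird`` = frame owner, ``candidate`` = the other
    bird), so 'a bird in front of k' is a row with ``bird == k, ns > 0``.
    """
    out = rels.rename(columns={"leader": "bird", "follower": "candidate"})
    return out[["bird", "candidate", "timestamp", "ew", "ns", "ud", "dist3d"]]


def assign_leaders(scored: pd.DataFrame, front: pd.DataFrame, tau: float = 0.0) -> WakeAssignment:
    """Resolve one follower's state at one snapshot.

    ``scored`` holds the follower's scored candidate rows (its own
    position in each candidate leader's frame) at a single timestamp;
    ``front`` holds the candidates' positions in the follower's frame at
    the same snapshot (see :func:`front_candidates`), used for the
    nearest-bird-in-front fallback.  An empty ``scored`` with an empty
    ``front`` yields the alone state.
    """
    if len(scored):
        follower = str(scored["follower"].iloc[0])
        t = float(scored["timestamp"].iloc[0])
        order = scored.sort_values(
            ["output", "dist3d", "leader"], ascending=[False, True, True]
        )
        win = order.iloc[0]
        if win["output"] > tau:
            return WakeAssignment(
                follower, t, IN_WAKE, str(win["leader"]),
                float(win["ew"]), float(win["ns"]), float(win["ud"]),
                float(win["output"]),
            )
        output = float(win["output"])
    elif len(front):
        follower = str(front["bird"].iloc[0])
        t = float(front["timestamp"].iloc[0])
        output = 0.0
    else:
        raise ValueError("empty snapshot: no candidates in either orientation")
    ahead = front[front["ns"] > 0]
    if len(ahead):
        near = ahead.sort_values(["dist3d", "candidate"]).iloc[0]
        return WakeAssignment(
            follower, t, NOT_IN_WAKE_FRONT, str(near["candidate"]),
            float(near["ew"]), float(near["ns"]), float(near["ud"]), output,
        )
    return WakeAssignment(follower, t, ALONE_NO_FRONT, None, 0.0, 0.0, 0.0, output)


def assign_all(scored: pd.DataFrame, tau: float = 0.0) -> pd.DataFrame:
    """Per-snapshot leader assignment for every follower (vectorised).

    Exactly one row per (follower, timestamp) present in ``scored``; at
    most one outgoing wake edge per follower (the single-upwash
    constraint).  The winner is the candidate with the highest defuzzified
    output (ties broken by smaller 3D distance, then lexicographic id);
    when even the winner does not clear ``tau`` the record falls back to
    the nearest bird in front of the follower, in the follower's own
    frame, or zeros when nobody is in front.  Returns columns
    ``follower, timestamp, state, leader, ew, ns, ud, output``.
    """
    df = scored
    # winner per group: stable sort puts best candidate first
    order = df.sort_values(
        ["follower", "timestamp", "output", "dist3d", "leader"],
        ascending=[True, True, False, True, True],
        kind="mergesort",
    )
    win = order.drop_duplicates(["follower", "timestamp"], keep="first").copy()
    in_wake = (win["output"] > tau).to_numpy()

    # fallback: nearest bird in front of the follower, in its own frame
    fc = front_candidates(df)
    front = fc[fc["ns"] > 0].sort_values(
        ["bird", "timestamp", "dist3d", "candidate"], kind="mergesort"
    )
    front = front.drop_duplicates(["bird", "timestamp"], keep="first")
    front = front.set_index(["bird", "timestamp"])
    front.index.names = ["follower", "timestamp"]

    win = win.set_index(["follower", "timestamp"])
    out = pd.DataFrame(index=win.index)
    out["state"] = np.where(in_wake, IN_WAKE, ALONE_NO_FRONT)
    out["leader"] = win["leader"].where(in_wake, None)
    for col in ("ew", "ns", "ud"):
        out[col] = win[col].where(in_wake, 0.0)
    out["output"] = win["output"]

    need_front = out.index[out["state"] == ALONE_NO_FRONT]
    have_front = need_front.intersection(front.index)
    out.loc[have_front, "state"] = NOT_IN_WAKE_FRONT
    out.loc[have_front, "leader"] = front.loc[have_front, "candidate"]
    for col in ("ew", "ns", "ud"):
        out.loc[have_front, col] = front.loc[have_front, col]

    out = out.reset_index().sort_values(["follower", "timestamp"], ignore_index=True)
    return out


def response_grid(
    base: RuleBase,
    plane: str = "ud",
    value: float = 0.0,
    ew_range: tuple[float, float] = (-2.5, 2.5),
    ns_range: tuple[float, float] = (-6.0, 0.0),
    ud_range: tuple[float, float] = (-1.5, 1.5),
    resolution: float = 0.01,
):
    """Dense defuzzified-output grid over the two axes not fixed by ``plane``.

    Returns ``(axis1, axis2, matrix)`` where ``matrix[i, j]`` is the output
    at ``axis1[i], axis2[j]``; axis order is (ew, ns) for the co-planar
    plane, (ew, ud) when ns is fixed and (ns, ud) when ew is fixed.
    """
    if resolution <= 0:
        raise ConfigError("grid resolution must be positive")
    ranges = {"ew": ew_range, "ns": ns_range, "ud": ud_range}
    if plane not in ranges:
        raise ConfigError(f"plane must be one of {sorted(ranges)}")
    free = [a for a in ("ew", "ns", "ud") if a != plane]

    def axis(name):
        lo, hi = ranges[name]
        n = int(round((hi - lo) / resolution))
        if n < 1:
            raise ConfigError(f"degenerate grid for axis {name!r}")
        return lo + resolution * np.arange(n + 1)

    a1, a2 = axis(free[0]), axis(free[1])
    g1, g2 = np.meshgrid(a1, a2, indexing="ij")
    coords = {plane: np.full_like(g1, value), free[0]: g1, free[1]: g2}
    inputs = {
        "bird_ew": coords["ew"].ravel(),
        "bird_ns": coords["ns"].ravel(),
        "bird_plane": coords["ud"].ravel(),
    }
    out, _, _ = base.defuzzify(inputs)
    return a1, a2, np.asarray(out).reshape(g1.shape)
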