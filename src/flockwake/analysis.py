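"""Flock-level analytics over per-snapshot wake assignments.

Everything here consumes the assignment stream produced by
:func:`flockwake.wake_model.assign_all` (one row per follower per
snapshot): behavioural bouts, alone-time budgets, leader preference with a
bootstrap null, per-snapshot formation graphs with weakly connected
subgroups, and agreement between the fuzzy model and the
frontal-nearest-neighbour baseline.
"""

from __future__ import annotations

import warnings

import networkx as nx
import numpy as np
import pandas as pd

from .errors import AlignmentError, ConfigError
from .fnn import FNN_LEADER
from .wake_model import ALONE_NO_FRONT, IN_WAKE, NOT_IN_WAKE_FRONT

__all__ = [
    "extract_bouts",
    "alone_stats",
    "preference_with_bootstrap",
    "formation_graph",
    "formation_components",
    "subgroup_size_distribution",
    "model_agreement",
    "positional_histograms",
]


def _binary_state(states: pd.Series) -> pd.Series:
    return np.where(states == IN_WAKE, "in_wake", "not_in_wake")


def extract_bouts(
    assignments: pd.DataFrame,
    dt: float = 0.2,
    split_on_leader_change: bool = True,
) -> pd.DataFrame:
    """Run-length decomposition of assignment streams into bouts.

    A bout is a maximal run of consecutive snapshots in which a bird keeps
    the same binary state (in-wake vs not) and — when
    ``split_on_leader_change`` is on — the same leader while in-wake.
    Gaps in the timestamp grid terminate runs.  Duration is the number of
    samples times the sampling interval ``dt``.

    Returns columns
    ``follower, state, leader, start_t, end_t, n_samples, duration_s``.
    """
    if len(assignments) == 0:
        return pd.DataFrame(
            columns=[
                "follower", "state", "leader", "start_t", "end_t",
                "n_samples", "duration_s",
            ]
        )
    df = assignments.sort_values(["follower", "timestamp"]).reset_index(drop=True)
    binary = pd.Series(_binary_state(df["state"]), index=df.index)
    leader = df["leader"].where(binary == "in_wake", None)

    new_bird = df["follower"] != df["follower"].shift()
    tick = np.round(df["timestamp"] / dt).astype(np.int64)
    gap = tick.diff() != 1
    state_change = binary != binary.shift()
    boundary = new_bird | gap | state_change
    if split_on_leader_change:
        boundary |= (binary == "in_wake") & (leader != leader.shift())
    run = boundary.cumsum()

    g = df.groupby(run)
    out = pd.DataFrame(
        {
            "follower": g["follower"].first(),
            "state": binary.groupby(run).first(),
            "leader": leader.groupby(run).first(),
            "start_t": g["timestamp"].first(),
            "end_t": g["timestamp"].last(),
            "n_samples": g.size(),
        }
    ).reset_index(drop=True)
    out["duration_s"] = out["n_samples"] * dt
    return out


def alone_stats(assignments: pd.DataFrame) -> pd.DataFrame:
    """Per-bird proportion of snapshots spent not in-wake, split by cause.

    ``prop_no_front`` — nobody in front at all; ``prop_front_not_in_wake``
    — somebody in front but no wake exploited.  The two sum to
    ``prop_alone``.
    """
    g = assignments.groupby("follower")["state"]
    n = g.size()
    no_front = g.apply(lambda s: (s == ALONE_NO_FRONT).sum())
    front_not = g.apply(lambda s: (s == NOT_IN_WAKE_FRONT).sum())
    out = pd.DataFrame(
        {
            "n_snapshots": n,
            "prop_no_front": no_front / n,
            "prop_front_not_in_wake": front_not / n,
        }
    )
    out["prop_alone"] = out["prop_no_front"] + out["prop_front_not_in_wake"]
    return out.reset_index()


def preference_with_bootstrap(
    assignments: pd.DataFrame,
    n_boot: int = 1000,
    seed: int | np.random.Generator = 0,
    dt: float = 0.2,
    all_birds: list[str] | None = None,
    unit: str = "bout",
    ci: float = 0.95,
) -> pd.DataFrame:
    """Observed leader-following proportions with a bootstrap null band.

    For each follower, the observed statistic is the proportion of its
    in-wake snapshots spent behind each potential leader.  The null of no
    individual preference is simulated by redrawing the leader of every
    in-wake bout uniformly at random from the other N − 1 birds, keeping
    the bout durations fixed; the per-leader CI is the empirical
    2.5/97.5 percentile band (for ``ci=0.95``) over ``n_boot`` replicates.
    Bouts, not snapshots, are the resampling unit by default because
    consecutive snapshots are strongly autocorrelated; ``unit="snapshot"``
    treats every snapshot as its own bout.

    Returns columns
    ``follower, leader, observed, ci_low, ci_high, favourite``.
    """
    if n_boot < 1:
        raise ConfigError("n_boot must be >= 1")
    if unit not in ("bout", "snapshot"):
        raise ConfigError("unit must be 'bout' or 'snapshot'")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    birds = sorted(all_birds) if all_birds is not None else sorted(
        set(assignments["follower"]).union(
            assignments.loc[assignments["state"] == IN_WAKE, "leader"].dropna()
        )
    )
    index = {b: i for i, b in enumerate(birds)}
    n_birds = len(birds)
    if n_birds < 2:
        raise ConfigError("preference needs at least 2 birds")

    bouts = extract_bouts(assignments, dt=dt, split_on_leader_change=True)
    wake = bouts[bouts["state"] == "in_wake"]
    lo, hi = (1 - ci) / 2 * 100, (1 + ci) / 2 * 100

    rows = []
    for follower in sorted(assignments["follower"].unique()):
        fb = wake[wake["follower"] == follower]
        if len(fb) == 0:
            warnings.warn(f"bird {follower} has no in-wake time; skipped")
            continue
        if unit == "bout":
            weights = fb["n_samples"].to_numpy(dtype=float)
            leaders = fb["leader"].to_numpy()
        else:
            weights = np.ones(int(fb["n_samples"].sum()))
            leaders = np.repeat(fb["leader"].to_numpy(), fb["n_samples"].to_numpy())
        total = weights.sum()

        obs = np.zeros(n_birds)
        for ld, w in zip(leaders, weights):
            obs[index[ld]] += w
        obs /= total

        # null replicates: each bout's leader uniform over the other birds
        others = np.array([i for b, i in index.items() if b != follower])
        draws = rng.integers(0, len(others), size=(n_boot, len(weights)))
        picked = others[draws]
        null = np.zeros((n_boot, n_birds))
        np.add.at(
            null,
            (np.repeat(np.arange(n_boot), len(weights)), picked.ravel()),
            np.tile(weights, n_boot),
        )
        null /= total
        ci_low = np.percentile(null, lo, axis=0)
        ci_high = np.percentile(null, hi, axis=0)

        fav = birds[int(np.argmax(obs))]
        for b in birds:
            if b == follower:
                continue
            i = index[b]
            rows.append(
                {
                    "follower": follower,
                    "leader": b,
                    "observed": obs[i],
                    "ci_low": ci_low[i],
                    "ci_high": ci_high[i],
                    "favourite": b == fav,
                }
            )
    return pd.DataFrame(rows)


def formation_graph(assignments: pd.DataFrame, t: float) -> nx.DiGraph:
    """Directed wake graph (follower → leader arcs) at one snapshot."""
    snap = assignments[assignments["timestamp"] == t]
    g = nx.DiGraph()
    g.add_nodes_from(snap["follower"])
    wake = snap[snap["state"] == IN_WAKE]
    g.add_edges_from(zip(wake["follower"], wake["leader"]))
    return g


def formation_components(
    assignments: pd.DataFrame, include_singletons: bool = False
) -> tuple[pd.DataFrame, list[float]]:
    """Weakly connected subgroups of the wake graph, per snapshot.

    Weak connectivity ignores arc direction, so cycles (possible in
    principle because each bird's frame is its own) do not break the
    decomposition; snapshots whose wake graph contains a directed cycle
    are reported in the second return value.

    Returns ``(components, cyclic_timestamps)`` where ``components`` has
    columns ``timestamp, component_id, size, members``.
    """
    rows = []
    cyclic = []
    for t, snap in assignments.groupby("timestamp"):
        g = nx.DiGraph()
        g.add_nodes_from(snap["follower"])
        wake = snap[snap["state"] == IN_WAKE]
        g.add_edges_from(zip(wake["follower"], wake["leader"]))
        if not nx.is_directed_acyclic_graph(g):
            cyclic.append(float(t))
        for cid, comp in enumerate(nx.weakly_connected_components(g)):
            if len(comp) == 1 and not include_singletons:
                continue
            rows.append(
                {
                    "timestamp": float(t),
                    "component_id": cid,
                    "size": len(comp),
                    "members": ";".join(sorted(comp)),
                }
            )
    cols = ["timestamp", "component_id", "size", "members"]
    return pd.DataFrame(rows, columns=cols), cyclic


def subgroup_size_distribution(components: pd.DataFrame) -> pd.DataFrame:
    """Frequency of subgroup sizes aggregated over snapshots."""
    if len(components) == 0:
        return pd.DataFrame(columns=["size", "count", "proportion"])
    counts = components["size"].value_counts().sort_index()
    return pd.DataFrame(
        {"size": counts.index, "count": counts.values, "proportion": counts.values / counts.sum()}
    )


def _named_leader(df: pd.DataFrame) -> pd.Series:
    state_ok = df["state"].isin([IN_WAKE, FNN_LEADER])
    return df["leader"].where(state_ok, None)


def model_agreement(
    fis: pd.DataFrame, fnn: pd.DataFrame, mode: str = "both"
) -> tuple[float, pd.DataFrame, pd.DataFrame]:
    """Leader-identity agreement between the fuzzy and FNN assignments.

    ``mode`` controls the denominator: ``"both"`` restricts to snapshots
    where both models name a leader, ``"either"`` to snapshots where at
    least one does (a missing leader counts as disagreement), ``"all"``
    uses every snapshot (two empty answers agree).

    Returns ``(overall, per_bird, merged)`` where ``merged`` carries one
    row per comparable snapshot with both models' leaders and positions
    (columns suffixed ``_fis`` / ``_fnn``) and an ``agree`` flag — the
    input for the positional-distribution panels.
    """
    if mode not in ("both", "either", "all"):
        raise ConfigError("mode must be 'both', 'either' or 'all'")
    a = fis.copy()
    b = fnn.copy()
    a["named"] = _named_leader(a)
    b["named"] = _named_leader(b)
    merged = a.merge(
        b, on=["follower", "timestamp"], how="outer", suffixes=("_fis", "_fnn"),
        indicator=True,
    )
    if (merged["_merge"] != "both").any():
        raise AlignmentError("FIS and FNN assignment streams cover different snapshots")
    merged = merged.drop(columns="_merge")

    has_a = merged["named_fis"].notna()
    has_b = merged["named_fnn"].notna()
    if mode == "both":
        comparable = has_a & has_b
    elif mode == "either":
        comparable = has_a | has_b
    else:
        comparable = pd.Series(True, index=merged.index)
    merged = merged[comparable].copy()
    merged["agree"] = (
        (merged["named_fis"] == merged["named_fnn"])
        | (merged["named_fis"].isna() & merged["named_fnn"].isna())
    )
    if len(merged) == 0:
        warnings.warn("no comparable snapshots between the two models")
        return float("nan"), pd.DataFrame(columns=["follower", "n", "agreement"]), merged
    per_bird = (
        merged.groupby("follower")["agree"]
        .agg(n="size", agreement="mean")
        .reset_index()
    )
    return float(merged["agree"].mean()), per_bird, merged


def positional_histograms(
    merged: pd.DataFrame,
    bins: int = 60,
    ranges: dict | None = None,
) -> pd.DataFrame:
    """Marginal ew/ns/ud histograms of each model's chosen-leader position.

    ``merged`` is the third return of :func:`model_agreement`.  Emits one
    long-format table with columns
    ``axis, model, subset, bin_left, bin_right, count`` where ``subset``
    is ``all`` or ``disagree``.  Only snapshots where the model in
    question names a leader contribute.
    """
    ranges = ranges or {"ew": (-3.0, 3.0), "ns": (-6.0, 6.0), "ud": (-1.5, 1.5)}
    rows = []
    for axis in ("ew", "ns", "ud"):
        edges = np.linspace(*ranges[axis], bins + 1)
        for model in ("fis", "fnn"):
            named = merged[merged[f"named_{model}"].notna()]
            for subset, sub in (("all", named), ("disagree", named[~named["agree"]])):
                counts, _ = np.histogram(sub[f"{axis}_{model}"], bins=edges)
                rows.extend(
                    {
                        "axis": axis,
                        "model": model,
                        "subset": subset,
                        "bin_left": edges[i],
                        "bin_right": edges[i + 1],
                        "count": int(c),
                    }
                    for i, c in enumerate(counts)
                )
    return pd.DataFrame(rows)
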