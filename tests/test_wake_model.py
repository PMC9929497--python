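import numpy as np
import pandas as pd
import pytest

from flockwake import (
    RelativePosition,
    WakeModelConfig,
    assign_all,
    assign_leaders,
    build_rulebase,
    response_grid,
    score_dyad,
    score_table,
)
from flockwake.errors import ConfigError
from flockwake.wake_model import (
    ALONE_NO_FRONT,
    IN_WAKE,
    NOT_IN_WAKE_FRONT,
    front_candidates,
)


def rel(ew, ns, ud, follower="F", leader="L", t=1.0):
    return RelativePosition(follower, leader, t, ew, ns, ud)


class TestRuleBaseConstruction:
    def test_exactly_five_rules(self, base):
        assert len(base.rules) == 5
        assert [r.consequent_label for r in base.rules] == [
            "in_wake", "not_in_wake", "not_in_wake", "not_in_wake", "not_in_wake",
        ]

    def test_rule1_fires_fully_at_the_optimum(self, base):
        s = base.rule_strength(
            base.rules[0], {"bird_ew": 1.3, "bird_ns": -0.1, "bird_plane": 0.0}
        )
        assert s == 1.0

    def test_misaligned_is_one_in_the_downwash_corridor(self, base):
        mf = base.variables["bird_ew"].terms["wingtip_misaligned"]
        for x in (-0.8, -0.5, 0.0, 0.5, 0.8):
            assert mf(x) == 1.0
        assert mf(2.5) == 1.0  # and beyond the outer zero

    def test_complement_identities(self, base, rng):
        ew = base.variables["bird_ew"]
        plane = base.variables["bird_plane"]
        for x in rng.uniform(-3, 3, 200):
            assert ew.membership("wingtip_aligned", x) + ew.membership(
                "wingtip_misaligned", x
            ) == pytest.approx(1.0, abs=1e-15)
            assert plane.membership("same_plane", x) + plane.membership(
                "different_plane", x
            ) == pytest.approx(1.0, abs=1e-15)
        assert plane.membership("same_plane", -0.75) + plane.membership(
            "different_plane", -0.75
        ) == 1.0

    def test_invalid_config_rejected(self):
        with pytest.raises(ConfigError):
            WakeModelConfig(ew_inner_zero=1.5)  # inner zero beyond the peak
        with pytest.raises(ConfigError):
            WakeModelConfig(tau=1.0)
        with pytest.raises(ConfigError):
            WakeModelConfig(ns_peak=0.1)

    def test_peak_plateau_config(self):
        base = build_rulebase(WakeModelConfig(ew_peak_halfwidth=0.1))
        mf = base.variables["bird_ew"].terms["wingtip_aligned"]
        assert mf(1.2) == mf(1.3) == mf(1.4) == 1.0
        assert mf(1.8) == 0.0


class TestScoreDyad:
    @pytest.mark.parametrize(
        "ew, ns, ud, expected",
        [
            (1.3, -0.1, 0.0, 1.0),   # optimum: only the in-wake rule fires
            (0.0, -1.0, 0.0, 0.0),   # directly behind: downwash
            (1.3, 1.0, 0.0, 0.0),    # follower ahead
            (-1.3, -0.1, 0.0, 1.0),  # left/right symmetry
        ],
    )
    def test_canonical_positions(self, base, ew, ns, ud, expected):
        assert score_dyad(rel(ew, ns, ud), base).output == pytest.approx(expected)

    def test_left_right_symmetry(self, base, rng):
        ew = rng.uniform(0, 3, 300)
        ns = rng.uniform(-7, 1, 300)
        ud = rng.uniform(-2, 2, 300)
        a, _, _ = base.defuzzify({"bird_ew": ew, "bird_ns": ns, "bird_plane": ud})
        b, _, _ = base.defuzzify({"bird_ew": -ew, "bird_ns": ns, "bird_plane": ud})
        np.testing.assert_allclose(a, b, atol=1e-14)

    def test_vertical_symmetry(self, base, rng):
        ew = rng.uniform(-3, 3, 300)
        ns = rng.uniform(-7, 1, 300)
        ud = rng.uniform(0, 2, 300)
        a, _, _ = base.defuzzify({"bird_ew": ew, "bird_ns": ns, "bird_plane": ud})
        b, _, _ = base.defuzzify({"bird_ew": ew, "bird_ns": ns, "bird_plane": -ud})
        np.testing.assert_allclose(a, b, atol=1e-14)

    def test_zero_output_for_nonnegative_ns(self, base, rng):
        ew = rng.uniform(-3, 3, 500)
        ns = rng.uniform(0, 5, 500)
        ud = rng.uniform(-2, 2, 500)
        out, _, _ = base.defuzzify({"bird_ew": ew, "bird_ns": ns, "bird_plane": ud})
        assert (np.asarray(out) == 0.0).all()

    def test_monotone_decay_behind_the_optimum(self, base):
        ns = np.linspace(-0.1, -5.0, 1000)
        out, _, _ = base.defuzzify(
            {"bird_ew": np.full_like(ns, 1.3), "bird_ns": ns, "bird_plane": np.zeros_like(ns)}
        )
        assert (np.diff(out) <= 1e-12).all()
        far, _, _ = base.defuzzify({"bird_ew": 1.3, "bird_ns": -6.0, "bird_plane": 0.0})
        assert far == 0.0

    def test_score_table_matches_scalar_path(self, base, rng):
        rows = pd.DataFrame(
            {
                "follower": "F",
                "leader": "L",
                "timestamp": np.arange(50) * 0.2,
                "ew": rng.uniform(-3, 3, 50),
                "ns": rng.uniform(-6, 1, 50),
                "ud": rng.uniform(-1, 1, 50),
            }
        )
        rows["dist3d"] = np.sqrt(rows.ew**2 + rows.ns**2 + rows.ud**2)
        scored = score_table(rows, base)
        for _, r in scored.iterrows():
            d = score_dyad(rel(r.ew, r.ns, r.ud), base)
            assert r.output == pytest.approx(d.output, abs=1e-15)
            assert tuple(r[["r1", "r2", "r3", "r4", "r5"]]) == pytest.approx(
                d.rule_strengths, abs=1e-15
            )


def scored_frame(rows):
    """rows: (follower, leader, t, ew, ns, ud, output)"""
    df = pd.DataFrame(
        rows, columns=["follower", "leader", "timestamp", "ew", "ns", "ud", "output"]
    )
    df["dist3d"] = np.sqrt(df.ew**2 + df.ns**2 + df.ud**2)
    return df


class TestAssignLeaders:
    def test_argmax_wins(self):
        df = scored_frame(
            [("F", "B", 1.0, 1.3, -0.5, 0.0, 0.9), ("F", "C", 1.0, 1.6, -2.0, 0.0, 0.4)]
        )
        a = assign_leaders(df, front_candidates(df.iloc[0:0]), tau=0.0)
        assert a.state == IN_WAKE and a.leader_id == "B"
        assert a.output == pytest.approx(0.9)

    def test_fallback_to_nearest_front_bird(self):
        scored = scored_frame([("F", "B", 1.0, 0.0, -2.0, 0.0, 0.0)])
        # B is 2 m ahead of F in F's own frame
        front = pd.DataFrame(
            {"bird": ["F"], "candidate": ["B"], "timestamp": [1.0],
             "ew": [0.0], "ns": [2.0], "ud": [0.0], "dist3d": [2.0]}
        )
        a = assign_leaders(scored, front, tau=0.0)
        assert a.state == NOT_IN_WAKE_FRONT and a.leader_id == "B"
        assert a.ns == pytest.approx(2.0)

    def test_alone_when_nobody_in_front(self):
        scored = scored_frame([("F", "B", 1.0, 0.0, 3.0, 0.0, 0.0)])
        front = pd.DataFrame(
            {"bird": ["F"], "candidate": ["B"], "timestamp": [1.0],
             "ew": [0.0], "ns": [-3.0], "ud": [0.0], "dist3d": [3.0]}
        )
        a = assign_leaders(scored, front, tau=0.0)
        assert a.state == ALONE_NO_FRONT
        assert (a.ew, a.ns, a.ud) == (0.0, 0.0, 0.0)
        assert a.leader_id is None

    def test_tie_broken_by_distance_then_id(self):
        df = scored_frame(
            [("F", "C", 1.0, 1.3, -2.0, 0.0, 0.5), ("F", "B", 1.0, 1.3, -0.5, 0.0, 0.5)]
        )
        a = assign_leaders(df, df.iloc[0:0], tau=0.0)
        assert a.leader_id == "B"  # closer of the tied pair
        df2 = scored_frame(
            [("F", "C", 1.0, 1.3, -0.5, 0.0, 0.5), ("F", "B", 1.0, -1.3, -0.5, 0.0, 0.5)]
        )
        a2 = assign_leaders(df2, df2.iloc[0:0], tau=0.0)
        assert a2.leader_id == "B"  # equal distance: lexicographic

    def test_tau_threshold_is_strict(self):
        df = scored_frame([("F", "B", 1.0, 1.3, -0.5, 0.0, 0.5)])
        front = front_candidates(df.iloc[0:0])
        assert assign_leaders(df, front, tau=0.49).state == IN_WAKE
        assert assign_leaders(df, front, tau=0.5).state == ALONE_NO_FRONT


class TestAssignAll:
    def test_one_row_per_follower_snapshot_and_outdegree(self, noisy_v_run):
        _, _, _, scored, assignments = noisy_v_run
        key = assignments[["follower", "timestamp"]]
        assert not key.duplicated().any()
        expected = scored[["follower", "timestamp"]].drop_duplicates()
        assert len(assignments) == len(expected)
        # out-degree <= 1 is structural: one row per follower per snapshot
        wake = assignments[assignments.state == IN_WAKE]
        assert not wake[["follower", "timestamp"]].duplicated().any()

    def test_matches_single_snapshot_resolver(self, noisy_v_run):
        _, _, rels, scored, assignments = noisy_v_run
        fc = front_candidates(rels)
        sample = assignments.sample(25, random_state=1)
        for _, row in sample.iterrows():
            s = scored[(scored.follower == row.follower) & (scored.timestamp == row.timestamp)]
            f = fc[(fc.bird == row.follower) & (fc.timestamp == row.timestamp)]
            a = assign_leaders(s, f, tau=0.0)
            assert a.state == row.state
            assert (a.leader_id or None) == (row.leader or None)


class TestResponseGrid:
    def test_coplanar_argmax_at_the_wake_optimum(self, base):
        ew, ns, grid = response_grid(base, plane="ud", value=0.0, resolution=0.05)
        i, j = np.unravel_index(np.argmax(grid), grid.shape)
        assert abs(ew[i]) == pytest.approx(1.3)
        assert ns[j] == pytest.approx(-0.1)

    def test_directly_behind_plane_is_all_zero(self, base):
        # with ew = 0 the misalignment rule fires fully everywhere
        ns, ud, grid = response_grid(base, plane="ew", value=0.0, resolution=0.1)
        assert (grid == 0.0).all()

    def test_left_right_mirror_symmetry(self, base):
        ew, ns, grid = response_grid(base, plane="ud", value=0.0, resolution=0.05)
        np.testing.assert_allclose(grid, grid[::-1, :], atol=1e-14)

    def test_degenerate_grid_rejected(self, base):
        with pytest.raises(ConfigError):
            response_grid(base, resolution=-0.1)
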