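import numpy as np
import pandas as pd
import pytest

from flockwake.analysis import (
    alone_stats,
    extract_bouts,
    formation_components,
    formation_graph,
    model_agreement,
    positional_histograms,
    preference_with_bootstrap,
    subgroup_size_distribution,
)
from flockwake.errors import AlignmentError

from .conftest import make_assignments

W, N, A = "in_wake", "not_in_wake_front_bird", "alone_no_front"


def stream(bird, states_leaders, t0=0.0, dt=0.2):
    return make_assignments(
        [
            (bird, t0 + i * dt, s, ld)
            for i, (s, ld) in enumerate(states_leaders)
        ]
    )


class TestBouts:
    def test_runs_split_on_state_change(self):
        df = stream("F", [(W, "A"), (W, "A"), (N, None), (W, "A")])
        bouts = extract_bouts(df, dt=0.2, split_on_leader_change=False)
        assert list(bouts.duration_s) == [0.4, 0.2, 0.2]
        assert list(bouts.state) == ["in_wake", "not_in_wake", "in_wake"]

    def test_leader_change_splits_when_flagged(self):
        df = stream("F", [(W, "A"), (W, "B")])
        split = extract_bouts(df, dt=0.2, split_on_leader_change=True)
        assert len(split) == 2 and list(split.duration_s) == [0.2, 0.2]
        merged = extract_bouts(df, dt=0.2, split_on_leader_change=False)
        assert len(merged) == 1 and merged.duration_s.iloc[0] == pytest.approx(0.4)

    def test_long_constant_run(self):
        df = stream("F", [(A, None)] * 50)
        bouts = extract_bouts(df, dt=0.2)
        assert len(bouts) == 1
        assert bouts.duration_s.iloc[0] == pytest.approx(10.0)

    def test_gap_terminates_run(self):
        df = pd.concat(
            [stream("F", [(W, "A")] * 3), stream("F", [(W, "A")] * 3, t0=2.0)],
            ignore_index=True,
        )
        bouts = extract_bouts(df, dt=0.2)
        assert len(bouts) == 2

    def test_durations_sum_to_total_flight(self, noisy_v_run):
        _, _, _, _, assignments = noisy_v_run
        bouts = extract_bouts(assignments, dt=0.2)
        per_bird = bouts.groupby("follower")["duration_s"].sum()
        counts = assignments.groupby("follower").size() * 0.2
        pd.testing.assert_series_equal(
            per_bird, counts.rename("duration_s"), check_like=True
        )


class TestAloneStats:
    def test_always_front_never_in_wake(self):
        df = stream("F", [(N, None)] * 10)
        s = alone_stats(df).iloc[0]
        assert s.prop_alone == 1.0
        assert s.prop_front_not_in_wake == 1.0 and s.prop_no_front == 0.0

    def test_always_in_wake(self):
        df = stream("F", [(W, "A")] * 10)
        assert alone_stats(df).iloc[0].prop_alone == 0.0

    def test_mixed_split(self):
        df = stream("F", [(W, "A")] * 7 + [(A, None)] * 2 + [(N, None)] * 1)
        s = alone_stats(df).iloc[0]
        assert s.prop_alone == pytest.approx(0.3)
        assert s.prop_no_front == pytest.approx(0.2)
        assert s.prop_front_not_in_wake == pytest.approx(0.1)


class TestPreference:
    def test_single_leader_gets_full_proportion(self):
        df = stream("F", [(W, "A")] * 10)
        pref = preference_with_bootstrap(df, n_boot=50, seed=0, all_birds=["F", "A", "B"])
        row = pref[pref.leader == "A"].iloc[0]
        assert row.observed == 1.0 and row.favourite
        assert pref[pref.leader == "B"].iloc[0].observed == 0.0

    def test_bout_counting_proportions(self):
        # 3 bouts behind A, 1 behind B, all one sample long
        df = stream("F", [(W, "A"), (N, None), (W, "A"), (N, None), (W, "A"), (N, None), (W, "B")])
        pref = preference_with_bootstrap(df, n_boot=50, seed=0, all_birds=["F", "A", "B"])
        assert pref[pref.leader == "A"].iloc[0].observed == pytest.approx(0.75)
        assert pref[pref.leader == "B"].iloc[0].observed == pytest.approx(0.25)

    def test_ci_bounds_ordered_and_in_unit_interval(self):
        df = stream("F", [(W, "A"), (W, "B"), (W, "C")] * 5)
        pref = preference_with_bootstrap(df, n_boot=200, seed=3)
        assert (pref.ci_low <= pref.ci_high).all()
        assert (pref.observed >= 0).all() and (pref.observed <= 1).all()

    def test_no_wake_time_warns_and_skips(self):
        df = stream("F", [(A, None)] * 5)
        with pytest.warns(UserWarning):
            pref = preference_with_bootstrap(df, n_boot=10, seed=0, all_birds=["F", "A"])
        assert len(pref) == 0

    def test_proportions_sum_to_one_per_follower(self, noisy_v_run):
        _, _, _, _, assignments = noisy_v_run
        pref = preference_with_bootstrap(assignments, n_boot=20, seed=5)
        sums = pref.groupby("follower")["observed"].sum()
        np.testing.assert_allclose(sums, 1.0)


class TestFormation:
    def test_shared_leader_joins_component(self):
        df = make_assignments(
            [("A", 0.0, W, "B"), ("C", 0.0, W, "B"), ("B", 0.0, A, None)]
        )
        comps, cyclic = formation_components(df)
        assert len(comps) == 1 and comps.iloc[0]["size"] == 3
        assert comps.iloc[0].members == "A;B;C"
        assert cyclic == []

    def test_chain_is_one_component(self):
        df = make_assignments(
            [("A", 0.0, W, "B"), ("B", 0.0, W, "C"), ("C", 0.0, W, "D"), ("D", 0.0, A, None)]
        )
        comps, _ = formation_components(df)
        assert comps.iloc[0]["size"] == 4
        # union-find oracle
        parent = {x: x for x in "ABCD"}

        def find(x):
            while parent[x] != x:
                x = parent[x]
            return x

        for u, v in [("A", "B"), ("B", "C"), ("C", "D")]:
            parent[find(u)] = find(v)
        assert len({find(x) for x in "ABCD"}) == 1

    def test_singletons_excluded_by_default(self):
        df = make_assignments([(b, 0.0, A, None) for b in "ABCDE"])
        comps, _ = formation_components(df)
        assert len(comps) == 0
        with_singletons, _ = formation_components(df, include_singletons=True)
        assert len(with_singletons) == 5
        assert (with_singletons["size"] == 1).all()

    def test_two_cycle_detected_but_component_returned(self):
        df = make_assignments([("A", 0.0, W, "B"), ("B", 0.0, W, "A")])
        comps, cyclic = formation_components(df)
        assert cyclic == [0.0]
        assert comps.iloc[0]["size"] == 2

    def test_component_sizes_sum_to_n_with_singletons(self, noisy_v_run):
        _, _, _, _, assignments = noisy_v_run
        comps, _ = formation_components(assignments, include_singletons=True)
        n = assignments["follower"].nunique()
        assert (comps.groupby("timestamp")["size"].sum() == n).all()

    def test_formation_graph_outdegree(self, noisy_v_run):
        _, _, _, _, assignments = noisy_v_run
        t = assignments["timestamp"].iloc[100]
        g = formation_graph(assignments, t)
        assert max(dict(g.out_degree).values()) <= 1

    def test_size_distribution(self):
        comps = pd.DataFrame({"timestamp": [0, 0, 1], "component_id": [0, 1, 0],
                              "size": [2, 3, 2], "members": ["a;b", "c;d;e", "a;b"]})
        dist = subgroup_size_distribution(comps)
        assert dist[dist["size"] == 2]["count"].iloc[0] == 2
        assert dist["proportion"].sum() == pytest.approx(1.0)


class TestAgreement:
    def test_identical_streams_agree_fully(self):
        fis = stream("F", [(W, "A")] * 5)
        fnn = fis.copy()
        fnn["state"] = "fnn_leader"
        overall, per_bird, merged = model_agreement(fis, fnn)
        assert overall == 1.0
        assert per_bird.agreement.iloc[0] == 1.0

    def test_symmetry_and_bounds(self, noisy_v_run):
        from flockwake.fnn import fnn_table

        _, _, rels, _, fis = noisy_v_run
        fnn = fnn_table(rels)
        a, _, _ = model_agreement(fis, fnn)
        b, _, _ = model_agreement(fnn, fis)
        assert a == pytest.approx(b)
        assert 0.0 <= a <= 1.0

    def test_mode_denominators(self):
        fis = stream("F", [(W, "A"), (A, None), (A, None)])
        fnn = stream("F", [("fnn_leader", "B"), ("fnn_leader", "B"), ("no_front_neighbour", None)])
        both, _, _ = model_agreement(fis, fnn, mode="both")
        either, _, _ = model_agreement(fis, fnn, mode="either")
        alls, _, _ = model_agreement(fis, fnn, mode="all")
        assert both == 0.0          # 1 comparable snapshot, different leaders
        assert either == 0.0        # 2 snapshots, no agreement
        assert alls == pytest.approx(1 / 3)  # both-empty counts as agreement

    def test_mismatched_snapshots_raise(self):
        fis = stream("F", [(W, "A")] * 3)
        fnn = stream("F", [("fnn_leader", "A")] * 4)
        with pytest.raises(AlignmentError):
            model_agreement(fis, fnn)

    def test_positional_histograms_count_named_snapshots(self):
        fis = stream("F", [(W, "A")] * 4)
        fis[["ew", "ns", "ud"]] = [[1.3, -0.5, 0.0]] * 4
        fnn = fis.copy()
        fnn["state"] = "fnn_leader"
        _, _, merged = model_agreement(fis, fnn)
        hist = positional_histograms(merged, bins=10)
        ew_fis = hist[(hist.axis == "ew") & (hist.model == "fis") & (hist.subset == "all")]
        assert ew_fis["count"].sum() == 4
        disagree = hist[hist.subset == "disagree"]
        assert disagree["count"].sum() == 0
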