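"""Region membership, occupancy, visit, residence, and entry statistics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ionsite.regions import (
    Region,
    count_entries,
    extract_visits,
    make_region,
    membership_series,
    occupancy_counts,
    occupancy_fractions,
    residence_stats,
    visits_from_membership,
)

from conftest import make_topology, oracle_min_image, oracle_visits, pattern_system


class TestMakeRegion:
    def test_anchor_point_is_member(self):
        top, traj = pattern_system([[1]])
        region = make_region(top, ["LYS:539"], radius=6.0)
        assert region.contains(
            np.array([[25.0, 25.0, 25.0]]), traj.coords[0], traj.box[0]
        )[0]

    def test_point_beyond_radius_is_not(self):
        top, traj = pattern_system([[1]])
        region = make_region(top, ["LYS:539"], radius=6.0)
        pt = np.array([[25.0 + 6.1, 25.0, 25.0]])
        assert not region.contains(pt, traj.coords[0], traj.box[0])[0]

    def test_membership_matches_union_of_spheres_oracle(self, rng):
        top = make_topology(
            0, anchors=(("LYS", 539, "NZ"), ("ARG", 730, "CZ"), ("GLU", 535, "CD"))
        )
        frame = rng.uniform(0, 50, size=(top.n_atoms, 3))
        box = np.array([50.0, 50.0, 50.0])
        region = make_region(top, ["LYS:539", "ARG:730", "GLU:535"], radius=7.0)
        points = rng.uniform(0, 50, size=(1000, 3))
        got = region.contains(points, frame, box)
        anchors = frame[:3]
        for k, p in enumerate(points):
            expect = any(
                oracle_min_image(p, a, box) <= 7.0 for a in anchors
            )
            assert got[k] == expect

    def test_unmatched_selector_lists_names(self):
        top = make_topology(1)
        with pytest.raises(ValueError, match="ARG:999"):
            make_region(top, ["LYS:539", "ARG:999"], radius=6.0)

    def test_slab_restricts_membership(self):
        top, traj = pattern_system([[1]])
        region = make_region(top, ["LYS:539"], radius=6.0,
                             slab_axis=2, slab_bounds=(24.0, 26.0))
        inside = np.array([[25.0, 25.0, 25.0]])
        above = np.array([[25.0, 25.0, 28.0]])
        assert region.contains(inside, traj.coords[0], traj.box[0])[0]
        assert not region.contains(above, traj.coords[0], traj.box[0])[0]

    def test_nonpositive_radius_rejected(self):
        with pytest.raises(ValueError, match="radius"):
            Region(name="r", anchor_groups=[np.array([0])], radius=0.0)


class TestOccupancy:
    def test_always_inside_counts_one(self):
        top, traj = pattern_system([np.ones(10)])
        region = make_region(top, ["LYS:539"], radius=6.0, name="cav")
        table = occupancy_counts(traj, top, [region], ["Cl-"])
        assert np.all(table.counts[:, 0, 0] == 1)

    def test_alternating_pattern(self):
        top, traj = pattern_system([[1, 0, 1, 0, 1, 0]])
        region = make_region(top, ["LYS:539"], radius=6.0)
        table = occupancy_counts(traj, top, [region], ["Cl-"])
        assert list(table.counts[:, 0, 0]) == [1, 0, 1, 0, 1, 0]

    def test_counts_match_brute_force_recount(self, rng):
        # independent O(frames*ions*anchors) recomputation on a 50-frame fixture
        n_frames, n_ions = 50, 4
        patterns = rng.integers(0, 2, size=(n_ions, n_frames))
        top, traj = pattern_system(list(patterns))
        region = make_region(top, ["LYS:539"], radius=6.0)
        table = occupancy_counts(traj, top, [region], ["Cl-"])
        for f in range(n_frames):
            anchor = traj.coords[f, 0]
            expect = sum(
                oracle_min_image(traj.coords[f, 1 + i], anchor, traj.box[f]) <= 6.0
                for i in range(n_ions)
            )
            assert table.counts[f, 0, 0] == expect

    def test_unknown_species_rejected(self):
        top, traj = pattern_system([[1]])
        region = make_region(top, ["LYS:539"], radius=6.0)
        with pytest.raises(ValueError, match="unknown species"):
            occupancy_counts(traj, top, [region], ["Xx+"])

    def test_fractions_all_zero(self):
        top, traj = pattern_system([np.zeros(20)])
        region = make_region(top, ["LYS:539"], radius=6.0)
        table = occupancy_counts(traj, top, [region], ["Cl-"])
        fr = occupancy_fractions(table)
        assert fr.iloc[0]["0"] == 100.0

    def test_fractions_60_40(self):
        pat1 = np.ones(100)                    # in all 100 frames
        pat2 = np.r_[np.zeros(60), np.ones(40)]  # joins for the last 40
        top, traj = pattern_system([pat1, pat2])
        region = make_region(top, ["LYS:539"], radius=6.0)
        table = occupancy_counts(traj, top, [region], ["Cl-"])
        fr = occupancy_fractions(table)
        assert fr.iloc[0]["1"] == pytest.approx(60.0)
        assert fr.iloc[0]["2"] == pytest.approx(40.0)

    @given(counts=st.lists(st.integers(min_value=0, max_value=6),
                           min_size=1, max_size=60))
    @settings(max_examples=50, deadline=None)
    def test_fraction_rows_sum_to_100(self, counts):
        from ionsite.regions import OccupancyTable

        table = OccupancyTable(
            counts=np.array(counts, dtype=int).reshape(-1, 1, 1),
            regions=["r"], species=["Cl-"], dt=0.1,
        )
        fr = occupancy_fractions(table)
        total = fr.iloc[0][["0", "1", "2", "3+"]].sum()
        assert abs(total - 100.0) < 1e-9


class TestVisits:
    def test_single_run_gap0(self):
        visits = visits_from_membership([0, 0, 0, 1, 1, 1, 0, 0], 0, 1)
        assert visits == [(3, 5)]

    def test_gap1_bridges(self):
        assert visits_from_membership([0, 0, 1, 1, 0, 1, 1], 1, 1) == [(2, 6)]

    def test_gap0_splits(self):
        assert visits_from_membership([0, 0, 1, 1, 0, 1, 1], 0, 1) == [
            (2, 3), (5, 6)
        ]

    @given(member=st.lists(st.booleans(), min_size=1, max_size=30),
           gap=st.integers(min_value=0, max_value=4),
           min_dur=st.integers(min_value=1, max_value=4))
    @settings(max_examples=200, deadline=None)
    def test_matches_scan_oracle(self, member, gap, min_dur):
        assert visits_from_membership(member, gap, min_dur) == oracle_visits(
            member, gap, min_dur
        )

    @given(member=st.lists(st.booleans(), min_size=1, max_size=30),
           gap=st.integers(min_value=0, max_value=4))
    @settings(max_examples=100, deadline=None)
    def test_merging_monotonicity(self, member, gap):
        # more bridging or a higher duration floor never adds visits
        n_lo = len(visits_from_membership(member, gap, 1))
        n_hi = len(visits_from_membership(member, gap + 1, 1))
        assert n_hi <= n_lo
        n_dur = len(visits_from_membership(member, gap, 2))
        assert n_dur <= n_lo

    def test_extract_visits_censoring_flags(self):
        top, traj = pattern_system([[1, 1, 0, 0, 1, 1]])
        region = make_region(top, ["LYS:539"], radius=6.0, name="cav")
        v = extract_visits(traj, top, region, ["Cl-"], gap_tolerance=0,
                           min_duration=1)
        assert len(v) == 2
        assert bool(v.iloc[0]["censored_start"]) and not bool(v.iloc[0]["censored_end"])
        assert bool(v.iloc[1]["censored_end"]) and not bool(v.iloc[1]["censored_start"])
        assert v.iloc[0]["duration_ns"] == pytest.approx(0.2)

    def test_conservation_vs_occupancy(self, rng):
        # sum over ions of in-region frames (gap 0, min 1) == sum of counts
        patterns = rng.integers(0, 2, size=(5, 40))
        top, traj = pattern_system(list(patterns))
        region = make_region(top, ["LYS:539"], radius=6.0, name="cav")
        table = occupancy_counts(traj, top, [region], ["Cl-"])
        v = extract_visits(traj, top, region, ["Cl-"], gap_tolerance=0,
                           min_duration=1)
        frames_in = int((v["end"] - v["start"] + 1).sum())
        assert frames_in == int(table.counts.sum())


class TestResidenceStats:
    def _visits(self, durations, censored=None):
        n = len(durations)
        censored = censored or [False] * n
        return pd.DataFrame({
            "ion": range(n), "species": ["Cl-"] * n, "region": ["cav"] * n,
            "start": [10] * n, "end": [10 + int(d * 10) - 1 for d in durations],
            "duration_ns": durations,
            "censored_start": [False] * n, "censored_end": censored,
        })

    def test_mean_of_three(self):
        stats = residence_stats(self._visits([1.0, 2.0, 3.0]))
        assert stats.iloc[0]["mean_ns"] == pytest.approx(2.0)
        assert stats.iloc[0]["n_visits"] == 3

    def test_no_visits_undefined_sentinel(self):
        stats = residence_stats(self._visits([5.0], censored=[True]))
        assert stats.iloc[0]["n_visits"] == 0
        assert stats.iloc[0]["n_censored"] == 1
        assert np.isnan(stats.iloc[0]["mean_ns"])

    def test_empty_frame(self):
        stats = residence_stats(pd.DataFrame(columns=[
            "ion", "species", "region", "start", "end", "duration_ns",
            "censored_start", "censored_end"]))
        assert len(stats) == 0

    def test_markov_estimator_recovery(self):
        # geometric closed form via the full coordinate pipeline
        from ionsite.synthetic import MarkovModel, MarkovState, simulate_markov_ions

        model = MarkovModel(
            states=[MarkovState("bulk", kind="bulk"),
                    MarkovState("bound", center=[30.0, 30.0, 30.0], jitter_sd=0.3)],
            transition=np.array([[0.7, 0.3], [0.05, 0.95]]),
            dt=0.1, ions={"Cl-": 6}, box=np.ones(3) * 60, seed=23,
        )
        top, traj, truth = simulate_markov_ions(model, 4000)
        # static anchor atom at the bound-state center defines the region
        top2, _ = _with_anchor(top, traj, [30.0, 30.0, 30.0])
        region = make_region(top2, ["LYS:1"], radius=6.0, name="site")
        traj2 = _prepend_static_atom(traj, [30.0, 30.0, 30.0])
        v = extract_visits(traj2, top2, region, ["Cl-"], gap_tolerance=0,
                           min_duration=1)
        stats = residence_stats(v)
        # region membership must reproduce the generator's state sequence,
        # so the estimate equals the ground-truth visit mean exactly
        truth_lengths = []
        for seq in truth["state_sequence"]:
            s = np.asarray(seq)
            run = 0
            for i, val in enumerate(np.append(s, 0)):
                if val == 1:
                    run += 1
                elif run:
                    if i - run != 0 and i != len(s):
                        truth_lengths.append(run)
                    run = 0
        assert stats.iloc[0]["n_visits"] == len(truth_lengths)
        assert stats.iloc[0]["mean_ns"] == pytest.approx(
            np.mean(truth_lengths) * model.dt
        )
        expect = truth["expected_residence_ns"]["bound"]
        n = stats.iloc[0]["n_visits"]
        se = stats.iloc[0]["mean_ns"] / np.sqrt(n)  # geometric sd ~ mean
        assert abs(stats.iloc[0]["mean_ns"] - expect) < 3 * se


def _with_anchor(top, traj, pos):
    from conftest import make_topology

    anchor_top = make_topology(0, anchors=(("LYS", 1, "NZ"),), box=top.box)
    return anchor_top.concat(top), None


def _prepend_static_atom(traj, pos):
    from ionsite.io import Trajectory

    static = np.tile(np.asarray(pos, dtype=float), (traj.n_frames, 1, 1))
    return Trajectory(coords=np.concatenate([static, traj.coords], axis=1),
                      dt=traj.dt, box=traj.box)


class TestEntries:
    def test_single_visit_one_entry(self):
        top, traj = pattern_system([[0, 1, 1, 1, 0, 0]])
        region = make_region(top, ["LYS:539"], radius=6.0, name="cav")
        v = extract_visits(traj, top, region, ["Cl-"], 0, 1)
        ent = count_entries(v, traj.n_frames)
        assert ent.iloc[0]["n_entries"] == 1
        assert ent.iloc[0]["n_exchanges"] == 0

    def test_two_ion_exchange(self):
        # ion A occupies frames 1-3; ion B takes over at frame 4 with no
        # empty frame in between: 2 entries, 1 exchange
        top, traj = pattern_system([
            [0, 1, 1, 1, 0, 0, 0, 0, 0, 0],
            [0, 0, 0, 0, 1, 1, 1, 1, 1, 0],
        ])
        region = make_region(top, ["LYS:539"], radius=6.0, name="cav")
        v = extract_visits(traj, top, region, ["Cl-"], 0, 1)
        ent = count_entries(v, traj.n_frames)
        assert ent.iloc[0]["n_entries"] == 2
        assert ent.iloc[0]["n_exchanges"] == 1

    def test_censored_start_not_an_entry(self):
        top, traj = pattern_system([[1, 1, 0, 0]])
        region = make_region(top, ["LYS:539"], radius=6.0, name="cav")
        v = extract_visits(traj, top, region, ["Cl-"], 0, 1)
        ent = count_entries(v, traj.n_frames)
        assert ent.iloc[0]["n_entries"] == 0

    def test_empty_region_zero_entries(self):
        top, traj = pattern_system([np.zeros(10)])
        region = make_region(top, ["LYS:539"], radius=6.0, name="cav")
        v = extract_visits(traj, top, region, ["Cl-"], 0, 1)
        assert v.empty
        assert count_entries(v, traj.n_frames).empty

    def test_join_without_exchange(self):
        # B joins while A stays: entries yes, exchange no
        top, traj = pattern_system([
            [0, 1, 1, 1, 1, 0],
            [0, 0, 1, 1, 1, 0],
        ])
        region = make_region(top, ["LYS:539"], radius=6.0, name="cav")
        v = extract_visits(traj, top, region, ["Cl-"], 0, 1)
        ent = count_entries(v, traj.n_frames)
        assert ent.iloc[0]["n_entries"] == 2
        assert ent.iloc[0]["n_exchanges"] == 0

    def test_entries_exits_differ_by_at_most_one_per_ion(self, rng):
        patterns = rng.integers(0, 2, size=(4, 60))
        top, traj = pattern_system(list(patterns))
        region = make_region(top, ["LYS:539"], radius=6.0, name="cav")
        v = extract_visits(traj, top, region, ["Cl-"], 0, 1)
        for ion, grp in v.groupby("ion"):
            entries = int((~grp["censored_start"]).sum())
            exits = int((~grp["censored_end"]).sum())
            assert abs(entries - exits) <= 1


class TestMembershipSeries:
    def test_matches_patterns(self, rng):
        patterns = rng.integers(0, 2, size=(3, 25))
        top, traj = pattern_system(list(patterns))
        region = make_region(top, ["LYS:539"], radius=6.0)
        for i in range(3):
            got = membership_series(traj, region, 1 + i)
            assert np.array_equal(got, patterns[i].astype(bool))
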