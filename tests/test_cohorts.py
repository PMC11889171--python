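"""Depth/backside binning, matched controls, threshold sets."""

import numpy as np
import pandas as pd
import pytest

from fibdamage.cohorts import (
    CohortAssignment,
    assign_backside_bins,
    assign_depth_bins,
    backside_particle_distance,
    draw_matched_control,
    split_threshold_sets,
)


def frame(ids, tomos, depths):
    return pd.DataFrame(
        {"particle_id": ids, "tomogram_id": tomos, "depth_nm": depths, "inside": True}
    )


class TestDepthBins:
    def test_half_open_binning(self):
        df = frame(["a", "b", "c"], ["t"] * 3, [7.3, 60.0, 59.999])
        bins = assign_depth_bins(df)
        by_label = {c.label: set(c.member_ids) for c in bins}
        assert "a" in by_label["depth_05_10"]
        assert "c" in by_label["depth_55_60"]
        assert all("b" not in m for m in by_label.values())  # 60 is out (half-open)

    def test_counts_match_binomial_expectation(self):
        rng = np.random.default_rng(0)
        n = 10000
        # uniform through a 200-nm slab: depth to the nearer of two surfaces
        z = rng.uniform(0, 200, n)
        depth = np.minimum(z, 200 - z)
        df = frame([f"p{i}" for i in range(n)], ["t"] * n, depth)
        bins = assign_depth_bins(df)
        p = 2 * 5 / 200
        expect = n * p
        sd = np.sqrt(n * p * (1 - p))
        for c in bins:
            assert abs(len(c) - expect) < 4 * sd

    def test_empty_bins_raise(self):
        df = frame(["a"], ["t"], [500.0])
        with pytest.raises(ValueError, match="no particle"):
            assign_depth_bins(df)

    def test_partition_property(self, depth_frame):
        bins = assign_depth_bins(depth_frame)
        all_ids = [i for c in bins for i in c.member_ids]
        assert len(all_ids) == len(set(all_ids))  # disjoint
        binned = set(all_ids)
        excluded = set(depth_frame["particle_id"]) - binned
        assert {i for i in depth_frame[depth_frame["depth_nm"] >= 60]["particle_id"]} <= excluded


class TestBacksideDistance:
    def test_offset_rule(self):
        assert backside_particle_distance(2.0, 0.5) == pytest.approx(2.5)
        assert backside_particle_distance(1.0, 0.0) == pytest.approx(1.0)

    def test_negative_flagged(self):
        assert np.isnan(backside_particle_distance(1.0, -1.2))

    def test_negative_acquisition_rejected(self):
        with pytest.raises(ValueError):
            backside_particle_distance(-0.1, 0.0)

    def test_binning(self):
        df = pd.DataFrame(
            {
                "particle_id": ["a", "b"],
                "tomogram_id": ["t", "t"],
                "backside_um": [2.5, 0.2],
            }
        )
        bins = assign_backside_bins(df)
        by_label = {c.label: set(c.member_ids) for c in bins}
        assert "a" in by_label["backside_2_3um"]
        assert "b" in by_label["backside_0_1um"]


class TestMatchedControl:
    def test_short_pool_downsamples_group(self):
        # group {T1:3, T2:2}, deep pool {T1:5, T2:1} -> control & group {T1:3, T2:1}
        rows = []
        for i in range(3):
            rows.append((f"g1{i}", "T1", 10.0))
        for i in range(2):
            rows.append((f"g2{i}", "T2", 10.0))
        for i in range(5):
            rows.append((f"d1{i}", "T1", 80.0))
        rows.append(("d20", "T2", 80.0))
        df = frame(*map(list, zip(*rows)))
        group = CohortAssignment(
            "depth_05_10",
            np.array([f"g1{i}" for i in range(3)] + [f"g2{i}" for i in range(2)]),
            {"T1": 3, "T2": 2},
            bin_edges=(5.0, 10.0),
        )
        control, eq = draw_matched_control(group, df, seed=1)
        assert control.per_tomogram == {"T1": 3, "T2": 1}
        assert eq.per_tomogram == {"T1": 3, "T2": 1}
        assert len(control.member_ids) == len(eq.member_ids) == 4

    def test_same_seed_reproduces_members(self, depth_frame):
        bins = assign_depth_bins(depth_frame)
        group = bins[2]
        c1, g1 = draw_matched_control(group, depth_frame, seed=9)
        c2, g2 = draw_matched_control(group, depth_frame, seed=9)
        assert set(c1.member_ids) == set(c2.member_ids)
        assert set(g1.member_ids) == set(g2.member_ids)
        c3, _ = draw_matched_control(group, depth_frame, seed=10)
        assert set(c1.member_ids) != set(c3.member_ids)

    def test_guarantees_over_seeds(self, depth_frame):
        bins = assign_depth_bins(depth_frame)
        group = bins[4]
        depths = depth_frame.set_index("particle_id")["depth_nm"]
        for seed in range(5):
            control, eq = draw_matched_control(group, depth_frame, seed=seed)
            assert control.per_tomogram == eq.per_tomogram
            assert (depths.loc[control.member_ids] > control.eligibility_floor_nm).all()

    def test_tomogram_without_pool_drops_group(self):
        df = frame(["g0", "g1"], ["T1", "T2"], [10.0, 12.0])
        df = pd.concat(
            [df, frame(["d0"], ["T1"], [90.0])], ignore_index=True
        )
        group = CohortAssignment(
            "depth_10_15", np.array(["g0", "g1"]), {"T1": 1, "T2": 1}, bin_edges=(10.0, 15.0)
        )
        control, eq = draw_matched_control(group, df, seed=0)
        assert control.per_tomogram == {"T1": 1}
        assert "T2" in control.dropped_tomograms
        assert eq.per_tomogram == {"T1": 1}


class TestThresholdSets:
    def test_exact_sizes_and_disjoint_strata(self, depth_frame):
        sets = split_threshold_sets(depth_frame, threshold_nm=30, n=500, seed=0)
        assert {len(s) for s in sets.values()} == {500}
        depths = depth_frame.set_index("particle_id")["depth_nm"]
        assert (depths.loc[sets["lt_threshold"].member_ids] < 30).all()
        assert (depths.loc[sets["gt_threshold"].member_ids] >= 30).all()

    def test_insufficient_stratum_reports_count(self, depth_frame):
        with pytest.raises(ValueError, match=r"\d+ particles"):
            split_threshold_sets(depth_frame, n=10**6)

    def test_seed_determinism(self, depth_frame):
        a = split_threshold_sets(depth_frame, n=300, seed=5)
        b = split_threshold_sets(depth_frame, n=300, seed=5)
        c = split_threshold_sets(depth_frame, n=300, seed=6)
        for k in a:
            assert set(a[k].member_ids) == set(b[k].member_ids)
        assert set(a["all"].member_ids) != set(c["all"].member_ids)
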