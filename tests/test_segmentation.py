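"""Moving-window segmentation: window alignment, the state-cutting rules,
directional classification and per-segment statistics."""
import numpy as np
import pytest

from hurstnet import fbm, segmentation
from hurstnet.errors import ParameterError
from hurstnet.segmentation import (
    ANTI_PERSISTENT,
    PERSISTENT,
    UNCLASSIFIED,
    CellGeometry,
    HurstSeries,
    Segment,
)
from hurstnet.trajectory import Trajectory


def hs_from(values, window=15, dt=1.0):
    values = np.asarray(values, dtype=float)
    half = (window - 1) // 2
    centers = np.arange(values.size) + half
    return HurstSeries(window, centers, values, dt=dt)


class TestWindowedHurst:
    def test_single_window_track(self, model_n15):
        traj = fbm.simulate_fbm(fbm.FbmParams(0.5, 15, seed=0))
        hs = segmentation.windowed_hurst(model_n15, traj, 15)
        assert hs.h_values.shape == (1,)
        assert hs.center_indices[0] == 7

    def test_alignment_and_length(self, model_n15):
        traj = fbm.simulate_fbm(fbm.FbmParams(0.5, 60, seed=1))
        hs = segmentation.windowed_hurst(model_n15, traj, 15)
        assert hs.h_values.size == 60 - 15 + 1
        assert hs.center_indices[0] == 7 and hs.center_indices[-1] == 52

    def test_window_validation(self, model_n15):
        traj = fbm.simulate_fbm(fbm.FbmParams(0.5, 60, seed=2))
        with pytest.raises(ParameterError):
            segmentation.windowed_hurst(model_n15, traj, 14)
        with pytest.raises(ParameterError):
            segmentation.windowed_hurst(model_n15, traj, 61)
        with pytest.raises(ParameterError):
            segmentation.windowed_hurst(model_n15, traj, 17)

    def test_recovers_constant_h(self, model_n15):
        """Mean local estimate tracks the true H; at 15-point windows the
        estimator carries a regression-to-the-prior bias of ~0.1 toward
        0.5 at the edges of the H range, so the persistent-side check uses
        a bound just outside it and the classification margin."""
        means = []
        for i in range(30):
            traj = fbm.simulate_fbm(fbm.FbmParams(0.8, 200, seed=100 + i))
            hs = segmentation.windowed_hurst(model_n15, traj, 15)
            means.append(np.nanmean(hs.h_values))
        assert abs(np.mean(means) - 0.8) < 0.12
        assert np.mean(means) > 0.55  # classified persistent on average


class TestSegmentStates:
    def test_all_persistent(self):
        segs = segmentation.segment_states(hs_from([0.8] * 40))
        assert [s.state for s in segs] == [PERSISTENT]
        assert segs[0].mean_h == pytest.approx(0.8)

    def test_three_block_example(self):
        h = [0.3] * 20 + [0.5] * 20 + [0.9] * 20
        segs = segmentation.segment_states(hs_from(h), min_len=15)
        assert [s.state for s in segs] == [ANTI_PERSISTENT, UNCLASSIFIED, PERSISTENT]

    def test_neutral_series_has_no_classified_segment(self):
        segs = segmentation.segment_states(hs_from([0.5] * 40))
        assert {s.state for s in segs} == {UNCLASSIFIED}

    def test_short_runs_demoted(self):
        h = [0.8] * 10 + [0.5] * 30
        segs = segmentation.segment_states(hs_from(h), min_len=15)
        assert {s.state for s in segs} == {UNCLASSIFIED}

    def test_bridging_merges_same_state_across_short_gap(self):
        h = [0.8] * 30 + [0.5] * 5 + [0.8] * 30
        plain = segmentation.segment_states(hs_from(h), min_len=15)
        assert [s.state for s in plain] == [PERSISTENT, UNCLASSIFIED, PERSISTENT]
        bridged = segmentation.segment_states(hs_from(h), min_len=15, bridge_gaps=True)
        assert [s.state for s in bridged] == [PERSISTENT]
        assert bridged[0].end_index - bridged[0].start_index == 64

    def test_bridging_never_joins_opposite_states(self):
        h = [0.8] * 30 + [0.5] * 5 + [0.2] * 30
        bridged = segmentation.segment_states(hs_from(h), min_len=15, bridge_gaps=True)
        assert [s.state for s in bridged] == [PERSISTENT, UNCLASSIFIED, ANTI_PERSISTENT]

    def test_every_slot_in_exactly_one_segment(self):
        rng = np.random.default_rng(4)
        h = rng.uniform(0, 1, 300)
        segs = segmentation.segment_states(hs_from(h), min_len=15)
        covered = np.concatenate(
            [np.arange(s.start_index, s.end_index + 1) for s in segs]
        )
        half = 7
        np.testing.assert_array_equal(np.sort(covered), np.arange(300) + half)

    def test_bad_bounds(self):
        with pytest.raises(ParameterError):
            segmentation.segment_states(hs_from([0.5] * 30), lower=0.6, upper=0.4)


def radial_track(direction, n=60, step=0.05):
    """2D track moving radially (direction=+1 outward, -1 inward)."""
    r0 = 5.0 if direction < 0 else 1.0
    r = r0 + direction * step * np.arange(n)
    xy = np.column_stack([r, np.zeros(n)])
    return Trajectory("r", 0.02, xy)


def persistent_cover(traj, window=15):
    n_win = traj.n_points - window + 1
    return segmentation.segment_states(
        hs_from([0.9] * n_win, window=window, dt=traj.dt), traj=traj
    )


class TestDirection:
    def test_outward_is_anterograde(self):
        traj = radial_track(+1)
        segs = persistent_cover(traj)
        out = segmentation.classify_direction(traj, segs, CellGeometry((0.0, 0.0)))
        directed = [s for s in out if s.direction is not None]
        assert len(directed) == 1 and directed[0].direction == "anterograde"

    def test_inward_is_retrograde(self):
        traj = radial_track(-1)
        segs = persistent_cover(traj)
        out = segmentation.classify_direction(traj, segs, CellGeometry((0.0, 0.0)))
        directed = [s for s in out if s.direction is not None]
        assert len(directed) == 1 and directed[0].direction == "retrograde"

    def test_circular_arc_unlabeled(self):
        theta = np.linspace(0, 1.5 * np.pi, 80)
        xy = np.column_stack([3 * np.cos(theta), 3 * np.sin(theta)])
        traj = Trajectory("c", 0.02, xy)
        segs = persistent_cover(traj)
        out = segmentation.classify_direction(traj, segs, CellGeometry((0.0, 0.0)))
        assert all(s.direction is None for s in out)

    def test_rotation_invariance(self):
        rng = np.random.default_rng(5)
        xy = np.cumsum(rng.standard_normal((100, 2)), axis=0) + [4.0, 4.0]
        traj = Trajectory("w", 0.02, xy)
        segs = persistent_cover(traj)
        geom = CellGeometry((0.0, 0.0))
        base = segmentation.classify_direction(traj, segs, geom)
        ang = 1.1
        rot = np.array([[np.cos(ang), -np.sin(ang)], [np.sin(ang), np.cos(ang)]])
        traj_r = Trajectory("w", 0.02, xy @ rot.T)
        segs_r = persistent_cover(traj_r)
        rotated = segmentation.classify_direction(traj_r, segs_r, geom)
        assert [s.direction for s in base] == [s.direction for s in rotated]
        assert [(s.start_index, s.end_index) for s in base] == [
            (s.start_index, s.end_index) for s in rotated
        ]


class TestFilters:
    @staticmethod
    def seg(state, lo, hi):
        return Segment(state, lo, hi, float(hi - lo), 0.1, 0.1, 0.8)

    def make(self, positions, states):
        traj = Trajectory("f", 0.02, np.asarray(positions, dtype=float))
        segs = [self.seg(s, 20 * i, 20 * i + 19) for i, s in enumerate(states)]
        return traj, segs

    def test_stationary_track_removed(self):
        xy = np.tile([1.0, 1.0], (100, 1)) + 1e-4
        traj = Trajectory("s", 0.02, xy)
        kept = segmentation.filter_tracks_for_direction([(traj, [])])
        assert kept == []

    def test_single_switch_removed_and_alternating_kept(self):
        xy = np.column_stack([np.linspace(0, 3, 100), np.zeros(100)])
        one_switch = self.make(xy, [PERSISTENT, ANTI_PERSISTENT])
        alternating = self.make(
            xy, [PERSISTENT, ANTI_PERSISTENT, PERSISTENT, ANTI_PERSISTENT, PERSISTENT]
        )
        kept = segmentation.filter_tracks_for_direction([one_switch, alternating])
        assert len(kept) == 1 and kept[0][0] is alternating[0]

    def test_switch_count_ignores_unclassified(self):
        segs = [
            self.seg(PERSISTENT, 0, 19),
            self.seg(UNCLASSIFIED, 20, 39),
            self.seg(ANTI_PERSISTENT, 40, 59),
            self.seg(PERSISTENT, 60, 79),
        ]
        assert segmentation.count_switches(segs) == 2


class TestSegmentStats:
    def test_straight_segment_arithmetic(self):
        # 10 points, dt = 0.02 s, step 0.05 um: 0.45 um, 0.18 s, 2.5 um/s
        xy = np.column_stack([0.05 * np.arange(10), np.zeros(10)])
        traj = Trajectory("a", 0.02, xy)
        seg = Segment(PERSISTENT, 0, 9, 0.18, 0.45, 2.5, 0.8)
        table = segmentation.segment_stats([seg], traj)
        row = table.iloc[0]
        assert row["displacement_um"] == pytest.approx(0.45)
        assert row["duration_s"] == pytest.approx(0.18)
        assert row["mean_speed_um_s"] == pytest.approx(2.5)

    def test_closed_loop_zero_displacement(self):
        theta = np.linspace(0, 2 * np.pi, 21)
        xy = np.column_stack([np.cos(theta), np.sin(theta)])
        traj = Trajectory("loop", 0.1, xy)
        seg = Segment(PERSISTENT, 0, 20, 2.0, 0.0, 0.0, 0.8)
        row = segmentation.segment_stats([seg], traj).iloc[0]
        assert row["displacement_um"] == pytest.approx(0.0, abs=1e-12)
        assert row["mean_speed_um_s"] == pytest.approx(0.0, abs=1e-12)

    def test_duration_additivity(self):
        rng = np.random.default_rng(6)
        xy = np.cumsum(rng.standard_normal((61, 2)), axis=0)
        traj = Trajectory("b", 0.5, xy)
        s1 = Segment(PERSISTENT, 0, 30, 15.0, 0, 0, 0.8)
        s2 = Segment(PERSISTENT, 30, 60, 15.0, 0, 0, 0.8)
        whole = Segment(PERSISTENT, 0, 60, 30.0, 0, 0, 0.8)
        t = segmentation.segment_stats([s1, s2, whole], traj)
        assert t["duration_s"][0] + t["duration_s"][1] == pytest.approx(t["duration_s"][2])

    def test_zero_duration_rejected(self):
        traj = Trajectory("c", 0.1, np.zeros((10, 2)) + np.arange(10)[:, None])
        seg = Segment(PERSISTENT, 3, 3, 0.0, 0.0, 0.0, 0.8)
        with pytest.raises(ParameterError):
            segmentation.segment_stats([seg], traj)
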