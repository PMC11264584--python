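"""Kinematic post-processing: cleaning, state inference, occupancy."""

import numpy as np
import pandas as pd
import pytest

from socialoperant.intervals import IntervalSet
from socialoperant.kinematics import (
    AlignmentError,
    SessionStartNotFound,
    align_to_fr_bins,
    clean_track,
    detect_session_start,
    infer_door_intervals,
    locomotion_path_length,
    nose_zone_intervals,
    occupancy_summary,
    reward_ordinal_contrast,
)
from socialoperant.simulate import (
    PoseNoiseConfig,
    TrueSubjectParams,
    simulate_pose_track,
    simulate_session,
)

from helpers import make_track, point_in_polygon, short_single_program


def const(n, v):
    return np.full(n, float(v))


class TestCleanTrack:
    def test_all_valid_is_identity(self):
        track = make_track({"nose": (np.arange(10.0), const(10, 5), const(10, 1.0))})
        out = clean_track(track)
        pd.testing.assert_frame_equal(out.df, track.df)
        assert not out.interpolated["nose"].any()

    def test_interior_gap_linear_midpoint(self):
        x = np.array([0, 0, 2.0])
        y = np.array([0, 0, 2.0])
        lk = np.array([1.0, 0.3, 1.0])
        out = clean_track(make_track({"nose": (x, y, lk)}))
        assert out.part("nose")["x"].iloc[1] == pytest.approx(1.0)
        assert out.part("nose")["y"].iloc[1] == pytest.approx(1.0)
        assert out.interpolated["nose"][1]

    def test_leading_trailing_held_not_extrapolated(self):
        x = np.array([9.0, 1.0, 2.0, 9.0])
        lk = np.array([0.1, 1.0, 1.0, 0.2])
        out = clean_track(make_track({"nose": (x, x.copy(), lk)}))
        assert out.part("nose")["x"].iloc[0] == pytest.approx(1.0)
        assert out.part("nose")["x"].iloc[-1] == pytest.approx(2.0)

    def test_idempotent(self, rng):
        n = 500
        x = rng.uniform(0, 900, n)
        lk = rng.uniform(0, 1, n)
        track = make_track({"nose": (x, x.copy(), lk)})
        once = clean_track(track)
        twice = clean_track(once)
        pd.testing.assert_frame_equal(once.df, twice.df)

    def test_dead_part_marked_unusable(self):
        track = make_track({"nose": (const(5, 1), const(5, 1), const(5, 0.1))})
        out = clean_track(track)
        assert "nose" in out.unusable_parts
        with pytest.raises(ValueError, match="unusable"):
            locomotion_path_length(out, part="nose")


class TestSessionStart:
    def make_lever_track(self, high_from, n=400, blip=None):
        lk_a = np.where(np.arange(n) >= high_from, 0.95, 0.3)
        lk_i = lk_a.copy()
        if blip:
            lk_a[blip[0] : blip[1]] = 0.95
            lk_i[blip[0] : blip[1]] = 0.95
        xy = const(n, 100)
        return make_track(
            {"lever_active": (xy, xy, lk_a), "lever_inactive": (xy, xy, lk_i)}
        )

    def test_first_qualifying_span(self):
        frame, t = detect_session_start(self.make_lever_track(150))
        assert frame == 150
        assert t == pytest.approx(10.0)

    def test_sub_second_blip_rejected(self):
        track = self.make_lever_track(300, blip=(100, 110))
        frame, _ = detect_session_start(track)
        assert frame == 300

    def test_never_extended_raises(self):
        track = self.make_lever_track(10**6, n=200)
        with pytest.raises(SessionStartNotFound):
            detect_session_start(track)


class TestDoorInference:
    def make_cue_track(self, lit_spans, n=2000, fps=15.0):
        lk = const(n, 0.2)
        for s, e in lit_spans:
            lk[s:e] = 0.95
        xy = const(n, 50)
        return make_track({"cue_active": (xy, xy, lk)}, fps=fps)

    def test_onsets_and_fixed_duration(self):
        track = self.make_cue_track([(150, 600), (900, 1350)])
        iv = infer_door_intervals(track, reward_duration_s=30.0)
        assert len(iv) == 2
        assert iv.starts[0] == pytest.approx(10.0)
        assert iv.ends[0] == pytest.approx(40.0)

    def test_sub_second_blips_only_give_empty_set(self):
        track = self.make_cue_track([(100, 110), (500, 514)])
        assert len(infer_door_intervals(track, 30.0)) == 0

    def test_refractory_suppression_within_open_period(self):
        # a second qualifying span inside the open period is the same
        # door event, not a new reward
        track = self.make_cue_track([(150, 300), (330, 480)])
        iv = infer_door_intervals(track, reward_duration_s=60.0)
        assert len(iv) == 1

    def test_no_cue_gives_empty(self):
        track = self.make_cue_track([])
        iv = infer_door_intervals(track, 30.0)
        assert iv.total == 0.0


class TestNoseZone:
    def test_nose_at_centroid_spans_session(self, landmarks):
        c = landmarks.door_polygon.centroid
        n = 300
        track = make_track({"nose": (const(n, c.x), const(n, c.y), const(n, 1.0))})
        iv = nose_zone_intervals(track, landmarks)
        assert len(iv) == 1
        assert iv.total == pytest.approx(n / 15.0)

    def test_nose_at_opposite_wall_empty(self, landmarks):
        n = 300
        track = make_track({"nose": (const(n, 120), const(n, 300), const(n, 1.0))})
        assert nose_zone_intervals(track, landmarks).total == 0.0

    def test_margin_dilation_admits_nearby_points(self, landmarks):
        x0, y0 = landmarks.door_corners[0]
        n = 10
        track = make_track(
            {"nose": (const(n, x0 - 3), const(n, y0 + 45), const(n, 1.0))}
        )
        assert nose_zone_intervals(track, landmarks).total == 0.0
        assert nose_zone_intervals(track, landmarks, margin_px=5.0).total > 0.0

    def test_matches_brute_force_point_in_polygon(self, landmarks, rng):
        # independent ray-casting oracle, frame by frame
        for _ in range(20):
            n = 1500
            x = rng.uniform(700, 928, n)
            y = rng.uniform(150, 450, n)
            track = make_track({"nose": (x, y, const(n, 1.0))})
            iv = nose_zone_intervals(track, landmarks)
            oracle = sum(
                point_in_polygon(xi, yi, landmarks.door_corners)
                for xi, yi in zip(x, y)
            )
            assert round(iv.total * 15.0) == oracle


class TestOccupancy:
    def test_full_occupancy_proportion_one(self):
        door = IntervalSet([(10, 40), (60, 90)])
        summ = occupancy_summary(door, door, (0, 100))
        assert summ["prop_open_door_nose"] == pytest.approx(1.0)

    def test_zero_rewards_reported_missing(self):
        nose = IntervalSet([(5, 10)])
        summ = occupancy_summary(nose, IntervalSet(), (0, 100))
        assert summ["prop_open_door_nose"] is None
        assert summ["time_nose_open_door_s"] == 0.0
        assert "zero rewards" in summ["missing_reason"]
        assert summ["prop_closed_door_nose"] == pytest.approx(0.05)

    def test_open_closed_partition_identity(self, rng):
        for _ in range(20):
            nose = IntervalSet(
                (s, s + d)
                for s, d in zip(rng.uniform(0, 90, 6), rng.uniform(0.5, 8, 6))
            )
            door = IntervalSet(
                (s, s + d)
                for s, d in zip(rng.uniform(0, 90, 4), rng.uniform(1, 10, 4))
            )
            span = (0.0, 100.0)
            summ = occupancy_summary(nose, door, span)
            total = summ["time_nose_open_door_s"] + summ["time_nose_closed_door_s"]
            assert total == pytest.approx(nose.clip(span).total, abs=1e-9)
            for key in ("prop_open_door_nose", "prop_closed_door_nose"):
                if summ[key] is not None:
                    assert 0.0 <= summ[key] <= 1.0


class TestLocomotion:
    def test_stationary_part_zero(self):
        track = make_track({"body_centre": (const(50, 7), const(50, 9), const(50, 1))})
        assert locomotion_path_length(track)["path_length_px"] == 0.0

    def test_constant_velocity(self):
        x = np.arange(101.0) * 2.0
        track = make_track({"body_centre": (x, const(101, 5), const(101, 1))})
        out = locomotion_path_length(track, jitter_floor_px=0.5)
        assert out["path_length_px"] == pytest.approx(200.0)

    def test_jitter_floor_suppresses_micro_motion(self):
        x = np.cumsum(const(100, 0.2))
        track = make_track({"body_centre": (x, const(100, 5), const(100, 1))})
        assert locomotion_path_length(track, jitter_floor_px=0.5)[
            "path_length_px"
        ] == 0.0


class TestOrdinalContrast:
    def test_uniform_behaviour_equal_proportions(self):
        door = IntervalSet([(i * 50.0, i * 50.0 + 10.0) for i in range(8)])
        nose = IntervalSet([(i * 50.0, i * 50.0 + 5.0) for i in range(8)])
        out = reward_ordinal_contrast(nose, door)
        assert out["prop_first"] == pytest.approx(out["prop_last"])

    def test_insufficient_rewards_missing(self):
        door = IntervalSet([(i * 50.0, i * 50.0 + 10.0) for i in range(5)])
        out = reward_ordinal_contrast(IntervalSet(), door, 3, 3)
        assert out["prop_first"] is None
        assert "only 5 rewards" in out["missing_reason"]

    def test_satiety_decay_detected_in_most_replicates(
        self, baseline_params, landmarks
    ):
        # Monte-Carlo oracle: nose engagement decays within session, so
        # the first-3 proportion should beat the last-3 almost always
        prog = short_single_program(1, operant_s=420.0, pre_s=30.0)
        noise = PoseNoiseConfig(
            dropout_rate=0.0, nose_engage_prob=0.95, engage_decay_halflife_s=120.0
        )
        wins = trials = 0
        for seed in range(40):
            sim = simulate_session(baseline_params, prog, seed=seed)
            if sim.truth.rewards < 6:
                continue
            track, truth = simulate_pose_track(sim.log, landmarks, noise, seed=seed)
            door = IntervalSet(
                (o, o + 30.0) for o in truth.door_onsets_s
            )
            out = reward_ordinal_contrast(truth.nose_in_door, door)
            trials += 1
            wins += out["prop_first"] > out["prop_last"]
        assert trials >= 30
        assert wins / trials >= 0.9


class TestAlignment:
    def run_session(self, seed, offset):
        params = TrueSubjectParams("s0", 20.0, 3e-3)
        prog = short_single_program(1, operant_s=420.0, pre_s=30.0)
        sim = simulate_session(params, prog, seed=seed)
        noise = PoseNoiseConfig(dropout_rate=0.0, video_offset_s=offset)
        from socialoperant.chamber import default_landmarks

        track, truth = simulate_pose_track(sim.log, default_landmarks(), noise, seed)
        return sim, track, truth

    def test_injected_clock_shift_recovered(self):
        sim, track, truth = self.run_session(seed=11, offset=30.0)
        door = infer_door_intervals(track, 30.0)
        nose = truth.nose_in_door
        out = align_to_fr_bins(track, sim.log, nose, door)
        assert out.attrs["clock_shift_s"] == pytest.approx(30.0, abs=1 / 15)
        assert len(out) == 1  # unbinned log: whole-session summary
        assert out.loc[0, "rewards_inferred"] == sim.truth.rewards

    def test_gross_clock_disagreement_raises(self):
        sim, track, truth = self.run_session(seed=12, offset=0.0)
        door = infer_door_intervals(track, 30.0).shift(90.0)
        with pytest.raises(AlignmentError):
            align_to_fr_bins(track, sim.log, truth.nose_in_door, door)

    def test_binned_session_per_bin_rewards_match_log(self, landmarks):
        from socialoperant.programs import PHASE3

        params = TrueSubjectParams("s0", 7.0, 3e-3)
        sim = simulate_session(params, PHASE3, seed=13)
        noise = PoseNoiseConfig(dropout_rate=0.0, video_offset_s=12.0)
        track, truth = simulate_pose_track(sim.log, landmarks, noise, seed=13)
        door = infer_door_intervals(track, 30.0)
        out = align_to_fr_bins(track, sim.log, truth.nose_in_door, door)
        assert list(out["fr"]) == [1, 2, 4, 6, 9, 12]
        logged = dict(sim.truth.bin_rewards)
        for row in out.itertuples(index=False):
            assert row.rewards_inferred == logged[row.fr]
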