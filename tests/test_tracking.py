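"""Federated tracker: association, lifetimes, spawning, coasting."""

import itertools

import numpy as np
import pytest

from surgitrack.frame_io import Frame
from surgitrack.kalman import constant_velocity_state
from surgitrack.regions import Detection
from surgitrack.tracking import (
    FederatedTracker,
    Track,
    TrackerParams,
    associate_labels,
    track_sequence,
    update_lifetime,
)


def make_track(label, x, y):
    state = constant_velocity_state(x, y)
    return Track(
        label=label, kind="instrument", local_seg=state,
        local_tmpl=constant_velocity_state(x, y),
        master_x=state.x.copy(), master_P=state.P.copy(), lifetime=100.0,
        template_buffer=None, last_seg_frame=0, last_tmpl_frame=0,
        prev_position=(x, y), last_area=100, spawn_frame=0,
    )


def det(x, y, area=300, frame=1):
    return Detection(kind="instrument", centroid=(x, y), area_px=area,
                     frame_index=frame)


class TestAssociation:
    def test_track_takes_nearest_detection_and_far_one_stays_unassigned(self):
        tracks = [make_track(1, 100, 100)]
        dets = [det(102, 101), det(300, 300)]
        assigned, unassigned = associate_labels(tracks, dets, gate_radius=64)
        assert assigned == {0: 0}
        assert unassigned == [1]

    def test_assignment_invariant_to_detection_order(self):
        tracks = [make_track(1, 50, 50), make_track(2, 200, 60)]
        d1, d2 = det(53, 51), det(196, 62)
        a_fwd, _ = associate_labels(tracks, [d1, d2])
        a_rev, _ = associate_labels(tracks, [d2, d1])
        assert {tracks[t].label: [d1, d2][d].centroid for t, d in a_fwd.items()} == {
            tracks[t].label: [d2, d1][d].centroid for t, d in a_rev.items()
        }

    def test_greedy_matches_exhaustive_optimum_for_separated_clusters(self):
        rng = np.random.default_rng(0)
        positions = [(50.0, 50.0), (200.0, 50.0), (125.0, 200.0)]
        for _ in range(20):
            tracks = [make_track(i + 1, x, y) for i, (x, y) in enumerate(positions)]
            dets = [
                det(x + rng.uniform(-5, 5), y + rng.uniform(-5, 5))
                for x, y in positions
            ]
            assigned, _ = associate_labels(tracks, dets)
            # brute-force optimal assignment over all 3! permutations
            best = min(
                itertools.permutations(range(3)),
                key=lambda perm: sum(
                    np.hypot(dets[perm[i]].centroid[0] - positions[i][0],
                             dets[perm[i]].centroid[1] - positions[i][1])
                    for i in range(3)
                ),
            )
            assert assigned == {i: best[i] for i in range(3)}


class TestLifetime:
    def test_four_recognitions_from_spawn_reach_full_lifetime(self):
        tr = make_track(1, 0, 0)
        tr.lifetime = 20.0
        for _ in range(4):
            update_lifetime(tr, True)
        assert tr.lifetime == 100.0
        update_lifetime(tr, True)
        assert tr.lifetime == 100.0  # capped

    def test_five_misses_from_full_lifetime_reach_zero(self):
        tr = make_track(1, 0, 0)
        for _ in range(5):
            update_lifetime(tr, False)
        assert tr.lifetime == 0.0

    def test_alternating_hit_miss_is_stationary(self):
        tr = make_track(1, 0, 0)
        tr.lifetime = 60.0
        for _ in range(10):
            update_lifetime(tr, True)
            update_lifetime(tr, False)
        assert tr.lifetime == 60.0

    def test_track_without_template_dies_after_one_miss_at_spawn_lifetime(self):
        tracker = FederatedTracker("hemorrhage", TrackerParams(lifetime_decay=20.0))
        frame = Frame(index=0, time_s=0.0,
                      pixels=np.zeros((48, 64, 3), dtype=np.uint8))
        tracker.step(frame, [det(30, 20, frame=0)])
        assert len(tracker.tracks) == 1
        frame1 = Frame(index=1, time_s=0.1, pixels=frame.pixels)
        tracker.step(frame1, [])
        assert tracker.tracks == []  # 20 - 20 = 0: "does not exist"


class TestTrackerBehaviour:
    def test_pure_coasting_follows_constant_velocity_during_gap(self):
        params = TrackerParams(lifetime_decay=0.5)  # keep the track alive
        tracker = FederatedTracker("hemorrhage", params)
        px = np.zeros((200, 300, 3), dtype=np.uint8)
        vx, vy = 2.0, 1.0
        truth = lambda i: (50 + vx * i, 40 + vy * i)
        i = 0
        for _ in range(30):  # feed exact measurements: velocity locks in
            x, y = truth(i)
            tracker.step(Frame(index=i, time_s=i / 10, pixels=px),
                         [det(x, y, frame=i)])
            i += 1
        errs = []
        for _ in range(20):  # occlusion: no measurements at all
            x, y = truth(i)
            out = tracker.step(Frame(index=i, time_s=i / 10, pixels=px), [])
            assert len(out) == 1
            errs.append(np.hypot(out[0].centroid[0] - x, out[0].centroid[1] - y))
            i += 1
        assert errs[-1] <= 2.0  # error stays bounded over the whole gap
        assert max(errs) <= 2.0

    def test_new_labels_never_reused_and_spawn_suppressed_near_live_track(self):
        tracker = FederatedTracker("instrument", TrackerParams())
        px = np.zeros((200, 300, 3), dtype=np.uint8)
        out0 = tracker.step(Frame(index=0, time_s=0, pixels=px),
                            [det(50, 50, frame=0), det(200, 100, frame=0)])
        assert sorted(d.label for d in out0) == [1, 2]
        # a fragment near track 1 must not mint label 3
        out1 = tracker.step(
            Frame(index=1, time_s=0.1, pixels=px),
            [det(51, 51, frame=1), det(80, 60, frame=1), det(201, 101, frame=1)],
        )
        assert sorted(d.label for d in out1) == [1, 2]
        # a genuinely new far-away object gets a fresh label
        out2 = tracker.step(
            Frame(index=2, time_s=0.2, pixels=px),
            [det(52, 52, frame=2), det(202, 102, frame=2), det(150, 180, frame=2)],
        )
        assert sorted(d.label for d in out2) == [1, 2, 3]

    def test_three_instrument_preset_keeps_exactly_three_persistent_labels(
        self, run_three_instruments
    ):
        _, frames, _, result = run_three_instruments
        counts = {}
        for h in result.history:
            counts[h["label"]] = counts.get(h["label"], 0) + 1
        persistent = [l for l, c in counts.items() if c >= 0.6 * len(frames)]
        assert len(persistent) == 3

    def test_fused_output_covers_every_frame_through_occlusion(
        self, run_hemorrhage_occlusion
    ):
        _, frames, _, result = run_hemorrhage_occlusion
        assert all(len(dets) >= 1 for dets in result.fused)

    def test_track_sequence_is_deterministic(self):
        from surgitrack.synthetic_scenes import (BloodEvent, SceneSpec,
                                                 linear_path, render_scene)

        spec = SceneSpec(width=96, height=72, n_frames=6, seed=2,
                         blood_events=[BloodEvent(
                             path=linear_path((48, 36), (1, 0)),
                             area=lambda i: 400.0)])
        frames, _ = render_scene(spec)
        r1 = track_sequence(frames, kinds=("hemorrhage",))
        r2 = track_sequence(frames, kinds=("hemorrhage",))
        assert [
            [(d.label, d.centroid) for d in dets] for dets in r1.fused
        ] == [[(d.label, d.centroid) for d in dets] for dets in r2.fused]
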