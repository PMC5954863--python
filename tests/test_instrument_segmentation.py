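"""Instrument segmentation: LAB k-means, motion subtraction, combination."""

import numpy as np
import pytest
from skimage import color

from surgitrack.frame_io import Frame
from surgitrack.instruments import (
    ClusterModel,
    DegenerateClusterError,
    InstrumentParams,
    cluster_lab,
    combine_and_label,
    motion_mask,
    segment_instruments,
    select_instrument_cluster,
)
from surgitrack.regions import BinaryMask


def _frame(pixels, index=0):
    return Frame(index=index, time_s=index / 10.0, pixels=np.asarray(pixels, np.uint8))


class TestClusterLab:
    def test_two_flat_patches_recovered_exactly(self):
        px = np.zeros((10, 10, 3), dtype=np.uint8)
        px[:, :5] = (200, 50, 50)
        px[:, 5:] = (50, 50, 200)
        model = cluster_lab(_frame(px), k=2, seed=0)
        lab = color.rgb2lab(px)
        expected = {tuple(np.round(lab[0, 0], 6)), tuple(np.round(lab[0, 9], 6))}
        got = {tuple(np.round(c, 6)) for c in model.centers}
        assert got == expected
        # assignment splits exactly along the patch boundary
        assert len(np.unique(model.assignment[:, :5])) == 1
        assert len(np.unique(model.assignment[:, 5:])) == 1
        assert model.assignment[0, 0] != model.assignment[0, 9]

    def test_same_seed_gives_identical_model(self):
        rng = np.random.default_rng(0)
        px = rng.integers(0, 256, size=(12, 12, 3), dtype=np.uint8)
        m1 = cluster_lab(_frame(px), k=3, seed=4)
        m2 = cluster_lab(_frame(px), k=3, seed=4)
        np.testing.assert_array_equal(m1.centers, m2.centers)
        np.testing.assert_array_equal(m1.assignment, m2.assignment)

    def test_converged_inertia_beats_1000_random_center_triples(self):
        rng = np.random.default_rng(1)
        px = rng.integers(0, 256, size=(8, 8, 3), dtype=np.uint8)
        model = cluster_lab(_frame(px), k=3, seed=0)
        lab = color.rgb2lab(px).reshape(-1, 3)
        for _ in range(1000):
            centers = lab[rng.choice(len(lab), 3, replace=False)]
            d2 = ((lab[:, None, :] - centers[None]) ** 2).sum(axis=2).min(axis=1)
            assert model.inertia <= d2.sum() + 1e-9

    def test_k_exceeding_distinct_values_is_degenerate(self):
        px = np.full((6, 6, 3), 120, dtype=np.uint8)
        with pytest.raises(DegenerateClusterError):
            cluster_lab(_frame(px), k=2, seed=0)


class TestSelectInstrumentCluster:
    def _model(self, centers):
        centers = np.asarray(centers, dtype=float)
        return ClusterModel(k=len(centers), centers=centers,
                            assignment=np.zeros((2, 2), dtype=int), inertia=0.0)

    def test_minimal_chroma_cluster_selected(self):
        model = self._model([(60, 2, 1), (50, 40, 30)])
        model.assignment = np.array([[0, 1], [1, 0]])
        mask = select_instrument_cluster(model)
        np.testing.assert_array_equal(mask.data, [[True, False], [False, True]])

    def test_chroma_tie_broken_by_higher_luminance(self):
        model = self._model([(40, 3, 4), (70, 4, 3)])  # equal chroma 5
        model.assignment = np.array([[0, 1], [0, 1]])
        mask = select_instrument_cluster(model)
        np.testing.assert_array_equal(mask.data, [[False, True], [False, True]])

    def test_gray_tool_mask_overlaps_truth_on_three_region_frame(self):
        rng = np.random.default_rng(2)
        px = np.full((60, 80, 3), (140, 60, 55), dtype=float)
        px[45:, :] = (30, 15, 15)  # dark region
        tool = np.zeros((60, 80), dtype=bool)
        tool[10:22, 15:65] = True
        px[tool] = (175, 175, 180)
        px += rng.normal(0, 2.0, size=px.shape)
        model = cluster_lab(_frame(np.clip(px, 0, 255)), k=3, seed=0)
        mask = select_instrument_cluster(model).data
        jaccard = (mask & tool).sum() / (mask | tool).sum()
        assert jaccard >= 0.8


class TestMotionMask:
    def test_identical_frames_give_zero_mask(self):
        px = np.random.default_rng(0).integers(0, 256, (10, 10, 3), dtype=np.uint8)
        mask = motion_mask(_frame(px, 1), _frame(px, 0), diff_threshold=20)
        assert not mask.data.any()

    def test_single_changed_pixel_is_the_only_motion(self):
        px = np.full((10, 10, 3), 100, dtype=np.uint8)
        px2 = px.copy()
        px2[4, 7] = 255
        mask = motion_mask(_frame(px2, 1), _frame(px, 0), diff_threshold=20)
        assert mask.data.sum() == 1 and mask.data[4, 7]

    def test_translated_rectangle_matches_footprint_xor_oracle(self):
        a = np.zeros((40, 40, 3), dtype=np.uint8)
        b = np.zeros((40, 40, 3), dtype=np.uint8)
        a[10:20, 5:25] = 180
        b[10:20, 10:30] = 180  # translated 5 px right
        mask = motion_mask(_frame(b, 1), _frame(a, 0), diff_threshold=20)
        fa = np.zeros((40, 40), bool); fa[10:20, 5:25] = True
        fb = np.zeros((40, 40), bool); fb[10:20, 10:30] = True
        np.testing.assert_array_equal(mask.data, fa ^ fb)

    def test_first_frame_yields_all_zero_mask(self):
        px = np.full((8, 8, 3), 50, dtype=np.uint8)
        assert not motion_mask(_frame(px), None).data.any()

    def test_size_mismatch_raises(self):
        with pytest.raises(ValueError):
            motion_mask(_frame(np.zeros((8, 8, 3), np.uint8), 1),
                        _frame(np.zeros((8, 10, 3), np.uint8), 0))


class TestCombineAndLabel:
    def test_static_gray_distractor_excluded_when_gating_on(self):
        cluster = np.zeros((60, 60), dtype=bool)
        cluster[5:25, 5:25] = True  # moving object
        cluster[35:55, 35:55] = True  # static distractor
        motion = np.zeros((60, 60), dtype=bool)
        motion[5:25, 4:7] = True  # motion shell on the first component only
        params = InstrumentParams(min_area=50)
        dets = combine_and_label(BinaryMask(cluster, "instrument"),
                                 BinaryMask(motion, "motion"), params)
        assert len(dets) == 1
        assert dets[0].centroid == pytest.approx((14.5, 14.5), abs=1.5)

    def test_empty_combined_mask_yields_no_detections(self):
        empty = BinaryMask(np.zeros((20, 20), bool), "instrument")
        assert combine_and_label(empty, empty) == []

    def test_moving_gray_rectangle_detected_at_true_centroid(self):
        base = np.full((80, 120, 3), (140, 60, 55), dtype=np.uint8)
        base[70:, :] = (30, 15, 15)  # dark region: three material classes
        f0 = base.copy(); f0[30:50, 20:70] = (175, 175, 180)
        f1 = base.copy(); f1[30:50, 24:74] = (175, 175, 180)
        params = InstrumentParams(min_area=200)
        dets = segment_instruments(_frame(f1, 1), _frame(f0, 0), params)
        assert len(dets) == 1
        assert dets[0].centroid == pytest.approx((48.5, 39.5), abs=2.0)


class TestPipelineConventions:
    def test_instrument_path_consumes_raw_frames_without_equalization(
        self, monkeypatch
    ):
        import surgitrack.hemorrhage as hem

        def _boom(*a, **k):
            raise AssertionError("equalization must not run in the instrument path")

        monkeypatch.setattr(hem, "equalize_rgb", _boom)
        base = np.full((60, 80, 3), (140, 60, 55), dtype=np.uint8)
        base[52:, :] = (30, 15, 15)
        f0 = base.copy(); f0[20:35, 10:50] = (175, 175, 180)
        f1 = base.copy(); f1[20:35, 14:54] = (175, 175, 180)
        dets = segment_instruments(_frame(f1, 1), _frame(f0, 0),
                                   InstrumentParams(min_area=100))
        assert len(dets) == 1

    def test_per_frame_recall_at_least_095_on_unoccluded_preset_frames(
        self, scene_three_instruments
    ):
        _, frames, ann = scene_three_instruments
        truth = {}
        for r in ann:
            truth.setdefault(r.frame_index, []).append(r)
        hits = total = 0
        for f in frames[1:100:7]:  # unoccluded window
            dets = segment_instruments(f, frames[f.index - 1])
            for t in truth[f.index]:
                total += 1
                if any(
                    np.hypot(d.centroid[0] - t.centroid[0],
                             d.centroid[1] - t.centroid[1]) < 640 / 15
                    for d in dets
                ):
                    hits += 1
        assert hits / total >= 0.95
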