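"""Hemorrhage segmentation: equalization, AND-thresholding, refinement."""

import numpy as np
import pytest
from scipy import ndimage
from skimage import morphology

from surgitrack.frame_io import Frame
from surgitrack.hemorrhage import (
    HemorrhageParams,
    equalize_rgb,
    extract_detections,
    mutually_inclusive_threshold,
    refine_mask,
    segment_hemorrhage,
)
from surgitrack.regions import BinaryMask


def _frame(pixels):
    return Frame(index=0, time_s=0.0, pixels=np.asarray(pixels, dtype=np.uint8))


def _rgb(h, w, value):
    return np.full((h, w, 3), value, dtype=np.uint8)


class TestEqualize:
    def test_constant_channel_stays_constant(self):
        eq = equalize_rgb(_frame(_rgb(8, 8, (77, 140, 200))))
        for c, v in enumerate((77, 140, 200)):
            assert (eq.pixels[..., c] == v).all()

    def test_uniform_ramp_maps_to_near_identity(self):
        # a full 0..255 uniform histogram has a linear CDF, so equalization
        # is the identity up to the half-bin offset of the mapping
        ramp = np.tile(np.arange(256, dtype=np.uint8), (8, 1))
        px = np.stack([ramp] * 3, axis=-1)
        eq = equalize_rgb(_frame(px))
        diff = eq.pixels.astype(int) - px.astype(int)
        assert np.abs(diff).max() <= 2

    def test_two_level_channel_keeps_two_levels_with_max_contrast(self):
        px = _rgb(8, 8, (0, 0, 0))
        px[:, 4:] = 255
        eq = equalize_rgb(_frame(px))
        levels = np.unique(eq.pixels[..., 0])
        assert len(levels) == 2
        assert levels[-1] == 255
        # ordering preserved
        assert (eq.pixels[:, :4, 0] < eq.pixels[:, 4:, 0]).all()


class TestMutuallyInclusiveThreshold:
    BOUNDS = dict(r_bounds=(150, 255), g_bounds=(0, 80), b_bounds=(0, 80))

    def test_pixel_satisfying_all_three_channels_is_labelled(self):
        mask = mutually_inclusive_threshold(_frame(_rgb(2, 2, (200, 30, 40))), **self.BOUNDS)
        assert mask.data.all()

    def test_single_channel_failure_unlabels_the_pixel(self):
        mask = mutually_inclusive_threshold(_frame(_rgb(2, 2, (200, 120, 40))), **self.BOUNDS)
        assert not mask.data.any()

    def test_matches_per_pixel_brute_force_on_random_frame(self):
        rng = np.random.default_rng(42)
        px = rng.integers(0, 256, size=(16, 16, 3), dtype=np.uint8)
        mask = mutually_inclusive_threshold(_frame(px), **self.BOUNDS)
        bounds = [self.BOUNDS["r_bounds"], self.BOUNDS["g_bounds"], self.BOUNDS["b_bounds"]]
        for y in range(16):
            for x in range(16):
                expect = all(
                    bounds[c][0] <= px[y, x, c] <= bounds[c][1] for c in range(3)
                )
                assert mask.data[y, x] == expect

    def test_and_mask_is_subset_of_each_channel_mask(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            px = rng.integers(0, 256, size=(20, 20, 3), dtype=np.uint8)
            mask = mutually_inclusive_threshold(_frame(px), **self.BOUNDS)
            for c, (lo, hi) in enumerate(
                (self.BOUNDS["r_bounds"], self.BOUNDS["g_bounds"], self.BOUNDS["b_bounds"])
            ):
                single = (px[..., c] >= lo) & (px[..., c] <= hi)
                assert (mask.data <= single).all()

    def test_inverted_bounds_are_a_config_error(self):
        with pytest.raises(ValueError):
            mutually_inclusive_threshold(_frame(_rgb(2, 2, 0)), r_bounds=(200, 100))


class TestRefineMask:
    def test_solid_blob_on_noiseless_background_retained(self):
        # entropy pruning disabled: a noiseless flat blob carries no local
        # entropy, and this case isolates the morphology/area stages
        px = _rgb(64, 64, (105, 70, 68))
        px[10:40, 10:40] = (150, 20, 25)
        mask = np.zeros((64, 64), dtype=bool)
        mask[10:40, 10:40] = True
        params = HemorrhageParams(entropy_min=0.0, min_area=10)
        out = refine_mask(BinaryMask(mask), _frame(px), params)
        assert (out.data[10:40, 10:40]).all()

    def test_two_pixel_speckle_removed_by_area_filter(self):
        px = _rgb(32, 32, (105, 70, 68))
        mask = np.zeros((32, 32), dtype=bool)
        mask[5, 5:7] = True
        params = HemorrhageParams(entropy_min=0.0, opening_radius=0, min_area=25)
        out = refine_mask(BinaryMask(mask), _frame(px), params)
        assert not out.data.any()

    def test_one_pixel_crack_closed_like_dilation_erosion_oracle(self):
        mask = np.zeros((40, 40), dtype=bool)
        mask[10:30, 10:30] = True
        mask[:, 19] = False  # 1-px crack splitting the square
        px = _rgb(40, 40, (105, 70, 68))
        params = HemorrhageParams(entropy_min=0.0, opening_radius=0,
                                  closing_radius=1, min_area=10)
        out = refine_mask(BinaryMask(mask), _frame(px), params)
        selem = morphology.disk(1).astype(bool)
        oracle = ndimage.binary_erosion(
            ndimage.binary_dilation(mask, structure=selem), structure=selem
        )
        np.testing.assert_array_equal(out.data, oracle)
        assert out.data[15, 19]  # the crack is sealed

    def test_never_adds_pixels_outside_dilation_of_input(self):
        rng = np.random.default_rng(3)
        px = rng.integers(0, 256, size=(48, 48, 3), dtype=np.uint8)
        params = HemorrhageParams(min_area=1)
        selem = morphology.disk(params.closing_radius).astype(bool)
        for _ in range(5):
            mask = rng.random((48, 48)) < 0.2
            out = refine_mask(BinaryMask(mask), _frame(px), params)
            allowed = ndimage.binary_dilation(mask, structure=selem)
            assert not (out.data & ~allowed).any()

    def test_flat_specular_region_pruned_but_textured_blob_kept(self):
        rng = np.random.default_rng(11)
        base = np.full((80, 160, 3), (105, 70, 68), dtype=float)
        base += rng.normal(0, 4.0, size=base.shape)  # sensor noise: entropy > 3 bits
        base[20:50, 20:50] = (150, 20, 25)
        base[20:50, 20:50] += rng.normal(0, 4.0, size=(30, 30, 3))
        base[20:50, 100:130] = 250.0  # saturated flat specular patch
        px = np.clip(base, 0, 255).astype(np.uint8)
        mask = np.zeros((80, 160), dtype=bool)
        mask[20:50, 20:50] = True
        mask[20:50, 100:130] = True
        out = refine_mask(BinaryMask(mask), _frame(px), HemorrhageParams(min_area=50))
        assert out.data[25:45, 25:45].mean() > 0.9  # noisy blob survives
        assert out.data[25:45, 105:125].mean() < 0.1  # flat patch pruned


class TestExtractDetections:
    def test_square_component_centroid_and_area(self):
        mask = np.zeros((30, 40), dtype=bool)
        mask[5:15, 20:30] = True
        dets = extract_detections(BinaryMask(mask), frame_index=7)
        assert len(dets) == 1
        d = dets[0]
        assert d.centroid == (24.5, 9.5)
        assert d.area_px == 100
        assert d.frame_index == 7

    def test_empty_mask_yields_no_detections(self):
        assert extract_detections(BinaryMask(np.zeros((10, 10), bool)), 0) == []

    def test_two_disjoint_blobs_yield_two_detections_with_correct_areas(self):
        mask = np.zeros((40, 40), dtype=bool)
        mask[2:8, 2:10] = True  # 6x8 = 48
        mask[20:30, 20:26] = True  # 10x6 = 60
        dets = extract_detections(BinaryMask(mask), 0)
        assert sorted(d.area_px for d in dets) == [48, 60]


class TestOnSyntheticScene:
    def test_centroid_error_within_5px_on_unoccluded_frames(
        self, scene_hemorrhage_occlusion
    ):
        _, frames, ann = scene_hemorrhage_occlusion
        truth = {r.frame_index: r for r in ann}
        for f in frames[4:96:10]:
            dets = segment_hemorrhage(f)
            assert dets, f"no detection in frame {f.index}"
            t = truth[f.index]
            best = min(
                dets,
                key=lambda d: (d.centroid[0] - t.centroid[0]) ** 2
                + (d.centroid[1] - t.centroid[1]) ** 2,
            )
            err = np.hypot(best.centroid[0] - t.centroid[0],
                           best.centroid[1] - t.centroid[1])
            assert err <= 5.0, f"frame {f.index}: centroid error {err:.2f}"
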