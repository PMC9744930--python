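"""Stimulus disruptions: grayscale, equalization, occlusion, rescaling."""

import numpy as np
import pytest

from facebench import stimuli
from facebench.faces import DEFAULT_CANVAS, default_layout
from facebench.geometry import Rect


class TestGrayscale:
    def test_output_channels_equal_and_idempotent(self, continuum):
        g = stimuli.to_grayscale(continuum.images[0])
        assert g.shape == continuum.images[0].shape
        np.testing.assert_array_equal(g[..., 0], g[..., 1])
        np.testing.assert_array_equal(g[..., 0], g[..., 2])
        np.testing.assert_array_equal(stimuli.to_grayscale(g), g)

    def test_pure_red_maps_to_bt601_red_weight(self):
        img = np.zeros((2, 2, 3))
        img[..., 0] = 1.0
        np.testing.assert_allclose(stimuli.to_grayscale(img)[..., 0], 0.299)

    def test_bad_shape_rejected(self):
        with pytest.raises(ValueError):
            stimuli.to_grayscale(np.zeros((4, 4, 2)))


class TestEqualizeLuminance:
    @staticmethod
    def _ramp(mean, sd, shape=(20, 20)):
        base = np.linspace(-1, 1, shape[0] * shape[1]).reshape(shape)
        base = (base - base.mean()) / base.std()
        return np.clip(mean + sd * base, 0, 1)

    def test_moments_match_across_set(self):
        imgs = [self._ramp(0.4, 0.05), self._ramp(0.55, 0.1), self._ramp(0.5, 0.08)]
        res = stimuli.equalize_luminance(imgs)
        lums = [stimuli.luminance(im) for im in res.images]
        for l in lums:
            assert abs(l.mean() - res.target_mean) < 1e-6
            assert abs(l.std() - res.target_sd) < 1e-6
        assert res.n_clipped == 0

    def test_two_image_means_average(self):
        imgs = [self._ramp(0.3, 0.05), self._ramp(0.5, 0.05)]
        res = stimuli.equalize_luminance(imgs)
        for im in res.images:
            assert abs(stimuli.luminance(im).mean() - 0.4) < 1e-9

    def test_identical_set_is_fixed_point(self):
        im = self._ramp(0.5, 0.1)
        res = stimuli.equalize_luminance([im, im.copy()])
        for out in res.images:
            np.testing.assert_allclose(out, im, atol=1e-12)

    def test_rank_order_preserved(self):
        im1, im2 = self._ramp(0.3, 0.04), self._ramp(0.6, 0.12)
        res = stimuli.equalize_luminance([im1, im2])
        assert (np.argsort(im1.ravel()) == np.argsort(res.images[0].ravel())).all()

    def test_flat_input_flagged_and_set_to_target_mean(self):
        flat = np.full((20, 20), 0.2)
        res = stimuli.equalize_luminance([flat, self._ramp(0.6, 0.1)])
        assert res.flat_flags == [True, False]
        np.testing.assert_allclose(res.images[0], res.target_mean)

    def test_clipping_is_counted(self):
        # a mostly-dark image forces the low-mean target below the other
        # image's reach, so its rescale clips at 0
        dark = np.full((20, 20), 0.0)
        dark[:3] = 0.9
        mid = np.linspace(0.3, 0.7, 400).reshape(20, 20)
        res = stimuli.equalize_luminance([dark, mid])
        assert res.n_clipped > 0
        for im in res.images:
            assert im.min() >= 0 and im.max() <= 1


class TestBoxPlacement:
    LAYOUT = default_layout(DEFAULT_CANVAS)

    def test_default_box_has_published_area(self):
        boxes = stimuli.place_feature_boxes(self.LAYOUT, ["nose"], (162, 63),
                                            DEFAULT_CANVAS)
        assert len(boxes) == 1
        assert boxes[0].area == 162 * 63 == 10206

    def test_both_eyes_covers_union_of_single_eye_boxes(self):
        both = stimuli.place_feature_boxes(self.LAYOUT, ["both_eyes"], (162, 63),
                                           DEFAULT_CANVAS)
        left = stimuli.place_feature_boxes(self.LAYOUT, ["left_eye"], (162, 63),
                                           DEFAULT_CANVAS)
        right = stimuli.place_feature_boxes(self.LAYOUT, ["right_eye"], (162, 63),
                                            DEFAULT_CANVAS)
        assert set(both) == {left[0], right[0]}

    def test_oversized_box_clipped_to_canvas(self):
        boxes = stimuli.place_feature_boxes(self.LAYOUT, ["nose"], (2000, 2000),
                                            DEFAULT_CANVAS)
        assert boxes[0] == Rect(0, 0, *DEFAULT_CANVAS)

    def test_unknown_feature_rejected(self):
        with pytest.raises(ValueError):
            stimuli.place_feature_boxes(self.LAYOUT, ["chin"], (10, 10),
                                        DEFAULT_CANVAS)


class TestOcclusionAndVisibility:
    def test_mask_zeroes_inside_and_preserves_outside(self, continuum):
        spec = stimuli.OcclusionSpec("mask", ("nose",))
        img = continuum.images[5]
        out = stimuli.apply_occlusion(img, continuum.feature_layout, spec)
        boxes = stimuli.boxes_for_image(img, continuum.feature_layout, spec)
        mask = np.zeros(img.shape[:2], dtype=bool)
        for b in boxes:
            rs, cs = b.slices
            mask[rs, cs] = True
        assert (out[mask] == 0).all()
        np.testing.assert_array_equal(out[~mask], img[~mask])

    def test_mask_and_visibility_partition_the_image(self, continuum):
        spec_m = stimuli.OcclusionSpec("mask", ("both_eyes",))
        spec_v = stimuli.OcclusionSpec("visible_only", ("both_eyes",))
        img = continuum.images[3]
        occ = stimuli.apply_occlusion(img, continuum.feature_layout, spec_m)
        vis = stimuli.apply_visibility(img, continuum.feature_layout, spec_v)
        np.testing.assert_array_equal(occ + vis, img)

    def test_whole_canvas_visibility_is_identity(self, continuum):
        spec = stimuli.OcclusionSpec("visible_only", ("nose",),
                                     box_size=(5000, 5000))
        img = continuum.images[0]
        out = stimuli.apply_visibility(img, continuum.feature_layout, spec)
        np.testing.assert_array_equal(out, img)

    def test_occlusion_battery_yields_6_sets_of_21(self, continuum):
        sets = stimuli.occlusion_battery(continuum)
        assert len(sets) == 6
        assert [s.condition for s in sets] == [
            "original", "both_eyes", "left_eye", "right_eye", "nose", "mouth"]
        assert sum(len(s.images) for s in sets) == 126

    def test_visible_areas_ordered_by_box_size(self, continuum):
        sets = stimuli.visibility_battery(continuum)
        assert len(sets) == 9
        areas = {}
        for s in sets:
            if s.condition.startswith("eyes"):
                areas[s.provenance["size_name"]] = (s.images[0] > 0).sum()
        assert areas["small"] < areas["default"] < areas["large"]


class TestResizeWithMasks:
    def test_published_box_scaling_arithmetic(self):
        layout = {"box": Rect.from_center(281, 381, 162, 63)}
        img = np.zeros((762, 562))
        _, scaled = stimuli.resize_with_masks(img, layout, (224, 224))
        assert scaled["box"].width == round(162 * 224 / 562) == 65
        assert scaled["box"].height == round(63 * 224 / 762) == 19

    def test_same_size_is_identity(self, continuum):
        img = continuum.images[0]
        out, layout = stimuli.resize_with_masks(img, continuum.feature_layout,
                                                continuum.canvas_size)
        np.testing.assert_array_equal(out, img)
        assert layout == continuum.feature_layout

    def test_tiny_target_rejected(self):
        with pytest.raises(ValueError):
            stimuli.resize_with_masks(np.zeros((32, 32)), {}, (4, 4))

    def test_masking_commutes_with_resizing_up_to_boundary(self, continuum):
        """Mask-then-resize leaves the eroded interior of the scaled mask at
        (near) zero, matching resize-then-mask away from box boundaries."""
        spec = stimuli.OcclusionSpec("mask", ("nose",))
        img = continuum.images[10]
        masked = stimuli.apply_occlusion(img, continuum.feature_layout, spec)
        resized, layout = stimuli.resize_with_masks(masked, continuum.feature_layout,
                                                    (48, 48))
        for b in stimuli.boxes_for_image(resized, layout, spec):
            inner = Rect(b.x0 + 1, b.y0 + 1, b.x1 - 1, b.y1 - 1)
            rs, cs = inner.slices
            assert np.abs(resized[rs, cs]).max() < 1e-9
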