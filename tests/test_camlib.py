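"""Activation mapping: formula oracles, identities, overlays, metrics."""

import numpy as np
import pytest

from facebench import camlib
from facebench.geometry import Rect


# -- explicit per-pixel loop oracles, independent of the vectorized code ----

def cam_oracle(a, w):
    k_, h, w_ = a.shape
    m = np.zeros((h, w_))
    for x in range(h):
        for y in range(w_):
            for k in range(k_):
                m[x, y] += w[k] * a[k, x, y]
    return m


def grad_cam_oracle(a, g):
    k_, h, w_ = a.shape
    alpha = [g[k].sum() / (h * w_) for k in range(k_)]
    m = np.zeros((h, w_))
    for x in range(h):
        for y in range(w_):
            for k in range(k_):
                m[x, y] += alpha[k] * a[k, x, y]
    return np.maximum(m, 0.0)


def layer_cam_oracle(a, g):
    k_, h, w_ = a.shape
    m = np.zeros((h, w_))
    for x in range(h):
        for y in range(w_):
            for k in range(k_):
                m[x, y] += max(g[k, x, y], 0.0) * a[k, x, y]
    return np.maximum(m, 0.0)


def random_stack(rng, kmax=8, smax=8):
    k = int(rng.integers(1, kmax + 1))
    h = int(rng.integers(1, smax + 1))
    w = int(rng.integers(1, smax + 1))
    return rng.standard_normal((k, h, w)), rng.standard_normal((k, h, w))


class TestFormulaOracles:
    @pytest.mark.parametrize("seed", range(20))
    def test_all_three_methods_match_loop_oracles(self, seed):
        rng = np.random.default_rng(seed)
        a, g = random_stack(rng)
        w = rng.standard_normal(a.shape[0])
        np.testing.assert_allclose(camlib.cam(a, w).values, cam_oracle(a, w),
                                   atol=1e-12)
        np.testing.assert_allclose(camlib.grad_cam(a, g).values,
                                   grad_cam_oracle(a, g), atol=1e-12)
        np.testing.assert_allclose(camlib.layer_cam(a, g).values,
                                   layer_cam_oracle(a, g), atol=1e-12)

    def test_single_channel_unit_weight_is_identity(self, rng):
        a = rng.random((1, 4, 4))
        np.testing.assert_array_equal(camlib.cam(a, np.ones(1)).values, a[0])

    def test_zero_weights_give_zero_map(self, rng):
        a = rng.random((3, 4, 4))
        assert (camlib.cam(a, np.zeros(3)).values == 0).all()

    def test_hand_computed_layer_cam_value(self):
        m = camlib.layer_cam(np.array([[[2.0]]]), np.array([[[3.0]]]))
        assert m.values[0, 0] == 6.0

    def test_negative_gradients_zero_the_layer_cam(self, rng):
        a = rng.random((4, 5, 5)) + 1.0
        g = -rng.random((4, 5, 5)) - 0.1
        assert (camlib.layer_cam(a, g).values == 0).all()

    def test_everywhere_negative_sum_floors_grad_cam(self, rng):
        a = rng.random((2, 3, 3)) + 1.0
        g = -np.ones((2, 3, 3))
        assert (camlib.grad_cam(a, g).values == 0).all()

    def test_layer_cam_reduces_to_grad_cam_for_constant_nonneg_grads(self, rng):
        a = rng.standard_normal((5, 6, 6))
        g = np.repeat(rng.random(5)[:, None, None], 36, axis=1).reshape(5, 6, 6)
        np.testing.assert_allclose(camlib.layer_cam(a, g).values,
                                   camlib.grad_cam(a, g).values, atol=1e-12)

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            camlib.grad_cam(rng.random((2, 3, 3)), rng.random((2, 4, 3)))
        with pytest.raises(ValueError):
            camlib.cam(rng.random((2, 3, 3)), np.ones(3))


class TestInvariances:
    def test_nonnegativity_of_gradient_maps(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            a, g = random_stack(rng)
            assert camlib.grad_cam(a, g).values.min() >= 0
            assert camlib.layer_cam(a, g).values.min() >= 0

    def test_mirror_equivariance_and_asymmetry_negation(self, rng):
        a, g = rng.random((3, 6, 8)), rng.random((3, 6, 8))
        m = camlib.layer_cam(a, g).values
        m_flip = camlib.layer_cam(a[:, :, ::-1], g[:, :, ::-1]).values
        np.testing.assert_array_equal(m_flip, m[:, ::-1])
        layout = {"box": Rect(1, 1, 4, 5)}
        asym = camlib.attention_metrics(m, layout).left_right_asymmetry
        mirrored_layout = {"box": Rect(8 - 4, 1, 8 - 1, 5)}
        asym_flip = camlib.attention_metrics(m[:, ::-1],
                                             mirrored_layout).left_right_asymmetry
        assert abs(asym + asym_flip) < 1e-12

    def test_positive_gradient_scaling_leaves_normalized_map_unchanged(self, rng):
        a, g = rng.random((4, 5, 5)), rng.standard_normal((4, 5, 5))
        m1 = camlib.layer_cam(a, g).normalized
        m2 = camlib.layer_cam(a, 7.3 * g).normalized
        np.testing.assert_allclose(m1, m2, atol=1e-12)

    def test_normalized_range(self, rng):
        a, g = rng.random((2, 4, 4)), rng.standard_normal((2, 4, 4))
        norm = camlib.layer_cam(a, g).normalized
        if not np.allclose(norm, 0):
            assert norm.min() == 0.0 and norm.max() == 1.0


class TestStageMaps:
    def test_one_map_per_stage_at_input_resolution(self, assets):
        img = np.random.default_rng(0).random((48, 48, 3))
        maps = camlib.stage_maps(assets.model, img, 0, method="layer_cam")
        assert len(maps) == 5
        for m in maps:
            assert m.values.shape == (48, 48)

    def test_final_stage_matches_direct_computation(self, assets):
        from skimage.transform import resize

        img = np.random.default_rng(1).random((48, 48, 3))
        maps = camlib.stage_maps(assets.model, img, 1, method="layer_cam")
        a = assets.model.activations_at("stage5", img)
        g = assets.model.gradients_at("stage5", img, 1)
        direct = camlib.layer_cam(a, g).normalized
        up = resize(direct, (48, 48), order=1, mode="edge",
                    anti_aliasing=False, preserve_range=True)
        np.testing.assert_allclose(maps[-1].values, up, atol=1e-12)

    def test_cam_requires_head_compatible_stage(self, assets):
        img = np.random.default_rng(2).random((48, 48, 3))
        with pytest.raises(ValueError):
            camlib.stage_maps(assets.model, img, 0, method="cam")

    def test_unknown_method_rejected(self, assets):
        with pytest.raises(ValueError):
            camlib.stage_maps(assets.model, np.zeros((48, 48, 3)), 0, method="x")


class TestOverlay:
    def test_alpha_extremes(self, rng):
        img = rng.random((6, 6, 3))
        m = camlib.CAMap(rng.random((6, 6)), "layer_cam")
        np.testing.assert_allclose(camlib.overlay(m, img, alpha=0.0), img)
        pure = camlib.overlay(m, img, alpha=1.0)
        np.testing.assert_allclose(camlib.overlay(m, np.zeros_like(img), alpha=1.0),
                                   pure)

    def test_grayscale_input_promoted_to_rgb(self, rng):
        out = camlib.overlay(camlib.CAMap(rng.random((5, 5)), "cam"),
                             rng.random((5, 5)))
        assert out.shape == (5, 5, 3)
        assert out.min() >= 0 and out.max() <= 1


class TestAttentionMetrics:
    def test_concentrated_mass_gives_full_overlap_and_left_asymmetry(self):
        m = np.zeros((10, 10))
        m[2:4, 1:3] = 1.0
        layout = {"left_eye": Rect(1, 2, 3, 4), "right_eye": Rect(7, 2, 9, 4)}
        met = camlib.attention_metrics(m, layout)
        assert met.overlap["left_eye"] == 1.0
        assert met.overlap["right_eye"] == 0.0
        assert met.left_right_asymmetry == 1.0
        assert camlib.dominant_feature(met) == "both_eyes"

    def test_mirror_symmetric_map_has_zero_asymmetry(self):
        m = np.zeros((6, 8))
        m[2, 1] = m[2, 6] = 1.0
        met = camlib.attention_metrics(m, {})
        assert met.left_right_asymmetry == 0.0

    def test_uniform_map_overlap_equals_area_fraction(self):
        m = np.ones((20, 30))
        layout = {"nose": Rect(5, 5, 11, 10)}
        met = camlib.attention_metrics(m, layout)
        assert abs(met.overlap["nose"] - (6 * 5) / (20 * 30)) < 1e-12

    def test_zero_map_flagged_undefined(self):
        met = camlib.attention_metrics(np.zeros((4, 4)), {"nose": Rect(0, 0, 2, 2)})
        assert not met.defined
        with pytest.raises(ValueError):
            camlib.dominant_feature(met)
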