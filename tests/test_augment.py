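import numpy as np
import pytest
from scipy import stats

from posekit.augment import (
    AugmentConfig,
    NoiseParams,
    SpatialParams,
    no_noise,
    noise_transform,
    sample_params,
    spatial_transform,
)
from posekit.confmaps import draw_keypoint_maps
from posekit.peaks import subpixel_maxima
from posekit.skeleton import KeypointSet


def _image(h=160, w=160, seed=0):
    return np.random.default_rng(seed).integers(0, 255, (h, w, 1), dtype=np.uint8)


class TestSpatialTransform:
    def test_horizontal_flip_mirrors_and_swaps(self, simple_skeleton):
        img = _image(160, 192)
        coords = np.array([[96.0, 80.0], [96.0, 60.0], [96.0, 100.0],
                           [10.0, 80.0], [180.0, 80.0]])
        kp = KeypointSet(coords)
        out, kp2 = spatial_transform(img, kp, simple_skeleton,
                                     SpatialParams(flip_h=True))
        # left_arm slot now holds the mirrored right_arm coordinate
        i_left = simple_skeleton.index("left_arm")
        i_right = simple_skeleton.index("right_arm")
        assert kp2.coords[i_left, 0] == pytest.approx(191 - 180.0)
        assert kp2.coords[i_right, 0] == pytest.approx(191 - 10.0)
        assert out.shape == img.shape

    def test_double_flip_is_identity(self, simple_skeleton, rng):
        coords = rng.uniform(20, 140, (5, 2))
        kp = KeypointSet(coords)
        img = _image()
        p = SpatialParams(flip_h=True)
        img1, kp1 = spatial_transform(img, kp, simple_skeleton, p)
        img2, kp2 = spatial_transform(img1, kp1, simple_skeleton, p)
        assert np.allclose(kp2.coords, coords)

    def test_rotation_about_center(self, simple_skeleton):
        # 90 degrees clockwise in (x, y-down): (89.5, 79.5) -> (79.5, 89.5)
        coords = np.tile([[89.5, 79.5]], (5, 1))
        _, kp2 = spatial_transform(
            _image(160, 160), KeypointSet(coords), simple_skeleton,
            SpatialParams(theta_deg=90.0),
        )
        assert np.allclose(kp2.coords[0], [79.5, 89.5], atol=1e-9)

    def test_scale_about_center(self, simple_skeleton):
        coords = np.tile([[89.5, 79.5]], (5, 1))
        _, kp2 = spatial_transform(
            _image(160, 160), KeypointSet(coords), simple_skeleton,
            SpatialParams(scale=1.25),
        )
        assert np.allclose(kp2.coords[0], [92.0, 79.5])

    def test_out_of_frame_becomes_invisible(self, simple_skeleton):
        coords = np.tile([[150.0, 80.0]], (5, 1))
        _, kp2 = spatial_transform(
            _image(160, 160), KeypointSet(coords), simple_skeleton,
            SpatialParams(tx=0.2),
        )
        assert not kp2.visible.any()
        assert np.isnan(kp2.coords).all()

    def test_commutes_with_confidence_map_drawing(self, simple_skeleton, rng):
        # peak of the warped map ~ map of the warped keypoint
        stride = 2
        for _ in range(10):
            xy = rng.uniform(50, 110, 2)
            params = SpatialParams(
                flip_h=bool(rng.random() < 0.5),
                theta_deg=rng.uniform(-180, 180),
                scale=rng.uniform(0.9, 1.1),
                tx=rng.uniform(-0.05, 0.05),
                ty=rng.uniform(-0.05, 0.05),
            )
            kp = KeypointSet(np.tile(xy, (5, 1)))
            maps = draw_keypoint_maps(kp, (160, 160), stride, 5.0)
            from posekit.augment import affine_matrix, warp_image

            m_img = affine_matrix(params, (160, 160))
            scale_mat = np.diag([1 / stride, 1 / stride, 1.0])
            m_map = scale_mat @ m_img @ np.linalg.inv(scale_mat)
            warped = warp_image(maps[0][..., None], m_map)[..., 0]

            _, kp2 = spatial_transform(_image(), kp, simple_skeleton, params)
            if not kp2.visible[0]:
                continue
            redrawn = draw_keypoint_maps(kp2, (160, 160), stride, 5.0)[0]
            pa = subpixel_maxima(warped[None], 1, 5 / stride, 16).coords[0]
            pb = subpixel_maxima(redrawn[None], 1, 5 / stride, 16).coords[0]
            assert np.abs(pa - pb).max() <= 0.5


class TestNoiseTransform:
    def test_identity_at_zero_strength(self, rng):
        img = _image()
        out = noise_transform(img, NoiseParams(), rng)
        assert np.array_equal(out, img)

    def test_full_dropout_blanks_image(self, rng):
        out = noise_transform(
            _image(), NoiseParams(dropout_fraction=1.0, dropout_fill=0.0), rng
        )
        assert np.all(out == 0)

    def test_additive_amplitude_bound(self, rng):
        img = np.full((32, 32, 1), 128, dtype=np.uint8)
        a = 17.0
        out = noise_transform(img, NoiseParams(additive_amplitude=a), rng)
        assert np.abs(out.astype(int) - 128).max() <= np.ceil(a)

    def test_output_stays_in_range(self, rng):
        img = _image()
        out = noise_transform(
            img,
            NoiseParams(additive_amplitude=100, contrast_factor=2.0,
                        sharpen_amount=1.0),
            rng,
        )
        assert out.dtype == np.uint8


class TestSampling:
    def test_flip_rate_matches_bernoulli_half(self):
        rng = np.random.default_rng(7)
        cfg = AugmentConfig()
        n = 10_000
        flips = sum(sample_params(cfg, rng)[0].flip_h for _ in range(n))
        sigma = np.sqrt(n * 0.25)
        assert abs(flips - 0.5 * n) < 3 * sigma

    def test_rotation_uniform(self):
        rng = np.random.default_rng(8)
        cfg = AugmentConfig()
        thetas = np.array(
            [sample_params(cfg, rng)[0].theta_deg for _ in range(3000)]
        )
        assert thetas.min() >= -180 and thetas.max() < 180
        _, p = stats.kstest((thetas + 180) / 360, "uniform")
        assert p > 0.01

    def test_deterministic_given_seed(self):
        cfg = AugmentConfig()
        a = [sample_params(cfg, np.random.default_rng(3)) for _ in range(5)]
        b = [sample_params(cfg, np.random.default_rng(3)) for _ in range(5)]
        assert a == b

    def test_no_noise_helper_zeroes_strengths(self):
        cfg = no_noise(AugmentConfig())
        _, noise = sample_params(cfg, np.random.default_rng(0))
        assert noise.additive_amplitude == 0
        assert noise.contrast_factor == 1.0

    def test_config_validation(self):
        with pytest.raises(ValueError):
            AugmentConfig(flip_p=1.5)
        with pytest.raises(ValueError):
            AugmentConfig(scale_range=(1.2, 0.8))
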