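import dataclasses

import numpy as np
import pytest
from shapely.geometry import LineString

from vesselseg.errors import DimensionMismatchError
from vesselseg.io_datasets import FundusSample, split_dataset
from vesselseg.synth_fundus import (AugmentConfig, FundusRenderConfig,
                                    VesselTreeConfig, augment_sample,
                                    default_configs, generate_vessel_mask,
                                    make_synthetic_dataset,
                                    render_fundus_image)


class TestVesselMask:
    def test_seeded_determinism(self):
        cfg, _ = default_configs((64, 64), seed=3)
        np.testing.assert_array_equal(generate_vessel_mask(cfg),
                                      generate_vessel_mask(cfg))

    def test_invalid_configs(self):
        cfg, _ = default_configs((64, 64))
        with pytest.raises(ValueError):
            generate_vessel_mask(dataclasses.replace(cfg, n_roots=0))
        with pytest.raises(ValueError):
            generate_vessel_mask(dataclasses.replace(cfg, image_size=(0, 64)))
        with pytest.raises(ValueError):
            generate_vessel_mask(dataclasses.replace(cfg, min_width=99.0))

    def test_single_straight_stroke_area(self):
        """One unbranched depth-1 walk covers approximately the area of the
        segment buffered by half its width (shapely polygon oracle)."""
        cfg = VesselTreeConfig(image_size=(256, 256), n_roots=1, max_depth=1,
                               branch_prob=0.0, step_len=40.0,
                               angle_jitter_sd=0.0, root_width=5.0,
                               width_decay=1.0, min_width=1.0, seed=9)
        mask = generate_vessel_mask(cfg)
        count = int(mask.sum())
        lo = cfg.step_len * (cfg.root_width - 1)
        hi = cfg.step_len * (cfg.root_width + 2)
        assert lo <= count <= hi
        # independent polygon-area oracle: stroke = segment buffer
        area = LineString([(0, 0), (cfg.step_len, 0)]).buffer(
            cfg.root_width / 2).area
        perimeter = 2 * cfg.step_len + np.pi * cfg.root_width
        assert abs(count - area) <= 1.5 * perimeter

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_foreground_fraction_sparse(self, seed):
        cfg, _ = default_configs((128, 128), seed=seed)
        frac = generate_vessel_mask(cfg).mean()
        assert 0.0 < frac < 0.35

    def test_mask_is_binary(self):
        cfg, _ = default_configs((64, 64), seed=5)
        assert set(np.unique(generate_vessel_mask(cfg))) <= {0, 1}


class TestRenderFundus:
    def test_flat_background_without_vessels_or_noise(self):
        cfg = FundusRenderConfig(noise_sd=0.0, illumination_gradient=0.0,
                                 background_level=0.7)
        img = render_fundus_image(np.zeros((64, 64), dtype=np.uint8), cfg)
        h, w = 64, 64
        yy, xx = np.mgrid[0:h, 0:w]
        fov = ((yy - 31.5) ** 2 + (xx - 31.5) ** 2) <= (0.95 * 32) ** 2
        np.testing.assert_allclose(img[fov][:, 0], 0.7, atol=1e-12)
        for ch in range(3):  # spatially constant per channel inside FOV
            assert np.ptp(img[fov][:, ch]) < 1e-12
        np.testing.assert_allclose(img[~fov], 0.0)
        assert img[..., 0].mean() > img[..., 2].mean()  # red-dominant tint

    def test_zero_contrast_decouples_from_mask(self, rng):
        cfg = FundusRenderConfig(vessel_contrast=0.0, noise_sd=0.0, seed=4)
        m1 = (rng.random((32, 32)) < 0.2).astype(np.uint8)
        img1 = render_fundus_image(m1, cfg)
        img2 = render_fundus_image(np.zeros((32, 32), dtype=np.uint8), cfg)
        np.testing.assert_array_equal(img1, img2)

    def test_vessels_darker_than_background(self):
        tree, render = default_configs((64, 64), seed=6)
        render = dataclasses.replace(render, noise_sd=0.0)
        mask = generate_vessel_mask(tree)
        img = render_fundus_image(mask, render)
        red = img[..., 0]
        fov = red > 0
        assert red[mask.astype(bool) & fov].mean() < \
            red[(~mask.astype(bool)) & fov].mean()

    def test_bad_mask_shape(self):
        with pytest.raises(DimensionMismatchError):
            render_fundus_image(np.zeros((4, 4, 2)), FundusRenderConfig())


def _flip_seed(cfg):
    """First draw seed whose transform includes the horizontal flip."""
    for seed in range(50):
        rng = np.random.default_rng(seed)
        rng.uniform(-cfg.max_rotation_deg, cfg.max_rotation_deg)
        rng.uniform(-cfg.shift_frac, cfg.shift_frac)
        rng.uniform(-cfg.shift_frac, cfg.shift_frac)
        rng.uniform(1 - cfg.max_zoom_frac, 1 + cfg.max_zoom_frac)
        if rng.random() < 0.5:
            return seed
    raise AssertionError("no flipping seed found")


class TestAugment:
    def _sample(self, rng, size=32):
        img = rng.random((size, size, 3))
        msk = (rng.random((size, size)) < 0.2).astype(np.uint8)
        return FundusSample(id="t", image=img, mask=msk)

    def test_identity_config(self, rng):
        s = self._sample(rng)
        cfg = AugmentConfig(max_rotation_deg=0, shift_frac=0,
                            max_zoom_frac=0, hflip=False)
        out = augment_sample(s, cfg, draw_seed=7)
        np.testing.assert_allclose(out.image, s.image, atol=1e-12)
        np.testing.assert_array_equal(out.mask, s.mask)

    def test_pure_hflip_is_involution(self, rng):
        s = self._sample(rng)
        cfg = AugmentConfig(max_rotation_deg=0, shift_frac=0,
                            max_zoom_frac=0, hflip=True)
        seed = _flip_seed(cfg)
        once = augment_sample(s, cfg, seed)
        np.testing.assert_allclose(once.image, s.image[:, ::-1], atol=1e-9)
        np.testing.assert_array_equal(once.mask, s.mask[:, ::-1])
        twice = augment_sample(once, cfg, seed)
        np.testing.assert_allclose(twice.image, s.image, atol=1e-9)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_output_ranges_and_size(self, rng, seed):
        s = self._sample(rng)
        out = augment_sample(s, AugmentConfig(), seed)
        assert out.image.shape == s.image.shape
        assert out.mask.shape == s.mask.shape
        assert set(np.unique(out.mask)) <= {0, 1}
        assert 0 <= out.image.min() and out.image.max() <= 1

    def test_image_mask_geometric_consistency(self, rng):
        """A mask marking the image's darkest quartile still overlaps the
        warped image's darkest quartile after augmentation (within the
        region that stays in bounds)."""
        from scipy.ndimage import gaussian_filter
        img1 = gaussian_filter(rng.random((64, 64)), 3)
        img1 = (img1 - img1.min()) / np.ptp(img1)
        q = np.quantile(img1, 0.25)
        msk = (img1 < q).astype(np.uint8)
        s = FundusSample(id="q", image=np.stack([img1] * 3, -1), mask=msk)
        cfg = AugmentConfig(max_rotation_deg=10, shift_frac=0.05,
                            max_zoom_frac=0.1, hflip=True)
        out = augment_sample(s, cfg, draw_seed=3)
        valid = augment_sample(
            FundusSample(id="v", image=np.ones((64, 64, 3)),
                         mask=np.ones((64, 64), dtype=np.uint8)),
            cfg, draw_seed=3).mask.astype(bool)
        warped = out.image[..., 0]
        dark = (warped < q) & valid
        fg = out.mask.astype(bool) & valid
        if fg.sum():
            assert (fg & dark).sum() / fg.sum() >= 0.90

    def test_default_policy_values(self):
        cfg = AugmentConfig()
        assert (cfg.max_rotation_deg, cfg.shift_frac,
                cfg.max_zoom_frac, cfg.hflip) == (15.0, 0.10, 0.20, True)


class TestMakeDataset:
    def test_determinism_and_ids(self):
        tree, render = default_configs((32, 32))
        a = make_synthetic_dataset(2, tree, render, seed=9)
        b = make_synthetic_dataset(2, tree, render, seed=9)
        assert [s.id for s in a] == ["synth_0000", "synth_0001"]
        np.testing.assert_array_equal(a[0].image, b[0].image)
        np.testing.assert_array_equal(a[1].mask, b[1].mask)
        assert all(s.source == "synthetic" for s in a)

    def test_n_validation(self):
        with pytest.raises(ValueError):
            make_synthetic_dataset(0)

    def test_usable_with_split(self):
        tree, render = default_configs((32, 32))
        samples = make_synthetic_dataset(20, tree, render, seed=1)
        split = split_dataset(samples, 14)
        assert len(split.train) == 14 and len(split.test) == 6
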