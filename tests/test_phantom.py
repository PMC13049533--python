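"""Phantom generator: determinism, geometry oracles, boxes, splits."""

import json

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import sonoseg as ss
from sonoseg.errors import (ConfigurationError, EmptyMaskError, GeometryError)
from sonoseg.phantom import load_manifest, split_indices


class TestSpeckle:
    def test_deterministic_per_seed(self, phantom_config):
        a = ss.render_speckle(phantom_config, 7)
        b = ss.render_speckle(phantom_config, 7)
        assert np.array_equal(a, b)

    def test_distinct_seeds_differ(self, phantom_config):
        a = ss.render_speckle(phantom_config, 7)
        b = ss.render_speckle(phantom_config, 8)
        assert (a != b).mean() >= 0.01

    def test_zero_scale_is_constant(self):
        cfg = ss.PhantomConfig(speckle_scale=0.0)
        img = ss.render_speckle(cfg, 3)
        assert np.ptp(img) == 0.0

    def test_range(self, phantom_config):
        img = ss.render_speckle(phantom_config, 5)
        assert img.min() >= 0.0 and img.max() <= 1.0

    def test_invalid_dims_rejected(self):
        with pytest.raises(ConfigurationError):
            ss.PhantomConfig(image_height=8, image_width=8)


class TestNeedle:
    def test_horizontal_mask_count_matches_rasterization(self):
        # 201 columns x 3 rows within 1.5 px of the axis, plus end caps
        cfg = ss.PhantomConfig(occlusion_prob=0.0)
        mask, _ = ss.render_needle(((100, 20), (100, 220)), cfg, 0)
        brute = 0
        rows, cols = np.mgrid[0:256, 0:256]
        d = np.abs(rows - 100.0)
        inline = (cols >= 20) & (cols <= 220) & (d <= 1.5)
        assert mask.sum() >= inline.sum() == 603
        assert mask.sum() - inline.sum() <= 2 * 3  # rounded end caps only

    def test_no_occlusion_layer_support_covers_mask(self):
        cfg = ss.PhantomConfig(occlusion_prob=0.0)
        mask, layer = ss.render_needle(((100, 20), (100, 220)), cfg, 0)
        assert (layer[mask] > 0).all()

    def test_ground_truth_is_pre_occlusion(self):
        cfg0 = ss.PhantomConfig(occlusion_prob=0.0)
        cfg5 = ss.PhantomConfig(occlusion_prob=0.5)
        m0, l0 = ss.render_needle(((100, 20), (100, 220)), cfg0, 3)
        m5, l5 = ss.render_needle(((100, 20), (100, 220)), cfg5, 3)
        assert np.array_equal(m0, m5)          # GT unchanged
        assert (l5[m5] == 0).any()             # image layer loses chunks

    def test_zero_length_segment_rejected(self, phantom_config):
        with pytest.raises(GeometryError):
            ss.render_needle(((50, 50), (50, 50)), phantom_config, 0)

    def test_endpoint_outside_image_rejected(self, phantom_config):
        with pytest.raises(GeometryError):
            ss.render_needle(((50, -3), (50, 200)), phantom_config, 0)


class TestTumor:
    def test_disc_area_matches_analytic(self):
        cfg = ss.PhantomConfig(tumor_irregularity=0.0)
        mask = ss.render_tumor((128, 128), (20, 20), cfg, 0)
        assert abs(mask.sum() - np.pi * 400) / (np.pi * 400) < 0.03

    def test_single_connected_component(self):
        from scipy import ndimage
        cfg = ss.PhantomConfig(tumor_irregularity=0.4)
        for seed in range(5):
            mask = ss.render_tumor((128, 128), (30, 22), cfg, seed)
            _, n = ndimage.label(mask)
            assert n == 1

    def test_deterministic(self, phantom_config):
        a = ss.render_tumor((100, 120), (25, 18), phantom_config, 9)
        b = ss.render_tumor((100, 120), (25, 18), phantom_config, 9)
        assert np.array_equal(a, b)

    def test_oversized_radii_rejected(self, phantom_config):
        with pytest.raises(GeometryError):
            ss.render_tumor((128, 128), (500, 20), phantom_config, 0)


class TestTightBox:
    def test_known_extent(self):
        mask = np.zeros((100, 100), bool)
        mask[10:21, 30:61] = True
        assert ss.tight_box(mask, 0) == (30, 10, 61, 21)

    def test_full_image(self):
        mask = np.ones((64, 96), bool)
        assert ss.tight_box(mask, 0) == (0, 0, 96, 64)

    def test_single_pixel_with_margin(self):
        mask = np.zeros((32, 32), bool)
        mask[5, 5] = True
        assert ss.tight_box(mask, 2) == (3, 3, 8, 8)

    def test_empty_mask_rejected(self):
        with pytest.raises(EmptyMaskError):
            ss.tight_box(np.zeros((16, 16), bool), 0)

    @settings(deadline=None, max_examples=25)
    @given(seed=st.integers(0, 10_000), margin=st.integers(0, 8))
    def test_containment_property(self, seed, margin):
        rng = np.random.default_rng(seed)
        mask = rng.random((40, 40)) > 0.95
        if not mask.any():
            mask[rng.integers(40), rng.integers(40)] = True
        x0, y0, x1, y1 = ss.tight_box(mask, margin)
        rows, cols = np.nonzero(mask)
        assert (cols >= x0).all() and (cols < x1).all()
        assert (rows >= y0).all() and (rows < y1).all()


class TestDataset:
    def test_split_80_10_10(self):
        s = split_indices(10)
        assert (len(s["train"]), len(s["val"]), len(s["test"])) == (8, 1, 1)

    def test_single_sample_goes_to_train(self):
        s = split_indices(1)
        assert s["train"] == [0] and not s["val"] and not s["test"]

    def test_regeneration_is_identical(self, phantom_config, tmp_path):
        a, ma = ss.generate_dataset(3, phantom_config, seed=42, out_dir=tmp_path / "a")
        b, mb = ss.generate_dataset(3, phantom_config, seed=42, out_dir=tmp_path / "b")
        assert json.dumps(ma["samples"]) == json.dumps(mb["samples"])
        for x, y in zip(a, b):
            assert np.array_equal(x.us_image, y.us_image)
            assert np.array_equal(x.needle_mask, y.needle_mask)

    def test_manifest_roundtrip(self, phantom_config, tmp_path):
        samples, _ = ss.generate_dataset(2, phantom_config, seed=5, out_dir=tmp_path)
        loaded, manifest = load_manifest(tmp_path / "dataset.json")
        assert len(loaded) == 2
        assert loaded[0].boxes == samples[0].boxes
        # masks survive the 8-bit PNG roundtrip exactly
        assert np.array_equal(loaded[0].needle_mask, samples[0].needle_mask)
        assert np.allclose(loaded[0].us_image, samples[0].us_image, atol=1 / 255)

    def test_boxes_contain_masks(self, small_dataset):
        for s in small_dataset[0]:
            for cls, mask in (("needle", s.needle_mask), ("tumor", s.tumor_mask)):
                x0, y0, x1, y1 = s.boxes[cls]
                rows, cols = np.nonzero(mask)
                assert (cols >= x0).all() and (cols < x1).all()
                assert (rows >= y0).all() and (rows < y1).all()

    def test_needle_angle_recovered_by_line_fit(self):
        cfg = ss.PhantomConfig(occlusion_prob=0.0)
        mask, _ = ss.render_needle(((60, 20), (140, 220)), cfg, 0)
        true_angle = np.degrees(np.arctan2(140 - 60, 220 - 20))
        fit = ss.fit_needle_line(mask)
        assert abs(fit.angle_deg - true_angle) < 2.0

    def test_spacing_roundtrip_identity(self, small_dataset):
        s = small_dataset[0][0]
        d_px = 123.4
        assert (d_px * s.pixel_spacing) / s.pixel_spacing == pytest.approx(d_px)
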