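"""Metric suite vs. brute-force oracles, algebraic identities, geometry."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import sonoseg as ss
from sonoseg.errors import ShapeError, UndefinedMetricError
from sonoseg.metrics import mask_points, needle_length


def brute_mhd(xp, yg):
    """All-pairs oracle for the modified Hausdorff distance."""
    xp = np.asarray(xp, float)
    yg = np.asarray(yg, float)
    d = np.sqrt(((xp[:, None, :] - yg[None, :, :]) ** 2).sum(-1))
    return max(d.min(axis=1).mean(), d.min(axis=0).mean())


def random_mask_pair(rng, shape=(12, 12), p=0.3):
    a = rng.random(shape) < p
    b = rng.random(shape) < p
    return a, b


class TestOverlapMetrics:
    def test_identical_masks(self, rng):
        m = rng.random((10, 10)) < 0.4
        m[0, 0] = True
        assert ss.iou(m, m) == 1.0
        assert ss.dice(m, m) == 1.0
        assert ss.precision(m, m) == 1.0
        assert ss.recall(m, m) == 1.0

    def test_worked_2x2_overlap(self):
        # Mp rows 0-1, Mg rows 1-2 of a 2-wide strip: |∩|=2, union 6
        mp = np.zeros((3, 2), bool)
        mg = np.zeros((3, 2), bool)
        mp[0:2] = True
        mg[1:3] = True
        assert ss.iou(mp, mg) == pytest.approx(2 / 6)
        assert ss.dice(mp, mg) == pytest.approx(0.5)
        assert ss.precision(mp, mg) == pytest.approx(0.5)
        assert ss.recall(mp, mg) == pytest.approx(0.5)

    def test_disjoint_and_empty_conventions(self):
        a = np.zeros((4, 4), bool)
        b = np.zeros((4, 4), bool)
        a[0, 0] = True
        assert ss.iou(a, np.roll(a, 1, axis=0)) == 0.0
        assert ss.dice(b, b) == 1.0 and ss.iou(b, b) == 1.0
        assert ss.dice(a, b) == 0.0
        assert ss.precision(b, a) == 0.0 and ss.recall(a, b) == 0.0

    def test_subset_relations(self, rng):
        g = rng.random((10, 10)) < 0.5
        g[3:6, 3:6] = True
        p = g & (rng.random((10, 10)) < 0.7)
        p[4, 4] = True
        assert ss.precision(p, g) == 1.0     # pred ⊂ gt
        assert ss.recall(g | p, g) == 1.0    # gt ⊂ pred

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ShapeError):
            ss.iou(np.zeros((3, 3), bool), np.zeros((4, 4), bool))

    @settings(deadline=None, max_examples=50)
    @given(seed=st.integers(0, 10 ** 6))
    def test_dice_iou_and_f1_identities(self, seed):
        rng = np.random.default_rng(seed)
        p, g = random_mask_pair(rng)
        i = ss.iou(p, g)
        d = ss.dice(p, g)
        assert d == pytest.approx(2 * i / (1 + i), abs=1e-12)
        pr, rc = ss.precision(p, g), ss.recall(p, g)
        if pr + rc > 0:
            assert d == pytest.approx(2 * pr * rc / (pr + rc), abs=1e-12)

    def test_recall_monotone_under_dilation(self, rng):
        from scipy import ndimage
        g = rng.random((20, 20)) < 0.2
        g[5:9, 5:9] = True
        p = rng.random((20, 20)) < 0.2
        prev = ss.recall(p, g)
        for _ in range(4):
            p = ndimage.binary_dilation(p)
            cur = ss.recall(p, g)
            assert cur >= prev
            prev = cur


class TestPixelAccuracy:
    def test_identical_maps(self):
        m = np.arange(16).reshape(4, 4) % 3
        assert ss.pixel_accuracy(m, m, 3) == 1.0

    def test_known_disagreement(self):
        g = np.zeros((4, 4), int)
        p = g.copy()
        p[0, 0] = p[3, 3] = 1
        assert ss.pixel_accuracy(p, g, 2) == pytest.approx(14 / 16)

    def test_constant_prediction_on_balanced_map(self):
        g = np.zeros((4, 4), int)
        g[:2] = 1
        assert ss.pixel_accuracy(np.zeros((4, 4), int), g, 2) == pytest.approx(0.5)

    def test_out_of_range_labels_rejected(self):
        with pytest.raises(ValueError):
            ss.pixel_accuracy(np.full((2, 2), 5), np.zeros((2, 2), int), 2)


class TestMHD:
    def test_identical_sets_zero(self):
        pts = np.array([[0, 0], [3, 4], [7, 1]], float)
        assert ss.mhd(pts, pts) == 0.0

    def test_worked_asymmetric_example(self):
        xp = [(0, 0), (3, 0)]
        yg = [(0, 4)]
        # forward mean (4+5)/2 = 4.5, reverse 4 -> max 4.5
        assert ss.mhd(xp, yg) == pytest.approx(4.5)
        assert ss.mhd(yg, xp) == pytest.approx(4.5)   # symmetric

    def test_mm_conversion_linear_in_spacing(self):
        xp = [(0, 0), (3, 0)]
        yg = [(0, 4)]
        assert ss.mhd(xp, yg, spacing=0.1) == pytest.approx(0.45)
        assert ss.mhd(xp, yg, spacing=0.2) == pytest.approx(0.90)

    def test_empty_set_is_undefined(self):
        with pytest.raises(UndefinedMetricError):
            ss.mhd(np.empty((0, 2)), [(0, 0)])

    @settings(deadline=None, max_examples=40)
    @given(seed=st.integers(0, 10 ** 6))
    def test_matches_all_pairs_oracle(self, seed):
        rng = np.random.default_rng(seed)
        xp = rng.uniform(0, 50, size=(rng.integers(1, 100), 2))
        yg = rng.uniform(0, 50, size=(rng.integers(1, 100), 2))
        assert ss.mhd(xp, yg) == pytest.approx(brute_mhd(xp, yg), abs=1e-9)


class TestNeedleLine:
    def test_horizontal_row(self):
        m = np.zeros((200, 200), bool)
        m[100, 20:180] = True
        assert ss.fit_needle_line(m).angle_deg == pytest.approx(0.0, abs=1e-9)

    def test_diagonal_45_degrees(self):
        m = np.zeros((50, 50), bool)
        for i in range(5, 45):
            m[i, i] = True
        assert ss.fit_needle_line(m).angle_deg == pytest.approx(45.0, abs=1e-9)

    def test_thick_noisy_segment_angle_recovery(self):
        cfg = ss.PhantomConfig(occlusion_prob=0.0)
        r0, c0 = 40.0, 20.0
        c1 = 220.0
        r1 = r0 + np.tan(np.deg2rad(30)) * (c1 - c0)
        mask, _ = ss.render_needle(((r0, c0), (r1, c1)), cfg, 0)
        assert abs(ss.fit_needle_line(mask).angle_deg - 30.0) < 2.0

    def test_too_few_pixels_rejected(self):
        m = np.zeros((10, 10), bool)
        m[5, 5] = True
        with pytest.raises(UndefinedMetricError):
            ss.fit_needle_line(m)


class TestTargetingError:
    def test_identical_masks_zero(self):
        m = np.zeros((64, 64), bool)
        m[30, 10:50] = True
        assert ss.targeting_error(m, m, (64, 64), 0.1) == 0.0

    def test_worked_horizontal_lines(self):
        g = np.zeros((256, 256), bool)
        p = np.zeros((256, 256), bool)
        g[100, 20:236] = True    # distance to center row 128 -> 28 px
        p[104, 20:236] = True    # 24 px
        te = ss.targeting_error(g, p, (256, 256), spacing=0.1)
        assert te == pytest.approx(0.4, abs=1e-9)

    def test_symmetric_in_arguments(self):
        g = np.zeros((256, 256), bool)
        p = np.zeros((256, 256), bool)
        g[90, 30:220] = True
        p[110, 30:220] = True
        a = ss.targeting_error(g, p, (256, 256), 0.1)
        b = ss.targeting_error(p, g, (256, 256), 0.1)
        assert a == pytest.approx(b)


class TestNLSRandNLR:
    @staticmethod
    def _masks_with_overlap(n_g, n_p, n_inter):
        g = np.zeros((40, 40), bool)
        p = np.zeros((40, 40), bool)
        g.ravel()[:n_g] = True
        p.ravel()[n_g - n_inter:n_g - n_inter + n_p] = True
        assert np.logical_and(g, p).sum() == n_inter
        return g, p

    def test_strict_threshold_rule(self):
        g, p = self._masks_with_overlap(100, 60, 31)
        assert ss.nlsr(g, p) is True          # 31 > 30
        g, p = self._masks_with_overlap(100, 60, 30)
        assert ss.nlsr(g, p) is False         # boundary: 30 > 30 fails

    def test_disjoint_fails(self):
        g, p = self._masks_with_overlap(50, 50, 0)
        assert ss.nlsr(g, p) is False

    def test_empty_prediction_fails(self):
        g = np.ones((8, 8), bool)
        assert ss.nlsr(g, np.zeros((8, 8), bool)) is False

    def test_nlr_worked_example(self):
        g = np.zeros((100, 100), bool)
        p = np.zeros((100, 100), bool)
        g[50, 10:61] = True    # extent 50
        p[50, 10:56] = True    # extent 45
        assert needle_length(g) == pytest.approx(50.0)
        assert ss.nlr(g, p) == pytest.approx(0.9)

    def test_nlr_identity_and_overshoot(self):
        g = np.zeros((100, 100), bool)
        g[50, 10:61] = True
        assert ss.nlr(g, g) == pytest.approx(1.0)
        p = np.zeros((100, 100), bool)
        p[50, 5:66] = True
        assert ss.nlr(g, p) > 1.0             # not clipped


class TestEvaluateDataset:
    def _needle_like(self, row, length=40):
        m = np.zeros((64, 64), bool)
        m[row:row + 2, 10:10 + length] = True
        return m

    def test_perfect_predictions(self):
        masks = [self._needle_like(r) for r in (10, 20, 30, 40, 50)]
        rep = ss.evaluate_dataset(masks, masks, spacing=0.1)
        assert rep.aggregates["dice"]["mean"] == pytest.approx(1.0)
        assert rep.aggregates["dice"]["std"] == pytest.approx(0.0)
        assert rep.aggregates["nlsr_pct"]["value"] == 100.0
        assert rep.failures == {"mhd_mm": 0, "te_mm": 0, "nlr": 0}

    def test_mean_of_known_dice_values(self):
        g1 = self._needle_like(10, 40)
        p1 = np.zeros_like(g1)
        p1[10:12, 10:42] = True              # dice 2*64/(64+80) ≈ 0.888...
        rep = ss.evaluate_dataset([p1, g1], [g1, g1], spacing=0.1)
        d1 = ss.dice(p1, g1)
        assert rep.aggregates["dice"]["mean"] == pytest.approx((d1 + 1.0) / 2)

    def test_empty_prediction_counts_as_failure_not_zero(self):
        g = self._needle_like(10)
        p = np.zeros_like(g)
        rep = ss.evaluate_dataset([p], [g], spacing=0.1)
        assert rep.failures["mhd_mm"] == 1
        assert rep.failures["te_mm"] == 1
        assert np.isnan(rep.per_sample[0]["mhd_mm"])

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError):
            ss.evaluate_dataset([], [], spacing=0.1)

    def test_serialization_roundtrip(self, tmp_path):
        m = self._needle_like(12)
        rep = ss.evaluate_dataset([m], [m], spacing=0.1)
        rep.to_csv(tmp_path / "per_sample.csv")
        rep.to_json(tmp_path / "agg.json")
        import json
        agg = json.loads((tmp_path / "agg.json").read_text())
        assert agg["n_samples"] == 1
        assert (tmp_path / "per_sample.csv").read_text().count("\n") == 2


def test_mask_points_matches_nonzero(rng):
    m = rng.random((9, 9)) < 0.3
    pts = mask_points(m)
    assert pts.shape[0] == m.sum()
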