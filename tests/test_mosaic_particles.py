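import numpy as np
import pandas as pd
import pytest
from shapely.geometry import box

from synfp import mosaic_particles as mp
from synfp.containers import PointPattern
from synfp.synthgen import SimConfig, gen_mosaics, roi_polygon

PX = 25.0


def render_spots(shape, centers_px, amp=100.0, sd=2.0):
    yy, xx = np.mgrid[: shape[0], : shape[1]]
    img = np.zeros(shape)
    for cx, cy in centers_px:
        img += amp * np.exp(-((xx + 0.5 - cx) ** 2 + (yy + 0.5 - cy) ** 2)
                            / (2 * sd**2))
    return img


class TestPreprocess:
    def test_constant_image_removed(self):
        stack = np.full((5, 40, 40), 50.0)
        roi = np.ones((40, 40), bool)
        img = mp.preprocess(stack, stack, roi, ball_radius_px=10)
        assert np.abs(img.ch1).max() < 1.0

    def test_spot_preserved_within_5_percent(self):
        spot = render_spots((48, 48), [(24.5, 24.5)], amp=100.0)
        stack = (spot + 20.0)[None].repeat(5, axis=0)
        roi = np.ones((48, 48), bool)
        img = mp.preprocess(stack, stack, roi, ball_radius_px=10)
        assert img.ch1.max() == pytest.approx(spot.max(), rel=0.05)

    def test_signal_outside_roi_cleared(self):
        spot = render_spots((48, 48), [(10, 10)], amp=100.0)
        roi = np.zeros((48, 48), bool)
        roi[30:40, 30:40] = True  # ROI away from the spot
        img = mp.preprocess(spot[None], spot[None], roi, ball_radius_px=10)
        assert np.abs(img.ch1).max() < 1.0

    def test_roi_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            mp.preprocess(np.zeros((3, 8, 8)), np.zeros((3, 8, 8)),
                          np.ones((9, 9), bool))


class TestAlign:
    def test_known_shift_recovered(self):
        base = render_spots((64, 64), [(20, 30), (40, 25), (32, 45)])
        shifted = np.roll(base, 3, axis=1)  # ch2 = ch1 shifted +3 in x
        roi = np.ones((64, 64), bool)
        tr, out = mp.align_channels(base, shifted, roi, max_shift_px=5,
                                    max_angle_deg=0)
        assert (tr["dx"], tr["dy"]) == (-3, 0)
        assert tr["corr_after"] >= tr["corr_before"]

    def test_identity_for_equal_channels(self):
        base = render_spots((48, 48), [(20, 20), (30, 28)])
        tr, _ = mp.align_channels(base, base.copy(), np.ones((48, 48), bool),
                                  max_shift_px=3, max_angle_deg=3)
        assert (tr["dx"], tr["dy"], tr["angle_deg"]) == (0, 0, 0.0)

    def test_known_rotation_recovered(self):
        from scipy import ndimage

        base = render_spots((64, 64), [(18, 30), (44, 22), (36, 48)])
        rotated = ndimage.rotate(base, 5.0, reshape=False, order=1)
        roi = np.zeros((64, 64), bool)
        roi[8:-8, 8:-8] = True
        tr, _ = mp.align_channels(base, rotated, roi, max_shift_px=2,
                                  max_angle_deg=8)
        assert tr["angle_deg"] == pytest.approx(-5.0, abs=1.0)

    def test_flat_channel_warns_identity(self):
        base = render_spots((32, 32), [(16, 16)])
        with pytest.warns(UserWarning, match="flat channel"):
            tr, out = mp.align_channels(base, np.zeros_like(base),
                                        np.ones((32, 32), bool))
        assert (tr["dx"], tr["dy"]) == (0, 0)


class TestDetect:
    def test_two_resolvable_spots(self):
        img = render_spots((64, 64), [(22, 32), (32, 32)])  # 10 px apart
        mask = img > 5.0
        pat = mp.detect_particles(img, mask, pixel_size_nm=PX)
        assert pat.n == 2
        got = np.sort(pat.coords[:, 0])
        np.testing.assert_allclose(got, [22 * PX, 32 * PX], atol=0.5 * PX)
        np.testing.assert_allclose(pat.coords[:, 1], 32 * PX, atol=0.5 * PX)

    def test_unresolvable_pair_merged(self):
        img = render_spots((64, 64), [(31.5, 32), (32.5, 32)])  # 1 px apart
        mask = img > 5.0
        pat = mp.detect_particles(img, mask, pixel_size_nm=PX)
        assert pat.n == 1

    def test_empty_inputs(self):
        img = np.zeros((32, 32))
        assert mp.detect_particles(img, np.zeros((32, 32), bool)).n == 0
        assert mp.detect_particles(img, np.ones((32, 32), bool)).n == 0

    def test_marks_match_region_properties(self):
        img = render_spots((48, 48), [(24, 24)], amp=80.0)
        mask = img > 4.0
        pat = mp.detect_particles(img, mask, pixel_size_nm=PX)
        assert pat.n == 1
        m = pat.marks.iloc[0]
        assert m.area_nm2 == pytest.approx(mask.sum() * PX**2)
        assert m.total_intensity == pytest.approx(img[mask].sum())
        assert m.avg_intensity == pytest.approx(img[mask].mean())


class TestParticleSummary:
    @staticmethod
    def _pattern(n=5):
        coords = np.column_stack([np.linspace(100, 500, n), np.full(n, 200.0)])
        marks = pd.DataFrame({"area_nm2": np.full(n, 1250.0),
                              "total_intensity": np.full(n, 90.0),
                              "avg_intensity": np.full(n, 45.0)})
        return PointPattern(coords, box(0, 0, 1000, 1000), marks=marks)

    def test_density_arithmetic(self):
        mask = np.zeros((40, 40), bool)
        mask[:25, :40] = True  # 1000 px^2
        out = mp.particle_summary(self._pattern(5), mask, pixel_size_nm=PX)
        assert out["density_per_nm2"] == pytest.approx(5 / (1000 * 625))

    def test_factor_one_is_identity(self):
        mask = np.ones((20, 20), bool)
        out1 = mp.particle_summary(self._pattern(), mask, correction_factor=1.0)
        assert out1["mean_area_nm2"] == pytest.approx(1250.0)

    def test_factor_exponents(self):
        mask = np.ones((20, 20), bool)
        raw = mp.particle_summary(self._pattern(), mask, correction_factor=1.0)
        out = mp.particle_summary(self._pattern(), mask, correction_factor=1.1)
        assert out["mean_area_nm2"] == pytest.approx(raw["mean_area_nm2"] / 1.21)
        assert out["density_per_nm2"] == pytest.approx(
            raw["density_per_nm2"] * 1.21)
        assert out["mean_total_intensity"] == raw["mean_total_intensity"]

    def test_zero_mask_rejected(self):
        with pytest.raises(ValueError):
            mp.particle_summary(self._pattern(), np.zeros((4, 4), bool))


class TestManders:
    def test_identical_masks(self):
        rng = np.random.default_rng(0)
        ch = rng.uniform(0, 1, (16, 16))
        m = np.zeros((16, 16), bool)
        m[4:12, 4:12] = True
        assert mp.manders(ch, ch, m, m) == pytest.approx((1.0, 1.0))

    def test_disjoint_masks(self):
        ch = np.ones((16, 16))
        m1 = np.zeros((16, 16), bool)
        m2 = np.zeros((16, 16), bool)
        m1[:4], m2[8:12] = True, True
        assert mp.manders(ch, ch, m1, m2) == pytest.approx((0.0, 0.0))

    def test_half_overlap(self):
        ch1 = np.zeros((16, 16))
        m1 = np.zeros((16, 16), bool)
        m1[0, :10] = True
        ch1[m1] = 3.0  # uniform on the 10-px mask
        m2 = np.zeros((16, 16), bool)
        m2[0, 5:15] = True  # covers 5 of them
        M1, _ = mp.manders(ch1, np.ones((16, 16)), m1, m2)
        assert M1 == pytest.approx(0.5)

    def test_swap_symmetry(self):
        rng = np.random.default_rng(1)
        ch1, ch2 = rng.uniform(0, 1, (2, 12, 12))
        m1 = rng.random((12, 12)) > 0.5
        m2 = rng.random((12, 12)) > 0.5
        a = mp.manders(ch1, ch2, m1, m2)
        b = mp.manders(ch2, ch1, m2, m1)
        assert a[0] == pytest.approx(b[1]) and a[1] == pytest.approx(b[0])
        assert 0 <= a[0] <= 1 and 0 <= a[1] <= 1


class TestNnd:
    def test_collinear_oracle(self):
        # points at 0, 1, 3: NND1 = (1 + 1 + 2)/3, NND2 = (3 + 2 + 3)/3
        pat = PointPattern(np.array([[0, 0], [1, 0], [3, 0]], float),
                           box(-1, -1, 4, 1))
        out = mp.nnd_profile(pat, K=2)
        assert out.mean_nnd_nm.tolist() == pytest.approx([4 / 3, 8 / 3])
        assert not out.truncated.any()  # K = n - 1 is computable in full
        flagged = mp.nnd_profile(pat, K=5)  # requesting more than n - 1
        assert flagged.k.max() == 2 and flagged.truncated.all()

    def test_regular_grid_nnd1_is_spacing(self):
        g = np.stack(np.meshgrid(np.arange(5) * 70.0, np.arange(5) * 70.0),
                     -1).reshape(-1, 2)
        pat = PointPattern(g, box(-10, -10, 300, 300))
        out = mp.nnd_profile(pat, K=1)
        assert out.mean_nnd_nm.iloc[0] == pytest.approx(70.0)

    def test_brute_force_oracle_random_patterns(self):
        rng = np.random.default_rng(2)
        for _ in range(3):
            pts = rng.uniform(0, 1000, (30, 2))
            pat = PointPattern(pts, box(0, 0, 1000, 1000))
            out = mp.nnd_profile(pat, K=8)
            d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
            d.sort(axis=1)
            expected = d[:, 1:9].mean(axis=0)  # brute-force k-NN means
            np.testing.assert_allclose(out.mean_nnd_nm, expected, rtol=1e-12)
            assert (np.diff(out.mean_nnd_nm) >= 0).all()

    def test_correction_factor_divides(self):
        pat = PointPattern(np.array([[0, 0], [100, 0]], float), box(-1, -1, 101, 1))
        out = mp.nnd_profile(pat, K=1, correction_factor=2.0)
        assert out.mean_nnd_nm.iloc[0] == pytest.approx(50.0)


class TestRipley:
    def test_two_point_hand_computation(self):
        # K(r) = 0 below the pair distance, |W| at or above it
        W = box(0, 0, 1000, 1000)
        pat = PointPattern(np.array([[300, 500], [700, 500]], float), W)
        r, K, dev = mp.ripley_csr(pat, r_max_px=20, step_px=4,
                                  pixel_size_nm=25.0, correction="none")
        expected = np.where(r >= 400.0, 1e6, 0.0)
        np.testing.assert_allclose(K, expected)

    def test_k_non_decreasing(self):
        rng = np.random.default_rng(3)
        pat = PointPattern(rng.uniform(0, 1200, (40, 2)), box(0, 0, 1200, 1200))
        _, K, _ = mp.ripley_csr(pat)
        assert (np.diff(K) >= -1e-9).all()

    def test_clustered_positive_inhibited_negative(self):
        cfg = SimConfig(seed=9, n_synapses=3, n_points=40,
                        point_process="thomas", thomas_parents=4,
                        thomas_sd_nm=40.0)
        W = roi_polygon(cfg)
        _, gt = gen_mosaics(cfg)
        devs_thomas = [
            mp.ripley_csr(PointPattern(
                g[["x_nm", "y_nm"]].to_numpy(), W))[2]
            for _, g in gt.points.query("channel == 1").groupby("synapse_id")]
        cfg_hc = cfg.with_(point_process="hardcore", hardcore_radius_nm=150.0,
                           n_points=30)
        _, gt_hc = gen_mosaics(cfg_hc)
        devs_hc = [
            mp.ripley_csr(PointPattern(
                g[["x_nm", "y_nm"]].to_numpy(), W))[2]
            for _, g in gt_hc.points.query("channel == 1").groupby("synapse_id")]
        assert np.mean(devs_thomas) > 0
        assert np.mean(devs_hc) < 0

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            mp.ripley_csr(PointPattern(np.array([[1.0, 1.0]]), box(0, 0, 2, 2)))


class TestOverlapPairs:
    def test_identical_masks_zero_distance(self):
        m = np.zeros((20, 20), int)
        m[2:5, 2:5] = 1
        m[10:14, 10:14] = 2
        table, mean = mp.overlap_pair_distances(m, m.copy())
        assert len(table) == 2
        assert mean == pytest.approx(0.0, abs=1e-9)

    def test_unit_squares_two_pixels_apart(self):
        # centers at (10, 10) and (12, 10) px, overlapping by one pixel
        m1 = np.zeros((24, 24), int)
        m2 = np.zeros((24, 24), int)
        m1[9:12, 9:12] = 1   # center (10, 10)
        m2[9:12, 11:14] = 1  # center (10, 12) -> overlap column 11
        table, mean = mp.overlap_pair_distances(m1, m2, pixel_size_nm=1.0)
        assert len(table) == 1
        assert mean == pytest.approx(2.0)

    def test_one_region_two_partners_counts_two_pairs(self):
        m1 = np.zeros((20, 30), int)
        m1[8:12, 5:25] = 1  # one long region
        m2 = np.zeros((20, 30), int)
        m2[8:12, 6:9] = 1
        m2[8:12, 20:23] = 2
        table, _ = mp.overlap_pair_distances(m1, m2)
        assert len(table) == 2

    def test_no_overlap_flagged_nan(self):
        m1 = np.zeros((10, 10), int)
        m2 = np.zeros((10, 10), int)
        m1[0:2, 0:2] = 1
        m2[6:8, 6:8] = 1
        table, mean = mp.overlap_pair_distances(m1, m2)
        assert len(table) == 0 and np.isnan(mean)

    def test_planted_offset_recovered_on_truth_masks(self):
        cfg = SimConfig(seed=12, n_synapses=4, n_points=12, coupling="paired",
                        pairing_offset_nm=50.0, pairing_fraction=1.0)
        samples, _ = gen_mosaics(cfg)
        means = [mp.overlap_pair_distances(s.mask1, s.mask2)[1] for s in samples]
        assert np.nanmean(means) == pytest.approx(50.0, abs=10.0)
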