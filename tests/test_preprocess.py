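"""Preprocessing chain: BM fit, ROI, CLAHE dialect, registration, resize."""

import numpy as np
import pytest

from octseg.preprocess import (
    ClaheParams,
    RoiBounds,
    augment_rotation,
    clahe,
    compute_roi,
    fit_bm,
    global_hist_equalize,
    mask_outside_roi,
    overlay_labels,
    register,
    resize,
)


class TestFitBM:
    def test_constant_candidates_give_constant_line(self):
        y = np.full(64, 300.0)
        assert np.allclose(fit_bm(y, degree=2), 300.0)

    def test_exact_parabola_interpolated(self):
        x = np.arange(512.0)
        y = 0.001 * (x - 250) ** 2 + 200
        fitted = fit_bm(y, degree=2)
        assert np.max(np.abs(fitted - y)) <= 1e-6

    def test_noisy_parabola_within_three_standard_errors(self):
        # least-squares oracle: repeated fits recover coefficients within 3 SE
        rng = np.random.default_rng(0)
        x = np.arange(512.0)
        true = np.array([2e-4, -0.05, 260.0])
        y_true = np.polyval(true, x)
        coefs = []
        for _ in range(50):
            y = y_true + rng.normal(0, 2.0, size=x.size)
            c = np.polyfit(x, fit_bm(y, degree=2), 2)
            coefs.append(c)
        coefs = np.array(coefs)
        se = coefs.std(axis=0, ddof=1) / np.sqrt(len(coefs))
        assert np.all(np.abs(coefs.mean(axis=0) - true) < 3 * se + 1e-9)

    def test_missing_candidates_are_ignored(self):
        y = np.full(100, 120.0)
        y[10:90] = np.nan
        assert np.allclose(fit_bm(y, degree=1), 120.0)

    def test_insufficient_candidates_raise(self):
        y = np.full(10, np.nan)
        y[0] = 5.0
        with pytest.raises(ValueError):
            fit_bm(y, degree=2)


class TestComputeRoi:
    def test_offset_arithmetic(self):
        roi = compute_roi(np.full(4, 100), np.full(4, 300), offset_um=390,
                          axial_resolution=3.87)
        assert np.all(roi.upper == 100)
        assert np.all(roi.lower == 300 + 101)  # round(390 / 3.87) = 101

    def test_zero_offset_gives_bm(self):
        roi = compute_roi(np.full(4, 100), np.full(4, 300), offset_um=0,
                          axial_resolution=3.87)
        assert np.all(roi.lower == 300)

    def test_lower_clamped_to_depth(self):
        roi = compute_roi(np.full(4, 100), np.full(4, 490), offset_um=390,
                          axial_resolution=3.87, image_depth=496)
        assert np.all(roi.lower == 495)


class TestMaskOutsideRoi:
    def test_column_bounds(self):
        img = np.ones((6, 1), dtype=np.uint8)
        out = mask_outside_roi(img, RoiBounds(upper=[2], lower=[4]))
        assert out[:, 0].tolist() == [0, 0, 1, 1, 1, 0]

    def test_full_roi_is_identity(self):
        img = np.arange(24, dtype=np.uint8).reshape(6, 4)
        roi = RoiBounds(upper=np.zeros(4, int), lower=np.full(4, 5))
        assert np.array_equal(mask_outside_roi(img, roi), img)

    def test_matches_pixel_loop_oracle(self, rng):
        img = rng.integers(0, 255, size=(20, 15)).astype(np.uint8)
        upper = rng.integers(0, 10, size=15)
        lower = upper + rng.integers(0, 10, size=15)
        roi = RoiBounds(upper=upper, lower=lower)
        got = mask_outside_roi(img, roi)
        for r in range(20):
            for c in range(15):
                expect = img[r, c] if upper[c] <= r <= lower[c] else 0
                assert got[r, c] == expect

    def test_masking_is_idempotent(self, rng):
        img = rng.integers(0, 255, size=(30, 20)).astype(np.uint8)
        roi = RoiBounds(upper=np.full(20, 5), lower=np.full(20, 22))
        once = mask_outside_roi(img, roi)
        assert np.array_equal(mask_outside_roi(once, roi), once)

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError):
            mask_outside_roi(np.ones((4, 4)), RoiBounds(upper=[0], lower=[3]))


def _clahe_reference(img, gh, gw, clip_limit, n_bins=256):
    """Straight-line per-pixel reference of the stated CLAHE algorithm."""
    h, w = img.shape
    th, tw = h // gh, w // gw  # exact division in the tests that use this
    area = th * tw
    clip = max(1, round(clip_limit * area / n_bins))
    luts = np.zeros((gh, gw, n_bins))
    for i in range(gh):
        for j in range(gw):
            tile = img[i * th:(i + 1) * th, j * tw:(j + 1) * tw]
            hist = np.zeros(n_bins, dtype=int)
            for v in tile.ravel():
                hist[int(v) * n_bins // 256] += 1
            excess = sum(max(0, hv - clip) for hv in hist)
            hist = np.minimum(hist, clip)
            hist += excess // n_bins
            for b in range(excess % n_bins):
                hist[b] += 1
            luts[i, j] = np.round(np.cumsum(hist) * 255.0 / area)
    out = np.zeros((h, w))
    for r in range(h):
        for c in range(w):
            ty, tx = (r + 0.5) / th - 0.5, (c + 0.5) / tw - 0.5
            y0, x0 = int(np.floor(ty)), int(np.floor(tx))
            fy = 0.0 if ty < 0 else ty - y0
            fx = 0.0 if tx < 0 else tx - x0
            y0c, y1c = np.clip([y0, y0 + 1], 0, gh - 1)
            x0c, x1c = np.clip([x0, x0 + 1], 0, gw - 1)
            b = int(img[r, c]) * n_bins // 256
            out[r, c] = ((1 - fy) * ((1 - fx) * luts[y0c, x0c][b] + fx * luts[y0c, x1c][b])
                         + fy * ((1 - fx) * luts[y1c, x0c][b] + fx * luts[y1c, x1c][b]))
    return np.round(out).astype(np.uint8)


class TestClahe:
    def test_matches_per_pixel_reference(self, rng):
        img = np.zeros((64, 64), dtype=np.uint8)
        img[:, ::3] = 40
        img[10:50, 20:40] = 200  # two-tone plus a bright block
        got = clahe(img, ClaheParams(grid_size=(8, 8), clip_limit=1.0))
        ref = _clahe_reference(img, 8, 8, 1.0)
        assert np.array_equal(got, ref)

    def test_random_image_matches_reference(self, rng):
        img = rng.integers(0, 256, size=(32, 48)).astype(np.uint8)
        got = clahe(img, ClaheParams(grid_size=(4, 4), clip_limit=2.0))
        ref = _clahe_reference(img, 4, 4, 2.0)
        assert np.array_equal(got, ref)

    def test_unbounded_single_tile_equals_global_equalization(self, rng):
        img = rng.integers(0, 200, size=(40, 40)).astype(np.uint8)
        got = clahe(img, ClaheParams(grid_size=(1, 1), clip_limit=1e9))
        assert np.array_equal(got, global_hist_equalize(img))

    def test_output_range_and_dtype(self, rng):
        img = rng.integers(0, 256, size=(64, 64)).astype(np.uint8)
        out = clahe(img, ClaheParams())
        assert out.dtype == np.uint8  # implies range [0, 255]

    def test_tile_mappings_monotone(self, rng):
        # equalisation must never invert the grey-level order within a tile
        img = np.repeat(np.arange(0, 256, 4, dtype=np.uint8)[None, :], 64, axis=0)
        out = clahe(img, ClaheParams(grid_size=(1, 1), clip_limit=3.0))
        assert np.all(np.diff(out[0].astype(int)) >= 0)

    def test_image_smaller_than_grid_raises(self):
        with pytest.raises(ValueError):
            clahe(np.zeros((4, 4), dtype=np.uint8), ClaheParams(grid_size=(8, 8)))


class TestRegister:
    def _scan_with_line(self, depth=496, width=512, r_left=200, r_right=240):
        img = np.zeros((depth, width), dtype=np.uint8)
        cols = np.arange(width)
        line = np.round(r_left + (r_right - r_left) * cols / (width - 1)).astype(int)
        img[line, cols] = 255
        return img, line

    def test_endpoints_land_on_anchor_row(self):
        img, line = self._scan_with_line()
        out, _, params = register(img, None, (0, 200), (511, 240))
        anchor = round(0.65 * 496)
        assert anchor == 322
        # the bright line is flat on the anchor row after registration
        rows = np.argmax(out, axis=0)
        assert abs(rows[0] - anchor) <= 1 and abs(rows[-1] - anchor) <= 1
        assert np.all(np.abs(rows[5:-5] - anchor) <= 1)

    def test_level_endpoints_at_anchor_is_identity(self, rng):
        depth = 496
        anchor = round(0.65 * depth)
        img = rng.integers(0, 255, size=(depth, 64)).astype(np.uint8)
        out, _, params = register(img, None, (0, anchor), (63, anchor))
        assert params.shear_per_column == 0 and params.vertical_shift == 0
        assert np.array_equal(out, img)

    def test_mask_area_preserved_within_two_percent(self):
        depth, width = 200, 200
        img = np.zeros((depth, width), dtype=np.uint8)
        mask = np.zeros((depth, width), dtype=np.uint8)
        mask[80:100, 60:140] = 3  # blob away from borders
        out_img, out_mask, _ = register(img, mask, (0, 90), (199, 110),
                                        anchor_fraction=0.5)
        before = int((mask == 3).sum())
        after = int((out_mask == 3).sum())
        assert abs(after - before) / before < 0.02

    def test_same_column_endpoints_raise(self):
        img = np.zeros((10, 10), dtype=np.uint8)
        with pytest.raises(ValueError):
            register(img, None, (3, 2), (3, 8))


class TestResizeAndAugment:
    def test_mask_value_set_preserved(self, rng):
        mask = rng.integers(0, 4, size=(496, 512)).astype(np.uint8)
        out = resize(mask, 224, is_mask=True)
        assert out.shape == (224, 224)
        assert set(np.unique(out)) <= {0, 1, 2, 3}

    def test_same_size_is_identity(self, rng):
        img = rng.integers(0, 255, size=(64, 64)).astype(np.uint8)
        assert np.array_equal(resize(img, 64), img)

    def test_constant_image_stays_constant(self):
        img = np.full((96, 80), 17, dtype=np.uint8)
        assert np.all(resize(img, 32) == 17)

    def test_probability_zero_is_identity(self, rng):
        img = rng.integers(0, 255, size=(32, 32)).astype(np.uint8)
        mask = rng.integers(0, 4, size=(32, 32)).astype(np.uint8)
        out_i, out_m = augment_rotation(img, mask, rng, probability=0.0)
        assert np.array_equal(out_i, img) and np.array_equal(out_m, mask)

    def test_fixed_seed_reproducible_angle(self):
        img = np.zeros((16, 16), dtype=np.uint8)
        img[8, :] = 200
        mask = (img > 0).astype(np.uint8)
        a = augment_rotation(img, mask, np.random.default_rng(3), probability=1.0)
        b = augment_rotation(img, mask, np.random.default_rng(3), probability=1.0)
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])

    def test_application_rate_is_binomial(self):
        # count how often the coin fires over 10k draws at p = 0.5
        rng = np.random.default_rng(11)
        img = np.zeros((2, 2), dtype=np.uint8)
        img[0, 0] = 255
        mask = np.zeros((2, 2), dtype=np.uint8)
        applied = 0
        for _ in range(10_000):
            out, _ = augment_rotation(img, mask, rng, probability=0.5)
            applied += not np.array_equal(out, img)
        assert 4850 <= applied <= 5150


class TestOverlayLabels:
    def test_disjoint_union(self):
        irf = np.zeros((4, 4)); irf[0, 0] = 1
        srf = np.zeros((4, 4)); srf[1, 1] = 1
        ped = np.zeros((4, 4)); ped[2, 2] = 1
        out = overlay_labels(irf, srf, ped)
        assert out[0, 0] == 1 and out[1, 1] == 2 and out[2, 2] == 3
        assert out.sum() == 6

    def test_overlap_takes_highest_class(self):
        irf = np.ones((2, 2))
        ped = np.ones((2, 2))
        out = overlay_labels(irf, np.zeros((2, 2)), ped)
        assert np.all(out == 3)

    def test_all_empty_gives_zero(self):
        z = np.zeros((3, 3))
        assert not overlay_labels(z, z, z).any()

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError):
            overlay_labels(np.zeros((2, 2)), np.zeros((3, 3)), np.zeros((2, 2)))
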