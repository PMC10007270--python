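"""Feature descriptors: worked toy examples, brute-force oracles, invariants."""

import warnings

import numpy as np
import pytest

from seedage.descriptors import (
    BLOCK_INDEX,
    FEATURE_LENGTH,
    color_structure,
    column_layout,
    cooccurrence_stats,
    edge_histogram,
    extract_all,
    feature_column_names,
    glcm_features,
    load_features_csv,
    region_shape,
    rgb_means,
    save_features_csv,
)
from seedage.imagedata import SeedCrop, crop_seed, generate_seed_image

LUMA = np.array([0.299, 0.587, 0.114])


def solid_crop(color, h=20, w=20):
    img = np.zeros((h, w, 3), dtype=np.uint8)
    img[:] = color
    mask = np.ones((h, w), dtype=bool)
    return SeedCrop(img, mask)


# ---------------------------------------------------------------------------
# color structure
# ---------------------------------------------------------------------------

def brute_force_color_structure(crop):
    """Direct window enumeration oracle (mirrors the bin definition only)."""
    from skimage.color import rgb2hsv

    hsv = rgb2hsv(crop.image)
    h = np.minimum((hsv[..., 0] * 8).astype(int), 7)
    s = (hsv[..., 1] >= 0.5).astype(int)
    v = (hsv[..., 2] >= 0.5).astype(int)
    bins = h * 4 + s * 2 + v
    H, W = bins.shape
    counts = np.zeros(32)
    for r in range(H - 7):
        for c in range(W - 7):
            wb = bins[r:r + 8, c:c + 8]
            wm = crop.mask[r:r + 8, c:c + 8]
            if not wm.any():
                continue
            for b in set(wb[wm].ravel()):
                counts[b] += 1
    return counts / counts.sum() if counts.sum() else counts


class TestColorStructure:
    def test_uniform_seed_single_bin(self):
        hist = color_structure(solid_crop((100, 150, 200)))
        assert np.count_nonzero(hist) == 1
        assert hist.max() == pytest.approx(1.0)

    def test_two_color_seed_matches_window_enumeration(self):
        img = np.zeros((16, 16, 3), dtype=np.uint8)
        img[:, :8] = (200, 40, 40)   # red halves
        img[:, 8:] = (40, 40, 200)   # blue halves
        crop = SeedCrop(img, np.ones((16, 16), dtype=bool))
        hist = color_structure(crop)
        oracle = brute_force_color_structure(crop)
        assert np.allclose(hist, oracle)
        assert 0 < hist[hist > 0].min() and hist.max() < 1.0

    def test_background_pixels_ignored(self):
        img = np.zeros((16, 16, 3), dtype=np.uint8)
        img[:] = (200, 40, 40)
        mask = np.zeros((16, 16), dtype=bool)
        mask[4:12, 4:12] = True
        img[~mask] = (40, 200, 40)  # background color must not appear
        hist = color_structure(SeedCrop(img, mask))
        oracle = brute_force_color_structure(SeedCrop(img, mask))
        assert np.allclose(hist, oracle)
        assert np.count_nonzero(hist) == 1

    def test_small_crop_padded_with_warning(self):
        img = np.full((6, 6, 3), 120, dtype=np.uint8)
        mask = np.ones((6, 6), dtype=bool)
        mask[5, 5] = False
        with pytest.warns(UserWarning, match="padding"):
            hist = color_structure(SeedCrop(img, mask))
        assert hist.sum() == pytest.approx(1.0)


# ---------------------------------------------------------------------------
# edge histogram
# ---------------------------------------------------------------------------

class TestEdgeHistogram:
    def test_constant_crop_all_zero(self):
        assert np.all(edge_histogram(solid_crop((90, 90, 90))) == 0.0)

    def test_vertical_step_lands_in_vertical_bins(self):
        # step between columns 8 and 9: only 2x2 blocks straddling it count
        img = np.zeros((16, 16, 3), dtype=np.uint8)
        img[:, 9:] = 200
        crop = SeedCrop(img, np.ones((16, 16), dtype=bool))
        hist = edge_histogram(crop).reshape(16, 5)
        vertical = hist[:, 0]
        assert hist.sum() == pytest.approx(1.0)
        assert vertical.sum() == pytest.approx(1.0)
        # the step sits in sub-image grid column 2 (cols 8-11) of every row
        expected_subimages = {0 * 4 + 2, 1 * 4 + 2, 2 * 4 + 2, 3 * 4 + 2}
        assert set(np.flatnonzero(vertical)) == expected_subimages
        assert np.allclose(vertical[sorted(expected_subimages)], 0.25)

    def test_normalization_when_edges_present(self, crop):
        hist = edge_histogram(crop)
        assert hist.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all((0 <= hist) & (hist <= 1))


# ---------------------------------------------------------------------------
# region shape (ART)
# ---------------------------------------------------------------------------

def brute_force_art(mask):
    """Independent pixel-sum evaluation of the ART basis (plain loops)."""
    ys, xs = np.nonzero(mask)
    cy, cx = ys.mean(), xs.mean()
    pts = [(y - cy, x - cx) for y, x in zip(ys, xs)]
    rmax = max(np.hypot(dy, dx) for dy, dx in pts)
    out = []
    for n in range(3):
        for m in range(12):
            total = 0j
            for dy, dx in pts:
                rho = np.hypot(dy, dx) / rmax
                theta = np.arctan2(dy, dx)
                radial = 1.0 if n == 0 else 2.0 * np.cos(np.pi * n * rho)
                total += radial * np.exp(-1j * m * theta) / (2 * np.pi)
            out.append(abs(total))
    out = np.array(out) / out[0]
    return np.delete(out, 0)


def ellipse_mask(h, w, ry, rx):
    yy, xx = np.mgrid[:h, :w]
    return ((yy - h / 2 + 0.5) / ry) ** 2 + ((xx - w / 2 + 0.5) / rx) ** 2 <= 1.0


class TestRegionShape:
    def test_disk_kills_angular_terms(self):
        # large radius so lattice discretization sits below the bound
        mask = ellipse_mask(505, 505, 250, 250)
        desc = region_shape(mask)
        # entries for m != 0: positions 0..10 (n=0), 12..22, 24..34
        m_nonzero = np.r_[desc[0:11], desc[12:23], desc[24:35]]
        assert np.all(m_nonzero < 1e-3)

    def test_matches_brute_force_on_ellipse(self):
        mask = ellipse_mask(33, 17, 15, 7)
        assert np.allclose(region_shape(mask), brute_force_art(mask), atol=1e-6)

    @pytest.mark.parametrize("angle", [37, 90, 142])
    def test_rotation_invariance(self, angle):
        from skimage.transform import rotate

        # anti-aliased rotation of a decently sized ellipse: magnitudes
        # agree within 2% (of the DC-normalized unit scale)
        mask = np.pad(ellipse_mask(121, 61, 57, 27), 40)
        rotated = rotate(mask.astype(float), angle, order=1) > 0.5
        a, b = region_shape(mask), region_shape(rotated)
        assert np.allclose(a, b, rtol=0.02, atol=0.02)

    def test_translation_invariance(self):
        mask = np.pad(ellipse_mask(33, 17, 15, 7), ((3, 21), (25, 2)))
        shifted = np.roll(mask, (9, -13), axis=(0, 1))
        assert np.allclose(region_shape(mask), region_shape(shifted), atol=1e-12)

    def test_degenerate_mask_rejected(self):
        mask = np.zeros((20, 20), dtype=bool)
        mask[3, 3:9] = True  # 6 pixels
        with pytest.raises(ValueError, match="degenerate-shape"):
            region_shape(mask)


# ---------------------------------------------------------------------------
# GLCM
# ---------------------------------------------------------------------------

def brute_force_glcm(gray, mask, levels):
    """Pair enumeration in plain Python loops."""
    vals = gray[mask]
    vmin, vmax = vals.min(), vals.max()
    H, W = gray.shape
    q = {}
    for r in range(H):
        for c in range(W):
            if mask[r, c]:
                if vmax == vmin:
                    q[(r, c)] = 0
                else:
                    q[(r, c)] = min(
                        int(levels * (gray[r, c] - vmin) / (vmax - vmin)),
                        levels - 1,
                    )
    P = np.zeros((levels, levels))
    for r in range(H):
        for c in range(W - 1):
            if (r, c) in q and (r, c + 1) in q:
                P[q[(r, c)], q[(r, c + 1)]] += 1
                P[q[(r, c + 1)], q[(r, c)]] += 1
    P /= P.sum()
    i, j = np.meshgrid(range(levels), range(levels), indexing="ij")
    d = i - j
    pi = P.sum(axis=1)
    mu = (np.arange(levels) * pi).sum()
    var = ((np.arange(levels) - mu) ** 2 * pi).sum()
    corr = float((P * (i - mu) * (j - mu)).sum() / var) if var > 0 else 0.0
    return np.array([
        (P * d**2).sum(), (P * abs(d)).sum(), (P / (1 + d**2)).sum(),
        (P**2).sum(), corr, (P**2).sum(),
    ])


class TestGLCM:
    def test_two_pair_hand_example(self):
        g = cooccurrence_stats(np.array([[0.0, 0.0], [1.0, 1.0]]),
                               np.ones((2, 2), dtype=bool), levels=2)
        assert g.contrast == pytest.approx(0.0)
        assert g.homogeneity == pytest.approx(1.0)
        assert g.energy == pytest.approx(0.5)
        assert g.angular_second_moment == pytest.approx(0.5)

    def test_constant_image(self):
        g = cooccurrence_stats(np.full((3, 3), 7.0),
                               np.ones((3, 3), dtype=bool), levels=4)
        assert g.contrast == 0.0
        assert g.energy == pytest.approx(1.0)
        assert g.homogeneity == pytest.approx(1.0)
        assert g.correlation == 0.0  # zero marginal variance

    def test_checkerboard(self):
        gray = np.indices((4, 4)).sum(axis=0) % 2
        g = cooccurrence_stats(gray.astype(float),
                               np.ones((4, 4), dtype=bool), levels=2)
        assert g.contrast == pytest.approx(1.0)
        assert g.energy == pytest.approx(0.5)

    def test_matches_brute_force_on_small_images(self, rng):
        """Exhaustive small-instance equivalence: sizes <= 6x6, levels <= 4."""
        for h in range(2, 7):
            for w in range(2, 7):
                for levels in (2, 3, 4):
                    for _ in range(3):
                        gray = rng.integers(0, 256, (h, w)).astype(float)
                        mask = rng.random((h, w)) < 0.8
                        left_right = mask[:, :-1] & mask[:, 1:]
                        if left_right.sum() < 2:
                            continue
                        got = cooccurrence_stats(gray, mask, levels).as_array()
                        want = brute_force_glcm(gray, mask, levels)
                        assert np.allclose(got, want, atol=1e-12)

    def test_too_few_pairs_rejected(self):
        mask = np.zeros((3, 3), dtype=bool)
        mask[0, 0] = mask[0, 1] = True  # a single co-occurring pair
        with pytest.raises(ValueError, match="fewer than 2"):
            cooccurrence_stats(np.ones((3, 3)), mask, levels=2)


# ---------------------------------------------------------------------------
# simple statistics
# ---------------------------------------------------------------------------

class TestRGBMeans:
    def test_uniform_color(self):
        assert np.allclose(rgb_means(solid_crop((100, 150, 200))), [100, 150, 200])

    def test_arithmetic_mean_over_foreground(self):
        img = np.zeros((4, 8, 3), dtype=np.uint8)
        img[:, 4:] = (200, 0, 0)
        crop = SeedCrop(img, np.ones((4, 8), dtype=bool))
        assert np.allclose(rgb_means(crop), [100, 0, 0])

    def test_background_change_has_no_effect(self):
        img = np.full((8, 8, 3), 120, dtype=np.uint8)
        mask = np.zeros((8, 8), dtype=bool)
        mask[2:6, 2:6] = True
        a = rgb_means(SeedCrop(img.copy(), mask))
        img[0] = 255
        b = rgb_means(SeedCrop(img, mask))
        assert np.array_equal(a, b)


class TestColumnLayout:
    def test_uniform_seed_equal_thirds(self):
        out = column_layout(solid_crop((90, 90, 90)))
        assert out[0] == pytest.approx(out[1]) == pytest.approx(out[2])

    def test_darker_left_third(self):
        img = np.full((9, 9, 3), 150, dtype=np.uint8)
        img[:, :3] = 100  # 50 luminance units darker
        crop = SeedCrop(img, np.ones((9, 9), dtype=bool))
        out = column_layout(crop)
        assert out[0] == pytest.approx(out[1] - 50, abs=0.5)

    def test_width_four_floor_rule(self):
        # thirds of widths 1, 1, 2
        img = np.zeros((16, 4, 3), dtype=np.uint8)
        img[:, 0] = 10
        img[:, 1] = 20
        img[:, 2:] = 30
        crop = SeedCrop(img, np.ones((16, 4), dtype=bool))
        lum = np.array([10, 20, 30]) @ LUMA * np.array([1, 1, 1])
        out = column_layout(crop)
        assert out[0] == pytest.approx(10 * LUMA.sum(), abs=0.01)
        assert out[1] == pytest.approx(20 * LUMA.sum(), abs=0.01)
        assert out[2] == pytest.approx(30 * LUMA.sum(), abs=0.01)

    def test_empty_third_contributes_zero(self):
        img = np.full((9, 9, 3), 150, dtype=np.uint8)
        mask = np.zeros((9, 9), dtype=bool)
        mask[:, 4:] = True  # left third has no foreground
        out = column_layout(SeedCrop(img, mask))
        assert out[0] == 0.0 and out[1] > 0


# ---------------------------------------------------------------------------
# full vector
# ---------------------------------------------------------------------------

class TestExtractAll:
    def test_length_and_block_layout(self, crop):
        fv = extract_all(crop)
        assert fv.values.shape == (FEATURE_LENGTH,)
        assert sum(length for _, length in BLOCK_INDEX.values()) == FEATURE_LENGTH
        offsets = [off for off, _ in BLOCK_INDEX.values()]
        assert offsets == sorted(offsets)

    def test_deterministic(self, crop):
        assert np.array_equal(extract_all(crop).values, extract_all(crop).values)

    def test_half_turn_preserves_region_shape_block(self, crop):
        rotated = SeedCrop(np.rot90(crop.image, 2).copy(),
                           np.rot90(crop.mask, 2).copy())
        a = extract_all(crop).block("region_shape")
        b = extract_all(rotated).block("region_shape")
        assert np.allclose(a, b, rtol=0.02, atol=0.01)

    def test_never_nan_on_generator_output(self, default_spec):
        """All-finite feature vectors across 500 random synthetic crops."""
        classes = [
            (v, y) for v in default_spec.seed_length
            for y in (2012, 2016, 2020)
            if (v, y) in default_spec.counts
        ]
        for k in range(500):
            variety, year = classes[k % len(classes)]
            img, mask = generate_seed_image(default_spec, variety, year, 9000 + k)
            fv = extract_all(crop_seed(img, mask))
            assert np.all(np.isfinite(fv.values))
            cs = fv.block("color_structure")
            eh = fv.block("edge_histogram")
            assert cs.sum() == pytest.approx(1.0)
            assert eh.sum() == pytest.approx(1.0) or np.all(eh == 0)


def test_features_csv_round_trip_is_bit_exact(tmp_path, crop):
    import pandas as pd

    fv = extract_all(crop)
    table = pd.DataFrame([fv.values], columns=feature_column_names())
    table.insert(0, "sample_id", ["s0"])
    table["variety"] = "Koshihikari"
    table["harvest_year"] = 2016
    table["split"] = "train"
    save_features_csv(table, tmp_path / "f.csv")
    loaded = load_features_csv(tmp_path / "f.csv")
    assert np.array_equal(
        loaded[feature_column_names()].to_numpy()[0], fv.values
    )
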