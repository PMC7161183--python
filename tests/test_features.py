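import numpy as np
import pytest

from fundusma.candidates import CandidatePatch, CandidateRegion, regions_from_mask
from fundusma.features import (FEATURE_NAMES, color_stats, dlc, extract_all,
                               gaussian_bank_features, glcm_matrix,
                               gradient_features, grayscale_stats,
                               quantize_levels, shape_features, texture_features)
from fundusma.preprocess import PreprocessedPlanes
from tests.conftest import disk_mask


def _patch_from_window(window, region=None, rgb=None):
    if region is None:
        px = np.array([[12, 12]])
        region = CandidateRegion(pixels=px, centroid=(12.0, 12.0), area=1,
                                 perimeter=1.0, major_axis=1.0, minor_axis=1.0,
                                 axis_ratio=1.0, boundary_pixels=px)
    if rgb is None:
        rgb = np.stack([window] * 3, axis=2)
    return CandidatePatch(region=region, window=window, window_rgb=rgb,
                          window_green=window, center=(12, 12))


def _planes_for(window):
    fov = np.ones_like(window, dtype=bool)
    return PreprocessedPlanes(i_sc=window, i_clahe=window, i_gauss=window,
                              mean_green=float(window.mean()), fov=fov, green=window)


class TestDlc:
    def test_uniform_window_gives_all_zero(self):
        v = dlc(np.full((25, 25), 0.6))
        assert v.dlc.shape == (12,)
        assert np.allclose(v.dlc, 0.0)

    def test_dark_center_hand_value(self):
        w = np.full((25, 25), 100 / 255)
        w[12, 12] = 50 / 255
        v = dlc(w)
        assert np.allclose(v.dlc, (50 - 100) / 100)

    def test_twelve_angles_at_30_degree_steps(self):
        v = dlc(np.random.default_rng(0).uniform(0.2, 0.8, (25, 25)))
        assert len(v.dlc) == 12

    def test_lower_bound_for_nonnegative_intensities(self, rng):
        w = rng.uniform(0.0, 1.0, (25, 25))
        v = dlc(w)
        assert np.all(v.dlc >= -1.0)

    def test_matches_brute_force_ray_sampling(self, rng):
        w = rng.uniform(0.1, 0.9, (25, 25))
        v = dlc(w, radius=12, n_angles=12)
        for a in range(12):
            theta = 2 * np.pi * a / 12
            samples = []
            for k in range(1, 13):
                x = int(np.rint(12 + k * np.cos(theta)))
                y = int(np.rint(12 + k * np.sin(theta)))
                samples.append(w[y, x])
            mean_i = np.mean(samples)
            assert v.dlc[a] == pytest.approx((w[12, 12] - mean_i) / mean_i, abs=1e-12)

    def test_zero_denominator_guarded(self):
        w = np.zeros((25, 25))
        w[12, 12] = 0.5
        v = dlc(w)
        assert np.all(np.isfinite(v.dlc))

    def test_radius_larger_than_window_rejected(self):
        with pytest.raises(ValueError):
            dlc(np.zeros((25, 25)), radius=13)


class TestColorAndGray:
    def test_gray_patch_rgb_stats(self):
        rgb = np.full((25, 25, 3), 0.5)
        f = color_stats(rgb)
        assert f[0] == pytest.approx(0.5)
        assert f[1] == pytest.approx(0.0)

    def test_pure_red_hsv_pooled_mean(self):
        rgb = np.zeros((25, 25, 3))
        rgb[:, :, 0] = 1.0
        f = color_stats(rgb)
        assert f[2] == pytest.approx(2 / 3)      # mean of (H=0, S=1, V=1)

    def test_two_tone_pooled_std_matches_brute_force(self, rng):
        rgb = rng.choice([0.2, 0.8], size=(25, 25, 3))
        f = color_stats(rgb)
        assert f[1] == pytest.approx(np.std(rgb.reshape(-1)), abs=1e-12)

    def test_grayscale_stats_constant_and_impulse(self):
        const = np.full((25, 25), 0.3)
        impulse = np.zeros((25, 25))
        impulse[0, 0] = 1.0
        f = grayscale_stats(const, impulse)
        assert f[1] == 0.0
        assert f[2] == pytest.approx(1 / 625)

    def test_grayscale_stats_match_brute_force(self, rng):
        a = rng.uniform(size=(25, 25))
        b = rng.uniform(size=(25, 25))
        f = grayscale_stats(a, b)
        assert f[0] == pytest.approx(a.mean()) and f[1] == pytest.approx(a.std())
        assert f[2] == pytest.approx(b.mean()) and f[3] == pytest.approx(b.std())


class TestShapeFeatures:
    def test_disk_limits(self):
        reg = regions_from_mask(disk_mask((40, 40), (20, 20), 8))[0]
        area, perim, circ, ecc, aspect, solidity = shape_features(reg)
        assert area == reg.area
        assert 0.85 <= circ <= 1.25
        assert ecc < 0.1
        assert solidity > 0.95

    def test_rectangle_aspect_and_solidity(self):
        mask = np.zeros((40, 40), dtype=bool)
        mask[10:15, 5:25] = True
        reg = regions_from_mask(mask)[0]
        _, _, _, _, aspect, solidity = shape_features(reg)
        assert aspect == pytest.approx(4.0, rel=0.10)
        assert solidity == pytest.approx(1.0, abs=1e-9)

    def test_l_shape_solidity_matches_hull_rasterization(self):
        mask = np.zeros((30, 30), dtype=bool)
        mask[5:25, 5:10] = True
        mask[20:25, 5:25] = True
        reg = regions_from_mask(mask)[0]
        solidity = shape_features(reg)[5]
        # brute-force oracle: hull of pixel centers, rasterized by testing
        # every pixel center against all hull half-planes
        from scipy.spatial import ConvexHull
        pts = np.argwhere(mask).astype(float)
        hull = ConvexHull(pts)
        yy, xx = np.mgrid[:30, :30]
        centers = np.column_stack([yy.ravel(), xx.ravel(), np.ones(900)])
        inside = np.all(centers @ hull.equations.T <= 1e-9, axis=1)
        assert solidity == pytest.approx(reg.area / inside.sum(), abs=1e-9)
        assert solidity < 0.8

    def test_eccentricity_bounds(self):
        mask = np.zeros((40, 40), dtype=bool)
        mask[10:14, 5:35] = True
        reg = regions_from_mask(mask)[0]
        ecc = shape_features(reg)[3]
        assert 0.0 <= ecc < 1.0

    def test_single_pixel_region_finite(self):
        mask = np.zeros((10, 10), dtype=bool)
        mask[5, 5] = True
        reg = regions_from_mask(mask)[0]
        f = shape_features(reg)
        assert np.all(np.isfinite(f))
        assert f[0] == 1


class TestTextureFeatures:
    def test_constant_window_limits(self):
        f = texture_features(np.full((25, 25), 0.5))
        entropy, energy, homogeneity, skewness = f
        assert entropy == 0.0
        assert energy == pytest.approx(1.0)
        assert homogeneity == pytest.approx(1.0)
        assert skewness == 0.0

    def test_checkerboard_glcm_by_hand(self):
        board = np.indices((24, 24)).sum(axis=0) % 2 * 0.99
        q = quantize_levels(board)
        assert set(np.unique(q)) == {0, 7}
        glcm = glcm_matrix(q)
        # horizontal/vertical neighbors always differ (levels 0 vs 7) while
        # diagonal neighbors are always equal, so after averaging the four
        # normalized orientation matrices exactly half the mass is diagonal
        i, j = np.indices(glcm.shape)
        offdiag = glcm[i != j].sum()
        assert offdiag == pytest.approx(0.5, abs=1e-12)
        homogeneity = float((glcm / (1 + np.abs(i - j))).sum())
        # 0.5 on the diagonal (weight 1) + 0.5 at |i-j| = 7 (weight 1/8)
        assert homogeneity == pytest.approx(0.5 + 0.5 / 8, abs=1e-12)

    def test_entropy_and_skewness_match_brute_force(self, rng):
        w = rng.uniform(0, 1, size=(25, 25))
        entropy, _, _, skewness = texture_features(w)
        q = quantize_levels(w)
        counts = np.bincount(q.ravel(), minlength=8) / q.size
        exp_entropy = -sum(p * np.log2(p) for p in counts if p > 0)
        assert entropy == pytest.approx(exp_entropy, abs=1e-12)
        x = w.ravel()
        exp_skew = np.mean((x - x.mean()) ** 3) / x.std() ** 3
        assert skewness == pytest.approx(exp_skew, abs=1e-12)

    def test_glcm_energy_matches_brute_force_pairs(self, rng):
        w = rng.uniform(0, 1, size=(10, 10))
        q = quantize_levels(w)
        # brute-force symmetric co-occurrence counts, distance 1, 4 angles
        offsets = [(0, 1), (-1, 1), (-1, 0), (-1, -1)]
        mats = []
        for dr, dc in offsets:
            m = np.zeros((8, 8))
            for r in range(10):
                for c in range(10):
                    r2, c2 = r + dr, c + dc
                    if 0 <= r2 < 10 and 0 <= c2 < 10:
                        m[q[r, c], q[r2, c2]] += 1
                        m[q[r2, c2], q[r, c]] += 1
            mats.append(m / m.sum())
        expected = np.mean(mats, axis=0)
        assert np.allclose(glcm_matrix(q), expected, atol=1e-12)


class TestGaussianBank:
    def test_constant_plane(self):
        plane = np.full((64, 64), 0.4)
        f = gaussian_bank_features(plane, (32, 32))
        assert np.allclose(f[0::2], 0.4)
        assert np.allclose(f[1::2], 0.0)

    def test_four_sigmas_give_eight_values(self, rng):
        f = gaussian_bank_features(rng.uniform(size=(64, 64)), (32, 32))
        assert f.shape == (8,)

    def test_bright_dot_mean_decreases_with_sigma(self):
        plane = np.zeros((64, 64))
        plane[32, 32] = 1.0
        f = gaussian_bank_features(plane, (32, 32))
        means = f[0::2]
        # diffusion moves mass out of the window once sigma is comparable
        # to the window half-size; the means can never increase
        assert np.all(np.diff(means) <= 1e-15)
        assert means[-1] < means[0]


class TestGradientFeatures:
    def test_constant_window_all_zero(self):
        px = np.array([[12, 12]])
        reg = CandidateRegion(pixels=px, centroid=(12.0, 12.0), area=1,
                              perimeter=1.0, major_axis=1.0, minor_axis=1.0,
                              axis_ratio=1.0, boundary_pixels=px)
        f = gradient_features(np.full((25, 25), 0.5), reg)
        assert np.allclose(f, 0.0)

    def test_linear_ramp(self):
        px = np.array([[12, 12]])
        reg = CandidateRegion(pixels=px, centroid=(12.0, 12.0), area=1,
                              perimeter=1.0, major_axis=1.0, minor_axis=1.0,
                              axis_ratio=1.0, boundary_pixels=px)
        xx = np.arange(25, dtype=float)[None, :].repeat(25, axis=0)
        f = gradient_features(0.01 * xx, reg)
        assert f[0] == pytest.approx(0.01, abs=1e-12)
        assert f[1] == pytest.approx(0.0, abs=1e-12)

    def test_dark_dot_boundary_gradient_exceeds_center(self):
        yy, xx = np.mgrid[:25, :25]
        r2 = (yy - 12.0) ** 2 + (xx - 12.0) ** 2
        window = 0.8 - 0.5 * np.exp(-r2 / (2 * 2.5 ** 2))
        mask = r2 <= 16
        reg = regions_from_mask(mask)[0]
        dy, dx = np.gradient(window)
        gmag = np.hypot(dx, dy)
        boundary_mag = gmag[reg.boundary_pixels[:, 0], reg.boundary_pixels[:, 1]].mean()
        assert boundary_mag > gmag[12, 12] + 0.01


class TestExtractAll:
    def test_vector_has_44_named_features(self, rng):
        w = rng.uniform(0.1, 0.9, size=(25, 25))
        patch = _patch_from_window(w)
        fv = extract_all(patch, _planes_for(w))
        assert fv.values.shape == (44,)
        assert len(FEATURE_NAMES) == 44
        assert np.all(np.isfinite(fv.values))

    def test_deterministic(self, rng):
        w = rng.uniform(0.1, 0.9, size=(25, 25))
        patch = _patch_from_window(w)
        a = extract_all(patch, _planes_for(w)).values
        b = extract_all(patch, _planes_for(w)).values
        assert np.array_equal(a, b)

    def test_dlc_block_sits_at_f11_to_f22(self, rng):
        w = rng.uniform(0.1, 0.9, size=(25, 25))
        patch = _patch_from_window(w)
        fv = extract_all(patch, _planes_for(w))
        assert np.allclose(fv.values[10:22], dlc(w).dlc)


class TestDlcClassSeparation:
    def test_anova_rejects_and_ma_most_negative(self, small_scene, small_planes, rng):
        """Mean DLC separates MA / hemorrhage / vessel / background patches."""
        from scipy import stats
        from fundusma.synthetic import sample_class_patches

        img, truth = small_scene
        groups = sample_class_patches(img, truth, small_planes.i_clahe, rng,
                                      n_vessel=20, n_background=20)
        means = {cls: [float(dlc(w).dlc.mean()) for w in ws]
                 for cls, ws in groups.items() if ws}
        assert set(means) >= {"ma", "vessel", "background"}
        f_stat, p = stats.f_oneway(*means.values())
        assert p < 0.05
        assert np.mean(means["ma"]) < np.mean(means["background"])
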