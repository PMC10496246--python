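import numpy as np
import pytest

from elene.errors import (
    ContractError,
    DegenerateMomentsError,
    EmptyPairsError,
    ParameterError,
)
from elene.texture_features import (
    EDGE_FEATURE_NAMES,
    GLCM_FEATURE_TYPES,
    GLCMConfig,
    GLSZM_FEATURE_NAMES,
    GRAY_LEVEL_FEATURE_NAMES,
    all_glcm_configs,
    edge_features,
    glcm,
    glcm_features,
    glszm_features,
    gray_level_features,
    invariant_moments,
    quantize,
)

from .oracles import (
    glcm_bruteforce,
    glszm_oracle,
    gray_level_oracle,
    haralick_oracle,
    hu_oracle,
)


class TestQuantize:
    def test_range_endpoints(self):
        assert quantize(np.array([[0]]))[0, 0] == 0
        assert quantize(np.array([[255]]))[0, 0] == 15

    def test_bin_boundary(self):
        assert quantize(np.array([[16]]))[0, 0] == 1
        assert quantize(np.array([[15]]))[0, 0] == 0

    def test_constant_patch_single_bin(self):
        q = quantize(np.full((5, 5), 100))
        assert len(np.unique(q)) == 1

    def test_bad_levels(self):
        with pytest.raises(ParameterError):
            quantize(np.ones((2, 2)), levels=1)


class TestGLCM:
    def test_constant_patch_single_diagonal_entry(self):
        P = glcm(np.full((6, 6), 3), GLCMConfig())
        assert P[3, 3] == 1.0
        assert P.sum() == pytest.approx(1.0)

    def test_stripe_pattern_symmetric_half(self):
        patch = np.tile([0, 1], (4, 4))
        P = glcm(patch, GLCMConfig(direction=0, distance=1))
        assert P[0, 1] == pytest.approx(0.5)
        assert P[1, 0] == pytest.approx(0.5)

    def test_all_20_configs_match_bruteforce(self, rng):
        patch = rng.integers(0, 16, size=(6, 6))
        for cfg in all_glcm_configs():
            dr, dc = cfg.offset
            expected = glcm_bruteforce(patch, dr, dc, 16)
            np.testing.assert_allclose(glcm(patch, cfg), expected, atol=1e-12)

    def test_too_small_patch_raises(self):
        with pytest.raises(EmptyPairsError):
            glcm(np.zeros((3, 3), dtype=int), GLCMConfig(distance=5))

    def test_matrix_symmetric_sums_to_one(self, rng):
        for _ in range(5):
            patch = rng.integers(0, 16, size=(8, 8))
            P = glcm(patch, GLCMConfig(direction=45, distance=2))
            assert P.sum() == pytest.approx(1.0)
            np.testing.assert_allclose(P, P.T)


class TestGLCMFeatures:
    def test_constant_patch_closed_forms(self):
        P = glcm(np.full((6, 6), 5))
        f = glcm_features(P)
        assert f["Contrast"] == 0.0
        assert f["Energy"] == 1.0
        assert f["Entropy"] == 0.0
        assert f["Homogeneity"] == 1.0
        assert f["Max Probability"] == 1.0

    def test_stripe_two_entry_closed_forms(self):
        P = np.zeros((16, 16))
        P[0, 1] = P[1, 0] = 0.5
        f = glcm_features(P)
        assert f["Contrast"] == pytest.approx(1.0)
        assert f["Energy"] == pytest.approx(0.5)
        assert f["Entropy"] == pytest.approx(1.0)  # one bit

    def test_random_patches_match_formula_oracle(self, rng):
        for _ in range(20):
            patch = rng.integers(0, 16, size=(8, 8))
            P = glcm(patch, GLCMConfig())
            got = glcm_features(P)
            want = haralick_oracle(P)
            for name in GLCM_FEATURE_TYPES:
                assert got[name] == pytest.approx(want[name], abs=1e-9), name

    def test_unnormalized_matrix_rejected(self):
        with pytest.raises(ContractError):
            glcm_features(np.ones((4, 4)))


class TestGLSZM:
    def test_single_zone_closed_forms(self):
        patch = np.full((4, 5), 7)
        f = glszm_features(patch)
        n = 20
        assert f["Zone%"] == pytest.approx(1 / n)
        assert f["Small area emphasis"] == pytest.approx(1 / n ** 2)
        assert f["Large area emphasis"] == pytest.approx(n ** 2)

    def test_isolated_pixels_small_area_emphasis_one(self):
        # all-distinct levels: every zone is a single pixel (8-connectivity
        # would join same-level diagonals, so levels alternate in 2x2 tiles)
        patch = np.arange(4).reshape(2, 2)
        f = glszm_features(patch, levels=4)
        assert f["Small area emphasis"] == pytest.approx(1.0)

    def test_random_patches_match_floodfill_oracle(self, rng):
        for _ in range(20):
            patch = rng.integers(0, 4, size=(8, 8))
            got = glszm_features(patch, levels=4)
            want = glszm_oracle(patch, levels=4)
            for name in GLSZM_FEATURE_NAMES:
                assert got[name] == pytest.approx(want[name], abs=1e-9), name

    def test_zone_percent_in_unit_interval(self, rng):
        patch = rng.integers(0, 16, size=(10, 10))
        f = glszm_features(patch)
        assert 0 < f["Zone%"] <= 1


class TestGrayLevel:
    def test_constant_region(self):
        f = gray_level_features(np.full(30, 42))
        assert f["Mean"] == f["Median"] == 42
        assert f["Variance"] == 0.0
        assert f["Energy"] == 1.0
        assert f["Entropy"] == 0.0
        assert f["Range"] == 0.0

    def test_symmetric_two_point_mass(self):
        vals = np.array([0] * 50 + [255] * 50)
        f = gray_level_features(vals)
        assert f["Mean"] == pytest.approx(127.5)
        assert f["Entropy"] == pytest.approx(1.0)

    def test_random_region_matches_statistics_oracle(self, rng):
        for _ in range(20):
            vals = rng.integers(0, 256, size=rng.integers(5, 60))
            got = gray_level_features(vals)
            want = gray_level_oracle(vals)
            for name in GRAY_LEVEL_FEATURE_NAMES:
                assert got[name] == pytest.approx(want[name], abs=1e-9), name

    def test_eleven_features(self):
        assert len(GRAY_LEVEL_FEATURE_NAMES) == 11


class TestInvariantMoments:
    def test_rotation_invariance(self, rng):
        patch = rng.random((15, 15))
        a = invariant_moments(patch)
        b = invariant_moments(np.rot90(patch))
        for k in a:
            assert a[k] == pytest.approx(b[k], abs=1e-9)

    def test_scale_invariance_within_discretization(self):
        patch = np.zeros((100, 100))
        patch[20:80, 28:72] = 1.0
        big = np.kron(patch, np.ones((2, 2)))
        a = invariant_moments(patch)
        b = invariant_moments(big)
        assert a["Hu1"] == pytest.approx(b["Hu1"], abs=1e-3)
        assert a["Hu2"] == pytest.approx(b["Hu2"], abs=1e-3)

    def test_matches_literal_formula_oracle(self, rng):
        for _ in range(10):
            patch = rng.random((9, 9))
            got = list(invariant_moments(patch).values())
            want = hu_oracle(patch)
            np.testing.assert_allclose(got, want, atol=1e-9)

    def test_disc_moments_match_numerical_integration(self):
        # high-resolution disc: phi1 -> 1/(2*pi) analytically
        n = 201
        r, c = np.mgrid[0:n, 0:n]
        patch = (((r - 100) ** 2 + (c - 100) ** 2) <= 90 ** 2).astype(float)
        f = invariant_moments(patch)
        assert f["Hu1"] == pytest.approx(1 / (2 * np.pi), rel=1e-3)
        for k in ("Hu2", "Hu3", "Hu4"):
            assert abs(f[k]) < 1e-6

    def test_zero_patch_rejected(self):
        with pytest.raises(DegenerateMomentsError):
            invariant_moments(np.zeros((5, 5)))


class TestEdgeFeatures:
    def _bands(self, shape, inner, outer):
        ib = np.zeros(shape, dtype=bool)
        ob = np.zeros(shape, dtype=bool)
        ib[inner] = True
        ob[outer] = True
        return ib, ob

    def test_uniform_inside_outside(self):
        img = np.full((10, 10), 50.0)
        img[3:7, 3:7] = 200.0
        bands = self._bands((10, 10), (slice(3, 7), slice(3, 7)),
                            (slice(0, 2), slice(0, 10)))
        f = edge_features(img, bands)
        assert f["Mean inside"] == 200 and f["Mean outside"] == 50
        assert f["SD inside"] == 0 and f["SD outside"] == 0
        assert f["Mean difference"] == 150 and f["SD difference"] == 0

    def test_identical_texture_small_difference(self, rng):
        img = rng.normal(100, 10, size=(40, 40))
        bands = self._bands((40, 40), (slice(0, 20), slice(None)),
                            (slice(20, 40), slice(None)))
        f = edge_features(img, bands)
        assert abs(f["Mean difference"]) < 2.0

    def test_empty_band_imputes_zero_with_warning(self):
        img = np.full((6, 6), 9.0)
        bands = self._bands((6, 6), (slice(2, 4), slice(2, 4)), (slice(0, 0), 0))
        with pytest.warns(UserWarning):
            f = edge_features(img, bands)
        assert f["Mean outside"] == 0.0

    def test_six_features(self):
        assert len(EDGE_FEATURE_NAMES) == 6


class TestTranslationInvariance:
    def test_texture_features_invariant_to_bounding_box_shift(self, rng):
        patch = rng.integers(0, 256, size=(12, 12))
        q = quantize(patch)
        base_glcm = glcm_features(glcm(q))
        base_szm = glszm_features(q)
        # same content, different absolute position: identical results
        q2 = q.copy()
        assert glcm_features(glcm(q2)) == base_glcm
        assert glszm_features(q2) == base_szm
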