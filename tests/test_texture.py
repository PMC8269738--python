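"""Filter bank, texture vocabulary, signatures and the chi-square score."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.ndimage import gaussian_filter
from scipy.spatial.distance import cdist

import eggshade as eg
from eggshade.errors import DataError, DomainError, ShapeError
from eggshade.texture import (TextureModel, assign_labels, chi_square_distance,
                              fit_texture_model, oriented_kernel,
                              region_signature)


class TestFilterBank:
    def test_cardinalities(self):
        bank = eg.build_filter_bank()
        assert len(bank) == 56
        assert all(n == 14 for n in bank.per_scale_counts().values())
        assert set(bank.per_scale_counts()) == {16.0, 32.0, 64.0, 128.0}

    def test_zero_sums_and_gaussian_normalization(self, small_bank):
        for k in small_bank.kernels:
            if k.kind in ("odd", "even", "log"):
                assert abs(k.array.sum()) <= 1e-10, k.kind
            else:
                assert k.array.sum() == pytest.approx(1.0, abs=1e-12)

    def test_orientations_evenly_spaced_over_half_turn(self, small_bank):
        thetas = sorted({k.orientation for k in small_bank.kernels
                         if k.orientation is not None})
        assert thetas == [0.0, 36.0, 72.0, 108.0, 144.0]

    def test_half_turn_rotation_symmetry(self):
        for theta in (0.0, 36.0, 72.0):
            odd = oriented_kernel(3.0, theta, "odd")
            odd_pi = oriented_kernel(3.0, theta + 180.0, "odd")
            assert np.allclose(odd_pi, -odd, atol=1e-12)
            even = oriented_kernel(3.0, theta, "even")
            even_pi = oriented_kernel(3.0, theta + 180.0, "even")
            assert np.allclose(even_pi, even, atol=1e-12)

    def test_invalid_scales_rejected(self):
        with pytest.raises(DomainError):
            eg.build_filter_bank(scales=(0.0,))


class TestApplyFilterBank:
    def test_three_channel_image_gives_168_responses(self, small_bank):
        img = np.random.default_rng(0).uniform(size=(64, 64, 3))
        stack = eg.apply_filter_bank(img, small_bank)
        # 3 channels x (2 scales x 14 kernels) here; the full bank gives
        # 3 x 56 = 168
        assert stack.shape == (64, 64, 3 * len(small_bank))
        full = eg.build_filter_bank(scale_factor=0.125)
        assert 3 * len(full) == 168

    def test_constant_image_responses(self, small_bank):
        stack = eg.apply_filter_bank(np.full((48, 48), 0.7), small_bank)
        centre = stack[24, 24]
        for i, k in enumerate(small_bank.kernels):
            if k.kind == "gaussian":
                assert centre[i] == pytest.approx(0.7, abs=1e-5)
            else:
                assert abs(centre[i]) <= 1e-6

    def test_impulse_response_matches_convolution_definition(self):
        """(delta * k)[n] = k[n - p]: an impulse at p reproduces the kernel
        centred on p (for the symmetric kernels this coincides with the
        correlation response; the odd kernels pin down the convention)."""
        bank = eg.build_filter_bank(scales=(16.0,), scale_factor=0.0625)  # sigma 1
        img = np.zeros((41, 41))
        img[20, 20] = 1.0
        stack = eg.apply_filter_bank(img, bank)
        for i, k in enumerate(bank.kernels):
            hw = k.array.shape[0] // 2
            got = stack[20 - hw:20 + hw + 1, 20 - hw:20 + hw + 1, i]
            # stack is float32: tolerance at single-precision resolution
            assert np.allclose(got, k.array, atol=1e-6), k.kind

    def test_translation_equivariance_away_from_borders(self, small_bank):
        rng = np.random.default_rng(3)
        img = rng.uniform(size=(80, 80))
        shifted = np.roll(img, (5, 7), axis=(0, 1))
        a = eg.apply_filter_bank(img, small_bank)
        b = eg.apply_filter_bank(shifted, small_bank)
        m = small_bank.max_kernel_size  # keep clear of padded borders
        assert np.allclose(a[m:-m - 5, m:-m - 7],
                           b[m + 5:-m, m + 7:-m], atol=1e-4)

    def test_image_smaller_than_kernel_rejected(self):
        bank = eg.build_filter_bank()  # max kernel > 1000 px
        with pytest.raises(ShapeError):
            eg.apply_filter_bank(np.zeros((64, 64)), bank)


class TestTextureModel:
    def test_planted_two_texture_recovery(self, small_bank):
        """K-means with k=2 separates a dark smooth half from a bright
        high-frequency half."""
        rng = np.random.default_rng(5)
        h, w = 96, 96
        img = np.empty((h, w))
        smooth = gaussian_filter(rng.standard_normal((h, 48)), 4)
        img[:, :48] = 0.30 + 0.03 * smooth / smooth.std()
        img[:, 48:] = 0.70 + 0.12 * rng.standard_normal((h, 48))
        stack = eg.apply_filter_bank(np.clip(img, 0, 1), small_bank)
        mask = np.zeros((h, w), dtype=bool)
        mask[12:-12, 12:36] = True    # interior of the smooth half
        mask[12:-12, 60:-12] = True   # interior of the rough half
        model = fit_texture_model(stack, mask, k=2, seed=0)
        labels = assign_labels(stack, model)
        left = labels[12:-12, 12:36].ravel()
        right = labels[12:-12, 60:-12].ravel()
        maj_l = np.bincount(left).argmax()
        maj_r = np.bincount(right).argmax()
        assert maj_l != maj_r
        acc = ((left == maj_l).mean() + (right == maj_r).mean()) / 2
        assert acc >= 0.95

    def test_default_k_gives_twenty_centres(self, small_bank):
        rng = np.random.default_rng(6)
        stack = eg.apply_filter_bank(rng.uniform(size=(64, 64)), small_bank)
        model = fit_texture_model(stack, np.ones((64, 64), bool), k=20, seed=1)
        assert model.k == 20 and model.centres.shape[0] == 20

    def test_duplication_invariance_of_centres(self):
        # two well-separated blobs; duplicating every point leaves the
        # converged centres unchanged
        rng = np.random.default_rng(7)
        pts = np.vstack([rng.normal(0, 0.05, (50, 3)),
                         rng.normal(5, 0.05, (50, 3))])
        stack = pts.reshape(10, 10, 3)
        mask = np.ones((10, 10), bool)
        m1 = fit_texture_model(stack, mask, k=2, seed=3)
        dup = np.vstack([pts, pts]).reshape(20, 10, 3)
        m2 = fit_texture_model(dup, np.ones((20, 10), bool), k=2, seed=3)
        c1 = m1.centres * m1.feature_std[None] + m1.feature_mean[None]
        c2 = m2.centres * m2.feature_std[None] + m2.feature_mean[None]
        assert np.allclose(np.sort(c1, axis=0), np.sort(c2, axis=0), atol=1e-6)

    def test_too_few_pixels_rejected(self, small_bank):
        stack = np.zeros((8, 8, 5))
        mask = np.zeros((8, 8), bool)
        mask[0, :3] = True
        with pytest.raises(DataError):
            fit_texture_model(stack, mask, k=20)


class TestAssignLabels:
    def _model(self, centres):
        c = np.asarray(centres, dtype=float)
        return TextureModel(centres=c, feature_mean=np.zeros(c.shape[1]),
                            feature_std=np.ones(c.shape[1]), seed=0,
                            inertia=0.0, n_iter=0)

    def test_exact_centre_match(self):
        centres = np.arange(30).reshape(10, 3).astype(float)
        model = self._model(centres)
        stack = centres[7].reshape(1, 1, 3)
        assert assign_labels(stack, model)[0, 0] == 7

    def test_tie_breaks_to_lowest_index(self):
        centres = np.zeros((6, 2))
        centres[2] = (1.0, 0.0)
        centres[5] = (-1.0, 0.0)
        centres[0] = (0.0, 3.0)
        centres[1] = (0.0, 3.0)
        centres[3] = (0.0, 3.0)
        centres[4] = (0.0, 3.0)
        stack = np.zeros((1, 1, 2))  # equidistant from centres 2 and 5
        assert assign_labels(stack, model := self._model(centres))[0, 0] == 2

    def test_matches_exhaustive_distance_oracle(self):
        rng = np.random.default_rng(9)
        centres = rng.normal(size=(20, 6))
        model = self._model(centres)
        stack = rng.normal(size=(10, 10, 6))      # 100 pixels
        labels = assign_labels(stack, model)
        oracle = cdist(stack.reshape(-1, 6), centres).argmin(axis=1)
        assert np.array_equal(labels.ravel(), oracle)

    def test_feature_length_mismatch_rejected(self):
        model = self._model(np.zeros((3, 4)))
        with pytest.raises(ShapeError):
            assign_labels(np.zeros((2, 2, 5)), model)


class TestRegionSignature:
    def test_single_label_indicator(self):
        labels = np.full((4, 4), 3)
        sig = region_signature(labels, np.ones((4, 4), bool), k=5)
        assert np.array_equal(sig, [0, 0, 0, 1, 0])

    def test_direct_count(self):
        labels = np.array([[0, 0], [1, 3]])
        sig = region_signature(labels, np.ones((2, 2), bool), k=4)
        assert np.array_equal(sig, [0.5, 0.25, 0.0, 0.25])

    @settings(deadline=None, derandomize=True)
    @given(st.lists(st.integers(0, 7), min_size=1, max_size=50))
    def test_sums_to_one(self, values):
        labels = np.array(values).reshape(1, -1)
        sig = region_signature(labels, np.ones_like(labels, bool), k=8)
        assert sig.sum() == pytest.approx(1.0, abs=1e-9)
        assert (sig >= 0).all()

    def test_empty_mask_rejected(self):
        with pytest.raises(DataError):
            region_signature(np.zeros((3, 3), int), np.zeros((3, 3), bool), k=2)


class TestChiSquareDistance:
    def test_identity_is_zero(self):
        h = np.array([0.2, 0.3, 0.5])
        assert chi_square_distance(h, h) == 0.0

    def test_disjoint_supports_is_one(self):
        a = np.array([0.5, 0.5, 0.0, 0.0])
        b = np.array([0.0, 0.0, 0.25, 0.75])
        assert chi_square_distance(a, b) == pytest.approx(1.0)

    def test_hand_computed_example(self):
        got = chi_square_distance(np.array([0.5, 0.5]), np.array([0.25, 0.75]))
        assert got == pytest.approx(0.066667, abs=1e-6)

    @settings(deadline=None, derandomize=True)
    @given(st.integers(0, 2 ** 32 - 1))
    def test_symmetric_and_bounded(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.dirichlet(np.ones(20))
        b = rng.dirichlet(np.ones(20))
        d_ab = chi_square_distance(a, b)
        assert d_ab == pytest.approx(chi_square_distance(b, a))
        assert 0.0 <= d_ab <= 1.0

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ShapeError):
            chi_square_distance(np.ones(3) / 3, np.ones(4) / 4)
        with pytest.raises(DomainError):
            chi_square_distance(np.array([0.5, 0.6]), np.array([0.5, 0.5]))


@pytest.fixture(scope="module")
def fine_bank():
    return eg.build_filter_bank(scales=(8.0, 16.0, 32.0, 64.0),
                                scale_factor=0.125)


class TestCamouflageDistance:
    def test_background_matching_eggs_score_near_zero(self, fine_bank):
        """Egg regions carrying the background's own texture are nearly
        indistinguishable from the microhabitat (sampling noise only)."""
        p = eg.SceneParams(image_size=(384, 384), px_per_cm=8.0, n_eggs=5,
                           egg_axes_cm=(8.0, 6.0), spot_fraction=0.0,
                           noise_sd=0.004, rng_seed=11)
        sc = eg.render_scene(p, paint_eggs=False)
        score = eg.camouflage_distance(sc.image[..., :3], sc.regions,
                                       seed=0, bank=fine_bank)
        assert score.value <= 0.05

    def test_conspicuous_eggs_score_high(self, fine_bank):
        p = eg.SceneParams(image_size=(384, 384), px_per_cm=8.0, n_eggs=5,
                           egg_axes_cm=(8.0, 6.0), spot_fraction=0.0,
                           band_reflectance_egg_ground=(0.9,) * 4,
                           band_reflectance_background_base=(0.08,) * 4,
                           noise_sd=0.004, rng_seed=12)
        sc = eg.render_scene(p)
        score = eg.camouflage_distance(sc.image[..., :3], sc.regions,
                                       seed=0, bank=fine_bank)
        assert score.value >= 0.5

    def test_deterministic_given_seed(self, fine_bank, default_scene):
        img = default_scene.image[..., :3]
        s1 = eg.camouflage_distance(img, default_scene.regions, seed=5,
                                    bank=fine_bank)
        s2 = eg.camouflage_distance(img, default_scene.regions, seed=5,
                                    bank=fine_bank)
        assert s1.value == s2.value

    def test_microhabitat_outside_frame_rejected(self, fine_bank,
                                                 default_scene):
        regions = eg.RegionSet(
            egg_polygons=default_scene.regions.egg_polygons,
            standard_polygon=default_scene.regions.standard_polygon,
            nest_centre=(-4000.0, -4000.0),
            px_per_cm=default_scene.regions.px_per_cm)
        from eggshade.errors import GeometryError
        with pytest.raises(GeometryError):
            eg.camouflage_distance(default_scene.image[..., :3], regions,
                                   bank=fine_bank)
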