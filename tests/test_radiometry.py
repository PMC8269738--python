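"""Camera linearization, grey-standard normalization and region extraction."""

import numpy as np
import pytest
import shapely.geometry as sgeom

import eggshade as eg
from eggshade.camera import CameraResponseParams, encode_camera, linearize
from eggshade.errors import (CalibrationError, ConfigError, DomainError,
                             GeometryError)
from eggshade.radiometry import (normalize_to_reflectance, percent_change,
                                 roi_mean_reflectance, summarize_radiation)
from eggshade.regions import polygon_mask

RECT = np.array([[1.5, 1.5], [30.5, 1.5], [30.5, 30.5], [1.5, 30.5]])


class TestLinearize:
    def test_linear_camera_inverts_exactly(self):
        crp = CameraResponseParams(gamma=1.0, gain=1000.0, black_level=100.0)
        raw = np.array([[100, 600, 1100]], dtype=np.uint16)
        lin, sat = linearize(raw, crp)
        assert np.allclose(lin, [[0.0, 0.5, 1.0]])
        assert not sat.any()

    def test_black_level_maps_to_zero_and_saturation_flagged(self):
        crp = CameraResponseParams(bit_depth=8, black_level=16.0, gamma=2.0)
        raw = np.array([[16, 255]], dtype=np.uint16)
        lin, sat = linearize(raw, crp)
        assert lin[0, 0] == 0.0
        assert sat.tolist() == [[False, True]]

    def test_round_trip_on_representable_ramp(self):
        """Encode then linearize recovers a DN-grid ramp to <= 1e-6."""
        crp = CameraResponseParams(gamma=1.0, black_level=0.0, bit_depth=16)
        dn_grid = np.arange(1, 65535, 257)
        ramp = dn_grid / crp.gain                 # exactly representable
        raw = encode_camera(ramp, crp)
        lin, _ = linearize(raw, crp)
        assert np.max(np.abs(lin - ramp) / ramp) <= 1e-6

    def test_bit_depth_below_8_rejected(self):
        with pytest.raises(ConfigError):
            CameraResponseParams(bit_depth=4)

    def test_encode_full_scale_and_black(self):
        crp = CameraResponseParams(gamma=1.0, black_level=12.0, bit_depth=12,
                                   gain=2 ** 12 - 1 - 12)
        assert encode_camera(np.array(1.0), crp) == 2 ** 12 - 1
        assert encode_camera(np.array(0.0), crp) == 12


class TestNormalize:
    def test_uniform_image_maps_to_standard_reflectance(self):
        img = np.full((40, 40), 7.3)
        out = normalize_to_reflectance(img, RECT)
        assert np.allclose(out, 0.25)

    def test_double_the_standard_is_half_reflectance_unit(self):
        img = np.full((40, 40), 2.0)
        img[35, 35] = 4.0
        out = normalize_to_reflectance(img, RECT)
        assert out[35, 35] == pytest.approx(0.5)

    def test_idempotent(self):
        rng = np.random.default_rng(0)
        img = rng.uniform(0.5, 2.0, size=(40, 40, 4))
        once = normalize_to_reflectance(img, RECT)
        twice = normalize_to_reflectance(once, RECT)
        assert np.allclose(once, twice)

    def test_exposure_invariance(self):
        rng = np.random.default_rng(1)
        img = rng.uniform(0.5, 2.0, size=(40, 40, 4))
        a = normalize_to_reflectance(img, RECT)
        b = normalize_to_reflectance(3.7 * img, RECT)
        assert np.allclose(a, b)

    def test_too_few_standard_pixels_rejected(self):
        tiny = np.array([[0.5, 0.5], [5.5, 0.5], [5.5, 5.5], [0.5, 5.5]])
        with pytest.raises(CalibrationError):
            normalize_to_reflectance(np.ones((40, 40)), tiny)

    def test_zero_standard_rejected(self):
        with pytest.raises(CalibrationError):
            normalize_to_reflectance(np.zeros((40, 40)), RECT)

    def test_full_chain_recovers_known_reflectance(self):
        """Render -> encode -> linearize -> normalize returns the egg's true
        reflectance to within 1% (noiseless chain)."""
        p = eg.SceneParams(spot_fraction=0.0, noise_sd=0.0, rng_seed=5,
                           band_reflectance_egg_ground=(0.175, 0.175, 0.175, 0.124))
        sc = eg.render_scene(p)
        crp = CameraResponseParams(gamma=2.2, shot_noise_sd=0.0)
        lin, sat = linearize(encode_camera(sc.image, crp), crp)
        refl = normalize_to_reflectance(lin, sc.regions.standard_polygon,
                                        saturated=sat)
        vis = np.mean([roi_mean_reflectance(refl, q, "VIS")
                       for q in sc.regions.egg_polygons])
        uv = np.mean([roi_mean_reflectance(refl, q, "UV")
                      for q in sc.regions.egg_polygons])
        assert vis == pytest.approx(0.175, rel=0.01)
        assert uv == pytest.approx(0.124, rel=0.01)


class TestRoiMean:
    def test_constant_image(self):
        img = np.full((20, 20, 4), 0.42)
        poly = np.array([[2.3, 2.3], [15.3, 2.3], [15.3, 15.3], [2.3, 15.3]])
        assert roi_mean_reflectance(img, poly, "VIS") == pytest.approx(0.42)
        assert roi_mean_reflectance(img, poly, "UV") == pytest.approx(0.42)

    def test_two_pixel_arithmetic_mean(self):
        img = np.zeros((3, 4, 4))
        img[1, 1, :3] = 0.1
        img[1, 2, :3] = 0.3
        poly = np.array([[0.5, 0.5], [2.5, 0.5], [2.5, 1.5], [0.5, 1.5]])
        assert roi_mean_reflectance(img, poly, "VIS") == pytest.approx(0.2)

    def test_concave_polygon_matches_point_in_polygon_oracle(self):
        # L-shaped concave polygon, vertices off the half-integer grid
        poly = np.array([[2.3, 2.3], [18.7, 2.3], [18.7, 9.2], [9.4, 9.2],
                         [9.4, 17.6], [2.3, 17.6]])
        mask = polygon_mask(poly, (24, 24))
        shp = sgeom.Polygon(poly)
        oracle = np.zeros((24, 24), dtype=bool)
        for r in range(24):
            for c in range(24):
                oracle[r, c] = shp.contains(sgeom.Point(c, r))
        assert np.array_equal(mask, oracle)

    def test_empty_polygon_rejected(self):
        img = np.zeros((10, 10, 4))
        off_frame = np.array([[50.2, 50.2], [60.2, 50.2], [55.2, 60.2]])
        with pytest.raises(GeometryError):
            roi_mean_reflectance(img, off_frame, "VIS")


class TestPercentChange:
    @pytest.mark.parametrize("r0,rt,expected", [
        (0.2, 0.4, 100.0),
        (0.5, 0.5, 0.0),
        (0.175, 0.361, 106.2857142857143),
    ])
    def test_values(self, r0, rt, expected):
        assert percent_change(r0, rt) == pytest.approx(expected)

    def test_nonpositive_baseline_rejected(self):
        with pytest.raises(DomainError):
            percent_change(0.0, 0.3)


class TestSummarizeRadiation:
    def test_constant_series(self):
        import pandas as pd
        rec = pd.DataFrame({"day": [0] * 10, "irradiance_wm2": 5.0,
                            "illuminance_lux": 600.0, "uv_index": 1.0})
        s = summarize_radiation(rec)
        assert s["irradiance_wm2"] == 5.0

    def test_mean_of_daily_maxima(self):
        import pandas as pd
        rec = pd.DataFrame({
            "day": [0, 0, 3, 3, 7, 7],
            "irradiance_wm2": [700, 10, 730, 11, 760, 12],
            "illuminance_lux": 0.0, "uv_index": 0.0})
        assert summarize_radiation(rec)["irradiance_wm2"] == pytest.approx(730)

    def test_against_exhaustive_scan(self):
        rec = eg.simulate_radiation(eg.TREATMENTS["white2"], [0, 3, 7], seed=4)
        s = summarize_radiation(rec)
        expected = np.mean([rec.loc[rec.day == d, "uv_index"].to_numpy().max()
                            for d in (0, 3, 7)])
        assert s["uv_index"] == pytest.approx(expected)
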