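"""Synthetic nest scenes, radiation schedules and egg-fading trajectories.

Generates ground-nest scenes with known ground truth emulating the two field
experiments: spotted quail eggs laid in rows inside a scrape, a heterogeneous
sandy background, an in-frame 25% grey standard, and a dose-driven fading of
the eggshell in four camera bands (VIS-R, VIS-G, VIS-B, UV).

Fading is linear-with-cap in cumulative normalized dose: one unit of dose is
seven days under direct-sun irradiance.  VIS and UV doses are tracked
separately (illuminance-scaled vs UV-index-scaled), because the field
dose-response shows UV fading proportional to the UV dose with a different
proportionality than the visible bands.  Default slopes are calibrated so a
direct-sun week raises a 0.175 VIS reflectance to 0.361 (+106%) and a 0.124
UV reflectance to 0.213 (+71%), the averages measured on exposed eggs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .camera import encode_camera  # noqa: F401  (re-exported: scene → camera encoding)
from .errors import ConfigError, DataError, DomainError, GeometryError
from .regions import RegionSet, polygon_mask

__all__ = [
    "CHANNELS", "VIS_BANDS", "UV_BAND",
    "BackgroundTexture", "SceneParams", "FadingParams", "RadiationSchedule",
    "Scene", "TREATMENTS", "FIELD_DOSE_RESPONSE",
    "render_scene", "apply_fading", "encode_camera", "simulate_radiation",
    "normalized_dose",
]

#: Channel order of every 4-band image in the package.
CHANNELS = ("vis_r", "vis_g", "vis_b", "uv")
VIS_BANDS = slice(0, 3)
UV_BAND = 3

#: Field dose-response anchor: per-treatment reflectance increases (percent
#: over one week) against the radiation received (mean of daily maxima over
#: the three recording days).  These measured values calibrate the default
#: fading slopes and are the inputs to the radiation-correlation analysis.
FIELD_DOSE_RESPONSE = pd.DataFrame(
    {
        "treatment": ["direct", "white1", "white2", "white4", "black"],
        "delta_vis_pct": [106.07, 48.64, 52.78, 37.08, 20.26],
        "delta_uv_pct": [71.44, 25.56, 13.55, 7.38, 0.14],
        "irradiance_wm2": [730.0, 224.0, 160.0, 97.0, 7.0],
        "uv_index": [7.5, 2.3, 1.6, 1.0, 0.1],
    }
)

_DIRECT_PEAK_WM2 = 730.0
_DIRECT_PEAK_UVI = 7.5
#: Approximate daylight luminous efficacy used to report illuminance in lux.
_LUX_PER_WM2 = 120.0


@dataclass(frozen=True)
class BackgroundTexture:
    """Procedural clutter model: band-correlated Gaussian blobs.

    grain_cm : correlation length of the clutter, cm
    contrast : relative reflectance modulation depth
    band_decorrelation : weight of the per-band independent component
    """

    grain_cm: float = 2.0
    contrast: float = 0.25
    band_decorrelation: float = 0.3

    def __post_init__(self) -> None:
        if self.grain_cm <= 0:
            raise ConfigError("grain_cm must be positive")
        if not 0 <= self.contrast < 1:
            raise ConfigError("contrast must be in [0, 1)")


@dataclass(frozen=True)
class SceneParams:
    """Geometry, reflectances and noise of one synthetic nest scene."""

    image_size: tuple[int, int] = (512, 512)          # (H, W) pixels
    px_per_cm: float = 10.0
    n_eggs: int = 3
    egg_axes_cm: tuple[float, float] = (3.3, 2.5)     # (major, minor)
    spot_fraction: float = 0.2
    band_reflectance_egg_ground: tuple[float, ...] = (0.204, 0.204, 0.204, 0.145)
    band_reflectance_egg_spot: tuple[float, ...] = (0.060, 0.060, 0.060, 0.040)
    band_reflectance_background_base: tuple[float, ...] = (0.20, 0.19, 0.18, 0.12)
    background_texture: BackgroundTexture = field(default_factory=BackgroundTexture)
    standard_side_cm: float = 3.0
    noise_sd: float = 0.004
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.px_per_cm <= 0:
            raise ConfigError("px_per_cm must be positive")
        if self.n_eggs < 1:
            raise ConfigError("n_eggs must be >= 1")
        if not 0 <= self.spot_fraction < 1:
            raise ConfigError("spot_fraction must be in [0, 1)")
        for name in ("band_reflectance_egg_ground", "band_reflectance_egg_spot",
                     "band_reflectance_background_base"):
            vec = getattr(self, name)
            if len(vec) != 4 or any(not 0 <= v <= 1 for v in vec):
                raise ConfigError(f"{name} must be four reflectances in [0, 1]")
        if self.egg_axes_cm[0] < self.egg_axes_cm[1] or self.egg_axes_cm[1] <= 0:
            raise ConfigError("egg_axes_cm must be (major >= minor > 0)")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be >= 0")


@dataclass(frozen=True)
class FadingParams:
    """Linear-with-cap dose response of eggshell reflectance.

    slope_per_band : reflectance increase per unit normalized dose, one per
        camera band; one dose unit is seven days at direct-sun irradiance
    cap : reflectance ceiling after fading
    """

    slope_per_band: tuple[float, ...] = (0.186, 0.186, 0.186, 0.089)
    cap: float = 0.95

    def __post_init__(self) -> None:
        if len(self.slope_per_band) != 4 or any(s < 0 for s in self.slope_per_band):
            raise ConfigError("slope_per_band must be four non-negative slopes")
        if not 0 < self.cap <= 1:
            raise ConfigError("cap must be in (0, 1]")


@dataclass(frozen=True)
class RadiationSchedule:
    """Radiation regime of one shading treatment.

    Transmittances scale a common direct-sun diurnal curve; the direct
    treatment has transmittance 1 by definition.  Sampling is every 5 min
    over a 12-h window (145 points per day).
    """

    treatment: str
    vis_transmittance: float
    uv_transmittance: float
    peak_irradiance_wm2: float = _DIRECT_PEAK_WM2
    peak_uv_index: float = _DIRECT_PEAK_UVI

    def __post_init__(self) -> None:
        for t in (self.vis_transmittance, self.uv_transmittance):
            if not 0 <= t <= 1:
                raise ConfigError("transmittances must be in [0, 1]")
        if self.treatment == "direct" and (
                self.vis_transmittance != 1 or self.uv_transmittance != 1):
            raise ConfigError("the direct treatment must have transmittance 1")


def _schedules() -> dict[str, RadiationSchedule]:
    rows = FIELD_DOSE_RESPONSE.set_index("treatment")
    return {
        name: RadiationSchedule(
            treatment=name,
            vis_transmittance=rows.loc[name, "irradiance_wm2"] / _DIRECT_PEAK_WM2,
            uv_transmittance=rows.loc[name, "uv_index"] / _DIRECT_PEAK_UVI,
        )
        for name in rows.index
    }


#: Shading treatments of the radiation experiment, transmittances anchored to
#: the measured per-treatment radiation maxima.
TREATMENTS: dict[str, RadiationSchedule] = _schedules()


@dataclass
class Scene:
    """A rendered scene: reflectance image, annotations, and ground truth."""

    image: np.ndarray              # (H, W, 4) float reflectance
    regions: RegionSet
    ground_truth: dict


# --------------------------------------------------------------------------
# fading
# --------------------------------------------------------------------------

def _dose_vector(dose) -> np.ndarray:
    """Accept a scalar dose, a (vis, uv) pair, or a per-band 4-vector."""
    d = np.asarray(dose, dtype=float)
    if d.ndim == 0:
        d = np.full(4, float(d))
    elif d.shape == (2,):
        d = np.array([d[0], d[0], d[0], d[1]])
    elif d.shape != (4,):
        raise DomainError("dose must be scalar, (vis, uv), or a 4-vector")
    if (d < 0).any():
        raise DomainError("dose must be non-negative")
    return d


def apply_fading(reflectance, dose, fp: FadingParams | None = None) -> np.ndarray:
    """Fade reflectance by a normalized dose: ``min(r + slope * dose, cap)``.

    ``reflectance`` is a 4-vector or an (H, W, 4) image; ``dose`` a scalar,
    a (vis, uv) pair, or a per-band 4-vector.  Identity at dose 0 and
    monotone non-decreasing in dose; values already above the cap are left
    unchanged rather than pulled down.
    """
    fp = fp or FadingParams()
    r = np.asarray(reflectance, dtype=float)
    if r.shape[-1] != 4:
        raise DomainError("reflectance must have 4 bands on the last axis")
    d = _dose_vector(dose)
    faded = r + np.asarray(fp.slope_per_band) * d
    return np.where(faded > fp.cap, np.maximum(r, fp.cap), faded)


# --------------------------------------------------------------------------
# scene rendering
# --------------------------------------------------------------------------

def _row_layout(n: int) -> list[int]:
    """Split n eggs into clutch-like rows of at most four.

    Ten eggs give the 3/4/3 arrangement used in the radiation experiment.
    """
    n_rows = max(1, math.ceil(n / 4))
    base, extra = divmod(n, n_rows)
    rows = [base + 1 if i < extra else base for i in range(n_rows)]
    # put the fuller rows in the middle
    rows.sort()
    mid = len(rows) // 2
    rows[mid], rows[-1] = rows[-1], rows[mid]
    return rows


def _ellipse_polygon(cx: float, cy: float, a: float, b: float,
                     angle: float, n_vertices: int = 48) -> np.ndarray:
    t = np.linspace(0.0, 2.0 * np.pi, n_vertices, endpoint=False)
    x = a * np.cos(t)
    y = b * np.sin(t)
    ca, sa = np.cos(angle), np.sin(angle)
    return np.column_stack([cx + ca * x - sa * y, cy + sa * x + ca * y])


def _background(params: SceneParams, rng: np.random.Generator) -> np.ndarray:
    h, w = params.image_size
    tex = params.background_texture
    sigma = 0.5 * tex.grain_cm * params.px_per_cm
    shared = gaussian_filter(rng.standard_normal((h, w)), sigma)
    shared /= max(shared.std(), 1e-12)
    base = np.asarray(params.band_reflectance_background_base)
    out = np.empty((h, w, 4))
    wd = tex.band_decorrelation
    ws = math.sqrt(max(1.0 - wd * wd, 0.0))
    for b in range(4):
        own = gaussian_filter(rng.standard_normal((h, w)), sigma)
        own /= max(own.std(), 1e-12)
        fieldmap = ws * shared + wd * own
        out[..., b] = base[b] * (1.0 + tex.contrast * fieldmap)
    return np.clip(out, 0.0, 1.0)


def _egg_centres(params: SceneParams, rng: np.random.Generator
                 ) -> list[tuple[float, float]]:
    h, w = params.image_size
    cx, cy = w / 2.0, h / 2.0
    a = 0.5 * params.egg_axes_cm[0] * params.px_per_cm
    b = 0.5 * params.egg_axes_cm[1] * params.px_per_cm
    dx, dy = 2.3 * a, 2.3 * b
    rows = _row_layout(params.n_eggs)
    centres = []
    for i, n_in_row in enumerate(rows):
        y = cy + (i - (len(rows) - 1) / 2.0) * dy
        for j in range(n_in_row):
            x = cx + (j - (n_in_row - 1) / 2.0) * dx
            jx, jy = rng.uniform(-0.15, 0.15, 2) * min(a, b)
            centres.append((x + jx, y + jy))
    return centres


def _paint_spots(egg_mask: np.ndarray, params: SceneParams,
                 rng: np.random.Generator) -> np.ndarray:
    """Random maculation disks covering ~spot_fraction of the egg area."""
    spot = np.zeros_like(egg_mask)
    area = egg_mask.sum()
    if params.spot_fraction <= 0 or area == 0:
        return spot
    minor_px = params.egg_axes_cm[1] * params.px_per_cm
    target = params.spot_fraction * area
    covered = 0.0
    rows_idx, cols_idx = np.nonzero(egg_mask)
    h, w = egg_mask.shape
    # cap iterations: overlap makes exact coverage unnecessary
    for _ in range(200):
        if covered >= target:
            break
        k = rng.integers(0, len(rows_idx))
        r0, c0 = rows_idx[k], cols_idx[k]
        rad = 0.12 * minor_px * (0.5 + rng.random())
        rr = slice(max(int(r0 - rad) - 1, 0), min(int(r0 + rad) + 2, h))
        cc = slice(max(int(c0 - rad) - 1, 0), min(int(c0 + rad) + 2, w))
        ys, xs = np.mgrid[rr, cc]
        disk = (ys - r0) ** 2 + (xs - c0) ** 2 <= rad ** 2
        new = (disk & egg_mask[rr, cc] & ~spot[rr, cc]).sum()
        # stop at the disk count closest to the target coverage
        if covered + new > target and (covered + new - target) > (target - covered):
            break
        spot[rr, cc] |= disk & egg_mask[rr, cc]
        covered += new
    return spot


def render_scene(params: SceneParams, day: int = 0, dose=0.0,
                 fading: FadingParams | None = None,
                 paint_eggs: bool = True) -> Scene:
    """Render one nest scene at a given fading dose.

    Returns a :class:`Scene` whose image is (H, W, 4) reflectance, whose
    regions exactly delimit the eggs and the grey standard, and whose
    ground truth records the true (faded) egg reflectances and pixel masks.
    The grey standard has true reflectance 0.25 in every band.  Rendering is
    fully deterministic given ``params.rng_seed``.
    """
    fading = fading or FadingParams()
    d = _dose_vector(dose)
    h, w = params.image_size
    rng = np.random.default_rng(params.rng_seed)
    image = _background(params, rng)

    a = 0.5 * params.egg_axes_cm[0] * params.px_per_cm
    b = 0.5 * params.egg_axes_cm[1] * params.px_per_cm
    ground = apply_fading(np.asarray(params.band_reflectance_egg_ground), d, fading)
    spot_refl = apply_fading(np.asarray(params.band_reflectance_egg_spot), d, fading)

    egg_polys: list[np.ndarray] = []
    egg_mask = np.zeros((h, w), dtype=bool)
    spot_mask = np.zeros((h, w), dtype=bool)
    for cx, cy in _egg_centres(params, rng):
        angle = rng.uniform(0.0, np.pi)
        poly = _ellipse_polygon(cx, cy, a, b, angle)
        if (poly[:, 0].min() < 0 or poly[:, 1].min() < 0
                or poly[:, 0].max() >= w or poly[:, 1].max() >= h):
            raise GeometryError(
                f"egg at ({cx:.0f}, {cy:.0f}) does not fit inside the "
                f"{h}x{w} frame; enlarge image_size or reduce n_eggs")
        mask = polygon_mask(poly, (h, w))
        spots = _paint_spots(mask, params, rng)
        if paint_eggs:
            image[mask] = ground
            image[spots] = spot_refl
        egg_polys.append(poly)
        egg_mask |= mask
        spot_mask |= spots

    # grey standard: axis-aligned square on half-integer bounds so pixel
    # centres are never on the polygon boundary
    side = int(round(params.standard_side_cm * params.px_per_cm))
    sc0, sr0 = int(round(0.08 * w)), int(round(0.08 * h))
    sc1, sr1 = sc0 + side - 1, sr0 + side - 1
    if sc1 >= w or sr1 >= h:
        raise GeometryError("grey standard does not fit inside the frame")
    std_poly = np.array([
        [sc0 - 0.5, sr0 - 0.5], [sc1 + 0.5, sr0 - 0.5],
        [sc1 + 0.5, sr1 + 0.5], [sc0 - 0.5, sr1 + 0.5]])
    std_mask = polygon_mask(std_poly, (h, w))
    if (std_mask & egg_mask).any():
        raise GeometryError("grey standard overlaps an egg")
    image[std_mask] = 0.25

    if params.noise_sd > 0:
        image = image + rng.normal(0.0, params.noise_sd, size=image.shape)
    image = np.clip(image, 0.0, 1.0)

    regions = RegionSet(
        egg_polygons=egg_polys,
        standard_polygon=std_poly,
        nest_centre=(w / 2.0, h / 2.0),
        px_per_cm=params.px_per_cm,
    )
    ground_truth = {
        "day": day,
        "dose_per_band": d,
        "egg_ground_reflectance": ground,
        "egg_spot_reflectance": spot_refl,
        "egg_mask": egg_mask,
        "spot_mask": spot_mask,
        "standard_mask": std_mask,
    }
    return Scene(image=image, regions=regions, ground_truth=ground_truth)


# --------------------------------------------------------------------------
# radiation
# --------------------------------------------------------------------------

def simulate_radiation(schedule: RadiationSchedule, days: list[int],
                       seed: int = 0) -> pd.DataFrame:
    """Simulate the 5-min radiation log of one treatment over recording days.

    The diurnal curve is a half-cosine bell over a 12-h window starting at
    10:00 GMT, scaled by the treatment transmittance, with a small day-to-day
    amplitude jitter.  Columns: day, timestamp, irradiance_wm2,
    illuminance_lux, uv_index.
    """
    if not isinstance(schedule, RadiationSchedule):
        raise ConfigError(f"unknown treatment schedule: {schedule!r}")
    if len(days) == 0:
        raise DataError("at least one recording day is required")
    rng = np.random.default_rng(seed)
    frac = np.arange(145) / 144.0              # 5-min grid over 12 h
    bell = np.sin(np.pi * frac)
    frames = []
    for day in days:
        day_factor = float(np.clip(1.0 + 0.02 * rng.standard_normal(), 0.9, 1.1))
        jitter = 1.0 + 0.005 * rng.standard_normal(bell.shape)
        shape = np.clip(bell * day_factor * jitter, 0.0, None)
        start = pd.Timestamp("2020-06-01 10:00:00") + pd.Timedelta(days=int(day))
        ts = start + pd.to_timedelta(np.arange(145) * 5, unit="m")
        wm2 = schedule.peak_irradiance_wm2 * schedule.vis_transmittance * shape
        frames.append(pd.DataFrame({
            "day": int(day),
            "timestamp": ts,
            "irradiance_wm2": wm2,
            "illuminance_lux": wm2 * _LUX_PER_WM2,
            "uv_index": schedule.peak_uv_index * schedule.uv_transmittance * shape,
        }))
    return pd.concat(frames, ignore_index=True)


def normalized_dose(schedule: RadiationSchedule, days_elapsed: float
                    ) -> tuple[float, float]:
    """Normalized (vis, uv) fading dose after ``days_elapsed`` days.

    One dose unit is seven days under the direct-sun curve, so the direct
    treatment reaches (1, 1) at day 7.
    """
    if days_elapsed < 0:
        raise DomainError("days_elapsed must be >= 0")
    f = days_elapsed / 7.0
    return f * schedule.vis_transmittance, f * schedule.uv_transmittance


def with_seed(params: SceneParams, seed: int) -> SceneParams:
    """Copy of ``params`` with a different rng seed (each clutch is unique)."""
    return replace(params, rng_seed=int(seed))
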