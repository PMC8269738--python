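"""Reflectance calibration and extraction — the measurement core.

Camera images are linearized (see :mod:`eggshade.camera`) and normalized to
the in-frame grey standard of known 25% reflectance, per channel:

    R(p) = 0.25 * L(p) / mean(L over the standard polygon)

which makes reflectance invariant to global exposure.  Region means are
taken over pixels whose centres fall inside the annotated polygons; the VIS
reading of a region is the mean over pixels of the mean of the R, G and B
channels, the UV reading the mean of the UV channel.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .camera import CameraResponseParams, linearize  # noqa: F401  (re-export)
from .errors import CalibrationError, DataError, DomainError, GeometryError
from .regions import RegionSet, polygon_mask

__all__ = [
    "linearize", "normalize_to_reflectance", "roi_mean_reflectance",
    "percent_change", "summarize_radiation", "extract_egg_reflectances",
]

#: Minimum unsaturated pixels required inside the standard polygon.
MIN_STANDARD_PIXELS = 100


def normalize_to_reflectance(linear: np.ndarray, standard_polygon: np.ndarray,
                             standard_reflectance: float = 0.25,
                             saturated: np.ndarray | None = None) -> np.ndarray:
    """Normalize a linear image to the grey standard, channel by channel.

    By construction the mean over the standard polygon equals
    ``standard_reflectance`` in every channel.  Values above 1 (specular
    pixels) are retained, not clipped.
    """
    lin = np.asarray(linear, dtype=float)
    if lin.ndim == 2:
        lin = lin[..., None]
    mask = polygon_mask(standard_polygon, lin.shape[:2])
    if saturated is not None:
        sat2d = saturated.any(axis=-1) if saturated.ndim == 3 else saturated
        mask &= ~sat2d
    n = int(mask.sum())
    if n < MIN_STANDARD_PIXELS:
        raise CalibrationError(
            f"only {n} unsaturated pixels inside the standard polygon "
            f"(need >= {MIN_STANDARD_PIXELS})")
    std_mean = lin[mask].mean(axis=0)
    if (std_mean <= 0).any():
        raise CalibrationError("non-positive standard mean; cannot normalize")
    out = standard_reflectance * lin / std_mean
    return out if np.asarray(linear).ndim == 3 else out[..., 0]


def roi_mean_reflectance(image: np.ndarray, polygon: np.ndarray,
                         band_set: str = "VIS") -> float:
    """Mean reflectance of a polygonal region in the VIS or UV band set.

    VIS averages the mean of the three visible channels over the region;
    UV averages the fourth channel.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 3 or img.shape[2] != 4:
        raise DomainError("image must be (H, W, 4)")
    mask = polygon_mask(polygon, img.shape[:2])
    if not mask.any():
        raise GeometryError("polygon rasterizes to an empty pixel set")
    if band_set.upper() == "VIS":
        return float(img[mask][:, :3].mean())
    if band_set.upper() == "UV":
        return float(img[mask][:, 3].mean())
    raise DomainError(f"band_set must be 'VIS' or 'UV', got {band_set!r}")


def percent_change(r0: float, rt: float) -> float:
    """Percent change of a reflectance, ``100 * (rt - r0) / r0``."""
    if r0 <= 0:
        raise DomainError(f"initial reflectance must be positive, got {r0}")
    return 100.0 * (rt - r0) / r0


def summarize_radiation(record: pd.DataFrame) -> pd.Series:
    """Per-treatment dose summary: daily maxima averaged across recording days.

    ``record`` must carry columns ``day``, ``irradiance_wm2``,
    ``illuminance_lux`` and ``uv_index`` (one row per 5-min sample).
    """
    cols = ["irradiance_wm2", "illuminance_lux", "uv_index"]
    missing = [c for c in ["day", *cols] if c not in record.columns]
    if missing:
        raise DataError(f"radiation record missing columns {missing}")
    if record.empty:
        raise DataError("empty radiation record")
    per_day = record.groupby("day")[cols]
    if (per_day.size() == 0).any():
        raise DataError("a recording day has an empty series")
    return per_day.max().mean(axis=0)


def extract_egg_reflectances(image: np.ndarray, regions: RegionSet,
                             scene_id: str = "", day: int = 0,
                             treatment: str = "") -> pd.DataFrame:
    """Tidy per-egg reflectance table for one calibrated scene.

    Columns: scene_id, day, treatment, egg_id, band_set, mean_reflectance.
    """
    rows = []
    for egg_id, poly in enumerate(regions.egg_polygons):
        for band_set in ("VIS", "UV"):
            rows.append({
                "scene_id": scene_id, "day": day, "treatment": treatment,
                "egg_id": egg_id, "band_set": band_set,
                "mean_reflectance": roi_mean_reflectance(image, poly, band_set),
            })
    return pd.DataFrame(rows)
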