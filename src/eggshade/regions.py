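"""Region annotations: egg polygons, grey-standard polygon, nest centre.

Coordinate convention (documented in the JSON schema shipped with the repo):
0-based pixel coordinates, x to the right (columns), y down (rows); the
centre of pixel ``(row r, col c)`` is the point ``(x=c, y=r)``.  Polygons are
closed implicitly (last vertex connects back to the first).  Rasterization
follows the pixel-centre-inside rule: a pixel belongs to a polygon iff its
centre falls strictly inside it.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass

import numpy as np
from matplotlib.path import Path as MplPath

from .errors import GeometryError

__all__ = ["RegionSet", "polygon_mask", "disk_mask"]


def polygon_mask(polygon: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Boolean mask of the pixels whose centres fall inside ``polygon``.

    Parameters
    ----------
    polygon
        ``(N, 2)`` array of ``(x, y)`` vertices, N >= 3.
    shape
        ``(H, W)`` of the target image.
    """
    poly = np.asarray(polygon, dtype=float)
    if poly.ndim != 2 or poly.shape[1] != 2 or poly.shape[0] < 3:
        raise GeometryError(f"polygon must be (N>=3, 2), got shape {poly.shape}")
    h, w = shape
    mask = np.zeros((h, w), dtype=bool)
    # restrict the point-in-polygon test to the bounding box
    c0 = max(int(np.floor(poly[:, 0].min())), 0)
    c1 = min(int(np.ceil(poly[:, 0].max())) + 1, w)
    r0 = max(int(np.floor(poly[:, 1].min())), 0)
    r1 = min(int(np.ceil(poly[:, 1].max())) + 1, h)
    if c0 >= c1 or r0 >= r1:
        return mask
    cols, rows = np.meshgrid(np.arange(c0, c1), np.arange(r0, r1))
    pts = np.column_stack([cols.ravel(), rows.ravel()]).astype(float)
    # note: Path(..., closed=True) would treat the final vertex as a
    # CLOSEPOLY marker and drop it; the plain form closes implicitly
    inside = MplPath(poly).contains_points(pts)
    mask[r0:r1, c0:c1] = inside.reshape(r1 - r0, c1 - c0)
    return mask


def disk_mask(centre_xy: tuple[float, float], radius_px: float,
              shape: tuple[int, int]) -> np.ndarray:
    """Boolean mask of pixels whose centres lie within ``radius_px`` of a point."""
    h, w = shape
    cx, cy = centre_xy
    cols, rows = np.meshgrid(np.arange(w), np.arange(h))
    return (cols - cx) ** 2 + (rows - cy) ** 2 <= radius_px ** 2


@dataclass
class RegionSet:
    """Analysis regions of one nest scene.

    Attributes
    ----------
    egg_polygons
        One ``(N, 2)`` vertex array per egg, pixel coordinates.
    standard_polygon
        Vertex array delimiting the in-frame 25% grey standard.
    nest_centre
        ``(x, y)`` of the nest scrape centre; anchors the 45-cm
        microhabitat circle.
    px_per_cm
        Pixel scale of the photograph.
    """

    egg_polygons: list[np.ndarray]
    standard_polygon: np.ndarray
    nest_centre: tuple[float, float]
    px_per_cm: float

    def __post_init__(self) -> None:
        self.egg_polygons = [np.asarray(p, dtype=float) for p in self.egg_polygons]
        self.standard_polygon = np.asarray(self.standard_polygon, dtype=float)
        if self.px_per_cm <= 0:
            raise GeometryError("px_per_cm must be positive")
        for p in [*self.egg_polygons, self.standard_polygon]:
            if p.ndim != 2 or p.shape[1] != 2 or p.shape[0] < 3:
                raise GeometryError("polygons must be (N>=3, 2) vertex arrays")

    # -- masks ---------------------------------------------------------------

    def egg_mask(self, shape: tuple[int, int]) -> np.ndarray:
        """Union of all egg polygons."""
        mask = np.zeros(shape, dtype=bool)
        for poly in self.egg_polygons:
            mask |= polygon_mask(poly, shape)
        return mask

    def standard_mask(self, shape: tuple[int, int]) -> np.ndarray:
        return polygon_mask(self.standard_polygon, shape)

    def microhabitat_mask(self, shape: tuple[int, int],
                          diameter_cm: float = 45.0,
                          exclude_eggs: bool = True) -> np.ndarray:
        """Disk of ``diameter_cm`` around the nest centre, minus the eggs.

        Raises
        ------
        GeometryError
            If the circle lies entirely outside the frame.
        """
        radius_px = 0.5 * diameter_cm * self.px_per_cm
        mask = disk_mask(self.nest_centre, radius_px, shape)
        if not mask.any():
            raise GeometryError(
                f"{diameter_cm}-cm microhabitat circle lies entirely outside the frame")
        if exclude_eggs:
            mask &= ~self.egg_mask(shape)
        return mask

    # -- (de)serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "schema": "eggshade/regions-v1",
            "px_per_cm": float(self.px_per_cm),
            "nest_centre": [float(self.nest_centre[0]), float(self.nest_centre[1])],
            "standard_polygon": self.standard_polygon.tolist(),
            "egg_polygons": [p.tolist() for p in self.egg_polygons],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RegionSet":
        for key in ("px_per_cm", "nest_centre", "standard_polygon", "egg_polygons"):
            if key not in d:
                raise GeometryError(f"region JSON missing required key '{key}'")
        return cls(
            egg_polygons=[np.asarray(p, dtype=float) for p in d["egg_polygons"]],
            standard_polygon=np.asarray(d["standard_polygon"], dtype=float),
            nest_centre=(float(d["nest_centre"][0]), float(d["nest_centre"][1])),
            px_per_cm=float(d["px_per_cm"]),
        )

    def save(self, path: str | os.PathLike) -> None:
        tmp = f"{path}.tmp"
        with open(tmp, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)
        os.replace(tmp, path)

    @classmethod
    def load(cls, path: str | os.PathLike) -> "RegionSet":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))
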