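"""File formats: 16-bit TIFF scene images, float32 cone-catch TIFFs,
region JSON and CSV tables.

Writers stage to a temporary file and rename, so a failed write never
leaves a partial result behind.  Scene images are stored as one 3-channel
VIS file plus one single-channel UV file per scene, mirroring the two
exposures taken in the field.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .errors import DataError
from .regions import RegionSet  # noqa: F401  (re-exported reader/writer host)

__all__ = [
    "write_image", "read_image", "write_scene_images", "read_scene_images",
    "write_table", "read_table",
]


def write_image(path: str | os.PathLike, array: np.ndarray) -> None:
    """Write an image as TIFF (16-bit for integer data, float32 otherwise)."""
    arr = np.asarray(array)
    if arr.dtype.kind in "ui":
        arr = arr.astype(np.uint16)
    else:
        arr = arr.astype(np.float32)
    tmp = f"{path}.tmp"
    tifffile.imwrite(tmp, arr, photometric="minisblack"
                     if arr.ndim == 2 else "rgb" if arr.shape[-1] == 3 else None)
    os.replace(tmp, path)


def read_image(path: str | os.PathLike) -> np.ndarray:
    try:
        return tifffile.imread(path)
    except Exception as exc:
        raise DataError(f"cannot read image {path}: {exc}") from exc


def write_scene_images(directory: str | os.PathLike, scene_id: str,
                       image4: np.ndarray) -> tuple[Path, Path]:
    """Write a 4-band image as a VIS (RGB) file and a UV file."""
    arr = np.asarray(image4)
    if arr.ndim != 3 or arr.shape[2] != 4:
        raise DataError("expected an (H, W, 4) image")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    vis_path = directory / f"{scene_id}_vis.tif"
    uv_path = directory / f"{scene_id}_uv.tif"
    write_image(vis_path, arr[..., :3])
    write_image(uv_path, arr[..., 3])
    return vis_path, uv_path


def read_scene_images(vis_path: str | os.PathLike,
                      uv_path: str | os.PathLike) -> np.ndarray:
    """Load a VIS + UV file pair back into an (H, W, 4) array."""
    vis = read_image(vis_path)
    uv = read_image(uv_path)
    if vis.ndim != 3 or vis.shape[2] != 3:
        raise DataError(f"VIS image must be (H, W, 3), got {vis.shape}")
    if uv.shape != vis.shape[:2]:
        raise DataError("UV image geometry does not match the VIS image")
    return np.dstack([vis, uv])


def write_table(path: str | os.PathLike, table: pd.DataFrame) -> None:
    tmp = f"{path}.tmp"
    table.to_csv(tmp, index=False)
    os.replace(tmp, path)


def read_table(path: str | os.PathLike) -> pd.DataFrame:
    try:
        return pd.read_csv(path)
    except Exception as exc:
        raise DataError(f"cannot read table {path}: {exc}") from exc
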