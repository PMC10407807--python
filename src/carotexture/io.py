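"""File I/O: 8-bit images, annotation JSON, polygon masks."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import imageio.v3 as iio
import tifffile
from skimage.draw import polygon as _sk_polygon

from .errors import CarotextureError

__all__ = [
    "read_image",
    "write_image",
    "read_image_annotation",
    "write_image_annotation",
    "polygon_mask",
]


def read_image(path) -> np.ndarray:
    """Read a single-channel 8-bit TIFF/PNG as a 2-D uint8 array."""
    path = Path(path)
    try:
        if path.suffix.lower() in (".tif", ".tiff"):
            arr = tifffile.imread(path)
        else:
            arr = iio.imread(path)
    except FileNotFoundError:
        raise
    except Exception as exc:  # decoder errors vary wildly across plugins
        raise CarotextureError(f"{path.name}: unreadable image ({exc})") from exc
    arr = np.asarray(arr)
    if arr.ndim == 3:  # collapse an RGB(A) export of a grayscale frame
        arr = arr[..., :3].mean(axis=2)
    if arr.ndim != 2:
        raise CarotextureError(f"{path.name}: expected a 2-D grayscale image")
    if arr.dtype != np.uint8:
        if arr.max() > 255 or arr.min() < 0:
            raise CarotextureError(f"{path.name}: intensities outside [0, 255]")
        arr = arr.astype(np.uint8)
    return arr


def write_image(path, pixels: np.ndarray):
    """Write a 2-D uint8 array as TIFF or PNG depending on the suffix."""
    path = Path(path)
    pixels = np.asarray(pixels, dtype=np.uint8)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, pixels)
    else:
        iio.imwrite(path, pixels)


def read_image_annotation(path) -> dict:
    """Read an ultrasound-frame annotation JSON.

    Layout::

        {"blood": [[x, y], ...], "adventitia": [[x, y], ...],
         "im_upper": [[x, y], ...], "im_lower": [[x, y], ...],
         "pixel_density_per_mm": 190}

    ``blood``/``adventitia`` are reference-region polygons; ``im_upper``
    and ``im_lower`` are the traced blood-intima and media-adventitia
    boundary polylines.
    """
    data = json.loads(Path(path).read_text())
    for key in ("blood", "adventitia", "im_upper", "im_lower"):
        if key not in data:
            raise CarotextureError(f"annotation file missing {key!r}")
        data[key] = np.asarray(data[key], dtype=float)
    data.setdefault("pixel_density_per_mm", 190.0)
    return data


def write_image_annotation(path, blood, adventitia, im_upper, im_lower,
                           pixel_density_per_mm: float = 190.0):
    data = {
        "blood": np.asarray(blood, dtype=float).tolist(),
        "adventitia": np.asarray(adventitia, dtype=float).tolist(),
        "im_upper": np.asarray(im_upper, dtype=float).tolist(),
        "im_lower": np.asarray(im_lower, dtype=float).tolist(),
        "pixel_density_per_mm": pixel_density_per_mm,
    }
    Path(path).write_text(json.dumps(data))


def polygon_mask(vertices, shape: tuple[int, int]) -> np.ndarray:
    """Rasterize an (x, y) polygon to a boolean mask of the given shape."""
    v = np.asarray(vertices, dtype=float)
    if v.ndim != 2 or v.shape[0] < 3:
        raise CarotextureError("a polygon needs at least three vertices")
    rr, cc = _sk_polygon(v[:, 1], v[:, 0], shape=shape)
    mask = np.zeros(shape, dtype=bool)
    mask[rr, cc] = True
    return mask
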