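"""Raster I/O helpers.

PNG/TIFF/PGM via imageio and tifffile; channel order in memory is always
(R, G, B) regardless of the on-disk dialect.  Label images are written as
16-bit TIFF so region ids survive round-trips.
"""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile

from .colorspace import ColorImage
from .errors import ConfigError

__all__ = [
    "read_color",
    "read_gray",
    "write_image",
    "write_mask",
    "write_labels",
    "read_labels",
]


def read_color(path: str | Path) -> ColorImage:
    """Read an image file as an 8-bit RGB :class:`ColorImage`.

    Grayscale files are replicated across channels; an alpha channel, if
    present, is dropped.
    """
    arr = np.asarray(iio.imread(Path(path)))
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    elif arr.ndim == 3 and arr.shape[2] >= 3:
        arr = arr[:, :, :3]
    else:
        raise ConfigError(f"unsupported image layout {arr.shape} in {path}")
    if arr.dtype != np.uint8:
        arr = np.clip(arr, 0, 255).astype(np.uint8)
    return ColorImage(arr, "rgb")


def read_gray(path: str | Path) -> np.ndarray:
    """Read a grayscale raster (color inputs are reduced by channel mean)."""
    arr = np.asarray(iio.imread(Path(path))).astype(np.float64)
    if arr.ndim == 3:
        arr = arr[:, :, :3].mean(axis=-1)
    return arr


def write_image(path: str | Path, img: "ColorImage | np.ndarray") -> None:
    """Write an RGB or grayscale 8-bit raster (format from the suffix)."""
    if isinstance(img, ColorImage):
        data = img.to_uint8().data
    else:
        data = np.asarray(img)
        if data.dtype != np.uint8:
            data = np.clip(np.floor(np.asarray(data, float) + 0.5), 0, 255).astype(np.uint8)
    iio.imwrite(Path(path), data)


def write_mask(path: str | Path, mask: np.ndarray) -> None:
    """Write a boolean mask as an 8-bit PNG (255 = True)."""
    iio.imwrite(Path(path), (np.asarray(mask, bool) * np.uint8(255)))


def write_labels(path: str | Path, labels: np.ndarray) -> None:
    """Write a label image as 16-bit TIFF (watershed lines stay 0)."""
    lab = np.asarray(labels)
    if lab.min() < 0 or lab.max() > np.iinfo(np.uint16).max:
        raise ConfigError("labels out of range for a 16-bit TIFF")
    tifffile.imwrite(Path(path), lab.astype(np.uint16))


def read_labels(path: str | Path) -> np.ndarray:
    """Read a label image written by :func:`write_labels`."""
    return np.asarray(tifffile.imread(Path(path))).astype(np.int32)
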