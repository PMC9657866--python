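"""Luminance/chrominance color decomposition.

The segmentation pipeline works on the luma (Y) plane of a color image:
luma carries the edge structure of the scene while being far less sensitive
than raw RGB to saturated specular highlights, which inject strong spurious
gradients into all three RGB channels at once.

Two coefficient sets are available for every conversion:

``"native"``
    The package's native coefficients.  The Y row is
    ``0.295 R + 0.585 G + 0.12 B`` (row sum exactly 1, so gray pixels map to
    themselves), and the two chroma rows are shared between the YUV and
    YCbCr variants (YCbCr adds a +128 offset per chroma plane).  Note these
    chroma rows do *not* map gray pixels to 128; they are kept as-is.

``"bt601"``
    The ITU-R BT.601 full-range coefficients (Y = 0.299 R + 0.587 G +
    0.114 B), the broadcast-standard benchmark.  This set round-trips
    RGB -> YCbCr -> RGB within one intensity level.

All conversions are per-pixel affine maps; the channel-space of an image is
carried as an explicit tag so that a plane is never misinterpreted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ChannelTagError, ConfigError, ShapeMismatchError

__all__ = [
    "ColorImage",
    "ColorModel",
    "rgb_to_ycbcr",
    "rgb_to_yuv",
    "rgb_to_yiq",
    "ycbcr_to_rgb",
    "luminance",
]

#: Recognized channel-space tags.
SPACES = ("rgb", "ycbcr", "yuv", "yiq")

# Y row shared by the three native spaces; rows sum to 1.000 exactly.
_NATIVE_Y = (0.295, 0.585, 0.12)
# Chroma rows shared by the native YUV and YCbCr variants.
_NATIVE_U = (-0.153, -0.317, 0.47)
_NATIVE_V = (0.500, -0.129, -0.081)

_MATRICES = {
    # space -> name -> (3x3 row-major matrix, offsets)
    "ycbcr": {
        # plane order (Y, Cb, Cr)
        "native": ((_NATIVE_Y, _NATIVE_U, _NATIVE_V), (0.0, 128.0, 128.0)),
        "bt601": (
            (
                (0.299, 0.587, 0.114),
                (-0.168736, -0.331264, 0.5),
                (0.5, -0.418688, -0.081312),
            ),
            (0.0, 128.0, 128.0),
        ),
    },
    "yuv": {
        "native": ((_NATIVE_Y, _NATIVE_U, _NATIVE_V), (0.0, 0.0, 0.0)),
        "bt601": (
            (
                (0.299, 0.587, 0.114),
                (-0.147108, -0.288804, 0.435912),
                (0.614777, -0.514799, -0.099978),
            ),
            (0.0, 0.0, 0.0),
        ),
    },
    "yiq": {
        "native": (
            (_NATIVE_Y, (0.496, -0.275, -0.221), (0.212, -0.423, 0.211)),
            (0.0, 0.0, 0.0),
        ),
        "bt601": (
            (
                (0.299, 0.587, 0.114),
                (0.595716, -0.274453, -0.321263),
                (0.211456, -0.522591, 0.311135),
            ),
            (0.0, 0.0, 0.0),
        ),
    },
}


def _round_half_up(x: np.ndarray) -> np.ndarray:
    """Round to nearest integer with .5 always going up."""
    return np.floor(np.asarray(x, dtype=np.float64) + 0.5)


@dataclass(frozen=True)
class ColorModel:
    """A named affine RGB -> (luma, chroma, chroma) transform.

    Attributes
    ----------
    name
        ``"native"`` or ``"bt601"``.
    space
        Target space the matrix produces (``"ycbcr"``, ``"yuv"``, ``"yiq"``).
    matrix
        3x3 coefficient matrix, one row per output plane.
    offsets
        Per-plane additive offsets applied after the matrix product.
    """

    name: str
    space: str
    matrix: np.ndarray = field(repr=False)
    offsets: np.ndarray = field(repr=False)

    @classmethod
    def get(cls, space: str, name: str = "native") -> "ColorModel":
        try:
            mat, off = _MATRICES[space][name]
        except KeyError:
            raise ConfigError(
                f"no color model {name!r} for space {space!r}; "
                f"spaces: {sorted(_MATRICES)}, names: 'native', 'bt601'"
            ) from None
        return cls(
            name=name,
            space=space,
            matrix=np.asarray(mat, dtype=np.float64),
            offsets=np.asarray(off, dtype=np.float64),
        )


@dataclass
class ColorImage:
    """A 3-plane raster with an explicit channel-space tag.

    ``data`` has shape ``(H, W, 3)``; intensities live on the 8-bit scale
    [0, 255] but may be stored as floats (e.g. exact conversion results
    before rounding).
    """

    data: np.ndarray
    space: str = "rgb"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if (
            self.data.ndim != 3
            or self.data.shape[2] != 3
            or self.data.shape[0] < 1
            or self.data.shape[1] < 1
        ):
            raise ShapeMismatchError(
                f"expected an (H, W, 3) raster with H, W >= 1, got shape {self.data.shape}"
            )
        if self.space not in SPACES:
            raise ChannelTagError(f"unknown channel space {self.space!r}")
        if not np.all(np.isfinite(np.asarray(self.data, dtype=np.float64))):
            raise ValueError("color image contains non-finite samples")

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape[:2]

    def plane(self, i: int) -> np.ndarray:
        """Return channel ``i`` as a 2-D array (a view when possible)."""
        return self.data[:, :, i]

    def require(self, space: str) -> None:
        if self.space != space:
            raise ChannelTagError(
                f"expected a {space!r}-tagged image, got {self.space!r}"
            )

    def to_uint8(self) -> "ColorImage":
        """Clamp to [0, 255] and round half-up to an 8-bit image."""
        d = _round_half_up(np.clip(self.data, 0.0, 255.0)).astype(np.uint8)
        return ColorImage(d, self.space)


def _convert(img: ColorImage, space: str, model, clamp: bool, integer: bool) -> ColorImage:
    img.require("rgb")
    if isinstance(model, str):
        model = ColorModel.get(space, model)
    elif model.space != space:
        raise ConfigError(f"model targets {model.space!r}, requested {space!r}")
    rgb = np.asarray(img.data, dtype=np.float64)
    out = np.einsum("ij,hwj->hwi", model.matrix, rgb) + model.offsets
    if clamp:
        out = np.clip(out, 0.0, 255.0)
    if integer:
        out = _round_half_up(np.clip(out, 0.0, 255.0)).astype(np.uint8)
    return ColorImage(out, space)


def rgb_to_ycbcr(
    img: ColorImage,
    model: "ColorModel | str" = "native",
    *,
    clamp: bool = True,
    integer: bool = False,
) -> ColorImage:
    """Convert an RGB image to (Y, Cb, Cr) planes.

    Parameters
    ----------
    img
        RGB-tagged :class:`ColorImage`.
    model
        ``"native"`` (default), ``"bt601"``, or an explicit
        :class:`ColorModel` targeting ``"ycbcr"``.
    clamp
        Clamp results to [0, 255] (the 8-bit pipeline convention).
    integer
        Additionally round half-up and return ``uint8`` planes.

    Returns
    -------
    ColorImage
        YCbCr-tagged image, float64 planes unless ``integer``.
    """
    return _convert(img, "ycbcr", model, clamp, integer)


def rgb_to_yuv(img, model="native", *, clamp=True, integer=False) -> ColorImage:
    """Convert RGB to YUV (no chroma offsets; negative chroma clamps to 0
    under the default 8-bit output policy, pass ``clamp=False`` for the raw
    affine values)."""
    return _convert(img, "yuv", model, clamp, integer)


def rgb_to_yiq(img, model="native", *, clamp=True, integer=False) -> ColorImage:
    """Convert RGB to YIQ (chroma I/Q are rotated U/V axes)."""
    return _convert(img, "yiq", model, clamp, integer)


def ycbcr_to_rgb(
    img: ColorImage,
    model: "ColorModel | str" = "native",
    *,
    integer: bool = True,
) -> ColorImage:
    """Invert :func:`rgb_to_ycbcr` (matrix inverse of the same model)."""
    img.require("ycbcr")
    if isinstance(model, str):
        model = ColorModel.get("ycbcr", model)
    ycc = np.asarray(img.data, dtype=np.float64) - model.offsets
    inv = np.linalg.inv(model.matrix)
    rgb = np.einsum("ij,hwj->hwi", inv, ycc)
    rgb = np.clip(rgb, 0.0, 255.0)
    if integer:
        rgb = _round_half_up(rgb).astype(np.uint8)
    return ColorImage(rgb, "rgb")


def luminance(img: ColorImage) -> np.ndarray:
    """Extract the Y plane of a YCbCr image as the working grayscale image.

    Returns a copy so downstream filtering never aliases the color planes.
    """
    img.require("ycbcr")
    return np.array(img.plane(0), copy=True)
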