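"""Morphological and multiscale morphological gradients.

A watershed wants a gradient whose ridge *height* equals the intensity jump
across an edge (not the edge slope, which is what derivative operators
report on blurred ramp edges).  The flat morphological gradient
``dilate - erode`` has that property; averaging it over several structuring
element radii ("scales"), each eroded back by the next-smaller element,
trades noise sensitivity against edge localization.
"""

from __future__ import annotations

from collections.abc import Sequence

import numpy as np

from .errors import ConfigError
from .morphology import StructuringElement, dilate, erode

__all__ = ["morphological_gradient", "multiscale_gradient", "rescale_to_8bit"]


def morphological_gradient(f: np.ndarray, se: StructuringElement) -> np.ndarray:
    """``dilate(f, se) - erode(f, se)``, elementwise; always >= 0.

    Returns float64 regardless of input dtype so later averaging and
    rescaling lose nothing to truncation.
    """
    a = np.asarray(f, dtype=np.float64)
    return dilate(a, se) - erode(a, se)


def _se_at(radius: int, shape: str) -> StructuringElement:
    if shape == "disk":
        return StructuringElement.disk(radius)
    if shape == "square":
        return StructuringElement.square(2 * radius + 1)
    raise ConfigError(f"unsupported SE shape for gradients: {shape!r}")


def multiscale_gradient(
    f: np.ndarray,
    scales: Sequence[int] = (1, 2, 3),
    shape: str = "disk",
) -> np.ndarray:
    """Mean of per-scale gradients, each eroded by the next-smaller SE.

    For each radius ``s`` in ``scales`` (ascending, positive):

    * ``m_s  = morphological_gradient(f, SE(s))``
    * ``mg_s = erode(m_s, SE(s - 1))`` -- radius 0 is the single-point SE,
      so the first scale passes through unchanged.

    The output is the arithmetic mean of the ``mg_s``, kept as reals.
    The erosion thins each coarse gradient ridge back toward the edge
    position before averaging, so coarse scales contribute height without
    smearing localization.
    """
    scales = list(scales)
    if not scales:
        raise ConfigError("scales must be a nonempty ascending list of positive radii")
    if any(s <= 0 for s in scales) or any(b <= a for a, b in zip(scales, scales[1:])):
        raise ConfigError(f"scales must be ascending positive radii, got {scales}")
    a = np.asarray(f, dtype=np.float64)
    acc = np.zeros_like(a)
    for s in scales:
        m = morphological_gradient(a, _se_at(s, shape))
        acc += erode(m, _se_at(s - 1, shape))
    return acc / len(scales)


def rescale_to_8bit(g: np.ndarray) -> np.ndarray:
    """Affinely map [min, max] to [0, 255] and round half-up to ``uint8``.

    A constant image maps to all zeros.  Used before any histogram-based
    step (Otsu, manual H-minima depths quoted on the 8-bit scale).
    """
    a = np.asarray(g, dtype=np.float64)
    lo, hi = float(a.min()), float(a.max())
    if hi == lo:
        return np.zeros(a.shape, dtype=np.uint8)
    out = (a - lo) * (255.0 / (hi - lo))
    return np.floor(out + 0.5).astype(np.uint8)
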