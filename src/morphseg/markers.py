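"""Automatic marker extraction for the marker-controlled watershed.

A watershed run directly on a gradient image floods from *every* regional
minimum, so gradient noise and fine texture shatter objects into spurious
basins.  The cure is to flood only from markers: deep gradient minima that
correspond to object interiors and background.  This module provides

* exact 256-bin histograms and Otsu's between-class-variance threshold
  (used to pick the minima-depth cutoff H automatically),
* the H-minima transform (suppresses regional minima of dynamic < h) and
  the extended-minima detector built on it,
* the per-scale union variant that pools extended minima of gradient
  images filtered at several structuring-element radii,
* :func:`extract_markers`, the mode dispatcher used by the pipeline.
"""

from __future__ import annotations

from collections.abc import Sequence
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import ConfigError, DegenerateHistogramError, NoMarkerError
from .gradient import rescale_to_8bit
from .morphology import (
    StructuringElement,
    connectivity_se,
    openclose_reconstruction_filter,
    reconstruct_by_erosion,
)

__all__ = [
    "Histogram",
    "OtsuResult",
    "histogram",
    "otsu_threshold",
    "hminima",
    "regional_minima",
    "extended_minima",
    "scale_union_markers",
    "extract_markers",
    "binarize_gradient",
    "label_markers",
]


@dataclass(frozen=True)
class Histogram:
    """Exact 256-bin gray-level histogram of an 8-bit image."""

    counts: np.ndarray = field(repr=False)  # (256,) int64

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=np.int64)
        if c.shape != (256,) or (c < 0).any():
            raise ConfigError("histogram needs 256 nonnegative counts")
        object.__setattr__(self, "counts", c)

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass(frozen=True)
class OtsuResult:
    """Outcome of exhaustive between-class-variance maximization.

    ``threshold`` assigns levels ``<= T`` to class 1 and ``> T`` to class 2;
    ``sigma2_profile[t]`` is the between-class variance of the candidate
    split at ``t`` (NaN where a class would be empty).  The area fractions
    and class means satisfy ``theta1 + theta2 == 1`` and the mixture
    identity ``u == u1 * theta1 + u2 * theta2``.
    """

    threshold: int
    sigma2_profile: np.ndarray = field(repr=False)
    theta1: float
    theta2: float
    u: float
    u1: float
    u2: float


def histogram(f: np.ndarray) -> Histogram:
    """Count pixels per gray level for an integer image with values 0..255."""
    a = np.asarray(f)
    if not np.issubdtype(a.dtype, np.integer):
        if not np.allclose(a, np.round(a)):
            raise ConfigError("histogram requires integer gray levels (rescale first)")
        a = np.round(a).astype(np.int64)
    if a.min() < 0 or a.max() > 255:
        raise ConfigError("histogram requires gray levels in [0, 255]")
    return Histogram(np.bincount(a.ravel().astype(np.int64), minlength=256))


def otsu_threshold(h: Histogram) -> OtsuResult:
    """Exhaustively maximize the between-class variance over all splits.

    For every candidate ``t`` the criterion is
    ``sigma_B^2(t) = theta1(t) * theta2(t) * (u1(t) - u2(t))^2``;
    the returned threshold is the smallest maximizing ``t``.

    Raises
    ------
    DegenerateHistogramError
        If fewer than two bins are occupied (no two-class split exists).
    """
    counts = h.counts
    n = int(counts.sum())
    if np.count_nonzero(counts) < 2:
        raise DegenerateHistogramError("histogram has fewer than two occupied gray levels")
    levels = np.arange(256, dtype=np.int64)
    # integer cumulants keep class emptiness and means exact
    c1 = np.cumsum(counts)  # class-1 pixel count at split t (levels <= t)
    s1 = np.cumsum(counts * levels)  # class-1 intensity sum
    s_total = int(s1[-1])
    c2 = n - c1
    valid = (c1 > 0) & (c2 > 0)
    w1 = c1 / n
    w2 = c2 / n
    with np.errstate(divide="ignore", invalid="ignore"):
        m1 = s1 / c1
        m2 = (s_total - s1) / c2
        sigma2 = np.where(valid, w1 * w2 * (m1 - m2) ** 2, np.nan)
    t = int(np.nanargmax(sigma2))  # ties: smallest t (argmax scans left to right)
    return OtsuResult(
        threshold=t,
        sigma2_profile=sigma2,
        theta1=float(w1[t]),
        theta2=float(w2[t]),
        u=s_total / n,
        u1=float(m1[t]),
        u2=float(m2[t]),
    )


def hminima(f: np.ndarray, h: float, connectivity: int = 8) -> np.ndarray:
    """Suppress every regional minimum of dynamic (depth) < ``h``.

    Implemented as reconstruction by erosion of ``f + h`` above ``f``; the
    result ``r`` satisfies ``f <= r <= f + h``.  Minima whose dynamic in
    ``f`` is below ``h`` are merged into their surroundings; each surviving
    minimum is one of the original image with dynamic >= ``h``, raised by
    ``h`` (so its residual depth is its original dynamic minus ``h``).
    """
    if h < 0:
        raise ConfigError("H-minima depth must be >= 0")
    a = np.asarray(f, dtype=np.float64)
    if h == 0:
        return a.copy()
    return reconstruct_by_erosion(a + h, a, connectivity)


def _shifts(connectivity: int):
    if connectivity == 4:
        return ((-1, 0), (1, 0), (0, -1), (0, 1))
    if connectivity == 8:
        return tuple(
            (u, v) for u in (-1, 0, 1) for v in (-1, 0, 1) if (u, v) != (0, 0)
        )
    raise ConfigError(f"connectivity must be 4 or 8, got {connectivity!r}")


def regional_minima(f: np.ndarray, connectivity: int = 8) -> np.ndarray:
    """Boolean mask of regional minima.

    A regional minimum is a maximal connected plateau of constant intensity
    whose exterior neighbors are all strictly greater.  A pixel is first
    excluded if it has a strictly lower neighbor; exclusion then propagates
    across equal-valued neighbors until stable, so partially-draining
    plateaus are rejected as a whole.
    """
    a = np.asarray(f, dtype=np.float64)
    if a.ndim != 2:
        raise ConfigError("regional_minima expects a 2-D image")
    h, w = a.shape
    shifts = _shifts(connectivity)
    padded = np.pad(a, 1, mode="constant", constant_values=np.inf)
    views = {s: padded[1 + s[0] : 1 + s[0] + h, 1 + s[1] : 1 + s[1] + w] for s in shifts}
    nonmin = np.zeros((h, w), dtype=bool)
    for s in shifts:
        nonmin |= views[s] < a
    # propagate "drains somewhere" across flat plateaus
    while True:
        pad_nm = np.pad(nonmin, 1, mode="constant", constant_values=False)
        grown = nonmin.copy()
        for s in shifts:
            nm_view = pad_nm[1 + s[0] : 1 + s[0] + h, 1 + s[1] : 1 + s[1] + w]
            grown |= nm_view & (views[s] == a)
        if np.array_equal(grown, nonmin):
            return ~nonmin
        nonmin = grown


def extended_minima(f: np.ndarray, h: float, connectivity: int = 8) -> np.ndarray:
    """Regional minima of the H-minima transform: minima of dynamic >= h."""
    return regional_minima(hminima(f, h, connectivity), connectivity)


def binarize_gradient(f: np.ndarray, t: float) -> np.ndarray:
    """Literal ``f > t`` binarization of a gradient image.

    Diagnostic only: this marks edge ridges, not basins, and cannot seed a
    watershed; see :func:`scale_union_markers` for the marker semantics.
    """
    return np.asarray(f, dtype=np.float64) > t


def scale_union_markers(
    f: np.ndarray,
    scales: Sequence[int] = (1, 2, 3),
    t: float = 0.0,
    shape: str = "disk",
    connectivity: int = 8,
) -> np.ndarray:
    """Union over SE radii of depth-filtered minima of the filtered gradient.

    For each radius ``r`` the gradient is simplified with the open-close
    reconstruction filter at that radius and its extended minima at depth
    ``t`` are collected; the union over radii marks objects that survive at
    any of the scales.
    """
    if not scales or any(s <= 0 for s in scales):
        raise ConfigError("scales must be nonempty positive radii")
    a = np.asarray(f, dtype=np.float64)
    out = np.zeros(a.shape, dtype=bool)
    for r in scales:
        se = (
            StructuringElement.disk(r)
            if shape == "disk"
            else StructuringElement.square(2 * r + 1)
        )
        filtered = openclose_reconstruction_filter(a, se, connectivity)
        out |= extended_minima(filtered, t, connectivity)
    return out


def extract_markers(
    grec: np.ndarray,
    mode: str = "otsu_hmin",
    h_manual: float | None = None,
    scales: Sequence[int] = (1, 2, 3),
    connectivity: int = 8,
) -> np.ndarray:
    """Extract a binary marker mask from a (reconstructed) gradient image.

    Modes
    -----
    ``"otsu_hmin"`` (default)
        H = Otsu threshold of the 8-bit-rescaled gradient histogram, then
        extended minima at depth H.  Fully automatic.
    ``"manual"``
        Extended minima at the user-supplied depth ``h_manual`` (quoted on
        the 8-bit scale).
    ``"scale_union"``
        :func:`scale_union_markers` on the gradient, using ``h_manual`` as
        the depth if given, else the Otsu-derived H.

    Raises
    ------
    DegenerateHistogramError
        Flat gradient in an Otsu-based mode.
    NoMarkerError
        The marker mask came out empty.
    """
    g8 = rescale_to_8bit(grec)
    if mode == "manual":
        if h_manual is None or h_manual < 0:
            raise ConfigError("manual marker mode requires a nonnegative depth")
        mask = extended_minima(g8.astype(np.float64), float(h_manual), connectivity)
    elif mode == "otsu_hmin":
        h = float(otsu_threshold(histogram(g8)).threshold)
        mask = extended_minima(g8.astype(np.float64), h, connectivity)
    elif mode == "scale_union":
        depth = (
            float(h_manual)
            if h_manual is not None
            else float(otsu_threshold(histogram(g8)).threshold)
        )
        mask = scale_union_markers(
            g8.astype(np.float64), scales=scales, t=depth, connectivity=connectivity
        )
    else:
        raise ConfigError(f"unknown marker mode {mode!r}")
    if not mask.any():
        raise NoMarkerError(f"marker extraction ({mode}) produced an empty marker set")
    return mask


def label_markers(mask: np.ndarray, connectivity: int = 8) -> tuple[np.ndarray, int]:
    """Connected-component labeling of a marker mask (helper)."""
    structure = connectivity_se(connectivity).footprint
    lab, n = ndimage.label(mask, structure=structure)
    return lab, int(n)
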