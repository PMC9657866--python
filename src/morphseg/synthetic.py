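"""Seeded generator of grain/cell-like test scenes with ground truth.

The generator emulates the conditions the segmentation pipeline is built
for: bright convex objects (rice grains, chips, nuclei) on a darker
background, optionally carrying saturated specular highlights ("reflected
light"), a linear illumination ramp, per-channel Gaussian sensor noise, and
salt-and-pepper (impulse) corruption added separately.  Every scene carries
a crisp per-pixel ground truth and regenerates bit-identically from its
recorded parameters.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import numpy as np

from .colorspace import ColorImage
from .errors import ConfigError, PackingError

__all__ = ["GrainSceneParams", "SyntheticScene", "generate_grains", "add_salt_pepper"]


@dataclass(frozen=True)
class GrainSceneParams:
    """Full parameter record of a generated scene (regeneration key)."""

    n_objects: int = 20
    height: int = 256
    width: int = 256
    radius_min: float = 8.0
    radius_max: float = 14.0
    aspect_max: float = 1.3
    object_intensity: float = 180.0
    background_intensity: float = 70.0
    illumination_slope: float = 0.0  # gray levels per pixel along columns
    specular_fraction: float = 0.5
    specular_radius_fraction: float = 0.25  # of the minor semi-axis
    noise_sd: float = 3.0
    min_gap: float = 10.0  # clearance between object boundaries, px
    seed: int = 0

    def as_dict(self) -> dict:
        return asdict(self)


@dataclass
class SyntheticScene:
    """A rendered scene with its ground truth.

    ``truth_labels`` uses 1 for the background region and 2..n+1 for the
    objects (no watershed-line pixels in the truth);
    ``truth_foreground`` is ``truth_labels >= 2``.
    """

    image: ColorImage
    truth_labels: np.ndarray
    truth_foreground: np.ndarray
    params: GrainSceneParams = field(repr=False)

    @property
    def n_regions(self) -> int:
        """Ground-truth region count (objects + background)."""
        return int(self.truth_labels.max())


def _place_ellipses(p: GrainSceneParams, rng: np.random.Generator):
    """Rejection-sample non-overlapping ellipse parameters."""
    placed = []  # (cy, cx, a, b, theta) with a = major semi-axis
    attempts = 0
    limit = 1000 * max(p.n_objects, 1)
    while len(placed) < p.n_objects:
        if attempts >= limit:
            raise PackingError(
                f"could not place {p.n_objects} objects of radius "
                f"{p.radius_min}-{p.radius_max} on a {p.height}x{p.width} canvas "
                f"with {p.min_gap} px clearance"
            )
        attempts += 1
        r = rng.uniform(p.radius_min, p.radius_max)
        aspect = rng.uniform(1.0, p.aspect_max)
        a, b = r * aspect, r
        theta = rng.uniform(0.0, np.pi)
        margin = a + 2.0
        if 2 * margin >= min(p.height, p.width):
            raise PackingError("objects do not fit on the canvas")
        cy = rng.uniform(margin, p.height - margin)
        cx = rng.uniform(margin, p.width - margin)
        ok = all(
            np.hypot(cy - qy, cx - qx) >= a + qa + p.min_gap
            for qy, qx, qa, _, _ in placed
        )
        if ok:
            placed.append((cy, cx, a, b, theta))
    return placed


def generate_grains(
    n_objects: int = 20,
    shape: tuple[int, int] = (256, 256),
    radius_range: tuple[float, float] = (8.0, 14.0),
    object_intensity: float = 180.0,
    background_intensity: float = 70.0,
    illumination_slope: float = 0.0,
    specular_fraction: float = 0.5,
    noise_sd: float = 3.0,
    min_gap: float = 10.0,
    aspect_max: float = 1.3,
    seed: int = 0,
) -> SyntheticScene:
    """Render a grain scene with per-pixel ground truth.

    Parameters
    ----------
    n_objects
        Number of non-overlapping ellipses to place (0 gives a
        background-only scene).
    shape
        Canvas (height, width) in pixels.
    radius_range
        Minor semi-axis range in pixels; the major axis is up to
        ``aspect_max`` times longer.
    object_intensity, background_intensity
        Mean 8-bit gray levels of objects and background.
    illumination_slope
        Linear shading, gray levels per pixel along the column axis
        (0 = flat lighting).
    specular_fraction
        Fraction of objects receiving a saturated (255, 255, 255) circular
        highlight patch, emulating reflected light.
    noise_sd
        Per-channel Gaussian sensor noise standard deviation.
    min_gap
        Minimum clearance between object boundaries in pixels.
    seed
        RNG seed; identical parameters reproduce the scene bit-for-bit.

    Raises
    ------
    PackingError
        If the objects cannot be placed after bounded retries.
    """
    if n_objects < 0:
        raise ConfigError("n_objects must be >= 0")
    lo, hi = radius_range
    if lo <= 0 or hi < lo:
        raise ConfigError("radius_range must satisfy 0 < min <= max")
    params = GrainSceneParams(
        n_objects=n_objects,
        height=int(shape[0]),
        width=int(shape[1]),
        radius_min=float(lo),
        radius_max=float(hi),
        aspect_max=float(aspect_max),
        object_intensity=float(object_intensity),
        background_intensity=float(background_intensity),
        illumination_slope=float(illumination_slope),
        specular_fraction=float(specular_fraction),
        noise_sd=float(noise_sd),
        min_gap=float(min_gap),
        seed=int(seed),
    )
    rng = np.random.default_rng(params.seed)
    h, w = params.height, params.width
    rows, cols = np.mgrid[0:h, 0:w].astype(np.float64)

    labels = np.ones((h, w), dtype=np.int32)  # background region = 1
    base = np.full((h, w), params.background_intensity, dtype=np.float64)
    if params.illumination_slope:
        base += params.illumination_slope * (cols - w / 2.0)

    ellipses = _place_ellipses(params, rng) if n_objects else []
    for i, (cy, cx, a, b, theta) in enumerate(ellipses):
        dy, dx = rows - cy, cols - cx
        du = dx * np.cos(theta) + dy * np.sin(theta)
        dv = -dx * np.sin(theta) + dy * np.cos(theta)
        inside = (du / a) ** 2 + (dv / b) ** 2 <= 1.0
        labels[inside] = i + 2
        base[inside] = params.object_intensity
        if params.illumination_slope:
            base[inside] += params.illumination_slope * (cols[inside] - w / 2.0)

    # specular highlights on a seeded subset of objects
    n_spec = int(round(params.specular_fraction * len(ellipses)))
    spec_idx = rng.choice(len(ellipses), size=n_spec, replace=False) if n_spec else []
    spec_mask = np.zeros((h, w), dtype=bool)
    for i in spec_idx:
        cy, cx, a, b, theta = ellipses[i]
        # random interior center, well inside the boundary
        off_u = rng.uniform(-0.4, 0.4) * a
        off_v = rng.uniform(-0.4, 0.4) * b
        py = cy + off_u * np.sin(theta) + off_v * np.cos(theta)
        px = cx + off_u * np.cos(theta) - off_v * np.sin(theta)
        pr = params.specular_radius_fraction * b
        patch = (rows - py) ** 2 + (cols - px) ** 2 <= pr * pr
        spec_mask |= patch & (labels == i + 2)

    rgb = base[:, :, None] + rng.normal(0.0, params.noise_sd, size=(h, w, 3))
    rgb[spec_mask] = 255.0  # saturated highlight, all channels
    rgb = np.clip(np.floor(rgb + 0.5), 0, 255).astype(np.uint8)

    return SyntheticScene(
        image=ColorImage(rgb, "rgb"),
        truth_labels=labels,
        truth_foreground=labels >= 2,
        params=params,
    )


def add_salt_pepper(img: ColorImage, density: float, seed: int = 0) -> ColorImage:
    """Replace each pixel, with probability ``density``, by pure black or
    pure white (equal odds); the classic impulse-noise model.

    The replacement is per pixel (all three channels saturate together),
    matching how transmission dropouts corrupt color images.
    """
    if not 0.0 <= density <= 1.0:
        raise ConfigError("salt-and-pepper density must lie in [0, 1]")
    img.require("rgb")
    rng = np.random.default_rng(seed)
    h, w = img.shape
    out = np.array(img.data, copy=True)
    hit = rng.random((h, w)) < density
    white = rng.random((h, w)) < 0.5
    out[hit & white] = 255
    out[hit & ~white] = 0
    return ColorImage(out, "rgb")
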