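# Methods

`morphseg` segments color images of bright, roughly convex objects
(grains, chips, cell nuclei) on a darker background with a
marker-controlled immersion watershed built entirely from flat grayscale
morphology.  This note records the model, the parameter choices that
matter, the numerical conventions, and what the synthetic test scenes do
and do not demonstrate.

## Pipeline model

The watershed transform treats a gradient image as a topographic relief
and floods it from its regional minima; the flood fronts meet on
watershed lines, which are the object contours.  Run naively on a raw
gradient the transform over-segments badly, because every noise or
texture minimum spawns a basin.  The pipeline controls this at three
points:

1. **Gradient construction.**  The working grayscale image is the luma
   (Y) plane of a YCbCr decomposition.  After an open–close prefilter
   (flat disk, radius 4 by default) the gradient is the *multiscale
   morphological gradient*: for disk radii `s = 1, 2, 3`,
   `mg_s = erode(dilate(f, B_s) − erode(f, B_s), B_{s−1})`, averaged over
   scales (radius 0 = the identity element).  Unlike derivative
   operators, the flat morphological gradient reports the intensity
   *height* of an edge rather than its slope, which is what the flooding
   depth semantics need; the inner erosion pulls each coarse ridge back
   toward the edge position before averaging.  Gradient arithmetic stays
   in floats; rescaling to the 8-bit range happens once, before any
   histogram is taken, so averaging never truncates.

2. **Marker extraction.**  The 8-bit gradient is simplified with an
   open–close *reconstruction* filter (radius 1), which deletes extrema
   smaller than the element while restoring surviving contours exactly.
   Markers are the extended minima of this surface at depth `H`, i.e. the
   regional minima that survive an H-minima transform
   (`reconstruct_by_erosion(f + H, f)`).  `H` is chosen automatically as
   the Otsu threshold of the simplified gradient's histogram: the
   between-class variance `θ1·θ2·(u1 − u2)²` is maximized exhaustively
   over all 256 candidate splits (integer cumulants, ties to the smallest
   threshold).  This replaces the hand-tuned depth of classical H-minima
   marking; fixed depths (e.g. 5/15/25 on the 8-bit scale) remain
   available as `marker_mode="manual"`, and a per-scale union variant
   (`"scale_union"`) pools extended minima of the gradient filtered at
   several radii.

3. **Minima imposition and flooding.**  The *original* (unreconstructed)
   multiscale gradient — optionally peak-enhanced, below — is rewritten
   so its regional minima are exactly the marker components
   (reconstruction by erosion of a 0/max marker function).  The immersion
   watershed then floods this surface with an ordered priority queue
   seeded at the markers; within a gray level, ties resolve
   first-in-first-out.  A pixel whose decided neighbors belong to two
   different basins becomes a watershed-line pixel (label 0) and the
   flood continues past it, so lines stay one pixel thin, every pair of
   adjacent basins is separated by a closed line, and the basin count
   equals the marker-component count by construction.  This priority-
   flood formulation was chosen over the classical per-level
   sort-and-FIFO sweep because the latter can leave two basins touching
   across a two-pixel-wide crest without any line pixel; the
   contract — deterministic labels, one basin per marker, complete
   lines — is what the rest of the package relies on.

**Peak enhancement.**  The smoothing inherent in the multiscale gradient
weakens faint edges.  A Canny detector (derivative-of-Gaussian gradients,
4-sector non-maximum suppression, Otsu-derived double thresholds with
`low = 0.4·high`, hysteresis by connected components) runs on each of the
three YCbCr planes; the three maps are OR-fused so iso-luminant color
edges survive.  Along the fused edges, dilated by one pixel to absorb the
registration offset between the Canny localization and the morphological
ridge, the flooded gradient is raised by
`g' = g + β·(max(g) − g)` with `β = 0.5` by default.  No published
formula exists for this correction; the β-deficit rule is this package's
own definition, it never decreases any pixel, never touches non-edge
pixels, and can be disabled (`enhance_peaks=False`).  Crucially, markers
are extracted from the *un-enhanced, reconstructed* gradient: enhancing
first would let specular-highlight rings seed spurious basins, which is
precisely the failure mode the pipeline is meant to suppress.

## Color conversion

Two coefficient sets are provided.  The package's native set uses
`Y = 0.295R + 0.585G + 0.12B` (row sum exactly 1, so gray pixels keep
their value) with chroma rows `(0.5, −0.129, −0.081)` and
`(−0.153, −0.317, 0.47)`, offset by +128 in YCbCr; the same Y row feeds
the YUV and YIQ variants.  The `bt601` set carries the ITU-R BT.601
broadcast coefficients and round-trips RGB→YCbCr→RGB within ±1 intensity
level.  The native chroma rows do not map gray pixels to 128; they are
kept as printed rather than re-normalized, since only the Y plane feeds
the segmentation path.  All conversions clamp to [0, 255] (8-bit
pipeline); rounding is half-up when integer planes are requested, and
float planes are available for the gradient path.

## Numerical conventions

* **Flat structuring elements only**, with domain-restricted borders
  (extrema over in-image samples, equivalent to ±inf padding).  `disk(r)`
  is the Euclidean disk `u² + v² ≤ r²`; `disk(1)` is the 4-neighborhood
  plus center; connectivity elements are `disk(1)` (4) and the 3×3 square
  (8; the default everywhere).
* **Reconstruction** is iterated vectorized geodesic dilation/erosion to
  the fixed point; the contract is the fixed point, not the schedule, and
  termination is guaranteed because every intermediate value is drawn
  from the finite set of input values.
* **H-minima depth accounting.**  A minimum surviving `hminima(f, h)` is
  an original minimum of dynamic ≥ h raised by h, so its *residual*
  depth is its original dynamic minus h.  Depth guarantees are therefore
  stated—and tested—against the original image's dynamics, not the
  transformed one, matching what `imhmin`-style implementations actually
  do.
* **Otsu on integers.**  Class weights and means use integer cumulative
  sums, so class emptiness is decided exactly and the mixture identity
  `u = u1θ1 + u2θ2` holds to machine precision at every candidate split.
* **Degenerate inputs.**  A featureless image yields a flat gradient and
  raises a no-marker error rather than returning an arbitrary partition;
  undefined precision/recall ratios are reported as 0 with an explicit
  flag so batch tables stay rectangular.

## Synthetic scenes and what the tests show

`generate_grains` renders non-overlapping ellipses (minor semi-axis
8–14 px, aspect ≤ 1.3, ≥ 10 px clearance) at intensity 180 on a
70-intensity background on a 256×256 canvas, with per-channel Gaussian
noise (σ = 3), an optional linear illumination ramp, and saturated
(255, 255, 255) circular specular patches — radius 25 % of the minor
semi-axis, random interior center — on half the objects by default.
Salt-and-pepper corruption (each pixel replaced by pure black or white
with equal odds) is applied separately at density 0.02 in the test
conditions.  Everything is seeded and regenerates bit-identically.

The evaluation study (10 scenes, 20 objects each; the same sizes are used
by the acceptance script) measures pixel precision/recall of the
recovered foreground.  Basins are classified as object when their mean
(median-filtered) luma exceeds the image's Otsu threshold; a watershed-
line pixel bounding an object basin counts as object when its own luma is
above the threshold, so the one-pixel contour straddling the true edge is
split between object and background at sub-pixel fidelity instead of
being attributed wholesale to one side.

These scenes exercise the failure modes the pipeline targets — specular
highlights, impulse noise, near-tangent objects — but they are
intensity-homogeneous, crisp-edged, and noise-independent across pixels.
Passing them demonstrates over-segmentation control and boundary accuracy
under those conditions; it does not demonstrate robustness to textured
objects, blur, vignetting-scale shading, or correlated sensor noise.

## Default parameters

| Parameter | Default | Why |
|---|---|---|
| prefilter SE | disk(4) | removes specular bumps (≤ ~4 px) without rounding grains of radius ≥ 8 |
| median window | 3×3 | standard impulse-noise suppressor; 0 disables |
| gradient scales | 1, 2, 3 | three disk radii; more scales trade localization for smoothness |
| reconstruction SE | disk(1) | deletes single-pixel gradient extrema, keeps contours exact |
| marker mode | `otsu_hmin` | parameter-free depth selection |
| β (peak enhancement) | 0.5 | half-deficit raise; 0 disables, 1 saturates edges to the max |
| Canny σ / thresholds | 1.0 / auto | Otsu-derived `high`, `low = 0.4·high` |
| connectivity | 8 | 4 selectable everywhere |

## Known limitations

* The Canny peak-enhancement correction is a package-defined rule (no
  published formula); its benefit is geometric (line placement), not
  region-count, and it can be switched off.
* The watershed inner loop is pure Python over a heap; a 256×256 scene
  segments in about a second, but megapixel images will be slow.
* Basin classification assumes bright objects on a darker background; for
  the inverse polarity, invert the image before evaluation.
* The native color coefficients are non-standard (chroma rows do not
  center gray at 128); use `bt601` when interoperability matters.
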