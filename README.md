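# morphseg

Marker-controlled watershed segmentation of color images, built from flat
grayscale morphology.

`morphseg` is for images of bright, roughly convex objects on a darker
background — rice grains, colored chips, seeds, cell nuclei — where the
goal is a closed, single-pixel contour around every object and nothing
else.  A plain watershed transform of a gradient image shatters such
scenes into hundreds of noise basins; `morphseg` suppresses the
over-segmentation with automatically extracted markers and is explicitly
hardened against two classic spoilers: saturated specular highlights
("reflected light") inside objects, and salt-and-pepper noise.

## Method

For an RGB image `I` the pipeline computes, in order:

1. **Y = luma(YCbCr(I))** — the working grayscale image (specular
   highlights perturb all RGB channels at once; luma isolates them), with
   an optional 3×3 median prefilter against impulse noise;
2. **open–close prefilter** — flat-disk opening then closing of `Y`
   removes bright specular bumps and fine texture;
3. **multiscale morphological gradient** —
   `G = mean_s erode(δ_Bs(Y) − ε_Bs(Y), B_{s−1})` over disk radii
   `s = 1, 2, 3`; a flat morphological gradient reports edge *height*
   (the gray jump across the edge), which is what flooding depth needs;
4. **markers** — `G` is simplified by an open–close *reconstruction*
   filter, the depth `H` is chosen as the Otsu maximizer of
   `θ1 θ2 (u1 − u2)²` on the gradient histogram, and the markers
   `P = EMIN_H(G_rec)` are the regional minima of dynamic ≥ H;
5. **peak enhancement** — Canny edges of the three YCbCr planes,
   OR-fused, raise the gradient along true boundaries:
   `G' = G + β (max G − G)` on edge pixels (β = 0.5);
6. **minima imposition + immersion watershed** —
   `labels = WS(Mormin(G', P))`: the regional minima of `G'` are forced
   to be exactly the marker components, then an ordered flood labels
   basins `1..K` and one-pixel watershed lines `0`.  Basin count equals
   marker count by construction.

Every stage is exposed as a library function (`dilate`, `erode`,
`reconstruct_by_dilation`, `hminima`, `otsu_threshold`,
`watershed_transform`, ...), and the pipeline as `segment`.
See `docs/methods.md` for assumptions, parameter rationale and limits.

## Worked example

```python
from morphseg import (PipelineConfig, add_salt_pepper, classify_foreground,
                      confusion_counts, generate_grains, luminance,
                      median_filter, rgb_to_ycbcr, segment)

scene = generate_grains(n_objects=20, specular_fraction=0.5, seed=11)
noisy = add_salt_pepper(scene.image, density=0.02, seed=12)

result = segment(noisy, PipelineConfig())
print("otsu H:        ", result.provenance["otsu_h"])
print("markers found: ", result.provenance["n_markers"])
print("basins:        ", result.n_regions, "(truth:", scene.n_regions, "regions)")

gray = median_filter(luminance(rgb_to_ycbcr(noisy)), 3)
fg = classify_foreground(result.labels, gray)
m = confusion_counts(fg, scene.truth_foreground)
print(f"precision:      {m.precision:.4f}")
print(f"recall:         {m.recall:.4f}")
```

prints

```
otsu H:         21.0
markers found:  21
basins:         21 (truth: 21 regions)
precision:      0.9952
recall:         0.9964
```

The scene has 20 grains (half with saturated highlights) plus background
= 21 true regions; the Otsu-selected depth H = 21 yields exactly one
marker per region, the watershed returns exactly 21 basins (no
over-segmentation from highlights or impulse noise), and the recovered
foreground agrees with ground truth to better than half a percent of
pixels in both directions.

The same pipeline is scriptable from a shell:

```sh
morphseg synth   --out-image scene.png --out-truth truth.tif --seed 11
morphseg segment --input scene.png --output labels.tif \
                 --overlay lines.png --foreground fg.png --provenance run.json
morphseg evaluate --pred fg.png --truth truth.tif --out-csv metrics.csv
```

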