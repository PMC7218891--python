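# Methods

## Problem and approach

Crops and weeds that share color and general morphology — e.g. canola and
wild radish rosettes — defeat color-index classifiers, and plain texture
descriptors degrade when plants are photographed at different growth
stages.  This package implements a two-branch descriptor that separates
the two sources of signal:

* **pass branch** — filtered multi-scale local binary pattern (LBP)
  histograms of the raw grayscale image: leaf-surface *texture*;
* **cmask branch** — the same LBP machinery applied to a thin contour
  band traced along the segmented plant boundary: leaf-margin *shape*.

The branches are fused elementwise as `k·pass + cmask` and classified by
a one-vs-one RBF-kernel SVM under stratified 5-fold cross-validation.
Because the contour band is a local, scale-free encoding of margin style
(smooth vs lobed vs serrated vs blade), the fused descriptor transfers
from large (mature) to small (early-stage) plants far better than
whole-image texture alone.

## Pipeline definition

**Segmentation.**  Vegetation is the set of pixels with positive excess
green minus excess red index on chromatic coordinates
`r = R/(R+G+B)` etc.: `ExG = 2g − r − b`, `ExR = 1.4r − g`, vegetation ⇔
`ExG − ExR > 0`.  Pixels with `R+G+B = 0` are background.  The index is
invariant to uniform brightness scaling.

**Smoothing and contour band.**  The RGB image is smoothed channelwise by
morphological opening then closing with a square 5×5 structuring element
(edge-replicated borders), segmented, and the *inner* boundary band is
extracted as `veg AND NOT erode^t(veg)` with a 3×3 element applied
`t = thickness` times (default 2).  Along a straight edge the band is
exactly `t` px wide; for a solid a×b rectangle its pixel count is
`a·b − (a−2t)(b−2t)`, which the tests assert.  An outer band
(`dilate^t(veg) AND NOT veg`) is available via
`MorphologyConfig(band_style="outer")`.

**LBP codes.**  For each operator `(P, R)` — default multiresolution
triple (8,1), (16,2), (24,3) — each interior pixel compares `P`
circularly interpolated neighbors at radius `R` against the center with
the `neighbor ≥ center → 1` tie convention.  Patterns with ≤ 2 circular
transitions map to their bit count (0..P), all others to the single
non-uniform code P+1 ("riu2"), giving `P+2` bins per operator and a
54-dimensional concatenation for the default triple.  Bilinear
interpolation samples non-integer neighbor positions; interpolated values
are rounded to 6 decimals before comparison so exact ties in flat regions
are platform-independent.  Border pixels of width `R` are excluded.

**Filtering and normalization.**  Each operator histogram has its single
highest bin zeroed (ties → lowest index).  Plant images are dominated by
one flat-region pattern (code `P`), so this removes an uninformative
majority and spreads weight over discriminative bins.  Each filtered
histogram is then L1-normalized (an all-zero histogram stays zero) before
concatenation, making vectors comparable across image sizes and stages.

**cmask input.**  The contour band is itself rasterized as a 0/255 image
and fed to the LBP operators.  On a binary raster every background pixel
and every interior band pixel takes the all-ones code `P` (the dominant
bin, removed by filtering), so the surviving mass describes precisely the
band-edge geometry: straight runs, convex corners, concave notches.  The
alternative reading — grayscale texture restricted to the band region —
is exposed as `LBPConfig(cmask_input="grayscale")`.

**Fusion and classification.**  `combined = k·pass + cmask` (defaults
`k = 0.2`, `thickness = 2`).  `k = 0` reduces to pure contour features.
The SVM defaults to `C = 30`; `gamma` defaults to the median heuristic
`γ = 1/median‖xᵢ−xⱼ‖²` computed on the training fold (capped at 500 rows,
deterministic), because fixed γ magnitudes appropriate for raw histogram
counts are meaningless after L1 normalization rescales features by
roughly four orders of magnitude.  `gamma="scale"` and explicit floats
remain available; grid search covers C ∈ {1, 10, 30, 100, 1000},
γ ∈ {10⁻⁸…10⁻¹}, k ∈ {0, 0.1, 0.2, 0.5, 1}, thickness ∈ {1, 2, 3} with
ties resolved to the earliest cell in (C, γ, k, thickness) ascending
order.  Feature standardization is off by default (histograms are already
normalized) and, when enabled, is fit on the training fold only.

**Cross-validation determinism.**  Images are sorted by
(label, stage, rotation, SHA-1 of pixels) before the seed-driven
stratified shuffle, so results are invariant to input row order and
bitwise reproducible per seed.

## Synthetic data generator

The generator emulates the *structure* of laboratory crop/weed datasets
at desk scale: 228×228 RGB scenes of a brown soil texture plus one or two
green plants, rendered across growth stages (scale), eight 45° rotations,
and illumination gains in [0.75, 1.25], with additive Gaussian pixel
noise (σ = 3/255).  Stages map to scale as {1: 0.30, 2: 0.45, 3: 0.70,
4: 1.00}; a stage-4 plant fills (and its lobes overflow) the frame.

Species are deliberately near-identical in hue (HSV 0.300/0.315/0.330)
and equalized in expected leaf area, so color and size carry almost no
class signal; they differ in margin morphology and venation-stripe
frequency:

| species      | margin                                             | venation (cy/px) |
|--------------|----------------------------------------------------|------------------|
| canola_like  | shallow smooth lobes (depth 0.08, 7 lobes)         | 0.050            |
| radish_like  | deep lobes (0.35, 5) + fine serration (0.15, 36)   | 0.110            |
| barley_like  | 7 narrow grass blades                              | 0.080            |

Leaves are star-shaped polygons with cosine-series margin modulation
(area-normalized so species differ in shape, not size), rasterized
analytically; blades are tapered quadrilaterals.  A `background` class
renders bare soil.  Two species in one scene give a mixed class.  A
dataset refuses specs that differ only in hue, enforcing the premise that
color must not be the discriminating feature.

The margin contrast was chosen so that the class separation in contour
feature space dominates the systematic cross-scale shift of those
features: boundary-corner density per band pixel falls roughly as
1/scale for *both* classes (a covariate shift along the same axis that
separates smooth from serrated margins), so a smooth-vs-strongly-serrated
contrast keeps stage-2 test points on the correct side of a boundary
learned at stage 4.  This mirrors what makes the method work on real
plants, where margin style is a scale-stable property of the species.

**What passing tests do not show.**  The renderer has no occlusion,
shadows, soil clutter, damaged leaves, specular highlights, or natural
illumination fields, and its margins are low-order harmonic — not real
leaf outlines.  Results on it demonstrate the internal consistency and
scale-transfer mechanics of the pipeline, not field performance.

## Numerical choices and degenerate inputs

* Constant images produce all-zero feature vectors (the only occupied bin
  is dominant and removed); an image without vegetation produces an
  all-zero cmask vector.  Zero vectors are valid SVM inputs.
* Dominant-bin ties break to the lowest bin index; grid ties to the
  earliest cell; the neighbor-vs-center tie counts as 1.
* Morphology pads by edge replication, so image borders generate no
  spurious contour bands and opening/closing is translation-equivariant
  away from borders.
* Erosion applied `t` times with the 3×3 square equals erosion by a
  (2t+1)² square, giving the exact rectangle band formula above.
* The median-heuristic γ falls back to `"scale"` if all training rows
  coincide.

## Experiment sizes

The shipped experiments run at desk scale: same-stage CV uses 4 classes ×
100 images (stages 2–4 interleaved), and stage transfer trains on 2 × 200
stage-4 images and tests on 2 × 100 stage-2 images, all at 228×228.  At
these sizes feature extraction is ~60 ms/image and either experiment
completes in about a minute on one CPU.

## Known limitations

* The cmask branch on binary band rasters discards band *placement*; two
  different plants with identical margin statistics are indistinguishable
  to it (by design — that is what makes it scale- and rotation-robust).
* Stage transfer degrades when the training scale's smoothing (5×5)
  erases margin detail that is still visible at the test scale, or vice
  versa; margins whose roughness lives at a single spatial frequency are
  the worst case.
* The grid search evaluates each cell by full 5-fold CV (no nested CV),
  so its best accuracy is an optimistic estimate of generalization.
* `pass_region="vegetation"` and `cmask_input="grayscale"` are provided
  but not exercised by the shipped experiments.
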