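# Methods

This note documents the models, conventions and numerical choices behind
`phenotraits`: what each trait means, how the synthetic scenes are built,
and where the design was genuinely open.

## Measurement model

The unit of analysis is one image of one plant (top-view rosette) or one
scanned branch system (siliques). Segmentation is an input, not a product:
every measurement consumes an integer instance label map (0 = background,
k = organ k) paired with an 8-bit RGB image. Label maps are relabeled to a
contiguous `{0..N}` on load, in raster order of first appearance, so
downstream code can index instances densely; the pixel partition is
untouched. Polygon annotations (LabelMe dialect) are rasterized with a
pixel-center, even-odd rule — a pixel belongs to a polygon iff its center
lies inside, boundary centers counting as inside — and later shapes
overwrite earlier ones, matching annotation-tool layering. Coordinates are
row-major, origin top-left, x = column, y = row, 0-based. All traits are
reported in pixel units; converting to metric units is the caller's
business (scale object or known resolution).

## Morphological traits (35)

Per-instance geometry:

* **Area** — pixel count of the instance support.
* **Perimeter** — length of the closed Moore-neighbor boundary trace through
  boundary *pixel centers*; axis steps count 1, diagonal steps √2. An
  n×n square gives exactly 4(n−1). A single pixel has perimeter 0
  (degenerate) and is excluded from roundness aggregates. Holes are
  ignored (outer contour only). An instance that is not 8-connected is
  measured on its largest component, with a warning; instances touching the
  image border are measured as-is.
  This chain-length convention overestimates smooth contours: on a
  digitized disk of radius 50 the trace measures ≈ 329.7 against
  2π·50 ≈ 314.2 (+4.9 %), and the fine-grid limit for a circle is
  ≈ (2√2−2)/(π/4) − 1 ≈ +5.5 %. The tests assert the disk perimeter within
  6 % of 2πr, and the disk's *roundness* within [0.9, 1.1]; a corrected
  chain estimator (Vossepoel–Smeulders) was rejected because it would break
  the exact 4(n−1) square contract that pins the convention down.
* **Roundness** — the isoperimetric ratio 4πA/P², not clipped; 1 for an
  ideal circle, π/4 for an ideal square, ≈ 0.9 for a digitized disk under
  the perimeter convention above.
* **Orthogonal box** (`length_ori`/`width_ori`) — axis-aligned pixel extents
  (max − min + 1 per axis), larger extent first.
* **Minimum bounding rectangle** (`Length`/`Width`/`MBB_Area`) — exact
  minimum-area enclosing rectangle of the instance, computed by the
  edge-orientation (rotating-calipers) search over the convex hull: the
  optimum has a side collinear with a hull edge. Implemented directly
  because GEOS's `minimum_rotated_rectangle` is aligned to the minimum-width
  direction and is measurably non-minimal (up to ~0.2 % area on random
  point sets).
* **Convex hull** — hull and rectangle geometry is computed over the
  *corner points* of boundary pixels (each pixel a closed unit square).
  This keeps the chain `area ≤ hull_area ≤ mbb_area ≤ ortho box area`
  exact (a pixel-center hull violates the first inequality by the
  Pick's-theorem boundary term), and makes the MBB sides of an axis-aligned
  n×m block equal n and m — i.e. rectangle sides measure true drawn organ
  dimensions.

Plant-level aggregation (Average / Maximum / STD / CV families over
perimeter, roundness, area, orthogonal extents, MBB sides and MBB area):
dispersion uses the **population** SD (divide by n) since per-plant trait
dispersion is descriptive, not inferential; CV is the plain ratio SD/mean,
not a percentage. `c_max_ori`/`h_max_ori` are the maxima of the orthogonal
extents. `Total Leaf Number` is the instance count and `Total Leaf Area`
the summed pixel count. For the ratio traits the names were read at plant
level: `Average Area/MBB_Area` averages the per-instance ratios;
`Average Perimeter/Area` is mean perimeter ÷ mean area; the STD variants
divide the numerator trait's SD by the mean denominator. `Convex Hull Leaf
Area` is the hull over the union of all instances. The per-instance-ratio
alternative for `Average Perimeter/Area` is a plausible alternate reading;
the plant-level one was chosen and is fixed in the column contract.

An empty scene yields count 0, totals 0, and NaN for every mean/SD/CV.
NaN is the universal undefined-trait sentinel; it serializes as an empty
CSV cell, never 0, so aggregation across images is not silently biased.

## Color traits (7)

Each organ pixel maps to chromatic coordinates r = R/(R+G+B), g, b; a pure
black pixel contributes the simplex center (⅓, ⅓, ⅓). Traits are the mean
and population SD of each coordinate over the union of all organ pixels
(SDs are over pixels, not over per-leaf means), plus `G_All_mean`, the
whole-plant green proportion — identical to `G_Ratio_mean` by construction
and kept so the 64-column catalog stays intact. Chromatic ratios, rather
than raw 0–255 channel means, make the traits invariant to global
intensity scaling; raw channel means are available as auxiliary,
non-catalog columns behind `include_raw=True`.

## Texture traits (22)

**Hu moments** φ₁..φ₇ are computed on the binary union support (silhouette
descriptors): central moments normalized by μ₀₀^((p+q)/2+1), standard
closed forms (scikit-image), with φ₇'s sign preserved so mirror images are
distinguishable. A grayscale-weighted variant sits behind a flag. On ideal
shapes φ₁ = 1/6 for a square and 1/(2π) for a disk; digitized shapes of
≥ 500 px reproduce these within 1 %. Rotation/scale invariance of φ₁..φ₆
holds within 1 % on smooth digital shapes of ~10⁴ px warped with
order-1 interpolation; much smaller or nearest-neighbor-warped shapes show
larger drift in the high-order invariants, which is digitization, not
implementation.

**GGCM** — the gray-gradient co-occurrence matrix is the joint histogram of
quantized gray level and quantized gradient magnitude over organ pixels.
Choices (standard practice; fixed as part of the file contract):

* grayscale by ITU-R BT.601 luma, 0.299R + 0.587G + 0.114B;
* gradient by 3×3 Sobel; before filtering, background pixels are replicated
  from their nearest organ pixel (Euclidean distance transform) so the
  support boundary does not inject spurious gradients;
* 16 gray bins linear over [0, 255]; 16 gradient bins linear over
  [0, max gradient in support] (an all-constant organ puts all mass in
  gradient bin 0);
* the 15 canonical features in fixed order: small/large gradient dominance,
  gray/gradient asymmetry, energy, gray/gradient mean, gray/gradient
  variance, correlation, gray/gradient/mixed entropy, inertia, inverse
  difference moment. Entropies use the natural logarithm with 0·log 0 = 0;
  the variances are second central moments of the marginals; correlation is
  the marginal cross-correlation normalized by σ_g σ_s (0 when either
  marginal is degenerate).

Texture (and color) traits are per-plant (union of instances), so they are
invariant to instance relabeling.

## Evaluation

Instance matching: all predicted–truth pairs with pixel-set IoU ≥ the
threshold are candidates; pairs are accepted greedily in descending IoU
with deterministic tie-breaks (lower predicted label, then lower truth
label); each instance joins at most one pair. TP = accepted pairs,
FP = unmatched predictions, FN = unmatched truths, TN ≡ 0. The default IoU
threshold is 0.5 and configurable — the field's conventional TP criterion.
Greedy selection equals the optimal assignment's TP count on all tested
small scenes (exhaustive-permutation oracle); the tie-breaks make reports
reproducible.

Precision, recall and F1 follow their standard forms; undefined
denominators yield NaN with a warning rather than 0. DiC is the absolute
count difference per image; batch DiC is the mean of per-image values.
MAPE is in percent and requires nonzero manual values (a zero raises,
naming the index). R² comes from the OLS fit of manual (response) on
automated (predictor) — the orientation of the usual agreement scatter
plots — via 1 − SS_res/SS_tot, with a constant response defined as R² = 0
and a zero-variance predictor as NaN.

## Baselines

ExG = 2G − R − B on 0–255 channels (range [−510, 510]), affinely rescaled
to [0, 255] before thresholding. Otsu's threshold maximizes between-class
variance over the 256-bin histogram; the comparison runs in exact integer
arithmetic ((S₁w₀ − S₀w₁)²/(w₀w₁) compared by cross-multiplication) so the
tie-break toward the lower threshold is bit-reproducible; foreground is
strictly above the threshold (vegetation indices are high on plants).
K-means clusters RGB triples (k-means++ seeding, Lloyd iterations, fixed
random state; backed by scikit-learn); the cluster with the highest mean
ExG is called "plant". Connected components (4- or 8-connectivity) are
labeled in raster-scan order of first pixel; components under 20 px
(configurable) are dropped as salt noise. RGB was chosen as the K-means
feature space; ExG as the vegetation index feeding Otsu.

## Synthetic scenes

The generator emulates the two acquisition setups the trait engine
targets, with exact ground truth; it does not attempt photorealism.

**Rosettes** — 3–20 elliptical blades (aspect 0.42–0.55) on thin petiole
stalks radiating from the image center, lengths drawn from the configurable
size range (default 40–90 px on a 512 px canvas; tests use 320–384 px
canvases), green with per-leaf hue jitter, over a flat or textured
soil-brown background. Occlusion is realized by draw order — later leaves
overwrite earlier ones in both image and label map — so ground truth is
the *visible* pixel set, exactly what a segmenter can recover; latent
(pre-occlusion) masks and drawn lengths/widths are stored alongside. With
overlap target 0, placement is rejection-sampled to pixel-disjointness
(petioles start slightly off-center so the crown stays disjoint); with a
positive target, neighbors are fanned at an angular gap derived from the
two-ellipse lens-overlap formula with a single empirical correction factor
(0.6) for the wedge geometry, calibrated once; the realized mean
occluded-area fraction tracks the target within ±0.1 over targets 0.1–0.5.

**Silique scenes** — a wobbling stem polyline (drawn in the image, but
background in the label map, mirroring the stem/pod distinction of real
annotations) with elongated capsules (width 5–9 px, length from the size
range) attached alternately left/right. A positive overlap target forces
⌈overlap·n/2⌉ capsule pairs to cross through each other's midpoints — the
configuration that makes binary connected-component baselines merge
instances, turning the classical failure mode into an assertable
inequality (baseline FN > 0, DiC > 0, while truth-vs-truth evaluation is
exactly perfect).

**Augmentation** — hflip, rotate90, Gaussian noise, color dithering, random
scaling, random cropping; geometric ops apply identically to image and
label map (nearest-neighbor for labels, so they stay integral), photometric
ops to the image only; everything is driven by a single seed. Image
stitching can be composed from `random_crop` plus placement.

What the synthetic scenes do **not** emulate: real leaf venation and
serration, specular highlights, shadows, soil clutter, growth stages, or
the segmentation errors of any particular model. Passing the recovery
tests therefore validates the *measurement* chain (given a correct mask,
traits are exact) and the metric implementations — not segmentation
accuracy on real images.

## Determinism and problem sizes

All randomness flows from explicit seeds (`numpy.random.default_rng`);
identical seeds give bit-identical scenes and byte-identical trait tables.
The test suite and the acceptance script run on deliberately modest sizes —
384 px scenes, 20-seed recovery sweeps, 200 random polygons for the
rectangle oracle, 100 histograms for the Otsu oracle — chosen so the whole
suite completes in well under a minute while every check retains its
discriminating power.

## Known limitations

* Perimeter (and hence roundness) carries the ~5 % chain-code bias on
  smooth contours discussed above; comparisons *between* plants measured
  under the same convention are unaffected.
* Skeleton-based leaf length (midrib arc length), petiole/blade
  decomposition, curved-silique arc length, and 3D traits are out of scope;
  MBB length is the elongation proxy.
* Color traits assume a roughly uniform illuminant; there is no color
  correction.
* The texture traits are per-plant; per-instance texture would need a
  windowing policy for small organs and is not provided.
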