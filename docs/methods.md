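# Methods

This note documents the models, conventions and design choices behind the
package, in the order the data flows: annotation geometry, tiling and
augmentation, the synthetic scene generator, the classical reference
detector, the evaluation protocol, and the composition analyses. It closes
with known limitations and the numerical conventions used throughout.

## Annotation geometry

Boxes are YOLO normalized center format: `(cx, cy, w, h)` as fractions of
image width/height. Pixel conversion is continuous, `x_px = cx · W`, with
no half-pixel offset — the convention of the LabelImg export format the
label files follow. Conversions round-trip to machine precision.

Validation tolerates float noise: a box whose extent leaves `[0, 1]` by at
most 1e−6 is clipped silently; a larger violation raises, since it
indicates corrupted coordinates rather than arithmetic residue. Class-id
order is never implicit: every dataset carries a `classes.txt`, and the
package's canonical six-class order is alphabetical within the clinical
groupings — echinocyte, erythrocyte, lymphocyte, monocyte, neutrophil,
platelet — with explicit remap tables to the 4-class
(leukocyte-consolidated) and 3-class (red-cell-consolidated) schemes.

## Tiling and augmentation

Frames are cut into `tile_px` (default 416) squares on a `stride_px` grid;
the final row/column is shifted inward so coverage reaches the frame edge
exactly. The tile-origin rule is checked against a brute-force enumeration
oracle in the tests. An annotation survives into a tile only when every
box edge lies strictly more than `edge_margin_px` (default 5) from every
tile border, so kept objects are fully visible; the same physical cell may
legitimately appear in several overlapping tiles. A 3088×2064 capture
frame yields an 8×5 grid of 40 tiles at stride 416 (the shifted edge tiles
overlap slightly), 70 tiles at stride 312, and 126 at stride 208 (50 %
overlap) — workflows reporting "~60 tiles per frame" imply partial
overlap, so the stride is exposed as configuration, not guessed.

Geometric augmentations (rotations by 90/180/270°, horizontal/vertical
flips) transform annotations analytically — e.g. clockwise 90°:
`(cx, cy, w, h) → (1−cy, cx, h, w)` — and are exact involutions/cycles on
the pixel grid. Photometric augmentations are defined operationally, since
"±5 %" alone under-determines them: contrast/brightness/saturation/
sharpness scale by a factor 1 ± 0.05, hue rotates by ±5 % of the hue
circle, and blur applies a Gaussian with σ = 20 px × |magnitude| (1 px at
the default ±5 %). When a photometric magnitude is unset, its sign is
drawn from the seeded generator, so augmented sets are bit-reproducible.

## Synthetic scene generator

The generator emulates unstained cells in a 200 µm-wide, 50 µm-deep
microfluidic channel imaged at 40×: bright background (default grey level
200) with mild vignetting, darker channel-wall bands when the frame spans
more than the channel width, and cells rendered at physical scale
(0.13791 µm/px = 57.37 µm per 416-px tile).

Per-class morphology and size, with sizes drawn uniformly per cell:

| class       | diameter (µm) | rendering                                   |
|-------------|---------------|---------------------------------------------|
| erythrocyte | 6–8           | biconcave disc: dark ring, brighter dimple  |
| echinocyte  | 6–8           | same profile on a wavy boundary r₀(1+a·sin kθ), k ∈ [8,16], a ∈ [0.08,0.20] |
| lymphocyte  | 10–15         | granular sphere (multiplicative speckle, sd 0.15) |
| neutrophil  | 12–17         | granular sphere                             |
| monocyte    | 12–22         | granular sphere                             |
| platelet    | 2–5           | small uniform dark dot                      |

The platelet default covers the typical bulk (most platelets are ≤ 5 µm);
the largest platelets can reach 7 µm and a user-supplied `CellSpec` can
widen the range. Spicule parameters are the package's own defaults chosen
so spiculated and smooth discs are separable by a contour-roughness score;
they are not measured values. All profiles keep the full cell footprint
darker than background (sharp refractive edge), so the visible extent of a
noiseless cell coincides with its geometric mask — which is what makes the
ground-truth contract exact: every rendered cell contributes one
annotation, the tight bounding box of its rendered mask.

The per-tile cell count is a rounded, zero-truncated draw from
Normal(mean 4, sd 3), the simplest distribution matching the stated
density of ~4 ± 3 cells per tile (truncation biases the realised mean up
by ≈ 0.13; the Monte-Carlo test allows for this). Class frequencies follow
the mixture, whose default is the composition of the six-class training
corpus (53,100 : 33,200 : 7,100 : 3,300 : 4,100 : 9,600, i.e. 48.1 %
echinocytes … 8.7 % platelets), consolidated proportionally for the
3-class default.

Placement treats cells as rigid bodies in a shallow channel: partial
projection overlap is allowed (centers must be farther apart than half the
sum of radii), full superposition is not; `allow_overlap=False` forbids
contact entirely. A configurable fraction of platelets (default 0.1)
receives extra local blur, emulating platelets drifting outside the focal
plane — the mechanism suspected behind platelet undercounts in real runs.

Reproducibility: each dataset spawns per-frame child seeds from one root
`SeedSequence`, so identical config + seed gives bit-identical pixels and
labels regardless of how many frames are drawn.

What the generator does *not* emulate: diffraction and phase-contrast
optics, motion blur, debris and background artefacts, cell deformation in
shear, and the full continuum of real morphological variability. Passing
tests on synthetic scenes therefore validate the *pipeline* — geometry,
bookkeeping, matching, metric derivation — not detector performance on
real imagery.

## Classical reference detector

The detector exists so the full simulate → detect → evaluate loop runs on
one CPU without a trained network; it is a classical segmentation pipeline,
not a neural-network surrogate of any particular model:

1. **Background flattening.** Grey-closing with a window larger than the
   widest cell (default 171 px > the ~160 px of a 22 µm monocyte) erases
   dark objects; a Gaussian blur (σ 25 px) smooths the result; dividing
   the image by this background leaves a relative *deficit* map. The
   closing step matters: a plain heavy blur underestimates the background
   inside cells larger than its kernel and hollows them out.
2. **Segmentation.** Threshold the deficit by Otsu (AUTO), floored at
   0.08 — cells are at least ~10 % darker than background, and without the
   floor Otsu carves structure out of vignette residue on near-empty
   frames. Ring-shaped red-cell footprints are hole-filled.
3. **Declumping.** Every component is offered one watershed pass seeded by
   deep maxima of its distance transform (depth ≥ 0.3 × max, min
   separation 0.3 × max). Single cells — including spiculated discs, whose
   spicule-tip maxima are shallow — come back whole; touching or partially
   overlapping cells split at the waist. For split parts the occluded
   extent is reconstructed from the seeding peak: its distance value is
   the inradius ≈ radius of a circular cell, and the box is the square of
   that radius about the peak.
4. **Classification.** By equivalent diameter: < 5 µm platelet, 5–9.5 µm
   red cell, > 9.5 µm leukocyte. Within the red-cell bin, the contour
   roughness score std(r)/mean(r) over the centroid-to-contour radius
   separates echinocytes (score ≈ a/√2 for a spiculated boundary) from
   erythrocytes at threshold 0.06. Just above the red-cell bin
   (≤ 11.5 µm ≈ √2 × the 8 µm red-cell maximum, the largest a fused pair
   can measure) an interior texture test disambiguates: a granular
   leukocyte has a low interior coefficient of variation (< 0.20), an
   unsplit red-cell pair a high one (ring + dimple structure).
5. **Confidence** is the component's mean deficit × 4, clipped to
   [0.05, 0.99] — a sortable, monotone-in-contrast score; its exact form
   is irrelevant to the evaluation contract.

The detector cannot subtype leukocytes (lymphocyte/monocyte/neutrophil
ranges overlap heavily, and without staining no texture cue is modelled);
`resolve_classes` maps its vocabulary onto a target scheme and folds
echinocyte/erythrocyte into `red cell` when the scheme is coarse.

## Evaluation protocol

IoU is computed analytically on axis-aligned boxes and cross-checked in
tests against shapely's polygon engine and a brute-force rasterization
oracle. Matching is greedy one-to-one: detections in descending confidence
(ties: descending best IoU, then input order) each claim their highest-IoU
unmatched annotation with IoU ≥ 0.75 (inclusive). A class-mismatched claim
is a wrong-class false positive and fills confusion cell
[gt class, predicted class]; a detection whose best IoU falls below
threshold is spurious; one whose only qualifying annotations are taken is
a duplicate; unclaimed annotations land in the non-detected column. The
greedy rule is verified against an exhaustive replay on random small
scenes. Conservation — TP + misclassified + non-detected = ground-truth
count, per class — holds identically by construction and is asserted in
every end-to-end test.

Recall counts misclassification and non-detection against the class;
precision counts wrong-class claims and spurious detections against the
predictor. Macro metrics are unweighted class means. Printed reference
matrices carry no spurious row; loading them with spurious = 0 reproduces
their published precisions exactly (e.g. 81/(81+9) = 90.0 %). A few of the
summary percentages that accompany the reference tables differ from
recomputation by exactly 0.1 (a non-detected share of 10.5 % that
recomputes to 10.6 %, an F1 of 95.0 % that recomputes to 94.9 %, a recall
of 82.6 % that recomputes to 82.7 %) — upstream rounding slips, not
asserted by the tests.

Stratified splitting buckets images by dominant annotation class
(background images form their own bucket), shuffles each bucket with the
seeded generator, and allocates 70/20/10 by largest remainder, which
bounds every subset's per-class image count within one image of the pooled
proportion; each of the k folds reshuffles independently. Fold aggregation
reports mean ± sample standard deviation (denominator k−1, the standard
convention for k = 5 cross-validation) on the percentage scale.

Reported percentages round half-up to one decimal, implemented in decimal
arithmetic so `x.x5` never rounds down through binary float
representation.

## Composition analyses

Sizing multiplies normalized extents by image pixel size and µm/px
(default 57.37/416). Bounding boxes overestimate non-circular cells, and a
spiculated boundary adds up to the spicule amplitude; ±2 µm is the
practical accuracy of box-derived sizes. Ratio tables are plain per-class
fractions of the total count and are scheme-agnostic, so consolidated and
granular tables are consistent by construction. `compare_ratios` fits
ordinary least squares per class across paired samples and reports R²
(squared Pearson correlation), slope, intercept and the slope's standard
error; a zero-variance series yields an undefined (None) result rather
than a fabricated number. Dilution datasets are composed by
largest-remainder apportionment of image counts (verified exhaustively
against optimal apportionment at small n) with seeded sampling without
replacement.

## Problem sizes in the test suite and acceptance script

The pipeline invariants run on 100 simulated 1040×640 frames at elevated
density (mean 25 cells/frame) to exercise tiling densely; the tile-origin
rule for the full 3088×2064 capture geometry is checked once against the
enumeration oracle, which is resolution-independent. The end-to-end
recovery runs 300 noiseless 416×416 three-class tiles at the default
density; the IoU oracle uses 1,000 random pairs and the matcher oracle 500
random scenes. These sizes give stable statistics (≈ 1,200 cells end to
end) while the whole acceptance run completes in about a minute.

## Known limitations

* The reference detector is tuned to the generator's optical model; its
  absolute scores do not transfer to real imagery and are meant as an
  internal quality bar for the pipeline.
* Deeply overlapped cell pairs whose distance transform is unimodal cannot
  be declumped; at default density this caps red-cell recall a few percent
  below 100 on overlapping scenes.
* Leukocyte subtyping is out of the classical detector's reach; six-class
  evaluation requires external (e.g. Darknet) detections.
* The dilution-series grid is taken as an explicit ratio list; the package
  does not guess a step size for "1:1,000 to 1:1" style ranges.
* Absolute concentrations (cells/µL) are out of scope — they need
  flow-rate and imaged-volume calibration that the imaging geometry alone
  does not provide.
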