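# Methods

## Model of a membrane contact site

Two organelle membranes form a contact site when they are apposed within a
tethering distance without fusing. On a 2D EM section segmented at 10 nm/px,
the package models a contact as a pair of boundary pixels — one on the
mitochondria (or lipid-droplet) outline, one on the ER outline — whose
center-to-center Euclidean distance is at most `T` pixels (default `T = 10`,
covering 0–100 nm). The quantity of interest is the contact-width profile:
for each integer width bin `b ∈ 0..T`, the number of mitochondria boundary
pixels whose contact distance rounds up to `b` pixels, and that number
divided by the total mitochondria boundary length.

Biologically a tethering site on one membrane communicates with a unique
site on the other, but true sites (1–2 nm) are an order of magnitude smaller
than the pixel grid, so strict one-to-one matching is not enforceable.
Instead a relaxed rule is used: an ER boundary pixel `e` may support a
contact at distance `d` only if `d < MinDistance(e) + 1`, where
`MinDistance(e)` is the distance from `e` to its nearest mitochondria
boundary pixel. An ER pixel that is 2 px from one mitochondrion therefore
cannot simultaneously be scored as a 5-px-wide contact to another.

### Numerical choices

* **Boundary operator.** The inner morphological boundary (foreground pixel
  with a 4-connected background neighbor, or on the image border) is used.
  On binary masks this is deterministic and parameter-free, and its pixel
  count doubles as the perimeter measure, so contact lengths and perimeters
  live on the same scale. Gradient-based edge detectors need thresholds and
  degenerate on binary input.
* **Distance metric and binning.** Euclidean distance between pixel centers;
  width bin `b = ⌈d⌉` for `d > 0`, bin 0 reserved for overlap pixels. A
  contact requires `⌈d⌉ ≤ T`; this makes the contact test and the binning
  consistent (a distance of 10.05 px at `T = 10` is neither a contact nor
  binnable, rather than a contact that falls outside every bin). All
  distances are square roots of integers, so `⌈d⌉` is numerically exact —
  IEEE square roots of perfect squares are exact, and non-squares are never
  within rounding distance of an integer at these magnitudes.
* **Overlap handling.** Pixels claimed by both masks (a segmenter artifact,
  or genuine apposition at sub-pixel distance) are excluded from both
  candidate sets; mitochondria boundary pixels inside the overlap are
  assigned distance 0 and counted in bin 0.
* **Search window.** `MinDistance` and the distance map are computed with a
  KD-tree nearest-neighbor / pair query bounded at Euclidean radius `T`,
  with sentinel `T + 1` beyond. This is exactly equivalent to both a
  `(2T+1)²` window scan and a windowless search for every reported
  quantity: whenever a candidate pair has `d ≤ T`, the ER pixel's true
  minimum is also `≤ T` and is found exactly; when the true minimum exceeds
  `T`, every pair distance at that ER pixel also exceeds `T`
  (`d ≥ MinDistance` by definition), so no contact can be affected by the
  clipped value — the admissibility test `d < MinDistance + 1` passes under
  both the exact value and the sentinel. The windowless brute-force oracle
  (`brute_force_contact`, exhaustive all-pairs with integer-exact binning
  and an independently computed boundary via binary erosion) verifies this
  equivalence bin-for-bin on hundreds of seeded scenes.
* **Degenerate inputs.** A patch with no mitochondria boundary has no
  defined contact ratio; the ratio columns are flagged undefined (None)
  rather than silently reported as 0, and `contact_ratio` raises. Empty ER
  yields an all-zero profile with ratios 0, which is well-defined.
* **Reported counts.** Both the contacting-pixel count (`n_contact_px`) and
  the number of 8-connected contacting runs (`n_contact_segments`) appear
  in every report row: discrete "number of contact sites" statistics
  plausibly refer to either, so neither is silently substituted for the
  other.

## Aggregation

Per-image statistics sum boundary lengths and per-bin contact lengths over
all patches of the image and recompute ratios from the sums. The mean of
per-patch ratios is a different (and biased) estimator — a patch with 10 px
of boundary would weigh as much as one with 1,000 px — and is deliberately
not used; a regression test pins the distinction (100+300 px of boundary
with 10+90 px of bin-1 contact must aggregate to 0.25, not 0.20).
Instance counts are summed over patches, so a mitochondrion spanning two
patches (or sampled by two overlapping random patches) is counted in each;
mean perimeter and mean elongation are per-instance means under that
convention.

## Preprocessing

* **Standardization.** Images and masks are resampled to 10 nm/px;
  dimensions map as `round(dim × native_nm / target_nm)`. Masks use
  nearest-neighbor (label sets preserved), intensities bilinear
  interpolation. Resampling at the target resolution is the identity.
* **Normalization.** Intensities are clipped at the 1st/99th percentiles
  and min-max rescaled to [0, 1]; robust rescaling tolerates the hot/dead
  pixels common in scanning EM, and constant images map to zeros so the
  operation is total.
* **Patches.** Training uses a sliding window (1,024 px, step 512) with a
  final window anchored flush to each far border when the stride does not
  land exactly — full coverage, never any padding. Inference draws 5
  patches uniformly over valid origins (overlap permitted, seeded).
* **RoI filter (tissue mode).** A patch is retained iff the annotated cell
  territory covers strictly more than 0.15 of its area. The coverage
  fraction (RoI pixels in patch / patch pixels) is the thresholded
  quantity, and the comparison is strict at the boundary.
* **Augmentation.** Flips, quarter-turn rotations, affine jitter within
  ±5% scale and ±5° rotation, and Gaussian blur with σ ∈ [0, 1.5] px
  (image only; masks get the identical geometric transform at
  nearest-neighbor). The jitter magnitudes are conventional mild EM
  augmentation settings and are exposed in `AugmentParams` rather than
  hard-coded.
* **Polygon rasterization.** Labelme-style polygons are rasterized by
  pixel-center containment under the even-odd rule, with half-open edge
  semantics (a center exactly on the maximal edge is outside). This is the
  one hand-written geometric primitive in the package, because the exact
  membership convention is part of the I/O contract; it is cross-checked
  against an independent point-in-polygon oracle on random convex polygons.

## Evaluation metrics and training support

Dice, IoU/mIoU and the match ratio (correctly predicted pixels over
annotated pixels, in percent) are implemented literally; the match ratio is
annotation recall and ignores false positives, which is why Dice and mIoU
are always reported alongside. Active-learning selection returns the
⌈fraction·N⌉ lowest-mIoU images (ties by ascending id, ceiling so the
selection is never empty).

The top-likelihood loss reductions operate on scored proposals:
`L_tploss` averages `L_cls(p_i, 1) + λ·L_reg` over the `N_pos`
lowest-scoring positives, `L_tnloss` averages `L_cls(p_i, 0)` over the
`N_neg` highest-scoring negatives. The component losses are supplied per
anchor — they are the standard detection losses, and keeping them abstract
makes the reductions testable without any network. The companion
similarity penalty between positive and negative proposal features has no
fixed functional form; it is a pluggable callable defaulting to zero.

## Synthetic scenes

The generator emulates segmenter *output*: disk- and blob-shaped
mitochondria/lipid-droplet instances and ribbon-shaped ER regions placed at
controlled gaps, rendered as instance/region masks and optionally written as
label PNG + polygon JSON so the whole I/O path is exercised. Default
random-scene settings (4–6 instances of radius 3–12 px, up to 6 ER ribbons
of half-width 1–2.5 px on 96–160 px grids) give boundary densities and
contact fractions comparable to a cytoplasmic EM patch at the same scale.
What the scenes do **not** emulate: EM texture and noise (masks are the
input contract, so texture is irrelevant to the quantification path),
segmentation errors, organelle shape realism beyond compact-vs-elongated,
and 3D effects of sectioning. Passing tests therefore establish the
correctness of the quantification arithmetic on arbitrary mask geometry,
not the accuracy of any upstream segmenter.

The parallel-bar family provides closed-form ground truth: two aligned
1-px-wide vertical bars with `g` background columns between have facing
edges `g+1` px apart, every mitochondria boundary pixel contacts at exactly
that distance, so the entire profile sits in bin `g+1` with count equal to
the bar height (empty when `g+1 > T`). Random-blob scenes have no closed
form and are checked against the brute-force oracle.

## Problem sizes

The test suite and the acceptance script run on 96–160 px scenes (hundreds
of boundary pixels) where the exhaustive oracle is exact and cheap; the
optimized pipeline itself is routinely used on full 1,024² patches, where
the KD-tree pair query at radius 10 px is the dominant cost. Oracle
equivalence is checked on 200 scenes × 2 thresholds per run; symmetry,
monotonicity and conservation properties on 8–50 seeded scenes each.

## Known limitations

* Strictly 2D: no volumetric contact analysis and no correction for
  section-angle foreshortening of contact widths.
* Perimeter is a boundary-pixel count, which undercounts diagonal and
  curved outlines relative to arc length; elongation values are therefore
  comparative, not absolute (a digital disk scores around 0.8, below the
  continuous circle's 1).
* Segmentation is an input, not a stage: the package ships no trained
  models, and the loss reductions document training semantics rather than
  perform training.
* The contact definition is purely geometric; no tether-protein or
  functional inference is made.
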