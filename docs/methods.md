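# Methods

## Model

`histoquant` is a supervised per-pixel color classifier. The model is a
pair of objects:

* the **color table**: counts `n(q, k)` of quantized color `q` observed
  under label `k` (each declared positive class, plus `negative`) inside
  user-annotated polygon regions of training images;
* the **palette**: the set of quantized colors classified positive for each
  class, derived from the table by a majority-fraction rule.

Classification of an image is a per-pixel table lookup, so the classifier
is deterministic, order-independent, and exactly reproducible; spatial
structure enters only through the optional post-processing (morphology and
component size filters). The approach assumes that the feature of interest
is defined by color alone and that all images in a batch share the staining
palette of the training images; it makes no attempt to model morphology,
texture, or stain variation between batches (retrain per batch, or merge a
new table into a saved one for a second pass).

## Fixed conventions

All counts depend on three conventions, fixed and documented here:

* **Quantization** — bin index `⌊c·levels/256⌋` per channel, uniform over
  [0, 255]. Default `levels = 64` (4-wide bins): coarse enough to absorb
  ±2–3 grey levels of sensor noise, fine enough to separate visually
  distinct shades. Exposed in config; all tables/palettes record it and
  refuse to merge across different values.
* **Pixel geometry** — pixel `(row i, col j)` has center `(j+0.5, i+0.5)`,
  origin top-left, polygon coordinates in pixels.
* **Polygon membership** — even-odd (ray crossing) rule at pixel centers
  with strict inequalities. This yields half-open boundaries: two polygons
  sharing an edge never both claim a pixel. Rasterization is implemented in
  the package (vectorized over the bounding box) because library
  rasterizers differ precisely in these boundary conventions; tests pin it
  to an exhaustive scalar point-in-polygon oracle.

## Palette derivation

A color `q` is assigned to class `k` iff `k` uniquely maximizes
`n(q, ·)` over the positive classes **and** `n(q, k) / Σ_j n(q, j) >
threshold`. Default threshold 0.5 (strict majority) — the simplest rule
that resolves colors seen under both polarities; the strict inequality
makes the 50/50 case negative. Ties between positive classes go negative,
which enforces disjoint per-class color sets. The rule depends only on
count fractions, so palettes are invariant under count scaling, and a
second training pass is a plain entrywise table merge (commutative,
associative). Overlapping annotations increment both labels' counts —
conflicting annotations soften the model instead of failing.

Colors absent from the table are negative by default (conservative: novel
hues never create false positives). The optional `nearest` policy labels an
unseen color by its nearest observed color in bin-index space (Euclidean);
if equidistant observed colors disagree, the pixel is negative. The palette
file therefore stores the observed-negative color set alongside the
positive lists. Nearest-neighbor queries use a k-d tree with k = 8
candidate neighbors; ties deeper than that are resolved by the first
minimal-distance set, which in practice requires a pathological training
set to matter.

## Post-processing

Order: background exclusion → morphology → component size filter, per
class, recombined in class declaration order (first class wins a contested
pixel, which can only arise from mask-growing steps such as `close`). Size
thresholds therefore apply to final, cleaned components. Background is
near-white: all three channels ≥ `background_min_channel` (default 220),
matching blank slide under brightfield; it is a readout convention, not a
tissue detector. Morphology uses a disk structuring element (radius 0 =
identity); hole filling fills false regions not connected to the border.
Default connectivity is 8 (diagonally touching stained pixels read as one
feature); 4 is available.

## Quantification

Percent positive area = `100 · positive / denominator`, with the
denominator either all pixels (default, matching a per-image-field
readout) or non-background pixels (`tissue_only`, for tiles with blank
regions). Both the mode and the denominator size are recorded in every
report row, so results are never ambiguous. Counts are exact integers;
only the final division is floating point. Class-area ratios with an empty
denominator mask raise and propagate as missing values in CSV — never a
silent 0. Batch summaries report median (midpoint interpolation for even
n), quartiles (linear interpolation), min and max over image fields.

## Evaluation

Confusion counts are integer tallies over pixels (optionally restricted to
an evaluation region). Youden's J, F-score and MCC follow the standard
formulas; MCC's numerator and radicand are computed in exact integer
arithmetic, so it is overflow-safe for gigapixel counts. Degenerate cases:
metrics with a zero denominator are NaN and flagged, except MCC which is 0
with a flag (a constant prediction carries chance-level information, and a
numeric value keeps batch tables rectangular). Multi-annotator references
combine by intersection (consensus = pixels all annotators selected);
majority vote is available as an explicitly non-default option for larger
panels. Batch evaluation reports per-image metrics and the micro-averaged
(summed-counts) pooled metrics — the pooled value is not the mean of
per-image values, and both are labeled.

## Box-threshold baseline

`threshold_baseline` classifies by an axis-aligned box in RGB space — the
standard color-thresholding method this package is an alternative to. For
comparisons, `best_box_threshold` maximizes Youden's J over every box whose
bounds are multiples of a grid step (default 8). Because a box's J equals
`TP/P − FP/N`, the search reduces to maximizing a box sum over the
3-D histogram of (positive density − negative density): prefix sums over
red and green plus a vectorized maximum-subarray (Kadane) scan over blue
make the exhaustive grid search O(bins⁴) ≈ 10⁷ operations, under a second
at step 8.

## Synthetic fixtures

The generator emulates what matters to a color classifier about
brightfield histology tiles: a noisy tissue-colored background (optionally
a mixture of background colors), elliptical or star-convex blob features
with per-pixel color noise around one of several class means, and an
optional near-white slide margin. It does **not** emulate texture,
gradients, chromatic aberration, stain bleed, or out-of-focus blur — so
passing tests demonstrate correctness of the pipeline's bookkeeping and
the joint-color-vs-marginal separability argument, not robustness to real
staining variability.

Design points:

* Truth masks record exactly the pixels painted (later paint wins), and
  metadata records realized per-class area fractions and every feature's
  parameters; tests recount masks against metadata.
* Noise is uniform integer offsets in `[-spread, +spread]`, clamped —
  bounded support makes separability statements exact rather than
  probabilistic.
* Target area fractions are hit by sizing each new feature to the
  remaining deficit (equivalent radius `√(remaining/π)`, clipped to the
  class size range), stopping within the stated tolerance; non-overlap is
  enforced by rejection sampling with an attempt budget, and a packing
  feasibility check (requested fraction ≤ 0.6 of the interior) rejects
  impossible specs before drawing.
* Training pairs are two freshly seeded images from the same spec
  (child seeds via `SeedSequence.spawn`, kept below 2³¹); positive
  annotations trace feature boundaries inset ~1 px to avoid boundary
  mixing, negatives are rectangles over untouched background (plus one
  margin patch when a margin exists).
* The `blended` preset realizes the scenario where box thresholds
  provably fail: background colors form a plus-pattern in (R, G) around
  (130, 130, 120) and positive features draw from the two off-diagonal
  means (180, 80, 120) and (80, 180, 120). Every channel marginal of the
  positive distribution overlaps the background's, yet all clusters are
  disjoint in joint RGB, so any single box covering both positive modes
  also covers background — capping box J near 0.5 — while the palette
  separates them exactly.
* The `tunel` preset fixes blue and brown target fractions at 0.125 and
  0.02 (truth brown:blue area ratio 0.16, with tight per-class
  tolerances so the constructed ratio is meaningful at the third decimal).
* Preset feature counts are stated for a 256×256 tile and scale with
  area; problem sizes throughout the tests (128–256 px tiles, 5 seeds per
  scenario) were chosen as the smallest at which per-class color
  statistics are stable.

## CLI

Subcommands `train` / `run` / `evaluate` / `simulate` replace an
interactive GUI; annotations arrive as JSON polygon files from any
external annotator. Exit codes: 0 success, 1 for the package's own
usage/config errors, 2 for a partially failed batch (unreadable images are
logged and skipped, never abort the batch); `click` itself exits 2 on
unparseable command lines. Every run snapshots its resolved config.
Determinism of `simulate` is guaranteed as bit-identical regeneration from
(spec, seed) and asserted by double-run manifest comparison rather than
frozen image hashes, to avoid coupling tests to a PNG encoder version.
Edge-image filtering (excluding tiles that are mostly blank slide) is off
by default and logs what it excludes, keeping a human in the loop.

## Known limitations

* Features distinguishable only by morphology or texture, not color, are
  out of scope by design.
* The classifier is batch-specific: palettes do not transfer across
  staining days/facilities without retraining (mergeable tables mitigate
  this).
* No whole-slide pyramid support; the unit of analysis is a
  field-of-view tile.
* `unseen_policy="nearest"` extrapolates in quantized color space and can
  propagate training idiosyncrasies to novel hues; the conservative
  default is `negative`.
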