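# Methods notes

This note records the modeling choices behind gleasonkit, the defaults
that matter, and what the synthetic-fixture experiments do and do not
establish.

## Quality control

Each tile is scored on five issues, over tissue pixels only (a tile
whose tissue fraction is ≤ 0.1 is background and excluded from slide
summaries):

| score | definition | flag fires when | default |
|---|---|---|---|
| focus | var(3×3 Laplacian) / var(gray) | below `focus_min` | 0.05 |
| contrast | (P95 − P5) of gray / 255 | below `contrast_min` | 0.12 |
| saturation | clipped pixels (any channel ≥ 250 or all ≤ 5) over tissue∪clipped | above `saturation_max` | 0.05 |
| artifact | pixels outside an H&E color envelope (value < 0.25, or saturated hue in the green–cyan band 0.15–0.60) | above `artifact_max` | 0.04 |
| uniformity | coefficient of variation of 32-px block variances of gray | below `uniformity_min` | 0.10 |

Design rationale:

* The focus score is normalized by the grayscale variance so that it is
  invariant to global contrast scaling — a low-contrast tile is not
  mistaken for a blurred one. It decreases monotonically with Gaussian
  blur σ.
* Clipped-white pixels are color-indistinguishable from glass and drop
  out of the tissue mask; the saturation denominator therefore adds
  them back (tissue ∪ clipped), otherwise a fully clipped highlight
  would erase its own evidence.
* The uniformity score flags *too-flat* texture (scan faults render
  constant regions). A tile whose mean block variance is < 0.5 gray²
  is reported as 0 (maximally uniform) to avoid a 0/0.
* All five statistics are exactly invariant to 90° rotations and flips
  for tile sides divisible by the 32-px block.

Thresholds were calibrated once on the seeded synthetic tile suite
(`synthetic.make_qc_tile_suite`, 200 tiles, several suite seeds), placed
mid-gap between the clean and degraded score distributions, and shipped
as the `QcThresholds` defaults; every threshold is overridable. They are
calibrated to these fixtures, not to any real scanner, and should be
re-calibrated for real data.

A tile is low quality at ≥ 2 flagged issues (`issue_count_for_low_quality`,
default 2).

## Appearance migration

The reference PDF is the **average of per-image** 256-bin tissue
histograms, not a pooled-pixel histogram, so reference images with
unequal tissue areas contribute equally. The per-channel transform is
`T = invCDF_ref ∘ CDF_source` with the source CDF estimated on tissue
pixels and `T` applied to all pixels (leaving background unmapped would
create seams at the tissue boundary). Numerical details:

* 256 integer bins; the inverse reference CDF is linearly interpolated
  over its strictly increasing points, ties broken toward the lowest
  intensity; outputs are rounded and clipped to [0, 255]. The resulting
  lookup table is monotone non-decreasing by construction.
* A constant (degenerate) source channel cannot define a CDF; it is
  shifted so the constant lands on the reference median, with a warning.
* `migrate_image` defaults to the image's own tissue mask when present,
  which keeps repeated migrations consistent even when the color shift
  moves background pixels across the color-based mask threshold;
  migration is then idempotent to well under one intensity unit.

A discrete monotone lookup table cannot split a source histogram bin
across several reference bins, so a *single* migrated image's histogram
retains quantization holes and its intersection with the reference
plateaus around 0.92 on our fixtures. The convergence diagnostic is
therefore computed **dataset-level** — histogram intersection between
the reference PDF and the average PDF of the migrated image set — which
is also what the underlying evaluation practice compares (baseline
dataset versus migrated dataset). Across datasets of images with varied
composition the hole positions decorrelate and the dataset-level
intersection exceeds 0.95.

## Patch pipeline

* Window side *x* must be odd so the stride *(x−1)/2* is integral; the
  overlap ratio *(x+1)/2x* then holds exactly.
* A window yields a patch only when a **single class** covers more than
  `coverage_min` = 0.70 of it. Windows with high total but mixed-class
  coverage are ambiguous and skipped; whether such windows should carry
  a majority label is genuinely open, and skipping is the conservative
  choice.
* Resizing to the 224-px classifier input uses a box (area-averaging)
  filter — deterministic and interpolation-free for integer ratios.
  The effective resolution *x·r/224* is reported to two decimals; note
  *x* = 1001 at 0.5 µm/pixel gives 2.23 µm/pixel by this formula.
* Color-augmentation presets apply per-channel gain/offset/gamma jitter
  drawn uniformly from preset ranges: `scannerB`/`scannerC` biased dark
  (negative offsets, gamma > 1), `scannerD` biased light. Geometric
  augmentation uses exact 90° rotations and flips.
* Class weights are `w_i = (1/n_i)·K/Σ(1/n_j)` over the K classes with
  patches, i.e. inverse frequency normalized to mean 1, applied as
  per-sample loss weights.
* Train/test splits are by image id, never by patch, to avoid leakage
  between overlapping windows.

## Baseline classifier and incremental updating

The baseline classifier is a fixed, hand-crafted feature map
(per-channel 8-bin color histograms, channel means/stds, grayscale std,
normalized Laplacian energy, block-variance CV, edge density — 34
features) with a weighted multinomial logistic-regression head
(newton-cg, C = 10, tol = 1e-12). It exists to exercise the windowing,
voting, migration and evaluation machinery at desk scale; it is **not**
a CNN surrogate in accuracy terms, and any model implementing
`predict_proba` over the five-class vocabulary can replace it.

Incremental updating freezes the feature map (including its
standardization statistics) and refits only the head, warm-started from
the current parameters, over the classifier's cached feature vectors
plus the corrected patches. Caching features (a few floats per patch,
no pixels) means original patches are not needed at update time, and
because the regularized head objective is strictly convex, sequential
updates and a single combined update converge to the same optimum
(agreement ~1e-12 in predicted probabilities on our fixtures; the
bundled tests assert 1e-6).

## Inference and vote fusion

Windows are enumerated over the tissue bounding box; windows with less
than `min_tissue` = 0.5 tissue fraction are skipped. Each scored window
adds its probability vector to all its pixels and one vote to its argmax
class. Fusion policies: `max_votes` (argmax vote count) and
`max_mean_score` (argmax of score sum / coverage). The tie-break is
total and deterministic: higher mean score first, then the more severe
class (GP5 > GP4 > GP3 > benign > stroma) — when the evidence is
balanced we prefer not to miss tumor. Pixels under no window are coded
0 ("unscored") and excluded from all downstream metrics. Accumulation is
unweighted; window-distance weighting would be a possible refinement
but there is no basis here for choosing a kernel.

Prediction simplification alternates circular majority smoothing
(radius 2 px by default) with small-region merging (regions under
`min_region_area` = 100 px are absorbed into the neighbor sharing the
longest boundary) and iterates to a fixed point, so a second
simplification pass changes nothing; class areas move by well under 10%
on our fixtures.

## Evaluation

* Instance reconciliation takes the predicted class with the largest
  pixel area inside the annotation polygon; exact ties go to the more
  severe class. Instances with more than half their pixels unscored are
  excluded from annotation-level metrics.
* Macro F1 is the arithmetic mean of per-class F1 over classes present
  in ground truth or prediction; classes absent from both are excluded
  with a warning.
* Slide Gleason: the primary pattern has the largest predicted area;
  the secondary is the next-largest pattern whose area reaches 5% of
  the total malignant area, else the primary is doubled. The 5% floor
  is a common clinical convention — how a production system should
  derive patterns from segmentation areas is genuinely open — and it is
  configurable (`secondary_min_fraction`).
* Quadratic weighted kappa is computed on Grade Groups 1–5 (k = 5),
  benign slides excluded pairwise. Degenerate marginals (both raters
  constant and equal) return κ = 1.

## The synthetic fixtures: what they are and are not

The generator produces 8-bit RGB images in a purple/pink H&E-like
palette with an exhaustive label raster. Class regions are contiguous
runs of layout cells along a serpentine path (cell size configurable;
default side/16, clipped to [8, 32] px); cell quotas use largest-
remainder apportionment, so realized class fractions land within one
cell of their targets. Textures are procedural and intentionally
simple: ring/gland motifs (benign), small separated discs (GP3), fused
blobs (GP4), modulated fine speckle (GP5), a smooth low-frequency pink
field (stroma), near-white background. Scanner styles are global
per-channel gain/offset/gamma transforms, offset-dominant (two darker,
one lighter), and degradations cover the five QC categories with
controlled magnitudes.

These fixtures make the pipeline *testable*: they establish that the
code implements the stated rules (windowing arithmetic, coverage and
voting rules, monotone matching, the ≥ 2-issue rule, Grade-Group
mapping) and that the stages compose (migration restores cross-scanner
prediction consistency; corrections raise the corrected class's F1).
They do **not** establish clinical performance: real H&E tissue has
nuclear morphology, stain covariation, scanner optics and annotation
noise the fixtures lack, so detection rates, F1 values and agreement
numbers measured on fixtures say nothing quantitative about real
slides.

Fixture problem sizes used by the test and acceptance suites — chosen
as the smallest sizes at which every stage is exercised with several
windows/tiles per image: QC suites of 200 tiles at 256 px; migration
suites of 24 reference + 24 evaluation images at 384 px with
Dirichlet-varied composition (α = 4, 90% tissue); patch/classifier
fixtures of 1255-px images with 251-px layout cells (4 training,
2 testing, 2 correction images; 251-px windows); vote-fusion oracle
fixtures up to 1501 px; cross-scanner consistency on ten 768-px slides
× three scanner styles.

## Known limitations

* No pyramidal/tiled WSI reader: inputs are in-memory rasters or
  standard image files; gigapixel slides would need a tile-streaming
  front end (the migration map is global per image, so tile streams and
  whole images give identical results by construction).
* The artifact color envelope is fixed, not fit per laboratory.
* Stain-deconvolution-based normalization (e.g. Macenko/Vahadane) is
  out of scope; migration is purely distributional and per-channel.
* The baseline classifier's features are color-dominated; it degrades
  sharply under scanner shifts (which the cross-scanner tests exploit)
  and is not robust the way an augmented CNN would be.
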