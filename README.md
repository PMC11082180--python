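# gleasonkit

A desk-scale Python toolkit for the full development loop of patch-based
Gleason grading on digitized prostate histology: tile-level image quality
control, scanner appearance migration, annotation-driven patch extraction
and classification, sliding-window slide inference with vote fusion,
human-in-the-loop incremental model updating, and annotation-/slide-level
evaluation including Grade Groups and quadratic weighted kappa.

It is aimed at computational-pathology developers who want to prototype,
test and teach every stage of such a pipeline on a single CPU, without
gigapixel slides or GPU training: a seeded synthetic-fixture module
generates tissue-like labeled images, scanner-style color shifts, quality
degradations and partial polygon annotations, so the whole pipeline runs
end to end in seconds. A trained CNN can be dropped in wherever the
bundled baseline classifier is used — anything exposing
`predict_proba(patches) -> (n, 5)` works.

## The methods in brief

**Quality control.** Slides are tiled (default 512 px) and each tissue
tile is scored on the five common whole-slide-image quality issues —
out of focus, low contrast, saturation, artifacts and texture
uniformity. A tile is *low quality* when two or more issues are
flagged; slide reports give the low-quality tile percentage.

**Appearance migration.** Scanners render the same tissue with
systematically different color. A reference probability density
function is estimated per RGB channel over tissue pixels of a reference
image set; any image is migrated into that space with the monotone map
`T = invCDF_ref ∘ CDF_source` (per-channel histogram specification,
estimated on tissue pixels, applied to all pixels). Convergence is
measured by histogram intersection `Σ min(p, q)` and by the compactness
of per-image mean-RGB clusters.

**Patch pipeline.** Annotated regions are cut by a sliding window of
side *x* and stride *(x−1)/2*, giving adjacent windows an overlap ratio
of *(x+1)/2x*. A window becomes a labeled patch only when a single
class covers more than 70% of it; patches are resized to 224 × 224, so
a window of side *x* scanned at *r* µm/pixel samples tissue at
*x·r/224* µm/pixel (0.56, 1.12, 2.23 and 4.47 µm/pixel for
*x* = 251, 501, 1001, 2001 at *r* = 0.5). Class weights are inverse to
patch counts, normalized to mean 1.

**Inference and voting.** The classifier is slid over the tissue region
at the training stride; every window adds its class-probability vector
to all its pixels and one vote to its argmax class. Pixels are fused
either by most votes or highest mean score, with ties broken by higher
mean score and then clinical severity (GP5 > GP4 > GP3 > benign >
stroma). Predictions can be simplified (small-region merging + majority
smoothing, iterated to a fixed point) for pathologist review.

**Incremental updating.** Pathologist-corrected patches update the
model without full retraining: the feature map stays frozen and only
the linear head is refit (warm-started, convex objective), so
sequential and combined updates agree.

**Evaluation.** Each annotated instance takes the predicted class with
the largest pixel area inside it; per-class precision/sensitivity/F1,
macro F1 and binary malignant-vs-non-malignant sensitivity/specificity/
PPV/NPV follow. Slide-level Gleason scores are derived from predicted
pattern areas (primary = largest, secondary = next largest ≥ 5% of the
malignant area, else primary doubled) and mapped to Grade Groups
(GG1 = score 6, GG2 = 3+4, GG3 = 4+3, GG4 = score 8, GG5 = 9–10).
Observer agreement uses quadratic weighted kappa,
`κ = 1 − Σ w·O / Σ w·E` with `w_ij = (i−j)²/(k−1)²`.

## Worked example

```python
import numpy as np
from gleasonkit import (
    TissueLayoutSpec, PatchScale, generate_tissue_image, extract_patches,
    train_classifier, predict_slide, vote, slide_gleason,
    classification_metrics, generate_annotation_set, evaluate_annotations,
    timing_summary,
)

fractions = {c: 0.19 for c in ("stroma", "benign", "GP3", "GP4", "GP5")}
def slide(seed, side=1255):
    return generate_tissue_image(TissueLayoutSpec(
        image_side=side, cell_side=251, class_fractions=fractions,
        background_fraction=0.05, seed=seed))

scale = PatchScale(side=251)           # 0.56 um/pixel after resize to 224
train = [p for s in range(4) for p in
         extract_patches(slide(100 + s), slide(100 + s).labels, scale)]
clf = train_classifier(train, seed=0)

test = slide(200)
acc = predict_slide(test, clf, scale, mask=np.ones(test.shape, bool))
pred = vote(acc)

annotations = generate_annotation_set(test.labels, completeness=1.0, seed=0)
gt_labels, pred_labels = evaluate_annotations(pred, annotations)
metrics = classification_metrics(gt_labels, pred_labels)
gg = slide_gleason(pred)

print(f"annotation-level macro F1: {metrics.macro_f1:.2f}")
print(f"binary NPV: {metrics.binary['npv']:.2f}")
print(f"slide Gleason {gg.primary}+{gg.secondary} -> Grade Group {gg.group}")

t = timing_summary([1267.0] * 4, [508.0] * 4)
print(f"semi-automatic annotation speedup: {t.fold_speedup}x")
```

prints

```
annotation-level macro F1: 0.93
binary NPV: 1.00
slide Gleason 4+3 -> Grade Group 3
semi-automatic annotation speedup: 2.5x
```

The macro F1 is over annotated instances reconciled by majority pixel
area; NPV 1.00 means no malignant instance was called non-malignant;
the Grade Group comes from the predicted GP4/GP3 areas of this
particular synthetic slide; the timing summary compares per-image
annotation times of a fully manual versus a model-assisted workflow.

## Command line

Every stage is also exposed as a thin CLI:

```bash
gleasonkit qc --input slide.png --tile-side 512 --out report.csv --heatmap qc.png
gleasonkit migrate fit --ref-dir refs/ --out ref.json
gleasonkit migrate apply --ref ref.json --input slide.png --out migrated.png
gleasonkit patches --image slide.png --ann ann.geojson --side 501 --out patches/
gleasonkit infer --image slide.png --model model.bin --side 501 --out pred.png
gleasonkit evaluate --gt ann.geojson --raster pred.png --out metrics.csv
```

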