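"""Baseline patch classifier with a frozen feature map and a linear head.

The feature map is fixed and hand-crafted — per-channel color
histograms plus simple texture statistics — and the head is a weighted
multinomial logistic regression.  This is deliberately lightweight: it
plays the role a deep CNN plays at production scale, exposing the same
``predict_proba`` interface over the five-class vocabulary, so the
windowing, voting, migration and evaluation machinery can be exercised
end to end on a single CPU.  Any external model implementing
``predict_proba(patches) -> (n, 5)`` can be substituted.

Incremental updating follows the human-in-the-loop recipe: the feature
map (and its standardization) stays frozen; only the linear head is
refit, warm-started from its current parameters, over the compact
feature cache plus the newly corrected patches.  Because the head
objective is strictly convex, sequential updates and one combined
update converge to the same parameters.
"""

from __future__ import annotations

import pickle
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage
from sklearn.linear_model import LogisticRegression

from .patches import LabeledPatch, compute_class_weights
from .types import CLASS_NAMES

__all__ = ["PatchClassifier", "train_classifier", "incremental_update",
           "patch_features"]

_HIST_BINS = 8


def patch_features(pixels: np.ndarray) -> np.ndarray:
    """Fixed feature map: color histograms + texture statistics.

    Features: per-channel 8-bin normalized histograms (24), per-channel
    mean and std (6), grayscale std, normalized Laplacian energy, block
    variance coefficient of variation, and edge density (4).
    """
    v = pixels.astype(float)
    feats = []
    for c in range(3):
        hist = np.bincount((pixels[..., c] >> 5).ravel(), minlength=_HIST_BINS)
        feats.append(hist / hist.sum())
    for c in range(3):
        feats.append([v[..., c].mean() / 255.0, v[..., c].std() / 255.0])
    gray = v.mean(axis=-1)
    var_gray = gray.var()
    lap = ndimage.laplace(gray)
    block = 32
    h, w = gray.shape
    nh, nw = max(1, h // block), max(1, w // block)
    trimmed = gray[: nh * block, : nw * block]
    bvars = (trimmed.reshape(nh, block, nw, block)
             .transpose(0, 2, 1, 3).reshape(nh * nw, -1).var(axis=1))
    mean_bv = bvars.mean()
    feats.append([
        gray.std() / 255.0,
        lap.var() / max(var_gray, 1e-6),
        bvars.std() / max(mean_bv, 1e-6),
        float((np.abs(lap) > 10).mean()),
    ])
    return np.concatenate([np.asarray(f, dtype=float).ravel() for f in feats])


@dataclass
class PatchClassifier:
    """Frozen feature map + weighted multinomial linear head.

    The classifier caches the (features, label, weight) triples it was
    trained on — a few floats per patch, no pixels — so head-only
    refits during incremental updates re-optimize the full convex
    objective without needing the original patches.
    """

    head: LogisticRegression
    feature_mean: np.ndarray
    feature_scale: np.ndarray
    train_features: np.ndarray
    train_labels: np.ndarray  # indices into CLASS_NAMES
    train_weights: np.ndarray
    format_version: int = 1

    @property
    def classes(self) -> tuple[str, ...]:
        return CLASS_NAMES

    def _transform(self, patches: Sequence[LabeledPatch] | np.ndarray) -> np.ndarray:
        if isinstance(patches, np.ndarray) and patches.ndim == 2:
            feats = patches
        else:
            feats = np.stack([
                patch_features(p.pixels if isinstance(p, LabeledPatch) else p)
                for p in patches
            ])
        return (feats - self.feature_mean) / self.feature_scale

    def predict_proba(self, patches) -> np.ndarray:
        """Class probabilities over the full five-class vocabulary."""
        x = self._transform(patches)
        raw = self.head.predict_proba(x)
        out = np.zeros((len(x), len(CLASS_NAMES)))
        out[:, self.head.classes_] = raw
        return out

    def predict(self, patches) -> list[str]:
        proba = self.predict_proba(patches)
        return [CLASS_NAMES[i] for i in proba.argmax(axis=1)]

    def save(self, path: str | Path) -> None:
        Path(path).write_bytes(pickle.dumps(self))

    @classmethod
    def load(cls, path: str | Path) -> "PatchClassifier":
        obj = pickle.loads(Path(path).read_bytes())
        if not isinstance(obj, cls):
            raise TypeError("not a PatchClassifier file")
        return obj


def _labels_to_idx(patches: Sequence[LabeledPatch]) -> np.ndarray:
    try:
        return np.array([CLASS_NAMES.index(p.label) for p in patches])
    except ValueError as err:
        raise ValueError("patch label outside the class vocabulary") from err


def _head(seed: int) -> LogisticRegression:
    # newton-cg with a tight tolerance: head refits must land on the
    # convex optimum precisely enough that update order is irrelevant
    return LogisticRegression(
        C=10.0, tol=1e-12, max_iter=20000, solver="newton-cg",
        warm_start=True, random_state=seed,
    )


def train_classifier(
    patches: Sequence[LabeledPatch],
    weights: Optional[dict[str, float]] = None,
    seed: int = 0,
) -> PatchClassifier:
    """Fit the baseline classifier on labeled patches.

    ``weights`` maps class name to a loss weight (inverse-frequency by
    default, computed from the training counts); each sample's loss is
    scaled by its class weight.  Training is deterministic given the
    seed.
    """
    labels_idx = _labels_to_idx(patches)
    if len(np.unique(labels_idx)) < 2:
        raise ValueError("need at least 2 classes to train")
    if weights is None:
        counts: dict[str, int] = {}
        for p in patches:
            counts[p.label] = counts.get(p.label, 0) + 1
        weights = compute_class_weights(counts)
    feats = np.stack([patch_features(p.pixels) for p in patches])
    mean = feats.mean(axis=0)
    scale = feats.std(axis=0)
    scale[scale < 1e-9] = 1.0
    x = (feats - mean) / scale
    sample_w = np.array([weights.get(p.label, 1.0) for p in patches])
    head = _head(seed)
    head.fit(x, labels_idx, sample_weight=sample_w)
    return PatchClassifier(
        head=head, feature_mean=mean, feature_scale=scale,
        train_features=feats, train_labels=labels_idx, train_weights=sample_w,
    )


def incremental_update(
    classifier: PatchClassifier,
    corrected: Sequence[LabeledPatch],
    seed: int = 0,
    weight: float = 1.0,
) -> PatchClassifier:
    """Head-only refit with newly corrected patches.

    The feature map and its standardization are frozen; the linear head
    is warm-started from the current parameters and re-optimized over
    the cached training features plus the corrections.  An empty
    correction set returns a classifier with identical predictions.
    Two sequential updates agree with one combined update (convex
    objective, shared optimum).
    """
    if len(corrected) == 0:
        return classifier
    new_idx = _labels_to_idx(corrected)
    new_feats = np.stack([patch_features(p.pixels) for p in corrected])
    feats = np.concatenate([classifier.train_features, new_feats])
    labels = np.concatenate([classifier.train_labels, new_idx])
    sample_w = np.concatenate([
        classifier.train_weights, np.full(len(corrected), weight)
    ])
    x = (feats - classifier.feature_mean) / classifier.feature_scale
    head = _head(seed)
    # warm start from the current head when the class set is unchanged
    if set(np.unique(labels)) == set(classifier.head.classes_):
        head.classes_ = classifier.head.classes_.copy()
        head.coef_ = classifier.head.coef_.copy()
        head.intercept_ = classifier.head.intercept_.copy()
    head.fit(x, labels, sample_weight=sample_w)
    return PatchClassifier(
        head=head, feature_mean=classifier.feature_mean,
        feature_scale=classifier.feature_scale,
        train_features=feats, train_labels=labels, train_weights=sample_w,
    )
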