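"""Shared fixtures: synthetic images, patch datasets, trained classifier.

Expensive fixtures are session-scoped; everything is seeded, so the
suite is fully deterministic.
"""

from __future__ import annotations

import numpy as np
import pytest

from gleasonkit import (PatchScale, TissueLayoutSpec, extract_patches,
                        generate_tissue_image, train_classifier)
from gleasonkit.types import CLASS_NAMES

#: Equal-composition layout used for patch/classifier fixtures: large
#: layout cells (251 px) so that 251-px windows are class-dominated.
EQUAL_FRACTIONS = {name: 0.19 for name in CLASS_NAMES}


def make_patch_image(seed: int, side: int = 1255, cell: int = 251):
    return generate_tissue_image(TissueLayoutSpec(
        image_side=side, cell_side=cell, class_fractions=EQUAL_FRACTIONS,
        background_fraction=0.05, seed=seed,
    ))


def patches_of(img, image_id: str):
    return extract_patches(img, img.labels, PatchScale(side=251),
                           image_id=image_id)


@pytest.fixture(scope="session")
def tissue_image():
    """Default mixed-class 512-px labeled image."""
    return generate_tissue_image(TissueLayoutSpec(image_side=512, seed=7))


@pytest.fixture(scope="session")
def patch_dataset():
    """Train/test patch sets split by image (no leakage)."""
    train_imgs = [make_patch_image(100 + s) for s in range(4)]
    test_imgs = [make_patch_image(200 + s) for s in range(2)]
    correction_imgs = [make_patch_image(300 + s) for s in range(2)]
    train = [p for i, im in enumerate(train_imgs)
             for p in patches_of(im, f"train{i}")]
    test = [p for i, im in enumerate(test_imgs)
            for p in patches_of(im, f"test{i}")]
    corrections = [p for i, im in enumerate(correction_imgs)
                   for p in patches_of(im, f"corr{i}")]
    return {"train_images": train_imgs, "test_images": test_imgs,
            "train": train, "test": test, "corrections": corrections}


@pytest.fixture(scope="session")
def trained_classifier(patch_dataset):
    return train_classifier(patch_dataset["train"], seed=0)


class StubClassifier:
    """Deterministic stand-in classifier for windowing/voting tests.

    Produces a probability vector from simple crop statistics, so fused
    rasters depend on the input in a nontrivial but reproducible way.
    """

    def predict_proba(self, crops) -> np.ndarray:
        out = []
        for crop in crops:
            v = np.asarray(crop, dtype=float)
            m = v.mean(axis=(0, 1)) / 255.0
            s = v.std() / 255.0
            raw = np.array([m[0], m[1], m[2], s, (m[0] * 7.3) % 0.9 + 0.05])
            out.append(raw / raw.sum())
        return np.asarray(out)


@pytest.fixture()
def stub_classifier():
    return StubClassifier()


@pytest.fixture(scope="session")
def patch_image_factory():
    """Factory for the large-cell layout images used by patch fixtures."""
    return make_patch_image
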