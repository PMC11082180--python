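"""Appearance migration: tissue masking, reference PDF estimation,
PDF-matching transform and its diagnostics."""

import numpy as np
import pytest

from gleasonkit import (LabeledImage, ReferencePDF, TissueLayoutSpec,
                        apply_scanner_style, channel_mean_summary,
                        estimate_reference_pdf, generate_tissue_image,
                        histogram_intersection, migrate_image, tissue_mask)
from gleasonkit.migration import _matching_lut, image_pdf
from gleasonkit.synthetic import SCANNER_STYLES, ScannerStyle


def _pdf_from_channel(vec):
    pdf = np.zeros((3, 256))
    pdf[:] = np.asarray(vec) / np.sum(vec)
    return ReferencePDF(pdf)


class TestTissueMask:
    def test_pure_white_image_is_all_background(self):
        img = np.full((128, 128, 3), 250, dtype=np.uint8)
        assert not tissue_mask(img).any()

    def test_fixture_mask_matches_generator(self, tissue_image):
        mask = tissue_mask(tissue_image)
        truth = tissue_image.tissue
        iou = (mask & truth).sum() / (mask | truth).sum()
        assert iou >= 0.9

    def test_mask_invariant_under_identity_style(self, tissue_image):
        styled = apply_scanner_style(tissue_image, ScannerStyle())
        assert np.array_equal(tissue_mask(styled.rgb), tissue_mask(tissue_image.rgb))


class TestReferencePdf:
    def test_constant_image_gives_point_mass(self):
        img = np.full((32, 32, 3), 100, dtype=np.uint8)
        ref = estimate_reference_pdf([img], masks=[np.ones((32, 32), bool)])
        for c in range(3):
            assert ref.pdf[c, 100] == pytest.approx(1.0)

    def test_average_of_per_image_pdfs_not_pooled(self):
        """Two toy images of unequal tissue area contribute equally."""
        a = np.full((4, 4, 3), 10, dtype=np.uint8)       # 16 px at 10
        b = np.full((2, 2, 3), 20, dtype=np.uint8)       # 4 px at 20
        ref = estimate_reference_pdf(
            [a, b], masks=[np.ones((4, 4), bool), np.ones((2, 2), bool)])
        # per-image average: 0.5 at each value (pooled would be 0.8/0.2)
        assert ref.pdf[0, 10] == pytest.approx(0.5)
        assert ref.pdf[0, 20] == pytest.approx(0.5)

    def test_channels_sum_to_one(self, tissue_image):
        ref = estimate_reference_pdf([tissue_image])
        assert np.allclose(ref.pdf.sum(axis=1), 1.0, atol=1e-9)

    def test_all_empty_masks_rejected(self):
        img = np.zeros((8, 8, 3), dtype=np.uint8)
        with pytest.raises(ValueError):
            estimate_reference_pdf([img], masks=[np.zeros((8, 8), bool)])


class TestHistogramIntersection:
    def test_identical_pdfs_give_one(self, tissue_image):
        pdf = image_pdf(tissue_image, tissue_image.tissue)
        per, mean = histogram_intersection(pdf, pdf)
        assert mean == pytest.approx(1.0)

    def test_disjoint_supports_give_zero(self):
        a = np.zeros(256); a[10] = 1.0
        b = np.zeros(256); b[200] = 1.0
        _, mean = histogram_intersection(a[None, :], b[None, :])
        assert mean == 0.0

    def test_hand_computed_overlap(self):
        a = np.zeros(256); a[0] = 0.5; a[1] = 0.5
        b = np.zeros(256); b[0] = 0.25; b[1] = 0.25; b[2] = 0.5
        _, mean = histogram_intersection(a[None, :], b[None, :])
        assert mean == pytest.approx(0.5)

    def test_symmetry(self, tissue_image):
        a = image_pdf(tissue_image, tissue_image.tissue)
        shifted = apply_scanner_style(tissue_image, SCANNER_STYLES["scannerC"])
        b = image_pdf(shifted, shifted.tissue)
        assert histogram_intersection(a, b)[1] == pytest.approx(
            histogram_intersection(b, a)[1])


class TestMigration:
    def test_self_migration_is_near_identity(self, tissue_image):
        ref = estimate_reference_pdf([tissue_image], masks=[tissue_image.tissue])
        out = migrate_image(tissue_image, ref, mask=tissue_image.tissue)
        hi = histogram_intersection(image_pdf(out, tissue_image.tissue),
                                    ref.pdf)[1]
        assert hi >= 0.99
        # rank order preserved per channel
        for c in range(3):
            src = tissue_image.rgb[..., c][tissue_image.tissue]
            dst = out.rgb[..., c][tissue_image.tissue]
            order = np.argsort(src, kind="stable")
            assert (np.diff(dst[order].astype(int)) >= 0).all()

    def test_lut_is_monotone(self, tissue_image):
        ref = estimate_reference_pdf([tissue_image], masks=[tissue_image.tissue])
        shifted = apply_scanner_style(tissue_image, SCANNER_STYLES["scannerB"])
        src_pdf = image_pdf(shifted, shifted.tissue)
        for c in range(3):
            lut = _matching_lut(src_pdf[c], ref.pdf[c])
            assert (np.diff(lut.astype(int)) >= 0).all()

    def test_migration_improves_hi_and_is_idempotent(self, tissue_image):
        others = [generate_tissue_image(TissueLayoutSpec(image_side=384, seed=s))
                  for s in (11, 12, 13)]
        ref = estimate_reference_pdf(others, masks=[o.tissue for o in others])
        shifted = apply_scanner_style(tissue_image, SCANNER_STYLES["scannerC"])
        hi_pre = histogram_intersection(image_pdf(shifted, shifted.tissue), ref.pdf)[1]
        once = migrate_image(shifted, ref)
        hi_post = histogram_intersection(image_pdf(once, once.tissue), ref.pdf)[1]
        assert hi_post > hi_pre
        twice = migrate_image(once, ref)
        delta = np.abs(twice.rgb.astype(float).mean(axis=(0, 1))
                       - once.rgb.astype(float).mean(axis=(0, 1)))
        assert (delta < 1.0).all()

    def test_labels_untouched(self, tissue_image):
        ref = estimate_reference_pdf([tissue_image])
        shifted = apply_scanner_style(tissue_image, SCANNER_STYLES["scannerD"])
        out = migrate_image(shifted, ref)
        assert np.array_equal(out.labels, tissue_image.labels)

    def test_degenerate_channel_maps_to_reference_median(self, tissue_image):
        ref = estimate_reference_pdf([tissue_image], masks=[tissue_image.tissue])
        const = LabeledImage(rgb=np.full((64, 64, 3), 80, dtype=np.uint8))
        with pytest.warns(UserWarning, match="constant"):
            out = migrate_image(const, ref, mask=np.ones((64, 64), bool))
        for c in range(3):
            cdf = np.cumsum(ref.pdf[c])
            median = int(np.searchsorted(cdf, 0.5))
            assert int(out.rgb[0, 0, c]) == median


class TestChannelMeanSummary:
    def test_identical_images_have_zero_compactness(self, tissue_image):
        _, compactness = channel_mean_summary([tissue_image, tissue_image])
        assert compactness == 0.0

    def test_order_invariance(self, tissue_image):
        shifted = apply_scanner_style(tissue_image, SCANNER_STYLES["scannerB"])
        _, c1 = channel_mean_summary([tissue_image, shifted])
        _, c2 = channel_mean_summary([shifted, tissue_image])
        assert c1 == pytest.approx(c2)

    def test_migration_tightens_clusters(self):
        imgs = [generate_tissue_image(TissueLayoutSpec(image_side=320, seed=s))
                for s in range(4)]
        ref = estimate_reference_pdf(imgs, masks=[i.tissue for i in imgs])
        shifted = [apply_scanner_style(im, SCANNER_STYLES["scannerC"])
                   for im in imgs[:2]] + list(imgs[2:])
        migrated = [migrate_image(im, ref) for im in shifted]
        _, pre = channel_mean_summary(shifted, masks=[im.tissue for im in shifted])
        _, post = channel_mean_summary(migrated, masks=[im.tissue for im in migrated])
        assert post < pre
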