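"""Instance reconciliation, classification metrics, Gleason Grade Group
derivation, quadratic weighted kappa, timing summaries."""

import itertools

import numpy as np
import pytest
from shapely.geometry import box

from gleasonkit import (classification_metrics, grade_group_from_patterns,
                        quadratic_weighted_kappa, reconcile_instance_label,
                        slide_gleason, timing_summary)
from gleasonkit.grading import GradeGroup, evaluate_annotations
from gleasonkit.geo import Annotation
from gleasonkit.types import CLASS_CODES


class TestReconcileInstanceLabel:
    def _raster(self, areas):
        """1-D strip raster with the requested per-class pixel areas."""
        total = sum(areas.values())
        raster = np.zeros((1, total), dtype=np.uint8)
        col = 0
        for name, n in areas.items():
            raster[0, col: col + n] = CLASS_CODES[name]
            col += n
        return raster

    def test_largest_area_wins(self):
        raster = self._raster({"GP3": 600, "GP4": 400})
        poly = box(-0.5, -0.5, 999.5, 0.5)
        assert reconcile_instance_label(raster, poly) == "GP3"

    def test_single_class_region(self):
        raster = self._raster({"benign": 100})
        assert reconcile_instance_label(raster, box(-0.5, -0.5, 99.5, 0.5)) == "benign"

    def test_exact_tie_goes_to_more_severe(self):
        raster = self._raster({"GP3": 500, "GP4": 500})
        assert reconcile_instance_label(raster, box(-0.5, -0.5, 999.5, 0.5)) == "GP4"

    def test_fully_unscored_polygon_rejected(self):
        raster = np.zeros((10, 10), dtype=np.uint8)
        with pytest.raises(ValueError):
            reconcile_instance_label(raster, box(0, 0, 5, 5))

    def test_mostly_unscored_instances_excluded(self):
        raster = np.zeros((1, 100), dtype=np.uint8)
        raster[0, :10] = CLASS_CODES["GP3"]  # 90% unscored
        anns = [Annotation(box(-0.5, -0.5, 99.5, 0.5), "GP3")]
        gt, pred = evaluate_annotations(raster, anns)
        assert gt == [] and pred == []


class TestClassificationMetrics:
    def test_perfect_agreement(self):
        labels = ["GP3", "GP4", "benign", "stroma", "GP5"]
        table = classification_metrics(labels, labels)
        assert table.macro_f1 == pytest.approx(1.0)
        assert all(v == pytest.approx(1.0) for v in table.binary.values())

    def test_binary_two_by_two_arithmetic(self):
        gt = ["GP3", "GP4", "benign", "stroma"]
        pred = ["GP3", "benign", "benign", "stroma"]
        table = classification_metrics(gt, pred)
        assert table.binary["sensitivity"] == pytest.approx(0.5)
        assert table.binary["specificity"] == pytest.approx(1.0)
        assert table.binary["ppv"] == pytest.approx(1.0)
        assert table.binary["npv"] == pytest.approx(2 / 3)

    def test_gp5_counts_as_malignant(self):
        table = classification_metrics(["GP5", "benign"], ["GP5", "benign"])
        assert table.binary["sensitivity"] == pytest.approx(1.0)

    def test_macro_is_arithmetic_mean_of_f1(self):
        gt = ["GP3", "GP3", "GP4", "benign"]
        pred = ["GP3", "GP4", "GP4", "benign"]
        table = classification_metrics(gt, pred)
        assert table.macro_f1 == pytest.approx(table.per_class["f1"].mean(),
                                               abs=1e-12)

    def test_absent_class_excluded_with_warning(self):
        with pytest.warns(UserWarning):
            table = classification_metrics(["GP3", "GP4"], ["GP3", "GP4"])
        assert "GP5" not in table.per_class.index

    def test_joint_permutation_invariance(self):
        rng = np.random.default_rng(0)
        gt = rng.choice(["GP3", "GP4", "benign"], 50).tolist()
        pred = rng.choice(["GP3", "GP4", "benign"], 50).tolist()
        perm = rng.permutation(50)
        t1 = classification_metrics(gt, pred)
        t2 = classification_metrics([gt[i] for i in perm], [pred[i] for i in perm])
        assert t1.macro_f1 == pytest.approx(t2.macro_f1, abs=1e-12)


class TestGradeGroup:
    @pytest.mark.parametrize("primary,secondary,group", [
        (3, 3, 1),            # score 6
        (3, 4, 2), (4, 3, 3),  # the two score-7 groups
        (4, 4, 4), (3, 5, 4), (5, 3, 4),  # score 8
        (4, 5, 5), (5, 4, 5), (5, 5, 5),  # scores 9-10
    ])
    def test_mapping(self, primary, secondary, group):
        assert grade_group_from_patterns(primary, secondary) == group

    def test_mapping_total_over_pattern_pairs(self):
        for p, s in itertools.product((3, 4, 5), repeat=2):
            assert grade_group_from_patterns(p, s) in {1, 2, 3, 4, 5}

    def test_benign_slide_has_no_group(self):
        assert GradeGroup(None, None).group is None


class TestSlideGleason:
    def _raster(self, areas, side=100):
        raster = np.zeros((side, side), dtype=np.uint8)
        row = 0
        for name, frac in areas.items():
            rows = int(round(frac * side))
            raster[row: row + rows] = CLASS_CODES[name]
            row += rows
        return raster

    def test_primary_secondary_from_areas(self):
        gg = slide_gleason(self._raster({"GP3": 0.6, "GP4": 0.4}))
        assert (gg.primary, gg.secondary, gg.group) == (3, 4, 2)

    def test_single_pattern_doubles(self):
        gg = slide_gleason(self._raster({"GP4": 0.5, "benign": 0.5}))
        assert (gg.gleason_score, gg.group) == (8, 4)

    def test_benign_only_raster(self):
        gg = slide_gleason(self._raster({"benign": 0.7, "stroma": 0.3}))
        assert gg.group is None

    def test_tiny_secondary_ignored(self):
        gg = slide_gleason(self._raster({"GP4": 0.97, "GP5": 0.01,
                                         "stroma": 0.02}))
        assert (gg.primary, gg.secondary) == (4, 4)


class TestQuadraticWeightedKappa:
    def test_identical_vectors(self):
        assert quadratic_weighted_kappa([1, 2, 3, 4, 5], [1, 2, 3, 4, 5], 5) == 1.0

    def test_two_by_two_antisymmetric_case(self):
        assert quadratic_weighted_kappa([1, 2], [2, 1], 2) == pytest.approx(-1.0)

    def test_rater_symmetry(self):
        rng = np.random.default_rng(1)
        a = rng.integers(1, 6, 40)
        b = rng.integers(1, 6, 40)
        assert quadratic_weighted_kappa(a, b, 5) == pytest.approx(
            quadratic_weighted_kappa(b, a, 5), abs=1e-12)

    def test_matches_direct_formula_oracle(self):
        """Cross-check against scikit-learn's quadratic Cohen kappa."""
        from sklearn.metrics import cohen_kappa_score
        rng = np.random.default_rng(2)
        for _ in range(100):
            n = rng.integers(5, 60)
            a = rng.integers(1, 6, n)
            b = rng.integers(1, 6, n)
            if len(np.union1d(a, b)) < 2:
                continue
            ours = quadratic_weighted_kappa(a, b, 5)
            theirs = cohen_kappa_score(a, b, labels=[1, 2, 3, 4, 5],
                                       weights="quadratic")
            assert ours == pytest.approx(theirs, abs=1e-12)

    def test_too_few_categories_rejected(self):
        with pytest.raises(ValueError):
            quadratic_weighted_kappa([1, 1], [1, 1], 1)


class TestTimingSummary:
    def test_annotation_speedup(self):
        """Mean 1267 s vs 508 s per image is a 2.5-fold speedup."""
        summary = timing_summary([1267.0] * 5, [508.0] * 5)
        assert summary.fold_speedup == pytest.approx(2.5)

    def test_examination_time_reduction(self):
        """148/147 s before vs 84 s after is a 43% reduction."""
        summary = timing_summary([148.0, 147.0], [84.0, 84.0])
        assert summary.mean_before == pytest.approx(147.5)
        assert summary.percent_reduction == 43

    def test_identical_conditions(self):
        summary = timing_summary([100.0, 100.0], [100.0, 100.0])
        assert summary.fold_speedup == 1.0
        assert summary.percent_reduction == 0

    def test_unpaired_samples_warn_and_omit_p(self):
        with pytest.warns(UserWarning):
            summary = timing_summary([100.0, 90.0, 80.0], [50.0, 40.0])
        assert summary.p_value is None

    def test_paired_t_test_reported(self):
        summary = timing_summary([100.0, 110.0, 95.0], [50.0, 55.0, 52.0])
        assert 0.0 < summary.p_value < 0.05

    def test_nonpositive_times_rejected(self):
        with pytest.raises(ValueError):
            timing_summary([0.0], [10.0])
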