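"""LOPO folds, confusion-matrix metrics, AUC and aggregation conventions."""

import itertools

import numpy as np
import pytest
from sklearn.metrics import f1_score, matthews_corrcoef, recall_score, roc_auc_score

from esohsi.evaluate import (
    FoldSplit,
    aggregate,
    confusion,
    difference_map,
    lopo_splits,
    per_class_metrics,
    roc_auc,
)
from esohsi.hsi_io import AnnotationMask


class TestLopoSplits:
    def test_minimum_cohort_gives_one_training_patient_per_fold(self):
        folds = lopo_splits([f"P{i}" for i in range(5)], seed=0)
        assert len(folds) == 5
        assert all(len(f.training_patients) == 1 for f in folds)

    def test_each_fold_partitions_the_cohort(self):
        ids = [f"P{i}" for i in range(9)]
        for f in lopo_splits(ids, seed=1):
            union = {f.test_patient} | set(f.validation_patients) | set(f.training_patients)
            assert union == set(ids)
            assert len(f.validation_patients) == 3

    def test_reproducible_under_seed(self):
        ids = [f"P{i}" for i in range(8)]
        assert lopo_splits(ids, seed=5) == lopo_splits(ids, seed=5)

    def test_overlapping_sets_rejected(self):
        with pytest.raises(ValueError, match="disjoint"):
            FoldSplit("a", ("b", "c", "b"), ("d",))

    def test_small_cohort_rejected(self):
        with pytest.raises(ValueError):
            lopo_splits(["a", "b", "c", "d"], seed=0)


class TestConfusion:
    def test_perfect_prediction_is_diagonal(self):
        np.testing.assert_array_equal(confusion([0, 1, 2], [0, 1, 2]), np.eye(3))

    def test_empty_input_gives_zero_matrix(self):
        np.testing.assert_array_equal(confusion([], []), np.zeros((3, 3)))

    def test_hand_counted_example(self):
        cm = confusion([0, 0, 1, 2], [0, 1, 1, 1])
        np.testing.assert_array_equal(cm, [[1, 1, 0], [0, 1, 0], [0, 1, 0]])

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            confusion([0, 1], [0])


class TestPerClassMetrics:
    def test_perfect_two_class_matrix(self):
        cm = np.diag([2, 2, 0])
        m = per_class_metrics(cm, 0)
        assert m["sensitivity"] == m["specificity"] == m["f1"] == m["mcc"] == 1.0

    def test_independence_point(self):
        cm = np.array([[1, 1, 0], [1, 1, 0], [0, 0, 0]])
        m = per_class_metrics(cm, 0)
        assert m["mcc"] == pytest.approx(0.0)
        assert m["f1"] == pytest.approx(0.5)

    def test_binary_textbook_example(self):
        cm = np.array([[8, 2], [3, 7]])
        m = per_class_metrics(cm, 0)
        assert m["sensitivity"] == pytest.approx(0.8)
        assert m["specificity"] == pytest.approx(0.7)
        assert m["mcc"] == pytest.approx(50 / np.sqrt(9900))

    def test_zero_denominators_yield_zero(self):
        m = per_class_metrics(np.zeros((3, 3)), 1)
        assert all(v == 0.0 for v in m.values())

    def test_exhaustive_agreement_with_expansion_oracle(self):
        """All 4^9 confusion matrices with cells <= 3, every class, against
        an independently written one-vs-rest computation."""
        grids = np.stack(np.meshgrid(*[np.arange(4)] * 9, indexing="ij"),
                         axis=-1).reshape(-1, 3, 3)
        for c in range(3):
            got = per_class_metrics(grids, c)
            # oracle: collapse counts by explicit slicing, then formulas
            tp = grids[:, c, c].astype(float)
            fn = grids[:, c].sum(axis=1) - tp
            fp = grids[:, :, c].sum(axis=1) - tp
            tn = grids.sum(axis=(1, 2)) - tp - fn - fp
            def div(n, d):
                return np.where(d > 0, n / np.maximum(d, 1), 0.0)
            np.testing.assert_allclose(got["sensitivity"], div(tp, tp + fn), atol=1e-12)
            np.testing.assert_allclose(got["specificity"], div(tn, tn + fp), atol=1e-12)
            np.testing.assert_allclose(got["f1"], div(2 * tp, 2 * tp + fp + fn), atol=1e-12)
            mcc = div(tp * tn - fp * fn,
                      np.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)))
            np.testing.assert_allclose(got["mcc"], mcc, atol=1e-12)

    def test_subsample_against_sklearn(self):
        """Seeded label-vector expansion cross-checked with sklearn."""
        rng = np.random.default_rng(0)
        for _ in range(50):
            cm = rng.integers(0, 4, (3, 3))
            y_true = np.repeat(np.repeat([0, 1, 2], 3), cm.ravel())
            y_pred = np.repeat(np.tile([0, 1, 2], 3), cm.ravel())
            if y_true.size == 0:
                continue
            np.testing.assert_array_equal(confusion(y_true, y_pred), cm)
            for c in range(3):
                m = per_class_metrics(cm, c)
                t, p = y_true == c, y_pred == c
                if t.any():
                    assert m["sensitivity"] == pytest.approx(
                        recall_score(t, p, zero_division=0))
                if t.any() and (~t).any() and cm.sum() > 0:
                    sk_mcc = matthews_corrcoef(t, p)
                    assert m["mcc"] == pytest.approx(sk_mcc, abs=1e-12)
                    assert m["f1"] == pytest.approx(f1_score(t, p, zero_division=0))


class TestRocAuc:
    def test_perfect_separation(self):
        assert roc_auc([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9]) == 1.0

    def test_all_ties_give_half(self):
        assert roc_auc([0, 1, 0, 1], [0.5, 0.5, 0.5, 0.5]) == 0.5

    def test_three_of_four_pairs_ordered(self):
        assert roc_auc([1, 0, 1, 0], [0.9, 0.8, 0.7, 0.6]) == pytest.approx(0.75)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="one class"):
            roc_auc([1, 1, 1], [0.1, 0.2, 0.3])

    def test_rank_sum_equals_trapezoid_on_random_vectors(self):
        """1,000 seeded score vectors (continuous and heavily tied) agree
        with sklearn's trapezoidal ROC integration within 1e-9."""
        rng = np.random.default_rng(42)
        for i in range(1000):
            n = int(rng.integers(10, 60))
            y = rng.integers(0, 2, n)
            if y.min() == y.max():
                y[0] = 1 - y[0]
            scores = rng.random(n)
            if i % 2:  # force ties
                scores = np.round(scores, 1)
            assert roc_auc(y, scores) == pytest.approx(
                roc_auc_score(y, scores), abs=1e-9)


class TestAggregate:
    @staticmethod
    def _rows(values, metric="sensitivity"):
        rows = []
        for cls, v in zip(("cancer", "stomach", "esophagus"), values):
            row = {"patient_id": f"p-{cls}", "tissue_class": cls,
                   "sensitivity": 0.5, "specificity": 0.5, "f1": 0.5,
                   "mcc": 0.5, "auc": 0.5}
            row[metric] = v
            rows.append(row)
        return rows

    def test_macro_sensitivity_convention(self):
        """Per-class means (0.65, 0.77, 0.81) summarize to 74 +/- 8 %."""
        agg = aggregate(self._rows([0.65, 0.77, 0.81]))
        macro = agg["macro"]["sensitivity"]
        assert round(100 * macro["mean"]) == 74
        assert round(100 * macro["sd"]) == 8

    def test_macro_auc_convention(self):
        """Per-class means (0.80, 0.79, 0.84) summarize to 81 +/- 3 %."""
        agg = aggregate(self._rows([0.80, 0.79, 0.84], metric="auc"))
        macro = agg["macro"]["auc"]
        assert macro["mean"] == pytest.approx(0.81)
        assert round(100 * macro["sd"]) == 3

    def test_identical_rows_have_zero_sd(self):
        rows = self._rows([0.7, 0.7, 0.7]) * 2
        for i, row in enumerate(rows):
            row = dict(row)
            row["patient_id"] = f"p{i}"
            rows[i] = row
        agg = aggregate(rows)
        for cls in agg["per_class"]:
            assert agg["per_class"][cls]["sensitivity"]["sd"] == 0.0

    def test_missing_rows_excluded_not_zero_filled(self):
        rows = self._rows([0.6, 0.8, 0.9])[:2]  # esophagus absent
        agg = aggregate(rows)
        assert "esophagus" not in agg["per_class"]
        assert agg["macro"]["sensitivity"]["mean"] == pytest.approx((0.6 + 0.8) / 2)


class TestDifferenceMap:
    def test_perfect_prediction_all_correct(self):
        mask = AnnotationMask(np.array([[1, 2], [3, 0]], dtype=np.uint8))
        pred = np.array([[1, 2], [3, 2]], dtype=np.uint8)
        out = difference_map(pred, mask)
        np.testing.assert_array_equal(out, [[1, 2], [3, 0]])

    def test_uniform_misprediction_encoded(self):
        mask = AnnotationMask(np.full((2, 2), 2, dtype=np.uint8))  # stomach
        pred = np.full((2, 2), 1, dtype=np.uint8)                 # esophagus
        out = difference_map(pred, mask)
        np.testing.assert_array_equal(out, np.full((2, 2), 12))   # pred 1, true 2

    def test_category_counts_match_confusion(self):
        rng = np.random.default_rng(0)
        true = rng.integers(0, 4, (12, 12)).astype(np.uint8)
        pred = rng.integers(1, 4, (12, 12)).astype(np.uint8)
        mask = AnnotationMask(true)
        out = difference_map(pred, mask)
        usable = true > 0
        cm = confusion(true[usable] - 1, pred[usable] - 1)
        for j, k in itertools.product(range(1, 4), repeat=2):
            if j != k:
                assert (out == 10 * j + k).sum() == cm[k - 1, j - 1]
            else:
                assert (out == k).sum() == cm[k - 1, k - 1]
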