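import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from vesselx import (
    BinaryMask,
    ConfusionCounts,
    ConsistencyError,
    DegenerateInputError,
    MetricsRow,
    aggregate,
    confusion_counts,
    dice,
    load_reference_metrics,
    metrics,
    write_report_csv,
)


def _mask(coords, shape=(4, 4)):
    px = np.zeros(shape, dtype=np.uint8)
    for r, c in coords:
        px[r, c] = 1
    return BinaryMask(px)


class TestConfusionCounts:
    def test_hand_enumerated_4x4_example(self):
        pred = _mask([(0, 0), (0, 1), (1, 1)])
        truth = _mask([(0, 1), (1, 1), (2, 2)])
        c = confusion_counts(pred, truth)
        assert (c.tp, c.fp, c.fn, c.tn) == (2, 1, 1, 12)

    def test_perfect_prediction(self, rng):
        px = (rng.random((10, 10)) > 0.7).astype(np.uint8)
        c = confusion_counts(BinaryMask(px), BinaryMask(px))
        assert c.fp == c.fn == 0
        assert c.tp == px.sum()
        assert c.tn == 100 - px.sum()

    def test_all_ones_prediction(self):
        truth = _mask([(1, 1), (2, 2)])
        pred = BinaryMask(np.ones((4, 4), dtype=np.uint8))
        c = confusion_counts(pred, truth)
        assert (c.tp, c.fp, c.tn, c.fn) == (2, 14, 0, 0)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ConsistencyError):
            confusion_counts(
                BinaryMask(np.zeros((4, 4), dtype=np.uint8)),
                BinaryMask(np.zeros((5, 5), dtype=np.uint8)),
            )

    def test_fov_restriction_only_removes_pixels(self, rng):
        pred = BinaryMask((rng.random((12, 12)) > 0.5).astype(np.uint8))
        truth = BinaryMask((rng.random((12, 12)) > 0.5).astype(np.uint8))
        fov = BinaryMask((rng.random((12, 12)) > 0.3).astype(np.uint8))
        full = confusion_counts(pred, truth)
        sub = confusion_counts(pred, truth, fov)
        for field in ("tp", "fp", "tn", "fn"):
            assert getattr(sub, field) <= getattr(full, field)


class TestMetrics:
    def test_arithmetic_on_known_counts(self):
        row = metrics(ConfusionCounts(tp=8, fp=2, tn=88, fn=2))
        assert row.sensitivity == pytest.approx(0.8)
        assert row.specificity == pytest.approx(88 / 90)
        assert row.accuracy == pytest.approx(0.96)
        assert row.precision == pytest.approx(0.8)

    def test_perfect_prediction_gives_all_ones(self):
        row = metrics(ConfusionCounts(tp=10, fp=0, tn=90, fn=0))
        assert (row.sensitivity, row.specificity, row.accuracy, row.precision) == (
            1.0, 1.0, 1.0, 1.0,
        )

    def test_zero_denominator_marks_undefined(self):
        row = metrics(ConfusionCounts(tp=0, fp=0, tn=5, fn=0))
        assert math.isnan(row.sensitivity)
        assert math.isnan(row.precision)
        assert row.specificity == 1.0

    def test_all_zero_counts_degenerate(self):
        with pytest.raises(DegenerateInputError):
            metrics(ConfusionCounts(tp=0, fp=0, tn=0, fn=0))

    @settings(derandomize=True, max_examples=50)
    @given(
        tp=st.integers(0, 1000), fp=st.integers(0, 1000),
        tn=st.integers(0, 1000), fn=st.integers(0, 1000),
    )
    def test_accuracy_is_prevalence_weighted_mean_of_se_sp(self, tp, fp, tn, fn):
        if tp + fn == 0 or tn + fp == 0:
            return
        row = metrics(ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn))
        p, n = tp + fn, tn + fp
        expected = (row.sensitivity * p + row.specificity * n) / (p + n)
        assert row.accuracy == pytest.approx(expected, abs=1e-12)

    def test_swap_symmetry_of_sensitivity_and_precision(self, rng):
        pred = BinaryMask((rng.random((10, 10)) > 0.5).astype(np.uint8))
        truth = BinaryMask((rng.random((10, 10)) > 0.5).astype(np.uint8))
        a = metrics(confusion_counts(pred, truth))
        b = metrics(confusion_counts(truth, pred))
        assert a.sensitivity == pytest.approx(b.precision)
        assert a.precision == pytest.approx(b.sensitivity)


class TestAggregate:
    def test_single_row_mean_equals_row(self):
        row = MetricsRow("a", 0.5, 0.6, 0.7, 0.8)
        rep = aggregate([row])
        assert rep.means.sensitivity == 0.5
        assert rep.means.precision == 0.8

    def test_means_are_unweighted_column_averages(self, rng):
        rows = [
            MetricsRow(f"r{i}", *rng.random(4).tolist()) for i in range(7)
        ]
        rep = aggregate(rows)
        for name in ("sensitivity", "specificity", "accuracy", "precision"):
            expected = np.mean([getattr(r, name) for r in rows])
            assert getattr(rep.means, name) == pytest.approx(expected, abs=1e-12)

    def test_nan_rows_skipped_and_counted(self):
        rows = [
            MetricsRow("a", math.nan, 0.9, 0.9, 0.5),
            MetricsRow("b", 0.6, 0.9, 0.9, 0.5),
        ]
        rep = aggregate(rows)
        assert rep.means.sensitivity == pytest.approx(0.6)
        assert rep.skipped["sensitivity"] == 1
        assert rep.skipped["accuracy"] == 0

    def test_empty_list_degenerate(self):
        with pytest.raises(DegenerateInputError):
            aggregate([])


class TestReferenceTables:
    def test_row_counts_match_public_test_sets(self):
        assert len(load_reference_metrics("drive")) == 20
        assert len(load_reference_metrics("chase_db1")) == 14

    def test_unknown_dataset_rejected(self):
        with pytest.raises(ValueError):
            load_reference_metrics("stare")


class TestReportOutput:
    def test_csv_roundtrip_with_mean_row(self, tmp_path):
        rows = [MetricsRow("a", 0.5, 0.6, 0.7, 0.8), MetricsRow("b", 0.7, 0.8, 0.9, 1.0)]
        rep = aggregate(rows)
        path = tmp_path / "report.csv"
        write_report_csv(rep, path)
        lines = path.read_text().strip().splitlines()
        assert lines[0] == "image_id,sensitivity,specificity,accuracy,precision"
        assert len(lines) == 4
        assert lines[-1].startswith("mean,")
        assert float(lines[-1].split(",")[1]) == pytest.approx(0.6)


class TestDice:
    def test_known_overlap(self):
        pred = _mask([(0, 0), (0, 1), (1, 1)])
        truth = _mask([(0, 1), (1, 1), (2, 2)])
        assert dice(pred, truth) == pytest.approx(2 * 2 / (3 + 3))

    def test_identical_masks_give_one(self, rng):
        m = BinaryMask((rng.random((8, 8)) > 0.5).astype(np.uint8))
        assert dice(m, m) == 1.0
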