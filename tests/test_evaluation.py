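"""Metric protocol: confusion counts, Dice/sensitivity/specificity,
skip-empty aggregation, class weighting and the lesion-size analysis."""

import numpy as np
import pandas as pd
import pytest

from octseg.evaluation import (
    EvalRecord,
    aggregate,
    assign_quartile,
    confusion,
    dice,
    evaluate_pair,
    export_report,
    lesion_size_analysis,
    lesion_size_quartiles,
    records_frame,
    sensitivity,
    specificity,
    weighted_mean,
)


def _brute_force_counts(ref, pred, c):
    tp = fp = fn = tn = 0
    for r in range(ref.shape[0]):
        for col in range(ref.shape[1]):
            a, b = ref[r, col] == c, pred[r, col] == c
            tp += a and b
            fp += (not a) and b
            fn += a and (not b)
            tn += (not a) and (not b)
    return tp, fp, fn, tn


class TestConfusion:
    def test_perfect_prediction(self):
        ref = np.zeros((10, 10), dtype=np.uint8)
        ref[:2, :2] = 1
        rec = confusion(ref, ref, 1)
        assert rec.fp == rec.fn == 0 and rec.tp == rec.ref_area == 4

    def test_disjoint_masks(self):
        ref = np.zeros((10, 10), dtype=np.uint8)
        pred = np.zeros((10, 10), dtype=np.uint8)
        ref[0, :4] = 2
        pred[1, :4] = 2
        rec = confusion(ref, pred, 2)
        assert (rec.tp, rec.fp, rec.fn, rec.tn) == (0, 4, 4, 92)

    def test_matches_pixel_loop_oracle(self, rng):
        ref = rng.integers(0, 4, size=(16, 16)).astype(np.uint8)
        pred = rng.integers(0, 4, size=(16, 16)).astype(np.uint8)
        for c in (1, 2, 3):
            rec = confusion(ref, pred, c)
            assert (rec.tp, rec.fp, rec.fn, rec.tn) == _brute_force_counts(ref, pred, c)
            assert rec.n_pixels == 256

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError):
            confusion(np.zeros((2, 2)), np.zeros((3, 3)), 1)


class TestMetrics:
    def test_identical_masks_score_one(self):
        rec = EvalRecord("i", 1, tp=4, fp=0, fn=0, tn=96)
        assert dice(rec) == 1.0 and sensitivity(rec) == 1.0 and specificity(rec) == 1.0

    def test_half_overlap_dice(self):
        rec = EvalRecord("i", 1, tp=2, fp=2, fn=2, tn=94)
        assert dice(rec) == 2 * 2 / 8 == 0.5

    def test_empty_prediction_sensitivity_zero_specificity_one(self):
        rec = EvalRecord("i", 1, tp=0, fp=0, fn=4, tn=96)
        assert sensitivity(rec) == 0.0 and specificity(rec) == 1.0


class TestAggregate:
    def test_perfect_image_gives_weighted_dice_one(self):
        ref = np.zeros((12, 12), dtype=np.uint8)
        ref[0, 0:2] = 1
        ref[1, 0:3] = 2
        ref[2, 0:4] = 3
        agg = aggregate(evaluate_pair(ref, ref, "img"))
        assert agg.weighted["dice"] == 1.0
        assert abs(sum(agg.weights.values()) - 1.0) < 1e-12

    def test_published_weighted_mean_reproduced(self):
        # per-class Dice and presence counts reproduce the printed MEAN
        got = weighted_mean([0.423, 0.582, 0.444], [1783, 3203, 1416])
        assert round(got, 4) == 0.5072
        assert round(got, 3) == round(0.508, 3) or abs(got - 0.508) < 1e-3

    def test_empty_reference_excluded_only_for_that_class(self):
        ref = np.zeros((8, 8), dtype=np.uint8)
        pred = np.zeros((8, 8), dtype=np.uint8)
        ref[0, :2] = 2  # SRF present; IRF absent in both
        pred[0, :2] = 2
        agg = aggregate(evaluate_pair(ref, pred, "img"))
        per = {row["class"]: row for _, row in agg.per_class.iterrows()}
        assert per["IRF"]["n_used"] == 0 and per["IRF"]["n_skipped"] == 1
        assert per["SRF"]["n_used"] == 1
        assert np.isnan(per["IRF"]["dice_mean"])  # missing, not zero

    def test_pure_false_positive_images_are_skipped(self):
        # side effect of the skip rule, preserved verbatim
        ref = np.zeros((8, 8), dtype=np.uint8)
        pred = np.zeros((8, 8), dtype=np.uint8)
        pred[0, :3] = 1  # prediction invents IRF, reference empty
        agg = aggregate(evaluate_pair(ref, pred, "img"))
        per = {row["class"]: row for _, row in agg.per_class.iterrows()}
        assert per["IRF"]["n_used"] == 0

    def test_permutation_invariance_and_oracle_equivalence(self, rng):
        records = []
        masks = []
        for i in range(12):
            ref = rng.integers(0, 4, size=(8, 8)).astype(np.uint8)
            pred = rng.integers(0, 4, size=(8, 8)).astype(np.uint8)
            masks.append((ref, pred))
            records.extend(evaluate_pair(ref, pred, f"img{i}"))
        agg = aggregate(records)
        perm = [records[i] for i in rng.permutation(len(records))]
        agg_perm = aggregate(perm)
        for m in ("dice", "sensitivity", "specificity"):
            assert np.isclose(agg.weighted[m], agg_perm.weighted[m])
        # brute-force recomputation from the raw masks
        for c, cname in ((1, "IRF"), (2, "SRF"), (3, "PED")):
            vals = []
            for i, (ref, pred) in enumerate(masks):
                tp, fp, fn, tn = _brute_force_counts(ref, pred, c)
                if (tp + fn) > 0 and (tp + fp) > 0:
                    vals.append(2 * tp / (2 * tp + fp + fn))
            row = agg.per_class[agg.per_class["class"] == cname].iloc[0]
            assert np.isclose(row["dice_mean"], np.mean(vals))

    def test_weighted_mean_bounded_by_class_means(self, rng):
        records = []
        for i in range(10):
            ref = rng.integers(0, 4, size=(10, 10)).astype(np.uint8)
            pred = rng.integers(0, 4, size=(10, 10)).astype(np.uint8)
            records.extend(evaluate_pair(ref, pred, f"img{i}"))
        agg = aggregate(records)
        means = agg.per_class["dice_mean"].dropna()
        assert means.min() - 1e-12 <= agg.weighted["dice"] <= means.max() + 1e-12


class TestLesionSize:
    def test_sizes_one_to_eight_bin_in_pairs(self):
        bounds = lesion_size_quartiles(np.arange(1, 9))
        bins = [assign_quartile(a, bounds) for a in range(1, 9)]
        assert bins == [1, 1, 2, 2, 3, 3, 4, 4]

    def test_all_equal_sizes_fall_in_first_bin(self):
        bounds = lesion_size_quartiles(np.full(10, 7.0))
        assert all(assign_quartile(7.0, bounds) == 1 for _ in range(3))

    def test_mean_dice_monotone_when_built_that_way(self):
        # construction oracle: larger lesions get strictly better Dice
        records = []
        for i in range(40):
            area = 10 + i * 5
            tp = int(area * (0.3 + 0.017 * i))
            records.append(EvalRecord(f"i{i}", 1, tp=tp, fp=area - tp, fn=area - tp,
                                      tn=10_000))
        df = lesion_size_analysis(records)
        sub = df[df["class"] == "IRF"].sort_values("quartile")
        means = sub["dice_mean"].to_numpy()
        assert np.all(np.diff(means) > 0)

    def test_too_few_records_raise(self):
        recs = [EvalRecord("a", 1, 1, 1, 1, 97)] * 3
        with pytest.raises(ValueError):
            lesion_size_analysis(recs)


class TestExportReport:
    def test_roundtrip_preserves_counts(self, tmp_path, rng):
        ref = rng.integers(0, 4, size=(8, 8)).astype(np.uint8)
        pred = rng.integers(0, 4, size=(8, 8)).astype(np.uint8)
        records = evaluate_pair(ref, pred, "img0")
        agg = aggregate(records)
        paths = export_report(tmp_path, records, agg)
        back = pd.read_csv(paths["records"])
        assert len(back) == 3
        orig = records_frame(records)
        pd.testing.assert_frame_equal(back, orig)

    def test_empty_records_give_headers_only(self, tmp_path):
        paths = export_report(tmp_path, [])
        back = pd.read_csv(paths["records"])
        assert len(back) == 0
        assert "ref_area" in back.columns
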