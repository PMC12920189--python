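"""Threshold sweep, patient/voxel/object-wise metrics, pooling, sensitivity."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from perivox import (
    BinaryMask,
    ClassificationCounts,
    FoldStats,
    ProbabilityMap,
    classification_metrics,
    hd95,
    objectwise_metrics,
    pair_components,
    patientwise_outcome,
    pooled_estimates,
    select_best_threshold,
    sensitivity_analysis,
    threshold_sweep,
    voxelwise_metrics,
)

from conftest import cube_mask, random_blob_mask


class TestThresholdSweep:
    def test_ten_equally_spaced_thresholds(self):
        pm = ProbabilityMap(np.zeros((4, 4, 4)))
        ts = [t for t, _ in threshold_sweep(pm, 10)]
        assert np.allclose(ts, [0.1 * k for k in range(1, 11)])

    def test_uniform_map_step_behaviour(self):
        pm = ProbabilityMap(np.full((4, 4, 4), 0.55))
        for t, mask in threshold_sweep(pm, 10):
            assert mask.values.all() if t <= 0.5 else not mask.values.any()

    @settings(derandomize=True, max_examples=20)
    @given(seed=st.integers(0, 10_000), n=st.integers(2, 12))
    def test_masks_nested(self, seed, n):
        pm = ProbabilityMap(np.random.default_rng(seed).random((8, 8, 8)))
        masks = [m for _, m in threshold_sweep(pm, n)]
        for lower, higher in zip(masks, masks[1:]):
            assert not (higher.values & ~lower.values).any()

    def test_too_few_thresholds_rejected(self):
        with pytest.raises(ValueError):
            threshold_sweep(ProbabilityMap(np.zeros((2, 2, 2))), 1)


class TestPatientwise:
    def test_identical_positive_masks_are_tp(self, policy):
        mask = cube_mask((20, 20, 20), (5, 5, 5), (12, 12, 12))  # 0.343 ml
        assert patientwise_outcome(mask, mask, "ET", policy) == "TP"

    def test_both_empty_is_tn(self, policy):
        empty = BinaryMask(np.zeros((10, 10, 10), dtype=bool))
        assert patientwise_outcome(empty, empty, "ET", policy) == "TN"

    def test_disjoint_positive_masks_are_fn(self, policy):
        gt = cube_mask((30, 30, 30), (1, 1, 1), (11, 11, 11))
        pred = cube_mask((30, 30, 30), (15, 15, 15), (25, 25, 25))
        assert patientwise_outcome(gt, pred, "ET", policy) == "FN"

    def test_prediction_only_is_fp(self, policy):
        empty = BinaryMask(np.zeros((30, 30, 30), dtype=bool))
        pred = cube_mask((30, 30, 30), (5, 5, 5), (15, 15, 15))
        assert patientwise_outcome(empty, pred, "ET", policy) == "FP"

    def test_subthreshold_gt_volume_is_negative(self, policy):
        """A ground-truth residual below 0.175 ml is a negative sample."""
        values = np.zeros((20, 20, 20), dtype=bool)
        values.ravel()[:174] = True
        gt = BinaryMask(values)
        empty = BinaryMask(np.zeros((20, 20, 20), dtype=bool))
        assert patientwise_outcome(gt, empty, "ET", policy) == "TN"

    def test_unknown_structure_rejected(self, policy):
        mask = cube_mask((10, 10, 10), (0, 0, 0), (5, 5, 5))
        with pytest.raises(ValueError):
            patientwise_outcome(mask, mask, "WT", policy)


class TestClassificationMetrics:
    def test_perfect_counts(self):
        m = classification_metrics(ClassificationCounts(TP=10, TN=10))
        assert all(v == 100.0 for v in m.values())

    def test_worked_example(self):
        m = classification_metrics(ClassificationCounts(TP=8, FN=2, TN=3, FP=7))
        assert m["recall"] == pytest.approx(80.0)
        assert m["specificity"] == pytest.approx(30.0)
        assert m["bAcc"] == pytest.approx(55.0)

    def test_degenerate_denominator_not_applicable(self):
        m = classification_metrics(ClassificationCounts(TN=5, FP=2))
        assert m["recall"] is None and m["bAcc"] is None

    @settings(derandomize=True, max_examples=60)
    @given(tp=st.integers(0, 50), fp=st.integers(0, 50),
           tn=st.integers(0, 50), fn=st.integers(0, 50))
    def test_metrics_bounded_and_consistent(self, tp, fp, tn, fn):
        c = ClassificationCounts(TP=tp, FP=fp, TN=tn, FN=fn)
        m = classification_metrics(c)
        for v in m.values():
            assert v is None or 0.0 <= v <= 100.0
        if m["recall"] is not None and m["specificity"] is not None:
            assert m["bAcc"] == pytest.approx((m["recall"] + m["specificity"]) / 2)


def brute_force_voxelwise(gt, pred, spacing=(1.0, 1.0, 1.0)):
    """Independent loops-and-all-pairs implementation of the voxel metrics."""
    inter = int(np.sum(gt & pred))
    n_gt, n_pred = int(gt.sum()), int(pred.sum())
    if n_gt == 0 and n_pred == 0:
        return {"dice": 100.0, "hd95": 0.0}
    dice = 100.0 * 2 * inter / (n_gt + n_pred)
    if n_gt == 0 or n_pred == 0:
        return {"dice": dice, "hd95": None}

    def surface(m):
        out = []
        for c in map(tuple, np.argwhere(m)):
            on_border = any(c[i] in (0, m.shape[i] - 1) for i in range(3))
            if on_border:
                out.append(c)
                continue
            for d in ((1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)):
                if not m[c[0] + d[0], c[1] + d[1], c[2] + d[2]]:
                    out.append(c)
                    break
        return np.array(out, dtype=float) * np.asarray(spacing)

    sa, sb = surface(gt), surface(pred)
    d_ab = [min(np.sqrt(((p - sb) ** 2).sum(axis=1))) for p in sa]
    d_ba = [min(np.sqrt(((p - sa) ** 2).sum(axis=1))) for p in sb]
    return {"dice": dice,
            "hd95": max(np.percentile(d_ab, 95), np.percentile(d_ba, 95))}


class TestVoxelwise:
    def test_identical_masks_perfect(self):
        mask = cube_mask((16, 16, 16), (4, 4, 4), (12, 12, 12))
        m = voxelwise_metrics(mask, mask)
        assert m["dice"] == 100.0 and m["hd95"] == 0.0

    def test_half_overlapping_cubes(self):
        gt = cube_mask((20, 20, 20), (0, 0, 0), (10, 10, 10))
        pred = cube_mask((20, 20, 20), (5, 0, 0), (15, 10, 10))
        assert voxelwise_metrics(gt, pred)["dice"] == pytest.approx(50.0)

    def test_two_voxels_three_mm_apart(self):
        a = np.zeros((10, 10, 10), dtype=bool)
        b = np.zeros((10, 10, 10), dtype=bool)
        a[2, 2, 2] = True
        b[5, 2, 2] = True
        assert hd95(BinaryMask(a), BinaryMask(b)) == pytest.approx(3.0)

    def test_empty_cases(self):
        empty = BinaryMask(np.zeros((8, 8, 8), dtype=bool))
        full = cube_mask((8, 8, 8), (2, 2, 2), (5, 5, 5))
        both = voxelwise_metrics(empty, empty)
        assert both["dice"] == 100.0 and both["hd95"] == 0.0
        one = voxelwise_metrics(full, empty)
        assert one["dice"] == 0.0 and one["hd95"] is None

    def test_dice_symmetry_and_range_random(self):
        rng = np.random.default_rng(30)
        for _ in range(20)    :
            a = random_blob_mask(rng)
            b = random_blob_mask(rng)
            ab = voxelwise_metrics(a, b)["dice"]
            ba = voxelwise_metrics(b, a)["dice"]
            assert ab == pytest.approx(ba)
            assert 0.0 <= ab <= 100.0

    def test_matches_brute_force_on_random_pairs(self):
        """Dice and HD95 equal an independent all-pairs implementation."""
        rng = np.random.default_rng(31)
        for _ in range(25):
            a = random_blob_mask(rng)
            b = random_blob_mask(rng)
            got = voxelwise_metrics(a, b)
            exp = brute_force_voxelwise(a.values, b.values)
            assert got["dice"] == pytest.approx(exp["dice"], abs=1e-6)
            if exp["hd95"] is None:
                assert got["hd95"] is None
            else:
                assert got["hd95"] == pytest.approx(exp["hd95"], abs=1e-6)


def exhaustive_best_assignment(dice_matrix):
    """Max total Dice over all one-to-one assignments (zero-overlap forbidden)."""
    n, m = dice_matrix.shape
    best = 0.0
    smaller, larger = (range(n), range(m)) if n <= m else (range(m), range(n))
    for perm in itertools.permutations(larger, len(list(smaller))):
        total = 0.0
        for i, j in zip(smaller, perm):
            d = dice_matrix[i, j] if n <= m else dice_matrix[j, i]
            if d > 0:
                total += d
        best = max(best, total)
    return best


class TestPairing:
    def _labelled(self, rng, shape=(20, 20, 20), k=3):
        labels = np.zeros(shape, dtype=np.int32)
        for lab in range(1, k + 1):
            c = rng.integers(3, 17, size=3)
            r = rng.integers(1, 4)
            g = np.meshgrid(*[np.arange(s) for s in shape], indexing="ij")
            d2 = sum((gi - ci) ** 2 for gi, ci in zip(g, c))
            labels[(d2 <= r**2) & (labels == 0)] = lab
        return labels

    def test_single_overlapping_pair_matched(self):
        gt = np.zeros((10, 10, 10), dtype=np.int32)
        pred = np.zeros_like(gt)
        gt[2:6, 2:6, 2:6] = 1
        pred[3:7, 3:7, 3:7] = 1
        pairs, un_gt, un_pred = pair_components(gt, pred)
        assert len(pairs) == 1 and not un_gt and not un_pred

    def test_zero_overlap_never_matched(self):
        gt = np.zeros((10, 10, 10), dtype=np.int32)
        pred = np.zeros_like(gt)
        gt[1:3, 1:3, 1:3] = 1
        pred[6:9, 6:9, 6:9] = 1
        pairs, un_gt, un_pred = pair_components(gt, pred)
        assert pairs == [] and un_gt == [1] and un_pred == [1]

    def test_hungarian_beats_greedy_and_equals_exhaustive(self):
        """On random configurations up to 4x4 components the assignment's
        total Dice equals the exhaustive optimum and is never below greedy."""
        rng = np.random.default_rng(40)
        for _ in range(60):
            gt = self._labelled(rng, k=int(rng.integers(1, 5)))
            pred = self._labelled(rng, k=int(rng.integers(1, 5)))
            pairs, _, _ = pair_components(gt, pred)
            total = sum(d / 100.0 for _, _, d in pairs)

            gt_ids = [v for v in np.unique(gt) if v]
            pred_ids = [v for v in np.unique(pred) if v]
            if not gt_ids or not pred_ids:
                assert total == 0.0
                continue
            dm = np.zeros((len(gt_ids), len(pred_ids)))
            for i, g in enumerate(gt_ids):
                for j, p in enumerate(pred_ids):
                    inter = int(((gt == g) & (pred == p)).sum())
                    if inter:
                        dm[i, j] = 2 * inter / ((gt == g).sum() + (pred == p).sum())
            assert total == pytest.approx(exhaustive_best_assignment(dm), abs=1e-9)

            # greedy best-first baseline
            greedy, used_g, used_p = 0.0, set(), set()
            for i, j in sorted(np.ndindex(dm.shape), key=lambda ij: -dm[ij]):
                if i not in used_g and j not in used_p and dm[i, j] > 0:
                    greedy += dm[i, j]
                    used_g.add(i)
                    used_p.add(j)
            assert total >= greedy - 1e-9


class TestObjectwise:
    def test_single_pair_reduces_to_voxelwise(self, policy):
        gt = cube_mask((30, 30, 30), (5, 5, 5), (15, 15, 15))   # 1000 voxels
        pred = cube_mask((30, 30, 30), (7, 5, 5), (17, 15, 15))
        ow = objectwise_metrics(gt, pred, "ET", policy)
        vw = voxelwise_metrics(gt, pred)
        for key in ("dice", "recall", "precision", "hd95"):
            assert ow[key] == pytest.approx(vw[key])

    def test_missed_component_halves_object_dice(self, policy):
        gt_values = np.zeros((40, 40, 40), dtype=bool)
        gt_values[2:8, 2:8, 2:8] = True     # 216 voxels, detected
        gt_values[20:26, 20:26, 20:26] = True  # 216 voxels, missed
        pred_values = np.zeros_like(gt_values)
        pred_values[2:8, 2:8, 2:8] = True
        ow = objectwise_metrics(BinaryMask(gt_values), BinaryMask(pred_values),
                                "ET", policy)
        assert ow["dice"] == pytest.approx(50.0)
        assert ow["recall"] == pytest.approx(50.0)
        assert ow["precision"] == pytest.approx(100.0)

    def test_netc_smaller_minimum_size(self, policy):
        """A 60-voxel component is kept for NETC (min 50) but discarded for
        ET (min 75)."""
        values = np.zeros((20, 20, 20), dtype=bool)
        values[2:7, 2:6, 2:5] = True  # 5*4*3 = 60 voxels
        mask = BinaryMask(values)
        empty = BinaryMask(np.zeros_like(values))
        netc = objectwise_metrics(mask, empty, "NETC", policy)
        et = objectwise_metrics(mask, empty, "ET", policy)
        assert netc["dice"] == 0.0       # unmatched gt component counts
        assert et["dice"] is None        # filtered out entirely

    def test_small_distant_false_positive_does_not_affect_hd95(self, policy):
        gt = cube_mask((40, 40, 40), (5, 5, 5), (15, 15, 15))
        pred_values = gt.values.copy()
        with_frag = pred_values.copy()
        with_frag[34:38, 34:38, 34:38] = True  # 64 voxels < 75 minimum
        base = objectwise_metrics(gt, BinaryMask(pred_values), "ET", policy)
        frag = objectwise_metrics(gt, BinaryMask(with_frag), "ET", policy)
        assert frag["hd95"] == pytest.approx(base["hd95"])
        assert frag["dice"] == pytest.approx(base["dice"])

    def test_no_surviving_components_not_applicable(self, policy):
        empty = BinaryMask(np.zeros((10, 10, 10), dtype=bool))
        ow = objectwise_metrics(empty, empty, "ET", policy)
        assert all(v is None for v in ow.values())


class TestPooled:
    def test_identical_folds_unchanged(self):
        folds = [FoldStats(str(i), 4, {"dice": 80.0}, {"dice": 5.0}) for i in range(3)]
        pooled = pooled_estimates(folds)
        assert pooled["dice"]["mean"] == pytest.approx(80.0)

    def test_two_fold_worked_example(self):
        folds = [FoldStats("a", 2, {"m": 0.5}, {"m": 0.0}),
                 FoldStats("b", 2, {"m": 1.0}, {"m": 0.0})]
        pooled = pooled_estimates(folds)
        assert pooled["m"]["mean"] == pytest.approx(0.75)
        assert pooled["m"]["sd"] == pytest.approx(np.std([0.5, 0.5, 1.0, 1.0], ddof=1))

    def test_matches_concatenated_sample_statistics(self):
        rng = np.random.default_rng(50)
        samples, folds = [], []
        for i in range(5):
            n = int(rng.integers(2, 30))
            vals = rng.normal(70, 15, size=n)
            samples.append(vals)
            folds.append(FoldStats(str(i), n, {"m": vals.mean()},
                                   {"m": vals.std(ddof=1)}))
        pooled = pooled_estimates(folds)
        allv = np.concatenate(samples)
        assert pooled["m"]["mean"] == pytest.approx(allv.mean(), abs=1e-9)
        assert pooled["m"]["sd"] == pytest.approx(allv.std(ddof=1), abs=1e-9)


class TestSelectionAndSensitivity:
    def _records(self, dice_by_threshold, positives=True):
        rows = []
        for t, dices in dice_by_threshold.items():
            for d in dices:
                rows.append({"threshold": t, "dice": d, "gt_positive": positives})
        return pd.DataFrame(rows)

    def test_argmax_matches_exhaustive_scan(self):
        rng = np.random.default_rng(60)
        profile = {round(0.1 * k, 1): list(rng.uniform(40, 90, 5)) for k in range(1, 11)}
        df = self._records(profile)
        best = select_best_threshold(df)
        means = {t: np.mean(v) for t, v in profile.items()}
        assert best == max(means, key=lambda t: (means[t], t))

    def test_tie_broken_toward_higher_threshold(self):
        df = self._records({0.4: [80.0], 0.5: [80.0], 0.3: [10.0]})
        assert select_best_threshold(df) == 0.5

    def test_no_positive_samples_rejected(self):
        df = self._records({0.5: [80.0]}, positives=False)
        with pytest.raises(ValueError):
            select_best_threshold(df)

    def _cohort(self):
        rng = np.random.default_rng(61)
        rows = []
        for i in range(20):
            pos = i < 14
            rows.append({
                "gt_positive": pos,
                "pred_positive": pos if i != 13 else False,
                "dice": float(rng.uniform(0, 100)) if pos else 0.0,
            })
        return pd.DataFrame(rows)

    def test_manual_tally_of_tp_counts(self):
        df = self._cohort()
        table = sensitivity_analysis(df, (0.1, 25.0, 75.0))
        for _, row in table.iterrows():
            thr = row["dice_threshold_pct"]
            expected_tp = int(sum(
                r["gt_positive"] and r["pred_positive"] and r["dice"] > thr
                for _, r in df.iterrows()))
            assert row["TP"] == expected_tp
            assert row["TP"] + row["FN"] == 14

    def test_tp_non_increasing_in_threshold(self):
        table = sensitivity_analysis(self._cohort())
        tps = table["TP"].tolist()
        assert tps == sorted(tps, reverse=True)

    def test_negative_rows_unchanged_across_thresholds(self):
        table = sensitivity_analysis(self._cohort())
        assert table["FP"].nunique() == 1 and table["TN"].nunique() == 1
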