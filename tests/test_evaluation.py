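"""Localization/classification metrics against independent brute-force oracles."""

import numpy as np
import pytest

from patchmil.evaluation import (
    EvalCase,
    auroc,
    binarize,
    bootstrap_ci,
    case_category,
    classification_thresholds,
    compute_hits,
    hit_indicator,
    hit_rate,
    iou,
    miou,
    sensitivity_specificity_accuracy,
    tune_thresholds,
)


def oracle_hit(values, gt):
    """Scan all pixels for the max; report membership of the first (row-major)."""
    best, best_pos = -np.inf, None
    S = values.shape[0]
    for y in range(S):
        for x in range(values.shape[1]):
            if values[y, x] > best:
                best, best_pos = values[y, x], (y, x)
    return int(gt[best_pos])


def oracle_iou(a, b):
    inter = int(np.sum((a == 1) & (b == 1)))
    union = int(np.sum((a == 1) | (b == 1)))
    return inter / union


class TestHitIndicator:
    def test_max_inside_mask_is_hit(self):
        values = np.zeros((4, 4))
        values[2, 2] = 5.0
        gt = np.zeros((4, 4), dtype=int)
        gt[2, 2] = 1
        assert hit_indicator(values, gt) == 1

    def test_max_outside_mask_is_miss(self):
        values = np.zeros((4, 4))
        values[0, 0] = 5.0
        gt = np.zeros((4, 4), dtype=int)
        gt[3, 3] = 1
        assert hit_indicator(values, gt) == 0

    def test_constant_map_tie_breaks_to_first_row_major_pixel(self):
        values = np.ones((4, 4))
        gt = np.ones((4, 4), dtype=int)
        gt[0, 0] = 0  # mask everywhere except the tie-break winner
        assert hit_indicator(values, gt) == 0
        assert hit_indicator(values, gt, permissive=True) == 1

    def test_empty_mask_is_undefined(self):
        with pytest.raises(ValueError, match="empty"):
            hit_indicator(np.ones((3, 3)), np.zeros((3, 3), dtype=int))

    def test_matches_oracle_on_random_instances(self, rng):
        for _ in range(200):
            values = rng.normal(size=(6, 6))
            if rng.random() < 0.3:  # force ties sometimes
                values = np.round(values)
            gt = (rng.random((6, 6)) < 0.4).astype(int)
            if not gt.any():
                gt[rng.integers(6), rng.integers(6)] = 1
            assert hit_indicator(values, gt) == oracle_hit(values, gt)


class TestHitRate:
    def _case(self, hit):
        c = EvalCase("i", "l", 1, np.zeros((2, 2)), np.ones((2, 2), dtype=int))
        c.hit = hit
        return c

    def test_hand_computed_fraction(self):
        assert hit_rate([self._case(h) for h in (1, 0, 1, 1)]) == pytest.approx(0.75)

    def test_all_hits_is_one(self):
        assert hit_rate([self._case(1)] * 5) == 1.0

    def test_empty_set_is_error(self):
        with pytest.raises(ValueError, match="empty"):
            hit_rate([])

    def test_compute_hits_skips_cases_without_masks(self, rng):
        cases = [
            EvalCase("a", "l", 1, rng.normal(size=(4, 4)), np.eye(4, dtype=int)),
            EvalCase("b", "l", 1, rng.normal(size=(4, 4)), None),
            EvalCase("c", "l", 1, rng.normal(size=(4, 4)), np.zeros((4, 4), dtype=int)),
        ]
        kept = compute_hits(cases)
        assert [c.image_id for c in kept] == ["a"]
        assert kept[0].hit in (0, 1)


class TestBinarizeIoU:
    def test_threshold_above_max_gives_empty_mask(self, rng):
        values = rng.normal(size=(5, 5))
        assert binarize(values, values.max() + 1).sum() == 0

    def test_threshold_below_min_gives_full_mask(self, rng):
        values = rng.normal(size=(5, 5))
        assert binarize(values, values.min() - 1).all()

    def test_strict_inequality_at_threshold(self):
        values = np.array([[1.0, 2.0]] * 2)[:2, :2]
        assert binarize(values, 1.0).tolist() == [[0, 1], [0, 1]]

    def test_block_map_thresholded_recovers_block(self):
        values = np.zeros((4, 4))
        values[:2, :2] = 2.0
        mask = binarize(values, 1.0)
        assert mask[:2, :2].all() and mask[2:, :].sum() == 0 and mask[:, 2:].sum() == 0

    def test_identical_masks_iou_one(self):
        m = np.eye(4, dtype=int)
        assert iou(m, m) == 1.0

    def test_disjoint_masks_iou_zero(self):
        a = np.zeros((3, 3), dtype=int)
        b = np.zeros((3, 3), dtype=int)
        a[0, 0] = 1
        b[2, 2] = 1
        assert iou(a, b) == 0.0

    def test_hand_counted_overlap(self):
        a = np.zeros((3, 3), dtype=int)
        b = np.zeros((3, 3), dtype=int)
        a[0, 0] = a[0, 1] = 1
        b[0, 1] = b[0, 2] = 1
        assert iou(a, b) == pytest.approx(1 / 3)

    def test_both_empty_is_undefined(self):
        z = np.zeros((2, 2), dtype=int)
        with pytest.raises(ValueError, match="both masks"):
            iou(z, z)


class TestCaseCategory:
    @pytest.mark.parametrize(
        "label,nonempty,expected",
        [(1, True, "TP"), (0, True, "FP"), (1, False, "FN"), (0, False, "TN")],
    )
    def test_all_quadrants(self, label, nonempty, expected):
        mask = np.zeros((2, 2), dtype=int)
        if nonempty:
            mask[0, 0] = 1
        assert case_category(label, mask) == expected


class TestMiou:
    def _cases_tp_fn(self):
        # TP with perfect overlap: saliency = 1 on the gt block, threshold 0.5
        gt = np.zeros((4, 4), dtype=int)
        gt[:2, :2] = 1
        tp = EvalCase("a", "l", 1, gt.astype(float), gt)
        # FN: saliency below threshold everywhere, label positive
        fn = EvalCase("b", "l", 1, np.zeros((4, 4)), gt)
        return [tp, fn]

    def test_tp_plus_fn_hand_computation(self):
        cases = self._cases_tp_fn()
        assert miou(cases, 0.5, mode="tp_fp_fn") == pytest.approx(0.5)
        assert miou(cases, 0.5, mode="tp_only") == pytest.approx(1.0)

    def test_all_tn_is_error(self):
        tn = EvalCase("a", "l", 0, np.zeros((4, 4)), None)
        with pytest.raises(ValueError, match="no cases"):
            miou([tn], 0.5)

    def test_matches_bruteforce_oracle_on_random_instances(self, rng):
        for _ in range(200):
            label = int(rng.random() < 0.6)
            values = rng.normal(size=(5, 5))
            gt = (rng.random((5, 5)) < 0.4).astype(int)
            if label == 1 and not gt.any():
                gt[0, 0] = 1
            t = float(rng.normal())
            case = EvalCase("x", "l", label, values, gt if label else None)
            pred = (values > t).astype(int)
            if label == 0 and not pred.any():
                continue  # TN: excluded, nothing to average
            if label == 1 and pred.any():
                expected = oracle_iou(pred, gt)
            else:
                expected = 0.0
            assert abs(miou([case], t) - expected) < 1e-9

    def test_tp_fp_fn_never_exceeds_tp_only(self, rng):
        cases = []
        for i in range(30):
            label = int(rng.random() < 0.5)
            values = rng.normal(size=(5, 5))
            gt = (rng.random((5, 5)) < 0.3).astype(int)
            if label and not gt.any():
                gt[2, 2] = 1
            cases.append(EvalCase(str(i), "l", label, values, gt if label else None))
        try:
            full, tp_only = miou(cases, 0.0), miou(cases, 0.0, mode="tp_only")
        except ValueError:
            return
        assert full <= tp_only + 1e-12


class TestTuneThresholds:
    def test_single_case_optimum_lies_in_open_interval(self):
        gt = np.zeros((4, 4), dtype=int)
        gt[:2, :2] = 1
        values = gt * 3.0  # saliency v=3 on the block, 0 elsewhere
        case = EvalCase("a", "les", 1, values, gt)
        t = tune_thresholds([case], grid_size=50)["les"]
        assert 0.0 <= t < 3.0
        assert miou([case], t) == pytest.approx(1.0)

    def test_flat_saliency_picks_better_of_two_outcomes(self):
        gt = np.zeros((4, 4), dtype=int)
        gt[:2, :] = 1  # covers half the image
        case = EvalCase("a", "les", 1, np.ones((4, 4)), gt)
        t = tune_thresholds([case], grid_size=10)["les"]
        # all-ones prediction gives IoU 0.5 > empty prediction's 0
        assert miou([case], t) == pytest.approx(0.5)

    def test_tuned_threshold_beats_every_grid_candidate(self, rng):
        cases = []
        for i in range(12):
            label = int(rng.random() < 0.7)
            values = rng.normal(size=(6, 6))
            gt = (rng.random((6, 6)) < 0.3).astype(int)
            if label and not gt.any():
                gt[1, 1] = 1
            cases.append(EvalCase(str(i), "l", label, values, gt if label else None))
        best = tune_thresholds(cases, grid_size=40)["l"]
        achieved = miou(cases, best)
        pooled = np.concatenate([np.asarray(c.saliency).ravel() for c in cases])
        grid = np.concatenate(
            ([-np.inf], np.unique(np.quantile(pooled, np.linspace(0, 1, 40))))
        )
        for t in grid:
            try:
                assert miou(cases, float(t)) <= achieved + 1e-12
            except ValueError:
                continue

    def test_larger_grid_never_hurts_validation_miou(self, rng):
        cases = []
        for i in range(8):
            values = rng.normal(size=(5, 5))
            gt = (rng.random((5, 5)) < 0.4).astype(int)
            if not gt.any():
                gt[0, 0] = 1
            cases.append(EvalCase(str(i), "l", 1, values, gt))
        scores = []
        for gs in (3, 10, 50):
            t = tune_thresholds(cases, grid_size=gs)["l"]
            scores.append(miou(cases, t))
        assert scores[0] <= scores[1] + 1e-12 <= scores[2] + 2e-12


class TestClassificationThresholds:
    def test_separable_scores_reach_perfect_youden(self):
        scores = {"l": np.array([0.1, 0.2, 0.8, 0.9])}
        labels = {"l": np.array([0, 0, 1, 1])}
        t = classification_thresholds(scores, labels)["l"]
        assert 0.2 < t < 0.8
        sens, spec, acc = sensitivity_specificity_accuracy(scores["l"], labels["l"], t)
        assert sens == 1.0 and spec == 1.0 and acc == 1.0

    def test_random_scores_give_youden_sum_near_one(self, rng):
        scores = {"l": rng.normal(size=10_000)}
        labels = {"l": rng.integers(0, 2, size=10_000)}
        t = classification_thresholds(scores, labels)["l"]
        sens, spec, _ = sensitivity_specificity_accuracy(scores["l"], labels["l"], t)
        # optimum over noise gives a small optimistic bias above 1.0
        assert 0.98 < sens + spec < 1.1

    def test_matches_exhaustive_midpoint_search(self, rng):
        for trial in range(20):
            s = rng.normal(size=25)
            y = rng.integers(0, 2, size=25)
            if len(np.unique(y)) < 2:
                continue
            t = classification_thresholds({"l": s}, {"l": y})["l"]
            uniq = np.sort(np.unique(s))
            cands = np.concatenate(
                ([uniq[0] - 1], (uniq[:-1] + uniq[1:]) / 2, [uniq[-1] + 1])
            )
            best = -np.inf
            for c in cands:
                pred = s > c
                j = (pred[y == 1].mean()) + ((~pred)[y == 0].mean())
                best = max(best, j)
            pred = s > t
            achieved = pred[y == 1].mean() + (~pred)[y == 0].mean()
            assert achieved == pytest.approx(best)

    def test_single_class_label_skipped_with_warning(self):
        with pytest.warns(UserWarning, match="single class"):
            out = classification_thresholds(
                {"l": np.array([0.1, 0.9])}, {"l": np.array([1, 1])}
            )
        assert "l" not in out


class TestAuroc:
    def test_perfect_and_reversed_ranking(self):
        y = np.array([0, 0, 1, 1])
        assert auroc(np.array([1, 2, 3, 4]), y) == 1.0
        assert auroc(np.array([4, 3, 2, 1]), y) == 0.0

    def test_random_scores_near_half_at_large_n(self, rng):
        s = rng.normal(size=10_000)
        y = rng.integers(0, 2, size=10_000)
        assert abs(auroc(s, y) - 0.5) < 0.02

    def test_matches_mannwhitney_pair_count(self, rng):
        s = rng.normal(size=40).round(1)  # rounding forces ties
        y = rng.integers(0, 2, size=40)
        if len(np.unique(y)) < 2:
            y[0] = 1 - y[0]
        pos, neg = s[y == 1], s[y == 0]
        wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
        assert auroc(s, y) == pytest.approx(wins / (len(pos) * len(neg)))

    def test_invariant_under_strictly_monotone_transform(self, rng):
        s = rng.normal(size=200)
        y = rng.integers(0, 2, size=200)
        base = auroc(s, y)
        assert auroc(np.exp(s), y) == pytest.approx(base)
        assert auroc(2 * s - 7, y) == pytest.approx(base)

    def test_single_class_undefined(self):
        with pytest.raises(ValueError, match="single class"):
            auroc(np.array([0.1, 0.9]), np.array([1, 1]))


class TestBootstrap:
    def test_constant_metric_collapses_to_point(self):
        rep = bootstrap_ci(lambda cs: 0.7, list(range(20)), resamples=50, seed=1)
        assert rep.ci_lower == rep.ci_upper == rep.estimate == 0.7

    def test_same_seed_reproduces_report(self, rng):
        data = list(rng.normal(size=30))
        f = lambda cs: float(np.mean(cs))
        a = bootstrap_ci(f, data, resamples=200, seed=9)
        b = bootstrap_ci(f, data, resamples=200, seed=9)
        assert a == b

    def test_zero_resamples_gives_point_estimate_only(self):
        rep = bootstrap_ci(lambda cs: float(np.mean(cs)), [1.0, 2.0], resamples=0, seed=0)
        assert rep.ci_lower is None and rep.ci_upper is None and rep.estimate == 1.5

    def test_undefined_resamples_are_skipped_and_counted(self):
        def picky(cs):
            if sum(cs) == 0:
                raise ValueError("degenerate")
            return float(np.mean(cs))

        rep = bootstrap_ci(picky, [0, 0, 1], resamples=300, seed=3)
        assert rep.skipped_resamples > 0
        assert rep.resamples + rep.skipped_resamples == 300
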