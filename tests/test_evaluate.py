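"""Score fusion, 30-px matched evaluation, PR curves."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import linear_sum_assignment

from mitdet.evaluate import (
    compute_metrics,
    f_score,
    fuse_scores,
    match_detections,
    pr_curve,
)


class TestFuseScores:
    def test_highest_confidence_dictates_class(self):
        # p_mitosis 0.9 / 0.4 / 0.45 -> confidences 0.9 / 0.6 / 0.55
        is_mit, conf, p = fuse_scores({"a": [0.9], "b": [0.4], "c": [0.45]})
        assert bool(is_mit[0]) is True
        assert conf[0] == pytest.approx(0.9)
        assert p[0] == pytest.approx(0.9)

    def test_unanimous_nonmitosis(self):
        is_mit, conf, _ = fuse_scores({"a": [0.1], "b": [0.2], "c": [0.3]})
        assert bool(is_mit[0]) is False
        assert conf[0] == pytest.approx(0.9)

    def test_matches_bruteforce_argmax_oracle(self, rng):
        probs = {name: rng.random(20) for name in ("a", "b", "c")}
        is_mit, conf, p = fuse_scores(probs)
        names = list(probs)
        for i in range(20):
            confs = [max(probs[n][i], 1 - probs[n][i]) for n in names]
            win = int(np.argmax(confs))  # first max = priority order
            assert conf[i] == pytest.approx(confs[win])
            assert bool(is_mit[i]) == (probs[names[win]][i] > 0.5)

    def test_misaligned_or_single_rejected(self):
        with pytest.raises(ValueError):
            fuse_scores({"a": [0.5, 0.5], "b": [0.5]})
        with pytest.raises(ValueError):
            fuse_scores({"a": [0.5]})


class TestMatchDetections:
    def test_distance_exactly_30_counts(self):
        m = match_detections([(0.0, 30.0)], None, [(0.0, 0.0)], 30.0)
        assert (m.tp, m.fp, m.fn) == (1, 0, 0)

    def test_distance_31_is_miss(self):
        m = match_detections([(0.0, 31.0)], None, [(0.0, 0.0)], 30.0)
        assert (m.tp, m.fp, m.fn) == (0, 1, 1)

    def test_telophase_pair_counts_once(self):
        lobes = [(50.0, 40.0), (50.0, 60.0)]  # one dividing cell, two lobes
        pred = [(50.0, 50.0)]  # between the lobes
        m = match_detections(pred, None, lobes, 30.0, groups=["t1", "t1"])
        assert (m.tp, m.fp, m.fn) == (1, 0, 0)

    def test_surplus_near_matched_target_suppressed_not_fp(self):
        m = match_detections([(0.0, 0.0), (0.0, 10.0)], None, [(0.0, 0.0)], 30.0)
        assert (m.tp, m.fp, m.fn) == (1, 0, 0)
        assert m.suppressed == [1]
        strict = match_detections([(0.0, 0.0), (0.0, 10.0)], None, [(0.0, 0.0)], 30.0, surplus="fp")
        assert (strict.tp, strict.fp, strict.fn) == (1, 1, 0)

    def test_tp_bounded_by_targets_and_partition(self):
        m = match_detections([(0, 0), (1, 1), (2, 2)], None, [(0, 0)], 30.0)
        assert m.tp <= 1
        assert m.tp + m.fn == 1

    @given(d=st.floats(0, 60))
    @settings(max_examples=30, derandomize=True, deadline=None)
    def test_raising_max_dist_never_decreases_tp(self, d):
        preds = [(0.0, d)]
        gt = [(0.0, 0.0)]
        tp_small = match_detections(preds, None, gt, 20.0).tp
        tp_big = match_detections(preds, None, gt, 40.0).tp
        assert tp_big >= tp_small


def _hungarian_tp(preds, gts, max_dist=30.0):
    """Brute-force optimal-assignment oracle on truncated distances."""
    if len(preds) == 0 or len(gts) == 0:
        return 0
    d = np.linalg.norm(np.asarray(preds)[:, None, :] - np.asarray(gts)[None, :, :], axis=2)
    big = 1e6
    cost = np.where(d <= max_dist, d, big)
    n = max(len(preds), len(gts))
    sq = np.full((n, n), big)
    sq[: len(preds), : len(gts)] = cost
    r, c = linear_sum_assignment(sq)
    return int(np.sum(sq[r, c] < big))


class TestGreedyVsOptimal:
    def test_dense_regime_disagreement_is_bounded(self):
        """Greedy matching is suboptimal in pathologically dense point clouds,
        but its TP count stays within 2 of the optimal assignment."""
        rng = np.random.default_rng(0)
        worst = 0
        for _ in range(200):
            n_gt, n_pred = int(rng.integers(0, 9)), int(rng.integers(0, 9))
            gts = rng.uniform(0, 120, size=(n_gt, 2))
            preds = rng.uniform(0, 120, size=(n_pred, 2))
            m = match_detections(preds, None, gts, 30.0)
            worst = max(worst, abs(m.tp - _hungarian_tp(preds, gts)))
        assert worst <= 2


class TestMetrics:
    @pytest.mark.parametrize(
        "precision,recall,expected",
        [(0.734, 0.768, 0.75), (0.70, 0.76, 0.73), (0.29, 0.40, 0.34)],
    )
    def test_f_score_reproduces_published_pairs(self, precision, recall, expected):
        assert round(f_score(precision, recall), 2) == expected

    def test_harmonic_mean_fixed_point(self):
        assert f_score(0.6, 0.6) == pytest.approx(0.6)

    def test_zero_tp_guard(self):
        from mitdet.evaluate import MatchResult

        rep = compute_metrics(MatchResult(tp=0, fp=5, fn=3, pairing=[]))
        assert rep.precision == rep.recall == rep.f_score == 0.0

    @given(tp=st.integers(1, 50), fp=st.integers(0, 50), fn=st.integers(0, 50))
    @settings(max_examples=50, derandomize=True, deadline=None)
    def test_f_is_exact_harmonic_mean_of_reported_p_and_r(self, tp, fp, fn):
        from mitdet.evaluate import MatchResult

        rep = compute_metrics(MatchResult(tp=tp, fp=fp, fn=fn, pairing=[]))
        assert 0 <= rep.precision <= 1 and 0 <= rep.recall <= 1
        assert rep.f_score == pytest.approx(f_score(rep.precision, rep.recall))


class TestPRCurve:
    def test_perfect_detector_auc_1(self):
        gt = [(10.0, 10.0), (50.0, 50.0)]
        rep = pr_curve(gt, [1.0, 1.0], gt, 30.0)
        assert rep.pr_auc == pytest.approx(1.0)

    def test_no_true_hits_auc_0(self):
        rep = pr_curve([(500.0, 500.0)], [0.9], [(0.0, 0.0)], 30.0)
        assert rep.pr_auc == 0.0

    def test_random_scores_auc_near_candidate_prevalence(self):
        """With uninformative scores the PR-AUC hovers at the positive prevalence."""
        n_pos, n_neg = 8, 24
        prevalence = n_pos / (n_pos + n_neg)
        gt = [(100.0 * i, 100.0 * i) for i in range(n_pos)]
        negs = [(100.0 * i + 50.0, 100.0 * i) for i in range(n_neg)]
        aucs = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            scores = rng.random(n_pos + n_neg)
            rep = pr_curve(gt + negs, scores, gt, 30.0)
            aucs.append(rep.pr_auc)
        assert abs(np.mean(aucs) - prevalence) < 0.1

    def test_scores_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError):
            pr_curve([(0.0, 0.0)], [1.5], [(0.0, 0.0)], 30.0)
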