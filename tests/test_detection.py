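"""Candidate detection: anchors, IoU, proposal selection, losses, reference detector."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mitdet import detection, synthetic
from mitdet.detection import (
    Box,
    CandidateRegion,
    DetectorConfig,
    DetectorError,
    classification_loss,
    detect_candidates,
    generate_anchors,
    iou,
    mask_loss,
    multi_objective_loss,
    select_proposals,
    smooth_l1_loss,
    train_reference_detector,
)


class TestAnchors:
    def test_twelve_anchors_for_published_config(self):
        anchors = generate_anchors()
        assert len(anchors.anchors) == 12
        assert len(anchors.scales) * len(anchors.aspect_ratios) == 12

    def test_square_anchor_at_scale_32(self):
        anchors = generate_anchors(scales=[32], aspect_ratios=[1.0], position=(100, 100))
        box = anchors.anchors[0]
        assert box.row_max - box.row_min == 32
        assert box.col_max - box.col_min == 32
        assert box.center == (100, 100)

    def test_ratio_2_to_1_preserves_area_within_2pct(self):
        anchors = generate_anchors(scales=[64], aspect_ratios=[2.0])
        box = anchors.anchors[0]
        w = box.col_max - box.col_min
        h = box.row_max - box.row_min
        assert w == round(64 * math.sqrt(2)) and h == round(64 / math.sqrt(2))
        assert abs(w * h - 4096) <= 0.02 * 4096

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            generate_anchors(scales=[], aspect_ratios=[1.0])
        with pytest.raises(ValueError):
            generate_anchors(scales=[-2], aspect_ratios=[1.0])

    @given(
        scales=st.lists(st.integers(8, 256), min_size=1, max_size=5),
        ratios=st.lists(st.floats(0.25, 4.0), min_size=1, max_size=4),
    )
    @settings(max_examples=30, derandomize=True, deadline=None)
    def test_anchor_count_is_product(self, scales, ratios):
        anchors = generate_anchors(scales=scales, aspect_ratios=ratios, position=(500, 500))
        assert len(anchors.anchors) == len(scales) * len(ratios)


class TestIoU:
    def test_identical_boxes(self):
        assert iou((0, 0, 10, 10), (0, 0, 10, 10)) == 1.0

    def test_disjoint_boxes(self):
        assert iou((0, 0, 5, 5), (10, 10, 20, 20)) == 0.0

    def test_direct_area_arithmetic(self):
        # intersection 2, union 6
        assert iou((0, 0, 2, 2), (0, 1, 2, 3)) == pytest.approx(1 / 3)

    @given(
        boxes=st.tuples(
            *[st.tuples(st.floats(0, 50), st.floats(0, 50), st.floats(1, 50), st.floats(1, 50)) for _ in range(2)]
        )
    )
    @settings(max_examples=50, derandomize=True, deadline=None)
    def test_symmetry_and_self_iou(self, boxes):
        mk = lambda t: (t[0], t[1], t[0] + t[2], t[1] + t[3])
        a, b = mk(boxes[0]), mk(boxes[1])
        assert iou(a, b) == pytest.approx(iou(b, a))
        assert iou(a, a) == pytest.approx(1.0)
        assert 0.0 <= iou(a, b) <= 1.0


class TestSelectProposals:
    def _ladder(self):
        """Proposals with exact IoUs 0.1 .. 1.0 against one ground-truth box."""
        gt = (0, 0, 100, 100)
        proposals = [(0, 0, 100, 10 * k) for k in range(1, 11)]
        return proposals, [gt]

    def test_exact_070_retained_069_dropped(self):
        gt = [(0, 0, 100, 100)]
        assert select_proposals([(0, 0, 100, 70)], gt, 0.7)  # IoU 0.70 inclusive
        assert not select_proposals([(0, 0, 100, 69)], gt, 0.7)

    def test_ladder_keeps_exactly_four(self):
        proposals, gt = self._ladder()
        kept = select_proposals(proposals, gt, 0.7)
        assert len(kept) == 4

    @given(thr=st.floats(0.05, 1.0))
    @settings(max_examples=30, derandomize=True, deadline=None)
    def test_monotone_in_threshold(self, thr):
        proposals, gt = self._ladder()
        assert len(select_proposals(proposals, gt, thr)) >= len(
            select_proposals(proposals, gt, min(thr + 0.1, 1.0))
        )


class TestLosses:
    def test_classification_trivials(self):
        assert classification_loss(1.0) == 0.0
        assert classification_loss(0.5) == pytest.approx(math.log(2))
        assert classification_loss(0.0) == pytest.approx(-math.log(detection.EPS))

    def test_smooth_l1_branches(self):
        assert smooth_l1_loss((0, 0, 10, 10), (0, 0, 10, 10)) == 0.0
        assert smooth_l1_loss((0.5, 0.5, 0.5, 0.5), (0, 0, 0, 0)) == pytest.approx(0.5)
        assert smooth_l1_loss((2, 2, 2, 2), (0, 0, 0, 0)) == pytest.approx(6.0)

    def test_mask_loss_hand_evaluated(self):
        gt = np.array([[1, 0], [0, 1]])
        p = np.array([[0.9, 0.1], [0.2, 0.8]])
        expected = np.mean([-math.log(0.9), -math.log(0.9), -math.log(0.8), -math.log(0.8)])
        assert mask_loss(p, gt) == pytest.approx(expected)

    def test_mask_loss_perfect_prediction_near_zero(self):
        gt = np.array([[1.0, 0.0]])
        assert 0 <= mask_loss(gt, gt) <= -math.log(1 - detection.EPS) + 1e-12

    def test_mask_loss_uniform_half_is_ln2(self):
        gt = np.array([[1, 0, 1]])
        assert mask_loss(np.full_like(gt, 0.5, dtype=float), gt) == pytest.approx(math.log(2))

    def test_mask_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            mask_loss(np.zeros((2, 2)), np.zeros((3, 3)))

    def test_total_is_exact_sum(self):
        lc = classification_loss(0.5)
        lr = smooth_l1_loss((0.5, 0.5, 0.5, 0.5), (0, 0, 0, 0))
        gt = np.array([[1, 0]])
        lm = mask_loss(np.full((1, 2), 0.5), gt)
        breakdown = multi_objective_loss(lc, lr, lm)
        assert breakdown.total == pytest.approx(math.log(2) + 0.5 + math.log(2))
        assert breakdown.total == breakdown.l_clas + breakdown.l_reg + breakdown.l_mask

    @given(st.floats(0.0, 1.0), st.floats(0.0, 5.0), st.floats(0.0, 5.0))
    @settings(max_examples=30, derandomize=True, deadline=None)
    def test_components_nonnegative_total_additive(self, p, lr, lm):
        lc = classification_loss(max(p, 1e-9))
        assert lc >= 0
        b = multi_objective_loss(lc, lr, lm)
        assert b.total == pytest.approx(lc + lr + lm)


class TestDetectCandidates:
    def test_strict_threshold(self):
        regions = [
            CandidateRegion(box=(0, 0, 10, 10), confidence=0.4),
            CandidateRegion(box=(20, 20, 30, 30), confidence=0.6),
        ]
        kept = detect_candidates(np.zeros((64, 64, 3)), lambda img: regions, 0.5)
        assert len(kept) == 1 and kept[0].confidence == 0.6
        at = detect_candidates(np.zeros((64, 64, 3)), lambda img: [CandidateRegion(box=(0, 0, 1, 1), confidence=0.5)], 0.5)
        assert at == []  # "more than 50%" is strict

    def test_empty_image_empty_list(self):
        assert detect_candidates(np.zeros((64, 64, 3)), lambda img: [], 0.5) == []

    def test_provider_failure_is_typed(self):
        def broken(img):
            raise RuntimeError("boom")

        with pytest.raises(DetectorError):
            detect_candidates(np.zeros((8, 8, 3)), broken)


@pytest.fixture(scope="module")
def trained():
    scenes = [
        synthetic.generate_scene(synthetic.SceneSpec(n_mitoses=4, n_nonmitoses=15, seed=s))
        for s in range(6)
    ]
    cfg = DetectorConfig(epochs=12, seed=0)
    det, history = train_reference_detector(
        [s.image for s in scenes], [s.gt_masks for s in scenes], cfg
    )
    return scenes, det, history, cfg


class TestReferenceDetector:
    def test_loss_trend_decreases(self, trained):
        _, _, history, _ = trained
        total = history["total"]
        assert np.median(total[-5:]) < np.median(total[:5])

    def test_deterministic_training(self, trained):
        scenes, _, history, cfg = trained
        _, history2 = train_reference_detector(
            [s.image for s in scenes], [s.gt_masks for s in scenes], cfg
        )
        assert history2["total"] == history["total"]

    def test_recovers_mitoses_on_training_scene(self, trained):
        scenes, det, _, _ = trained
        found = 0
        total = 0
        for scene in scenes[:3]:
            regions = detect_candidates(scene.image, det, 0.3)
            pts = [r.point for r in regions]
            for gr, gc in scene.gt_centroids:
                total += 1
                if any(np.hypot(gr - r, gc - c) <= 30 for r, c in pts):
                    found += 1
        assert found / total >= 0.9

    def test_no_positive_anchors_rejected(self):
        blank = np.full((96, 96, 3), 240, dtype=np.uint8)
        with pytest.raises(ValueError):
            train_reference_detector([blank], [[]], DetectorConfig(epochs=1))

    def test_proposals_per_step_default_is_128(self):
        assert DetectorConfig().proposals_per_step == 128
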