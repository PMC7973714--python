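"""Tissue-level probable-mitosis region selection.

Covers the detection-side primitives of the pipeline: anchor generation
(scales x aspect ratios), IoU-based proposal selection, the three-part
multi-objective loss (classification + smooth-L1 box regression + per-pixel
mask cross-entropy, summed unweighted), confidence thresholding, and a small
from-scratch reference detector so the pipeline runs end to end on one CPU.
Production-scale instance detectors plug in behind the same provider
interface (anything with ``predict(image) -> [CandidateRegion]``).

Boxes are ``(row_min, col_min, row_max, col_max)`` in pixels, half-open.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Sequence

import numpy as np

from . import nn

__all__ = [
    "Box",
    "AnchorSet",
    "CandidateRegion",
    "LossBreakdown",
    "DetectorError",
    "generate_anchors",
    "iou",
    "select_proposals",
    "classification_loss",
    "smooth_l1_loss",
    "mask_loss",
    "multi_objective_loss",
    "detect_candidates",
    "ReferenceDetector",
    "DetectorConfig",
    "train_reference_detector",
]

EPS = 1e-7

#: published anchor configuration: 12 anchors per position
DEFAULT_SCALES = (32, 64, 128, 256)
DEFAULT_RATIOS = (0.5, 1.0, 2.0)  # w:h of 1:2, 1:1, 2:1


class DetectorError(RuntimeError):
    """A detector provider failed while producing candidates."""


def box_valid(box) -> bool:
    r0, c0, r1, c1 = box
    return r1 > r0 and c1 > c0


@dataclass(frozen=True)
class Box:
    row_min: float
    col_min: float
    row_max: float
    col_max: float

    def __post_init__(self):
        if not box_valid(self.astuple()):
            raise ValueError(f"degenerate box {self}")

    def astuple(self):
        return (self.row_min, self.col_min, self.row_max, self.col_max)

    @property
    def center(self):
        return ((self.row_min + self.row_max) / 2.0, (self.col_min + self.col_max) / 2.0)

    @property
    def area(self):
        return (self.row_max - self.row_min) * (self.col_max - self.col_min)


@dataclass
class AnchorSet:
    scales: tuple
    aspect_ratios: tuple
    anchors: list  # one Box per (scale, ratio), centred on the query position


@dataclass
class CandidateRegion:
    box: tuple  # (row_min, col_min, row_max, col_max)
    confidence: float
    mask: np.ndarray | None = None  # full-frame boolean, or None
    predicted_class: str = "mitosis"

    def __post_init__(self):
        if not 0.0 <= self.confidence <= 1.0:
            raise ValueError("confidence must lie in [0, 1]")

    @property
    def point(self):
        """Representative point: mask centroid when a mask exists, else box centre."""
        if self.mask is not None and self.mask.any():
            rr, cc = np.nonzero(self.mask)
            return (float(rr.mean()), float(cc.mean()))
        r0, c0, r1, c1 = self.box
        return ((r0 + r1) / 2.0, (c0 + c1) / 2.0)


@dataclass
class LossBreakdown:
    l_clas: float
    l_reg: float
    l_mask: float

    @property
    def total(self) -> float:
        return self.l_clas + self.l_reg + self.l_mask


def generate_anchors(
    scales: Sequence[float] = DEFAULT_SCALES,
    aspect_ratios: Sequence[float] = DEFAULT_RATIOS,
    position=(0.0, 0.0),
    clip_to=None,
) -> AnchorSet:
    """One anchor per (scale, ratio) centred at ``position``.

    Area is preserved under the ratio: width = s*sqrt(r), height = s/sqrt(r)
    (r = w:h), rounded to integers.  ``clip_to=(H, W)`` clips to the image.
    """
    if len(scales) == 0 or len(aspect_ratios) == 0:
        raise ValueError("scales and aspect_ratios must be non-empty")
    if any(s <= 0 for s in scales) or any(r <= 0 for r in aspect_ratios):
        raise ValueError("scales and ratios must be positive")
    row, col = position
    anchors = []
    for s in scales:
        for r in aspect_ratios:
            w = int(round(s * math.sqrt(r)))
            h = int(round(s / math.sqrt(r)))
            box = [row - h / 2.0, col - w / 2.0, row + h / 2.0, col + w / 2.0]
            if clip_to is not None:
                box[0] = max(box[0], 0.0)
                box[1] = max(box[1], 0.0)
                box[2] = min(box[2], float(clip_to[0]))
                box[3] = min(box[3], float(clip_to[1]))
            anchors.append(Box(*box))
    return AnchorSet(scales=tuple(scales), aspect_ratios=tuple(aspect_ratios), anchors=anchors)


def _astuple(box):
    return box.astuple() if isinstance(box, Box) else tuple(box)


def iou(a, b) -> float:
    """Intersection over union of two boxes, in [0, 1]."""
    ar0, ac0, ar1, ac1 = _astuple(a)
    br0, bc0, br1, bc1 = _astuple(b)
    if not (box_valid((ar0, ac0, ar1, ac1)) and box_valid((br0, bc0, br1, bc1))):
        raise ValueError("iou requires valid boxes")
    ih = max(0.0, min(ar1, br1) - max(ar0, br0))
    iw = max(0.0, min(ac1, bc1) - max(ac0, bc0))
    inter = ih * iw
    union = (ar1 - ar0) * (ac1 - ac0) + (br1 - br0) * (bc1 - bc0) - inter
    return inter / union if union > 0 else 0.0


def iou_matrix(boxes_a: np.ndarray, boxes_b: np.ndarray) -> np.ndarray:
    """Pairwise IoU for (N, 4) x (M, 4) arrays of boxes."""
    a = np.asarray(boxes_a, dtype=float).reshape(-1, 4)
    b = np.asarray(boxes_b, dtype=float).reshape(-1, 4)
    r0 = np.maximum(a[:, None, 0], b[None, :, 0])
    c0 = np.maximum(a[:, None, 1], b[None, :, 1])
    r1 = np.minimum(a[:, None, 2], b[None, :, 2])
    c1 = np.minimum(a[:, None, 3], b[None, :, 3])
    inter = np.clip(r1 - r0, 0, None) * np.clip(c1 - c0, 0, None)
    area_a = (a[:, 2] - a[:, 0]) * (a[:, 3] - a[:, 1])
    area_b = (b[:, 2] - b[:, 0]) * (b[:, 3] - b[:, 1])
    union = area_a[:, None] + area_b[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(union > 0, inter / union, 0.0)
    return out


def select_proposals(proposals: Sequence, gt_boxes: Sequence, min_iou: float = 0.7) -> list:
    """Keep proposals whose best IoU against any ground-truth box is >= min_iou."""
    if not 0.0 < min_iou <= 1.0:
        raise ValueError("min_iou must lie in (0, 1]")
    if len(gt_boxes) == 0:
        return []
    props = np.array([_astuple(p) for p in proposals], dtype=float).reshape(-1, 4)
    gts = np.array([_astuple(g) for g in gt_boxes], dtype=float).reshape(-1, 4)
    best = iou_matrix(props, gts).max(axis=1) if len(props) else np.zeros(0)
    return [p for p, b in zip(proposals, best) if b >= min_iou]


def classification_loss(predicted_prob_of_true_class: float) -> float:
    """-ln(p) with p clamped to [EPS, 1]."""
    p = min(max(float(predicted_prob_of_true_class), EPS), 1.0)
    return -math.log(p)


def smooth_l1_loss(pred, gt) -> float:
    """Per-coordinate 0.5 d^2 (|d| < 1) else |d| - 0.5, summed over coordinates."""
    d = np.asarray(pred, dtype=float) - np.asarray(gt, dtype=float)
    ad = np.abs(d)
    return float(np.where(ad < 1.0, 0.5 * d * d, ad - 0.5).sum())


def mask_loss(predicted_mask_probs: np.ndarray, gt_mask: np.ndarray) -> float:
    """Mean binary cross-entropy over all pixels of the proposal region."""
    p = np.asarray(predicted_mask_probs, dtype=float)
    y = np.asarray(gt_mask, dtype=float)
    if p.shape != y.shape:
        raise ValueError(f"mask shape mismatch: {p.shape} vs {y.shape}")
    p = np.clip(p, EPS, 1.0 - EPS)
    return float(-(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)).mean())


def multi_objective_loss(l_clas: float, l_reg: float, l_mask: float) -> LossBreakdown:
    """Unweighted sum of the three components."""
    return LossBreakdown(l_clas=float(l_clas), l_reg=float(l_reg), l_mask=float(l_mask))


def nms(boxes: np.ndarray, scores: np.ndarray, iou_threshold: float = 0.3) -> np.ndarray:
    """Greedy non-maximum suppression; returns kept indices sorted by score."""
    order = np.argsort(-np.asarray(scores), kind="stable")
    boxes = np.asarray(boxes, dtype=float)
    keep = []
    while len(order):
        i = order[0]
        keep.append(int(i))
        if len(order) == 1:
            break
        rest = order[1:]
        ious = iou_matrix(boxes[i][None], boxes[rest])[0]
        order = rest[ious <= iou_threshold]
    return np.array(keep, dtype=int)


def detect_candidates(image: np.ndarray, detector, confidence_threshold: float = 0.5) -> List[CandidateRegion]:
    """Run a detector provider and keep regions with confidence strictly above threshold."""
    try:
        if hasattr(detector, "predict"):
            regions = detector.predict(image)
        else:
            regions = detector(image)
    except Exception as exc:  # surface as a typed error
        raise DetectorError(f"detector provider failed: {exc}") from exc
    out = []
    for r in regions:
        if isinstance(r, dict):
            r = CandidateRegion(box=tuple(r["box"]), confidence=float(r["score"]), mask=r.get("mask"))
        if r.confidence > confidence_threshold:
            out.append(r)
    return out


# ---------------------------------------------------------------------------
# reference detector


@dataclass
class DetectorConfig:
    """Reference-detector settings; anchor defaults are scaled to desk-size scenes."""

    anchor_scales: tuple = (16, 24, 32)
    anchor_ratios: tuple = (1.0,)
    base_channels: int = 8
    mask_size: int = 20
    stride: int = 4
    epochs: int = 40
    learning_rate: float = 2e-2
    momentum: float = 0.9
    weight_decay: float = 1e-5
    proposals_per_step: int = 128
    max_positive_fraction: float = 0.5
    pos_iou: float = 0.5
    neg_iou: float = 0.3
    masks_per_step: int = 8
    nms_iou: float = 0.3
    seed: int = 0


class ReferenceDetector:
    """Anchor-based objectness + box offsets + per-region mask head, in NumPy.

    The trunk is two stride-2 conv blocks (total stride 4); objectness and box
    heads are 1x1 convolutions over the trunk features with one anchor shape
    per (scale, ratio) at every feature-map cell.  The mask head is a small
    conv net applied to the image crop of each candidate box (resized to
    ``mask_size``), giving a per-region segmentation.  Box offsets use the
    (center, log-size) encoding.
    """

    def __init__(self, config: DetectorConfig | None = None):
        self.config = config or DetectorConfig()
        cfg = self.config
        c = cfg.base_channels
        self.n_anchors = len(cfg.anchor_scales) * len(cfg.anchor_ratios)
        self.trunk = nn.Sequential(
            [
                nn.Conv2d(3, c, 3, 2, 1), nn.BatchNorm2d(c), nn.LeakyReLU(),
                nn.Conv2d(c, 2 * c, 3, 1, 1), nn.BatchNorm2d(2 * c), nn.LeakyReLU(),
                nn.Conv2d(2 * c, 2 * c, 3, 2, 1), nn.BatchNorm2d(2 * c), nn.LeakyReLU(),
            ],
            name="trunk",
        )
        self.obj_head = nn.Conv2d(2 * c, self.n_anchors, 1)
        self.box_head = nn.Conv2d(2 * c, 4 * self.n_anchors, 1)
        self.mask_net = nn.Sequential(
            [
                nn.Conv2d(3, 8, 3, 1, 1), nn.LeakyReLU(),
                nn.Conv2d(8, 8, 3, 1, 1), nn.LeakyReLU(),
                nn.Conv2d(8, 1, 1),
            ],
            name="mask-head",
        )
        nn.init_network(self.trunk, seed=cfg.seed, mode="glorot")
        nn.init_network(self.obj_head, seed=cfg.seed + 1, mode="glorot")
        nn.init_network(self.box_head, seed=cfg.seed + 2, mode="glorot")
        nn.init_network(self.mask_net, seed=cfg.seed + 3, mode="glorot")

    def params(self):
        return (
            self.trunk.params()
            + self.obj_head.params()
            + self.box_head.params()
            + self.mask_net.params()
        )

    # -- anchors ---------------------------------------------------------

    def _anchor_grid(self, image_shape):
        """(K, 4) anchors over the feature grid, K = h*w*n_anchors."""
        cfg = self.config
        h = (image_shape[0] + 1) // 2
        h = (h + 1) // 2
        w = (image_shape[1] + 1) // 2
        w = (w + 1) // 2
        centers_r = (np.arange(h) + 0.5) * cfg.stride
        centers_c = (np.arange(w) + 0.5) * cfg.stride
        shapes = []
        for s in cfg.anchor_scales:
            for r in cfg.anchor_ratios:
                shapes.append((s / math.sqrt(r), s * math.sqrt(r)))  # (h, w)
        boxes = np.empty((h, w, len(shapes), 4))
        for k, (ah, aw) in enumerate(shapes):
            boxes[:, :, k, 0] = centers_r[:, None] - ah / 2
            boxes[:, :, k, 1] = centers_c[None, :] - aw / 2
            boxes[:, :, k, 2] = centers_r[:, None] + ah / 2
            boxes[:, :, k, 3] = centers_c[None, :] + aw / 2
        return boxes.reshape(-1, 4), (h, w, len(shapes))

    @staticmethod
    def _encode(anchors: np.ndarray, gt: np.ndarray) -> np.ndarray:
        """(center, log-size) offsets of gt boxes relative to anchors."""
        acr = (anchors[:, 0] + anchors[:, 2]) / 2
        acc = (anchors[:, 1] + anchors[:, 3]) / 2
        ah = anchors[:, 2] - anchors[:, 0]
        aw = anchors[:, 3] - anchors[:, 1]
        gcr = (gt[:, 0] + gt[:, 2]) / 2
        gcc = (gt[:, 1] + gt[:, 3]) / 2
        gh = np.maximum(gt[:, 2] - gt[:, 0], 1e-3)
        gw = np.maximum(gt[:, 3] - gt[:, 1], 1e-3)
        return np.stack(
            [(gcr - acr) / ah, (gcc - acc) / aw, np.log(gh / ah), np.log(gw / aw)], axis=1
        )

    @staticmethod
    def _decode(anchors: np.ndarray, offsets: np.ndarray) -> np.ndarray:
        acr = (anchors[:, 0] + anchors[:, 2]) / 2
        acc = (anchors[:, 1] + anchors[:, 3]) / 2
        ah = anchors[:, 2] - anchors[:, 0]
        aw = anchors[:, 3] - anchors[:, 1]
        off = np.clip(offsets, -4.0, 4.0)
        cr = acr + off[:, 0] * ah
        cc = acc + off[:, 1] * aw
        h = ah * np.exp(off[:, 2])
        w = aw * np.exp(off[:, 3])
        return np.stack([cr - h / 2, cc - w / 2, cr + h / 2, cc + w / 2], axis=1)

    # -- forward helpers -------------------------------------------------

    @staticmethod
    def _to_input(image: np.ndarray) -> np.ndarray:
        x = np.asarray(image, dtype=np.float32) / 255.0
        return np.transpose(x, (2, 0, 1))[None]

    def _heads_forward(self, image: np.ndarray, train: bool):
        feats = self.trunk.forward(self._to_input(image), train=train)
        obj = self.obj_head.forward(feats, train=train)  # (1, A, h, w)
        off = self.box_head.forward(feats, train=train)  # (1, 4A, h, w)
        return feats, obj, off

    def _crop_resized(self, image: np.ndarray, box) -> np.ndarray:
        """Image crop of a box, nearest-resized to (mask_size, mask_size), CHW in [0,1]."""
        h, w = image.shape[:2]
        r0 = int(np.clip(np.floor(box[0]), 0, h - 1))
        c0 = int(np.clip(np.floor(box[1]), 0, w - 1))
        r1 = int(np.clip(np.ceil(box[2]), r0 + 1, h))
        c1 = int(np.clip(np.ceil(box[3]), c0 + 1, w))
        crop = image[r0:r1, c0:c1].astype(np.float32) / 255.0
        m = self.config.mask_size
        ri = np.clip((np.arange(m) + 0.5) * (r1 - r0) / m, 0, r1 - r0 - 1).astype(int)
        ci = np.clip((np.arange(m) + 0.5) * (c1 - c0) / m, 0, c1 - c0 - 1).astype(int)
        return np.transpose(crop[np.ix_(ri, ci)], (2, 0, 1)), (r0, c0, r1, c1)

    # -- inference -------------------------------------------------------

    def predict(self, image: np.ndarray, score_floor: float = 0.05, max_regions: int = 100) -> List[CandidateRegion]:
        cfg = self.config
        anchors, (h, w, a) = self._anchor_grid(image.shape[:2])
        _, obj, off = self._heads_forward(image, train=False)
        scores = 1.0 / (1.0 + np.exp(-obj[0].transpose(1, 2, 0).reshape(-1)))
        offsets = off[0].reshape(a, 4, h, w).transpose(2, 3, 0, 1).reshape(-1, 4)
        keep = scores > score_floor
        if not keep.any():
            return []
        boxes = self._decode(anchors[keep], offsets[keep])
        scores = scores[keep]
        # clip to image and drop degenerates
        boxes[:, 0::2] = np.clip(boxes[:, 0::2], 0, image.shape[0])
        boxes[:, 1::2] = np.clip(boxes[:, 1::2], 0, image.shape[1])
        ok = (boxes[:, 2] - boxes[:, 0] > 2) & (boxes[:, 3] - boxes[:, 1] > 2)
        boxes, scores = boxes[ok], scores[ok]
        if len(boxes) == 0:
            return []
        kept = nms(boxes, scores, cfg.nms_iou)[:max_regions]
        regions = []
        for i in kept:
            box = tuple(float(v) for v in boxes[i])
            crop, (r0, c0, r1, c1) = self._crop_resized(image, box)
            logits = self.mask_net.forward(crop[None], train=False)[0, 0]
            prob = 1.0 / (1.0 + np.exp(-logits))
            small = prob >= 0.5
            # nearest-neighbour paste back to the box footprint
            mh, mw = r1 - r0, c1 - c0
            ri = np.clip((np.arange(mh) + 0.5) * small.shape[0] / mh, 0, small.shape[0] - 1).astype(int)
            ci = np.clip((np.arange(mw) + 0.5) * small.shape[1] / mw, 0, small.shape[1] - 1).astype(int)
            full = np.zeros(image.shape[:2], dtype=bool)
            full[r0:r1, c0:c1] = small[np.ix_(ri, ci)]
            regions.append(CandidateRegion(box=box, confidence=float(scores[i]), mask=full))
        return regions


def _instance_boxes(masks: Sequence[np.ndarray]) -> np.ndarray:
    boxes = []
    for m in masks:
        rr, cc = np.nonzero(m)
        boxes.append([rr.min(), cc.min(), rr.max() + 1, cc.max() + 1])
    return np.asarray(boxes, dtype=float).reshape(-1, 4)


def train_reference_detector(scenes: Sequence, labels: Sequence[Sequence[np.ndarray]], config: DetectorConfig | None = None):
    """Train the reference detector on labelled scenes with the summed three-part loss.

    ``scenes`` are (H, W, 3) uint8 images; ``labels[i]`` is the list of
    instance masks for scene i.  Returns ``(detector, history)`` with the
    per-epoch mean total loss and its components.
    """
    cfg = config or DetectorConfig()
    if len(scenes) == 0:
        raise ValueError("need at least one labelled scene")
    det = ReferenceDetector(cfg)
    rng = np.random.default_rng(cfg.seed)
    opt = nn.SGD(det.params(), cfg.learning_rate, cfg.momentum, cfg.weight_decay)

    # precompute per-scene anchor assignments
    prepared = []
    any_pos = False
    for img, masks in zip(scenes, labels):
        anchors, grid = det._anchor_grid(np.asarray(img).shape[:2])
        gt = _instance_boxes(masks)
        if len(gt):
            ious = iou_matrix(anchors, gt)
            best_iou = ious.max(axis=1)
            best_gt = ious.argmax(axis=1)
            pos = np.flatnonzero(best_iou >= cfg.pos_iou)
            # guarantee every gt its best anchor
            forced = ious.argmax(axis=0)
            pos = np.unique(np.concatenate([pos, forced]))
            neg = np.flatnonzero(best_iou < cfg.neg_iou)
            neg = np.setdiff1d(neg, pos)
        else:
            pos = np.zeros(0, dtype=int)
            best_gt = np.zeros(len(anchors), dtype=int)
            neg = np.arange(len(anchors))
        if len(pos):
            any_pos = True
        prepared.append((np.asarray(img), masks, anchors, grid, gt, pos, best_gt, neg))
    if not any_pos:
        raise ValueError("no positive anchors in the training data")

    total_steps = cfg.epochs * len(prepared)
    history = {"total": [], "l_clas": [], "l_reg": [], "l_mask": []}
    step = 0
    for epoch in range(cfg.epochs):
        order = rng.permutation(len(prepared))
        ep = {"total": [], "l_clas": [], "l_reg": [], "l_mask": []}
        for si in order:
            img, masks, anchors, (gh, gw, ga), gt, pos, best_gt, neg = prepared[si]
            n_pos = min(len(pos), int(cfg.proposals_per_step * cfg.max_positive_fraction))
            n_neg = cfg.proposals_per_step - max(n_pos, 1)
            sel_pos = rng.choice(pos, size=n_pos, replace=False) if n_pos else np.zeros(0, int)
            sel_neg = rng.choice(neg, size=min(n_neg, len(neg)), replace=False)
            sel = np.concatenate([sel_pos, sel_neg]).astype(int)
            target = np.zeros(len(sel), dtype=np.float32)
            target[: len(sel_pos)] = 1.0

            feats, obj, off = det._heads_forward(img, train=True)
            obj_flat = obj[0].transpose(1, 2, 0).reshape(-1)
            prob = 1.0 / (1.0 + np.exp(-obj_flat[sel]))
            l_clas = float(
                np.mean([classification_loss(p if t == 1 else 1.0 - p) for p, t in zip(prob, target)])
            )

            off_all = off[0].reshape(ga, 4, gh, gw).transpose(2, 3, 0, 1).reshape(-1, 4)
            if len(sel_pos):
                enc = det._encode(anchors[sel_pos], gt[best_gt[sel_pos]])
                diffs = off_all[sel_pos] - enc
                l_reg = float(
                    np.mean([smooth_l1_loss(d, np.zeros(4)) for d in diffs])
                )
            else:
                l_reg = 0.0

            # backward: objectness (BCE) + box (smooth L1) through the trunk
            d_obj = np.zeros_like(obj_flat)
            d_obj[sel] = (prob - target) / len(sel)
            d_obj_map = d_obj.reshape(gh, gw, ga).transpose(2, 0, 1)[None]
            d_off = np.zeros_like(off_all)
            if len(sel_pos):
                d = diffs
                d_off[sel_pos] = np.where(np.abs(d) < 1.0, d, np.sign(d)) / len(sel_pos)
            d_off_map = d_off.reshape(gh, gw, ga, 4).transpose(2, 3, 0, 1).reshape(1, 4 * ga, gh, gw)

            opt.zero_grad()
            d_feats = det.obj_head.backward(d_obj_map.astype(np.float32))
            d_feats = d_feats + det.box_head.backward(d_off_map.astype(np.float32))
            det.trunk.backward(d_feats)

            # mask head on image crops of positive ground-truth boxes
            l_mask = 0.0
            if len(sel_pos):
                take = rng.choice(len(sel_pos), size=min(cfg.masks_per_step, len(sel_pos)), replace=False)
                crops, targets = [], []
                m = cfg.mask_size
                for ai in sel_pos[take]:
                    gbox = gt[best_gt[ai]]
                    crop, (r0, c0, r1, c1) = det._crop_resized(img, gbox)
                    crops.append(crop)
                    gm = masks[best_gt[ai]][r0:r1, c0:c1]
                    ri = np.clip((np.arange(m) + 0.5) * gm.shape[0] / m, 0, gm.shape[0] - 1).astype(int)
                    ci = np.clip((np.arange(m) + 0.5) * gm.shape[1] / m, 0, gm.shape[1] - 1).astype(int)
                    targets.append(gm[np.ix_(ri, ci)].astype(np.float32))
                x = np.stack(crops)
                y = np.stack(targets)[:, None]
                logits = det.mask_net.forward(x, train=True)
                p = 1.0 / (1.0 + np.exp(-logits))
                l_mask = float(mask_loss(np.clip(p, EPS, 1 - EPS), y))
                det.mask_net.backward(((p - y) / p.size).astype(np.float32))

            lr = nn.cosine_lr(cfg.learning_rate, step, total_steps)
            opt.step(lr)
            step += 1

            breakdown = multi_objective_loss(l_clas, l_reg, l_mask)
            ep["total"].append(breakdown.total)
            ep["l_clas"].append(l_clas)
            ep["l_reg"].append(l_reg)
            ep["l_mask"].append(l_mask)
        for k in history:
            history[k].append(float(np.mean(ep[k])))
    return det, history
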