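"""Desk-scale end-to-end pipeline on synthetic scenes.

Chains every stage on seed-controlled synthetic data: scene generation ->
stain normalization -> weak-label refinement -> reference-detector training
-> candidate detection -> blob analysis -> cell-patch extraction -> reduced
MitosRes-CNN training -> scoring -> 30-px matched evaluation.  Geometry is
~4x smaller than real 40x patches, so the area/patch-size parameters are the
published values scaled accordingly (documented per field).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from . import blobs as blob_ops
from . import detection, refine, stain, synthetic
from .classifier import (
    PatchSet,
    TrainingConfig,
    build_reduced_mitosres_cnn,
    init_weights,
    predict_scores,
    train_classifier,
)
from .evaluate import compute_metrics, match_detections, pr_curve

__all__ = ["SyntheticPipelineConfig", "run_pipeline"]


@dataclass
class SyntheticPipelineConfig:
    """Stated world for the synthetic end-to-end run (objects ~4x smaller than 40x)."""

    n_train_scenes: int = 16
    n_val_scenes: int = 4
    n_test_scenes: int = 6
    scene_width: int = 192
    scene_height: int = 192
    n_mitoses: int = 4
    n_nonmitoses: int = 28
    telophase_fraction: float = 0.25
    # detection (anchor scales match the ~18-26 px synthetic nuclei)
    detector_epochs: int = 50
    detector_lr: float = 2e-2
    confidence_threshold: float = 0.5
    # blob analysis: 600 px at full scale / 4^2 ~ 38; nuclei here are >75 px
    blob_min_area: int = 60
    match_dist: float = 30.0
    # cell-level classifier (reduced MitosRes-CNN on 40 px patches)
    patch_size: int = 40
    classifier_epochs: int = 30
    classifier_lr: float = 1e-3
    classifier_batch: int = 16
    classifier_threshold: float = 0.5
    seed: int = 0

    def to_dict(self) -> dict:
        return asdict(self)


def _scene_specs(cfg: SyntheticPipelineConfig, n: int, seed0: int):
    return [
        synthetic.SceneSpec(
            width=cfg.scene_width,
            height=cfg.scene_height,
            n_mitoses=cfg.n_mitoses,
            n_nonmitoses=cfg.n_nonmitoses,
            telophase_fraction=cfg.telophase_fraction,
            seed=seed0 + i,
        )
        for i in range(n)
    ]


def _normalize_scene(scene, target_basis):
    bg = scene.spec.background_intensity if scene.spec is not None else 255.0
    try:
        src = stain.estimate_stain_basis(stain.rgb_to_od(scene.image, bg))
    except stain.StainEstimationError:
        return scene
    img = stain.normalize_to_target(scene.image, src, target_basis, background_intensity=bg)
    return synthetic.replace_image(scene, img)


def _candidates_to_patches(scene_img, regions, patch_size):
    return np.stack(
        [synthetic.crop_patch(scene_img, r.point, patch_size) for r in regions]
    ) if regions else np.zeros((0, patch_size, patch_size, 3), dtype=np.uint8)


def run_pipeline(config: SyntheticPipelineConfig | None = None, seed: int | None = None) -> dict:
    """Run all stages; returns a deterministic report dict (no timestamps)."""
    cfg = config or SyntheticPipelineConfig()
    if seed is not None:
        cfg = SyntheticPipelineConfig(**{**cfg.to_dict(), "seed": int(seed)})
    base = int(cfg.seed) % (2**20)

    # --- data -----------------------------------------------------------
    train_specs = _scene_specs(cfg, cfg.n_train_scenes, base * 1000 + 1)
    val_specs = _scene_specs(cfg, cfg.n_val_scenes, base * 1000 + 501)
    test_specs = _scene_specs(cfg, cfg.n_test_scenes, base * 1000 + 701)
    train_scenes = [synthetic.generate_scene(s) for s in train_specs]
    val_scenes = [synthetic.generate_scene(s) for s in val_specs]
    test_scenes = [synthetic.generate_scene(s) for s in test_specs]

    target_basis = stain.StainBasis(stain.DEFAULT_HE_BASIS.copy())
    train_scenes = [_normalize_scene(s, target_basis) for s in train_scenes]
    val_scenes = [_normalize_scene(s, target_basis) for s in val_scenes]
    test_scenes = [_normalize_scene(s, target_basis) for s in test_scenes]

    # --- weak-label refinement -----------------------------------------
    provider = refine.stain_threshold_provider()
    anns = [
        [refine.CentroidAnnotation(f"train{i}", p) for p in s.gt_centroids]
        for i, s in enumerate(train_scenes)
    ]
    refined = refine.refine_labels(
        [s.image for s in train_scenes], anns, provider, seed=base + 11
    )
    n_pseudo = sum(1 for labs in refined for l in labs if l.provenance == "pseudo_circle")
    n_refined = sum(len(labs) for labs in refined)

    # --- reference detector --------------------------------------------
    det_cfg = detection.DetectorConfig(
        epochs=cfg.detector_epochs, learning_rate=cfg.detector_lr, seed=base + 23
    )
    detector, det_history = detection.train_reference_detector(
        [s.image for s in train_scenes],
        [[l.mask for l in labs] for labs in refined],
        det_cfg,
    )

    # --- candidates -> blobs -> labelled cell patches -------------------
    def scene_candidates(scene):
        regions = detection.detect_candidates(scene.image, detector, cfg.confidence_threshold)
        kept = []
        for r in regions:
            if r.mask is not None and r.mask.any():
                bl = blob_ops.filter_blobs_by_area(blob_ops.extract_blobs(r.mask, r), cfg.blob_min_area)
                if not bl:
                    continue
            kept.append(r)
        return kept

    def collect_patchset(scenes, name):
        imgs, labels, patients = [], [], []
        for i, scene in enumerate(scenes):
            regions = scene_candidates(scene)
            tags = blob_ops.label_by_centroid_distance(regions, scene.gt_centroids, cfg.match_dist)
            for r, t in zip(regions, tags):
                imgs.append(synthetic.crop_patch(scene.image, r.point, cfg.patch_size))
                labels.append(int(t))
                patients.append(f"{name}{i}")
        if not imgs:
            return PatchSet(
                images=np.zeros((0, cfg.patch_size, cfg.patch_size, 3), np.uint8),
                labels=np.zeros(0, int),
                patients=np.zeros(0, object),
            )
        return PatchSet(
            images=np.stack(imgs), labels=np.asarray(labels), patients=np.asarray(patients, object)
        )

    train_patches = collect_patchset(train_scenes, "train")
    val_patches = collect_patchset(val_scenes, "val")

    # top up positives straight from ground truth (the refiner knows every
    # centroid, so the classifier may train on all annotated mitoses)
    extra_imgs, extra_pat = [], []
    for i, scene in enumerate(train_scenes):
        for p in scene.gt_centroids:
            extra_imgs.append(synthetic.crop_patch(scene.image, p, cfg.patch_size))
            extra_pat.append(f"train{i}")
    train_patches = PatchSet(
        images=np.concatenate([train_patches.images, np.stack(extra_imgs)]),
        labels=np.concatenate([train_patches.labels, np.ones(len(extra_imgs), int)]),
        patients=np.concatenate([train_patches.patients, np.asarray(extra_pat, object)]),
    )
    if not np.any(train_patches.labels == 0):
        # degenerate but possible: a perfectly precise detector leaves no hard
        # negatives, so fall back to random tissue crops away from mitoses
        rng = np.random.default_rng(base + 41)
        neg_imgs, neg_pat = [], []
        for i, scene in enumerate(train_scenes):
            h, w = scene.image.shape[:2]
            while len([p for p in neg_pat if p == f"train{i}"]) < cfg.n_mitoses:
                r, c = rng.uniform(0, h), rng.uniform(0, w)
                if all(np.hypot(r - gr, c - gc) > cfg.match_dist for gr, gc in scene.gt_centroids):
                    neg_imgs.append(synthetic.crop_patch(scene.image, (r, c), cfg.patch_size))
                    neg_pat.append(f"train{i}")
        train_patches = PatchSet(
            images=np.concatenate([train_patches.images, np.stack(neg_imgs)]),
            labels=np.concatenate([train_patches.labels, np.zeros(len(neg_imgs), int)]),
            patients=np.concatenate([train_patches.patients, np.asarray(neg_pat, object)]),
        )

    # --- reduced MitosRes-CNN ------------------------------------------
    net = build_reduced_mitosres_cnn(input_size=cfg.patch_size)
    init_weights(net, seed=base + 31)
    train_cfg = TrainingConfig(
        batch_size=cfg.classifier_batch,
        learning_rate=cfg.classifier_lr,
        epochs=cfg.classifier_epochs,
        seed=base + 37,
    )
    net, cls_history = train_classifier(net, train_patches, val_patches, train_cfg)
    mu, sigma = cls_history["mu"], cls_history["sigma"]

    # --- final detection on held-out scenes ----------------------------
    all_points, all_scores, all_gt, all_groups = [], [], [], []
    offset = 0.0
    for i, scene in enumerate(test_scenes):
        regions = scene_candidates(scene)
        if regions:
            patches = _candidates_to_patches(scene.image, regions, cfg.patch_size)
            probs = predict_scores(net, patches, stats=(mu, sigma))[:, 1]
        else:
            probs = np.zeros(0)
        # scenes are evaluated jointly by shifting each into its own band
        for r, p in zip(regions, probs):
            pt = r.point
            all_points.append((pt[0] + offset, pt[1]))
            all_scores.append(float(p))
        for r, c, g in scene.lobe_centroids:
            all_gt.append((r + offset, c))
            all_groups.append(f"s{i}g{g}")
        offset += cfg.scene_height + 1000.0

    all_scores_arr = np.asarray(all_scores)
    keep = all_scores_arr > cfg.classifier_threshold
    final_match = match_detections(
        [p for p, k in zip(all_points, keep) if k],
        None,
        all_gt,
        cfg.match_dist,
        all_groups,
    )
    final = compute_metrics(final_match)
    curve = (
        pr_curve(all_points, all_scores_arr, all_gt, cfg.match_dist, all_groups,
                 default_threshold=cfg.classifier_threshold)
        if len(all_points)
        else None
    )

    report = {
        "config": cfg.to_dict(),
        "refinement": {
            "n_instances": n_refined,
            "n_pseudo": n_pseudo,
            "n_centroids": sum(len(a) for a in anns),
        },
        "detector": {
            "final_loss": det_history["total"][-1],
            "first_loss": det_history["total"][0],
        },
        "classifier": {
            "best_val_f": cls_history["best_val_f"],
            "final_train_loss": cls_history["train_loss"][-1],
        },
        "evaluation": {
            "tp": final_match.tp,
            "fp": final_match.fp,
            "fn": final_match.fn,
            "precision": final.precision,
            "recall": final.recall,
            "f_score": final.f_score,
            "pr_auc": curve.pr_auc if curve is not None else None,
        },
    }
    return report
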