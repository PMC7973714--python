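"""Weak-label refinement: centroid annotations -> instance labels.

Mitosis challenge datasets annotate each mitosis with a single centroid
pixel, which is too little supervision for an instance-segmentation model.
The refiner upgrades every centroid to a pixel-level instance label by
matching detector-predicted masks to the centroids (containment first, then
mask-centroid distance up to 30 px, greedy nearest-first); centroids the
provider misses receive a circular pseudo-label with an integer radius drawn
uniformly from 10-16 px.  Spurious masks — predictions explaining no
centroid — are discarded.  Every centroid ends with exactly one label.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label

from .stain import DEFAULT_HE_BASIS, StainBasis, compute_saturations, rgb_to_od

__all__ = [
    "CentroidAnnotation",
    "InstanceLabel",
    "PSEUDO_RADIUS_RANGE",
    "match_masks_to_centroids",
    "make_circular_label",
    "refine_labels",
    "stain_threshold_provider",
]

PSEUDO_RADIUS_RANGE = (10, 16)  # inclusive integer pseudo-circle radii, pixels
MATCH_DIST = 30.0  # reuse the evaluation criterion for refiner matching


@dataclass(frozen=True)
class CentroidAnnotation:
    image_id: str
    position: tuple  # (row, col), 0-based


@dataclass
class InstanceLabel:
    mask: np.ndarray  # boolean (H, W)
    centroid_link: CentroidAnnotation
    provenance: str  # "segmented" | "pseudo_circle"
    radius: int | None = None  # pseudo circles only

    def __post_init__(self):
        if self.provenance not in ("segmented", "pseudo_circle"):
            raise ValueError(f"unknown provenance {self.provenance!r}")
        if not self.mask.any():
            raise ValueError("instance mask must be non-empty")


def _mask_centroid(mask: np.ndarray) -> tuple:
    rr, cc = np.nonzero(mask)
    return (float(rr.mean()), float(cc.mean()))


def match_masks_to_centroids(
    masks: Sequence[np.ndarray], centroids: Sequence[tuple], max_dist: float = MATCH_DIST
):
    """One-to-one greedy assignment of predicted masks to centroid annotations.

    A mask may claim a centroid if the centroid lies inside it (distance 0)
    or if the mask's centroid is within ``max_dist`` (Euclidean).  Pairs are
    taken nearest-first, ties broken by (mask index, centroid index).
    Returns ``(matched_pairs, unmatched_centroid_idx, spurious_mask_idx)``
    where matched pairs are ``(mask_idx, centroid_idx)``.
    """
    candidates = []
    mask_cents = [_mask_centroid(m) if m.any() else None for m in masks]
    for mi, m in enumerate(masks):
        if mask_cents[mi] is None:
            continue
        for ci, (r, c) in enumerate(centroids):
            ri, cj = int(round(r)), int(round(c))
            inside = (
                0 <= ri < m.shape[0] and 0 <= cj < m.shape[1] and bool(m[ri, cj])
            )
            if inside:
                d = 0.0
            else:
                d = float(np.hypot(mask_cents[mi][0] - r, mask_cents[mi][1] - c))
                if d > max_dist:
                    continue
            candidates.append((d, mi, ci))
    candidates.sort()
    used_m, used_c, pairs = set(), set(), []
    for d, mi, ci in candidates:
        if mi in used_m or ci in used_c:
            continue
        pairs.append((mi, ci))
        used_m.add(mi)
        used_c.add(ci)
    unmatched = [ci for ci in range(len(centroids)) if ci not in used_c]
    spurious = [mi for mi in range(len(masks)) if mi not in used_m]
    return pairs, unmatched, spurious


def make_circular_label(
    centroid: CentroidAnnotation | tuple,
    radius: int,
    image_shape: tuple,
    radius_range: tuple = PSEUDO_RADIUS_RANGE,
) -> InstanceLabel:
    """Disc of all pixels with squared distance <= radius^2, clipped to the image."""
    if not radius_range[0] <= radius <= radius_range[1]:
        raise ValueError(f"pseudo radius {radius} outside {radius_range}")
    ann = centroid if isinstance(centroid, CentroidAnnotation) else CentroidAnnotation("", tuple(centroid))
    r, c = ann.position
    h, w = image_shape[:2]
    if not (0 <= r < h and 0 <= c < w):
        raise ValueError(f"centroid {ann.position} outside image {image_shape}")
    rows = np.arange(h)[:, None]
    cols = np.arange(w)[None, :]
    mask = (rows - r) ** 2 + (cols - c) ** 2 <= radius**2
    return InstanceLabel(mask=mask, centroid_link=ann, provenance="pseudo_circle", radius=int(radius))


def refine_labels(
    images: Sequence[np.ndarray],
    centroid_annotations: Sequence[Sequence[CentroidAnnotation]],
    mask_provider: Callable[[np.ndarray], Sequence[np.ndarray]] | None,
    seed: int = 0,
    max_dist: float = MATCH_DIST,
    radius_range: tuple = PSEUDO_RADIUS_RANGE,
):
    """Per-image instance-label sets covering every centroid exactly once.

    Matched provider masks become ``segmented`` labels; unmatched centroids
    get seeded pseudo circles.  Output instances are kept pixel-disjoint:
    pixels of a later label that fall inside an earlier one are removed (the
    annotated centroid pixel is always retained so no label can vanish).
    """
    rng = np.random.default_rng(seed)
    per_image = []
    for image, anns in zip(images, centroid_annotations):
        masks = list(mask_provider(image)) if mask_provider is not None else []
        centroids = [a.position for a in anns]
        pairs, unmatched, _spurious = match_masks_to_centroids(masks, centroids, max_dist)
        occupied = np.zeros(image.shape[:2], dtype=bool)
        labels: list[InstanceLabel | None] = [None] * len(anns)
        for mi, ci in pairs:
            mask = masks[mi] & ~occupied
            ri, cj = (int(round(v)) for v in anns[ci].position)
            mask[np.clip(ri, 0, mask.shape[0] - 1), np.clip(cj, 0, mask.shape[1] - 1)] = True
            labels[ci] = InstanceLabel(mask=mask, centroid_link=anns[ci], provenance="segmented")
            occupied |= mask
        for ci in unmatched:
            radius = int(rng.integers(radius_range[0], radius_range[1] + 1))
            circ = make_circular_label(anns[ci], radius, image.shape, radius_range)
            mask = circ.mask & ~occupied
            ri, cj = (int(round(v)) for v in anns[ci].position)
            mask[np.clip(ri, 0, mask.shape[0] - 1), np.clip(cj, 0, mask.shape[1] - 1)] = True
            labels[ci] = InstanceLabel(
                mask=mask, centroid_link=anns[ci], provenance="pseudo_circle", radius=radius
            )
            occupied |= mask
        assert all(l is not None for l in labels)
        per_image.append(labels)
    return per_image


def stain_threshold_provider(
    basis: StainBasis | None = None,
    min_area: int = 40,
    background_intensity=255.0,
) -> Callable[[np.ndarray], list]:
    """Bootstrap mask provider: Otsu threshold on the haematoxylin channel.

    Stands in for a strongly-supervised segmentation model: it proposes one
    mask per connected haematoxylin-dense component; the refiner's matching
    step discards the (many) non-mitotic proposals.
    """
    stains = basis or StainBasis(DEFAULT_HE_BASIS.copy())

    def provider(image: np.ndarray) -> list:
        od = rgb_to_od(image, background_intensity)
        h_conc = compute_saturations(od, stains).concentrations[..., 0]
        finite = h_conc[np.isfinite(h_conc)]
        if finite.size == 0 or finite.std() < 1e-6:
            return []
        thr = threshold_otsu(finite)
        binary = h_conc > thr
        lab = cc_label(binary, connectivity=2)
        masks = []
        for k in range(1, lab.max() + 1):
            m = lab == k
            if m.sum() >= min_area:
                masks.append(m)
        return masks

    return provider
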