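"""Blob analysis: post-processing between detection and cell-level classification.

Candidate masks are split into 8-connected components ("blobs"); fragmentary
blobs are removed by a strict area cut (area must exceed ``min_area``, 600 px
at full 40x scale); surviving regions are labelled true/false mitosis by
greedy centroid matching against ground truth within 30 px, and fixed-size
cell patches are cropped around each region for the classifier.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Sequence

import numpy as np
from skimage.measure import label as cc_label
from skimage.transform import resize as sk_resize

from .synthetic import crop_patch

__all__ = [
    "Blob",
    "CellPatch",
    "extract_blobs",
    "filter_blobs_by_area",
    "label_by_centroid_distance",
    "extract_cell_patches",
]

DEFAULT_MIN_AREA = 600
DEFAULT_MATCH_DIST = 30.0


@dataclass
class Blob:
    pixels: np.ndarray  # (K, 2) int coordinates of the connected set
    area: int
    centroid: tuple  # (row, col) float
    source_region: object = None


@dataclass
class CellPatch:
    image: np.ndarray  # (size, size, 3)
    label: str  # "mitosis" | "nonmitosis" | "unknown"
    origin: dict  # image_id + box


def extract_blobs(mask: np.ndarray, source_region=None) -> List[Blob]:
    """Connected components under 8-connectivity with areas and centroids."""
    lab = cc_label(np.asarray(mask).astype(bool), connectivity=2)
    blobs = []
    for k in range(1, lab.max() + 1):
        rr, cc = np.nonzero(lab == k)
        blobs.append(
            Blob(
                pixels=np.stack([rr, cc], axis=1),
                area=int(len(rr)),
                centroid=(float(rr.mean()), float(cc.mean())),
                source_region=source_region,
            )
        )
    return blobs


def filter_blobs_by_area(blobs: Sequence[Blob], min_area: int = DEFAULT_MIN_AREA) -> List[Blob]:
    """Keep blobs whose area is strictly greater than ``min_area``."""
    if min_area < 0:
        raise ValueError("min_area must be >= 0")
    return [b for b in blobs if b.area > min_area]


def _region_point(region, use_mask_centroid: bool = True) -> tuple:
    if hasattr(region, "point") and use_mask_centroid:
        return region.point
    if hasattr(region, "centroid"):
        return region.centroid
    if hasattr(region, "box"):
        r0, c0, r1, c1 = region.box
        return ((r0 + r1) / 2.0, (c0 + c1) / 2.0)
    return tuple(region)


def label_by_centroid_distance(
    pred_regions: Sequence,
    gt_centroids: Sequence[tuple],
    max_dist: float = DEFAULT_MATCH_DIST,
    use_mask_centroid: bool = True,
):
    """Tag each predicted region true/false mitosis by one-to-one greedy matching.

    A region can claim at most one ground-truth centroid within ``max_dist``
    (inclusive) of its representative point (mask centroid when available,
    else box centre).  Ties in distance resolve by lowest (row, col) of the
    predicted point.  Returns a list of booleans aligned with
    ``pred_regions`` (True = matched a ground-truth mitosis).
    """
    if max_dist < 0:
        raise ValueError("max_dist must be >= 0")
    points = [_region_point(r, use_mask_centroid) for r in pred_regions]
    candidates = []
    for pi, (pr, pc) in enumerate(points):
        for gi, (gr, gc) in enumerate(gt_centroids):
            d = float(np.hypot(pr - gr, pc - gc))
            if d <= max_dist:
                candidates.append((d, pr, pc, pi, gi))
    candidates.sort()
    used_p, used_g = set(), set()
    tags = [False] * len(pred_regions)
    for d, _, _, pi, gi in candidates:
        if pi in used_p or gi in used_g:
            continue
        tags[pi] = True
        used_p.add(pi)
        used_g.add(gi)
    return tags


def extract_cell_patches(
    image: np.ndarray,
    regions: Sequence,
    size: int = 80,
    resize_to: int | None = None,
    labels: Sequence[str] | None = None,
    image_id: str = "",
) -> List[CellPatch]:
    """size x size crops centred on each region (reflect-padded at borders).

    ``resize_to`` rescales with bilinear interpolation (the convention for
    feeding 80 px cells to 120/224 px classifier inputs).
    """
    if size <= 0:
        raise ValueError("patch size must be positive")
    h, w = image.shape[:2]
    out = []
    for i, region in enumerate(regions):
        if hasattr(region, "box"):
            r0, c0, r1, c1 = region.box
            center = ((r0 + r1) / 2.0, (c0 + c1) / 2.0)
            if r1 <= 0 or c1 <= 0 or r0 >= h or c0 >= w:
                raise ValueError(f"region {region.box} lies outside the image")
            box = tuple(region.box)
        else:
            center = _region_point(region)
            if not (0 <= center[0] < h and 0 <= center[1] < w):
                raise ValueError(f"region centre {center} lies outside the image")
            box = (center[0] - size / 2, center[1] - size / 2, center[0] + size / 2, center[1] + size / 2)
        patch = crop_patch(image, center, size)
        if resize_to is not None and resize_to != size:
            patch = sk_resize(
                patch.astype(float), (resize_to, resize_to), order=1, mode="reflect", anti_aliasing=False
            )
            if np.issubdtype(image.dtype, np.integer):
                patch = np.clip(np.rint(patch), 0, 255).astype(image.dtype)
        out.append(
            CellPatch(
                image=patch,
                label=labels[i] if labels is not None else "unknown",
                origin={"image_id": image_id, "box": box},
            )
        )
    return out
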