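"""Tiling, file formats and run configuration.

Coordinate convention everywhere: 0-based (row, col), row increasing
downward.  Centroid CSVs are ``row,col`` per line with a comment header
documenting the dialect; a ``one_based`` flag shifts coordinates by exactly
1 for datasets that use 1-based pixel indices.  Instance masks are exchanged
as COCO JSON — segmentation either as uncompressed RLE (pixel-exact,
column-major counts per the COCO convention) or as polygons (x=col, y=row).
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import List, Sequence

import numpy as np
import yaml
from PIL import Image
from skimage.draw import polygon as draw_polygon

__all__ = [
    "TileGrid",
    "RunConfig",
    "tile_image",
    "read_image",
    "write_image",
    "read_centroid_csv",
    "write_centroid_csv",
    "rle_encode",
    "rle_decode",
    "write_coco",
    "read_coco",
    "read_scores_csv",
    "write_scores_csv",
    "write_report",
]


# ---------------------------------------------------------------------------
# tiling


@dataclass
class TileGrid:
    tile_size: int
    overlap: float
    origins: list  # [(row, col)] top-left corners, image frame

    def to_image_coords(self, tile_index: int, point) -> tuple:
        r0, c0 = self.origins[tile_index]
        return (point[0] + r0, point[1] + c0)

    def to_tile_coords(self, tile_index: int, point) -> tuple:
        r0, c0 = self.origins[tile_index]
        return (point[0] - r0, point[1] - c0)


def _axis_origins(dim: int, size: int, stride: int) -> list:
    if size >= dim:
        return [0]
    origins = list(range(0, dim - size + 1, stride))
    if origins[-1] != dim - size:
        origins.append(dim - size)
    return origins


def tile_image(image: np.ndarray, size: int = 512, overlap: float = 0.15):
    """Cover an image with equal-sized tiles.

    Stride = floor(size * (1 - overlap)); the last row/column of tiles is
    shifted inward so every tile stays in bounds.  Images smaller than the
    tile are reflect-padded to a single tile.  Returns ``(grid, tiles)``.
    """
    if size <= 0:
        raise ValueError("tile size must be positive")
    if not 0.0 <= overlap < 1.0:
        raise ValueError("overlap must lie in [0, 1)")
    h, w = image.shape[:2]
    if size > h or size > w:
        pad_h, pad_w = max(size - h, 0), max(size - w, 0)
        widths = ((0, pad_h), (0, pad_w)) + ((0, 0),) * (image.ndim - 2)
        padded = np.pad(image, widths, mode="reflect")
        grid = TileGrid(tile_size=size, overlap=overlap, origins=[(0, 0)])
        return grid, [padded[:size, :size]]
    stride = int(math.floor(size * (1.0 - overlap)))
    stride = max(stride, 1)
    rows = _axis_origins(h, size, stride)
    cols = _axis_origins(w, size, stride)
    origins = [(r, c) for r in rows for c in cols]
    tiles = [image[r : r + size, c : c + size] for r, c in origins]
    return TileGrid(tile_size=size, overlap=overlap, origins=origins), tiles


# ---------------------------------------------------------------------------
# images


def read_image(path) -> np.ndarray:
    return np.asarray(Image.open(path).convert("RGB"))


def write_image(path, image: np.ndarray) -> None:
    Image.fromarray(np.asarray(image).astype(np.uint8)).save(path)


# ---------------------------------------------------------------------------
# centroid CSV (TUPAC-style: one mitosis per line)

CSV_HEADER = "# row,col  (0-based pixel coordinates, row increases downward)"


def write_centroid_csv(path, centroids: Sequence[tuple], one_based: bool = False) -> None:
    offset = 1 if one_based else 0
    lines = [CSV_HEADER if not one_based else "# row,col  (1-based pixel coordinates)"]
    for r, c in centroids:
        lines.append(f"{r + offset:.0f},{c + offset:.0f}" if float(r).is_integer() and float(c).is_integer()
                     else f"{r + offset},{c + offset}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_centroid_csv(path, one_based: bool = False) -> List[tuple]:
    offset = -1 if one_based else 0
    out = []
    for ln, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split(",")
        if len(parts) != 2:
            raise ValueError(f"{path}:{ln}: expected 'row,col', got {raw!r}")
        try:
            r, c = float(parts[0]), float(parts[1])
        except ValueError as exc:
            raise ValueError(f"{path}:{ln}: non-numeric coordinate in {raw!r}") from exc
        out.append((r + offset, c + offset))
    return out


# ---------------------------------------------------------------------------
# COCO JSON (hand-rolled: uncompressed RLE + polygons)


def rle_encode(mask: np.ndarray) -> dict:
    """Uncompressed COCO RLE: column-major run lengths, starting with zeros."""
    m = np.asarray(mask).astype(np.uint8)
    flat = m.flatten(order="F")
    if flat.size == 0:
        return {"counts": [], "size": list(m.shape)}
    change = np.flatnonzero(np.diff(flat)) + 1
    bounds = np.concatenate([[0], change, [flat.size]])
    counts = np.diff(bounds).tolist()
    if flat[0] == 1:  # counts must start with the number of leading zeros
        counts = [0] + counts
    return {"counts": [int(c) for c in counts], "size": [int(m.shape[0]), int(m.shape[1])]}


def rle_decode(rle: dict) -> np.ndarray:
    h, w = rle["size"]
    flat = np.zeros(h * w, dtype=bool)
    pos = 0
    val = False
    for count in rle["counts"]:
        if val:
            flat[pos : pos + count] = True
        pos += count
        val = not val
    return flat.reshape((h, w), order="F")


def _polygon_to_mask(poly: Sequence[float], shape) -> np.ndarray:
    xs = np.asarray(poly[0::2], dtype=float)  # x = col
    ys = np.asarray(poly[1::2], dtype=float)  # y = row
    rr, cc = draw_polygon(ys, xs, shape=shape)
    mask = np.zeros(shape, dtype=bool)
    mask[rr, cc] = True
    return mask


def write_coco(path, images: Sequence[dict], annotations_per_image: Sequence[Sequence[np.ndarray]],
               category: str = "mitosis", encoding: str = "rle") -> None:
    """Write instance masks as a COCO dataset.

    ``images`` is a list of {"id", "file_name", "height", "width"};
    ``annotations_per_image[i]`` the boolean masks of image i.  ``encoding``
    is ``"rle"`` (uncompressed, pixel-exact) or ``"polygon"`` (convex-ish
    outline from the mask's boundary pixels; approximate).
    """
    if encoding not in ("rle", "polygon"):
        raise ValueError("encoding must be 'rle' or 'polygon'")
    anns = []
    ann_id = 1
    for img, masks in zip(images, annotations_per_image):
        for m in masks:
            rr, cc = np.nonzero(m)
            if len(rr) == 0:
                continue
            bbox = [int(cc.min()), int(rr.min()), int(cc.max() - cc.min() + 1), int(rr.max() - rr.min() + 1)]
            if encoding == "rle":
                seg = rle_encode(m)
            else:
                seg = [_mask_outline_polygon(m)]
            anns.append(
                {
                    "id": ann_id,
                    "image_id": img["id"],
                    "category_id": 1,
                    "segmentation": seg,
                    "bbox": bbox,
                    "area": int(len(rr)),
                    "iscrowd": 0,
                }
            )
            ann_id += 1
    doc = {
        "images": [dict(im) for im in images],
        "annotations": anns,
        "categories": [{"id": 1, "name": category}],
    }
    Path(path).write_text(json.dumps(doc, sort_keys=True))


def _mask_outline_polygon(mask: np.ndarray) -> list:
    """Approximate outline polygon (x, y interleaved): boundary pixels ordered by
    angle around the centroid (adequate for star-convex nuclei outlines)."""
    from scipy.ndimage import binary_erosion

    boundary = mask & ~binary_erosion(mask)
    rr, cc = np.nonzero(boundary if boundary.any() else mask)
    cr, ccen = np.nonzero(mask)[0].mean(), np.nonzero(mask)[1].mean()
    angles = np.arctan2(rr - cr, cc - ccen)
    order = np.argsort(angles)
    pts = np.stack([cc[order], rr[order]], axis=1).astype(float)
    step = max(len(pts) // 60, 1)
    return pts[::step].reshape(-1).tolist()


def read_coco(path) -> dict:
    """Read a COCO file -> {image_id: {"info": image dict, "masks": [bool arrays]}}."""
    doc = json.loads(Path(path).read_text())
    by_id = {im["id"]: {"info": im, "masks": []} for im in doc["images"]}
    for ann in doc["annotations"]:
        entry = by_id[ann["image_id"]]
        h, w = entry["info"]["height"], entry["info"]["width"]
        seg = ann["segmentation"]
        if isinstance(seg, dict):
            mask = rle_decode(seg)
        else:
            mask = np.zeros((h, w), dtype=bool)
            for poly in seg:
                mask |= _polygon_to_mask(poly, (h, w))
        entry["masks"].append(mask)
    return by_id


# ---------------------------------------------------------------------------
# scores / reports


def write_scores_csv(path, ids: Sequence, p_mitosis: Sequence[float]) -> None:
    lines = ["patch_id,p_mitosis"]
    lines += [f"{i},{p:.6f}" for i, p in zip(ids, p_mitosis)]
    Path(path).write_text("\n".join(lines) + "\n")


def read_scores_csv(path):
    ids, probs = [], []
    for ln, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#") or line.startswith("patch_id"):
            continue
        parts = line.split(",")
        if len(parts) != 2:
            raise ValueError(f"{path}:{ln}: expected 'patch_id,p_mitosis', got {raw!r}")
        ids.append(parts[0])
        probs.append(float(parts[1]))
    return ids, np.asarray(probs)


def write_report(path, report: dict) -> None:
    """Deterministic JSON report (sorted keys, fixed float formatting)."""
    Path(path).write_text(json.dumps(_roundtrip_safe(report), sort_keys=True, indent=2) + "\n")


def _roundtrip_safe(obj):
    if isinstance(obj, dict):
        return {str(k): _roundtrip_safe(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_roundtrip_safe(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        return round(float(obj), 10)
    if isinstance(obj, (np.integer, int)):
        return int(obj)
    if isinstance(obj, np.ndarray):
        return _roundtrip_safe(obj.tolist())
    return obj


# ---------------------------------------------------------------------------
# run configuration


@dataclass
class RunConfig:
    """Every stage's parameters; defaults are the published full-scale values.

    ``scaled`` profiles for desk-size synthetic runs live in
    :mod:`mitdet.pipeline`, not here.
    """

    seed: int = 0
    # tiling
    tile_size: int = 512
    tile_overlap: float = 0.15
    # refinement
    pseudo_radius_min: int = 10
    pseudo_radius_max: int = 16
    refine_match_dist: float = 30.0
    # detection
    anchor_scales: list = field(default_factory=lambda: [32, 64, 128, 256])
    anchor_ratios: list = field(default_factory=lambda: [0.5, 1.0, 2.0])
    proposal_min_iou: float = 0.7
    confidence_threshold: float = 0.5
    proposals_per_step: int = 128
    # blob analysis
    blob_min_area: int = 600
    match_dist: float = 30.0
    # cell patches
    cell_patch_size: int = 80
    classifier_input: int = 120
    adapted_input: int = 224
    # classifier training
    batch_size: int = 16
    pretrained_batch_size: int = 6
    learning_rate: float = 1e-3
    weight_decay: float = 1e-5
    epochs: int = 250

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        return cls(**d)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))
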