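"""Seed-controlled generator of H&E-like tissue scenes with exact ground truth.

The generator states a simplified world with the features the detection
pipeline must cope with: two-stain colour mixing in optical-density space,
sparse irregular (spiculated or bilobed) mitotic nuclei, abundant round
non-mitotic nuclei, eosin-rich stroma texture, heavy class imbalance and
scanner-style photometric variation.  A bilobed telophase figure is a single
instance with a single centroid, exactly as mitosis-counting protocols treat
the two daughter lobes of one dividing cell.

Colours are produced by drawing per-pixel stain concentrations, mixing them
through the two stain vectors in OD space and exponentiating back to
intensity; the OD cloud of any generated scene therefore lies in the span of
the spec's stain basis up to the additive intensity noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage as ndi
from skimage.draw import polygon as draw_polygon
from skimage.draw import disk as draw_disk

from .stain import DEFAULT_HE_BASIS

__all__ = [
    "SceneSpec",
    "SyntheticScene",
    "PatchDataset",
    "PlacementError",
    "generate_scene",
    "generate_patch_dataset",
    "perturb_dataset",
]

PHASE_TAGS = (
    "prophase-like",
    "metaphase-like",
    "anaphase-like",
    "telophase-like",
    "nonmitosis",
)


class PlacementError(RuntimeError):
    """Raised when objects cannot be placed without overlap within the retry budget."""


@dataclass(frozen=True)
class SceneSpec:
    """Declarative description of one synthetic tissue scene.

    Default geometry is desk-scale: nuclei of ~10-25 px diameter in a 192 px
    field, i.e. the pixel size of real 40x patches scaled down ~4x so the
    whole pipeline trains on one CPU.  Mitoses carry a higher haematoxylin
    concentration (hyperchromatic chromatin) than interphase nuclei.
    """

    width: int = 192
    height: int = 192
    n_mitoses: int = 4
    n_nonmitoses: int = 28
    telophase_fraction: float = 0.25
    stain_basis: np.ndarray = field(default_factory=lambda: DEFAULT_HE_BASIS.copy())
    background_intensity: tuple = (242.0, 242.0, 242.0)
    noise_sd: float = 2.0
    seed: int = 0
    mitosis_radius: tuple = (9.0, 13.0)
    nonmitosis_radius: tuple = (5.0, 9.0)

    def validate(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ValueError("scene must have positive area")
        if self.n_mitoses < 0 or self.n_nonmitoses < 0:
            raise ValueError("object counts must be >= 0")
        if not 0.0 <= self.telophase_fraction <= 1.0:
            raise ValueError("telophase_fraction must lie in [0, 1]")
        basis = np.asarray(self.stain_basis, dtype=float)
        if basis.shape != (2, 3):
            raise ValueError("stain_basis must be (2, 3)")
        if not np.allclose(np.linalg.norm(basis, axis=1), 1.0, atol=1e-6):
            raise ValueError("stain vectors must be unit norm")
        if np.linalg.norm(np.cross(basis[0], basis[1])) < 1e-6:
            raise ValueError("stain vectors must be linearly independent")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass
class SyntheticScene:
    """A generated scene: image plus exact instance-level ground truth.

    ``gt_centroids``/``gt_masks``/``phase_tags`` are aligned per instance
    (mitoses first).  ``lobe_centroids`` expands telophase figures into their
    two lobes with a shared ``group_id`` so evaluation code can exercise the
    "telophase counted once" rule; every other mitosis is its own group.
    """

    image: np.ndarray  # (H, W, 3) uint8
    gt_centroids: list  # [(row, col)] of mitoses only
    gt_masks: list  # per-mitosis boolean (H, W)
    phase_tags: list  # per instance incl. non-mitoses
    nonmitosis_centroids: list
    nonmitosis_masks: list
    lobe_centroids: list  # [(row, col, group_id)]
    spec: SceneSpec | None = None


def _star_polygon(rng, center, radius, n_vertices=14, spikiness=0.45):
    """Star-convex spiculated outline: radial noise on a disc."""
    angles = np.linspace(0, 2 * np.pi, n_vertices, endpoint=False)
    angles = angles + rng.uniform(0, 2 * np.pi / n_vertices)
    radii = radius * (1.0 + spikiness * (rng.random(n_vertices) - 0.5) * 2.0)
    radii = np.maximum(radii, 2.0)
    rows = center[0] + radii * np.sin(angles)
    cols = center[1] + radii * np.cos(angles)
    return rows, cols


def _rasterize_polygon(rows, cols, shape):
    rr, cc = draw_polygon(rows, cols, shape=shape)
    mask = np.zeros(shape, dtype=bool)
    mask[rr, cc] = True
    return mask


def _telophase_mask(rng, center, radius, shape):
    """Two lobes joined by a thin chromatin bridge; one instance, one centroid."""
    sep = 0.85 * radius
    theta = rng.uniform(0, np.pi)
    dr, dc = sep * np.sin(theta), sep * np.cos(theta)
    lobe_r = max(0.62 * radius, 3.0)
    c1 = (center[0] - dr, center[1] - dc)
    c2 = (center[0] + dr, center[1] + dc)
    mask = np.zeros(shape, dtype=bool)
    for c in (c1, c2):
        rr, cc = draw_disk(c, lobe_r, shape=shape)
        mask[rr, cc] = True
    # bridge: thick line through the centroid so it lies inside the mask
    n = max(int(2 * sep) + 1, 3)
    ts = np.linspace(0, 1, 4 * n)
    br = c1[0] + ts * (c2[0] - c1[0])
    bc = c1[1] + ts * (c2[1] - c1[1])
    for orow in (-1, 0, 1):
        for ocol in (-1, 0, 1):
            rr = np.clip(np.rint(br + orow).astype(int), 0, shape[0] - 1)
            cc = np.clip(np.rint(bc + ocol).astype(int), 0, shape[1] - 1)
            mask[rr, cc] = True
    return mask, (c1, c2)


def _ellipse_mask(rng, center, radius, shape):
    rr = np.arange(shape[0])[:, None]
    cc = np.arange(shape[1])[None, :]
    a = radius * rng.uniform(0.85, 1.15)
    b = radius * rng.uniform(0.7, 1.0)
    theta = rng.uniform(0, np.pi)
    dr, dc = rr - center[0], cc - center[1]
    u = dr * np.cos(theta) + dc * np.sin(theta)
    v = -dr * np.sin(theta) + dc * np.cos(theta)
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


def _place_centers(rng, shape, radii, max_retries=1000):
    """Rejection sampling with minimum centre distance = sum of radii (+2 px)."""
    centers: list[tuple[float, float]] = []
    placed_r: list[float] = []
    for r in radii:
        margin = r + 2.0
        ok = False
        for _ in range(max_retries):
            row = rng.uniform(margin, shape[0] - margin)
            col = rng.uniform(margin, shape[1] - margin)
            if all(
                np.hypot(row - pr, col - pc) >= r + orr + 2.0
                for (pr, pc), orr in zip(centers, placed_r)
            ):
                ok = True
                break
        if not ok:
            raise PlacementError(
                f"could not place object of radius {r:.1f} after {max_retries} retries"
            )
        centers.append((row, col))
        placed_r.append(r)
    return centers


def generate_scene(spec: SceneSpec) -> SyntheticScene:
    """Render one scene; identical spec+seed gives a bit-identical result."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    shape = (spec.height, spec.width)
    basis = np.asarray(spec.stain_basis, dtype=float)

    mit_radii = rng.uniform(*spec.mitosis_radius, size=spec.n_mitoses)
    non_radii = rng.uniform(*spec.nonmitosis_radius, size=spec.n_nonmitoses)
    max_r = max(spec.mitosis_radius[1], spec.nonmitosis_radius[1])
    if 2.0 * (max_r + 2.0) > min(shape):
        raise PlacementError("image too small for the requested object sizes")
    centers = _place_centers(rng, shape, np.concatenate([mit_radii, non_radii]))

    n_telo = int(round(spec.telophase_fraction * spec.n_mitoses))
    telo_idx = set(rng.choice(spec.n_mitoses, size=n_telo, replace=False).tolist()) if n_telo else set()

    conc_h = np.zeros(shape)
    conc_e = np.zeros(shape)
    gt_centroids, gt_masks, phase_tags, lobes = [], [], [], []
    for i in range(spec.n_mitoses):
        center, r = centers[i], mit_radii[i]
        if i in telo_idx:
            mask, (c1, c2) = _telophase_mask(rng, center, r, shape)
            tag = "telophase-like"
            lobes.append((c1[0], c1[1], i))
            lobes.append((c2[0], c2[1], i))
        else:
            rows, cols = _star_polygon(rng, center, r)
            mask = _rasterize_polygon(rows, cols, shape)
            mask[int(round(center[0])), int(round(center[1]))] = True
            tag = str(rng.choice(PHASE_TAGS[:3]))
            lobes.append((center[0], center[1], i))
        # hyperchromatic: mitotic chromatin is haematoxylin-dense, nearly eosin-free
        conc_h[mask] = rng.uniform(0.95, 1.25)
        gt_centroids.append((float(center[0]), float(center[1])))
        gt_masks.append(mask)
        phase_tags.append(tag)

    non_centroids, non_masks = [], []
    for j in range(spec.n_nonmitoses):
        center, r = centers[spec.n_mitoses + j], non_radii[j]
        mask = _ellipse_mask(rng, center, r, shape)
        conc_h[mask] = rng.uniform(0.30, 0.50)
        conc_e[mask] = rng.uniform(0.0, 0.04)
        non_centroids.append((float(center[0]), float(center[1])))
        non_masks.append(mask)
        phase_tags.append("nonmitosis")

    # eosin-rich stroma texture between nuclei (nearly haematoxylin-free so a
    # Macenko estimate sees close-to-pure examples of both stains)
    field_raw = rng.random(shape)
    stroma = ndi.gaussian_filter(field_raw, sigma=8.0)
    stroma = (stroma - stroma.min()) / max(float(np.ptp(stroma)), 1e-9)
    nucleus_any = np.zeros(shape, dtype=bool)
    for m in gt_masks + non_masks:
        nucleus_any |= m
    conc_e += np.where(nucleus_any, 0.0, 0.45 * stroma**1.5)
    conc_h += np.where(nucleus_any, 0.0, 0.01 * stroma)

    conc = np.stack([conc_h, conc_e], axis=-1)  # (H, W, 2)
    od = conc @ basis  # (H, W, 3)
    bg = np.asarray(spec.background_intensity, dtype=float)
    intensity = bg * np.power(10.0, -od)
    if spec.noise_sd > 0:
        intensity = intensity + rng.normal(0.0, spec.noise_sd, size=intensity.shape)
    image = np.clip(np.rint(intensity), 0, 255).astype(np.uint8)

    return SyntheticScene(
        image=image,
        gt_centroids=gt_centroids,
        gt_masks=gt_masks,
        phase_tags=phase_tags,
        nonmitosis_centroids=non_centroids,
        nonmitosis_masks=non_masks,
        lobe_centroids=lobes,
        spec=spec,
    )


@dataclass
class PatchDataset:
    """Labelled cell patches: ``patches[i]`` is (size, size, 3) uint8."""

    patches: np.ndarray  # (N, size, size, 3)
    labels: np.ndarray  # (N,) 1 = mitosis
    scene_ids: np.ndarray  # (N,) index of the source scene (acts as patient id)
    centers: np.ndarray  # (N, 2) patch centre in scene coordinates


def crop_patch(image: np.ndarray, center, size: int) -> np.ndarray:
    """size x size crop centred on ``center`` with reflect padding at borders."""
    half = size // 2
    r, c = int(round(center[0])), int(round(center[1]))
    padded = np.pad(image, ((half, half), (half, half), (0, 0)), mode="reflect")
    return padded[r : r + size, c : c + size]


def generate_patch_dataset(
    specs: Sequence[SceneSpec],
    patch_size: int = 40,
    imbalance_ratio: float = 10.0,
    seed: int = 0,
    scenes: Sequence[SyntheticScene] | None = None,
) -> PatchDataset:
    """Cell-patch collection with a controlled negative:positive ratio.

    Positives are centred on mitosis centroids; negatives on non-mitotic
    nuclei plus random tissue positions at least 30 px from every mitosis.
    """
    if imbalance_ratio <= 0:
        raise ValueError("imbalance_ratio must be > 0")
    if scenes is None:
        scenes = [generate_scene(s) for s in specs]
    max_diam = 2 * max(
        max((s.spec.mitosis_radius[1] for s in scenes if s.spec), default=0.0),
        max((s.spec.nonmitosis_radius[1] for s in scenes if s.spec), default=0.0),
    )
    if max_diam and patch_size < max_diam:
        raise ValueError(
            f"patch_size {patch_size} smaller than largest object diameter {max_diam:.0f}"
        )
    rng = np.random.default_rng(seed)

    pos, neg = [], []  # (scene_idx, row, col)
    for i, scene in enumerate(scenes):
        pos.extend((i, r, c) for (r, c) in scene.gt_centroids)
        neg.extend((i, r, c) for (r, c) in scene.nonmitosis_centroids)
    n_pos = len(pos)
    if n_pos == 0:
        raise ValueError("no mitoses in the provided scenes")
    n_neg_target = int(round(imbalance_ratio * n_pos))
    while len(neg) < n_neg_target:  # top up with random tissue positions
        i = int(rng.integers(len(scenes)))
        scene = scenes[i]
        h, w = scene.image.shape[:2]
        r, c = rng.uniform(0, h), rng.uniform(0, w)
        if all(np.hypot(r - gr, c - gc) > 30.0 for gr, gc in scene.gt_centroids):
            neg.append((i, r, c))
    if len(neg) > n_neg_target:
        keep = rng.choice(len(neg), size=n_neg_target, replace=False)
        neg = [neg[k] for k in sorted(keep)]

    entries = [(s, r, c, 1) for s, r, c in pos] + [(s, r, c, 0) for s, r, c in neg]
    patches = np.stack(
        [crop_patch(scenes[s].image, (r, c), patch_size) for s, r, c, _ in entries]
    )
    return PatchDataset(
        patches=patches,
        labels=np.array([e[3] for e in entries], dtype=int),
        scene_ids=np.array([e[0] for e in entries], dtype=int),
        centers=np.array([[e[1], e[2]] for e in entries], dtype=float),
    )


VARIATIONS = ("position", "contrast", "brightness", "saturation")


def _shift_image(image: np.ndarray, dr: int, dc: int) -> np.ndarray:
    pr, pc = abs(dr), abs(dc)
    padded = np.pad(image, ((pr, pr), (pc, pc)) + ((0, 0),) * (image.ndim - 2), mode="reflect")
    h, w = image.shape[:2]
    return padded[pr - dr : pr - dr + h, pc - dc : pc - dc + w]


def perturb_dataset(scene: SyntheticScene, variation: str, magnitude, seed: int = 0) -> SyntheticScene:
    """Scanner/position robustness variations.

    position: ``magnitude`` = integer (dr, dc); image content and all ground
    truth shift together (reflect fill at the trailing edge).  Photometric
    variations take a scalar magnitude in [-0.5, 0.5] and leave geometry
    untouched: contrast scales deviations from the per-channel mean (mean
    preserved up to clipping), brightness scales intensities, saturation
    scales deviations from the luminance.
    """
    if variation not in VARIATIONS:
        raise ValueError(f"unknown variation {variation!r}; expected one of {VARIATIONS}")
    img = scene.image.astype(float)
    if variation == "position":
        dr, dc = int(magnitude[0]), int(magnitude[1])
        h, w = img.shape[:2]
        if abs(dr) >= h or abs(dc) >= w:
            raise ValueError("position shift larger than the image")
        new_img = _shift_image(scene.image, dr, dc)
        return SyntheticScene(
            image=new_img,
            gt_centroids=[(r + dr, c + dc) for r, c in scene.gt_centroids],
            gt_masks=[_shift_image(m, dr, dc) for m in scene.gt_masks],
            phase_tags=list(scene.phase_tags),
            nonmitosis_centroids=[(r + dr, c + dc) for r, c in scene.nonmitosis_centroids],
            nonmitosis_masks=[_shift_image(m, dr, dc) for m in scene.nonmitosis_masks],
            lobe_centroids=[(r + dr, c + dc, g) for r, c, g in scene.lobe_centroids],
            spec=scene.spec,
        )
    m = float(magnitude)
    if not -0.5 <= m <= 0.5:
        raise ValueError("photometric magnitude must lie in [-0.5, 0.5]")
    if variation == "contrast":
        mean = img.reshape(-1, 3).mean(axis=0)
        out = mean + (1.0 + m) * (img - mean)
    elif variation == "brightness":
        out = (1.0 + m) * img
    else:  # saturation
        gray = img @ np.array([0.299, 0.587, 0.114])
        out = gray[..., None] + (1.0 + m) * (img - gray[..., None])
    out = np.clip(np.rint(out), 0, 255).astype(np.uint8)
    return replace_image(scene, out)


def replace_image(scene: SyntheticScene, image: np.ndarray) -> SyntheticScene:
    """Copy of a scene with a different pixel array (geometry unchanged)."""
    return SyntheticScene(
        image=image,
        gt_centroids=list(scene.gt_centroids),
        gt_masks=list(scene.gt_masks),
        phase_tags=list(scene.phase_tags),
        nonmitosis_centroids=list(scene.nonmitosis_centroids),
        nonmitosis_masks=list(scene.nonmitosis_masks),
        lobe_centroids=list(scene.lobe_centroids),
        spec=scene.spec,
    )
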