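"""Macenko-style H&E stain normalization and per-channel standardization.

Haematoxylin and eosin absorb light multiplicatively, so stains mix *linearly*
in optical-density (OD) space, ``OD = -log10(I / I0)``.  A patch is separated
into two stain "saturation" (concentration) channels by least squares against a
3x2 basis of unit stain vectors; re-expressing those concentrations in a common
target basis removes lab-to-lab colour variation before any learning happens.

All images are ``(H, W, 3)`` arrays.  Intensities are 0-255 (uint8 or float);
a floor of 1 is applied before the log so OD stays finite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ODImage",
    "StainBasis",
    "SaturationMap",
    "NormalizationStats",
    "StainEstimationError",
    "DEFAULT_HE_BASIS",
    "rgb_to_od",
    "od_to_rgb",
    "estimate_stain_basis",
    "compute_saturations",
    "normalize_to_target",
    "standardize",
    "unstandardize",
]

#: Conventional haematoxylin / eosin OD directions (unit norm, H first).
DEFAULT_HE_BASIS = np.array(
    [[0.650, 0.704, 0.286], [0.072, 0.990, 0.105]], dtype=float
)
DEFAULT_HE_BASIS /= np.linalg.norm(DEFAULT_HE_BASIS, axis=1, keepdims=True)

INTENSITY_FLOOR = 1.0  # on the 0-255 scale, keeps the log finite


class StainEstimationError(ValueError):
    """Raised when a stain basis cannot be estimated (no tissue / single stain)."""


@dataclass
class ODImage:
    """Per-pixel optical density with the background reference it was taken against."""

    values: np.ndarray  # (H, W, 3), dimensionless, >= 0 up to noise
    background_intensity: np.ndarray  # (3,)


@dataclass
class StainBasis:
    """Two unit 3-vectors in OD space, H first by convention."""

    vectors: np.ndarray  # (2, 3)

    def __post_init__(self) -> None:
        v = np.asarray(self.vectors, dtype=float)
        if v.shape != (2, 3):
            raise ValueError(f"stain basis must be (2, 3), got {v.shape}")
        norms = np.linalg.norm(v, axis=1)
        if np.any(norms < 1e-12):
            raise ValueError("stain vectors must be non-zero")
        v = v / norms[:, None]
        cross = np.linalg.norm(np.cross(v[0], v[1]))
        if cross < 1e-6:
            raise ValueError("stain vectors are collinear")
        self.vectors = v


@dataclass
class SaturationMap:
    """Two stain concentrations per pixel (least-squares fit of OD = V.S)."""

    concentrations: np.ndarray  # (H, W, 2)


@dataclass
class NormalizationStats:
    """Dataset-level per-channel mean/std for the final standardization step."""

    mu: np.ndarray
    sigma: np.ndarray

    @classmethod
    def from_images(cls, images, per_channel: bool = True) -> "NormalizationStats":
        stack = np.concatenate(
            [np.asarray(im, dtype=float).reshape(-1, 3) for im in images], axis=0
        )
        if per_channel:
            return cls(mu=stack.mean(axis=0), sigma=stack.std(axis=0))
        return cls(mu=np.full(3, stack.mean()), sigma=np.full(3, stack.std()))


def _background(background_intensity) -> np.ndarray:
    bg = np.broadcast_to(np.asarray(background_intensity, dtype=float), (3,)).copy()
    if np.any(bg <= 0):
        raise ValueError("background intensity must be positive")
    return bg


def rgb_to_od(image: np.ndarray, background_intensity=255.0) -> ODImage:
    """OD = -log10(I / I0), elementwise, with intensities floored at 1."""
    bg = _background(background_intensity)
    intensity = np.maximum(np.asarray(image, dtype=float), INTENSITY_FLOOR)
    od = -np.log10(intensity / bg)
    return ODImage(values=od, background_intensity=bg)


def od_to_rgb(od: ODImage, clip: bool = True) -> np.ndarray:
    """Invert :func:`rgb_to_od`; returns float intensities on the 0-255 scale."""
    intensity = od.background_intensity * np.power(10.0, -od.values)
    if clip:
        intensity = np.clip(intensity, 0.0, 255.0)
    return intensity


def estimate_stain_basis(
    od: ODImage, od_threshold: float = 0.15, angle_percentile: float = 1.0
) -> StainBasis:
    """Estimate the two dominant stain vectors (Macenko).

    Tissue pixels (OD magnitude above ``od_threshold``) are projected onto the
    top-2 eigenvector plane of their covariance; the extreme-angle percentiles
    within that plane are taken as the pure-stain directions.  The vector with
    the larger blue-channel OD component is labelled H (haematoxylin binds DNA
    and absorbs strongly in the blue/red channels).
    """
    pix = od.values.reshape(-1, 3)
    tissue = pix[np.linalg.norm(pix, axis=1) > od_threshold]
    if tissue.shape[0] < 2:
        raise StainEstimationError("not enough tissue pixels above OD threshold")

    cov = np.cov(tissue, rowvar=False)
    evals, evecs = np.linalg.eigh(cov)
    if evals[-2] <= 1e-10 * max(evals[-1], 1e-30):
        raise StainEstimationError("OD cloud is rank deficient (single stain?)")
    plane = evecs[:, [-1, -2]]  # (3, 2), columns span the dominant plane
    # orient so that most projections are positive (deterministic sign fix)
    proj = tissue @ plane
    for k in range(2):
        if proj[:, k].sum() < 0:
            plane[:, k] *= -1
            proj[:, k] *= -1

    angles = np.arctan2(proj[:, 1], proj[:, 0])
    lo, hi = np.percentile(angles, [angle_percentile, 100.0 - angle_percentile])
    v1 = plane @ np.array([np.cos(lo), np.sin(lo)])
    v2 = plane @ np.array([np.cos(hi), np.sin(hi)])
    vecs = np.stack([v1, v2])
    vecs *= np.where(vecs.sum(axis=1, keepdims=True) < 0, -1.0, 1.0)
    vecs /= np.linalg.norm(vecs, axis=1, keepdims=True)
    # H = larger blue-channel OD component
    if vecs[0, 2] < vecs[1, 2]:
        vecs = vecs[::-1]
    return StainBasis(vectors=vecs)


def compute_saturations(od: ODImage, basis: StainBasis) -> SaturationMap:
    """Per-pixel least-squares solution of OD = V.S.

    V is 3x2, so the Moore-Penrose generalized inverse is used: S = pinv(V) OD.
    """
    v = basis.vectors.T  # (3, 2)
    pinv = np.linalg.pinv(v)  # (2, 3)
    h, w, _ = od.values.shape
    conc = od.values.reshape(-1, 3) @ pinv.T
    return SaturationMap(concentrations=conc.reshape(h, w, 2))


def _percentile_scale(conc: np.ndarray, pct: float = 99.0) -> np.ndarray:
    """Robust per-stain concentration scale (99th percentile of positives)."""
    scale = np.percentile(np.maximum(conc.reshape(-1, 2), 0.0), pct, axis=0)
    return np.maximum(scale, 1e-6)


def normalize_to_target(
    image: np.ndarray,
    source_basis: StainBasis,
    target_basis: StainBasis,
    concentration_scaling=None,
    background_intensity=255.0,
) -> np.ndarray:
    """Re-express a patch's stain concentrations in a target basis.

    ``concentration_scaling`` is a length-2 per-stain multiplier; ``None``
    derives it by matching 99th-percentile concentrations to
    ``target_scale``-free unit scaling (i.e. the source scale is kept).  Pass a
    tuple ``(target_scale, source_scale)`` of per-stain percentile scales to
    match a reference distribution, or an explicit length-2 array.
    """
    od = rgb_to_od(image, background_intensity)
    sat = compute_saturations(od, source_basis).concentrations
    if concentration_scaling is None:
        scaling = np.ones(2)
    elif isinstance(concentration_scaling, tuple) and len(concentration_scaling) == 2 and np.ndim(concentration_scaling[0]) == 1:
        target_scale, source_scale = concentration_scaling
        scaling = np.asarray(target_scale, float) / np.maximum(np.asarray(source_scale, float), 1e-6)
    else:
        scaling = np.broadcast_to(np.asarray(concentration_scaling, float), (2,))
    sat = np.maximum(sat, 0.0) * scaling
    od_new = ODImage(
        values=sat @ target_basis.vectors,
        background_intensity=od.background_intensity,
    )
    out = od_to_rgb(od_new)
    if np.issubdtype(np.asarray(image).dtype, np.integer):
        out = np.rint(out).astype(np.asarray(image).dtype)
    return out


def match_concentration_scales(
    source_image: np.ndarray,
    target_image: np.ndarray,
    source_basis: StainBasis,
    target_basis: StainBasis,
    background_intensity=255.0,
    pct: float = 99.0,
):
    """Per-stain scaling that matches the source's percentile concentrations to the target's."""
    src = compute_saturations(
        rgb_to_od(source_image, background_intensity), source_basis
    ).concentrations
    tgt = compute_saturations(
        rgb_to_od(target_image, background_intensity), target_basis
    ).concentrations
    return (_percentile_scale(tgt, pct), _percentile_scale(src, pct))


def standardize(
    image: np.ndarray, stats: NormalizationStats, tolerance: float = 1e-8
) -> np.ndarray:
    """(x - mu) / sigma per channel."""
    sigma = np.asarray(stats.sigma, dtype=float)
    if np.any(sigma <= tolerance):
        raise ValueError("sigma must be positive for standardization")
    return (np.asarray(image, dtype=float) - stats.mu) / sigma


def unstandardize(image: np.ndarray, stats: NormalizationStats) -> np.ndarray:
    """Inverse of :func:`standardize`."""
    return np.asarray(image, dtype=float) * stats.sigma + stats.mu
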