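"""Stain normalization: OD transform, Macenko basis estimation, standardization."""

import numpy as np
import pytest

from mitdet import stain
from mitdet.stain import (
    DEFAULT_HE_BASIS,
    NormalizationStats,
    StainBasis,
    StainEstimationError,
    compute_saturations,
    estimate_stain_basis,
    normalize_to_target,
    od_to_rgb,
    rgb_to_od,
    standardize,
    unstandardize,
)

ALT_BASIS = np.array([[0.55, 0.76, 0.35], [0.10, 0.95, 0.29]])
ALT_BASIS = ALT_BASIS / np.linalg.norm(ALT_BASIS, axis=1, keepdims=True)


def _angle_deg(a, b):
    return np.degrees(np.arccos(np.clip(abs(np.dot(a, b)), -1.0, 1.0)))


def synth_image(basis, conc_h, conc_e, bg=255.0):
    conc = np.stack([conc_h, conc_e], axis=-1)
    od = conc @ np.asarray(basis)
    return np.clip(np.rint(bg * 10.0 ** (-od)), 0, 255).astype(np.uint8)


class TestODTransform:
    @pytest.mark.parametrize(
        "intensity,expected_od", [(200.0, 0.0), (20.0, 1.0), (2.0, 2.0)]
    )
    def test_log10_values(self, intensity, expected_od):
        img = np.full((2, 2, 3), intensity)
        od = rgb_to_od(img, background_intensity=200.0)
        assert np.allclose(od.values, expected_od, atol=1e-9)

    def test_roundtrip_identity_above_floor(self, rng):
        img = rng.integers(5, 255, size=(8, 8, 3)).astype(float)
        od = rgb_to_od(img, 255.0)
        assert np.allclose(od_to_rgb(od), img, atol=1e-9)

    def test_nonpositive_background_rejected(self):
        with pytest.raises(ValueError):
            rgb_to_od(np.ones((2, 2, 3)), 0.0)


class TestBasisEstimation:
    def _mixed_image(self, basis, seed=0, n=4000):
        rng = np.random.default_rng(seed)
        h = rng.uniform(0, 1.0, n)
        e = rng.uniform(0, 0.8, n)
        # include nearly pure pixels of each stain so the extreme angles exist
        h[: n // 10] = rng.uniform(0.5, 1.0, n // 10)
        e[: n // 10] = 0.0
        h[n // 10 : n // 5] = 0.0
        e[n // 10 : n // 5] = rng.uniform(0.4, 0.8, n // 10)
        return synth_image(basis, h.reshape(-1, 80), e.reshape(-1, 80))

    @pytest.mark.parametrize("basis", [DEFAULT_HE_BASIS, ALT_BASIS], ids=["he", "alt"])
    def test_recovers_known_basis_within_2_degrees(self, basis):
        img = self._mixed_image(basis)
        est = estimate_stain_basis(rgb_to_od(img, 255.0))
        for k in range(2):
            assert _angle_deg(est.vectors[k], basis[k]) < 2.0

    def test_pure_background_errors(self):
        img = np.full((16, 16, 3), 250, dtype=np.uint8)
        with pytest.raises(StainEstimationError):
            estimate_stain_basis(rgb_to_od(img, 255.0))

    def test_channel_permutation_equivariance(self):
        img = self._mixed_image(DEFAULT_HE_BASIS)
        perm = [2, 0, 1]
        est = estimate_stain_basis(rgb_to_od(img, 255.0))
        est_p = estimate_stain_basis(rgb_to_od(img[..., perm], 255.0))
        permuted = est.vectors[:, perm]
        # compare as unordered sets (the H/E blue-channel convention may swap)
        d = min(
            max(_angle_deg(a, b) for a, b in zip(est_p.vectors, permuted)),
            max(_angle_deg(a, b) for a, b in zip(est_p.vectors, permuted[::-1])),
        )
        assert d < 0.5

    def test_pixel_order_invariance(self):
        img = self._mixed_image(DEFAULT_HE_BASIS)
        shuffled = img.reshape(-1, 3)[np.random.default_rng(0).permutation(img.shape[0] * img.shape[1])]
        est_a = estimate_stain_basis(rgb_to_od(img, 255.0))
        est_b = estimate_stain_basis(rgb_to_od(shuffled.reshape(img.shape), 255.0))
        assert np.allclose(est_a.vectors, est_b.vectors, atol=1e-6)


class TestSaturations:
    def test_exact_reconstruction_recovers_concentrations(self, rng):
        basis = StainBasis(DEFAULT_HE_BASIS.copy())
        s0 = rng.uniform(0, 1.2, size=(6, 7, 2))
        od = stain.ODImage(values=s0 @ basis.vectors, background_intensity=np.full(3, 255.0))
        sat = compute_saturations(od, basis)
        assert np.allclose(sat.concentrations, s0, atol=1e-9)

    def test_zero_od_gives_zero_saturation(self):
        basis = StainBasis(DEFAULT_HE_BASIS.copy())
        od = stain.ODImage(values=np.zeros((4, 4, 3)), background_intensity=np.full(3, 255.0))
        assert np.allclose(compute_saturations(od, basis).concentrations, 0.0)

    def test_least_squares_optimal_on_grid(self, rng):
        """Brute-force oracle: no grid perturbation of S improves the residual."""
        basis = StainBasis(DEFAULT_HE_BASIS.copy())
        od_val = (rng.uniform(0, 1, (1, 1, 2)) @ basis.vectors) + rng.normal(0, 0.05, (1, 1, 3))
        od = stain.ODImage(values=od_val, background_intensity=np.full(3, 255.0))
        s_star = compute_saturations(od, basis).concentrations[0, 0]

        def residual(s):
            return np.linalg.norm(od_val[0, 0] - s @ basis.vectors)

        base = residual(s_star)
        for dh in np.linspace(-0.2, 0.2, 9):
            for de in np.linspace(-0.2, 0.2, 9):
                assert base <= residual(s_star + np.array([dh, de])) + 1e-12


class TestNormalizeToTarget:
    def test_identity_when_bases_match(self, rng):
        basis = StainBasis(DEFAULT_HE_BASIS.copy())
        img = synth_image(DEFAULT_HE_BASIS, rng.uniform(0, 1, (20, 20)), rng.uniform(0, 0.5, (20, 20)))
        out = normalize_to_target(img, basis, basis)
        assert np.max(np.abs(out.astype(int) - img.astype(int))) <= 1

    def test_reduces_rmse_between_differently_stained_twins(self, rng):
        h = rng.uniform(0, 1, (30, 30))
        e = rng.uniform(0, 0.6, (30, 30))
        img_a = synth_image(DEFAULT_HE_BASIS, h, e)
        img_b = synth_image(ALT_BASIS, h, e)
        target = StainBasis(DEFAULT_HE_BASIS.copy())
        norm_a = normalize_to_target(img_a, StainBasis(DEFAULT_HE_BASIS.copy()), target)
        norm_b = normalize_to_target(img_b, StainBasis(ALT_BASIS.copy()), target)
        rmse_before = np.sqrt(np.mean((img_a.astype(float) - img_b.astype(float)) ** 2))
        rmse_after = np.sqrt(np.mean((norm_a.astype(float) - norm_b.astype(float)) ** 2))
        assert rmse_after < rmse_before

    def test_background_stays_background(self):
        img = np.full((10, 10, 3), 255, dtype=np.uint8)
        img[:5] = synth_image(DEFAULT_HE_BASIS, np.full((5, 10), 0.8), np.zeros((5, 10)))
        out = normalize_to_target(img, StainBasis(DEFAULT_HE_BASIS.copy()), StainBasis(ALT_BASIS.copy()))
        assert np.all(np.abs(out[5:].astype(int) - 255) <= 2)

    def test_idempotent(self, rng):
        src = StainBasis(ALT_BASIS.copy())
        tgt = StainBasis(DEFAULT_HE_BASIS.copy())
        img = synth_image(ALT_BASIS, rng.uniform(0, 1, (15, 15)), rng.uniform(0, 0.5, (15, 15)))
        once = normalize_to_target(img, src, tgt)
        twice = normalize_to_target(once, tgt, tgt)
        assert np.max(np.abs(twice.astype(int) - once.astype(int))) <= 1


class TestStandardize:
    def test_constant_image_maps_to_zero(self):
        stats = NormalizationStats(mu=np.full(3, 42.0), sigma=np.ones(3))
        assert np.allclose(standardize(np.full((4, 4, 3), 42.0), stats), 0.0)

    def test_invertible(self, rng):
        img = rng.uniform(0, 255, (6, 6, 3))
        stats = NormalizationStats(mu=np.array([10.0, 20.0, 30.0]), sigma=np.array([2.0, 3.0, 4.0]))
        assert np.allclose(unstandardize(standardize(img, stats), stats), img, atol=1e-9)

    def test_dataset_level_zero_mean_unit_sd(self, rng):
        imgs = [rng.uniform(0, 255, (8, 8, 3)) for _ in range(5)]
        stats = NormalizationStats.from_images(imgs)
        z = np.concatenate([standardize(im, stats).reshape(-1, 3) for im in imgs])
        assert np.all(np.abs(z.mean(axis=0)) < 1e-6)
        assert np.all(np.abs(z.std(axis=0) - 1.0) < 1e-6)

    def test_zero_sigma_rejected(self):
        stats = NormalizationStats(mu=np.zeros(3), sigma=np.zeros(3))
        with pytest.raises(ValueError):
            standardize(np.ones((2, 2, 3)), stats)
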