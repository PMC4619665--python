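"""SEMI densities, gradient-flow forces, assembly and global metrics."""

import numpy as np
import pytest
from scipy import integrate, ndimage

from vkreg.mesh import build_uniform_trimesh
from vkreg.pipeline import warp_image
from vkreg.semi import (
    SemiParams,
    UndefinedMetricError,
    assemble_external_force,
    local_joint_density,
    metric_mi,
    metric_msd,
    metric_nc,
    metric_nmi,
    parzen_kernel,
    semi_force_field,
    semi_similarity,
    spatial_weight,
)
from vkreg.synth import make_phantom


@pytest.fixture(scope="module")
def phantom():
    return ndimage.gaussian_filter(make_phantom(64, 64, 3), 1.0)


class TestParzenKernel:
    def test_peak_value(self):
        beta = 0.05
        assert parzen_kernel(0.0, 0.0, beta) == pytest.approx(1 / (2 * np.pi * beta**2))

    def test_symmetry(self, rng):
        a, b = rng.normal(size=(2, 20))
        np.testing.assert_allclose(parzen_kernel(a, b, 0.1), parzen_kernel(b, a, 0.1))

    def test_unit_integral(self):
        beta = 0.08
        val, _ = integrate.dblquad(
            lambda y2, y1: parzen_kernel(y1, y2, beta),
            -6 * beta, 6 * beta, -6 * beta, 6 * beta,
        )
        assert val == pytest.approx(1.0, abs=1e-6)

    def test_invalid_beta(self):
        with pytest.raises(ValueError):
            parzen_kernel(0.0, 0.0, 0.0)


class TestSpatialWeight:
    def test_peak(self):
        gamma = 3.75
        assert spatial_weight([5.0, 5.0], [5.0, 5.0], gamma) == pytest.approx(
            1 / (2 * np.pi * gamma**2)
        )

    def test_distance_gamma_is_e_fold(self):
        gamma = 2.5
        peak = spatial_weight([0.0, 0.0], [0.0, 0.0], gamma)
        # printed exponent is |x-x'|^2 / gamma^2 (no factor 2)
        assert spatial_weight([gamma, 0.0], [0.0, 0.0], gamma) == pytest.approx(
            peak * np.exp(-1.0)
        )

    def test_normalizer_translation_invariant(self):
        gamma = 3.0
        Y, X = np.mgrid[0:64, 0:64].astype(float)
        sums = []
        for c in ([25.0, 30.0], [30.0, 25.0], [32.0, 32.0]):
            w = spatial_weight(np.stack([X, Y], axis=-1), c, gamma)
            sums.append(w.sum())
        assert np.ptp(sums) / sums[0] < 1e-6


class TestLocalJointDensity:
    def test_constant_images_concentrated(self):
        p = SemiParams()
        img = np.full((32, 32), 0.5)
        dens = local_joint_density(img, img, (16, 16), p)
        w = p.bin_width
        assert dens.sum() * w**2 == pytest.approx(1.0, abs=1e-3)
        # mass concentrated around the (0.5, 0.5) bin
        i = np.unravel_index(np.argmax(dens), dens.shape)
        assert abs(p.bin_centers[i[0]] - 0.5) <= w
        assert abs(p.bin_centers[i[1]] - 0.5) <= w

    def test_normalization_random_patches(self, rng):
        p = SemiParams()
        for _ in range(10):
            a = rng.random((40, 40))
            b = rng.random((40, 40))
            c = rng.integers(8, 32, size=2)
            dens = local_joint_density(a, b, c, p)
            assert dens.min() >= 0
            assert dens.sum() * p.bin_width**2 == pytest.approx(1.0, abs=1e-3)

    def test_brute_force_summation_oracle(self):
        # two-level 9x9 patch: direct summation over all pixels, no shortcuts
        p = SemiParams(d=9, n_bins=8)
        rng = np.random.default_rng(0)
        a = (rng.random((9, 9)) > 0.5) * 0.75 + 0.25 / 2
        b = (rng.random((9, 9)) > 0.5) * 0.75 + 0.25 / 2
        center = (4, 4)
        dens = local_joint_density(a, b, center, p)

        # oracle: per-pixel normalized kernels, explicit double loop
        c = p.bin_centers
        w = p.bin_width
        P = np.zeros((p.n_bins, p.n_bins))
        wsum = 0.0
        for y in range(9):
            for x in range(9):
                g = np.exp(-((x - 4) ** 2 + (y - 4) ** 2) / p.gamma**2)
                ka = np.exp(-((a[y, x] - c) ** 2) / (2 * p.beta**2))
                kb = np.exp(-((b[y, x] - c) ** 2) / (2 * p.beta**2))
                P += g * np.outer(ka / ka.sum(), kb / kb.sum())
                wsum += g
        np.testing.assert_allclose(dens, P / wsum / w**2, rtol=1e-10)


class TestSemiForceField:
    def test_constant_images_zero_force(self):
        p = SemiParams()
        img = np.full((32, 32), 0.4)
        f = semi_force_field(img, img, np.zeros((32, 32, 2)), p)
        np.testing.assert_allclose(f, 0.0)

    def test_ascent_direction(self, phantom, rng):
        # a small step along the force must not decrease the SEMI similarity
        p = SemiParams()
        mesh = build_uniform_trimesh(64, 64, 17)
        flt = np.roll(phantom, 2, axis=1)
        u0 = np.zeros((64, 64, 2))
        f = semi_force_field(phantom, flt, u0, p, mesh=mesh)
        step = 0.25 / np.abs(f).max()
        centers = np.column_stack([rng.integers(12, 52, 20), rng.integers(12, 52, 20)])
        gains = []
        for cx, cy in centers:
            s0 = semi_similarity(phantom, flt, p, [(cx, cy)])
            s1 = semi_similarity(phantom, warp_image(flt, f * step), p, [(cx, cy)])
            gains.append(s1 - s0)
        assert np.mean(np.array(gains) > -1e-9) >= 0.9

    def test_near_equilibrium_force_small(self, phantom):
        p = SemiParams()
        mesh = build_uniform_trimesh(64, 64, 17)
        u0 = np.zeros((64, 64, 2))
        f_eq = np.linalg.norm(
            semi_force_field(phantom, phantom, u0, p, mesh=mesh), axis=-1
        ).mean()
        flt = np.roll(phantom, 5, axis=1)
        f_mis = np.linalg.norm(
            semi_force_field(phantom, flt, u0, p, mesh=mesh), axis=-1
        ).mean()
        assert f_eq < 0.05 * f_mis

    def test_zero_gradient_zero_force(self):
        p = SemiParams()
        ref = np.tile(np.linspace(0, 1, 32), (32, 1))
        flt = np.full((32, 32), 0.5)  # constant -> grad m = 0
        f = semi_force_field(ref, flt, np.zeros((32, 32, 2)), p)
        np.testing.assert_allclose(f, 0.0, atol=1e-12)

    def test_uniform_weights_match_global_parzen_gradient(self, phantom):
        # gamma -> inf and a window covering the image: spatially encoded
        # force must collapse to the classical global Parzen MI gradient
        n = 64
        p = SemiParams(d=4 * n, gamma=1e6, beta=1 / 32, n_bins=32)
        flt = np.roll(phantom, 3, axis=1)
        f = semi_force_field(phantom, flt, np.zeros((n, n, 2)), p)

        # independent oracle: flat global computation
        nb = p.n_bins
        c = p.bin_centers
        beta = p.beta

        def tables(img):
            y = img[..., None] - c
            raw = np.exp(-(y**2) / (2 * beta**2))
            S = raw.sum(-1, keepdims=True)
            draw = -(y / beta**2) * raw
            dS = draw.sum(-1, keepdims=True)
            return raw / S, (draw * S - raw * dS) / S**2

        phiR, dphiR = tables(phantom)
        phiM, dphiM = tables(flt)
        P = phiR.reshape(-1, nb).T @ phiM.reshape(-1, nb) / (n * n)
        pr, pm = P.sum(1), P.sum(0)
        L = 1 + np.log(np.maximum(P, 1e-12)) - np.log(
            np.maximum(np.outer(pr, pm), 1e-12)
        )
        gy, gx = np.gradient(flt)
        s = np.einsum("yxr,rm,yxm->yx", phiR, L, dphiM - dphiR) / (n * n)
        oracle = np.stack([s * gx, s * gy], axis=-1)
        denom = np.abs(oracle).max()
        assert np.abs(f - oracle).max() / denom < 1e-3


class TestAssembleExternalForce:
    def test_zero_field(self, small_mesh):
        R = assemble_external_force(small_mesh, np.zeros((10, 10, 2)))
        np.testing.assert_allclose(R.values, 0.0)

    def test_uniform_field_total(self):
        mesh = build_uniform_trimesh(33, 33, 5)
        field = np.zeros((33, 33, 2))
        field[..., 0] = 1.0
        R = assemble_external_force(mesh, field, force_weight=2.0)
        assert R.values[:, 0].sum() == pytest.approx(32 * 32 * 2.0, rel=1e-9)
        assert R.values[:, 1].sum() == pytest.approx(0.0, abs=1e-9)

    def test_linear_field_closed_form(self):
        # f = x on a one-cell mesh: integral of f * N_i has the closed form
        # A (2 f_i + f_j + f_k) / 12 per triangle (linear-times-linear)
        mesh = build_uniform_trimesh(33, 33, 2)
        field = np.zeros((33, 33, 2))
        field[..., 0] = np.arange(33)[None, :] / 32.0
        R = assemble_external_force(mesh, field)
        expected = np.zeros((4, 2))
        for el in range(2):
            fv = mesh.element_nodes(el)[:, 0] / 32.0
            for i, node in enumerate(mesh.elements[el]):
                others = fv.sum() - fv[i]
                expected[node, 0] += mesh.area[el] * (2 * fv[i] + others) / 12.0
        np.testing.assert_allclose(R.values, expected, rtol=2e-2, atol=0.3)


class TestMetrics:
    def test_identity(self, phantom):
        assert metric_msd(phantom, phantom) == 0.0
        assert metric_nc(phantom, phantom) == pytest.approx(1.0)
        assert metric_nmi(phantom, phantom, 64) == pytest.approx(2.0)

    def test_anticorrelation(self, phantom):
        assert metric_nc(phantom, -phantom + 1.0) == pytest.approx(-1.0)

    def test_independent_images_mi_near_zero(self):
        rng = np.random.default_rng(1)
        a = rng.random((256, 256))
        b = rng.random((256, 256))
        assert abs(metric_mi(a, b, 64)) < 0.05

    def test_nmi_bounds(self, rng):
        for _ in range(5):
            a = rng.random((32, 32))
            b = rng.random((32, 32))
            assert 1.0 <= metric_nmi(a, b, 16) <= 2.0

    def test_constant_image_undefined(self):
        const = np.full((16, 16), 0.3)
        img = np.random.default_rng(0).random((16, 16))
        with pytest.raises(UndefinedMetricError):
            metric_nc(const, img)
        with pytest.raises(UndefinedMetricError):
            metric_nmi(const, img)

    def test_msd_shift(self):
        a = np.zeros((8, 8))
        b = np.full((8, 8), 0.5)
        assert metric_msd(a, b) == pytest.approx(0.25)
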