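"""Spatial Gaussian kernels, derivatives and the convolution engine."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as hst
from scipy import ndimage, signal

from rfspace import (Image2D, SpatialCovariance, SpatialKernelSpec,
                     affine_gaussian_kernel, convolve,
                     directional_derivative_kernel, gaussian_derivative_kernel,
                     gaussian_kernel, laplacian_of_gaussian_kernel, smooth)
from rfspace.errors import ParameterError, SizeError, UnsupportedOrderError
from rfspace.fixtures import smooth_noise_texture, warp_affine


class TestSpatialCovariance:
    @given(lam2=hst.floats(0.5, 16.0), ratio=hst.floats(1.0, 8.0),
           theta=hst.floats(0.0, np.pi - 1e-6))
    def test_eigen_round_trip(self, lam2, ratio, theta):
        lam1 = lam2 * ratio
        cov = SpatialCovariance.from_eigen(lam1, lam2, theta)
        r1, r2, th = cov.eigen
        assert abs(r1 - lam1) < 1e-9 * lam1
        assert abs(r2 - lam2) < 1e-9 * lam1
        if ratio > 1.0 + 1e-6:
            # orientation only defined for anisotropic covariances
            assert min(abs(th - theta), np.pi - abs(th - theta)) < 1e-6
        rebuilt = SpatialCovariance.from_eigen(r1, r2, th)
        assert np.allclose(rebuilt.matrix, cov.matrix, atol=1e-12 * lam1)

    def test_rejects_indefinite(self):
        with pytest.raises(ParameterError):
            SpatialCovariance(np.array([[1.0, 2.0], [2.0, 1.0]]))


class TestGaussianKernel:
    def test_center_tap_closed_form(self):
        k = gaussian_kernel(2.0)
        assert k.values[k.origin] == pytest.approx(1.0 / (4 * np.pi), rel=1e-3)

    def test_unit_sum_and_rotational_symmetry(self):
        k = gaussian_kernel(4.0)
        assert k.values.sum() == pytest.approx(1.0, abs=1e-6)
        assert np.array_equal(k.values, np.rot90(k.values))

    def test_rejects_nonpositive_scale(self):
        with pytest.raises(ParameterError):
            gaussian_kernel(0.0)

    def test_semigroup_of_sampled_kernels(self):
        a = gaussian_kernel(1.0).values
        b = gaussian_kernel(3.0).values
        both = signal.convolve2d(a, b)
        direct = gaussian_kernel(4.0).values
        r = (both.shape[0] - direct.shape[0]) // 2
        embedded = np.zeros_like(both)
        embedded[r:r + direct.shape[0], r:r + direct.shape[1]] = direct
        assert np.abs(both - embedded).sum() < 1e-3


class TestDerivativeKernels:
    def test_odd_kernel_vanishes_on_axis(self):
        k = gaussian_derivative_kernel(SpatialKernelSpec(orders=(1, 0), scale=2.0))
        assert abs(k.values[k.origin]) < 1e-15

    def test_laplacian_center_closed_form(self):
        kxx = gaussian_derivative_kernel(SpatialKernelSpec(orders=(2, 0), scale=2.0))
        kyy = gaussian_derivative_kernel(SpatialKernelSpec(orders=(0, 2), scale=2.0))
        total = kxx.values[kxx.origin] + kyy.values[kyy.origin]
        assert total == pytest.approx(-1.0 / (4 * np.pi), rel=1e-3)
        klog = laplacian_of_gaussian_kernel(2.0)
        assert klog.values[klog.origin] == pytest.approx(-1.0 / (4 * np.pi), rel=1e-3)

    def test_quarter_turn_maps_x_to_y_derivative(self):
        kx_rot = gaussian_derivative_kernel(
            SpatialKernelSpec(orders=(1, 0), scale=2.0, direction=np.pi / 2))
        ky = gaussian_derivative_kernel(
            SpatialKernelSpec(orders=(0, 1), scale=2.0, direction=0.0))
        assert np.abs(kx_rot.values - ky.values).max() < 1e-12

    @pytest.mark.parametrize("orders", [(1, 0), (2, 1), (0, 3), (2, 2)])
    def test_derivative_zero_sum(self, orders):
        k = gaussian_derivative_kernel(SpatialKernelSpec(orders=orders, scale=3.0))
        assert abs(k.values.sum()) < 1e-6

    def test_order_beyond_four_rejected(self):
        with pytest.raises(UnsupportedOrderError):
            SpatialKernelSpec(orders=(3, 2), scale=2.0)


class TestAffineKernels:
    def test_isotropic_reduction_exact(self):
        cov = SpatialCovariance.isotropic(2.0)
        assert np.abs(affine_gaussian_kernel(cov).values
                      - gaussian_kernel(2.0).values).max() == 0.0

    @pytest.mark.parametrize("theta", [0.0, np.pi / 4, 2.0])
    def test_tap_mass_second_moment_recovers_sigma(self, theta):
        cov = SpatialCovariance.from_eigen(8.0, 2.0, theta)
        k = affine_gaussian_kernel(cov)
        x, y = k.grid()
        w = k.values
        measured = np.array([[(w * x * x).sum(), (w * x * y).sum()],
                             [(w * x * y).sum(), (w * y * y).sum()]])
        assert np.abs(measured - cov.matrix).max() < 0.02 * cov.matrix.max()

    def test_rotated_kernel_matches_resampled(self):
        k0 = affine_gaussian_kernel(SpatialCovariance.from_eigen(8.0, 2.0, 0.0))
        k45 = affine_gaussian_kernel(SpatialCovariance.from_eigen(8.0, 2.0, np.pi / 4))
        n = max(k45.values.shape + k0.values.shape)
        embedded = np.zeros((n, n))
        ry = (n - k0.values.shape[0]) // 2
        rx = (n - k0.values.shape[1]) // 2
        embedded[ry:ry + k0.values.shape[0], rx:rx + k0.values.shape[1]] = k0.values
        ry45 = (n - k45.values.shape[0]) // 2
        rx45 = (n - k45.values.shape[1]) // 2
        target = np.zeros((n, n))
        target[ry45:ry45 + k45.values.shape[0],
               rx45:rx45 + k45.values.shape[1]] = k45.values
        rotated = ndimage.rotate(embedded, -45.0, reshape=False, order=3)
        assert np.abs(target - rotated).max() < 0.05 * target.max()

    def test_directional_identity_isotropic(self):
        cov = SpatialCovariance.isotropic(3.0)
        kd = directional_derivative_kernel(cov, (1, 0), phi=0.0)
        kp = gaussian_derivative_kernel(SpatialKernelSpec(orders=(1, 0), scale=3.0))
        assert np.abs(kd.values - kp.values).max() < 1e-12

    def test_directional_derivative_zero_sum_and_antisymmetry(self):
        cov = SpatialCovariance.from_eigen(8.0, 2.0, np.pi / 6)
        k = directional_derivative_kernel(cov, (1, 0))   # phi defaults to theta
        assert abs(k.values.sum()) < 1e-6
        # antisymmetric under point reflection about the center
        assert np.abs(k.values + k.values[::-1, ::-1]).max() < 1e-12

    def test_directional_matches_finite_difference(self):
        cov = SpatialCovariance.from_eigen(8.0, 2.0, 0.0)
        k = directional_derivative_kernel(cov, (1, 0), phi=0.0)
        x, y = k.grid()
        S = cov.inverse
        h = 0.01

        def g(xx, yy):
            quad = S[0, 0] * xx * xx + 2 * S[0, 1] * xx * yy + S[1, 1] * yy * yy
            return np.exp(-0.5 * quad) / (2 * np.pi * np.sqrt(np.linalg.det(cov.matrix)))

        fd = (g(x + h / 2, y) - g(x - h / 2, y)) / h
        assert (np.linalg.norm(k.values - fd) / np.linalg.norm(fd)) < 0.01


class TestConvolve:
    def test_identity_kernel_exact(self, rng):
        img = rng.standard_normal((16, 16))
        from rfspace.spatial import Kernel2D
        out = convolve(img, Kernel2D(np.ones((1, 1))))
        assert np.array_equal(out, img)

    def test_constant_preserved_under_mirror(self):
        img = np.full((32, 32), 3.7)
        out = convolve(img, gaussian_kernel(4.0))
        assert np.abs(out - 3.7).max() < 1e-10

    @given(a=hst.floats(-3, 3), b=hst.floats(-3, 3))
    def test_linearity(self, a, b):
        rng = np.random.default_rng(7)
        f1 = rng.standard_normal((24, 24))
        f2 = rng.standard_normal((24, 24))
        k = gaussian_kernel(2.0)
        lhs = convolve(a * f1 + b * f2, k)
        rhs = a * convolve(f1, k) + b * convolve(f2, k)
        assert np.abs(lhs - rhs).max() < 1e-10 * (1 + abs(a) + abs(b))

    def test_oversized_kernel_rejected(self):
        with pytest.raises(SizeError):
            convolve(np.zeros((5, 5)), gaussian_kernel(16.0))

    def test_image2d_round_trips_type(self):
        img = Image2D(np.zeros((8, 8)))
        assert isinstance(convolve(img, gaussian_kernel(1.0)), Image2D)


class TestScaleSpaceAxioms:
    def test_cascade_matches_direct_smoothing(self, rng):
        img = smooth_noise_texture((96, 96), correlation_scale=4.0, seed=3)
        direct = smooth(img, 8.0, radius_factor=6.0)
        two_step = smooth(smooth(img, 3.0, radius_factor=6.0), 5.0, radius_factor=6.0)
        err = np.abs(direct - two_step)[20:-20, 20:-20]
        assert err.max() < 1e-6 * (img.max() - img.min())

    def test_diffusion_residual_converges(self):
        img = smooth_noise_texture((96, 96), correlation_scale=4.0, seed=5)
        s = 4.0
        lap = (convolve(img, laplacian_of_gaussian_kernel(s, radius_factor=6.0)))

        def residual(delta):
            ds = (smooth(img, s + delta, radius_factor=6.0)
                  - smooth(img, s, radius_factor=6.0)) / delta
            err = (ds - 0.5 * lap)[20:-20, 20:-20]
            return np.linalg.norm(err) / np.linalg.norm(lap[20:-20, 20:-20])

        coarse, fine = residual(0.1 * s), residual(0.01 * s)
        assert fine < coarse
        assert fine < 0.01

    def test_non_enhancement_of_extrema(self):
        img = smooth_noise_texture((96, 96), correlation_scale=6.0, seed=11)
        a = smooth(img, 2.0, radius_factor=6.0)
        b = smooth(a, 2.0, radius_factor=6.0)
        m = 18
        interior = a[m:-m, m:-m]
        is_max = np.ones_like(interior, dtype=bool)
        is_min = np.ones_like(interior, dtype=bool)
        for dy in (-1, 0, 1):
            for dx in (-1, 0, 1):
                if dx == dy == 0:
                    continue
                nb = a[m + dy:a.shape[0] - m + dy, m + dx:a.shape[1] - m + dx]
                is_max &= interior > nb
                is_min &= interior < nb
        diff = b[m:-m, m:-m] - interior
        assert is_max.any() and is_min.any()
        assert diff[is_max].max() <= 1e-9
        assert diff[is_min].min() >= -1e-9

    def test_affine_covariance_of_smoothing(self):
        # out = in ∘ A smoothed with Sigma' equals (in smoothed with A Sigma' Aᵀ) ∘ A
        tex = smooth_noise_texture((129, 129), correlation_scale=4.0, seed=2)
        A = np.array([[1.5, 0.4], [0.1, 0.8]])       # condition number < 4
        sig_p = SpatialCovariance.isotropic(4.0)
        sig = SpatialCovariance(A @ sig_p.matrix @ A.T)
        warped = warp_affine(tex, A)
        lhs = convolve(warped, affine_gaussian_kernel(sig_p))
        rhs = warp_affine(convolve(tex, affine_gaussian_kernel(sig)), A)
        m = 30
        err = (lhs - rhs)[m:-m, m:-m]
        ref = rhs[m:-m, m:-m]
        assert np.linalg.norm(err) / np.linalg.norm(ref) < 0.02
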