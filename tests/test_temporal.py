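"""Temporal cascades, recursive updating, and spatio-temporal kernels."""

import numpy as np
import pytest

from rfspace import (STCovariance, STKernelSpec, SpatialCovariance,
                     cascade_stream, convolve_sequence, exp_cascade_kernel,
                     galilean_warp, gaussian_st_kernel,
                     recursive_temporal_update, st_derivative_kernel,
                     time_causal_st_kernel, translating_sequence)
from rfspace.errors import ParameterError
from rfspace.fixtures import gaussian_blob


class TestExpCascade:
    def test_single_exponential_density_and_causality(self):
        k = exp_cascade_kernel((2.0,), dt=0.01)
        assert k.taps[0] / k.dt == pytest.approx(0.5, rel=0.01)
        assert np.all(k.times >= 0)
        assert k.taps.sum() == pytest.approx(1.0, abs=1e-9)

    def test_variance_additivity(self):
        k = exp_cascade_kernel((1.0, 2.0))
        assert k.variance() == pytest.approx(5.0, rel=0.02)

    def test_mean_additivity(self):
        k = exp_cascade_kernel((1.0, 1.0, 1.0, 1.0))
        assert k.mean() == pytest.approx(4.0, rel=0.02)

    def test_empty_list_rejected(self):
        with pytest.raises(ParameterError):
            exp_cascade_kernel(())


class TestRecursiveUpdate:
    def test_constant_steady_state(self):
        out = 0.0
        for _ in range(400):
            out = recursive_temporal_update(out, 3.2, mu=2.0, dt=0.5)
        assert out == pytest.approx(3.2, abs=1e-10)

    def test_impulse_response_closed_form(self):
        mu, dt = 2.0, 0.01
        n = int(5.0 / dt)
        response = np.empty(n)
        state = 0.0
        for i in range(n):
            state = recursive_temporal_update(state, 1.0 if i == 0 else 0.0, mu, dt)
            response[i] = state
        t = np.arange(n) * dt
        for t_check in (1.0, 2.0, 4.0):
            i = int(round(t_check / dt))
            expected = 0.5 * np.exp(-t_check / 2.0) * dt
            assert response[i] == pytest.approx(expected, rel=0.01)

    def test_cascaded_integrators_match_convolution(self, rng):
        x = rng.standard_normal(300)
        streamed = cascade_stream(x, (2.0, 4.0), dt=1.0)
        taps = exp_cascade_kernel((2.0, 4.0), dt=1.0, align="grid").taps
        batch = np.convolve(x, taps)[:x.size]
        assert np.abs(streamed - batch).max() < 1e-6

    def test_streaming_over_fields(self, rng):
        seq = rng.standard_normal((50, 8, 8))
        streamed = cascade_stream(seq, (1.5,), dt=1.0, axis=0)
        taps = exp_cascade_kernel((1.5,), dt=1.0, align="grid").taps
        batch = np.apply_along_axis(lambda s: np.convolve(s, taps)[:s.size], 0, seq)
        assert np.abs(streamed - batch).max() < 1e-10


class TestSTKernels:
    def _cov(self, v=(0.0, 0.0), s=2.0, lt=2.0):
        return STCovariance(SpatialCovariance.isotropic(s), v, lt)

    def test_zero_velocity_separable(self):
        kern = gaussian_st_kernel(STKernelSpec(covariance=self._cov()))
        spatial = kern.values.sum(axis=0)
        temporal = kern.values.sum(axis=(1, 2))
        outer = temporal[:, None, None] * spatial[None] / kern.values.sum()
        assert np.abs(kern.values - outer).max() < 1e-10

    def test_covariance_matrix_galilean_structure(self):
        cov = self._cov(v=(0.5, -0.25), s=3.0, lt=2.0)
        m = cov.matrix()
        assert np.allclose(m, m.T)
        assert m[0, 2] == pytest.approx(2.0 * 0.5)
        assert m[1, 2] == pytest.approx(2.0 * -0.25)
        assert m[0, 0] == pytest.approx(3.0 + 2.0 * 0.25)
        assert np.linalg.eigvalsh(m)[0] > 0

    def test_velocity_kernel_is_sheared_static_kernel(self):
        v = (0.5, 0.0)
        kv = gaussian_st_kernel(STKernelSpec(covariance=self._cov(v=v)))
        unsheared = galilean_warp_centered(kv.values, kv.times, v)
        k0 = gaussian_st_kernel(STKernelSpec(covariance=self._cov()))
        # compare on the k0 support, centered inside kv
        ct = np.where(kv.times == 0)[0][0]
        ct0 = np.where(k0.times == 0)[0][0]
        ry = (kv.values.shape[1] - k0.values.shape[1]) // 2
        rx = (kv.values.shape[2] - k0.values.shape[2]) // 2
        sub = unsheared[ct - ct0:ct + ct0 + 1,
                        ry:ry + k0.values.shape[1],
                        rx:rx + k0.values.shape[2]]
        assert np.abs(sub - k0.values).max() < 0.02 * k0.values.max()

    def test_spatial_marginal_is_temporal_gaussian(self):
        lt = 2.0
        kern = gaussian_st_kernel(STKernelSpec(covariance=self._cov(lt=lt)))
        marginal = kern.values.sum(axis=(1, 2))
        expected = np.exp(-kern.times ** 2 / (2 * lt)) / np.sqrt(2 * np.pi * lt)
        expected /= expected.sum()
        assert np.abs(marginal - expected).max() < 0.01 * expected.max()

    def test_causal_kernel_zero_before_stimulus(self):
        spec = STKernelSpec(covariance=self._cov(v=(1.0, 0.0)), causal=True,
                            time_constants=(1.0, 2.0))
        kern = time_causal_st_kernel(spec)
        assert np.all(kern.values[kern.times < 0] == 0.0)

    def test_causal_separable_at_zero_velocity(self):
        spec = STKernelSpec(covariance=self._cov(), causal=True,
                            time_constants=(2.0,))
        kern = time_causal_st_kernel(spec)
        spatial = kern.values.sum(axis=0)
        temporal = kern.values.sum(axis=(1, 2))
        outer = temporal[:, None, None] * spatial[None] / kern.values.sum()
        assert np.abs(kern.values - outer).max() < 1e-10

    def test_causal_centroid_tracks_velocity(self):
        spec = STKernelSpec(covariance=self._cov(v=(1.0, 0.0)), causal=True,
                            time_constants=(2.0,))
        kern = time_causal_st_kernel(spec)
        rx = (kern.values.shape[2] - 1) // 2
        x = np.arange(kern.values.shape[2]) - rx
        for i, t in enumerate(kern.times):
            frame = kern.values[i]
            if t < 0 or frame.sum() < 1e-4 * kern.values.max():
                continue
            centroid = (frame.sum(axis=0) * x).sum() / frame.sum()
            assert abs(centroid - t * 1.0) < 0.05


class TestSTDerivatives:
    def _cov(self, v=(0.0, 0.0)):
        return STCovariance(SpatialCovariance.isotropic(2.0), v, 2.0)

    def test_zero_velocity_transport_derivative_is_plain_dt(self):
        spec = STKernelSpec(covariance=self._cov(), temporal_order=1)
        kern = st_derivative_kernel(spec)
        # must factor into (spatial Gaussian) x (temporal Gaussian derivative)
        lt = 2.0
        t = kern.times
        dtemp = -(t / lt) * np.exp(-t ** 2 / (2 * lt)) / np.sqrt(2 * np.pi * lt)
        spatial = gaussian_st_kernel(STKernelSpec(covariance=self._cov())).values.sum(axis=0)
        outer = dtemp[:, None, None] * spatial[None]
        outer -= outer.mean()
        # the zero-order marginal is renormalized after truncation, so the
        # two constructions agree up to that (~1e-4) normalization factor
        assert np.abs(kern.values - outer).max() < 1e-3 * np.abs(kern.values).max()

    def test_derivative_kernel_zero_sum(self):
        for spec in (STKernelSpec(covariance=self._cov((0.5, 0.0)), temporal_order=1),
                     STKernelSpec(covariance=self._cov(), spatial_orders=(1, 1)),
                     STKernelSpec(covariance=self._cov(), spatial_orders=(2, 0),
                                  temporal_order=2)):
            assert abs(st_derivative_kernel(spec).values.sum()) < 1e-6

    def test_transport_derivative_annihilates_comoving_pattern(self):
        v = (0.5, 0.0)
        seq = translating_sequence((48, 48), 24, v, t0=8.0)
        adapted = st_derivative_kernel(
            STKernelSpec(covariance=self._cov(v), temporal_order=1))
        plain = st_derivative_kernel(
            STKernelSpec(covariance=self._cov(), temporal_order=1))
        r_adapted = convolve_sequence(seq, adapted)
        r_plain = convolve_sequence(seq, plain)
        core = (slice(8, 16), slice(12, 36), slice(12, 36))
        assert (np.abs(r_adapted[core]).max()
                < 1e-3 * np.abs(r_plain[core]).max() + 1e-12)


class TestGalileanCovariance:
    def test_velocity_adapted_responses_commute_with_warp(self, rng):
        # f'(x,t) = f(x-u·t, t); (v+u)-kernel on f' == warped v-kernel response
        from rfspace.fixtures import smooth_noise_texture
        u = (0.5, 0.0)
        base = smooth_noise_texture((44, 44), correlation_scale=3.0, seed=9)
        f = np.stack([base] * 16)
        f_prime = galilean_warp(f, (-u[0], -u[1]))
        cov_u = STCovariance(SpatialCovariance.isotropic(2.0), u, 2.0)
        cov_0 = STCovariance(SpatialCovariance.isotropic(2.0), (0.0, 0.0), 2.0)
        r_prime = convolve_sequence(f_prime, gaussian_st_kernel(STKernelSpec(covariance=cov_u)))
        r_base = convolve_sequence(f, gaussian_st_kernel(STKernelSpec(covariance=cov_0)))
        r_expected = galilean_warp(r_base, (-u[0], -u[1]))
        core = (slice(5, 11), slice(12, 32), slice(12, 32))
        num = np.linalg.norm(r_prime[core] - r_expected[core])
        den = np.linalg.norm(r_expected[core])
        assert num / den < 0.03


def galilean_warp_centered(values, times, v):
    """Unshear kernel slabs: out(x, t) = in(x + v·t, t) about the center tap."""
    from scipy import ndimage
    out = np.empty_like(values)
    cy = (values.shape[1] - 1) / 2.0
    cx = (values.shape[2] - 1) / 2.0
    y, x = np.mgrid[:values.shape[1], :values.shape[2]].astype(float)
    for i, t in enumerate(times):
        out[i] = ndimage.map_coordinates(values[i],
                                         [y + v[1] * t, x + v[0] * t],
                                         order=3, mode="constant")
    return out
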