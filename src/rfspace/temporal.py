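"""Temporal and spatio-temporal smoothing kernels with velocity adaptation.

Two temporal smoothers are provided:

* a non-causal temporal Gaussian with variance ``lambda_t`` and optional
  delay ``delta`` — convenient for batch analysis, but it has access to the
  future;
* a time-causal cascade of truncated exponential filters
  (1/mu_k) exp(-t/mu_k) for t >= 0, coupled in cascade. The composed kernel
  has mean sum(mu_k) and variance sum(mu_k²), is exactly zero for t < 0, and
  is time-recursive: it can be computed by streaming first-order integrator
  updates without storing the past.

Spatio-temporal kernels combine an affine spatial Gaussian translating with
image velocity v (pixels/frame) with one of the temporal smoothers; the
spatio-temporal covariance has the Galilean structure
[[Sigma + l_t v vᵀ, l_t v], [l_t vᵀ, l_t]]. Velocity-adapted temporal
differentiation is the transport derivative  d/dt̄ = v·∇ + d/dt, which
annihilates any pattern translating exactly at v.

Kernel arrays are indexed (t, y, x) with the time axis stored on a symmetric
integer grid around t = 0, so causal kernels carry explicit zero taps at
negative times.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.polynomial import polynomial as npoly

from .errors import ParameterError, SizeError, UnsupportedOrderError
from .spatial import (DEFAULT_RADIUS_FACTOR, MAX_ORDER, SpatialCovariance,
                      _derivative_polynomial)

MAX_TEMPORAL_ORDER = 2


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class ImageSequence:
    """Dense 2+1-D stimulus f(x, y, t), frames indexed (t, row, col)."""

    frames: np.ndarray
    frame_spacing: float = 1.0
    pixel_spacing: float = 1.0

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[0] < 3:
            raise ParameterError("ImageSequence requires >= 3 frames of 2-D data")
        if not np.all(np.isfinite(self.frames)):
            raise ParameterError("ImageSequence values must be finite")
        if self.frame_spacing <= 0 or self.pixel_spacing <= 0:
            raise ParameterError("spacings must be positive")

    @property
    def shape(self):
        return self.frames.shape


@dataclass(frozen=True)
class TemporalKernelSpec:
    """Temporal smoother selector: non-causal Gaussian or exponential cascade."""

    kind: str = "gaussian_noncausal"
    temporal_variance: float | None = None
    delay: float = 0.0
    time_constants: tuple = ()

    def __post_init__(self):
        if self.kind not in ("gaussian_noncausal", "exp_cascade"):
            raise ParameterError(f"unknown temporal kind {self.kind!r}")
        if self.kind == "gaussian_noncausal":
            if self.temporal_variance is None or not self.temporal_variance > 0:
                raise ParameterError("gaussian temporal kernel needs temporal_variance > 0")
        else:
            if len(self.time_constants) < 1 or any(m <= 0 for m in self.time_constants):
                raise ParameterError("exp_cascade needs at least one positive time constant")


@dataclass(frozen=True)
class STCovariance:
    """Spatio-temporal covariance: spatial Sigma, velocity v, temporal variance."""

    spatial: SpatialCovariance
    velocity: tuple = (0.0, 0.0)
    temporal_variance: float = 1.0

    def __post_init__(self):
        if not self.temporal_variance > 0:
            raise ParameterError("temporal_variance must be positive")
        if len(self.velocity) != 2:
            raise ParameterError("velocity must be (vx, vy)")
        if np.linalg.eigvalsh(self.matrix())[0] <= 0:
            raise ParameterError("spatio-temporal covariance must be positive definite")

    def matrix(self) -> np.ndarray:
        """3x3 covariance over (x, y, t) induced by the Galilean shear."""
        v = np.asarray(self.velocity, dtype=float)
        lt = float(self.temporal_variance)
        m = np.empty((3, 3))
        m[:2, :2] = self.spatial.matrix + lt * np.outer(v, v)
        m[:2, 2] = lt * v
        m[2, :2] = lt * v
        m[2, 2] = lt
        return m


@dataclass(frozen=True)
class STKernelSpec:
    """One spatio-temporal receptive field: spatial orders (m1, m2) along
    (phi, phi+pi/2), temporal order n, causal or non-causal smoother."""

    covariance: STCovariance
    spatial_orders: tuple = (0, 0)
    temporal_order: int = 0
    causal: bool = False
    delay: float = 0.0
    time_constants: tuple = ()
    direction: float | None = None

    def __post_init__(self):
        m1, m2 = self.spatial_orders
        if m1 + m2 > MAX_ORDER:
            raise UnsupportedOrderError(f"spatial order {m1 + m2} > {MAX_ORDER}")
        if self.temporal_order > MAX_TEMPORAL_ORDER:
            raise UnsupportedOrderError(
                f"temporal order {self.temporal_order} > {MAX_TEMPORAL_ORDER}")
        if self.causal and not self.time_constants:
            raise ParameterError("causal spatio-temporal kernel needs time_constants")

    @property
    def phi(self) -> float:
        if self.direction is not None:
            return float(self.direction)
        return self.covariance.spatial.eigen[2]


@dataclass
class TemporalKernel1D:
    """Sampled 1-D temporal kernel: taps summing to 1 at times ``times``."""

    taps: np.ndarray
    times: np.ndarray
    dt: float
    causal: bool = True

    def mean(self) -> float:
        return float(np.sum(self.taps * self.times) / np.sum(self.taps))

    def variance(self) -> float:
        m = self.mean()
        return float(np.sum(self.taps * (self.times - m) ** 2) / np.sum(self.taps))


@dataclass
class STKernel3D:
    """Sampled 3-D kernel indexed (t, y, x); ``times`` gives the time of each
    slab (symmetric integer grid around 0, zeros at t < 0 for causal kernels)."""

    values: np.ndarray
    times: np.ndarray
    order: int = 0

    @property
    def support_radius(self):
        return tuple((n - 1) // 2 for n in self.values.shape)


# ---------------------------------------------------------------------------
# time-causal cascade
# ---------------------------------------------------------------------------

def exp_cascade_kernel(time_constants, dt: float | None = None,
                       align: str = "midpoint") -> TemporalKernel1D:
    """Cascade of truncated exponential filters with the given time constants.

    The sampled taps are the impulse response of the cascade of exact-step
    first-order integrators (decay e^{-dt/mu} per step), which equals the
    midpoint-sampled, renormalized continuous cascade. With
    ``align='midpoint'`` tap k of a K-stage cascade sits at
    t = (k + K/2)·dt, giving O(dt²) errors in mean (≈ sum mu_k) and variance
    (≈ sum mu_k²); ``align='grid'`` uses t = k·dt, the alignment produced by
    streaming updates on a frame grid.

    dt defaults to min(1, min(mu)/4).
    """
    mus = [float(m) for m in time_constants]
    if not mus:
        raise ParameterError("need at least one time constant")
    if any(m <= 0 for m in mus):
        raise ParameterError("time constants must be positive")
    if dt is None:
        dt = min(1.0, min(mus) / 4.0)
    if dt <= 0:
        raise ParameterError("dt must be positive")
    taps = np.ones(1)
    for mu in mus:
        a = np.exp(-dt / mu)
        n = int(np.ceil(-30.0 / np.log(a))) + 1  # tail mass a^n < 1e-13
        stage = (1.0 - a) * a ** np.arange(n)
        taps = np.convolve(taps, stage)
    taps = taps / taps.sum()
    if align == "midpoint":
        times = (np.arange(taps.size) + 0.5 * len(mus)) * dt
    elif align == "grid":
        times = np.arange(taps.size) * dt
    else:
        raise ParameterError(f"unknown align {align!r}")
    return TemporalKernel1D(taps=taps, times=times, dt=dt, causal=True)


def recursive_temporal_update(previous_output, new_input, mu: float, dt: float = 1.0):
    """One exact-exponential first-order integrator step.

    out = a·previous + (1-a)·input with a = e^{-dt/mu}: unit DC gain and
    unconditional stability for any mu, dt > 0.
    """
    if mu <= 0 or dt <= 0:
        raise ParameterError("mu and dt must be positive")
    a = np.exp(-dt / mu)
    return a * np.asarray(previous_output, dtype=float) \
        + (1.0 - a) * np.asarray(new_input, dtype=float)


def cascade_stream(signal, time_constants, dt: float = 1.0, axis: int = 0):
    """Run the integrator cascade over a sampled signal along ``axis``.

    Equivalent to causal convolution with ``exp_cascade_kernel`` taps at the
    same dt (grid alignment); buffers start at zero.
    """
    x = np.moveaxis(np.asarray(signal, dtype=float), axis, 0)
    out = np.empty_like(x)
    states = [np.zeros(x.shape[1:]) for _ in time_constants]
    for i in range(x.shape[0]):
        cur = x[i]
        for k, mu in enumerate(time_constants):
            states[k] = recursive_temporal_update(states[k], cur, mu, dt)
            cur = states[k]
        out[i] = cur
    return np.moveaxis(out, 0, axis)


# ---------------------------------------------------------------------------
# temporal Gaussian
# ---------------------------------------------------------------------------

def _temporal_gaussian_taps(lambda_t: float, delay: float, order: int, t: np.ndarray):
    """n-th derivative of the delayed temporal Gaussian, sampled at t."""
    if lambda_t <= 0:
        raise ParameterError("temporal variance must be positive")
    u = t - delay
    g = np.exp(-u * u / (2.0 * lambda_t)) / np.sqrt(2.0 * np.pi * lambda_t)
    if order == 0:
        return g
    # d^n/du^n g = (-1/sqrt(l))^n He_n(u/sqrt(l)) g  (probabilists' Hermite)
    z = u / np.sqrt(lambda_t)
    he = np.polynomial.hermite_e.hermeval(z, [0.0] * order + [1.0])
    return (-1.0 / np.sqrt(lambda_t)) ** order * he * g


def _causal_taps_on_grid(time_constants, n_frames: int):
    """Per-frame cascade taps h(0..n_frames-1) (grid alignment, dt = 1)."""
    k = exp_cascade_kernel(time_constants, dt=1.0, align="grid")
    taps = np.zeros(n_frames)
    m = min(n_frames, k.taps.size)
    taps[:m] = k.taps[:m]
    return taps


def _temporal_backward_diff(taps: np.ndarray, order: int):
    """Backward differences preserve exact causality (zero taps stay zero)."""
    for _ in range(order):
        taps = taps - np.concatenate([[0.0], taps[:-1]])
    return taps


# ---------------------------------------------------------------------------
# spatio-temporal kernels
# ---------------------------------------------------------------------------

def _st_grid(spec: STKernelSpec, radius_factor: float):
    cov = spec.covariance
    vx, vy = cov.velocity
    if spec.causal:
        t_max = int(np.ceil(sum(spec.time_constants)
                            + radius_factor * np.sqrt(sum(m * m for m in spec.time_constants))))
    else:
        sig_t = np.sqrt(cov.temporal_variance)
        t_max = int(np.ceil(abs(spec.delay) + radius_factor * sig_t))
    t_max = max(t_max, 1)
    sx, sy = cov.spatial.marginal_stds()
    rx = max(1, int(np.ceil(radius_factor * sx + abs(vx) * t_max)))
    ry = max(1, int(np.ceil(radius_factor * sy + abs(vy) * t_max)))
    t = np.arange(-t_max, t_max + 1, dtype=float)
    y, x = np.mgrid[-ry:ry + 1, -rx:rx + 1].astype(float)
    return t, y, x


def _spatial_factor(spec: STKernelSpec, x, y, t):
    """Velocity-translating (affine-derivative) spatial factor at each frame."""
    cov = spec.covariance.spatial
    vx, vy = spec.covariance.velocity
    S = cov.inverse
    norm = 1.0 / (2.0 * np.pi * np.sqrt(np.linalg.det(cov.matrix)))
    order = spec.spatial_orders[0] + spec.spatial_orders[1]
    poly = (_derivative_polynomial(cov, spec.spatial_orders, spec.phi)
            if order else None)
    out = np.empty((t.size,) + x.shape)
    for i, ti in enumerate(t):
        xs = x - vx * ti
        ys = y - vy * ti
        quad = S[0, 0] * xs * xs + 2 * S[0, 1] * xs * ys + S[1, 1] * ys * ys
        g = norm * np.exp(-0.5 * quad)
        if poly is not None:
            g = g * npoly.polyval2d(xs, ys, poly)
        out[i] = g
    return out


def _temporal_factor(spec: STKernelSpec, t: np.ndarray):
    if spec.causal:
        n_pos = int(t.max()) + 1
        pos = _causal_taps_on_grid(spec.time_constants, n_pos)
        pos = _temporal_backward_diff(pos, spec.temporal_order)
        taps = np.zeros(t.size)
        taps[t >= 0] = pos
        return taps
    return _temporal_gaussian_taps(spec.covariance.temporal_variance,
                                   spec.delay, spec.temporal_order, t)


def _finalize_st(values, t, spec: STKernelSpec) -> STKernel3D:
    order = spec.spatial_orders[0] + spec.spatial_orders[1] + spec.temporal_order
    if order == 0:
        values = values / values.sum()
    else:
        if spec.causal:
            # mean-correct over the causal support only, so t<0 taps stay exactly zero
            mask = t >= 0
            values[mask] = values[mask] - values[mask].sum() / values[mask].size
        else:
            values = values - values.mean()
    return STKernel3D(values=values, times=t, order=order)


def gaussian_st_kernel(spec: STKernelSpec,
                       radius_factor: float = DEFAULT_RADIUS_FACTOR) -> STKernel3D:
    """Non-causal zero-order spatio-temporal Gaussian.

    Sampled as g(x - v t; Sigma) · g1(t - delta; lambda_t): a 3-D Gaussian
    with the Galilean covariance structure and mean (delta·v, delta); exactly
    space-time separable when v = 0.
    """
    if spec.causal:
        raise ParameterError("use time_causal_st_kernel for causal specs")
    base = STKernelSpec(covariance=spec.covariance, spatial_orders=(0, 0),
                        temporal_order=0, causal=False, delay=spec.delay,
                        direction=spec.direction)
    t, y, x = _st_grid(base, radius_factor)
    values = _spatial_factor(base, x, y, t) * _temporal_factor(base, t)[:, None, None]
    return _finalize_st(values, t, base)


def time_causal_st_kernel(spec: STKernelSpec,
                          radius_factor: float = DEFAULT_RADIUS_FACTOR) -> STKernel3D:
    """Time-causal zero-order kernel: g(x - v t; Sigma) · exp-cascade(t).

    Exactly zero for every t < 0 (a receptive field cannot access the
    future); one tap per frame along the time axis.
    """
    if not spec.causal:
        raise ParameterError("spec.causal must be True")
    base = STKernelSpec(covariance=spec.covariance, spatial_orders=(0, 0),
                        temporal_order=0, causal=True,
                        time_constants=tuple(spec.time_constants),
                        direction=spec.direction)
    t, y, x = _st_grid(base, radius_factor)
    values = _spatial_factor(base, x, y, t) * _temporal_factor(base, t)[:, None, None]
    return _finalize_st(values, t, base)


def st_derivative_kernel(spec: STKernelSpec,
                         radius_factor: float = DEFAULT_RADIUS_FACTOR) -> STKernel3D:
    """Spatio-temporal derivative kernel.

    Applies the directional spatial derivatives along (phi, phi+pi/2) and the
    velocity-adapted temporal derivative d/dt̄ = vx ∂x + vy ∂y + ∂t (n times)
    to the zero-order kernel. Because d/dt̄ annihilates the sheared spatial
    factor g(x - v t; Sigma), the result factorizes into the spatial
    derivative factor (evaluated at x - v t) times the n-th plain temporal
    derivative of the temporal smoother.
    """
    t, y, x = _st_grid(spec, radius_factor)
    values = _spatial_factor(spec, x, y, t) * _temporal_factor(spec, t)[:, None, None]
    return _finalize_st(values, t, spec)


# ---------------------------------------------------------------------------
# convolution over sequences
# ---------------------------------------------------------------------------

def convolve_sequence(seq, kernel: STKernel3D, boundary: str = "mirror"):
    """Convolve an image sequence with a sampled 3-D kernel (same size out)."""
    from scipy import signal

    frames = seq.frames if isinstance(seq, ImageSequence) else np.asarray(seq, dtype=float)
    kv = kernel.values
    modes = {"mirror": "reflect", "constant": "constant", "replicate": "edge"}
    if boundary not in modes:
        raise ParameterError(f"unknown boundary mode {boundary!r}")
    radii = tuple((k - 1) // 2 for k in kv.shape)
    if any(r >= n for r, n in zip(radii, frames.shape)):
        raise SizeError(f"kernel {kv.shape} larger than padded sequence {frames.shape}")
    padded = np.pad(frames, tuple((r, r) for r in radii), mode=modes[boundary])
    out = signal.fftconvolve(padded, kv, mode="valid")
    if isinstance(seq, ImageSequence):
        return ImageSequence(out, frame_spacing=seq.frame_spacing,
                             pixel_spacing=seq.pixel_spacing)
    return out
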