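"""Second-moment (structure tensor) measurement and affine shape adaptation.

The second-moment matrix is the Gaussian-weighted average of outer products
of first-order derivative responses,

    mu = w(.; s_int) * [Lx² LxLy; LxLy Ly²],

with a local scale for differentiation and an integration scale for the
averaging window. Its affine extension computes the derivatives with an
affine Gaussian of covariance Sigma_local and averages with an affine window
Sigma_int = r²·Sigma_local (fixed coupling ratio r).

Affine shape adaptation iterates Sigma toward the fixed point Sigma ∝ mu⁻¹;
at the fixed point the second moment measured in the normalized frame is
isotropic, and measurements there are affinely invariant up to an overall
scale and a free rotation. The normalizing transform is proportional to the
principal square root mu^{1/2}, normalized to unit determinant (the overall
size is handled by the scalar scale channel).

Warp convention throughout: out(x) = in(A x) (pull-back); under this map the
second moments at corresponding points with matched windows are related by
mu_out = Aᵀ mu_in A.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, signal

from .errors import (ConvergenceError, DegeneracyError, DomainError,
                     ParameterError)
from .spatial import (DEFAULT_RADIUS_FACTOR, SpatialCovariance,
                      SpatialKernelSpec, _values_of, affine_gaussian_kernel,
                      gaussian_derivative_kernel)

DEFAULT_INTEGRATION_RATIO = 2.0


@dataclass
class SecondMoment2D:
    """Measured 2x2 second-moment matrix with its measurement scales."""

    mu: np.ndarray
    local: SpatialCovariance
    integration: SpatialCovariance

    def __post_init__(self):
        self.mu = np.asarray(self.mu, dtype=float)
        if self.mu.shape != (2, 2):
            raise ParameterError("second moment must be 2x2")
        if np.linalg.eigvalsh(0.5 * (self.mu + self.mu.T))[0] < -1e-10 * max(
                1.0, np.trace(self.mu)):
            raise ParameterError("second moment must be PSD")


@dataclass
class AffineFrame:
    """Result of affine shape adaptation.

    ``transform`` is the unit-determinant normalizing transform ∝ mu^{1/2}
    (forward: it maps image coordinates to the isotropized frame);
    ``fixed_point_residual`` is the isotropy measure
    lambda_max/lambda_min - 1 of the second moment seen in that frame.
    """

    transform: np.ndarray
    fixed_point_residual: float
    iterations: int
    residual_trace: list = field(default_factory=list)


# ---------------------------------------------------------------------------
# measurement helpers
# ---------------------------------------------------------------------------

def _conv_same_mirror(values, kernel):
    """FFT convolution with mirror (reflect-101) padding, same-size output."""
    ry = (kernel.shape[0] - 1) // 2
    rx = (kernel.shape[1] - 1) // 2
    padded = np.pad(values, ((ry, ry), (rx, rx)), mode="reflect")
    return signal.fftconvolve(padded, kernel, mode="valid")


def _window_average(field_vals, point, sigma_int: SpatialCovariance,
                    radius_factor: float):
    """Gaussian-weighted average of ``field_vals`` centered at a (possibly
    sub-pixel) point: the window taps are evaluated analytically at the
    fractional offset rather than resampling the field."""
    x, y = float(point[0]), float(point[1])
    h, w = field_vals.shape
    if not (0 <= x < w and 0 <= y < h):
        raise DomainError(f"point {point} outside image {field_vals.shape}")
    ix, iy = int(round(x)), int(round(y))
    fx, fy = x - ix, y - iy
    sx, sy = sigma_int.marginal_stds()
    rx = max(1, int(np.ceil(radius_factor * sx)))
    ry = max(1, int(np.ceil(radius_factor * sy)))
    gy, gx = np.mgrid[-ry:ry + 1, -rx:rx + 1].astype(float)
    S = sigma_int.inverse
    xs = gx - fx
    ys = gy - fy
    quad = S[0, 0] * xs * xs + 2 * S[0, 1] * xs * ys + S[1, 1] * ys * ys
    window = np.exp(-0.5 * quad)
    padded = np.pad(field_vals, ((ry, ry), (rx, rx)), mode="reflect")
    patch = padded[iy:iy + 2 * ry + 1, ix:ix + 2 * rx + 1]
    return float(np.sum(patch * window) / np.sum(window))


def affine_second_moment(image, point, sigma_local: SpatialCovariance,
                         sigma_int: SpatialCovariance | None = None,
                         integration_ratio: float = DEFAULT_INTEGRATION_RATIO,
                         radius_factor: float = DEFAULT_RADIUS_FACTOR) -> SecondMoment2D:
    """Affine-extended second moment at ``point``.

    Derivatives use affine Gaussian derivative kernels of covariance
    Sigma_local; the averaging window is the affine Gaussian of Sigma_int
    (default r²·Sigma_local).
    """
    if sigma_int is None:
        sigma_int = SpatialCovariance(integration_ratio ** 2 * sigma_local.matrix)
    values = _values_of(image)
    kx = gaussian_derivative_kernel(
        SpatialKernelSpec(orders=(1, 0), covariance=sigma_local, direction=0.0),
        radius_factor=radius_factor)
    ky = gaussian_derivative_kernel(
        SpatialKernelSpec(orders=(0, 1), covariance=sigma_local, direction=0.0),
        radius_factor=radius_factor)
    lx = _conv_same_mirror(values, kx.values)
    ly = _conv_same_mirror(values, ky.values)
    mu = np.array([
        [_window_average(lx * lx, point, sigma_int, radius_factor),
         _window_average(lx * ly, point, sigma_int, radius_factor)],
        [0.0, _window_average(ly * ly, point, sigma_int, radius_factor)],
    ])
    mu[1, 0] = mu[0, 1]
    return SecondMoment2D(mu=mu, local=sigma_local, integration=sigma_int)


def second_moment(image, point, local_scale: float, integration_scale: float,
                  radius_factor: float = DEFAULT_RADIUS_FACTOR) -> SecondMoment2D:
    """Isotropic second moment (structure tensor) at ``point``."""
    if not (integration_scale >= local_scale > 0):
        raise ParameterError("need integration_scale >= local_scale > 0")
    return affine_second_moment(
        image, point,
        SpatialCovariance.isotropic(local_scale),
        SpatialCovariance.isotropic(integration_scale),
        radius_factor=radius_factor)


# ---------------------------------------------------------------------------
# fixed-point adaptation
# ---------------------------------------------------------------------------

def _sym_sqrt(m):
    w, v = np.linalg.eigh(m)
    return v @ np.diag(np.sqrt(np.maximum(w, 0.0))) @ v.T


def _unit_det(m):
    d = np.linalg.det(m)
    if d <= 0:
        raise DegeneracyError("matrix not positive definite")
    return m / np.sqrt(d)


def _isotropy_residual(mu, sigma_hat):
    """cond - 1 of the second moment as seen in the Sigma-normalized frame."""
    b = _sym_sqrt(sigma_hat)
    m = b @ mu @ b
    w = np.linalg.eigvalsh(m)
    if w[0] <= 0:
        raise DegeneracyError("rank-deficient second moment")
    return float(w[1] / w[0] - 1.0)


def affine_adapt(image, point, init_sigma: SpatialCovariance | float = 4.0,
                 tol: float = 0.05, max_iter: int = 20,
                 integration_ratio: float = DEFAULT_INTEGRATION_RATIO,
                 min_gradient: float = 1e-8,
                 max_anisotropy: float = 100.0) -> AffineFrame:
    """Iterate the smoothing covariance toward the fixed point Sigma ∝ mu⁻¹.

    Each iteration measures the affine second moment with the current
    shape-adapted covariance (integration window co-scaled by the fixed
    ratio), updates the unit-determinant shape to normalize(mu⁻¹), and stops
    when the isotropy residual drops below ``tol``. A damping step (average
    with the previous shape) engages when the residual increases.

    Raises DegeneracyError on (near-)rank-deficient or flat structure and
    ConvergenceError (carrying the residual trace) if ``max_iter`` is hit.
    """
    if max_iter < 1 or tol <= 0:
        raise ParameterError("need max_iter >= 1 and tol > 0")
    if not isinstance(init_sigma, SpatialCovariance):
        init_sigma = SpatialCovariance.isotropic(float(init_sigma))
    values = _values_of(image)
    dyn_range = float(values.max() - values.min())
    area = float(np.sqrt(np.linalg.det(init_sigma.matrix)))  # det Sigma_local stays fixed
    sigma_hat = _unit_det(init_sigma.matrix)
    residuals = []
    mu = None
    for it in range(1, max_iter + 1):
        sigma_local = SpatialCovariance(area * sigma_hat)
        sm = affine_second_moment(image, point, sigma_local,
                                  integration_ratio=integration_ratio)
        mu = sm.mu
        w = np.linalg.eigvalsh(mu)
        # flat patch: gradient rms far below the image's dynamic range
        if np.sqrt(max(np.trace(mu), 0.0) / 2.0) <= min_gradient ** 0.5 * dyn_range:
            raise DegeneracyError(
                f"patch at {point} is flat relative to the image (trace {np.trace(mu):.3e})")
        if w[0] <= min_gradient * max(w[1], min_gradient):
            raise DegeneracyError(
                f"second moment rank-deficient at {point} (eigenvalues {w})")
        q = _isotropy_residual(mu, sigma_hat)
        residuals.append(q)
        if q < tol:
            return AffineFrame(transform=_unit_det(_sym_sqrt(mu)),
                               fixed_point_residual=q, iterations=it,
                               residual_trace=residuals)
        # correct the current shape by the anisotropy observed in its own
        # normalized frame: Sigma <- B·normalize(mu_hat)^-1·B with B = Sigma^1/2
        b = _sym_sqrt(sigma_hat)
        mu_hat = _unit_det(b @ mu @ b)
        target = _unit_det(b @ np.linalg.inv(mu_hat) @ b)
        if len(residuals) >= 2 and residuals[-1] > residuals[-2]:
            target = _unit_det(0.5 * (sigma_hat + target))  # damping on oscillation
        wt = np.linalg.eigvalsh(target)
        if wt[1] / wt[0] > max_anisotropy:
            # runaway elongation: the local pattern is effectively 1-D
            # (ridge), for which the fixed point is degenerate
            raise DegeneracyError(
                f"shape adaptation diverged at {point}: local structure is "
                f"nearly one-dimensional (anisotropy {wt[1] / wt[0]:.0f})")
        sigma_hat = target
    raise ConvergenceError(
        f"no fixed point within {max_iter} iterations (residual {residuals[-1]:.4f})",
        residuals=residuals)


def affine_normalize_patch(image, point, frame: AffineFrame,
                           reference_size: int = 32, scale: float = 1.0,
                           order: int = 3):
    """Resample a patch in the affine-normalized frame.

    Samples out(u) = image(point + T⁻¹·u·scale) with T = frame.transform
    (unit determinant); ``scale`` sets pixels per output sample and is the
    channel through which scale selection handles overall size.
    """
    values = _values_of(image)
    inv = np.linalg.inv(frame.transform)
    r = (reference_size - 1) / 2.0
    u = (np.arange(reference_size) - r) * scale
    uu, vv = np.meshgrid(u, u)            # uu = x-like, vv = y-like
    xs = point[0] + inv[0, 0] * uu + inv[0, 1] * vv
    ys = point[1] + inv[1, 0] * uu + inv[1, 1] * vv
    h, w = values.shape
    if xs.min() < -1 or ys.min() < -1 or xs.max() > w or ys.max() > h:
        raise DomainError("normalized patch maps outside the image")
    return ndimage.map_coordinates(values, [ys, xs], order=order, mode="mirror")
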