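"""Spatial Gaussian scale-space kernels and the convolution engine.

Kernels are sampled from the continuous closed forms at integer pixel
coordinates with the origin at the kernel center, truncated at
``radius_factor`` marginal standard deviations per axis (default 4), and

* zero-order kernels are renormalized to unit sum, so that constants are
  preserved exactly, while
* derivative kernels are mean-corrected to an exactly zero tap sum, so that
  responses to constants vanish to machine precision.

The scale parameter ``s`` is a variance in pixel² throughout (s = sigma²).
Coordinates follow the (x=col, y=row) convention with y increasing with the
row index; orientation angles are measured from the +x axis toward +y.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.polynomial import polynomial as npoly

from .errors import ParameterError, SizeError, UnsupportedOrderError

MAX_ORDER = 4  # receptive fields are well modelled by derivatives up to order four
DEFAULT_RADIUS_FACTOR = 4.0


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class Image2D:
    """Dense 2-D scalar stimulus f(x, y) with square pixels."""

    values: np.ndarray
    pixel_spacing: float = 1.0

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or min(self.values.shape) < 3:
            raise ParameterError("Image2D requires a 2-D grid of at least 3x3 pixels")
        if not np.all(np.isfinite(self.values)):
            raise ParameterError("Image2D values must be finite")
        if not self.pixel_spacing > 0:
            raise ParameterError("pixel_spacing must be positive")

    @property
    def shape(self):
        return self.values.shape


@dataclass(frozen=True)
class SpatialCovariance:
    """2x2 symmetric positive-definite covariance Sigma (pixel² units).

    Parameterized either directly by the matrix or by eigenvalues
    (lambda1 >= lambda2 > 0) and the orientation theta of the lambda1
    eigenvector, theta in [0, pi).
    """

    matrix: np.ndarray

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (2, 2):
            raise ParameterError("covariance must be 2x2")
        if not np.allclose(m, m.T, atol=1e-10):
            raise ParameterError("covariance must be symmetric")
        m = 0.5 * (m + m.T)
        if np.linalg.eigvalsh(m)[0] <= 0:
            raise ParameterError("covariance must be positive definite")
        object.__setattr__(self, "matrix", m)

    @classmethod
    def isotropic(cls, s: float) -> "SpatialCovariance":
        if not s > 0:
            raise ParameterError("scale must be positive")
        return cls(np.eye(2) * float(s))

    @classmethod
    def from_eigen(cls, lambda1: float, lambda2: float, theta: float) -> "SpatialCovariance":
        if not (lambda1 > 0 and lambda2 > 0):
            raise ParameterError("eigenvalues must be positive")
        c, s_ = np.cos(theta), np.sin(theta)
        rot = np.array([[c, -s_], [s_, c]])
        return cls(rot @ np.diag([lambda1, lambda2]) @ rot.T)

    @property
    def eigen(self):
        """(lambda1, lambda2, theta) with lambda1 >= lambda2, theta in [0, pi)."""
        w, v = np.linalg.eigh(self.matrix)       # ascending
        lam1, lam2 = w[1], w[0]
        vec = v[:, 1]
        theta = float(np.arctan2(vec[1], vec[0])) % np.pi
        return float(lam1), float(lam2), theta

    @property
    def inverse(self) -> np.ndarray:
        return np.linalg.inv(self.matrix)

    def marginal_stds(self):
        """Per-axis marginal standard deviations (sqrt of diagonal)."""
        return float(np.sqrt(self.matrix[0, 0])), float(np.sqrt(self.matrix[1, 1]))


@dataclass(frozen=True)
class SpatialKernelSpec:
    """One member of the spatial receptive-field family.

    ``orders=(m1, m2)`` differentiate along the phi axis and its orthogonal
    complement; exactly one of ``scale`` (isotropic variance) or
    ``covariance`` must be given.
    """

    orders: tuple = (0, 0)
    scale: float | None = None
    covariance: SpatialCovariance | None = None
    direction: float | None = None

    def __post_init__(self):
        m1, m2 = self.orders
        if m1 < 0 or m2 < 0 or int(m1) != m1 or int(m2) != m2:
            raise ParameterError("orders must be non-negative integers")
        if m1 + m2 > MAX_ORDER:
            raise UnsupportedOrderError(
                f"total derivative order {m1 + m2} exceeds supported maximum {MAX_ORDER}")
        if (self.scale is None) == (self.covariance is None):
            raise ParameterError("exactly one of scale/covariance must be set")
        if self.scale is not None and not self.scale > 0:
            raise ParameterError("scale must be positive")

    @property
    def cov(self) -> SpatialCovariance:
        if self.covariance is not None:
            return self.covariance
        return SpatialCovariance.isotropic(self.scale)

    @property
    def phi(self) -> float:
        if self.direction is not None:
            return float(self.direction)
        if self.covariance is not None:
            return self.covariance.eigen[2]
        return 0.0


@dataclass
class Kernel2D:
    """Sampled 2-D filter with odd side lengths and center origin."""

    values: np.ndarray
    order: int = 0

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or any(n % 2 == 0 for n in self.values.shape):
            raise ParameterError("kernel must be 2-D with odd side lengths")

    @property
    def support_radius(self):
        return ((self.values.shape[0] - 1) // 2, (self.values.shape[1] - 1) // 2)

    @property
    def origin(self):
        return self.support_radius

    def grid(self):
        """(x, y) coordinate arrays of the taps (x=col, y=row, center origin)."""
        ry, rx = self.support_radius
        y, x = np.mgrid[-ry:ry + 1, -rx:rx + 1]
        return x.astype(float), y.astype(float)


# ---------------------------------------------------------------------------
# bivariate polynomial helpers (coeff array c[i, j] <-> x^i y^j)
# ---------------------------------------------------------------------------

def _pad_to(c, shape):
    out = np.zeros(shape)
    out[: c.shape[0], : c.shape[1]] = c
    return out


def _padd(a, b):
    shape = (max(a.shape[0], b.shape[0]), max(a.shape[1], b.shape[1]))
    return _pad_to(a, shape) + _pad_to(b, shape)


def _mul_x(c):
    return np.pad(c, ((1, 0), (0, 0)))


def _mul_y(c):
    return np.pad(c, ((0, 0), (1, 0)))


def _dx(c):
    if c.shape[0] == 1:
        return np.zeros((1, c.shape[1]))
    return c[1:] * np.arange(1, c.shape[0])[:, None]


def _dy(c):
    if c.shape[1] == 1:
        return np.zeros((c.shape[0], 1))
    return c[:, 1:] * np.arange(1, c.shape[1])[None, :]


def _apply_directional(poly, S, a, b):
    """Polynomial factor of (a ∂x + b ∂y)(P·g) given g has precision S=Sigma^-1."""
    dxp = _padd(_dx(poly), -_padd(S[0, 0] * _mul_x(poly), S[0, 1] * _mul_y(poly)))
    dyp = _padd(_dy(poly), -_padd(S[0, 1] * _mul_x(poly), S[1, 1] * _mul_y(poly)))
    return _padd(a * dxp, b * dyp)


def _derivative_polynomial(cov: SpatialCovariance, orders, phi):
    """Polynomial P with ∂φ^m1 ∂φ⊥^m2 g(x; Sigma) = P(x, y) · g(x; Sigma)."""
    S = cov.inverse
    m1, m2 = orders
    poly = np.ones((1, 1))
    for _ in range(int(m1)):
        poly = _apply_directional(poly, S, np.cos(phi), np.sin(phi))
    for _ in range(int(m2)):
        poly = _apply_directional(poly, S, -np.sin(phi), np.cos(phi))
    return poly


# ---------------------------------------------------------------------------
# kernel constructors
# ---------------------------------------------------------------------------

def _sample_gaussian(cov: SpatialCovariance, poly=None, radius_factor=DEFAULT_RADIUS_FACTOR):
    sx, sy = cov.marginal_stds()
    rx = max(1, int(np.ceil(radius_factor * sx)))
    ry = max(1, int(np.ceil(radius_factor * sy)))
    y, x = np.mgrid[-ry:ry + 1, -rx:rx + 1].astype(float)
    S = cov.inverse
    quad = S[0, 0] * x * x + 2 * S[0, 1] * x * y + S[1, 1] * y * y
    g = np.exp(-0.5 * quad) / (2 * np.pi * np.sqrt(np.linalg.det(cov.matrix)))
    if poly is not None:
        g = g * npoly.polyval2d(x, y, poly)
    return g


def _finalize(values, order):
    if order == 0:
        values = values / values.sum()
    else:
        values = values - values.mean()   # exact zero sum for derivative kernels
    return Kernel2D(values, order=order)


def gaussian_kernel(scale: float, radius_factor: float = DEFAULT_RADIUS_FACTOR) -> Kernel2D:
    """Rotationally symmetric Gaussian g(x, y; s) = exp(-(x²+y²)/2s)/(2πs).

    ``scale`` is the variance s (pixel²). Truncated at ``radius_factor``
    standard deviations and renormalized to unit sum.
    """
    cov = SpatialCovariance.isotropic(scale)
    return _finalize(_sample_gaussian(cov, radius_factor=radius_factor), 0)


def affine_gaussian_kernel(covariance: SpatialCovariance,
                           radius_factor: float = DEFAULT_RADIUS_FACTOR) -> Kernel2D:
    """Affine Gaussian g(x; Sigma) = exp(-xᵀSigma⁻¹x/2)/(2π√det Sigma).

    The support radius per axis follows the per-axis marginal standard
    deviation, so rotated anisotropic kernels are fully contained.
    """
    return _finalize(_sample_gaussian(covariance, radius_factor=radius_factor), 0)


def gaussian_derivative_kernel(spec: SpatialKernelSpec,
                               radius_factor: float = DEFAULT_RADIUS_FACTOR) -> Kernel2D:
    """Sampled analytic Gaussian derivative ∂φ^m1 ∂φ⊥^m2 g(·; s or Sigma)."""
    cov = spec.cov
    order = spec.orders[0] + spec.orders[1]
    poly = _derivative_polynomial(cov, spec.orders, spec.phi) if order else None
    return _finalize(_sample_gaussian(cov, poly=poly, radius_factor=radius_factor), order)


def directional_derivative_kernel(covariance: SpatialCovariance, orders,
                                  phi: float | None = None,
                                  radius_factor: float = DEFAULT_RADIUS_FACTOR) -> Kernel2D:
    """Directional derivative of the affine Gaussian along (φ, φ+π/2).

    Expands (cos φ ∂x + sin φ ∂y)^m1 (−sin φ ∂x + cos φ ∂y)^m2 applied to
    g(·; Sigma); φ defaults to the orientation of Sigma's major eigenvector.
    """
    spec = SpatialKernelSpec(orders=tuple(orders), covariance=covariance, direction=phi)
    return gaussian_derivative_kernel(spec, radius_factor=radius_factor)


def laplacian_of_gaussian_kernel(scale: float,
                                 radius_factor: float = DEFAULT_RADIUS_FACTOR) -> Kernel2D:
    """∇²g(·; s); center value −1/(πs²) before mean correction."""
    cov = SpatialCovariance.isotropic(scale)
    p = _padd(_derivative_polynomial(cov, (2, 0), 0.0),
              _derivative_polynomial(cov, (0, 2), 0.0))
    return _finalize(_sample_gaussian(cov, poly=p, radius_factor=radius_factor), 2)


# ---------------------------------------------------------------------------
# convolution engine
# ---------------------------------------------------------------------------

def _values_of(image):
    return image.values if isinstance(image, Image2D) else np.asarray(image, dtype=float)


_PAD_MODES = {"mirror": "reflect", "constant": "constant", "replicate": "edge"}


def convolve(image, kernel: Kernel2D, boundary: str = "mirror"):
    """Convolve an image with a sampled kernel (same-size output).

    Linear and shift-invariant away from borders; ``boundary`` is one of
    mirror (reflect-101, default), constant (zero pad) or replicate. The
    image is padded by the kernel radius and convolved by FFT, so kernels up
    to one radius larger than the image are supported.
    """
    from scipy import signal  # local import keeps module load light

    values = _values_of(image)
    kv = kernel.values if isinstance(kernel, Kernel2D) else np.asarray(kernel, dtype=float)
    if boundary not in _PAD_MODES:
        raise ParameterError(f"unknown boundary mode {boundary!r}")
    ry = (kv.shape[0] - 1) // 2
    rx = (kv.shape[1] - 1) // 2
    if ry >= values.shape[0] or rx >= values.shape[1]:
        raise SizeError(f"kernel {kv.shape} larger than padded image {values.shape}")
    padded = np.pad(values, ((ry, ry), (rx, rx)), mode=_PAD_MODES[boundary])
    out = signal.convolve(padded, kv, mode="valid", method="auto")
    if isinstance(image, Image2D):
        return Image2D(out, pixel_spacing=image.pixel_spacing)
    return out


def smooth(image, scale: float, boundary: str = "mirror",
           radius_factor: float = DEFAULT_RADIUS_FACTOR):
    """Scale-space representation L(·; s) = g(·; s) * f."""
    return convolve(image, gaussian_kernel(scale, radius_factor=radius_factor), boundary)


def derivative_response(image, orders, scale: float, phi: float = 0.0,
                        boundary: str = "mirror",
                        radius_factor: float = DEFAULT_RADIUS_FACTOR):
    """L_{φ^m1 φ⊥^m2}(·; s): Gaussian-derivative receptive-field response."""
    spec = SpatialKernelSpec(orders=tuple(orders), scale=scale, direction=phi)
    return convolve(image, gaussian_derivative_kernel(spec, radius_factor=radius_factor),
                    boundary)
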