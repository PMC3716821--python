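"""Scale-normalized derivatives, scale-space signatures and scale selection.

Multiplying derivative responses by s^{gamma·order/2} makes their local
extrema over scale comparable across scales; at gamma = 1 the underlying
receptive fields have constant L1-type norm over scale and the closed-form
blob results hold: for a Gaussian blob of variance t0, both the
scale-normalized Laplacian s·∇²L and the scale-normalized determinant of the
Hessian s²·det(H L) assume their scale extremum at s = t0 when measured at
the blob center. Selected scales transform as ŝ' = c²·ŝ under image
rescaling by a factor c, which is what makes extremum-based selection a
scale-invariance mechanism: resampling the image patch by sqrt(s_ref/ŝ)
cancels the unknown scaling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import DomainError, ParameterError, SelectionError
from .spatial import Image2D, _values_of, derivative_response


@dataclass
class ScaleStack:
    """Ordered stack of (scale, response grid) at one normalization power."""

    scales: np.ndarray
    levels: list
    gamma: float = 1.0
    operator_name: str = ""

    def __post_init__(self):
        self.scales = np.asarray(self.scales, dtype=float)
        if np.any(np.diff(self.scales) <= 0):
            raise ParameterError("scales must be strictly increasing")
        if len(self.levels) != self.scales.size:
            raise ParameterError("one response grid per scale required")


@dataclass
class ScaleSignature:
    """Signature r(s) of one operator at one image point, with its scale
    extrema refined by 3-point quadratic interpolation in log s."""

    point: tuple
    scales: np.ndarray
    values: np.ndarray
    extrema: list = field(default_factory=list)  # (s_hat, value, 'max'|'min')


def log_scale_grid(s_min: float = 1.0, s_max: float = 256.0,
                   per_octave: int = 2) -> np.ndarray:
    """Logarithmic scale grid, ``per_octave`` levels per factor 2 in variance."""
    if not (s_max > s_min > 0) or per_octave < 1:
        raise ParameterError("need s_max > s_min > 0 and per_octave >= 1")
    n = int(np.floor(np.log2(s_max / s_min) * per_octave)) + 1
    return s_min * 2.0 ** (np.arange(n) / per_octave)


def normalized_derivative_response(image, orders, s: float, gamma: float = 1.0,
                                   phi: float = 0.0, boundary: str = "mirror"):
    """s^{gamma(m1+m2)/2} · L_{φ^m1 φ⊥^m2}(·; s)."""
    if not s > 0 or not gamma > 0:
        raise ParameterError("s and gamma must be positive")
    order = orders[0] + orders[1]
    resp = derivative_response(image, orders, s, phi=phi, boundary=boundary)
    factor = s ** (gamma * order / 2.0)
    if isinstance(resp, Image2D):
        return Image2D(resp.values * factor, pixel_spacing=resp.pixel_spacing)
    return resp * factor


def norm_laplacian(image, s: float, gamma: float = 1.0, boundary: str = "mirror"):
    """Scale-normalized Laplacian s^gamma·(Lxx + Lyy)."""
    if not s > 0:
        raise ParameterError("s must be positive")
    lxx = derivative_response(image, (2, 0), s, boundary=boundary)
    lyy = derivative_response(image, (0, 2), s, boundary=boundary)
    out = (s ** gamma) * (_values_of(lxx) + _values_of(lyy))
    return Image2D(out) if isinstance(image, Image2D) else out


def norm_det_hessian(image, s: float, gamma: float = 1.0, boundary: str = "mirror"):
    """Scale-normalized determinant of the Hessian s^{2·gamma}·(Lxx·Lyy - Lxy²)."""
    if not s > 0:
        raise ParameterError("s must be positive")
    lxx = _values_of(derivative_response(image, (2, 0), s, boundary=boundary))
    lyy = _values_of(derivative_response(image, (0, 2), s, boundary=boundary))
    lxy = _values_of(derivative_response(image, (1, 1), s, boundary=boundary))
    out = (s ** (2.0 * gamma)) * (lxx * lyy - lxy * lxy)
    return Image2D(out) if isinstance(image, Image2D) else out


_OPERATORS = {
    "lap": norm_laplacian,
    "dethess": norm_det_hessian,
}


def scale_stack(image, operator: str, scale_grid, gamma: float = 1.0) -> ScaleStack:
    op = _OPERATORS.get(operator)
    if op is None:
        raise ParameterError(f"unknown operator {operator!r}; use one of {sorted(_OPERATORS)}")
    grid = np.asarray(scale_grid, dtype=float)
    levels = [_values_of(op(image, s, gamma=gamma)) for s in grid]
    return ScaleStack(scales=grid, levels=levels, gamma=gamma, operator_name=operator)


def _refine_log_quadratic(u, v):
    """Vertex of the parabola through three (log s, value) samples."""
    denom = v[0] - 2.0 * v[1] + v[2]
    if denom == 0:
        return u[1], v[1]
    delta = 0.5 * (v[0] - v[2]) / denom
    delta = float(np.clip(delta, -1.0, 1.0))
    du = u[1] - u[0]
    u_hat = u[1] + delta * du
    v_hat = v[1] - 0.25 * (v[0] - v[2]) * delta
    return u_hat, v_hat


def scale_signature(image, point, operator: str, scale_grid,
                    gamma: float = 1.0) -> ScaleSignature:
    """Sample the scale-space signature of ``operator`` at ``point`` and
    localize its interior extrema over scale.

    ``point`` is (x, y) in pixel coordinates and must be interior.
    """
    values = _values_of(image)
    x, y = int(round(point[0])), int(round(point[1]))
    if not (0 < x < values.shape[1] - 1 and 0 < y < values.shape[0] - 1):
        raise DomainError(f"point {point} not interior to image {values.shape}")
    grid = np.asarray(scale_grid, dtype=float)
    if grid.size < 3:
        raise ParameterError("need at least 3 scales for extremum detection")
    stack = scale_stack(image, operator, grid, gamma=gamma)
    sig = np.array([lev[y, x] for lev in stack.levels])
    u = np.log(grid)
    extrema = []
    for i in range(1, sig.size - 1):
        if sig[i] > sig[i - 1] and sig[i] >= sig[i + 1]:
            u_hat, v_hat = _refine_log_quadratic(u[i - 1:i + 2], sig[i - 1:i + 2])
            extrema.append((float(np.exp(u_hat)), float(v_hat), "max"))
        elif sig[i] < sig[i - 1] and sig[i] <= sig[i + 1]:
            u_hat, v_hat = _refine_log_quadratic(u[i - 1:i + 2], sig[i - 1:i + 2])
            extrema.append((float(np.exp(u_hat)), float(v_hat), "min"))
    return ScaleSignature(point=(x, y), scales=grid, values=sig, extrema=extrema)


def select_scale(image, point, operator: str, scale_grid,
                 gamma: float = 1.0) -> tuple:
    """Strongest |normalized response| extremum over scale: (s_hat, value)."""
    sig = scale_signature(image, point, operator, scale_grid, gamma=gamma)
    if not sig.extrema:
        raise SelectionError(f"no interior scale extremum at {point}", signature=sig)
    s_hat, v_hat, _ = max(sig.extrema, key=lambda e: abs(e[1]))
    return s_hat, v_hat


def extract_patch(image, point, sampling_step: float, reference_size: int = 32,
                  order: int = 3):
    """Resample a square patch centered at ``point`` with the given step
    (pixels per output sample), bicubic with mirror boundary."""
    values = _values_of(image)
    r = (reference_size - 1) / 2.0
    u = (np.arange(reference_size) - r) * sampling_step
    xs = point[0] + u[None, :] * np.ones((reference_size, 1))
    ys = point[1] + u[:, None] * np.ones((1, reference_size))
    return ndimage.map_coordinates(values, [ys, xs], order=order, mode="mirror")


def select_scale_and_normalize(image, point, operator: str, scale_grid,
                               reference_size: int = 32, s_ref: float = 4.0,
                               gamma: float = 1.0):
    """Select the scale at ``point`` and cut a scale-normalized patch.

    The patch is sampled with step sqrt(ŝ/s_ref), so two images related by
    f'(x) = f(x/c) produce the same normalized patch (up to interpolation):
    the selected scales differ by c² and the sampling steps by c.

    Returns (s_hat, patch).
    """
    s_hat, _ = select_scale(image, point, operator, scale_grid, gamma=gamma)
    step = float(np.sqrt(s_hat / s_ref))
    patch = extract_patch(image, point, step, reference_size=reference_size)
    return s_hat, patch
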