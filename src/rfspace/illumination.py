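"""Logarithmic luminosity and invariance under multiplicative illumination.

Image luminosity is the product of scene albedo (surface reflectance) and an
illumination field. On a logarithmic intensity scale the product becomes a
sum, so any receptive field with at least one order of spatial
differentiation — whose kernel has exactly zero tap sum — is exactly
invariant to a global multiplicative rescaling f -> c·f (exposure change,
uniform illumination change), and approximately invariant to slowly varying
illumination fields: its response measures the albedo wherever the
illumination is close to constant over the kernel support. A zero-order
(pure smoothing) receptive field is *not* invariant; it shifts by log c.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ParameterError
from .spatial import (Image2D, SpatialKernelSpec, _values_of, convolve,
                      gaussian_derivative_kernel)

DEFAULT_FLOOR_FRACTION = 1e-6


@dataclass
class LuminanceImage:
    """Strictly positive linear luminosities with a positive clamp floor."""

    values: np.ndarray
    floor: float | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.floor is None:
            peak = float(self.values.max()) if self.values.size else 1.0
            self.floor = DEFAULT_FLOOR_FRACTION * max(peak, np.finfo(float).tiny)
        if not self.floor > 0:
            raise ParameterError("floor must be positive")


@dataclass
class IlluminationScene:
    """Scene luminosity f = albedo · illumination, both strictly positive."""

    albedo: np.ndarray
    illumination: np.ndarray

    def __post_init__(self):
        self.albedo = np.asarray(self.albedo, dtype=float)
        self.illumination = np.asarray(self.illumination, dtype=float)
        if self.albedo.shape != self.illumination.shape:
            raise ParameterError("albedo and illumination must share a shape")
        if np.any(self.albedo <= 0) or np.any(self.illumination <= 0):
            raise ParameterError("albedo and illumination must be strictly positive")

    @property
    def composed(self) -> np.ndarray:
        return self.albedo * self.illumination


def log_transform(image) -> tuple:
    """Natural log of the clamped luminosities.

    Returns (Image2D, n_clamped): values below the floor are clamped to it
    and counted rather than producing -inf.
    """
    if not isinstance(image, LuminanceImage):
        image = LuminanceImage(np.asarray(image, dtype=float))
    clamped = np.maximum(image.values, image.floor)
    n_clamped = int(np.count_nonzero(image.values < image.floor))
    return Image2D(np.log(clamped)), n_clamped


def multiplicative_invariance_check(image, kernel_spec: SpatialKernelSpec,
                                    factor: float) -> float:
    """Max abs difference between derivative responses of log(f) and log(c·f).

    Exactly zero up to floating point for any derivative order >= 1 since
    log(c·f) = log f + log c and derivative kernels have zero tap sum.
    Zero-order kernels are rejected: their response shifts by log c.
    """
    if factor <= 0:
        raise ParameterError("factor must be positive")
    if kernel_spec.orders[0] + kernel_spec.orders[1] < 1:
        raise ParameterError(
            "zero-order receptive fields are not illumination invariant; "
            "their response shifts by log c under f -> c·f")
    kern = gaussian_derivative_kernel(kernel_spec)
    base = image.values if isinstance(image, LuminanceImage) else _values_of(image)
    log_f, _ = log_transform(base)
    log_cf, _ = log_transform(base * factor)
    r1 = _values_of(convolve(log_f, kern))
    r2 = _values_of(convolve(log_cf, kern))
    return float(np.abs(r1 - r2).max())


def scene_response_decomposition(scene: IlluminationScene,
                                 kernel_spec: SpatialKernelSpec):
    """Derivative responses to log(albedo·illumination) and to log(albedo).

    Where the illumination is constant over the kernel support the two
    agree: the receptive field sees the surface, not the lighting.
    """
    kern = gaussian_derivative_kernel(kernel_spec)
    log_f, _ = log_transform(scene.composed)
    log_a, _ = log_transform(scene.albedo)
    return (_values_of(convolve(log_f, kern)),
            _values_of(convolve(log_a, kern)))
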