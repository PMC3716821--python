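"""Idealized phenomenological receptive-field models.

LGN relay cells are modelled as space-time separable center–surround
operators: a polarity-signed Laplacian of Gaussian in space composed with a
temporal derivative of a temporal smoothing kernel. V1 simple cells are
modelled as oriented affine Gaussian directional derivatives, optionally
velocity-adapted over space-time.

Sign convention: an on-center (polarity +1) cell responds positively to a
bright spot on its center, which corresponds to the spatial weighting
−∇²g(·; s) (center-positive taps). Off-center cells are the negation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ParameterError
from .spatial import (DEFAULT_RADIUS_FACTOR, Kernel2D, SpatialCovariance,
                      SpatialKernelSpec, gaussian_derivative_kernel,
                      gaussian_kernel, laplacian_of_gaussian_kernel)
from .temporal import (STCovariance, STKernel3D, STKernelSpec,
                       TemporalKernelSpec, _temporal_factor, st_derivative_kernel)


@dataclass(frozen=True)
class LGNSpec:
    """Center–surround (retina/LGN) receptive field.

    polarity +1 = on-center/off-surround, -1 = off-center/on-surround;
    ``spatial_scale`` is the variance s of the underlying Gaussian;
    ``temporal`` selects the temporal smoother (None for a purely spatial
    field); ``temporal_order`` is the order of temporal differentiation.
    """

    polarity: int = 1
    spatial_scale: float = 4.0
    temporal: TemporalKernelSpec | None = None
    temporal_order: int = 0

    def __post_init__(self):
        if self.polarity not in (1, -1):
            raise ParameterError("polarity must be +1 or -1")
        if not self.spatial_scale > 0:
            raise ParameterError("spatial_scale must be positive")
        if self.temporal_order < 0:
            raise ParameterError("temporal_order must be >= 0")
        if self.temporal_order > 0 and self.temporal is None:
            raise ParameterError("temporal differentiation needs a temporal kernel")


@dataclass(frozen=True)
class V1SimpleSpec:
    """Oriented (optionally velocity-adapted) simple-cell receptive field."""

    covariance: SpatialCovariance
    spatial_orders: tuple = (1, 0)
    direction: float | None = None
    velocity: tuple = (0.0, 0.0)
    temporal: TemporalKernelSpec | None = None
    temporal_order: int = 0
    causal: bool = False


# ---------------------------------------------------------------------------
# LGN
# ---------------------------------------------------------------------------

def lgn_spatial_kernel(spec: LGNSpec,
                       radius_factor: float = DEFAULT_RADIUS_FACTOR) -> Kernel2D:
    """Spatial component: ∓∇²g(·; s), mean-corrected to an exactly zero sum."""
    log = laplacian_of_gaussian_kernel(spec.spatial_scale, radius_factor=radius_factor)
    return Kernel2D(-spec.polarity * log.values, order=2)


def lgn_kernel(spec: LGNSpec, radius_factor: float = DEFAULT_RADIUS_FACTOR):
    """Full LGN model; returns a Kernel2D when no temporal part is requested,
    otherwise an STKernel3D of the separable space-time product."""
    spatial = lgn_spatial_kernel(spec, radius_factor=radius_factor)
    if spec.temporal is None:
        return spatial
    st = _separable_st(spatial.values, spec.temporal, spec.temporal_order,
                       radius_factor)
    return st


def _separable_st(spatial_values, temporal: TemporalKernelSpec, n: int,
                  radius_factor: float) -> STKernel3D:
    cov = STCovariance(SpatialCovariance.isotropic(1.0), (0.0, 0.0),
                       temporal.temporal_variance or 1.0)
    helper = STKernelSpec(covariance=cov, temporal_order=n,
                          causal=(temporal.kind == "exp_cascade"),
                          delay=temporal.delay,
                          time_constants=tuple(temporal.time_constants))
    if helper.causal:
        t_max = int(np.ceil(sum(temporal.time_constants)
                            + radius_factor * np.sqrt(sum(m * m for m in temporal.time_constants))))
    else:
        t_max = int(np.ceil(abs(temporal.delay)
                            + radius_factor * np.sqrt(temporal.temporal_variance)))
    t = np.arange(-max(t_max, 1), max(t_max, 1) + 1, dtype=float)
    taps = _temporal_factor(helper, t)
    values = taps[:, None, None] * spatial_values[None]
    return STKernel3D(values=values, times=t, order=2 + n)


# ---------------------------------------------------------------------------
# DoG vs LoG
# ---------------------------------------------------------------------------

def dog_kernel(s1: float, s2: float,
               radius_factor: float = DEFAULT_RADIUS_FACTOR) -> Kernel2D:
    """Difference of Gaussians g(·; s2) - g(·; s1), s2 > s1 > 0.

    A bandpass operator with exactly zero tap sum; as s2/s1 -> 1 it
    approaches the scaled Laplacian (s2-s1)/2 · ∇²g via the diffusion
    equation ∂s g = ½∇²g.
    """
    if not (s2 > s1 > 0):
        raise ParameterError("need s2 > s1 > 0")
    # sample both Gaussians on the common (larger) support so the
    # truncation/renormalization error cancels in the difference
    r = max(1, int(np.ceil(radius_factor * np.sqrt(s2))))
    y, x = np.mgrid[-r:r + 1, -r:r + 1].astype(float)
    r2 = x * x + y * y
    g1 = np.exp(-r2 / (2.0 * s1)) / (2.0 * np.pi * s1)
    g2 = np.exp(-r2 / (2.0 * s2)) / (2.0 * np.pi * s2)
    return Kernel2D(g2 / g2.sum() - g1 / g1.sum(), order=2)


def log_dog_discrepancy(s1: float, s2: float, radius_factor: float = 6.0) -> float:
    """Relative L2 error of the DoG against (s2-s1)·½∇²g at the geometric
    mid-scale sqrt(s1·s2), both sampled on the DoG support."""
    dog = dog_kernel(s1, s2, radius_factor=radius_factor)
    r = dog.support_radius[0]
    y, x = np.mgrid[-r:r + 1, -r:r + 1].astype(float)
    s_mid = float(np.sqrt(s1 * s2))
    r2 = x * x + y * y
    g = np.exp(-r2 / (2.0 * s_mid)) / (2.0 * np.pi * s_mid)
    log_vals = (r2 / s_mid ** 2 - 2.0 / s_mid) * g
    target = (s2 - s1) * 0.5 * log_vals
    return float(np.linalg.norm(dog.values - target) / np.linalg.norm(target))


# ---------------------------------------------------------------------------
# V1 simple cells
# ---------------------------------------------------------------------------

def v1_simple_kernel(spec: V1SimpleSpec,
                     radius_factor: float = DEFAULT_RADIUS_FACTOR):
    """Oriented simple-cell kernel.

    Purely spatial (no temporal part): directional derivative of the affine
    Gaussian along (phi, phi+pi/2). With a temporal part: velocity-adapted
    spatio-temporal derivative kernel.
    """
    if spec.temporal is None:
        return gaussian_derivative_kernel(
            SpatialKernelSpec(orders=tuple(spec.spatial_orders),
                              covariance=spec.covariance,
                              direction=spec.direction),
            radius_factor=radius_factor)
    st_cov = STCovariance(spec.covariance, tuple(spec.velocity),
                          spec.temporal.temporal_variance or 1.0)
    st_spec = STKernelSpec(covariance=st_cov,
                           spatial_orders=tuple(spec.spatial_orders),
                           temporal_order=spec.temporal_order,
                           causal=spec.causal or spec.temporal.kind == "exp_cascade",
                           delay=spec.temporal.delay,
                           time_constants=tuple(spec.temporal.time_constants),
                           direction=spec.direction)
    return st_derivative_kernel(st_spec, radius_factor=radius_factor)


# ---------------------------------------------------------------------------
# parameter galleries
# ---------------------------------------------------------------------------

def sample_hemisphere_covariances(n: int, lambda1: float = 16.0, seed: int = 0):
    """Sample spatial covariances as seen for surface patches whose normals
    are uniformly distributed on the upper viewing hemisphere.

    Foreshortening compresses the pattern along the tilt direction:
    lambda2/lambda1 = cos²(slant), theta = azimuth mod pi. For a uniform
    hemisphere cos(slant) is uniform on (0, 1].
    """
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(int(n)):
        cos_slant = 1.0 - rng.uniform(0.0, 1.0)  # uniform (0, 1]
        theta = rng.uniform(0.0, 2.0 * np.pi) % np.pi
        lam2 = max(lambda1 * cos_slant ** 2, 1e-3 * lambda1)
        out.append(SpatialCovariance.from_eigen(lambda1, lam2, theta))
    return out


def rf_gallery(param_grid):
    """Deterministically enumerate a grid of model kernels.

    ``param_grid`` is an iterable of dicts with a ``model`` key ('lgn' or
    'v1') plus the corresponding spec fields. Returns a list of
    (name, kernel, params) triples in enumeration order.
    """
    results = []
    for i, params in enumerate(param_grid):
        p = dict(params)
        model = p.pop("model", "v1")
        if model == "lgn":
            kern = lgn_kernel(LGNSpec(**p))
        elif model == "v1":
            kern = v1_simple_kernel(V1SimpleSpec(**p))
        else:
            raise ParameterError(f"unknown model {model!r}")
        tags = "_".join(f"{k}-{_fmt(v)}" for k, v in sorted(p.items()))
        results.append((f"{i:03d}_{model}_{tags}", kern, dict(params)))
    return results


def _fmt(v):
    if isinstance(v, SpatialCovariance):
        l1, l2, th = v.eigen
        return f"{l1:g}x{l2:g}a{th:.2f}"
    if isinstance(v, (tuple, list)):
        return "x".join(f"{float(u):g}" for u in v)
    if isinstance(v, TemporalKernelSpec):
        if v.kind == "exp_cascade":
            return "mu" + "x".join(f"{m:g}" for m in v.time_constants)
        return f"lt{v.temporal_variance:g}"
    return f"{v}"
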