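"""Spatio-temporal second moments, Galilean diagonalization and velocity.

A constant relative motion shears space-time: x -> x + v·t. The 3x3
spatio-temporal second-moment matrix of first-derivative products
(Lx², LxLy, Ly², LxLt, LyLt, Lt²) transforms predictably under this shear,
and there is a unique Galilean transformation that cancels its mixed
space-time entries. The velocity that achieves this block diagonalization
solves

    [mu_xx mu_xy; mu_xy mu_yy] · v = -[mu_xt; mu_yt],

the same normal equations used for least-squares optic flow. The velocity is
additive under superimposed Galilean transformations, and for a pattern
translating rigidly at v the solution is exact in the continuum
(Lt + v·∇L = 0 identically). A one-dimensional pattern leaves the spatial
block singular — the aperture problem — and is reported as a degeneracy
rather than a silent estimate.

Derivatives default to separable non-causal Gaussian smoothing (spatial
variance s, temporal variance lambda_t); the time-causal exponential cascade
can be selected instead for streaming-compatible analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import DegeneracyError, DomainError, ParameterError
from .fixtures import galilean_warp
from .spatial import DEFAULT_RADIUS_FACTOR
from .temporal import ImageSequence, _causal_taps_on_grid, _temporal_backward_diff

DEFAULT_CONDITION_CAP = 1e4
DEFAULT_INTEGRATION_RATIO = 2.0


@dataclass(frozen=True)
class STDerivativeSpec:
    """How the first derivatives for the second moment are computed."""

    spatial_scale: float = 2.0
    temporal_variance: float = 2.0
    causal: bool = False
    time_constants: tuple = (1.0, 2.0)


@dataclass
class SecondMoment3D:
    """3x3 second moment over (x, y, t) with its measurement spec."""

    mu: np.ndarray
    derivative_spec: STDerivativeSpec
    integration_ratio: float = DEFAULT_INTEGRATION_RATIO

    def __post_init__(self):
        self.mu = np.asarray(self.mu, dtype=float)
        if self.mu.shape != (3, 3):
            raise ParameterError("spatio-temporal second moment must be 3x3")

    @property
    def spatial_block(self):
        return self.mu[:2, :2]


@dataclass
class VelocityEstimate:
    """Velocity (px/frame) from Galilean diagonalization of a second moment."""

    v: tuple
    diag_residual: float
    condition: float


# ---------------------------------------------------------------------------
# separable derivative engine
# ---------------------------------------------------------------------------

def _gauss_taps_1d(s, order, radius_factor):
    r = max(1, int(np.ceil(radius_factor * np.sqrt(s))))
    x = np.arange(-r, r + 1, dtype=float)
    g = np.exp(-x * x / (2.0 * s))
    g /= g.sum()
    if order == 0:
        return g
    z = x / np.sqrt(s)
    he = np.polynomial.hermite_e.hermeval(z, [0.0] * order + [1.0])
    d = (-1.0 / np.sqrt(s)) ** order * he * g
    return d - d.mean()


def _smooth_derivative(frames, dx, dy, dt, spec: STDerivativeSpec,
                       radius_factor=DEFAULT_RADIUS_FACTOR):
    """Separable spatio-temporal Gaussian (or causal-cascade) derivative."""
    out = frames
    out = ndimage.convolve1d(out, _gauss_taps_1d(spec.spatial_scale, dx, radius_factor),
                             axis=2, mode="mirror")
    out = ndimage.convolve1d(out, _gauss_taps_1d(spec.spatial_scale, dy, radius_factor),
                             axis=1, mode="mirror")
    if spec.causal:
        n = out.shape[0]
        taps = _causal_taps_on_grid(spec.time_constants, n)
        taps = _temporal_backward_diff(taps, dt)
        full = np.zeros(2 * n - 1)
        full[n - 1:] = taps          # index = temporal lag; zeros at negative lags
        out = ndimage.convolve1d(out, full, axis=0, mode="mirror")
    else:
        out = ndimage.convolve1d(out, _gauss_taps_1d(spec.temporal_variance, dt,
                                                     radius_factor),
                                 axis=0, mode="mirror")
    return out


def st_second_moment(seq, point, derivative_spec: STDerivativeSpec | None = None,
                     integration_ratio: float = DEFAULT_INTEGRATION_RATIO,
                     radius_factor: float = DEFAULT_RADIUS_FACTOR) -> SecondMoment3D:
    """Weighted averages of the six first-derivative products at ``point``.

    ``point`` is (x, y, t); the integration window is a separable Gaussian
    with variances r²·(s, s, lambda_t) centered at the point (time delay
    matched for causal smoothing via the cascade mean).
    """
    if derivative_spec is None:
        derivative_spec = STDerivativeSpec()
    frames = seq.frames if isinstance(seq, ImageSequence) else np.asarray(seq, float)
    if frames.shape[0] < 3:
        raise DomainError("need at least 3 frames")
    lx = _smooth_derivative(frames, 1, 0, 0, derivative_spec, radius_factor)
    ly = _smooth_derivative(frames, 0, 1, 0, derivative_spec, radius_factor)
    lt = _smooth_derivative(frames, 0, 0, 1, derivative_spec, radius_factor)

    x, y, t = (int(round(c)) for c in point)
    nt, h, w = frames.shape
    if not (0 <= x < w and 0 <= y < h and 0 <= t < nt):
        raise DomainError(f"point {point} outside sequence {frames.shape}")
    r2 = integration_ratio ** 2
    ws = _gauss_taps_1d(r2 * derivative_spec.spatial_scale, 0, radius_factor)
    wt = _gauss_taps_1d(r2 * derivative_spec.temporal_variance, 0, radius_factor)

    def avg(a):
        v = ndimage.convolve1d(a, ws, axis=2, mode="mirror")
        v = ndimage.convolve1d(v, ws, axis=1, mode="mirror")
        v = ndimage.convolve1d(v, wt, axis=0, mode="mirror")
        return v[t, y, x]

    mu = np.empty((3, 3))
    mu[0, 0] = avg(lx * lx)
    mu[0, 1] = mu[1, 0] = avg(lx * ly)
    mu[1, 1] = avg(ly * ly)
    mu[0, 2] = mu[2, 0] = avg(lx * lt)
    mu[1, 2] = mu[2, 1] = avg(ly * lt)
    mu[2, 2] = avg(lt * lt)
    return SecondMoment3D(mu=mu, derivative_spec=derivative_spec,
                          integration_ratio=integration_ratio)


# ---------------------------------------------------------------------------
# diagonalization and velocity
# ---------------------------------------------------------------------------

def galilean_diagonalize(moment: SecondMoment3D, v) -> SecondMoment3D:
    """Transform the second moment into the frame moving at velocity v.

    Under the warp out(x, t) = in(x + v·t, t) derivatives transform with the
    Galilean shear G = [[1,0,vx],[0,1,vy],[0,0,1]]ᵀ-structure; the mixed
    space-time entries vanish exactly when v solves the normal equations.
    """
    vx, vy = float(v[0]), float(v[1])
    g = np.array([[1.0, 0.0, vx],
                  [0.0, 1.0, vy],
                  [0.0, 0.0, 1.0]])
    return SecondMoment3D(mu=g.T @ moment.mu @ g,
                          derivative_spec=moment.derivative_spec,
                          integration_ratio=moment.integration_ratio)


def estimate_velocity(moment: SecondMoment3D,
                      condition_cap: float = DEFAULT_CONDITION_CAP) -> VelocityEstimate:
    """Solve for the velocity that block-diagonalizes the second moment."""
    s = moment.spatial_block
    w, vecs = np.linalg.eigh(s)
    if w[1] <= 0 or w[0] <= 0 or w[1] / max(w[0], np.finfo(float).tiny) > condition_cap:
        deficient = vecs[:, 0]
        raise DegeneracyError(
            "aperture problem: spatial second-moment block is (near-)singular; "
            f"deficient direction (x, y) = ({deficient[0]:+.3f}, {deficient[1]:+.3f})")
    rhs = -moment.mu[:2, 2]
    # snap numerically-zero mixed entries so static input yields exactly v = 0
    rhs[np.abs(rhs) <= 1e-14 * max(np.trace(moment.mu), np.finfo(float).tiny)] = 0.0
    v = np.linalg.solve(s, rhs)
    diag = galilean_diagonalize(moment, v)
    residual = float(max(abs(diag.mu[0, 2]), abs(diag.mu[1, 2])))
    return VelocityEstimate(v=(float(v[0]), float(v[1])), diag_residual=residual,
                            condition=float(w[1] / w[0]))


def velocity_stabilize(seq, v, order: int = 3):
    """Resample frames by x -> x + v·t so a pattern moving at v becomes static."""
    frames = seq.frames if isinstance(seq, ImageSequence) else np.asarray(seq, float)
    nt, h, w = frames.shape
    if abs(v[0]) * (nt - 1) > w or abs(v[1]) * (nt - 1) > h:
        raise DomainError("stabilization warp leaves the image bounds")
    if v[0] == 0.0 and v[1] == 0.0:
        out = frames.copy()
    else:
        out = galilean_warp(frames, v, order=order)
    if isinstance(seq, ImageSequence):
        return ImageSequence(out, frame_spacing=seq.frame_spacing,
                             pixel_spacing=seq.pixel_spacing)
    return out
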