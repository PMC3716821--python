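"""Seeded synthetic stimuli: blobs, gratings, textures, warps, sequences.

All fixtures are deterministic functions of their parameters and a seed, and
carry their ground truth (blob variance t0, warp matrix A, velocity v,
albedo/illumination factors) so tests can compare estimated quantities
against the construction.

Warp convention (used everywhere): out(x) = in(W(x)) — the output at x pulls
the input value at the warped coordinate; interpolation is bicubic with
mirror boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import ParameterError
from .spatial import Image2D
from .temporal import ImageSequence

_KINDS = ("blob", "grating", "smooth_noise_texture", "affine_warp",
          "translate_seq", "illum_scene")


@dataclass(frozen=True)
class FixtureSpec:
    """Declarative fixture request; deterministic for fixed spec + seed."""

    kind: str
    size: tuple = (96, 96)
    parameters: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        if self.kind not in _KINDS:
            raise ParameterError(f"unknown fixture kind {self.kind!r}; one of {_KINDS}")


# ---------------------------------------------------------------------------
# warps
# ---------------------------------------------------------------------------

def warp_affine(values, A, center=None, order: int = 3):
    """out(x) = in(c + A·(x - c)) for a 2x2 matrix A (x = (col, row))."""
    values = np.asarray(values, dtype=float)
    A = np.asarray(A, dtype=float)
    h, w = values.shape
    if center is None:
        center = ((w - 1) / 2.0, (h - 1) / 2.0)
    y, x = np.mgrid[:h, :w].astype(float)
    dx = x - center[0]
    dy = y - center[1]
    xs = center[0] + A[0, 0] * dx + A[0, 1] * dy
    ys = center[1] + A[1, 0] * dx + A[1, 1] * dy
    return ndimage.map_coordinates(values, [ys, xs], order=order, mode="mirror")


def shift_image(values, dx: float, dy: float, order: int = 3):
    """out(x, y) = in(x - dx, y - dy): content moves by (+dx, +dy)."""
    values = np.asarray(values, dtype=float)
    h, w = values.shape
    y, x = np.mgrid[:h, :w].astype(float)
    return ndimage.map_coordinates(values, [y - dy, x - dx], order=order, mode="mirror")


def galilean_warp(frames, v, order: int = 3):
    """out(x, t) = in(x + v·t, t): removes a translation at velocity v."""
    frames = np.asarray(frames, dtype=float)
    out = np.empty_like(frames)
    for t in range(frames.shape[0]):
        out[t] = shift_image(frames[t], -v[0] * t, -v[1] * t, order=order)
    return out


# ---------------------------------------------------------------------------
# primitive stimuli
# ---------------------------------------------------------------------------

def gaussian_blob(size, t0: float, center=None, amplitude: float = 1.0):
    """Analytic Gaussian blob of variance t0, rendered exactly.

    By default the blob is centered on the middle pixel ((size-1)//2), so
    closed-form scale-selection results hold without sub-pixel offsets.
    """
    if not t0 > 0:
        raise ParameterError("t0 must be positive")
    h, w = size
    if center is None:
        center = ((w - 1) // 2, (h - 1) // 2)
    y, x = np.mgrid[:h, :w].astype(float)
    r2 = (x - center[0]) ** 2 + (y - center[1]) ** 2
    return amplitude * np.exp(-r2 / (2.0 * t0))


def grating(size, wavelength: float, phase: float = 0.0, orientation: float = 0.0,
            amplitude: float = 1.0, offset: float = 0.0):
    """Sinusoidal grating; ``orientation`` is the normal (propagation) angle."""
    if not wavelength > 0:
        raise ParameterError("wavelength must be positive")
    h, w = size
    y, x = np.mgrid[:h, :w].astype(float)
    u = np.cos(orientation) * x + np.sin(orientation) * y
    return offset + amplitude * np.sin(2.0 * np.pi * u / wavelength + phase)


def smooth_noise_texture(size, correlation_scale: float = 2.0, seed: int = 0):
    """Gaussian-correlated random texture, zero mean and unit variance."""
    rng = np.random.default_rng(seed)
    noise = rng.standard_normal(size)
    tex = ndimage.gaussian_filter(noise, np.sqrt(correlation_scale), mode="wrap")
    tex -= tex.mean()
    sd = tex.std()
    if sd == 0:
        raise ParameterError("degenerate texture")
    return tex / sd


def translating_sequence(size, n_frames: int, v, pattern=None, t0: float = 6.0,
                         order: int = 3, centered: bool = True):
    """Sequence whose frame k shows the pattern translated by v·k.

    With ``pattern=None`` a Gaussian blob (variance t0) is rendered
    analytically at its exact sub-pixel position in every frame; an explicit
    pattern array is shifted by bicubic interpolation instead. With
    ``centered`` the blob trajectory is centered mid-sequence; otherwise it
    starts at the image center in frame 0.
    """
    if n_frames < 3:
        raise ParameterError("need at least 3 frames")
    h, w = size
    frames = np.empty((n_frames, h, w))
    if pattern is None:
        half = (n_frames - 1) / 2.0 if centered else 0.0
        c0 = ((w - 1) // 2 - v[0] * half,
              (h - 1) // 2 - v[1] * half)
        for k in range(n_frames):
            frames[k] = gaussian_blob(size, t0,
                                      center=(c0[0] + v[0] * k, c0[1] + v[1] * k))
    else:
        pattern = np.asarray(pattern, dtype=float)
        for k in range(n_frames):
            frames[k] = shift_image(pattern, v[0] * k, v[1] * k, order=order)
    return frames


def illumination_scene(size, albedo_kind: str = "texture",
                       illumination_kind: str = "step", contrast: float = 5.0,
                       gradient: float = 1e-3, seed: int = 0):
    """Synthetic albedo × illumination scene (see illumination module)."""
    from .illumination import IlluminationScene  # local import avoids a cycle
    h, w = size
    if albedo_kind == "texture":
        tex = smooth_noise_texture(size, correlation_scale=2.0, seed=seed)
        albedo = 0.55 + 0.4 * np.tanh(tex)          # in (0.15, 0.95)
        if illumination_kind == "step":
            # paired design: both illumination levels see the same texture
            # content (right half mirrors the left), so response ratios
            # between halves isolate the illumination effect
            albedo[:, w - w // 2:] = albedo[:, :w // 2][:, ::-1]
    elif albedo_kind == "blob":
        albedo = 0.2 + 0.75 * gaussian_blob(size, t0=float(min(h, w)) / 6.0)
    else:
        raise ParameterError(f"unknown albedo kind {albedo_kind!r}")
    y, x = np.mgrid[:h, :w].astype(float)
    if illumination_kind == "constant":
        illum = np.ones(size)
    elif illumination_kind == "ramp":
        illum = 1.0 + gradient * (x - (w - 1) / 2.0)
    elif illumination_kind == "step":
        illum = np.where(x < w / 2.0, float(contrast), 1.0)
    else:
        raise ParameterError(f"unknown illumination kind {illumination_kind!r}")
    return IlluminationScene(albedo=albedo, illumination=illum)


# ---------------------------------------------------------------------------
# dispatcher
# ---------------------------------------------------------------------------

def make_fixture(spec: FixtureSpec):
    """Build the fixture described by ``spec``; returns (object, metadata)."""
    p = dict(spec.parameters)
    meta = {"kind": spec.kind, "size": list(spec.size), "seed": spec.seed,
            **{k: (list(v) if isinstance(v, (tuple, np.ndarray)) else v)
               for k, v in p.items() if not isinstance(v, np.ndarray) or np.ndim(v) <= 1}}
    if spec.kind == "blob":
        img = gaussian_blob(spec.size, p.get("t0", 4.0),
                            center=p.get("center"),
                            amplitude=p.get("amplitude", 1.0))
        return Image2D(img), meta
    if spec.kind == "grating":
        img = grating(spec.size, p["wavelength"], p.get("phase", 0.0),
                      p.get("orientation", 0.0), p.get("amplitude", 1.0),
                      p.get("offset", 0.0))
        return Image2D(img), meta
    if spec.kind == "smooth_noise_texture":
        img = smooth_noise_texture(spec.size, p.get("correlation_scale", 2.0),
                                   seed=spec.seed)
        return Image2D(img), meta
    if spec.kind == "affine_warp":
        base = p.get("base")
        if base is None:
            base = smooth_noise_texture(spec.size, p.get("correlation_scale", 2.0),
                                        seed=spec.seed)
        A = np.asarray(p["A"], dtype=float)
        meta["A"] = A.tolist()
        return Image2D(warp_affine(base, A)), meta
    if spec.kind == "translate_seq":
        frames = translating_sequence(spec.size[-2:], p.get("n_frames", 16),
                                      p["v"], pattern=p.get("pattern"),
                                      t0=p.get("t0", 6.0))
        meta["v"] = list(p["v"])
        return ImageSequence(frames), meta
    if spec.kind == "illum_scene":
        scene = illumination_scene(spec.size, p.get("albedo_kind", "texture"),
                                   p.get("illumination_kind", "step"),
                                   p.get("contrast", 5.0), p.get("gradient", 1e-3),
                                   seed=spec.seed)
        return scene, meta
    raise ParameterError(f"unhandled kind {spec.kind!r}")
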