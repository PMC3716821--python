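# Methods

This note records the mathematical model, the discretization and numerical
choices, what the synthetic stimuli do and do not emulate, and the design
decisions taken where more than one reasonable construction exists.

## Receptive-field model

The spatial family is the affine Gaussian scale-space: zero-order kernels
g(x; Σ) = exp(−xᵀΣ⁻¹x/2)/(2π√det Σ) with Σ symmetric positive definite, and
directional derivatives ∂φ^{m1} ∂φ⊥^{m2} g up to total order four
(higher orders add nothing for the modelled cell classes). The scale
parameter is always a **variance** in pixel²; σ-style inputs are squared at
the CLI boundary. Anisotropic orientation enters analytically through
Σ = R(θ) diag(λ1, λ2) R(θ)ᵀ — rotated kernels are never produced by
resampling. Derivatives are generated by the recursion
∂(P·g) = (∂P − P·(Σ⁻¹x))·g on bivariate polynomial coefficients, so every
derivative kernel is an exact sample of a closed form.

The spatio-temporal family multiplies a velocity-translating spatial factor
g(x − v t; Σ) with a temporal smoother, giving a 3-D Gaussian whose
covariance has the Galilean structure [[Σ + λt v vᵀ, λt v], [λt vᵀ, λt]].
Two temporal smoothers exist:

- **non-causal**: a temporal Gaussian with variance λt and optional delay δ
  (default δ = 0; when causal-like alignment of a non-causal kernel is
  wanted, δ = 3σt is the recommended setting);
- **time-causal**: a cascade of K truncated exponential filters with time
  constants μ1..μK — mean Σμk, variance Σμk², identically zero for t < 0,
  and time-recursive: one first-order integrator state per stage, updated
  as out ← a·out + (1−a)·in with the exact decay a = e^{−Δt/μ} (unit DC
  gain, unconditionally stable).

Velocity-adapted temporal differentiation is the transport derivative
∂t̄ = vx∂x + vy∂y + ∂t. Because ∂t̄ annihilates the sheared factor
g(x − v t; Σ), the n-th velocity-adapted derivative kernel factorizes into
the spatial derivative factor evaluated at x − v t times the n-th plain
derivative of the temporal smoother; this identity is used for
construction and makes the advection-annihilation property (zero response
to a pattern co-moving at v) hold to discretization accuracy.

Cell models: retina/LGN center–surround cells are ±∇²g(·; s) composed with
a temporal smoother (on-center = −∇²g, i.e. center-positive taps; the
polarity sign convention is ours, the literature states it only
qualitatively). The temporal operator is the plain n-th derivative; a
power-law time reparametrization is deliberately not applied because its
exponent is a free parameter with no canonical value. V1 simple cells are
directional affine Gaussian derivatives, velocity-adapted when a temporal
part is present.

## Discretization

Kernels sample the continuous closed forms at integer pixel offsets with
the origin at the center tap, truncated at `radius_factor` marginal
standard deviations per axis. Zero-order kernels are renormalized to unit
sum (constants are preserved exactly); derivative kernels are
mean-corrected to an exactly zero tap sum (responses to constants vanish,
which is also what makes log-domain illumination invariance exact).
Convolution mirrors the image (reflect-101; constant and replicate padding
are selectable) and runs through FFT on the padded array.

`radius_factor` defaults to 4, which keeps kernels compact and leaves
~1.3·10⁻⁴ of truncated mass in 2-D — adequate for responses and for the
semigroup check at the 10⁻³ level. The cascade identity
g(s2) * f = g(s2−s1) * g(s1) * f holds to 10⁻⁶ of the dynamic range only
with ~6σ support (the truncation error, not aliasing, dominates; sampled
Gaussians alias at e^{−2π²s} ≈ 10⁻⁹ already at s = 1), so
cascade-sensitive checks use `radius_factor=6`. Both numbers follow from
the forward error analysis above and were fixed before tuning anything
else.

The 1-D exponential cascade is sampled at resolution dt (default
min(1, min(μ)/4)): per stage, midpoint sampling plus renormalization gives
exactly the geometric impulse response (1−a)aᵏ of the integrator, so
streaming equals batch convolution to machine precision, while the
midpoint time assignment t = (k + K/2)·dt keeps mean and variance accurate
to O(dt²) (~0.5% at the default). Inside 3-D kernels the time axis is one
tap per frame; causal kernels store explicit zeros at negative lags and
temporal differentiation uses backward differences so causality stays
bitwise exact. A kernel's time axis, not its storage order, carries the
delay; convolution therefore looks only into the past for causal kernels.

Warps (affine, translation, Galilean) are bicubic pull-backs
out(x) = in(W(x)) with mirror boundary; coordinates are (x=col, y=row)
with angles measured from +x toward +y; velocities are pixels/frame with
positive vx rightward.

## Selection mechanisms

**Scale selection.** Normalized derivatives use γ = 1 (the value at which
the blob closed forms hold: |s∇²L| at the center of a blob of variance t0
equals s/(π(s+t0)²)·A, maximized at s = t0; s²det H L gives
s²/(4π²(s+t0)⁴), same argmax). The scale grid is logarithmic (default 2
levels/octave on [1, 256]); extrema of the signature are refined by a
3-point quadratic fit in (log s, value) — both blob signatures are
symmetric to third order in log s around their peak, which is why the
selected scale lands within 0.1% of t0 despite the coarse grid. Among
multiple extrema the strongest |normalized response| wins; all are
reported. Patch normalization resamples with step √(ŝ/s_ref).

**Affine adaptation.** The second moment uses affine Gaussian derivative
kernels at Σ_local and an affine Gaussian window Σ_int = r²Σ_local (fixed
coupling, default r = 2); the window taps are evaluated at the fractional
offset so probe points may be sub-pixel. The iteration normalizes Σ to
unit determinant each step (overall area is the scale channel, handled by
scale selection; the fixed point determines only the two foreshortening
degrees of freedom) and updates toward μ⁻¹, with a 0.5 damping step when
the residual increases. Convergence is declared when the second moment
seen in the normalized frame has λmax/λmin − 1 below `tol` (default 0.05;
the validation fixtures refine to 0.01 because the returned frame's
accuracy is set by the stopping tolerance). Two behaviours are reported as
errors rather than silently returned: a flat patch (gradient RMS far below
the image's dynamic range) and runaway elongation (cond(Σ̂) beyond 100),
which occurs when the local pattern is effectively one-dimensional — a
ridge has no well-posed affine frame, the 2-D analogue of the aperture
problem. Empirically about a quarter of random-texture points are of this
kind, so consumers should probe several candidate points and use the ones
that converge, as the validation suite does.

Two facts found during validation are worth recording. First, the
fixed point is exactly covariant under affine maps — measuring in two
views with matched windows reproduces μ' = Aᵀ μ A to 10⁻⁴ — but only at
*corresponding window areas*; since unit-determinant normalization leaves
area fixed, two-view comparisons are meaningful for area-preserving warps
(det A = 1), which is exactly the foreshortening-modulo-scale case the
mechanism is for. Second, at a genuine fixed point the frame error is set
by the stopping tolerance, not by estimator noise, so tightening `tol`
directly tightens cross-view frame consistency.

**Galilean diagonalization.** First derivatives (Lx, Ly, Lt) are computed
with separable Gaussian smoothing (spatial variance s = 2, temporal
variance λt = 2 by default) or the causal cascade; the six products are
averaged with a separable Gaussian window at r²·(s, s, λt), r = 2. The
velocity solving the 2×2 normal equations zeroes the mixed entries of the
transformed second moment exactly (by construction), is exact for rigid
translation in the continuum, and is additive under composed Galilean
warps. A spatial block with eigenvalue ratio beyond 10⁴ raises a
degeneracy error naming the deficient direction (aperture problem).
Right-hand sides below 10⁻¹⁴ of the trace are snapped to zero so a static
sequence yields exactly v = 0.

**Illumination.** Log luminosity uses the natural logarithm with a floor
clamp at 10⁻⁶ of the peak (counted, not silent). Invariance of
derivative responses under f → c·f is exact because the kernels have
exactly zero tap sum; zero-order kernels are rejected explicitly since
their response shifts by log c.

## Synthetic stimuli

Fixtures are deterministic functions of parameters and a seed and carry
their ground truth: analytic Gaussian blobs (rendered from the closed
form, centered on a pixel so closed-form selection results apply),
sinusoidal gratings, Gaussian-correlated noise textures, affine warps,
translating sequences (blob trajectories rendered analytically at exact
sub-pixel positions; arbitrary patterns shifted bicubically), and
albedo × illumination scenes. The sun/shade scene uses a paired design —
the shaded half mirrors the sunlit half's albedo — so between-half response
ratios isolate the illumination effect rather than texture sampling noise.

What these stimuli do not emulate: sensor noise, occlusion and
disocclusion, perspective (warps are globally affine, not projective),
temporal illumination changes, aliasing from genuinely band-unlimited
content, and natural-image statistics. Passing tests therefore establish
the correctness and the stated covariance/invariance properties of the
operators, not detection or estimation performance on natural footage.

## Problem sizes and tolerances

The validation suite runs on desk-scale fixtures: images of 48–161 px,
sequences of 16–24 frames, 20 random images for the non-enhancement sweep,
a 5×5 velocity grid on 48×48×16 sequences. Key tolerances: semigroup L1
error < 10⁻³; cascade < 10⁻⁶ of range; blob scale within 5% (measured
~0.03%); velocity within 0.05 px/frame (measured ~0.02); cascade variance
within 2% (measured ~0.5%); affine isotropy residual < 0.05 within 20
iterations with two-view frame consistency < 5%; illumination gain
invariance < 10⁻¹⁰ (measured ~10⁻¹⁶); DoG vs (s2−s1)·½∇²g below 2% at
scale ratio 1.05 and monotone in the ratio. Interior margins exclude one
kernel radius near borders wherever boundary handling would otherwise
contaminate a comparison (boundary extension does not commute with
cascading or warping).

## Known limitations

- The affine fixed-point search is local; with poor initialization or
  strongly oriented structure it reports degeneracy rather than searching
  globally.
- Temporal scale covariance is only approximate for the exponential
  cascade (exact temporal rescaling covariance is not achievable in a
  time-recursive model with pre-fixed scale levels).
- Per-pixel (dense) velocity fields are supported only by evaluating the
  regional estimator at many points; there is no joint velocity/scale
  extremum search.
- Derivative order is capped at four spatially and two temporally.
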