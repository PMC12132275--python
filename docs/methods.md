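# Methods

This note documents the models implemented in `mle`, the defaults and why
they were chosen, what the digital phantoms emulate, and the numerical
decisions a user should know before trusting the outputs.

## Spectral model and unmixing

Reflectance at the 8 system wavelengths (406, 446, 468, 522, 543, 562, 635,
657 nm) is converted to absorbance `A = −log₁₀ R` and modeled per pixel with
the modified Beer-Lambert law

    A(λ) = (ε_HbO₂(λ) c_HbO₂ + ε_Hb(λ) c_Hb) · L + O

with a single optical pathlength `L` assumed constant across wavelengths and
an offset `O` absorbing scattering loss and residual absorbers. The design
matrix therefore has columns ε_HbO₂(λ), ε_Hb(λ), and a constant; the fit is
per-pixel non-negative least squares (active-set NNLS; an unconstrained
least-squares fast path is used where its solution is already non-negative —
the two coincide exactly in that case). Non-negativity makes
`StO₂ = c_HbO₂/(c_HbO₂+c_Hb)` land in [0, 1] by construction; pixels with
zero total hemoglobin are masked rather than given a saturation. The offset
is fit per pixel, since the model is per pixel and tissue heterogeneity
makes a global offset unjustifiable. Concentration units are relative
throughout: only ratios and changes are meaningful, not absolute molarity.

A Kubelka-Munk pathway converts reflectance to absorption as
`K(λ) = S(λ)(1−R)²/(2R)` with an explicit reduced-scattering spectrum and an
optional melanin column in the design, for skin-like targets where melanin
and scattering dominate the 657 nm-normalized signal.

The bundled extinction table (`src/mle/data/hemoglobin_extinction.csv`) is
an approximate transcription of the standard compiled oxy/deoxy-hemoglobin
molar extinction curves, stored in mm⁻¹·mM⁻¹ on a 10 nm grid with linear
interpolation onto the band centers; the narrowband diodes are treated as
delta functions. Because all outputs are relative, only the spectral shape
matters, and the shape (Soret band, 542/577 oxy peaks, 555 deoxy peak,
isosbestic crossings, red-region separation) is reproduced.

Band registration note: the system's registration reference channel and red
normalization channel are quoted in the hardware description as 561/562 nm
and 657/659 nm; the package carries one band named 562 and one named 657.

Preprocessing defaults: 5×5 Gaussian denoising with σ = 0.5 px (the kernel
support is exactly 5×5), saturation/underexposure thresholds 0.98/0.02 on
the [0, 1] intensity scale, and reflectance kept inside (0, 1) either by
global max-plus-ε normalization (ε = 10⁻³) or per-pixel 657 nm-channel
normalization.

## Speckle flow model

Speckle contrast is `K = σ/⟨I⟩` over a sliding 5×5 window using the
population (1/n) standard deviation; the estimator bias of so small a window
is accepted because all comparisons are relative. Flow contrast is
`V = 1/K²`. Temporal improvement averages V frames (not K) within a
window after registering the paired white-light frames to the window-center
frame with the MSE estimator and applying the same transforms to V;
pixels carried out of the field of view are masked. The library computes the
averaged map for one (central) window; a rolling series is a loop over this
primitive. A 9×9 median filter is available for display only and is never
applied before quantification.

Two between-ROI metrics are provided and they answer different questions:

- `rms_contrast` — union std/mean over the two ROIs: scale-invariant,
  symmetric; used to compare lesion/background contrast across modalities on
  a single map.
- `contrast_to_noise` — |μ_a − μ_b| divided by the pooled within-ROI
  standard deviation. This is the quantity temporal averaging improves.
  Linear averaging of decorrelated V frames leaves all region means fixed
  and shrinks within-region variance, so *any* mean-relative union statistic
  is non-increasing in the window size — the emergence of vasculature with
  averaging is a contrast-to-noise effect, and the √n-shaped growth of
  `contrast_to_noise` with window size (steep over the first few frames,
  gradual beyond) is the phantom counterpart of that observation.

## Photometric stereo

Normals are the per-pixel least-squares solution of `I = S n⃗` with
`S` the (N≥3)×3 matrix of unit light directions and albedo `π|n⃗|`; the
solve is a single pseudoinverse applied to all pixels. Speculars are
inpainted first (threshold 0.95 after 1 px dilation, harmonic fill via a
sparse Laplace solve with the surrounding pixels as boundary); frames can be
MSE-registered to the first of each directional triple. The distant-light
Lambertian model is knowingly wrong at low spatial frequencies for
near-camera anisotropic sources; that error is removed, not modeled: each
normal component is high-pass filtered (Gaussian low-pass subtracted,
σ = 150 px at the native 1350 px frame width, scaled proportionally with
image width), the z-component is recentered by +1, and the field is
renormalized to unit length. The filter entry point exists for normals
(default) and heights (`compare_height`); heights are therefore meaningful
only above the filter's cutoff and up to scale.

Height integration minimizes ‖∇h − (p, q)‖² with `p = −n_x/n_z`,
`q = −n_y/n_z` (n_z clamped at 10⁻³), forward-difference gradients, Neumann
boundaries, and the zero-mean gauge; the normal equations are diagonalized
by a type-II DCT and solved exactly — spectrally equivalent to multigrid,
and exact (to round-off) for discretely integrable fields, so planes
reconstruct to machine precision and discrete-curl perturbations are
invisible. Re-lighting uses Phong shading (ambient 0.1, specular 0.3,
exponent 16) from normals recomputed off the integrated height.

## Spectral enhancement

Color images are simulated as `channel_c = Σ_λ R(λ) w_c(λ)` with
non-negative per-band weights playing the role of camera transmission ×
illumination. Before scoring, each pixel is scaled so its maximum channel
is 0.8 (brightness removal); display images are instead scaled to mean 0.4.
Scores are the mean CIEDE2000 over all normal×lesion pairs of sampled
pixels (default 100 per class) after a linear-RGB → XYZ (D65) → Lab
conversion; the clinical processor's display gamma is unknown and
deliberately not modeled. The CIEDE2000 implementation is the full formula
(lightness/chroma/hue weights, blue-region rotation term, k factors 1) and
reproduces the canonical 34-pair test set bundled under `src/mle/data/` to
better than 10⁻⁴.

Optimization is projected gradient ascent: central finite-difference
gradients (the Lab conversion makes analytic gradients unrewarding), step
halving/growth with backtracking, projection to the non-negative simplex per
channel after every step. Per-channel sum normalization is a deliberate
constraint: brightness-normalized scores are scale-degenerate without it.
The WLE preset uses smooth Gaussian RGB band responses (610/540/450 nm,
σ 50/45/40 nm); the NBI preset puts the 415 nm hemoglobin band in the
display blue+green channels and the 540 nm band in red, the conventional
narrow-band display mapping; true camera/illuminant spectra of a specific
clinical system are not published, so presets are parametric stand-ins.
Dataset rescaling (band means equalized across cubes) is applied before
color work only, never before unmixing. Weight sets are optimized per image;
pooling across a dataset is possible by concatenating sampled spectra.

## Preprocessing and registration

Interlaced frames are split by parity (1-based odd video fields live in
0-based even row indices) and each field is vertically re-expanded by linear
interpolation with edge replication, so decimating an output at its own
parity returns the original field rows exactly. Undistortion inverse-maps
through the Brown-Conrady model (k₁,k₂,k₃,p₁,p₂) with bilinear sampling and
masks out-of-view pixels; measuring intrinsics is out of scope.

Both registration estimators share an affine parameterization (tx, ty,
rotation, scale, shear — shear off by default) acting about the image
center, a 3-level coarse-to-fine pyramid, and return the transform mapping
moving → fixed with convergence diagnostics instead of exceptions. The MSE
estimator follows gradient descent with step-halving line search on a
normalized numerical gradient (relative tolerance 10⁻⁶, 200 iterations);
the MI estimator maximizes a 64-bin joint-histogram mutual information made
smooth by bilinear (partial-volume) soft binning, optimized with Powell per
pyramid level. On phantom fixtures both recover 5 px / 2° jitter to better
than 0.01 px / 0.01°.

Auto-exposure solves `observed(pw) = target` by a secant step on the last
two distinct (pulse width, observed intensity) samples, returns the pulse
width unchanged when within tolerance (default 0.01), falls back to a
proportional `target/observed` rescale when the secant denominator
vanishes, and clips to configured bounds.

## What the phantoms emulate — and what they do not

- Tissue scenes drive the same Beer-Lambert forward model the unmixer
  inverts, with defaults chosen as realistic colonic-mucosa magnitudes
  (total hemoglobin 0.05 mM, pathlength 2 mm, offset 0.1, background StO₂
  0.60, lesion 0.80) and multiplicative Gaussian reflectance noise (1% in
  the standard conditions). Forward/inverse consistency tests therefore
  validate the inversion, not the physics: wavelength-dependent pathlength,
  partial volume, and nonlinear detector response are absent.
- Speckle sequences are low-pass-filtered circular complex Gaussian fields
  (fully developed speckle, unit contrast, grain default 2 px) whose white
  field evolves by Ornstein-Uhlenbeck steps; each frame integrates 8
  sub-exposures so intra-exposure motion blurs the speckle — the mechanism
  LSCI reads. Velocity maps to channel decorrelation time as τ = 2/v frames
  over the microvascular range 0.4–2.2 mm/s; only monotonicity of this map
  is asserted anywhere. No photon transport, no static-scatterer layer over
  the channel, no exposure-time calibration: absolute velocity is out of
  scope.
- Surface scenes render Lambertian shading from central-difference normals
  of a known height map, matching the solver's model exactly; real tissue
  adds near-field illumination falloff, subsurface scattering, and
  interreflections that appear only as the low-frequency error the high-pass
  removes.
- Scope motion is small affine jitter (≤10 px) with retained ground truth;
  real endoscope motion includes perspective and non-rigid components the
  affine model only approximates.

Passing tests on these phantoms shows the estimators are correct for their
models at phantom scale (64–128 px frames, chosen so the full suite and the
acceptance script run in seconds); it does not certify accuracy on clinical
data, where the benchmark numbers depend on the physical endoscope.

## Numerical conventions

Pixel values are float in [0, 1] (integer rasters normalized by full bit
range at read); coordinates are row-major, origin top-left, x right,
y down, camera along +z, 0-based. All generators and the pipeline are
deterministic given a seed; the CLI derives independent per-stage seeds by
hashing so stages can be re-run in isolation. Masks carry reason codes
(saturated, underexposed, out_of_fov, specular), combine by union, and
propagate through every map-producing operation; degenerate pixels (zero
window mean, K = 0, |n⃗| < 10⁻⁸, R ≤ 0) are masked, not raised.
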