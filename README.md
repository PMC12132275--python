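# mle — multi-contrast laser endoscopy processing

Processing stack for multi-contrast laser endoscopy: an imaging approach in
which a clinical endoscope is driven by rapidly tunable narrowband, coherent,
and directional laser illumination so that, alongside standard white-light
video, it measures **tissue chromophores**, **blood flow**, and **surface
topography**. This package implements the computational half of that system
for researchers in biomedical optics and gastrointestinal imaging, together
with digital phantoms that stand in for the endoscope hardware so every
stage is testable on a desk.

Four contrasts are produced:

- **Multispectral reflectance → StO₂** (`mle.spectral`). Per-pixel absorbance
  at 8 narrowband wavelengths (406–657 nm) is modeled with the modified
  Beer-Lambert law, `A(λ) = −log₁₀ R(λ) = (ε_HbO₂(λ)c_HbO₂ + ε_Hb(λ)c_Hb)·L + O`,
  and inverted by non-negative least squares; total oxygen saturation is
  `StO₂ = c_HbO₂/(c_HbO₂ + c_Hb)`. A Kubelka-Munk pathway
  (`K = S(1−R)²/2R`, optional melanin column) handles strongly scattering
  targets.
- **Laser speckle contrast imaging** (`mle.lsci`). Speckle contrast
  `K = σ/⟨I⟩` in a sliding 5×5 window, flow contrast `V = 1/K²`, and
  registered temporal averaging of V frames guided by interlaced white-light
  frames.
- **Photometric stereo** (`mle.photostereo`). Per-pixel least-squares solution
  of `I_{N×1} = S_{N×3} n⃗` under a Lambertian model (`|n⃗| = ρ_d/π`),
  low-frequency error suppression by Gaussian high-pass of the normal field
  (σ = 150 px at full frame width), and Poisson integration of the gradient
  field to a height map (Neumann boundaries, DCT solve).
- **Spectral enhancement** (`mle.enhance`). Simulated RGB from per-band
  weights, full CIEDE2000 (ΔE₀₀) color difference, and projected gradient
  ascent on the mean ΔE₀₀ between lesion and normal pixel samples.

`mle.preprocess` supplies dark subtraction, deinterlacing, Brown-Conrady
undistortion, mutual-information and mean-square-error affine registration,
and the secant auto-exposure update; `mle.frameio` defines the data model
(TIFF + JSON sidecar stacks, spectra CSV, geometry JSON); `mle.phantoms`
generates Beer-Lambert tissue scenes, dynamic speckle with intra-exposure
decorrelation, directionally lit height maps, affine-jittered stacks, and a
Macbeth-style chart, each retaining its ground truth.

## Worked example

Run the full pipeline on a phantom bundle:

```sh
mle all --out runs/demo --size 64 --seed 1
```

which prints

```
spectral: mean StO2 0.6248
lsci: channel V 2.116, rms contrast 0.3552, n_averaged 15
pse: height MAE (matched high-pass) 0.1274
enhance: dE00 WLE 0.370 -> optimized 11.538
```

Reading the numbers: the tissue phantom is 60% oxygenated mucosa with a
lesion at 80%, so the mean recovered StO₂ of 0.62 sits between the two; the
flow stage reports the mean flow contrast V inside the channel and the
between-ROI RMS contrast of the averaged map; the surface stage reports the
mean absolute height error against the generator's ground truth after both
maps receive the same high-pass filter and unit normalization; the
enhancement stage shows the lesion/normal CIEDE2000 color difference rising
from 0.37 under the white-light preset to 11.5 with optimized spectral
weights. Each run directory contains the resolved configuration, StO₂ and
chromophore rasters, K/V flow maps, the normal/height/relit surface
outputs, optimized weights with their score trace, a log, and a
`manifest.json` with SHA-256 checksums of every artifact (byte-identical
across runs at a fixed seed).

The same stages are available as library calls; see the module docstrings
in `src/mle/` and the examples exercised in `tests/`.

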