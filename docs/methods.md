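# Methods

## The problem

An infrared micro-spectrometer records, per wavenumber channel, the fraction
of radiation lost between source and detector.  For an intact micro-sample
(a fungal cell, a pollen grain, a PMMA bead) that loss mixes two physically
different effects: molecular absorption, and Mie-type scattering out of the
collection cone of the objective.  The scattering itself depends on the
sample's complex refractive index — hence on its chemistry — so the measured
"absorbance" entangles morphology, optics and chemistry nonlinearly.

`irtomo` treats this as an electromagnetic inverse scattering problem for
samples well approximated by two concentric spherical layers (cell wall and
interior).  The forward map is solved exactly; the inverse map is learned by
a neural network trained purely on simulated spectra; a closed-loop
re-simulation from the network's predictions validates them per spectrum.

## Forward model

For each of 737 wavenumber channels spanning 1006–3844 cm⁻¹:

1. **Layer optics.**  Each layer's complex refractive index is built from its
   molecular absorption spectrum α(ν̃) through the Kramers–Kronig pair

       Im n(ν̃) = ln(10) α(ν̃) / (4π ν̃ d)
       Re n(ν̃) = n₀ + (c/π) P ∫ α(Ω)/(Ω² − ν̃²) dΩ,

   with n₀ the constant real effective index of the layer in the IR window
   (the standard IR assumption), d a path-length-like scale (cm) and c a
   dispersion scale.  A constant imaginary offset models diffuse attenuation.
   Only the products of α's unit with d (resp. c) are identifiable, so both
   scales are exposed as free parameters.

2. **Scattering.**  Coated-sphere Mie coefficients aₙ, bₙ are computed by
   logarithmic-derivative downward recursion inside each layer with
   bounded-ratio layer transfer (the numerically stable stratified-sphere
   scheme; upward recursion of the regular radial functions diverges for
   absorbing media).  Truncation follows the Wiscombe criterion
   N = ⌈x + 4x^(1/3) + 2⌉ on the outer size parameter x = 2πν̃a
   (radii in μm are converted to cm against ν̃ in cm⁻¹).  The host medium is
   vacuum/air (index 1).

3. **Detection.**  The scattering loss that registers as absorbance is the
   radiation scattered beyond the collection half-angle θ_NA:

       Q_sca^NA = (2πν̃a)⁻² ∫_{θ_NA}^{π} (|S₁|² + |S₂|²) sinθ dθ,

   evaluated with Gauss–Legendre quadrature (max(256, 4N) nodes; the
   integrand oscillates on the 1/x angular scale).  The unpolarized
   azimuth-averaged form is used, which reduces to the series Q_sca at
   θ_NA = 0.  With Q_abs = Q_ext − Q_sca, mixing ratio C and detector fill
   fraction g/G, the apparent absorbance is

       A = −log₁₀(1 − (g/G)(C·Q_abs + Q_sca^NA)),

   base-10 by the absorbance convention (the same ln 10 that appears in the
   KK imaginary part).  (g/G)(C·Q_abs + Q_sca^NA) ≥ 1 is rejected as total
   extinction.

Numerical validation: the coefficients agree with an extended-precision
boundary-condition oracle to ~10⁻¹⁵, conserve energy to 10⁻⁸, satisfy the
optical theorem, collapse to homogeneous Mie when the layers match, and
reach the Rayleigh x⁴ limit and the coated-sphere electrostatic
polarizability closed form for small x.

### Principal-value evaluation

The KK real part is computed with the Maclaurin alternating-point scheme on
the uniform grid: channel i sums the integrand over the opposite-parity
sub-grid with weight 2h, which skips the singular node exactly and converges
at O(h²).  α is taken as zero outside the grid; the resulting smooth
baseline-like bias is absorbed by the free parameters c and n₀ during
refinement.  Note the 1/(Ω²−ν̃²) kernel carries, besides the familiar
antisymmetric resonance shape, a smooth positive background
≈ ∫α dΩ / π(ν̃₀²−ν̃²) — about 10% of the dispersion extremum for a typical
amide-width band — so "dispersion vanishes far from the band" holds for the
resonant odd component only.  The default simulation scale is d = 10⁻³ cm
with the causally consistent c = ln(10)/(2πd) ≈ 366, which produces the
Δn ≈ 0.05 anomalous-dispersion excursions (for unit-peak α) that give
measured spectra their derivative-like band distortions; with c = 1 the
dispersion term would be ~10⁻⁴ and invisible next to n₀ ∈ [1.3, 1.6].

## Synthetic training data

The generator draws i.i.d. samples of the study conditions:

| quantity | distribution | rationale |
|---|---|---|
| outer radius a_cw | U[1.25, 20] μm | the simulated size span |
| wall thickness | U[0.02, 0.5] × a_cw | brackets fungal (~0.1–0.3) and pollen (~0.2–0.3) relative walls |
| n₀ (both layers) | U[1.3, 1.6] | the simulated index span |
| layer chemistry | PCA latent spaces | see below |
| α amplitude | U[0.3, 1.0] | peak absorbance order 0.1–1 |
| C | log-U[0.3, 3] | absorption/scattering mixing unknown per instrument |
| g/G | U[0.1, 1] | sample/detector fill fraction |
| θ_NA | 30° ± 5° jitter | typical Cassegrain collection |
| diffuse Im n | U[0, 0.01] | weak diffuse attenuation |

Chemistry: "scatter-free" biological absorption spectra are synthesised as
non-negative Lorentzian/Gaussian mixtures over 16 canonical mid-IR bands
(ester C=O 1745, amide I/II/III, CH₂/CH₃ stretches, amide A, carbohydrate
C–O, phosphate), grouped into lipid/protein/carbohydrate/nucleic emphases.
16 latent spaces (default) are built by PCA (6 components) over 48 such
spectra each with a distinct random group emphasis; training chemistry is
sampled per layer as mean + scores·loadings with per-component Gaussian
scores truncated at ±3 sd and negative excursions clipped.  This emulates
latent spaces decomposed from measured spectral libraries; it does **not**
contain measured band-shape correlations, water-vapour structure, or real
biological covariance between layers, so quantitative recovery numbers on
synthetic data say nothing about instrument-specific artefacts — they test
the inverse solver under the stated physics.

Augmentation (in order): Gaussian ripple smoothing (FWHM 16 cm⁻¹ — sharp
resonance ripples are rarely resolved by real instruments), an asymmetric
atmospheric CO₂ doublet near 2350 cm⁻¹, a quadratic baseline in the
normalised spectral coordinate, then additive Gaussian noise (sd 0.005
absorbance); smoothing precedes noise so the noise itself is not smoothed.
Per-channel multiplicative radius perturbation (0.5% relative, low-pass) and
the NA jitter act inside the physics, not as post-processing.

## The inverse solver

A 737-channel spectrum is standardised (per-channel training statistics) and
encoded by blocks of attention-augmented 1D convolutions: each block
concatenates a convolution (kernel 7) with multi-head self-attention along
the channel axis, then batch-norm, ReLU and max-pool.  Attention carries the
global spectral context — the scattering wiggles span the whole spectrum —
that local convolutions miss.  A fully connected layer yields the latent
code.  Three heads decode it:

* two mirrored 1D decoders (nearest-neighbour unpooling + convolution;
  softplus output, so α ≥ 0) for interior and wall absorption;
* a parameter head with bounded transforms: a_cw ∈ [1.25, 20] μm by scaled
  sigmoid, a_int = a_cw·σ(u) (so a_int < a_cw structurally), n₀ ∈ [1.3, 1.6];
* a ShapeNet of 3D transpose convolutions decoding the voxelised
  effective-index map (value 0 outside the sample), pre-trained as the
  decoder of a 3D convolutional autoencoder over rasterised concentric
  spheres.

Training is two-phase: phase 1 fits encoder, absorption decoders and the
parameter head; phase 2 swaps the parameter head for the pre-trained
ShapeNet, fine-tuning the encoder at 10× lower learning rate (our choice;
freezing it is the conservative alternative).  Losses: per-spectrum
MSE + λ(1 − Pearson r) with λ = 1 for the absorptions (MSE anchors scale,
the r term scores shape, which is what matters in IR); parameter MSE
weighted by inverse squared sampling-range widths so radii and indices carry
equal importance; for the ShapeNet, a distance-transform-weighted squared
error mean((p−t)²(1 + DT_t² + DT_p²)) — a differentiable surrogate that
penalises misplaced boundary voxels quadratically in their distance, with
the exact set Hausdorff distance (KD-tree max–min) reported alongside as the
metric.  Constant-target rows skip the Pearson term with a warning.
Optimisation is Adam (default 10⁻³, batch 64), all runs seeded and
reproducible from (seed, config, dataset hash).

The network stack runs on a compact NumPy reverse-mode autodiff engine
written for this package (float32 by default; conv1d via im2col + BLAS,
conv3d by kernel-offset accumulation, fused batch-norm).  Every layer's
gradient is verified against central finite differences in the test suite.

## Closed-loop refinement

Given predictions for one measured spectrum, the spectrum is re-simulated
through the identical forward pipeline and the non-learned parameters —
KK dispersion scale c, mixing ratio C, and baseline/linear/quadratic
coefficients (on the normalised coordinate, for trust-region conditioning) —
are fitted by COBYQA, a bound-constrained derivative-free trust-region
quadratic-model method of the Powell (BOBYQA) family, minimising the MSE
within bounds (default budget 500 evaluations, one restart from a perturbed
best point).  d is held fixed: c·d and C are partially degenerate with the
overall absorbance scale.  The refined fit correlation r_fit is the validity
check: no free-parameter setting rescues wrong radii/indices, so correct
predictions separate cleanly from randomised ones.

## Problem sizes

Unit tests run at fixture scale (16–64 records).  The acceptance study
trains the reduced configuration (5 encoder blocks, 12→48 channels,
attention in the two deepest blocks, latent 64) on 4 000 simulated records
for 14 epochs and evaluates on 800 held-out records; the refinement study
uses 12–20 unaugmented spectra at 60–70-evaluation optimizer budgets.  These sizes were
chosen so the full study reruns on a single CPU in minutes; parameter
recovery improves steadily with corpus size and epochs (the full-scale
configuration in `ModelConfig()` with ≥2×10⁴ records is the research-grade
setting), and the reported R² values at this scale are therefore
substantially below the full-scale ceiling, with the difficulty *ordering*
(outer radius easiest, interior index hardest) already stable.

## Numerical choices and edge cases

* Truncation: Wiscombe order on the outer size parameter; the shared batch
  order for a whole spectrum is the criterion at the largest channel.
* Coefficients are checked finite; a negative Q_abs beyond −10⁻⁸ raises
  instead of being silently clamped.
* Degenerate spectra: constant targets skip the Pearson term; empty
  thresholded voxel sets in the shape metric fall back to the grid-diagonal
  penalty; zero-width refinement bounds return the fixed parameters.
* Spectra files are accepted in either grid orientation and resampled by
  linear interpolation; files already on the common grid are passed through
  untouched.
* Total-extinction parameter draws during dataset generation are redrawn;
  the same condition on user input raises with the offending channel.

## Known limitations

* Two concentric spherical layers only; ellipsoids, cylinders, off-centre
  inclusions and >2 layers are out of scope (the forward recursion
  generalises, the sample types do not).
* Focusing optics are not modelled; the collection geometry enters only
  through θ_NA.
* The synthetic chemistry spans band mixtures, not measured libraries;
  applying a model trained on it to real measurements benefits from
  retraining with latent spaces built from measured scatter-free spectra.
* The voxel map is a proof-of-concept output: layer parameters are read from
  the parameter head, not segmented out of the continuous voxel field.
* The shape autoencoder reconstructs held-out spheres to RMSE ≈ 0.05–0.1
  index units at the 16³ CPU-scale configuration — boundary staircase
  voxels dominate this number; background voxels stay below 0.05.
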