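# irtomo — infrared diffraction micro-tomography

`irtomo` recovers the 3D optical, structural and chemical properties of
spherical micro-samples — fungal cells, algae, pollen grains, polymer beads —
from single infrared absorbance spectra.  Instead of *correcting* Mie
scattering out of measured spectra, it *exploits* it: the broad interference
wiggles and band distortions that scattering imprints on a spectrum encode
the sample's morphology and refractive index, and a neural inverse-scattering
solver trained on exactly simulated spectra reads them back out.

For a two-layer concentric sphere (cell wall + interior) the package
delivers, from one 737-channel spectrum (3844–1006 cm⁻¹):

* the molecular absorption spectrum of each layer, α_int(ν̃) and α_cw(ν̃),
* the outer radius a_cw and interior radius a_int (μm),
* the effective refractive index of each layer, n₀_int and n₀_cw,
* optionally a voxelised 3D map of the effective refractive index,
* a closed-loop validity check: the spectrum re-simulated from the
  predictions, with the non-learned parameters refined by derivative-free
  optimisation, and its fit correlation r_fit.

## The model in brief

Per wavenumber channel ν̃, each layer's complex index follows from its
molecular absorption via the Kramers–Kronig pair
Im n = ln(10)·α/(4πν̃d) and Re n = n₀ + (c/π)·P∫α(Ω)/(Ω²−ν̃²)dΩ; the
coated-sphere scattering problem is solved exactly (stable log-derivative
recursions); the loss registered by a detector of collection half-angle θ_NA
is Q_ext^NA = C·Q_abs + Q_sca^NA with
Q_sca^NA = (2πν̃a)⁻²∫_{θ_NA}^π(|S₁|²+|S₂|²)sinθ dθ, giving the apparent
absorbance A = −log₁₀(1 − (g/G)·Q_ext^NA).  The inverse map A(ν̃) → (α, a,
n₀) is learned by an attention-augmented 1D CNN encoder with two absorption
decoders, a bounded parameter head and a 3D transpose-convolutional ShapeNet,
trained in two phases on simulated spectra.  See `docs/methods.md` for the
full account.

## Worked example

```bash
python examples/01_forward_simulation.py
```

prints:

```
simulated absorbance over 737 channels (1006-3844 cm^-1)
  apparent absorbance range: 0.173 .. 0.474  (peak at 1021 cm^-1)
  fingerprint-region mean:   0.360
The broad oscillations are Mie 'wiggles' from the 6 um sphere; the
molecular bands (ester 1745, amide 1655/1545 cm^-1) ride on top of
them, distorted by the anomalous dispersion each band induces.
```

Even where the cell absorbs nothing the apparent absorbance stays near 0.2 —
pure scattering loss — and the strongest feature sits in the carbohydrate
region where wall absorption and its anomalous dispersion reinforce; that
mixing is the signal the inverse solver disentangles.  The other
examples train a small solver (`02`), run the closed-loop reconstruction
check (`03`) and bin a hyperspectral focal-plane-array cube to one spectrum
per sample before prediction (`04`).

## Command line

The same workflow as a tool:

```bash
irtomo simulate --n 4000 --seed 0 --out train.h5
irtomo train --dataset train.h5 --epochs 14 --out model.npz
irtomo predict --model model.npz --spectrum measured.txt --out pred.json
irtomo reconstruct --pred pred.json --spectrum measured.txt --out fit.json
irtomo bin-fpa --cube cube.h5 --mask roi.txt --out binned.txt
irtomo pipeline --out-dir run/   # end-to-end with a YAML config
```

`measured.txt` is a two-column wavenumber/absorbance text file covering
1006–3844 cm⁻¹ (either order); spectra are resampled to the common grid.

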