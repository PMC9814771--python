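"""Simulate the scatter-distorted IR absorbance spectrum of a layered cell.

Builds a two-layer concentric sphere (lipid-rich interior, protein/
carbohydrate wall), solves the coated-sphere scattering problem per
wavenumber channel, and prints how scattering reshapes the spectrum.
"""

import numpy as np

from irtomo.chemistry import BAND_LIBRARY, synth_scatter_free_spectrum
from irtomo.grids import common_grid
from irtomo.specsim import InstrumentModel, LayeredSample, simulate_measurement

nu = common_grid()

# interior: triglyceride-like; wall: protein + carbohydrate
amps_int = {k: 0.0 for k in BAND_LIBRARY}
amps_int.update(ester_co=1.0, ch2_asym=0.7, ch2_sym=0.5, ch3_asym=0.3,
                ch2_bend=0.25, carb_1155=0.3)
amps_cw = {k: 0.0 for k in BAND_LIBRARY}
amps_cw.update(amide_i=1.0, amide_ii=0.6, amide_a=0.4, carb_1030=0.7,
               carb_1080=0.6)

sample = LayeredSample(
    a_cw=6.0, a_int=5.0, n0_int=1.47, n0_cw=1.40,
    alpha_int=synth_scatter_free_spectrum(amplitudes=amps_int),
    alpha_cw=synth_scatter_free_spectrum(amplitudes=amps_cw),
)
instrument = InstrumentModel(theta_na=np.deg2rad(30.0), g_over_g=0.4)

spectrum = simulate_measurement(sample, instrument)

peak = nu[np.argmax(spectrum)]
fingerprint = spectrum[(nu > 1000) & (nu < 1800)]
print(f"simulated absorbance over {nu.size} channels "
      f"({nu[0]:.0f}-{nu[-1]:.0f} cm^-1)")
print(f"  apparent absorbance range: {spectrum.min():.3f} .. "
      f"{spectrum.max():.3f}  (peak at {peak:.0f} cm^-1)")
print(f"  fingerprint-region mean:   {fingerprint.mean():.3f}")
print("The broad oscillations are Mie 'wiggles' from the 6 um sphere; the")
print("molecular bands (ester 1745, amide 1655/1545 cm^-1) ride on top of")
print("them, distorted by the anomalous dispersion each band induces.")
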