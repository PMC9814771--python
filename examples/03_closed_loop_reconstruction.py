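"""Closed-loop validation: re-simulate a spectrum from predictions and refine
the non-learned parameters.

Uses ground-truth values as the 'prediction' for one simulated record (the
best case the solver could achieve), reconstructs the spectrum through the
same physics, refines (c, C, baseline terms) by derivative-free trust-region
search, and prints the fit correlation against a deliberately wrong
prediction for contrast.
"""

import numpy as np

from irtomo.chemistry import default_latent_spaces
from irtomo.reconstruct import (PredictionResult, refine_free_params)
from irtomo.specsim import InstrumentModel, generate_dataset

clean = InstrumentModel(theta_na_jitter=0.0, smoothing_fwhm=0.0, noise_sd=0.0,
                        co2_amplitude=0.0, baseline_sd=(0.0, 0.0, 0.0),
                        radius_perturb_sd=0.0, diffuse_imag=0.0)
ds = generate_dataset(2, seed=5, latent_spaces=default_latent_spaces(seed=0),
                      instrument=clean, augmented=False)
s = ds.sample(0)
measured = ds.spectra[0]
inst = ds.instruments[0]

correct = PredictionResult(s.alpha_int, s.alpha_cw, s.a_cw, s.a_int,
                           s.n0_int, s.n0_cw)
rng = np.random.default_rng(0)
a_wrong = float(rng.uniform(1.25, 20.0))
wrong = PredictionResult(s.alpha_int, s.alpha_cw, a_wrong, 0.7 * a_wrong,
                         float(rng.uniform(1.3, 1.6)),
                         float(rng.uniform(1.3, 1.6)))

free_c, rep_c = refine_free_params(measured, correct, inst, budget=100,
                                   n_quad_nodes=128)
free_w, rep_w = refine_free_params(measured, wrong, inst, budget=100,
                                   n_quad_nodes=128)

print(f"truth: a_cw={s.a_cw:.2f} um, a_int={s.a_int:.2f} um, "
      f"n0_int={s.n0_int:.3f}, n0_cw={s.n0_cw:.3f}, C={inst.c_ratio:.3f}")
print(f"refined from correct prediction:  r_fit = {rep_c.r_fit:.4f} "
      f"(C recovered as {free_c.c_ratio:.3f})")
print(f"refined from randomised radii/indices (a_cw={wrong.a_cw:.2f}): "
      f"r_fit = {rep_w.r_fit:.4f}")
print("No setting of the free parameters rescues wrong morphology — the fit")
print("correlation gap is the closed-loop check that predictions are right.")
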