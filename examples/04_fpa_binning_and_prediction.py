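"""From a hyperspectral FPA cube to a per-sample prediction.

Builds a synthetic focal-plane-array cube containing one spherical sample,
bins the pixels covering it to a single spectrum (emulating a single-element
measurement), and pushes the spectrum through a freshly trained solver.
"""

import numpy as np

from irtomo.chemistry import default_latent_spaces
from irtomo.grids import common_grid
from irtomo.inverse import TrainConfig, small_config, train
from irtomo.io import HyperCube, fpa_bin
from irtomo.specsim import generate_dataset

spaces = default_latent_spaces(seed=0)
ds = generate_dataset(64, seed=3, latent_spaces=spaces)
truth = ds.sample(0)

# synthetic 16x16 FPA cube: sample pixels carry the sample spectrum plus
# pixel noise, background pixels carry baseline noise
rng = np.random.default_rng(0)
H = W = 16
cube = 0.02 * rng.standard_normal((H, W, 737))
yy, xx = np.mgrid[0:H, 0:W]
mask = (yy - 8) ** 2 + (xx - 8) ** 2 <= 16
cube[mask] += ds.spectra[0]
cube = HyperCube(cube, common_grid(), pixel_size=5.5)

binned = fpa_bin(cube, mask)
print(f"binned {mask.sum()} pixels covering the sample into one spectrum "
      f"(max A = {binned.max():.3f})")

tm = train(ds, small_config(seed=0),
           TrainConfig(epochs=4, batch_size=32, seed=0), phase=1)
pred = tm.model.predict(binned[None, :])
p = pred["params"][0]
print(f"predicted a_cw={p[0]:.2f} um (truth {truth.a_cw:.2f}), "
      f"a_int={p[1]:.2f} um (truth {truth.a_int:.2f})")
print(f"predicted n0_int={p[2]:.3f} (truth {truth.n0_int:.3f}), "
      f"n0_cw={p[3]:.3f} (truth {truth.n0_cw:.3f})")
print("(a 64-record training run is a toy; accuracy grows with corpus size)")
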