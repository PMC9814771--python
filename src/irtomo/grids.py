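"""The common spectral grid.

All spectra in the package live on one wavenumber grid: 737 uniformly spaced
channels spanning 3844 to 1006 cm^-1 (stored ascending; file I/O accepts
either orientation and resamples).
"""

from __future__ import annotations

import numpy as np

NU_MIN = 1006.0
NU_MAX = 3844.0
N_CHANNELS = 737


def common_grid() -> np.ndarray:
    """Ascending wavenumber grid, 737 channels over [1006, 3844] cm^-1."""
    return np.linspace(NU_MIN, NU_MAX, N_CHANNELS)


def on_common_grid(nu: np.ndarray, atol: float = 1e-6) -> bool:
    nu = np.asarray(nu, dtype=float)
    return nu.shape == (N_CHANNELS,) and bool(np.allclose(nu, common_grid(), atol=atol))
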