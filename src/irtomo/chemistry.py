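"""Scatter-free biological absorption spectra and latent chemistry spaces.

Measured "scatter-free" IR spectra of biological material are mixtures of a
modest set of vibrational bands (lipid esters, amides, CH stretches,
carbohydrate C-O, phosphates...).  This module manufactures such spectra as
non-negative Lorentzian/Gaussian band mixtures at the canonical positions,
builds PCA latent spaces over collections of them, and samples new plausible
absorption spectra from those spaces — the simulator's stand-in for latent
spaces built from measured spectral libraries.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dispersion import AbsorptionSpectrum
from .grids import common_grid

__all__ = [
    "Band",
    "BAND_LIBRARY",
    "GROUPS",
    "synth_scatter_free_spectrum",
    "LatentChemistrySpace",
    "build_latent_space",
    "sample_absorption",
    "default_latent_spaces",
]


@dataclass(frozen=True)
class Band:
    """One vibrational band: center (cm^-1), FWHM (cm^-1), line shape."""

    center: float
    fwhm: float
    shape: str = "lorentz"  # or "gauss"

    def profile(self, nu: np.ndarray) -> np.ndarray:
        if self.shape == "lorentz":
            g = self.fwhm / 2.0
            return g * g / ((nu - self.center) ** 2 + g * g)
        s = self.fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
        return np.exp(-0.5 * ((nu - self.center) / s) ** 2)


# canonical mid-IR band assignments for biological material
BAND_LIBRARY: dict[str, Band] = {
    "ester_co": Band(1745.0, 28.0),                 # lipid C=O stretch
    "amide_i": Band(1655.0, 42.0),                  # protein C=O / amide I
    "amide_ii": Band(1545.0, 40.0),                 # protein N-H / amide II
    "amide_iii": Band(1240.0, 55.0),                # amide III / PO2- asym
    "ch2_bend": Band(1465.0, 26.0),
    "coo_sym": Band(1400.0, 35.0),
    "ch3_asym": Band(2958.0, 24.0),
    "ch2_asym": Band(2922.0, 26.0),
    "ch3_sym": Band(2872.0, 22.0),
    "ch2_sym": Band(2852.0, 20.0),
    "olefinic_ch": Band(3010.0, 22.0),
    "amide_a": Band(3290.0, 160.0, "gauss"),        # N-H / O-H stretch
    "carb_1155": Band(1155.0, 35.0),                # C-O-C carbohydrates
    "carb_1080": Band(1080.0, 45.0),                # C-O / PO2- sym
    "carb_1030": Band(1030.0, 40.0),
    "phosphate_1215": Band(1215.0, 45.0),
}

# coarse chemical groups used to give latent spaces distinct emphases
GROUPS: dict[str, tuple[str, ...]] = {
    "lipid": ("ester_co", "ch2_asym", "ch2_sym", "ch3_asym", "ch3_sym",
              "ch2_bend", "olefinic_ch", "carb_1155"),
    "protein": ("amide_i", "amide_ii", "amide_iii", "amide_a", "ch3_asym",
                "ch2_asym", "coo_sym"),
    "carbohydrate": ("carb_1030", "carb_1080", "carb_1155", "ch2_bend",
                     "amide_a", "ch2_asym"),
    "nucleic": ("phosphate_1215", "carb_1080", "amide_i", "amide_ii",
                "coo_sym"),
}


def synth_scatter_free_spectrum(band_library: dict[str, Band] | None = None,
                                rng: np.random.Generator | None = None,
                                amplitudes: dict[str, float] | None = None,
                                nu_grid: np.ndarray | None = None) -> AbsorptionSpectrum:
    """One synthetic scatter-free molecular absorption spectrum.

    A non-negative band mixture: amplitudes either given explicitly or drawn
    from the rng (log-uniform over ~1.5 decades so that a few bands dominate),
    then peak-normalised.  Deterministic for a seeded rng.
    """
    if band_library is None:
        band_library = BAND_LIBRARY
    if not band_library:
        raise ValueError("band library must be non-empty")
    nu = common_grid() if nu_grid is None else np.asarray(nu_grid, dtype=float)
    total = np.zeros_like(nu)
    for name, band in band_library.items():
        if amplitudes is not None:
            amp = amplitudes.get(name, 0.0)
        else:
            if rng is None:
                raise ValueError("need either amplitudes or an rng")
            amp = 10.0 ** rng.uniform(-1.2, 0.3)
        total += amp * band.profile(nu)
    peak = total.max()
    if peak > 0:
        total = total / peak
    return AbsorptionSpectrum(nu, total)


@dataclass(frozen=True)
class LatentChemistrySpace:
    """Centered principal-component decomposition of a set of scatter-free
    spectra, plus the empirical per-component score statistics used for
    sampling."""

    mean_spectrum: np.ndarray
    loadings: np.ndarray          # (n_components, n_channels), orthonormal rows
    score_mean: np.ndarray        # (n_components,)
    score_sd: np.ndarray          # (n_components,)
    explained_variance_ratio: np.ndarray = field(repr=False, default=None)

    @property
    def n_components(self) -> int:
        return self.loadings.shape[0]


def build_latent_space(spectra: np.ndarray, n_components: int) -> LatentChemistrySpace:
    """PCA latent space over rows of ``spectra`` (n_samples x n_channels).

    Raises on rank-deficient input with more components requested than the
    centered data can support.
    """
    spectra = np.asarray(spectra, dtype=float)
    if spectra.ndim != 2 or spectra.shape[0] < n_components + 1:
        raise ValueError("need at least n_components + 1 spectra")
    mean = spectra.mean(axis=0)
    xc = spectra - mean
    # SVD-based PCA; sklearn's PCA is equivalent but this keeps the loadings'
    # sign convention under our control for reproducible serialisation
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    rank = int(np.sum(s > s[0] * 1e-10)) if s.size and s[0] > 0 else 0
    if n_components > rank:
        raise ValueError(f"requested {n_components} components but rank is {rank}")
    # fix signs: largest-magnitude element of each loading is positive
    vt = vt[:n_components]
    signs = np.sign(vt[np.arange(n_components), np.argmax(np.abs(vt), axis=1)])
    vt = vt * signs[:, None]
    scores = xc @ vt.T
    var = s**2
    return LatentChemistrySpace(
        mean_spectrum=mean,
        loadings=vt,
        score_mean=scores.mean(axis=0),
        score_sd=scores.std(axis=0, ddof=1),
        explained_variance_ratio=var[:n_components] / var.sum(),
    )


def sample_absorption(space: LatentChemistrySpace,
                      rng: np.random.Generator,
                      nu_grid: np.ndarray | None = None) -> AbsorptionSpectrum:
    """Draw one absorption spectrum from the latent space.

    Scores are Gaussian per component with the empirical location/scale,
    truncated at +-3 sd; negative spectral excursions are clipped to zero.
    """
    z = rng.standard_normal(space.n_components)
    z = np.clip(z, -3.0, 3.0)
    scores = space.score_mean + z * space.score_sd
    alpha = space.mean_spectrum + scores @ space.loadings
    nu = common_grid() if nu_grid is None else np.asarray(nu_grid, dtype=float)
    return AbsorptionSpectrum(nu, np.clip(alpha, 0.0, None))


def default_latent_spaces(n_spaces: int = 16, spectra_per_space: int = 48,
                          n_components: int = 6,
                          seed: int = 0) -> list[LatentChemistrySpace]:
    """The simulator's default bank of latent chemistry spaces.

    Each space is built from band mixtures with a distinct random emphasis on
    the chemical groups (lipid / protein / carbohydrate / nucleic), emulating
    decompositions of chemically different measured data sets.
    """
    rng = np.random.default_rng(seed)
    group_names = list(GROUPS)
    spaces = []
    for _ in range(n_spaces):
        w = rng.dirichlet(np.full(len(group_names), 0.8))
        base = {name: 0.0 for name in BAND_LIBRARY}
        for gname, gw in zip(group_names, w):
            for bname in GROUPS[gname]:
                base[bname] += gw
        mat = np.empty((spectra_per_space, common_grid().size))
        for i in range(spectra_per_space):
            amps = {name: base[name] * 10.0 ** rng.uniform(-0.5, 0.5)
                    for name in base}
            mat[i] = synth_scatter_free_spectrum(amplitudes=amps).alpha
        spaces.append(build_latent_space(mat, n_components))
    return spaces
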