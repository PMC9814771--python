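"""Forward simulation of scatter-distorted IR absorbance spectra.

The measurement model per wavenumber channel:

1. each layer's complex refractive index is built from its molecular
   absorption via the Kramers–Kronig pair (``irtomo.dispersion``),
2. coated-sphere expansion coefficients are evaluated at the channel's size
   parameters (``irtomo.mie``),
3. the molecular loss Q_abs and the NA-limited scattering loss Q_sca^NA
   combine into the apparent absorbance
   A = -log10(1 - (g/G)(C Q_abs + Q_sca^NA)).

Physics-level randomness (per-channel radius perturbation, NA jitter) happens
inside :func:`simulate_measurement` when an rng is supplied; post-processing
augmentation (ripple smoothing, CO2 doublet, baselines, noise) lives in
:func:`augment`.  ``generate_dataset`` ties everything together into fully
seeded training collections.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import gaussian_filter1d

from . import mie
from .chemistry import LatentChemistrySpace, default_latent_spaces, sample_absorption
from .dispersion import AbsorptionSpectrum, KKScaling, consistent_c, layer_complex_index
from .grids import common_grid

__all__ = [
    "LayeredSample",
    "InstrumentModel",
    "VoxelMap",
    "SimulatedRecord",
    "SpectralDataset",
    "SamplingRanges",
    "simulate_measurement",
    "augment",
    "rasterize",
    "generate_dataset",
]

A_CW_RANGE = (1.25, 20.0)     # outer radius, um
N0_RANGE = (1.3, 1.6)         # effective refractive index, both layers
REL_WALL_RANGE = (0.02, 0.5)  # wall thickness as a fraction of a_cw


@dataclass(frozen=True)
class LayeredSample:
    """Ground truth of one two-layer concentric sphere.

    Radii in um (a_int < a_cw), constant real effective indices per layer,
    and each layer's molecular absorption spectrum.
    """

    a_cw: float
    a_int: float
    n0_int: float
    n0_cw: float
    alpha_int: AbsorptionSpectrum
    alpha_cw: AbsorptionSpectrum

    def __post_init__(self) -> None:
        if not (A_CW_RANGE[0] <= self.a_cw <= A_CW_RANGE[1]):
            raise ValueError(f"a_cw must lie in {A_CW_RANGE}, got {self.a_cw}")
        if not (0.0 < self.a_int < self.a_cw):
            raise ValueError("need 0 < a_int < a_cw")
        for name, n0 in (("n0_int", self.n0_int), ("n0_cw", self.n0_cw)):
            if not (N0_RANGE[0] <= n0 <= N0_RANGE[1]):
                raise ValueError(f"{name} must lie in {N0_RANGE}, got {n0}")


@dataclass(frozen=True)
class InstrumentModel:
    """Detector geometry and augmentation magnitudes.

    theta_na         collection half-angle of the objective (radians)
    theta_na_jitter  half-width of the uniform per-record NA jitter (radians)
    g_over_g         sample cross-section / detector area fill fraction
    c_ratio          absorption/scattering mixing ratio C
    smoothing_fwhm   ripple-suppression Gaussian kernel FWHM (cm^-1)
    noise_sd         additive Gaussian noise sd (absorbance)
    co2_amplitude    amplitude of the atmospheric CO2 doublet (absorbance)
    baseline_sd      (b0, b1, b2) scales of the polynomial baseline draw;
                     b1, b2 apply to the normalised coordinate
                     u = (nu - nu_mid)/(nu_span/2) in [-1, 1]
    radius_perturb_sd  relative sd of the per-channel radius perturbation
    diffuse_imag     constant imaginary index offset (diffuse attenuation)
    """

    theta_na: float = np.deg2rad(30.0)
    theta_na_jitter: float = np.deg2rad(5.0)
    g_over_g: float = 0.5
    c_ratio: float = 1.0
    smoothing_fwhm: float = 16.0
    noise_sd: float = 0.005
    co2_amplitude: float = 0.02
    baseline_sd: tuple[float, float, float] = (0.02, 0.01, 0.005)
    radius_perturb_sd: float = 0.005
    diffuse_imag: float = 0.005

    def __post_init__(self) -> None:
        if not (0.0 < self.theta_na < np.pi / 2):
            raise ValueError("theta_na must lie in (0, pi/2)")
        if not (0.0 < self.g_over_g <= 1.0):
            raise ValueError("g_over_g must lie in (0, 1]")
        for name in ("theta_na_jitter", "c_ratio", "smoothing_fwhm", "noise_sd",
                     "co2_amplitude", "radius_perturb_sd", "diffuse_imag"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass(frozen=True)
class VoxelMap:
    """G x G x G scalar field of the effective refractive index; 0 outside the
    sample, n0 of the containing layer at each voxel center."""

    grid: np.ndarray
    voxel_size: float

    @property
    def grid_size(self) -> int:
        return self.grid.shape[0]


@dataclass(frozen=True)
class SimulatedRecord:
    spectrum: np.ndarray            # apparent absorbance on the common grid
    truth: LayeredSample
    instrument: InstrumentModel     # the realised (jittered) instrument
    voxel_truth: VoxelMap | None = None


# ---------------------------------------------------------------------------
# forward simulation
# ---------------------------------------------------------------------------

def _smooth_field(rng: np.random.Generator, n: int, sd: float,
                  corr_channels: float = 25.0) -> np.ndarray:
    """Zero-mean low-pass Gaussian random field with pointwise sd ``sd``."""
    w = rng.standard_normal(n)
    f = gaussian_filter1d(w, corr_channels, mode="nearest")
    s = f.std()
    return sd * f / s if s > 0 else np.zeros(n)


def simulate_measurement(sample: LayeredSample, instrument: InstrumentModel,
                         scaling: KKScaling | None = None,
                         rng: np.random.Generator | None = None,
                         n_quad_nodes: int | None = None) -> np.ndarray:
    """Apparent absorbance spectrum A(nu) of one layered sample.

    Deterministic when ``rng`` is None; with an rng the physics-level draws
    (per-channel radius perturbation, per-record NA jitter) are applied.
    ``scaling`` supplies the KK scales d and c (its n0 is ignored — the layer
    n0 values come from the sample); default d = 1e-3 cm with the causally
    consistent c = ln(10)/(2 pi d).
    """
    nu = sample.alpha_int.nu_grid
    if scaling is None:
        scaling = KKScaling(d=1e-3, c=consistent_c(1e-3), n0=1.4)

    n_int = layer_complex_index(
        sample.alpha_int, replace(scaling, n0=sample.n0_int), instrument.diffuse_imag
    ).n
    n_cw = layer_complex_index(
        sample.alpha_cw, replace(scaling, n0=sample.n0_cw), instrument.diffuse_imag
    ).n

    theta_na = instrument.theta_na
    r_factor = np.ones(nu.size)
    if rng is not None:
        if instrument.theta_na_jitter > 0:
            theta_na = theta_na + rng.uniform(-instrument.theta_na_jitter,
                                              instrument.theta_na_jitter)
        if instrument.radius_perturb_sd > 0:
            r_factor = 1.0 + _smooth_field(rng, nu.size, instrument.radius_perturb_sd)

    k = 2.0 * np.pi * nu * mie.UM_TO_CM
    x_shell = k * sample.a_cw * r_factor
    x_core = k * sample.a_int * r_factor
    a, b = mie.coated_coefficients_grid(n_int, n_cw, x_core, x_shell)
    q_ext, q_sca, q_abs = mie.efficiencies_grid(a, b, x_shell)
    q_na = mie.q_sca_na_grid(a, b, x_shell, theta_na, n_nodes=n_quad_nodes)
    try:
        return mie.apparent_absorbance(np.clip(q_abs, 0.0, None), q_na,
                                       instrument.c_ratio, instrument.g_over_g)
    except ValueError as err:
        q_ext_na = instrument.c_ratio * q_abs + q_na
        bad = int(np.argmax(instrument.g_over_g * q_ext_na))
        raise ValueError(f"{err} (channel {bad}, nu={nu[bad]:.1f} cm^-1)") from err


def augment(spectrum: np.ndarray, instrument: InstrumentModel,
            rng: np.random.Generator,
            nu_grid: np.ndarray | None = None) -> np.ndarray:
    """Post-processing augmentation, applied in order: ripple smoothing,
    CO2 doublet in the 2200-2500 cm^-1 inactive region, polynomial baseline,
    additive Gaussian noise.  With all magnitudes zero this is the identity.
    """
    nu = common_grid() if nu_grid is None else np.asarray(nu_grid, dtype=float)
    out = np.asarray(spectrum, dtype=float).copy()
    h = abs(nu[1] - nu[0])

    if instrument.smoothing_fwhm > 0:
        sigma = instrument.smoothing_fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0))) / h
        out = gaussian_filter1d(out, sigma, mode="nearest")

    if instrument.co2_amplitude > 0:
        # asymmetric rovibrational doublet of the CO2 asymmetric stretch
        amp = instrument.co2_amplitude * rng.uniform(0.2, 1.0)
        for center, rel, g in ((2362.0, 1.0, 9.0), (2336.0, 0.72, 9.0)):
            out += amp * rel * g * g / ((nu - center) ** 2 + g * g)

    b0_sd, b1_sd, b2_sd = instrument.baseline_sd
    if any(s > 0 for s in instrument.baseline_sd):
        u = (nu - 0.5 * (nu[0] + nu[-1])) / (0.5 * abs(nu[-1] - nu[0]))
        out += (rng.normal(0.0, b0_sd) if b0_sd > 0 else 0.0)
        out += (rng.normal(0.0, b1_sd) if b1_sd > 0 else 0.0) * u
        out += (rng.normal(0.0, b2_sd) if b2_sd > 0 else 0.0) * u * u

    if instrument.noise_sd > 0:
        out += rng.normal(0.0, instrument.noise_sd, nu.size)
    return out


def rasterize(sample: LayeredSample, grid_size: int = 32,
              voxel_size: float | None = None) -> VoxelMap:
    """Voxelised ground-truth refractive-index map.

    Voxel value = n0_cw for a_int < r <= a_cw, n0_int for r <= a_int, and 0
    outside, with r measured from the grid center to the voxel center.
    The default voxel size is fixed across samples (the grid covers 1.1x the
    largest supported diameter) so that absolute morphology is encoded in
    the map — a shape decoder trained on per-sample-scaled grids could never
    express the radius.
    """
    if voxel_size is None:
        voxel_size = 2.2 * A_CW_RANGE[1] / grid_size
    if grid_size * voxel_size <= 2.0 * sample.a_cw:
        raise ValueError("grid does not cover the sphere")
    c = (grid_size - 1) / 2.0
    ax = (np.arange(grid_size) - c) * voxel_size
    r = np.sqrt(ax[:, None, None] ** 2 + ax[None, :, None] ** 2
                + ax[None, None, :] ** 2)
    grid = np.zeros((grid_size,) * 3)
    grid[r <= sample.a_cw] = sample.n0_cw
    grid[r <= sample.a_int] = sample.n0_int
    return VoxelMap(grid, voxel_size)


# ---------------------------------------------------------------------------
# dataset generation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SamplingRanges:
    """Uniform sampling ranges of the ground-truth and per-record instrument
    draws.  C is sampled log-uniformly."""

    a_cw: tuple[float, float] = A_CW_RANGE
    rel_wall: tuple[float, float] = REL_WALL_RANGE
    n0: tuple[float, float] = N0_RANGE
    g_over_g: tuple[float, float] = (0.1, 1.0)
    c_ratio: tuple[float, float] = (0.3, 3.0)
    diffuse_imag: tuple[float, float] = (0.0, 0.01)
    alpha_scale: tuple[float, float] = (0.3, 1.0)

    def validate(self) -> None:
        if not (A_CW_RANGE[0] <= self.a_cw[0] < self.a_cw[1] <= A_CW_RANGE[1]):
            raise ValueError("a_cw range outside the supported span")
        if not (0.0 < self.rel_wall[0] < self.rel_wall[1] < 1.0):
            raise ValueError("rel_wall must lie inside (0, 1)")
        if not (N0_RANGE[0] <= self.n0[0] < self.n0[1] <= N0_RANGE[1]):
            raise ValueError("n0 range outside the supported span")


PARAM_NAMES = ("a_cw", "a_int", "n0_int", "n0_cw", "kk_cd", "c_ratio")


@dataclass
class SpectralDataset:
    """Column-oriented collection of simulated records.

    ``params`` columns follow :data:`PARAM_NAMES`:
    (a_cw, a_int, n0_int, n0_cw, c*d proxy of the KK scales, C).
    """

    nu_grid: np.ndarray
    spectra: np.ndarray          # (n, 737)
    params: np.ndarray           # (n, 6)
    alpha_int: np.ndarray        # (n, 737)
    alpha_cw: np.ndarray         # (n, 737)
    instruments: list[InstrumentModel]
    seed: int | None = None
    config_hash: str | None = None
    voxels: np.ndarray | None = None
    voxel_size: np.ndarray | None = None

    def __len__(self) -> int:
        return self.spectra.shape[0]

    def sample(self, i: int) -> LayeredSample:
        p = self.params[i]
        return LayeredSample(
            a_cw=float(p[0]), a_int=float(p[1]), n0_int=float(p[2]),
            n0_cw=float(p[3]),
            alpha_int=AbsorptionSpectrum(self.nu_grid, self.alpha_int[i]),
            alpha_cw=AbsorptionSpectrum(self.nu_grid, self.alpha_cw[i]),
        )

    def record(self, i: int, with_voxels: bool = False,
               grid_size: int = 32) -> SimulatedRecord:
        truth = self.sample(i)
        vox = None
        if with_voxels:
            vox = rasterize(truth, grid_size)
        elif self.voxels is not None:
            vox = VoxelMap(self.voxels[i], float(self.voxel_size[i]))
        return SimulatedRecord(self.spectra[i], truth, self.instruments[i], vox)


def config_digest(cfg: dict) -> str:
    return hashlib.sha256(json.dumps(cfg, sort_keys=True, default=str)
                          .encode()).hexdigest()[:16]


def generate_dataset(n: int, ranges: SamplingRanges | None = None,
                     instrument: InstrumentModel | None = None,
                     seed: int = 0,
                     latent_spaces: list[LatentChemistrySpace] | None = None,
                     scaling: KKScaling | None = None,
                     augmented: bool = True,
                     store_voxels: bool = False,
                     voxel_grid: int = 32,
                     n_quad_nodes: int | None = None) -> SpectralDataset:
    """Generate ``n`` i.i.d. simulated records, fully reproducible from seed.

    Ground-truth parameters are sampled uniformly over ``ranges`` (C
    log-uniformly); each layer's chemistry is drawn from a randomly chosen
    latent space scaled by a per-record amplitude; the base instrument's
    augmentation magnitudes apply to every record.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    ranges = ranges or SamplingRanges()
    ranges.validate()
    instrument = instrument or InstrumentModel()
    scaling = scaling or KKScaling(d=1e-3, c=consistent_c(1e-3), n0=1.4)
    rng = np.random.default_rng(seed)
    if latent_spaces is None:
        latent_spaces = default_latent_spaces(seed=int(rng.integers(2**31)))

    nu = common_grid()
    cfg_hash = config_digest({
        "n": n, "ranges": ranges.__dict__, "instrument": instrument.__dict__,
        "scaling": (scaling.d, scaling.c), "augmented": augmented,
        "n_spaces": len(latent_spaces), "seed": seed,
    })

    spectra = np.empty((n, nu.size))
    params = np.empty((n, 6))
    alpha_int = np.empty((n, nu.size))
    alpha_cw = np.empty((n, nu.size))
    instruments: list[InstrumentModel] = []
    voxels = np.empty((n, voxel_grid, voxel_grid, voxel_grid),
                      dtype=np.float32) if store_voxels else None
    voxel_size = np.empty(n) if store_voxels else None

    i = 0
    while i < n:
        a_cw = rng.uniform(*ranges.a_cw)
        rel_wall = rng.uniform(*ranges.rel_wall)
        a_int = a_cw * (1.0 - rel_wall)
        n0_int = rng.uniform(*ranges.n0)
        n0_cw = rng.uniform(*ranges.n0)
        s_int = rng.integers(len(latent_spaces))
        s_cw = rng.integers(len(latent_spaces))
        amp_int = rng.uniform(*ranges.alpha_scale)
        amp_cw = rng.uniform(*ranges.alpha_scale)
        al_int = sample_absorption(latent_spaces[s_int], rng)
        al_cw = sample_absorption(latent_spaces[s_cw], rng)
        al_int = AbsorptionSpectrum(nu, amp_int * al_int.alpha)
        al_cw = AbsorptionSpectrum(nu, amp_cw * al_cw.alpha)
        inst = replace(
            instrument,
            g_over_g=rng.uniform(*ranges.g_over_g),
            c_ratio=float(np.exp(rng.uniform(np.log(ranges.c_ratio[0]),
                                             np.log(ranges.c_ratio[1])))),
            diffuse_imag=rng.uniform(*ranges.diffuse_imag),
        )
        truth = LayeredSample(a_cw, a_int, n0_int, n0_cw, al_int, al_cw)
        try:
            spec = simulate_measurement(truth, inst, scaling, rng=rng,
                                        n_quad_nodes=n_quad_nodes)
        except ValueError:
            # total extinction for this parameter draw; redraw
            continue
        if augmented:
            spec = augment(spec, inst, rng, nu)
        spectra[i] = spec
        params[i] = (a_cw, a_int, n0_int, n0_cw, scaling.c * scaling.d,
                     inst.c_ratio)
        alpha_int[i] = al_int.alpha
        alpha_cw[i] = al_cw.alpha
        instruments.append(inst)
        if store_voxels:
            vm = rasterize(truth, voxel_grid)
            voxels[i] = vm.grid
            voxel_size[i] = vm.voxel_size
        i += 1

    return SpectralDataset(nu, spectra, params, alpha_int, alpha_cw,
                           instruments, seed=seed, config_hash=cfg_hash,
                           voxels=voxels, voxel_size=voxel_size)
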