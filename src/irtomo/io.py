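"""File formats, FPA binning and the end-to-end pipeline.

Formats:

* two-column delimited text (wavenumber cm^-1, absorbance) for single
  spectra, either grid orientation, optional header;
* one HDF5 container layout for datasets (groups /spectra, /nu_grid,
  /params, /alpha_int, /alpha_cw, optionally /voxels) and hypercubes
  (/cube, /nu_grid, /pixel_size), each carrying seed and config-hash
  attributes;
* JSON for prediction results and fit reports.
"""

from __future__ import annotations

import time
import warnings
from dataclasses import dataclass

import h5py
import numpy as np
from scipy.ndimage import label

from .grids import NU_MAX, NU_MIN, common_grid
from .specsim import InstrumentModel, SpectralDataset

__all__ = [
    "ParseError",
    "CoverageError",
    "LoadedSpectrum",
    "read_spectrum",
    "write_spectrum",
    "HyperCube",
    "roi_validate",
    "fpa_bin",
    "save_dataset",
    "load_dataset",
    "save_hypercube",
    "load_hypercube",
    "run_pipeline",
]


class ParseError(ValueError):
    pass


class CoverageError(ValueError):
    pass


@dataclass(frozen=True)
class LoadedSpectrum:
    """A spectrum resampled onto the common grid, with the original samples
    retained."""

    absorbance: np.ndarray        # on the common 737-channel grid
    nu_original: np.ndarray
    absorbance_original: np.ndarray
    path: str | None = None


def read_spectrum(path, delimiter: str | None = None) -> LoadedSpectrum:
    """Read a two-column wavenumber/absorbance text file.

    Accepts ascending or descending wavenumber order and an optional header
    line; resamples to the common grid by linear interpolation.  Raises
    :class:`ParseError` naming the first malformed line, or
    :class:`CoverageError` when the file does not span the common grid.
    """
    nus, vals = [], []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.replace(",", " ").split() if delimiter is None \
                else line.split(delimiter)
            if lineno == 1:
                try:
                    float(parts[0])
                except ValueError:
                    continue  # header line
            if len(parts) < 2:
                raise ParseError(f"{path}: line {lineno}: expected two columns")
            try:
                nus.append(float(parts[0]))
                vals.append(float(parts[1]))
            except ValueError as err:
                raise ParseError(f"{path}: line {lineno}: {err}") from err
    if len(nus) < 2:
        raise ParseError(f"{path}: fewer than two data rows")
    nu = np.asarray(nus)
    val = np.asarray(vals)
    order = np.argsort(nu)
    nu_s, val_s = nu[order], val[order]
    if nu_s[0] > NU_MIN + 1e-9 or nu_s[-1] < NU_MAX - 1e-9:
        raise CoverageError(
            f"{path}: spectrum spans [{nu_s[0]:.1f}, {nu_s[-1]:.1f}] cm^-1, "
            f"needs [{NU_MIN:.0f}, {NU_MAX:.0f}]")
    from .grids import on_common_grid
    if on_common_grid(nu_s, atol=1e-4):
        resampled = val_s.copy()  # already on the common grid
    else:
        resampled = np.interp(common_grid(), nu_s, val_s)
    return LoadedSpectrum(resampled, nu, val, str(path))


def write_spectrum(path, absorbance: np.ndarray,
                   nu: np.ndarray | None = None) -> None:
    nu = common_grid() if nu is None else np.asarray(nu, dtype=float)
    a = np.asarray(absorbance, dtype=float)
    if nu.shape != a.shape:
        raise ValueError("wavenumber and absorbance lengths differ")
    np.savetxt(path, np.column_stack([nu, a]), fmt="%.10g",
               header="wavenumber_cm-1 absorbance")


# ---------------------------------------------------------------------------
# hypercubes / FPA
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class HyperCube:
    """H x W x n_channels absorbance cube on the common grid."""

    data: np.ndarray
    nu_grid: np.ndarray
    pixel_size: float = 1.0

    def __post_init__(self) -> None:
        if self.data.ndim != 3 or self.data.shape[2] != self.nu_grid.size:
            raise ValueError("cube must be H x W x n_channels")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("cube contains non-finite values")


def roi_validate(mask: np.ndarray) -> np.ndarray:
    mask = np.asarray(mask, dtype=bool)
    if mask.ndim != 2 or not mask.any():
        raise ValueError("ROI mask must be 2-D with at least one true pixel")
    _, n_blobs = label(mask)
    if n_blobs > 1:
        warnings.warn(f"ROI mask has {n_blobs} disconnected components")
    return mask


def fpa_bin(cube: HyperCube, mask: np.ndarray) -> np.ndarray:
    """Bin a hyperspectral image to one spectrum: the unweighted per-channel
    mean over the masked pixels (emulating a single-element measurement of
    the sample the mask covers)."""
    mask = roi_validate(mask)
    if mask.shape != cube.data.shape[:2]:
        raise ValueError("mask shape does not match the cube")
    return cube.data[mask].mean(axis=0)


# ---------------------------------------------------------------------------
# HDF5 containers
# ---------------------------------------------------------------------------


def save_dataset(path, ds: SpectralDataset) -> None:
    inst = ds.instruments
    inst_arr = np.array([
        (i.theta_na, i.g_over_g, i.c_ratio, i.diffuse_imag) for i in inst
    ]) if inst else np.empty((0, 4))
    with h5py.File(path, "w") as f:
        f.create_dataset("spectra", data=ds.spectra)
        f.create_dataset("nu_grid", data=ds.nu_grid)
        f.create_dataset("params", data=ds.params)
        f.create_dataset("alpha_int", data=ds.alpha_int)
        f.create_dataset("alpha_cw", data=ds.alpha_cw)
        f.create_dataset("instruments", data=inst_arr)
        if ds.voxels is not None:
            f.create_dataset("voxels", data=ds.voxels)
            f.create_dataset("voxel_size", data=ds.voxel_size)
        f.attrs["seed"] = -1 if ds.seed is None else ds.seed
        f.attrs["config_hash"] = ds.config_hash or ""


def load_dataset(path) -> SpectralDataset:
    with h5py.File(path, "r") as f:
        inst_arr = f["instruments"][...]
        base = InstrumentModel()
        instruments = [
            InstrumentModel(theta_na=row[0], g_over_g=row[1], c_ratio=row[2],
                            diffuse_imag=row[3],
                            theta_na_jitter=base.theta_na_jitter,
                            smoothing_fwhm=base.smoothing_fwhm,
                            noise_sd=base.noise_sd,
                            co2_amplitude=base.co2_amplitude,
                            baseline_sd=base.baseline_sd,
                            radius_perturb_sd=base.radius_perturb_sd)
            for row in inst_arr
        ]
        return SpectralDataset(
            nu_grid=f["nu_grid"][...],
            spectra=f["spectra"][...],
            params=f["params"][...],
            alpha_int=f["alpha_int"][...],
            alpha_cw=f["alpha_cw"][...],
            instruments=instruments,
            seed=int(f.attrs["seed"]),
            config_hash=str(f.attrs["config_hash"]) or None,
            voxels=f["voxels"][...] if "voxels" in f else None,
            voxel_size=f["voxel_size"][...] if "voxel_size" in f else None,
        )


def save_hypercube(path, cube: HyperCube, seed: int | None = None,
                   config_hash: str | None = None) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("cube", data=cube.data)
        f.create_dataset("nu_grid", data=cube.nu_grid)
        f.create_dataset("pixel_size", data=cube.pixel_size)
        f.attrs["seed"] = -1 if seed is None else seed
        f.attrs["config_hash"] = config_hash or ""


def load_hypercube(path) -> HyperCube:
    with h5py.File(path, "r") as f:
        return HyperCube(f["cube"][...], f["nu_grid"][...],
                         float(f["pixel_size"][()]))


# ---------------------------------------------------------------------------
# end-to-end pipeline
# ---------------------------------------------------------------------------

PIPELINE_DEFAULTS = {
    "n_train": 256,
    "n_test": 64,
    "n_pretrain_spheres": 32,
    "seed": 0,
    "epochs_phase1": 2,
    "epochs_phase2": 1,
    "epochs_pretrain": 5,
    "batch_size": 32,
    "lr": 1e-3,
    "voxel_grid": 16,
    "model": "small",          # "small" or "default"
    "augmented": True,
}


def _validate_config(config: dict) -> dict:
    cfg = dict(PIPELINE_DEFAULTS)
    unknown = set(config) - set(cfg)
    if unknown:
        raise ValueError(f"unknown pipeline config keys: {sorted(unknown)}")
    cfg.update(config)
    for key in ("n_train", "n_test", "n_pretrain_spheres", "epochs_phase1",
                "epochs_phase2", "epochs_pretrain", "batch_size", "seed",
                "voxel_grid"):
        if not isinstance(cfg[key], (int, np.integer)) or cfg[key] < 0:
            raise ValueError(f"pipeline config {key} must be a non-negative int")
    if cfg["model"] not in ("small", "default"):
        raise ValueError("model must be 'small' or 'default'")
    return cfg


def run_pipeline(config: dict, out_dir, log=print) -> dict:
    """simulate -> pretrain-shape -> train phase 1 -> train phase 2 ->
    evaluate, fully seeded; persists artifacts under ``out_dir`` and returns
    the evaluation report.
    """
    import json
    from pathlib import Path

    from .chemistry import default_latent_spaces
    from .inverse import (ModelConfig, TrainConfig, evaluate,
                          pretrain_shape_autoencoder, small_config, train)
    from .specsim import config_digest, generate_dataset, rasterize

    cfg = _validate_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    digest = config_digest(cfg)
    seed = cfg["seed"]
    stages: list[dict] = []

    def stage(name):
        t0 = time.time()
        log(f"[pipeline] {name} ...")
        return t0

    def done(name, t0):
        dt = time.time() - t0
        stages.append({"stage": name, "seconds": round(dt, 2)})
        log(f"[pipeline] {name} done in {dt:.1f}s")

    t0 = stage("simulate")
    spaces = default_latent_spaces(seed=seed)
    ds_train = generate_dataset(cfg["n_train"], seed=seed, latent_spaces=spaces,
                                augmented=cfg["augmented"])
    ds_test = generate_dataset(cfg["n_test"], seed=seed + 1,
                               latent_spaces=spaces,
                               augmented=cfg["augmented"])
    save_dataset(out / "train.h5", ds_train)
    save_dataset(out / "test.h5", ds_test)
    done("simulate", t0)

    mcfg = (small_config(voxel_grid=cfg["voxel_grid"], seed=seed)
            if cfg["model"] == "small" else
            ModelConfig(voxel_grid=cfg["voxel_grid"], seed=seed))

    t0 = stage("pretrain-shape")
    rng = np.random.default_rng(seed + 2)
    vox = np.stack([
        rasterize(ds_train.sample(int(i)), cfg["voxel_grid"]).grid
        for i in rng.integers(0, len(ds_train),
                              min(cfg["n_pretrain_spheres"], len(ds_train)))
    ])
    _, dec_weights, _ = pretrain_shape_autoencoder(
        vox, mcfg, epochs=cfg["epochs_pretrain"],
        batch_size=min(16, len(vox)), seed=seed + 3)
    done("pretrain-shape", t0)

    t0 = stage("train-phase1")
    tc1 = TrainConfig(epochs=cfg["epochs_phase1"], batch_size=cfg["batch_size"],
                      lr=cfg["lr"], seed=seed + 4)
    tm = train(ds_train, mcfg, tc1, phase=1)
    tm.save(str(out / "model_phase1.npz"))
    done("train-phase1", t0)

    t0 = stage("train-phase2")
    tc2 = TrainConfig(epochs=cfg["epochs_phase2"], batch_size=cfg["batch_size"],
                      lr=cfg["lr"], seed=seed + 5)
    tm2 = train(ds_train, train_config=tc2, model=tm.model, phase=2,
                shapenet_init=dec_weights)
    tm2.save(str(out / "model_phase2.npz"))
    done("train-phase2", t0)

    t0 = stage("evaluate")
    report = evaluate(tm2.model, ds_test)
    preds = tm2.model.predict(ds_test.spectra)
    np.savez(out / "predictions.npz", params=preds["params"],
             alpha_int=preds["alpha_int"], alpha_cw=preds["alpha_cw"],
             truth_params=ds_test.params[:, :4])
    report["config_hash"] = digest
    report["seed"] = seed
    report["stages"] = stages
    (out / "report.json").write_text(json.dumps(report, indent=2))
    done("evaluate", t0)
    return report
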