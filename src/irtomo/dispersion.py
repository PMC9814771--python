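"""Kramers–Kronig construction of a layer's complex refractive index spectrum.

The causality-enforced pair used throughout the package:

    Im{n}(nu) = ln(10) / (4 pi nu d) * alpha(nu)
    Re{n}(nu) = n0 + (c/pi) * P int_0^inf alpha(Omega) / (Omega^2 - nu^2) dOmega

where alpha is the molecular absorption spectrum on the common grid, d is a
path-length-like scale (cm), c a dispersion scale, and n0 the constant real
effective refractive index of the layer in the IR window.  alpha is assumed
zero outside the grid (truncated integral); the resulting small baseline-like
bias is absorbed by the free parameters c and n0 during refinement.

The principal value is evaluated with the Maclaurin (alternating-point)
discrete Hilbert scheme on the uniform grid: the integrand is summed over the
sub-grid of opposite parity to the evaluation channel with weight 2h, which
skips the singular node exactly and converges at O(h^2).  Since only the
product of alpha's unit and d (resp. c) enters the transforms, d and c are
exposed as free scaling parameters rather than fixed physical constants.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "AbsorptionSpectrum",
    "KKScaling",
    "ComplexIndexSpectrum",
    "kk_imag",
    "kk_real",
    "layer_complex_index",
    "consistent_c",
]


def consistent_c(d: float) -> float:
    """The dispersion scale that makes the transform pair causally consistent.

    Substituting Im{n} = ln(10) alpha / (4 pi nu d) into the standard KK
    relation Re{n} - n0 = (2/pi) P int Omega Im{n}(Omega) / (Omega^2 - nu^2)
    dOmega collapses it onto the package's alpha-form with c = ln(10)/(2 pi d).
    """
    return float(np.log(10.0) / (2.0 * np.pi * d))


@dataclass(frozen=True)
class AbsorptionSpectrum:
    """Molecular absorption alpha(nu) >= 0 on a strictly monotone grid."""

    nu_grid: np.ndarray
    alpha: np.ndarray

    def __post_init__(self) -> None:
        nu = np.asarray(self.nu_grid, dtype=float)
        al = np.asarray(self.alpha, dtype=float)
        if nu.ndim != 1 or nu.shape != al.shape:
            raise ValueError("nu_grid and alpha must be 1-D and equal length")
        d = np.diff(nu)
        if not (np.all(d > 0) or np.all(d < 0)):
            raise ValueError("nu_grid must be strictly monotone")
        if not np.all(np.isfinite(al)):
            raise ValueError("alpha must be finite")
        if np.any(al < 0):
            raise ValueError("alpha must be non-negative")
        object.__setattr__(self, "nu_grid", nu)
        object.__setattr__(self, "alpha", al)

    def ascending(self) -> "AbsorptionSpectrum":
        if self.nu_grid[1] > self.nu_grid[0]:
            return self
        return AbsorptionSpectrum(self.nu_grid[::-1].copy(), self.alpha[::-1].copy())


@dataclass(frozen=True)
class KKScaling:
    """Scales of the transform pair: d (path-length-like, cm), c (dispersion
    scale), n0 (constant real effective index)."""

    d: float = 1e-3
    c: float = 1.0
    n0: float = 1.4

    def __post_init__(self) -> None:
        if self.d <= 0 or self.c <= 0:
            raise ValueError("d and c must be positive")
        if not (1.0 <= self.n0 <= 2.0):
            raise ValueError("n0 must lie in [1.0, 2.0]")


@dataclass(frozen=True)
class ComplexIndexSpectrum:
    nu_grid: np.ndarray
    n_real: np.ndarray
    n_imag: np.ndarray

    @property
    def n(self) -> np.ndarray:
        return self.n_real + 1j * self.n_imag


def kk_imag(alpha: AbsorptionSpectrum, scaling: KKScaling) -> np.ndarray:
    """Imaginary index Im{n} = ln(10)/(4 pi nu d) * alpha(nu); linear in alpha."""
    if np.any(alpha.nu_grid <= 0):
        raise ValueError("wavenumbers must be positive")
    return np.log(10.0) / (4.0 * np.pi * alpha.nu_grid * scaling.d) * alpha.alpha


def _maclaurin_matrix(nu: np.ndarray) -> np.ndarray:
    """Weight matrix W with (dispersion term)_i = (c/pi) * sum_j W[i, j] alpha_j.

    W[i, j] = 2h / (nu_j^2 - nu_i^2) on the opposite-parity sub-grid, 0 on the
    same-parity nodes (including the singular diagonal).
    """
    n = nu.size
    h = float(nu[1] - nu[0])
    den = nu[None, :] ** 2 - nu[:, None] ** 2
    idx = np.arange(n)
    mask = ((idx[None, :] - idx[:, None]) % 2).astype(float)  # 1 on opposite parity
    with np.errstate(divide="ignore", invalid="ignore"):
        w = np.where(mask > 0, 2.0 * h / den, 0.0)
    return w


_MACLAURIN_CACHE: dict[tuple[int, float, float], np.ndarray] = {}


def _maclaurin_cached(nu: np.ndarray) -> np.ndarray:
    key = (nu.size, float(nu[0]), float(nu[-1]))
    w = _MACLAURIN_CACHE.get(key)
    if w is None:
        w = _maclaurin_matrix(nu)
        if len(_MACLAURIN_CACHE) > 8:
            _MACLAURIN_CACHE.clear()
        _MACLAURIN_CACHE[key] = w
    return w


def kk_real(alpha: AbsorptionSpectrum, scaling: KKScaling) -> np.ndarray:
    """Real index Re{n} = n0 + (c/pi) P int alpha(Omega)/(Omega^2 - nu^2) dOmega.

    Requires a uniform grid (the Maclaurin scheme's parity trick needs equal
    spacing); alpha is treated as zero outside the grid.
    """
    spec = alpha.ascending()
    nu = spec.nu_grid
    if np.unique(nu).size != nu.size:
        raise ValueError("duplicate wavenumbers in grid")
    h = np.diff(nu)
    if not np.allclose(h, h[0], rtol=1e-8):
        raise ValueError("kk_real requires a uniform grid")
    disp = (scaling.c / np.pi) * (_maclaurin_cached(nu) @ spec.alpha)
    if alpha.nu_grid[1] < alpha.nu_grid[0]:
        disp = disp[::-1]
    return scaling.n0 + disp


def layer_complex_index(alpha: AbsorptionSpectrum, scaling: KKScaling,
                        diffuse_imag: float = 0.0) -> ComplexIndexSpectrum:
    """Full complex index of one layer:

        n = [n0 + KK real dispersion term] + i [KK imaginary term + diffuse_imag]

    ``diffuse_imag`` is a constant imaginary offset representing diffuse
    attenuation of light traversing the sample.
    """
    if diffuse_imag < 0:
        raise ValueError("diffuse_imag must be >= 0")
    return ComplexIndexSpectrum(
        nu_grid=alpha.nu_grid,
        n_real=kk_real(alpha, scaling),
        n_imag=kk_imag(alpha, scaling) + diffuse_imag,
    )
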