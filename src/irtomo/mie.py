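"""Exact far-field scattering and absorption of a coated (two-layer concentric) sphere.

Implements the stable stratified-sphere scheme: logarithmic derivatives of the
Riccati–Bessel functions are propagated by downward recursion inside each layer
(upward recursion of the regular internal functions is numerically unstable for
absorbing media), and layer-to-layer transfer uses only ratios that remain O(1).

Conventions
-----------
* size parameter  x = 2 pi nu a  with the wavenumber nu in cm^-1 and the radius
  a in cm (radii elsewhere in the package are in um; see ``size_parameters``),
* surrounding medium index 1 (vacuum/air), so relative indices equal sample
  indices,
* time dependence exp(-i omega t); Im(m) >= 0 for passive (absorbing) media,
* efficiencies are cross sections normalised by the geometric cross section
  pi a^2 of the *outer* sphere.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "SizeParameters",
    "ComplexIndexPair",
    "MieCoefficients",
    "AmplitudeSet",
    "EfficiencySet",
    "size_parameters",
    "n_max_wiscombe",
    "coated_sphere_coefficients",
    "homogeneous_sphere_coefficients",
    "scattering_amplitudes",
    "efficiencies",
    "q_sca_na",
    "apparent_absorbance",
    "forward_amplitude",
]

UM_TO_CM = 1e-4


class NumericalFailure(RuntimeError):
    """Raised when the recursion produces a non-finite expansion coefficient."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SizeParameters:
    """Dimensionless size parameters of the two boundaries, x = 2 pi nu a."""

    x_core: float
    x_shell: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.x_core) and np.isfinite(self.x_shell)):
            raise ValueError("size parameters must be finite")
        if not (0.0 < self.x_core <= self.x_shell):
            raise ValueError(
                f"need 0 < x_core <= x_shell, got x_core={self.x_core}, "
                f"x_shell={self.x_shell}"
            )


@dataclass(frozen=True)
class ComplexIndexPair:
    """Complex relative refractive indices of interior (core) and wall (shell)."""

    m_core: complex
    m_shell: complex

    def __post_init__(self) -> None:
        for name, m in (("m_core", self.m_core), ("m_shell", self.m_shell)):
            if not np.isfinite(m):
                raise ValueError(f"{name} must be finite")
            if m.real <= 0:
                raise ValueError(f"{name} must have positive real part")
            if m.imag < 0:
                raise ValueError(f"{name} must have non-negative imaginary part")


@dataclass(frozen=True)
class MieCoefficients:
    """Expansion coefficients a_n, b_n for orders n = 1 .. N_max."""

    a_n: np.ndarray
    b_n: np.ndarray

    @property
    def n_max(self) -> int:
        return len(self.a_n)

    def __post_init__(self) -> None:
        if self.n_max < 1 or len(self.b_n) != self.n_max:
            raise ValueError("a_n and b_n must be equal-length, non-empty")


@dataclass(frozen=True)
class AmplitudeSet:
    """Angular scattering amplitudes S1, S2 on a polar-angle grid in [0, pi].

    For a spherically symmetric scatterer the amplitude matrix is diagonal
    (S3 = S4 = 0), so S1 and S2 carry the complete far field.
    """

    theta_grid: np.ndarray
    S1: np.ndarray
    S2: np.ndarray


@dataclass(frozen=True)
class EfficiencySet:
    Q_ext: float
    Q_sca: float
    Q_abs: float
    Q_sca_NA: float | None = None


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def size_parameters(a_core_um: float, a_shell_um: float, nu_cm: float) -> SizeParameters:
    """Size parameters from radii in um and a wavenumber in cm^-1."""
    k = 2.0 * np.pi * nu_cm
    return SizeParameters(k * a_core_um * UM_TO_CM, k * a_shell_um * UM_TO_CM)


def n_max_wiscombe(x_shell: float) -> int:
    """Series truncation order: N = ceil(x + 4 x^(1/3) + 2).

    The tail |a_n|, |b_n| decays super-exponentially beyond this order.
    """
    return max(3, int(np.ceil(x_shell + 4.0 * x_shell ** (1.0 / 3.0) + 2.0)))


def _log_deriv_d1(z: complex | np.ndarray, n_max: int, n_extra: int = 15) -> np.ndarray:
    """D1_n(z) = psi_n'(z)/psi_n(z), n = 0..n_max, by downward recursion.

    Started n_extra orders above n_max with D1 = 0; the recursion contracts
    towards the correct value, so the start error is irrelevant at n <= n_max.
    Vectorised over z.
    """
    z = np.asarray(z, dtype=complex)
    n_start = n_max + n_extra + int(np.max(np.abs(z)) ** 0.5)
    d = np.zeros_like(z)
    out = np.empty((n_max + 1,) + z.shape, dtype=complex)
    for n in range(n_start, 0, -1):
        d = n / z - 1.0 / (d + n / z)
        if n - 1 <= n_max:
            out[n - 1] = d
    return out


def _log_deriv_d3_and_products(z: complex | np.ndarray, n_max: int,
                               d1: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """D3_n(z) = xi_n'(z)/xi_n(z) and the products psi_n(z)*xi_n(z), upward.

    Uses psi_0*xi_0 = (1 - exp(2iz))/2 and
    psi_n xi_n = psi_{n-1} xi_{n-1} (n/z - D1_{n-1})(n/z - D3_{n-1});
    D3_n = D1_n + i/(psi_n xi_n).  All quantities stay O(1) for Im(z) >= 0.
    """
    z = np.asarray(z, dtype=complex)
    d3 = np.empty_like(d1)
    pchi = np.empty_like(d1)
    pchi[0] = 0.5 * (1.0 - np.exp(2j * z))
    d3[0] = d1[0] + 1j / pchi[0]
    for n in range(1, n_max + 1):
        pchi[n] = pchi[n - 1] * (n / z - d1[n - 1]) * (n / z - d3[n - 1])
        d3[n] = d1[n] + 1j / pchi[n]
    return d3, pchi


def _ratio_psi_xi(z: complex | np.ndarray, n_max: int, d1: np.ndarray,
                  d3: np.ndarray) -> np.ndarray:
    """R_n(z) = psi_n(z)/xi_n(z), upward from R_0 = (1 - exp(-2iz))/2."""
    z = np.asarray(z, dtype=complex)
    r = np.empty_like(d1)
    r[0] = 0.5 * (1.0 - np.exp(-2j * z))
    for n in range(1, n_max + 1):
        r[n] = r[n - 1] * (d3[n] + n / z) / (d1[n] + n / z)
    return r


def _riccati_psi_xi_real(x: float | np.ndarray, n_max: int) -> tuple[np.ndarray, np.ndarray]:
    """psi_n(x) and xi_n(x) = psi_n - i chi_n at real argument, n = 0..n_max.

    psi by downward log-derivative recursion (upward is unstable for n > x);
    chi by upward recursion (stable).  Vectorised over x.
    """
    x = np.asarray(x, dtype=float)
    d1 = _log_deriv_d1(x.astype(complex), n_max)
    psi = np.empty((n_max + 1,) + x.shape, dtype=float)
    psi[0] = np.sin(x)
    for n in range(1, n_max + 1):
        # psi_{n-1} = psi_n (D1_n + n/x)  =>  psi_n = psi_{n-1} / (D1_n + n/x)
        psi[n] = psi[n - 1] / np.real(d1[n] + n / x)
    chi = np.empty_like(psi)
    chi[0] = np.cos(x)
    chi_m1 = -np.sin(x)  # chi_{-1}
    prev2, prev1 = chi_m1, chi[0]
    for n in range(1, n_max + 1):
        chi[n] = (2 * n - 1) / x * prev1 - prev2
        prev2, prev1 = prev1, chi[n]
    return psi, psi - 1j * chi


# ---------------------------------------------------------------------------
# coefficients
# ---------------------------------------------------------------------------

def coated_sphere_coefficients(m: ComplexIndexPair, x: SizeParameters,
                               n_max: int | None = None) -> MieCoefficients:
    """Expansion coefficients of a two-layer concentric sphere.

    Logarithmic derivatives Ha_n, Hb_n of the interior field are propagated
    from the core through the shell; only bounded ratios enter the transfer,
    which keeps the scheme stable for absorbing layers (Im(m) up to ~0.5,
    x_shell up to ~100).

    Parameters
    ----------
    m : ComplexIndexPair
    x : SizeParameters
    n_max : optional explicit truncation order (default: Wiscombe criterion
        on ``x.x_shell``).

    Raises
    ------
    ValueError : non-finite inputs (via the dataclass invariants).
    NumericalFailure : a non-finite coefficient was produced; the message
        carries the first offending order.
    """
    if n_max is None:
        n_max = n_max_wiscombe(x.x_shell)
    m1, m2 = complex(m.m_core), complex(m.m_shell)
    x1, x2 = float(x.x_core), float(x.x_shell)

    # layer 1 (core): Ha = Hb = D1 at m1*x1
    d1_m1x1 = _log_deriv_d1(m1 * x1, n_max)
    ha = d1_m1x1.copy()
    hb = d1_m1x1.copy()

    # layer 2 (shell): transfer across the core boundary, then to the surface
    d1_m2x1 = _log_deriv_d1(m2 * x1, n_max)
    d3_m2x1, _ = _log_deriv_d3_and_products(m2 * x1, n_max, d1_m2x1)
    r_m2x1 = _ratio_psi_xi(m2 * x1, n_max, d1_m2x1, d3_m2x1)
    d1_m2x2 = _log_deriv_d1(m2 * x2, n_max)
    d3_m2x2, _ = _log_deriv_d3_and_products(m2 * x2, n_max, d1_m2x2)
    r_m2x2 = _ratio_psi_xi(m2 * x2, n_max, d1_m2x2, d3_m2x2)
    q = r_m2x1 / r_m2x2

    g1 = m2 * ha - m1 * d1_m2x1
    g2 = m2 * ha - m1 * d3_m2x1
    ha = (g2 * d1_m2x2 - q * g1 * d3_m2x2) / (g2 - q * g1)
    g1 = m1 * hb - m2 * d1_m2x1
    g2 = m1 * hb - m2 * d3_m2x1
    hb = (g2 * d1_m2x2 - q * g1 * d3_m2x2) / (g2 - q * g1)

    # match to the host medium at the outer surface
    psi, xi = _riccati_psi_xi_real(np.array(x2), n_max)
    ns = np.arange(1, n_max + 1)
    fa = ha[1:] / m2 + ns / x2
    fb = hb[1:] * m2 + ns / x2
    a_n = (fa * psi[1:] - psi[:-1]) / (fa * xi[1:] - xi[:-1])
    b_n = (fb * psi[1:] - psi[:-1]) / (fb * xi[1:] - xi[:-1])

    bad = ~(np.isfinite(a_n) & np.isfinite(b_n))
    if bad.any():
        raise NumericalFailure(
            f"non-finite expansion coefficient at order n={int(np.argmax(bad)) + 1}"
        )
    return MieCoefficients(np.ascontiguousarray(a_n), np.ascontiguousarray(b_n))


def homogeneous_sphere_coefficients(m_rel: complex, x: float,
                                    n_max: int | None = None) -> MieCoefficients:
    """Classic Mie coefficients of a homogeneous sphere (used for degeneracy
    checks and as the single-layer fast path)."""
    if n_max is None:
        n_max = n_max_wiscombe(x)
    d1 = _log_deriv_d1(complex(m_rel) * x, n_max)
    psi, xi = _riccati_psi_xi_real(np.array(float(x)), n_max)
    ns = np.arange(1, n_max + 1)
    fa = d1[1:] / m_rel + ns / x
    fb = d1[1:] * m_rel + ns / x
    a_n = (fa * psi[1:] - psi[:-1]) / (fa * xi[1:] - xi[:-1])
    b_n = (fb * psi[1:] - psi[:-1]) / (fb * xi[1:] - xi[:-1])
    return MieCoefficients(a_n, b_n)


# ---------------------------------------------------------------------------
# amplitudes and efficiencies
# ---------------------------------------------------------------------------

def _pi_tau(mu: np.ndarray, n_max: int) -> tuple[np.ndarray, np.ndarray]:
    """Angular functions pi_n(mu), tau_n(mu) for n = 1..n_max (rows) by the
    standard upward recursion; mu = cos(theta)."""
    mu = np.asarray(mu, dtype=float)
    pi = np.empty((n_max, mu.size))
    tau = np.empty_like(pi)
    pi_nm2 = np.zeros_like(mu)   # pi_0
    pi[0] = np.ones_like(mu)     # pi_1
    tau[0] = mu * pi[0] - 2.0 * pi_nm2
    for n in range(2, n_max + 1):
        pi[n - 1] = ((2 * n - 1) / (n - 1)) * mu * pi[n - 2] - (n / (n - 1)) * pi_nm2
        tau[n - 1] = n * mu * pi[n - 1] - (n + 1) * pi[n - 2]
        pi_nm2 = pi[n - 2]
    return pi, tau


def scattering_amplitudes(coeffs: MieCoefficients,
                          theta_grid: np.ndarray) -> AmplitudeSet:
    """Complex scattering amplitudes S1(theta), S2(theta).

    S1 = sum_n (2n+1)/(n(n+1)) (a_n pi_n + b_n tau_n),
    S2 = sum_n (2n+1)/(n(n+1)) (a_n tau_n + b_n pi_n);
    S1(0) = S2(0) by forward-direction symmetry.
    """
    theta = np.atleast_1d(np.asarray(theta_grid, dtype=float))
    if np.any(theta < -1e-12) or np.any(theta > np.pi + 1e-12):
        raise ValueError("theta must lie in [0, pi]")
    n_max = coeffs.n_max
    pi_n, tau_n = _pi_tau(np.cos(theta), n_max)
    ns = np.arange(1, n_max + 1)
    w = (2 * ns + 1) / (ns * (ns + 1))
    wa = (w * coeffs.a_n)
    wb = (w * coeffs.b_n)
    s1 = wa @ pi_n + wb @ tau_n
    s2 = wa @ tau_n + wb @ pi_n
    return AmplitudeSet(theta, s1, s2)


def forward_amplitude(coeffs: MieCoefficients) -> complex:
    """S(0) = (1/2) sum_n (2n+1)(a_n + b_n); enters the optical theorem
    Q_ext = (4/x^2) Re S(0)."""
    ns = np.arange(1, coeffs.n_max + 1)
    return complex(0.5 * np.sum((2 * ns + 1) * (coeffs.a_n + coeffs.b_n)))


def efficiencies(coeffs: MieCoefficients, x_shell: float,
                 tol: float = 1e-8) -> EfficiencySet:
    """Q_ext, Q_sca from the coefficient sums; Q_abs = Q_ext - Q_sca.

    A tiny negative Q_abs (within ``tol``) is clamped to zero; a larger one
    signals unstable coefficients and raises :class:`NumericalFailure`.
    """
    if not (np.all(np.isfinite(coeffs.a_n)) and np.all(np.isfinite(coeffs.b_n))):
        raise ValueError("coefficients must be finite")
    ns = np.arange(1, coeffs.n_max + 1)
    w = 2 * ns + 1.0
    pref = 2.0 / (x_shell * x_shell)
    q_ext = pref * float(np.sum(w * np.real(coeffs.a_n + coeffs.b_n)))
    q_sca = pref * float(np.sum(w * (np.abs(coeffs.a_n) ** 2 + np.abs(coeffs.b_n) ** 2)))
    q_abs = q_ext - q_sca
    if q_abs < -tol:
        raise NumericalFailure(f"Q_abs = {q_abs} < -{tol}: unstable coefficients")
    return EfficiencySet(q_ext, q_sca, max(q_abs, 0.0))


def q_sca_na(amps_or_coeffs, theta_na: float, nu_cm: float, a_cm: float,
             n_nodes: int | None = None) -> float:
    """Scattering efficiency lost outside the collection cone (apparent loss):

        Q_sca^NA = 1/(2 pi nu a)^2 * int_{theta_NA}^{pi} (|S1|^2 + |S2|^2) sin(theta) dtheta

    evaluated by Gauss–Legendre quadrature on [theta_NA, pi].  Accepts either a
    :class:`MieCoefficients` (amplitudes evaluated at the quadrature nodes,
    the accurate route) or a precomputed :class:`AmplitudeSet` (interpolated).
    Non-increasing in ``theta_na``; at theta_na = 0 it equals the total Q_sca.
    """
    if not (0.0 <= theta_na <= np.pi):
        raise ValueError("theta_NA must lie in [0, pi]")
    if a_cm <= 0 or nu_cm <= 0:
        raise ValueError("radius and wavenumber must be positive")
    if theta_na >= np.pi:
        return 0.0
    if isinstance(amps_or_coeffs, MieCoefficients):
        n_max = amps_or_coeffs.n_max
        if n_nodes is None:
            n_nodes = max(256, 4 * n_max)
        nodes, wts = np.polynomial.legendre.leggauss(n_nodes)
        theta = 0.5 * (np.pi - theta_na) * nodes + 0.5 * (np.pi + theta_na)
        wts = 0.5 * (np.pi - theta_na) * wts
        amps = scattering_amplitudes(amps_or_coeffs, theta)
        integrand = (np.abs(amps.S1) ** 2 + np.abs(amps.S2) ** 2) * np.sin(theta)
        integral = float(np.sum(wts * integrand))
    else:
        amps: AmplitudeSet = amps_or_coeffs
        f = (np.abs(amps.S1) ** 2 + np.abs(amps.S2) ** 2) * np.sin(amps.theta_grid)
        mask = amps.theta_grid >= theta_na
        integral = float(np.trapezoid(f[mask], amps.theta_grid[mask]))
    x = 2.0 * np.pi * nu_cm * a_cm
    return integral / (x * x)


def coated_coefficients_grid(m_core: np.ndarray, m_shell: np.ndarray,
                             x_core: np.ndarray, x_shell: np.ndarray,
                             n_max: int | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Coated-sphere coefficients for a whole spectrum at once.

    Same recursion as :func:`coated_sphere_coefficients`, vectorised over K
    channels with one shared truncation order (Wiscombe at max x_shell; the
    extra orders for smaller channels are harmless tail).  Returns (a, b) of
    shape (K, n_max).
    """
    m1 = np.asarray(m_core, dtype=complex)
    m2 = np.asarray(m_shell, dtype=complex)
    x1 = np.asarray(x_core, dtype=float)
    x2 = np.asarray(x_shell, dtype=float)
    if n_max is None:
        n_max = n_max_wiscombe(float(np.max(x2)))

    ha = _log_deriv_d1(m1 * x1, n_max)
    hb = ha.copy()
    d1_s1 = _log_deriv_d1(m2 * x1, n_max)
    d3_s1, _ = _log_deriv_d3_and_products(m2 * x1, n_max, d1_s1)
    r_s1 = _ratio_psi_xi(m2 * x1, n_max, d1_s1, d3_s1)
    d1_s2 = _log_deriv_d1(m2 * x2, n_max)
    d3_s2, _ = _log_deriv_d3_and_products(m2 * x2, n_max, d1_s2)
    r_s2 = _ratio_psi_xi(m2 * x2, n_max, d1_s2, d3_s2)
    q = r_s1 / r_s2

    g1 = m2 * ha - m1 * d1_s1
    g2 = m2 * ha - m1 * d3_s1
    ha = (g2 * d1_s2 - q * g1 * d3_s2) / (g2 - q * g1)
    g1 = m1 * hb - m2 * d1_s1
    g2 = m1 * hb - m2 * d3_s1
    hb = (g2 * d1_s2 - q * g1 * d3_s2) / (g2 - q * g1)

    psi, xi = _riccati_psi_xi_real(x2, n_max)
    ns = np.arange(1, n_max + 1).reshape((-1,) + (1,) * x2.ndim)
    fa = ha[1:] / m2 + ns / x2
    fb = hb[1:] * m2 + ns / x2
    a_n = (fa * psi[1:] - psi[:-1]) / (fa * xi[1:] - xi[:-1])
    b_n = (fb * psi[1:] - psi[:-1]) / (fb * xi[1:] - xi[:-1])
    if not (np.all(np.isfinite(a_n)) and np.all(np.isfinite(b_n))):
        raise NumericalFailure("non-finite coefficient in batch evaluation")
    return np.moveaxis(a_n, 0, -1), np.moveaxis(b_n, 0, -1)


def efficiencies_grid(a: np.ndarray, b: np.ndarray,
                      x_shell: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Q_ext, Q_sca, Q_abs per channel from (K, N) coefficient arrays."""
    ns = np.arange(1, a.shape[-1] + 1)
    w = 2 * ns + 1.0
    pref = 2.0 / np.asarray(x_shell) ** 2
    q_ext = pref * np.sum(w * np.real(a + b), axis=-1)
    q_sca = pref * np.sum(w * (np.abs(a) ** 2 + np.abs(b) ** 2), axis=-1)
    return q_ext, q_sca, q_ext - q_sca


def q_sca_na_grid(a: np.ndarray, b: np.ndarray, x_shell: np.ndarray,
                  theta_na: float, n_nodes: int | None = None) -> np.ndarray:
    """NA-limited scattering loss per channel (vectorised form of
    :func:`q_sca_na` over (K, N) coefficient arrays, one collection angle)."""
    if not (0.0 <= theta_na <= np.pi):
        raise ValueError("theta_NA must lie in [0, pi]")
    if theta_na >= np.pi:
        return np.zeros(a.shape[0])
    n_max = a.shape[-1]
    if n_nodes is None:
        n_nodes = max(256, 4 * n_max)
    nodes, wts = np.polynomial.legendre.leggauss(n_nodes)
    theta = 0.5 * (np.pi - theta_na) * nodes + 0.5 * (np.pi + theta_na)
    wts = 0.5 * (np.pi - theta_na) * wts * np.sin(theta)
    pi_n, tau_n = _pi_tau(np.cos(theta), n_max)
    ns = np.arange(1, n_max + 1)
    w = (2 * ns + 1) / (ns * (ns + 1))
    s1 = (w * a) @ pi_n + (w * b) @ tau_n
    s2 = (w * a) @ tau_n + (w * b) @ pi_n
    integral = (np.abs(s1) ** 2 + np.abs(s2) ** 2) @ wts
    return integral / np.asarray(x_shell) ** 2


def apparent_absorbance(q_abs: float | np.ndarray, q_sca_na_val: float | np.ndarray,
                        c_ratio: float, g_over_g: float) -> float | np.ndarray:
    """Absorbance registered by the instrument.

    The total loss at the numerical aperture is Q_ext^NA = C Q_abs + Q_sca^NA
    (C mixes molecular absorption against scattering loss), and with the
    sample/detector fill fraction g/G the absorbance is

        A = -log10(1 - (g/G) Q_ext^NA).

    Raises a domain error when (g/G) Q_ext^NA >= 1 (total extinction —
    an unphysical parameter combination).
    """
    if c_ratio <= 0:
        raise ValueError("C must be positive")
    if not (0.0 < g_over_g <= 1.0):
        raise ValueError("g/G must lie in (0, 1]")
    q_ext_na = c_ratio * np.asarray(q_abs) + np.asarray(q_sca_na_val)
    arg = 1.0 - g_over_g * q_ext_na
    if np.any(arg <= 0.0):
        raise ValueError("(g/G) * Q_ext^NA >= 1: total extinction")
    a = -np.log10(arg)
    return float(a) if np.ndim(a) == 0 else a
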