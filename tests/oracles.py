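"""Independent high-precision oracles used only by the test suite.

The coated-sphere oracle evaluates Riccati–Bessel functions directly from
mpmath's Bessel functions at 50 significant digits (no recursion anywhere)
and solves the raw boundary-condition linear system per order — a route
entirely disjoint from the package's log-derivative recursion scheme.
"""

from __future__ import annotations

import mpmath as mp
import numpy as np

mp.mp.dps = 50


def _psi(n, z):
    """psi_n(z) = z j_n(z) = sqrt(pi z / 2) J_{n+1/2}(z)."""
    return mp.sqrt(mp.pi * z / 2) * mp.besselj(n + mp.mpf(1) / 2, z)


def _chi(n, z):
    """chi_n(z) = -z y_n(z) = -sqrt(pi z / 2) Y_{n+1/2}(z)."""
    return -mp.sqrt(mp.pi * z / 2) * mp.bessely(n + mp.mpf(1) / 2, z)


def _xi(n, z):
    """xi_n(z) = psi_n(z) - i chi_n(z) (outgoing)."""
    return _psi(n, z) - 1j * _chi(n, z)


def _deriv(f, n, z, h=None):
    """Derivative via the exact recurrence f_n'(z) = f_{n-1}(z) - (n/z) f_n(z),
    valid for psi, chi and xi alike."""
    return f(n - 1, z) - (n / z) * f(n, z)


def coated_coefficients_oracle(m_core: complex, m_shell: complex,
                               x_core: float, x_shell: float, n_max: int):
    """a_n, b_n (n = 1..n_max) from the boundary-condition linear systems.

    Unknowns per polarization: core amplitude d, shell amplitudes (f, g) of the
    regular/irregular radial functions, scattered amplitude a.  TM (a-type)
    modes: u and u'/m continuous across each interface; TE (b-type) modes:
    u/m and u' continuous.  Outside: u = psi(x) - a xi(x).
    """
    m1, m2 = mp.mpmathify(m_core), mp.mpmathify(m_shell)
    x1, x2 = mp.mpf(x_core), mp.mpf(x_shell)
    a_out, b_out = [], []
    for n in range(1, n_max + 1):
        z1c, z1s, z2s = m1 * x1, m2 * x1, m2 * x2
        psi_c, dpsi_c = _psi(n, z1c), _deriv(_psi, n, z1c)
        psi_s1, dpsi_s1 = _psi(n, z1s), _deriv(_psi, n, z1s)
        chi_s1, dchi_s1 = _chi(n, z1s), _deriv(_chi, n, z1s)
        psi_s2, dpsi_s2 = _psi(n, z2s), _deriv(_psi, n, z2s)
        chi_s2, dchi_s2 = _chi(n, z2s), _deriv(_chi, n, z2s)
        psi_x, dpsi_x = _psi(n, x2), _deriv(_psi, n, x2)
        xi_x, dxi_x = _xi(n, x2), _deriv(_xi, n, x2)

        # TM: rows = [u cont @ r1, u'/m cont @ r1, u cont @ r2, u'/m cont @ r2]
        # unknowns (d, f, g, a); RHS from the incident wave psi(x).
        A = mp.matrix(4, 4)
        rhs = mp.matrix(4, 1)
        A[0, 0], A[0, 1], A[0, 2] = psi_c, -psi_s1, -chi_s1
        A[1, 0], A[1, 1], A[1, 2] = dpsi_c / m1, -dpsi_s1 / m2, -dchi_s1 / m2
        A[2, 1], A[2, 2], A[2, 3] = psi_s2, chi_s2, xi_x
        rhs[2] = psi_x
        A[3, 1], A[3, 2], A[3, 3] = dpsi_s2 / m2, dchi_s2 / m2, dxi_x
        rhs[3] = dpsi_x
        sol = mp.lu_solve(A, rhs)
        a_out.append(complex(sol[3]))

        # TE: rows = [u/m cont, u' cont] at each interface
        B = mp.matrix(4, 4)
        rhs = mp.matrix(4, 1)
        B[0, 0], B[0, 1], B[0, 2] = psi_c / m1, -psi_s1 / m2, -chi_s1 / m2
        B[1, 0], B[1, 1], B[1, 2] = dpsi_c, -dpsi_s1, -dchi_s1
        B[2, 1], B[2, 2], B[2, 3] = psi_s2 / m2, chi_s2 / m2, xi_x
        rhs[2] = psi_x
        B[3, 1], B[3, 2], B[3, 3] = dpsi_s2, dchi_s2, dxi_x
        rhs[3] = dpsi_x
        sol = mp.lu_solve(B, rhs)
        b_out.append(complex(sol[3]))
    return np.array(a_out), np.array(b_out)


def efficiencies_oracle(a_n: np.ndarray, b_n: np.ndarray, x: float):
    ns = np.arange(1, len(a_n) + 1)
    w = 2 * ns + 1.0
    q_ext = 2.0 / x**2 * np.sum(w * np.real(a_n + b_n))
    q_sca = 2.0 / x**2 * np.sum(w * (np.abs(a_n) ** 2 + np.abs(b_n) ** 2))
    return q_ext, q_sca, q_ext - q_sca


def rayleigh_coated_qsca(m_core: complex, m_shell: complex,
                         x_core: float, x_shell: float) -> float:
    """Small-particle (electrostatic) limit of the coated-sphere scattering
    efficiency via the core-shell polarizability:

        Q_sca = (8/3) x^4 |K|^2,
        K = [(m2^2-1)(m1^2+2 m2^2) + f^3 (2 m2^2+1)(m1^2-m2^2)]
            / [(m2^2+2)(m1^2+2 m2^2) + f^3 (2 m2^2-2)(m1^2-m2^2)],  f = x1/x2.
    """
    e1, e2 = m_core**2, m_shell**2
    f3 = (x_core / x_shell) ** 3
    k = ((e2 - 1) * (e1 + 2 * e2) + f3 * (2 * e2 + 1) * (e1 - e2)) / (
        (e2 + 2) * (e1 + 2 * e2) + f3 * (2 * e2 - 2) * (e1 - e2)
    )
    return 8.0 / 3.0 * x_shell**4 * abs(k) ** 2


def lorentzian_dispersion_oracle(nu_eval: np.ndarray, amp: float, nu0: float,
                                 gamma: float, c: float,
                                 window: tuple[float, float] | None = None) -> np.ndarray:
    """Dense adaptive-quadrature principal value of
    (c/pi) int alpha(O)/(O^2-nu^2) dO for a Lorentzian band
    alpha = amp * gamma^2 / ((O-nu0)^2 + gamma^2) supported on ``window``
    (alpha = 0 outside), via scipy's Cauchy-weight quadrature."""
    from scipy.integrate import quad

    if window is None:
        lo = max(1e-6, nu0 - 400 * gamma)  # stay on the positive axis
        hi = nu0 + 400 * gamma
    else:
        lo, hi = window

    def alpha(om):
        return amp * gamma**2 / ((om - nu0) ** 2 + gamma**2)

    out = np.empty_like(np.asarray(nu_eval, dtype=float))
    for i, nu in enumerate(np.atleast_1d(nu_eval)):
        # 1/(O^2 - nu^2) = 1/((O - nu)(O + nu)); Cauchy weight handles 1/(O - nu)
        g = lambda om: alpha(om) / (om + nu)
        if lo < nu < hi:
            val, _ = quad(g, lo, hi, weight="cauchy", wvar=float(nu),
                          limit=400)
        else:
            val, _ = quad(lambda om: alpha(om) / (om**2 - nu**2), lo, hi,
                          limit=400)
        out[i] = c / np.pi * val
    return out
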