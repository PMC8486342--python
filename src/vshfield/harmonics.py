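"""Complex spherical harmonics and vector spherical harmonics (VSH).

Conventions
-----------
Orthonormal complex spherical harmonics with the Condon–Shortley phase,

.. math:: \\int Y_{lm}^* Y_{l'm'} \\, d\\Omega = \\delta_{ll'} \\delta_{mm'},
          \\qquad Y_{l,-m} = (-1)^m \\, Y_{lm}^*.

Three vector-valued families are exposed, all evaluated in the local
spherical frame ``(e_r, e_theta, e_phi)``:

* ``vsh_nu``    -- :math:`\\nu_{lm} = -(l+1) Y_{lm}\\,e_r
  + \\partial_\\theta Y_{lm}\\,e_\\theta + \\frac{i m Y_{lm}}{\\sin\\theta}
  e_\\phi`, the angular part of :math:`\\nabla(Y_{lm}/r^{l+1}) \\cdot r^{l+2}`.
  It carries fields of sources *closer* to the origin than the field point.
* ``vsh_omega`` -- :math:`\\omega_{lm} = l\\,Y_{lm}\\,e_r
  + \\partial_\\theta Y_{lm}\\,e_\\theta + \\frac{i m Y_{lm}}{\\sin\\theta}
  e_\\phi`, the angular part of :math:`\\nabla(r^l Y_{lm}) / r^{l-1}`,
  carrying fields of *more distant* sources.
* ``vsh_x``     -- the tangential, unit-L2-normalized
  :math:`X_{lm} = \\mathbf{L} Y_{lm} / \\sqrt{l(l+1)}` appearing in the
  magnetostatic source kernel; :math:`X_{00} \\equiv 0`.

Pole safety
-----------
The apparent ``1/sin(theta)`` singularities are removed analytically:
``dtheta`` uses the same-degree ladder identity and ``m Y/sin(theta)`` the
degree-``l-1`` associated-Legendre identity, so every function is finite at
``theta = 0`` and ``theta = pi`` (sensors may sit on the z-axis).
"""

from __future__ import annotations

import math

import numpy as np
from scipy import special as _special

__all__ = [
    "spherical_harmonic",
    "dtheta_spherical_harmonic",
    "m_over_sin_spherical_harmonic",
    "vsh_nu",
    "vsh_omega",
    "vsh_x",
    "cart_to_spherical",
    "spherical_frame",
    "vsh_to_cartesian",
]


def _check_degree_order(l: int, m: int, *, allow_any_m: bool = False) -> None:
    if l < 0:
        raise ValueError(f"degree l must be >= 0, got {l}")
    if not allow_any_m and abs(m) > l:
        raise ValueError(f"order m must satisfy |m| <= l, got (l, m) = ({l}, {m})")


def spherical_harmonic(l: int, m: int, theta, phi):
    """Orthonormal complex spherical harmonic ``Y_lm(theta, phi)``.

    ``theta`` is the polar angle from +z, ``phi`` the azimuth from +x.
    Broadcasts over array-valued angles.
    """
    _check_degree_order(l, m)
    return _special.sph_harm_y(l, m, np.asarray(theta), np.asarray(phi))


def _norm_legendre(l: int, m: int, theta):
    """Normalized associated Legendre part of Y_lm (phi factor removed), real.

    Returns 0 for |m| > l; for m < 0 applies the (-1)^m conjugation symmetry.
    """
    if l < 0 or abs(m) > l:
        return np.zeros(np.shape(theta))
    val = _special.sph_harm_y(l, abs(m), np.asarray(theta), 0.0).real
    if m < 0 and abs(m) % 2 == 1:
        val = -val
    return val


def dtheta_spherical_harmonic(l: int, m: int, theta, phi):
    """Polar-angle derivative ``dY_lm/dtheta``, finite at the poles.

    Uses the ladder identity
    ``2 dY/dtheta = sqrt((l-m)(l+m+1)) Y_{l,m+1} e^{-i phi}
    - sqrt((l+m)(l-m+1)) Y_{l,m-1} e^{i phi}``.
    """
    _check_degree_order(l, m)
    theta = np.asarray(theta, dtype=float)
    phi = np.asarray(phi, dtype=float)
    out = np.zeros(np.broadcast(theta, phi).shape, dtype=complex)
    c_up = math.sqrt(max((l - m) * (l + m + 1), 0))
    c_dn = math.sqrt(max((l + m) * (l - m + 1), 0))
    if c_up:
        out += c_up * _special.sph_harm_y(l, m + 1, theta, phi) * np.exp(-1j * phi)
    if c_dn:
        out -= c_dn * _special.sph_harm_y(l, m - 1, theta, phi) * np.exp(1j * phi)
    return 0.5 * out


def m_over_sin_spherical_harmonic(l: int, m: int, theta, phi):
    """``m * Y_lm(theta, phi) / sin(theta)``, evaluated pole-safely.

    For m >= 0 the degree-(l-1) identity
    ``m P_l^m / sin = -1/2 [P_{l-1}^{m+1} + (l+m-1)(l+m) P_{l-1}^{m-1}]``
    is used in normalized form; m < 0 follows from conjugation symmetry.
    """
    _check_degree_order(l, m)
    theta = np.asarray(theta, dtype=float)
    phi = np.asarray(phi, dtype=float)
    if m == 0 or l == 0:
        return np.zeros(np.broadcast(theta, phi).shape, dtype=complex)
    ma = abs(m)
    pref = math.sqrt((2 * l + 1) / (2 * l - 1))
    c_up = math.sqrt(max((l - ma) * (l - ma - 1), 0))
    c_dn = math.sqrt(max((l + ma) * (l + ma - 1), 0))
    lam = np.zeros(theta.shape if theta.shape else (), dtype=float)
    if c_up:
        lam = lam + c_up * _norm_legendre(l - 1, ma + 1, theta)
    if c_dn:
        lam = lam + c_dn * _norm_legendre(l - 1, ma - 1, theta)
    lam = -0.5 * pref * lam  # == ma * Lambda_{l,ma} / sin(theta)
    if m > 0:
        return lam * np.exp(1j * ma * phi)
    # m<0: m Y_{l,m}/sin = (-1)^(ma+1) conj(ma Y_{l,ma}/sin)
    sign = -1.0 if ma % 2 == 0 else 1.0
    return sign * lam * np.exp(-1j * ma * phi)


def _stack_vsh(r_c, t_c, p_c):
    return np.stack(np.broadcast_arrays(
        np.asarray(r_c, dtype=complex),
        np.asarray(t_c, dtype=complex),
        np.asarray(p_c, dtype=complex)), axis=-1)


def vsh_nu(l: int, m: int, theta, phi):
    """Interior-family VSH ``nu_lm`` as an ``(..., 3)`` array in
    ``(e_r, e_theta, e_phi)`` components."""
    y = spherical_harmonic(l, m, theta, phi)
    return _stack_vsh(-(l + 1) * y,
                      dtheta_spherical_harmonic(l, m, theta, phi),
                      1j * m_over_sin_spherical_harmonic(l, m, theta, phi))


def vsh_omega(l: int, m: int, theta, phi):
    """Exterior-family VSH ``omega_lm`` as an ``(..., 3)`` array."""
    y = spherical_harmonic(l, m, theta, phi)
    return _stack_vsh(l * y,
                      dtheta_spherical_harmonic(l, m, theta, phi),
                      1j * m_over_sin_spherical_harmonic(l, m, theta, phi))


def vsh_x(l: int, m: int, theta, phi):
    """Tangential VSH ``X_lm`` (unit L2 norm on the sphere); ``X_00 = 0``."""
    _check_degree_order(l, m)
    theta = np.asarray(theta, dtype=float)
    phi = np.asarray(phi, dtype=float)
    if l == 0:
        shape = np.broadcast(theta, phi).shape
        return np.zeros(shape + (3,), dtype=complex)
    s = math.sqrt(l * (l + 1))
    return _stack_vsh(0.0,
                      -m_over_sin_spherical_harmonic(l, m, theta, phi) / s,
                      -1j * dtheta_spherical_harmonic(l, m, theta, phi) / s)


# ---------------------------------------------------------------------------
# Coordinate helpers
# ---------------------------------------------------------------------------

def cart_to_spherical(points):
    """Cartesian ``(..., 3)`` -> ``(r, theta, phi)`` with phi in [0, 2pi).

    On the z-axis phi is set to 0 (any value is geometrically equivalent and
    the VSH evaluations remain consistent with the returned frame).
    """
    p = np.asarray(points, dtype=float)
    x, y, z = p[..., 0], p[..., 1], p[..., 2]
    r = np.sqrt(x * x + y * y + z * z)
    rho = np.hypot(x, y)
    theta = np.arctan2(rho, z)
    phi = np.mod(np.arctan2(y, x), 2.0 * np.pi)
    return r, theta, phi


def spherical_frame(theta, phi):
    """Unit vectors ``(e_r, e_theta, e_phi)`` as rows of an ``(..., 3, 3)``
    array of Cartesian components."""
    theta = np.asarray(theta, dtype=float)
    phi = np.asarray(phi, dtype=float)
    st, ct = np.sin(theta), np.cos(theta)
    sp, cp = np.sin(phi), np.cos(phi)
    e_r = np.stack(np.broadcast_arrays(st * cp, st * sp, ct), axis=-1)
    e_t = np.stack(np.broadcast_arrays(ct * cp, ct * sp, -st), axis=-1)
    e_p = np.stack(np.broadcast_arrays(-sp, cp, np.zeros_like(sp)), axis=-1)
    return np.stack([e_r, e_t, e_p], axis=-2)


def vsh_to_cartesian(values, theta, phi):
    """Convert ``(..., 3)`` spherical-component vectors to Cartesian."""
    frame = spherical_frame(theta, phi)  # (..., 3, 3): rows e_r, e_t, e_p
    return np.einsum("...c,...cd->...d", np.asarray(values), frame)
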