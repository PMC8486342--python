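"""Electro/magnetostatic multipole moments of discrete sources and field
synthesis outside the source volume.

Under the quasi-static approximation both the electric and the magnetic field
outside the sources are gradients of a harmonic potential and share one VSH
expansion; they differ only through their multipole moments and an overall
scale (``c_e = -1/eps0`` for E, ``c_b = -mu0`` for B):

.. math::

    F(r) = c \\Big[ \\sum_{lm} a_{lm} \\frac{\\nu_{lm}(\\Omega)}{r^{l+2}}
           + \\sum_{lm} b_{lm}\\, r^{l-1} \\omega_{lm}(\\Omega) \\Big].

Interior moments (sources closer to the origin than the field point):

* electrostatic:  ``a_lm = 1/(2l+1) * sum_k q_k r_k^l conj(Y_lm)(Omega_k)``
* magnetostatic:  ``a_lm = i/(2l+1) sqrt(l/(l+1))
  * sum_k r_k^l conj(X_lm)(Omega_k) . Q_k``  (``a_00 = 0`` always -- no
  magnetic monopoles, since ``X_00 = 0``)

Moments exclude the physical scale ``c``; it is applied at synthesis time
(recorded by ``MultipoleMoments.kind``).  All quantities are SI.

Sources are discrete point sets: volume integrals become finite sums; closed
current loops may alternatively be handed to
:func:`magnetostatic_moments_divergence_form`, which integrates the
divergence-form kernel by parts along the polyline (exact for closed loops).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import harmonics as hm

__all__ = [
    "EPSILON_0",
    "MU_0",
    "PointCharge",
    "CurrentElement",
    "MagneticDipole",
    "MultipoleMoments",
    "electrostatic_moments",
    "magnetostatic_moments",
    "magnetostatic_moments_divergence_form",
    "loop_elements",
    "electrostatic_exterior_moments",
    "magnetic_dipole_exterior_moments",
    "synthesize_field",
    "synthesize_potential",
    "magnetic_dipole_field",
    "coulomb_potential",
]

#: Vacuum permittivity, F/m (CODATA 2018).
EPSILON_0 = 8.8541878128e-12
#: Vacuum permeability, H/m (CODATA 2018).
MU_0 = 1.25663706212e-6

_C_SCALE = {"electric": -1.0 / EPSILON_0, "magnetic": -MU_0}


@dataclass(frozen=True)
class PointCharge:
    """Point charge: ``position`` in meters, ``charge`` in coulombs.

    ``charge`` may be a scalar or a 1-D time series; time series propagate to
    a trailing sample axis on the moments.
    """

    position: np.ndarray
    charge: float | np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "position", np.asarray(self.position, dtype=float))
        if not np.all(np.isfinite(self.position)):
            raise ValueError("point-charge position must be finite")


@dataclass(frozen=True)
class CurrentElement:
    """Point current element ``Q`` (A*m) at ``position`` (m)."""

    position: np.ndarray
    moment: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "position", np.asarray(self.position, dtype=float))
        object.__setattr__(self, "moment", np.asarray(self.moment, dtype=float))
        if not (np.all(np.isfinite(self.position)) and np.all(np.isfinite(self.moment))):
            raise ValueError("current element fields must be finite")


@dataclass(frozen=True)
class MagneticDipole:
    """Point magnetic dipole ``m`` (A*m^2) at ``position`` (m); used as an
    exterior interference source."""

    position: np.ndarray
    moment: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "position", np.asarray(self.position, dtype=float))
        object.__setattr__(self, "moment", np.asarray(self.moment, dtype=float))


@dataclass
class MultipoleMoments:
    """Multipole moments about ``origin`` with truncation order ``L``.

    ``a`` holds interior coefficients in an ``(L+1, 2L+1[, T])`` complex array
    indexed ``a[l, m]`` (negative ``m`` wraps, matching the storage of
    ``scipy.special.sph_harm_y_all``); slots with ``|m| > l`` stay zero.
    ``b`` (optional) holds exterior coefficients the same way with order
    ``L_out``.  The physical scale ``c_e``/``c_b`` is *not* folded in; it is
    applied by :func:`synthesize_field` / :func:`synthesize_potential`.
    """

    kind: str
    origin: np.ndarray
    L: int
    a: np.ndarray
    b: np.ndarray | None = None
    L_out: int | None = None
    source_radius: float | None = None

    def __post_init__(self):
        if self.kind not in ("electric", "magnetic"):
            raise ValueError(f"kind must be 'electric' or 'magnetic', got {self.kind!r}")
        self.origin = np.asarray(self.origin, dtype=float)

    def moment(self, l: int, m: int) -> complex | np.ndarray:
        """Interior coefficient ``a_lm``."""
        if l < 0 or l > self.L or abs(m) > l:
            raise ValueError(f"(l, m) = ({l}, {m}) outside truncation L = {self.L}")
        return self.a[l, m]

    @property
    def n_samples(self) -> int | None:
        return self.a.shape[2] if self.a.ndim == 3 else None


def _empty_moments(L: int, n_samples: int | None) -> np.ndarray:
    shape = (L + 1, 2 * L + 1) if n_samples is None else (L + 1, 2 * L + 1, n_samples)
    return np.zeros(shape, dtype=complex)


def _check_order(L: int) -> None:
    if L < 0:
        raise ValueError(f"truncation order L must be >= 0, got {L}")


def electrostatic_moments(charges: Sequence[PointCharge], origin, L: int) -> MultipoleMoments:
    """Interior electrostatic moments of a set of point charges.

    ``a_lm = 1/(2l+1) sum_k q_k r_k^l conj(Y_lm)(Omega_k)``.
    """
    _check_order(L)
    origin = np.asarray(origin, dtype=float)
    n_samples = None
    for c in charges:
        q = np.asarray(c.charge)
        if q.ndim == 1:
            n_samples = q.shape[0]
    a = _empty_moments(L, n_samples)
    r_src = 0.0
    for c in charges:
        rel = c.position - origin
        r, theta, phi = hm.cart_to_spherical(rel)
        r_src = max(r_src, float(r))
        q = np.asarray(c.charge, dtype=float)
        for l in range(L + 1):
            pref = r**l / (2 * l + 1)
            for m in range(-l, l + 1):
                contrib = pref * np.conj(hm.spherical_harmonic(l, m, theta, phi))
                if n_samples is not None:
                    a[l, m] = a[l, m] + contrib * np.broadcast_to(q, (n_samples,))
                else:
                    a[l, m] = a[l, m] + contrib * q
    return MultipoleMoments("electric", origin, L, a, source_radius=r_src)


def magnetostatic_moments(elements: Sequence[CurrentElement], origin, L: int) -> MultipoleMoments:
    """Interior magnetostatic moments of point current elements.

    ``a_lm = i/(2l+1) sqrt(l/(l+1)) sum_k r_k^l conj(X_lm)(Omega_k) . Q_k``;
    the monopole ``a_00`` is identically zero (``X_00 = 0``) and is stored as
    an exact 0.
    """
    _check_order(L)
    origin = np.asarray(origin, dtype=float)
    a = _empty_moments(L, None)
    r_src = 0.0
    for el in elements:
        rel = el.position - origin
        r, theta, phi = hm.cart_to_spherical(rel)
        r_src = max(r_src, float(r))
        frame = hm.spherical_frame(theta, phi)          # rows e_r, e_t, e_p
        q_sph = frame @ el.moment                        # spherical components
        for l in range(1, L + 1):
            pref = 1j / (2 * l + 1) * math.sqrt(l / (l + 1)) * r**l
            for m in range(-l, l + 1):
                x = hm.vsh_x(l, m, theta, phi)
                a[l, m] += pref * np.conj(x) @ q_sph
    return MultipoleMoments("magnetic", origin, L, a, source_radius=r_src)


def loop_elements(vertices, current: float, points_per_segment: int = 8) -> list[CurrentElement]:
    """Discretize a closed polyline loop carrying ``current`` (A) into
    Gauss–Legendre weighted point current elements.

    ``vertices`` is an ``(V, 3)`` array with ``vertices[0] == vertices[-1]``.
    Because ``r^l Y_lm`` is a degree-``l`` polynomial, the resulting elements
    reproduce the exact line integrals of the moment kernels for
    ``l < 2 * points_per_segment``.
    """
    v = np.asarray(vertices, dtype=float)
    if v.ndim != 2 or v.shape[1] != 3 or v.shape[0] < 2:
        raise ValueError("vertices must be a (V, 3) array with V >= 2")
    if not np.allclose(v[0], v[-1], atol=1e-12):
        raise ValueError("polyline must be closed (first vertex == last vertex); "
                         "an open current path violates charge continuity")
    nodes, weights = np.polynomial.legendre.leggauss(points_per_segment)
    elements: list[CurrentElement] = []
    for p0, p1 in zip(v[:-1], v[1:]):
        seg = p1 - p0
        mid = 0.5 * (p0 + p1)
        for t, w in zip(nodes, weights):
            pos = mid + 0.5 * t * seg
            elements.append(CurrentElement(pos, current * 0.5 * w * seg))
    return elements


def magnetostatic_moments_divergence_form(vertices, current: float, origin, L: int,
                                          points_per_segment: int | None = None) -> MultipoleMoments:
    """Magnetostatic moments of a closed current loop via the divergence-form
    kernel, integrated by parts along the polyline.

    The distributional kernel ``r^l Y* div(r x J)`` is rewritten (for a closed
    loop, where the boundary term vanishes) as
    ``a_lm = 1/((2l+1)(l+1)) * I * \\oint grad(r^l conj(Y_lm)) . (r x dl)``
    with ``grad(r^l Y_lm) = r^{l-1} omega_lm``.  Segment integrals use
    Gauss–Legendre quadrature, exact for the polynomial integrand.
    """
    _check_order(L)
    origin = np.asarray(origin, dtype=float)
    v = np.asarray(vertices, dtype=float)
    if not np.allclose(v[0], v[-1], atol=1e-12):
        raise ValueError("polyline must be closed (first vertex == last vertex); "
                         "an open current path violates charge continuity")
    npts = points_per_segment or max(4, L // 2 + 2)
    nodes, weights = np.polynomial.legendre.leggauss(npts)
    a = _empty_moments(L, None)
    r_src = 0.0
    for p0, p1 in zip(v[:-1], v[1:]):
        seg = p1 - p0
        mid = 0.5 * (p0 + p1)
        for t, w in zip(nodes, weights):
            pos = mid + 0.5 * t * seg - origin
            dl = 0.5 * w * seg
            r, theta, phi = hm.cart_to_spherical(pos)
            r_src = max(r_src, float(r))
            rxdl = np.cross(pos, dl)
            frame = hm.spherical_frame(theta, phi)
            rxdl_sph = frame @ rxdl
            for l in range(1, L + 1):
                pref = current * r ** (l - 1) / ((2 * l + 1) * (l + 1))
                for m in range(-l, l + 1):
                    om = np.conj(hm.vsh_omega(l, m, theta, phi))
                    a[l, m] += pref * om @ rxdl_sph
    return MultipoleMoments("magnetic", origin, L, a, source_radius=r_src)


# ---------------------------------------------------------------------------
# Exterior (interference-source) moments
# ---------------------------------------------------------------------------

def electrostatic_exterior_moments(charges: Sequence[PointCharge], origin, L: int) -> MultipoleMoments:
    """Exterior moments ``b_lm`` of point charges *farther* from the origin
    than the evaluation points: ``b_lm = q conj(Y_lm)(Omega_0) /
    ((2l+1) d^{l+1})`` per charge at distance ``d`` (convention: the same
    ``c_e``-scaled field expansion as the interior terms)."""
    _check_order(L)
    origin = np.asarray(origin, dtype=float)
    b = _empty_moments(L, None)
    for c in charges:
        rel = c.position - origin
        d, theta, phi = hm.cart_to_spherical(rel)
        if d == 0:
            raise ValueError("exterior charge cannot sit at the expansion origin")
        for l in range(L + 1):
            pref = float(np.asarray(c.charge)) / ((2 * l + 1) * d ** (l + 1))
            for m in range(-l, l + 1):
                b[l, m] += pref * np.conj(hm.spherical_harmonic(l, m, theta, phi))
    empty_a = _empty_moments(0, None)
    return MultipoleMoments("electric", origin, 0, empty_a, b=b, L_out=L)


def magnetic_dipole_exterior_moments(dipoles: Sequence[MagneticDipole], origin, L: int) -> MultipoleMoments:
    """Exterior moments ``b_lm`` of distant point magnetic dipoles:
    ``b_lm = m . conj(nu_lm)(Omega_0) / ((2l+1) d^{l+2})``."""
    _check_order(L)
    origin = np.asarray(origin, dtype=float)
    b = _empty_moments(L, None)
    for dp in dipoles:
        rel = dp.position - origin
        d, theta, phi = hm.cart_to_spherical(rel)
        if d == 0:
            raise ValueError("exterior dipole cannot sit at the expansion origin")
        frame = hm.spherical_frame(theta, phi)
        m_sph = frame @ dp.moment
        for l in range(1, L + 1):
            pref = 1.0 / ((2 * l + 1) * d ** (l + 2))
            for m in range(-l, l + 1):
                nu = np.conj(hm.vsh_nu(l, m, theta, phi))
                b[l, m] += pref * nu @ m_sph
    empty_a = _empty_moments(0, None)
    return MultipoleMoments("magnetic", origin, 0, empty_a, b=b, L_out=L)


# ---------------------------------------------------------------------------
# Synthesis
# ---------------------------------------------------------------------------

def _synthesize_complex(moments: MultipoleMoments, points) -> np.ndarray:
    pts = np.atleast_2d(np.asarray(points, dtype=float)) - moments.origin
    r, theta, phi = hm.cart_to_spherical(pts)
    if np.any(r == 0):
        raise ValueError("field evaluation point coincides with the expansion origin")
    has_t = moments.a.ndim == 3
    out_shape = pts.shape[:-1] + (3,) + ((moments.a.shape[2],) if has_t else ())
    field = np.zeros(out_shape, dtype=complex)
    for l in range(moments.L + 1):
        radial = r ** -(l + 2)
        for m in range(-l, l + 1):
            coef = moments.a[l, m]
            if not np.any(coef):
                continue
            nu = hm.vsh_nu(l, m, theta, phi)  # (N, 3)
            term = nu * radial[..., None]
            if has_t:
                field += term[..., None] * coef
            else:
                field += term * coef
    if moments.b is not None:
        for l in range(moments.L_out + 1):
            radial = r ** (l - 1)
            for m in range(-l, l + 1):
                coef = moments.b[l, m]
                if not np.any(coef):
                    continue
                om = hm.vsh_omega(l, m, theta, phi)
                term = om * radial[..., None]
                if has_t:
                    field += term[..., None] * coef
                else:
                    field += term * coef
    field *= _C_SCALE[moments.kind]
    # spherical -> Cartesian
    frame = hm.spherical_frame(theta, phi)  # (N, 3, 3)
    if has_t:
        return np.einsum("ncs,ncd->nds", field, frame)
    return np.einsum("nc,ncd->nd", field, frame)


def synthesize_field(moments: MultipoleMoments, points) -> np.ndarray:
    """Real Cartesian E (V/m) or B (T) at ``points`` from the expansion,
    with the physical scale ``c_e``/``c_b`` applied.

    Interior terms require points outside the source radius; exterior terms
    require points inside the exterior-source radius (not checked here beyond
    the origin singularity)."""
    return np.real(_synthesize_complex(moments, points))


def synthesize_potential(moments: MultipoleMoments, points) -> np.ndarray:
    """Real electric potential (V) at ``points``; ``kind`` must be electric."""
    if moments.kind != "electric":
        raise ValueError("potential synthesis requires electric moments")
    pts = np.atleast_2d(np.asarray(points, dtype=float)) - moments.origin
    r, theta, phi = hm.cart_to_spherical(pts)
    if np.any(r == 0):
        raise ValueError("potential evaluation point coincides with the expansion origin")
    has_t = moments.a.ndim == 3
    out_shape = pts.shape[:-1] + ((moments.a.shape[2],) if has_t else ())
    pot = np.zeros(out_shape, dtype=complex)
    for l in range(moments.L + 1):
        radial = r ** -(l + 1)
        for m in range(-l, l + 1):
            coef = moments.a[l, m]
            if not np.any(coef):
                continue
            y = hm.spherical_harmonic(l, m, theta, phi)
            term = y * radial
            pot += term[..., None] * coef if has_t else term * coef
    if moments.b is not None:
        for l in range(moments.L_out + 1):
            radial = r**l
            for m in range(-l, l + 1):
                coef = moments.b[l, m]
                if not np.any(coef):
                    continue
                y = hm.spherical_harmonic(l, m, theta, phi)
                term = y * radial
                pot += term[..., None] * coef if has_t else term * coef
    # V = -c_e * (expansion): the sign pairs with E = c_e * sum(...) so that
    # E = -grad V and a positive point charge has a positive potential.
    return np.real(-_C_SCALE["electric"] * pot)


# ---------------------------------------------------------------------------
# Closed-form point-source fields (used as simulation ground truth)
# ---------------------------------------------------------------------------

def magnetic_dipole_field(dipole: MagneticDipole, points) -> np.ndarray:
    """Free-space field of a point magnetic dipole,
    ``B = mu0/(4 pi) (3 (m.rhat) rhat - m)/R^3``."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    rel = pts - dipole.position
    d = np.linalg.norm(rel, axis=-1, keepdims=True)
    if np.any(d == 0):
        raise ValueError("field point coincides with the dipole position")
    rhat = rel / d
    mdot = rhat @ dipole.moment
    return MU_0 / (4 * np.pi) * (3 * mdot[:, None] * rhat - dipole.moment) / d**3


def coulomb_potential(charges: Sequence[PointCharge], points) -> np.ndarray:
    """Free-space Coulomb potential of point charges (scalar or time-series
    charges; trailing sample axis in the latter case)."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    out = None
    for c in charges:
        d = np.linalg.norm(pts - c.position, axis=-1)
        if np.any(d == 0):
            raise ValueError("potential evaluation point coincides with a charge")
        q = np.asarray(c.charge, dtype=float)
        term = (1.0 / (4 * np.pi * EPSILON_0 * d))[..., None] * q if q.ndim else q / (4 * np.pi * EPSILON_0 * d)
        out = term if out is None else out + term
    if out is None:
        return np.zeros(pts.shape[0])
    return out
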