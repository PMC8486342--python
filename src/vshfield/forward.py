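"""Analytic spherical-conductor forward models.

Two classical solutions for a current dipole embedded in a spherically
symmetric head model:

* :func:`sarvas_field` -- the closed-form exterior magnetic field (Sarvas
  formula).  In spherical symmetry the volume currents are externally
  magnetically silent, so the field depends only on the tangential part of
  the primary dipole and on the sphere *center*, not on the conductivity
  profile.
* :func:`shell_potential` -- the scalp potential for an arbitrary number of
  concentric shells, solved per Legendre degree by 2x2 interface-transfer
  recursion with an insulating exterior.  The default geometry is a 4-shell
  head of radius 91 mm: brain (0.90; 0.33 S/m), CSF (0.92; 1.0), skull
  (0.97; 0.004), scalp (1.0; 0.33).

:func:`build_forward` assembles channels x (3 * n_sources) free-orientation
gain matrices for electrode or field-sensor arrays on top of these.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .multipoles import MU_0

__all__ = [
    "CurrentDipole",
    "ConductorModel",
    "default_head_model",
    "SourceGrid",
    "build_source_grid",
    "sarvas_field",
    "shell_potential",
    "shell_potential_basis",
    "build_forward",
]


@dataclass(frozen=True)
class CurrentDipole:
    """Primary current dipole: ``position`` (m), ``moment`` (A*m), optional
    amplitude time course (unitless multiplier per sample)."""

    position: np.ndarray
    moment: np.ndarray
    amplitude: np.ndarray | None = None

    def __post_init__(self):
        object.__setattr__(self, "position", np.asarray(self.position, dtype=float))
        object.__setattr__(self, "moment", np.asarray(self.moment, dtype=float))
        if self.amplitude is not None:
            object.__setattr__(self, "amplitude", np.asarray(self.amplitude, dtype=float))


@dataclass(frozen=True)
class ConductorModel:
    """Concentric spherical shells: ``radii`` strictly increasing outward
    (m), one conductivity (S/m) per shell, innermost first."""

    center: np.ndarray
    radii: np.ndarray
    conductivities: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "center", np.asarray(self.center, dtype=float))
        object.__setattr__(self, "radii", np.asarray(self.radii, dtype=float))
        object.__setattr__(self, "conductivities", np.asarray(self.conductivities, dtype=float))
        if self.radii.ndim != 1 or len(self.radii) != len(self.conductivities):
            raise ValueError("radii and conductivities must be 1-D and equally long")
        if np.any(np.diff(self.radii) <= 0):
            raise ValueError("shell radii must be strictly increasing")
        if np.any(self.conductivities <= 0):
            raise ValueError("conductivities must be positive")

    @property
    def inner_radius(self) -> float:
        return float(self.radii[0])

    @property
    def outer_radius(self) -> float:
        return float(self.radii[-1])


def default_head_model(center=(0.0, 0.0, 0.0), head_radius: float = 0.091) -> ConductorModel:
    """4-shell head model: relative radii (0.90, 0.92, 0.97, 1.0) and
    conductivities (0.33, 1.0, 0.004, 0.33) S/m."""
    rel = np.array([0.90, 0.92, 0.97, 1.00])
    sig = np.array([0.33, 1.0, 0.004, 0.33])
    return ConductorModel(np.asarray(center, float), head_radius * rel, sig)


@dataclass(frozen=True)
class SourceGrid:
    """Volumetric dipole-position grid inside the innermost shell."""

    spacing: float
    positions: np.ndarray


def build_source_grid(model: ConductorModel, spacing: float = 0.007,
                      max_radius: float | None = None,
                      min_radius: float = 0.0) -> SourceGrid:
    """Cubic lattice of candidate dipole positions with ``spacing`` (default
    7 mm) inside ``max_radius`` (default 0.9 x innermost shell radius) around
    the model center; optionally keep only radii >= ``min_radius``."""
    if max_radius is None:
        max_radius = 0.9 * model.inner_radius
    n = int(np.floor(max_radius / spacing))
    ax = spacing * np.arange(-n, n + 1)
    X, Y, Z = np.meshgrid(ax, ax, ax, indexing="ij")
    pts = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])
    r = np.linalg.norm(pts, axis=1)
    keep = (r <= max_radius) & (r >= min_radius)
    return SourceGrid(spacing, pts[keep] + model.center)


def sarvas_field(dipole: CurrentDipole, center, points) -> np.ndarray:
    """Exterior magnetic field (T) of a current dipole in a spherically
    symmetric conductor centered at ``center`` (Sarvas closed form).

    Radial dipoles (moment parallel to position - center) and dipoles at the
    center give an exactly zero field."""
    center = np.asarray(center, dtype=float)
    pts = np.atleast_2d(np.asarray(points, dtype=float)) - center
    r0 = dipole.position - center
    r = np.linalg.norm(pts, axis=1)
    if np.any(r <= np.linalg.norm(r0)):
        raise ValueError("all field points must lie farther from the sphere center "
                         "than the dipole")
    q_x_r0 = np.cross(dipole.moment, r0)
    if not np.any(q_x_r0):
        return np.zeros_like(pts)
    a_vec = pts - r0
    a = np.linalg.norm(a_vec, axis=1)
    adotr = np.einsum("ij,ij->i", a_vec, pts)
    F = a * (r * a + r**2 - pts @ r0)
    gradF = ((a**2 / r + adotr / a + 2 * a + 2 * r)[:, None] * pts
             - (a + 2 * r + adotr / a)[:, None] * r0)
    B = MU_0 / (4 * np.pi * F[:, None] ** 2) * (
        F[:, None] * q_x_r0 - (pts @ q_x_r0)[:, None] * gradF)
    return B


# ---------------------------------------------------------------------------
# Multi-shell scalp potential
# ---------------------------------------------------------------------------

def _legendre_p_and_dp(n_max: int, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """P_n(x) and P_n'(x) for n = 0..n_max via upward recurrence; shapes
    (n_max+1, ...)."""
    x = np.asarray(x, dtype=float)
    P = np.zeros((n_max + 1,) + x.shape)
    dP = np.zeros_like(P)
    P[0] = 1.0
    if n_max >= 1:
        P[1] = x
        dP[1] = 1.0
    for n in range(1, n_max):
        P[n + 1] = ((2 * n + 1) * x * P[n] - n * P[n - 1]) / (n + 1)
        dP[n + 1] = dP[n - 1] + (2 * n + 1) * P[n]
    return P, dP


def _shell_radial_factors(model: ConductorModel, b_over_R: float, n_terms: int) -> np.ndarray:
    """Per-degree scalp factors ``f_n`` such that
    ``V(scalp) = sum_n f_n (b/R)^{n-1} h_n(rhat)`` for a dipole at radius b.

    Solved in normalized radius u = r/R by inward 2x2 interface transfer from
    the insulating outer boundary."""
    R = model.outer_radius
    u = model.radii / R
    sig = model.conductivities
    M = len(u)
    n = np.arange(1, n_terms + 1, dtype=float)
    # region M trial solution: beta_M = 1, alpha_M = (n+1)/n  (dV/du = 0 at u=1)
    alpha = (n + 1) / n
    beta = np.ones_like(n)
    for j in range(M - 2, -1, -1):  # interface at u[j] between region j and j+1
        uj = u[j]
        rhs1 = alpha * uj**n + beta * uj ** -(n + 1)
        rhs2 = sig[j + 1] * (alpha * n * uj ** (n - 1) - beta * (n + 1) * uj ** -(n + 2))
        det = -sig[j] * (2 * n + 1) * uj**-2
        alpha = (rhs1 * (-sig[j] * (n + 1) * uj ** -(n + 2)) - uj ** -(n + 1) * rhs2) / det
        beta = (uj**n * rhs2 - sig[j] * n * uj ** (n - 1) * rhs1) / det
    # region-1 source coefficient: beta_1^src = 1/(4 pi sigma_1 R^2) (b/R)^{n-1}
    # (the (b/R)^{n-1} factor is kept outside; see caller)
    beta1_src = 1.0 / (4 * np.pi * sig[0] * R**2)
    scale = beta1_src / beta
    return scale * (2 * n + 1) / n  # f_n


def shell_potential_basis(position, model: ConductorModel, electrodes,
                          n_terms: int = 200) -> np.ndarray:
    """Matrix ``(E, 3)`` mapping a dipole moment at ``position`` to scalp
    potentials at ``electrodes`` (projected radially onto the outer surface).
    """
    center = model.center
    R = model.outer_radius
    x0 = np.asarray(position, dtype=float) - center
    b = float(np.linalg.norm(x0))
    if b >= model.inner_radius:
        raise ValueError("dipole must lie strictly inside the innermost shell")
    pts = np.atleast_2d(np.asarray(electrodes, dtype=float)) - center
    norms = np.linalg.norm(pts, axis=1)
    if np.any(norms == 0):
        raise ValueError("electrode at the sphere center")
    rhat = pts / norms[:, None]
    rhat0 = x0 / b if b > 0 else np.array([0.0, 0.0, 1.0])
    cosg = rhat @ rhat0
    P, dP = _legendre_p_and_dp(n_terms, cosg)            # (N+1, E)
    f_n = _shell_radial_factors(model, b / R, n_terms)   # (N,)
    nn = np.arange(1, n_terms + 1, dtype=float)
    with np.errstate(divide="ignore"):
        bpow = np.where(nn == 1, 1.0, (b / R) ** (nn - 1))
    w = f_n * bpow                                       # (N,)
    # h_n(rhat) = n (p.rhat0) P_n + P_n' (p.rhat - cosg (p.rhat0)); linear in p
    # accumulate the (E, 3) map
    coef_r0 = (w * nn) @ P[1:] - (w[:, None] * dP[1:] * cosg).sum(axis=0)  # (E,)
    G = np.einsum("n,ne,ed->ed", w, dP[1:], rhat)
    G += coef_r0[:, None] * rhat0
    return G


def shell_potential(dipole: CurrentDipole, model: ConductorModel, electrodes,
                    n_terms: int = 200) -> np.ndarray:
    """Scalp potential (V) of a current dipole in the layered-sphere model at
    each electrode (series solution, default 200 Legendre degrees)."""
    G = shell_potential_basis(dipole.position, model, electrodes, n_terms)
    return G @ dipole.moment


def build_forward(positions, model_or_center, array, n_terms: int = 200) -> np.ndarray:
    """Free-orientation gain matrix ``G`` (channels x 3*n_sources).

    Columns are ordered (source, orientation x/y/z).  For electrode arrays a
    :class:`ConductorModel` is required and the array's reference
    (an explicit position or average reference) is applied to every column;
    for magnetometer arrays a model or a bare center is accepted (Sarvas).
    Sources outside the innermost shell raise with the offending indices.
    """
    from .signal_space import SensorArray  # cyclic at import time otherwise

    if not isinstance(array, SensorArray):
        raise TypeError("array must be a SensorArray")
    positions = np.atleast_2d(np.asarray(positions, dtype=float))
    n_src = positions.shape[0]
    if isinstance(model_or_center, ConductorModel):
        model = model_or_center
        center = model.center
        bad = np.where(np.linalg.norm(positions - center, axis=1) >= model.inner_radius)[0]
        if bad.size:
            raise ValueError(f"sources outside the innermost shell: indices {bad.tolist()}")
    else:
        model = None
        center = np.asarray(model_or_center, dtype=float)

    G = np.zeros((array.n_channels, 3 * n_src))
    if array.kind == "electrode":
        if model is None:
            raise ValueError("electrode forward model requires a ConductorModel")
        for k, pos in enumerate(positions):
            Ge = shell_potential_basis(pos, model, array.positions, n_terms)
            if isinstance(array.reference, str):  # average reference
                Ge = Ge - Ge.mean(axis=0, keepdims=True)
            else:
                Gr = shell_potential_basis(pos, model, array.reference[None], n_terms)
                Ge = Ge - Gr
            G[:, 3 * k:3 * k + 3] = Ge
    else:
        for k, pos in enumerate(positions):
            for j, e in enumerate(np.eye(3)):
                B = sarvas_field(CurrentDipole(pos, e), center, array.positions)
                G[:, 3 * k + j] = np.einsum("ij,ij->i", B, array.orientations)
    return G
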