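"""VSH signal bases for sensor arrays, moment estimation, interference
suppression, and dimensionality analysis (signal space separation, SSS).

A truncated VSH expansion turns an N-channel momentary measurement into

.. math:: d(t) = [S_{in}\\ S_{out}]\\, x(t),

where the interior block carries multipole moments of sources closer to the
expansion origin than the sensors (the brain) and the exterior block those of
more distant sources (environmental interference).  Columns are built per
channel from the same expansions the synthesis routines use:

* field sensor (orientation ``o``):  ``o . nu_lm / r^{l+2}`` (interior),
  ``r^{l-1} o . omega_lm`` (exterior), scaled by ``c_e`` / ``c_b``;
* potential electrode:  ``Y_lm / r^{l+1}`` (interior), ``r^l Y_lm``
  (exterior), scaled by ``-c_e = 1/eps0``, with the reference electrode's own
  component (or the column mean, under average reference) subtracted.

Magnetic bases exclude ``l = 0`` in both blocks (no magnetic monopoles;
``omega_00 == 0`` identically).  Complex ``(l, +-m)`` pairs are recombined
into real columns (``sqrt(2) Re``, ``-sqrt(2) Im``) so that bases, data and
recovered coefficient time courses are all real.  Columns are normalized to
unit Euclidean norm before pseudoinversion; the recorded scales convert
recovered coefficients back to physical multipole moments.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import linalg as sla

from . import harmonics as hm
from .multipoles import EPSILON_0, MU_0, MultipoleMoments

__all__ = [
    "SensorArray",
    "SignalBasis",
    "DataMatrix",
    "MomentTimecourse",
    "SubspaceReport",
    "IllConditionedBasisError",
    "fit_sphere",
    "build_basis",
    "decompose",
    "suppress_interference",
    "reconstruct_lowrank",
    "variance_explained",
    "basis_dimension",
    "subspace_diagnostics",
]

_C_SCALE = {"electric": -1.0 / EPSILON_0, "magnetic": -MU_0}

#: Default truncation orders per array kind: interior / exterior.
DEFAULT_ORDERS = {"magnetometer": (8, 3), "efield": (8, 3), "electrode": (4, 0)}


class IllConditionedBasisError(RuntimeError):
    """Joint [S_in S_out] basis too ill-conditioned for a unique split."""


@dataclass
class SensorArray:
    """Homogeneous sensor array.

    ``kind`` is one of ``electrode`` (scalar potential with a reference),
    ``magnetometer`` (point projection of B onto a unit orientation) or
    ``efield`` (same for E).  ``reference`` applies to electrode arrays:
    either an explicit reference-electrode position or the string
    ``"average"``.
    """

    kind: str
    positions: np.ndarray
    orientations: np.ndarray | None = None
    reference: np.ndarray | str | None = None
    names: list[str] | None = None

    def __post_init__(self):
        if self.kind not in ("electrode", "magnetometer", "efield"):
            raise ValueError(f"unknown array kind {self.kind!r}")
        self.positions = np.atleast_2d(np.asarray(self.positions, dtype=float))
        if self.positions.shape[0] < 1:
            raise ValueError("array must contain at least one channel")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("sensor positions must be finite")
        if self.kind == "electrode":
            if self.reference is None:
                self.reference = "average"
            if isinstance(self.reference, str):
                if self.reference != "average":
                    raise ValueError("reference must be a position or 'average'")
            else:
                self.reference = np.asarray(self.reference, dtype=float)
        else:
            if self.orientations is None:
                raise ValueError(f"{self.kind} array requires orientations")
            self.orientations = np.atleast_2d(np.asarray(self.orientations, dtype=float))
            norms = np.linalg.norm(self.orientations, axis=1)
            if np.any(np.abs(norms - 1.0) > 1e-12):
                raise ValueError("orientations must be unit-norm to 1e-12")
        if self.names is None:
            prefix = {"electrode": "EEG", "magnetometer": "MAG", "efield": "EF"}[self.kind]
            self.names = [f"{prefix}{i:03d}" for i in range(self.positions.shape[0])]
        if len(self.names) != self.positions.shape[0]:
            raise ValueError("number of names does not match number of channels")

    @property
    def n_channels(self) -> int:
        return self.positions.shape[0]

    @property
    def field_kind(self) -> str:
        """'electric' or 'magnetic' -- which physical scale applies."""
        return "magnetic" if self.kind == "magnetometer" else "electric"


@dataclass
class DataMatrix:
    """Channels x samples recording with sampling rate and channel names."""

    values: np.ndarray
    sfreq: float
    names: list[str]

    def __post_init__(self):
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if not np.all(np.isfinite(self.values)):
            bad = [self.names[i] for i in np.where(~np.isfinite(self.values).all(axis=1))[0]]
            raise ValueError(f"non-finite data in channels: {bad}")
        if len(self.names) != self.values.shape[0]:
            raise ValueError("channel-name count does not match data rows")

    @property
    def n_channels(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]


@dataclass
class SignalBasis:
    """Channels x components real basis with per-column (l, m, region)
    labels; ``m > 0`` labels the sqrt(2)*Re column of the (l, m) pair,
    ``m < 0`` the -sqrt(2)*Im column, ``m = 0`` the bare real column.

    ``matrix`` holds unit-norm columns; ``scales`` the raw Euclidean norms
    removed from them (zero-norm columns keep scale 0 and a zero column).
    """

    matrix: np.ndarray
    scales: np.ndarray
    labels: list[tuple[int, int, str]]
    origin: np.ndarray
    L_in: int
    L_out: int | None
    kind: str
    channel_names: list[str]

    @property
    def n_in(self) -> int:
        return sum(1 for _, _, reg in self.labels if reg == "in")

    @property
    def interior(self) -> np.ndarray:
        return self.matrix[:, : self.n_in]

    @property
    def exterior(self) -> np.ndarray:
        return self.matrix[:, self.n_in:]


@dataclass
class MomentTimecourse:
    """Real coefficient time courses of a basis (components x samples)."""

    values: np.ndarray
    basis: SignalBasis
    condition_number: float

    def __post_init__(self):
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.values.shape[0] != len(self.basis.labels):
            raise ValueError("coefficient count does not match basis columns")

    def interior_moments(self) -> MultipoleMoments:
        """Map the interior real coefficients back to complex ``a_lm``."""
        L = self.basis.L_in
        T = self.values.shape[1]
        a = np.zeros((L + 1, 2 * L + 1, T), dtype=complex)
        for k, (l, m, reg) in enumerate(self.basis.labels):
            if reg != "in":
                continue
            x = self.values[k]
            if m == 0:
                a[l, 0] += x
            elif m > 0:
                a[l, m] += x / np.sqrt(2.0)
                a[l, -m] += (-1) ** m * x / np.sqrt(2.0)
            else:
                ma = -m
                a[l, ma] += 1j * x / np.sqrt(2.0)
                a[l, -ma] += (-1) ** ma * (-1j) * x / np.sqrt(2.0)
        kind = "magnetic" if self.basis.kind == "magnetometer" else "electric"
        return MultipoleMoments(kind, self.basis.origin, L, a)


def fit_sphere(points) -> tuple[np.ndarray, float]:
    """Least-squares sphere fit; returns (center, radius)."""
    p = np.atleast_2d(np.asarray(points, dtype=float))
    A = np.column_stack([2.0 * p, np.ones(len(p))])
    sol, *_ = np.linalg.lstsq(A, (p**2).sum(axis=1), rcond=None)
    center = sol[:3]
    radius = float(np.sqrt(max(sol[3] + center @ center, 0.0)))
    return center, radius


def basis_dimension(L: int, kind: str) -> int:
    """Degrees of freedom of a truncated expansion: ``(L+1)^2`` for
    potential/electric sampling, ``(L+1)^2 - 1`` for magnetic (no
    monopole)."""
    if L < 0:
        raise ValueError(f"truncation order must be >= 0, got {L}")
    if kind in ("potential", "electric", "electrode", "efield"):
        return (L + 1) ** 2
    if kind in ("magnetic", "magnetometer"):
        return (L + 1) ** 2 - 1
    raise ValueError(f"unknown kind {kind!r}")


# ---------------------------------------------------------------------------
# Basis construction
# ---------------------------------------------------------------------------

def _origin_inside_hull(origin: np.ndarray, points: np.ndarray) -> bool:
    from scipy.spatial import Delaunay

    try:
        hull = Delaunay(points)
    except Exception:
        return True  # degenerate geometry; skip the warning
    return bool(hull.find_simplex(origin) >= 0)


def _complex_channel_values(array: SensorArray, origin: np.ndarray,
                            l: int, m: int, region: str) -> np.ndarray:
    """Complex per-channel response to a unit (l, m) moment (plus the
    reference electrode's value for electrode arrays, not yet subtracted)."""
    rel = array.positions - origin
    if array.kind == "electrode" and not isinstance(array.reference, str):
        rel = np.vstack([rel, array.reference - origin])
    r, theta, phi = hm.cart_to_spherical(rel)
    if array.kind == "electrode":
        y = hm.spherical_harmonic(l, m, theta, phi)
        radial = r ** -(l + 1) if region == "in" else r**l
        return (1.0 / EPSILON_0) * y * radial
    frame = hm.spherical_frame(theta, phi)
    o_sph = np.einsum("ncd,nd->nc", frame, array.orientations)
    if region == "in":
        v = hm.vsh_nu(l, m, theta, phi)
        radial = r ** -(l + 2)
    else:
        v = hm.vsh_omega(l, m, theta, phi)
        radial = r ** (l - 1)
    return _C_SCALE[array.field_kind] * np.einsum("nc,nc->n", v, o_sph) * radial


def build_basis(array: SensorArray, origin=None, L_in: int | None = None,
                L_out: int | None = None) -> SignalBasis:
    """Assemble the real [S_in S_out] basis for ``array``.

    ``origin`` defaults to a least-squares sphere fit of the sensor
    positions.  ``L_in``/``L_out`` default per array kind (8/3 magnetic,
    4/0 potential).  ``L_out=None`` suppresses the exterior block entirely.
    A warning (not an error) is issued when the origin falls outside the
    sensor convex hull or when the basis has more columns than channels.
    """
    if L_in is None:
        L_in = DEFAULT_ORDERS[array.kind][0]
    if L_in < 0 or (L_out is not None and L_out < 0):
        raise ValueError("truncation orders must be >= 0")
    if origin is None:
        origin, _ = fit_sphere(array.positions)
    origin = np.asarray(origin, dtype=float)
    if not _origin_inside_hull(origin, array.positions):
        warnings.warn("expansion origin lies outside the convex hull of the "
                      "sensor positions; interior/exterior separation may be "
                      "biased", stacklevel=2)

    magnetic = array.kind == "magnetometer"
    blocks: list[tuple[int, int, str]] = []
    for l in range(1 if magnetic else 0, L_in + 1):
        for m in range(-l, l + 1):
            blocks.append((l, m, "in"))
    if L_out is not None:
        for l in range(1 if magnetic else 0, L_out + 1):
            for m in range(-l, l + 1):
                blocks.append((l, m, "out"))

    n_ch = array.n_channels
    cols = np.zeros((n_ch, len(blocks)))
    pre_norms = np.zeros(len(blocks))
    cache: dict[tuple[int, int, str], np.ndarray] = {}
    for k, (l, m, reg) in enumerate(blocks):
        ma = abs(m)
        key = (l, ma, reg)
        if key not in cache:
            cache[key] = _complex_channel_values(array, origin, l, ma, reg)
        s = cache[key]
        if m == 0:
            col = s.real.copy()
        elif m > 0:
            col = np.sqrt(2.0) * s.real
        else:
            col = -np.sqrt(2.0) * s.imag
        pre_norms[k] = np.linalg.norm(col)
        if array.kind == "electrode":
            if isinstance(array.reference, str):
                col = col - col.mean()
            else:
                col = col[:-1] - col[-1]
        cols[:, k] = col

    scales = np.linalg.norm(cols, axis=0)
    # a column whose reference subtraction cancels essentially all of its
    # magnitude (e.g. the monopole on a single-radius referenced montage)
    # vanishes analytically and must not resurrect from rounding noise
    tiny = scales < 1e-13 * pre_norms
    scales = np.where(tiny, 0.0, scales)
    cols[:, tiny] = 0.0
    safe = np.where(scales > 0, scales, 1.0)
    matrix = cols / safe
    if len(blocks) > n_ch:
        warnings.warn(f"basis is overdetermined: {len(blocks)} components for "
                      f"{n_ch} channels", stacklevel=2)
    return SignalBasis(matrix, scales, blocks, origin, L_in, L_out,
                       array.kind, list(array.names))


# ---------------------------------------------------------------------------
# Decomposition and reconstruction
# ---------------------------------------------------------------------------

def _truncated_pinv(S: np.ndarray, rcond: float) -> tuple[np.ndarray, float]:
    """SVD pseudoinverse with relative singular-value threshold; returns
    (pinv, condition number over the retained spectrum)."""
    U, s, Vt = np.linalg.svd(S, full_matrices=False)
    if s.size == 0 or s[0] == 0:
        return S.T * 0.0, np.inf
    keep = s > rcond * s[0]
    inv = np.zeros_like(s)
    inv[keep] = 1.0 / s[keep]
    cond = float(s[0] / s[keep].min()) if keep.any() else np.inf
    return (Vt.T * inv) @ U.T, cond


def _data_values(basis: SignalBasis, data) -> np.ndarray:
    if isinstance(data, DataMatrix):
        if data.names != basis.channel_names:
            diff = set(data.names) ^ set(basis.channel_names)
            raise ValueError(f"channel mismatch between data and basis: {sorted(diff)}")
        return data.values
    return np.atleast_2d(np.asarray(data, dtype=float))


def decompose(basis: SignalBasis, data, rcond: float = 1e-8) -> MomentTimecourse:
    """Estimate coefficient time courses ``x(t) = S^+ d(t)`` by truncated-SVD
    pseudoinversion of the full (normalized) basis; coefficients are returned
    on the physical (raw-column) scale."""
    D = _data_values(basis, data)
    pinv, cond = _truncated_pinv(basis.matrix, rcond)
    x_norm = pinv @ D
    safe = np.where(basis.scales > 0, basis.scales, 1.0)
    x_raw = x_norm / safe[:, None]
    x_raw[basis.scales == 0] = 0.0
    return MomentTimecourse(x_raw, basis, cond)


def suppress_interference(basis: SignalBasis, data,
                          cond_threshold: float = 1e6,
                          rcond: float = 1e-8) -> DataMatrix:
    """SSS interference suppression: decompose onto [S_in S_out] and
    reconstruct from the interior coefficients only.

    Refuses (raises :class:`IllConditionedBasisError`) when the joint basis
    condition number exceeds ``cond_threshold`` -- the scalar-potential (EEG)
    case, where interior and exterior columns are nearly parallel -- since the
    in/out split is then not unique; low-order interior-only reconstruction
    (:func:`reconstruct_lowrank`) is the available alternative.
    """
    if basis.L_out is None or basis.matrix.shape[1] == basis.n_in:
        raise ValueError("suppress_interference requires an exterior block (L_out >= 1)")
    D = _data_values(basis, data)
    s = np.linalg.svd(basis.matrix, compute_uv=False)
    cond = np.inf if s[-1] == 0 else float(s[0] / s[-1])
    if cond > cond_threshold:
        raise IllConditionedBasisError(
            f"joint [S_in S_out] basis condition number {cond:.3g} exceeds "
            f"{cond_threshold:.3g}; the interior/exterior split is not unique "
            "for this array. Use reconstruct_lowrank (interior-only, low "
            "order) instead.")
    pinv, _ = _truncated_pinv(basis.matrix, rcond)
    x = pinv @ D
    clean = basis.interior @ x[: basis.n_in]
    if isinstance(data, DataMatrix):
        return DataMatrix(clean, data.sfreq, list(data.names))
    return DataMatrix(clean, float("nan"), list(basis.channel_names))


def reconstruct_lowrank(basis: SignalBasis, data, rcond: float = 1e-8) -> DataMatrix:
    """Orthogonal projection of each sample onto span(S_in):
    ``d_in(t) = S_in S_in^+ d(t)``."""
    D = _data_values(basis, data)
    pinv, _ = _truncated_pinv(basis.interior, rcond)
    proj = basis.interior @ (pinv @ D)
    if isinstance(data, DataMatrix):
        return DataMatrix(proj, data.sfreq, list(data.names))
    return DataMatrix(proj, float("nan"), list(basis.channel_names))


def variance_explained(basis: SignalBasis, G, rcond: float = 1e-8) -> float:
    """Share of a forward model (or data matrix) captured by the basis:
    ``100 * ||S S^+ G||_F / ||G||_F``."""
    G = np.atleast_2d(np.asarray(G, dtype=float))
    gnorm = np.linalg.norm(G)
    if gnorm == 0:
        raise ValueError("zero forward matrix: variance explained undefined")
    pinv, _ = _truncated_pinv(basis.matrix, rcond)
    return float(100.0 * np.linalg.norm(basis.matrix @ (pinv @ G)) / gnorm)


@dataclass
class SubspaceReport:
    """Conditioning diagnostics of a joint [S_in S_out] basis."""

    condition_number: float
    principal_angles: np.ndarray  # radians, ascending
    per_order_singular_values: dict[tuple[str, int], np.ndarray]

    @property
    def min_angle(self) -> float:
        return float(self.principal_angles[0])


def subspace_diagnostics(basis: SignalBasis, rcond: float = 1e-8) -> SubspaceReport:
    """Condition number of [S_in S_out], principal angles between the two
    column spans, and singular values of each per-degree column block."""
    S_in, S_out = basis.interior, basis.exterior
    if S_in.size == 0 or S_out.size == 0:
        raise ValueError("both interior and exterior blocks are required")
    s = np.linalg.svd(basis.matrix, compute_uv=False)
    cond = np.inf if s[-1] == 0 else float(s[0] / s[-1])
    Q_in = sla.orth(S_in, rcond=rcond)
    Q_out = sla.orth(S_out, rcond=rcond)
    angles = np.sort(sla.subspace_angles(Q_in, Q_out))
    per_order: dict[tuple[str, int], np.ndarray] = {}
    for reg in ("in", "out"):
        for l in sorted({l for l, _, r in basis.labels if r == reg}):
            idx = [k for k, (ll, _, r) in enumerate(basis.labels)
                   if r == reg and ll == l]
            per_order[(reg, l)] = np.linalg.svd(basis.matrix[:, idx],
                                                compute_uv=False)
    return SubspaceReport(cond, angles, per_order)
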