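"""Synthetic arrays, sources, and recordings, plus all text-file I/O.

Everything here is a pure function of its recipe and seed, so any experiment
in the package can be reproduced without external data.  Arrays are
quasi-uniform Fibonacci-spiral caps; magnetometer recipes default to the
symmetry-breaking features a separable [S_in S_out] basis requires (a
fraction of tilted sensors and radial position scatter), while electrode
recipes default to a clean single-radius cap with a reference electrode at
the cap vertex.

Recordings superpose interior brain-like sources (current dipoles in a
spherical conductor, or free-space sources) and exterior interference
sources placed at room scale (meters away, as environmental interference in
practice is), each with its own sinusoid or band-limited-noise time course,
plus optional white sensor noise.

File formats are comma-delimited UTF-8 text with a mandatory header row and
a JSON sidecar (``<file>.json``) carrying units, frame, and provenance;
numeric values round-trip exactly through their shortest decimal
representation.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field as dfield
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import signal as sps

from .forward import ConductorModel, CurrentDipole, sarvas_field, shell_potential
from .multipoles import (CurrentElement, MagneticDipole, PointCharge,
                         coulomb_potential, magnetic_dipole_field,
                         magnetostatic_moments, synthesize_field)
from .signal_space import DataMatrix, SensorArray, SignalBasis, fit_sphere

__all__ = [
    "ArrayRecipe",
    "Waveform",
    "SceneRecipe",
    "generate_array",
    "waveform_samples",
    "simulate_recording",
    "write_array",
    "read_array",
    "write_data",
    "read_data",
    "write_sources",
    "read_sources",
    "write_basis",
    "scene_from_dict",
]

_GOLDEN = np.pi * (1.0 + np.sqrt(5.0))


@dataclass(frozen=True)
class ArrayRecipe:
    """Recipe for a quasi-uniform spherical-cap sensor array.

    ``cap_angle_deg`` is the maximum polar angle of the cap (120 degrees
    covers well past the upper hemisphere, like an EEG cap).  For
    magnetometers, ``tilt_fraction`` rotates that share of sensors from
    radial to tangential orientation and ``radial_jitter`` scatters sensor
    radii; both default to the symmetry-breaking values a well-conditioned
    SSS basis needs (0.1 and 5 mm).  Electrodes default to a single exact
    radius with the reference at the cap vertex.
    """

    kind: str
    count: int = 60
    radius: float | None = None
    cap_angle_deg: float = 120.0
    tilt_fraction: float | None = None
    radial_jitter: float | None = None
    center: tuple[float, float, float] = (0.0, 0.0, 0.0)
    seed: int = 0

    def __post_init__(self):
        if self.kind not in ("electrode", "magnetometer", "efield"):
            raise ValueError(f"unknown array kind {self.kind!r}")
        if self.count < 1:
            raise ValueError("count must be >= 1")
        if self.tilt_fraction is not None and not 0 <= self.tilt_fraction <= 1:
            raise ValueError("tilt_fraction must lie in [0, 1]")

    @property
    def effective_radius(self) -> float:
        if self.radius is not None:
            return self.radius
        return 0.091 if self.kind == "electrode" else 0.12

    @property
    def effective_tilt(self) -> float:
        if self.tilt_fraction is not None:
            return self.tilt_fraction
        return 0.0 if self.kind == "electrode" else 0.1

    @property
    def effective_jitter(self) -> float:
        if self.radial_jitter is not None:
            return self.radial_jitter
        return 0.0 if self.kind == "electrode" else 0.005


def generate_array(recipe: ArrayRecipe) -> SensorArray:
    """Deterministic Fibonacci-spiral cap array from a recipe."""
    rng = np.random.default_rng(recipe.seed)
    n = recipe.count
    theta_max = np.deg2rad(recipe.cap_angle_deg)
    i = np.arange(n) + 0.5
    cos_t = 1.0 - (1.0 - np.cos(theta_max)) * i / n
    theta = np.arccos(np.clip(cos_t, -1.0, 1.0))
    phi = _GOLDEN * i
    unit = np.column_stack([np.sin(theta) * np.cos(phi),
                            np.sin(theta) * np.sin(phi),
                            np.cos(theta)])
    radii = recipe.effective_radius + rng.normal(0.0, recipe.effective_jitter, n) \
        if recipe.effective_jitter > 0 else np.full(n, recipe.effective_radius)
    positions = unit * radii[:, None] + np.asarray(recipe.center)
    if recipe.kind == "electrode":
        reference = np.array([0.0, 0.0, recipe.effective_radius]) + np.asarray(recipe.center)
        return SensorArray("electrode", positions, reference=reference,
                           names=[f"EEG{k:03d}" for k in range(n)])
    orientations = unit.copy()
    n_tilt = int(round(recipe.effective_tilt * n))
    if n_tilt:
        idx = rng.choice(n, n_tilt, replace=False)
        e_theta = np.column_stack([np.cos(theta) * np.cos(phi),
                                   np.cos(theta) * np.sin(phi),
                                   -np.sin(theta)])
        orientations[idx] = e_theta[idx]
    prefix = "MAG" if recipe.kind == "magnetometer" else "EF"
    return SensorArray(recipe.kind, positions, orientations=orientations,
                       names=[f"{prefix}{k:03d}" for k in range(n)])


@dataclass(frozen=True)
class Waveform:
    """Source time course: a sinusoid (``freq`` Hz, ``phase`` rad) or
    band-limited Gaussian noise (``band`` Hz, RMS = ``amplitude``)."""

    kind: str = "sine"
    amplitude: float = 1.0
    freq: float = 10.0
    phase: float = 0.0
    band: tuple[float, float] = (1.0, 40.0)

    def __post_init__(self):
        if self.kind not in ("sine", "noise"):
            raise ValueError(f"unknown waveform kind {self.kind!r}")


def waveform_samples(wf: Waveform, n_samples: int, sfreq: float,
                     rng: np.random.Generator) -> np.ndarray:
    if wf.kind == "sine":
        t = np.arange(n_samples) / sfreq
        return wf.amplitude * np.sin(2 * np.pi * wf.freq * t + wf.phase)
    lo, hi = wf.band
    white = rng.standard_normal(n_samples)
    nyq = sfreq / 2.0
    sos = sps.butter(4, [lo / nyq, hi / nyq], btype="band", output="sos")
    x = sps.sosfiltfilt(sos, white)
    rms = np.sqrt(np.mean(x**2))
    return wf.amplitude * x / rms if rms > 0 else x


@dataclass
class SceneRecipe:
    """Interior sources, exterior interference, and noise for a recording.

    ``interior`` and ``exterior`` are lists of ``(source, Waveform)`` pairs;
    interior sources must lie inside the sensor shell and exterior ones
    beyond it (checked against the array at simulation time).
    """

    interior: list = dfield(default_factory=list)
    exterior: list = dfield(default_factory=list)
    noise_sd: float = 0.0
    n_samples: int = 1000
    sfreq: float = 1000.0
    seed: int = 0


def _referenced(values: np.ndarray, ref_value: float | np.ndarray | None,
                average: bool) -> np.ndarray:
    if average:
        return values - values.mean(axis=0, keepdims=True)
    return values - ref_value


def _interior_pattern(source, array: SensorArray, model: ConductorModel | None,
                      center: np.ndarray) -> np.ndarray:
    if array.kind == "electrode":
        explicit = not isinstance(array.reference, str)
        if isinstance(source, CurrentDipole):
            if model is None:
                raise ValueError("current-dipole EEG simulation requires a "
                                 "ConductorModel")
            v = shell_potential(source, model, array.positions)
            ref = shell_potential(source, model, array.reference[None])[0] \
                if explicit else None
            return _referenced(v, ref, not explicit)
        if isinstance(source, PointCharge):
            v = coulomb_potential([source], array.positions)
            ref = coulomb_potential([source], array.reference[None])[0] \
                if explicit else None
            return _referenced(v, ref, not explicit)
        raise TypeError(f"unsupported interior source for electrodes: {type(source).__name__}")
    # field arrays
    if isinstance(source, CurrentDipole):
        if model is not None:
            B = sarvas_field(source, model.center, array.positions)
        else:
            mm = magnetostatic_moments(
                [CurrentElement(source.position, source.moment)], center, 20)
            B = synthesize_field(mm, array.positions)
        return np.einsum("ij,ij->i", B, array.orientations)
    raise TypeError(f"unsupported interior source for field sensors: {type(source).__name__}")


def _exterior_pattern(source, array: SensorArray) -> np.ndarray:
    if array.kind == "electrode":
        if not isinstance(source, PointCharge):
            raise TypeError("exterior electrode interference must be a PointCharge")
        explicit = not isinstance(array.reference, str)
        v = coulomb_potential([source], array.positions)
        ref = coulomb_potential([source], array.reference[None])[0] \
            if explicit else None
        return _referenced(v, ref, not explicit)
    if not isinstance(source, MagneticDipole):
        raise TypeError("exterior field-sensor interference must be a MagneticDipole")
    B = magnetic_dipole_field(source, array.positions)
    return np.einsum("ij,ij->i", B, array.orientations)


def simulate_recording(scene: SceneRecipe, array: SensorArray,
                       model: ConductorModel | None = None) -> DataMatrix:
    """Channels x samples recording of the scene on the array.

    Interior sources propagate through the conductor model when one is given
    (Sarvas field / layered-sphere potentials) or through free-space
    synthesis otherwise; exterior sources use free-space closed forms.
    Geometry is validated against the fitted sensor shell; violations raise
    with the offending source index.
    """
    center = model.center if model is not None else fit_sphere(array.positions)[0]
    sensor_r = np.linalg.norm(array.positions - center, axis=1)
    rng = np.random.default_rng(scene.seed)
    data = np.zeros((array.n_channels, scene.n_samples))
    for k, (source, wf) in enumerate(scene.interior):
        r_src = np.linalg.norm(np.asarray(source.position) - center)
        if r_src >= sensor_r.min():
            raise ValueError(f"interior source {k} at radius {r_src:.4f} m is "
                             f"not inside the sensor shell (min sensor radius "
                             f"{sensor_r.min():.4f} m)")
        pattern = _interior_pattern(source, array, model, center)
        data += pattern[:, None] * waveform_samples(wf, scene.n_samples,
                                                    scene.sfreq, rng)[None, :]
    for k, (source, wf) in enumerate(scene.exterior):
        r_src = np.linalg.norm(np.asarray(source.position) - center)
        if r_src <= sensor_r.max():
            raise ValueError(f"exterior source {k} at radius {r_src:.4f} m is "
                             f"not outside the sensor shell (max sensor radius "
                             f"{sensor_r.max():.4f} m)")
        pattern = _exterior_pattern(source, array)
        data += pattern[:, None] * waveform_samples(wf, scene.n_samples,
                                                    scene.sfreq, rng)[None, :]
    if scene.noise_sd > 0:
        data += rng.normal(0.0, scene.noise_sd, data.shape)
    return DataMatrix(data, scene.sfreq, list(array.names))


# ---------------------------------------------------------------------------
# File I/O: comma-delimited text + JSON sidecar
# ---------------------------------------------------------------------------

def _sidecar_path(path) -> Path:
    return Path(str(path) + ".json")


def _write_sidecar(path, payload: dict) -> None:
    _sidecar_path(path).write_text(json.dumps(payload, indent=1) + "\n")


def _read_sidecar(path) -> dict:
    p = _sidecar_path(path)
    return json.loads(p.read_text()) if p.exists() else {}


def write_array(path, array: SensorArray) -> None:
    """CSV columns: name,type,x,y,z,ox,oy,oz,is_reference (SI meters)."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["name", "type", "x", "y", "z", "ox", "oy", "oz", "is_reference"])
        for j in range(array.n_channels):
            o = array.orientations[j] if array.orientations is not None else ("", "", "")
            w.writerow([array.names[j], array.kind,
                        *(repr(float(v)) for v in array.positions[j]),
                        *(repr(float(v)) if v != "" else "" for v in o), 0])
        if array.kind == "electrode" and not isinstance(array.reference, str):
            w.writerow(["REF", "electrode",
                        *(repr(float(v)) for v in array.reference), "", "", "", 1])
    _write_sidecar(path, {"kind": array.kind, "units": "m", "frame": "head",
                          "reference": "average"
                          if isinstance(array.reference, str) else "explicit"})


def read_array(path) -> SensorArray:
    path = Path(path)
    meta = _read_sidecar(path)
    names, positions, orientations = [], [], []
    kind = meta.get("kind")
    reference: np.ndarray | str | None = "average" if meta.get("reference") == "average" else None
    with path.open(newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None or header[0] != "name":
            raise ValueError(f"{path}: line 1: missing or malformed header row")
        for lineno, row in enumerate(reader, start=2):
            if not row or all(not c.strip() for c in row):
                continue
            if len(row) != 9:
                raise ValueError(f"{path}: line {lineno}: expected 9 columns, got {len(row)}")
            name, typ = row[0], row[1]
            if kind is None:
                kind = typ
            try:
                pos = [float(v) for v in row[2:5]]
            except ValueError as err:
                raise ValueError(f"{path}: line {lineno}: bad position: {err}") from None
            if row[8].strip() == "1":
                reference = np.asarray(pos)
                continue
            if typ in ("magnetometer", "efield"):
                if any(not v.strip() for v in row[5:8]):
                    raise ValueError(f"{path}: line {lineno}: field sensor "
                                     f"{name!r} is missing orientation columns")
                orientations.append([float(v) for v in row[5:8]])
            names.append(name)
            positions.append(pos)
    if kind is None:
        raise ValueError(f"{path}: no channel rows found")
    return SensorArray(kind, np.asarray(positions),
                       orientations=np.asarray(orientations) if orientations else None,
                       reference=reference if kind == "electrode" else None,
                       names=names)


def write_data(path, data: DataMatrix) -> None:
    path = Path(path)
    with path.open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["name"] + [f"s{j}" for j in range(data.n_samples)])
        for name, row in zip(data.names, data.values):
            w.writerow([name] + [repr(float(v)) for v in row])
    _write_sidecar(path, {"sfreq": data.sfreq, "names": data.names})


def read_data(path) -> DataMatrix:
    path = Path(path)
    meta = _read_sidecar(path)
    names, rows = [], []
    with path.open(newline="") as fh:
        reader = csv.reader(fh)
        next(reader)
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            names.append(row[0])
            try:
                rows.append([float(v) for v in row[1:]])
            except ValueError as err:
                raise ValueError(f"{path}: line {lineno}: bad sample: {err}") from None
    return DataMatrix(np.asarray(rows), float(meta.get("sfreq", float("nan"))), names)


_SOURCE_TYPES = {"charge": PointCharge, "current_element": CurrentElement,
                 "current_dipole": CurrentDipole, "magnetic_dipole": MagneticDipole}


def write_sources(path, sources: Sequence, kind: str = "mixed") -> None:
    """Rows: type,x,y,z,q|qx,qy,qz -- charge in C, moments in A*m / A*m^2."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["type", "x", "y", "z", "q_or_qx", "qy", "qz"])
        for s in sources:
            typ = {PointCharge: "charge", CurrentElement: "current_element",
                   CurrentDipole: "current_dipole",
                   MagneticDipole: "magnetic_dipole"}[type(s)]
            if typ == "charge":
                vals = [repr(float(np.asarray(s.charge))), "", ""]
            else:
                vals = [repr(float(v)) for v in s.moment]
            w.writerow([typ, *(repr(float(v)) for v in s.position), *vals])
    _write_sidecar(path, {"units": "SI", "kind": kind})


def read_sources(path) -> list:
    path = Path(path)
    out = []
    with path.open(newline="") as fh:
        reader = csv.reader(fh)
        next(reader)
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            typ = row[0]
            if typ not in _SOURCE_TYPES:
                raise ValueError(f"{path}: line {lineno}: unknown source type {typ!r}")
            try:
                pos = [float(v) for v in row[1:4]]
                if typ == "charge":
                    out.append(PointCharge(pos, float(row[4])))
                else:
                    out.append(_SOURCE_TYPES[typ](pos, [float(v) for v in row[4:7]]))
            except ValueError as err:
                raise ValueError(f"{path}: line {lineno}: {err}") from None
    return out


def write_basis(path, basis: SignalBasis) -> None:
    path = Path(path)
    with path.open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["channel"] + [f"{reg}_l{l}_m{m}" for l, m, reg in basis.labels])
        for name, row in zip(basis.channel_names, basis.matrix):
            w.writerow([name] + [repr(float(v)) for v in row])
    _write_sidecar(path, {
        "origin": [float(v) for v in basis.origin],
        "L_in": basis.L_in, "L_out": basis.L_out, "kind": basis.kind,
        "labels": [[l, m, reg] for l, m, reg in basis.labels],
        "scales": [repr(float(v)) for v in basis.scales]})


def scene_from_dict(cfg: dict) -> SceneRecipe:
    """Build a SceneRecipe from a plain JSON/YAML-style dict (CLI config)."""
    def mk_source(d):
        typ = d["type"]
        if typ == "charge":
            return PointCharge(d["position"], d["charge"])
        if typ not in _SOURCE_TYPES:
            raise ValueError(f"unknown source type {typ!r}")
        return _SOURCE_TYPES[typ](d["position"], d["moment"])

    def mk_wave(d):
        d = dict(d or {})
        if "band" in d:
            d["band"] = tuple(d["band"])
        return Waveform(**d)

    return SceneRecipe(
        interior=[(mk_source(e["source"]), mk_wave(e.get("waveform")))
                  for e in cfg.get("interior", [])],
        exterior=[(mk_source(e["source"]), mk_wave(e.get("waveform")))
                  for e in cfg.get("exterior", [])],
        noise_sd=cfg.get("noise_sd", 0.0),
        n_samples=cfg.get("n_samples", 1000),
        sfreq=cfg.get("sfreq", 1000.0),
        seed=cfg.get("seed", 0))
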