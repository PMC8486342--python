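"""Multipole moments and synthesis against electrostatic / magnetostatic
closed forms: Coulomb sums, Biot-Savart / point-dipole limits, and
finite-difference Maxwell checks on the synthesized exterior fields."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import vshfield as vf
from vshfield import multipoles as mp


def square_loop(side=2e-3, z=0.05):
    s = side / 2
    return np.array([[s, s, z], [-s, s, z], [-s, -s, z], [s, -s, z], [s, s, z]])


def circle_loop(radius=1e-3, n=64):
    ph = np.linspace(0, 2 * np.pi, n + 1)
    return np.column_stack([radius * np.cos(ph), radius * np.sin(ph),
                            np.zeros(n + 1)])


# ---------------------------------------------------------------------------
# Electrostatic moments
# ---------------------------------------------------------------------------

def test_single_charge_at_origin_is_pure_monopole():
    mm = mp.electrostatic_moments([mp.PointCharge([0, 0, 0], 1.0)], [0, 0, 0], 4)
    assert mm.moment(0, 0) == pytest.approx(1 / math.sqrt(4 * math.pi))
    higher = mm.a.copy()
    higher[0, 0] = 0
    assert np.all(higher == 0)


def test_axial_charge_dipole_moments():
    q = mp.PointCharge([0, 0, 0.01], 1.0)
    mm = mp.electrostatic_moments([q], [0, 0, 0], 2)
    assert mm.moment(1, 0) == pytest.approx(0.01 * math.sqrt(3 / (4 * math.pi)) / 3)
    pair = [q, mp.PointCharge([0, 0, -0.01], -1.0)]
    mm = mp.electrostatic_moments(pair, [0, 0, 0], 2)
    assert mm.moment(0, 0) == 0
    assert mm.moment(1, 0) == pytest.approx(2 * 0.01 * math.sqrt(3 / (4 * math.pi)) / 3)


def test_empty_source_set_gives_zero_moments():
    mm = mp.electrostatic_moments([], [0, 0, 0], 3)
    assert np.all(mm.a == 0)
    assert np.all(mp.synthesize_field(mm, [[0.1, 0, 0]]) == 0)


def test_negative_truncation_order_rejected():
    with pytest.raises(ValueError):
        mp.electrostatic_moments([], [0, 0, 0], -1)


def test_coulomb_field_and_potential_of_point_charge():
    mm = mp.electrostatic_moments([mp.PointCharge([0, 0, 0], 1.0)], [0, 0, 0], 0)
    E = mp.synthesize_field(mm, [[0.1, 0, 0]])[0]
    assert E[0] == pytest.approx(1 / (4 * np.pi * mp.EPSILON_0 * 0.01), rel=1e-12)
    V = mp.synthesize_potential(mm, [[0, 0, 0.2]])[0]
    assert V == pytest.approx(1 / (4 * np.pi * mp.EPSILON_0 * 0.2), rel=1e-12)


def test_physical_dipole_matches_coulomb_sum_far_away():
    d = 0.01
    charges = [mp.PointCharge([0, 0, d], 1.0), mp.PointCharge([0, 0, -d], -1.0)]
    mm = mp.electrostatic_moments(charges, [0, 0, 0], 8)
    pts = np.array([[0.6, 0.3, 0.74]])
    pts *= (50 * 2 * d) / np.linalg.norm(pts)  # r = 50 x separation
    assert mp.synthesize_potential(mm, pts)[0] == pytest.approx(
        mp.coulomb_potential(charges, pts)[0], rel=1e-4)


def test_potential_gradient_consistency(rng):
    charges = [mp.PointCharge(rng.normal(scale=0.01, size=3), rng.normal())
               for _ in range(4)]
    mm = mp.electrostatic_moments(charges, [0, 0, 0], 10)
    for _ in range(10):
        p = rng.normal(size=3)
        p *= rng.uniform(0.1, 0.3) / np.linalg.norm(p)
        E = mp.synthesize_field(mm, p[None])[0]
        g = np.zeros(3)
        for i in range(3):
            step = np.zeros(3)
            step[i] = 1e-7
            g[i] = -(mp.synthesize_potential(mm, (p + step)[None])
                     - mp.synthesize_potential(mm, (p - step)[None]))[0] / 2e-7
        assert np.linalg.norm(g - E) / np.linalg.norm(E) < 1e-6


def test_truncation_error_decays_geometrically(rng):
    """RMS truncation error over a sphere of field points shrinks by
    ~ r'/r = 0.5 per added order (the multipole amplitude hierarchy); at a
    single point the successive-term oscillation masks the decay, so the
    error is averaged over directions."""
    charge = [mp.PointCharge([0, 0, 0.05], 1.0)]
    pts = rng.normal(size=(60, 3))
    pts = pts / np.linalg.norm(pts, axis=1, keepdims=True) * 0.1
    exact = mp.coulomb_potential(charge, pts)
    errs = []
    for L in range(2, 10):
        mm = mp.electrostatic_moments(charge, [0, 0, 0], L)
        errs.append(np.linalg.norm(mp.synthesize_potential(mm, pts) - exact))
    ratios = np.array(errs[1:]) / np.array(errs[:-1])
    assert np.all(ratios < 0.75) and np.all(ratios > 1 / 3)


def test_moments_support_charge_time_series(rng):
    q_t = rng.normal(size=5)
    mm = mp.electrostatic_moments([mp.PointCharge([0, 0, 0.02], q_t)], [0, 0, 0], 3)
    assert mm.a.shape == (4, 7, 5)
    V = mp.synthesize_potential(mm, [[0, 0, 0.1]])
    base = mp.electrostatic_moments([mp.PointCharge([0, 0, 0.02], 1.0)], [0, 0, 0], 3)
    V1 = mp.synthesize_potential(base, [[0, 0, 0.1]])[0]
    assert V[0] == pytest.approx(list(q_t * V1))


# ---------------------------------------------------------------------------
# Magnetostatic moments
# ---------------------------------------------------------------------------

@settings(deadline=None, derandomize=True, max_examples=50)
@given(seed=st.integers(0, 10_000))
def test_magnetic_monopole_vanishes_identically(seed):
    rng = np.random.default_rng(seed)
    els = [mp.CurrentElement(rng.normal(scale=0.03, size=3),
                             rng.normal(scale=1e-8, size=3))
           for _ in range(rng.integers(1, 6))]
    mm = mp.magnetostatic_moments(els, [0, 0, 0], 3)
    assert mm.moment(0, 0) == 0.0  # exact zero, not approximately


def test_radial_current_elements_are_silent(rng):
    """A current element parallel to its position vector contributes nothing:
    exactly zero for axis-aligned elements (representable exactly in floats),
    and zero to rounding (<= 1e-13 of an equal-magnitude tangential element)
    for general directions, where the stored moment vector itself is only
    parallel to within machine precision."""
    el = mp.CurrentElement([0, 0, 0.05], [0, 0, 1e-8])
    mm = mp.magnetostatic_moments([el], [0, 0, 0], 8)
    assert np.all(mm.a == 0)
    assert np.all(mp.synthesize_field(mm, [[0.2, 0.1, 0.2]]) == 0)
    for _ in range(20):
        pos = rng.normal(size=3)
        pos *= rng.uniform(0.01, 0.08) / np.linalg.norm(pos)
        q = abs(rng.normal()) * 1e-8
        radial = mp.magnetostatic_moments(
            [mp.CurrentElement(pos, q * pos / np.linalg.norm(pos))], [0, 0, 0], 8)
        tang_dir = np.cross(pos, [0.0, 0.0, 1.0])
        tang_dir /= np.linalg.norm(tang_dir)
        tangential = mp.magnetostatic_moments(
            [mp.CurrentElement(pos, q * tang_dir)], [0, 0, 0], 8)
        assert np.abs(radial.a).max() <= 1e-13 * np.abs(tangential.a).max()


def test_element_at_origin_has_no_moments():
    el = mp.CurrentElement([0, 0, 0], [1e-8, 2e-8, 0])
    mm = mp.magnetostatic_moments([el], [0, 0, 0], 6)
    assert np.all(mm.a == 0)


def test_small_loop_matches_point_dipole_field():
    radius, current, n = 1e-3, 1e-6, 64
    els = mp.loop_elements(circle_loop(radius, n), current)
    mm = mp.magnetostatic_moments(els, [0, 0, 0], 6)
    # the discretized loop is an n-gon; its dipole moment is I x polygon area
    area = 0.5 * n * radius**2 * np.sin(2 * np.pi / n)
    dipole = mp.MagneticDipole([0, 0, 0], [0, 0, current * area])
    pts = np.array([[0.07, 0.03, 0.06], [0.0, -0.05, 0.08], [0.1, 0.0, 0.01]])
    pts = pts / np.linalg.norm(pts, axis=1, keepdims=True) * 0.1
    B = mp.synthesize_field(mm, pts)
    B_ref = mp.magnetic_dipole_field(dipole, pts)
    assert np.linalg.norm(B - B_ref) / np.linalg.norm(B_ref) < 1e-3


def test_divergence_form_equals_tangential_kernel_for_closed_loop():
    loop = square_loop()
    m_div = mp.magnetostatic_moments_divergence_form(loop, 1e-6, [0, 0, 0], 8)
    m_tan = mp.magnetostatic_moments(mp.loop_elements(loop, 1e-6, 8), [0, 0, 0], 8)
    assert np.abs(m_div.a - m_tan.a).max() / np.abs(m_tan.a).max() < 1e-10


def test_zero_current_loop_has_zero_moments():
    mm = mp.magnetostatic_moments_divergence_form(square_loop(), 0.0, [0, 0, 0], 4)
    assert np.all(mm.a == 0)


def test_open_polyline_rejected():
    open_path = square_loop()[:-1]
    with pytest.raises(ValueError, match="closed"):
        mp.magnetostatic_moments_divergence_form(open_path, 1e-6, [0, 0, 0], 4)
    with pytest.raises(ValueError, match="closed"):
        mp.loop_elements(open_path, 1e-6)


def test_loop_field_matches_biot_savart_quadrature(rng):
    """Dense Biot-Savart sum over the same polygon as the independent oracle
    for a loop that is *not* small compared to the field points."""
    polygon = circle_loop(radius=0.02, n=256)
    current = 1e-6
    mm = mp.magnetostatic_moments(mp.loop_elements(polygon, current),
                                  [0, 0, 0], 12)
    pts = rng.normal(size=(20, 3))
    pts = pts / np.linalg.norm(pts, axis=1, keepdims=True) * 0.1
    # Biot-Savart over the identical polygon, each edge subdivided 50x:
    # B = mu0 I / 4pi * sum dl x (r - r') / |r - r'|^3
    frac = (np.arange(50) + 0.5) / 50
    mids = np.concatenate([polygon[:-1, None] + frac[None, :, None]
                           * np.diff(polygon, axis=0)[:, None]]).reshape(-1, 3)
    dls = np.repeat(np.diff(polygon, axis=0) / 50, 50, axis=0)
    B_ref = np.zeros_like(pts)
    for k, p in enumerate(pts):
        rel = p - mids
        d3 = np.linalg.norm(rel, axis=1) ** 3
        B_ref[k] = mp.MU_0 * current / (4 * np.pi) * np.sum(
            np.cross(dls, rel) / d3[:, None], axis=0)
    B = mp.synthesize_field(mm, pts)
    assert np.linalg.norm(B - B_ref) / np.linalg.norm(B_ref) < 1e-3


# ---------------------------------------------------------------------------
# Synthesized-field Maxwell properties
# ---------------------------------------------------------------------------

def _fd_jacobian(field_fn, p, h=1e-6):
    J = np.zeros((3, 3))
    for i in range(3):
        d = np.zeros(3)
        d[i] = h
        J[:, i] = (field_fn((p + d)[None])[0] - field_fn((p - d)[None])[0]) / (2 * h)
    return J


@pytest.mark.parametrize("case", ["electric", "magnetic", "exterior"])
def test_exterior_fields_are_curl_and_divergence_free(case, rng):
    if case == "electric":
        mm = mp.electrostatic_moments(
            [mp.PointCharge(rng.normal(scale=0.01, size=3), 1e-9)
             for _ in range(3)], [0, 0, 0], 8)
    elif case == "magnetic":
        mm = mp.magnetostatic_moments(
            [mp.CurrentElement(rng.normal(scale=0.02, size=3),
                               rng.normal(scale=1e-8, size=3))
             for _ in range(3)], [0, 0, 0], 8)
    else:
        mm = mp.magnetic_dipole_exterior_moments(
            [mp.MagneticDipole([0.5, 0.5, 1.0], [1e-3, 0, -1e-3])], [0, 0, 0], 6)

    def field(pts):
        return mp.synthesize_field(mm, pts)

    for _ in range(5):
        p = rng.normal(size=3)
        p *= rng.uniform(0.1, 0.2) / np.linalg.norm(p)
        J = _fd_jacobian(field, p)
        scale = np.linalg.norm(field(p[None])[0])
        curl = np.array([J[2, 1] - J[1, 2], J[0, 2] - J[2, 0], J[1, 0] - J[0, 1]])
        div = np.trace(J)
        assert np.linalg.norm(curl) / scale * 0.01 < 1e-6  # per-meter scale
        assert abs(div) / scale * 0.01 < 1e-6


def test_fields_of_real_sources_are_real(rng):
    els = [mp.CurrentElement(rng.normal(scale=0.02, size=3),
                             rng.normal(scale=1e-8, size=3)) for _ in range(4)]
    mm = mp.magnetostatic_moments(els, [0, 0, 0], 8)
    # conjugate symmetry of the moments of a real source
    for l in range(1, 9):
        for m in range(1, l + 1):
            assert mm.a[l, -m] == pytest.approx((-1) ** m * np.conj(mm.a[l, m]),
                                                abs=1e-20)
    pts = rng.normal(size=(5, 3)) * 0.2
    pts = pts / np.linalg.norm(pts, axis=1, keepdims=True) * 0.15
    complex_field = mp._synthesize_complex(mm, pts)
    assert np.abs(complex_field.imag).max() <= 1e-12 * np.abs(complex_field.real).max()


def test_synthesis_rejects_origin_point():
    mm = mp.electrostatic_moments([mp.PointCharge([0, 0, 0.01], 1.0)], [0, 0, 0], 2)
    with pytest.raises(ValueError, match="origin"):
        mp.synthesize_field(mm, [[0.0, 0.0, 0.0]])


# ---------------------------------------------------------------------------
# Exterior moments
# ---------------------------------------------------------------------------

def test_exterior_charge_expansion_matches_coulomb(rng):
    ch = mp.PointCharge([0.3, -0.2, 0.5], 3e-9)
    mm = mp.electrostatic_exterior_moments([ch], [0, 0, 0], 14)
    pts = rng.normal(size=(10, 3))
    pts = pts / np.linalg.norm(pts, axis=1, keepdims=True) * 0.08
    V = mp.synthesize_potential(mm, pts)
    assert V == pytest.approx(mp.coulomb_potential([ch], pts), rel=1e-6)


def test_exterior_dipole_expansion_matches_closed_form(rng):
    dip = mp.MagneticDipole([0.4, 0.8, 1.2], [5e-3, -2e-3, 1e-3])
    mm = mp.magnetic_dipole_exterior_moments([dip], [0, 0, 0], 10)
    pts = rng.normal(size=(10, 3))
    pts = pts / np.linalg.norm(pts, axis=1, keepdims=True) * 0.1
    B = mp.synthesize_field(mm, pts)
    B_ref = mp.magnetic_dipole_field(dip, pts)
    assert np.linalg.norm(B - B_ref) / np.linalg.norm(B_ref) < 1e-6
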