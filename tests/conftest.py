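"""Shared fixtures: deterministic arrays, random sources, planted moments."""

import numpy as np
import pytest

import vshfield as vf


@pytest.fixture(scope="session")
def meg_array():
    """150-magnetometer cap with the default symmetry breaking."""
    return vf.generate_array(vf.ArrayRecipe("magnetometer", count=150, seed=0))


@pytest.fixture(scope="session")
def eeg_array():
    """60-electrode single-radius cap, reference at the vertex."""
    return vf.generate_array(vf.ArrayRecipe("electrode", count=60, seed=0))


@pytest.fixture(scope="session")
def head_model():
    return vf.default_head_model()


def random_interior_moments(kind: str, L: int, rng: np.random.Generator,
                            scale_radius: float = 0.05,
                            n_samples: int | None = None) -> vf.MultipoleMoments:
    """Random conjugate-symmetric moments with an r^l amplitude hierarchy
    (as produced by sources inside ``scale_radius``)."""
    shape = () if n_samples is None else (n_samples,)
    size = (L + 1, 2 * L + 1) + shape
    a = np.zeros(size, dtype=complex)
    l0 = 1 if kind == "magnetic" else 0
    for l in range(l0, L + 1):
        amp = scale_radius**l
        a[l, 0] = amp * rng.normal(size=shape)
        for m in range(1, l + 1):
            z = amp * (rng.normal(size=shape) + 1j * rng.normal(size=shape))
            a[l, m] = z
            a[l, -m] = (-1) ** m * np.conj(z)
    return vf.MultipoleMoments(kind, np.zeros(3), L, a)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
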