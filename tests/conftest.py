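"""Shared fixtures: small models, deformation generators, stress oracle."""

import numpy as np
import pytest

from ligknee import (
    FiberFamily,
    HGOMaterial,
    build_knee_model,
    default_geometry,
    strain_energy,
    to_uniaxial,
)


@pytest.fixture(scope="session")
def geometry():
    return default_geometry()


@pytest.fixture(scope="session")
def sym_geometry():
    return default_geometry(symmetric=True)


@pytest.fixture(scope="session")
def small_anatomic(geometry):
    """Coarse anatomic model (4 fibers/bundle) for fast unit tests."""
    return build_knee_model(geometry, "anatomic_3d", n_fibers_per_bundle=4)


@pytest.fixture(scope="session")
def small_uniaxial(small_anatomic):
    return to_uniaxial(small_anatomic)


@pytest.fixture
def one_family_material():
    return HGOMaterial(c=1.0, families=(FiberFamily((1.0, 0.0, 0.0), 0.1, 10.0, 1.0),))


@pytest.fixture
def two_family_material():
    th = np.radians(20.0)
    return HGOMaterial(
        c=1.5,
        families=(
            FiberFamily((np.cos(th), np.sin(th), 0.0), 0.08, 4.0, 12.0),
            FiberFamily((np.cos(th), -np.sin(th), 0.0), 0.08, 4.0, 12.0),
        ),
    )


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform-ish proper rotation from a QR decomposition."""
    A = rng.normal(size=(3, 3))
    Q, R = np.linalg.qr(A)
    Q = Q @ np.diag(np.sign(np.diag(R)))
    if np.linalg.det(Q) < 0:
        Q[:, 0] = -Q[:, 0]
    return Q


def random_incompressible_F(rng: np.random.Generator, lo=0.8, hi=1.3) -> np.ndarray:
    """det(F) = 1 with principal stretches in [lo, hi]."""
    while True:
        l1, l2 = rng.uniform(lo, hi, size=2)
        l3 = 1.0 / (l1 * l2)
        if lo <= l3 <= hi:
            break
    return random_rotation(rng) @ np.diag([l1, l2, l3]) @ random_rotation(rng)


def finite_difference_stress(mat: HGOMaterial, F: np.ndarray, h: float = 1e-6) -> np.ndarray:
    """Independent Cauchy-stress oracle: sigma = (dPsi/dF) F^T via central FD.

    Because the energy depends only on the isochoric part of F, the result
    is automatically deviatoric; it equals the analytic stress at p = 0 up
    to the hydrostatic part.
    """
    P = np.zeros((3, 3))
    for i in range(3):
        for k in range(3):
            Fp = F.copy()
            Fm = F.copy()
            Fp[i, k] += h
            Fm[i, k] -= h
            P[i, k] = (strain_energy(mat, Fp / np.linalg.det(Fp) ** (1 / 3))
                       - strain_energy(mat, Fm / np.linalg.det(Fm) ** (1 / 3))) / (2 * h)
    sigma = P @ F.T / np.linalg.det(F)
    return 0.5 * (sigma + sigma.T)


def deviator(sig: np.ndarray) -> np.ndarray:
    return sig - np.trace(sig) / 3.0 * np.eye(3)
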