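"""Incompressible Holzapfel–Gasser–Ogden (HGO) material point.

The strain-energy density splits into an isotropic neo-Hookean ground
matrix and one or two dispersed collagen-fiber families,

    psi = c/2 * (I1bar - 3)
        + sum_i k1/(2 k2) * (exp(k2 * E_i**2) - 1),

with the fiber pseudo-strain

    E_i = kappa_i * I1bar + (1 - 3*kappa_i) * I4bar_i - 1

built from the isochoric invariants I1bar = tr(Cbar) and
I4bar_i = a0_i . Cbar a0_i.  kappa in [0, 1/3] measures in-plane fiber
dispersion (0 = perfectly aligned, 1/3 = isotropic).  Collagen buckles in
compression, so a family contributes only while its pseudo-strain is
positive; the alternative recruitment switch I4bar > 1 is available as a
material flag.

Units: stresses and energy densities in MPa, stretches dimensionless,
angles in degrees at the public interface.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import InvalidDeformationError, InvalidMaterialError

__all__ = [
    "FiberFamily",
    "HGOMaterial",
    "DeformationState",
    "isochoric_invariants",
    "strain_energy",
    "cauchy_stress",
    "uniaxial_stress",
]

_UNIT_TOL = 1e-12
_DET_TOL = 1e-9


@dataclass(frozen=True)
class FiberFamily:
    """One dispersed collagen-fiber family.

    a0 : mean fiber direction in the reference configuration (unit vector)
    kappa : dispersion parameter, in [0, 1/3]
    k1 : fiber stiffness-like coefficient (MPa), >= 0
    k2 : dimensionless exponential coefficient, > 0
    """

    a0: tuple[float, float, float]
    kappa: float
    k1: float
    k2: float

    def __post_init__(self):
        a0 = np.asarray(self.a0, dtype=float)
        if a0.shape != (3,) or not np.all(np.isfinite(a0)):
            raise InvalidMaterialError("a0 must be a finite 3-vector")
        if abs(np.linalg.norm(a0) - 1.0) > 1e-9:
            raise InvalidMaterialError(f"a0 must be a unit vector, |a0|={np.linalg.norm(a0)}")
        # store exactly normalized for downstream tensor algebra
        object.__setattr__(self, "a0", tuple(a0 / np.linalg.norm(a0)))
        if not (0.0 <= self.kappa <= 1.0 / 3.0 + _UNIT_TOL):
            raise InvalidMaterialError(f"kappa must lie in [0, 1/3], got {self.kappa}")
        if self.k1 < 0.0:
            raise InvalidMaterialError(f"k1 must be >= 0, got {self.k1}")
        if self.k2 <= 0.0:
            raise InvalidMaterialError(f"k2 must be > 0, got {self.k2}")

    @property
    def direction(self) -> np.ndarray:
        return np.asarray(self.a0, dtype=float)


@dataclass(frozen=True)
class HGOMaterial:
    """Ground matrix plus 1–2 fiber families.

    c : neo-Hookean ground-matrix coefficient (MPa), > 0
    families : one family for collateral-type ligaments, two for cruciates
    recruitment : "pseudo_strain" (fiber active while E > 0, the default,
        C1-continuous at the switch) or "i4" (active while I4bar > 1)
    """

    c: float
    families: tuple[FiberFamily, ...]
    recruitment: str = "pseudo_strain"

    def __post_init__(self):
        if self.c <= 0.0:
            raise InvalidMaterialError(f"c must be > 0, got {self.c}")
        fams = tuple(self.families)
        if not 1 <= len(fams) <= 2:
            raise InvalidMaterialError(f"need 1 or 2 fiber families, got {len(fams)}")
        object.__setattr__(self, "families", fams)
        if self.recruitment not in ("pseudo_strain", "i4"):
            raise InvalidMaterialError(f"unknown recruitment switch {self.recruitment!r}")

    def with_recruitment(self, mode: str) -> "HGOMaterial":
        return replace(self, recruitment=mode)


@dataclass(frozen=True)
class DeformationState:
    """Cached kinematic quantities at a material point (J = 1 contract)."""

    F: np.ndarray
    Cbar: np.ndarray = field(init=False)
    I1bar: float = field(init=False)

    def __post_init__(self):
        F = np.asarray(self.F, dtype=float)
        _check_F(F)
        J = np.linalg.det(F)
        if abs(J - 1.0) > _DET_TOL:
            raise InvalidDeformationError(f"det(F) = {J}, expected 1 within {_DET_TOL}")
        Fbar = J ** (-1.0 / 3.0) * F
        Cbar = Fbar.T @ Fbar
        object.__setattr__(self, "F", F)
        object.__setattr__(self, "Cbar", Cbar)
        object.__setattr__(self, "I1bar", float(np.trace(Cbar)))

    def I4bar(self, a0: np.ndarray) -> float:
        a0 = np.asarray(a0, dtype=float)
        return float(a0 @ self.Cbar @ a0)


def _check_F(F: np.ndarray) -> None:
    if F.shape != (3, 3) or not np.all(np.isfinite(F)):
        raise InvalidDeformationError("F must be a finite 3x3 tensor")
    if np.linalg.det(F) <= 0.0:
        raise InvalidDeformationError("det(F) must be positive")


def isochoric_invariants(F: np.ndarray, a0: np.ndarray) -> tuple[float, float]:
    """Return (I1bar, I4bar) of the isochoric right Cauchy–Green tensor.

    Cbar = J^(-2/3) F^T F; I1bar = tr(Cbar); I4bar = a0 . Cbar a0 is the
    squared isochoric stretch along the mean fiber direction a0.
    """
    F = np.asarray(F, dtype=float)
    _check_F(F)
    J = np.linalg.det(F)
    Cbar = J ** (-2.0 / 3.0) * (F.T @ F)
    a0 = np.asarray(a0, dtype=float)
    a0 = a0 / np.linalg.norm(a0)
    return float(np.trace(Cbar)), float(a0 @ Cbar @ a0)


def _pseudo_strain(fam: FiberFamily, I1bar: float, I4bar: float) -> float:
    return fam.kappa * I1bar + (1.0 - 3.0 * fam.kappa) * I4bar - 1.0


def _fiber_active(mat: HGOMaterial, fam: FiberFamily, I1bar, I4bar):
    E = fam.kappa * I1bar + (1.0 - 3.0 * fam.kappa) * I4bar - 1.0
    if mat.recruitment == "i4":
        return E, I4bar > 1.0
    return E, E > 0.0


def strain_energy(mat: HGOMaterial, F: np.ndarray) -> float:
    """Strain-energy density (MPa) at deformation gradient F (det F = 1)."""
    state = DeformationState(np.asarray(F, dtype=float))
    psi = 0.5 * mat.c * (state.I1bar - 3.0)
    for fam in mat.families:
        I4 = state.I4bar(fam.direction)
        E, active = _fiber_active(mat, fam, state.I1bar, I4)
        if active:
            psi += fam.k1 / (2.0 * fam.k2) * np.expm1(fam.k2 * E * E)
    return float(psi)


def cauchy_stress(mat: HGOMaterial, F: np.ndarray, p: float = 0.0) -> np.ndarray:
    """Cauchy stress sigma = -p*I + dev(F Sbar F^T) for the incompressible HGO solid.

    Sbar = 2 d(psi)/d(Cbar) = c*I + sum_i 2 k1 E_i exp(k2 E_i^2) H_i with the
    generalized structure tensor H_i = kappa*I + (1-3kappa) a0 (x) a0.  The
    deviatoric projection makes the isochoric contribution traction-neutral
    in the hydrostatic direction; p carries the constraint pressure.
    """
    state = DeformationState(np.asarray(F, dtype=float))
    J = np.linalg.det(state.F)
    Fbar = J ** (-1.0 / 3.0) * state.F
    Sbar = mat.c * np.eye(3)
    for fam in mat.families:
        a0 = fam.direction
        I4 = state.I4bar(a0)
        E, active = _fiber_active(mat, fam, state.I1bar, I4)
        if active:
            H = fam.kappa * np.eye(3) + (1.0 - 3.0 * fam.kappa) * np.outer(a0, a0)
            Sbar = Sbar + 2.0 * fam.k1 * E * np.exp(fam.k2 * E * E) * H
    sigma_iso = Fbar @ Sbar @ Fbar.T
    sigma_iso = sigma_iso - np.trace(sigma_iso) / 3.0 * np.eye(3)
    sigma = -p * np.eye(3) + sigma_iso
    return 0.5 * (sigma + sigma.T)


def uniaxial_stress(mat: HGOMaterial, stretch, fiber_angle: float = 0.0):
    """Closed-form incompressible uniaxial Cauchy stress sigma11 (MPa).

    F = diag(lambda, lambda^-1/2, lambda^-1/2) with the hydrostatic pressure
    eliminated from the traction-free out-of-plane face (sigma33 = 0; for
    fibers along the load axis sigma22 = sigma33 so both lateral faces are
    traction-free).  `fiber_angle` rotates the load axis away from the
    material 1-axis within the 1–2 plane, i.e. each family direction is
    rotated by -fiber_angle about the 3-axis before evaluation.

    Accepts a scalar or array `stretch`; returns matching shape.
    """
    lam = np.asarray(stretch, dtype=float)
    scalar = lam.ndim == 0
    lam = np.atleast_1d(lam)
    if np.any(lam <= 0.0) or not np.all(np.isfinite(lam)):
        raise InvalidDeformationError("stretch must be positive and finite")

    I1 = lam**2 + 2.0 / lam
    B11 = lam**2
    B33 = 1.0 / lam
    sigma = mat.c * (B11 - B33)

    th = np.deg2rad(fiber_angle)
    R = np.array(
        [
            [np.cos(th), np.sin(th), 0.0],
            [-np.sin(th), np.cos(th), 0.0],
            [0.0, 0.0, 1.0],
        ]
    )
    for fam in mat.families:
        a = R @ fam.direction
        I4 = lam**2 * a[0] ** 2 + (a[1] ** 2 + a[2] ** 2) / lam
        # increment form: both invariant deviations vanish identically at
        # lambda = 1, so the switch is exactly closed in the reference state
        I1m3 = (lam**2 - 1.0) + 2.0 * (1.0 / lam - 1.0)
        I4m1 = a[0] ** 2 * (lam**2 - 1.0) + (a[1] ** 2 + a[2] ** 2) * (1.0 / lam - 1.0)
        E = fam.kappa * I1m3 + (1.0 - 3.0 * fam.kappa) * I4m1
        if mat.recruitment == "i4":
            active = I4 > 1.0
        else:
            active = E > 0.0
        # exponent clamp keeps exploratory solver steps finite; unreachable
        # for physical fiber stretches (argument ~ 10 at 30% strain)
        g = np.where(active, 2.0 * fam.k1 * E * np.exp(np.minimum(fam.k2 * E * E, 350.0)), 0.0)
        # (F a)_1^2 - (F a)_3^2 with F diagonal
        fa_sq = lam**2 * a[0] ** 2 - a[2] ** 2 / lam
        sigma = sigma + g * (fam.kappa * (B11 - B33) + (1.0 - 3.0 * fam.kappa) * fa_sq)

    return float(sigma[0]) if scalar else sigma
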