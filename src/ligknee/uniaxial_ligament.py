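"""Tension-only nonlinear truss ligament elements.

The simplified ligament representation: a line element that carries axial
tension only, with the canonical quadratic-toe / linear force law used
throughout the knee rigid-body and FE lineage,

    f(eps) = 0                          eps <= 0        (slack)
    f(eps) = k * eps^2 / (4 eps_l)      0 < eps <= 2 eps_l   (toe)
    f(eps) = k * (eps - eps_l)          eps > 2 eps_l   (linear)

where eps is engineering strain relative to the slack length, k (N) is the
linear-region stiffness parameter and eps_l the toe-region half-width.
The law is C1-continuous and non-decreasing.  The source study cites its
truss material without printing it; this standard law stands in and is
documented as a non-paper default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateGeometryError

__all__ = ["TrussElement", "truss_force", "truss_tension_from_geometry"]


@dataclass(frozen=True)
class TrussElement:
    """One tension-only truss line.

    origin/insertion are the reference endpoint coordinates (mm, femur- and
    tibia-fixed respectively); reference_length (mm) is the slack length;
    stiffness_k (N) the linear-region stiffness; toe_limit the strain eps_l;
    area (mm^2) a nominal cross-section carried for bookkeeping.
    """

    origin: tuple[float, float, float]
    insertion: tuple[float, float, float]
    reference_length: float
    stiffness_k: float
    toe_limit: float
    area: float = 0.0
    name: str = ""

    def __post_init__(self):
        if self.reference_length <= 0.0:
            raise ValueError(f"reference_length must be > 0, got {self.reference_length}")
        if self.stiffness_k < 0.0:
            raise ValueError(f"stiffness_k must be >= 0, got {self.stiffness_k}")
        if self.toe_limit <= 0.0:
            raise ValueError(f"toe_limit must be > 0, got {self.toe_limit}")
        object.__setattr__(self, "origin", tuple(float(v) for v in self.origin))
        object.__setattr__(self, "insertion", tuple(float(v) for v in self.insertion))


def truss_force(el: TrussElement, strain) -> float | np.ndarray:
    """Axial tension (N) at the given engineering strain(s).

    Zero in slack (strain <= 0), quadratic toe up to 2*eps_l, linear beyond;
    continuous and C1 at the toe/linear junction.
    """
    eps = np.asarray(strain, dtype=float)
    if np.any(eps <= -1.0):
        raise ValueError("strain must be > -1")
    k, el_ = el.stiffness_k, el.toe_limit
    toe = k * eps**2 / (4.0 * el_)
    lin = k * (eps - el_)
    f = np.where(eps <= 0.0, 0.0, np.where(eps <= 2.0 * el_, toe, lin))
    return float(f) if f.ndim == 0 else f


def truss_strain_energy(el: TrussElement, strain) -> float | np.ndarray:
    """Stored energy (N*mm) per element: integral of f over length change.

    Closed form of the piecewise law; used by the equilibrium solver so
    that forces are exactly the energy gradient.
    """
    eps = np.asarray(strain, dtype=float)
    k, el_ = el.stiffness_k, el.toe_limit
    L0 = el.reference_length
    e_toe = k * eps**3 / (12.0 * el_)
    e_toe_full = k * (2.0 * el_) ** 3 / (12.0 * el_)  # at eps = 2 eps_l
    e_lin = e_toe_full + 0.5 * k * ((eps - el_) ** 2 - el_**2)
    e = np.where(eps <= 0.0, 0.0, np.where(eps <= 2.0 * el_, e_toe, e_lin)) * L0
    return float(e) if e.ndim == 0 else e


def truss_tension_from_geometry(
    el: TrussElement, origin_now, insertion_now
) -> tuple[float, np.ndarray]:
    """Tension (N) and pull direction (insertion -> origin, unit) at the current endpoints."""
    o = np.asarray(origin_now, dtype=float)
    i = np.asarray(insertion_now, dtype=float)
    d = o - i
    L = np.linalg.norm(d)
    if L < 1e-9:
        raise DegenerateGeometryError("coincident truss endpoints")
    strain = (L - el.reference_length) / el.reference_length
    return float(truss_force(el, strain)), d / L
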