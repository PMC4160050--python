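"""Reduced-order quasi-static tibiofemoral joint model.

This is an explicit desk-scale surrogate for a full hexahedral FE knee
model: rigid femur and tibia, penalty sphere-on-plane condyle contact,
ligaments as line elements (anatomic fiber bundles with HGO material, or
tension-only nonlinear trusses), two resultant muscle forces, and the four
quasi-static load cases of the source experiment (abduction moment ramp at
25 deg flexion, the same plus a constant internal tibial moment, an
unloaded 0-90 deg flexion sweep, and a 15 N*m internal moment over the
sweep, all under 400 N quadriceps / 200 N hamstrings loads).

Coordinates: the femur frame is the world frame, x = anterior,
y = proximal, z = medial; all lengths in mm, forces in N, moments in N*mm.
The tibia pose is parametrized by the prescribed knee flexion angle and
five free DOF q = (valgus, internal rotation [rad], world translation
[mm x3]).  Positive knee flexion / valgus / internal rotation follow the
clinical convention; in this frame knee flexion is a negative rotation
about the z axis and internal rotation a negative rotation about the
tibial y axis (left-knee axes), handled by two sign constants below.

Equilibrium at each load step minimizes the total potential energy
(ligament strain energy + contact penalty energy - work of applied moments
and muscle forces) over q with a damped quasi-Newton scheme on numerical
gradients, warm-started along the ramp.  The reported residual is the
max-norm of the generalized-force residual normalized by the gross
internal load (sum of element tensions, contact forces and muscle forces
times a 50 mm lever, plus the applied moments).
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .calibration import ligament_presets
from .constitutive import HGOMaterial, uniaxial_stress
from .errors import ConfigError, DegenerateGeometryError, SolverError
from .joint_kinematics import GroodSuntayAngles, RigidPose
from .uniaxial_ligament import TrussElement, truss_force

__all__ = [
    "LigamentBundle",
    "ContactModel",
    "MuscleForce",
    "KneeModel",
    "LoadCase",
    "KinematicCurve",
    "EquilibriumSolution",
    "build_knee_model",
    "ligament_wrench",
    "solve_equilibrium",
    "run_load_case",
    "to_uniaxial",
    "default_load_cases",
]

LIGAMENT_NAMES = ("ACL", "PCL", "MCL", "LCL")

# Left-knee axes (z medial): positive knee flexion is a negative rotation
# about z; positive internal tibial rotation a negative rotation about y.
_FLEX_SIGN = -1.0
_INT_SIGN = -1.0

_GAUSS_X, _GAUSS_W = np.polynomial.legendre.leggauss(12)
_GAUSS_X = 0.5 * (_GAUSS_X + 1.0)  # nodes on [0, 1]
_GAUSS_W = 0.5 * _GAUSS_W

_GOLDEN = np.pi * (3.0 - np.sqrt(5.0))


# --------------------------------------------------------------------------
# model data types


@dataclass(frozen=True)
class LigamentBundle:
    """Anatomic ligament: N parallel fiber lines sampled over the footprints."""

    name: str
    origins: np.ndarray  # (N, 3) femur-fixed, mm
    insertions: np.ndarray  # (N, 3) tibia-fixed, mm
    reference_lengths: np.ndarray  # (N,) slack lengths, mm
    areas: np.ndarray  # (N,) mm^2
    material: HGOMaterial

    def __post_init__(self):
        o = np.atleast_2d(np.asarray(self.origins, dtype=float))
        i = np.atleast_2d(np.asarray(self.insertions, dtype=float))
        L0 = np.atleast_1d(np.asarray(self.reference_lengths, dtype=float))
        A = np.atleast_1d(np.asarray(self.areas, dtype=float))
        n = o.shape[0]
        if n < 1 or i.shape != (n, 3) or L0.shape != (n,) or A.shape != (n,):
            raise ConfigError(f"inconsistent fiber arrays for bundle {self.name}")
        if np.any(L0 <= 0.0):
            raise ConfigError(f"non-positive reference length in bundle {self.name}")
        for attr, val in (("origins", o), ("insertions", i), ("reference_lengths", L0), ("areas", A)):
            object.__setattr__(self, attr, val)

    @property
    def n_fibers(self) -> int:
        return self.origins.shape[0]

    @property
    def total_area(self) -> float:
        return float(self.areas.sum())


@dataclass(frozen=True)
class ContactModel:
    """Two femoral condyle spheres on a tibial plateau plane (penalty)."""

    centers: np.ndarray  # (2, 3) femur-fixed sphere centers, mm
    radii: np.ndarray  # (2,) mm
    plane_point: np.ndarray  # (3,) tibia-fixed, mm
    plane_normal: np.ndarray  # (3,) tibia-fixed unit vector
    stiffness: float  # N/mm penalty stiffness per condyle

    def __post_init__(self):
        if self.stiffness <= 0.0:
            raise ConfigError("contact stiffness must be > 0")
        c = np.asarray(self.centers, dtype=float).reshape(2, 3)
        r = np.asarray(self.radii, dtype=float).reshape(2)
        p = np.asarray(self.plane_point, dtype=float).reshape(3)
        n = np.asarray(self.plane_normal, dtype=float).reshape(3)
        n = n / np.linalg.norm(n)
        for attr, val in (("centers", c), ("radii", r), ("plane_point", p), ("plane_normal", n)):
            object.__setattr__(self, attr, val)


@dataclass(frozen=True)
class MuscleForce:
    """Resultant trans-knee muscle force as a constant-tension cable.

    The cable runs from a tibia-fixed attachment to a femur-fixed via point
    (the patellar/trochlear groove for the quadriceps, a proximal-posterior
    anchor for the hamstrings) and pulls with constant tension along the
    current line; its potential is magnitude * cable length, so the force
    realigns toward the anchor as the joint moves instead of keeping a
    frozen direction.  The via point follows the prescribed flexion only
    (rotated about the flexion axis), keeping each solve conservative.
    """

    name: str
    attach_tibia: np.ndarray  # (3,) tibia-fixed application point, mm
    via_femur: np.ndarray  # (3,) femur-fixed anchor at full extension, mm
    magnitude: float  # N

    def __post_init__(self):
        object.__setattr__(self, "attach_tibia", np.asarray(self.attach_tibia, dtype=float).reshape(3))
        object.__setattr__(self, "via_femur", np.asarray(self.via_femur, dtype=float).reshape(3))

    def anchor_world(self, flexion_deg: float) -> np.ndarray:
        a = _FLEX_SIGN * np.radians(flexion_deg)
        ca, sa = np.cos(a), np.sin(a)
        Rz = np.array([[ca, -sa, 0.0], [sa, ca, 0.0], [0.0, 0.0, 1.0]])
        return Rz @ self.via_femur

    def force_world(self, flexion_deg: float, attach_world: np.ndarray) -> np.ndarray:
        d = self.anchor_world(flexion_deg) - np.asarray(attach_world, dtype=float)
        return self.magnitude * d / np.linalg.norm(d)


@dataclass
class KneeModel:
    representation: str  # "anatomic_3d" | "uniaxial"
    bundles: dict  # name -> LigamentBundle (anatomic) or tuple[TrussElement] (uniaxial)
    secondary: tuple  # capsule / secondary restraints, always TrussElement
    contact: ContactModel
    muscles: tuple
    config: dict = field(default_factory=dict, repr=False)
    _packed: dict | None = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        if self.representation not in ("anatomic_3d", "uniaxial"):
            raise ConfigError(f"unknown representation {self.representation!r}")
        missing = [n for n in LIGAMENT_NAMES if n not in self.bundles]
        if missing:
            raise ConfigError(f"missing ligament block(s): {missing}")

    # ---- packed arrays for vectorized energy evaluation ----
    def packed(self) -> dict:
        if self._packed is not None:
            return self._packed
        fibers = []
        trusses: list[TrussElement] = list(self.secondary)
        for name in LIGAMENT_NAMES:
            lig = self.bundles[name]
            if isinstance(lig, LigamentBundle):
                fibers.append(
                    (lig.origins, lig.insertions, lig.reference_lengths, lig.areas, lig.material)
                )
            else:
                trusses.extend(lig)
        packed = {"fibers": fibers}
        if trusses:
            packed["truss_O"] = np.array([t.origin for t in trusses])
            packed["truss_P"] = np.array([t.insertion for t in trusses])
            packed["truss_L0"] = np.array([t.reference_length for t in trusses])
            packed["truss_k"] = np.array([t.stiffness_k for t in trusses])
            packed["truss_el"] = np.array([t.toe_limit for t in trusses])
        else:
            packed["truss_O"] = np.zeros((0, 3))
        self._packed = packed
        return packed


@dataclass(frozen=True)
class LoadCase:
    """One quasi-static loading protocol.

    prescribed_flexion: a fixed flexion angle (deg) with an abduction-moment
    ramp 0 -> abduction_moment_max, or a (start, end, steps) flexion sweep.
    applied_internal_moment is held constant over the ramp/sweep.  Moments
    in N*mm.
    """

    name: str
    prescribed_flexion: float | tuple[float, float, int]
    abduction_moment_max: float = 0.0
    applied_internal_moment: float = 0.0
    steps: int = 50
    muscle_on: bool = True

    def __post_init__(self):
        if self.is_sweep:
            s = self.prescribed_flexion
            if len(s) != 3 or int(s[2]) < 2:
                raise ConfigError("flexion sweep needs (start, end, steps>=2)")
            object.__setattr__(self, "prescribed_flexion", (float(s[0]), float(s[1]), int(s[2])))
        elif self.steps < 2:
            raise ConfigError("moment ramp needs steps >= 2")

    @property
    def is_sweep(self) -> bool:
        return isinstance(self.prescribed_flexion, (tuple, list))

    @property
    def primary_angle(self) -> str:
        return "internal_rotation" if self.is_sweep else "abduction"

    @property
    def abscissa(self) -> np.ndarray:
        if self.is_sweep:
            a, b, n = self.prescribed_flexion
            return np.linspace(a, b, n)
        return np.linspace(0.0, self.abduction_moment_max, self.steps)


@dataclass(frozen=True)
class KinematicCurve:
    """Joint angles along a ramp or sweep (clinical sign convention, deg)."""

    case_name: str
    abscissa: np.ndarray  # applied moment (N*mm) or flexion (deg)
    flexion: np.ndarray
    abduction: np.ndarray  # valgus positive
    internal_rotation: np.ndarray
    primary_angle: str = "abduction"
    residuals: np.ndarray | None = None
    meta: dict = field(default_factory=dict, compare=False)

    def __post_init__(self):
        x = np.asarray(self.abscissa, dtype=float)
        if np.any(np.diff(x) < 0.0):
            raise ValueError("abscissa must be monotone non-decreasing")
        for attr in ("abscissa", "flexion", "abduction", "internal_rotation"):
            v = np.asarray(getattr(self, attr), dtype=float)
            if v.shape != x.shape:
                raise ValueError("curve columns must have equal lengths")
            object.__setattr__(self, attr, v)
        if self.residuals is not None:
            object.__setattr__(self, "residuals", np.asarray(self.residuals, dtype=float))

    @property
    def angles(self) -> list[GroodSuntayAngles]:
        return [
            GroodSuntayAngles(f, a, r)
            for f, a, r in zip(self.flexion, self.abduction, self.internal_rotation)
        ]

    def angle_values(self, which: str) -> np.ndarray:
        if which not in ("flexion", "abduction", "internal_rotation"):
            raise ValueError(f"unknown angle {which!r}")
        return getattr(self, which)


@dataclass(frozen=True)
class EquilibriumSolution:
    q: np.ndarray  # (valgus_rad, internal_rad, tx, ty, tz)
    pose: RigidPose
    flexion: float  # deg, prescribed
    residual: float  # normalized generalized-force residual
    energy: float  # potential at the solution, N*mm
    energy_start: float  # potential at the warm-start point, N*mm
    n_iterations: int

    @property
    def abduction_deg(self) -> float:
        return float(np.degrees(self.q[0]))

    @property
    def internal_rotation_deg(self) -> float:
        return float(np.degrees(self.q[1]))


# --------------------------------------------------------------------------
# model construction


def _footprint_basis(axis: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    helper = np.array([0.0, 0.0, 1.0])
    if abs(axis @ helper) > 0.9:
        helper = np.array([1.0, 0.0, 0.0])
    ea = np.cross(helper, axis)
    ea /= np.linalg.norm(ea)
    return ea, np.cross(axis, ea)


def _footprint_offsets(n: int, major: float, minor: float, axis: np.ndarray) -> np.ndarray:
    """Deterministic center-out sunflower sampling of an elliptical footprint."""
    ea, eb = _footprint_basis(axis)
    offs = np.zeros((n, 3))
    if n == 1:
        return offs
    for i in range(n):
        r = np.sqrt((i + 0.5) / n) if i > 0 else 0.0
        phi = i * _GOLDEN
        offs[i] = major * r * np.cos(phi) * ea + minor * r * np.sin(phi) * eb
    return offs


def build_knee_model(
    geometry_config: dict,
    representation: str = "anatomic_3d",
    n_fibers_per_bundle: int = 10,
    materials: dict[str, HGOMaterial] | None = None,
    reference_strain_override: float | None = None,
) -> KneeModel:
    """Assemble the knee model from a geometry configuration.

    The anatomic representation samples `n_fibers_per_bundle` parallel fiber
    lines over each ligament's elliptical origin/insertion footprints with
    the total area split equally; cruciates receive two-family materials and
    collaterals one-family (presets unless `materials` overrides).  Slack
    lengths are set from the reference (full-extension) pose via each
    ligament's configured reference strain, or `reference_strain_override`
    for all of them when given.  Deterministic for a given config.
    """
    if representation not in ("anatomic_3d", "uniaxial"):
        raise ConfigError(f"unknown representation {representation!r}")
    if n_fibers_per_bundle < 1:
        raise ConfigError("n_fibers_per_bundle must be >= 1")
    cfg = geometry_config
    for key in ("ligaments", "condyles", "plateau", "muscles"):
        if key not in cfg:
            raise ConfigError(f"missing config block {key!r}")
    missing = [n for n in LIGAMENT_NAMES if n not in cfg["ligaments"]]
    if missing:
        raise ConfigError(f"missing ligament block(s): {missing}")

    mats = dict(materials or {n: p.material for n, p in ligament_presets().items()})

    bundles: dict[str, LigamentBundle] = {}
    for name in LIGAMENT_NAMES:
        lig = cfg["ligaments"][name]
        O = np.asarray(lig["femur"], dtype=float)
        P = np.asarray(lig["tibia"], dtype=float)
        axis = P - O
        Lref = np.linalg.norm(axis)
        if Lref < 1e-9:
            raise DegenerateGeometryError(f"{name}: coincident attachment centers")
        axis = axis / Lref
        offs = _footprint_offsets(
            n_fibers_per_bundle,
            float(lig.get("footprint_major", 0.0)),
            float(lig.get("footprint_minor", 0.0)),
            axis,
        )
        pre = (
            float(lig.get("reference_strain", 0.0))
            if reference_strain_override is None
            else float(reference_strain_override)
        )
        origins = O[None, :] + offs
        insertions = P[None, :] + offs
        lengths = np.linalg.norm(insertions - origins, axis=1)
        L0 = lengths / (1.0 + pre)
        areas = np.full(n_fibers_per_bundle, float(lig["area"]) / n_fibers_per_bundle)
        bundles[name] = LigamentBundle(name, origins, insertions, L0, areas, mats[name])

    secondary = []
    for sec in cfg.get("secondary", []):
        O = np.asarray(sec["femur"], dtype=float)
        P = np.asarray(sec["tibia"], dtype=float)
        Lref = np.linalg.norm(P - O)
        pre = (
            float(sec.get("reference_strain", 0.0))
            if reference_strain_override is None
            else float(reference_strain_override)
        )
        secondary.append(
            TrussElement(
                origin=tuple(O),
                insertion=tuple(P),
                reference_length=Lref / (1.0 + pre),
                stiffness_k=float(sec["k"]),
                toe_limit=float(sec.get("eps_l", 0.03)),
                name=sec.get("name", "secondary"),
            )
        )

    cond = cfg["condyles"]
    contact = ContactModel(
        centers=np.array([cond["medial"]["center"], cond["lateral"]["center"]], dtype=float),
        radii=np.array([cond["medial"]["radius"], cond["lateral"]["radius"]], dtype=float),
        plane_point=np.asarray(cfg["plateau"]["point"], dtype=float),
        plane_normal=np.asarray(cfg["plateau"]["normal"], dtype=float),
        stiffness=float(cond.get("stiffness", 2000.0)),
    )

    muscles = []
    for mname, m in cfg["muscles"].items():
        muscles.append(
            MuscleForce(
                mname,
                np.asarray(m["attach_tibia"], dtype=float),
                np.asarray(m["via_femur"], dtype=float),
                float(m["force"]),
            )
        )

    model = KneeModel(
        representation="anatomic_3d",
        bundles=bundles,
        secondary=tuple(secondary),
        contact=contact,
        muscles=tuple(muscles),
        config=copy.deepcopy(cfg),
    )
    if representation == "uniaxial":
        model = to_uniaxial(model)
    return model


def to_uniaxial(model: KneeModel) -> KneeModel:
    """Substitute each anatomic bundle by its configured number of trusses.

    The trusses reuse the bundle's most central fibers, so origins,
    insertions and initial orientations are identical to the anatomic
    model's central fiber lines; contact, muscles and secondary restraints
    are untouched.  Raises ConfigError if the model is already uniaxial.
    """
    if model.representation != "anatomic_3d":
        raise ConfigError("model is already uniaxial")
    new_bundles: dict = {}
    for name in LIGAMENT_NAMES:
        bundle: LigamentBundle = model.bundles[name]
        tcfg = model.config["ligaments"][name].get("truss", {})
        n = int(tcfg.get("n", 3))
        if n < 1 or n > bundle.n_fibers:
            raise ConfigError(
                f"{name}: truss count {n} must be in [1, n_fibers={bundle.n_fibers}]"
            )
        k_total = float(tcfg.get("k_total", 5000.0))
        eps_l = float(tcfg.get("eps_l", 0.03))
        new_bundles[name] = tuple(
            TrussElement(
                origin=tuple(bundle.origins[i]),
                insertion=tuple(bundle.insertions[i]),
                reference_length=float(bundle.reference_lengths[i]),
                stiffness_k=k_total / n,
                toe_limit=eps_l,
                area=bundle.total_area / n,
                name=name,
            )
            for i in range(n)
        )
    return KneeModel(
        representation="uniaxial",
        bundles=new_bundles,
        secondary=model.secondary,
        contact=model.contact,
        muscles=model.muscles,
        config=model.config,
    )


# --------------------------------------------------------------------------
# kinematics and potential energy


def _rot_batch(flexion_deg: float, valgus: np.ndarray, internal: np.ndarray) -> np.ndarray:
    """Batched tibia rotation R = Rz(a) Rx(b) Ry(c) for the z-x-y JCS sequence."""
    a = _FLEX_SIGN * np.radians(flexion_deg)
    b = np.asarray(valgus, dtype=float)
    c = _INT_SIGN * np.asarray(internal, dtype=float)
    ca, sa = np.cos(a), np.sin(a)
    Rz = np.array([[ca, -sa, 0.0], [sa, ca, 0.0], [0.0, 0.0, 1.0]])
    cb, sb = np.cos(b), np.sin(b)
    cc, sc = np.cos(c), np.sin(c)
    m = b.shape[0]
    RxRy = np.empty((m, 3, 3))
    RxRy[:, 0, 0] = cc
    RxRy[:, 0, 1] = 0.0
    RxRy[:, 0, 2] = sc
    RxRy[:, 1, 0] = sb * sc
    RxRy[:, 1, 1] = cb
    RxRy[:, 1, 2] = -sb * cc
    RxRy[:, 2, 0] = -cb * sc
    RxRy[:, 2, 1] = sb
    RxRy[:, 2, 2] = cb * cc
    return np.einsum("ij,mjk->mik", Rz, RxRy)


def pose_from_dof(flexion_deg: float, q: np.ndarray) -> RigidPose:
    """Tibia pose for DOF vector q = (valgus, internal [rad], tx, ty, tz [mm])."""
    R = _rot_batch(flexion_deg, np.array([q[0]]), np.array([q[1]]))[0]
    return RigidPose(R, np.asarray(q[2:5], dtype=float))


def _fiber_energy_density(mat: HGOMaterial, lam: np.ndarray) -> np.ndarray:
    """integral_1^lambda sigma11(u) du per unit reference area*length (MPa)."""
    lam_e = np.maximum(lam, 1.0)
    span = lam_e - 1.0
    u = 1.0 + span[..., None] * _GAUSS_X
    sig = uniaxial_stress(mat, u)
    return span * np.einsum("...g,g->...", sig, _GAUSS_W)


def _potential_batch(
    model: KneeModel,
    flexion_deg: float,
    Q: np.ndarray,
    abduction_moment: float,
    internal_moment: float,
    muscle_on: bool,
) -> np.ndarray:
    """Total potential energy (N*mm) for a batch of DOF vectors Q (m, 5)."""
    Q = np.atleast_2d(Q)
    R = _rot_batch(flexion_deg, Q[:, 0], Q[:, 1])
    t = Q[:, 2:5]
    E = np.zeros(Q.shape[0])
    packed = model.packed()

    for O, P, L0, A, mat in packed["fibers"]:
        X = np.einsum("mij,fj->mfi", R, P) + t[:, None, :]
        L = np.linalg.norm(X - O[None, :, :], axis=2)
        lam = L / L0
        E += np.einsum("mf,f->m", _fiber_energy_density(mat, lam), A * L0)

    if packed["truss_O"].shape[0]:
        O = packed["truss_O"]
        P = packed["truss_P"]
        L0 = packed["truss_L0"]
        k = packed["truss_k"]
        el = packed["truss_el"]
        X = np.einsum("mij,fj->mfi", R, P) + t[:, None, :]
        eps = (np.linalg.norm(X - O[None, :, :], axis=2) - L0) / L0
        e_toe = k * eps**3 / (12.0 * el)
        e_lin = k * (2.0 * el) ** 3 / (12.0 * el) + 0.5 * k * ((eps - el) ** 2 - el**2)
        e = np.where(eps <= 0.0, 0.0, np.where(eps <= 2.0 * el, e_toe, e_lin))
        E += np.einsum("mf,f->m", e, L0)

    # penalty contact: femoral condyle spheres on the tibial plateau plane
    ct = model.contact
    p = np.einsum("mij,j->mi", R, ct.plane_point) + t
    n = np.einsum("mij,j->mi", R, ct.plane_normal)
    for j in range(2):
        h = np.einsum("mi,mi->m", ct.centers[j][None, :] - p, n)
        pen = np.clip(ct.radii[j] - h, 0.0, None)
        E += 0.5 * ct.stiffness * pen**2

    if muscle_on:
        for mus in model.muscles:
            X = np.einsum("mij,j->mi", R, mus.attach_tibia) + t
            A = mus.anchor_world(flexion_deg)
            E += mus.magnitude * np.linalg.norm(X - A[None, :], axis=1)

    E -= abduction_moment * Q[:, 0] + internal_moment * Q[:, 1]
    return E


def _element_forces(model: KneeModel, pose: RigidPose, include_secondary: bool = True):
    """Per passive element (tension N, pull direction, world attachment point)."""
    R, t = pose.rotation, pose.translation
    out = []
    for name in LIGAMENT_NAMES:
        lig = model.bundles[name]
        if isinstance(lig, LigamentBundle):
            X = lig.insertions @ R.T + t
            d = lig.origins - X
            L = np.linalg.norm(d, axis=1)
            if np.any(L < 1e-9):
                raise DegenerateGeometryError(f"{name}: degenerate fiber geometry")
            lam = L / lig.reference_lengths
            sig = np.maximum(uniaxial_stress(lig.material, lam), 0.0)
            sig[lam <= 1.0] = 0.0
            T = sig * lig.areas
            for i in range(lig.n_fibers):
                out.append((float(T[i]), d[i] / L[i], X[i]))
        else:
            for tr in lig:
                X = R @ np.asarray(tr.insertion) + t
                d = np.asarray(tr.origin) - X
                L = np.linalg.norm(d)
                if L < 1e-9:
                    raise DegenerateGeometryError(f"{name}: degenerate truss geometry")
                eps = (L - tr.reference_length) / tr.reference_length
                out.append((float(truss_force(tr, eps)), d / L, X))
    if include_secondary:
        for tr in model.secondary:
            X = R @ np.asarray(tr.insertion) + t
            d = np.asarray(tr.origin) - X
            L = np.linalg.norm(d)
            if L < 1e-9:
                raise DegenerateGeometryError("secondary: degenerate truss geometry")
            eps = (L - tr.reference_length) / tr.reference_length
            out.append((float(truss_force(tr, eps)), d / L, X))
    return out


def ligament_wrench(model: KneeModel, pose: RigidPose) -> tuple[np.ndarray, np.ndarray]:
    """Net ligament force (N) and moment (N*mm) about the tibial origin.

    Sums every passive line element (anatomic fibers or trusses, plus the
    secondary restraints); slack elements contribute zero.  At the
    reference pose with zero pre-strain everywhere the wrench vanishes.
    """
    F = np.zeros(3)
    M = np.zeros(3)
    for T, u, X in _element_forces(model, pose):
        F += T * u
        M += np.cross(X - pose.translation, T * u)
    return F, M


def _contact_forces(model: KneeModel, pose: RigidPose) -> float:
    ct = model.contact
    R, t = pose.rotation, pose.translation
    p = R @ ct.plane_point + t
    n = R @ ct.plane_normal
    total = 0.0
    for j in range(2):
        h = (ct.centers[j] - p) @ n
        total += ct.stiffness * max(0.0, ct.radii[j] - h)
    return total


# --------------------------------------------------------------------------
# equilibrium solver

_FD_H = np.array([1e-5, 1e-5, 1e-4, 1e-4, 1e-4])  # rad, rad, mm, mm, mm


def _grad(model, flexion, q, mab, mint, muscle_on) -> np.ndarray:
    Q = np.repeat(q[None, :], 10, axis=0)
    for i in range(5):
        Q[2 * i, i] += _FD_H[i]
        Q[2 * i + 1, i] -= _FD_H[i]
    E = _potential_batch(model, flexion, Q, mab, mint, muscle_on)
    return (E[0::2] - E[1::2]) / (2.0 * _FD_H)


def _gross_load_scale(model, flexion, q, mab, mint, muscle_on) -> float:
    """Characteristic generalized-force magnitude used to normalize residuals."""
    pose = pose_from_dof(flexion, q)
    tension = sum(T for T, _, _ in _element_forces(model, pose))
    contact = _contact_forces(model, pose)
    muscle = sum(m.magnitude for m in model.muscles) if muscle_on else 0.0
    return 100.0 + abs(mab) + abs(mint) + 50.0 * (tension + contact + muscle)


def solve_equilibrium(
    model: KneeModel,
    flexion: float,
    abduction_moment: float = 0.0,
    internal_moment: float = 0.0,
    muscle_on: bool = True,
    q0: np.ndarray | None = None,
    tol: float = 1e-6,
    max_iter: int = 200,
) -> EquilibriumSolution:
    """Quasi-static equilibrium at one load point.

    Flexion is prescribed; the remaining five DOF minimize the total
    potential energy, warm-started from `q0` (the previous ramp step).
    Raises SolverError (carrying the last normalized residual) on
    non-convergence.
    """
    q = np.zeros(5) if q0 is None else np.asarray(q0, dtype=float).copy()

    def fun(x):
        return float(_potential_batch(model, flexion, x[None, :], abduction_moment, internal_moment, muscle_on)[0])

    def jac(x):
        return _grad(model, flexion, x, abduction_moment, internal_moment, muscle_on)

    energy_start = fun(q)
    res = minimize(fun, q, jac=jac, method="BFGS", options={"gtol": 1e-4, "maxiter": max_iter})
    q = res.x
    n_iter = int(res.nit)

    # damped Newton polish on the numerical gradient
    residual = np.inf
    for _ in range(40):
        g = jac(q)
        scale = _gross_load_scale(model, flexion, q, abduction_moment, internal_moment, muscle_on)
        residual = float(np.abs(g).max() / scale)
        if residual <= tol:
            break
        H = np.empty((5, 5))
        for i in range(5):
            dq = np.zeros(5)
            dq[i] = _FD_H[i] * 10.0
            H[i] = (jac(q + dq) - jac(q - dq)) / (2.0 * dq[i])
        H = 0.5 * (H + H.T)
        w = np.linalg.eigvalsh(H)
        mu = max(0.0, 1e-6 * abs(w).max() - w.min())
        step = np.linalg.solve(H + mu * np.eye(5), -g)
        e0 = fun(q)
        alpha, accepted = 1.0, False
        while alpha > 1e-8:
            q_try = q + alpha * step
            if fun(q_try) <= e0 + 1e-10 * (1.0 + abs(e0)):
                q, accepted = q_try, True
                break
            alpha *= 0.5
        n_iter += 1
        if not accepted:
            break
        if n_iter >= max_iter:
            break

    g = jac(q)
    scale = _gross_load_scale(model, flexion, q, abduction_moment, internal_moment, muscle_on)
    residual = float(np.abs(g).max() / scale)
    if residual > tol:
        raise SolverError(
            f"equilibrium not converged (normalized residual {residual:.3e} > {tol:.1e})",
            residual=residual,
        )
    return EquilibriumSolution(
        q=q,
        pose=pose_from_dof(flexion, q),
        flexion=float(flexion),
        residual=residual,
        energy=fun(q),
        energy_start=energy_start,
        n_iterations=n_iter,
    )


def run_load_case(model: KneeModel, case: LoadCase, tol: float = 1e-6) -> KinematicCurve:
    """Step the case's ramp/sweep, solving equilibrium at each point.

    Each step is warm-started from the previous solution; the very first
    point ramps the constant applied loads up in sub-steps so the cold
    start stays in the solver's basin.  Solver failures are re-raised with
    the failing step identified.
    """
    x = case.abscissa
    q = np.zeros(5)
    sols: list[EquilibriumSolution] = []
    for i, xi in enumerate(x):
        if case.is_sweep:
            flexion, mab, mint = float(xi), 0.0, case.applied_internal_moment
        else:
            flexion, mab, mint = float(case.prescribed_flexion), float(xi), case.applied_internal_moment
        try:
            if i == 0 and (abs(mab) > 0.0 or abs(mint) > 0.0):
                for s in (0.25, 0.5, 0.75):
                    sol = solve_equilibrium(
                        model, flexion, s * mab, s * mint, case.muscle_on, q0=q, tol=max(tol, 1e-5)
                    )
                    q = sol.q
            sol = solve_equilibrium(model, flexion, mab, mint, case.muscle_on, q0=q, tol=tol)
        except SolverError as err:
            raise SolverError(
                f"case {case.name!r} failed at step {i} (abscissa {xi:g}): {err}",
                residual=err.residual,
            ) from err
        q = sol.q
        sols.append(sol)

    return KinematicCurve(
        case_name=case.name,
        abscissa=x,
        flexion=np.array([s.flexion for s in sols]),
        abduction=np.array([s.abduction_deg for s in sols]),
        internal_rotation=np.array([s.internal_rotation_deg for s in sols]),
        primary_angle=case.primary_angle,
        residuals=np.array([s.residual for s in sols]),
        meta={
            "energies": np.array([s.energy for s in sols]),
            "energy_starts": np.array([s.energy_start for s in sols]),
        },
    )


def default_load_cases(steps: int = 50) -> dict[str, LoadCase]:
    """The four quasi-static loading conditions of the source experiment.

    Moments internally in N*mm (50 N*m abduction, 20 / 15 N*m internal);
    all four run under 400 N quadriceps and 200 N hamstrings loads.
    """
    return {
        "pure_abduction": LoadCase(
            "pure_abduction", prescribed_flexion=25.0, abduction_moment_max=50_000.0, steps=steps
        ),
        "abduction_internal": LoadCase(
            "abduction_internal",
            prescribed_flexion=25.0,
            abduction_moment_max=50_000.0,
            applied_internal_moment=20_000.0,
            steps=steps,
        ),
        "baseline_flexion": LoadCase(
            "baseline_flexion", prescribed_flexion=(0.0, 90.0, steps)
        ),
        "internal_rotation": LoadCase(
            "internal_rotation",
            prescribed_flexion=(0.0, 90.0, steps),
            applied_internal_moment=15_000.0,
        ),
    }
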