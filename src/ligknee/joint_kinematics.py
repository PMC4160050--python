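"""Grood–Suntay joint coordinate system for the tibiofemoral joint.

The relative rotation of the tibia with respect to the femur is decomposed
about three ordered axes: the femoral medial–lateral axis e1 (flexion), the
tibial long axis e3 (internal/external rotation), and the floating axis
e2 = e3 x e1 (ab/adduction, valgus positive).  With body frames chosen as
x = anterior, y = proximal (long axis), z = medial–lateral, this is the
intrinsic z–x–y Euler sequence

    R = Rz(flexion) @ Rx(abduction) @ Ry(internal_rotation).

Translations are reported as the clinical projections t . e_i of the
relative translation on the (generally non-orthogonal) JCS axes;
`compose_pose` inverts those projections exactly, so compose/decompose is
an identity on the non-singular domain |abduction| < 90 deg.

Sign conventions are this module's own (the source experiments' in-figure
conventions are not recoverable): flexion, valgus (abduction) and internal
rotation are all positive as defined by the right-hand rule about
(e1, e2, e3).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import SingularPoseError

__all__ = ["RigidPose", "GroodSuntayAngles", "decompose_pose", "compose_pose"]

_ORTHO_TOL = 1e-10
_SING_COS = 1e-7  # |cos(abduction)| below this is treated as gimbal


@dataclass(frozen=True)
class RigidPose:
    """Proper rigid transform: world point = rotation @ body point + translation."""

    rotation: np.ndarray
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        R = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float)
        if R.shape != (3, 3) or not np.all(np.isfinite(R)):
            raise ValueError("rotation must be a finite 3x3 matrix")
        if np.abs(R.T @ R - np.eye(3)).max() > _ORTHO_TOL:
            raise ValueError("rotation must be orthogonal to 1e-10")
        if np.linalg.det(R) < 0.0:
            raise ValueError("rotation must be proper (det = +1)")
        if t.shape != (3,) or not np.all(np.isfinite(t)):
            raise ValueError("translation must be a finite 3-vector")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    @classmethod
    def identity(cls) -> "RigidPose":
        return cls(np.eye(3), np.zeros(3))

    def inverse(self) -> "RigidPose":
        return RigidPose(self.rotation.T, -self.rotation.T @ self.translation)

    def compose(self, other: "RigidPose") -> "RigidPose":
        """self then other: x -> self(other(x))."""
        return RigidPose(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )


@dataclass(frozen=True)
class GroodSuntayAngles:
    """Clinical angles (degrees) and translations (mm) in the joint frame."""

    flexion: float
    abduction: float
    internal_rotation: float
    translations: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        if abs(self.abduction) >= 90.0:
            raise SingularPoseError(
                f"|abduction| must be < 90 deg (floating-axis singularity), got {self.abduction}"
            )
        object.__setattr__(self, "translations", tuple(float(v) for v in self.translations))


def _rz(a):
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def _rx(a):
    c, s = np.cos(a), np.sin(a)
    return np.array([[1.0, 0.0, 0.0], [0.0, c, -s], [0.0, s, c]])


def _ry(a):
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])


def _jcs_axes(R_rel: np.ndarray) -> np.ndarray:
    """Columns e1 (femoral z), e2 (floating), e3 (tibial y), femur frame."""
    e1 = np.array([0.0, 0.0, 1.0])
    e3 = R_rel @ np.array([0.0, 1.0, 0.0])
    e2 = np.cross(e3, e1)
    n = np.linalg.norm(e2)
    if n < _SING_COS:
        raise SingularPoseError("floating axis degenerate: tibial long axis parallel to flexion axis")
    return np.column_stack([e1, e2 / n, e3])


def decompose_pose(femur: RigidPose, tibia: RigidPose) -> GroodSuntayAngles:
    """Decompose the tibia-relative-to-femur transform into JCS angles.

    Raises SingularPoseError in the gimbal configuration (flexion axis
    parallel to the tibial long axis, |abduction| -> 90 deg).
    """
    rel = femur.inverse().compose(tibia)
    R = rel.rotation
    # R = Rz(a) Rx(b) Ry(c):  R[2,1] = sin b;  R[0,1] = -sin a cos b;
    # R[1,1] = cos a cos b;  R[2,0] = -cos b sin c;  R[2,2] = cos b cos c.
    sb = np.clip(R[2, 1], -1.0, 1.0)
    cb = np.sqrt(max(0.0, 1.0 - sb * sb))
    if cb < _SING_COS:
        raise SingularPoseError("gimbal configuration: |e1 . e3| -> 1")
    b = np.arcsin(sb)
    a = np.arctan2(-R[0, 1], R[1, 1])
    c = np.arctan2(-R[2, 0], R[2, 2])

    A = _jcs_axes(R)
    trans = rel.translation @ A  # clinical projections t . e_i
    return GroodSuntayAngles(
        flexion=float(np.degrees(a)),
        abduction=float(np.degrees(b)),
        internal_rotation=float(np.degrees(c)),
        translations=tuple(trans),
    )


def compose_pose(angles: GroodSuntayAngles) -> RigidPose:
    """Tibia pose relative to the femur realizing the given JCS angles.

    The translation is chosen so that its projections on (e1, e2, e3)
    reproduce `angles.translations`, making this the exact inverse of
    `decompose_pose(identity, .)`.
    """
    a = np.radians(angles.flexion)
    b = np.radians(angles.abduction)
    c = np.radians(angles.internal_rotation)
    if abs(np.cos(b)) < _SING_COS:
        raise SingularPoseError("singular abduction angle")
    R = _rz(a) @ _rx(b) @ _ry(c)
    A = _jcs_axes(R)
    q = np.asarray(angles.translations, dtype=float)
    t = np.linalg.solve(A.T, q)  # projections t.e_i = q_i
    return RigidPose(R, t)
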