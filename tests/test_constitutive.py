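"""HGO material point: invariants, energy, stress, closed-form limits."""

import numpy as np
import pytest

from conftest import (
    deviator,
    finite_difference_stress,
    random_incompressible_F,
    random_rotation,
)
from ligknee import (
    DeformationState,
    FiberFamily,
    HGOMaterial,
    cauchy_stress,
    isochoric_invariants,
    strain_energy,
    uniaxial_stress,
)
from ligknee.errors import InvalidDeformationError, InvalidMaterialError

UNIAX = lambda lam: np.diag([lam, lam**-0.5, lam**-0.5])  # noqa: E731


class TestInvariants:
    def test_undeformed(self):
        assert isochoric_invariants(np.eye(3), (1, 0, 0)) == pytest.approx((3.0, 1.0))

    def test_uniaxial_hand_values(self):
        # tr Cbar = 1.21 + 2/1.1, a0.Cbar a0 = 1.21 for stretch 1.1 along x
        I1, I4 = isochoric_invariants(UNIAX(1.1), (1, 0, 0))
        assert I1 == pytest.approx(1.21 + 2 / 1.1, abs=1e-12)
        assert I4 == pytest.approx(1.21, abs=1e-12)
        # cross-check against direct matrix arithmetic
        C = UNIAX(1.1).T @ UNIAX(1.1)
        assert I1 == pytest.approx(np.trace(C))
        assert I4 == pytest.approx(C[0, 0])

    def test_rigid_motion_strain_free(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            R = random_rotation(rng)
            a0 = rng.normal(size=3)
            a0 /= np.linalg.norm(a0)
            I1, I4 = isochoric_invariants(R, a0)
            assert I1 == pytest.approx(3.0, abs=1e-12)
            assert I4 == pytest.approx(1.0, abs=1e-12)

    def test_volume_change_removed(self):
        # pure dilation has no isochoric strain
        I1, I4 = isochoric_invariants(1.3 * np.eye(3), (0, 1, 0))
        assert (I1, I4) == pytest.approx((3.0, 1.0))

    def test_singular_F_rejected(self):
        with pytest.raises(InvalidDeformationError):
            isochoric_invariants(np.diag([1.0, 1.0, 0.0]), (1, 0, 0))
        with pytest.raises(InvalidDeformationError):
            isochoric_invariants(np.full((3, 3), np.nan), (1, 0, 0))


class TestStrainEnergy:
    def test_zero_at_identity(self, one_family_material):
        assert strain_energy(one_family_material, np.eye(3)) == 0.0

    def test_formula_with_independent_invariants(self, one_family_material):
        # psi = c/2 (I1-3) + k1/(2 k2) [exp(k2 E^2) - 1] with E from the
        # invariants computed by direct matrix arithmetic
        F = UNIAX(1.1)
        C = F.T @ F
        I1, I4 = np.trace(C), C[0, 0]
        E = 0.1 * I1 + 0.7 * I4 - 1.0
        expected = 0.5 * (I1 - 3.0) + 10.0 / 2.0 * (np.exp(E * E) - 1.0)
        assert strain_energy(one_family_material, F) == pytest.approx(expected, rel=1e-12)

    def test_shortened_fiber_excluded(self, one_family_material):
        # fiber along x compressed: E < 0, only the ground matrix remains
        F = UNIAX(0.9)
        C = F.T @ F
        E = 0.1 * np.trace(C) + 0.7 * C[0, 0] - 1.0
        assert E < 0.0
        assert strain_energy(one_family_material, F) == pytest.approx(
            0.5 * (np.trace(C) - 3.0), rel=1e-12
        )

    def test_nonnegative_over_random_deformations(self, two_family_material):
        rng = np.random.default_rng(11)
        for _ in range(50):
            F = random_incompressible_F(rng)
            assert strain_energy(two_family_material, F) >= 0.0

    def test_i4_recruitment_switch(self):
        # a strongly dispersed family transverse to the load has I4 < 1 but
        # E > 0: active under the pseudo-strain switch, silent under I4 > 1
        mat = HGOMaterial(c=1.0, families=(FiberFamily((0, 1, 0), 0.3, 5.0, 2.0),))
        F = UNIAX(1.3)
        C = F.T @ F
        E = 0.3 * np.trace(C) + 0.1 * C[1, 1] - 1.0
        assert E > 0.0 > C[1, 1] - 1.0
        assert strain_energy(mat.with_recruitment("i4"), F) == pytest.approx(
            0.5 * (np.trace(C) - 3.0)
        )
        assert strain_energy(mat, F) > strain_energy(mat.with_recruitment("i4"), F)


class TestCauchyStress:
    def test_zero_at_identity(self, two_family_material):
        assert cauchy_stress(two_family_material, np.eye(3), 0.0) == pytest.approx(
            np.zeros((3, 3))
        )

    def test_matches_finite_difference_oracle(self, one_family_material):
        F = UNIAX(1.1)
        sig = cauchy_stress(one_family_material, F, 0.0)
        sig_fd = finite_difference_stress(one_family_material, F)
        assert deviator(sig) == pytest.approx(deviator(sig_fd), rel=1e-6)
        # lateral-traction-free pressure elimination gives sigma11 ~ 2.99 MPa
        sigma11 = sig[0, 0] - sig[1, 1]
        assert sigma11 == pytest.approx(2.9886, abs=2e-4)

    def test_objectivity(self, two_family_material):
        rng = np.random.default_rng(3)
        F = random_incompressible_F(rng)
        sig = cauchy_stress(two_family_material, F, 0.4)
        for _ in range(5):
            Q = random_rotation(rng)
            sig_rot = cauchy_stress(two_family_material, Q @ F, 0.4)
            assert sig_rot == pytest.approx(Q @ sig @ Q.T, abs=1e-9)

    def test_isotropic_dispersion_direction_independent(self):
        # kappa = 1/3 makes the structure tensor isotropic
        rng = np.random.default_rng(5)
        F = random_incompressible_F(rng)
        mats = [
            HGOMaterial(c=1.0, families=(FiberFamily(tuple(a), 1 / 3, 5.0, 3.0),))
            for a in ((1, 0, 0), (0, 0, 1), np.ones(3) / np.sqrt(3))
        ]
        sigs = [cauchy_stress(m, F, 0.0) for m in mats]
        assert sigs[0] == pytest.approx(sigs[1], abs=1e-9)
        assert sigs[0] == pytest.approx(sigs[2], abs=1e-9)

    def test_symmetry(self, two_family_material):
        rng = np.random.default_rng(13)
        F = random_incompressible_F(rng)
        sig = cauchy_stress(two_family_material, F, 1.0)
        assert sig == pytest.approx(sig.T)


class TestUniaxialStress:
    def test_zero_at_unit_stretch(self, one_family_material, two_family_material):
        assert uniaxial_stress(one_family_material, 1.0) == 0.0
        assert uniaxial_stress(two_family_material, 1.0) == 0.0

    def test_consistent_with_tensor_path(self, one_family_material):
        # closed form equals the full tensor computation with p from
        # traction-free lateral faces
        sig = cauchy_stress(one_family_material, UNIAX(1.1), 0.0)
        assert uniaxial_stress(one_family_material, 1.1) == pytest.approx(
            sig[0, 0] - sig[2, 2], rel=1e-12
        )

    def test_neo_hookean_limit(self):
        mat = HGOMaterial(c=2.3, families=(FiberFamily((1, 0, 0), 0.1, 0.0, 1.0),))
        lam = np.linspace(0.7, 1.4, 20)
        assert uniaxial_stress(mat, lam) == pytest.approx(
            2.3 * (lam**2 - 1.0 / lam), abs=1e-12
        )

    def test_strictly_increasing_in_tension(self, two_family_material):
        lam = np.linspace(1.0, 1.3, 200)
        sig = uniaxial_stress(two_family_material, lam)
        assert np.all(np.diff(sig) > 0.0)

    def test_tension_only_matches_k1_zero_in_compression(self, one_family_material):
        mat0 = HGOMaterial(
            c=1.0, families=(FiberFamily((1, 0, 0), 0.1, 0.0, 1.0),)
        )
        lam = np.linspace(0.8, 0.999, 25)
        assert uniaxial_stress(one_family_material, lam) == pytest.approx(
            uniaxial_stress(mat0, lam), abs=0.0
        )

    def test_two_families_sum(self, two_family_material):
        # a two-family material carries twice one family's fiber stress
        fam = two_family_material.families[0]
        single = HGOMaterial(c=1.5, families=(fam,))
        ground = HGOMaterial(c=1.5, families=(FiberFamily((1, 0, 0), 0.0, 0.0, 1.0),))
        lam = 1.12
        fiber_one = uniaxial_stress(single, lam) - uniaxial_stress(ground, lam)
        total = uniaxial_stress(two_family_material, lam)
        # families at +/-theta have identical diagonal response
        assert total == pytest.approx(uniaxial_stress(ground, lam) + 2 * fiber_one, rel=1e-9)

    def test_fiber_angle_rotates_load_axis(self, one_family_material):
        # fiber at 90 deg to the load axis carries (almost) no fiber stress
        s0 = uniaxial_stress(one_family_material, 1.1, fiber_angle=0.0)
        s90 = uniaxial_stress(one_family_material, 1.1, fiber_angle=90.0)
        assert s90 < s0

    def test_bad_stretch_rejected(self, one_family_material):
        with pytest.raises(InvalidDeformationError):
            uniaxial_stress(one_family_material, -0.5)


class TestValidation:
    def test_material_bounds(self):
        with pytest.raises(InvalidMaterialError):
            FiberFamily((1, 0, 0), kappa=0.5, k1=1.0, k2=1.0)
        with pytest.raises(InvalidMaterialError):
            FiberFamily((1, 0, 0), kappa=0.1, k1=-1.0, k2=1.0)
        with pytest.raises(InvalidMaterialError):
            FiberFamily((1, 0, 0), kappa=0.1, k1=1.0, k2=0.0)
        with pytest.raises(InvalidMaterialError):
            FiberFamily((2, 0, 0), kappa=0.1, k1=1.0, k2=1.0)
        fam = FiberFamily((1, 0, 0), 0.1, 1.0, 1.0)
        with pytest.raises(InvalidMaterialError):
            HGOMaterial(c=-1.0, families=(fam,))
        with pytest.raises(InvalidMaterialError):
            HGOMaterial(c=1.0, families=(fam, fam, fam))

    def test_deformation_state_enforces_incompressibility(self):
        with pytest.raises(InvalidDeformationError):
            DeformationState(np.diag([1.2, 1.0, 1.0]))
        state = DeformationState(UNIAX(1.05))
        assert state.I1bar == pytest.approx(1.05**2 + 2 / 1.05)
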