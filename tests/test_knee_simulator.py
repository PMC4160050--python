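"""Knee model assembly, wrenches, equilibrium and load cases (coarse settings)."""

import numpy as np
import pytest

from ligknee import (
    KinematicCurve,
    LoadCase,
    build_knee_model,
    default_geometry,
    default_load_cases,
    ligament_presets,
    ligament_wrench,
    run_load_case,
    solve_equilibrium,
    to_uniaxial,
    truss_force,
    uniaxial_stress,
)
from ligknee.errors import ConfigError
from ligknee.knee_simulator import LIGAMENT_NAMES, LigamentBundle, pose_from_dof


class TestBuild:
    def test_bundle_structure(self, small_anatomic):
        assert small_anatomic.representation == "anatomic_3d"
        for name in LIGAMENT_NAMES:
            b = small_anatomic.bundles[name]
            assert isinstance(b, LigamentBundle)
            assert b.n_fibers == 4
            assert np.all(b.reference_lengths > 0)
        assert small_anatomic.bundles["LCL"].material == small_anatomic.bundles["MCL"].material

    def test_area_split_equally(self, small_anatomic, geometry):
        for name in LIGAMENT_NAMES:
            b = small_anatomic.bundles[name]
            assert b.total_area == pytest.approx(geometry["ligaments"][name]["area"])
            assert np.ptp(b.areas) == 0.0

    def test_reference_strain_sets_slack_length(self, geometry):
        m = build_knee_model(geometry, "anatomic_3d", 1)
        acl = m.bundles["ACL"]
        taut = np.linalg.norm(acl.insertions[0] - acl.origins[0])
        pre = geometry["ligaments"]["ACL"]["reference_strain"]
        assert acl.reference_lengths[0] == pytest.approx(taut / (1 + pre))

    def test_errors(self, geometry):
        with pytest.raises(ConfigError):
            build_knee_model(geometry, "anatomic_3d", 0)
        with pytest.raises(ConfigError):
            build_knee_model(geometry, "hexahedral", 4)
        broken = {k: v for k, v in geometry.items()}
        broken["ligaments"] = {k: v for k, v in geometry["ligaments"].items() if k != "PCL"}
        with pytest.raises(ConfigError):
            build_knee_model(broken, "anatomic_3d", 4)

    def test_deterministic(self, geometry):
        a = build_knee_model(geometry, "anatomic_3d", 6)
        b = build_knee_model(geometry, "anatomic_3d", 6)
        for name in LIGAMENT_NAMES:
            assert np.array_equal(a.bundles[name].origins, b.bundles[name].origins)


class TestToUniaxial:
    def test_endpoints_match_central_fibers(self, small_anatomic, small_uniaxial, geometry):
        for name in LIGAMENT_NAMES:
            n = geometry["ligaments"][name]["truss"]["n"]
            bundle = small_anatomic.bundles[name]
            trusses = small_uniaxial.bundles[name]
            assert len(trusses) == n
            for i, tr in enumerate(trusses):
                assert tr.origin == pytest.approx(bundle.origins[i])
                assert tr.insertion == pytest.approx(bundle.insertions[i])
                assert tr.reference_length == pytest.approx(bundle.reference_lengths[i])

    def test_non_ligament_blocks_untouched(self, small_anatomic, small_uniaxial):
        assert small_uniaxial.contact is small_anatomic.contact
        assert small_uniaxial.muscles is small_anatomic.muscles
        assert small_uniaxial.secondary is small_anatomic.secondary

    def test_double_substitution_rejected(self, small_uniaxial):
        with pytest.raises(ConfigError):
            to_uniaxial(small_uniaxial)

    def test_uniaxial_via_build(self, geometry, small_uniaxial):
        direct = build_knee_model(geometry, "uniaxial", 4)
        assert direct.representation == "uniaxial"
        for name in LIGAMENT_NAMES:
            for a, b in zip(direct.bundles[name], small_uniaxial.bundles[name]):
                assert a.origin == b.origin and a.insertion == b.insertion


class TestLigamentWrench:
    def test_zero_at_reference_with_zero_prestrain(self, geometry):
        m = build_knee_model(geometry, "anatomic_3d", 4, reference_strain_override=0.0)
        F, M = ligament_wrench(m, pose_from_dof(0.0, np.zeros(5)))
        assert F == pytest.approx(np.zeros(3), abs=1e-9)
        assert M == pytest.approx(np.zeros(3), abs=1e-9)

    def test_matches_brute_force_element_sum(self, small_anatomic):
        # independent re-summation over fibers/trusses with public operations
        pose = pose_from_dof(12.0, np.array([0.02, -0.03, 1.0, -2.0, 0.5]))
        F, M = ligament_wrench(small_anatomic, pose)
        Fb = np.zeros(3)
        Mb = np.zeros(3)
        for name in LIGAMENT_NAMES:
            b = small_anatomic.bundles[name]
            for i in range(b.n_fibers):
                X = pose.rotation @ b.insertions[i] + pose.translation
                d = b.origins[i] - X
                L = np.linalg.norm(d)
                lam = L / b.reference_lengths[i]
                T = max(uniaxial_stress(b.material, lam), 0.0) * b.areas[i] if lam > 1 else 0.0
                Fb += T * d / L
                Mb += np.cross(X - pose.translation, T * d / L)
        for tr in small_anatomic.secondary:
            X = pose.rotation @ np.array(tr.insertion) + pose.translation
            d = np.array(tr.origin) - X
            L = np.linalg.norm(d)
            T = truss_force(tr, (L - tr.reference_length) / tr.reference_length)
            Fb += T * d / L
            Mb += np.cross(X - pose.translation, T * d / L)
        assert F == pytest.approx(Fb, rel=1e-12)
        assert M == pytest.approx(Mb, rel=1e-12)

    def test_single_fiber_acl_tension(self, geometry):
        # one-fiber ACL stretched ~10% along its own axis carries
        # sigma11(lambda) x area
        m = build_knee_model(geometry, "anatomic_3d", 1, reference_strain_override=0.0)
        acl = m.bundles["ACL"]
        axis = acl.insertions[0] - acl.origins[0]
        L = np.linalg.norm(axis)
        pose = pose_from_dof(0.0, np.concatenate([[0.0, 0.0], 0.1 * axis]))
        F, _ = ligament_wrench(m, pose)
        lam = np.linalg.norm(axis + 0.1 * axis) / L
        expected_acl = uniaxial_stress(acl.material, lam) * acl.total_area
        # project the total wrench on the stretched ACL line and remove the
        # other (also displaced) elements by brute force
        contrib = np.zeros(3)
        for name in LIGAMENT_NAMES:
            if name == "ACL":
                continue
            b = m.bundles[name]
            X = pose.rotation @ b.insertions[0] + pose.translation
            d = b.origins[0] - X
            Ln = np.linalg.norm(d)
            lam_n = Ln / b.reference_lengths[0]
            T = max(uniaxial_stress(b.material, lam_n), 0.0) * b.areas[0] if lam_n > 1 else 0.0
            contrib += T * d / Ln
        for tr in m.secondary:
            X = pose.rotation @ np.array(tr.insertion) + pose.translation
            d = np.array(tr.origin) - X
            Ln = np.linalg.norm(d)
            T = truss_force(tr, (Ln - tr.reference_length) / tr.reference_length)
            contrib += T * d / Ln
        acl_force = F - contrib
        assert np.linalg.norm(acl_force) == pytest.approx(expected_acl, rel=1e-9)
        assert acl_force / np.linalg.norm(acl_force) == pytest.approx(-1.1 * axis / np.linalg.norm(1.1 * axis), rel=1e-9)

    def test_representations_differ_at_nonreference_pose(self, small_anatomic, small_uniaxial):
        pose = pose_from_dof(20.0, np.array([0.03, 0.05, 0.5, -1.0, 0.2]))
        F3, M3 = ligament_wrench(small_anatomic, pose)
        F1, M1 = ligament_wrench(small_uniaxial, pose)
        assert np.linalg.norm(F3 - F1) + np.linalg.norm(M3 - M1) > 1.0


class TestEquilibrium:
    def test_symmetric_unloaded(self, sym_geometry):
        m = build_knee_model(sym_geometry, "anatomic_3d", 4)
        sol = solve_equilibrium(m, 0.0, muscle_on=False)
        assert abs(sol.abduction_deg) < 0.1
        assert abs(sol.internal_rotation_deg) < 0.1
        assert sol.residual < 1e-6

    def test_descent_and_residual(self, small_anatomic):
        sol = solve_equilibrium(small_anatomic, 25.0, abduction_moment=20_000.0)
        assert sol.residual < 1e-6
        assert sol.energy <= sol.energy_start

    def test_warm_start_speeds_convergence(self, small_anatomic):
        a = solve_equilibrium(small_anatomic, 25.0, abduction_moment=20_000.0)
        b = solve_equilibrium(
            small_anatomic, 25.0, abduction_moment=21_000.0, q0=a.q
        )
        assert b.n_iterations <= a.n_iterations


class TestLoadCases:
    def test_registry_contract(self):
        cases = default_load_cases()
        assert len(cases) == 4
        assert max(c.abduction_moment_max for c in cases.values()) == 50_000.0
        assert cases["abduction_internal"].applied_internal_moment == 20_000.0
        assert cases["internal_rotation"].applied_internal_moment == 15_000.0
        assert all(c.muscle_on for c in cases.values())

    def test_case_validation(self):
        with pytest.raises(ConfigError):
            LoadCase("bad", prescribed_flexion=(0.0, 90.0, 1))
        with pytest.raises(ConfigError):
            LoadCase("bad", prescribed_flexion=25.0, abduction_moment_max=1000.0, steps=1)

    def test_small_ramp_curve(self, small_anatomic):
        case = LoadCase("mini", prescribed_flexion=25.0, abduction_moment_max=15_000.0, steps=5)
        curve = run_load_case(small_anatomic, case)
        assert len(curve.abscissa) == 5
        assert curve.primary_angle == "abduction"
        assert np.all(np.diff(curve.abduction) >= -1e-9)
        assert np.all(curve.residuals < 1e-6)

    def test_small_sweep_curve(self, small_anatomic):
        case = LoadCase("sweep", prescribed_flexion=(0.0, 30.0, 5))
        curve = run_load_case(small_anatomic, case)
        assert curve.primary_angle == "internal_rotation"
        assert curve.flexion == pytest.approx(np.linspace(0, 30, 5))

    def test_curve_validation(self):
        with pytest.raises(ValueError):
            KinematicCurve("x", [0, 1, 2], [0, 0], [0, 0, 0], [0, 0, 0])
        with pytest.raises(ValueError):
            KinematicCurve("x", [0, 2, 1], [0] * 3, [0] * 3, [0] * 3)
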