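"""Voxel FE solver oracles: patch tests, closed-form bars and beams,
equilibrium, linearity, frame behaviour, principal stresses, damage."""

import numpy as np
import pytest

from nestmech.volume_io import MaskVolume, VoxelVolume
from nestmech import voxfem
from nestmech.voxfem import (FEError, LoadROI, MaterialModel, apply_damage,
                             build_model, hex_stiffness, principal_stress,
                             reaction_forces, solve)

BIRD_N = 0.1569


def _bar(n_axial=10, nt=1, spacing=1.0, E=155.0, nu=0.0):
    """Prismatic bar along B-F, pinned at the wall face."""
    m = np.ones((nt, n_axial, nt), dtype=bool)
    model = build_model(MaskVolume(m, spacing), None, MaterialModel(E=E, nu=nu))
    return model


def _end_load(model, total, axis=1):
    L = model.nodes[:, axis].max()
    far = np.flatnonzero(model.nodes[:, axis] == L)
    f = np.zeros(3)
    f[axis] = total
    model.load_sets = {"end": (far, f)}
    return far


class TestElement:
    def test_stiffness_symmetric_and_rigid_body_neutral(self):
        K = hex_stiffness(155.0, 0.3, 0.8)
        np.testing.assert_allclose(K, K.T, atol=1e-10)
        # translations produce no force
        for d in range(3):
            u = np.zeros(24)
            u[d::3] = 1.0
            assert np.abs(K @ u).max() < 1e-9

    def test_mesh_counts_on_2x2x2_solid(self):
        m = np.ones((2, 2, 2), dtype=bool)
        model = build_model(MaskVolume(m, 1.0), None, MaterialModel())
        assert model.n_nodes == 27 and model.n_elements == 8


class TestBarOracles:
    def test_uniaxial_stress_exact(self):
        # 1x1x10 mm bar, axial load 0.1569 N on 1 mm^2: centroid axial
        # stress = F/A in every element (constant-stress patch state)
        model = _bar()
        _end_load(model, BIRD_N)
        f = solve(model, gravity=False)
        np.testing.assert_allclose(f.stress_tensor[:, 1], BIRD_N, rtol=1e-8)
        np.testing.assert_allclose(f.max_principal, BIRD_N, rtol=1e-8)

    def test_end_displacement_closed_form(self):
        model = _bar()
        far = _end_load(model, BIRD_N)
        f = solve(model, gravity=False)
        expected = BIRD_N * 10.0 / (1.0 * 155.0)     # FL/AE
        assert f.displacements[far, 1].mean() == pytest.approx(expected,
                                                               rel=1e-8)

    def test_patch_state_exact_at_any_resolution(self):
        # same bar at half the element size: stress still exact
        model = _bar(n_axial=20, nt=2, spacing=0.5)
        _end_load(model, BIRD_N)
        f = solve(model, gravity=False)
        np.testing.assert_allclose(f.stress_tensor[:, 1], BIRD_N / 1.0,
                                   rtol=1e-7)

    def test_zero_load_zero_field(self):
        model = _bar()
        f = solve(model, gravity=False)
        assert np.abs(f.displacements).max() == 0.0
        assert np.abs(f.max_principal).max() == 0.0

    def test_cantilever_matches_euler_bernoulli(self):
        # slenderness 10, 4 elements through the thickness
        nt, L = 4, 40
        m = np.ones((nt, L, nt), dtype=bool)
        model = build_model(MaskVolume(m, 1.0), None,
                            MaterialModel(E=155.0, nu=0.3))
        tip = np.flatnonzero(model.nodes[:, 1] == L)
        P = 0.01
        model.load_sets = {"tip": (tip, np.array([-P, 0.0, 0.0]))}
        f = solve(model, gravity=False)
        I = nt ** 4 / 12.0
        expected = P * L ** 3 / (3 * 155.0 * I)
        tipdef = -f.displacements[tip, 0].mean()
        assert tipdef == pytest.approx(expected, rel=0.10)


class TestEquilibriumAndLinearity:
    def test_reactions_balance_applied_loads_with_gravity(self):
        m = np.ones((3, 6, 3), dtype=bool)
        model = build_model(MaskVolume(m, 1.0), None,
                            MaterialModel(total_mass_g=2.0))
        _end_load(model, -0.05, axis=0)
        f = solve(model)
        r = reaction_forces(model, f, gravity=True).sum(axis=0)
        applied = model.total_applied_force(gravity=True)
        assert np.linalg.norm(r + applied) <= 1e-6 * np.linalg.norm(applied)

    def test_doubling_loads_doubles_response(self):
        model = _bar(nt=2, n_axial=8)
        _end_load(model, 0.1)
        f1 = solve(model, gravity=False)
        _end_load(model, 0.2)
        f2 = solve(model, gravity=False)
        np.testing.assert_allclose(f2.displacements, 2 * f1.displacements,
                                   rtol=1e-6, atol=1e-15)
        np.testing.assert_allclose(f2.stress_tensor, 2 * f1.stress_tensor,
                                   rtol=1e-6, atol=1e-12)

    def test_rotating_geometry_and_load_permutes_stress(self):
        # bar along B-F loaded axially vs the same bar along R-L: the
        # stress tensor components permute accordingly
        m1 = np.ones((2, 8, 2), dtype=bool)
        mod1 = build_model(MaskVolume(m1, 1.0), None, MaterialModel(nu=0.3))
        _end_load(mod1, 0.1, axis=1)
        f1 = solve(mod1, gravity=False)

        m2 = np.ones((2, 2, 8), dtype=bool)
        mod2 = build_model(MaskVolume(m2, 1.0), None, MaterialModel(nu=0.3),
                           pin_axis="R-L", pin_face=0)
        _end_load(mod2, 0.1, axis=2)
        f2 = solve(mod2, gravity=False)
        np.testing.assert_allclose(np.sort(f1.stress_tensor[:, 1]),
                                   np.sort(f2.stress_tensor[:, 2]), rtol=1e-6)
        assert f1.max_principal.max() == pytest.approx(
            f2.max_principal.max(), rel=1e-6)


class TestPrincipalStress:
    def test_uniaxial(self):
        T = np.diag([2.0, 0.0, 0.0])
        assert principal_stress(T) == pytest.approx((2.0, 0.0, 0.0))

    def test_pure_shear(self):
        T = np.zeros((3, 3))
        T[0, 1] = T[1, 0] = 1.0
        assert principal_stress(T) == pytest.approx((1.0, 0.0, -1.0))

    def test_hydrostatic_compression(self):
        assert principal_stress(-3.0 * np.eye(3)) == pytest.approx(
            (-3.0, -3.0, -3.0))

    def test_asymmetric_rejected(self):
        T = np.zeros((3, 3))
        T[0, 1] = 1.0
        with pytest.raises(FEError, match="symmetric"):
            principal_stress(T)


class TestModelBuilding:
    def test_density_calibrates_to_total_mass(self):
        m = np.ones((3, 3, 3), dtype=bool)
        gray = VoxelVolume(np.full((3, 3, 3), 100, dtype=np.uint8), 1.0)
        model = build_model(MaskVolume(m, 1.0), gray,
                            MaterialModel(total_mass_g=5.93))
        rho = model.material.density
        assert np.ptp(rho) == 0.0                   # uniform grayscale
        total_g = rho.sum() * 1.0 / voxfem.G_TO_TONNE
        assert total_g == pytest.approx(5.93, rel=1e-9)

    def test_density_follows_grayscale_gradient(self):
        m = np.ones((1, 1, 4), dtype=bool)
        g = np.array([[[40, 80, 120, 160]]], dtype=np.uint8)
        model = build_model(MaskVolume(m, 1.0), VoxelVolume(g, 1.0),
                            MaterialModel(total_mass_g=1.0))
        rho = model.material.density
        np.testing.assert_allclose(rho / rho[0], [1, 2, 3, 4])

    def test_roi_in_air_is_an_error(self):
        m = np.ones((2, 4, 2), dtype=bool)
        roi = LoadROI("bird", np.array([0, 0, -0.1]), kind="cuboid",
                      center=(0, 100.0, 100.0), size=(2.0, 2.0))
        with pytest.raises(FEError, match="intersects no material"):
            build_model(MaskVolume(m, 1.0), None, MaterialModel(),
                        load_rois=[roi])

    def test_free_floating_model_rejected(self):
        m = np.zeros((3, 4, 3), dtype=bool)
        m[:, 2:, :] = True                          # nothing on the wall face
        with pytest.raises(FEError, match="pinned"):
            build_model(MaskVolume(m, 1.0), None, MaterialModel())

    def test_empty_mask_rejected(self):
        with pytest.raises(FEError, match="empty"):
            build_model(MaskVolume(np.zeros((2, 2, 2), bool), 1.0), None,
                        MaterialModel())

    def test_invalid_material_rejected(self):
        with pytest.raises(FEError):
            MaterialModel(E=-1)
        with pytest.raises(FEError):
            MaterialModel(nu=0.5)


class TestDamage:
    def test_zero_radius_is_identity(self):
        m = np.ones((4, 4, 4), dtype=bool)
        out = apply_damage(MaskVolume(m, 1.0), [((2, 2, 2), 0.0)])
        np.testing.assert_array_equal(out.data, m)

    def test_ball_removal_matches_voxel_count_oracle(self):
        n = 21
        m = np.ones((n, n, n), dtype=bool)
        r, c = 4.0, (10.5, 10.5, 10.5)
        out = apply_damage(MaskVolume(m, 1.0), [(c, r)])
        idx = np.indices((n, n, n)) + 0.5
        ball = sum((idx[d] - c[d]) ** 2 for d in range(3)) <= r * r
        assert (m.sum() - out.count()) == ball.sum()

    def test_removing_whole_wall_face_rejected(self):
        m = np.ones((3, 3, 3), dtype=bool)
        with pytest.raises(FEError, match="wall"):
            apply_damage(MaskVolume(m, 1.0), [((1.5, 0.0, 1.5), 50.0)])
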