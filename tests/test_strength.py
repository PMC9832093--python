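import numpy as np
import pytest

from silicofem import meshing
from silicofem.phantom import DensityParams, assign_materials, deform_instance
from silicofem.strength import (
    StrengthConfig,
    assemble_system,
    averaged_principal_strains,
    element_strain_tensors,
    failure_load,
    failure_surface,
    load_direction_grid,
    reference_fall_axis,
    solve_case,
)


class TestLoadGrid:
    def test_grid_has_28_cases_on_stated_ranges(self):
        cases = load_direction_grid()
        assert len(cases) == 28
        assert sorted({c.ap_angle for c in cases}) == [-30, -20, -10, 0, 10, 20, 30]
        assert sorted({c.ml_angle for c in cases}) == [0, 10, 20, 30]

    def test_zero_angle_case_is_reference_fall_axis(self, coarse_template):
        lms = coarse_template.landmark_coords
        cases = load_direction_grid(lms)
        zero = next(c for c in cases if c.ap_angle == 0 and c.ml_angle == 0)
        assert np.allclose(zero.direction, reference_fall_axis(lms), atol=1e-12)

    def test_all_directions_unit_norm(self):
        for c in load_direction_grid():
            assert np.linalg.norm(c.direction) == pytest.approx(1.0, abs=1e-12)


@pytest.fixture(scope="module")
def bar():
    """Axial bar 10 x 10 x 100 mm, E = 10 GPa, loaded with uniform end traction."""
    coords, tets = meshing.box_mesh((10.0, 10.0, 100.0), (2, 2, 8))
    E = np.full(len(tets), 10_000.0)  # MPa
    system = assemble_system(coords, tets, E, nu=0.3)
    return coords, tets, E, system


def _end_face_forces(coords, tets, total_force, z_val):
    """Consistent nodal forces for uniform traction on the z = z_val face."""
    faces = meshing.boundary_faces(tets)
    f = np.zeros((len(coords), 3))
    on_face = np.isclose(coords[:, 2], z_val)
    area_total = 0.0
    for tri in faces:
        if np.all(on_face[tri]):
            a, b, c = coords[tri]
            area = 0.5 * np.linalg.norm(np.cross(b - a, c - a))
            area_total += area
            for n in tri:
                f[n, 2] += area / 3.0
    f[:, 2] *= total_force / area_total
    return f.ravel()


class TestLinearSolve:
    def test_zero_load_gives_zero_displacements(self, bar):
        coords, tets, E, system = bar
        pinned = np.flatnonzero(np.isclose(coords[:, 2], 0.0))
        u = solve_case(system, np.zeros(system.n_dof), pinned)
        assert np.all(u == 0)

    def test_axial_bar_matches_FL_over_EA(self, bar):
        # uniform uniaxial stress is exactly representable by CST elements,
        # so the tip displacement must match FL/(EA) to solver precision
        coords, tets, E, system = bar
        F, L, A, Emod = 500.0, 100.0, 100.0, 10_000.0
        bottom = np.flatnonzero(np.isclose(coords[:, 2], 0.0))
        f = _end_face_forces(coords, tets, F, 100.0)
        # constrain only axial dof at the bottom + lateral rigid-body dofs,
        # leaving Poisson contraction free
        ndof = system.n_dof
        fixed_dofs = set(3 * bottom + 2)
        corner = bottom[np.lexsort((coords[bottom, 1], coords[bottom, 0]))]
        fixed_dofs |= {3 * corner[0], 3 * corner[0] + 1, 3 * corner[1]}
        free = np.setdiff1d(np.arange(ndof), sorted(fixed_dofs))
        from scipy.sparse.linalg import spsolve

        K = system.K.tocsc()
        u = np.zeros(ndof)
        u[free] = spsolve(K[free][:, free], f[free])
        tip = np.flatnonzero(np.isclose(coords[:, 2], 100.0))
        uz_tip = u.reshape(-1, 3)[tip, 2]
        expected = F * L / (Emod * A)
        assert np.allclose(uz_tip, expected, rtol=1e-9)
        # constant-strain patch: every element strain equals F/(EA)
        strains = element_strain_tensors(system, u)
        assert np.allclose(strains[:, 2, 2], F / (Emod * A), rtol=1e-9)

    def test_strains_scale_inversely_with_modulus(self, bar):
        coords, tets, E, system = bar
        pinned = np.flatnonzero(np.isclose(coords[:, 2], 0.0))
        f = _end_face_forces(coords, tets, 200.0, 100.0)
        u1 = solve_case(system, f, pinned)
        system2 = assemble_system(coords, tets, 2.0 * E, nu=0.3)
        u2 = solve_case(system2, f, pinned)
        s1 = element_strain_tensors(system, u1)
        s2 = element_strain_tensors(system2, u2)
        assert np.allclose(s2, 0.5 * s1, rtol=1e-9, atol=1e-16)


class TestStrainAveraging:
    def test_uniform_field_unchanged(self):
        centroids = np.random.default_rng(0).uniform(0, 10, (50, 3))
        T = np.tile(np.diag([0.002, -0.001, 0.0005]), (50, 1, 1))
        e1, e3 = averaged_principal_strains(T, centroids, centroids[:5], radius=3.0)
        assert np.allclose(e1, 0.002)
        assert np.allclose(e3, -0.001)

    def test_radius_zero_takes_nearest_element(self):
        centroids = np.array([[0.0, 0, 0], [10.0, 0, 0]])
        T = np.stack([np.diag([0.01, 0, 0]), np.diag([0.02, 0, 0])])
        pts = np.array([[1.0, 0, 0], [9.0, 0, 0]])
        e1, _ = averaged_principal_strains(T, centroids, pts, radius=0.0)
        assert e1[0] == pytest.approx(0.01)
        assert e1[1] == pytest.approx(0.02)

    def test_two_tensor_hand_average(self):
        A = np.array([[0.004, 0.001, 0.0], [0.001, -0.002, 0.0], [0.0, 0.0, 0.0]])
        B = np.array([[0.002, -0.001, 0.0], [-0.001, 0.0, 0.0], [0.0, 0.0, 0.001]])
        centroids = np.array([[0.0, 0, 0], [1.0, 0, 0]])
        pts = np.array([[0.5, 0.0, 0.0]])
        e1, e3 = averaged_principal_strains(
            np.stack([A, B]), centroids, pts, radius=2.0
        )
        expected = np.linalg.eigvalsh(0.5 * (A + B))
        assert e1[0] == pytest.approx(expected[2], rel=1e-12)
        assert e3[0] == pytest.approx(expected[0], rel=1e-12)


class TestFailureLoad:
    def test_dominant_tensile_node_hand_value(self):
        eps1 = np.array([0.001, 0.00365, 0.002])
        eps3 = np.array([-0.001, -0.001, -0.001])
        assert failure_load(eps1, eps3, 1000.0) == pytest.approx(2000.0)

    def test_node_exactly_at_limit(self):
        assert failure_load(
            np.array([0.0073]), np.array([-0.0001]), 1000.0
        ) == pytest.approx(1000.0)

    def test_tension_compression_tie(self):
        k = 2.0
        fl = failure_load(np.array([0.0073 * k]), np.array([-0.0104 * k]), 1000.0)
        assert fl == pytest.approx(1000.0 / k)

    def test_all_zero_strains_raise(self):
        with pytest.raises(ValueError, match="unloaded"):
            failure_load(np.zeros(4), np.zeros(4))

    def test_lowering_limits_never_increases_load(self):
        rng = np.random.default_rng(2)
        eps1 = rng.uniform(0, 0.01, 20)
        eps3 = -rng.uniform(0, 0.01, 20)
        base = failure_load(eps1, eps3, 1000.0, 0.0073, 0.0104)
        lower = failure_load(eps1, eps3, 1000.0, 0.0050, 0.0104)
        assert lower <= base


@pytest.fixture(scope="module")
def coarse_subject(coarse_template):
    geom = deform_instance(coarse_template)
    mats = assign_materials(
        coarse_template, geom, DensityParams(), np.random.default_rng(3)
    )
    return coarse_template, geom, mats


class TestFailureSurface:
    def test_msf_is_grid_minimum(self, coarse_subject):
        tpl, geom, mats = coarse_subject
        grid = failure_surface(
            geom.node_coords, tpl.tets, mats.young_modulus,
            geom.landmark_coords, tpl.surface_node_ids,
        )
        assert grid.loads.shape == (7, 4)
        assert np.all(grid.loads > 0)
        assert grid.msf == np.min(grid.loads)

    def test_modulus_doubling_doubles_every_entry(self, coarse_subject):
        tpl, geom, mats = coarse_subject
        g1 = failure_surface(
            geom.node_coords, tpl.tets, mats.young_modulus,
            geom.landmark_coords, tpl.surface_node_ids,
        )
        g2 = failure_surface(
            geom.node_coords, tpl.tets, 2.0 * mats.young_modulus,
            geom.landmark_coords, tpl.surface_node_ids,
        )
        assert np.allclose(g2.loads, 2.0 * g1.loads, rtol=1e-9)
        assert g2.msf == pytest.approx(2.0 * g1.msf, rel=1e-9)

    def test_failure_load_invariant_to_trial_magnitude(self, coarse_subject):
        tpl, geom, mats = coarse_subject
        g1000 = failure_surface(
            geom.node_coords, tpl.tets, mats.young_modulus,
            geom.landmark_coords, tpl.surface_node_ids,
            StrengthConfig(magnitude=1000.0),
        )
        g500 = failure_surface(
            geom.node_coords, tpl.tets, mats.young_modulus,
            geom.landmark_coords, tpl.surface_node_ids,
            StrengthConfig(magnitude=500.0),
        )
        assert np.allclose(g500.loads, g1000.loads, rtol=1e-9)

    def test_density_deficit_strictly_lowers_msf(self, coarse_template):
        geom = deform_instance(coarse_template)
        full = assign_materials(
            coarse_template, geom, DensityParams(deficit=1.0),
            np.random.default_rng(9),
        )
        reduced = assign_materials(
            coarse_template, geom, DensityParams(deficit=0.5),
            np.random.default_rng(9),
        )
        g_full = failure_surface(
            geom.node_coords, coarse_template.tets, full.young_modulus,
            geom.landmark_coords, coarse_template.surface_node_ids,
        )
        g_half = failure_surface(
            geom.node_coords, coarse_template.tets, reduced.young_modulus,
            geom.landmark_coords, coarse_template.surface_node_ids,
        )
        assert g_half.msf < g_full.msf
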