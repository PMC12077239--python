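"""FE verification: load direction, patch test, closed forms, equilibrium."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import mc3fe as m
from mc3fe.fe import ElasticModel, nodal_load_vector, solve_reduced

from conftest import bar_frame, bar_labels_image


def _bar_mesh(nx=4, ny=4, nz=8, spacing=0.5):
    labels, image = bar_labels_image(nx, ny, nz, spacing)
    mesh = m.voxels_to_tets(labels, image, fine_edge_mm=spacing, coarse_edge_mm=spacing)
    return mesh


class TestDirectionFromAngles:
    def test_experimental_60_30_lies_in_sagittal_plane(self):
        frame = bar_frame()
        d = m.direction_from_angles(60.0, 30.0, frame)
        # medial component zero; dorsal sin60; proximal sin30
        assert d @ frame.sagittal_normal == pytest.approx(0.0, abs=1e-12)
        assert d @ frame.frontal_normal == pytest.approx(np.sin(np.radians(60)), abs=1e-12)
        assert d @ frame.long_axis == pytest.approx(0.5, abs=1e-12)

    def test_zero_frontal_ninety_transverse_is_pure_long_axis(self):
        frame = bar_frame()
        d = m.direction_from_angles(0.0, 90.0, frame)
        assert np.allclose(d, frame.long_axis, atol=1e-12)

    def test_infeasible_angles_rejected(self):
        with pytest.raises(m.InfeasibleAnglesError):
            m.direction_from_angles(90.0, 30.0, bar_frame())

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(af=st.floats(0.0, 89.0), at=st.floats(0.0, 89.0))
    def test_unit_norm_for_feasible_angles(self, af, at):
        sf, st_ = np.sin(np.radians(af)), np.sin(np.radians(at))
        if sf**2 + st_**2 > 1.0:
            return
        d = m.direction_from_angles(af, at, bar_frame())
        assert np.linalg.norm(d) == pytest.approx(1.0, abs=1e-12)


class TestElasticModelBasics:
    def test_stiffness_symmetric_and_psd_on_free_dofs(self):
        mesh = _bar_mesh(2, 2, 4)
        model = ElasticModel(mesh, nu=0.3)
        k = model.assemble(np.full(mesh.n_tets, 1000.0))
        asym = abs(k - k.T).max()
        assert asym < 1e-9 * abs(k).max()
        # PSD after constraining one end
        bottom = np.flatnonzero(mesh.nodes[:, 2] < 0.01)
        fixed = (3 * bottom[:, None] + np.arange(3)).ravel()
        free = np.setdiff1d(np.arange(k.shape[0]), fixed)
        kff = k[free][:, free].toarray()
        evals = np.linalg.eigvalsh(kff)
        assert evals.min() > 0

    def test_unconstrained_system_rejected(self):
        mesh = _bar_mesh(2, 2, 4)
        model = ElasticModel(mesh)
        k = model.assemble(np.full(mesh.n_tets, 1000.0))
        with pytest.raises(m.ConstraintDeficiencyError):
            solve_reduced(k, np.zeros(k.shape[0]), np.array([], dtype=int))


class TestClosedFormSolutions:
    def test_patch_test_linear_field_reproduced_exactly(self):
        """Imposing a linear displacement field on the whole boundary must
        reproduce its constant strain state exactly (CST patch test)."""
        mesh = _bar_mesh(3, 3, 3)
        model = ElasticModel(mesh, nu=0.3)
        k = model.assemble(np.full(mesh.n_tets, 1234.0))
        grad = np.array([[1e-3, 2e-4, 0.0], [0.0, -5e-4, 1e-4], [3e-4, 0.0, 7e-4]])
        u_exact = mesh.nodes @ grad.T
        boundary = np.unique(mesh.surface_facets)
        fixed = (3 * boundary[:, None] + np.arange(3)).ravel()
        u = solve_reduced(k, np.zeros(k.shape[0]), fixed, fixed_values=u_exact[boundary].ravel())
        assert np.allclose(u.reshape(-1, 3), u_exact, atol=1e-12)
        strain = model.strains(u)
        sym = 0.5 * (grad + grad.T)
        expected = np.array(
            [sym[0, 0], sym[1, 1], sym[2, 2], 2 * sym[0, 1], 2 * sym[1, 2], 2 * sym[0, 2]]
        )
        assert np.allclose(strain, expected[None, :], atol=1e-12)

    def test_uniaxial_bar_strain_equals_stress_over_modulus(self):
        """nu=0 bar under uniform end traction: eps_z = sigma/E to 1e-8."""
        mesh = _bar_mesh(4, 4, 12)
        frame = bar_frame()
        z_top = mesh.nodes[:, 2].max()
        patch = m.LoadPatchSpec(center_mm=(0.75, 0.75, z_top), radius_mm=100.0,
                                direction=(0.0, 0.0, 1.0), min_normal_dot=0.99)
        strip = m.PsgStripSpec(point_mm=(0.75, 0.75, z_top), normal=(1.0, 0.0, 0.0))
        m.tag_boundary_sets(mesh, frame, strip, patch, strip_width_mm=100.0)
        area = 2.0 * 2.0
        sigma = 10.0  # MPa
        e_mod = 1000.0
        load = m.LoadCase(total_force_n=sigma * area, angle_to_frontal_deg=0.0,
                          angle_to_transverse_deg=90.0, distribution="area-weighted")
        model = ElasticModel(mesh, nu=0.0)
        k = model.assemble(np.full(mesh.n_tets, e_mod))
        f = nodal_load_vector(mesh, load, frame)
        bottom = np.flatnonzero(mesh.nodes[:, 2] < 0.01)
        fixed = (3 * bottom[:, None] + np.arange(3)).ravel()
        u = solve_reduced(k, f, fixed)
        strain = model.strains(u)
        # load direction is the long axis = -z, so compression of -sigma/E
        assert np.allclose(strain[:, 2], -sigma / e_mod, atol=1e-8)

    def test_poisson_contraction_recovered(self):
        """Uniaxial stress with nu=0.3: lateral/axial strain = -0.3."""
        mesh = _bar_mesh(4, 4, 12)
        model = ElasticModel(mesh, nu=0.3)
        e_mod = 1000.0
        k = model.assemble(np.full(mesh.n_tets, e_mod))
        # uniform tensile traction sigma on the top face (+z), applied as
        # consistent nodal forces assembled by facet
        sigma = 10.0
        z_top = mesh.nodes[:, 2].max()
        top = np.flatnonzero(
            np.abs(mesh.facet_centroids()[:, 2] - z_top) < 1e-9
        )
        f = np.zeros((mesh.n_nodes, 3))
        _, areas = mesh.facet_normals_areas()
        for fi in top:
            f[mesh.surface_facets[fi], 2] += sigma * areas[fi] / 3.0
        # constraints compatible with a homogeneous strain field
        nodes = mesh.nodes
        bottom = np.flatnonzero(nodes[:, 2] < 1e-9)
        fixed = [3 * b + 2 for b in bottom]  # uz = 0 on bottom plane
        a_node = bottom[np.lexsort((nodes[bottom, 1], nodes[bottom, 0]))[0]]
        b_cands = bottom[np.abs(nodes[bottom, 1] - nodes[a_node, 1]) < 1e-9]
        b_node = b_cands[np.argmax(np.abs(nodes[b_cands, 0] - nodes[a_node, 0]))]
        fixed += [3 * a_node, 3 * a_node + 1, 3 * b_node + 1]
        u = solve_reduced(k, f.ravel(), np.array(fixed))
        strain = model.strains(u)
        axial = strain[:, 2]
        lateral = strain[:, 0]
        assert np.allclose(axial, sigma / e_mod, atol=1e-10)
        assert np.allclose(lateral / axial, -0.3, atol=1e-6)

    def test_dense_direct_oracle_agreement(self):
        """Sparse solution path agrees with a dense direct solve to 1e-8."""
        mesh = _bar_mesh(2, 2, 4)  # well under 500 free DOFs
        model = ElasticModel(mesh, nu=0.3)
        k = model.assemble(np.linspace(500.0, 5000.0, mesh.n_tets))
        rng = np.random.default_rng(3)
        f = rng.normal(0, 1.0, k.shape[0])
        bottom = np.flatnonzero(mesh.nodes[:, 2] < 0.01)
        fixed = (3 * bottom[:, None] + np.arange(3)).ravel()
        free = np.setdiff1d(np.arange(k.shape[0]), fixed)
        assert free.size <= 500
        u_sparse = solve_reduced(k, f, fixed, method="direct")
        u_cg = solve_reduced(k, f, fixed, method="cg")
        u_dense = np.zeros(k.shape[0])
        u_dense[free] = np.linalg.solve(k[free][:, free].toarray(), f[free])
        assert np.abs(u_sparse - u_dense).max() <= 1e-8
        assert np.abs(u_cg - u_dense).max() <= 1e-8


@pytest.fixture(scope="module")
def solved_bar():
    mesh = _bar_mesh(4, 4, 8)
    frame = bar_frame()
    z_top = mesh.nodes[:, 2].max()
    patch = m.LoadPatchSpec(center_mm=(0.75, 0.75, z_top), radius_mm=100.0,
                            direction=(0.0, 0.0, 1.0), min_normal_dot=0.99)
    strip = m.PsgStripSpec(point_mm=(0.75, 0.75, z_top), normal=(1.0, 0.0, 0.0))
    m.tag_boundary_sets(mesh, frame, strip, patch, strip_width_mm=1.0)
    youngs = np.full(mesh.n_tets, 2000.0)
    load = m.LoadCase(total_force_n=100.0)
    field = m.assemble_and_solve(mesh, youngs, frame, load)
    return mesh, frame, youngs, load, field


class TestLinearityAndSummary:
    def test_doubling_load_doubles_psg_summary(self, solved_bar):
        mesh, frame, youngs, load, field = solved_bar
        double = m.LoadCase(total_force_n=200.0)
        f2 = m.assemble_and_solve(mesh, youngs, frame, double)
        s1 = m.psg_summary(field, mesh).mean_max_principal
        s2 = m.psg_summary(f2, mesh).mean_max_principal
        assert s2 == pytest.approx(2.0 * s1, rel=1e-9)

    def test_uniform_modulus_scaling_inversely_scales_displacements(self, solved_bar):
        mesh, frame, youngs, load, field = solved_bar
        f2 = m.assemble_and_solve(mesh, 2.0 * youngs, frame, load)
        assert np.allclose(f2.displacements, 0.5 * field.displacements, atol=1e-12)

    def test_principal_strains_are_eigenvalues_sorted_descending(self, solved_bar):
        mesh, frame, youngs, load, field = solved_bar
        p = field.element_principal
        assert np.all(np.diff(p, axis=1) <= 1e-15)
        e = field.element_strain
        tr_tensor = e[:, 0] + e[:, 1] + e[:, 2]
        assert np.allclose(p.sum(axis=1), tr_tensor, atol=1e-12)

    def test_psg_summary_of_constant_field_is_that_constant(self, solved_bar):
        mesh, frame, youngs, load, field = solved_bar
        const = m.StrainField(
            displacements=field.displacements,
            element_strain=field.element_strain,
            element_principal=field.element_principal,
            surface_max_principal=np.full(mesh.surface_facets.shape[0], 0.01),
        )
        assert m.psg_summary(const, mesh).mean_max_principal == pytest.approx(0.01, abs=1e-15)

    def test_equilibrium_of_reactions(self, solved_bar):
        mesh, frame, youngs, load, field = solved_bar
        model = ElasticModel(mesh, nu=0.3)
        k = model.assemble(youngs)
        f = nodal_load_vector(mesh, load, frame)
        r = k @ field.displacements.ravel() - f
        fixed_nodes = mesh.node_sets["PROXIMAL_FIXED"]
        reactions = r.reshape(-1, 3)[fixed_nodes].sum(axis=0)
        applied = load.total_force_n * m.direction_from_angles(
            load.angle_to_frontal_deg, load.angle_to_transverse_deg, frame
        )
        assert np.allclose(reactions, -applied, rtol=1e-6, atol=1e-6 * load.total_force_n)


class TestConvergenceStudyValidation:
    def test_single_entry_rejected(self, small_phantom):
        with pytest.raises(m.InvalidInputError):
            m.convergence_study(
                small_phantom.labels,
                small_phantom.image,
                small_phantom.frame,
                small_phantom.psg_strip_spec,
                small_phantom.load_patch_spec,
                edge_schedule=[(1.0, 1.0)],
            )

    def test_non_monotone_schedule_rejected(self, small_phantom):
        with pytest.raises(m.InvalidInputError):
            m.convergence_study(
                small_phantom.labels,
                small_phantom.image,
                small_phantom.frame,
                small_phantom.psg_strip_spec,
                small_phantom.load_patch_spec,
                edge_schedule=[(0.5, 1.0), (1.0, 2.0)],
            )

    def test_repeated_level_gives_zero_relative_change(self, small_phantom):
        df = m.convergence_study(
            small_phantom.labels,
            small_phantom.image,
            small_phantom.frame,
            small_phantom.psg_strip_spec,
            small_phantom.load_patch_spec,
            edge_schedule=[(1.0, 1.0), (1.0, 1.0)],
        )
        assert df["rel_change_vs_finest"].iloc[0] == pytest.approx(0.0, abs=1e-12)
        assert df["n_elements"].iloc[0] == df["n_elements"].iloc[1]
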