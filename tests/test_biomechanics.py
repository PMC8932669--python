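import numpy as np
import pytest

from jawscape import (
    BoundaryCondition,
    MaterialModel,
    Outline,
    fit_quadratic_surface,
    identify_landmarks,
    monte_carlo_performance,
    randomize_bcs,
    rotational_efficiency,
    solve_cst,
    solve_cst_fea,
    triangulate,
)
from jawscape.biomechanics import LandmarkError, _FEAContext
from jawscape.meshing import TriMesh


@pytest.fixture(scope="module")
def rect_mesh():
    rect = Outline(np.array([[0.0, 0.0], [4.0, 0.0], [4.0, 1.0], [0.0, 1.0]]))
    return triangulate(rect, 600)


def _rotated_mesh(mesh, deg):
    a = np.radians(deg)
    r = np.array([[np.cos(a), -np.sin(a)], [np.sin(a), np.cos(a)]])
    return TriMesh(mesh.nodes @ r.T, mesh.elements, mesh.boundary_ring)


class TestLandmarks:
    def test_rectangle_top_edge_ends(self, rect_mesh):
        joint, bite = identify_landmarks(rect_mesh)
        jp, bp = rect_mesh.nodes[joint], rect_mesh.nodes[bite]
        assert np.isclose(jp[1], 1.0) and np.isclose(bp[1], 1.0)  # top edge
        assert jp[0] < 0.5 and bp[0] > 3.5  # near left / right ends

    def test_circle_sixty_degree_sector(self):
        t = np.linspace(0.0, 2.0 * np.pi, 400, endpoint=False)
        circ = Outline(np.column_stack([np.cos(t), np.sin(t)]))
        mesh = triangulate(circ, 500)
        joint, bite = identify_landmarks(mesh, vertical_tolerance_deg=30.0)
        # radial normals: qualifying nodes have polar angle in [60, 120] deg
        for node, target in ((joint, 120.0), (bite, 60.0)):
            ang = np.degrees(np.arctan2(*mesh.nodes[node][::-1]))
            assert abs(ang - target) < 5.0

    def test_orientation_dependence(self, rect_mesh):
        rot = _rotated_mesh(rect_mesh, 90.0)
        joint, bite = identify_landmarks(rot)
        sep = np.linalg.norm(rot.nodes[bite] - rot.nodes[joint])
        # after rotation the near-vertical margin is a short side
        assert sep < 2.0

    def test_failure_when_no_vertical_normal(self, rect_mesh):
        # rotate 20 deg: edge normals sit 20 deg off vertical, corner normals
        # 25 deg off, so a 10 deg tolerance leaves no qualifying node
        rot = _rotated_mesh(rect_mesh, 20.0)
        with pytest.raises(LandmarkError):
            identify_landmarks(rot, vertical_tolerance_deg=10.0)


class TestRotationalEfficiency:
    def test_rectangle_analytic(self):
        rect = Outline(np.array([[0, -0.125], [4, -0.125], [4, 0.125], [0, 0.125]], dtype=float))
        mesh = triangulate(rect, 2000)
        joint = int(np.argmin(np.linalg.norm(mesh.nodes - [0.0, 0.0], axis=1)))
        bite = int(np.argmin(np.linalg.norm(mesh.nodes - [4.0, 0.0], axis=1)))
        inertia = 4.0**2 / 3.0 + 0.25**2 / 12.0  # rectangle about edge midpoint
        expected = 4.0 * np.sqrt(2.0 / inertia)
        got = rotational_efficiency(mesh, joint, bite)
        assert abs(got - expected) < 0.005 * expected

    def test_rigid_motion_invariance(self, jaw_mesh):
        joint, bite = identify_landmarks(jaw_mesh)
        ref = rotational_efficiency(jaw_mesh, joint, bite)
        moved = _rotated_mesh(jaw_mesh.translated(2.0, -1.0), 33.0)
        assert abs(rotational_efficiency(moved, joint, bite) - ref) < 1e-9

    def test_density_scaling_law(self, jaw_mesh):
        joint, bite = identify_landmarks(jaw_mesh)
        r1 = rotational_efficiency(jaw_mesh, joint, bite, density=1.0)
        r2 = rotational_efficiency(jaw_mesh, joint, bite, density=2.0)
        assert abs(r2 - r1 / np.sqrt(2.0)) < 1e-12

    def test_coincident_landmarks_rejected(self, jaw_mesh):
        with pytest.raises(ValueError):
            rotational_efficiency(jaw_mesh, 0, 0)


def _uniaxial_loads(mesh, sigma):
    """Consistent nodal tractions +/-sigma on the x = max/min edges."""
    ring = mesh.boundary_ring
    pts = mesh.nodes[ring]
    loads = np.zeros(2 * len(mesh.nodes))
    for xval, sgn in ((pts[:, 0].max(), 1.0), (pts[:, 0].min(), -1.0)):
        sel = np.flatnonzero(np.isclose(pts[:, 0], xval))
        order = sorted(sel, key=lambda i: pts[i, 1])
        for a, b in zip(order[:-1], order[1:]):
            ell = abs(pts[b, 1] - pts[a, 1])
            for i in (a, b):
                loads[2 * ring[i]] += sgn * sigma * ell / 2.0
    return loads


class TestCSTSolver:
    def test_constant_stress_patch(self):
        rect = Outline(np.array([[0.0, 0.0], [2.0, 0.0], [2.0, 1.0], [0.0, 1.0]]))
        mesh = triangulate(rect, 400)
        mat = MaterialModel(young_modulus=1000.0, poisson_ratio=0.3)
        sigma = 5.0
        loads = _uniaxial_loads(mesh, sigma)
        n00 = int(np.argmin(np.linalg.norm(mesh.nodes - [0, 0], axis=1)))
        n01 = int(np.argmin(np.linalg.norm(mesh.nodes - [0, 1], axis=1)))
        res = solve_cst(mesh, mat, [(n00, 0), (n00, 1), (n01, 0)], loads)
        assert np.abs(res.element_stress[:, 0] - sigma).max() < 1e-6 * sigma
        assert np.abs(res.element_stress[:, 1:]).max() < 1e-6 * sigma
        assert np.abs(res.element_vms - sigma).max() < 1e-6 * sigma

    def test_zero_load_zero_response(self, jaw_mesh):
        joint, bite = identify_landmarks(jaw_mesh)
        res = solve_cst(
            jaw_mesh, MaterialModel(), [(joint, 0), (joint, 1), (bite, 1)],
            np.zeros(2 * len(jaw_mesh.nodes)),
        )
        assert np.allclose(res.nodal_displacements, 0.0)
        assert np.allclose(res.element_vms, 0.0)
        assert res.median_vms == 0.0

    def test_cantilever_beam_theory(self):
        length, width, load, e_mod = 10.0, 1.0, 1.0, 1000.0
        beam = Outline(
            np.array([[0, -width / 2], [length, -width / 2], [length, width / 2], [0, width / 2]])
        )
        mesh = triangulate(beam, 2500)
        ring = mesh.boundary_ring
        pts = mesh.nodes[ring]
        fixed = [
            (int(ring[i]), d)
            for i in np.flatnonzero(np.isclose(pts[:, 0], 0.0))
            for d in (0, 1)
        ]
        tip = int(np.argmin(np.linalg.norm(mesh.nodes - [length, 0.0], axis=1)))
        loads = np.zeros(2 * len(mesh.nodes))
        loads[2 * tip + 1] = -load
        res = solve_cst(mesh, MaterialModel(young_modulus=e_mod, poisson_ratio=0.0), fixed, loads)
        beam_i = width**3 / 12.0
        expected = -load * length**3 / (3.0 * e_mod * beam_i)
        got = res.nodal_displacements[tip, 1]
        assert abs(got - expected) < 0.10 * abs(expected)

    def test_force_linearity_exact(self, jaw_mesh):
        joint, bite = identify_landmarks(jaw_mesh)
        ctx = _FEAContext(jaw_mesh, MaterialModel(), [(joint, 0), (joint, 1), (bite, 1)])
        loads = np.zeros(ctx.ndof)
        force_node = int(jaw_mesh.boundary_ring[len(jaw_mesh.boundary_ring) // 2])
        loads[2 * force_node + 1] = 1.0
        r1 = ctx.solve(loads)
        r3 = ctx.solve(3.0 * loads)
        assert np.allclose(r3.element_stress, 3.0 * r1.element_stress, rtol=1e-12)
        assert np.allclose(r3.element_vms, 3.0 * r1.element_vms, rtol=1e-12)

    def test_median_vms_invariant_to_node_relabelling(self, jaw_mesh):
        joint, bite = identify_landmarks(jaw_mesh)
        base = identify_landmarks(jaw_mesh)
        bc_nodes = (joint, bite)
        n = len(jaw_mesh.nodes)
        rng = np.random.default_rng(5)
        perm = rng.permutation(n)
        inv = np.empty(n, dtype=np.int64)
        inv[perm] = np.arange(n)
        relabeled = TriMesh(jaw_mesh.nodes[perm], inv[jaw_mesh.elements], inv[jaw_mesh.boundary_ring])
        force_node = int(jaw_mesh.boundary_ring[len(jaw_mesh.boundary_ring) // 3])
        loads = np.zeros(2 * n)
        loads[2 * force_node + 1] = -1.0
        res = solve_cst(jaw_mesh, MaterialModel(), [(joint, 0), (joint, 1), (bite, 1)], loads)
        loads_p = np.zeros(2 * n)
        loads_p[2 * inv[force_node] + 1] = -1.0
        res_p = solve_cst(
            relabeled, MaterialModel(),
            [(int(inv[joint]), 0), (int(inv[joint]), 1), (int(inv[bite]), 1)], loads_p,
        )
        assert abs(res.median_vms - res_p.median_vms) < 1e-6 * res.median_vms

    def test_insufficient_constraints_raise(self, jaw_mesh):
        from jawscape.biomechanics import RigidBodyModeError

        loads = np.zeros(2 * len(jaw_mesh.nodes))
        loads[3] = 1.0
        with pytest.raises(RigidBodyModeError):
            solve_cst(jaw_mesh, MaterialModel(), [(0, 0)], loads)


class TestRandomizedBCs:
    def test_degenerate_windows_reproduce_base(self, jaw_mesh):
        base = identify_landmarks(jaw_mesh)
        rng = np.random.default_rng(0)
        jp, bp = randomize_bcs(jaw_mesh, base, 0.0, 0.0, "re", rng)
        assert np.allclose(jp, jaw_mesh.nodes[base[0]], atol=1e-9)
        assert np.allclose(bp, jaw_mesh.nodes[base[1]], atol=1e-9)
        bc = randomize_bcs(jaw_mesh, base, 0.0, 0.0, "vms", rng)
        assert (bc.joint_node, bc.bite_node) == base
        assert abs(np.hypot(*bc.force_vector) - 1.0) < 1e-12

    def test_support_bounds(self, jaw_mesh):
        base = identify_landmarks(jaw_mesh)
        rng = np.random.default_rng(1)
        _, normals, cum = __import__("jawscape.biomechanics", fromlist=["x"])._ring_geometry(jaw_mesh)
        perim = cum[-1]
        ring_pos = {int(n): cum[i] for i, n in enumerate(jaw_mesh.boundary_ring)}
        for _ in range(2000):
            bc = randomize_bcs(jaw_mesh, base, 0.05, 45.0, "vms", rng)
            fi = list(jaw_mesh.boundary_ring).index(bc.force_node)
            nx, ny = normals[fi]
            ang = np.degrees(
                np.arccos(np.clip(bc.force_vector[0] * nx + bc.force_vector[1] * ny, -1, 1))
            )
            assert ang <= 45.0 + 1e-6
        for _ in range(500):
            jp, bp = randomize_bcs(jaw_mesh, base, 0.05, 0.0, "re", rng)
            dj = min(np.hypot(*(jp - jaw_mesh.nodes[base[0]])), perim)
            assert dj <= 0.05 * perim + 1e-9  # chord <= arc offset

    def test_seeded_determinism(self, jaw_mesh):
        base = identify_landmarks(jaw_mesh)
        a = randomize_bcs(jaw_mesh, base, 0.05, 45.0, "vms", np.random.default_rng(7))
        b = randomize_bcs(jaw_mesh, base, 0.05, 45.0, "vms", np.random.default_rng(7))
        assert a == b


class TestMonteCarlo:
    def test_single_replicate_degenerate_stats(self, jaw_mesh):
        rec = monte_carlo_performance(jaw_mesh, n_replicates=1, seed=0)
        assert rec.re_mean == rec.re_p5 == rec.re_p95
        assert rec.vms_mean == rec.vms_p5 == rec.vms_p95

    def test_zero_windows_zero_spread(self, jaw_mesh):
        rec = monte_carlo_performance(
            jaw_mesh, n_replicates=100, seed=0, window_fraction=0.0, angle_window_deg=0.0
        )
        assert rec.re_p5 == rec.re_p95
        assert rec.vms_p5 == rec.vms_p95
        assert np.isclose(rec.re_mean, rec.re_p5, rtol=1e-12)
        assert np.isclose(rec.vms_mean, rec.vms_p5, rtol=1e-12)

    def test_seeded_determinism(self, jaw_mesh):
        a = monte_carlo_performance(jaw_mesh, n_replicates=50, seed=11)
        b = monte_carlo_performance(jaw_mesh, n_replicates=50, seed=11)
        assert a == b

    def test_percentiles_bracket_mean(self, jaw_mesh):
        rec = monte_carlo_performance(jaw_mesh, n_replicates=200, seed=2)
        assert rec.re_p5 <= rec.re_mean <= rec.re_p95
        assert rec.vms_p5 <= rec.vms_mean <= rec.vms_p95
        assert rec.re_p5 > 0 and rec.vms_p5 >= 0

    def test_longer_shallower_jaw_rotates_faster(self, jaw_family):
        # straight-dorsal family: speed falls as jaws get shorter and deeper
        from jawscape import SyntheticJawParams, generate_jaw_outline, standardize_area

        res = []
        for ratio in (5.5, 3.0):
            out = standardize_area(
                generate_jaw_outline(SyntheticJawParams(ratio, 0.0, 0.3, 0.0), seed=3)
            )
            mesh = triangulate(out, 800)
            joint, bite = identify_landmarks(mesh)
            res.append(rotational_efficiency(mesh, joint, bite))
        assert res[0] > res[1]


class TestQuadraticSurface:
    def test_exact_plane_with_cross_term(self):
        rng = np.random.default_rng(0)
        coords = rng.uniform(-1, 1, size=(40, 2))
        z = 1 + 2 * coords[:, 0] - coords[:, 1] + coords[:, 0] * coords[:, 1]
        fit = fit_quadratic_surface(coords, z)
        assert fit.sse < 1e-18
        assert abs(fit.r_squared - 1.0) < 1e-12

    def test_recovers_hyperbolic_paraboloid(self):
        u, v = np.meshgrid(np.linspace(-1, 1, 9), np.linspace(-1, 1, 9))
        coords = np.column_stack([u.ravel(), v.ravel()])
        z = coords[:, 0] ** 2 - coords[:, 1] ** 2
        fit = fit_quadratic_surface(coords, z)
        assert np.allclose(fit.coefficients, [0, 0, 0, 1, 0, -1], atol=1e-9)

    def test_noise_degrades_fit(self):
        rng = np.random.default_rng(3)
        coords = rng.uniform(-1, 1, size=(60, 2))
        z = coords[:, 0] ** 2 + rng.normal(0, 0.3, 60)
        fit = fit_quadratic_surface(coords, z)
        assert fit.r_squared < 1.0
        assert fit.adj_r_squared <= fit.r_squared
        assert np.isclose(fit.rmse, np.sqrt(fit.sse / 60))

    def test_rank_deficient_rejected(self):
        coords = np.column_stack([np.linspace(0, 1, 10), np.linspace(0, 1, 10)])
        with pytest.raises(ValueError):
            fit_quadratic_surface(coords, np.ones(10))
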