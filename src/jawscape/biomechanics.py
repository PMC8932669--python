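"""Rotational efficiency and plane-stress CST finite element analysis.

Two performance metrics are computed per jaw shape:

* **Rotational efficiency (RE)** — the speed of the bite point when the jaw
  rotates about its joint with one unit of rotational kinetic energy:
  ``E = I w^2 / 2 = 1  =>  w = sqrt(2 / I)`` and ``RE = v = L sqrt(2 / I)``,
  with ``L`` the joint-to-bite distance and ``I = sum_i m_i r_i^2`` the
  moment of inertia of the meshed jaw about the joint (``m_i`` = element
  mass, ``r_i`` = element centroid distance to the joint).  A proxy for
  speed of jaw closure.

* **Median von Mises stress (VMS)** — from a linear elastic plane-stress
  constant-strain-triangle (CST) solution of the jaw loaded by a unit
  muscle force and fixed at the joint (x and y) and bite point (y only).
  The median over elements is robust to the stress singularities at the
  constraints; lower median VMS reads as higher strength.

Boundary-condition uncertainty is propagated by Monte Carlo: joint/bite
positions slide along the outline (for RE) and the muscle force node and
direction are perturbed (for VMS), following uniform windows of 5% of the
outline length and +/-45 degrees about the local outward normal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix, csc_matrix
from scipy.sparse.linalg import splu

from .meshing import TriMesh, triangulate

__all__ = [
    "MaterialModel",
    "BoundaryCondition",
    "FEAResult",
    "PerformanceRecord",
    "QuadraticSurfaceFit",
    "identify_landmarks",
    "rotational_efficiency",
    "solve_cst",
    "solve_cst_fea",
    "randomize_bcs",
    "monte_carlo_performance",
    "grid_performance",
    "fit_quadratic_surface",
    "LandmarkError",
    "RigidBodyModeError",
]


class LandmarkError(ValueError):
    """No boundary node satisfies the near-vertical-normal criterion."""


class RigidBodyModeError(RuntimeError):
    """The constrained stiffness system is singular (rigid modes remain)."""


@dataclass(frozen=True)
class MaterialModel:
    """Linear elastic thin plate. Defaults: cortical-bone-like stiffness."""

    young_modulus: float = 2.0e9  # Pa
    poisson_ratio: float = 0.3
    thickness: float = 1.0
    density: float = 1.0

    def __post_init__(self) -> None:
        if self.young_modulus <= 0:
            raise ValueError("young_modulus must be positive")
        if not 0.0 <= self.poisson_ratio < 0.5:
            raise ValueError("poisson_ratio must be in [0, 0.5)")

    @property
    def d_matrix(self) -> np.ndarray:
        """Plane-stress constitutive matrix."""
        e, nu = self.young_modulus, self.poisson_ratio
        return (e / (1.0 - nu**2)) * np.array(
            [[1.0, nu, 0.0], [nu, 1.0, 0.0], [0.0, 0.0, (1.0 - nu) / 2.0]]
        )


@dataclass(frozen=True)
class BoundaryCondition:
    """Jaw loading case: joint fixed (x, y), bite fixed (y), unit force."""

    joint_node: int
    bite_node: int
    force_node: int
    force_vector: tuple[float, float]

    def __post_init__(self) -> None:
        if len({self.joint_node, self.bite_node, self.force_node}) != 3:
            raise ValueError("joint, bite and force nodes must be distinct")
        f = np.asarray(self.force_vector, dtype=float)
        if abs(np.hypot(*f) - 1.0) > 1e-12:
            raise ValueError("force_vector must have unit magnitude")


@dataclass(frozen=True)
class FEAResult:
    nodal_displacements: np.ndarray  # (n_nodes, 2)
    element_stress: np.ndarray  # (n_elements, 3): sigma_x, sigma_y, tau_xy
    element_vms: np.ndarray

    @property
    def median_vms(self) -> float:
        return float(np.median(self.element_vms))


@dataclass(frozen=True)
class PerformanceRecord:
    """Monte-Carlo summary of one shape's RE and median-VMS distributions."""

    re_mean: float
    re_p5: float
    re_p95: float
    vms_mean: float
    vms_p5: float
    vms_p95: float
    n_replicates: int
    seed: int | None = None


# ---------------------------------------------------------------------------
# landmarks and boundary parametrization
# ---------------------------------------------------------------------------

def _ring_geometry(mesh: TriMesh):
    """Ring points, per-node outward normals, cumulative arc lengths."""
    pts = mesh.nodes[mesh.boundary_ring]
    nxt = np.roll(pts, -1, axis=0)
    seg = nxt - pts
    seglen = np.hypot(seg[:, 0], seg[:, 1])
    tang = seg / seglen[:, None]
    edge_norm = np.column_stack([tang[:, 1], -tang[:, 0]])  # outward for CCW
    node_norm = edge_norm + np.roll(edge_norm, 1, axis=0)
    node_norm /= np.linalg.norm(node_norm, axis=1, keepdims=True)
    cum = np.concatenate([[0.0], np.cumsum(seglen)])
    return pts, node_norm, cum  # cum[-1] = perimeter


def identify_landmarks(mesh: TriMesh, vertical_tolerance_deg: float = 30.0) -> tuple[int, int]:
    """Initial joint and bite nodes from the near-vertical-normal rule.

    Among boundary nodes whose outward normal lies within the tolerance of
    +y (the dorsal direction in the canonical frame), the joint is the
    posterior-most (minimum x) and the bite point the anterior-most
    (maximum x).  Node indices refer to mesh nodes.
    """
    pts, normals, _ = _ring_geometry(mesh)
    ok = normals[:, 1] >= np.cos(np.radians(vertical_tolerance_deg))
    if not np.any(ok):
        raise LandmarkError("no boundary node has a near-vertical outward normal")
    cand = np.flatnonzero(ok)
    joint = cand[np.argmin(pts[cand, 0])]
    bite = cand[np.argmax(pts[cand, 0])]
    if joint == bite:
        raise LandmarkError("joint and bite landmarks coincide")
    return int(mesh.boundary_ring[joint]), int(mesh.boundary_ring[bite])


def _point_at_arc(pts: np.ndarray, cum: np.ndarray, s: float) -> np.ndarray:
    perim = cum[-1]
    s = s % perim
    i = int(np.searchsorted(cum, s, side="right") - 1)
    i = min(i, len(pts) - 1)
    nxt = pts[(i + 1) % len(pts)]
    seg = cum[i + 1] - cum[i]
    f = (s - cum[i]) / seg if seg > 0 else 0.0
    return pts[i] + f * (nxt - pts[i])


def _ring_index_at_arc(cum: np.ndarray, s: float, n: int) -> int:
    """Nearest ring node (by arc distance) to arc position ``s``."""
    perim = cum[-1]
    s = s % perim
    i = int(np.searchsorted(cum, s, side="right") - 1)
    i = min(i, n - 1)
    left, right = cum[i], cum[i + 1]
    return i if (s - left) <= (right - s) else (i + 1) % n


def rotational_efficiency(mesh: TriMesh, joint, bite, density: float = 1.0) -> float:
    """RE = L * sqrt(2 / I) about the joint (see module docstring).

    ``joint`` and ``bite`` may be node indices or (x, y) points on the
    boundary (Monte-Carlo draws slide them along the outline, off-node).
    """
    jp = mesh.nodes[joint] if np.isscalar(joint) else np.asarray(joint, dtype=float)
    bp = mesh.nodes[bite] if np.isscalar(bite) else np.asarray(bite, dtype=float)
    length = float(np.hypot(*(bp - jp)))
    if length == 0:
        raise ValueError("joint and bite positions coincide")
    masses = density * mesh.element_areas
    total = masses.sum()
    if total <= 0:
        raise ValueError("zero-mass mesh")
    r2 = np.sum((mesh.element_centroids - jp) ** 2, axis=1)
    inertia = float(np.sum(masses * r2))
    return length * np.sqrt(2.0 / inertia)


# ---------------------------------------------------------------------------
# CST plane-stress solver
# ---------------------------------------------------------------------------

def _element_b_matrices(mesh: TriMesh) -> tuple[np.ndarray, np.ndarray]:
    """Strain-displacement matrices B (m, 3, 6) and areas (m,)."""
    p = mesh.nodes[mesh.elements]  # (m, 3, 2)
    x, y = p[..., 0], p[..., 1]
    b = np.stack([y[:, 1] - y[:, 2], y[:, 2] - y[:, 0], y[:, 0] - y[:, 1]], axis=1)
    c = np.stack([x[:, 2] - x[:, 1], x[:, 0] - x[:, 2], x[:, 1] - x[:, 0]], axis=1)
    area2 = x[:, 0] * b[:, 0] + x[:, 1] * b[:, 1] + x[:, 2] * b[:, 2]
    m = mesh.n_elements
    bm = np.zeros((m, 3, 6))
    for k in range(3):
        bm[:, 0, 2 * k] = b[:, k]
        bm[:, 1, 2 * k + 1] = c[:, k]
        bm[:, 2, 2 * k] = c[:, k]
        bm[:, 2, 2 * k + 1] = b[:, k]
    bm /= area2[:, None, None]
    return bm, area2 / 2.0


def _assemble_stiffness(mesh: TriMesh, material: MaterialModel) -> csc_matrix:
    bm, areas = _element_b_matrices(mesh)
    d = material.d_matrix
    ke = material.thickness * areas[:, None, None] * np.einsum(
        "eij,jk,ekl->eil", bm.transpose(0, 2, 1), d, bm
    )
    dof = np.empty((mesh.n_elements, 6), dtype=np.int64)
    dof[:, 0::2] = 2 * mesh.elements
    dof[:, 1::2] = 2 * mesh.elements + 1
    rows = np.repeat(dof, 6, axis=1).ravel()
    cols = np.tile(dof, (1, 6)).ravel()
    ndof = 2 * mesh.nodes.shape[0]
    return coo_matrix((ke.ravel(), (rows, cols)), shape=(ndof, ndof)).tocsc()


class _FEAContext:
    """Factorized stiffness for one mesh + constraint set; reusable RHS solves."""

    def __init__(self, mesh: TriMesh, material: MaterialModel, fixed_dofs):
        self.mesh = mesh
        self.material = material
        self.bm, self.areas = _element_b_matrices(mesh)
        self.d = material.d_matrix
        ndof = 2 * mesh.nodes.shape[0]
        fixed = sorted({2 * node + comp for node, comp in fixed_dofs})
        if any(f < 0 or f >= ndof for f in fixed):
            raise ValueError("fixed DOF out of range")
        self.free = np.setdiff1d(np.arange(ndof), fixed)
        k = _assemble_stiffness(mesh, material)
        kff = k[np.ix_(self.free, self.free)].tocsc()
        try:
            self.lu = splu(kff)
        except RuntimeError as err:
            raise RigidBodyModeError(f"singular stiffness system: {err}") from err
        diag = self.lu.U.diagonal()
        if np.min(np.abs(diag)) < 1e-12 * np.max(np.abs(diag)):
            raise RigidBodyModeError("singular stiffness system: unconstrained rigid mode")
        self.ndof = ndof

    def solve(self, loads: np.ndarray) -> FEAResult:
        """``loads``: (ndof,) or (ndof, k) global force vector(s)."""
        loads = np.asarray(loads, dtype=float)
        single = loads.ndim == 1
        f = loads.reshape(self.ndof, -1)
        u = np.zeros_like(f)
        u[self.free] = self.lu.solve(f[self.free])
        if single:
            return self._postprocess(u[:, 0])
        return [self._postprocess(u[:, i]) for i in range(u.shape[1])]

    def median_vms_batch(self, loads: np.ndarray, chunk: int = 200) -> np.ndarray:
        """Median element VMS for many load cases at once (memory-chunked)."""
        f = np.asarray(loads, dtype=float).reshape(self.ndof, -1)
        nrep = f.shape[1]
        out = np.empty(nrep)
        dof = np.empty((self.mesh.n_elements, 6), dtype=np.int64)
        dof[:, 0::2] = 2 * self.mesh.elements
        dof[:, 1::2] = 2 * self.mesh.elements + 1
        db = np.einsum("ij,ejk->eik", self.d, self.bm)  # (m, 3, 6)
        for start in range(0, nrep, chunk):
            u = np.zeros((self.ndof, min(chunk, nrep - start)))
            u[self.free] = self.lu.solve(f[self.free, start : start + u.shape[1]])
            ue = u[dof]  # (m, 6, k)
            stress = np.einsum("eis,esk->eik", db, ue)  # (m, 3, k)
            sx, sy, txy = stress[:, 0], stress[:, 1], stress[:, 2]
            vms = np.sqrt(sx**2 - sx * sy + sy**2 + 3.0 * txy**2)
            out[start : start + u.shape[1]] = np.median(vms, axis=0)
        return out

    def _postprocess(self, u: np.ndarray) -> FEAResult:
        dof = np.empty((self.mesh.n_elements, 6), dtype=np.int64)
        dof[:, 0::2] = 2 * self.mesh.elements
        dof[:, 1::2] = 2 * self.mesh.elements + 1
        ue = u[dof]
        strain = np.einsum("eij,ej->ei", self.bm, ue)
        stress = strain @ self.d.T
        sx, sy, txy = stress[:, 0], stress[:, 1], stress[:, 2]
        vms = np.sqrt(sx**2 - sx * sy + sy**2 + 3.0 * txy**2)
        return FEAResult(u.reshape(-1, 2), stress, vms)


def solve_cst(mesh: TriMesh, material: MaterialModel, fixed_dofs, loads) -> FEAResult:
    """General CST solve with explicit (node, component) constraints.

    ``fixed_dofs`` is an iterable of ``(node_index, component)`` with
    component 0 = x, 1 = y; ``loads`` is a dense (2*n_nodes,) force vector.
    """
    return _FEAContext(mesh, material, fixed_dofs).solve(np.asarray(loads, dtype=float))


def solve_cst_fea(mesh: TriMesh, material: MaterialModel, bc: BoundaryCondition) -> FEAResult:
    """Jaw load case: joint pinned, bite vertically supported, unit force."""
    fixed = [(bc.joint_node, 0), (bc.joint_node, 1), (bc.bite_node, 1)]
    loads = np.zeros(2 * mesh.nodes.shape[0])
    loads[2 * bc.force_node] = bc.force_vector[0]
    loads[2 * bc.force_node + 1] = bc.force_vector[1]
    return _FEAContext(mesh, material, fixed).solve(loads)


# ---------------------------------------------------------------------------
# randomized boundary conditions and Monte Carlo
# ---------------------------------------------------------------------------

def _dorsal_arc_span(mesh: TriMesh, joint_ring: int, bite_ring: int):
    """Arc interval from joint to bite along the dorsal (higher-y) path.

    Returns (s_start, signed_length): walking from the joint's arc position
    by f*signed_length, f in [0, 1], traces the dorsal boundary path.
    """
    pts, _, cum = _ring_geometry(mesh)
    perim = cum[-1]
    sj, sb = cum[joint_ring], cum[bite_ring]
    fwd_len = (sb - sj) % perim
    n_probe = 64
    f = (np.arange(n_probe) + 0.5) / n_probe
    fwd_y = np.mean([_point_at_arc(pts, cum, sj + fi * fwd_len)[1] for fi in f])
    bwd_len = fwd_len - perim  # negative: walk backwards
    bwd_y = np.mean([_point_at_arc(pts, cum, sj + fi * bwd_len)[1] for fi in f])
    return (sj, fwd_len) if fwd_y >= bwd_y else (sj, bwd_len)


def randomize_bcs(
    mesh: TriMesh,
    base: tuple[int, int],
    window_fraction: float = 0.05,
    angle_window_deg: float = 45.0,
    mode: str = "vms",
    rng: np.random.Generator | None = None,
    max_retries: int = 100,
):
    """Draw one randomized boundary-condition replicate.

    ``mode="re"`` returns perturbed (joint_xy, bite_xy) points, each slid
    along the boundary by a uniform offset within ``+/-window_fraction`` of
    the perimeter.  ``mode="vms"`` keeps joint/bite at the base nodes and
    returns a :class:`BoundaryCondition` whose force node starts one third
    of the way along the dorsal joint->bite path, slides within the same
    window, and whose unit force is the outward normal rotated by a uniform
    angle within ``+/-angle_window_deg``.
    """
    rng = np.random.default_rng() if rng is None else rng
    pts, normals, cum = _ring_geometry(mesh)
    perim = cum[-1]
    ring = list(mesh.boundary_ring)
    joint_ring, bite_ring = ring.index(base[0]), ring.index(base[1])
    if mode == "re":
        dj = rng.uniform(-window_fraction, window_fraction) * perim
        db = rng.uniform(-window_fraction, window_fraction) * perim
        jp = _point_at_arc(pts, cum, cum[joint_ring] + dj)
        bp = _point_at_arc(pts, cum, cum[bite_ring] + db)
        if np.allclose(jp, bp):
            raise ValueError("perturbation window collapsed joint onto bite")
        return jp, bp
    if mode != "vms":
        raise ValueError("mode must be 're' or 'vms'")
    s0, span = _dorsal_arc_span(mesh, joint_ring, bite_ring)
    base_arc = s0 + span / 3.0
    n = len(pts)
    for _ in range(max_retries):
        s = base_arc + rng.uniform(-window_fraction, window_fraction) * perim
        fi = _ring_index_at_arc(cum, s, n)
        node = int(mesh.boundary_ring[fi])
        if node not in (base[0], base[1]):
            angle = np.radians(rng.uniform(-angle_window_deg, angle_window_deg))
            ca, sa = np.cos(angle), np.sin(angle)
            nx, ny = normals[fi]
            return BoundaryCondition(
                joint_node=base[0],
                bite_node=base[1],
                force_node=node,
                force_vector=(ca * nx - sa * ny, sa * nx + ca * ny),
            )
    raise ValueError("force-node window keeps colliding with joint/bite landmarks")


def monte_carlo_performance(
    mesh: TriMesh,
    material: MaterialModel | None = None,
    n_replicates: int = 1000,
    seed: int | None = None,
    window_fraction: float = 0.05,
    angle_window_deg: float = 45.0,
) -> PerformanceRecord:
    """Randomized-replicate performance of one meshed shape.

    RE replicates perturb joint and bite along the boundary; VMS replicates
    keep them fixed and perturb the muscle force node and direction (the
    stiffness factorization is reused across all force replicates).
    Deterministic for a fixed seed.
    """
    material = material or MaterialModel()
    base = identify_landmarks(mesh)
    rng = np.random.default_rng(seed)

    res = np.empty(n_replicates)
    for i in range(n_replicates):
        jp, bp = randomize_bcs(mesh, base, window_fraction, 0.0, "re", rng)
        res[i] = rotational_efficiency(mesh, jp, bp, density=material.density)

    ctx = _FEAContext(mesh, material, [(base[0], 0), (base[0], 1), (base[1], 1)])
    loads = np.zeros((ctx.ndof, n_replicates))
    for i in range(n_replicates):
        bc = randomize_bcs(mesh, base, window_fraction, angle_window_deg, "vms", rng)
        loads[2 * bc.force_node, i] = bc.force_vector[0]
        loads[2 * bc.force_node + 1, i] = bc.force_vector[1]
    vms = ctx.median_vms_batch(loads)

    def pct(a, q):
        return float(np.percentile(a, q))

    return PerformanceRecord(
        re_mean=float(res.mean()), re_p5=pct(res, 5), re_p95=pct(res, 95),
        vms_mean=float(vms.mean()), vms_p5=pct(vms, 5), vms_p95=pct(vms, 95),
        n_replicates=n_replicates, seed=seed,
    )


def grid_performance(
    grid,
    material: MaterialModel | None = None,
    target_elements: int = 2500,
    n_replicates: int = 1000,
    seed: int | None = None,
    on_error: str = "raise",
) -> pd.DataFrame:
    """Monte-Carlo performance of every valid theoretical grid shape.

    Returns the performance table (node, pc1, pc2, re/vms summaries).  With
    ``on_error="skip"``, shapes whose landmarks fail or whose system is
    singular are dropped from the table instead of aborting the sweep.
    """
    rng = np.random.default_rng(seed)
    coords = grid.node_coords()
    rows = []
    n2 = grid.pc2_values.size
    for k in range(grid.n_nodes):
        i, j = divmod(k, n2)
        if not grid.valid_mask[i, j]:
            continue
        node_seed = int(rng.integers(2**31))
        try:
            mesh = triangulate(grid.shapes[i][j], target_elements)
            rec = monte_carlo_performance(
                mesh, material, n_replicates=n_replicates, seed=node_seed
            )
        except (LandmarkError, RigidBodyModeError, RuntimeError, ValueError):
            if on_error == "skip":
                continue
            raise
        rows.append(
            {
                "node": k, "pc1": coords[k, 0], "pc2": coords[k, 1],
                "re_mean": rec.re_mean, "re_p5": rec.re_p5, "re_p95": rec.re_p95,
                "vms_mean": rec.vms_mean, "vms_p5": rec.vms_p5, "vms_p95": rec.vms_p95,
                "n": rec.n_replicates, "seed": node_seed,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# quadratic performance surfaces
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class QuadraticSurfaceFit:
    """Least-squares fit of z = c0 + c1 u + c2 v + c3 u^2 + c4 u v + c5 v^2."""

    coefficients: np.ndarray = field()
    sse: float = 0.0
    rmse: float = 0.0
    r_squared: float = 0.0
    adj_r_squared: float = 0.0

    def predict(self, coords: np.ndarray) -> np.ndarray:
        u, v = np.asarray(coords, dtype=float).T
        c = self.coefficients
        return c[0] + c[1] * u + c[2] * v + c[3] * u**2 + c[4] * u * v + c[5] * v**2


def fit_quadratic_surface(coords, values) -> QuadraticSurfaceFit:
    """Fit a second-order polynomial surface to performance values."""
    coords = np.asarray(coords, dtype=float)
    z = np.asarray(values, dtype=float)
    if coords.shape[0] < 6:
        raise ValueError("need at least 6 points")
    u, v = coords[:, 0], coords[:, 1]
    design = np.column_stack([np.ones_like(u), u, v, u**2, u * v, v**2])
    if np.linalg.matrix_rank(design) < 6:
        raise ValueError("rank-deficient design (collinear coordinates)")
    coef, *_ = np.linalg.lstsq(design, z, rcond=None)
    resid = z - design @ coef
    sse = float(resid @ resid)
    n = z.size
    sst = float(np.sum((z - z.mean()) ** 2))
    r2 = 1.0 - sse / sst if sst > 0 else 1.0
    adj = 1.0 - (1.0 - r2) * (n - 1) / (n - 6) if n > 6 else float("nan")
    return QuadraticSurfaceFit(
        coefficients=coef, sse=sse, rmse=float(np.sqrt(sse / n)),
        r_squared=r2, adj_r_squared=adj,
    )
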