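"""Synthetic jaw outlines, taxa, trees and Brownian trait histories.

Every downstream stage of the pipeline (EFA, morphospace, meshing, FEA,
Pareto ranking, phylogenetic comparative methods, disparity) is testable
without the fossil image dataset by generating inputs with the statistical
structure the analysis assumes:

* jaw-like silhouettes: a superellipse-profile ventral margin under a
  polynomial dorsal margin, parameterized by length/depth ratio (the
  dominant "long & shallow vs short & deep" axis), dorsal curvature
  (convex vs concave dorsal margin, the second axis), anterior taper and a
  small smooth roughness term;
* a taxon sample with four-clade labels and stratigraphic ranges across a
  late Silurian + seven Devonian stage-bin scheme;
* time-calibrated binary trees (Yule-style, ultrametric) and multivariate
  Brownian-motion trait evolution on them, returning the true internal
  states for recovery tests.

All randomness flows from the explicit ``seed`` argument of each call.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd

from .disparity import DEFAULT_BINS, TimeBin
from .outline import Outline, detect_self_intersection, resample_outline
from .phylo import TimedTree

__all__ = [
    "SyntheticJawParams",
    "TaxonRecord",
    "generate_jaw_outline",
    "generate_taxon_set",
    "generate_timed_tree",
    "simulate_bm_traits",
    "BMTraits",
]

CLADES = ("Sarcopterygii", "Placodermi", "Chondrichthyes", "Actinopterygii")
# empirical clade sample proportions (57, 48, 8, 8 of 121)
CLADE_WEIGHTS = np.array([57, 48, 8, 8]) / 121.0

# documented valid parameter box; outside it self-intersection is possible
VALID_BOX = {
    "length_depth_ratio": (2.0, 8.0),
    "dorsal_curvature": (-0.45, 0.45),
    "taper": (0.0, 0.7),
    "roughness": (0.0, 0.05),
}

_SUPERELLIPSE_EXPONENT = 2.5  # blunt, jaw-like anterior/posterior ends


@dataclass(frozen=True)
class SyntheticJawParams:
    """Knobs of the synthetic jaw silhouette.

    ``length_depth_ratio`` is jaw length over maximum depth;
    ``dorsal_curvature`` > 0 dips the dorsal margin down (concave),
    < 0 bows it up (convex), 0 leaves it straight; ``taper`` thins the
    anterior end; ``roughness`` adds a small smooth boundary perturbation.
    """

    length_depth_ratio: float = 3.5
    dorsal_curvature: float = 0.0
    taper: float = 0.3
    roughness: float = 0.0
    n_points: int = 600

    def validate(self) -> None:
        for name, (lo, hi) in VALID_BOX.items():
            val = getattr(self, name)
            if not lo <= val <= hi:
                raise ValueError(f"{name}={val} outside valid box [{lo}, {hi}]")
        if self.n_points < 100:
            raise ValueError("n_points must be >= 100")


@dataclass(frozen=True)
class TaxonRecord:
    taxon_id: str
    clade: str
    first_appearance: float  # Ma (older)
    last_appearance: float  # Ma (younger)
    raw_length: float

    def __post_init__(self) -> None:
        if self.clade not in CLADES:
            raise ValueError(f"unknown clade {self.clade!r}")
        if self.first_appearance < self.last_appearance:
            raise ValueError("first_appearance must be >= last_appearance (ages run backward)")
        if self.raw_length <= 0:
            raise ValueError("raw_length must be positive")


def generate_jaw_outline(params: SyntheticJawParams, seed: int = 0) -> Outline:
    """Deterministic jaw-like silhouette for the given parameters.

    Anterior points toward +x, dorsal toward +y (the canonical frame the
    landmark rules assume); the outline is counterclockwise, simple, and
    has ``params.n_points`` equally spaced vertices.
    """
    params.validate()
    rng = np.random.default_rng(seed)
    length = params.length_depth_ratio  # maximum depth is the unit
    m = _SUPERELLIPSE_EXPONENT
    n_dense = max(4 * params.n_points, 1200)
    # ventral margin, posterior (x=0) to anterior (x=L)
    nv = n_dense * 2 // 3
    u = np.linspace(0.0, 1.0, nv)
    depth = (1.0 - np.abs(2.0 * u - 1.0) ** m) ** (1.0 / m) * (1.0 - params.taper * u)
    ventral = np.column_stack([u * length, -depth])
    # dorsal margin back from anterior to posterior; parabolic bow
    ud = np.linspace(1.0, 0.0, n_dense - nv + 2)[1:-1]
    dorsal_y = -params.dorsal_curvature * 4.0 * ud * (1.0 - ud)
    dorsal = np.column_stack([ud * length, dorsal_y])
    base = Outline(np.vstack([ventral, dorsal]))

    if params.roughness > 0:
        v = resample_outline(base, n_dense).vertices
        s = np.linspace(0.0, 1.0, n_dense, endpoint=False)
        wiggle = np.zeros(n_dense)
        for k in (6, 9, 13):
            amp = params.roughness * rng.uniform(0.5, 1.0) / 3.0
            wiggle += amp * np.sin(2.0 * np.pi * k * s + rng.uniform(0, 2 * np.pi))
        # fade the perturbation out near the two high-curvature jaw tips,
        # where even a small normal displacement would fold the boundary
        tips = np.array([[0.0, 0.0], [length, 0.0]])
        tip_dist = np.minimum(
            np.hypot(*(v - tips[0]).T), np.hypot(*(v - tips[1]).T)
        )
        wiggle *= np.clip(tip_dist / 0.3, 0.0, 1.0)
        closed = np.vstack([v, v[:1]])
        tang = closed[1:] - closed[:-1]
        tang /= np.linalg.norm(tang, axis=1, keepdims=True)
        normals = np.column_stack([tang[:, 1], -tang[:, 0]])  # outward for CCW
        base = Outline(v + wiggle[:, None] * normals)

    out = resample_outline(base, params.n_points).ensure_ccw()
    if detect_self_intersection(out):  # cannot happen inside the valid box
        raise RuntimeError("generated outline self-intersects; parameters too extreme")
    return out


def _draw_params(rng: np.random.Generator) -> SyntheticJawParams:
    """Population distribution of jaw parameters used for taxon sets.

    Ratios span the realistic long-shallow to short-deep range; curvature
    is centered on straight dorsal margins with both convex and concave
    tails, mirroring the two dominant shape axes of the empirical data.
    """
    return SyntheticJawParams(
        length_depth_ratio=float(rng.uniform(2.5, 6.0)),
        dorsal_curvature=float(np.clip(rng.normal(0.0, 0.15), -0.4, 0.4)),
        taper=float(rng.uniform(0.1, 0.5)),
        roughness=0.005,
        n_points=600,
    )


def generate_taxon_set(
    n_taxa: int, bins: tuple[TimeBin, ...] = DEFAULT_BINS, seed: int = 0
) -> list[tuple[TaxonRecord, Outline]]:
    """Sample taxa with clade labels, ranges within the bin span and outlines."""
    if n_taxa < 2:
        raise ValueError("n_taxa must be >= 2")
    rng = np.random.default_rng(seed)
    old, young = bins[0].older_bound, bins[-1].younger_bound
    out = []
    for i in range(n_taxa):
        mid = rng.uniform(young, old)
        half = 0.5 * min(rng.exponential(8.0), 25.0)
        first = min(mid + half, old)
        last = max(mid - half, young)
        rec = TaxonRecord(
            taxon_id=f"T{i:03d}",
            clade=CLADES[rng.choice(len(CLADES), p=CLADE_WEIGHTS)],
            first_appearance=float(first),
            last_appearance=float(last),
            raw_length=float(rng.lognormal(np.log(10.0), 0.5)),
        )
        outline = generate_jaw_outline(_draw_params(rng), seed=int(rng.integers(2**31)))
        out.append((rec, outline))
    return out


def taxon_records_frame(taxa: list[tuple[TaxonRecord, Outline]]) -> pd.DataFrame:
    """Tabulate the metadata half of a taxon set."""
    return pd.DataFrame(
        [
            {
                "taxon_id": r.taxon_id,
                "clade": r.clade,
                "first_appearance": r.first_appearance,
                "last_appearance": r.last_appearance,
                "raw_length": r.raw_length,
            }
            for r, _ in taxa
        ]
    )


def generate_timed_tree(n_tips: int, root_age: float = 100.0, seed: int = 0) -> TimedTree:
    """Random rooted binary ultrametric tree with the given root age.

    Topology by recursive random bipartition; internal node ages by
    recursive uniform subdivision of the parent age, so every branch length
    is strictly positive and all tips sit at age 0 (depth = root_age).
    """
    if n_tips < 2:
        raise ValueError("n_tips must be >= 2")
    if root_age <= 0:
        raise ValueError("root_age must be positive")
    rng = np.random.default_rng(seed)
    taxa = dendropy.TaxonNamespace([f"T{i:03d}" for i in range(n_tips)])
    tree = dendropy.Tree(taxon_namespace=taxa)

    def build(node, tips: list[int], age: float) -> None:
        if len(tips) == 1:
            node.taxon = taxa[int(tips[0])]  # edge length already set by the parent
            return
        k = int(rng.integers(1, len(tips)))
        perm = rng.permutation(tips)
        for sub in (list(perm[:k]), list(perm[k:])):
            child = node.new_child()
            sub_age = float(rng.uniform(0.15, 0.85) * age) if len(sub) > 1 else 0.0
            child.edge.length = age - sub_age
            build(child, sub, sub_age)

    build(tree.seed_node, list(range(n_tips)), root_age)
    return TimedTree(tree)


@dataclass(frozen=True)
class BMTraits:
    """Simulated trait states: tips for analysis, internals for recovery tests."""

    tip_states: pd.DataFrame  # tip label x traits
    node_states: pd.DataFrame  # internal node label x traits (true values)


def simulate_bm_traits(
    tree: TimedTree,
    root_state: np.ndarray,
    rate_matrix: np.ndarray,
    seed: int = 0,
) -> BMTraits:
    """Multivariate Brownian motion along the tree.

    Each branch adds an independent Gaussian increment with covariance
    ``rate_matrix * branch_length``.  The rate matrix must be symmetric
    positive semi-definite.
    """
    root = np.atleast_1d(np.asarray(root_state, dtype=float))
    sigma = np.atleast_2d(np.asarray(rate_matrix, dtype=float))
    if sigma.shape != (root.size, root.size) or not np.allclose(sigma, sigma.T):
        raise ValueError("rate_matrix must be a symmetric (p, p) matrix")
    evals, evecs = np.linalg.eigh(sigma)
    if np.any(evals < -1e-10 * max(1.0, evals.max(initial=0.0))):
        raise ValueError("rate_matrix must be positive semi-definite")
    half = evecs @ np.diag(np.sqrt(np.clip(evals, 0.0, None)))

    rng = np.random.default_rng(seed)
    states: dict = {}
    tips, internals = {}, {}
    for node in tree.tree.preorder_node_iter():
        if node.parent_node is None:
            states[node] = root.copy()
        else:
            z = rng.standard_normal(root.size)
            states[node] = states[node.parent_node] + np.sqrt(node.edge.length) * (half @ z)
        if node.is_leaf():
            tips[node.taxon.label] = states[node]
        else:
            internals[node.label] = states[node]
    cols = [f"trait{i}" for i in range(root.size)]
    return BMTraits(
        tip_states=pd.DataFrame.from_dict(tips, orient="index", columns=cols),
        node_states=pd.DataFrame.from_dict(internals, orient="index", columns=cols),
    )
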