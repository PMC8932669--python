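"""Phylogenetic comparative methods on harmonic shape data.

Provides time-calibrated tree I/O (Newick via dendropy), maximum-likelihood
ancestral state reconstruction under Brownian motion (BM), projection of
ancestors into the shape space (phylomorphospace), and the multivariate
Blomberg K statistic (K_mult) with a permutation test.

Under BM the ML point estimates of ancestral states coincide with the
generalized-least-squares / weighted-squared-change solution: each internal
node sits at the weight-1/branch-length average of its neighbours, which is
a sparse linear system solved per trait.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "TimedTree",
    "AncestralStates",
    "read_timed_tree",
    "asr_bm",
    "phylomorphospace",
    "kmult",
]


@dataclass(frozen=True)
class TimedTree:
    """Rooted tree with strictly positive branch lengths in Ma.

    Wraps a :class:`dendropy.Tree`.  Internal nodes are labelled
    ``N0, N1, ...`` in preorder (``N0`` is the root) if unlabelled.
    """

    tree: dendropy.Tree = field()

    def __post_init__(self) -> None:
        t = self.tree
        labels = [leaf.taxon.label for leaf in t.leaf_node_iter()]
        if len(labels) != len(set(labels)):
            raise ValueError("tip labels must be unique")
        if len(labels) < 2:
            raise ValueError("need at least 2 tips")
        k = 0
        for node in t.preorder_node_iter():
            if node.parent_node is not None:
                if node.edge.length is None or node.edge.length <= 0:
                    raise ValueError("all branch lengths must be present and > 0")
            if not node.is_leaf() and not node.label:
                while f"N{k}" in labels:
                    k += 1
                node.label = f"N{k}"
                k += 1

    # -- convenience -------------------------------------------------------
    @property
    def tip_labels(self) -> list[str]:
        return [leaf.taxon.label for leaf in self.tree.leaf_node_iter()]

    @property
    def internal_labels(self) -> list[str]:
        return [n.label for n in self.tree.preorder_internal_node_iter()]

    @property
    def root_label(self) -> str:
        return self.tree.seed_node.label

    def edges(self) -> list[tuple[str, str]]:
        """(parent_label, child_label) pairs over all tree edges."""
        out = []
        for node in self.tree.preorder_node_iter():
            if node.parent_node is None:
                continue
            parent = node.parent_node.label
            child = node.taxon.label if node.is_leaf() else node.label
            out.append((parent, child))
        return out

    def as_newick(self) -> str:
        return self.tree.as_string(schema="newick", suppress_rooting=True).strip()

    def write_newick(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.as_newick() + "\n")


def read_timed_tree(newick_text: str) -> TimedTree:
    """Parse a Newick string (branch lengths required and positive)."""
    tree = dendropy.Tree.get(data=newick_text, schema="newick")
    return TimedTree(tree)


@dataclass(frozen=True)
class AncestralStates:
    """Per-internal-node trait vectors (and optional PC coordinates)."""

    states: pd.DataFrame  # internal node label x traits
    root_label: str

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.states.to_numpy())):
            raise ValueError("non-finite ancestral state")


def _node_key(node) -> str:
    return node.taxon.label if node.is_leaf() else node.label


def asr_bm(tree: TimedTree, tip_matrix: pd.DataFrame) -> AncestralStates:
    """ML ancestral states under Brownian motion, traits independent.

    Equivalent to minimizing the sum over edges of (state change)^2 / branch
    length: every internal node is the 1/branch-length weighted mean of its
    neighbours, giving a linear system shared by all traits.
    """
    tips = set(tree.tip_labels)
    missing = tips - set(map(str, tip_matrix.index))
    if missing:
        raise ValueError(f"missing tip data for: {sorted(missing)}")
    internal = list(tree.tree.preorder_internal_node_iter())
    index = {_node_key(n): i for i, n in enumerate(internal)}
    n_int = len(internal)
    y = tip_matrix.loc[[*map(str, tree.tip_labels)]].to_numpy(dtype=float)
    p = y.shape[1]

    lap = np.zeros((n_int, n_int))
    rhs = np.zeros((n_int, p))
    tip_data = {str(ix): row for ix, row in zip(tip_matrix.index, tip_matrix.to_numpy(dtype=float))}
    for node in tree.tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        w = 1.0 / node.edge.length
        pi = index[_node_key(node.parent_node)]
        if node.is_leaf():
            lap[pi, pi] += w
            rhs[pi] += w * tip_data[node.taxon.label]
        else:
            ci = index[_node_key(node)]
            lap[pi, pi] += w
            lap[ci, ci] += w
            lap[pi, ci] -= w
            lap[ci, pi] -= w
    states = np.linalg.solve(lap, rhs)
    df = pd.DataFrame(states, index=[_node_key(n) for n in internal], columns=tip_matrix.columns)
    return AncestralStates(states=df, root_label=tree.root_label)


def phylomorphospace(space, tree: TimedTree, tip_matrix: pd.DataFrame,
                     ancestors: AncestralStates):
    """Node PC coordinates plus tree edges for plotting over a morphospace.

    Tips are projected from their coefficient vectors (identical to their
    PCA scores when the space was fitted on them); ancestors are projected
    with the same loadings, never refitted.
    """
    tip_coords = space.project(tip_matrix.to_numpy(dtype=float))
    anc_coords = space.project(ancestors.states.to_numpy(dtype=float))
    coords = pd.DataFrame(
        np.vstack([tip_coords, anc_coords]),
        index=[*map(str, tip_matrix.index), *ancestors.states.index],
        columns=[f"pc{i + 1}" for i in range(tip_coords.shape[1])],
    )
    edges = tree.edges()
    for a, b in edges:
        if a not in coords.index or b not in coords.index:
            raise ValueError(f"edge ({a}, {b}) references a node without coordinates")
    return coords, edges


def _vcv_matrix(tree: TimedTree) -> tuple[np.ndarray, list[str]]:
    """Phylogenetic covariance: shared root-to-MRCA path length per tip pair."""
    pdm = tree.tree.phylogenetic_distance_matrix()
    taxa = list(tree.tree.taxon_namespace)
    labels = [t.label for t in taxa]
    depths = {}
    for leaf in tree.tree.leaf_node_iter():
        depths[leaf.taxon.label] = leaf.distance_from_root()
    n = len(labels)
    c = np.zeros((n, n))
    for i in range(n):
        c[i, i] = depths[labels[i]]
        for j in range(i + 1, n):
            dij = pdm.patristic_distance(taxa[i], taxa[j])
            c[i, j] = c[j, i] = 0.5 * (depths[labels[i]] + depths[labels[j]] - dij)
    return c, labels


def kmult(tree: TimedTree, tip_matrix: pd.DataFrame, n_permutations: int = 9999,
          seed: int | None = None) -> tuple[float, float]:
    """Multivariate Blomberg K and permutation p-value.

    K_mult is the ratio of observed to phylogenetically expected
    (non-phylogenetic over phylogenetically corrected) trait variation,
    scaled so that data evolved by Brownian motion on the tree have
    expectation 1.  Significance comes from permuting tip rows across the
    tips of the tree; p = (b + 1) / (n_permutations + 1) with
    b = #{K_perm >= K_obs}.
    """
    if len(tree.tip_labels) < 4:
        raise ValueError("need at least 4 tips")
    c, labels = _vcv_matrix(tree)
    y = tip_matrix.loc[labels].to_numpy(dtype=float)
    if np.allclose(y, y[0]):
        raise ValueError("constant tip data: K undefined")
    n = y.shape[0]
    cinv = np.linalg.inv(c)
    ones = np.ones(n)
    s = ones @ cinv @ ones
    expected = (np.trace(c) - n / s) / (n - 1)

    def _k(ymat: np.ndarray) -> float:
        a = (ones @ cinv @ ymat) / s
        d = ymat - a
        num = float(np.sum(d * d))
        den = float(np.sum(d * (cinv @ d)))
        return (num / den) / expected

    k_obs = _k(y)
    if n_permutations <= 0:
        return k_obs, float("nan")
    rng = np.random.default_rng(seed)
    b = 0
    for _ in range(n_permutations):
        if _k(y[rng.permutation(n)]) >= k_obs:
            b += 1
    return k_obs, (b + 1) / (n_permutations + 1)
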