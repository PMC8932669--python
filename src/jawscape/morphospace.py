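"""PCA shape space and the evenly spaced theoretical shape grid.

The normalized EFA coefficient vectors of the specimens (45 values each at
12 harmonics) are ordinated by a centered PCA.  A theoretical morphospace is
then a regular grid over the PC1-PC2 plane, each node inverse-transformed
back to a coefficient vector (higher PCs held at zero), traced as an
outline, screened for self-intersection and standardized to unit area.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .efa import EFACoefficients, efa_reconstruct
from .outline import Outline, detect_self_intersection, standardize_area, write_outline_csv

__all__ = ["ShapeSpace", "TheoreticalGrid", "fit_pca", "build_theoretical_grid"]


@dataclass(frozen=True)
class ShapeSpace:
    """Fitted PCA morphospace over coefficient vectors.

    ``loadings`` has orthonormal columns (one per retained axis); ``scores``
    are the per-specimen coordinates of the fitting data.
    """

    mean_vector: np.ndarray
    loadings: np.ndarray  # (n_features, n_axes), columns orthonormal
    eigenvalues: np.ndarray
    scores: np.ndarray  # (n_specimens, n_axes)
    variance_explained: np.ndarray
    specimen_ids: tuple[str, ...] = field(default=())

    @property
    def n_axes(self) -> int:
        return self.loadings.shape[1]

    def project(self, coeff_vector: np.ndarray) -> np.ndarray:
        """Coordinates of a coefficient vector: ``L^T (x - mean)``.

        Accepts a single vector or a (k, n_features) matrix.
        """
        x = np.asarray(coeff_vector, dtype=float)
        if x.shape[-1] != self.mean_vector.size:
            raise ValueError(
                f"expected vectors of length {self.mean_vector.size}, got {x.shape[-1]}"
            )
        return (x - self.mean_vector) @ self.loadings

    def inverse(self, pc_coords: np.ndarray) -> np.ndarray:
        """Coefficient vector at the given PC coordinates (missing axes = 0)."""
        s = np.asarray(pc_coords, dtype=float)
        k = s.shape[-1]
        if k > self.n_axes:
            raise ValueError("more coordinates than fitted axes")
        return self.mean_vector + s @ self.loadings[:, :k].T


def fit_pca(coeff_matrix: np.ndarray, specimen_ids=None) -> ShapeSpace:
    """Centered PCA of a specimens-by-features coefficient matrix."""
    x = np.asarray(coeff_matrix, dtype=float)
    if x.ndim != 2 or x.shape[0] < 3:
        raise ValueError("need a 2D matrix with at least 3 specimens")
    if not np.all(np.isfinite(x)):
        raise ValueError("coefficient matrix contains non-finite values")
    if np.allclose(x, x[0]):
        raise ValueError("constant matrix: no variation to ordinate")
    n_axes = min(x.shape[0] - 1, x.shape[1])
    pca = PCA(n_components=n_axes, svd_solver="full")
    scores = pca.fit_transform(x)
    ids = tuple(str(i) for i in specimen_ids) if specimen_ids is not None else ()
    return ShapeSpace(
        mean_vector=pca.mean_,
        loadings=pca.components_.T,
        eigenvalues=pca.explained_variance_,
        scores=scores,
        variance_explained=pca.explained_variance_ratio_,
        specimen_ids=ids,
    )


@dataclass(frozen=True)
class TheoreticalGrid:
    """Regular PC1-PC2 grid of reconstructed theoretical outlines.

    ``shapes`` is indexed ``[i1][i2]`` parallel to ``pc1_values`` and
    ``pc2_values``; ``valid_mask[i1, i2]`` is False where the reconstructed
    outline self-intersects (geometrically impossible morphology).
    """

    pc1_values: np.ndarray
    pc2_values: np.ndarray
    shapes: tuple  # tuple of tuples of Outline
    valid_mask: np.ndarray
    area_standardized: bool = True

    @property
    def n_nodes(self) -> int:
        return self.pc1_values.size * self.pc2_values.size

    def node_coords(self) -> np.ndarray:
        """(n_nodes, 2) array of (pc1, pc2) in i1-major order."""
        p1, p2 = np.meshgrid(self.pc1_values, self.pc2_values, indexing="ij")
        return np.column_stack([p1.ravel(), p2.ravel()])

    def manifest(self) -> pd.DataFrame:
        coords = self.node_coords()
        areas = [
            self.shapes[i][j].area
            for i in range(self.pc1_values.size)
            for j in range(self.pc2_values.size)
        ]
        return pd.DataFrame(
            {
                "node": np.arange(self.n_nodes),
                "pc1": coords[:, 0],
                "pc2": coords[:, 1],
                "valid": self.valid_mask.ravel(),
                "area": areas,
            }
        )

    def save(self, directory) -> None:
        """Write a manifest CSV plus one outline CSV per grid node."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.manifest().to_csv(directory / "manifest.csv", index=False)
        for k, (i, j) in enumerate(
            (i, j) for i in range(self.pc1_values.size) for j in range(self.pc2_values.size)
        ):
            write_outline_csv(self.shapes[i][j], directory / f"node_{k:04d}.csv")


def build_theoretical_grid(
    space: ShapeSpace,
    n1: int = 23,
    n2: int = 21,
    border_fraction: float = 0.2,
    n_outline_points: int = 300,
) -> TheoreticalGrid:
    """Evenly spaced grid over PC1-PC2 with a border beyond the data.

    Axis limits are the empirical per-axis [min, max] expanded on both ends
    by ``border_fraction`` times the *PC1* empirical range (the PC1 range is
    the yardstick for both axes, giving a uniform absolute margin).  Each
    node's outline is the inverse transform of ``(pc1, pc2, 0, ..., 0)``;
    self-intersecting reconstructions are masked invalid, valid ones are
    scaled to unit area.
    """
    if space.scores.shape[0] == 0 or space.n_axes < 2:
        raise ValueError("need a fitted space with at least 2 axes and scores")
    emp1, emp2 = space.scores[:, 0], space.scores[:, 1]
    border = border_fraction * (emp1.max() - emp1.min())
    pc1_values = np.linspace(emp1.min() - border, emp1.max() + border, n1)
    pc2_values = np.linspace(emp2.min() - border, emp2.max() + border, n2)

    shapes: list[list[Outline]] = []
    valid = np.zeros((n1, n2), dtype=bool)
    for i, p1 in enumerate(pc1_values):
        row: list[Outline] = []
        for j, p2 in enumerate(pc2_values):
            vec = space.inverse(np.array([p1, p2]))
            out = efa_reconstruct(EFACoefficients.from_flat(vec), n_outline_points)
            out = out.ensure_ccw()
            ok = not detect_self_intersection(out)
            if ok:
                out = standardize_area(out, 1.0)
            valid[i, j] = ok
            row.append(out)
        shapes.append(row)
    return TheoreticalGrid(
        pc1_values=pc1_values,
        pc2_values=pc2_values,
        shapes=tuple(tuple(r) for r in shapes),
        valid_mask=valid,
        area_standardized=True,
    )
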