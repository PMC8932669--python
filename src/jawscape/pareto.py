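"""Bidirectional Goldberg Pareto ranking and the adaptive landscape.

Shapes are ranked by iterative Pareto front peeling (Goldberg ranking) run
twice: once with the stated optimality directions (maximize rotational
efficiency, minimize median von Mises stress) giving front indices ``R_O``,
and once with both directions reversed giving ``R_S``.  The combined rank

    R = (R_S - 1) / (R_O + R_S - 2)

is a linear 0-to-1 optimality score: 1 on the Pareto-optimal front, 0 on
the fully dominated (sub-optimal) front.  A point that is simultaneously on
both first fronts (possible for singletons or corner points of a pure
trade-off set) makes the formula 0/0 and is assigned 0.5 by convention;
this degenerate case is symmetric and bounded but *every* point of a pure
two-point-metric trade-off set can hit it, so inspect ``r_optimal`` and
``r_suboptimal`` directly when that matters.

Ranks over the valid theoretical grid nodes form the adaptive landscape,
which is bilinearly interpolable at arbitrary in-grid coordinates (e.g., at
empirical taxon PC scores).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ParetoRanking",
    "AdaptiveLandscape",
    "goldberg_rank",
    "combined_pareto_rank",
    "build_adaptive_landscape",
    "interpolate_optimality",
]

DEGENERATE_RANK = 0.5  # combined rank of a point on both first fronts


def goldberg_rank(points: np.ndarray, maximize=(True, False)) -> np.ndarray:
    """Front index (1-based) per point by iterative non-dominated peeling.

    A point dominates another if it is better-or-equal in every metric and
    strictly better in at least one, with directions given by ``maximize``
    per metric column.  Duplicates never dominate each other.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 1:
        raise ValueError("need a (n, k) array with n >= 1")
    if not np.all(np.isfinite(pts)):
        raise ValueError("non-finite performance values")
    sign = np.where(np.asarray(maximize, dtype=bool), 1.0, -1.0)
    z = pts * sign  # larger is now better everywhere
    n = z.shape[0]
    fronts = np.zeros(n, dtype=np.int64)
    remaining = np.arange(n)
    front = 0
    while remaining.size:
        front += 1
        zr = z[remaining]
        ge = np.all(zr[:, None, :] >= zr[None, :, :], axis=2)
        gt = np.any(zr[:, None, :] > zr[None, :, :], axis=2)
        dominated = np.any(ge & gt, axis=0)  # dominated[j]: some i beats j
        if not np.any(~dominated):  # cannot happen with finite values
            raise RuntimeError("empty Pareto front")
        fronts[remaining[~dominated]] = front
        remaining = remaining[dominated]
    return fronts


@dataclass(frozen=True)
class ParetoRanking:
    r_optimal: np.ndarray  # front index, stated directions
    r_suboptimal: np.ndarray  # front index, reversed directions
    rank: np.ndarray  # combined rank in [0, 1]


def combined_pareto_rank(points: np.ndarray, maximize=(True, False)) -> ParetoRanking:
    """Bidirectional Goldberg ranking with the combined 0-1 rank."""
    r_opt = goldberg_rank(points, maximize)
    r_sub = goldberg_rank(points, tuple(not m for m in np.asarray(maximize, dtype=bool)))
    denom = r_opt + r_sub - 2
    rank = np.full(r_opt.shape, DEGENERATE_RANK, dtype=float)
    nz = denom > 0
    rank[nz] = (r_sub[nz] - 1) / denom[nz]
    return ParetoRanking(r_optimal=r_opt, r_suboptimal=r_sub, rank=rank)


@dataclass(frozen=True)
class AdaptiveLandscape:
    """Combined Pareto ranks over the valid nodes of a theoretical grid."""

    pc1_values: np.ndarray
    pc2_values: np.ndarray
    rank_grid: np.ndarray  # (n1, n2), NaN at invalid/unranked nodes
    ranking: ParetoRanking
    node_index: np.ndarray  # flat node ids that were ranked, in ranking order

    def interpolate(self, pc_coords) -> float:
        """Bilinear interpolation of the rank surface at (pc1, pc2).

        Raises ``ValueError`` outside the grid limits or where any
        contributing corner node is invalid/unranked.
        """
        p1, p2 = float(pc_coords[0]), float(pc_coords[1])
        x, y = self.pc1_values, self.pc2_values
        if not (x[0] <= p1 <= x[-1] and y[0] <= p2 <= y[-1]):
            raise ValueError(f"coordinates ({p1:.4g}, {p2:.4g}) outside the grid")
        i = min(int(np.searchsorted(x, p1, side="right") - 1), x.size - 2)
        j = min(int(np.searchsorted(y, p2, side="right") - 1), y.size - 2)
        i, j = max(i, 0), max(j, 0)
        fx = (p1 - x[i]) / (x[i + 1] - x[i])
        fy = (p2 - y[j]) / (y[j + 1] - y[j])
        w = np.array([(1 - fx) * (1 - fy), (1 - fx) * fy, fx * (1 - fy), fx * fy])
        z = np.array([
            self.rank_grid[i, j], self.rank_grid[i, j + 1],
            self.rank_grid[i + 1, j], self.rank_grid[i + 1, j + 1],
        ])
        live = w > 1e-12
        if np.any(np.isnan(z[live])):
            raise ValueError(
                f"coordinates ({p1:.4g}, {p2:.4g}) touch invalid (self-intersecting) "
                "morphospace"
            )
        return float(np.nansum(w * np.where(live, z, 0.0)))

    def table(self) -> pd.DataFrame:
        n2 = self.pc2_values.size
        rows = []
        for ordinal, k in enumerate(self.node_index):
            i, j = divmod(int(k), n2)
            rows.append({
                "node": int(k), "pc1": self.pc1_values[i], "pc2": self.pc2_values[j],
                "r_optimal": int(self.ranking.r_optimal[ordinal]),
                "r_suboptimal": int(self.ranking.r_suboptimal[ordinal]),
                "rank": self.ranking.rank[ordinal],
            })
        return pd.DataFrame(rows)


def build_adaptive_landscape(perf: pd.DataFrame, grid) -> AdaptiveLandscape:
    """Rank the performance table (re_mean maximized, vms_mean minimized).

    ``perf`` must hold one row per ranked grid node (column ``node`` = flat
    node id); nodes masked invalid in the grid, or absent from the table,
    are excluded from the ranking and left NaN in the surface.
    """
    n1, n2 = grid.pc1_values.size, grid.pc2_values.size
    valid_nodes = {k for k in range(grid.n_nodes) if grid.valid_mask[k // n2, k % n2]}
    nodes = perf["node"].to_numpy(dtype=int)
    unknown = set(nodes) - valid_nodes
    if unknown:
        raise ValueError(f"performance records for invalid grid nodes: {sorted(unknown)[:5]}")
    ranking = combined_pareto_rank(
        perf[["re_mean", "vms_mean"]].to_numpy(dtype=float), maximize=(True, False)
    )
    rank_grid = np.full((n1, n2), np.nan)
    for k, r in zip(nodes, ranking.rank):
        rank_grid[k // n2, k % n2] = r
    return AdaptiveLandscape(
        pc1_values=grid.pc1_values, pc2_values=grid.pc2_values,
        rank_grid=rank_grid, ranking=ranking, node_index=nodes,
    )


def interpolate_optimality(landscape: AdaptiveLandscape, pc_coords) -> float:
    """Functional alias of :meth:`AdaptiveLandscape.interpolate`."""
    return landscape.interpolate(pc_coords)
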