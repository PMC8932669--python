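import numpy as np
import pytest

from jawscape import (
    build_adaptive_landscape,
    combined_pareto_rank,
    goldberg_rank,
    interpolate_optimality,
)


def _brute_force_fronts(points, maximize):
    """Independent O(n^3) front peeling by explicit pairwise dominance."""
    sign = [1.0 if m else -1.0 for m in maximize]
    z = [[s * v for s, v in zip(sign, p)] for p in points]
    n = len(z)
    fronts = [0] * n
    alive = set(range(n))
    front = 0
    while alive:
        front += 1
        this = []
        for i in alive:
            dominated = False
            for j in alive:
                if j == i:
                    continue
                ge = all(zj >= zi for zj, zi in zip(z[j], z[i]))
                gt = any(zj > zi for zj, zi in zip(z[j], z[i]))
                if ge and gt:
                    dominated = True
                    break
            if not dominated:
                this.append(i)
        for i in this:
            fronts[i] = front
            alive.discard(i)
    return fronts


class TestGoldbergRank:
    def test_hand_worked_four_points(self):
        # (RE, VMS) with maximize RE, minimize VMS
        pts = np.array([[3, 1], [2, 1], [3, 2], [1, 3]], dtype=float)
        fronts = goldberg_rank(pts, maximize=(True, False))
        assert list(fronts) == [1, 2, 2, 3]

    def test_mutually_nondominated_single_front(self):
        pts = np.array([[1, 1], [2, 2], [3, 3]], dtype=float)  # pure trade-off
        assert list(goldberg_rank(pts, maximize=(True, True))) != [1, 1, 1]
        assert list(goldberg_rank(pts, maximize=(True, False))) == [1, 1, 1]

    def test_duplicates_share_front(self):
        pts = np.array([[1, 1], [1, 1], [0, 2]], dtype=float)
        fronts = goldberg_rank(pts, maximize=(True, False))
        assert fronts[0] == fronts[1]

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            goldberg_rank(np.array([[np.nan, 1.0]]))

    def test_matches_brute_force_on_random_clouds(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            n = int(rng.integers(2, 50))
            pts = np.round(rng.normal(size=(n, 2)), 2)  # rounding forces ties
            got = goldberg_rank(pts, maximize=(True, False))
            assert list(got) == _brute_force_fronts(pts.tolist(), (True, False))


class TestCombinedRank:
    def test_three_point_chain(self):
        pts = np.array([[3, 1], [2, 2], [1, 3]], dtype=float)
        ranking = combined_pareto_rank(pts, maximize=(True, False))
        assert list(ranking.r_optimal) == [1, 2, 3]
        assert list(ranking.r_suboptimal) == [3, 2, 1]
        assert list(ranking.rank) == [1.0, 0.5, 0.0]

    def test_degenerate_point_on_both_first_fronts(self):
        ranking = combined_pareto_rank(np.array([[1.0, 1.0]]))
        assert ranking.rank[0] == 0.5

    def test_matches_brute_force_formula_on_random_clouds(self):
        rng = np.random.default_rng(1)
        for _ in range(30):
            n = int(rng.integers(2, 50))
            pts = np.round(rng.normal(size=(n, 2)), 1)
            ranking = combined_pareto_rank(pts, maximize=(True, False))
            ro = _brute_force_fronts(pts.tolist(), (True, False))
            rs = _brute_force_fronts(pts.tolist(), (False, True))
            for i in range(n):
                denom = ro[i] + rs[i] - 2
                expected = 0.5 if denom == 0 else (rs[i] - 1) / denom
                assert ranking.rank[i] == expected

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(2)
        pts = rng.normal(size=(40, 2))
        ref = combined_pareto_rank(pts, maximize=(True, False))
        transformed = np.column_stack([np.exp(pts[:, 0]), pts[:, 1] ** 3 + 5 * pts[:, 1]])
        got = combined_pareto_rank(transformed, maximize=(True, False))
        assert np.array_equal(ref.rank, got.rank)

    def test_direction_reversal_flips_rank(self):
        rng = np.random.default_rng(3)
        pts = rng.normal(size=(30, 2))
        fwd = combined_pareto_rank(pts, maximize=(True, False))
        rev = combined_pareto_rank(pts, maximize=(False, True))
        assert np.array_equal(rev.r_optimal, fwd.r_suboptimal)
        assert np.array_equal(rev.r_suboptimal, fwd.r_optimal)
        degenerate = (fwd.r_optimal == 1) & (fwd.r_suboptimal == 1)
        flipped = np.where(degenerate, 0.5, 1.0 - fwd.rank)
        assert np.allclose(rev.rank, flipped)

    def test_invariant_rank_bounds(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            pts = rng.normal(size=(25, 2))
            ranking = combined_pareto_rank(pts)
            assert np.all(ranking.rank >= 0.0) and np.all(ranking.rank <= 1.0)
            first = ranking.r_optimal == 1
            nondeg = first & (ranking.r_suboptimal > 1)
            assert np.all(ranking.rank[nondeg] == 1.0)


class _FakeGrid:
    """Minimal grid stand-in for landscape tests (synthetic, not meshed)."""

    def __init__(self, pc1, pc2, valid):
        self.pc1_values = np.asarray(pc1, dtype=float)
        self.pc2_values = np.asarray(pc2, dtype=float)
        self.valid_mask = np.asarray(valid, dtype=bool)
        self.n_nodes = self.valid_mask.size


def _perf_table(grid, re_vals, vms_vals):
    import pandas as pd

    n2 = grid.pc2_values.size
    rows = []
    for k in range(grid.n_nodes):
        if grid.valid_mask[k // n2, k % n2]:
            rows.append({"node": k, "re_mean": re_vals[k], "vms_mean": vms_vals[k]})
    return pd.DataFrame(rows)


class TestAdaptiveLandscape:
    def setup_method(self):
        self.grid = _FakeGrid([0.0, 1.0, 2.0], [0.0, 1.0], np.ones((3, 2)))

    def test_identical_performance_all_half(self):
        perf = _perf_table(self.grid, np.ones(6), np.ones(6))
        ls = build_adaptive_landscape(perf, self.grid)
        assert np.allclose(ls.ranking.rank, 0.5)

    def test_two_point_domination_chain(self):
        grid = _FakeGrid([0.0, 1.0], [0.0], np.ones((2, 1)))
        perf = _perf_table(grid, [2.0, 1.0], [1.0, 2.0])
        ls = build_adaptive_landscape(perf, grid)
        assert list(ls.ranking.rank) == [1.0, 0.0]

    def test_masked_node_excluded_from_ranking(self):
        valid = np.ones((3, 2), dtype=bool)
        valid[0, 0] = False
        grid = _FakeGrid([0.0, 1.0, 2.0], [0.0, 1.0], valid)
        re_vals = np.array([9.0, 1.0, 2.0, 3.0, 4.0, 5.0])
        vms = np.full(6, 1.0)
        ls = build_adaptive_landscape(_perf_table(grid, re_vals, vms), grid)
        assert 0 not in set(ls.node_index)
        assert np.isnan(ls.rank_grid[0, 0])
        # ranking equals that of the subset without the masked node
        sub = combined_pareto_rank(
            np.column_stack([re_vals[1:], vms[1:]]), maximize=(True, False)
        )
        assert np.allclose(ls.ranking.rank, sub.rank)

    def test_interpolation_identities_and_domain_errors(self):
        perf = _perf_table(self.grid, [1, 2, 3, 4, 5, 6], np.ones(6))
        ls = build_adaptive_landscape(perf, self.grid)
        # exact node
        assert ls.interpolate([1.0, 0.0]) == ls.rank_grid[1, 0]
        # cell center = mean of 4 corners
        center = ls.interpolate([0.5, 0.5])
        assert np.isclose(center, ls.rank_grid[:2, :2].mean())
        with pytest.raises(ValueError):
            ls.interpolate([-0.1, 0.0])
        with pytest.raises(ValueError):
            interpolate_optimality(ls, [2.5, 0.5])

    def test_invalid_cell_rejected(self):
        valid = np.ones((3, 2), dtype=bool)
        valid[2, 1] = False
        grid = _FakeGrid([0.0, 1.0, 2.0], [0.0, 1.0], valid)
        ls = build_adaptive_landscape(_perf_table(grid, np.arange(6.0), np.ones(6)), grid)
        with pytest.raises(ValueError):
            ls.interpolate([1.9, 0.9])  # query weighted on the masked corner
        # but a query on the far edge of the grid is fine
        assert 0.0 <= ls.interpolate([0.5, 0.0]) <= 1.0
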