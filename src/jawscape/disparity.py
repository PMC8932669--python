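"""Disparity and optimality through time.

Taxa are binned into stratigraphic stages by the range-through rule (a
taxon counts in every bin between its first and last appearance), and per
bin the harmonic shape data yield two disparity metrics — sum of trait
variances (SoV) and mean pairwise Euclidean distance (MPD) — plus the mean
interpolated Pareto optimality, each with bootstrap confidence intervals.
Temporal trends are tested with Spearman rank correlation; the
disparity-optimality relation with Pearson correlation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist
from scipy.stats import pearsonr, spearmanr

__all__ = [
    "TimeBin",
    "TimeBinTable",
    "DEFAULT_BINS",
    "time_bin_taxa",
    "disparity_metrics",
    "bootstrap_summary",
    "mean_bin_optimality",
    "trend_tests",
    "disparity_through_time",
]


@dataclass(frozen=True)
class TimeBin:
    name: str
    older_bound: float  # Ma, larger number = older
    younger_bound: float

    def __post_init__(self) -> None:
        if self.older_bound <= self.younger_bound:
            raise ValueError("older_bound must exceed younger_bound (ages run backward)")

    def overlaps(self, first: float, last: float) -> bool:
        """Closed-interval overlap with a (first, last) appearance range."""
        return first >= self.younger_bound and last <= self.older_bound


# Late Silurian (Ludlow + Pridoli merged) plus the seven Devonian stages,
# ICS 2020 boundary ages in Ma; override by passing your own bin list.
DEFAULT_BINS: tuple[TimeBin, ...] = (
    TimeBin("late Silurian", 427.4, 419.2),
    TimeBin("Lochkovian", 419.2, 410.8),
    TimeBin("Pragian", 410.8, 407.6),
    TimeBin("Emsian", 407.6, 393.3),
    TimeBin("Eifelian", 393.3, 387.7),
    TimeBin("Givetian", 387.7, 382.7),
    TimeBin("Frasnian", 382.7, 372.2),
    TimeBin("Famennian", 372.2, 358.9),
)


@dataclass(frozen=True)
class TimeBinTable:
    """Ordered (old -> young) bins plus per-bin taxon membership."""

    bins: tuple[TimeBin, ...]
    membership: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for older, younger in zip(self.bins[:-1], self.bins[1:]):
            if older.younger_bound != younger.older_bound:
                raise ValueError("bins must be contiguous and ordered old -> young")

    @property
    def span(self) -> tuple[float, float]:
        return self.bins[0].older_bound, self.bins[-1].younger_bound


def time_bin_taxa(records: pd.DataFrame, bins=DEFAULT_BINS) -> TimeBinTable:
    """Assign taxa to bins by overlap, ranged through intermediate bins.

    ``records`` needs columns ``taxon_id``, ``first_appearance``,
    ``last_appearance`` (ages in Ma, first >= last).
    """
    bins = tuple(bins)
    old, young = bins[0].older_bound, bins[-1].younger_bound
    membership: dict[str, list[str]] = {b.name: [] for b in bins}
    for rec in records.itertuples(index=False):
        first, last = float(rec.first_appearance), float(rec.last_appearance)
        if first < last:
            raise ValueError(f"{rec.taxon_id}: first_appearance must be >= last_appearance")
        if last > old or first < young:
            raise ValueError(f"{rec.taxon_id}: range [{last}, {first}] outside all bins")
        hits = [i for i, b in enumerate(bins) if b.overlaps(first, last)]
        for i in range(min(hits), max(hits) + 1):  # range-through fill
            membership[bins[i].name].append(str(rec.taxon_id))
    return TimeBinTable(bins=bins, membership=membership)


def disparity_metrics(matrix: np.ndarray) -> tuple[float, float]:
    """(sum of variances, mean pairwise distance) of a taxa-by-traits block.

    SoV uses the n-1 sample variance; MPD averages Euclidean distances over
    all unordered pairs.  MPD needs >= 2 rows; SoV of a single row is 0.
    """
    x = np.asarray(matrix, dtype=float)
    if x.ndim != 2 or x.shape[0] < 1:
        raise ValueError("need a 2D matrix with at least one row")
    sov = 0.0 if x.shape[0] < 2 else float(np.sum(np.var(x, axis=0, ddof=1)))
    if x.shape[0] < 2:
        raise ValueError("mean pairwise distance needs at least 2 rows")
    mpd = float(np.mean(pdist(x)))
    return sov, mpd


def bootstrap_summary(values_fn, matrix: np.ndarray, n_boot: int = 10000,
                      seed: int | None = None) -> tuple[float, float, float]:
    """Bootstrap a row-resampled scalar metric: (mean, 2.5%, 97.5%)."""
    x = np.asarray(matrix, dtype=float)
    if x.shape[0] < 1:
        raise ValueError("need at least one row")
    rng = np.random.default_rng(seed)
    n = x.shape[0]
    vals = np.empty(n_boot)
    for i in range(n_boot):
        vals[i] = values_fn(x[rng.integers(0, n, size=n)])
    return float(vals.mean()), float(np.percentile(vals, 2.5)), float(np.percentile(vals, 97.5))


def mean_bin_optimality(bin_members: list[str], taxon_pc_coords: pd.DataFrame,
                        landscape, n_boot: int = 10000,
                        seed: int | None = None) -> tuple[float, float, float]:
    """Bootstrap mean of landscape optimality interpolated at member taxa.

    ``taxon_pc_coords`` holds pc1/pc2 per taxon_id.  Out-of-domain taxa
    raise with the offending taxon named.
    """
    ranks = []
    for taxon in bin_members:
        pc = taxon_pc_coords.loc[taxon, ["pc1", "pc2"]].to_numpy(dtype=float)
        try:
            ranks.append(landscape.interpolate(pc))
        except ValueError as err:
            raise ValueError(f"taxon {taxon}: {err}") from err
    ranks = np.asarray(ranks, dtype=float)
    rng = np.random.default_rng(seed)
    n = ranks.size
    means = np.array([ranks[rng.integers(0, n, size=n)].mean() for _ in range(n_boot)])
    return float(means.mean()), float(np.percentile(means, 2.5)), float(np.percentile(means, 97.5))


def trend_tests(series_by_bin: dict[str, np.ndarray] | pd.DataFrame,
                pairings: list[tuple[str, str]] = ()) -> pd.DataFrame:
    """Spearman trend of each per-bin series vs time order, plus optional
    Pearson correlations between named series pairs.

    ``series_by_bin`` maps series name -> values ordered old -> young.
    Returns one row per test with (test, series, statistic, p_value).
    """
    df = pd.DataFrame(series_by_bin)
    if df.shape[0] < 3:
        raise ValueError("need at least 3 bins")
    rows = []
    order = np.arange(df.shape[0])
    for name in df.columns:
        vals = df[name].to_numpy(dtype=float)
        if np.allclose(vals, vals[0]):
            raise ValueError(f"series {name!r} is constant: correlation undefined")
        rho, p = spearmanr(order, vals)
        rows.append({"test": "spearman_trend", "series": name, "statistic": rho, "p_value": p})
    for a, b in pairings:
        va, vb = df[a].to_numpy(dtype=float), df[b].to_numpy(dtype=float)
        r, p = pearsonr(va, vb)
        rows.append({"test": "pearson", "series": f"{a}~{b}", "statistic": r, "p_value": p})
    return pd.DataFrame(rows)


def disparity_through_time(coeff_frame: pd.DataFrame, bin_table: TimeBinTable,
                           taxon_pc_coords: pd.DataFrame | None = None,
                           landscape=None, n_boot: int = 10000,
                           seed: int | None = None) -> pd.DataFrame:
    """Per-bin disparity (and optionally mean optimality) with bootstrap CIs.

    ``coeff_frame`` is the taxa-by-45 harmonic table indexed by taxon_id.
    Bins with fewer than 2 members get NaN disparity (flagged, not dropped).
    """
    rng = np.random.default_rng(seed)
    rows = []
    for b in bin_table.bins:
        members = bin_table.membership.get(b.name, [])
        row: dict = {"bin": b.name, "older_bound": b.older_bound,
                     "younger_bound": b.younger_bound, "n_taxa": len(members)}
        if len(members) >= 2:
            block = coeff_frame.loc[members].to_numpy(dtype=float)
            sov, mpd = disparity_metrics(block)
            row["sov"], row["mpd"] = sov, mpd
            for key, fn in (("sov", lambda m: disparity_metrics(m)[0]),
                            ("mpd", lambda m: disparity_metrics(m)[1])):
                mean, lo, hi = bootstrap_summary(
                    fn, block, n_boot=n_boot, seed=int(rng.integers(2**31)))
                row[f"{key}_boot_mean"], row[f"{key}_ci_low"], row[f"{key}_ci_high"] = mean, lo, hi
        else:
            row.update({k: np.nan for k in (
                "sov", "mpd", "sov_boot_mean", "sov_ci_low", "sov_ci_high",
                "mpd_boot_mean", "mpd_ci_low", "mpd_ci_high")})
        if landscape is not None and taxon_pc_coords is not None and members:
            mean, lo, hi = mean_bin_optimality(
                members, taxon_pc_coords, landscape, n_boot=n_boot,
                seed=int(rng.integers(2**31)))
            row["mean_opt"], row["opt_ci_low"], row["opt_ci_high"] = mean, lo, hi
        rows.append(row)
    return pd.DataFrame(rows)
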