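"""Maximal Information Coefficient (MIC), implemented from scratch.

MIC measures association between two real variables by searching over
two-dimensional grids: for every grid with r rows and s columns such
that r * s <= B(n) = ceil(n^alpha), the empirical mutual information of
the induced 2-D histogram is maximized over grid-line placements and
normalized by log2(min(r, s)).  MIC is the maximum of this normalized
score over all admissible grid sizes.  It is 1 for a noiseless
functional relationship (linear or not) and near 0 for independent
data, which is why it complements the Pearson correlation in feature
ranking: a symmetric parabola has Pearson r ~ 0 but MIC ~ 1.

The exact maximization is intractable, so :func:`mic` uses the standard
heuristic: one axis is equipartitioned into equal-count bins, and the
other axis's partition is optimized exactly by dynamic programming over
"clump" boundaries (runs of consecutive points falling in the same row
of the fixed axis); the number of candidate clumps is capped at
``c * s``.  The score is symmetrized by taking the maximum over both
axis orientations.

Grids depend on the data only through ranks, so MIC is invariant under
strictly monotone transformations of either variable.  Ties are broken
deterministically by original index (stable rank), never by jitter.

:func:`mic_oracle` performs the exhaustive grid search on tiny inputs
(n <= 12) and bounds the heuristic from above in tests.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger("coexmod")


def mutual_information_grid(x: np.ndarray, y: np.ndarray,
                            x_edges: np.ndarray, y_edges: np.ndarray) -> float:
    """Empirical mutual information (bits) of the histogram on a fixed grid.

    Outer bins are closed: points beyond the outermost edges are
    assigned to the boundary bins.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x_edges = np.asarray(x_edges, dtype=float)
    y_edges = np.asarray(y_edges, dtype=float)
    for edges in (x_edges, y_edges):
        if len(edges) < 2 or np.any(np.diff(edges) <= 0):
            raise ValueError("edges must be strictly increasing with >= 2 entries")
    xi = np.clip(np.digitize(x, x_edges[1:-1]), 0, len(x_edges) - 2)
    yi = np.clip(np.digitize(y, y_edges[1:-1]), 0, len(y_edges) - 2)
    counts = np.zeros((len(x_edges) - 1, len(y_edges) - 1))
    np.add.at(counts, (xi, yi), 1.0)
    return _mutual_information(counts)


def _mutual_information(counts: np.ndarray) -> float:
    """Plug-in mutual information (bits) of a contingency table."""
    n = counts.sum()
    if n == 0:
        return 0.0
    p = counts / n
    px = p.sum(axis=1, keepdims=True)
    py = p.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = p * np.log2(p / (px * py))
    return float(np.nansum(terms))


@dataclass
class MICResult:
    mic: float
    grid: tuple[int, int]     # (rows, cols) of the best grid
    b: int                    # grid-size budget B(n)
    alpha: float
    c: float


def _stable_order(v: np.ndarray) -> np.ndarray:
    """Sort order by value with original index as deterministic tie-break."""
    return np.lexsort((np.arange(len(v)), v))


def _equipartition(order: np.ndarray, values: np.ndarray, n_bins: int) -> np.ndarray:
    """Assign points to ~equal-count bins along ``order``, ties in one bin.

    Returns a bin index per point (original indexing).  Runs of equal
    values are never split, so bin counts may be unequal under heavy
    ties and fewer than ``n_bins`` bins may be produced.
    """
    n = len(order)
    assignment = np.empty(n, dtype=np.int64)
    sorted_values = values[order]
    # group boundaries between distinct consecutive values
    group_starts = [0]
    for i in range(1, n):
        if sorted_values[i] != sorted_values[i - 1]:
            group_starts.append(i)
    group_starts.append(n)

    current = 0
    placed = 0
    in_current = 0
    desired = n / n_bins
    for g in range(len(group_starts) - 1):
        start, stop = group_starts[g], group_starts[g + 1]
        size = stop - start
        if in_current > 0 and current < n_bins - 1:
            overshoot = abs(in_current + size - desired)
            undershoot = abs(desired - in_current)
            if overshoot >= undershoot:
                current += 1
                in_current = 0
                remaining_bins = n_bins - current
                desired = (n - placed) / remaining_bins if remaining_bins else desired
        assignment[order[start:stop]] = current
        in_current += size
        placed += size
    return assignment


def _clumps(x_order: np.ndarray, rows: np.ndarray) -> np.ndarray:
    """Boundaries (in x-sorted position) between runs of constant row.

    Returns cumulative point counts at clump ends, i.e. an increasing
    array of candidate partition positions ending at n.
    """
    row_seq = rows[x_order]
    change = np.flatnonzero(row_seq[1:] != row_seq[:-1]) + 1
    return np.concatenate([change, [len(x_order)]])


def _superclumps(ends: np.ndarray, limit: int) -> np.ndarray:
    """Cap the number of candidate boundaries by equal-count merging."""
    if len(ends) <= limit:
        return ends
    n = ends[-1]
    targets = n * np.arange(1, limit + 1) / limit
    picked = np.unique(ends[np.searchsorted(ends, targets, side="left")
                            .clip(0, len(ends) - 1)])
    if picked[-1] != n:
        picked = np.append(picked, n)
    return picked


def _optimize_axis(ends: np.ndarray, row_cum: np.ndarray, n: int,
                   max_bins: int, h_rows: float) -> np.ndarray:
    """Best mutual information for 2..max_bins column bins by DP.

    ``ends`` are candidate boundary positions (cumulative counts);
    ``row_cum[i]`` holds per-row cumulative counts at ends[i-1] (with
    row_cum[0] = 0).  Mutual information decomposes as H(rows) plus a
    sum of per-column-bin terms, which makes the DP exact over the
    candidate boundaries.
    """
    m = len(ends)

    def bin_term(lo: int, hi: int) -> float:
        counts = row_cum[hi] - row_cum[lo]
        size = counts.sum()
        if size == 0:
            return 0.0
        nz = counts[counts > 0]
        return float(np.sum(nz / n * np.log2(nz / size)))

    term = np.full((m + 1, m + 1), -np.inf)
    for lo in range(m + 1):
        for hi in range(lo + 1, m + 1):
            term[lo, hi] = bin_term(lo, hi)

    best = np.full(max_bins + 1, -np.inf)
    f_prev = term[0, 1:m + 1].copy()           # exactly 1 bin over first i clumps
    for t in range(2, max_bins + 1):
        f_cur = np.full(m, -np.inf)
        for i in range(t - 1, m):
            # last bin covers clumps (j, i]; first j clumps hold t-1 bins
            f_cur[i] = np.max(f_prev[t - 2:i] + term[t - 1:i + 1, i + 1])
        best[t] = h_rows + f_cur[m - 1]
        f_prev = f_cur
    return best


def _characteristic_max(x: np.ndarray, y: np.ndarray, b: int, c: float
                        ) -> tuple[float, tuple[int, int]]:
    """Max normalized MI with y equipartitioned and x optimized."""
    n = len(x)
    best_score = 0.0
    best_grid = (2, 2)
    y_order = _stable_order(y)
    x_order = _stable_order(x)
    for s_rows in range(2, b // 2 + 1):
        rows = _equipartition(y_order, y, s_rows)
        n_rows = rows.max() + 1
        if n_rows < 2:
            continue
        row_counts = np.bincount(rows, minlength=n_rows)
        h_rows = -float(np.sum(row_counts / n * np.log2(row_counts / n)))
        max_cols = b // s_rows
        if max_cols < 2:
            continue
        ends = _clumps(x_order, rows)
        ends = _superclumps(ends, max(2, int(c * max_cols)))
        # per-row cumulative counts at candidate boundaries
        row_cum = np.zeros((len(ends) + 1, n_rows), dtype=np.int64)
        pos = 0
        for i, end in enumerate(ends, start=1):
            seg = rows[x_order[pos:end]]
            row_cum[i] = row_cum[i - 1] + np.bincount(seg, minlength=n_rows)
            pos = end
        scores = _optimize_axis(ends, row_cum, n, max_cols, h_rows)
        for t in range(2, max_cols + 1):
            if not np.isfinite(scores[t]):
                continue
            normalized = scores[t] / np.log2(min(t, n_rows))
            if normalized > best_score:
                best_score = normalized
                best_grid = (int(n_rows), int(t))
    return best_score, best_grid


def mic(x: np.ndarray, y: np.ndarray, alpha: float = 0.6, c: float = 15.0
        ) -> MICResult:
    """Maximal Information Coefficient of two vectors.

    Non-finite pairs are dropped.  Requires at least 8 complete pairs
    (the grid search needs resolution); a constant input yields MIC 0
    with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = len(x)
    if n < 8:
        raise ValueError("MIC needs at least 8 complete pairs")
    b = int(np.ceil(n ** alpha))
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        logger.warning("constant input; MIC undefined, reporting 0")
        return MICResult(0.0, (2, 2), b, alpha, c)

    score_xy, grid_xy = _characteristic_max(x, y, b, c)       # rows on y
    score_yx, grid_yx = _characteristic_max(y, x, b, c)       # rows on x
    if score_yx > score_xy:
        score, grid = score_yx, (grid_yx[1], grid_yx[0])
    else:
        score, grid = score_xy, (grid_xy[0], grid_xy[1])
    score = float(min(max(score, 0.0), 1.0))
    return MICResult(score, grid, b, alpha, c)


def mic_oracle(x: np.ndarray, y: np.ndarray, max_cells: int = 16) -> float:
    """Exhaustive MIC over ALL grids with r * s <= max_cells (n <= 12 only).

    Partition boundaries are placed between consecutive points in stable
    rank order, matching the tie policy of the heuristic, so on small
    inputs the oracle's search space is a superset of the heuristic's.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n > 12:
        raise ValueError("oracle limited to n <= 12 (combinatorial guard)")
    if max_cells > 16:
        raise ValueError("max_cells capped at 16")
    x_rank = np.empty(n, dtype=np.int64)
    x_rank[_stable_order(x)] = np.arange(n)
    y_rank = np.empty(n, dtype=np.int64)
    y_rank[_stable_order(y)] = np.arange(n)

    best = 0.0
    for r in range(2, max_cells // 2 + 1):
        for s in range(2, max_cells // r + 1):
            for x_cuts in itertools.combinations(range(1, n), r - 1):
                xi = np.searchsorted(np.array(x_cuts), x_rank, side="right")
                for y_cuts in itertools.combinations(range(1, n), s - 1):
                    yi = np.searchsorted(np.array(y_cuts), y_rank, side="right")
                    counts = np.zeros((r, s))
                    np.add.at(counts, (xi, yi), 1.0)
                    value = _mutual_information(counts) / np.log2(min(r, s))
                    if value > best:
                        best = value
    return float(min(best, 1.0))
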