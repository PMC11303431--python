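"""Weighted co-expression network construction.

The network is built the standard weighted-network way: a feature-by-
feature correlation matrix is raised elementwise to a soft-thresholding
power beta, chosen so that the connectivity distribution approximates
scale-free topology, and the resulting adjacency is converted to the
topological overlap matrix (TOM), a similarity that credits shared
neighbours and is far more robust to noise than the raw adjacency.

Unsigned networks (a_ij = |cor|^beta) are the default; signed networks
(a_ij = ((1 + cor)/2)^beta) are available via the ``signed`` flag.

All matrices are dense ``pandas.DataFrame`` objects indexed by feature
ID on both axes; the module refuses inputs above 20,000 features, the
desk-scale contract for this in-memory representation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger("coexmod")

MAX_FEATURES = 20_000

#: conventional candidate powers for the soft-threshold scan
DEFAULT_POWERS = tuple(range(1, 11)) + (12, 14, 16, 18, 20)


def _check_size(n_features: int) -> None:
    if n_features > MAX_FEATURES:
        raise ValueError(
            f"{n_features} features exceeds the {MAX_FEATURES} dense-matrix cap; "
            "filter features first"
        )


def correlation_matrix(matrix: pd.DataFrame, method: str = "pearson") -> pd.DataFrame:
    """All-pairs feature correlation across samples.

    Constant features are flagged and get correlation 0 with every other
    feature (their correlation is undefined, and 0 keeps them isolated
    in the network, which is the behaviour a practitioner wants).
    """
    if method not in ("pearson", "spearman"):
        raise ValueError(f"unknown correlation method {method!r}")
    if matrix.shape[0] < 3:
        raise ValueError("need at least 3 samples for a correlation network")
    if matrix.isna().any().any():
        raise ValueError("correlation_matrix requires a complete matrix")
    _check_size(matrix.shape[1])

    values = matrix.to_numpy(dtype=float)
    if method == "spearman":
        values = stats.rankdata(values, axis=0)
    sd = values.std(axis=0, ddof=1)
    constant = sd == 0
    if constant.any():
        logger.warning("%d constant feature(s); correlations set to 0",
                       int(constant.sum()))
    centered = values - values.mean(axis=0)
    safe_sd = np.where(constant, 1.0, sd)
    standardized = centered / safe_sd
    cor = standardized.T @ standardized / (values.shape[0] - 1)
    cor[constant, :] = 0.0
    cor[:, constant] = 0.0
    np.fill_diagonal(cor, 1.0)
    np.clip(cor, -1.0, 1.0, out=cor)
    return pd.DataFrame(cor, index=matrix.columns, columns=matrix.columns)


def adjacency(cor: pd.DataFrame, power: float, signed: bool = False) -> pd.DataFrame:
    """Soft-threshold a correlation matrix into a weighted adjacency.

    Unsigned: a_ij = |cor_ij|^power.  Signed: a_ij = ((1+cor_ij)/2)^power.
    The diagonal is set to 1.
    """
    if power < 1:
        raise ValueError("soft-threshold power must be >= 1")
    values = cor.to_numpy(dtype=float)
    if np.nanmax(np.abs(values)) > 1 + 1e-12:
        raise ValueError("correlation entries must lie in [-1, 1]")
    if signed:
        adj = ((1.0 + values) / 2.0) ** power
    else:
        adj = np.abs(values) ** power
    np.fill_diagonal(adj, 1.0)
    return pd.DataFrame(adj, index=cor.index, columns=cor.columns)


def connectivity(adj: pd.DataFrame) -> pd.Series:
    """Whole-network connectivity k_i = sum_{j != i} a_ij."""
    values = adj.to_numpy(dtype=float)
    k = values.sum(axis=1) - np.diag(values)
    return pd.Series(k, index=adj.index, name="k")


def scale_free_fit(k: np.ndarray, n_bins: int = 10) -> float:
    """Signed R^2 of the scale-free topology fit for a connectivity vector.

    Connectivities are discretized into ``n_bins`` equal-width bins;
    log10 of the per-bin frequency is regressed on log10 of the per-bin
    mean connectivity (empty bins and bins with zero mean dropped), and
    R^2 is reported with the sign of the slope negated, so a decaying
    (scale-free-like) distribution scores positively.
    """
    k = np.asarray(k, dtype=float)
    if np.ptp(k) == 0:
        logger.warning("all connectivities equal; scale-free fit undefined, "
                       "reporting 0")
        return 0.0
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    which = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
    mean_k = np.array([k[which == b].mean() if (which == b).any() else np.nan
                       for b in range(n_bins)])
    freq = np.array([(which == b).mean() for b in range(n_bins)])
    ok = ~np.isnan(mean_k) & (mean_k > 0) & (freq > 0)
    if ok.sum() < 2:
        logger.warning("fewer than 2 usable connectivity bins; reporting 0")
        return 0.0
    slope, _, r, _, _ = stats.linregress(np.log10(mean_k[ok]), np.log10(freq[ok]))
    return float(-np.sign(slope) * r**2)


def scan_soft_threshold(matrix: pd.DataFrame,
                        powers: tuple[float, ...] = DEFAULT_POWERS,
                        signed: bool = False,
                        method: str = "pearson") -> pd.DataFrame:
    """Evaluate candidate soft-threshold powers.

    Returns one row per power with the signed scale-free fit R^2 and the
    mean / median connectivity, the diagnostics used to pick beta.
    """
    if not powers:
        raise ValueError("powers must be nonempty")
    cor = correlation_matrix(matrix, method=method)
    base = cor.to_numpy(dtype=float)
    rows = []
    for power in powers:
        adj = adjacency(pd.DataFrame(base, index=cor.index, columns=cor.columns),
                        power, signed=signed)
        k = connectivity(adj).to_numpy()
        rows.append({
            "power": float(power),
            "r_squared": scale_free_fit(k),
            "mean_k": float(k.mean()),
            "median_k": float(np.median(k)),
        })
    return pd.DataFrame(rows)


@dataclass
class PowerChoice:
    power: float
    r_squared: float
    reached_cut: bool


def pick_power(scan: pd.DataFrame, r2_cut: float = 0.8) -> PowerChoice:
    """Pick the smallest power whose signed R^2 reaches the cut.

    If no power reaches the cut, the power with maximal signed R^2 is
    returned with ``reached_cut=False`` and a warning.
    """
    if scan.empty:
        raise ValueError("empty soft-threshold scan")
    ordered = scan.sort_values("power")
    hit = ordered[ordered["r_squared"] >= r2_cut]
    if len(hit):
        row = hit.iloc[0]
        return PowerChoice(float(row["power"]), float(row["r_squared"]), True)
    row = ordered.loc[ordered["r_squared"].idxmax()]
    logger.warning("no power reached R^2 >= %.2f; using power %g (R^2 = %.3f)",
                   r2_cut, row["power"], row["r_squared"])
    return PowerChoice(float(row["power"]), float(row["r_squared"]), False)


def recommended_max_power(n_samples: int, signed: bool = False) -> float:
    """Sample-size cap on the soft-threshold power.

    The scale-free fit index is a noisy statistic, and on cohorts where
    most features are unstructured it can keep climbing toward extreme
    powers at which the whole network disconnects.  Community practice
    caps beta at a sample-size-dependent default (the fewer the
    samples, the noisier the correlations and the higher the admissible
    power): unsigned networks use 9 / 8 / 7 / 6 for n < 20 / 30 / 40 /
    >= 40 samples, signed networks twice that.
    """
    if n_samples < 20:
        base = 9.0
    elif n_samples < 30:
        base = 8.0
    elif n_samples < 40:
        base = 7.0
    else:
        base = 6.0
    return base * 2 if signed else base


def topological_overlap(adj: pd.DataFrame) -> pd.DataFrame:
    """Topological overlap matrix of a weighted adjacency.

    TOM_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij), where
    l_ij = sum_{u != i,j} a_iu a_uj and k_i is the connectivity.  The
    diagonal is 1; a zero denominator (isolated node pair) yields 0.
    """
    a = adj.to_numpy(dtype=float)
    if not np.allclose(a, a.T, atol=1e-10):
        raise ValueError("adjacency must be symmetric")
    if a.min() < -1e-12 or a.max() > 1 + 1e-12:
        raise ValueError("adjacency entries must lie in [0, 1]")
    k = a.sum(axis=1) - np.diag(a)
    # (A @ A)_ij includes u = i and u = j; remove both terms
    diag = np.diag(a)
    shared = a @ a - diag[:, None] * a - a * diag[None, :]
    numerator = shared + a
    denominator = np.minimum.outer(k, k) + 1.0 - a
    with np.errstate(divide="ignore", invalid="ignore"):
        tom = np.where(denominator > 0, numerator / denominator, 0.0)
    np.fill_diagonal(tom, 1.0)
    np.clip(tom, 0.0, 1.0, out=tom)
    tom = (tom + tom.T) / 2.0
    return pd.DataFrame(tom, index=adj.index, columns=adj.columns)
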