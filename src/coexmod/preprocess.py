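"""Normalization and feature filtering ahead of network construction.

The microarray workflow this pipeline mirrors normalizes raw bead-level
intensities with robust spline normalization, whose output converges
toward quantile-equalized per-sample distributions.  Quantile
normalization is therefore the documented stand-in here; the downstream
network stages operate on correlations and are insensitive to any
monotone per-sample re-mapping of this kind.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger("coexmod")


@dataclass
class PreprocessReport:
    n_features_in: int
    n_features_out: int
    normalization_method: str
    variance_cutoff: float | None = None

    def __post_init__(self) -> None:
        if self.n_features_out > self.n_features_in:
            raise ValueError("cannot report more features out than in")


def log_transform(matrix: pd.DataFrame, offset: float = 1.0) -> pd.DataFrame:
    """Apply log2(x + offset) cellwise; raw-intensity convenience."""
    if offset < 0:
        raise ValueError("offset must be nonnegative")
    shifted = matrix.to_numpy(dtype=float) + offset
    bad = np.argwhere(shifted <= 0)
    if bad.size:
        i, j = bad[0]
        raise ValueError(
            f"log2 of nonpositive value at sample {matrix.index[i]!r}, "
            f"feature {matrix.columns[j]!r}"
        )
    return pd.DataFrame(np.log2(shifted), index=matrix.index, columns=matrix.columns)


def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Quantile-normalize samples (rows) to the mean sorted profile.

    After normalization every sample's sorted values equal the
    across-sample mean of sorted values.  Tied values within a sample
    receive the mean of the reference quantiles they span, which keeps
    the operation idempotent.
    """
    values = matrix.to_numpy(dtype=float)
    if np.isnan(values).any():
        raise ValueError(
            "quantile_normalize requires a complete matrix; impute or filter "
            "missing values first"
        )
    order = np.argsort(values, axis=1, kind="stable")
    reference = np.sort(values, axis=1).mean(axis=0)

    out = np.empty_like(values)
    n_samples, n_features = values.shape
    for s in range(n_samples):
        ranked = np.empty(n_features)
        ranked[order[s]] = reference
        row = values[s]
        # ties span a run of quantile slots; give each tied value the run mean
        uniq, inverse, counts = np.unique(row, return_inverse=True, return_counts=True)
        if len(uniq) < n_features:
            sums = np.zeros(len(uniq))
            np.add.at(sums, inverse, ranked)
            ranked = (sums / counts)[inverse]
        out[s] = ranked
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def filter_features(matrix: pd.DataFrame,
                    top_n: int | None = None,
                    min_variance: float | None = None,
                    ) -> tuple[pd.DataFrame, PreprocessReport]:
    """Keep the most variable features, by count or by variance cutoff.

    Exactly one criterion must be given.  Features are ranked by sample
    variance (denominator n-1), ties broken by feature ID ascending;
    the retained features keep their input column order.
    """
    if (top_n is None) == (min_variance is None):
        raise ValueError("give exactly one of top_n or min_variance")
    variances = matrix.var(axis=0, ddof=1)

    if top_n is not None:
        if top_n > matrix.shape[1]:
            logger.warning("top_n=%d exceeds %d features; keeping all",
                           top_n, matrix.shape[1])
            keep = set(matrix.columns)
        else:
            ranking = sorted(matrix.columns, key=lambda g: (-variances[g], g))
            keep = set(ranking[:top_n])
        cutoff = None
    else:
        keep = set(variances.index[variances >= min_variance])
        cutoff = min_variance

    filtered = matrix.loc[:, [g for g in matrix.columns if g in keep]]
    report = PreprocessReport(
        n_features_in=matrix.shape[1],
        n_features_out=filtered.shape[1],
        normalization_method="quantile",
        variance_cutoff=cutoff,
    )
    return filtered, report


def collapse_probes(matrix: pd.DataFrame, probe_to_gene: pd.Series) -> pd.DataFrame:
    """Collapse probes mapping to the same gene, keeping the max-variance probe.

    ``probe_to_gene`` maps probe IDs (matrix columns) to gene symbols;
    unmapped probes are kept under their probe ID.
    """
    variances = matrix.var(axis=0, ddof=1)
    chosen: dict[str, str] = {}
    for probe in matrix.columns:
        gene = probe_to_gene.get(probe, probe)
        best = chosen.get(gene)
        if best is None or variances[probe] > variances[best] or (
                variances[probe] == variances[best] and probe < best):
            chosen[gene] = probe
    collapsed = matrix.loc[:, list(chosen.values())]
    collapsed.columns = list(chosen.keys())
    return collapsed
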