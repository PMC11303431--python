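"""Eigengene-trait and feature-trait association.

Module-trait association is the Pearson correlation of module
eigengenes with quantitative histological traits (microvessel density,
%CD105+ angiogenic endothelium, alpha-SMA pericyte coverage, macrophage
content, ...), with the two-sided p-value from the Student-t transform
of the correlation.  Missing trait values are dropped pairwise, so a
hole in one trait never costs samples for another.

An ``auto`` method is offered that applies the Shapiro-Wilk normality
test at alpha = 0.05 to each variable of a pair and uses Pearson when
both pass, Spearman otherwise — the convention used for correlating
qPCR and protein measurements against traits.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .modules import Eigengenes

logger = logging.getLogger("coexmod")


def correlation_pvalue(r: float, n: int) -> float:
    """Two-sided p-value for a correlation via the t-transform.

    t = r * sqrt(n - 2) / sqrt(1 - r^2) with n - 2 degrees of freedom;
    |r| = 1 maps to p = 0.
    """
    if n < 3:
        raise ValueError("need n >= 3 for a correlation p-value")
    if abs(r) > 1:
        raise ValueError("|r| must be <= 1")
    if abs(r) == 1:
        return 0.0
    t = r * np.sqrt(n - 2) / np.sqrt(1.0 - r * r)
    return float(2.0 * stats.t.sf(abs(t), df=n - 2))


def auto_method(x: np.ndarray, alpha: float = 0.05) -> str:
    """Pick "pearson" or "spearman" by a Shapiro-Wilk normality test."""
    x = np.asarray(x, dtype=float)
    x = x[np.isfinite(x)]
    if len(x) < 3:
        raise ValueError("need at least 3 finite values")
    if np.ptp(x) == 0:
        raise ValueError("normality of a constant vector is undefined")
    _, p = stats.shapiro(x)
    return "pearson" if p >= alpha else "spearman"


def _pair_correlation(x: np.ndarray, y: np.ndarray, method: str
                      ) -> tuple[float, float, int, str]:
    """Correlation of one complete-case pair; returns (r, p, n_used, method)."""
    ok = np.isfinite(x) & np.isfinite(y)
    n = int(ok.sum())
    if n < 3:
        return np.nan, np.nan, n, method
    xv, yv = x[ok], y[ok]
    if np.ptp(xv) == 0 or np.ptp(yv) == 0:
        logger.warning("constant variable in correlation; reporting r = 0")
        return 0.0, 1.0, n, method
    if method == "auto":
        method = "pearson" if (auto_method(xv) == "pearson"
                               and auto_method(yv) == "pearson") else "spearman"
    if method == "spearman":
        xv, yv = stats.rankdata(xv), stats.rankdata(yv)
    r = float(np.corrcoef(xv, yv)[0, 1])
    r = float(np.clip(r, -1.0, 1.0))
    return r, correlation_pvalue(r, n), n, method


@dataclass
class ModuleTraitResult:
    """Correlation/p/n/method matrices between eigengenes and traits."""

    r: pd.DataFrame
    p: pd.DataFrame
    n_used: pd.DataFrame
    method: pd.DataFrame
    p_adjusted: pd.DataFrame | None = None


def correlate_with_traits(eigengenes: Eigengenes | pd.DataFrame,
                          traits: pd.DataFrame,
                          method: str = "pearson",
                          bh_correction: bool = False) -> ModuleTraitResult:
    """Module-trait matrix: correlate each eigengene with each trait.

    Samples with a missing trait value are dropped pairwise per cell;
    cells with fewer than 3 complete pairs are reported as absent (NaN).
    Raw p-values are reported by default; Benjamini-Hochberg adjusted
    p-values (across all cells) are added when ``bh_correction`` is set.
    """
    if method not in ("pearson", "spearman", "auto"):
        raise ValueError(f"unknown method {method!r}")
    e = eigengenes.values if isinstance(eigengenes, Eigengenes) else eigengenes
    shared = e.index.intersection(traits.index)
    if len(shared) == 0:
        raise ValueError("eigengene and trait tables share no samples")
    e = e.loc[shared]
    t = traits.loc[shared]

    shape = (e.shape[1], t.shape[1])
    r = np.full(shape, np.nan)
    p = np.full(shape, np.nan)
    n = np.zeros(shape, dtype=int)
    used = np.full(shape, "", dtype=object)
    for i, module in enumerate(e.columns):
        for j, trait in enumerate(t.columns):
            r[i, j], p[i, j], n[i, j], used[i, j] = _pair_correlation(
                e[module].to_numpy(dtype=float),
                t[trait].to_numpy(dtype=float), method)

    index = pd.Index(e.columns, name="module")
    columns = pd.Index(t.columns, name="trait")
    result = ModuleTraitResult(
        r=pd.DataFrame(r, index=index, columns=columns),
        p=pd.DataFrame(p, index=index, columns=columns),
        n_used=pd.DataFrame(n, index=index, columns=columns),
        method=pd.DataFrame(used, index=index, columns=columns),
    )
    if bh_correction:
        flat = result.p.to_numpy().ravel()
        ok = np.isfinite(flat)
        adjusted = np.full_like(flat, np.nan)
        if ok.any():
            adjusted[ok] = multipletests(flat[ok], method="fdr_bh")[1]
        result.p_adjusted = pd.DataFrame(adjusted.reshape(shape),
                                         index=index, columns=columns)
    return result


def gene_significance(matrix: pd.DataFrame,
                      traits: pd.DataFrame,
                      trait: str,
                      method: str = "pearson") -> pd.DataFrame:
    """Per-feature correlation with one trait (GS) plus its p-value."""
    if trait not in traits.columns:
        raise KeyError(
            f"unknown trait {trait!r}; available: {list(traits.columns)}")
    shared = matrix.index.intersection(traits.index)
    t = traits.loc[shared, trait].to_numpy(dtype=float)
    rows = []
    for feature in matrix.columns:
        x = matrix.loc[shared, feature].to_numpy(dtype=float)
        r, p, n, used = _pair_correlation(x, t, method)
        rows.append({"feature_id": feature, "gs": r, "p": p,
                     "n_used": n, "method": used})
    out = pd.DataFrame(rows).set_index("feature_id")
    out.attrs["trait"] = trait
    return out
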