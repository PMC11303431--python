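"""Module detection: clustering the TOM, eigengenes, membership, merging.

Features are clustered by average-linkage hierarchical clustering on
the TOM dissimilarity 1 - TOM, and modules are obtained by a static
height cut (a fixed dissimilarity threshold; branches below the cut
become clusters, clusters smaller than ``min_size`` are relabelled
"grey", i.e. unassigned).  Surviving modules are labelled "M1", "M2",
... in decreasing size order.

A module's eigengene is the first principal component of its
standardized expression submatrix, scaled to unit variance across
samples and sign-oriented so that it correlates positively with the
module's average standardized profile — the single per-sample summary
profile that module-trait association works on.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

logger = logging.getLogger("coexmod")

GREY = "grey"

#: WGCNA-style color aliases for the size-ordered labels, for familiarity
COLOR_ALIASES = (
    "turquoise", "blue", "brown", "yellow", "green", "red", "black", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan", "midnightblue",
    "lightcyan", "grey60", "lightgreen", "lightyellow", "royalblue",
)


@dataclass
class Dendrogram:
    """Average-linkage merge history over features (scipy linkage matrix)."""

    linkage: np.ndarray
    feature_ids: list[str]
    method: str = "average"


@dataclass
class Eigengenes:
    """Per-module summary profiles: samples x modules, unit variance."""

    values: pd.DataFrame               # samples x module labels
    variance_explained: pd.Series      # per module, in [0, 1]

    @property
    def modules(self) -> list[str]:
        return list(self.values.columns)


def cluster_features(tom: pd.DataFrame) -> Dendrogram:
    """Average-linkage tree on the dissimilarity 1 - TOM."""
    if tom.shape[0] < 2:
        raise ValueError("need at least 2 features to cluster")
    dissimilarity = 1.0 - tom.to_numpy(dtype=float)
    np.fill_diagonal(dissimilarity, 0.0)
    dissimilarity = np.clip((dissimilarity + dissimilarity.T) / 2.0, 0.0, None)
    linkage = hierarchy.linkage(squareform(dissimilarity, checks=False),
                                method="average")
    return Dendrogram(linkage=linkage, feature_ids=[str(c) for c in tom.columns])


def cut_tree(dendrogram: Dendrogram, height: float = 0.98,
             min_size: int = 30) -> pd.Series:
    """Static height cut of the dendrogram into labelled modules.

    Branches entirely below ``height`` (on the 1 - TOM scale) become
    clusters; clusters smaller than ``min_size`` are relabelled grey.
    Surviving clusters are labelled "M1", "M2", ... by decreasing size,
    ties broken by the lexicographically smallest member feature ID.
    """
    if not 0 < height < 1:
        raise ValueError("cut height must lie in (0, 1)")
    flat = hierarchy.fcluster(dendrogram.linkage, t=height, criterion="distance")
    ids = dendrogram.feature_ids
    clusters: dict[int, list[str]] = {}
    for feature, cluster in zip(ids, flat):
        clusters.setdefault(int(cluster), []).append(feature)

    surviving = [members for members in clusters.values() if len(members) >= min_size]
    surviving.sort(key=lambda members: (-len(members), min(members)))

    labels = pd.Series(GREY, index=pd.Index(ids, name="feature_id"), name="module")
    for rank, members in enumerate(surviving, start=1):
        labels.loc[members] = f"M{rank}"
    return labels


def color_alias_table(assignment: pd.Series) -> pd.DataFrame:
    """Map size-ordered module labels to conventional color names."""
    modules = sorted({m for m in assignment if m != GREY},
                     key=lambda label: int(label[1:]))
    colors = [COLOR_ALIASES[i] if i < len(COLOR_ALIASES) else f"color{i + 1}"
              for i in range(len(modules))]
    return pd.DataFrame({"module": modules, "color": colors})


def _standardize(values: np.ndarray) -> np.ndarray:
    sd = values.std(axis=0, ddof=1)
    if (sd == 0).any():
        raise ValueError("constant feature in module")
    return (values - values.mean(axis=0)) / sd


def compute_eigengenes(matrix: pd.DataFrame, assignment: pd.Series) -> Eigengenes:
    """First principal component per module, unit variance, sign-oriented.

    The sign convention: the eigengene correlates non-negatively with
    the module's average standardized profile; if that average is
    exactly orthogonal to the eigengene (e.g. a two-feature module with
    mirrored profiles), orientation falls back to a positive correlation
    with the lexicographically smallest member feature.
    """
    modules = sorted({m for m in assignment if m != GREY},
                     key=lambda label: int(label[1:]) if label[1:].isdigit() else 0)
    if not modules:
        raise ValueError("no non-grey modules to summarize")
    n = matrix.shape[0]
    columns = {}
    explained = {}
    for module in modules:
        members = sorted(assignment.index[assignment == module])
        if len(members) < 2:
            raise ValueError(f"module {module} has fewer than 2 features")
        sub = matrix.loc[:, members].to_numpy(dtype=float)
        if np.isnan(sub).any():
            raise ValueError(f"module {module} contains missing values")
        try:
            standardized = _standardize(sub)
        except ValueError:
            raise ValueError(f"module {module} contains a constant feature") from None
        u, s, _ = np.linalg.svd(standardized, full_matrices=False)
        eigengene = u[:, 0]
        sd = eigengene.std(ddof=1)
        eigengene = eigengene / sd
        average = standardized.mean(axis=1)
        orient = float(np.dot(eigengene, average - average.mean()))
        if abs(orient) < 1e-12:
            first = standardized[:, 0]
            orient = float(np.dot(eigengene, first - first.mean()))
        if orient < 0:
            eigengene = -eigengene
        columns[module] = eigengene
        explained[module] = float(s[0] ** 2 / np.sum(s**2))
    values = pd.DataFrame(columns, index=matrix.index)
    values.index.name = "sample_id"
    return Eigengenes(values=values,
                      variance_explained=pd.Series(explained, name="variance_explained"))


def module_membership(matrix: pd.DataFrame, eigengenes: Eigengenes) -> pd.DataFrame:
    """kME: correlation of each feature with each module eigengene.

    Constant features get kME 0 with a warning.
    """
    shared = matrix.index.intersection(eigengenes.values.index)
    if len(shared) < 3:
        raise ValueError("need at least 3 shared samples for kME")
    x = matrix.loc[shared].to_numpy(dtype=float)
    e = eigengenes.values.loc[shared].to_numpy(dtype=float)
    sd_x = x.std(axis=0, ddof=1)
    constant = sd_x == 0
    if constant.any():
        logger.warning("%d constant feature(s); kME set to 0", int(constant.sum()))
    zx = (x - x.mean(axis=0)) / np.where(constant, 1.0, sd_x)
    ze = (e - e.mean(axis=0)) / e.std(axis=0, ddof=1)
    kme = zx.T @ ze / (len(shared) - 1)
    kme[constant, :] = 0.0
    np.clip(kme, -1.0, 1.0, out=kme)
    return pd.DataFrame(kme, index=matrix.columns, columns=eigengenes.values.columns)


def merge_similar_modules(matrix: pd.DataFrame,
                          assignment: pd.Series,
                          eigengenes: Eigengenes | None = None,
                          max_dissimilarity: float = 0.2,
                          ) -> tuple[pd.Series, Eigengenes]:
    """Iteratively merge modules whose eigengenes are highly correlated.

    The closest pair (eigengene correlation >= 1 - max_dissimilarity) is
    merged first and eigengenes are recomputed after every merge, so
    chains of similar modules collapse transitively.  Merged modules are
    relabelled by decreasing size afterwards.
    """
    assignment = assignment.copy()
    if eigengenes is None:
        eigengenes = compute_eigengenes(matrix, assignment)
    while len(eigengenes.modules) > 1:
        cor = eigengenes.values.corr()
        np.fill_diagonal(cor.values, -np.inf)
        i, j = np.unravel_index(np.argmax(cor.values), cor.shape)
        if cor.values[i, j] < 1.0 - max_dissimilarity:
            break
        keep, drop = cor.index[min(i, j)], cor.index[max(i, j)]
        logger.info("merging module %s into %s (eigengene r = %.3f)",
                    drop, keep, cor.values[i, j])
        assignment[assignment == drop] = keep
        eigengenes = compute_eigengenes(matrix, assignment)

    # relabel by decreasing size, ties by smallest member
    modules = [m for m in assignment.unique() if m != GREY]
    modules.sort(key=lambda m: (-int((assignment == m).sum()),
                                min(assignment.index[assignment == m])))
    mapping = {old: f"M{rank}" for rank, old in enumerate(modules, start=1)}
    relabelled = assignment.map(lambda m: mapping.get(m, GREY))
    relabelled.name = "module"
    return relabelled, compute_eigengenes(matrix, relabelled)
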