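"""Candidate nomination: hub ranking, dual PCC/MIC ranking, set overlap.

Three procedures turn the network and association results into gene or
peptide candidates:

* **Hub ranking** inside a trait-correlated module: members are ranked
  by absolute trait correlation (gene significance) and by centrality
  in the module's subnetwork (intramodular connectivity kIM by default,
  eigengene membership kME as an alternative); the combined score is
  the mean of the two ranks.
* **Dual ranking** of omics features against a trait: every feature is
  scored by Pearson correlation and by MIC, the top-k lists under each
  are intersected, and both lists are cross-referenced against
  annotation gene sets (e.g. plasma proteins, hemorrhage-related
  proteins).
* **Set overlap**: a one-sided hypergeometric upper-tail test for the
  overlap of two gene sets in a common universe (e.g. a differential
  expression list against a module's gene set).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io import GeneSetCollection
from .mic import mic
from .modules import GREY

logger = logging.getLogger("coexmod")


def intramodular_connectivity(adj: pd.DataFrame, assignment: pd.Series,
                              module: str) -> pd.Series:
    """kIM: each member's summed adjacency to the other members."""
    members = sorted(assignment.index[assignment == module])
    if not members:
        raise KeyError(f"unknown or empty module {module!r}")
    if len(members) < 2:
        raise ValueError(f"module {module!r} has fewer than 2 members")
    sub = adj.loc[members, members].to_numpy(dtype=float)
    kim = sub.sum(axis=1) - np.diag(sub)
    return pd.Series(kim, index=pd.Index(members, name="feature_id"), name="kIM")


def rank_hub_genes(gs: pd.DataFrame, centrality: pd.Series,
                   members: list[str] | None = None) -> pd.DataFrame:
    """Rank module members by trait correlation and centrality.

    ``gs`` is a gene-significance table (``gs`` column); ``centrality``
    is kIM or kME over the same features.  Members are ranked by |gs|
    descending and by centrality descending (rank 1 = best; ties share
    the order of ascending feature ID); the combined score is the mean
    of the two ranks, and the combined rank sorts by that score with
    ties broken by the better gs rank, then feature ID.
    """
    if members is None:
        members = list(centrality.index)
    if not members:
        raise ValueError("empty module")
    members = sorted(members)
    missing = [m for m in members if m not in gs.index or m not in centrality.index]
    if missing:
        raise KeyError(f"features missing from gs/centrality: {missing[:5]}")

    table = pd.DataFrame({
        "gs": gs.loc[members, "gs"].astype(float),
        "centrality": centrality.loc[members].astype(float),
    })
    order_gs = sorted(members, key=lambda g: (-abs(table.at[g, "gs"]), g))
    order_c = sorted(members, key=lambda g: (-table.at[g, "centrality"], g))
    table["gs_rank"] = pd.Series({g: i for i, g in enumerate(order_gs, 1)})
    table["centrality_rank"] = pd.Series({g: i for i, g in enumerate(order_c, 1)})
    table["combined_score"] = (table["gs_rank"] + table["centrality_rank"]) / 2.0
    final = sorted(members, key=lambda g: (table.at[g, "combined_score"],
                                           table.at[g, "gs_rank"], g))
    table["combined_rank"] = pd.Series({g: i for i, g in enumerate(final, 1)})
    table.index.name = "feature_id"
    return table.sort_values("combined_rank")


@dataclass
class DualRankingResult:
    """Top-k lists under |Pearson| and under MIC, with their intersection."""

    trait: str
    scores: pd.DataFrame               # per feature: pcc, mic, n_used
    top_pcc: list[str]
    top_mic: list[str]
    intersection: list[str]
    annotation_hits: dict[str, dict[str, dict]] = field(default_factory=dict)


def dual_rank_features(matrix: pd.DataFrame, target: pd.Series, k: int = 100,
                       gene_sets: GeneSetCollection | None = None,
                       alpha: float = 0.6, c: float = 15.0,
                       normalize_ids: bool = False) -> DualRankingResult:
    """Rank features against a trait by Pearson and by MIC, intersect top-k.

    Features with fewer than 8 complete pairs are excluded with a
    warning (MIC needs that much resolution).  Both rankings are
    descending with ties broken by feature ID ascending, so the output
    is invariant to input feature order.
    """
    shared = matrix.index.intersection(target.index)
    t = target.loc[shared].to_numpy(dtype=float)
    rows = []
    for feature in sorted(matrix.columns):
        x = matrix.loc[shared, feature].to_numpy(dtype=float)
        ok = np.isfinite(x) & np.isfinite(t)
        if ok.sum() < 8:
            logger.warning("feature %r has %d complete pairs (< 8); excluded",
                           feature, int(ok.sum()))
            continue
        xv, tv = x[ok], t[ok]
        if np.ptp(xv) == 0 or np.ptp(tv) == 0:
            pcc = 0.0
        else:
            pcc = float(np.corrcoef(xv, tv)[0, 1])
        rows.append({"feature_id": feature, "pcc": pcc,
                     "mic": mic(xv, tv, alpha=alpha, c=c).mic,
                     "n_used": int(ok.sum())})
    if not rows:
        raise ValueError("no feature has enough complete pairs")
    scores = pd.DataFrame(rows).set_index("feature_id")
    if k > len(scores):
        raise ValueError(f"k={k} exceeds {len(scores)} rankable features")

    by_pcc = sorted(scores.index, key=lambda g: (-abs(scores.at[g, "pcc"]), g))
    by_mic = sorted(scores.index, key=lambda g: (-scores.at[g, "mic"], g))
    top_pcc = by_pcc[:k]
    top_mic = by_mic[:k]
    intersection = sorted(set(top_pcc) & set(top_mic))

    hits: dict[str, dict[str, dict]] = {}
    if gene_sets is not None:
        hits = {
            "pcc": annotate_overlap(top_pcc, gene_sets, normalize=normalize_ids),
            "mic": annotate_overlap(top_mic, gene_sets, normalize=normalize_ids),
            "intersection": annotate_overlap(intersection, gene_sets,
                                             normalize=normalize_ids),
        }
    return DualRankingResult(trait=str(target.name), scores=scores,
                             top_pcc=top_pcc, top_mic=top_mic,
                             intersection=intersection, annotation_hits=hits)


def annotate_overlap(features: list[str], sets: GeneSetCollection,
                     normalize: bool = False) -> dict[str, dict]:
    """Cross-reference a feature list against each annotation set.

    Matching is case-sensitive unless ``normalize`` uppercases both
    sides.  Returns, per set: the hit list, its count, and its fraction
    of the input list.
    """
    out: dict[str, dict] = {}
    listed = list(features)
    for name, members in sets.items():
        if normalize:
            members_cmp = {m.upper() for m in members}
            hit = [f for f in listed if f.upper() in members_cmp]
        else:
            hit = [f for f in listed if f in members]
        out[name] = {
            "hits": hit,
            "count": len(hit),
            "fraction": len(hit) / len(listed) if listed else 0.0,
        }
    return out


@dataclass
class OverlapTest:
    universe: int
    set1_size: int
    set2_size: int
    overlap: int
    p_value: float
    fold_enrichment: float


def hypergeometric_overlap(overlap: int, set1_size: int, set2_size: int,
                           universe: int) -> OverlapTest:
    """One-sided hypergeometric upper-tail test for a set overlap.

    With a universe of ``universe`` genes containing ``set1_size``
    marked genes, the p-value is P(X >= overlap) for a draw of
    ``set2_size`` genes; fold enrichment is the observed overlap rate
    over its expectation.
    """
    if not 0 <= overlap <= min(set1_size, set2_size) <= universe:
        raise ValueError("inconsistent overlap/set/universe sizes")
    if max(set1_size, set2_size) > universe:
        raise ValueError("set larger than universe")
    p = float(stats.hypergeom.sf(overlap - 1, universe, set1_size, set2_size))
    p = min(max(p, 0.0), 1.0)
    expected = set1_size / universe
    observed = overlap / set2_size if set2_size else 0.0
    fold = observed / expected if expected > 0 else np.nan
    return OverlapTest(universe=universe, set1_size=set1_size,
                       set2_size=set2_size, overlap=overlap,
                       p_value=p, fold_enrichment=fold)


def module_gene_set(assignment: pd.Series, module: str) -> set[str]:
    """The gene set of one module (convenience for overlap testing)."""
    members = set(assignment.index[assignment == module])
    if not members:
        raise KeyError(f"unknown or empty module {module!r}")
    if module == GREY:
        logger.warning("overlap against the grey (unassigned) set is rarely "
                       "meaningful")
    return members
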