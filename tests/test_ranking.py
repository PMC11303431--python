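import itertools
from math import comb

import numpy as np
import pandas as pd
import pytest

from coexmod import io, ranking


def _adj(values, ids=None):
    values = np.asarray(values, dtype=float)
    ids = ids or [f"g{i}" for i in range(values.shape[0])]
    return pd.DataFrame(values, index=ids, columns=ids)


class TestIntramodularConnectivity:
    def test_uniform_triangle(self):
        a = _adj(np.full((3, 3), 0.5))
        np.fill_diagonal(a.values, 1.0)
        labels = pd.Series("M1", index=a.index)
        kim = ranking.intramodular_connectivity(a, labels, "M1")
        assert np.allclose(kim.values, 1.0)

    def test_isolated_member(self):
        a = _adj([[1, 0.5, 0.0], [0.5, 1, 0.0], [0.0, 0.0, 1.0]])
        labels = pd.Series("M1", index=a.index)
        kim = ranking.intramodular_connectivity(a, labels, "M1")
        assert kim["g2"] == 0.0

    def test_matches_restricted_row_sum(self, rng):
        x = rng.uniform(0, 1, size=(8, 8))
        a = (x + x.T) / 2
        np.fill_diagonal(a, 1.0)
        ids = [f"g{i}" for i in range(8)]
        labels = pd.Series(["M1"] * 5 + ["grey"] * 3, index=ids)
        kim = ranking.intramodular_connectivity(_adj(a, ids), labels, "M1")
        for gi, g in enumerate(ids[:5]):
            brute = sum(a[gi, gj] for gj in range(5) if gj != gi)
            assert kim[g] == pytest.approx(brute, abs=1e-12)

    def test_unknown_module(self):
        a = _adj(np.eye(3))
        labels = pd.Series("M1", index=a.index)
        with pytest.raises(KeyError):
            ranking.intramodular_connectivity(a, labels, "M9")


def _gs_frame(values):
    return pd.DataFrame({"gs": values, "p": 0.5})


class TestRankHubGenes:
    def test_double_winner_is_first(self):
        gs = _gs_frame(pd.Series({"gA": 0.9, "gB": 0.2, "gC": 0.5}))
        centrality = pd.Series({"gA": 3.0, "gB": 1.0, "gC": 2.0})
        table = ranking.rank_hub_genes(gs, centrality)
        assert table.at["gA", "combined_rank"] == 1

    def test_mirrored_ranks_tiebreak_on_gs(self):
        gs = _gs_frame(pd.Series({"gA": 0.9, "gB": 0.2}))
        centrality = pd.Series({"gA": 1.0, "gB": 2.0})
        table = ranking.rank_hub_genes(gs, centrality)
        assert table.at["gA", "combined_score"] == 1.5
        assert table.at["gB", "combined_score"] == 1.5
        # gA has the better gs rank, so it wins the tie
        assert table.at["gA", "combined_rank"] == 1
        assert table.at["gB", "combined_rank"] == 2

    def test_abs_gs_used(self):
        gs = _gs_frame(pd.Series({"gA": -0.95, "gB": 0.4}))
        centrality = pd.Series({"gA": 1.0, "gB": 1.0})
        table = ranking.rank_hub_genes(gs, centrality)
        assert table.at["gA", "gs_rank"] == 1

    def test_ranks_are_permutation(self, rng):
        ids = [f"g{i}" for i in range(20)]
        gs = _gs_frame(pd.Series(rng.uniform(-1, 1, 20), index=ids))
        centrality = pd.Series(rng.uniform(0, 5, 20), index=ids)
        table = ranking.rank_hub_genes(gs, centrality)
        for column in ("gs_rank", "centrality_rank", "combined_rank"):
            assert sorted(table[column]) == list(range(1, 21))

    def test_empty_module_rejected(self):
        with pytest.raises(ValueError):
            ranking.rank_hub_genes(_gs_frame(pd.Series(dtype=float)),
                                   pd.Series(dtype=float), members=[])


class TestDualRankFeatures:
    def _target(self, n=40, seed=0):
        rng = np.random.default_rng(seed)
        return pd.Series(rng.standard_normal(n), name="MVD",
                         index=[f"s{i}" for i in range(n)])

    def test_exact_linear_feature_tops_both(self):
        t = self._target()
        rng = np.random.default_rng(1)
        m = pd.DataFrame({"lin": 2.0 * t + 1.0,
                          "n1": rng.standard_normal(len(t)),
                          "n2": rng.standard_normal(len(t))}, index=t.index)
        result = ranking.dual_rank_features(m, t, k=1)
        assert result.top_pcc == ["lin"] and result.top_mic == ["lin"]
        assert result.scores.at["lin", "pcc"] == pytest.approx(1.0)
        assert result.scores.at["lin", "mic"] == pytest.approx(1.0)

    def test_k_equal_to_n_features_intersects_all(self):
        t = self._target(n=20)
        rng = np.random.default_rng(2)
        m = pd.DataFrame(rng.standard_normal((20, 4)),
                         columns=list("abcd"), index=t.index)
        result = ranking.dual_rank_features(m, t, k=4)
        assert result.intersection == ["a", "b", "c", "d"]

    def test_feature_order_invariance(self):
        t = self._target(n=30, seed=3)
        rng = np.random.default_rng(4)
        m = pd.DataFrame(rng.standard_normal((30, 6)),
                         columns=[f"f{j}" for j in range(6)], index=t.index)
        shuffled = m[list(m.columns[::-1])]
        a = ranking.dual_rank_features(m, t, k=3)
        b = ranking.dual_rank_features(shuffled, t, k=3)
        assert a.top_pcc == b.top_pcc and a.top_mic == b.top_mic
        assert a.scores.equals(b.scores)

    def test_sparse_feature_excluded_with_warning(self, caplog):
        t = self._target(n=12)
        m = pd.DataFrame({"good": np.arange(12.0),
                          "sparse": [1.0] * 5 + [np.nan] * 7}, index=t.index)
        with caplog.at_level("WARNING", logger="coexmod"):
            result = ranking.dual_rank_features(m, t, k=1)
        assert "sparse" not in result.scores.index
        assert "excluded" in caplog.text

    def test_annotation_hits_attached(self):
        t = self._target(n=20, seed=5)
        m = pd.DataFrame({"A": 1.0 * t, "B": -1.0 * t,
                          "C": np.random.default_rng(6).standard_normal(20)},
                         index=t.index)
        sets = io.GeneSetCollection(sets={"plasma": {"A", "Z"}})
        result = ranking.dual_rank_features(m, t, k=2, gene_sets=sets)
        assert result.annotation_hits["pcc"]["plasma"]["count"] == 1


class TestAnnotateOverlap:
    def test_counts_and_fraction(self):
        sets = io.GeneSetCollection(sets={"S": {"a", "b", "x"}})
        out = ranking.annotate_overlap(["a", "b", "c", "d"], sets)
        assert out["S"]["count"] == 2 and out["S"]["fraction"] == 0.5
        assert out["S"]["hits"] == ["a", "b"]

    def test_empty_set(self):
        sets = io.GeneSetCollection(sets={"S": set()})
        assert ranking.annotate_overlap(["a"], sets)["S"]["count"] == 0

    def test_case_sensitivity_policy(self):
        sets = io.GeneSetCollection(sets={"S": {"SPTBN1"}})
        assert ranking.annotate_overlap(["Sptbn1"], sets)["S"]["count"] == 0
        normalized = ranking.annotate_overlap(["Sptbn1"], sets, normalize=True)
        assert normalized["S"]["count"] == 1


def _enumeration_pvalue(k, K, n, N):
    """Exact upper-tail overlap probability by exhaustive enumeration."""
    universe = range(N)
    marked = set(range(K))
    hits = sum(1 for draw in itertools.combinations(universe, n)
               if len(marked & set(draw)) >= k)
    return hits / comb(N, n)


class TestHypergeometricOverlap:
    def test_zero_overlap_has_p_one(self):
        test = ranking.hypergeometric_overlap(0, 4, 5, 10)
        assert test.p_value == pytest.approx(1.0)

    def test_enumeration_example(self):
        test = ranking.hypergeometric_overlap(3, 4, 5, 10)
        assert test.p_value == pytest.approx(66 / 252)
        assert test.p_value == pytest.approx(_enumeration_pvalue(3, 4, 5, 10))

    def test_forced_overlap_support(self):
        # K + n > N forces a minimum overlap; max overlap has p matching
        # enumeration over the feasible support
        test = ranking.hypergeometric_overlap(4, 7, 4, 9)
        assert test.p_value == pytest.approx(_enumeration_pvalue(4, 7, 4, 9))

    def test_matches_enumeration_broadly(self):
        for N in (5, 8, 11):
            for K in (2, N // 2, N - 1):
                for n in (2, N // 2):
                    for k in range(0, min(K, n) + 1):
                        got = ranking.hypergeometric_overlap(k, K, n, N).p_value
                        assert got == pytest.approx(
                            _enumeration_pvalue(k, K, n, N), abs=1e-12), \
                            (k, K, n, N)

    def test_fold_enrichment(self):
        test = ranking.hypergeometric_overlap(3, 4, 5, 10)
        assert test.fold_enrichment == pytest.approx((3 / 5) / (4 / 10))

    def test_inconsistent_sizes_rejected(self):
        with pytest.raises(ValueError):
            ranking.hypergeometric_overlap(5, 4, 5, 10)
        with pytest.raises(ValueError):
            ranking.hypergeometric_overlap(1, 4, 20, 10)
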