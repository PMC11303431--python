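import numpy as np
import pandas as pd
import pytest

from coexmod import modules
from coexmod.simulate import generate_modular_expression


def _tom(values, ids=None):
    values = np.asarray(values, dtype=float)
    ids = ids or [f"g{i}" for i in range(values.shape[0])]
    return pd.DataFrame(values, index=ids, columns=ids)


def _expr(values, features=None):
    values = np.asarray(values, dtype=float)
    features = features or [f"g{j}" for j in range(values.shape[1])]
    return pd.DataFrame(values,
                        index=[f"s{i}" for i in range(values.shape[0])],
                        columns=features)


def _block_tom(sizes, within=0.9, between=0.05):
    n = sum(sizes)
    tom = np.full((n, n), between)
    start = 0
    for size in sizes:
        tom[start:start + size, start:start + size] = within
        start += size
    np.fill_diagonal(tom, 1.0)
    return _tom(tom)


class TestClusterFeatures:
    def test_two_features_single_merge(self):
        d = modules.cluster_features(_tom([[1.0, 0.9], [0.9, 1.0]]))
        assert d.linkage.shape == (1, 4)
        assert d.linkage[0, 2] == pytest.approx(0.1)

    def test_block_structure_separates_last(self):
        d = modules.cluster_features(_block_tom([3, 3]))
        # the final merge joins the two blocks at the between-block height
        assert d.linkage[-1, 2] == pytest.approx(0.95)
        assert (np.diff(d.linkage[:, 2]) >= -1e-12).all()

    def test_hand_traced_average_linkage(self):
        # dissimilarities: d(0,1)=0.1, d(0,2)=0.4, d(1,2)=0.5, d(*,3)=0.9
        # average linkage: (0,1)@0.1, then {0,1}+2 @ (0.4+0.5)/2 = 0.45,
        # then +3 @ 0.9
        dis = np.array([
            [0.0, 0.1, 0.4, 0.9],
            [0.1, 0.0, 0.5, 0.9],
            [0.4, 0.5, 0.0, 0.9],
            [0.9, 0.9, 0.9, 0.0],
        ])
        d = modules.cluster_features(_tom(1.0 - dis))
        heights = d.linkage[:, 2]
        assert np.allclose(heights, [0.1, 0.45, 0.9])


class TestCutTree:
    def test_two_blocks_recovered(self):
        d = modules.cluster_features(_block_tom([50, 50], within=0.9))
        labels = modules.cut_tree(d, height=0.5, min_size=30)
        assert set(labels) == {"M1", "M2"}
        assert (labels.value_counts() == 50).all()

    def test_min_size_sends_small_clusters_to_grey(self):
        d = modules.cluster_features(_block_tom([50, 50]))
        labels = modules.cut_tree(d, height=0.5, min_size=60)
        assert (labels == modules.GREY).all()

    def test_labels_ordered_by_size(self):
        d = modules.cluster_features(_block_tom([30, 45]))
        labels = modules.cut_tree(d, height=0.5, min_size=10)
        assert (labels.value_counts()["M1"], labels.value_counts()["M2"]) == (45, 30)

    @pytest.mark.parametrize("height", [0.0, 1.0, -0.3, 2.0])
    def test_height_outside_unit_interval_rejected(self, height):
        d = modules.cluster_features(_block_tom([4, 4]))
        with pytest.raises(ValueError):
            modules.cut_tree(d, height=height)

    def test_planted_block_plus_noise(self, small_cohort):
        from coexmod import (adjacency, correlation_matrix, topological_overlap)

        matrix, truth = small_cohort
        tom = topological_overlap(adjacency(correlation_matrix(matrix), 6))
        labels = modules.cut_tree(modules.cluster_features(tom))
        for planted in ("M1", "M2"):
            members = truth.membership[truth.membership == planted].index
            found = labels.loc[members].value_counts().idxmax()
            assert found != modules.GREY
            assert (labels.loc[members] == found).mean() > 0.9


class TestEigengenes:
    def test_identical_profiles(self, rng):
        profile = rng.standard_normal(12)
        m = _expr(np.tile(profile[:, None], (1, 4)))
        labels = pd.Series("M1", index=m.columns)
        e = modules.compute_eigengenes(m, labels)
        r = np.corrcoef(e.values["M1"], profile)[0, 1]
        assert r == pytest.approx(1.0, abs=1e-10)
        assert e.variance_explained["M1"] == pytest.approx(1.0)

    def test_unit_variance_and_range(self, small_cohort):
        matrix, truth = small_cohort
        labels = truth.membership.loc[truth.membership != "noise"]
        e = modules.compute_eigengenes(matrix.loc[:, labels.index], labels)
        assert np.allclose(e.values.std(ddof=1), 1.0, atol=1e-8)
        assert ((e.variance_explained >= 0) & (e.variance_explained <= 1)).all()

    def test_mirrored_pair_orientation_tiebreak(self, rng):
        profile = rng.standard_normal(10)
        m = _expr(np.stack([profile, -profile], axis=1), features=["gA", "gB"])
        labels = pd.Series("M1", index=m.columns)
        e = modules.compute_eigengenes(m, labels)
        assert e.variance_explained["M1"] == pytest.approx(1.0)
        # average standardized profile is exactly 0: orient to first member
        r = np.corrcoef(e.values["M1"], m["gA"])[0, 1]
        assert r > 0.99

    def test_recovers_planted_factor(self):
        matrix, truth = generate_modular_expression(
            n_samples=40, module_sizes=(50,), loading=0.8, noise_sd=0.6,
            n_noise_features=0, seed=11)
        e = modules.compute_eigengenes(matrix, truth.membership)
        r = np.corrcoef(e.values["M1"], truth.factors["M1"])[0, 1]
        assert r >= 0.9

    def test_orientation_deterministic(self, small_cohort):
        matrix, truth = small_cohort
        labels = truth.membership.loc[truth.membership != "noise"]
        sub = matrix.loc[:, labels.index]
        a = modules.compute_eigengenes(sub, labels)
        b = modules.compute_eigengenes(sub, labels)
        assert np.array_equal(a.values.values, b.values.values)
        # a copied (re-laid-out) input may differ at float rounding level
        # but never in orientation
        c = modules.compute_eigengenes(sub.copy(), labels.copy())
        assert np.allclose(a.values.values, c.values.values, atol=1e-12)

    def test_constant_feature_named_in_error(self):
        m = _expr([[1.0, 5.0], [2.0, 5.0], [3.0, 5.0]])
        labels = pd.Series("M1", index=m.columns)
        with pytest.raises(ValueError, match="M1"):
            modules.compute_eigengenes(m, labels)


class TestModuleMembership:
    def test_gene_equal_to_eigengene(self, small_cohort):
        matrix, truth = small_cohort
        labels = truth.membership.loc[truth.membership != "noise"]
        e = modules.compute_eigengenes(matrix.loc[:, labels.index], labels)
        probe = matrix.copy()
        probe["copy"] = e.values["M1"]
        kme = modules.module_membership(probe, e)
        assert kme.loc["copy", "M1"] == pytest.approx(1.0)

    def test_orthogonal_gene_scores_zero(self):
        e_profile = np.array([1.0, -1.0, 1.0, -1.0])
        orthogonal = np.array([1.0, 1.0, -1.0, -1.0])
        m = _expr(np.stack([e_profile, e_profile, orthogonal], axis=1))
        labels = pd.Series({"g0": "M1", "g1": "M1", "g2": "grey"})
        e = modules.compute_eigengenes(m, labels)
        kme = modules.module_membership(m, e)
        assert kme.loc["g2", "M1"] == pytest.approx(0.0, abs=1e-10)

    def test_own_module_kme_dominates(self):
        matrix, truth = generate_modular_expression(
            n_samples=40, module_sizes=(50, 50, 50), n_noise_features=0, seed=5)
        e = modules.compute_eigengenes(matrix, truth.membership)
        kme = modules.module_membership(matrix, e)
        own = np.array([kme.at[g, truth.membership[g]] for g in matrix.columns])
        best_other = np.array([
            kme.loc[g].drop(truth.membership[g]).abs().max()
            for g in matrix.columns])
        assert (own > best_other).mean() >= 0.95


class TestMergeSimilarModules:
    def _split_cohort(self, seed=3):
        # one planted module artificially split in two -> eigengenes correlate
        matrix, truth = generate_modular_expression(
            n_samples=40, module_sizes=(60,), loading=0.9, noise_sd=0.3,
            n_noise_features=0, seed=seed)
        labels = truth.membership.copy()
        labels.iloc[:30] = "M1"
        labels.iloc[30:] = "M2"
        return matrix, labels

    def test_highly_correlated_modules_merge(self):
        matrix, labels = self._split_cohort()
        merged, e = modules.merge_similar_modules(matrix, labels,
                                                  max_dissimilarity=0.2)
        assert set(merged) == {"M1"}
        assert e.modules == ["M1"]

    def test_distant_modules_stay_separate(self):
        matrix, truth = generate_modular_expression(
            n_samples=40, module_sizes=(40, 40), loading=0.9, noise_sd=0.3,
            n_noise_features=0, seed=9)
        merged, _ = modules.merge_similar_modules(matrix, truth.membership,
                                                  max_dissimilarity=0.2)
        assert set(merged) == {"M1", "M2"}

    def test_three_way_transitive_merge(self):
        matrix, truth = generate_modular_expression(
            n_samples=40, module_sizes=(90,), loading=0.95, noise_sd=0.2,
            n_noise_features=0, seed=13)
        labels = truth.membership.copy()
        labels.iloc[:30], labels.iloc[30:60], labels.iloc[60:] = "M1", "M2", "M3"
        merged, _ = modules.merge_similar_modules(matrix, labels,
                                                  max_dissimilarity=0.2)
        assert set(merged) == {"M1"}


def test_color_alias_table():
    labels = pd.Series(["M1", "M2", "grey", "M1"],
                       index=["a", "b", "c", "d"])
    table = modules.color_alias_table(labels)
    assert list(table["module"]) == ["M1", "M2"]
    assert list(table["color"]) == ["turquoise", "blue"]
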