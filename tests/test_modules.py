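"""Clustering, tree cutting, eigengenes, merging and connectivity scores."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from wallnet.datasets import PlantedDesign, generate_expression
from wallnet.network import GeneMatrix
from wallnet.modules import (
    cluster_eigengenes,
    cluster_genes,
    connectivity,
    cut_tree,
    kme,
    merge_modules,
    module_eigengene,
    module_meta_network,
)

from _oracles import naive_linkage
from conftest import random_adjacency


def _diss(m: np.ndarray, ids=None) -> GeneMatrix:
    ids = ids or [f"g{i:02d}" for i in range(m.shape[0])]
    return GeneMatrix(pd.DataFrame(m, index=ids, columns=ids), "dissimilarity")


def _block_diss(sizes, within=0.0, between=1.0):
    n = sum(sizes)
    m = np.full((n, n), between)
    start = 0
    for s in sizes:
        m[start : start + s, start : start + s] = within
        start += s
    np.fill_diagonal(m, 0.0)
    return m


class TestClusterGenes:
    def test_two_blocks_merge_last_at_their_separation(self):
        den = cluster_genes(_diss(_block_diss([3, 3])))
        assert den.heights[-1] == pytest.approx(1.0)
        assert np.all(np.diff(den.heights) >= -1e-12)

    def test_two_leaves(self):
        den = cluster_genes(_diss(np.array([[0.0, 0.37], [0.37, 0.0]])))
        assert den.heights.tolist() == [pytest.approx(0.37)]

    def test_average_linkage_matches_naive_oracle(self, rng):
        m = rng.uniform(0.1, 1.0, (15, 15))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 0.0)
        den = cluster_genes(_diss(m))
        assert sorted(den.heights) == pytest.approx(naive_linkage(m, "average"))

    def test_nan_rejected(self):
        m = _block_diss([2, 2])
        m[0, 1] = m[1, 0] = np.nan
        with pytest.raises(ValueError, match="NaN"):
            cluster_genes(_diss(m))


class TestCutTree:
    def test_recovers_two_planted_blocks(self):
        d = PlantedDesign(module_sizes=(60, 60), n_noise_genes=0, noise_sd=0.1, seed=5)
        expr, truth = generate_expression(d)
        diss = _diss(1 - np.abs(np.corrcoef(expr)), ids=list(expr.index))
        labels = cut_tree(cluster_genes(diss), min_module_size=50)
        assert labels.max() == 2
        assert adjusted_rand_score(truth.labels, labels) == 1.0

    def test_min_size_above_n_leaves_everything_unassigned(self):
        den = cluster_genes(_diss(_block_diss([4, 4])))
        assert (cut_tree(den, min_module_size=100) == 0).all()

    def test_small_block_stays_unassigned(self):
        den = cluster_genes(_diss(_block_diss([30, 60])))
        labels = cut_tree(den, min_module_size=50)
        assert (labels.iloc[:30] == 0).all()
        assert (labels.iloc[30:] == 1).all()

    def test_invalid_min_size(self):
        den = cluster_genes(_diss(_block_diss([3, 3])))
        with pytest.raises(ValueError):
            cut_tree(den, min_module_size=0)


class TestEigengene:
    def _profile_expr(self, n_genes=6, seed=0, sign=1.0):
        rng = np.random.default_rng(seed)
        z = rng.standard_normal(12)
        rows = {f"g{i}": sign * z for i in range(n_genes)}
        df = pd.DataFrame(rows).T
        df.columns = [f"s{i}" for i in range(12)]
        return df, z

    def test_identical_genes_give_their_profile(self):
        expr, z = self._profile_expr()
        labels = pd.Series(1, index=expr.index)
        me, ve = module_eigengene(expr, labels)
        assert ve["ME1"] == pytest.approx(1.0)
        zs = (z - z.mean()) / np.linalg.norm(z - z.mean())
        assert np.allclose(me.loc["ME1"], zs, atol=1e-10)

    def test_antisymmetric_module_uses_first_member_tiebreak(self):
        expr, z = self._profile_expr(n_genes=1)
        expr = pd.concat([expr, -expr.rename(index={"g0": "g1"})])
        labels = pd.Series(1, index=expr.index)
        me, ve = module_eigengene(expr, labels)
        assert ve["ME1"] == pytest.approx(1.0)
        r = np.corrcoef(me.loc["ME1"], expr.loc["g0"])[0, 1]
        assert r == pytest.approx(1.0)

    def test_eigengene_is_unit_norm_and_beats_random_directions(self, rng):
        expr = pd.DataFrame(
            rng.standard_normal((40, 29)) + 0.5 * rng.standard_normal((1, 29)),
            index=[f"g{i:02d}" for i in range(40)],
            columns=[f"s{i}" for i in range(29)],
        )
        labels = pd.Series(1, index=expr.index)
        me, ve = module_eigengene(expr, labels)
        assert np.linalg.norm(me.loc["ME1"]) == pytest.approx(1.0)
        g = (expr.T - expr.mean(axis=1)).T
        g = (g.T / expr.std(axis=1, ddof=1)).T.to_numpy()
        total = (g**2).sum()
        for _ in range(200):
            v = rng.standard_normal(29)
            v /= np.linalg.norm(v)
            assert ((g @ v) ** 2).sum() / total <= ve["ME1"] + 1e-12

    def test_variance_explained_equals_leading_eigenvalue_fraction(self, rng):
        # cross-check against an eigendecomposition of the gene-gene correlation matrix
        expr = pd.DataFrame(
            rng.standard_normal((15, 20)),
            index=[f"g{i:02d}" for i in range(15)],
            columns=[f"s{i}" for i in range(20)],
        )
        _, ve = module_eigengene(expr, pd.Series(1, index=expr.index))
        c = np.corrcoef(expr.to_numpy())
        eig = np.linalg.eigvalsh(c)
        # correlation uses population scaling; variance fractions agree regardless
        assert ve["ME1"] == pytest.approx(eig[-1] / eig.sum(), abs=1e-8)


class TestMerge:
    def test_same_latent_modules_merge(self):
        d = PlantedDesign(module_sizes=(10,), n_noise_genes=0, noise_sd=0.0, seed=1)
        expr, _ = generate_expression(d)
        labels = pd.Series([1] * 5 + [2] * 5, index=expr.index)
        merged = merge_modules(expr, labels)
        assert merged.nunique() == 1

    def test_orthogonal_modules_stay_separate(self):
        d = PlantedDesign(module_sizes=(30, 30), n_noise_genes=0, noise_sd=0.2, seed=2)
        expr, truth = generate_expression(d)
        merged = merge_modules(expr, truth.labels)
        assert merged.nunique() == 2

    def test_single_module_unchanged(self):
        d = PlantedDesign(module_sizes=(10,), n_noise_genes=0, seed=3)
        expr, truth = generate_expression(d)
        pd.testing.assert_series_equal(
            merge_modules(expr, truth.labels), truth.labels.rename("module")
        )

    def test_merge_reaches_fixed_point(self):
        d = PlantedDesign(module_sizes=(20, 20, 20), n_noise_genes=0, noise_sd=1.5, seed=4)
        expr, truth = generate_expression(d)
        merged = merge_modules(expr, truth.labels, merge_cut_height=0.4)
        if merged.nunique() >= 2:
            me, _ = module_eigengene(expr, merged)
            dmat = 1 - np.corrcoef(me.to_numpy())
            np.fill_diagonal(dmat, np.inf)
            assert dmat.min() >= 0.4


class TestConnectivity:
    def test_uniform_clique(self):
        a = np.full((4, 4), 0.5)
        np.fill_diagonal(a, 1.0)
        ids = list("abcd")
        A = GeneMatrix(pd.DataFrame(a, index=ids, columns=ids), "adjacency")
        tab = connectivity(A, pd.Series(1, index=ids))
        assert np.allclose(tab["kTotal"], 1.5)
        assert np.allclose(tab["kWithin"], 1.5)
        assert np.allclose(tab["kOut"], 0.0)

    def test_singleton_module_has_zero_within(self, rng):
        A = GeneMatrix(random_adjacency(rng, 5), "adjacency")
        labels = pd.Series([1, 1, 1, 1, 2], index=A.gene_ids)
        tab = connectivity(A, labels)
        assert tab.loc[A.gene_ids[-1], "kWithin"] == 0.0

    def test_identity_holds_exactly(self, rng):
        for _ in range(10):
            A = GeneMatrix(random_adjacency(rng, 12), "adjacency")
            labels = pd.Series(rng.integers(0, 4, 12), index=A.gene_ids)
            tab = connectivity(A, labels)
            assert (tab["kTotal"] == tab["kWithin"] + tab["kOut"]).all()

    def test_missing_labels_rejected(self, rng):
        A = GeneMatrix(random_adjacency(rng, 4), "adjacency")
        with pytest.raises(ValueError, match="missing"):
            connectivity(A, pd.Series({"g000": 1}))


class TestKme:
    def test_gene_equal_to_its_eigengene(self):
        d = PlantedDesign(module_sizes=(10,), n_noise_genes=0, noise_sd=0.3, seed=6)
        expr, truth = generate_expression(d)
        me, _ = module_eigengene(expr, truth.labels)
        probe = pd.DataFrame(
            [me.loc["ME1"], -me.loc["ME1"]], index=["plus", "minus"]
        )
        km = kme(probe, me)
        assert km.loc["plus", "ME1"] == pytest.approx(1.0)
        assert km.loc["minus", "ME1"] == pytest.approx(-1.0)

    def test_null_gene_rarely_tracks_foreign_eigengene(self):
        hits, n_seeds = 0, 100
        d = PlantedDesign(module_sizes=(10,), n_noise_genes=0, seed=0)
        expr, truth = generate_expression(d)
        me, _ = module_eigengene(expr, truth.labels)
        rng = np.random.default_rng(123)
        for _ in range(n_seeds):
            noise = pd.DataFrame(
                rng.standard_normal((1, 29)), index=["x"], columns=expr.columns
            )
            hits += abs(kme(noise, me).loc["x", "ME1"]) < 0.5
        assert hits / n_seeds >= 0.95

    def test_top_kme_gene_is_the_module_hub(self):
        d = PlantedDesign(module_sizes=(50,), n_noise_genes=0, noise_sd=0.5, seed=8)
        expr, truth = generate_expression(d)
        me, _ = module_eigengene(expr, truth.labels)
        km = kme(expr, me)["ME1"]
        # the ranking is consistent: the max is attained within the module
        assert km.idxmax() in truth.labels[truth.labels == 1].index
        assert km.max() == km.sort_values(ascending=False).iloc[0]


class TestEigengeneClustering:
    def test_identical_and_anticorrelated_heights(self, rng):
        z = rng.standard_normal(10)
        me = pd.DataFrame([z, z, -z], index=["ME1", "ME2", "ME3"])
        den = cluster_eigengenes(me)
        assert den.heights[0] == pytest.approx(0.0, abs=1e-12)
        assert den.heights[-1] == pytest.approx(2.0, abs=1e-12)

    def test_complete_linkage_matches_naive_oracle(self, rng):
        me = pd.DataFrame(
            rng.standard_normal((5, 12)), index=[f"ME{i+1}" for i in range(5)]
        )
        den = cluster_eigengenes(me)
        d = 1 - np.corrcoef(me.to_numpy())
        np.fill_diagonal(d, 0.0)
        assert sorted(den.heights) == pytest.approx(naive_linkage(d, "complete"))


class TestMetaNetwork:
    def _mes(self, rng, n=4):
        return pd.DataFrame(
            rng.standard_normal((n, 15)), index=[f"ME{i+1}" for i in range(n)]
        )

    def test_threshold_extremes(self, rng):
        me = self._mes(rng)
        assert module_meta_network(me, threshold=0.0).number_of_edges() == 6
        assert module_meta_network(me, threshold=1.0 + 1e-9).number_of_edges() == 0

    def test_shared_driver_modules_connected(self):
        d = PlantedDesign(module_sizes=(20,), n_noise_genes=0, noise_sd=0.2, seed=9)
        expr, truth = generate_expression(d)
        half = pd.Series([1] * 10 + [2] * 10, index=expr.index)
        me, _ = module_eigengene(expr, half)
        g = module_meta_network(me, threshold=0.5)
        assert g.has_edge("ME1", "ME2")
        assert g["ME1"]["ME2"]["weight"] > 0.5
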