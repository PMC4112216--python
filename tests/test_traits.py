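"""Correlation p-values, the percentile screen and candidate classification."""

import numpy as np
import pandas as pd
import pytest

from wallnet.datasets import PlantedDesign, TraitLink, generate_expression, generate_traits
from wallnet.modules import module_eigengene
from wallnet.traits import (
    classify_candidates,
    cluster_modules_by_trait_profile,
    corr_with_p,
    CorrelationReport,
    module_trait_matrix,
    pearson_pvalue,
    percentile_cutoff,
    screen_candidates,
    trait_correlation_matrix,
)

from _oracles import naive_linkage, t_two_sided_p


class TestCorrWithP:
    def test_orthogonal_vectors_give_p_one(self):
        x = np.array([1.0, -1.0, 1.0, -1.0])
        y = np.array([1.0, 1.0, -1.0, -1.0])
        r, p = corr_with_p(x, y)
        assert r == pytest.approx(0.0, abs=1e-15)
        assert p == pytest.approx(1.0, abs=1e-12)

    def test_perfect_correlation_gives_p_zero(self):
        r, p = corr_with_p([1, 2, 3, 4], [2, 4, 6, 8])
        assert (r, p) == (1.0, 0.0)

    def test_r_half_at_n29_gives_t_three(self):
        # t^2 = r^2 (n-2) / (1-r^2) = 0.25*27/0.75 = 9 exactly
        r = 0.5
        t = r * np.sqrt(27) / np.sqrt(1 - r * r)
        assert t == pytest.approx(3.0, abs=1e-12)
        assert pearson_pvalue(r, 29) == pytest.approx(t_two_sided_p(3.0, 27), abs=1e-10)
        assert pearson_pvalue(r, 29) == pytest.approx(0.0058, abs=2e-4)

    @pytest.mark.parametrize("n", [10, 29, 100])
    def test_matches_integration_oracle(self, n):
        for r in np.arange(0.1, 0.95, 0.1):
            t = r * np.sqrt(n - 2) / np.sqrt(1 - r * r)
            assert pearson_pvalue(float(r), n) == pytest.approx(
                t_two_sided_p(t, n - 2), abs=1e-10
            )

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            corr_with_p([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_p_monotone_in_abs_r(self):
        ps = [pearson_pvalue(r, 29) for r in (0.1, 0.3, 0.5, 0.7, 0.9)]
        assert all(a > b for a, b in zip(ps, ps[1:]))


class TestModuleTraitMatrix:
    def test_noiseless_trait_hits_r_one(self):
        links = (TraitLink("t", 1, 1.0, 0.0),)
        d = PlantedDesign(
            n_samples=29, module_sizes=(60, 60, 60), n_noise_genes=40,
            noise_sd=0.5, seed=7, trait_links=links,
        )
        expr, truth = generate_expression(d)
        tt = generate_traits(truth, d)
        me, _ = module_eigengene(expr, truth.labels)
        rep = module_trait_matrix(me, tt)
        assert rep.r.shape == (3, 1)
        assert abs(rep.r.loc["ME1", "t"]) > 0.99

    def test_sample_mismatch_lists_ids(self, small_data):
        expr, truth, traits = small_data
        me, _ = module_eigengene(expr, truth.labels)
        bad = traits.rename(index={traits.index[0]: "WRONG"})
        with pytest.raises(ValueError, match="WRONG"):
            module_trait_matrix(me, bad)

    def test_permuted_trait_max_correlation_null(self):
        # 56 random eigengenes vs 1000 permutations of one trait at n=29:
        # the null max |r| stays clearly below 0.7 for 95% of permutations
        rng = np.random.default_rng(11)
        me = rng.standard_normal((56, 29))
        trait = rng.standard_normal(29)
        maxima = []
        mec = (me - me.mean(axis=1, keepdims=True))
        mec /= np.linalg.norm(mec, axis=1, keepdims=True)
        for _ in range(1000):
            perm = rng.permutation(trait)
            pc = (perm - perm.mean()) / np.linalg.norm(perm - perm.mean())
            maxima.append(np.abs(mec @ pc).max())
        assert np.quantile(maxima, 0.95) < 0.7


class TestTraitCorrelationMatrix:
    def test_diagonal_and_symmetry(self, small_data):
        _, _, traits = small_data
        rep = trait_correlation_matrix(traits)
        assert np.allclose(np.diag(rep.r), 1.0)
        assert np.allclose(rep.r, rep.r.T)
        assert np.allclose(rep.p, rep.p.T)

    def test_shared_module_traits_strongly_correlated(self, small_data):
        # cellulose and Xyl are driven by the same planted module
        _, _, traits = small_data
        rep = trait_correlation_matrix(traits)
        assert rep.r.loc["cellulose", "Xyl"] > 0.7
        assert rep.p.loc["cellulose", "Xyl"] < 0.01


class TestScreen:
    def test_percentile_cutoff_interpolates(self):
        assert percentile_cutoff([0.01, 0.2, 0.4, 0.8]) == pytest.approx(0.1525)

    def test_only_lowest_p_gene_selected(self):
        # four genes whose p-values reproduce the interpolation example shape
        rng = np.random.default_rng(5)
        trait = rng.standard_normal(20)
        rows = {}
        for name, mix in [("strong", 0.9), ("weak1", 0.25), ("weak2", 0.15), ("null", 0.0)]:
            rows[name] = mix * trait + (1 - mix) * rng.standard_normal(20)
        expr = pd.DataFrame(rows).T
        expr.columns = [f"s{i}" for i in range(20)]
        hits = screen_candidates(expr, trait)
        assert hits == ["strong"]

    def test_all_equal_pvalues_select_nothing(self):
        rng = np.random.default_rng(6)
        trait = rng.standard_normal(15)
        g = rng.standard_normal(15)
        expr = pd.DataFrame([g, g, g, g], index=list("abcd"))
        expr.columns = [f"s{i}" for i in range(15)]
        assert screen_candidates(expr, trait) == []

    def test_about_a_quarter_selected_from_continuum(self):
        rng = np.random.default_rng(7)
        trait = rng.standard_normal(30)
        expr = pd.DataFrame(
            rng.standard_normal((100, 30)),
            index=[f"g{i:03d}" for i in range(100)],
        )
        expr.columns = [f"s{i}" for i in range(30)]
        n = len(screen_candidates(expr, trait))
        assert 23 <= n <= 25  # bottom quartile, strict inequality

    def test_selection_never_exceeds_quarter_bound(self):
        rng = np.random.default_rng(8)
        for n_genes in (4, 10, 37, 80):
            trait = rng.standard_normal(25)
            expr = pd.DataFrame(
                rng.standard_normal((n_genes, 25)),
                index=[f"g{i:03d}" for i in range(n_genes)],
            )
            expr.columns = [f"s{i}" for i in range(25)]
            frac = len(screen_candidates(expr, trait)) / n_genes
            assert frac <= 0.25 + 2 / n_genes

    def test_empty_module_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            screen_candidates(pd.DataFrame(), np.zeros(5))


class TestClassify:
    def test_subgroup_labels(self):
        sets = {
            "cellulose": ["g1", "g2", "g4"],
            "Xyl": ["g2", "g4"],
            "Ara": ["g4"],
        }
        labels = classify_candidates(sets, trait_order=["cellulose", "Xyl", "Ara"])
        assert labels["g1"] == "Cel"
        assert labels["g2"] == "Cel + Xyl"
        assert labels["g4"] == "Multi"
        assert "g3" not in labels.index


class TestTraitProfileClustering:
    def test_identical_rows_merge_at_zero(self):
        r = pd.DataFrame(
            [[0.5, -0.2], [0.5, -0.2], [-0.9, 0.9]],
            index=["ME1", "ME2", "ME3"], columns=["cel", "xyl"],
        )
        rep = CorrelationReport(r=r, p=r * 0 + 0.5, n=29)
        den, clades = cluster_modules_by_trait_profile(rep, cut_height=0.1)
        assert den.heights[0] == pytest.approx(0.0)
        assert clades["ME1"] == clades["ME2"] != clades["ME3"]

    def test_two_rows_merge_at_their_euclidean_distance(self):
        r = pd.DataFrame([[0.0, 0.0], [3.0, 4.0]], index=["ME1", "ME2"], columns=list("ab"))
        rep = CorrelationReport(r=r, p=r * 0 + 0.5, n=29)
        den, _ = cluster_modules_by_trait_profile(rep)
        assert den.heights[0] == pytest.approx(5.0)

    def test_matches_naive_complete_linkage(self, rng):
        r = pd.DataFrame(
            rng.uniform(-1, 1, (6, 7)), index=[f"ME{i+1}" for i in range(6)]
        )
        rep = CorrelationReport(r=r, p=r * 0 + 0.5, n=29)
        den, _ = cluster_modules_by_trait_profile(rep)
        from scipy.spatial.distance import squareform, pdist

        d = squareform(pdist(r.to_numpy()))
        assert sorted(den.heights) == pytest.approx(naive_linkage(d, "complete"))


def test_planted_screen_enriches_linked_module_genes():
    """Genes of a trait-driving module survive the screen far beyond chance."""
    from scipy.stats import fisher_exact

    for seed in range(3):
        links = (TraitLink("t", 1, effect=1.0, noise_sd=0.3),)
        d = PlantedDesign(
            module_sizes=(60,), n_noise_genes=60, noise_sd=0.5, seed=seed,
            trait_links=links,
        )
        expr, truth = generate_expression(d)
        tt = generate_traits(truth, d)
        hits = set(screen_candidates(expr, tt["t"]))
        planted = set(truth.labels[truth.labels == 1].index)
        k = len(hits & planted)
        table = [
            [k, len(hits) - k],
            [len(planted) - k, len(expr) - len(hits) - len(planted) + k],
        ]
        assert fisher_exact(table, alternative="greater")[1] < 0.01
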