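import itertools
import math

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from macroevo_paths import pathsynth, synthgen
from macroevo_paths.pathsynth import CausalModel
from macroevo_paths.treekit import read_newick


def star_tree(n):
    return read_newick("(" + ",".join(f"s{i}:1" for i in range(n)) + ");")


class TestCausalModel:
    def test_cycle_rejected(self):
        with pytest.raises(ValueError):
            CausalModel("bad", (("BG", "SR"), ("SR", "BG")))

    def test_default_set_has_eleven_acyclic_models(self):
        models = pathsynth.default_model_set()
        assert len(models) == 11
        for m in models:
            assert nx.is_directed_acyclic_graph(m.graph)

    def test_first_four_are_single_direct_effects(self):
        models = pathsynth.default_model_set()
        for m in models[:4]:
            assert len(m.edges) == 1
            assert m.edges[0][1] == "SR"

    def test_json_round_trip(self):
        models = pathsynth.default_model_set()
        back = pathsynth.models_from_json([m.to_dict() for m in models])
        assert [m.edges for m in back] == [m.edges for m in models]


class TestDsepBasis:
    def test_single_edge_five_vertices_gives_nine_claims(self):
        model = CausalModel("m1", (("BG", "SR"),))
        assert len(pathsynth.dsep_basis(model)) == 9

    def test_complete_dag_gives_zero_claims(self):
        verts = ("a", "b", "c", "d", "e")
        edges = tuple((verts[i], verts[j])
                      for i in range(5) for j in range(i + 1, 5))
        model = CausalModel("full", edges, vertices=verts)
        assert pathsynth.dsep_basis(model) == []

    def test_chain_claim(self):
        G = nx.DiGraph([("BG", "climR"), ("climR", "SR")])
        assert pathsynth.dsep_basis(G) == [("BG", "SR", ("climR",))]

    def test_claims_grow_when_edges_removed(self):
        models = pathsynth.default_model_set()
        for m in models:
            for drop in range(len(m.edges)):
                smaller = CausalModel(
                    "sub", m.edges[:drop] + m.edges[drop + 1:])
                assert len(pathsynth.dsep_basis(smaller)) \
                    >= len(pathsynth.dsep_basis(m))

    def test_every_claim_is_d_separation(self):
        # oracle: networkx d-separation on random DAGs over 5 vertices
        rng = np.random.default_rng(0)
        verts = list("abcde")
        pairs = [(x, y) for x, y in itertools.permutations(verts, 2)]
        for _ in range(60):
            edges = [e for e in pairs if rng.uniform() < 0.3]
            G = nx.DiGraph()
            G.add_nodes_from(verts)
            G.add_edges_from(edges)
            if not nx.is_directed_acyclic_graph(G):
                continue
            for x, y, Z in pathsynth.dsep_basis(G):
                assert nx.is_d_separator(G, {x}, {y}, set(Z))


class TestPGLS:
    def test_star_tree_equals_ols(self):
        tree = star_tree(12)
        rng = np.random.default_rng(1)
        x = rng.normal(size=12)
        y = 1.0 + 0.5 * x + rng.normal(size=12) * 0.3
        fit = pathsynth.pgls_lambda(
            pd.Series(y, index=tree.tip_labels),
            pd.Series(x, index=tree.tip_labels, name="x"), tree, lam=0.0)
        slope, intercept = np.polyfit(x, y, 1)
        assert fit.params["x"] == pytest.approx(slope, abs=1e-8)
        assert fit.params["intercept"] == pytest.approx(intercept,
                                                        abs=1e-8)

    def test_exact_linear_relation(self, medium_tree):
        rng = np.random.default_rng(2)
        x = pd.Series(rng.normal(size=medium_tree.n_tips),
                      index=medium_tree.tip_labels, name="x")
        y = 2.0 * x
        fit = pathsynth.pgls_lambda(y, x, medium_tree)
        assert fit.params["x"] == pytest.approx(2.0, abs=1e-6)
        assert fit.pvalues["x"] < 1e-10

    def test_profile_maximum_beats_grid(self, medium_tree):
        # lambda-hat should not be worse than coarse grid alternatives
        y, _ = synthgen.simulate_traits_bm(medium_tree, 1.0, seed=3)
        y = y["trait_1"]
        rng = np.random.default_rng(3)
        x = pd.Series(rng.normal(size=medium_tree.n_tips),
                      index=medium_tree.tip_labels, name="x")
        free = pathsynth.pgls_lambda(y, x, medium_tree)
        for lam in (0.0, 0.5, 1.0):
            fixed = pathsynth.pgls_lambda(y, x, medium_tree, lam=lam)
            assert free.loglik >= fixed.loglik - 1e-6
        assert 0.0 <= free.lambda_ <= 1.0

    def test_matches_dense_gls_oracle(self, medium_tree):
        from macroevo_paths.treekit import shared_path_matrix

        rng = np.random.default_rng(4)
        n = medium_tree.n_tips
        x = rng.normal(size=n)
        y = 0.8 * x + rng.normal(size=n)
        lam = 0.6
        fit = pathsynth.pgls_lambda(
            pd.Series(y, index=medium_tree.tip_labels),
            pd.Series(x, index=medium_tree.tip_labels, name="x"),
            medium_tree, lam=lam)
        V = shared_path_matrix(medium_tree)
        Vs = V / V.diagonal().mean()
        C = lam * Vs + (1 - lam) * np.eye(n)
        X = np.column_stack([np.ones(n), x])
        Ci = np.linalg.inv(C)
        beta = np.linalg.solve(X.T @ Ci @ X, X.T @ Ci @ y)
        assert np.allclose(fit.params.values, beta, atol=1e-6)


class TestPhyloLogistic:
    def test_no_association_small_coefficient(self):
        tree = star_tree(4)
        y = pd.Series([0, 1, 0, 1], index=tree.tip_labels)
        x = pd.Series([1, 1, -1, -1], index=tree.tip_labels, name="x")
        fit = pathsynth.phylo_logistic(y, x, tree)
        assert abs(fit.params["x"]) < 0.2

    def test_complete_separation_stays_finite(self):
        tree = star_tree(4)
        y = pd.Series([0, 0, 1, 1], index=tree.tip_labels)
        x = pd.Series([-1, -1, 1, 1], index=tree.tip_labels, name="x")
        fit = pathsynth.phylo_logistic(y, x, tree)
        assert np.isfinite(fit.params["x"])
        assert fit.params["x"] > 0

    def test_species_order_invariance(self, medium_tree):
        rng = np.random.default_rng(5)
        n = medium_tree.n_tips
        y = pd.Series(rng.integers(0, 2, n),
                      index=medium_tree.tip_labels)
        x = pd.Series(rng.normal(size=n), index=medium_tree.tip_labels,
                      name="x")
        fit1 = pathsynth.phylo_logistic(y, x, medium_tree)
        perm = rng.permutation(n)
        fit2 = pathsynth.phylo_logistic(
            y.iloc[perm], x.iloc[perm], medium_tree)
        assert fit1.params["x"] == pytest.approx(fit2.params["x"],
                                                 abs=1e-8)

    def test_one_class_rejected(self):
        tree = star_tree(6)
        y = pd.Series(np.zeros(6), index=tree.tip_labels)
        x = pd.Series(np.arange(6.0), index=tree.tip_labels, name="x")
        with pytest.raises(ValueError):
            pathsynth.phylo_logistic(y, x, tree)


class TestFitModel:
    def _data(self, tree, seed=0):
        model = CausalModel("gen", (("BG", "climR"), ("climR", "SR")))
        df, _ = synthgen.make_ppa_dataset(
            tree, model.graph,
            {("BG", "climR"): 0.8, ("climR", "SR"): 0.8},
            residual_lambda=0.3, seed=seed)
        aux = np.random.default_rng(77_000 + seed)
        df["vegR"] = aux.normal(size=len(df))
        df["florR"] = aux.normal(size=len(df))
        return df[["BG", "climR", "vegR", "florR", "SR"]]

    def test_fisher_c_and_cicc_arithmetic(self):
        # C from two p-values of 0.5; chi2 tail with 4 df; CICc plug-in
        C = -2 * (math.log(0.5) + math.log(0.5))
        assert C == pytest.approx(2.773, abs=5e-4)
        assert stats.chi2.sf(C, 4) == pytest.approx(0.596, abs=1e-3)
        q, n = 5, 100
        assert 0 + 2 * q * n / (n - 1 - q) == pytest.approx(10.638,
                                                            abs=5e-4)

    def test_fit_reports_claims_and_edges(self, medium_tree):
        data = self._data(medium_tree)
        model = CausalModel("m5", (("BG", "climR"), ("climR", "SR")))
        fit = pathsynth.fit_model(model, data, medium_tree)
        assert fit.k == len(pathsynth.dsep_basis(model))
        assert fit.q == 2
        assert fit.C >= 0
        assert set(map(tuple, fit.edge_coefficients[["from", "to"]]
                       .to_numpy())) == set(model.edges)

    def test_true_model_fits_data_well(self, medium_tree):
        # the generating chain should usually not be rejected
        ps = []
        for s in range(8):
            data = self._data(medium_tree, seed=40 + s)
            model = CausalModel("m5", (("BG", "climR"), ("climR", "SR")))
            ps.append(pathsynth.fit_model(model, data,
                                          medium_tree).p_value)
        assert np.median(ps) > 0.05

    def test_all_unit_pvalues_give_zero_C(self):
        from macroevo_paths.pathsynth import PathFitStats

        # C is a pure function of the claim p-values
        assert -2 * sum(math.log(1.0) for _ in range(5)) == 0.0


class TestRankAndAverage:
    def test_identical_models_share_weight(self, medium_tree):
        data = TestFitModel()._data(medium_tree, seed=7)
        m = CausalModel("a", (("BG", "climR"), ("climR", "SR")))
        m2 = CausalModel("b", (("BG", "climR"), ("climR", "SR")))
        fits, avg = pathsynth.rank_and_average([m, m2], data,
                                               medium_tree)
        assert fits[0].weight == pytest.approx(0.5, abs=1e-6)
        assert fits[0].cicc == pytest.approx(fits[1].cicc, abs=1e-9)
        # averaged coefficients equal the single-model coefficients
        single = fits[0].edge_coefficients.sort_values(["from", "to"])
        merged = avg.sort_values(["from", "to"])
        assert np.allclose(single["coef"].values, merged["coef"].values,
                           atol=1e-9)

    def test_weights_sum_to_one_and_best_rel_lik_is_one(self,
                                                        medium_tree):
        data = TestFitModel()._data(medium_tree, seed=8)
        models = pathsynth.default_model_set()[:5]
        fits, _ = pathsynth.rank_and_average(models, data, medium_tree)
        assert sum(f.weight for f in fits) == pytest.approx(1.0,
                                                            abs=1e-9)
        assert fits[0].rel_likelihood == pytest.approx(1.0)
        assert all(fits[i].cicc <= fits[i + 1].cicc
                   for i in range(len(fits) - 1))

    def test_chain_structure_recovered(self):
        # data generated under BG -> climR -> SR should prefer the chain
        # over the single-edge alternatives
        chain = CausalModel("chain", (("BG", "climR"), ("climR", "SR")),
                            vertices=("BG", "climR", "SR"))
        alt1 = CausalModel("bg_sr", (("BG", "SR"),),
                           vertices=("BG", "climR", "SR"))
        alt2 = CausalModel("clim_sr", (("climR", "SR"),),
                           vertices=("BG", "climR", "SR"))
        tree, _ = synthgen.simulate_bd_tree(0.3, 0.0, crown_age=12.0,
                                            seed=77)
        wins = 0
        for s in range(10):
            df, _ = synthgen.make_ppa_dataset(
                tree, chain.graph,
                {("BG", "climR"): 0.9, ("climR", "SR"): 0.9},
                residual_lambda=0.3, seed=900 + s)
            fits, _ = pathsynth.rank_and_average([chain, alt1, alt2],
                                                 df, tree)
            wins += fits[0].model.name == "chain"
        assert wins >= 7
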