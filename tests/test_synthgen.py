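import math

import numpy as np
import pandas as pd
import pytest

from macroevo_paths import synthgen
from macroevo_paths.oushift import RegimePainting
from macroevo_paths.treekit import read_newick


class TestBDTreeSimulator:
    def test_pure_stasis_gives_two_tips(self):
        tree, _ = synthgen.simulate_bd_tree(1e-9, 0.0, crown_age=7.0,
                                            seed=0)
        assert tree.n_tips == 2
        assert np.allclose(tree.branch_lengths[tree.parent >= 0], 7.0)

    def test_fixed_seed_is_bit_identical(self):
        a, ta = synthgen.simulate_bd_tree(0.3, 0.1, crown_age=8.0, seed=5)
        b, tb = synthgen.simulate_bd_tree(0.3, 0.1, crown_age=8.0, seed=5)
        assert a.to_newick() == b.to_newick()
        assert ta.to_json() == tb.to_json()

    def test_yule_mean_tip_count(self):
        # E[N | 2 crown lineages, no extinction] = 2 e^{lambda T}; the
        # crown-survival conditioning is vacuous for a pure-birth process
        lam, T = 0.2, 10.0
        counts = [synthgen.simulate_bd_tree(lam, 0.0, crown_age=T,
                                            seed=s)[0].n_tips
                  for s in range(300)]
        expected = 2 * math.exp(lam * T)
        se = np.std(counts) / math.sqrt(len(counts))
        assert abs(np.mean(counts) - expected) < 4 * se + 0.5

    def test_sampling_fraction_thins_tips(self):
        full = [synthgen.simulate_bd_tree(0.3, 0.0, crown_age=10.0,
                                          seed=s)[0].n_tips
                for s in range(60)]
        half = [synthgen.simulate_bd_tree(0.3, 0.0, crown_age=10.0, f=0.5,
                                          seed=s)[0].n_tips
                for s in range(60)]
        assert np.mean(half) < 0.75 * np.mean(full)

    def test_crown_age_preserved_after_sampling(self):
        tree, _ = synthgen.simulate_bd_tree(0.3, 0.1, crown_age=9.0,
                                            f=0.5, seed=2)
        assert tree.crown_age == pytest.approx(9.0, rel=1e-9)


class TestRateShiftTree:
    def test_shift_elevates_dr_inside_clade(self):
        from macroevo_paths.tiprates import dr_statistic

        wins = 0
        total = 0
        for s in range(30):
            tree, truth = synthgen.simulate_rate_shift_tree(
                0.16, 0.0, shift_age=10.0, multiplier=3.0,
                crown_age=20.0, seed=s)
            shifted = set(truth.params["shifted_tips"])
            if len(shifted) < 3 or len(shifted) > tree.n_tips - 3:
                continue
            dr = dr_statistic(tree)
            inside = dr[dr.index.isin(shifted)].median()
            outside = dr[~dr.index.isin(shifted)].median()
            total += 1
            wins += inside > outside
        assert total >= 10
        assert wins / total >= 0.8

    def test_truth_records_shifted_lambda(self):
        _, truth = synthgen.simulate_rate_shift_tree(
            0.16, 0.0, shift_age=5.0, multiplier=3.0, crown_age=10.0,
            seed=1)
        assert truth.params["shifted_lambda"] == pytest.approx(0.48)

    def test_invalid_multiplier(self):
        with pytest.raises(ValueError):
            synthgen.simulate_rate_shift_tree(0.2, multiplier=0.0)


class TestTraitSimulators:
    def test_bm_zero_rate_keeps_root_value(self, balanced4):
        df, _ = synthgen.simulate_traits_bm(balanced4, 0.0, dims=2, seed=0)
        assert np.allclose(df.to_numpy(), 0.0)

    def test_bm_two_tip_variance(self):
        # Var(x_A - x_B) = 2 sigma2 t for a cherry with branch length t
        tree = read_newick("(A:2,B:2);")
        sigma2 = 0.7
        diffs = []
        for s in range(2000):
            df, _ = synthgen.simulate_traits_bm(tree, sigma2, seed=s)
            diffs.append(df.loc["A", "trait_1"] - df.loc["B", "trait_1"])
        var = np.var(diffs)
        assert var == pytest.approx(2 * sigma2 * 2.0, rel=0.15)

    def test_bm_clade_multiplier_inflates_variance(self):
        tree = read_newick("((A:1,B:1):3,(C:1,D:1):3);")
        hits = 0
        for s in range(40):
            df, _ = synthgen.simulate_traits_bm(
                tree, 0.5, clade_multipliers={("A", "B"): 10.0}, seed=s)
            v_in = df.loc[["A", "B"], "trait_1"].var()
            v_out = df.loc[["C", "D"], "trait_1"].var()
            hits += v_in > v_out
        assert hits >= 30

    def test_ou_alpha_zero_matches_bm_distribution(self):
        tree = read_newick("((A:1,B:1):1,(C:1,D:1):1);")
        p = RegimePainting.single_regime(tree)
        xs_ou = [synthgen.simulate_traits_ou(tree, p, 0.0, 1.0, [0.0],
                                             seed=s)[0]["A"]
                 for s in range(400)]
        xs_bm = [synthgen.simulate_traits_bm(tree, 1.0, seed=10_000 + s)[0]
                 .loc["A", "trait_1"] for s in range(400)]
        from scipy.stats import ks_2samp
        assert ks_2samp(xs_ou, xs_bm).pvalue > 0.01

    def test_ou_stationary_moments_under_strong_selection(self):
        tree = read_newick("(A:5,B:5);")
        alpha, sigma2, theta = 10.0, 2.0, 5.0
        p = RegimePainting.single_regime(tree)
        vals = [synthgen.simulate_traits_ou(tree, p, alpha, sigma2,
                                            [theta], seed=s)[0]["A"]
                for s in range(800)]
        assert np.mean(vals) == pytest.approx(theta, abs=0.1)
        assert np.var(vals) == pytest.approx(sigma2 / (2 * alpha),
                                             rel=0.25)

    def test_ou_zero_noise_converges_to_optimum(self):
        tree = read_newick("(A:50,B:50);")
        p = RegimePainting.single_regime(tree)
        x, _ = synthgen.simulate_traits_ou(tree, p, 1.0, 1e-12, [3.0],
                                           seed=0)
        assert np.allclose(x.values, 3.0, atol=1e-4)


class TestBinaryCharacter:
    def test_zero_rates_fixed_root(self, balanced4):
        x, _ = synthgen.simulate_binary_character(balanced4, 0.0, 0.0,
                                                  root_state=0, seed=0)
        assert (x == 0).all()

    def test_symmetric_rates_stationary_frequency(self):
        tree = read_newick("(" + ",".join(f"t{i}:50" for i in range(40))
                           + ");")
        freqs = [synthgen.simulate_binary_character(tree, 0.5, 0.5,
                                                    seed=s)[0].mean()
                 for s in range(50)]
        assert np.mean(freqs) == pytest.approx(0.5, abs=0.06)

    def test_seed_reproducibility(self, balanced4):
        a, _ = synthgen.simulate_binary_character(balanced4, 0.3, 0.2,
                                                  seed=9)
        b, _ = synthgen.simulate_binary_character(balanced4, 0.3, 0.2,
                                                  seed=9)
        assert (a == b).all()


class TestRangeSimulator:
    def test_no_events_keeps_root_range(self, balanced4):
        ranges, _ = synthgen.simulate_ranges_dec(
            balanced4, ["X", "Y"], d=0.0, e=0.0, root_range=["X"], seed=0)
        assert all(r == frozenset({"X"}) for r in ranges.values())

    def test_range_size_increases_with_dispersal(self, medium_tree):
        sizes = []
        for d in (0.005, 0.05, 0.5):
            mean_size = np.mean([
                np.mean([len(r) for r in synthgen.simulate_ranges_dec(
                    medium_tree, list("VWXYZ"), d=d, e=0.0,
                    root_range=["V"], seed=s)[0].values()])
                for s in range(5)])
            sizes.append(mean_size)
        assert sizes[0] < sizes[1] < sizes[2]

    def test_seed_reproducibility(self, medium_tree):
        a, _ = synthgen.simulate_ranges_dec(medium_tree, ["X", "Y"],
                                            d=0.1, e=0.05, seed=3)
        b, _ = synthgen.simulate_ranges_dec(medium_tree, ["X", "Y"],
                                            d=0.1, e=0.05, seed=3)
        assert a == b


class TestPaleoCurves:
    def test_flat_linear_curve(self):
        c = synthgen.make_paleo_curve("linear", 30, value0=5.0, slope=0.0)
        assert np.allclose(c(np.linspace(0, 30, 50)), 5.0)

    def test_sinusoid_periodicity(self):
        c = synthgen.make_paleo_curve("sinusoid", 40, amplitude=2.0,
                                      period_ma=10.0)
        ages = np.linspace(0, 28, 57)
        assert np.allclose(c(ages), c(ages + 10.0), atol=1e-9)

    def test_logistic_uplift_monotone_toward_present(self):
        c = synthgen.make_paleo_curve("logistic-uplift", 35, vmax=4000.0,
                                      midpoint_ma=12.0, steepness=0.4)
        ages = np.linspace(0, 35, 200)
        vals = c(ages)
        assert np.all(np.diff(vals) <= 1e-9)  # decreasing with age
        expected = 4000.0 / (1 + np.exp(-0.4 * (12.0 - ages)))
        assert np.allclose(vals, expected, rtol=1e-6, atol=1e-6)


class TestPPADataset:
    def test_zero_coefficients_independent(self, medium_tree):
        import networkx as nx

        G = nx.DiGraph([("BG", "SR")])
        slopes = []
        for s in range(40):
            df, _ = synthgen.make_ppa_dataset(
                medium_tree, G, {("BG", "SR"): 0.0}, residual_lambda=0.0,
                seed=s)
            x = df["BG"] - df["BG"].mean()
            slopes.append(np.polyfit(x, df["SR"], 1)[0])
        assert abs(np.mean(slopes)) < 0.15

    def test_bg_is_balanced_binary(self, medium_tree):
        import networkx as nx

        G = nx.DiGraph([("BG", "SR")])
        df, _ = synthgen.make_ppa_dataset(medium_tree, G,
                                          {("BG", "SR"): 0.5}, seed=1)
        counts = df["BG"].value_counts()
        assert set(counts.index) == {0.0, 1.0}
        assert abs(counts[0.0] - counts[1.0]) <= 1

    def test_missing_coefficient_rejected(self, medium_tree):
        import networkx as nx

        G = nx.DiGraph([("BG", "SR"), ("BG", "climR")])
        with pytest.raises(ValueError):
            synthgen.make_ppa_dataset(medium_tree, G,
                                      {("BG", "SR"): 0.5}, seed=0)

    def test_seed_reproducibility(self, medium_tree):
        import networkx as nx

        G = nx.DiGraph([("BG", "climR"), ("climR", "SR")])
        coef = {("BG", "climR"): 0.8, ("climR", "SR"): 0.8}
        a, _ = synthgen.make_ppa_dataset(medium_tree, G, coef, seed=4)
        b, _ = synthgen.make_ppa_dataset(medium_tree, G, coef, seed=4)
        pd.testing.assert_frame_equal(a, b)


class TestScenario:
    def test_bundle_shape_and_determinism(self):
        b1 = synthgen.merianieae_like_scenario(seed=12)
        b2 = synthgen.merianieae_like_scenario(seed=12)
        assert b1["tree"].to_newick() == b2["tree"].to_newick()
        tree = b1["tree"]
        assert 100 <= tree.n_tips <= 180
        assert tree.crown_age == pytest.approx(30.0, rel=1e-6)
        assert len(b1["clades"]) == 7
        clade_tips = [t for c in b1["clades"] for t in c.tips]
        assert sorted(clade_tips) == sorted(tree.tip_labels)
        assert set(b1["bg"].unique()) == {0, 1}
        assert b1["traits_clim"].shape == (tree.n_tips, 3)
        assert len(b1["ranges"]) == tree.n_tips
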