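import math

import numpy as np
import pytest
from scipy.linalg import expm

from macroevo_paths import decrange, synthgen
from macroevo_paths.decrange import DECParams, RangeStateSpace
from macroevo_paths.treekit import read_newick


@pytest.fixture
def space2():
    return RangeStateSpace(["X", "Y"], max_range_size=2)


class TestStateSpace:
    def test_state_count(self):
        space = RangeStateSpace(list("ABCDEFGHI"), max_range_size=5)
        expected = sum(math.comb(9, k) for k in range(1, 6)) + 1
        assert space.n_states == expected

    def test_null_is_last(self, space2):
        assert space2.states[space2.null_index] == frozenset()
        assert space2.n_states == 4

    def test_adjacency_mask_disconnects(self):
        space = RangeStateSpace(["A", "B", "C"], max_range_size=3)
        adj = np.array([[1, 1, 0], [1, 1, 0], [0, 0, 1]])  # C isolated
        mask = space.allowed_mask(adj)
        assert not mask[space.state_of(["A", "C"])]
        assert mask[space.state_of(["A", "B"])]
        assert not mask[space.null_index]


class TestBuildQ:
    def test_zero_rates_zero_matrix(self, space2):
        Q = decrange.build_q(space2, DECParams(d=0.0, e=0.0))
        assert np.allclose(Q, 0.0)

    def test_single_source_dispersal_rate(self, space2):
        Q = decrange.build_q(space2, DECParams(d=0.3, e=0.0))
        i = space2.state_of(["X"])
        j = space2.state_of(["X", "Y"])
        assert Q[i, j] == pytest.approx(0.3)

    def test_multiplier_power(self):
        space = RangeStateSpace(["X", "Y"], max_range_size=2)
        m = np.array([[1.0, 0.5], [0.5, 1.0]])
        params = DECParams(d=1.0, e=0.0, w=2.0, multipliers=[m])
        Q = decrange.build_q(space, params)
        i, j = space.state_of(["X"]), space.state_of(["X", "Y"])
        assert Q[i, j] == pytest.approx(0.25)

    def test_rows_sum_to_zero_and_probability_conservation(self):
        space = RangeStateSpace(list("ABCD"), max_range_size=3)
        rng = np.random.default_rng(0)
        for _ in range(5):
            params = DECParams(d=rng.uniform(0, 0.5),
                               e=rng.uniform(0, 0.5),
                               w=rng.uniform(0, 3))
            Q = decrange.build_q(space, params)
            assert np.allclose(Q.sum(axis=1), 0.0, atol=1e-12)
            P = expm(Q * rng.uniform(0.1, 5.0))
            assert np.allclose(P.sum(axis=1), 1.0, atol=1e-9)

    def test_single_area_extirpation_goes_to_null(self, space2):
        Q = decrange.build_q(space2, DECParams(d=0.0, e=0.2))
        i = space2.state_of(["X"])
        assert Q[i, space2.null_index] == pytest.approx(0.2)
        # null row is absorbing
        assert np.allclose(Q[space2.null_index], 0.0)


class TestLoglik:
    def test_one_area_no_events(self):
        tree = read_newick("(A:1,B:1);")
        space = RangeStateSpace(["X"], max_range_size=1)
        ll = decrange.dec_loglik(tree, {"A": {"X"}, "B": {"X"}}, space,
                                 DECParams(d=0.0, e=0.0))
        assert ll == pytest.approx(0.0, abs=1e-12)

    def test_pure_extirpation_matrix_exponential(self, space2):
        # both tips {X}, d = 0: survival of X along both branches plus
        # subdominant paths from wider root states, summed at the root
        tree = read_newick("(A:1,B:1);")
        ll = decrange.dec_loglik(tree, {"A": {"X"}, "B": {"X"}}, space2,
                                 DECParams(d=0.0, e=0.1))
        Q = decrange.build_q(space2, DECParams(d=0.0, e=0.1))
        P = expm(Q * 1.0)
        iX, iY = space2.state_of(["X"]), space2.state_of(["Y"])
        iXY = space2.state_of(["X", "Y"])
        total = P[iX, iX] ** 2  # root {X}: narrow sympatry
        # root {X,Y}: 6 scenarios, 2 put a daughter in {X} directly
        for left, right in [(iX, iXY), (iXY, iX)]:
            total += (P[left, iX] * P[right, iX]) / 6.0
        assert ll == pytest.approx(math.log(total), abs=1e-10)

    def test_uniform_multipliers_make_w_irrelevant(self, space2):
        tree = read_newick("((A:1,B:1):1,C:2);")
        tips = {"A": {"X"}, "B": {"X", "Y"}, "C": {"Y"}}
        lls = [decrange.dec_loglik(
            tree, tips, space2,
            DECParams(d=0.05, e=0.02, w=w,
                      multipliers=[np.ones((2, 2))]))
            for w in (0.0, 1.5, 3.0)]
        assert np.allclose(lls, lls[0], atol=1e-12)

    def test_stratified_equals_unstratified_with_same_matrices(self):
        tree = read_newick("((A:1,B:1):1,C:2);")
        space = RangeStateSpace(["X", "Y", "Z"], max_range_size=2)
        tips = {"A": {"X"}, "B": {"Y"}, "C": {"Z"}}
        m = np.array([[1, 0.4, 0.7], [0.4, 1, 0.2], [0.7, 0.2, 1.0]])
        flat = decrange.dec_loglik(
            tree, tips, space,
            DECParams(d=0.1, e=0.03, multipliers=[m]))
        strat = decrange.dec_loglik(
            tree, tips, space,
            DECParams(d=0.1, e=0.03,
                      strata=[(float("inf"), 1.3), (1.3, 0.6), (0.6, 0.0)],
                      multipliers=[m, m, m]))
        assert strat == pytest.approx(flat, abs=1e-10)

    def test_jump_changes_likelihood(self, space2):
        tree = read_newick("(A:1,B:1);")
        tips = {"A": {"X"}, "B": {"Y"}}
        plain = decrange.dec_loglik(tree, tips, space2,
                                    DECParams(d=0.01, e=0.0))
        jumpy = decrange.dec_loglik(tree, tips, space2,
                                    DECParams(d=0.01, e=0.0, j=1.0),
                                    clado="DEC+J")
        assert jumpy > plain

    def test_disallowed_tip_range_rejected(self):
        space = RangeStateSpace(["A", "B", "C"], max_range_size=2)
        adj = np.array([[1, 1, 0], [1, 1, 0], [0, 0, 1]])
        tree = read_newick("(s1:1,s2:1);")
        with pytest.raises(Exception):
            decrange.dec_loglik(
                tree, {"s1": {"A", "C"}, "s2": {"B"}}, space,
                DECParams(d=0.1, e=0.0, adjacency=[adj]))


class TestFitDEC:
    def test_fixed_parameters_reproduce_loglik(self, medium_tree):
        ranges, _ = synthgen.simulate_ranges_dec(
            medium_tree, ["X", "Y", "Z"], d=0.05, e=0.01, seed=0)
        space = RangeStateSpace(["X", "Y", "Z"], max_range_size=3)
        params, ll, aicc = decrange.fit_dec(
            medium_tree, ranges, space, free=("d",),
            init={"e": 0.01}, starts=1, seed=0)
        direct = decrange.dec_loglik(medium_tree, ranges, space, params)
        assert ll == pytest.approx(direct, abs=1e-8)
        assert params.e == 0.01

    def test_recovery_within_factor_two(self):
        # small-scale d, e recovery on a batch of simulated datasets
        d_true, e_true = 0.05, 0.015
        ds, es = [], []
        for s in range(6):
            tree, _ = synthgen.simulate_bd_tree(0.3, 0.0, crown_age=12.0,
                                                seed=500 + s)
            ranges, _ = synthgen.simulate_ranges_dec(
                tree, list("WXYZ"), d=d_true, e=e_true, seed=s)
            space = RangeStateSpace(list("WXYZ"), max_range_size=4)
            params, *_ = decrange.fit_dec(tree, ranges, space,
                                          free=("d", "e"), starts=1,
                                          seed=s)
            ds.append(params.d)
            es.append(params.e)
        assert d_true / 2 <= np.median(ds) <= d_true * 2


class TestAncestralRanges:
    def test_degenerate_single_area(self):
        tree = read_newick("((A:1,B:1):1,C:2);")
        space = RangeStateSpace(["X"], max_range_size=1)
        tips = {"A": {"X"}, "B": {"X"}, "C": {"X"}}
        marg = decrange.ancestral_ranges(tree, tips, space,
                                         DECParams(d=0.0, e=0.0))
        iX = space.state_of(["X"])
        assert np.allclose(marg[:, iX], 1.0)

    def test_rows_sum_to_one(self, medium_tree):
        ranges, _ = synthgen.simulate_ranges_dec(
            medium_tree, ["X", "Y", "Z"], d=0.05, e=0.01, seed=4)
        space = RangeStateSpace(["X", "Y", "Z"], max_range_size=3)
        marg = decrange.ancestral_ranges(medium_tree, ranges, space,
                                         DECParams(d=0.05, e=0.01))
        assert np.allclose(marg.sum(axis=1), 1.0, atol=1e-9)

    def test_matches_exhaustive_enumeration(self, space2):
        # brute force over all (root state, inner state) combinations
        tree = read_newick("((A:1,B:1):1,C:2);")
        tips = {"A": {"X"}, "B": {"Y"}, "C": {"X"}}
        params = DECParams(d=0.07, e=0.03)
        marg = decrange.ancestral_ranges(tree, tips, space2, params)
        Q = decrange.build_q(space2, params)
        P1, P2 = expm(Q * 1.0), expm(Q * 2.0)
        iA = space2.state_of(tips["A"])
        iB = space2.state_of(tips["B"])
        iC = space2.state_of(tips["C"])
        states = [space2.state_of(s)
                  for s in (["X"], ["Y"], ["X", "Y"])]

        def scen(s):
            sc = decrange.cladogenetic_scenarios(space2, s)
            w = np.array([x[2] for x in sc])
            return [(a, b, wi) for (a, b, _), wi in zip(sc, w / w.sum())]

        root_m = np.zeros(space2.n_states)
        inner_m = np.zeros(space2.n_states)
        tot = 0.0
        for r in states:
            for (l1, r1, w1) in scen(r):
                pC = P2[r1, iC]
                for inner in states:
                    pin = P1[l1, inner]
                    for (l2, r2, w2) in scen(inner):
                        p = w1 * pC * pin * w2 * P1[l2, iA] * P1[r2, iB]
                        tot += p
                        root_m[r] += p
                        inner_m[inner] += p
        inner_node = [n for n in tree.internal_nodes
                      if n != tree.root][0]
        assert np.allclose(marg[tree.root], root_m / tot, atol=1e-10)
        assert np.allclose(marg[inner_node], inner_m / tot, atol=1e-10)


class TestStateOrderInvariance:
    def test_likelihood_invariant_to_area_order(self):
        tree = read_newick("((A:1,B:1):1,C:2);")
        tips = {"A": {"X"}, "B": {"Y"}, "C": {"Z"}}
        lls = []
        for areas in (["X", "Y", "Z"], ["Z", "X", "Y"], ["Y", "Z", "X"]):
            space = RangeStateSpace(areas, max_range_size=2)
            lls.append(decrange.dec_loglik(tree, tips, space,
                                           DECParams(d=0.1, e=0.05)))
        assert np.allclose(lls, lls[0], atol=1e-10)
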