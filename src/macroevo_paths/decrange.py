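"""Time-stratified dispersal-extinction-cladogenesis (DEC, optionally +J).

Ancestral geographic ranges are subsets of discrete areas.  Along branches
ranges evolve anagenetically by dispersal (rate d, modulated by per-stratum
dispersal multipliers raised to the power w) and extirpation (rate e); at
speciation events ranges are inherited cladogenetically by sympatry, subset
sympatry, or vicariance, plus founder-event jumps weighted by j in the +J
variant.  Likelihoods use the pruning algorithm with dense matrix
exponentials; branch segments crossing stratum boundaries are split exactly
at the boundary ages and multiplied in chronological order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy.linalg import expm
from scipy.optimize import minimize

from .treekit import TreeError

__all__ = [
    "RangeStateSpace", "DECParams", "build_q", "dec_loglik", "fit_dec",
    "ancestral_ranges", "cladogenetic_scenarios",
]


class RangeStateSpace:
    """Ordered state space: nonempty area subsets up to a max size + null.

    The null (empty) range is the last state; it is an absorbing anagenetic
    state only and never appears at tips, in cladogenesis, or at the root.
    """

    def __init__(self, areas, max_range_size=5):
        self.areas = [str(a) for a in areas]
        if len(set(self.areas)) != len(self.areas):
            raise ValueError("duplicate area names")
        if len(self.areas) > 9:
            raise ValueError("at most 9 areas supported by default")
        self.max_range_size = min(int(max_range_size), len(self.areas))
        states = []
        for k in range(1, self.max_range_size + 1):
            for combo in combinations(range(len(self.areas)), k):
                states.append(frozenset(combo))
        states.append(frozenset())  # null range, last
        self.states = states
        self.index = {s: i for i, s in enumerate(states)}
        self.null_index = len(states) - 1

    @property
    def n_states(self):
        return len(self.states)

    def state_of(self, area_names):
        idx = frozenset(self.areas.index(str(a)) for a in area_names)
        if idx not in self.index:
            raise ValueError(f"range {sorted(area_names)} not in state space")
        return self.index[idx]

    def label(self, state_index):
        s = self.states[state_index]
        if not s:
            return "-"
        return "+".join(self.areas[i] for i in sorted(s))

    def allowed_mask(self, adjacency=None):
        """Boolean mask of states whose areas are mutually reachable.

        ``adjacency`` is an area x area 0/1 matrix; a multi-area range is
        allowed only if its areas form a connected subgraph.  Null is never
        allowed as an observable/ancestral state.
        """
        mask = np.ones(self.n_states, dtype=bool)
        mask[self.null_index] = False
        if adjacency is None:
            return mask
        adj = np.asarray(adjacency, dtype=bool)
        for i, s in enumerate(self.states):
            if len(s) <= 1:
                continue
            nodes = sorted(s)
            seen = {nodes[0]}
            stack = [nodes[0]]
            while stack:
                u = stack.pop()
                for v in nodes:
                    if v not in seen and (adj[u, v] or adj[v, u]):
                        seen.add(v)
                        stack.append(v)
            if seen != set(nodes):
                mask[i] = False
        return mask


@dataclass
class DECParams:
    """DEC rates and the time-stratification of dispersal multipliers.

    ``strata`` is a list of (start_ma, end_ma) intervals, oldest first,
    tiling [0, infinity); ``multipliers`` holds one area x area matrix per
    stratum (values in [1e-5, 1]).  ``adjacency`` optionally holds one 0/1
    area x area matrix per stratum restricting allowed ancestral states.
    """

    d: float
    e: float
    j: float = 0.0
    w: float = 1.0
    strata: list = field(default_factory=lambda: [(float("inf"), 0.0)])
    multipliers: list | None = None
    adjacency: list | None = None

    def __post_init__(self):
        if self.d < 0 or self.e < 0 or self.j < 0:
            raise ValueError("d, e, j must be nonnegative")
        starts = [s for s, _ in self.strata]
        ends = [e for _, e in self.strata]
        if ends[-1] != 0.0 or any(
                s <= e for s, e in self.strata) or any(
                starts[i + 1] != ends[i] for i in range(len(starts) - 1)):
            # strata listed oldest first: (34, 20), (20, 15), ... (5, 0)
            raise ValueError("strata must tile [0, inf), oldest first")

    def stratum_at(self, age):
        for i, (start, end) in enumerate(self.strata):
            if end <= age <= start:
                return i
        raise ValueError(f"age {age} outside strata")

    def multiplier(self, stratum):
        if self.multipliers is None:
            return None
        return np.asarray(self.multipliers[stratum], dtype=float)


def build_q(space, params, stratum=0):
    """Anagenetic DEC rate matrix for one stratum (rows sum to 0).

    Dispersal into area a from range R occurs at rate
    ``sum_{b in R} d * m(b, a)^w``; extirpation of any occupied area occurs
    at rate e; extirpation from a single-area range leads to the absorbing
    null range.
    """
    n = space.n_states
    A = len(space.areas)
    m = params.multiplier(stratum)
    if m is None:
        m = np.ones((A, A))
    mw = np.power(np.maximum(m, 0.0), params.w)
    Q = np.zeros((n, n))
    for i, R in enumerate(space.states):
        if not R:
            continue  # null range is absorbing
        # dispersal: R -> R + {a}
        if len(R) < space.max_range_size:
            for a in range(A):
                if a in R:
                    continue
                target = frozenset(R | {a})
                jdx = space.index.get(target)
                if jdx is None:
                    continue
                rate = params.d * sum(mw[b, a] for b in R)
                Q[i, jdx] += rate
        # extirpation: R -> R - {a}
        for a in R:
            target = frozenset(R - {a})
            Q[i, space.index[target]] += params.e
    np.fill_diagonal(Q, Q.diagonal() - Q.sum(axis=1))
    return Q


def cladogenetic_scenarios(space, parent_state, j=0.0):
    """Ordered (left, right, weight) daughter-state scenarios for a range.

    Classic DEC events all get weight 1: narrow sympatry for single-area
    ranges; subset sympatry and vicariance for wider ranges.  With j > 0,
    founder-event jumps to any single unoccupied area get weight j.
    Weights are normalized by the caller.
    """
    R = space.states[parent_state]
    if not R:
        raise ValueError("null range cannot speciate")
    out = []
    seen = set()

    def add(left, right, weight):
        if (left, right) not in seen:
            seen.add((left, right))
            out.append((left, right, weight))

    if len(R) == 1:
        add(parent_state, parent_state, 1.0)
    else:
        for a in R:
            sa = space.index[frozenset({a})]
            rest = space.index[frozenset(R - {a})]
            add(sa, parent_state, 1.0)   # subset sympatry
            add(parent_state, sa, 1.0)
            add(sa, rest, 1.0)           # vicariance
            add(rest, sa, 1.0)
    if j > 0:
        for a in range(len(space.areas)):
            if a in R:
                continue
            sa = space.index[frozenset({a})]
            out.append((sa, parent_state, j))
            out.append((parent_state, sa, j))
    return out


def _branch_transition(space, params, age_top, age_bottom, q_cache):
    """Transition matrix over a branch (old age -> young age), stratified."""
    P = None
    age = age_top
    while age > age_bottom + 1e-12:
        s = params.stratum_at(age - 1e-12)
        seg_end = max(age_bottom, params.strata[s][1])
        dt = age - seg_end
        if s not in q_cache:
            q_cache[s] = build_q(space, params, s)
        Pseg = expm(q_cache[s] * dt)
        P = Pseg if P is None else P @ Pseg
        age = seg_end
    if P is None:
        P = np.eye(space.n_states)
    return P


def _masks_by_stratum(space, params):
    masks = []
    for s in range(len(params.strata)):
        adj = None if params.adjacency is None else params.adjacency[s]
        masks.append(space.allowed_mask(adj).astype(float))
    return masks


class _DECPruning:
    """Shared up-pass machinery for likelihood and ancestral states."""

    def __init__(self, tree, tip_ranges, space, params, clado="DEC"):
        tree.require_ultrametric()
        tree.require_bifurcating()
        self.tree = tree
        self.space = space
        self.params = params
        self.jump = params.j if clado.upper().endswith("J") else 0.0
        self.q_cache = {}
        self.masks = _masks_by_stratum(space, params)
        self.scen_cache = {}
        # tip state vectors
        self.tip_states = {}
        terminal_mask = self.masks[params.stratum_at(0.0)]
        for label, ranges in tip_ranges.items():
            idx = space.state_of(ranges)
            if terminal_mask[idx] == 0.0:
                raise TreeError(
                    f"tip {label!r} range {space.label(idx)} not allowed "
                    "in the terminal stratum")
            self.tip_states[tree.tip_index(label)] = idx
        if len(self.tip_states) != tree.n_tips:
            raise TreeError("tip ranges missing for some tips")

    def scenarios(self, state):
        if state not in self.scen_cache:
            sc = cladogenetic_scenarios(self.space, state, self.jump)
            lefts = np.array([s[0] for s in sc])
            rights = np.array([s[1] for s in sc])
            ws = np.array([s[2] for s in sc])
            self.scen_cache[state] = (lefts, rights, ws / ws.sum())
        return self.scen_cache[state]

    def up_pass(self):
        tree, space, params = self.tree, self.space, self.params
        n_states = space.n_states
        ages = tree.ages
        self.cond = np.zeros((tree.n_nodes, n_states))
        self.branch_P = {}
        self.log_scale = np.zeros(tree.n_nodes)
        for node in tree.postorder():
            if tree.is_tip(node):
                v = np.zeros(n_states)
                v[self.tip_states[node]] = 1.0
            else:
                kids = tree.children[node]
                down = []
                for c in kids:
                    P = _branch_transition(space, params, ages[node],
                                           ages[c], self.q_cache)
                    self.branch_P[c] = P
                    down.append(P @ self.cond[c])
                v = np.zeros(n_states)
                mask = self.masks[params.stratum_at(ages[node])]
                for state in range(n_states):
                    if mask[state] == 0.0 or not space.states[state]:
                        continue
                    lefts, rights, ws = self.scenarios(state)
                    v[state] = float(np.sum(
                        ws * down[0][lefts] * down[1][rights]))
                self.log_scale[node] = sum(
                    self.log_scale[c] for c in kids)
            top = float(v.max())
            if top <= 0:
                raise TreeError("zero likelihood during pruning")
            v /= top
            self.log_scale[node] += math.log(top)
            self.cond[node] = v
        root = tree.root
        mask = self.masks[params.stratum_at(ages[root])]
        # classic DEC convention: root states weighted equally (weight 1,
        # i.e. summed, not averaged)
        prior = mask.astype(float)
        self.root_prior = prior
        lik = float(prior @ self.cond[root])
        if lik <= 0:
            raise TreeError("zero likelihood at root")
        return math.log(lik) + self.log_scale[root]


def dec_loglik(tree, tip_ranges, space, params, clado="DEC"):
    """DEC / DEC+J log-likelihood of observed tip ranges."""
    return _DECPruning(tree, tip_ranges, space, params, clado).up_pass()


def fit_dec(tree, tip_ranges, space, free=("d", "e"), clado="DEC",
            init=None, strata=None, multipliers=None, adjacency=None,
            starts=3, seed=0):
    """Bounded ML fit of a subset of {d, e, j, w}.

    d and e are optimized on the log10 scale; j and w on [0, 3].  Fixed
    parameters take their values from ``init``.  Returns (DECParams,
    loglik, aicc).
    """
    free = list(free)
    if not free:
        raise ValueError("need at least one free parameter")
    base = dict(d=0.01, e=0.01, j=0.0, w=1.0)
    if init:
        base.update(init)
    kw = {}
    if strata is not None:
        kw["strata"] = strata
    if multipliers is not None:
        kw["multipliers"] = multipliers
    if adjacency is not None:
        kw["adjacency"] = adjacency
    rng = np.random.default_rng(seed)

    def unpack(x):
        p = dict(base)
        for name, v in zip(free, x):
            p[name] = 10.0 ** v if name in ("d", "e") else v
        return DECParams(**p, **kw)

    def pack():
        out = []
        for name in free:
            v = base[name]
            out.append(math.log10(max(v, 1e-6)) if name in ("d", "e") else v)
        return np.array(out)

    def negll(x):
        try:
            return -dec_loglik(tree, tip_ranges, space, unpack(x), clado)
        except (TreeError, ValueError, FloatingPointError):
            return 1e10

    bounds = [(-6.0, 1.0) if nm in ("d", "e") else (0.0, 3.0) for nm in free]
    x0 = pack()
    best = None
    for s in range(max(1, starts)):
        xs = x0 if s == 0 else x0 + rng.normal(0, 0.7, size=x0.size)
        xs = np.clip(xs, [b[0] for b in bounds], [b[1] for b in bounds])
        res = minimize(negll, xs, method="L-BFGS-B", bounds=bounds,
                       options={"maxiter": 200})
        if best is None or res.fun < best.fun:
            best = res
    if best is None or best.fun >= 1e10:
        raise RuntimeError("all DEC optimizer starts failed")
    params = unpack(best.x)
    ll = -float(best.fun)
    n, k = tree.n_tips, len(free)
    aicc = -2 * ll + 2 * k + 2 * k * (k + 1) / (n - k - 1)
    return params, ll, aicc


def ancestral_ranges(tree, tip_ranges, space, params, clado="DEC"):
    """Marginal ancestral range probabilities per node.

    Two-pass algorithm: the tip-to-root pruning pass computes conditional
    likelihoods; the root-to-tip pass propagates 'outside' likelihoods
    through cladogenetic scenarios and branch transitions.  Returns an
    (n_nodes x n_states) array whose rows sum to 1.
    """
    pr = _DECPruning(tree, tip_ranges, space, params, clado)
    pr.up_pass()
    tree_, space_ = pr.tree, pr.space
    n_states = space_.n_states
    outside = np.zeros((tree_.n_nodes, n_states))
    outside[tree_.root] = pr.root_prior
    ages = tree_.ages
    for node in tree_.preorder():
        if tree_.is_tip(node):
            continue
        kids = tree_.children[node]
        down = {c: pr.branch_P[c] @ pr.cond[c] for c in kids}
        mask = pr.masks[pr.params.stratum_at(ages[node])]
        for ci, c in enumerate(kids):
            sib = kids[1 - ci]
            # H[s_top]: outside likelihood at the top of c's branch
            H = np.zeros(n_states)
            for state in range(n_states):
                if outside[node, state] == 0.0 or mask[state] == 0.0 \
                        or not space_.states[state]:
                    continue
                lefts, rights, ws = pr.scenarios(state)
                mine = lefts if ci == 0 else rights
                other = rights if ci == 0 else lefts
                contrib = outside[node, state] * ws * down[sib][other]
                np.add.at(H, mine, contrib)
            outside[c] = H @ pr.branch_P[c]
            top = outside[c].max()
            if top > 0:
                outside[c] /= top
    marg = outside * pr.cond
    sums = marg.sum(axis=1, keepdims=True)
    if np.any(sums <= 0):
        raise TreeError("underflow in ancestral-state marginals")
    return marg / sums
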