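"""Synthetic data generators with known truth for every pipeline stage.

Emulates the statistical structure of a Merianieae-like study system: a
~139-tip ultrametric tree of ~30 Ma crown age with named clades and
clade-specific sampling fractions, one clade with ~3-fold elevated
diversification, multivariate continuous traits with clade-structured
rates, a binary Andean/extra-Andean background, DEC-style geographic
ranges, and smooth paleo-environmental curves.  Every generator is a pure
function of (parameters, seed) and records its generating parameters in a
SimTruth object so parameter-recovery tests can compare against truth.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .treekit import TimeTree, TreeError, shared_path_matrix
from .envbd import PaleoCurve
from .oushift import RegimePainting
from .decrange import RangeStateSpace, DECParams, build_q, \
    cladogenetic_scenarios

__all__ = [
    "SimTruth", "simulate_bd_tree", "simulate_rate_shift_tree",
    "simulate_traits_bm", "simulate_traits_ou", "simulate_binary_character",
    "simulate_ranges_dec", "make_paleo_curve", "make_ppa_dataset",
]


@dataclass
class SimTruth:
    """Record of the generating parameters and seed of a simulation."""

    kind: str
    seed: int
    params: dict = field(default_factory=dict)

    def to_json(self, **kw):
        def default(o):
            if isinstance(o, (np.integer,)):
                return int(o)
            if isinstance(o, (np.floating,)):
                return float(o)
            if isinstance(o, np.ndarray):
                return o.tolist()
            if isinstance(o, (set, frozenset)):
                return sorted(o)
            return str(o)
        return json.dumps({"kind": self.kind, "seed": self.seed,
                           "params": self.params}, default=default, **kw)


# ----------------------------------------------------------------------
# Birth-death tree simulation
# ----------------------------------------------------------------------

class _Lineage:
    __slots__ = ("parent", "t_start", "t_end", "children", "mult", "alive")

    def __init__(self, parent, t_start, mult=1.0):
        self.parent = parent
        self.t_start = t_start
        self.t_end = None
        self.children = []
        self.mult = mult
        self.alive = True


def _rate_functions(lambda0, mu0, dependency):
    """Return (lam(age), mu(age)) callables for the forward simulator."""
    if dependency is None:
        return (lambda a: lambda0), (lambda a: mu0)
    curve, alpha, beta = dependency
    if curve == "time" or curve is None:
        return (lambda a: lambda0 * math.exp(alpha * a),
                lambda a: mu0 * math.exp(beta * a))
    return (lambda a: lambda0 * math.exp(alpha * float(curve(a))),
            lambda a: mu0 * math.exp(beta * float(curve(a))))


def _forward_bd(rng, lam_fn, mu_fn, T, shift=None, max_events=2_000_000,
                max_alive=20_000):
    """One forward crown-conditioned simulation over forward time [0, T].

    ``shift`` is an optional (forward_time, multiplier) pair; at that
    moment one random surviving lineage (and its descendants) gets its
    rates multiplied.  Returns (lineages, shifted_lineage_index or None).
    """
    grid = np.linspace(0.0, T, 257)
    max_mult = 1.0 if shift is None else max(1.0, shift[1])
    lam_max = max(lam_fn(T - s) for s in grid) * max_mult
    mu_max = max(mu_fn(T - s) for s in grid) * max_mult
    if lam_max + mu_max <= 0:
        lam_max = 1e-12
    lineages = [_Lineage(-1, 0.0)]
    lineages[0].t_end = 0.0
    lineages[0].alive = False
    for _ in range(2):
        lineages.append(_Lineage(0, 0.0))
        lineages[0].children.append(len(lineages) - 1)
    alive = [1, 2]
    s = 0.0
    shift_pending = shift is not None
    shifted_idx = None
    events = 0
    while alive and s < T:
        total_mult = sum(lineages[i].mult for i in alive)
        total = total_mult * (lam_max + mu_max)
        dt = rng.exponential(1.0 / total) if total > 0 else T
        if shift_pending and s + dt >= shift[0]:
            s = shift[0]
            shifted_idx = alive[rng.integers(len(alive))]
            stack = [shifted_idx]
            while stack:
                k = stack.pop()
                lineages[k].mult = shift[1]
                stack.extend(lineages[k].children)
            shift_pending = False
            continue
        s += dt
        if s >= T:
            break
        events += 1
        if events > max_events or len(alive) > max_alive:
            raise RuntimeError("birth-death simulation exceeded size cap")
        # choose lineage proportional to its multiplier
        mults = np.array([lineages[i].mult for i in alive])
        i = alive[rng.choice(len(alive), p=mults / mults.sum())]
        age = T - s
        lam = lam_fn(age) * lineages[i].mult
        mu = mu_fn(age) * lineages[i].mult
        u = rng.uniform(0.0, lineages[i].mult * (lam_max + mu_max))
        if u < lam:
            lineages[i].t_end = s
            lineages[i].alive = False
            alive.remove(i)
            for _ in range(2):
                child = _Lineage(i, s, lineages[i].mult)
                lineages.append(child)
                lineages[i].children.append(len(lineages) - 1)
                alive.append(len(lineages) - 1)
        elif u < lam + mu:
            lineages[i].t_end = s
            lineages[i].alive = False
            alive.remove(i)
    if shift_pending:
        raise RuntimeError("no lineage alive at the requested shift time")
    for i in alive:
        lineages[i].t_end = T
    return lineages, shifted_idx


def _lineages_to_tree(lineages, T):
    """Convert the full lineage record (with extinct tips) to a TimeTree."""
    tips = [k for k, ln in enumerate(lineages) if not ln.children and k > 0]
    internal = [k for k, ln in enumerate(lineages) if ln.children]
    order = tips + internal
    idx = {k: i for i, k in enumerate(order)}
    parent = np.full(len(order), -1, dtype=np.int64)
    blen = np.zeros(len(order))
    labels = [f"t{k}" for k in tips]
    for k in order:
        ln = lineages[k]
        if ln.parent >= 0:
            parent[idx[k]] = idx[ln.parent]
            blen[idx[k]] = ln.t_end - ln.t_start
    return TimeTree(parent, blen, labels), {f"t{k}": k for k in tips}


def simulate_bd_tree(lambda0, mu0=0.0, dependency=None, crown_age=None,
                     n_tips=None, f=1.0, seed=0, max_rejections=1000,
                     max_alive=20_000):
    """Simulate a crown-conditioned reconstructed birth-death tree.

    Starts from two crown lineages, prunes extinct lineages, then retains
    each surviving tip independently with probability f; rejection-samples
    until both crown lineages have at least one sampled surviving
    descendant (so the reconstructed crown age equals ``crown_age``).
    ``dependency`` is None or (curve-or-"time", alpha, beta) giving
    exponential dependence of the rates on age or on the curve's value.
    """
    if lambda0 < 0 or mu0 < 0:
        raise ValueError("rates must be nonnegative")
    if not (0 < f <= 1):
        raise ValueError("f must be in (0, 1]")
    if (crown_age is None) == (n_tips is None):
        raise ValueError("specify exactly one of crown_age / n_tips")
    lam_fn, mu_fn = _rate_functions(lambda0, mu0, dependency)
    rng = np.random.default_rng(seed)
    truth = SimTruth("bd_tree", seed, dict(
        lambda0=lambda0, mu0=mu0, f=f, crown_age=crown_age, n_tips=n_tips,
        dependency=None if dependency is None else
        (getattr(dependency[0], "name", str(dependency[0])),
         dependency[1], dependency[2])))

    for attempt in range(max_rejections):
        if crown_age is not None:
            T = crown_age
            try:
                lineages, _ = _forward_bd(rng, lam_fn, mu_fn, T,
                                          max_alive=max_alive)
            except RuntimeError:
                continue
        else:
            T = _time_to_n_tips(rng, lam_fn, mu_fn, n_tips)
            if T is None:
                continue
            lineages, _ = _forward_bd(rng, lam_fn, mu_fn, T)
        tree = _finish_bd(rng, lineages, T, f)
        if tree is not None:
            truth.params["attempts"] = attempt + 1
            return tree, truth
    raise RuntimeError(
        f"no surviving crown clade in {max_rejections} attempts")


def _time_to_n_tips(rng, lam_fn, mu_fn, n_target, t_cap=1e4):
    """Forward-simulate lineage counts only, to find a stopping time."""
    # constant-rate shortcut is exact enough for the stopping-time draw:
    # run a count-level Gillespie with the age-0 rates
    lam, mu = lam_fn(0.0), mu_fn(0.0)
    n, t = 2, 0.0
    while n != n_target:
        total = n * (lam + mu)
        if total <= 0 or n == 0 or t > t_cap:
            return None
        t += rng.exponential(1.0 / total)
        n += 1 if rng.uniform() < lam / (lam + mu) else -1
    return t


def _finish_bd(rng, lineages, T, f):
    """Prune extinct + unsampled tips; None if a crown side dies out."""
    full, tipmap = _lineages_to_tree(lineages, T)
    ages = full.ages
    extant = [lab for i, lab in enumerate(full.tip_labels)
              if abs(ages[i]) < 1e-9 * max(T, 1.0)]
    sampled = [lab for lab in extant if rng.uniform() < f]
    if len(sampled) < 2:
        return None
    tree = full.keep_tips(sampled)
    if abs(tree.crown_age - T) > 1e-6 * T:
        return None  # one crown side left no sampled survivor
    return tree


def simulate_rate_shift_tree(lambda0, mu0=0.0, shift_age=None, multiplier=3.0,
                             crown_age=30.0, f=1.0, seed=0,
                             max_rejections=1000, max_alive=20_000):
    """Birth-death tree with a single diversification-rate shift.

    At ``shift_age`` (Ma before present) one randomly chosen surviving
    lineage, and all its descendants, evolves with both rates multiplied.
    The truth records the sampled tips of the shifted clade.
    """
    if multiplier <= 0:
        raise ValueError("multiplier must be positive")
    if shift_age is None:
        shift_age = crown_age / 2.0
    if not (0 < shift_age < crown_age):
        raise ValueError("shift age must fall inside the crown interval")
    lam_fn, mu_fn = _rate_functions(lambda0, mu0, None)
    rng = np.random.default_rng(seed)
    s_star = crown_age - shift_age
    truth = SimTruth("rate_shift_tree", seed, dict(
        lambda0=lambda0, mu0=mu0, shift_age=shift_age,
        multiplier=multiplier, crown_age=crown_age, f=f,
        shifted_lambda=lambda0 * multiplier))
    for attempt in range(max_rejections):
        try:
            lineages, shifted = _forward_bd(
                rng, lam_fn, mu_fn, crown_age,
                shift=(s_star, multiplier), max_alive=max_alive)
        except RuntimeError:
            continue
        tree = _finish_bd(rng, lineages, crown_age, f)
        if tree is None:
            continue
        # tips descending from the shifted lineage
        shifted_tips = set()
        if shifted is not None:
            stack = [shifted]
            while stack:
                k = stack.pop()
                if not lineages[k].children:
                    shifted_tips.add(f"t{k}")
                stack.extend(lineages[k].children)
        shifted_tips &= set(tree.tip_labels)
        truth.params["shifted_tips"] = sorted(shifted_tips)
        truth.params["attempts"] = attempt + 1
        return tree, truth
    raise RuntimeError(
        f"no usable shifted tree in {max_rejections} attempts")


# ----------------------------------------------------------------------
# Trait and character simulation
# ----------------------------------------------------------------------

def _branch_multipliers(tree, clade_multipliers):
    mult = np.ones(tree.n_nodes)
    if clade_multipliers:
        for labels, m in clade_multipliers.items():
            if m <= 0:
                raise ValueError("clade rate multiplier must be positive")
            if hasattr(labels, "tips"):
                labels = labels.tips
            node = tree.mrca(labels)
            stack = list(tree.children[node])
            while stack:
                j = stack.pop()
                mult[j] = m
                if not tree.is_tip(j):
                    stack.extend(tree.children[j])
    return mult


def simulate_traits_bm(tree, sigma2, dims=1, clade_multipliers=None, seed=0):
    """Independent Brownian motion per trait dimension, root at 0.

    ``clade_multipliers`` maps tip-label collections (or CladeDefs) to
    rate multipliers applied to all branches inside the clade's crown
    group.  Returns (DataFrame tips x dims, SimTruth).
    """
    if sigma2 < 0:
        raise ValueError("sigma2 must be nonnegative")
    rng = np.random.default_rng(seed)
    mult = _branch_multipliers(tree, clade_multipliers)
    x = np.zeros((tree.n_nodes, dims))
    for node in tree.preorder():
        p = tree.parent[node]
        if p < 0:
            continue
        sd = math.sqrt(sigma2 * mult[node] * tree.branch_lengths[node])
        x[node] = x[p] + rng.normal(0.0, sd, size=dims)
    df = pd.DataFrame(x[: tree.n_tips],
                      index=tree.tip_labels,
                      columns=[f"trait_{k + 1}" for k in range(dims)])
    truth = SimTruth("traits_bm", seed, dict(
        sigma2=sigma2, dims=dims,
        clade_multipliers=None if not clade_multipliers else
        {",".join(sorted(getattr(k, "tips", k))): v
         for k, v in clade_multipliers.items()}))
    return df, truth


def simulate_traits_ou(tree, painting, alpha, sigma2, theta, seed=0):
    """Exact branch-wise OU transition sampling under a regime painting.

    x_child ~ Normal(theta_r + (x_parent - theta_r) e^{-alpha t},
    sigma2 (1 - e^{-2 alpha t}) / (2 alpha)); alpha = 0 degenerates to BM.
    The root starts at the root regime's optimum.
    """
    if alpha < 0 or sigma2 < 0:
        raise ValueError("alpha and sigma2 must be nonnegative")
    theta = np.asarray(theta, dtype=float)
    if len(painting.branch_regimes) != tree.n_nodes:
        raise ValueError("painting does not cover every branch")
    rng = np.random.default_rng(seed)
    x = np.zeros(tree.n_nodes)
    x[tree.root] = theta[painting.root_regime]
    for node in tree.preorder():
        p = tree.parent[node]
        if p < 0:
            continue
        t = tree.branch_lengths[node]
        th = theta[painting.branch_regimes[node]]
        if alpha == 0.0:
            mean, var = x[p], sigma2 * t
        else:
            w = math.exp(-alpha * t)
            mean = th + (x[p] - th) * w
            var = sigma2 * (1.0 - w * w) / (2.0 * alpha)
        x[node] = rng.normal(mean, math.sqrt(max(var, 0.0)))
    ser = pd.Series(x[: tree.n_tips], index=tree.tip_labels, name="trait")
    truth = SimTruth("traits_ou", seed, dict(
        alpha=alpha, sigma2=sigma2, theta=theta,
        root_regime=painting.root_regime, m=painting.m))
    return ser, truth


def simulate_binary_character(tree, q01, q10, root_state=None, seed=0):
    """Two-state continuous-time Markov character on the tree.

    The root state is drawn from the stationary distribution unless fixed.
    """
    if q01 < 0 or q10 < 0:
        raise ValueError("rates must be nonnegative")
    if q01 + q10 == 0 and root_state is None:
        raise ValueError("both rates zero requires a fixed root state")
    rng = np.random.default_rng(seed)
    x = np.zeros(tree.n_nodes, dtype=int)
    if root_state is None:
        pi1 = q01 / (q01 + q10)
        x[tree.root] = int(rng.uniform() < pi1)
    else:
        x[tree.root] = int(root_state)
    total = q01 + q10
    for node in tree.preorder():
        p = tree.parent[node]
        if p < 0:
            continue
        t = tree.branch_lengths[node]
        if total == 0:
            x[node] = x[p]
            continue
        decay = math.exp(-total * t)
        pi1 = q01 / total
        p1 = pi1 + ((1.0 - pi1) if x[p] == 1 else -pi1) * decay
        x[node] = int(rng.uniform() < p1)
    ser = pd.Series(x[: tree.n_tips], index=tree.tip_labels, name="state")
    truth = SimTruth("binary_character", seed, dict(
        q01=q01, q10=q10, root_state=root_state))
    return ser, truth


def simulate_ranges_dec(tree, areas, d, e, j=0.0, w=1.0, strata=None,
                        multipliers=None, max_range_size=5,
                        root_range=None, seed=0, max_branch_tries=100):
    """Forward DEC simulation of geographic ranges.

    Anagenetic dispersal/extirpation is simulated by Gillespie sampling
    along each branch (same rate structure as the DEC likelihood);
    cladogenetic inheritance at nodes uses the same scenario set.  A
    lineage hitting the null range has its branch re-drawn, conditioning
    the data on observed (surviving) tips.
    """
    space = RangeStateSpace(areas, max_range_size=max_range_size)
    kw = {}
    if strata is not None:
        kw["strata"] = strata
    if multipliers is not None:
        kw["multipliers"] = multipliers
    params = DECParams(d=d, e=e, j=j, w=w, **kw)
    rng = np.random.default_rng(seed)
    Q_by_stratum = {s: build_q(space, params, s)
                    for s in range(len(params.strata))}
    ages = tree.ages
    root_idx = (space.state_of(root_range) if root_range is not None
                else space.state_of([areas[0]]))
    state = np.zeros(tree.n_nodes, dtype=int)
    state[tree.root] = root_idx

    def evolve_branch(start_state, age_top, age_bottom):
        for _ in range(max_branch_tries):
            s, age = start_state, age_top
            dead = False
            while age > age_bottom + 1e-12:
                Q = Q_by_stratum[params.stratum_at(age - 1e-12)]
                seg_end = max(age_bottom,
                              params.strata[params.stratum_at(age - 1e-12)][1])
                total = -Q[s, s]
                if total <= 0:
                    age = seg_end
                    continue
                dt = rng.exponential(1.0 / total)
                if age - dt <= seg_end:
                    age = seg_end
                    continue
                age -= dt
                rates = np.maximum(Q[s].copy(), 0.0)
                rates[s] = 0.0
                s = int(rng.choice(space.n_states, p=rates / rates.sum()))
                if s == space.null_index:
                    dead = True
                    break
            if not dead:
                return s
        raise RuntimeError("branch re-draw cap exceeded (e too high?)")

    for node in tree.preorder():
        if tree.is_tip(node):
            continue
        kids = tree.children[node]
        sc = cladogenetic_scenarios(space, state[node],
                                    j if j > 0 else 0.0)
        ws = np.array([x[2] for x in sc])
        pick = sc[int(rng.choice(len(sc), p=ws / ws.sum()))]
        for child, child_top in zip(kids, pick[:2]):
            state[child] = evolve_branch(child_top, ages[node], ages[child])
    ranges = {lab: frozenset(space.areas[a]
                             for a in sorted(space.states[state[i]]))
              for i, lab in enumerate(tree.tip_labels)}
    truth = SimTruth("ranges_dec", seed, dict(
        d=d, e=e, j=j, w=w, areas=list(space.areas),
        root_range=sorted(space.states[root_idx])))
    return ranges, truth


# ----------------------------------------------------------------------
# Paleo curves
# ----------------------------------------------------------------------

def make_paleo_curve(kind, span_ma, step=0.25, name=None, **params):
    """Closed-form synthetic paleo-environmental curve.

    Kinds: ``linear`` (value0, slope per Ma of age), ``sinusoid`` (value0,
    amplitude, period_ma, phase), ``logistic-uplift`` (vmax, midpoint_ma,
    steepness) -- a staged mountain-building curve that rises monotonically
    toward the present.
    """
    if span_ma <= 0:
        raise ValueError("span must be positive")
    ages = np.arange(0.0, span_ma + step / 2, step)[::-1]
    if kind == "linear":
        v0 = params.get("value0", 0.0)
        slope = params.get("slope", 0.0)
        values = v0 + slope * ages
    elif kind == "sinusoid":
        v0 = params.get("value0", 0.0)
        amp = params.get("amplitude", 1.0)
        period = params.get("period_ma", 10.0)
        phase = params.get("phase", 0.0)
        values = v0 + amp * np.sin(2 * np.pi * ages / period + phase)
    elif kind == "logistic-uplift":
        vmax = params.get("vmax", 4000.0)
        mid = params.get("midpoint_ma", span_ma / 2)
        k = params.get("steepness", 0.5)
        values = vmax / (1.0 + np.exp(-k * (mid - ages)))
    else:
        raise ValueError(f"unknown curve kind {kind!r}")
    return PaleoCurve(ages, values, name=name or kind)


# ----------------------------------------------------------------------
# Path-analysis dataset
# ----------------------------------------------------------------------

def make_ppa_dataset(tree, dag, coefficients, residual_lambda=0.5,
                     noise_sigma=1.0, seed=0):
    """Generate a tip table for phylogenetic path analysis from a DAG.

    Variables are generated in topological order; each equals the sum of
    (coefficient x standardized parent) plus phylogenetically correlated
    noise with covariance sigma^2 [lambda V* + (1 - lambda) I], where V*
    is the Brownian covariance scaled to unit diagonal.  The variable
    named ``BG`` is produced by thresholding a latent phylogenetic
    variable at its median, guaranteeing both classes are present.

    ``dag`` is a networkx.DiGraph or a pathsynth.CausalModel;
    ``coefficients`` maps (parent, child) edges to path coefficients;
    ``residual_lambda`` / ``noise_sigma`` are scalars or per-variable
    dicts.
    """
    import networkx as nx

    G = dag if isinstance(dag, nx.DiGraph) else dag.graph
    if not nx.is_directed_acyclic_graph(G):
        raise ValueError("dag must be acyclic")
    missing = [e for e in G.edges if tuple(e) not in
               {tuple(k) for k in coefficients}]
    if missing:
        raise ValueError(f"missing coefficients for edges {missing}")
    coefficients = {tuple(k): float(v) for k, v in coefficients.items()}
    rng = np.random.default_rng(seed)
    n = tree.n_tips
    V = shared_path_matrix(tree)
    Vstar = V / V.diagonal().mean()

    def lam_of(var):
        return (residual_lambda.get(var, 0.5)
                if isinstance(residual_lambda, dict) else residual_lambda)

    def sig_of(var):
        return (noise_sigma.get(var, 1.0)
                if isinstance(noise_sigma, dict) else noise_sigma)

    def phylo_noise(lam, sigma):
        cov = sigma ** 2 * (lam * Vstar + (1 - lam) * np.eye(n))
        L = np.linalg.cholesky(cov + 1e-12 * np.eye(n))
        return L @ rng.standard_normal(n)

    data = {}
    for var in nx.topological_sort(G):
        if var == "BG":
            latent = phylo_noise(max(lam_of(var), 1e-6), 1.0)
            data[var] = (latent > np.median(latent)).astype(float)
            continue
        x = phylo_noise(lam_of(var), sig_of(var))
        for parent in G.predecessors(var):
            pv = data[parent]
            z = (pv - pv.mean()) / max(pv.std(), 1e-12)
            x = x + coefficients[(parent, var)] * z
        data[var] = x
    df = pd.DataFrame(data, index=tree.tip_labels)
    truth = SimTruth("ppa_dataset", seed, dict(
        edges={f"{a}->{b}": c for (a, b), c in coefficients.items()},
        residual_lambda=residual_lambda, noise_sigma=noise_sigma))
    return df, truth


# ----------------------------------------------------------------------
# Full demo scenario
# ----------------------------------------------------------------------

def _partition_clades(tree, n_clades):
    """Split the tree into ~n_clades tip partitions by the oldest nodes."""
    from .treekit import CladeDef

    groups = [tree.root]
    while len(groups) < n_clades:
        expandable = [g for g in groups if not tree.is_tip(g)]
        if not expandable:
            break
        oldest = max(expandable, key=lambda g: tree.ages[g])
        groups.remove(oldest)
        groups.extend(tree.children[oldest])
    return groups


def merianieae_like_scenario(seed=0, crown_age=30.0, lambda0=0.18,
                             mu0=0.03, shift_age=10.0, multiplier=3.0,
                             f=0.46, n_clades=7, tip_range=(100, 180),
                             areas=("AND", "AMA", "GUI", "ATL", "CAM"),
                             max_tries=200):
    """A full synthetic study system in the image of the Merianieae data.

    A ~139-tip reconstructed tree (crown ~30 Ma, global sampling fraction
    0.46) with one clade under ~3-fold elevated diversification starting
    mid-history; seven named clades; climatic (3 axes), vegetative and
    floral trait tables with elevated climatic-niche rates in the shifted
    clade; an Andean/extra-Andean binary background aligned with the
    shifted clade; DEC ranges over five areas; and temperature-like and
    uplift-like paleo-curves.  Returns a dict bundle plus truth records.
    """
    from .treekit import CladeDef

    rng = np.random.default_rng(seed)
    tree = truth = None
    for t in range(max_tries):
        tree_t, truth_t = simulate_rate_shift_tree(
            lambda0, mu0, shift_age=shift_age, multiplier=multiplier,
            crown_age=crown_age, f=f, seed=int(rng.integers(2 ** 31)),
            max_alive=3000)
        if (tip_range[0] <= tree_t.n_tips <= tip_range[1]
                and len(truth_t.params["shifted_tips"]) >= 10):
            tree, truth = tree_t, truth_t
            break
    if tree is None:
        raise RuntimeError("could not draw a tree of the target size")
    shifted = sorted(truth.params["shifted_tips"])

    clade_names = ["Meriania_core", "Graffenrieda", "Adelobotrys",
                   "Macrocentrum1", "Macrocentrum23", "Salpinga",
                   "Axinaea"]
    groups = _partition_clades(tree, n_clades)
    clades = []
    for i, g in enumerate(sorted(groups, key=lambda g: -len(
            tree.clade_tips(g)))):
        name = clade_names[i] if i < len(clade_names) else f"clade{i + 1}"
        clades.append(CladeDef(name, frozenset(tree.clade_tips(g)), f))

    clim, clim_truth = simulate_traits_bm(
        tree, sigma2=0.15, dims=3,
        clade_multipliers={frozenset(shifted): 4.0},
        seed=int(rng.integers(2 ** 31)))
    clim.columns = ["bio_temp", "bio_prec", "bio_seas"]
    veg_cont, _ = simulate_traits_bm(
        tree, sigma2=0.1, dims=2,
        clade_multipliers={frozenset(shifted): 2.0},
        seed=int(rng.integers(2 ** 31)))
    habit, _ = simulate_binary_character(tree, 0.05, 0.05,
                                         seed=int(rng.integers(2 ** 31)))
    veg = veg_cont.copy()
    veg.columns = ["leaf_area", "plant_height"]
    veg["woody"] = habit.map({0: "no", 1: "yes"})
    flor_cont, _ = simulate_traits_bm(
        tree, sigma2=0.12, dims=3, seed=int(rng.integers(2 ** 31)))
    poll, _ = simulate_binary_character(tree, 0.04, 0.04,
                                        seed=int(rng.integers(2 ** 31)))
    flor = flor_cont.copy()
    flor.columns = ["flower_size", "tube_length", "anther_pore"]
    flor["pollinator"] = poll.map({0: "bee", 1: "vertebrate"})

    bg = pd.Series([1 if t in set(shifted) else 0
                    for t in tree.tip_labels],
                   index=tree.tip_labels, name="BG")
    ranges, ranges_truth = simulate_ranges_dec(
        tree, areas, d=0.03, e=0.01,
        root_range=[areas[1]], seed=int(rng.integers(2 ** 31)))

    temp = make_paleo_curve("sinusoid", span_ma=35, value0=18.0,
                            amplitude=2.0, period_ma=20.0, name="temp")
    # superimpose a Cenozoic-style cooling trend toward the present
    temp = PaleoCurve(temp.ages, temp.values + 0.25 * temp.ages,
                      name="temp")
    elev = make_paleo_curve("logistic-uplift", span_ma=35, vmax=4000.0,
                            midpoint_ma=12.0, steepness=0.4, name="elev")
    truth.params["clim_multiplier"] = 4.0
    truth.params["dec"] = ranges_truth.params
    return {
        "tree": tree, "truth": truth, "clades": clades,
        "shifted_tips": shifted, "traits_clim": clim, "traits_veg": veg,
        "traits_flor": flor, "bg": bg, "ranges": ranges, "areas": list(areas),
        "temp_curve": temp, "elev_curve": elev, "f": f,
    }
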