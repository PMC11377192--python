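"""Per-tip diversification and trait-evolution rate estimators.

The DR statistic (inverse equal-splits measure) summarizes per-tip
speciation rate from branch lengths alone; phylogenetic ridge regression
estimates per-branch trait-evolution rates from tip values, from which a
per-tip rate is taken as the norm of the terminal-branch rates across
ordination axes.  A randomization test compares mean rates inside a focal
clade against equally sized random tip subsets.
"""

from __future__ import annotations

import math
import warnings

import numpy as np
import pandas as pd

from .treekit import TimeTree, TreeError, shared_path_matrix

__all__ = ["dr_statistic", "ridge_rates", "rate_shift_test"]


def dr_statistic(tree):
    """DR statistic: inverse of the equal-splits measure, per tip.

    For tip i with root-to-tip edges indexed j = 1 (terminal) .. N_i
    (root-adjacent) of lengths l_j, ES_i = sum_j l_j * 2^{-(j-1)} and
    DR_i = 1 / ES_i (units 1/Myr).
    """
    tree.require_ultrametric()
    if tree.n_tips < 2:
        raise TreeError("DR needs at least 2 tips")
    out = np.empty(tree.n_tips)
    for tip in range(tree.n_tips):
        edges = tree.tip_path_edges(tip)  # terminal edge first
        es = float(np.sum(edges * 0.5 ** np.arange(edges.size)))
        if es <= 0:
            raise TreeError(
                f"zero-length root-to-tip path for {tree.tip_labels[tip]!r}")
        out[tip] = 1.0 / es
    return pd.Series(out, index=tree.tip_labels, name="DR")


def _branch_incidence(tree):
    """Tips x branches matrix: L[i, b] = length of branch b if it lies on
    the root-to-tip-i path, else 0.  Branches are indexed by their child
    node (root excluded)."""
    branches = [n for n in range(tree.n_nodes) if tree.parent[n] >= 0]
    col = {b: k for k, b in enumerate(branches)}
    L = np.zeros((tree.n_tips, len(branches)))
    for tip in range(tree.n_tips):
        j = tip
        while tree.parent[j] >= 0:
            L[tip, col[j]] = tree.branch_lengths[j]
            j = tree.parent[j]
    return L, branches


def _gls_root(tree, y):
    V = shared_path_matrix(tree)
    one = np.ones(len(y))
    Vi_y = np.linalg.solve(V, y)
    Vi_1 = np.linalg.solve(V, one)
    return float(one @ Vi_y) / float(one @ Vi_1)


def ridge_rates(tree, traits, penalty="auto", seed=0):
    """Phylogenetic ridge regression of tip traits on branch incidence.

    Per axis, solves min_b ||y - y_root 1 - L b||^2 + lam ||b||^2 where L
    is the root-to-tip branch-incidence matrix and y_root the GLS root
    estimate under BM.  The per-branch rate is b; the per-tip rate is the
    Euclidean norm, across axes, of the terminal-branch rate.

    ``penalty`` is a positive float, 0 (unpenalized; raises on singular
    systems), or "auto" (generalized cross-validation over a log grid).
    Returns (branch_rates DataFrame, tip_rates DataFrame).
    """
    tree.require_ultrametric()
    if isinstance(traits, pd.Series):
        traits = traits.to_frame()
    traits = traits.loc[tree.tip_labels]
    if traits.isna().any().any():
        raise ValueError("traits contain missing values")
    L, branches = _branch_incidence(tree)
    n, m = L.shape
    U, s, Vt = np.linalg.svd(L, full_matrices=False)

    def solve(yc, lam):
        # ridge solution through the SVD; also the GCV score
        d = s / (s ** 2 + lam)
        beta = Vt.T @ (d * (U.T @ yc))
        fitted = L @ beta
        tr_hat = float(np.sum(s ** 2 / (s ** 2 + lam)))
        rss = float(np.sum((yc - fitted) ** 2))
        gcv = n * rss / max(n - tr_hat, 1e-9) ** 2
        return beta, gcv

    scale = float(np.sum(s ** 2)) / m
    betas = {}
    chosen = {}
    for colname in traits.columns:
        y = traits[colname].to_numpy(dtype=float)
        yc = y - _gls_root(tree, y)
        if penalty == "auto":
            grid = scale * np.logspace(-6, 3, 19)
            scores = [solve(yc, g)[1] for g in grid]
            lam = float(grid[int(np.argmin(scores))])
        else:
            lam = float(penalty)
            if lam == 0.0 and s.min() < 1e-10 * s.max():
                raise np.linalg.LinAlgError(
                    "unpenalized system is singular on this tree; "
                    "supply a positive ridge penalty")
        betas[colname], _ = solve(yc, lam)
        chosen[colname] = lam
    branch_df = pd.DataFrame(betas, index=[f"b{b}" for b in branches])
    branch_df.attrs["penalty"] = chosen
    branch_df.attrs["branch_child_nodes"] = branches
    # per-tip rate: norm across axes of the terminal-branch rate
    term_idx = {b: k for k, b in enumerate(branches)}
    tip_rate = np.empty(tree.n_tips)
    B = np.column_stack([betas[c] for c in traits.columns])
    for tip in range(tree.n_tips):
        tip_rate[tip] = float(np.linalg.norm(B[term_idx[tip]]))
    per_axis = pd.DataFrame(
        {c: [betas[c][term_idx[t]] for t in range(tree.n_tips)]
         for c in traits.columns}, index=tree.tip_labels)
    per_axis["rate"] = tip_rate
    return branch_df, per_axis


def rate_shift_test(tip_rates, clade, reps=1000, seed=0):
    """Two-tailed randomization test for elevated rates in a focal clade.

    The observed statistic is the mean absolute rate over the clade's
    tips; the null is the same statistic over ``reps`` uniformly drawn
    tip subsets of equal size.  Returns (p_value, effect_size) where the
    effect size is observed / mean(null).
    """
    rates = pd.Series(tip_rates).astype(float)
    tips = set(clade.tips) if hasattr(clade, "tips") else set(clade)
    unknown = tips - set(rates.index)
    if unknown:
        raise TreeError(f"unknown tips in clade: {sorted(unknown)}")
    if not (2 <= len(tips) < len(rates)):
        raise ValueError("clade size must be >= 2 and < number of tips")
    if reps < 100:
        warnings.warn("reps < 100 gives poor p-value resolution")
    rng = np.random.default_rng(seed)
    absr = rates.abs().to_numpy()
    labels = list(rates.index)
    idx = [labels.index(t) for t in tips]
    observed = float(absr[idx].mean())
    k = len(idx)
    null = np.array([absr[rng.choice(len(labels), size=k,
                                     replace=False)].mean()
                     for _ in range(reps)])
    p_hi = (1 + int(np.sum(null >= observed))) / (reps + 1)
    p_lo = (1 + int(np.sum(null <= observed))) / (reps + 1)
    p = min(1.0, 2.0 * min(p_hi, p_lo))
    effect = observed / float(null.mean()) if null.mean() > 0 else math.inf
    return p, effect
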