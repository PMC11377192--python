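"""Brownian-motion and multi-optimum Ornstein-Uhlenbeck (Hansen) models.

Fits BM and fixed-regime OU models to a continuous character (typically an
ordination axis) on an ultrametric tree, for a priori selective-regime
hypotheses painted on branches (e.g. a single shift at Andean colonization,
a core-clade shift, or multiple pollinator-shift regimes).  Candidate
models are compared with BIC or with pBIC, a BIC variant that additionally
penalizes the combinatorial multiplicity of shift placements.

The root state is assumed to sit at the root regime's optimum
(stationarity); the alpha -> 0 limit is handled analytically as BM.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.special import comb

from .treekit import TimeTree, TreeError, shared_path_matrix

__all__ = ["RegimePainting", "OUFit", "fit_bm", "fit_ou", "compare_ou"]

#: below this alpha * crown-age the OU model is treated as its BM limit
_ALPHA_BM_EPS = 1e-9


@dataclass(frozen=True)
class RegimePainting:
    """Per-branch regime assignment.

    ``branch_regimes[node]`` is the regime of the branch *above* each node
    (the root entry is ignored); ``root_regime`` is the regime the root
    state is drawn from.  Regime ids must be contiguous ``0 .. m-1``.
    """

    branch_regimes: tuple
    root_regime: int = 0
    name: str = ""

    def __post_init__(self):
        object.__setattr__(self, "branch_regimes",
                           tuple(int(r) for r in self.branch_regimes))
        ids = set(self.branch_regimes) | {self.root_regime}
        if any(r < 0 for r in ids):
            raise ValueError("negative regime id")
        m = max(ids) + 1
        if ids != set(range(m)):
            raise ValueError("regime ids must be contiguous 0..m-1")
        object.__setattr__(self, "m", m)

    @classmethod
    def single_regime(cls, tree, name="single"):
        return cls(tuple(0 for _ in range(tree.n_nodes)), 0, name=name)

    @classmethod
    def from_clades(cls, tree, clades, base_regime=0, include_stem=True,
                    name=""):
        """Paint each clade (list of tip-label collections) a fresh regime.

        Later clades overpaint earlier ones, so nested hypotheses can be
        expressed by listing the enclosing clade first.
        """
        regimes = [base_regime] * tree.n_nodes
        for k, labels in enumerate(clades, start=base_regime + 1):
            node = tree.mrca(labels)
            stack = list(tree.children[node])
            if include_stem:
                stack.append(node)
            seen = set()
            while stack:
                j = stack.pop()
                if j in seen:
                    continue
                seen.add(j)
                regimes[j] = k
                if not tree.is_tip(j):
                    stack.extend(tree.children[j])
        return cls(tuple(regimes), base_regime, name=name)


@dataclass
class OUFit:
    """Fitted OU (or BM-limit) model for one character."""

    alpha: float
    sigma2: float
    theta: np.ndarray
    loglik: float
    m: int
    n: int
    painting: RegimePainting | None = None
    name: str = ""
    bic: float = field(default=float("nan"))
    pbic: float = field(default=float("nan"))
    degenerate: bool = False

    @property
    def k(self):
        # alpha, sigma2, and one optimum per regime
        return 2 + self.m


def _regime_segments(tree, painting):
    """Per tip: list of (regime, age_start, age_end) segments root->tip."""
    ages = tree.ages
    segments = []
    for tip in range(tree.n_tips):
        path = []
        j = tip
        while tree.parent[j] >= 0:
            path.append(j)
            j = tree.parent[j]
        path.reverse()  # root-adjacent first
        segs = [(painting.branch_regimes[node], ages[tree.parent[node]],
                 ages[node]) for node in path]
        segments.append(segs)
    return segments


def _ou_design(tree, painting, alpha):
    """Hansen weight matrix W (tips x regimes) with a stationary root."""
    T = tree.crown_age
    n, m = tree.n_tips, painting.m
    W = np.zeros((n, m))
    for i, segs in enumerate(_regime_segments(tree, painting)):
        W[i, painting.root_regime] += math.exp(-alpha * T)
        for regime, a_old, a_young in segs:
            # branch spans ages [a_young, a_old]; contribution of e^{-a t}
            W[i, regime] += (math.exp(-alpha * a_young)
                             - math.exp(-alpha * a_old))
    return W


def _ou_cov(tree, alpha):
    """OU covariance /sigma2 on an ultrametric tree (stationary root)."""
    V = shared_path_matrix(tree)
    T = tree.crown_age
    t_anc = V  # shared path length = depth of MRCA
    d = 2.0 * (T - t_anc)  # phylogenetic distance between tips
    return (1.0 / (2.0 * alpha)) * np.exp(-alpha * d) \
        * (1.0 - np.exp(-2.0 * alpha * t_anc))


def _gls_profile(y, X, M):
    """Profile the mean parameters and sigma2 out of a Gaussian likelihood.

    y ~ N(X b, sigma2 M).  Returns (b_hat, sigma2_hat, loglik) with the ML
    (divisor n) variance estimate.
    """
    n = y.size
    L = np.linalg.cholesky(M)
    yw = np.linalg.solve(L, y)
    Xw = np.linalg.solve(L, X)
    b, *_ = np.linalg.lstsq(Xw, yw, rcond=None)
    resid = yw - Xw @ b
    rss = float(resid @ resid)
    sigma2 = rss / n
    logdet = 2.0 * np.sum(np.log(np.diag(L)))
    if sigma2 <= 0:
        return b, 0.0, float("inf"), True
    ll = -0.5 * (n * math.log(2 * math.pi * sigma2) + logdet + n)
    return b, sigma2, ll, False


def fit_bm(tree, y):
    """ML Brownian motion fit: returns (loglik, sigma2_hat, root_estimate).

    Constant data is flagged degenerate (sigma2 -> 0 boundary).
    """
    tree.require_ultrametric()
    y = np.asarray(y, dtype=float)
    if y.size != tree.n_tips:
        raise TreeError("trait vector length != number of tips")
    V = shared_path_matrix(tree)
    X = np.ones((y.size, 1))
    b, sigma2, ll, degenerate = _gls_profile(y, X, V)
    degenerate = degenerate or sigma2 <= 1e-12 * (1.0 + float(y @ y))
    return {"loglik": ll, "sigma2": sigma2, "root": float(b[0]),
            "degenerate": degenerate}


def _ou_loglik_at_alpha(tree, y, painting, alpha):
    if alpha * tree.crown_age < _ALPHA_BM_EPS:
        bm = fit_bm(tree, y)
        theta = np.full(painting.m, np.nan)
        theta[painting.root_regime] = bm["root"]
        return bm["loglik"], bm["sigma2"], theta, bm["degenerate"]
    W = _ou_design(tree, painting, alpha)
    M = _ou_cov(tree, alpha)
    theta, sigma2, ll, degenerate = _gls_profile(y, W, M)
    return ll, sigma2, np.asarray(theta, dtype=float), degenerate


def fit_ou(tree, y, painting, alpha=None, name=None):
    """ML multi-optimum OU fit with optima profiled by GLS.

    ``alpha`` fixes the selection strength (0 gives the BM limit);
    otherwise alpha is optimized on the log scale by bounded search.
    """
    tree.require_ultrametric()
    y = np.asarray(y, dtype=float)
    if y.size != tree.n_tips:
        raise TreeError("trait vector length != number of tips")
    if len(painting.branch_regimes) != tree.n_nodes:
        raise ValueError("painting does not cover every branch")
    T = tree.crown_age

    if alpha is not None:
        ll, sigma2, theta, degen = _ou_loglik_at_alpha(tree, y, painting,
                                                       alpha)
        return OUFit(alpha=float(alpha), sigma2=sigma2, theta=theta,
                     loglik=ll, m=painting.m, n=tree.n_tips,
                     painting=painting, degenerate=degen,
                     name=name or painting.name)

    def neg_ll(log_alpha):
        a = math.exp(log_alpha)
        try:
            ll, *_ = _ou_loglik_at_alpha(tree, y, painting, a)
        except np.linalg.LinAlgError:
            return 1e10
        return -ll if np.isfinite(ll) else 1e10

    lo, hi = math.log(1e-6 / T), math.log(1e3 / T)
    # coarse grid then local refinement guards against local optima
    grid = np.linspace(lo, hi, 25)
    vals = [neg_ll(g) for g in grid]
    g0 = grid[int(np.argmin(vals))]
    res = minimize_scalar(neg_ll, bounds=(max(lo, g0 - 2.0),
                                          min(hi, g0 + 2.0)),
                          method="bounded",
                          options={"xatol": 1e-8})
    candidates = [(neg_ll(res.x), res.x), (vals[int(np.argmin(vals))], g0)]
    # BM limit candidate
    bm = fit_bm(tree, y)
    best_nll, best_la = min(candidates)
    if -bm["loglik"] < best_nll - 1e-10:
        ll, sigma2, theta, degen = _ou_loglik_at_alpha(tree, y, painting, 0.0)
        return OUFit(alpha=0.0, sigma2=sigma2, theta=theta, loglik=ll,
                     m=painting.m, n=tree.n_tips, painting=painting,
                     degenerate=degen, name=name or painting.name)
    a = math.exp(best_la)
    ll, sigma2, theta, degen = _ou_loglik_at_alpha(tree, y, painting, a)
    if not np.isfinite(ll):
        raise RuntimeError("OU optimizer failed to find a finite likelihood")
    return OUFit(alpha=a, sigma2=sigma2, theta=theta, loglik=ll,
                 m=painting.m, n=tree.n_tips, painting=painting,
                 degenerate=degen, name=name or painting.name)


def compare_ou(fits, n=None, edges=None, penalty="pBIC"):
    """Rank OU/BM fits by BIC or pBIC (ascending).

    BIC = -2 logL + k ln n with k = 2 + m.  pBIC adds
    2 ln C(edges, m - 1), penalizing the number of ways m - 1 shifts could
    have been placed on the tree's ``edges`` branches.
    """
    fits = list(fits)
    if not fits:
        raise ValueError("no fits to compare")
    ns = {f.n for f in fits}
    if len(ns) != 1 or (n is not None and ns != {n}):
        raise ValueError("fits computed on inconsistent data sizes")
    n = fits[0].n
    if penalty not in ("BIC", "pBIC"):
        raise ValueError("penalty must be 'BIC' or 'pBIC'")
    if penalty == "pBIC" and edges is None:
        raise ValueError("pBIC requires the tree's edge count")
    for f in fits:
        f.bic = -2.0 * f.loglik + f.k * math.log(n)
        f.pbic = f.bic + (2.0 * math.log(comb(edges, f.m - 1, exact=True))
                          if penalty == "pBIC" else 0.0)
    key = (lambda f: f.pbic) if penalty == "pBIC" else (lambda f: f.bic)
    return sorted(fits, key=key)
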