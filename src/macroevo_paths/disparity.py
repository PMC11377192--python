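"""Morphospace construction and disparity analyses.

Builds climatic/vegetative/floral morphospaces (PCA for continuous tables,
Gower distance + principal coordinates for mixed trait types), computes
per-clade disparity as the average squared pairwise distance among
ordination coordinates, compares clades after rarefaction using the
Bhattacharyya coefficient, and runs disparity-through-time (DTT) against a
Brownian-motion null with the MDI statistic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .treekit import TimeTree, TreeError, shared_path_matrix

__all__ = [
    "Morphospace", "DTTResult", "gower_distance", "ordinate",
    "clade_disparity", "rarefied_disparity", "bhattacharyya",
    "dtt",
]

GOWER_TYPES = ("cont", "ord", "bin", "nom")


# ----------------------------------------------------------------------
# Gower distance
# ----------------------------------------------------------------------

def _infer_types(df):
    out = {}
    for col in df.columns:
        vals = df[col].dropna()
        if pd.api.types.is_numeric_dtype(vals):
            uniq = set(vals.unique())
            out[col] = "bin" if uniq <= {0, 1} else "cont"
        else:
            out[col] = "nom"
    return out


def gower_distance(df, types=None):
    """Gower dissimilarity for mixed-type trait tables, in [0, 1].

    Per-trait dissimilarity: continuous/ordinal |x - y| / range (ordinal
    columns are rank-transformed first); binary and nominal 0/1 mismatch.
    Missing values are excluded pairwise; a species pair sharing no
    comparable trait is an error.
    """
    if types is None:
        types = _infer_types(df)
    bad = {c: t for c, t in types.items() if t not in GOWER_TYPES}
    if bad:
        raise ValueError(f"unknown trait types: {bad}")
    n = len(df)
    num = np.zeros((n, n))
    cnt = np.zeros((n, n))
    for col in df.columns:
        t = types[col]
        raw = df[col]
        if t in ("cont", "ord"):
            x = (raw.rank(method="average") if t == "ord"
                 else raw.astype(float)).to_numpy(dtype=float)
            rng = np.nanmax(x) - np.nanmin(x)
            diff = np.abs(x[:, None] - x[None, :])
            # zero range: distances are 0 but missingness must survive
            d = diff / rng if rng > 0 else diff * 0.0
        else:
            x = raw.to_numpy()
            miss = pd.isna(x)
            d = (x[:, None] != x[None, :]).astype(float)
            d[miss[:, None] | miss[None, :]] = np.nan
        ok = ~np.isnan(d)
        num[ok] += d[ok]
        cnt += ok
    if np.any(cnt == 0):
        i, j = np.argwhere(cnt == 0)[0]
        raise ValueError(
            f"species pair ({df.index[i]}, {df.index[j]}) shares no "
            "comparable trait")
    D = num / cnt
    np.fill_diagonal(D, 0.0)
    return pd.DataFrame(D, index=df.index, columns=df.index)


def read_typed_traits(path_or_buf):
    """Read a trait TSV whose header encodes types as ``name:type``.

    Returns (DataFrame with plain column names, types dict).  Columns
    without a type suffix are inferred (numeric -> cont, 0/1 -> bin,
    else nom).  The first column must hold species labels.
    """
    df = pd.read_csv(path_or_buf, sep="\t", index_col=0)
    names, types = [], {}
    for col in df.columns:
        if ":" in col and col.rsplit(":", 1)[1] in GOWER_TYPES:
            name, t = col.rsplit(":", 1)
            types[name] = t
        else:
            name = col
        names.append(name)
    df.columns = names
    inferred = _infer_types(df)
    for name in names:
        types.setdefault(name, inferred[name])
    return df, types


# ----------------------------------------------------------------------
# Ordination
# ----------------------------------------------------------------------

@dataclass
class Morphospace:
    """Ordination scores with per-axis variance explained."""

    scores: pd.DataFrame
    variance_explained: np.ndarray  # fractions, nonincreasing
    method: str
    correction: str = "none"
    eigenvalues: np.ndarray = field(default=None)

    def axes(self, k):
        return self.scores.iloc[:, :k]


def ordinate(data, method="PCA", correction="none", scale=True):
    """PCA of a continuous table, or PCoA of a distance matrix.

    PCA centers (and by default scales to unit variance) the columns and
    eigendecomposes via SVD.  PCoA performs classical scaling of the
    double-centered -d^2/2 matrix; if negative eigenvalues exceed
    tolerance and ``correction == "Cailliez"``, the Cailliez constant is
    added to the off-diagonal dissimilarities first.  Scores are returned
    for all positive-eigenvalue axes.
    """
    if len(data) < 3:
        raise ValueError("need at least 3 species to ordinate")
    if method.upper() == "PCA":
        X = data.astype(float)
        if X.isna().any().any():
            raise ValueError("PCA requires a complete table")
        M = X.to_numpy() - X.to_numpy().mean(axis=0)
        if scale:
            sd = M.std(axis=0, ddof=1)
            sd[sd == 0] = 1.0
            M = M / sd
        U, s, Vt = np.linalg.svd(M, full_matrices=False)
        eig = s ** 2 / (len(X) - 1)
        keep = eig > 1e-12 * max(eig.max(), 1.0)
        scores = U[:, keep] * s[keep]
        ve = eig[keep] / eig.sum()
        cols = [f"PC{i + 1}" for i in range(int(keep.sum()))]
        return Morphospace(pd.DataFrame(scores, index=data.index,
                                        columns=cols),
                           ve, "PCA", "none", eig[keep])
    if method.upper() != "PCOA":
        raise ValueError("method must be 'PCA' or 'PCoA'")
    D = np.asarray(data, dtype=float)
    if D.shape[0] != D.shape[1] or not np.allclose(D, D.T, atol=1e-8):
        raise ValueError("PCoA requires a symmetric distance matrix")
    index = data.index if hasattr(data, "index") else pd.RangeIndex(len(D))
    n = D.shape[0]
    applied = "none"

    def classical(dmat):
        J = np.eye(n) - np.ones((n, n)) / n
        B = -0.5 * J @ (dmat ** 2) @ J
        w, V = np.linalg.eigh((B + B.T) / 2)
        return w[::-1], V[:, ::-1]

    w, V = classical(D)
    tol = 1e-8 * max(abs(w[0]), 1.0)
    if w[-1] < -tol and correction == "Cailliez":
        c = _cailliez_constant(D)
        D = D + c * (1 - np.eye(n))
        w, V = classical(D)
        applied = "Cailliez"
    keep = w > tol
    scores = V[:, keep] * np.sqrt(w[keep])
    ve = w[keep] / w[keep].sum()
    cols = [f"PCo{i + 1}" for i in range(int(keep.sum()))]
    return Morphospace(pd.DataFrame(scores, index=index, columns=cols),
                       ve, "PCoA", applied, w[keep])


def _cailliez_constant(D):
    """Smallest additive constant making D + c Euclidean (Cailliez 1983)."""
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B1 = -0.5 * J @ (D ** 2) @ J
    B2 = -0.5 * J @ D @ J
    M = np.block([[np.zeros((n, n)), 2 * B1],
                  [-np.eye(n), -4 * B2]])
    ev = np.linalg.eigvals(M)
    return float(np.max(ev.real))


# ----------------------------------------------------------------------
# Disparity
# ----------------------------------------------------------------------

def clade_disparity(scores, members=None):
    """Mean squared pairwise Euclidean distance among coordinates.

    Uses the algebraic identity: for n points this equals
    (2 / (n - 1)) * sum over axes of the (divisor-n) variance... computed
    here directly from the pairwise definition for clarity.
    """
    X = scores if members is None else scores.loc[list(members)]
    if isinstance(X, pd.DataFrame) and X.isna().any().any():
        raise ValueError("scores contain missing members")
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n = X.shape[0]
    if n < 2:
        raise ValueError("disparity needs at least 2 members")
    sq = np.sum((X[:, None, :] - X[None, :, :]) ** 2, axis=2)
    iu = np.triu_indices(n, 1)
    return float(sq[iu].mean())


def bhattacharyya(a, b, bins=None):
    """Bhattacharyya coefficient between two samples on shared bins.

    Bins default to Sturges' rule on the pooled sample.  BC = 1 for
    identical distributions, 0 for disjoint support.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    pooled = np.concatenate([a, b])
    if bins is None:
        bins = int(np.ceil(np.log2(pooled.size) + 1))
    lo, hi = pooled.min(), pooled.max()
    if hi <= lo:
        return 1.0
    edges = np.linspace(lo, hi, bins + 1)
    p = np.histogram(a, bins=edges)[0] / a.size
    q = np.histogram(b, bins=edges)[0] / b.size
    return float(np.sum(np.sqrt(p * q)))


def rarefied_disparity(scores, clades, n=4, reps=100, seed=0,
                       distinct_below=0.05):
    """Rarefied per-clade disparity distributions + pairwise Bhattacharyya.

    Each clade is rarefied to ``n`` random members ``reps`` times.
    Returns (DataFrame reps x clades, DataFrame of pairwise BC with a
    'distinct' flag when BC < ``distinct_below``).
    """
    rng = np.random.default_rng(seed)
    dists = {}
    for clade in clades:
        name = getattr(clade, "name", None) or str(clade)
        tips = sorted(clade.tips) if hasattr(clade, "tips") else sorted(clade)
        if len(tips) < n:
            raise ValueError(f"clade {name!r} smaller than rarefaction n={n}")
        vals = np.empty(reps)
        for r in range(reps):
            pick = rng.choice(len(tips), size=n, replace=False)
            vals[r] = clade_disparity(scores, [tips[i] for i in pick])
        dists[name] = vals
    table = pd.DataFrame(dists)
    rows = []
    names = list(table.columns)
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            bc = bhattacharyya(table[names[i]], table[names[j]])
            rows.append({"clade_a": names[i], "clade_b": names[j],
                         "bhattacharyya": bc,
                         "distinct": bc < distinct_below})
    return table, pd.DataFrame(rows)


# ----------------------------------------------------------------------
# Disparity through time
# ----------------------------------------------------------------------

@dataclass
class DTTResult:
    """DTT curve, BM-null envelope, and the MDI statistic."""

    times: np.ndarray          # node ages, descending from the crown age
    observed: np.ndarray       # relative disparity at each time
    null_median: np.ndarray
    null_low: np.ndarray
    null_high: np.ndarray
    mdi: float
    p_value: float
    sims: int
    null_mdi: np.ndarray = field(default=None, repr=False)


def _dtt_curve(tree, X, times):
    """Mean relative subclade disparity at each age in ``times``.

    Per-node disparities are time-invariant, so they are precomputed once
    with the algebraic identity mean-squared-pairwise-distance =
    2 * sum over axes of the (ddof = 1) variance.
    """
    ages = tree.ages
    eps = 1e-9 * max(tree.crown_age, 1.0)
    below = [None] * tree.n_nodes
    node_disp = np.zeros(tree.n_nodes)
    for node in tree.postorder():
        if tree.is_tip(node):
            below[node] = [node]
        else:
            below[node] = [t for c in tree.children[node]
                           for t in below[c]]
            Xi = X[below[node]]
            node_disp[node] = 2.0 * float(
                np.sum(np.var(Xi, axis=0, ddof=1)))
    total = node_disp[tree.root]
    if total <= 0:
        raise ValueError("zero total disparity")
    parent_age = np.where(tree.parent >= 0, ages[tree.parent],
                          np.inf)
    out = np.empty(len(times))
    for k, t in enumerate(times):
        crossing = (parent_age > t + eps) & (ages <= t + eps)
        out[k] = float(np.mean(node_disp[crossing])) / total
    return out


def _bm_rates_from_data(tree, X):
    """Per-axis ML BM rate estimates (GLS with the tree covariance)."""
    from .oushift import fit_bm

    return np.array([max(fit_bm(tree, X[:, k])["sigma2"], 1e-12)
                     for k in range(X.shape[1])])


def dtt(tree, scores, sims=1000, seed=0, time_bins=None):
    """Disparity-through-time with a Brownian-motion null and MDI.

    At each internal-node age (or at the supplied bin edges) the observed
    relative disparity is the mean, over lineages crossing that age, of
    the lineage's descendant-tip disparity divided by the total disparity.
    The null repeats the computation on multivariate BM data simulated on
    the tree with per-axis rates estimated from the observed scores.  MDI
    is the signed area (trapezoid, over relative time) between the
    observed curve and the null median; the p-value is the two-sided rank
    of the observed MDI among the null MDIs.
    """
    if sims < 2:
        raise ValueError("sims must be >= 2")
    tree.require_ultrametric()
    if tree.n_tips < 3:
        raise TreeError("DTT needs at least 3 tips")
    if isinstance(scores, pd.Series):
        scores = scores.to_frame()
    X = scores.loc[tree.tip_labels].to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValueError("scores contain missing values")
    if time_bins is None:
        times = tree.branching_times()
    else:
        times = np.sort(np.asarray(time_bins, dtype=float))[::-1]
    observed = _dtt_curve(tree, X, times)

    rates = _bm_rates_from_data(tree, X)
    rng = np.random.default_rng(seed)
    from .synthgen import simulate_traits_bm

    null_curves = np.empty((sims, len(times)))
    null_mdi = np.empty(sims)
    rel_t = (tree.crown_age - times) / tree.crown_age  # 0 at root -> 1
    for s in range(sims):
        sim = np.column_stack([
            simulate_traits_bm(tree, rates[k], dims=1,
                               seed=int(rng.integers(2 ** 31)))[0]
            .to_numpy()[:, 0]
            for k in range(X.shape[1])])
        null_curves[s] = _dtt_curve(tree, sim, times)
    null_median = np.median(null_curves, axis=0)
    null_low = np.quantile(null_curves, 0.025, axis=0)
    null_high = np.quantile(null_curves, 0.975, axis=0)
    mdi = float(np.trapezoid(observed - null_median, rel_t))
    for s in range(sims):
        null_mdi[s] = float(np.trapezoid(null_curves[s] - null_median,
                                         rel_t))
    ge = float(np.mean(null_mdi >= mdi))
    le = float(np.mean(null_mdi <= mdi))
    p = min(1.0, 2.0 * min(ge, le) + 1.0 / (sims + 1))
    return DTTResult(times=times, observed=observed,
                     null_median=null_median, null_low=null_low,
                     null_high=null_high, mdi=mdi, p_value=p, sims=sims,
                     null_mdi=null_mdi)
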