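"""Phylogenetic path analysis over causal models of diversification.

Candidate causal structures (DAGs over biogeographic background BG, rates
of climatic niche / vegetative / floral trait evolution, and speciation
rate SR) are evaluated through the d-separation test: each model's Shipley
basis of conditional-independence claims is tested by phylogenetic
regression (Pagel's-lambda GLS for continuous responses, Firth-penalized
phylogenetic logistic regression for the binary BG), the claim p-values
combine into Fisher's C, and models are ranked by the C-statistic
information criterion CICc with conditional model averaging of the path
coefficients.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import minimize_scalar

from .treekit import TimeTree, TreeError, shared_path_matrix

__all__ = [
    "CausalModel", "PGLSFit", "PathFitStats", "pgls_lambda",
    "phylo_logistic", "dsep_basis", "fit_model", "rank_and_average",
    "default_model_set",
]

DEFAULT_VERTICES = ("BG", "climR", "vegR", "florR", "SR")


# ----------------------------------------------------------------------
# Causal models
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class CausalModel:
    """A named DAG over the path-analysis variables."""

    name: str
    edges: tuple
    vertices: tuple = DEFAULT_VERTICES

    def __post_init__(self):
        object.__setattr__(self, "edges",
                           tuple((str(a), str(b)) for a, b in self.edges))
        object.__setattr__(self, "vertices", tuple(self.vertices))
        if len(set(self.vertices)) != len(self.vertices):
            raise ValueError("duplicate vertices")
        for a, b in self.edges:
            if a not in self.vertices or b not in self.vertices:
                raise ValueError(f"edge ({a}, {b}) uses unknown vertex")
        if not nx.is_directed_acyclic_graph(self.graph):
            raise ValueError(f"model {self.name!r} is cyclic")

    @property
    def graph(self):
        G = nx.DiGraph()
        G.add_nodes_from(self.vertices)
        G.add_edges_from(self.edges)
        return G

    @property
    def q(self):
        """Parameter count for CICc (number of directed edges)."""
        return len(self.edges)

    def to_dict(self):
        return {"name": self.name, "vertices": list(self.vertices),
                "edges": [list(e) for e in self.edges]}


def default_model_set():
    """The default battery of 11 increasingly complex causal models.

    Models 1-4 test single direct effects on SR; 5-10 add indirect
    chains through climatic niche evolution and trait evolution; model 11
    is the full model in which BG drives climR (and weakly SR), climR
    drives SR and both trait rates, and both trait rates affect SR.
    """
    E = lambda *e: tuple(e)
    defs = [
        ("m1_BG-SR", E(("BG", "SR"))),
        ("m2_climR-SR", E(("climR", "SR"))),
        ("m3_vegR-SR", E(("vegR", "SR"))),
        ("m4_florR-SR", E(("florR", "SR"))),
        ("m5_BG-climR-SR", E(("BG", "climR"), ("climR", "SR"))),
        ("m6_BG-climR-SR+BG-SR",
         E(("BG", "climR"), ("climR", "SR"), ("BG", "SR"))),
        ("m7_veg_chain",
         E(("BG", "climR"), ("climR", "SR"), ("climR", "vegR"),
           ("vegR", "SR"))),
        ("m8_flor_chain",
         E(("BG", "climR"), ("climR", "SR"), ("climR", "florR"),
           ("florR", "SR"))),
        ("m9_traits_only",
         E(("BG", "climR"), ("climR", "vegR"), ("climR", "florR"),
           ("vegR", "SR"), ("florR", "SR"))),
        ("m10_traits+climR",
         E(("BG", "climR"), ("climR", "SR"), ("climR", "vegR"),
           ("climR", "florR"), ("vegR", "SR"), ("florR", "SR"))),
        ("m11_full",
         E(("BG", "climR"), ("BG", "SR"), ("climR", "SR"),
           ("climR", "vegR"), ("climR", "florR"), ("vegR", "SR"),
           ("florR", "SR"))),
    ]
    return [CausalModel(name, edges) for name, edges in defs]


def models_from_json(obj):
    """Load a model set from parsed JSON: [{name, vertices?, edges}, ...]."""
    out = []
    for m in obj:
        kw = {"name": m["name"], "edges": tuple(map(tuple, m["edges"]))}
        if m.get("vertices"):
            kw["vertices"] = tuple(m["vertices"])
        out.append(CausalModel(**kw))
    return out


# ----------------------------------------------------------------------
# d-separation basis
# ----------------------------------------------------------------------

def dsep_basis(model):
    """Shipley's basis of conditional-independence claims for a DAG.

    One claim per non-adjacent vertex pair: (x, y, Z) reads "x independent
    of y given Z" where y is the pair member later in the (deterministic,
    lexicographically tie-broken) topological order and Z is the union of
    both members' parents, excluding the pair itself.
    """
    G = model.graph if isinstance(model, CausalModel) else model
    if not nx.is_directed_acyclic_graph(G):
        raise ValueError("model must be acyclic")
    order = list(nx.lexicographical_topological_sort(G))
    pos = {v: i for i, v in enumerate(order)}
    adjacent = {frozenset(e) for e in G.edges}
    claims = []
    for x, y in itertools.combinations(sorted(G.nodes), 2):
        if frozenset((x, y)) in adjacent:
            continue
        first, second = (x, y) if pos[x] < pos[y] else (y, x)
        Z = (set(G.predecessors(first)) | set(G.predecessors(second))) \
            - {first, second}
        claims.append((first, second, tuple(sorted(Z))))
    claims.sort()
    return claims


# ----------------------------------------------------------------------
# Phylogenetic regressions
# ----------------------------------------------------------------------

@dataclass
class PGLSFit:
    """Pagel's-lambda GLS regression fit."""

    params: pd.Series
    se: pd.Series
    pvalues: pd.Series
    lambda_: float
    loglik: float
    sigma2: float
    method: str = "pgls_lambda"


def _scaled_bm_cov(tree):
    V = shared_path_matrix(tree)
    return V / V.diagonal().mean()


def _design(X, species):
    if isinstance(X, pd.Series):
        X = X.to_frame()
    X = X.loc[species].astype(float)
    M = np.column_stack([np.ones(len(X)), X.to_numpy()])
    names = ["intercept", *X.columns]
    return M, names


def pgls_lambda(y, X, tree, lam=None):
    """Phylogenetic GLS with Pagel's lambda residual covariance.

    Covariance sigma2 [lam V* + (1 - lam) I] with V* the BM covariance
    scaled to unit diagonal; lam is estimated by bounded ML on [0, 1]
    unless fixed.  p-values are t-based.
    """
    species = tree.tip_labels
    yv = pd.Series(y).loc[species].to_numpy(dtype=float)
    M, names = _design(X, species)
    n, p = M.shape
    if n <= p + 1:  # p includes the intercept column
        raise ValueError("too few species for the design")
    Vstar = _scaled_bm_cov(tree)
    I = np.eye(n)

    def profile(l):
        C = l * Vstar + (1 - l) * I
        L = np.linalg.cholesky(C)
        yw = np.linalg.solve(L, yv)
        Xw = np.linalg.solve(L, M)
        XtX = Xw.T @ Xw
        if np.linalg.cond(XtX) > 1e12:
            raise np.linalg.LinAlgError("singular design")
        beta = np.linalg.solve(XtX, Xw.T @ yw)
        resid = yw - Xw @ beta
        sigma2 = float(resid @ resid) / n
        logdet = 2 * np.sum(np.log(np.diag(L)))
        if sigma2 <= 0:
            return beta, 0.0, XtX, float("inf")
        ll = -0.5 * (n * math.log(2 * math.pi * sigma2) + logdet + n)
        return beta, sigma2, XtX, ll

    if lam is None:
        res = minimize_scalar(lambda l: -profile(l)[3], bounds=(0.0, 1.0),
                              method="bounded", options={"xatol": 1e-6})
        cands = [0.0, 1.0, float(res.x)]
        lam = max(cands, key=lambda l: profile(l)[3])
    beta, sigma2, XtX, ll = profile(lam)
    dof = n - p
    # unbiased residual variance for the standard errors
    sig_u = sigma2 * n / dof
    cov = sig_u * np.linalg.inv(XtX)
    se = np.sqrt(np.diag(cov))
    tstat = np.where(se > 0, beta / np.where(se > 0, se, 1.0), np.inf)
    pv = 2 * stats.t.sf(np.abs(tstat), dof)
    return PGLSFit(params=pd.Series(beta, index=names),
                   se=pd.Series(se, index=names),
                   pvalues=pd.Series(pv, index=names),
                   lambda_=float(lam), loglik=ll, sigma2=sigma2)


def phylo_logistic(y, X, tree, phylo_scale_grid=(0.0, 0.25, 0.5, 1.0),
                   max_iter=80, tol=1e-8):
    """Firth-penalized logistic regression with a phylogenetic component.

    Fits logit P(y = 1) = X beta with Firth's Jeffreys-prior score
    correction (guaranteeing finite estimates under separation).  The
    phylogenetic random effect is approximated by a single variance
    component s2 on V*: for each s2 on a small grid, the penalized IRLS
    step whitens the working response by (W^-1 + s2 V*); the grid value
    maximizing the penalized working likelihood is kept.  s2 = 0 reduces
    exactly to plain Firth logistic regression.
    """
    species = tree.tip_labels
    yv = pd.Series(y).loc[species].to_numpy(dtype=float)
    classes = set(np.unique(yv))
    if not classes <= {0.0, 1.0} or len(classes) < 2:
        raise ValueError("binary response must contain both classes")
    M, names = _design(X, species)
    n, p = M.shape
    if n <= p + 1:  # p includes the intercept column
        raise ValueError("too few species for the design")
    Vstar = _scaled_bm_cov(tree)

    def firth_fit(s2):
        beta = np.zeros(p)
        ll_pen = -np.inf
        for _ in range(max_iter):
            eta = M @ beta
            mu = 1.0 / (1.0 + np.exp(-eta))
            w = np.clip(mu * (1 - mu), 1e-10, None)
            if s2 == 0.0:
                Sigma_inv = np.diag(w)  # (W^-1)^-1
                cov_work = np.diag(1.0 / w)
            else:
                cov_work = np.diag(1.0 / w) + s2 * Vstar
                Sigma_inv = np.linalg.inv(cov_work)
            info = M.T @ Sigma_inv @ M
            info_inv = np.linalg.inv(info)
            # hat diagonal for the Firth correction
            H = Sigma_inv @ M @ info_inv @ M.T
            h = np.diag(H)
            z = eta + (yv - mu) / w
            adj = h * (0.5 - mu) / w  # Jeffreys-prior working adjustment
            beta_new = info_inv @ (M.T @ (Sigma_inv @ (z + adj)))
            if np.max(np.abs(beta_new - beta)) < tol:
                beta = beta_new
                break
            beta = beta_new
        eta = M @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        ll = float(np.sum(yv * np.log(np.clip(mu, 1e-12, None))
                          + (1 - yv) * np.log(np.clip(1 - mu, 1e-12, None))))
        sign, logdet_info = np.linalg.slogdet(info)
        ll_pen = ll + 0.5 * logdet_info
        if s2 > 0:
            # Gaussian working-response correction for the random effect
            sign, logdet_cov = np.linalg.slogdet(cov_work)
            w = np.clip(mu * (1 - mu), 1e-10, None)
            resid = (yv - mu) / w
            Sigma_inv2 = np.linalg.inv(cov_work)
            ll_pen += -0.5 * (logdet_cov + resid @ Sigma_inv2 @ resid
                              - np.sum(np.log(1.0 / w))
                              - resid @ (w * resid))
        return beta, info, ll_pen

    best = None
    for s2 in phylo_scale_grid:
        try:
            beta, info, ll_pen = firth_fit(float(s2))
        except np.linalg.LinAlgError:
            continue
        if best is None or ll_pen > best[3]:
            best = (beta, info, float(s2), ll_pen)
    if best is None:
        raise RuntimeError("phylogenetic logistic fit failed on all s2")
    beta, info, s2, ll_pen = best
    cov = np.linalg.inv(info)
    se = np.sqrt(np.diag(cov))
    zstat = beta / np.where(se > 0, se, np.inf)
    pv = 2 * stats.norm.sf(np.abs(zstat))
    return PGLSFit(params=pd.Series(beta, index=names),
                   se=pd.Series(se, index=names),
                   pvalues=pd.Series(pv, index=names),
                   lambda_=s2, loglik=ll_pen, sigma2=float("nan"),
                   method="phylo_logistic_firth")


# ----------------------------------------------------------------------
# Model fitting, ranking, averaging
# ----------------------------------------------------------------------

@dataclass
class PathFitStats:
    """d-separation fit statistics of one causal model."""

    model: CausalModel
    k: int                     # independence claims
    C: float                   # Fisher's statistic
    p_value: float             # chi2 tail with 2k df
    q: int                     # parameter count (edges)
    n: int
    cicc: float
    claim_pvalues: dict = field(default_factory=dict)
    edge_coefficients: pd.DataFrame = None
    delta_cicc: float = float("nan")
    weight: float = float("nan")
    rel_likelihood: float = float("nan")


def standardize_path_data(data, binary=("BG",)):
    """z-score the continuous columns once, before all regressions."""
    out = data.copy().astype(float)
    for col in out.columns:
        if col in binary:
            continue
        sd = out[col].std(ddof=1)
        if sd <= 0:
            raise ValueError(f"column {col!r} has zero variance")
        out[col] = (out[col] - out[col].mean()) / sd
    return out


def _claim_regression(response, predictor, conditioning, data, tree,
                      binary):
    cols = [predictor, *conditioning]
    X = data[cols]
    if response in binary:
        fit = phylo_logistic(data[response], X, tree)
    else:
        fit = pgls_lambda(data[response], X, tree)
    return float(fit.pvalues[predictor]), fit


def fit_model(model, data, tree, binary=("BG",), q_mode="edges",
              standardized=False):
    """Test one causal model by d-separation and score it with CICc.

    Each basis claim (x _||_ y | Z) is tested by regressing the later
    pair member on the earlier plus Z; the claim p-value is that of the
    earlier member's coefficient.  C = -2 sum ln p ~ chi2(2k) under the
    model; CICc = C + 2 q n / (n - 1 - q) with q the number of edges
    (``q_mode='edges+vertices'`` adds the vertex count).
    """
    if not standardized:
        data = standardize_path_data(data, binary)
    data = data.loc[tree.tip_labels]
    claims = dsep_basis(model)
    k = len(claims)
    n = len(data)
    q = model.q + (len(model.vertices) if q_mode == "edges+vertices" else 0)
    if n - 1 - q <= 0:
        raise ValueError("too few species for CICc with this q")
    claim_p = {}
    for x, yv, Z in claims:
        p, _ = _claim_regression(yv, x, Z, data, tree, binary)
        claim_p[(x, yv, Z)] = max(p, 1e-300)
    C = -2.0 * sum(math.log(p) for p in claim_p.values())
    p_C = float(stats.chi2.sf(C, 2 * k)) if k > 0 else 1.0
    cicc = C + 2.0 * q * n / (n - 1 - q)
    # per-edge path coefficients: each vertex regressed on its parents
    rows = []
    G = model.graph
    for v in model.vertices:
        parents = sorted(G.predecessors(v))
        if not parents:
            continue
        if v in binary:
            fit = phylo_logistic(data[v], data[parents], tree)
        else:
            fit = pgls_lambda(data[v], data[parents], tree)
        for parent in parents:
            rows.append({"from": parent, "to": v,
                         "coef": float(fit.params[parent]),
                         "se": float(fit.se[parent]),
                         "p": float(fit.pvalues[parent]),
                         "lambda": fit.lambda_})
    edge_df = pd.DataFrame(rows,
                           columns=["from", "to", "coef", "se", "p",
                                    "lambda"])
    return PathFitStats(model=model, k=k, C=C, p_value=p_C, q=q, n=n,
                        cicc=cicc, claim_pvalues=claim_p,
                        edge_coefficients=edge_df)


def rank_and_average(models, data, tree, threshold=2.0, binary=("BG",),
                     q_mode="edges", fits=None):
    """Rank causal models by CICc and average coefficients of the top set.

    The averaging set contains every model with delta CICc < threshold;
    per-edge coefficients are averaged with renormalized CICc weights
    over the models that contain the edge (conditional averaging), with
    95% CIs from Buckland-style model-averaged variances.
    Returns (ranked fits, averaged-coefficient DataFrame).
    """
    if fits is None:
        data_std = standardize_path_data(data, binary)
        fits = [fit_model(m, data_std, tree, binary, q_mode,
                          standardized=True) for m in models]
    if not fits:
        raise ValueError("no models supplied")
    best = min(f.cicc for f in fits)
    for f in fits:
        f.delta_cicc = f.cicc - best
        f.rel_likelihood = math.exp(-f.delta_cicc / 2.0)
    total = sum(f.rel_likelihood for f in fits)
    for f in fits:
        f.weight = f.rel_likelihood / total
    fits = sorted(fits, key=lambda f: f.cicc)
    avg_set = [f for f in fits if f.delta_cicc < threshold]
    edges = sorted({(r["from"], r["to"])
                    for f in avg_set
                    for _, r in f.edge_coefficients.iterrows()})
    rows = []
    for a, b in edges:
        members = []
        for f in avg_set:
            sel = f.edge_coefficients[
                (f.edge_coefficients["from"] == a)
                & (f.edge_coefficients["to"] == b)]
            if len(sel):
                members.append((f.weight, float(sel["coef"].iloc[0]),
                                float(sel["se"].iloc[0])))
        wsum = sum(w for w, _, _ in members)
        coef = sum(w * c for w, c, _ in members) / wsum
        # Buckland model-averaged standard error
        se = sum(w * math.sqrt(s ** 2 + (c - coef) ** 2)
                 for w, c, s in members) / wsum
        rows.append({"from": a, "to": b, "coef": coef, "se": se,
                     "ci_low": coef - 1.96 * se,
                     "ci_high": coef + 1.96 * se,
                     "n_models": len(members)})
    return fits, pd.DataFrame(rows)


def ranking_frame(fits):
    """Tabulate ranked PathFitStats."""
    return pd.DataFrame([
        {"model": f.model.name, "k": f.k, "C": f.C, "p": f.p_value,
         "q": f.q, "n": f.n, "CICc": f.cicc, "dCICc": f.delta_cicc,
         "rel_lik": f.rel_likelihood, "weight": f.weight}
        for f in fits])
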