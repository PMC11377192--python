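"""Environment-dependent birth-death diversification models.

Implements reconstructed-tree likelihoods for birth-death processes whose
speciation rate lambda(t) and extinction rate mu(t) are constant, or depend
exponentially on time or on a smoothed paleo-environmental curve (global
temperature, Andean paleoelevation), with incomplete sampling handled by a
sampling fraction f.  A fixed battery of 14 models (2 constant + 4 forms x
3 drivers) is fitted by maximum likelihood and compared with AICc and
Akaike weights.

Conventions
-----------
Time t is measured in Ma before present (t = 0 at the tips).  The
time-dependent forms use lambda(t) = lambda0 * exp(alpha * t), so a
positive alpha means higher speciation deeper in time.  Environmental
forms use lambda(t) = lambda0 * exp(alpha * env(t)).  Likelihoods are
conditioned on the crown age and on survival of both crown lineages.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.interpolate import CubicSpline
from scipy.optimize import minimize

__all__ = [
    "PaleoCurve", "BDModelSpec", "BDFit", "smooth_curve",
    "bd_loglik", "fit_bd", "battery_14", "aicc_compare",
]


# ----------------------------------------------------------------------
# Paleo curves
# ----------------------------------------------------------------------

class PaleoCurve:
    """A smooth environmental function of age (Ma before present).

    Evaluation is defined for all ages: beyond the data support the curve
    is extrapolated at its boundary value (constant extrapolation).
    """

    def __init__(self, ages, values, spline=None, df=None, name=""):
        ages = np.asarray(ages, dtype=float)
        values = np.asarray(values, dtype=float)
        order = np.argsort(ages)
        self.ages = ages[order]
        self.values = values[order]
        if np.any(np.diff(self.ages) <= 0):
            raise ValueError("duplicate ages in paleo series")
        self.df = df
        self.name = name
        self._spline = spline if spline is not None else CubicSpline(
            self.ages, self.values)

    def __call__(self, age):
        age = np.clip(np.asarray(age, dtype=float),
                      self.ages[0], self.ages[-1])
        return self._spline(age)

    @classmethod
    def from_csv(cls, path, age_col="age_ma", value_col="value", name=""):
        df = pd.read_csv(path)
        return cls(df[age_col].to_numpy(), df[value_col].to_numpy(), name=name)

    def to_frame(self):
        return pd.DataFrame({"age_ma": self.ages, "value": self.values})


def _penalty_matrix(x):
    """K = D' W^-1 D of the natural cubic smoothing spline (Reinsch form).

    The penalized fit minimizes ||y - f||^2 + lam f' K f; the hat matrix
    is (I + lam K)^-1, whose trace is the effective degrees of freedom.
    """
    n = x.size
    h = np.diff(x)
    D = np.zeros((n - 2, n))
    for i in range(n - 2):
        D[i, i] = 1.0 / h[i]
        D[i, i + 1] = -1.0 / h[i] - 1.0 / h[i + 1]
        D[i, i + 2] = 1.0 / h[i + 1]
    W = np.zeros((n - 2, n - 2))
    for i in range(n - 2):
        W[i, i] = (h[i] + h[i + 1]) / 3.0
        if i + 1 < n - 2:
            W[i, i + 1] = W[i + 1, i] = h[i + 1] / 6.0
    return D.T @ np.linalg.solve(W, D)


def smooth_curve(ages, values, df=80, name=""):
    """Penalized cubic smoothing spline with a target effective df.

    The penalty is found by bisection so that the trace of the hat matrix
    (I + lam K)^-1 matches ``df`` (capped at the number of points; df == n
    gives exact interpolation, df == 2 approaches the least-squares line,
    which spans the null space of the roughness penalty).
    """
    ages = np.asarray(ages, dtype=float)
    values = np.asarray(values, dtype=float)
    order = np.argsort(ages)
    ages, values = ages[order], values[order]
    if ages.size < 4:
        raise ValueError("need at least 4 points to smooth")
    if np.any(np.diff(ages) <= 0):
        raise ValueError("duplicate ages")
    if df < 2:
        raise ValueError("df must be >= 2")
    n = ages.size
    df = min(float(df), float(n))
    if df >= n - 1e-9:
        spline = CubicSpline(ages, values, bc_type="natural")
        return PaleoCurve(ages, values, spline=spline, df=float(n), name=name)
    K = _penalty_matrix(ages)
    # eigenbasis of the penalty: shrinkage decouples per eigenvector and
    # the two zero modes (constant + linear trend) pass through exactly
    w, U = np.linalg.eigh((K + K.T) / 2)
    w = np.where(w < 1e-10 * max(w.max(), 1.0), 0.0, w)
    proj = U.T @ values

    def edf(lam):
        return float(np.sum(1.0 / (1.0 + lam * w)))

    lo, hi = -18.0, 18.0  # log10(lam); edf decreases monotonically
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if edf(10.0 ** mid) > df:
            lo = mid
        else:
            hi = mid
    lam = 10.0 ** (0.5 * (lo + hi))
    fitted = U @ (proj / (1.0 + lam * w))
    spline = CubicSpline(ages, fitted, bc_type="natural")
    return PaleoCurve(ages, fitted, spline=spline, df=df, name=name)


# ----------------------------------------------------------------------
# Model specification
# ----------------------------------------------------------------------

LAMBDA_FORMS = ("constant", "exp-time", "exp-env")
MU_FORMS = ("zero", "constant", "exp-time", "exp-env")


@dataclass(frozen=True)
class BDModelSpec:
    """Parametric birth-death model: forms, parameters, driver curve, f."""

    lambda_form: str = "constant"
    mu_form: str = "zero"
    lambda0: float = 0.1
    alpha: float = 0.0
    mu0: float = 0.0
    beta: float = 0.0
    curve: PaleoCurve | None = None
    sampling_fraction: float = 1.0
    name: str = ""

    def __post_init__(self):
        if self.lambda_form not in LAMBDA_FORMS:
            raise ValueError(f"unknown lambda form {self.lambda_form!r}")
        if self.mu_form not in MU_FORMS:
            raise ValueError(f"unknown mu form {self.mu_form!r}")
        if not (0 < self.sampling_fraction <= 1):
            raise ValueError("sampling fraction must be in (0, 1]")
        needs_curve = "env" in self.lambda_form or "env" in self.mu_form
        if needs_curve and self.curve is None:
            raise ValueError("environmental model requires a curve")

    @property
    def free_parameters(self):
        """Free-parameter names in canonical order."""
        out = ["lambda0"]
        if self.lambda_form != "constant":
            out.append("alpha")
        if self.mu_form != "zero":
            out.append("mu0")
        if self.mu_form in ("exp-time", "exp-env"):
            out.append("beta")
        return out

    @property
    def k(self):
        return len(self.free_parameters)

    def lambda_at(self, t):
        if self.lambda_form == "constant":
            return self.lambda0 * np.ones_like(np.asarray(t, dtype=float))
        if self.lambda_form == "exp-time":
            return self.lambda0 * np.exp(self.alpha * np.asarray(t, dtype=float))
        return self.lambda0 * np.exp(self.alpha * self.curve(t))

    def mu_at(self, t):
        t = np.asarray(t, dtype=float)
        if self.mu_form == "zero":
            return np.zeros_like(t)
        if self.mu_form == "constant":
            return self.mu0 * np.ones_like(t)
        if self.mu_form == "exp-time":
            return self.mu0 * np.exp(self.beta * t)
        return self.mu0 * np.exp(self.beta * self.curve(t))

    def with_params(self, **kw):
        return replace(self, **kw)


@dataclass
class BDFit:
    """A fitted birth-death model with its information-criterion scores."""

    model: BDModelSpec
    loglik: float
    k: int
    n_tips: int
    aicc: float = field(default=float("nan"))
    delta_aicc: float = field(default=float("nan"))
    weight: float = field(default=float("nan"))
    converged: bool = True
    message: str = ""

    def __post_init__(self):
        if math.isnan(self.aicc):
            self.aicc = aicc(self.loglik, self.k, self.n_tips)

    def params_dict(self):
        m = self.model
        return {"lambda0": m.lambda0, "alpha": m.alpha,
                "mu0": m.mu0, "beta": m.beta}


def aicc(loglik, k, n):
    """Small-sample corrected AIC; n = number of tips."""
    if n - k - 1 <= 0:
        raise ValueError(f"AICc undefined: n={n} <= k+1={k + 1}")
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


# ----------------------------------------------------------------------
# Likelihood
# ----------------------------------------------------------------------

def _solve_E_and_flow(model, t_max, rtol=1e-8, atol=1e-10, grid_n=4097):
    """Integrate E(t) and the log branch-flow primitive Phi(t) on [0, t_max].

    E(t) is the probability that a lineage alive at age t leaves no sampled
    descendant; Phi(t) = integral_0^t [-(lambda+mu) + 2 lambda E] ds, so the
    log flow along a branch spanning ages [a, b] is Phi(b) - Phi(a).
    The rate functions are tabulated once on a dense age grid and linearly
    interpolated inside the right-hand side (the tabulation is exact for
    constant and piecewise-linear rates and a fine quadrature otherwise).
    """
    f = model.sampling_fraction
    t_hi = max(t_max, 1e-12)
    tgrid = np.linspace(0.0, t_hi, grid_n)
    lam_tab = np.broadcast_to(model.lambda_at(tgrid), tgrid.shape).copy()
    mu_tab = np.broadcast_to(model.mu_at(tgrid), tgrid.shape).copy()
    if np.any(lam_tab <= 0) or not np.all(np.isfinite(lam_tab + mu_tab)):
        raise RuntimeError("invalid rates on [0, crown age]")

    def rhs(t, y):
        E = y[0]
        lam = np.interp(t, tgrid, lam_tab)
        mu = np.interp(t, tgrid, mu_tab)
        dE = mu - (lam + mu) * E + lam * E * E
        dPhi = -(lam + mu) + 2.0 * lam * E
        return (dE, dPhi)

    sol = solve_ivp(rhs, (0.0, t_hi), [1.0 - f, 0.0],
                    method="RK45", rtol=rtol, atol=atol, dense_output=True)
    if not sol.success:
        raise RuntimeError(f"E(t) ODE failed: {sol.message}")
    return sol.sol


def bd_loglik(tree, model, rtol=1e-8, atol=1e-10):
    """Log-likelihood of an ultrametric tree under a birth-death model.

    Conditioned on the crown age and survival of both crown lineages:
    the likelihood is divided by lambda(t_root) * (1 - E(t_root))^2.
    """
    tree.require_ultrametric()
    tree.require_bifurcating()
    f = model.sampling_fraction
    ages = tree.ages
    t_root = tree.crown_age
    sol = _solve_E_and_flow(model, t_root, rtol=rtol, atol=atol)
    EPhi = sol(np.clip(ages, 0.0, t_root))  # (2, n_nodes)
    Phi = EPhi[1]

    logL = tree.n_tips * math.log(f)
    # branch flows
    has_parent = tree.parent >= 0
    logL += float(np.sum(Phi[tree.parent[has_parent]]
                         - Phi[np.flatnonzero(has_parent)]))
    # speciation events at internal nodes (root included)
    lams = np.asarray(model.lambda_at(ages[tree.internal_nodes]),
                      dtype=float)
    if np.any(lams <= 0) or not np.all(np.isfinite(lams)):
        raise RuntimeError("non-positive or non-finite lambda at a node")
    logL += float(np.sum(np.log(lams)))
    # crown conditioning
    lam_root = float(model.lambda_at(t_root))
    surv = 1.0 - float(sol(t_root)[0])
    if surv <= 0:
        raise RuntimeError("survival probability vanished at the crown")
    logL -= math.log(lam_root) + 2.0 * math.log(surv)
    if not np.isfinite(logL):
        raise RuntimeError(
            f"non-finite log-likelihood for parameters {model}")
    return float(logL)


def constant_bd_loglik(tree, lambda0, mu0, f=1.0):
    """Closed-form constant-rate likelihood (same conditioning), for checks.

    Uses the analytic solutions of the E and flow equations with constant
    rates and tip sampling probability f.
    """
    tree.require_ultrametric()
    tree.require_bifurcating()
    lam, mu = float(lambda0), float(mu0)
    r = lam - mu

    def E(t):
        if abs(r) < 1e-12:
            # critical case lam == mu
            denom = 1.0 + lam * t * f
            return 1.0 - f / denom
        ert = math.exp(-r * t)
        return 1.0 - f * r / (f * lam + (lam * (1 - f) - mu) * ert)

    def logD_over_f(t):
        # log of D(t)/D(0) for a branch starting at age 0 (flow primitive)
        if abs(r) < 1e-12:
            return -2.0 * math.log(1.0 + lam * t * f)
        ert = math.exp(-r * t)
        denom = f * lam + (lam * (1 - f) - mu) * ert
        return -r * t + 2.0 * (math.log(abs(r)) - math.log(abs(denom)))

    ages = tree.ages
    logL = tree.n_tips * math.log(f)
    for node in range(tree.n_nodes):
        p = tree.parent[node]
        if p < 0:
            continue
        logL += logD_over_f(ages[p]) - logD_over_f(ages[node])
    for node in tree.internal_nodes:
        logL += math.log(lam)
    t_root = tree.crown_age
    logL -= math.log(lam) + 2.0 * math.log(1.0 - E(t_root))
    return float(logL)


# ----------------------------------------------------------------------
# Fitting
# ----------------------------------------------------------------------

#: bounds on log10 rates; dependence coefficients are bounded per driver
_LOG_RATE_BOUNDS = (-6.0, 1.0)
#: hard cap on lambda(t) + mu(t) during fitting (events / Myr) -- keeps
#: the E-equation non-stiff and excludes biologically absurd rates
_MAX_TOTAL_RATE = 500.0


def fit_bd(tree, template, starts=5, seed=0, rtol=1e-7, atol=1e-9):
    """Maximum-likelihood fit of a birth-death model template.

    Rates (lambda0, mu0) are optimized on the log10 scale; dependence
    coefficients (alpha, beta) are unconstrained.  Multi-start L-BFGS-B:
    the first start comes from the template's current parameter values
    (callers seed templates with the nested simpler model's estimates),
    the rest are jittered.
    """
    free = template.free_parameters
    if not free:
        ll = bd_loglik(tree, template, rtol=rtol, atol=atol)
        return BDFit(model=template, loglik=ll, k=0, n_tips=tree.n_tips)
    rng = np.random.default_rng(seed)

    def pack(model):
        x = []
        for name in free:
            v = getattr(model, name)
            if name in ("lambda0", "mu0"):
                x.append(math.log10(max(v, 1e-7)))
            else:
                x.append(v)
        return np.array(x)

    def unpack(x):
        kw = {}
        for name, v in zip(free, x):
            kw[name] = 10.0 ** v if name in ("lambda0", "mu0") else v
        return template.with_params(**kw)

    tgrid = np.linspace(0.0, tree.crown_age, 257)

    def negll(x):
        try:
            with np.errstate(over="ignore", invalid="ignore"):
                model = unpack(x)
                total = np.max(np.asarray(model.lambda_at(tgrid))
                               + np.asarray(model.mu_at(tgrid)))
                if not np.isfinite(total) or total > _MAX_TOTAL_RATE:
                    return 1e10
                return -bd_loglik(tree, model, rtol=rtol, atol=atol)
        except (RuntimeError, OverflowError, FloatingPointError):
            return 1e10

    # dependence coefficients live on the scale of the driver's values:
    # cap |alpha * driver| so the exponential rate stays representable
    t_root = tree.crown_age
    drv_scale = {}
    for nm, form in (("alpha", template.lambda_form),
                     ("beta", template.mu_form)):
        if form == "exp-time":
            drv_scale[nm] = t_root
        elif form == "exp-env":
            drv_scale[nm] = max(np.max(np.abs(
                template.curve(np.linspace(0, t_root, 257)))), 1e-12)
    bounds = []
    for nm in free:
        if nm in ("lambda0", "mu0"):
            bounds.append(_LOG_RATE_BOUNDS)
        else:
            cap = 10.0 / drv_scale[nm]
            bounds.append((-cap, cap))
    x0 = pack(template)
    # jitter scaled to each parameter's feasible width
    widths = np.array([min(b[1] - b[0], 10.0) for b in bounds])
    best = None
    for s in range(max(1, starts)):
        xs = x0 if s == 0 else x0 + rng.normal(0.0, 0.08 * widths)
        xs = np.clip(xs, [b[0] for b in bounds], [b[1] for b in bounds])
        res = minimize(negll, xs, method="L-BFGS-B", bounds=bounds,
                       options={"maxiter": 120, "ftol": 1e-10})
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun) or best.fun >= 1e10:
        raise RuntimeError(
            f"all optimizer starts failed for model {template.name!r}")
    model = unpack(best.x)
    return BDFit(model=model, loglik=-float(best.fun), k=len(free),
                 n_tips=tree.n_tips, converged=bool(best.success),
                 message=str(best.message))


def _battery_templates(temp_curve, elev_curve, f):
    """The 14-model battery: 2 constant + 4 forms for each of 3 drivers."""
    drivers = [("time", None), ("temp", temp_curve), ("elev", elev_curve)]
    out = [
        BDModelSpec("constant", "zero", sampling_fraction=f,
                    name="pure-birth constant"),
        BDModelSpec("constant", "constant", mu0=0.01, sampling_fraction=f,
                    name="constant birth-death"),
    ]
    for dname, curve in drivers:
        lf = "exp-time" if curve is None else "exp-env"
        out.extend([
            BDModelSpec(lf, "zero", curve=curve, sampling_fraction=f,
                        name=f"lambda({dname}), mu=0"),
            BDModelSpec(lf, "constant", mu0=0.01, curve=curve,
                        sampling_fraction=f,
                        name=f"lambda({dname}), mu constant"),
            BDModelSpec("constant", lf, mu0=0.01, curve=curve,
                        sampling_fraction=f,
                        name=f"lambda constant, mu({dname})"),
            BDModelSpec(lf, lf, mu0=0.01, curve=curve, sampling_fraction=f,
                        name=f"lambda({dname}), mu({dname})"),
        ])
    return out


def battery_14(tree, temp_curve, elev_curve, f=0.46, starts=3, seed=0,
               rtol=1e-6, atol=1e-8):
    """Fit the full 14-model battery and rank by AICc.

    Simpler models are fitted first and their estimates seed the starting
    values of the more complex models sharing their parameters.
    """
    if temp_curve is None or elev_curve is None:
        raise ValueError("both temperature and elevation curves are required")
    templates = _battery_templates(temp_curve, elev_curve, f)
    fits = []
    # fit the two constant models first to warm-start the rest
    pb = fit_bd(tree, templates[0], starts=starts, seed=seed,
                rtol=rtol, atol=atol)
    cbd = fit_bd(tree, templates[1], starts=starts, seed=seed + 1,
                 rtol=rtol, atol=atol)
    fits.extend([pb, cbd])
    for i, tpl in enumerate(templates[2:], start=2):
        warm = tpl.with_params(
            lambda0=cbd.model.lambda0 if "mu" in tpl.name else pb.model.lambda0,
            mu0=max(cbd.model.mu0, 1e-4),
        )
        try:
            fits.append(fit_bd(tree, warm, starts=starts, seed=seed + i,
                               rtol=rtol, atol=atol))
        except RuntimeError as exc:
            fits.append(BDFit(model=tpl, loglik=float("-inf"), k=tpl.k,
                              n_tips=tree.n_tips, aicc=float("inf"),
                              converged=False, message=str(exc)))
    return aicc_compare(fits, tree.n_tips)


def aicc_compare(fits, n):
    """Attach delta-AICc and Akaike weights; return fits sorted by AICc."""
    for fit in fits:
        if math.isnan(fit.aicc):
            fit.aicc = aicc(fit.loglik, fit.k, n)
    finite = [f for f in fits if math.isfinite(f.aicc)]
    if not finite:
        raise ValueError("no fit with finite AICc")
    best = min(f.aicc for f in finite)
    rel = []
    for fit in fits:
        fit.delta_aicc = fit.aicc - best
        rel.append(math.exp(-fit.delta_aicc / 2.0)
                   if math.isfinite(fit.delta_aicc) else 0.0)
    total = sum(rel)
    for fit, r in zip(fits, rel):
        fit.weight = r / total
    return sorted(fits, key=lambda f: f.aicc)


def fits_to_frame(fits):
    """Tabulate a battery as a DataFrame (model, parameters, scores)."""
    rows = []
    for fit in fits:
        row = {"model": fit.model.name, **fit.params_dict(),
               "logL": fit.loglik, "k": fit.k, "AICc": fit.aicc,
               "dAICc": fit.delta_aicc, "weight": fit.weight,
               "converged": fit.converged}
        rows.append(row)
    return pd.DataFrame(rows)
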