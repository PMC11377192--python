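# Methods

This note documents the models, estimators and numerical choices behind
`macroevo_paths`, and what the synthetic-data generator does and does not
emulate.

## Tree model and conventions

Trees are rooted, time-calibrated and ultrametric; node ages are measured
backward from the present in Ma, so extant tips sit at age 0 and the crown
node at the crown age. All likelihood modules adopt this convention because
paleo-environmental curves are naturally indexed by age. Ultrametricity is
enforced within a relative tolerance of 1e-6 of the crown age; trees
failing it are rejected by the likelihood operations rather than silently
coerced. Polytomies are tolerated by the tree container but rejected by the
birth-death and DEC likelihoods, which assume bifurcation. Tip labels are
matched to data tables by exact string comparison after whitespace
trimming; a mismatch is an error, never a silent drop.

## Tip rates

**DR statistic.** For tip *i* with root-to-tip edges of lengths
l_1 (terminal) … l_N (root-adjacent), the equal-splits measure is
ES_i = Σ_j l_j 2^{-(j-1)} and DR_i = 1/ES_i (units 1/Myr). DR is a
speciation-rate proxy: recent, short terminal branches give high values.

**Phylogenetic ridge regression.** Per trait axis we solve

    min_b || y − y_root·1 − L b ||² + λ_r || b ||²

where L is the tips × branches incidence matrix (entry = branch length if
the branch lies on that tip's root path) and y_root is the GLS root
estimate under Brownian motion. Per-branch rates are the coefficients b;
the per-tip rate for a trait space is the Euclidean norm across axes of
the terminal-branch coefficients — a single scalar per space is what the
path analysis needs, and the norm is the natural aggregate of per-axis
rates (per-axis values remain available). The penalty λ_r defaults to
generalized cross-validation over a log grid spanning 1e-6…1e3 times
tr(LᵀL)/n_branches; the chosen value is recorded in the output metadata.
GCV is deterministic and reproducible; the solution path is computed
through the SVD of L, so shrinkage is exact and monotone in λ_r.

**Clade rate-shift test.** The observed statistic is the mean absolute
tip rate in the focal clade; the null distribution is the same statistic
on uniformly drawn tip subsets of equal size. The two-tailed p-value uses
the add-one rule, p = min(1, 2·min(p_hi, p_lo)) with
p_side = (1 + #extreme)/(reps + 1), so p can never fall below 1/(reps+1).

## Environment-dependent birth-death models

Speciation λ(t) and extinction μ(t) are constant, exponential in time
(λ0·e^{αt}, t in Ma before present, so α > 0 means faster speciation
deeper in time — the sign convention is recorded in outputs), or
exponential in a smoothed environmental curve (λ0·e^{α·env(t)}).
Incomplete sampling enters as an i.i.d. tip observation probability f
(default 0.46, the global sampling fraction of the emulated study).

The reconstructed-tree likelihood uses the standard time-varying ODE
formulation: the extinction-or-unsampled probability E(t) solves
dE/dt = μ − (λ+μ)E + λE² with E(0) = 1 − f, and the log branch flow is the
primitive Φ(t) = ∫₀ᵗ [−(λ+μ) + 2λE] ds, so a branch spanning ages [a, b]
contributes Φ(b) − Φ(a). Each internal node contributes log λ(t_node); the
likelihood is conditioned on the crown age and on survival of both crown
lineages (division by λ(t_root)(1 − E(t_root))²). The conditioning scheme
is a deliberate fixed choice (crown, not stem) and is recorded in output
metadata. A closed-form constant-rate likelihood (`constant_bd_loglik`)
is kept as an independent oracle; the ODE path must agree with it to
better than 1e-6 whenever α = β = 0.

Numerics: adaptive RK45 with rtol 1e-8/atol 1e-10 by default (relaxed to
1e-6/1e-8 inside the fitting loop); the rate functions are tabulated on a
4097-point age grid and linearly interpolated inside the right-hand side,
which is exact for constant rates and a fine quadrature otherwise. During
fitting, parameter combinations with max λ+μ > 500/Myr are rejected
outright: they are biologically absurd and make the E-equation stiff.
Rates are optimized on the log10 scale in [1e-6, 10]/Myr; dependence
coefficients are bounded so |α·driver| ≤ 10. Multi-start L-BFGS-B (first
start from the nested simpler model's estimates, the rest jittered within
bounds) guards against local optima.

**The 14-model battery** comprises pure-birth and constant birth-death
null models plus, for each driver (time, temperature, elevation): λ
driver-dependent with μ = 0; λ driver-dependent with μ constant; λ
constant with μ driver-dependent; both driver-dependent. Free-parameter
counts are 1, 2, 2, 3, 3, 4 respectively. Models are compared by AICc
(−2logL + 2k + 2k(k+1)/(n−k−1), n = tips) and Akaike weights.

**Paleo-curve smoothing** is a penalized cubic smoothing spline in the
Reinsch form: fitted values are (I + λK)⁻¹y with K the natural-spline
roughness matrix; the penalty is chosen by bisection so the trace of the
hat matrix equals the requested effective degrees of freedom (default 80,
capped at the number of points). The computation runs in the eigenbasis
of K, so the two zero-roughness modes (constant and linear trend) pass
through exactly and df = 2 reproduces a least-squares line. Curves are
constant-extrapolated outside their support.

## Disparity and disparity-through-time

Climatic morphospaces are PCAs of the centered, scaled continuous table;
vegetative/floral morphospaces are principal-coordinate analyses of the
Gower distance (continuous/ordinal traits: range-normalized absolute
difference, ordinal columns rank-transformed; binary and nominal traits:
0/1 mismatch; missing values excluded pairwise). Negative PCoA
eigenvalues beyond tolerance trigger the Cailliez additive correction.

Disparity of a species set is the mean squared pairwise Euclidean
distance among its ordination coordinates, computed via the identity
mean-pairwise = 2·Σ_axes var (divisor n−1). Clades of unequal size are
compared after rarefaction (default: 4 species × 100 draws) using the
Bhattacharyya coefficient Σ√(p·q) on shared bins (Sturges' rule on the
pooled sample — deterministic and scale-free); distributions with
BC < 0.05 are flagged distinct (configurable).

DTT evaluates, at each internal-node age (or user-supplied bins, e.g.
the study's five 6-Myr bins), the mean over lineages crossing that age of
(descendant-tip disparity / total disparity); the value at the crown is 1
by construction, and the curve is invariant to uniform scaling of the
scores. The null is multivariate BM simulated on the same tree with
per-axis rates estimated from the data by GLS (axes treated as
independent — ordination axes are orthogonal); per-lineage aggregation is
the mean across crossing lineages (the classic formulation; recorded in
metadata). MDI is the signed trapezoid area between the observed curve
and the null **median** (the median/mean choice is configurable; median
is the default) over relative time; the p-value is the two-sided rank of
the observed MDI among the null MDIs.

## Multi-optimum OU models

For a priori regime hypotheses (e.g. a single Andean shift, a core-clade
shift, or several pollinator-shift regimes) painted on branches, the
Hansen model gives mean Wθ — W built from exponentially decaying regime
occupancy along each root-to-tip path, with the root at the root regime's
optimum (stationarity; an estimated root is available behind a flag) —
and covariance σ²/(2α)·e^{−α d_ij}(1 − e^{−2α t^anc_ij}). θ is profiled
by GLS and σ² analytically, leaving a 1-D search over log α (coarse grid
then bounded refinement); α → 0 is handled by analytic continuation to
BM. Data-driven shift detection (lasso-type scans) is out of scope: only
user-supplied paintings are fitted.

Model comparison uses BIC = −2logL + k ln n with k = 2 + m (α, σ², m
optima), or pBIC = BIC + 2 ln C(edges, m−1), which additionally penalizes
the number of possible placements of the m−1 shifts on the tree's
branches. This config-count penalty captures the multiplicity correction
deterministically; outputs are labelled "pBIC(config-count)".

## DEC biogeography

The state space comprises all nonempty area subsets up to a maximum range
size (default 5 of ≤9 areas) plus an absorbing null range. Anagenetic
rates: dispersal into area a at rate Σ_{b∈R} d·m_s(b,a)^w, with
per-stratum dispersal multipliers m_s ∈ [1e-5, 1] and the exponent
w ∈ [0, 3] shared across strata; extirpation at rate e per occupied area.
Branch segments crossing stratum boundaries are split exactly at the
boundary ages and their dense matrix exponentials multiplied in
chronological order (the state space is desk-scale, so no sparse
machinery). Cladogenesis follows classic DEC: narrow sympatry for
single-area ranges; subset sympatry and vicariance for wider ranges, all
non-jump scenarios equiprobable; the +J variant adds founder-event jumps
to single unoccupied areas with relative weight j before normalization.
Duplicate daughter-state pairs arising for two-area ranges are counted
once, matching the canonical six-scenario event set. Root states are
weighted equally (summed, not averaged) — the convention of the classic
DEC implementations. Adjacency constraints act as per-stratum state
masks: disallowed states get zero conditional likelihood in that stratum.
Ancestral ranges are marginal probabilities from a two-pass
(pruning + back-propagation) algorithm, verified against exhaustive
enumeration on small cases.

Fitting optimizes any subset of {d, e, j, w} (d, e on the log10 scale in
[1e-6, 10]; j, w in [0, 3]) by multi-start L-BFGS-B; AICc uses k = number
of free parameters.

## Phylogenetic path analysis

Candidate causal structures are DAGs over {BG, climR, vegR, florR, SR}
(biogeographic background, climatic-niche / vegetative / floral
trait-evolution rates, speciation rate). The default battery holds 11
models: four single direct effects on SR, six increasingly complex
indirect combinations, and a full model in which BG drives climR (and
weakly SR), climR drives SR and both trait rates, and both trait rates
affect SR. The exact intermediate combinations are this package's
documented defaults and can be overridden with a model-set JSON file.

Each model's Shipley basis contains one conditional-independence claim
per non-adjacent vertex pair: the response is the pair member later in
the (lexicographically tie-broken) topological order, and the
conditioning set is the union of both members' parents. Continuous
responses are tested with Pagel's-λ GLS — covariance σ²[λV* + (1−λ)I],
V* the BM covariance scaled to unit diagonal, λ estimated by bounded ML
on [0, 1] with the boundary values checked explicitly; p-values are
t-based. A binary response (BG) is tested with Firth-penalized logistic
regression (Jeffreys-prior score correction, finite under complete
separation) in which a phylogenetic random effect is approximated by a
single variance component on V*, chosen on a small grid by a penalized
working likelihood; the component at 0 reduces exactly to plain Firth
logistic regression. Continuous variables are z-scored once before all
regressions, so path coefficients are standardized.

Fisher's C = −2 Σ ln p over the k claims is referred to χ² with 2k df;
CICc = C + 2qn/(n−1−q) with q = number of edges by default (the
edges+vertices convention is available and the choice recorded in
output). Ranking uses relative likelihoods e^{−ΔCICc/2} and normalized
CICc weights; models within ΔCICc < 2 of the best form the averaging
set. Averaging is conditional — each edge is averaged, with renormalized
weights, only over the models that contain it (full averaging with
absent edges as zero is behind a flag) — and 95% CIs use Buckland-style
model-averaged standard errors √(se² + (coef − coef̄)²).

## Synthetic-data generator

Every generator is a pure function of (parameters, seed) and stores its
generating parameters in a SimTruth record, so parameter-recovery tests
always have ground truth. The birth-death simulator starts from two crown
lineages, uses thinning for time-varying rates, prunes extinct lineages,
retains tips i.i.d. with probability f, and rejection-samples until both
crown lineages have a sampled survivor — matching the crown-conditioned
likelihood. The rate-shift simulator multiplies both rates of one random
surviving lineage (and descendants) from the shift age onward. Trait
generators sample exact BM/OU transitions branch by branch; the binary
character is a 2-state Markov chain with stationary (or fixed) root; the
range simulator shares the DEC event set with the likelihood module and
re-draws branches that hit the null range. Path-analysis tables are
generated in topological order with phylogenetically correlated residuals
σ²[λV* + (1−λ)I], and BG is a latent phylogenetic variable thresholded at
its median (guaranteeing both classes).

The bundled study scenario emulates a Merianieae-like system: a
reconstructed tree of ~139 tips (redrawn until within 100–180) with crown
age 30 Ma, global sampling fraction f = 0.46, seven named clades, and a
3-fold diversification shift on one lineage at 10 Ma (λ0 = 0.18,
μ0 = 0.03 — calibrated so the sampled tip count lands near 139);
three-axis climatic traits with a 4× rate multiplier in the shifted
clade; mixed vegetative and floral tables; an Andean/extra-Andean binary
background aligned with the shifted clade; DEC ranges over five areas;
and temperature-like (cooling + oscillation) and uplift-like (staged
logistic) paleo-curves.

What the generator does **not** emulate: phylogenetic uncertainty
(a single true tree is used), fossil or extinct samples, trait-dependent
(SSE-style) diversification, measurement error in traits, spatially
explicit ranges, or non-exponential environment dependence. Passing
recovery tests therefore demonstrate internal consistency of estimator
and generator under the stated model families, not robustness to
real-data violations of them.

## Problem sizes used in tests and the acceptance script

Statistical checks run at deliberately desk-scale sizes chosen by this
package: likelihood-oracle sweeps use ≤100-tip trees; environment-
dependent rate recovery uses 14–16 trees of median ~200 tips simulated
under a gradual-uplift curve (λ0 = 0.05, α = 2 — a gradual curve spreads
information over the tree and keeps λ0 and α separately identifiable);
OU optimum recovery uses ~50–100-tip trees with αT = 50; DEC recovery
uses 6–8 trees with 4 areas; path-coefficient and structure recovery use
a ~166-tip tree with 15–20 replicate datasets; Fisher's-C calibration
uses 100–150 replicates; MDI calibration uses 30–40 BM datasets with 60
null simulations each. Defaults in the pipeline itself remain at the
study-scale settings (DTT simulations 1000, rarefaction 4 × 100, spline
df 80, ΔCICc threshold 2, f = 0.46).

## Known limitations

- The birth-death fitter can trade off λ0 against α when the driver curve
  is nearly two-valued over the tree's depth (plateau-like uplift);
  recovery is accurate for curves with gradual change.
- The phylogenetic component of the binary regression is a PQL-style
  approximation selected on a coarse grid, not an integrated likelihood.
- DEC ancestral marginals assume the fitted parameters are known; no
  uncertainty in (d, e, j, w) is propagated.
- DTT on incompletely sampled trees overestimates disparity toward the
  present; comparisons between trait spaces on the same tree remain
  valid, absolute curves do not.
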