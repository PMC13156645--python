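# Methods

## Models

**Poisson regression.** For counts y₁…yₙ over areal units with covariates
xᵢ ∈ ℝᵖ, the global Poisson model is log μᵢ = xᵢ′β with
ℓ(β) = Σ (yᵢ ln μᵢ − μᵢ − ln yᵢ!).  Its equidispersion assumption
E(Y) = Var(Y) is diagnosed with the deviance/df ratio; the default verdict
thresholds flag overdispersion above 1.5 (the usual rule of thumb) and
underdispersion below 1/1.5, both configurable.

**Negative binomial regression.** The NB model is the Poisson-Gamma
mixture with

  Var(Yᵢ) = μᵢ + θ μᵢ²,

and per-observation log-density

  ln Γ(y + 1/θ) − ln Γ(1/θ) − ln Γ(y+1) − (1/θ) ln(1 + θμ) + y ln(θμ/(1+θμ)).

θ here is the **dispersion** parameter: θ → 0 recovers Poisson, and θ is
the reciprocal of the "size" convention used by some other software
(`theta_to_size`/`size_to_theta` convert).  All likelihood code combines
the two θ-singular terms as ln Γ(y + r) − ln Γ(r) − r·log1p(θμ) with
r = 1/θ, and uses `log1p`/`xlogy`, so it is stable for θ down to 1e-8 and
counts up to 1e6.

**Global NB estimation.** β given θ is an ordinary GLM problem and is
delegated to statsmodels IRLS (NB family with fixed dispersion); θ is then
profiled by bounded 1-D maximization of the profile log-likelihood over
log θ ∈ [ln 1e-8, ln 1e6].  A θ̂ at the lower bound triggers a "data
consistent with equidispersion" warning.  Standard errors come from the
GLM information at (β̂, θ̂), the standard practice of treating θ̂ as fixed
for β-inference.  AIC counts θ as one parameter.  The NB deviance uses the
saturated model at the same θ̂ (the unit deviance
2[y ln(y/μ) − (y + 1/θ) ln((1+θy)/(1+θμ))]); the saturated likelihood's
dispersion is not otherwise pinned down, so sharing θ̂ is a documented
choice.

## Spatial diagnostics

Both diagnostics run on the **Pearson residuals of the global NB fit**
(raw counts are available behind a flag for Moran's I).

**Moran's I** uses a zero-diagonal spatial weight matrix; the default
scheme is inverse distance (wᵢⱼ = 1/dᵢⱼ, unstandardized), with kernel
weights and row-standardization as options — the scheme is recorded in the
output so results are auditable.  E(I) = −1/(n−1); the variance is the
classical closed form under the normality assumption (default; the
randomization form is an option) and inference is a two-sided normal test
on z = (I − E(I))/√var(I).  Degenerate topologies where var(I) = 0 exactly
(e.g. the complete graph at small n, where I is deterministic) return
z = 0 rather than 0/0.

**Breusch–Pagan** is implemented exactly in its classical score form
BP = ½ f′Z(Z′Z)⁻¹Z′f with fᵢ = eᵢ²/σ̂² − 1, σ̂² = Σe²/n, and
Z = [1 | standardized covariates]; df = p excludes the intercept.  The
studentized (Koenker) variant — the default of common regression-diagnostic
libraries, and more robust to non-normality — is available via
`variant="koenker"`.  Under homoscedastic normal residuals the classical
statistic's rejection rate at α = 0.05 is verified to sit within binomial
99% bounds of 0.05 over 2000 replicates.

## Kernel weights and bandwidth

Weights wᵢⱼ = K(dᵢⱼ/bᵢ) use planar Euclidean distances on the raw
longitude/latitude coordinates (no projection; matching the practice the
workflow targets — note the caveat below).  Families:

- bisquare (1 − (d/b)²)² for d < b, else 0 — compact support;
- gaussian exp(−½ (d/b)²) — the convention of the spgwr weighting
  functions, since no universal normalization exists.

Fixed mode uses one bandwidth in distance units; adaptive mode takes a
proportion q ∈ (0,1] and sets bᵢ to the distance of the ⌈qn⌉-th nearest
neighbour (ties broken by unit order, deterministic).  The self-weight at
d = 0 is always 1 — distinct from the zero-diagonal Moran matrix.  Any row
with fewer than p + 2 positive weights is rejected as degenerate, naming
the unit.

**Leave-one-out CV.** CV(b) = Σᵢ (yᵢ − ŷ₋ᵢ)², with ŷ₋ᵢ = exp(xᵢ′β̂₋ᵢ)
from the local fit at i with the self-weight forced to zero (the standard
GWR device for "excluding i").  During the bandwidth search θ is fixed at
the global NB estimate — local re-profiling inside CV would add an order
of magnitude of cost for no clear gain, and θ is re-profiled per location
in the final fit.  Locations that fail to converge contribute a large
penalty (the total sum of squares) and are logged; a bandwidth with > 20%
failures gets a sentinel (infinite) score.  The minimizer is found by
golden-section search — on log-bandwidth between the smallest scale that
keeps every row determined and twice the data diameter (fixed mode), or on
q ∈ [(p+2)/n, 1] (adaptive) — to 1e-3 relative interval; the evaluated
(bandwidth, CV) curve is returned/exported so users can audit unimodality,
and a minimizer at the upper bound warns that the data may favour the
global model.

## GWNBR estimation

At each location i the local parameters maximize
Σⱼ wᵢⱼ ℓ_NB(yⱼ; exp(xⱼ′β), θ).  With η = x′β and μ = exp(η),

  ∂ℓ/∂η = (y − μ)/(1 + θμ),   ∂²ℓ/∂η² = −μ(1 + θy)/(1 + θμ)²,

so the weighted gradient is g = X′[w ⊙ (y−μ)/(1+θμ)] and the observed
Hessian H = −X′ diag(w μ(1+θy)/(1+θμ)²) X.  Both are validated against
central finite differences (relative error < 1e-5) in the test suite.

**Newton–Raphson.** β ← β − H⁻¹g, initialized from the global NB
estimates, stopping when max|Δβ| < 1e-8 or after 20 iterations (both
configurable).  Steps that would lower the objective are halved up to 10
times, making the accepted log-likelihood sequence non-decreasing;
ill-conditioned Hessians get a 1e-8 ridge with a warning, and a still
singular system marks the unit as failed.  The linear predictor is capped
at ±500 so exp never overflows.

**Local dispersion.** θ(uᵢ,vᵢ) is profiled per location: bounded 1-D
maximization over log θ ∈ [ln 1e-8, ln 1e4] alternating with β Newton
updates until the joint change falls below tolerance (≤ 50 alternations;
non-convergence is logged and the last iterate returned).  The lower bound
is small enough to represent essentially-Poisson locations (θ̂ ~ 1e-5),
which legitimately occur even under global overdispersion when spatial
heterogeneity explains the extra variance.

**Inference and model size.** Local SEs are √diag(−H⁻¹) at the optimum
and zₖ(uᵢ,vᵢ) = β̂ₖ/SEₖ, so z always carries the coefficient's sign.  The
spatial hat matrix uses the IRLS working-weight leverage

  sᵢᵢ = aᵢᵢ · xᵢ′(X′AᵢX)⁻¹xᵢ,  Aᵢ = diag(wᵢⱼ vⱼ),  vⱼ = μⱼ/(1 + θ̂ᵢ μⱼ),

the standard construction in the geographically-weighted literature; it is
validated by the global-limit identity tr(S) → p+1 when all weights are 1
and by explicit hat-row construction on fixtures.  Whole-model quantities
evaluate each observation under its own location's parameters:
ℓ = Σᵢ ℓ(yᵢ; μ̂ᵢ, θ̂ᵢ), D_spatial from the matching unit deviances (the
saturated term uses the local θ̂ᵢ — a flagged choice, since no convention
pins it), and AIC = −2ℓ + 2(tr(S) + 1), counting one pooled dispersion
degree of freedom; the parameter count is configurable in the comparison
step.  Failed units carry the global estimates, are flagged in the
convergence report, and > 20% failures abort the fit.

## Model comparison

- **F-type fit test**: F = (D_global/df₁)/(D_spatial/df₂), df₁ = n−(p+1),
  df₂ = n − tr(S) passed to the continuous F distribution without
  rounding.  Caveat: when both deviances are computed under their own
  fitted dispersions, each ratio is ≈ 1 by construction and F hovers near
  1 even when the spatial model is clearly better by AIC — expect this
  test to be conservative on data where dispersion and heterogeneity are
  confounded.
- **MLRT**: 2[ℓ(full) − ℓ(restricted)] ~ χ²(p), where the restricted model
  keeps local intercepts and local dispersions and drops only the
  covariates, so df equals the covariate count.  A statistic below −1e-6
  raises a consistency error (the full fit cannot be worse); smaller
  negatives are clamped to zero.
- **AIC ranking** with ties broken by smaller k, then name.

## Synthetic data generator

`gwnbr.simulate` draws areal datasets with affine coefficient surfaces
βₖ(u,v) = aₖ + bₖ(u−E/2)/E + cₖ(v−E/2)/E on an E×E map (uniform or grid
coordinates), i.i.d. covariates, and counts from the exact Poisson-Gamma
mixture: λᵢ ~ Gamma(1/θ, θμᵢ), yᵢ ~ Poisson(λᵢ), so E(Y) = μ and
Var(Y) = μ + θμ² hold exactly (θ = 0 gives plain Poisson).  Each covariate
draws from a substream keyed by its name, so reordering covariates only
relabels columns.  Specs whose μ leaves [1e-3, 1e6] are rejected with a
diagnostic.

The **reference scenario** (n = 200 grid units, four covariates on
deliberately disparate scales — a percentage, two counts, a monetary
amount — θ = 0.1, seed 20260419) was designed as a *powered, clean*
recovery experiment:

- the two heterogeneous coefficients drift in **orthogonal** directions
  (poverty west–east, expenditure south–north).  During development we
  found that two strong drifts in the same direction confound each other:
  the mean-level trend each induces (drift × covariate mean) leaks into
  the other's local coefficient through finite-sample covariate–location
  correlations, and can even flip the recovered surface's sign — an
  identifiability artifact of the experiment, not of the estimator;
- the poverty drift (local β₁ from 0 to 0.12, a contrast far milder than
  the order-of-magnitude global-vs-local differences reported in real
  areal studies) is sized so its pointwise spread (~0.035) is about twice
  the local estimator's standard error at CV-selected bandwidths; the
  expenditure drift is deliberately near that noise floor and is *not*
  expected to be recoverable at n = 200.

What passing tests on this generator do show: the whole pipeline detects
overdispersion and spatial structure, the CV selector behaves, and GWNBR
recovers a well-identified smooth surface (r ≈ 0.86 with the truth at the
CV bandwidth).  What they do not show: performance under spatially
autocorrelated covariates, non-affine or discontinuous coefficient
surfaces, zero-inflation, small-n regimes (n ≈ 34 gives local noise well
above the surfaces used here), or real-geography irregular polygons.

## Numerical choices, degeneracies, defaults

| quantity | default | notes |
|---|---|---|
| Newton tolerance | 1e-8 (max\|Δβ\|) | configurable |
| Newton iteration cap | 20 | step-halving ≤ 10 per iteration |
| θ search range (global) | [1e-8, 1e6] | log-scale bounded Brent |
| θ search range (local) | [1e-8, 1e4] | lower bound ⇒ "locally equidispersed" |
| overdispersion threshold | 1.5 | deviance/df rule of thumb |
| kernel/mode | adaptive bisquare | the usual CV winner; all four selectable |
| CV search tolerance | 1e-3 relative | golden section; curve exported |
| α | 0.05 | all decisions cite statistic, critical value, α |
| integer cast tolerance | 1e-9 | counts given as reals |

Known limitations: planar distances on unprojected degrees distort at
scale (acceptable for the compact study regions this targets; no
great-circle option yet); no offsets/exposure terms, zero-inflated or
hurdle variants; no AICc or multiscale (per-covariate) bandwidths;
bootstrap inference for local coefficients is out of scope, so the local Z
tests inherit the usual caveat that θ̂ᵢ is treated as known.
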