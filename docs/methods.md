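# Methods

## The model

The unit of analysis is a balanced panel of zone-level proportions: `y_it`,
the weighted share of sampled children in zone `i` who died before age
five in survey wave `t`, plus `k` covariate proportions `X`. Spatial
structure enters through a contiguity matrix `W` (zero diagonal,
`w_ij = 1` for neighbours, row-standardized so `W y` is a neighbourhood
average). The general nesting space-time dynamic model (GNS) is

```
y_t = ρ W y_t + ϕ y_{t−1} + γ W y_{t−1} + X_t β + W X_t θ + u_t
u_t = λ W u_t + ε_t,   ε_t ~ iid N(0, σ² I_N)
```

- ρ — contemporaneous spatial dependence (a zone co-moves with its
  neighbours within a wave),
- ϕ — temporal dependence (persistence of a zone's own mortality),
- γ — space-time diffusion (a zone responds to its neighbours' mortality
  one wave earlier),
- λ — spatial dependence of the disturbances,
- θ — spatial-Durbin coefficients (neighbours' covariates).

Switching channels off yields the named submodels: SAR (ρ), SEM (λ),
SAC (ρ+λ), SDM (ρ+θ); the GNS contains all five channels and is the only
specification carrying exactly the parameter set (ρ, ϕ, γ, λ, β, θ).
No intercept is included: with zone-level dynamics and spatial terms a
common constant is collinear with the modeled levels. A user who wants
one can append a constant column to the covariate block, which is exactly
equivalent and keeps the parameter bookkeeping uniform.

Stationarity requires the spectral radius of `(I − ρW)⁻¹(ϕI + γW)` to be
below 1 and ρ, λ to lie in the interval `(1/ω_min, 1/ω_max)` given by the
extreme real eigenvalues of `W` (upper bound 1 for a row-standardized
matrix), which keeps both log-determinants finite.

## Estimation

The likelihood is Gaussian quasi-ML **conditional on the first observed
wave**. With only a handful of waves (the motivating surveys have T=4) an
unconditional likelihood would need a stationary initial-condition term
whose misspecification dominates; conditioning sidesteps that at the cost
of one wave. Innovations per period are

```
e_t = (I − λW)[(I − ρW) y_t − ϕ y_{t−1} − γ W y_{t−1} − X_t β − W X_t θ]
```

and the log-likelihood over the T′ = T−1 usable periods adds the Jacobian
terms `T′ ln|I − ρW| + T′ ln|I − λW|`, evaluated from the precomputed
eigenvalues of `W` (`ln|I − aW| = Σ ln(1 − a ω_i)`, real part; complex
eigenvalues of the row-standardized matrix occur in conjugate pairs so the
sum is real).

Everything except (ρ, λ) enters linearly: ϕ and γ are coefficients on
`y_{t−1}` and `W y_{t−1}` exactly as β and θ are on `X` and `WX`. They are
therefore concentrated out by least squares on the λ-filtered system, and
the numerical search is a 2-D (or 1-D / 0-D, per submodel) quasi-Newton
optimization over (ρ, λ) inside the admissible box shrunk by 1e−6,
multi-started from the grid {0, ±0.3}² to avoid boundary traps. This is a
smaller search space than optimizing (ρ, ϕ, γ, λ) directly but reaches the
identical optimum, since the concentration is exact algebra.

Standard errors are Wald, from the inverse numerical Hessian
(central differences, relative step 1e−4) of the **full** likelihood in
all free parameters (dependence parameters, β, θ, σ²) at the optimum;
CIs are estimate ± 1.96·SE and significance codes use the conventional
0.001 / 0.01 / 0.05 / 0.1 cuts. If the Hessian is not negative definite
the fit is returned with `ses_reliable=False` and pseudo-inverse SEs
rather than failing.

Model comparison drops the first wave for *every* specification — static
ones included — so all candidates see the same observations and AIC
(`2k − 2·loglik`, k counting all free parameters incl. σ²) is comparable.
`multiple_r2` is the squared correlation between observed `y` and the
reduced-form conditional mean `(I − ρ̂W)⁻¹(ϕ̂ y_{t−1} + γ̂ W y_{t−1} +
X β̂ + WX θ̂)`; the raw/transformed distinction matters and this raw-scale
definition is the one implemented. Ties in AIC go to fewer parameters,
then input order.

## Geostatistics

Distances are Euclidean between zone centroids in projected planar
coordinates; treating a zonal field as a point process at centroids is an
abstraction, adequate for zones of comparable size. The empirical
semivariogram uses 12 equal-width bins up to half the maximum pairwise
distance by default (common variogram practice); empty bins are omitted.
Model fitting minimizes `Σ_b |N(h_b)| (γ̂_b − γ_model(h_b))²` under
`0 ≤ nugget ≤ sill`, `range > 0` with L-BFGS-B multi-started over range
scales (Cressie weighting `|N|/γ_model²` is available via a flag). "Sill"
always means the **total** sill; the reported nugget is contained in it.

Conventions at the origin: the theoretical process has `γ(0) = 0`; any
`h > 0` includes the nugget; for *prediction* a target coincident with an
observation sees the nugget, so ordinary kriging reproduces observed
values exactly iff the nugget is zero. The kriging system is the
variogram-form bordered system with a Lagrange multiplier enforcing unit
weight sum; duplicate observation sites are rejected by name since they
make it singular. Leave-one-out cross-validation reports MSE and RMSSE
(root mean square of error / kriging-SE); RMSSE ≈ 1 indicates calibrated
variances. Family selection takes the lowest LOO MSE, breaking ties by
RMSSE closest to 1 — mirroring joint nugget/MSE/RMSSE reasoning rather
than a single score.

## Hotspots

Gi\* uses self-inclusion weight 1 and the *binary* contiguity matrix even
when a standardized one is supplied (the binary parent is carried along),
which is the statistic's standard form. When a zone's neighbourhood spans
the entire map the numerator and denominator are both identically zero;
the z-score is defined as 0 there (the local mean cannot deviate from the
global mean). Classification uses plain two-sided cutoffs 1.96 / 2.576
with no multiple-testing correction by default, matching common practice
in descriptive hotspot mapping; a Benjamini-Hochberg flag exists but is
off. Detection power depends on cluster compactness: boundary members of
a planted cluster average mostly-background neighbourhoods, so their
z-scores are diluted — at a 3-SD elevation about 80% of planted zones are
flagged, at 5 SD about 93%.

## Synthetic data

The generator emulates the motivating study design: 65 zones (an 8×8 unit
lattice plus one appended zone, centroids jittered ±0.25 to break lattice
distance ties), four waves with weighted child counts (10 873, 9 861,
11 654, 10 641) and per-wave prevalences (12.08%, 8.71%, 7.26%, 6.0%).
Zone mortality heterogeneity is a logit-scale random effect smoothed
through `(I − 0.6W)⁻¹` (SD 0.35); a per-wave intercept is solved by root
finding so the *expected* prevalence over the realized child-to-zone
allocation equals the configured value exactly. Sampling weights are
gamma(4) with mean 1, mimicking normalized survey weights; being
independent of the outcome they inflate prevalence variance by the design
effect 1 + 1/4 but add no bias — tolerance checks on simulated prevalence
use that inflated binomial interval. Covariate proportions are
logistic-normal fields with the same spatial smoothing and an AR(1) wave
evolution (persistence 0.7), which makes `WX` linearly independent of `X`
so θ is identifiable. Zone population shares are Dirichlet(8), uneven but
fixed per seed. Aggregation collapses covariates with weights by default
(an unweighted option exists; with DHS-style weights the difference is
small).

GNS panels start from the cross-sectional equilibrium
`y_0 = (I − ρW)⁻¹(X_1β + WX_1θ)` and discard 50 burn-in periods holding X
at its first-wave value, so recorded waves are draws from the stationary
regime. Default innovation variance is σ² = 0.005 (residual SD ≈ 0.07 on
the proportion scale, consistent with total spatial variances around
0.02–0.03 seen in zonal mortality fields).

What the generator does **not** emulate: real zone geographies (unit
squares, not administrative boundaries), DHS cluster displacement and
stratification beyond weights, unequal inter-wave gaps (waves are unit
time steps with year labels attached), covariate measurement error, and
outcome-covariate feedback at the child level. Tests passing on these data
therefore validate the estimators and plumbing, not substantive
epidemiology on any real country.

## Experiment sizes and known limitations

- Likelihood validation compares the concentrated optimum against a dense
  joint-density evaluation on N=6, T=3 instances (20 draws, tolerance
  1e−6); instances are sized so the optimum is interior — at N=4 the
  stacked sample is saturated by the parameter count and σ̂² collapses.
- Parameter recovery runs 100 replicates at N=65 for T ∈ {5, 10, 20};
  model-selection frequency 100 panels at T=10. These sizes give
  Monte-Carlo SEs small enough for 2-SE mean checks while keeping the
  whole suite under a minute.
- **Weak identification of small ρ.** At N=65, T=20 the replicate SD of
  ρ̂ is ≈ 0.06 and strongly anti-correlated with λ̂ (the classic SAC
  confounding). A true ρ of 0.04 is then < 1 SD from zero: estimates are
  unbiased, but sign recovery tops out near 80%, and no estimator at this
  information level can do much better. ϕ, γ, λ at their reference
  magnitudes recover sign essentially always.
- Panels with empty zone-wave cells are refused by the model-fitting stage
  (explicit error listing cells) rather than imputed; kriging and
  hotspots operate per wave on the observed zones only.
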