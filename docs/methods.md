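# Methods

This note documents the models, the defaults and why they are what they
are, the synthetic-data generator's scope, and the numerical choices that
a maintainer would otherwise have to reverse-engineer.

## Growth-parameter uncertainty

Individual growth follows von Bertalanffy,
L(a) = L∞·(1 − e^(−k·(a − t0))). Process uncertainty enters through the
parameters, sampled jointly from a Student-t copula with triangle
marginals:

| parameter | lower | mode | upper | rationale |
|---|---|---|---|---|
| L∞ (cm) | 104.520 | 130 | 155.480 | typical assessed value for a hake-like stock; bounds at ±1.96 sd with CV 10% |
| k (yr⁻¹) | 0.132 | 0.164 | 0.196 | same construction |
| t0 (yr) | −0.184 | −0.092 | 0 | upper bound 0 (no positive t0); symmetric triangle |

Triangle marginals make almost no distributional assumption beyond hard
bounds, which guarantees biologically admissible draws. The central
triangle parameter is treated as the **mode**; all default triangles are
symmetric, where mode and median coincide, but asymmetric user input is
interpreted as a mode. The t0 bounds are taken as fixed constants rather
than derived from the L∞/k ranges.

The copula needs only a correlation structure — any covariance a user
supplies is reduced to its correlation, so scaling the covariance by a
positive constant changes nothing (`CopulaSpec.from_covariance`). The
default correlation, ρ(L∞,k) = −0.7, ρ(k,t0) = +0.5, ρ(L∞,t0) = −0.2,
encodes the standard demersal life-history pattern (fast growers top out
smaller; positive k–t0 association; weak L∞–t0 link) and is positive
definite; it is fully user-overridable, as is the tail degrees-of-freedom
(default 4 — heavy enough tails to produce joint extremes, finite
variance). Sampling is the standard construction: correlated normals
divided by √(χ²_ν/ν), pushed through the t CDF to uniforms, then through
each triangle inverse CDF. Every random operation takes an explicit
integer seed; there is no hidden global state.

## Natural mortality

Two models span the structural axis:

* **constant** — M = 0.4 yr⁻¹ at every length and year, no process
  uncertainty (the convention many assessments use);
* **gislason** — M(L) = k·(L∞/L)^1.5, evaluated at length-class midpoints,
  then rescaled by a single factor so that the unweighted arithmetic mean
  of M over classes whose midpoints lie in the closed window [15, 60] cm
  equals 1.5·k. The window is interpreted as inclusive of its boundary
  classes. Process uncertainty is inherited by evaluating the curve at
  each growth draw's own (L∞, k) — the same draw used for slicing, so
  growth and mortality are always mutually consistent within an iteration.

The rescaling is exact by construction (tested to 1e-12) and idempotent.

## Length-to-age slicing

Each length class is assigned the age floor(inverse-growth-curve(midpoint)),
clamped below at 0; classes at or above L∞ (where the inverse curve is
undefined) join the oldest age + 1 and are absorbed by the plusgroup. The
class **midpoint** is the representative length (a lower-bound convention
is available in the configuration). Aggregation into ages: abundances sum;
mean weights (from W = a·L^b, defaults a = 6.59e-5, b = 3.01721) are
abundance-weighted means; M and maturity are unweighted means over
contributing classes. Ages that no class maps to (possible at old ages,
where one year of growth spans less than one length class) are filled from
the nearest younger populated age; they carry zero abundance so the fill
only affects bookkeeping, never totals.

Each iteration receives its own plusgroup: the smallest age whose
cumulative share of time-averaged catch biomass reaches 95% (threshold
configurable). Within the plusgroup, weight, M and maturity are
abundance-weighted, which preserves total biomass exactly — abundance and
biomass conservation to 1e-9 relative error are asserted in the tests.
Survey indices are sliced with the same growth draws and forced onto the
stock's per-iteration plusgroup.

The weight unit is carried through as a label only; all downstream uses
(SSB, catch biomass, harvest rate) are relative, so the absolute unit of
the weight–length coefficient does not affect any result.

## The catch-at-age estimator

Population dynamics are the standard age-structured accounting:
N(a+1, y+1) = N(a, y)·e^(−Z(a,y)) with Z = F + M, a terminal plusgroup
that accumulates its own survivors, catches from the Baranov equation and
survey indices I(a,y) = q(a,y)·N(a,y)·e^(−τ·Z(a,y)) at survey timing τ
(defaults 0.75 for October surveys, 0.875 for November).

Submodels (all on the log scale):

* **fmodel** — `age_year_factors` (additive one-hot age and year effects,
  corner constraint), `tensor_spline` (tensor product of cubic B-spline
  bases over age and year), or `logistic_age_by_year_smoother`
  (F(a,y) = plateau(y)/(1+e^(−(a−a50)/δ)) with log-plateau on a year
  smoother; a50, δ shared across years).
* **qmodel** — `age_smoother`, `age_and_year_smoothers` (year basis drops
  one column for identifiability against the age basis' partition of
  unity), or the logistic form; one spec applied to every survey.
* **rmodel** — `year_smoother` (recruitment is the smoother's prediction),
  or `ricker`: free log-recruitment per year plus a lognormal penalty with
  σ = 0.10 on deviations from R = α·S·e^(−βS), with (log α, log β)
  estimated. A deviation penalty was chosen over a prior on (α, β)
  themselves; it regularises recruitment toward the stock–recruit curve
  (with a 10% coefficient of variation) without pinning the curve's
  location.

Smoother basis dimensions default to df_age = min(6, n_ages − 2) and
df_year = min(8, ⌈n_years/4⌉ + 2) — both configurable — so flexibility
scales with the data. B-splines are cubic where df allows (linear at
df = 2), on clamped uniform knots; each basis is a partition of unity.

**Observation model and fitting.** Catch-at-age and each survey index get
independent lognormal errors with one variance per data source, profiled
out of the likelihood (each source contributes (n_s/2)·log(RSS_s/n_s));
cells with zero observations carry no information and are masked. A small
floor (1e-12) inside the log keeps the profiled objective finite on
perfectly fitting data. Optimisation is deterministic two-stage
quasi-Newton (L-BFGS-B): a warm start minimising the unweighted pooled sum
of squared log-residuals — well conditioned everywhere — followed by the
profiled likelihood from that point. The profiled objective alone has
steep per-source "log holes" near perfect fits that can trap a cold start;
the pooled stage removes that failure mode and makes the noise-free
self-consistency property (catches reproduced to 1e-6) hold. Start values
come from catch-curve slopes (total mortality), back-calculated numbers
(recruitment, initial abundance) and ratio-based catchability — all
deterministic, so refits are bit-identical. Multi-start is deliberately
not used: iterations that fail to converge are recorded and dropped, never
raised, mirroring how a grid of thousands of fits must behave.

A fit is *converged* when the optimizer reports success and the
central-difference Hessian of the negative log-likelihood at the optimum
is finite and positive definite; the parameter covariance is its inverse
(the Hessian is computed in-house with relative steps of 1e-4).
Estimation uncertainty = multivariate-normal draws around the estimates
with that covariance (default one draw per fitted iteration,
configurable), each mapped back through the model to a full population
state.

**GCV.** Only the catch-at-age matrix is scored:
GCV = n·RSS/(n − p)² with n the number of positive catch cells, RSS the
sum of squared log-catch residuals, and p the count of coefficients that
enter the catch predictor (fmodel + recruitment + initial-age parameters;
survey-only parameters excluded). Coefficient counting is a declared
stand-in for an effective-degrees-of-freedom calculation; it preserves the
ordering GCV is used for (overfit surfaces with p near n are heavily
penalised, which the tests assert).

Fbar defaults to the mean of F over ages 1–3 (configurable); SSB is
Σ_a N·w·maturity; harvest rate is catch biomass over total stock biomass.

## Filtering and model averaging

The final-year harvest rates of each variant's iterations are tested for
multimodality with Hartigan's dip statistic — the sup-distance between the
empirical CDF and the nearest unimodal CDF, computed by the iterative
greatest-convex-minorant / least-concave-majorant construction. The
implementation is validated against an independent brute-force oracle
(`scaaverage._unimodal_oracle`): exact linear programming over
piecewise-linear unimodal CDFs with an optional atom at the mode,
enumerated over mode positions. The statistic is floored at 1/(2n).

P-values come from a bootstrap null of uniform(0,1) samples (Hartigan's
calibration: the uniform is the asymptotically least-favourable unimodal
distribution), default 2000 replicates, rejection at α = 0.05 — both
configurable.
Variants with fewer than 10 fitted iterations (configurable floor, never
below the dip test's minimum) are rejected as "insufficient iterations".

Retained variants are weighted w_i ∝ 1/median(GCV_i) (normalised; invariant
to rescaling all GCVs). The ensemble draws n_select iterations — default
the minimum variant size, so no iteration can be over-represented — by
first choosing a variant with probability w_i, then an unused iteration
uniformly within it (without replacement within a variant). Provenance
(variant, original index) is recorded for every selected iteration, and
per-year 10/50/90% quantiles (configurable) summarise the result. The
"best single model" used for comparisons is the variant with the lowest
median GCV.

## The synthetic-data generator

The generator emulates the *shape* of length-based assessment inputs: an
age-structured truth (ages 0–10, 15 years by default) with von Bertalanffy
growth at the default marginal modes, a Gislason-shaped true M (so the
constant-M variant is deliberately mis-specified, exercising the
model-uncertainty axis), logistic fishing selectivity (a50 = 2, δ = 0.5)
with an effort trajectory rising 0.25 → 0.55 yr⁻¹, mean recruitment 1e6
with lognormal deviations (σ = 0.2), three surveys with logistic
catchability and timings (0.75, 0.75, 0.875), and lognormal observation
noise σ = 0.1 on both catches and indices. Length-at-age is normal around
the growth curve with a constant CV of 0.1 — this individual spread is
what makes deterministic slicing an approximation worth testing; catches
are rendered into 1 cm classes (1–129 cm) and indices into 2 cm classes,
conserving totals exactly. A logistic maturity-at-length ogive
(L50 = 42 cm, δ = 5) completes the bundle.

What it does **not** emulate: discard/landings structure, time-varying
growth or selectivity, sexual dimorphism, ageing error, or any real
stock's absolute scale. Passing tests therefore demonstrate internal
consistency and recovery under the stated statistical assumptions, not
performance on any particular real fishery.

## Problem sizes in tests and the acceptance script

The packaged checks run the pipeline at desk scale: scenarios of 12 years
and ages 0–8, 12–14 process-uncertainty iterations, a 2-configuration
subset of the grid, dip bootstraps of 200, and 20 replicates for recovery
metrics. These sizes were chosen so the whole suite runs on a single CPU
in minutes while still exercising every stage end to end; the pipeline
itself scales to the full 18×2 grid with 1000 iterations by configuration
(`n_iterations`, `scaa.grid`, `ensemble.n_boot`).

## Known limitations

* The slicing is deterministic (no probabilistic age–length key), so
  individual growth variability appears only through the parameter
  ensemble, not within an iteration.
* The GCV degrees of freedom are coefficient counts, not trace-based
  effective dimensions; comparisons across submodel families inherit that
  convention.
* The Ricker penalty regularises recruitment deviations; it is not a full
  stock–recruit likelihood with bias correction.
* Reference points, forecasting and management-strategy evaluation are out
  of scope, as is estimating the growth-parameter correlation matrix from
  external databases (it is a configuration input).
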