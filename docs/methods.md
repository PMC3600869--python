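# Methods

This note records the modelling assumptions, parameter conventions,
numerical choices and known limitations of `airdcm`, at the level of
detail a maintainer or a careful user needs.

## Model and state-space treatment

The observation model for pollutant *i* at site **s**, day *t* is

    y_i(s,t) = x_i(s,t)'β_i + [K z(t)]_i + α_i u_i(s,t)
               + Σ_j λ_{j,i} w_i^j(s,t) + ε_i(s,t).

The three latent blocks serve different purposes and can be switched on
and off (`ModelConfig`): the Markov state z(t) carries temporal
persistence common to all sites; the direct component u gives each
pollutant its own spatial correlation range; the linear model of
coregionalization (LCM) w imposes shared ranges with cross-pollutant
correlation matrices V_j and is the right choice when pollutants are
spatially cross-correlated. Scale identifiability is resolved by keeping
u and w unit-variance processes and putting all amplitude into α and λ;
V_j is constrained to a unit-diagonal correlation matrix.

Because u and w are independent across days, they contribute a per-day
spatial covariance Σ_t = C_u + C_w + diag(σ²_ε) around the common state,
and the model is exactly a linear-Gaussian state space with time-varying
measurement geometry. All inference (likelihood, smoothing, EM E-step)
goes through a fixed-interval Kalman smoother.

**Missing data.** Missing entries are handled without imputation by a
fixed-shape device: missing rows of y, X, H are zeroed and the
corresponding rows/columns of Σ_t replaced by the identity. This leaves
the filtered state and the observed-data likelihood unchanged (the
padded rows contribute unit-variance, zero-mean pseudo-observations
decoupled from the state, and their constant density terms are removed
with the observation counts) while keeping every per-day array the same
shape, so the T Cholesky factorizations batch through LAPACK. The
heterotopic case — disjoint site sets per pollutant — needs no special
handling beyond the stacked entry indexing.

**Initial state.** The prior for z(1) is N(0, P1). For simulation and
stand-alone likelihood evaluation P1 defaults to the stationary
covariance solving P = G P G' + Σ_η. During EM, P1 is computed once from
the initial parameters and then held fixed: with a fixed prior every
conditional M-step below is an exact maximizer and the likelihood trace
is monotone by the ECM argument, which would not be guaranteed if the
prior were re-tied to (G, Σ_η) each iteration. For T in the hundreds the
prior term is O(1) against an O(NT) likelihood and the practical effect
on the estimates is negligible.

## EM estimation

Each iteration runs the smoother at the current parameters and then three
conditional maximization steps, each exact or guaranteed-ascent on the
expected complete-data log-likelihood:

1. **G, Σ_η** — closed form from the smoothed second moments
   (S00, S10, S11 with the exact lag-one covariance identity
   Cov(z_t, z_{t+1}|Y) = J_t P^T_{t+1}); Σ_η eigenvalues floored at
   1e-10.
2. **β** — generalized least squares against the smoothed-state
   residuals, with the current Σ_t.
3. **Spatial/noise block (α, θ, λ, V, θ̃, σ²_ε)** — one bounded L-BFGS-B
   step (default 5 inner iterations) on the unconstrained
   reparameterization: logs for scales, variances and ranges,
   hyperspherical-Cholesky angles for V (so any iterate is a valid
   correlation matrix). The step starts at the current point and is only
   accepted if it improves the objective, so monotonicity is preserved
   even when the inner optimizer is stopped early. Ranges are boxed to
   [1, 10⁴] km; variances are floored at 1e-10 with a warning when the
   floor binds.

Initialization follows a simple partition: β by OLS; when the temporal
state is included, 20% of the per-pollutant residual variance is assigned
to it (G = 0.5 I) and the remainder split 50/50 between the spatial
block and measurement noise; all ranges start at the median inter-station
distance; an optional seeded log-normal jitter perturbs the variance
split. Convergence is declared when the relative log-likelihood change
drops below `tol` (default 1e-5, at most 400 iterations); non-convergence
returns the best iterate with a warning.

G is *not* projected to the stable region during EM — with a fixed P1 the
finite-sample likelihood is well defined for any G, and the closed-form
update is then exact; stability is enforced only where the stationary
distribution is actually needed (simulation, stationary priors).

**Standard errors.** `fisher_information` computes the central-difference
negative Hessian of the log-likelihood on the unconstrained scale
(per-parameter relative step 1e-4, symmetrized, pseudo-inverse with a
warning if singular) and maps standard deviations to the natural scale by
the delta method. For the regression coefficients alone,
`beta_information` returns the *exact* expected information
X'Ω⁻¹X in one multi-column filter pass using the innovations
decomposition; mean and covariance parameters are information-orthogonal
in a Gaussian model, so this block is valid on its own for Wald
intervals on β and is what the recovery checks use.

## Dynamic kriging

The prediction at a target (i, s*) on day t is the exact conditional
mean/variance of the noise-free field given **all** observations at the
plugged-in Ψ̂. Writing B_t = C_cross Σ_t⁻¹ and M_t = K_i − B_t H_t,
the disturbance-smoother identity E[v_t|Y] = Σ_t⁻¹(y_t − X_tβ − H_t ẑ_t)
gives

    mean = x'β + K_i ẑ^T(t) + B_t (y_t − X_tβ − H_t ẑ^T(t))
    var  = C** − B_t C_cross' + M_t P^T(t) M_t'

The M P M' term carries the latent-state uncertainty *and* its
(negative) correlation with the spatial interpolation error; the
measurement-error nugget is excluded (the target is the true
concentration). These formulas are verified to 1e-8 against dense
joint-Gaussian conditioning in the test suite. Two consequences used as
sanity checks: at an observed station with zero nugget the map
interpolates exactly with zero variance, and far from all stations it
reverts to x'β + Kẑ with the full prior variance.

**Back-transformation.** Concentrations are modelled on the
log-standardized scale. Maps report both the naive inverse transform and
the lognormal mean exp(μ + σ²/2); the lognormal mean is the default
because it is the conditional expectation on the original scale.

**Change of support.** Block values default to the pixel-centre
approximation, appropriate when blocks are small against the spatial
range (the default 20 km cells against a 50 km range are borderline but
adequate; the kriged mean surface is only kinked at station locations).
A k×k sub-sampling mode is available for verification; the two agree to
within 5% of the field standard deviation on fields that are smooth at
the block scale.

## Global air-quality indices

Concentrations are divided by per-pollutant scaling factors F_i
(µg m⁻³ per index unit) anchored to the UK index-and-banding system:
the concentration corresponding to index value 10 (128, 764, 360 µg m⁻³
for PM10, NO2, O3), divided by 10. NO2 and O3 are banded on hourly /
running-8-h statistics rather than daily means, so a configurable
daily-statistic conversion divisor (default 1) is exposed; users can
override any factor.

The reduced model ỹ_i(s,t) = k_i(s) z_i(t) + ε fixes the loadings to
k_i(s) = (station temporal average)/(network average) of the scaled
series, computed over non-missing entries network-wide — this removes
the rotational indeterminacy of a free loading matrix while keeping z on
the interpretable index scale. Only {G, Σ_η, σ²_ε} are estimated (EM,
all closed form). The z(1) prior is a fixed diffuse N(0, 10·max(ȳ², 1) I)
since the scaled data are not centred. All-missing stations are excluded
with a warning.

I2 averages and I3 maximizes the smoothed state across pollutants; the
variance of I2 is (1/q²)Σ_ij p_ij(t) and I3 intervals are seeded
Monte-Carlo quantiles of max N(ẑ(t), P^T(t)) (default 10⁴ draws; the
I3 interval is clipped to bracket the point value, which only binds in
near-degenerate cases).

## Exposure and risk

Exposure couples a temporally averaged concentration map with a
time-invariant population raster d(B): the regional index is
Σ d(B)ȳ(B)/D (the exposure of an average resident), and the cumulative
exposure distribution Φ(c) is the population fraction at or below c
(step form for computation; a Gaussian-kernel density with default
bandwidth 0.5 µg m⁻³ for display). Cells with undefined predictions are
excluded together with their population.

Exceedance probabilities deliberately do not use the Gaussian predictive
distribution directly: leave-one-site-out residuals are Studentized by
their kriging standard deviation and pooled into a kernel-smoothed CDF
F̂ (Silverman bandwidth by default), which absorbs model misspecification
and is heavier-tailed than the nominal normal. Then
π(B,t) = 1 − F̂((L̃ − ŷ)/σ) with the threshold L mapped through the same
log-standardization as the data, and ŷ, σ the transformed-scale kriging
mean and sd. Two deliberate conventions:

* the LOSO Studentization uses the prediction sd of the held-out
  *observation* (field variance + nugget), since the residual contains
  measurement error — this is what makes the pooled Studentized variance
  ≈ 1 under a correct model; the σ in π refers to the *true*
  concentration and excludes the nugget;
* F̂ is evaluated through a 4001-point interpolation table (absolute
  error < 1e-8), which keeps whole π surfaces and the bootstrap cheap.

Day counts N(B) = Σ_t Bernoulli(π(B,t)) treat days as independent; the
field is temporally correlated, so this is an approximation — it leaves
E[N] exact but understates the spread of N. The distribution of N is
computed exactly by the Poisson-binomial dynamic-programming convolution
(the default) or by seeded Monte-Carlo (500 runs), and the objective
P(N > M) uses M = 7 days by default. Aggregated daily risk is the
population-weighted mean of π (weights switchable to uniform).

Bootstrap bands draw R = 100 parameter sets from N(Ψ̂, Î⁻¹) on the
unconstrained reparameterization (positivity and correlation constraints
map back automatically), rerun the map→π pipeline per draw, and take
pointwise 2.5/97.5% quantiles; draws whose mapped parameters fail
validation (typically an unstable G) are redrawn and counted.

## Synthetic scenarios

The generator emulates the statistical structure of a national
monitoring campaign at desk scale, with every choice fixed as a default
rather than fitted: a 400 km planar square with a 20×20 cell grid;
population as a 5-cluster Gaussian-blob mixture (5.2M people) over a
thin rural background; stations placed in distinct cells with probability
∝ population (preferential urban placement); six covariates =
standardized log-population plus five unit-variance AR(1)-in-time
Gaussian random fields with a 0.8 day-to-day persistence and an 80 km
spatial range, typical of daily synoptic anomaly fields; true parameters
with a 20/55/25% variance split between the temporal state
(G = diag(0.6, 0.5, 0.4)), one LCM component (50 km range, O3
negatively cross-correlated with NO2 and PM10) and measurement noise;
per-pollutant missing rates 12.7/12.1/16.1%; station counts 12/4/10
(NO2/O3/PM10) and T = 120 days by default. Simulated values live on the
model (log-standardized) scale; a synthetic transform with geometric
means near observed national levels (32.2/55.8/16.6 µg m⁻³) maps them to
concentrations so thresholds (105/87/50 µg m⁻³) and exposure are
exercised on a realistic scale.

What the generator does *not* emulate: coastline/terrain geometry,
preferential sampling beyond population placement, temporally correlated
missingness (outages are independent per station-day, matching only the
marginal rates), seasonal covariate cycles, and non-Gaussian residual
behaviour. Passing tests therefore demonstrate internal correctness and
calibration under the model's own assumptions, not robustness to the
misspecifications real networks exhibit.

Problem sizes in the test suite and acceptance script (T = 120 for
single-fit checks, T = 300 with 20 seeds for recovery, 6×6 to 20×20
grids) are the package's scaled-down study conditions, chosen so each
statistical property is testable with comfortable power at interactive
run times.

## Known limitations

* One shared EM inner-step budget: very flat likelihoods (tiny networks,
  short series) may need more than the default iterations to converge;
  non-convergence is always flagged.
* The numerical Fisher information is a finite-difference Hessian at the
  estimate; near parameter-space boundaries (variances → 0) it can be
  indefinite, in which case a pseudo-inverse is used and reported.
* Exceedance day counts assume independence across days (see above).
* The pixel-centre change-of-support approximation degrades when blocks
  are large relative to the spatial range or contain stations.
* The CLI re-runs the smoother from stored parameters rather than
  serializing smoother state; this keeps artifacts plain-text at the cost
  of a few seconds per downstream command.
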