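# airdcm

Model-based country-level air-quality assessment: a multivariate
space–time **dynamic coregionalization model (DCM)** for unbalanced
pollutant monitoring networks, with maximum-likelihood estimation by EM,
dynamic kriging maps, latent-state global air-quality indices, and
population-weighted exposure and exceedance-risk indices with
uncertainty.

It is written for environmental statisticians and air-quality analysts
who need to turn sparse, heterotopic station records (different pollutants
measured at different sites, with missing days) into gridded concentration
fields, single-number daily indices, and regulatory risk summaries — all
with honest uncertainty.

## The model

For pollutant *i* ∈ {1..q} at location **s** and day *t*:

```
y_i(s,t) = x_i(s,t)'β_i + [K z(t)]_i + α_i u_i(s,t) + Σ_j λ_{j,i} w_i^j(s,t) + ε_i(s,t)

z(t)   = G z(t−1) + η(t),        η ~ N(0, Σ_η)          (latent common trend)
u_i    : independent unit GPs, corr exp(−h/θ_i)          (direct component)
w^j    : LCM component, Cov = diag(λ_j) V_j diag(λ_j) exp(−h/θ̃_j)
ε      : white noise, Var = σ²_ε,i                       (measurement error)
```

* z(t) is a p-dimensional Markov state with fixed loading matrix K; u and
  w are i.i.d. over days, so for inference they fold into a per-day
  spatial covariance and the Kalman smoother is exact.
* The full parameter set Ψ = {β, G, Σ_η, α, θ, λ, V, θ̃, σ²_ε} is
  estimated by EM (closed-form conditional updates for G, Σ_η, β; a
  bounded quasi-Newton step for the spatial/noise block), with a
  rigorously monotone likelihood trace and standard errors from an
  approximated Fisher information matrix.
* Dynamic kriging gives, per cell and day, the exact conditional mean and
  variance of the noise-free field given all observations (plug-in Ψ̂),
  including the latent-state uncertainty and its correlation with the
  spatial interpolation error.
* Global indices from a reduced common-trend model with station-average
  loadings: I1 (scalar trend), I2 = mean_i ẑ_i(t) with variance
  (1/q²)Σ_ij p_ij(t), I3 = max_i ẑ_i(t) with Monte-Carlo intervals.
* Exposure couples temporally averaged fields with a population raster;
  risk evaluates exceedance probabilities π(B,t) through a
  kernel-smoothed CDF of Studentized leave-one-site-out residuals, and
  day-count objectives P(N > M) via the exact Poisson-binomial
  distribution, with parametric-bootstrap confidence bands.

A synthetic-scenario generator reproduces the statistical structure of a
national network (clustered population, preferential station placement,
unbalanced 12/4/10-station networks, 12–16% missing days) so the entire
pipeline runs with no external data.

## Worked example

```python
import numpy as np
from airdcm import (make_scenario, em_fit, ModelConfig, loso_crossval,
                    fit_residual_cdf, krige, compute_risk_surface,
                    build_index_model, default_scaling_factors, index_I3,
                    temporal_average_map, exposure_index)

sc = make_scenario(T=120, seed=42)          # synthetic NO2/O3/PM10 network
config = ModelConfig(p=3, include_u=False, include_lcm=True, c=1)
fit = em_fit(sc.obs, sc.covariates, config)

cv = loso_crossval(fit.obs, fit.covariates, fit.psi,
                   init_state_cov=fit.init_state_cov)
maps = krige(fit, sc.covariates, sc.grid)

ix = build_index_model(sc.observations_original(),
                       default_scaling_factors(sc.network.pollutants))
i3 = index_I3(ix.smoother.z_smooth, ix.smoother.P_smooth, ix.pollutants,
              nsim=10000, seed=0)

avg = temporal_average_map(maps["PM10"], range(sc.obs.T))
exp_pm10 = exposure_index(avg, sc.population)
rs = compute_risk_surface(maps["PM10"], sc.thresholds.L["PM10"],
                          fit_residual_cdf(cv), sc.population, M=7)
```

Output (printed by the example as run on this machine):

```
stations: {'NO2': 12, 'O3': 4, 'PM10': 10}
missing:  {'NO2': 0.12, 'O3': 0.133, 'PM10': 0.155}
loglik -3480.9 after 20 EM iterations (converged=True)
LCM range (km): 46.9 | lambda: [0.73 0.79 0.83] | sigma_eps: [0.51 0.3  0.33]
cmse: {'NO2': 0.65, 'O3': 0.68, 'PM10': 0.71}
I3 max 2.73 on day 72 [2.31, 3.15] driven by PM10
PM10 population-weighted mean exposure: 18.9 ug/m3
PM10 P(N>7 days above 50 ug/m3), pop-weighted: 0.011
```

Reading it: the EM recovers the 50 km coregionalization range (46.9 km
here) and the noise scales; cross-validation mean-squared errors are on
the standardized log scale; the worst air-quality day of the season
reaches I3 = 2.7 (low band on the 1–10 index scale), driven by PM10; an
average resident is exposed to 18.9 µg m⁻³ of PM10; and the chance of
breaching the 7-day objective above 50 µg m⁻³ for the population-weighted
average block is about 1%.

## Command line

The same pipeline is scriptable on plain-text artifacts:

```bash
airdcm simulate --out run/ --seed 1 --t 120
airdcm fit      --dir run/
airdcm krige    --dir run/
airdcm indices  --dir run/
airdcm exposure --dir run/
airdcm risk     --dir run/
airdcm report   --dir run/
```

Every command writes a manifest (config echo, version, seeds) next to its
outputs; observations, covariates, rasters and maps are CSV, parameters
JSON.

## Layout

| module | contents |
| --- | --- |
| `airdcm.datamodel` | networks, observations, transforms, validation, CSV I/O |
| `airdcm.dcm_core` | model parameters, covariances, simulation, dense oracle |
| `airdcm.estimation` | Kalman smoother, EM, Fisher information, LOSO |
| `airdcm.mapping` | dynamic kriging, block aggregation, temporal averages |
| `airdcm.indices` | scaling factors, reduced model, indices I1–I3 |
| `airdcm.exposure_risk` | exposure, exceedance risk, Poisson-binomial, bootstrap |
| `airdcm.synthetic` | scenario generator and micro test fixture |
| `airdcm.cli` | `airdcm` command-line tool |

See `docs/methods.md` for the modelling assumptions, parameter defaults
and numerical choices.
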