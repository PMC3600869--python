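"""Population exposure indices and threshold-exceedance risk.

Exposure couples the predicted concentration field with the residential
population raster: the regional exposure index is the population-weighted
mean concentration, and the cumulative exposure distribution gives the
population fraction exposed at or below each level.

Risk is framed around a regulatory threshold L: the exceedance
probability pi(B, t) that the *true* concentration in block B on day t
exceeds L, the distribution of the number of exceedance days N(B)
(a Poisson-binomial sum of independent daily Bernoullis), and the
probability P(N > M) of breaching the M-day objective.

pi is evaluated from the dynamic kriging output through the predictive
residual distribution: leave-one-site-out residuals, Studentized by their
kriging standard deviation, are pooled into a kernel-smoothed CDF F-hat
(which absorbs model misspecification and is heavier-tailed than the
nominal Gaussian), and

    pi(B, t) = 1 - F-hat( (L-tilde - yhat(B,t)) / sigma(B,t) )

with L mapped to the transformed model scale and yhat, sigma the
transformed-scale kriging mean and standard deviation.  Uncertainty bands
come from a parametric bootstrap over the asymptotic distribution of the
estimated parameters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.stats import norm

from .datamodel import PopulationRaster, Thresholds, TransformRecord
from .dcm_core import ParameterSet
from .estimation import CrossvalResiduals, FisherInformation, FitResult
from .mapping import DynamicMap


# ---------------------------------------------------------------------------
# exposure
# ---------------------------------------------------------------------------

@dataclass
class ExposureSummary:
    """Population exposure to a temporally averaged concentration field.

    ``block_index`` is d(B) * ybar(B) per block (population-scaled
    concentration); ``region_average`` is the population-weighted mean
    concentration sum_B d(B) ybar(B) / D, i.e. the exposure of an average
    resident.  Blocks with undefined predictions are excluded together
    with their population.
    """

    block_index: np.ndarray
    region_average: float
    concentrations: np.ndarray
    weights: np.ndarray
    total_population: float

    def cdf(self, c) -> np.ndarray:
        """Cumulative exposure distribution Phi(c): population fraction
        exposed to a level <= c (step function, right-continuous)."""
        c = np.asarray(c, dtype=float)
        out = np.array(
            [self.weights[self.concentrations <= ci].sum() for ci in np.atleast_1d(c)]
        ) / self.weights.sum()
        return out if c.ndim else float(out[0])

    def density(self, c, bandwidth: float = 0.5) -> np.ndarray:
        """Gaussian-kernel smoothed exposure density (display aid)."""
        c = np.atleast_1d(np.asarray(c, dtype=float))
        w = self.weights / self.weights.sum()
        out = (w[None, :] * norm.pdf(
            (c[:, None] - self.concentrations[None, :]) / bandwidth
        )).sum(axis=1) / bandwidth
        return out


def exposure_index(avg_values: np.ndarray, population: PopulationRaster) -> ExposureSummary:
    """Exposure index of a static (temporally averaged) concentration map.

    ``avg_values`` holds one original-scale concentration per grid cell of
    the population raster.
    """
    avg_values = np.asarray(avg_values, dtype=float)
    if avg_values.shape != population.counts.shape:
        raise ValueError("map and population raster are on different grids")
    d = population.counts
    ok = np.isfinite(avg_values)
    if not ok.all():
        d = np.where(ok, d, 0.0)
    D = d.sum()
    if not D > 0:
        raise ValueError("total population is zero")
    block = d * np.where(ok, avg_values, 0.0)
    return ExposureSummary(
        block_index=block,
        region_average=float(block.sum() / D),
        concentrations=avg_values[ok],
        weights=d[ok],
        total_population=float(D),
    )


def cumulative_exposure(
    avg_values: np.ndarray,
    population: PopulationRaster,
    bandwidth: float = 0.5,
) -> ExposureSummary:
    """Cumulative exposure distribution of a static map (µg m⁻³ scale).

    Returns an ExposureSummary whose ``cdf``/``density`` evaluate the
    population-weighted step distribution and its Gaussian-kernel smoothed
    density (default bandwidth 0.5 µg m⁻³).
    """
    summary = exposure_index(avg_values, population)
    summary.default_bandwidth = bandwidth  # type: ignore[attr-defined]
    return summary


def daily_exceedance_population(
    dmap: DynamicMap,
    population: PopulationRaster,
    threshold: float,
    mode: str = "lognormal",
) -> np.ndarray:
    """Number of people exposed above the threshold, per day.

    count(t) = sum_B d(B) 1{yhat(B, t) > L} with predictions on the
    original concentration scale.
    """
    vals = dmap.values_original(mode=mode)          # (T, ncell)
    if vals.shape[1] != population.counts.shape[0]:
        raise ValueError("map and population raster are on different grids")
    above = np.where(np.isfinite(vals), vals > threshold, False)
    return above @ population.counts


# ---------------------------------------------------------------------------
# predictive residual distribution
# ---------------------------------------------------------------------------

@dataclass
class ResidualCdf:
    """Kernel-smoothed CDF of pooled Studentized cross-validation residuals.

    F-hat(x) = mean_k Phi((x - r_k) / h); non-decreasing with limits 0/1.
    Evaluation interpolates a dense precomputed table (absolute error
    below 1e-8), so querying whole probability surfaces stays cheap.
    """

    residuals: np.ndarray
    bandwidth: float

    def __post_init__(self) -> None:
        lo = self.residuals.min() - 8.0 * self.bandwidth
        hi = self.residuals.max() + 8.0 * self.bandwidth
        grid = np.linspace(lo, hi, 4001)
        vals = np.zeros_like(grid)
        # chunk the kernel sum to bound memory on large residual pools
        step = max(1, int(2e6 / grid.size))
        for start in range(0, self.residuals.size, step):
            r = self.residuals[start:start + step]
            vals += norm.cdf((grid[:, None] - r[None, :]) / self.bandwidth
                             ).sum(axis=1)
        self._grid = grid
        self._vals = vals / self.residuals.size

    def __call__(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        out = np.interp(np.atleast_1d(x), self._grid, self._vals,
                        left=0.0, right=1.0)
        return out if x.ndim else float(out[0])


def fit_residual_cdf(
    crossval: CrossvalResiduals | np.ndarray,
    bandwidth: Optional[float] = None,
    min_residuals: int = 50,
) -> ResidualCdf:
    """Pool Studentized LOSO residuals into a smooth CDF.

    The bandwidth defaults to Silverman's rule 1.06 sd n^(-1/5).
    """
    if isinstance(crossval, CrossvalResiduals):
        pooled = crossval.pooled_studentized()
    else:
        pooled = np.asarray(crossval, dtype=float).ravel()
        pooled = pooled[np.isfinite(pooled)]
    if pooled.size < min_residuals:
        raise ValueError(
            f"need at least {min_residuals} residuals, got {pooled.size}"
        )
    if bandwidth is None:
        bandwidth = 1.06 * float(pooled.std(ddof=1)) * pooled.size ** (-0.2)
    if not bandwidth > 0:
        raise ValueError("bandwidth must be > 0")
    return ResidualCdf(residuals=pooled, bandwidth=float(bandwidth))


# ---------------------------------------------------------------------------
# exceedance probability and day counts
# ---------------------------------------------------------------------------

def exceedance_probability(
    dmap: DynamicMap,
    threshold: float,
    residual_cdf: Callable[[np.ndarray], np.ndarray],
    transform: Optional[TransformRecord] = None,
) -> np.ndarray:
    """Exceedance probability surface pi(B, t) for one pollutant.

    The threshold (original µg m⁻³ scale) is mapped to the model scale
    with the same transform as the data; pi = 1 - F-hat((L~ - yhat)/sigma)
    with yhat, sigma the transformed-scale kriging mean/sd.  Cells with
    zero kriging sd compare directly (pi in {0, 1}).
    """
    tr = transform if transform is not None else dmap.transform
    L_t = tr.apply(dmap.pollutant, threshold) if tr is not None else threshold
    mean, sd = dmap.mean, dmap.sd
    pi = np.full_like(mean, np.nan)
    ok = np.isfinite(mean) & np.isfinite(sd)
    pos = ok & (sd > 0)
    z = (L_t - mean[pos]) / sd[pos]
    pi[pos] = 1.0 - np.asarray(residual_cdf(z))
    det = ok & (sd == 0)
    pi[det] = (mean[det] > L_t).astype(float)
    return np.clip(pi, 0.0, 1.0)


@dataclass
class DayCountDistribution:
    """Distribution of the number of exceedance days N over {0..T}."""

    pmf: np.ndarray
    M: int

    @property
    def mean(self) -> float:
        return float(np.arange(self.pmf.size) @ self.pmf)

    @property
    def p_exceed(self) -> float:
        """P(N > M)."""
        return float(self.pmf[self.M + 1:].sum()) if self.M + 1 < self.pmf.size else 0.0

    def cdf(self, m: int) -> float:
        return float(self.pmf[: m + 1].sum())


def day_count_distribution(
    pi: np.ndarray,
    M: int = 7,
    method: str = "exact",
    nsim: int = 500,
    seed: int = 0,
) -> DayCountDistribution:
    """Distribution of N = sum_t Bernoulli(pi_t), days independent.

    ``method='exact'`` computes the Poisson-binomial pmf by
    dynamic-programming convolution; ``method='montecarlo'`` simulates
    (nsim default 500, seeded).
    """
    pi = np.asarray(pi, dtype=float)
    if np.any((pi < 0) | (pi > 1) | ~np.isfinite(pi)):
        raise ValueError("daily probabilities must lie in [0, 1]")
    T = pi.size
    if method == "exact":
        pmf = np.zeros(T + 1)
        pmf[0] = 1.0
        for p in pi:
            pmf[1:] = pmf[1:] * (1 - p) + pmf[:-1] * p
            pmf[0] *= 1 - p
        pmf = np.clip(pmf, 0.0, None)
        pmf /= pmf.sum()
    elif method == "montecarlo":
        rng = np.random.default_rng(seed)
        counts = (rng.random((nsim, T)) < pi[None, :]).sum(axis=1)
        pmf = np.bincount(counts, minlength=T + 1) / nsim
    else:
        raise ValueError(f"unknown method {method!r}")
    return DayCountDistribution(pmf=pmf, M=M)


def aggregated_risk_series(
    pi_surface: np.ndarray,
    population: Optional[PopulationRaster] = None,
    weighted: bool = True,
) -> np.ndarray:
    """Country-level daily risk index: (population-)weighted mean of pi.

    ``pi_surface`` is (T, ncell).  With ``weighted`` (the default, in line
    with the exposure logic) blocks are weighted by population; otherwise
    the unweighted spatial mean is used.
    """
    pi_surface = np.asarray(pi_surface, dtype=float)
    if weighted:
        if population is None:
            raise ValueError("population raster required for weighted aggregation")
        w = population.counts
    else:
        w = np.ones(pi_surface.shape[1])
    ok = np.isfinite(pi_surface)
    wmat = np.where(ok, w[None, :], 0.0)
    num = np.nansum(pi_surface * wmat, axis=1)
    den = wmat.sum(axis=1)
    return num / np.where(den > 0, den, np.nan)


@dataclass
class RiskSurface:
    """Per-block exceedance risk for one pollutant and threshold."""

    pollutant: str
    threshold: float
    pi: np.ndarray                     # (T, ncell)
    mean_days: np.ndarray              # (ncell,) expected exceedance days
    p_exceed_M: np.ndarray             # (ncell,) P(N > M)
    M: int
    aggregated: np.ndarray             # (T,) daily aggregated risk index
    bands: Dict[str, Tuple[np.ndarray, np.ndarray]] = field(default_factory=dict)


def compute_risk_surface(
    dmap: DynamicMap,
    threshold: float,
    residual_cdf: Callable,
    population: PopulationRaster,
    M: int = 7,
    method: str = "exact",
    nsim: int = 500,
    seed: int = 0,
) -> RiskSurface:
    """Assemble the full risk surface for one pollutant."""
    pi = exceedance_probability(dmap, threshold, residual_cdf)
    ncell = pi.shape[1]
    mean_days = np.nansum(pi, axis=0)
    p_ex = np.zeros(ncell)
    for c in range(ncell):
        col = pi[:, c]
        col = col[np.isfinite(col)]
        if col.size == 0:
            p_ex[c] = np.nan
            continue
        d = day_count_distribution(col, M=M, method=method, nsim=nsim,
                                   seed=seed + c if method == "montecarlo" else 0)
        p_ex[c] = d.p_exceed
    agg = aggregated_risk_series(pi, population)
    return RiskSurface(
        pollutant=dmap.pollutant, threshold=threshold, pi=pi,
        mean_days=mean_days, p_exceed_M=p_ex, M=M, aggregated=agg,
    )


# ---------------------------------------------------------------------------
# parametric bootstrap
# ---------------------------------------------------------------------------

@dataclass
class BootstrapBands:
    """Pointwise quantile bands over bootstrap replicates of the pipeline."""

    quantiles: Dict[str, Tuple[np.ndarray, np.ndarray]]
    n_redrawn: int
    R: int


def bootstrap_bands(
    fit: FitResult,
    info: FisherInformation,
    pipeline: Callable[[ParameterSet], Dict[str, np.ndarray]],
    R: int = 100,
    seed: int = 0,
    levels: Tuple[float, float] = (0.025, 0.975),
) -> BootstrapBands:
    """Parametric-bootstrap uncertainty bands.

    Parameter sets are drawn from N(Psi-hat, I^{-1}) on the unconstrained
    reparameterization (positivity/PSD constraints map back automatically);
    each replicate re-runs ``pipeline`` (e.g. kriging + exceedance
    probabilities) and pointwise 2.5%/97.5% sample quantiles are returned
    per output key.  Replicates whose mapped parameters fail validation are
    redrawn (count reported).
    """
    rng = np.random.default_rng(seed)
    reps: Dict[str, List[np.ndarray]] = {}
    n_redrawn = 0
    done = 0
    attempts = 0
    while done < R:
        attempts += 1
        if attempts > 20 * R:
            raise RuntimeError("too many invalid bootstrap draws")
        psi_j = info.draw(rng, fit.psi)
        try:
            psi_j.validate(strict=True)
        except ValueError:
            n_redrawn += 1
            continue
        try:
            out = pipeline(psi_j)
        except (np.linalg.LinAlgError, ValueError):
            n_redrawn += 1
            continue
        for key, arr in out.items():
            reps.setdefault(key, []).append(np.asarray(arr, dtype=float))
        done += 1
    bands = {}
    for key, arrs in reps.items():
        stack = np.stack(arrs, axis=0)
        lo = np.nanquantile(stack, levels[0], axis=0)
        hi = np.nanquantile(stack, levels[1], axis=0)
        bands[key] = (lo, hi)
    return BootstrapBands(quantiles=bands, n_redrawn=n_redrawn, R=R)
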