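"""Global air-quality indices from a reduced common-trend model.

Concentrations are first divided by per-pollutant scaling factors F_i
(µg m⁻³ per index unit, aligned with the UK index-and-banding system) so
that all pollutants live on a common 0-10-ish index scale.  The reduced
model

    y_i(s,t) / F_i = k_i(s) z_i(t) + eps_i(s,t)

has *fixed* loadings k_i(s) = (station temporal average) / (network
average) of the scaled concentrations, which resolves the identifiability
of the common trend; only the state dynamics {G, Sigma_eta} and the noise
variances are estimated (by EM, closed-form M-steps).

Three daily indices summarize the smoothed state z^T(t):

* I1 = z^T(t) for a scalar state (p = 1, highly correlated pollutants);
* I2 = mean_i z_i^T(t), with variance (1/q^2) sum_ij p_ij(t);
* I3 = max_i z_i^T(t), with Monte-Carlo quantile intervals and the
  identity of the maximizing pollutant recorded per day.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np

from .datamodel import ObservationSet, Thresholds
from .estimation import SmootherOutput, _DayCache, _filter_smooth

# IBS concentrations corresponding to index value 10 (µg m^-3): running
# 24-h mean for PM10, hourly mean for NO2, running 8-h mean for O3.
_IBS_INDEX10 = {"PM10": 128.0, "NO2": 764.0, "O3": 360.0}


@dataclass
class ScalingFactors:
    """Per-pollutant scaling factors F_i, µg m⁻³ per index unit."""

    F: Dict[str, float]

    def __post_init__(self) -> None:
        for pol, v in self.F.items():
            if not v > 0:
                raise ValueError(f"scaling factor for {pol} must be > 0")


def default_scaling_factors(
    pollutants: Sequence[str],
    conversion: Optional[Dict[str, float]] = None,
    override: Optional[Dict[str, float]] = None,
) -> ScalingFactors:
    """Default scaling factors from the IBS index-10 concentrations.

    Each factor is (concentration at index 10) / 10.  For PM10 the IBS
    statistic is already a 24-h mean, giving F = 12.8.  NO2 and O3 are
    banded on hourly / running-8-h means; ``conversion`` optionally maps
    those statistics to daily means (divisor, default 1).
    """
    conversion = conversion or {}
    override = override or {}
    F: Dict[str, float] = {}
    for pol in pollutants:
        if pol in override:
            F[pol] = float(override[pol])
        elif pol in _IBS_INDEX10:
            F[pol] = _IBS_INDEX10[pol] / 10.0 / float(conversion.get(pol, 1.0))
        else:
            raise ValueError(
                f"no default scaling factor for {pol!r}; supply one via 'override'"
            )
    return ScalingFactors(F=F)


@dataclass
class IndexSeries:
    """Daily index series with uncertainty.

    ``variance`` is analytic (I1/I2) or None (I3, quantile-based);
    ``argmax`` names the maximizing pollutant per day for I3.
    """

    kind: str
    value: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    variance: Optional[np.ndarray] = None
    argmax: Optional[List[str]] = None

    def __post_init__(self) -> None:
        if np.any(self.lower > self.value + 1e-9) or np.any(self.value > self.upper + 1e-9):
            raise ValueError("index bounds must bracket the point value")


@dataclass
class IndexModelFit:
    """Fitted reduced common-trend model."""

    pollutants: List[str]
    p: int
    factors: ScalingFactors
    loadings: Dict[str, np.ndarray]
    G: np.ndarray
    Sigma_eta: np.ndarray
    sigma2_eps: np.ndarray
    smoother: SmootherOutput
    loglik_trace: np.ndarray
    excluded_stations: Dict[str, List[str]] = field(default_factory=dict)


def build_index_model(
    obs: ObservationSet,
    factors: ScalingFactors,
    p: Optional[int] = None,
    tol: float = 1e-6,
    max_iter: int = 200,
) -> IndexModelFit:
    """Fit the reduced model with station-average loadings fixed.

    ``obs`` must be on the original concentration scale.  p defaults to q
    (one latent trend per pollutant); p = 1 yields a single common trend.
    Stations with no observed day are excluded with a warning.
    """
    network = obs.network
    q = network.q
    if p is None:
        p = q
    if p not in (1, q):
        raise ValueError("the index model requires p in {1, q}")

    # scale, compute fixed loadings (non-missing entries only)
    scaled: Dict[str, np.ndarray] = {}
    loadings: Dict[str, np.ndarray] = {}
    excluded: Dict[str, List[str]] = {}
    for pol in network.pollutants:
        v = obs.values[pol] / factors.F[pol]
        scaled[pol] = v
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            st_avg = np.nanmean(v, axis=1)
        net_avg = np.nanmean(v)
        k = st_avg / net_avg
        empty = ~np.isfinite(k)
        if empty.any():
            ids = [network.site_ids[pol][i] for i in np.nonzero(empty)[0]]
            excluded[pol] = ids
            warnings.warn(f"excluding all-missing stations {ids} for {pol}")
            k = np.where(empty, 0.0, k)
        loadings[pol] = k

    Y = np.concatenate([scaled[pol] for pol in network.pollutants], axis=0)
    polidx = network.stacked_pollutant_index()
    N, T = Y.shape
    kvec = np.concatenate([loadings[pol] for pol in network.pollutants])
    H = np.zeros((N, p))
    if p == 1:
        H[:, 0] = kvec
    else:
        H[np.arange(N), polidx] = kvec
    # excluded stations: loading 0 and data forced missing
    Y = np.where(kvec[:, None] == 0.0, np.nan, Y)

    # initialization: state level ~ network mean, noise ~ residual variance
    zbar = np.nanmean(Y)
    G = 0.5 * np.eye(p)
    Sigma_eta = max(np.nanvar(Y) * 0.5, 1e-6) * np.eye(p)
    sigma2 = np.full(q, max(np.nanvar(Y) * 0.5, 1e-6))

    # EM restricted to {G, Sigma_eta, sigma2_eps}; the prior for z(1) is a
    # diffuse fixed N(zbar-ish, c I): use mean 0 with a large fixed variance
    # so the first smoothed states can reach the data level.
    P1 = (10.0 * max(zbar ** 2, 1.0)) * np.eye(p)

    trace: List[float] = []
    O = np.isfinite(Y)
    sm = None
    for it in range(max_iter):
        Sigma = np.diag(sigma2[polidx])
        cache = _DayCache(Y, np.zeros_like(Y), H, Sigma)
        sm = _filter_smooth(cache, G, Sigma_eta, P1)
        trace.append(sm.loglik)
        if it >= 1 and abs(trace[-1] - trace[-2]) < tol * (abs(trace[-2]) + 1e-12):
            break
        zs, Ps, lag = sm.z_smooth, sm.P_smooth, sm.lag_one
        if T > 1:
            S00 = Ps[:-1].sum(axis=0) + zs[:-1].T @ zs[:-1]
            S11 = Ps[1:].sum(axis=0) + zs[1:].T @ zs[1:]
            S10 = lag[1:].sum(axis=0) + zs[1:].T @ zs[:-1]
            G = np.linalg.solve(S00.T, S10.T).T
            Se = (S11 - G @ S10.T - S10 @ G.T + G @ S00 @ G.T) / (T - 1)
            Se = 0.5 * (Se + Se.T)
            w_e, U_e = np.linalg.eigh(Se)
            Sigma_eta = (U_e * np.maximum(w_e, 1e-10)) @ U_e.T
        fitted = H @ zs.T                                  # (N, T)
        resid2 = np.where(O, (Y - fitted) ** 2, 0.0)
        hPh = np.einsum("np,tpq,nq->nt", H, Ps, H)
        for i in range(q):
            sel = polidx == i
            cnt = O[sel].sum()
            if cnt:
                sigma2[i] = max(
                    (resid2[sel].sum() + (hPh[sel] * O[sel]).sum()) / cnt, 1e-10
                )

    return IndexModelFit(
        pollutants=list(network.pollutants), p=p, factors=factors,
        loadings=loadings, G=G, Sigma_eta=Sigma_eta, sigma2_eps=sigma2,
        smoother=sm, loglik_trace=np.asarray(trace), excluded_stations=excluded,
    )


def index_I1(fit: IndexModelFit) -> IndexSeries:
    """Scalar-state index: the smoothed common trend itself (p = 1)."""
    if fit.p != 1:
        raise ValueError("I1 requires a scalar latent state; use I2/I3 for p = q")
    z = fit.smoother.z_smooth[:, 0]
    v = fit.smoother.P_smooth[:, 0, 0]
    hw = 1.96 * np.sqrt(np.clip(v, 0.0, None))
    return IndexSeries(kind="I1", value=z, lower=z - hw, upper=z + hw, variance=v)


def index_I2(
    z: np.ndarray, P: np.ndarray, pollutants: Optional[Sequence[str]] = None
) -> IndexSeries:
    """Across-pollutant mean of the smoothed states.

    variance(t) = (1/q^2) sum_ij p_ij(t); the 95% interval is the Gaussian
    value +/- 1.96 sd.
    """
    z = np.asarray(z, float)
    P = np.asarray(P, float)
    if z.ndim != 2 or P.shape != (z.shape[0], z.shape[1], z.shape[1]):
        raise ValueError("z must be (T, q) and P (T, q, q)")
    q = z.shape[1]
    val = z.mean(axis=1)
    var = P.sum(axis=(1, 2)) / q ** 2
    hw = 1.96 * np.sqrt(np.clip(var, 0.0, None))
    return IndexSeries(kind="I2", value=val, lower=val - hw, upper=val + hw, variance=var)


def index_I3(
    z: np.ndarray,
    P: np.ndarray,
    pollutants: Sequence[str],
    nsim: int = 10000,
    seed: int = 0,
) -> IndexSeries:
    """Across-pollutant maximum of the smoothed states.

    The 95% interval per day is the 2.5%/97.5% Monte-Carlo quantile of
    max of N(z(t), P(t)) draws (seeded); the maximizing pollutant is
    recorded per day.
    """
    if nsim < 100:
        raise ValueError("nsim must be >= 100")
    z = np.asarray(z, float)
    P = np.asarray(P, float)
    if z.ndim != 2 or P.shape != (z.shape[0], z.shape[1], z.shape[1]):
        raise ValueError("z must be (T, q) and P (T, q, q)")
    T, q = z.shape
    rng = np.random.default_rng(seed)
    val = z.max(axis=1)
    amax = [pollutants[i] for i in z.argmax(axis=1)]
    lower = np.empty(T)
    upper = np.empty(T)
    eps = rng.standard_normal((T, nsim, q))
    for t in range(T):
        S = 0.5 * (P[t] + P[t].T)
        w, U = np.linalg.eigh(S)
        L = U * np.sqrt(np.maximum(w, 0.0))
        draws = z[t] + eps[t] @ L.T
        mx = draws.max(axis=1)
        lower[t], upper[t] = np.quantile(mx, [0.025, 0.975])
    lower = np.minimum(lower, val)
    upper = np.maximum(upper, val)
    return IndexSeries(kind="I3", value=val, lower=lower, upper=upper, argmax=amax)
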