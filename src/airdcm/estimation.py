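"""Maximum-likelihood estimation of the DCM by EM with Kalman smoothing.

State-space view: stacking the observed entries of day t, the model is

    y_t = X_t beta + H z(t) + v_t,      v_t ~ N(0, Sigma_t)
    z(t) = G z(t-1) + eta(t),           eta ~ N(0, Sigma_eta)

where H has row K_i for an entry of pollutant i, and Sigma_t is the
spatial-latent covariance (direct + LCM components) plus the
measurement-error nugget, restricted to the entries observed on day t.
Because u and w are i.i.d. over days they contribute to Sigma_t, not to
the state -- the filter/smoother is exact.

Missing data are handled with a fixed-shape device: missing rows of y, X
and H are zeroed and the corresponding rows/columns of Sigma_t replaced by
the identity, which leaves the state recursion and the likelihood of the
observed entries untouched while keeping every array (T, N, ...)-shaped so
the per-day Cholesky factorizations batch through LAPACK.

The EM implementation is an ECM: G and Sigma_eta have exact closed-form
updates from the smoothed second moments, beta has an exact GLS update,
and the spatial/noise block is increased by a bounded quasi-Newton step on
its unconstrained parameterization.  Each conditional step increases the
expected complete-data log-likelihood, so the observed-data log-likelihood
trace is monotone.  The initial-state prior N(0, P1) is held fixed across
iterations (stationary covariance at the starting parameters) to keep the
conditional maximizations exact.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import minimize

from .datamodel import CovariateField, ObservationSet, StationNetwork
from .dcm_core import (
    LCMComponent,
    ModelConfig,
    ParameterSet,
    _corr_to_uncon,
    _uncon_to_corr,
    cross_covariance,
    residual_covariance_full,
    stack_covariates,
)

_LOG2PI = np.log(2.0 * np.pi)


# ---------------------------------------------------------------------------
# results containers
# ---------------------------------------------------------------------------

@dataclass
class SmootherOutput:
    """Fixed-interval Kalman smoother output.

    ``z_smooth[t]`` is E[z(t)|Y], ``P_smooth[t]`` is Var[z(t)|Y], and
    ``lag_one[t]`` is Cov(z(t), z(t-1)|Y) for t >= 1 (index 0 unused).
    ``loglik_per_day`` are the per-day innovations log-likelihood
    contributions; their sum is the observed-data log-likelihood.
    """

    z_smooth: np.ndarray
    P_smooth: np.ndarray
    lag_one: np.ndarray
    loglik_per_day: np.ndarray

    @property
    def loglik(self) -> float:
        return float(self.loglik_per_day.sum())


@dataclass
class FitResult:
    """EM fit of the DCM: estimates, trace, smoother, and data references."""

    psi: ParameterSet
    loglik_trace: np.ndarray
    converged: bool
    n_iter: int
    smoother: SmootherOutput
    obs: ObservationSet
    covariates: CovariateField
    init_state_cov: np.ndarray
    spatial_latent_mean: Optional[np.ndarray] = None
    messages: List[str] = field(default_factory=list)

    @property
    def loglik(self) -> float:
        return float(self.loglik_trace[-1])


@dataclass
class CrossvalResiduals:
    """Leave-one-site-out cross-validation residuals (transformed scale).

    ``residual``/``sigma``/``studentized`` map pollutant -> (n_i, T)
    arrays (NaN where the observation is missing).  ``sigma`` is the
    dynamic kriging standard deviation of the held-out *observation*
    (field prediction sd plus measurement-error variance).  ``cmse`` is
    the per-pollutant cross-validation mean-squared error and
    ``insample_mse`` its in-sample (all data) counterpart.
    """

    residual: Dict[str, np.ndarray]
    sigma: Dict[str, np.ndarray]
    studentized: Dict[str, np.ndarray]
    cmse: Dict[str, float]
    insample_mse: Dict[str, float]
    single_station_pollutants: List[str] = field(default_factory=list)

    def pooled_studentized(self) -> np.ndarray:
        pooled = np.concatenate([v.ravel() for v in self.studentized.values()])
        return pooled[np.isfinite(pooled)]


# ---------------------------------------------------------------------------
# state-space engine (fixed-shape missing-data device)
# ---------------------------------------------------------------------------

class _DayCache:
    """Per-day whitened sufficient statistics for the filter/smoother."""

    __slots__ = ("obs_mask", "n_obs", "logdet", "chol", "Hw", "S", "b", "yy",
                 "H_masked", "resid")

    def __init__(self, Y, mean, H, Sigma):
        N, T = Y.shape
        p = H.shape[1]
        O = np.isfinite(Y)                       # (N, T)
        self.obs_mask = O
        self.n_obs = O.sum(axis=0)               # (T,)
        r = np.where(O, Y - mean, 0.0)           # (N, T)
        self.resid = r
        Hm = np.where(O.T[:, :, None], H[None, :, :], 0.0)   # (T, N, p)
        self.H_masked = Hm
        Om = O.T                                  # (T, N)
        pair = Om[:, :, None] & Om[:, None, :]
        SigT = np.where(pair, Sigma[None, :, :], 0.0)
        diag_idx = np.arange(N)
        SigT[:, diag_idx, diag_idx] = np.where(Om, Sigma[diag_idx, diag_idx], 1.0)
        L = np.linalg.cholesky(SigT)              # (T, N, N)
        self.chol = L
        self.logdet = 2.0 * np.log(np.einsum("tii->ti", L)).sum(axis=1)
        self.Hw = np.linalg.solve(L, Hm)          # (T, N, p)
        rw = np.linalg.solve(L, r.T[:, :, None])[:, :, 0]   # (T, N)
        self.S = np.einsum("tnp,tnq->tpq", self.Hw, self.Hw)
        self.b = np.einsum("tnp,tn->tp", self.Hw, rw)
        self.yy = np.einsum("tn,tn->t", rw, rw)


def _filter_smooth(cache: _DayCache, G, Q, P1, want_smooth=True):
    """Kalman filter + RTS smoother on whitened per-day statistics."""
    T = cache.S.shape[0]
    p = G.shape[0]
    Ip = np.eye(p)
    z_pred = np.zeros((T, p))
    P_pred = np.zeros((T, p, p))
    z_filt = np.zeros((T, p))
    P_filt = np.zeros((T, p, p))
    ll = np.zeros(T)
    zm = np.zeros(p)
    Pm = np.asarray(P1, float)
    for t in range(T):
        z_pred[t] = zm
        P_pred[t] = Pm
        S = cache.S[t]
        g = cache.b[t] - S @ zm
        A = Ip + Pm @ S
        Pp = np.linalg.solve(A, Pm)
        Pp = 0.5 * (Pp + Pp.T)
        zp = zm + Pp @ g
        quad = cache.yy[t] - 2.0 * zm @ cache.b[t] + zm @ S @ zm - g @ Pp @ g
        sign, ld = np.linalg.slogdet(A)
        ll[t] = -0.5 * (cache.n_obs[t] * _LOG2PI + cache.logdet[t] + quad + ld)
        z_filt[t] = zp
        P_filt[t] = Pp
        zm = G @ zp
        Pm = G @ Pp @ G.T + Q
        Pm = 0.5 * (Pm + Pm.T)
    if not want_smooth:
        return SmootherOutput(z_filt, P_filt, np.zeros((T, p, p)), ll)
    z_s = z_filt.copy()
    P_s = P_filt.copy()
    lag = np.zeros((T, p, p))
    for t in range(T - 2, -1, -1):
        Pn = P_pred[t + 1]
        J = np.linalg.solve(Pn.T, (P_filt[t] @ G.T).T).T
        z_s[t] = z_filt[t] + J @ (z_s[t + 1] - z_pred[t + 1])
        P_s[t] = P_filt[t] + J @ (P_s[t + 1] - Pn) @ J.T
        P_s[t] = 0.5 * (P_s[t] + P_s[t].T)
        # Cov(z_{t+1}, z_t | Y) = P_s[t+1] J' (exact smoothing identity)
        lag[t + 1] = P_s[t + 1] @ J.T
    return SmootherOutput(z_s, P_s, lag, ll)


def _loading_matrix(network: StationNetwork, psi: ParameterSet) -> np.ndarray:
    return psi.K[network.stacked_pollutant_index()]


def kalman_smooth(
    obs: ObservationSet,
    covariates: CovariateField,
    psi: ParameterSet,
    init_state_cov: Optional[np.ndarray] = None,
) -> SmootherOutput:
    """Exact fixed-interval smoother for the DCM state.

    The per-day measurement equation is built over the observed entries
    only; days with no observations propagate the prior.  The default
    initial-state prior is the stationary covariance of the Markov state.
    """
    psi.validate(strict=False)
    if np.min(np.linalg.eigvalsh(0.5 * (psi.Sigma_eta + psi.Sigma_eta.T))) < -1e-10:
        raise ValueError("innovation covariance must be PSD")
    network = obs.network
    T = obs.T
    Y = obs.stacked()
    X = stack_covariates(network, covariates, T)
    pol = network.stacked_pollutant_index()
    mean = np.einsum("ntk,nk->nt", X, psi.beta[pol])
    H = _loading_matrix(network, psi)
    Sigma = residual_covariance_full(network, psi)
    P1 = psi.stationary_state_cov() if init_state_cov is None else np.asarray(init_state_cov, float)
    cache = _DayCache(Y, mean, H, Sigma)
    return _filter_smooth(cache, psi.G, psi.Sigma_eta, P1)


def kalman_loglik(
    obs: ObservationSet,
    covariates: CovariateField,
    psi: ParameterSet,
    init_state_cov: Optional[np.ndarray] = None,
) -> float:
    """Observed-data log-likelihood via the Kalman filter (no smoothing)."""
    network = obs.network
    Y = obs.stacked()
    X = stack_covariates(network, covariates, obs.T)
    pol = network.stacked_pollutant_index()
    mean = np.einsum("ntk,nk->nt", X, psi.beta[pol])
    H = _loading_matrix(network, psi)
    Sigma = residual_covariance_full(network, psi)
    P1 = psi.stationary_state_cov() if init_state_cov is None else np.asarray(init_state_cov, float)
    cache = _DayCache(Y, mean, H, Sigma)
    out = _filter_smooth(cache, psi.G, psi.Sigma_eta, P1, want_smooth=False)
    return out.loglik


# ---------------------------------------------------------------------------
# EM fitting
# ---------------------------------------------------------------------------

def _phi_pack(psi: ParameterSet) -> Tuple[np.ndarray, List[Tuple[float, float]]]:
    """Unconstrained vector of the spatial/noise block, with box bounds."""
    parts: List[np.ndarray] = []
    bounds: List[Tuple[float, float]] = []
    rng_lo, rng_hi = np.log(1.0), np.log(1e4)
    if psi.has_u:
        parts.append(np.log(psi.alpha))
        bounds += [(-15.0, 15.0)] * psi.q
        parts.append(np.log(psi.theta))
        bounds += [(rng_lo, rng_hi)] * psi.q
    for comp in psi.lcm:
        parts.append(np.log(comp.lam))
        bounds += [(-15.0, 15.0)] * psi.q
        ang = _corr_to_uncon(comp.V)
        parts.append(ang)
        bounds += [(-12.0, 12.0)] * ang.size
        parts.append(np.array([np.log(comp.range_km)]))
        bounds += [(rng_lo, rng_hi)]
    parts.append(np.log(psi.sigma2_eps))
    bounds += [(np.log(1e-10), 12.0)] * psi.q
    return np.concatenate(parts), bounds


def _phi_unpack(psi: ParameterSet, x: np.ndarray) -> ParameterSet:
    out = psi.copy()
    q = psi.q
    pos = 0

    def take(n):
        nonlocal pos
        v = x[pos:pos + n]
        pos += n
        return v

    if psi.has_u:
        out.alpha = np.exp(take(q))
        out.theta = np.exp(take(q))
    n_ang = q * (q - 1) // 2
    for j in range(len(psi.lcm)):
        lam = np.exp(take(q))
        V = _uncon_to_corr(take(n_ang), q)
        rng = float(np.exp(take(1)[0]))
        out.lcm[j] = LCMComponent(lam=lam, V=V, range_km=rng)
    out.sigma2_eps = np.exp(take(q))
    return out


def _default_K(q: int, p: int) -> np.ndarray:
    if p == q:
        return np.eye(q)
    if p == 1:
        return np.ones((q, 1))
    K = np.zeros((q, p))
    for i in range(q):
        K[i, i % p] = 1.0
    return K


def default_init(
    obs: ObservationSet,
    covariates: CovariateField,
    config: ModelConfig,
    seed: Optional[int] = None,
) -> ParameterSet:
    """Spec'd initialization: OLS for beta, variance partition, G = 0.5 I,
    ranges at the median inter-station distance, optional seeded jitter."""
    network = obs.network
    q = network.q
    T = obs.T
    Y = obs.stacked()
    X = stack_covariates(network, covariates, T)
    pol = network.stacked_pollutant_index()
    k = X.shape[2]
    beta = np.zeros((q, k))
    resid_var = np.zeros(q)
    for i in range(q):
        sel = pol == i
        ys = Y[sel].ravel()
        xs = X[sel].reshape(-1, k)
        ok = np.isfinite(ys)
        coef, *_ = np.linalg.lstsq(xs[ok], ys[ok], rcond=None)
        beta[i] = coef
        r = ys[ok] - xs[ok] @ coef
        resid_var[i] = max(float(r.var()), 1e-6)

    jitter = np.ones(q)
    if seed is not None:
        jitter = np.exp(0.1 * np.random.default_rng(seed).standard_normal(q))

    xy = network.stacked_coords()
    dmat = network.distance_matrix(xy)
    med = float(np.median(dmat[np.triu_indices_from(dmat, k=1)])) if xy.shape[0] > 1 else 10.0
    med = max(med, 1.0)

    p = config.p if config.include_z else 1
    K = _default_K(q, p)
    z_share = 0.2 if config.include_z else 0.0
    rest = 1.0 - z_share
    sigma2 = 0.5 * rest * resid_var * jitter
    spat_var = 0.5 * rest * resid_var * jitter

    alpha = theta = None
    lcm: List[LCMComponent] = []
    n_spat = int(config.include_u) + (config.c if config.include_lcm else 0)
    if config.include_u:
        alpha = np.sqrt(spat_var / max(n_spat, 1))
        theta = np.full(q, med)
    if config.include_lcm:
        for _ in range(config.c):
            lcm.append(
                LCMComponent(
                    lam=np.sqrt(spat_var / max(n_spat, 1)),
                    V=np.eye(q),
                    range_km=med,
                )
            )
    G = 0.5 * np.eye(p)
    if config.include_z:
        v = z_share * float(np.mean(resid_var))
        Sigma_eta = v * (1.0 - 0.25) * np.eye(p)
    else:
        Sigma_eta = 1e-8 * np.eye(p)
        K = np.zeros((q, p))
    return ParameterSet(
        beta=beta, K=K, G=G, Sigma_eta=Sigma_eta, sigma2_eps=sigma2,
        alpha=alpha, theta=theta, lcm=lcm,
    )


def em_fit(
    obs: ObservationSet,
    covariates: CovariateField,
    config: ModelConfig,
    init: Optional[ParameterSet] = None,
    tol: float = 1e-5,
    max_iter: int = 400,
    seed: Optional[int] = None,
    inner_maxiter: int = 5,
    verbose: bool = False,
) -> FitResult:
    """Fit the DCM by ECM (EM with conditional M-steps).

    Stops when the relative log-likelihood change falls below ``tol``;
    returns the best iterate with a non-convergence flag otherwise.  The
    log-likelihood trace is monotone up to numerical slack.
    """
    network = obs.network
    T = obs.T
    q = network.q
    Y = obs.stacked()
    X = stack_covariates(network, covariates, T)
    pol = network.stacked_pollutant_index()
    k = X.shape[2]
    N = network.n_total
    O = np.isfinite(Y)

    psi = (init if init is not None else default_init(obs, covariates, config, seed)).copy()
    psi.validate(strict=False)
    P1 = psi.stationary_state_cov()
    if np.min(np.linalg.eigvalsh(P1)) < 1e-10:
        P1 = P1 + 1e-8 * np.eye(psi.p)

    # regressor tensor for the GLS beta update: one column per (pollutant, covariate)
    m_beta = q * k
    R = np.zeros((N, T, m_beta))
    for i in range(q):
        sel = pol == i
        R[sel, :, i * k:(i + 1) * k] = X[sel]
    R = np.where(O[:, :, None], R, 0.0)

    messages: List[str] = []
    trace: List[float] = []
    converged = False
    floor_hit = False

    for it in range(max_iter):
        # ---- E-step at current psi
        mean = np.einsum("ntk,nk->nt", X, psi.beta[pol])
        H = _loading_matrix(network, psi)
        Sigma = residual_covariance_full(network, psi)
        cache = _DayCache(Y, mean, H, Sigma)
        sm = _filter_smooth(cache, psi.G, psi.Sigma_eta, P1)
        trace.append(sm.loglik)
        if verbose:
            print(f"EM iter {it}: loglik = {sm.loglik:.6f}")
        if it >= 1:
            rel = (trace[-1] - trace[-2]) / (abs(trace[-2]) + 1e-12)
            if abs(rel) < tol:
                converged = True
                break

        zs, Ps, lag = sm.z_smooth, sm.P_smooth, sm.lag_one

        # ---- M-step 1: G, Sigma_eta (closed form)
        S00 = Ps[:-1].sum(axis=0) + zs[:-1].T @ zs[:-1]
        S11 = Ps[1:].sum(axis=0) + zs[1:].T @ zs[1:]
        S10 = lag[1:].sum(axis=0) + zs[1:].T @ zs[:-1]
        if T > 1 and config.include_z:
            G_new = np.linalg.solve(S00.T, S10.T).T
            Se = (S11 - G_new @ S10.T - S10 @ G_new.T + G_new @ S00 @ G_new.T) / (T - 1)
            Se = 0.5 * (Se + Se.T)
            w_e, U_e = np.linalg.eigh(Se)
            if w_e.min() < 1e-10:
                Se = (U_e * np.maximum(w_e, 1e-10)) @ U_e.T
            psi.G = G_new
            psi.Sigma_eta = Se

        # ---- M-step 2: beta (GLS given current spatial/noise block)
        resid_z = np.where(O, Y - np.einsum("np,tp->nt", H, zs), 0.0)
        Rw = np.linalg.solve(cache.chol, R.transpose(1, 0, 2))      # (T, N, m)
        rw = np.linalg.solve(cache.chol, resid_z.T[:, :, None])[:, :, 0]
        A = np.einsum("tnm,tnl->ml", Rw, Rw)
        bvec = np.einsum("tnm,tn->m", Rw, rw)
        beta_new = np.linalg.solve(A, bvec)
        psi.beta = beta_new.reshape(q, k)

        # ---- M-step 3: spatial/noise block (bounded quasi-Newton on Q)
        mean = np.einsum("ntk,nk->nt", X, psi.beta[pol])
        r = np.where(O, Y - mean - np.einsum("np,tp->nt", H, zs), 0.0)
        Hm = np.where(O.T[:, :, None], H[None, :, :], 0.0)
        HPH = np.einsum("tnp,tpq,tmq->tnm", Hm, Ps, Hm)
        A_T = r.T[:, :, None] * r.T[:, None, :] + HPH                # (T, N, N)
        diag_idx = np.arange(N)
        Om = O.T

        def q_obj(x: np.ndarray) -> float:
            psi_x = _phi_unpack(psi, x)
            Sig = residual_covariance_full(network, psi_x)
            pair = Om[:, :, None] & Om[:, None, :]
            SigT = np.where(pair, Sig[None, :, :], 0.0)
            SigT[:, diag_idx, diag_idx] = np.where(Om, Sig[diag_idx, diag_idx], 1.0)
            try:
                L = np.linalg.cholesky(SigT)
            except np.linalg.LinAlgError:
                return 1e12
            logdet = 2.0 * np.log(np.einsum("tii->ti", L)).sum()
            Xs = np.linalg.solve(SigT, A_T)
            tr = np.einsum("tii->", Xs)
            return 0.5 * (logdet + tr)

        x0, bounds = _phi_pack(psi)
        if x0.size:
            f0 = q_obj(x0)
            res = minimize(
                q_obj, x0, method="L-BFGS-B", bounds=bounds,
                options={"maxiter": inner_maxiter, "maxfun": 40 * (x0.size + 1)},
            )
            if np.isfinite(res.fun) and res.fun < f0:
                psi = _phi_unpack(psi, res.x)
            if np.any(psi.sigma2_eps <= 1.5e-10):
                floor_hit = True

    else:
        it = max_iter - 1

    if not converged:
        messages.append(f"EM did not converge in {max_iter} iterations")
        warnings.warn(messages[-1])
    if floor_hit:
        messages.append("a measurement-error variance hit the 1e-10 floor")
        warnings.warn(messages[-1])

    # final E-step at the last accepted parameters
    mean = np.einsum("ntk,nk->nt", X, psi.beta[pol])
    H = _loading_matrix(network, psi)
    Sigma = residual_covariance_full(network, psi)
    cache = _DayCache(Y, mean, H, Sigma)
    sm = _filter_smooth(cache, psi.G, psi.Sigma_eta, P1)
    if not trace or sm.loglik >= trace[-1] - 1e-9:
        trace.append(sm.loglik)

    # smoothed spatial-latent expectations at the stations
    lat_mean = _spatial_latent_mean(network, psi, cache, sm)

    return FitResult(
        psi=psi,
        loglik_trace=np.asarray(trace),
        converged=converged,
        n_iter=len(trace) - 1,
        smoother=sm,
        obs=obs,
        covariates=covariates,
        init_state_cov=P1,
        spatial_latent_mean=lat_mean,
        messages=messages,
    )


def _spatial_latent_mean(network, psi, cache: _DayCache, sm: SmootherOutput) -> np.ndarray:
    """E[alpha u + lambda w at the stations | Y], shape (N, T)."""
    pol = network.stacked_pollutant_index()
    xy = network.stacked_coords()
    C = cross_covariance(network, psi, pol, xy, pol, xy, nugget=False)
    T = cache.S.shape[0]
    N = xy.shape[0]
    out = np.zeros((N, T))
    r = cache.resid - np.einsum(
        "tnp,tp->tn", cache.H_masked, sm.z_smooth
    ).T * cache.obs_mask
    for t in range(T):
        o = cache.obs_mask[:, t]
        if not o.any():
            continue
        L = cache.chol[t][np.ix_(o, o)]
        rhs = np.linalg.solve(L, r[o, t])
        w = np.linalg.solve(L.T, rhs)
        out[:, t] = C[:, o] @ w
    return out


# ---------------------------------------------------------------------------
# Fisher information
# ---------------------------------------------------------------------------

@dataclass
class FisherInformation:
    """Approximate Fisher information on the unconstrained parameter scale.

    ``matrix`` is the symmetrized negative Hessian of the log-likelihood at
    the estimate; ``covariance`` its (pseudo-)inverse; ``sd`` maps each
    packed parameter name to a delta-method standard deviation on the
    natural scale.
    """

    names: List[str]
    x_hat: np.ndarray
    matrix: np.ndarray
    covariance: np.ndarray
    sd: Dict[str, float]
    pseudo_inverse: bool = False

    def draw(self, rng: np.random.Generator, psi_template: ParameterSet) -> ParameterSet:
        """One parametric-bootstrap draw Psi ~ N(Psi_hat, I^{-1}) mapped back."""
        C = 0.5 * (self.covariance + self.covariance.T)
        w, U = np.linalg.eigh(C)
        L = U * np.sqrt(np.maximum(w, 0.0))
        x = self.x_hat + L @ rng.standard_normal(self.x_hat.size)
        return psi_template.unpack_unconstrained(x)


def fisher_information(
    psi: ParameterSet,
    obs: ObservationSet,
    covariates: CovariateField,
    init_state_cov: Optional[np.ndarray] = None,
    rel_step: float = 1e-4,
) -> FisherInformation:
    """Numerical negative Hessian of the log-likelihood at psi.

    Central differences with a per-parameter relative step on the
    unconstrained parameterization; the result is symmetrized and standard
    deviations are obtained from the inverse diagonal (pseudo-inverse with
    a warning if the information is singular).
    """
    P1 = psi.stationary_state_cov() if init_state_cov is None else np.asarray(init_state_cov)
    x0 = psi.pack_unconstrained()
    names = psi.pack_names()
    n = x0.size
    steps = rel_step * np.maximum(np.abs(x0), 1.0)

    def ll(x: np.ndarray) -> float:
        p = psi.unpack_unconstrained(x)
        return kalman_loglik(obs, covariates, p, init_state_cov=P1)

    cache: Dict[Tuple[float, ...], float] = {}

    def ll_c(x: np.ndarray) -> float:
        key = tuple(np.round(x, 12))
        if key not in cache:
            cache[key] = ll(x)
        return cache[key]

    Hmat = np.zeros((n, n))
    f0 = ll_c(x0)
    for i in range(n):
        ei = np.zeros(n)
        ei[i] = steps[i]
        fpp = ll_c(x0 + ei)
        fmm = ll_c(x0 - ei)
        Hmat[i, i] = (fpp - 2 * f0 + fmm) / steps[i] ** 2
        for j in range(i):
            ej = np.zeros(n)
            ej[j] = steps[j]
            fa = ll_c(x0 + ei + ej)
            fb = ll_c(x0 + ei - ej)
            fc = ll_c(x0 - ei + ej)
            fd = ll_c(x0 - ei - ej)
            Hmat[i, j] = Hmat[j, i] = (fa - fb - fc + fd) / (4 * steps[i] * steps[j])
    info = -0.5 * (Hmat + Hmat.T)

    pseudo = False
    try:
        cov = np.linalg.inv(info)
        if not np.all(np.isfinite(cov)) or np.any(np.diag(cov) < 0):
            raise np.linalg.LinAlgError
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(info)
        pseudo = True
        warnings.warn("Fisher information not invertible; using pseudo-inverse")

    # delta method to the natural scale: d natural / d unconstrained
    def natural(x: np.ndarray) -> np.ndarray:
        p = psi.unpack_unconstrained(x)
        parts = [p.beta.ravel(), p.G.ravel(),
                 p.Sigma_eta[np.tril_indices(p.p)]]
        if p.has_u:
            parts += [p.alpha, p.theta]
        for comp in p.lcm:
            parts += [comp.lam, comp.V[np.tril_indices(p.q, k=-1)],
                      np.array([comp.range_km])]
        parts.append(p.sigma2_eps)
        return np.concatenate(parts)

    g0 = natural(x0)
    J = np.zeros((g0.size, n))
    for i in range(n):
        ei = np.zeros(n)
        ei[i] = steps[i]
        J[:, i] = (natural(x0 + ei) - natural(x0 - ei)) / (2 * steps[i])
    nat_cov = J @ cov @ J.T
    nat_sd = np.sqrt(np.clip(np.diag(nat_cov), 0.0, None))
    nat_names = _natural_names(psi)
    sd = dict(zip(nat_names, nat_sd))

    return FisherInformation(
        names=names, x_hat=x0, matrix=info, covariance=cov, sd=sd,
        pseudo_inverse=pseudo,
    )


def _natural_names(psi: ParameterSet) -> List[str]:
    names = [f"beta[{i},{j}]" for i in range(psi.q) for j in range(psi.k)]
    names += [f"G[{i},{j}]" for i in range(psi.p) for j in range(psi.p)]
    names += [f"Sigma_eta[{i},{j}]" for i, j in zip(*np.tril_indices(psi.p))]
    if psi.has_u:
        names += [f"alpha[{i}]" for i in range(psi.q)]
        names += [f"theta[{i}]" for i in range(psi.q)]
    for j in range(len(psi.lcm)):
        names += [f"lambda[{j},{i}]" for i in range(psi.q)]
        names += [f"V[{j}][{a},{b}]" for a, b in zip(*np.tril_indices(psi.q, k=-1))]
        names += [f"lcm_range[{j}]"]
    names += [f"sigma2_eps[{i}]" for i in range(psi.q)]
    return names


def beta_information(
    psi: ParameterSet,
    obs: ObservationSet,
    covariates: CovariateField,
    init_state_cov: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Exact expected Fisher information of beta, X' Omega^{-1} X.

    For a Gaussian model the information is block-diagonal between mean and
    covariance parameters, so this block alone yields valid Wald standard
    errors for the regression coefficients.  Computed exactly with one
    multi-column Kalman-filter pass (innovations decomposition of
    Omega^{-1}); rows/columns ordered (pollutant-major, covariate-minor).
    """
    network = obs.network
    T = obs.T
    q = network.q
    Y = obs.stacked()
    X = stack_covariates(network, covariates, T)
    pol = network.stacked_pollutant_index()
    k = X.shape[2]
    N = network.n_total
    O = np.isfinite(Y)
    m = q * k
    R = np.zeros((N, T, m))
    for i in range(q):
        sel = pol == i
        R[sel, :, i * k:(i + 1) * k] = X[sel]
    R = np.where(O[:, :, None], R, 0.0)

    H = _loading_matrix(network, psi)
    Sigma = residual_covariance_full(network, psi)
    cache = _DayCache(Y, np.where(O, Y, 0.0), H, Sigma)   # resid unused here
    P1 = psi.stationary_state_cov() if init_state_cov is None else np.asarray(init_state_cov)

    Rw = np.linalg.solve(cache.chol, R.transpose(1, 0, 2))     # (T, N, m)
    RtR = np.einsum("tnm,tnl->tml", Rw, Rw)
    B = np.einsum("tnp,tnm->tpm", cache.Hw, Rw)                # (T, p, m)

    p = psi.p
    Ip = np.eye(p)
    Z = np.zeros((p, m))
    Pm = np.asarray(P1, float)
    A = np.zeros((m, m))
    G, Q = psi.G, psi.Sigma_eta
    for t in range(T):
        S = cache.S[t]
        Gt = B[t] - S @ Z
        M = Ip + Pm @ S
        Pp = np.linalg.solve(M, Pm)
        Pp = 0.5 * (Pp + Pp.T)
        # innovations cross-products: nu = D_w - H_w Z_pred
        nu_quad = RtR[t] - B[t].T @ Z - Z.T @ B[t] + Z.T @ S @ Z
        A += nu_quad - Gt.T @ Pp @ Gt
        Z = G @ (Z + Pp @ Gt)
        Pm = G @ Pp @ G.T + Q
        Pm = 0.5 * (Pm + Pm.T)
    return 0.5 * (A + A.T)


# ---------------------------------------------------------------------------
# leave-one-site-out cross-validation
# ---------------------------------------------------------------------------

def loso_crossval(
    obs: ObservationSet,
    covariates: CovariateField,
    psi: ParameterSet,
    init_state_cov: Optional[np.ndarray] = None,
    refit: bool = False,
    refit_max_iter: int = 20,
) -> CrossvalResiduals:
    """Leave-one-site-out residuals under the fitted parameters.

    For each station, predictions at that station use all data except the
    station itself.  By default the parameter estimates are *not* re-run
    per held-out station (the plug-in convention; cost grows linearly in
    stations otherwise); ``refit=True`` re-runs a short EM warm-started at
    psi for every held-out station.  Residuals are Studentized by the
    dynamic kriging standard deviation of the held-out observation (field
    prediction variance plus measurement-error variance).  cmse is the
    per-pollutant mean squared residual on the transformed scale;
    insample_mse is the same quantity with the station's own data
    retained, which it always exceeds.
    """
    from .mapping import _krige_points   # local import to avoid a cycle

    network = obs.network
    T = obs.T
    P1 = psi.stationary_state_cov() if init_state_cov is None else np.asarray(init_state_cov)

    residual: Dict[str, np.ndarray] = {}
    sigma: Dict[str, np.ndarray] = {}
    student: Dict[str, np.ndarray] = {}
    cmse: Dict[str, float] = {}
    insample: Dict[str, float] = {}
    singles = [p for p in network.pollutants if network.n_sites(p) == 1]

    # in-sample pass once
    sm_full = kalman_smooth(obs, covariates, psi, init_state_cov=P1)

    for ip, polname in enumerate(network.pollutants):
        n_i = network.n_sites(polname)
        residual[polname] = np.full((n_i, T), np.nan)
        sigma[polname] = np.full((n_i, T), np.nan)
        student[polname] = np.full((n_i, T), np.nan)

    for ip, polname in enumerate(network.pollutants):
        n_i = network.n_sites(polname)
        coords = network.coords[polname]
        Xpol = covariates.station[polname]
        for s in range(n_i):
            held = obs.values[polname][s]
            if not np.isfinite(held).any():
                continue
            obs_minus = obs.copy()
            obs_minus.values[polname][s, :] = np.nan
            psi_s = psi
            if refit:
                config = ModelConfig(
                    p=psi.p, include_u=psi.has_u,
                    include_lcm=psi.has_lcm, c=max(len(psi.lcm), 1),
                    include_z=True,
                )
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore", UserWarning)
                    psi_s = em_fit(obs_minus, covariates, config, init=psi,
                                   tol=1e-5, max_iter=refit_max_iter).psi
            sm = kalman_smooth(obs_minus, covariates, psi_s, init_state_cov=P1)
            mean_t = Xpol[s] @ psi_s.beta[ip]                   # (T,)
            pred, var = _krige_points(
                obs_minus, covariates, psi_s, sm,
                np.array([ip]), coords[s:s + 1], mean_t[None, :],
            )
            var_obs = var[0] + psi_s.sigma2_eps[ip]
            e = held - pred[0]
            residual[polname][s] = e
            sigma[polname][s] = np.sqrt(var_obs)
            with np.errstate(invalid="ignore", divide="ignore"):
                student[polname][s] = np.where(var_obs > 0, e / np.sqrt(var_obs), np.nan)

    # in-sample predictions for the optimism comparison
    for ip, polname in enumerate(network.pollutants):
        coords = network.coords[polname]
        Xpol = covariates.station[polname]
        n_i = network.n_sites(polname)
        mean_t = np.einsum("stk,k->st", Xpol, psi.beta[ip])
        pred_in, _ = _krige_points(
            obs, covariates, psi, sm_full,
            np.full(n_i, ip), coords, mean_t,
        )
        e_in = obs.values[polname] - pred_in
        ok_in = np.isfinite(e_in)
        insample[polname] = float(np.mean(e_in[ok_in] ** 2)) if ok_in.any() else np.nan
        e = residual[polname]
        ok = np.isfinite(e)
        cmse[polname] = float(np.mean(e[ok] ** 2)) if ok.any() else np.nan

    return CrossvalResiduals(
        residual=residual, sigma=sigma, studentized=student,
        cmse=cmse, insample_mse=insample, single_station_pollutants=singles,
    )
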