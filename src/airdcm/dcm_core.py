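"""Generative dynamic coregionalization model (DCM).

The model for pollutant i at site s and day t is

    y_i(s,t) = x_i(s,t)' beta_i + [K z(t)]_i
               + alpha_i u_i(s,t) + sum_j lambda_{j,i} w_i^j(s,t)
               + eps_i(s,t)

with

* z(t) a p-dimensional latent Markov state, z(t) = G z(t-1) + eta(t),
  eta ~ N(0, Sigma_eta), G stable, K a fixed q x p loading matrix;
* u_i the *direct* spatial component: independent unit-variance Gaussian
  processes, one exponential correlation range theta_i per pollutant;
* w^j the *interaction* component: a linear model of coregionalization
  (LCM) of c components, each with cross-correlation matrix V_j (unit
  diagonal) and a shared exponential range; the scale vector lambda_j
  multiplies the unit-variance process so that
  Cov(w-part) = diag(lambda_j) V_j diag(lambda_j) rho(h; range_j);
* eps white measurement noise with per-pollutant variance sigma2_eps_i.

u and w are independent and identically distributed over days, so for
likelihood purposes they fold into a per-day spatial "measurement noise"
covariance around the common temporal state -- that is what makes the
Kalman-smoother route exact.

This module provides covariance construction, simulation from the model,
and a dense (brute-force) joint-Gaussian likelihood/conditioning path used
as the reference implementation on small instances.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.linalg import cho_factor, cho_solve, solve_discrete_lyapunov
from scipy.special import expit, logit

from .datamodel import CovariateField, ObservationSet, StationNetwork


# ---------------------------------------------------------------------------
# configuration and parameters
# ---------------------------------------------------------------------------

@dataclass
class ModelConfig:
    """Which components of the DCM are switched on.

    p is the latent temporal dimension; the common-trend index model
    requires p in {1, q}.  c is the number of LCM components.
    """

    p: int
    include_u: bool = False
    include_lcm: bool = True
    c: int = 1
    correlation: str = "exponential"
    include_z: bool = True

    def __post_init__(self) -> None:
        if self.correlation != "exponential":
            raise ValueError("only the exponential correlation family is supported")
        if self.include_lcm and self.c < 1:
            raise ValueError("c must be >= 1 when the LCM is included")
        if not (self.include_u or self.include_lcm or self.include_z):
            raise ValueError("at least one of u, w (LCM) or z must be included")
        if self.include_z and self.p < 1:
            raise ValueError("p must be >= 1")


@dataclass
class LCMComponent:
    """One coregionalization component: scales, cross-correlation, range."""

    lam: np.ndarray          # (q,) positive scale parameters
    V: np.ndarray            # (q, q) correlation matrix, unit diagonal
    range_km: float          # shared exponential correlation range

    def __post_init__(self) -> None:
        self.lam = np.asarray(self.lam, dtype=float)
        self.V = np.asarray(self.V, dtype=float)


@dataclass
class ParameterSet:
    """Full parameter set Psi of the DCM.

    beta is (q, k): one coefficient vector per pollutant over the k
    covariates.  K is the fixed/known q x p loading matrix.  alpha/theta
    are the scales/ranges of the direct component u (None if excluded);
    lcm is the list of LCM components (empty if excluded).
    """

    beta: np.ndarray
    K: np.ndarray
    G: np.ndarray
    Sigma_eta: np.ndarray
    sigma2_eps: np.ndarray
    alpha: Optional[np.ndarray] = None
    theta: Optional[np.ndarray] = None
    lcm: List[LCMComponent] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.beta = np.atleast_2d(np.asarray(self.beta, dtype=float))
        self.K = np.atleast_2d(np.asarray(self.K, dtype=float))
        self.G = np.atleast_2d(np.asarray(self.G, dtype=float))
        self.Sigma_eta = np.atleast_2d(np.asarray(self.Sigma_eta, dtype=float))
        self.sigma2_eps = np.asarray(self.sigma2_eps, dtype=float)
        if self.alpha is not None:
            self.alpha = np.asarray(self.alpha, dtype=float)
        if self.theta is not None:
            self.theta = np.asarray(self.theta, dtype=float)

    @property
    def q(self) -> int:
        return self.K.shape[0]

    @property
    def p(self) -> int:
        return self.K.shape[1]

    @property
    def k(self) -> int:
        return self.beta.shape[1]

    @property
    def has_u(self) -> bool:
        return self.alpha is not None

    @property
    def has_lcm(self) -> bool:
        return len(self.lcm) > 0

    def validate(self, strict: bool = True) -> None:
        """Check invariants.  strict=True additionally requires variances > 0."""
        q, p = self.q, self.p
        if self.G.shape != (p, p) or self.Sigma_eta.shape != (p, p):
            raise ValueError("G and Sigma_eta must be p x p")
        if np.max(np.abs(np.linalg.eigvals(self.G))) >= 1.0:
            raise ValueError("transition matrix G must be stable (spectral radius < 1)")
        if np.min(np.linalg.eigvalsh(0.5 * (self.Sigma_eta + self.Sigma_eta.T))) < -1e-10:
            raise ValueError("Sigma_eta must be PSD")
        if self.sigma2_eps.shape != (q,):
            raise ValueError("sigma2_eps must have length q")
        lower = 0.0 if strict else -1e-12
        if strict and np.any(self.sigma2_eps <= 0):
            raise ValueError("sigma2_eps must be > 0")
        if np.any(self.sigma2_eps < lower):
            raise ValueError("sigma2_eps must be >= 0")
        if self.has_u:
            if self.alpha.shape != (q,) or self.theta is None or self.theta.shape != (q,):
                raise ValueError("alpha and theta must have length q")
            if np.any(self.theta <= 0):
                raise ValueError("correlation ranges theta must be > 0")
            if strict and np.any(self.alpha <= 0):
                raise ValueError("alpha must be > 0")
        for comp in self.lcm:
            if comp.lam.shape != (q,) or comp.V.shape != (q, q):
                raise ValueError("LCM component has inconsistent dimensions")
            if not comp.range_km > 0:
                raise ValueError("LCM range must be > 0")
            if strict and np.any(comp.lam <= 0):
                raise ValueError("LCM scales must be > 0")
            if not np.allclose(np.diag(comp.V), 1.0, atol=1e-8):
                raise ValueError("V must have unit diagonal")
            if np.min(np.linalg.eigvalsh(0.5 * (comp.V + comp.V.T))) < -1e-10:
                raise ValueError("V must be PSD")

    def copy(self) -> "ParameterSet":
        return ParameterSet(
            beta=self.beta.copy(),
            K=self.K.copy(),
            G=self.G.copy(),
            Sigma_eta=self.Sigma_eta.copy(),
            sigma2_eps=self.sigma2_eps.copy(),
            alpha=None if self.alpha is None else self.alpha.copy(),
            theta=None if self.theta is None else self.theta.copy(),
            lcm=[LCMComponent(c.lam.copy(), c.V.copy(), c.range_km) for c in self.lcm],
        )

    def stationary_state_cov(self) -> np.ndarray:
        """Stationary covariance of z, solving P = G P G' + Sigma_eta."""
        P = solve_discrete_lyapunov(self.G, self.Sigma_eta)
        return 0.5 * (P + P.T)

    # -- unconstrained reparameterization (optimizer / Fisher / bootstrap) --

    def pack_names(self) -> List[str]:
        names = [f"beta[{i},{j}]" for i in range(self.q) for j in range(self.k)]
        names += [f"G[{i},{j}]" for i in range(self.p) for j in range(self.p)]
        names += [f"chol_Sigma_eta[{i},{j}]" for i in range(self.p) for j in range(i + 1)]
        if self.has_u:
            names += [f"log_alpha[{i}]" for i in range(self.q)]
            names += [f"log_theta[{i}]" for i in range(self.q)]
        for j, _ in enumerate(self.lcm):
            names += [f"log_lambda[{j},{i}]" for i in range(self.q)]
            names += [f"V_angle[{j},{m}]" for m in range(self.q * (self.q - 1) // 2)]
            names += [f"log_lcm_range[{j}]"]
        names += [f"log_sigma2_eps[{i}]" for i in range(self.q)]
        return names

    def pack_unconstrained(self) -> np.ndarray:
        parts = [self.beta.ravel(), self.G.ravel(), _spd_to_vec(self.Sigma_eta)]
        if self.has_u:
            parts += [np.log(self.alpha), np.log(self.theta)]
        for comp in self.lcm:
            parts += [
                np.log(comp.lam),
                _corr_to_uncon(comp.V),
                np.array([np.log(comp.range_km)]),
            ]
        parts.append(np.log(self.sigma2_eps))
        return np.concatenate(parts)

    def unpack_unconstrained(self, x: np.ndarray) -> "ParameterSet":
        """Build a new ParameterSet from an unconstrained vector (same layout)."""
        x = np.asarray(x, dtype=float)
        q, p, k = self.q, self.p, self.k
        pos = 0

        def take(n: int) -> np.ndarray:
            nonlocal pos
            out = x[pos:pos + n]
            pos += n
            return out

        beta = take(q * k).reshape(q, k)
        G = take(p * p).reshape(p, p)
        Sigma_eta = _vec_to_spd(take(p * (p + 1) // 2), p)
        alpha = theta = None
        if self.has_u:
            alpha = np.exp(take(q))
            theta = np.exp(take(q))
        lcm = []
        for _ in self.lcm:
            lam = np.exp(take(q))
            V = _uncon_to_corr(take(q * (q - 1) // 2), q)
            rng = float(np.exp(take(1)[0]))
            lcm.append(LCMComponent(lam=lam, V=V, range_km=rng))
        sigma2 = np.exp(take(q))
        if pos != x.size:
            raise ValueError("unconstrained vector has wrong length")
        return ParameterSet(
            beta=beta, K=self.K.copy(), G=G, Sigma_eta=Sigma_eta,
            sigma2_eps=sigma2, alpha=alpha, theta=theta, lcm=lcm,
        )


def psi_to_dict(psi: ParameterSet) -> dict:
    """JSON-serializable representation of a ParameterSet."""
    out = {
        "beta": psi.beta.tolist(),
        "K": psi.K.tolist(),
        "G": psi.G.tolist(),
        "Sigma_eta": psi.Sigma_eta.tolist(),
        "sigma2_eps": psi.sigma2_eps.tolist(),
        "alpha": None if psi.alpha is None else psi.alpha.tolist(),
        "theta": None if psi.theta is None else psi.theta.tolist(),
        "lcm": [
            {"lam": c.lam.tolist(), "V": c.V.tolist(), "range_km": c.range_km}
            for c in psi.lcm
        ],
    }
    return out


def psi_from_dict(d: dict) -> ParameterSet:
    return ParameterSet(
        beta=np.asarray(d["beta"], float),
        K=np.asarray(d["K"], float),
        G=np.asarray(d["G"], float),
        Sigma_eta=np.asarray(d["Sigma_eta"], float),
        sigma2_eps=np.asarray(d["sigma2_eps"], float),
        alpha=None if d.get("alpha") is None else np.asarray(d["alpha"], float),
        theta=None if d.get("theta") is None else np.asarray(d["theta"], float),
        lcm=[
            LCMComponent(
                lam=np.asarray(c["lam"], float),
                V=np.asarray(c["V"], float),
                range_km=float(c["range_km"]),
            )
            for c in d.get("lcm", [])
        ],
    )


# -- reparameterization helpers ---------------------------------------------

def _spd_to_vec(S: np.ndarray) -> np.ndarray:
    """Log-Cholesky vectorization of a symmetric positive definite matrix."""
    S = 0.5 * (S + S.T)
    p = S.shape[0]
    jitter = 0.0
    for _ in range(6):
        try:
            L = np.linalg.cholesky(S + jitter * np.eye(p))
            break
        except np.linalg.LinAlgError:
            jitter = max(jitter * 10, 1e-12)
    else:  # pragma: no cover
        raise np.linalg.LinAlgError("matrix not positive definite")
    out = []
    for i in range(p):
        for j in range(i + 1):
            out.append(np.log(L[i, i]) if i == j else L[i, j])
    return np.array(out)


def _vec_to_spd(v: np.ndarray, p: int) -> np.ndarray:
    L = np.zeros((p, p))
    pos = 0
    for i in range(p):
        for j in range(i + 1):
            L[i, j] = np.exp(v[pos]) if i == j else v[pos]
            pos += 1
    return L @ L.T


def _corr_to_angles(C: np.ndarray) -> np.ndarray:
    """Hyperspherical angles of the Cholesky factor of a correlation matrix."""
    q = C.shape[0]
    C = 0.5 * (C + C.T)
    w, U = np.linalg.eigh(C)
    if w.min() < 1e-10:
        C = (U * np.maximum(w, 1e-10)) @ U.T
        d = np.sqrt(np.diag(C))
        C = C / np.outer(d, d)
    L = np.linalg.cholesky(C)
    angles = []
    for i in range(1, q):
        prod = 1.0
        for j in range(i):
            c = np.clip(L[i, j] / max(prod, 1e-300), -1.0, 1.0)
            ang = np.arccos(c)
            angles.append(ang)
            prod *= np.sin(ang)
    return np.array(angles)


def _angles_to_corr(angles: np.ndarray, q: int) -> np.ndarray:
    L = np.zeros((q, q))
    L[0, 0] = 1.0
    pos = 0
    for i in range(1, q):
        prod = 1.0
        for j in range(i):
            ang = angles[pos]
            pos += 1
            L[i, j] = prod * np.cos(ang)
            prod *= np.sin(ang)
        L[i, i] = prod
    C = L @ L.T
    np.fill_diagonal(C, 1.0)
    return C


def _corr_to_uncon(C: np.ndarray) -> np.ndarray:
    ang = np.clip(_corr_to_angles(C) / np.pi, 1e-8, 1 - 1e-8)
    return logit(ang)


def _uncon_to_corr(x: np.ndarray, q: int) -> np.ndarray:
    return _angles_to_corr(np.pi * expit(x), q)


# ---------------------------------------------------------------------------
# covariance construction
# ---------------------------------------------------------------------------

def exp_correlation(h, theta: float):
    """Exponential spatial correlation exp(-h / theta).

    h is a distance (km, >= 0), theta the range parameter (km, > 0).  The
    correlation drops to about 0.05 at separation 3 * theta.
    """
    if not theta > 0:
        raise ValueError("correlation range theta must be > 0")
    h = np.asarray(h, dtype=float)
    if np.any(h < 0):
        raise ValueError("distances must be >= 0")
    out = np.exp(-h / theta)
    return float(out) if out.ndim == 0 else out


def cross_covariance(
    network: StationNetwork,
    psi: ParameterSet,
    pol_a: np.ndarray,
    coords_a: np.ndarray,
    pol_b: np.ndarray,
    coords_b: np.ndarray,
    nugget: bool = False,
) -> np.ndarray:
    """Spatial-latent covariance between two entry lists.

    An *entry* is a (pollutant index, coordinate) pair.  The covariance sums
    the direct component, the LCM components and (if ``nugget``) the
    measurement-error variance on exactly coincident same-pollutant entries.
    """
    pol_a = np.asarray(pol_a, int)
    pol_b = np.asarray(pol_b, int)
    h = network.distance_matrix(coords_a, coords_b)
    C = np.zeros_like(h)
    if psi.has_u:
        same = pol_a[:, None] == pol_b[None, :]
        for i in range(psi.q):
            sel = same & (pol_a[:, None] == i)
            if sel.any():
                C[sel] += (psi.alpha[i] ** 2) * np.exp(-h[sel] / psi.theta[i])
    for comp in psi.lcm:
        amp = comp.lam[pol_a][:, None] * comp.lam[pol_b][None, :]
        C += amp * comp.V[np.ix_(pol_a, pol_b)] * np.exp(-h / comp.range_km)
    if nugget:
        same_site = (h < 1e-9) & (pol_a[:, None] == pol_b[None, :])
        if same_site.any():
            idx = np.nonzero(same_site)
            C[idx] += psi.sigma2_eps[pol_a[idx[0]]]
    return C


def residual_covariance_full(network: StationNetwork, psi: ParameterSet) -> np.ndarray:
    """Per-day covariance of y around Xb + Kz over all stacked entries.

    This is the spatial-latent covariance plus the measurement-error
    nugget, shape (N, N) with entries ordered pollutant-major.
    """
    pol = network.stacked_pollutant_index()
    xy = network.stacked_coords()
    C = cross_covariance(network, psi, pol, xy, pol, xy, nugget=False)
    # nugget on the diagonal only: co-located distinct stations of the same
    # pollutant do NOT share measurement error
    C[np.diag_indices_from(C)] += psi.sigma2_eps[pol]
    return 0.5 * (C + C.T)


def build_residual_covariance(
    network: StationNetwork,
    pattern: np.ndarray,
    psi: ParameterSet,
) -> np.ndarray:
    """Residual covariance restricted to the observed entries of one day.

    ``pattern`` is a boolean mask of length N (stacked pollutant-major)
    selecting the observed entries; at least one entry must be observed.
    """
    pattern = np.asarray(pattern, dtype=bool)
    if pattern.shape != (network.n_total,):
        raise ValueError(f"pattern must have length {network.n_total}")
    if not pattern.any():
        raise ValueError("pattern selects no observed entry")
    C = residual_covariance_full(network, psi)
    return C[np.ix_(pattern, pattern)]


# ---------------------------------------------------------------------------
# stacking helpers
# ---------------------------------------------------------------------------

def stack_covariates(network: StationNetwork, covariates: CovariateField, T: int) -> np.ndarray:
    """Station covariates stacked pollutant-major, shape (N, T, k)."""
    mats = []
    for pol in network.pollutants:
        arr = covariates.station[pol]
        if arr.shape[:2] != (network.n_sites(pol), T):
            raise ValueError(f"covariates for {pol} must be (n_i, {T}, k)")
        mats.append(arr)
    return np.concatenate(mats, axis=0)


def stacked_mean(network: StationNetwork, covariates: CovariateField,
                 psi: ParameterSet, T: int) -> np.ndarray:
    """Fixed-effects mean X beta over stacked entries, shape (N, T)."""
    X = stack_covariates(network, covariates, T)
    pol = network.stacked_pollutant_index()
    B = psi.beta[pol]                       # (N, k)
    return np.einsum("ntk,nk->nt", X, B)


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------

@dataclass
class LatentState:
    """Simulated latent paths: temporal state and per-entry spatial draws."""

    z: np.ndarray                       # (T, p)
    u: Optional[np.ndarray]             # (N, T) direct-component draws (scaled)
    w: Optional[np.ndarray]             # (N, T) LCM draws (scaled, summed over c)
    extra_truth: Optional[np.ndarray] = None   # (n_extra, T) noise-free field


def simulate_dcm(
    psi: ParameterSet,
    network: StationNetwork,
    covariates: CovariateField,
    T: int,
    missing_prob=None,
    seed: int = 0,
    extra_pol: Optional[np.ndarray] = None,
    extra_coords: Optional[np.ndarray] = None,
    extra_covariates: Optional[np.ndarray] = None,
    time_index: Optional[object] = None,
) -> Tuple[ObservationSet, LatentState]:
    """Draw an ObservationSet (and latent paths) from the DCM.

    z(1) is drawn from the stationary distribution of the Markov state;
    u and w are drawn independently each day; missingness is independent
    Bernoulli per (entry, day) with per-pollutant probabilities.

    ``extra_*`` optionally request the noise-free field y - eps at
    additional (pollutant, coordinate) targets, e.g. grid cells, which is
    returned in ``LatentState.extra_truth``.
    """
    psi.validate(strict=False)
    rng = np.random.default_rng(seed)
    q, p = psi.q, psi.p
    N = network.n_total
    pol = network.stacked_pollutant_index()
    xy = network.stacked_coords()

    # temporal state
    P_stat = psi.stationary_state_cov()
    z = np.zeros((T, p))
    L_stat = _safe_cholesky(P_stat)
    L_eta = _safe_cholesky(psi.Sigma_eta)
    z[0] = L_stat @ rng.standard_normal(p)
    for t in range(1, T):
        z[t] = psi.G @ z[t - 1] + L_eta @ rng.standard_normal(p)

    # spatial latents at stations (+ extra targets)
    if extra_coords is not None:
        extra_pol = np.asarray(extra_pol, int)
        extra_coords = np.asarray(extra_coords, float)
        all_pol = np.concatenate([pol, extra_pol])
        all_xy = np.concatenate([xy, extra_coords], axis=0)
    else:
        all_pol, all_xy = pol, xy
    n_all = all_pol.size

    u_draws = np.zeros((n_all, T))
    w_draws = np.zeros((n_all, T))
    if psi.has_u:
        Cu = np.zeros((n_all, n_all))
        h = network.distance_matrix(all_xy, all_xy)
        for i in range(q):
            sel = all_pol == i
            if sel.any():
                Cu[np.ix_(sel, sel)] = (psi.alpha[i] ** 2) * np.exp(
                    -h[np.ix_(sel, sel)] / psi.theta[i]
                )
        Lu = _safe_cholesky(Cu)
        u_draws = Lu @ rng.standard_normal((n_all, T))
    if psi.has_lcm:
        Cw = cross_covariance(
            network, replace_components(psi, u=False), all_pol, all_xy,
            all_pol, all_xy, nugget=False,
        )
        Lw = _safe_cholesky(Cw)
        w_draws = Lw @ rng.standard_normal((n_all, T))

    Kz = psi.K[all_pol] @ z.T                         # (n_all, T)
    X = stack_covariates(network, covariates, T)
    mean_st = np.einsum("ntk,nk->nt", X, psi.beta[pol])
    field_all = Kz + u_draws + w_draws
    y = mean_st + field_all[:N]
    eps = rng.standard_normal((N, T)) * np.sqrt(psi.sigma2_eps[pol])[:, None]
    y = y + eps

    extra_truth = None
    if extra_coords is not None:
        if extra_covariates is None:
            raise ValueError("extra targets need extra_covariates (n_extra, T, k)")
        mean_extra = np.einsum("ntk,nk->nt", np.asarray(extra_covariates, float),
                               psi.beta[extra_pol])
        extra_truth = mean_extra + field_all[N:]

    # missingness
    if missing_prob is not None:
        probs = np.asarray(
            [missing_prob[i] if np.ndim(missing_prob) else missing_prob
             for i in pol], dtype=float,
        )
        mask = rng.random((N, T)) < probs[:, None]
        y = np.where(mask, np.nan, y)

    if time_index is None:
        import pandas as pd
        time_index = pd.RangeIndex(T)
    values = {}
    offset = 0
    for polname in network.pollutants:
        n_i = network.n_sites(polname)
        values[polname] = y[offset:offset + n_i]
        offset += n_i
    obs = ObservationSet(network=network, time_index=time_index, values=values)
    lat = LatentState(z=z, u=u_draws[:N] if psi.has_u else None,
                      w=w_draws[:N] if psi.has_lcm else None,
                      extra_truth=extra_truth)
    return obs, lat


def replace_components(psi: ParameterSet, u: Optional[bool] = None) -> ParameterSet:
    """Copy of psi with the direct component dropped (internal helper)."""
    out = psi.copy()
    if u is False:
        out.alpha = None
        out.theta = None
    return out


def _safe_cholesky(S: np.ndarray) -> np.ndarray:
    S = 0.5 * (S + S.T)
    p = S.shape[0]
    try:
        return np.linalg.cholesky(S)
    except np.linalg.LinAlgError:
        w, U = np.linalg.eigh(S)
        w = np.maximum(w, 0.0)
        return U * np.sqrt(w)


# ---------------------------------------------------------------------------
# dense joint-Gaussian reference path
# ---------------------------------------------------------------------------

def dense_joint(
    obs: ObservationSet,
    covariates: CovariateField,
    psi: ParameterSet,
    init_state_cov: Optional[np.ndarray] = None,
):
    """Mean and covariance of the full observed vector (dense, small n only).

    Stacks the non-missing entries of all days into one Gaussian vector;
    used as the brute-force reference for likelihood, smoothing and kriging
    on small instances.  Returns (mu, Sigma, entry_rows, entry_days) where
    entry_rows/entry_days give, for each element of the stacked vector, the
    stacked station row and the day it came from.
    """
    network = obs.network
    T = obs.T
    Y = obs.stacked()
    mean = stacked_mean(network, covariates, psi, T)
    C_day = residual_covariance_full(network, psi)
    H = psi.K[network.stacked_pollutant_index()]        # (N, p)

    P1 = psi.stationary_state_cov() if init_state_cov is None else init_state_cov
    Vz = _state_path_cov(psi.G, psi.Sigma_eta, P1, T)   # (T, T, p, p)

    rows, days = [], []
    for t in range(T):
        for n in np.nonzero(np.isfinite(Y[:, t]))[0]:
            rows.append(n)
            days.append(t)
    rows = np.array(rows, int)
    days = np.array(days, int)
    m = rows.size
    mu = mean[rows, days]
    Sigma = np.empty((m, m))
    Ht = H[rows]
    for a in range(m):
        za = Vz[days[a], days]                          # (m, p, p)
        Sigma[a] = np.einsum("j,mjk,mk->m", Ht[a], za, Ht)
    same_day = days[:, None] == days[None, :]
    Sigma[same_day] += C_day[rows[:, None], rows[None, :]][same_day]
    return mu, 0.5 * (Sigma + Sigma.T), rows, days


def _state_path_cov(G, Sigma_eta, P1, T) -> np.ndarray:
    """Cov(z_t, z_s) for the whole path, shape (T, T, p, p)."""
    p = G.shape[0]
    Vt = [np.asarray(P1, float)]
    for t in range(1, T):
        Vt.append(G @ Vt[-1] @ G.T + Sigma_eta)
    out = np.zeros((T, T, p, p))
    for s in range(T):
        out[s, s] = Vt[s]
        acc = Vt[s]
        for t in range(s + 1, T):
            acc = G @ acc
            out[t, s] = acc
            out[s, t] = acc.T
    return out


def loglik_exact(
    obs: ObservationSet,
    covariates: CovariateField,
    psi: ParameterSet,
    init_state_cov: Optional[np.ndarray] = None,
) -> float:
    """Exact log-likelihood by dense joint-Gaussian evaluation.

    Marginalizes z, u and w analytically; only feasible for small N*T.
    The result is invariant to station ordering and matches the
    Kalman-filter likelihood on any instance.
    """
    psi.validate(strict=False)
    mu, Sigma, rows, _ = dense_joint(obs, covariates, psi, init_state_cov)
    m = mu.size
    if m > 4000:
        raise ValueError("instance too large for dense evaluation")
    # gather observed values in the same order as dense_joint
    Y = obs.stacked()
    vals = []
    for t in range(obs.T):
        vals.append(Y[np.isfinite(Y[:, t]), t])
    yv = np.concatenate(vals)
    r = yv - mu
    c, low = cho_factor(Sigma + 1e-12 * np.eye(m))
    alpha = cho_solve((c, low), r)
    logdet = 2.0 * np.sum(np.log(np.diag(c)))
    return float(-0.5 * (m * np.log(2.0 * np.pi) + logdet + r @ alpha))


def dense_conditional(
    obs: ObservationSet,
    covariates: CovariateField,
    psi: ParameterSet,
    target_pol: np.ndarray,
    target_coords: np.ndarray,
    target_mean: np.ndarray,
    day: int,
    init_state_cov: Optional[np.ndarray] = None,
):
    """Brute-force conditional mean/cov of the noise-free field at targets.

    Conditions the joint Gaussian of (targets on ``day``, all observed
    data) on the data.  ``target_mean`` is the fixed-effects mean x'beta at
    the targets for that day.  Returns (mean, cov).
    """
    network = obs.network
    mu, Sigma, rows, days = dense_joint(obs, covariates, psi, init_state_cov)
    Y = obs.stacked()
    vals = []
    for t in range(obs.T):
        vals.append(Y[np.isfinite(Y[:, t]), t])
    yv = np.concatenate(vals)

    P1 = psi.stationary_state_cov() if init_state_cov is None else init_state_cov
    Vz = _state_path_cov(psi.G, psi.Sigma_eta, P1, obs.T)
    pol = network.stacked_pollutant_index()
    xy = network.stacked_coords()
    target_pol = np.asarray(target_pol, int)
    target_coords = np.asarray(target_coords, float)
    Ht = psi.K[target_pol]                                # (nt, p)
    Ho = psi.K[pol][rows]                                 # (m, p)

    # cross-covariance target x observed: temporal + same-day spatial
    m = rows.size
    nt = target_pol.size
    C_to = np.empty((nt, m))
    for a in range(nt):
        za = Vz[day, days]
        C_to[a] = np.einsum("j,mjk,mk->m", Ht[a], za, Ho)
    spat = cross_covariance(network, psi, target_pol, target_coords, pol, xy,
                            nugget=False)
    same = days == day
    C_to[:, same] += spat[:, rows[same]]

    # target covariance (no measurement error)
    C_tt = np.einsum("aj,jk,bk->ab", Ht, Vz[day, day], Ht)
    C_tt += cross_covariance(network, psi, target_pol, target_coords,
                             target_pol, target_coords, nugget=False)

    c, low = cho_factor(Sigma + 1e-12 * np.eye(m))
    w = cho_solve((c, low), (yv - mu))
    mean = np.asarray(target_mean, float) + C_to @ w
    cov = C_tt - C_to @ cho_solve((c, low), C_to.T)
    return mean, 0.5 * (cov + cov.T)


def dense_smoothed_state(
    obs: ObservationSet,
    covariates: CovariateField,
    psi: ParameterSet,
    init_state_cov: Optional[np.ndarray] = None,
):
    """Brute-force E[z_t | Y] and Var[z_t | Y] for every day (small n only)."""
    network = obs.network
    mu, Sigma, rows, days = dense_joint(obs, covariates, psi, init_state_cov)
    Y = obs.stacked()
    vals = []
    for t in range(obs.T):
        vals.append(Y[np.isfinite(Y[:, t]), t])
    yv = np.concatenate(vals)
    P1 = psi.stationary_state_cov() if init_state_cov is None else init_state_cov
    Vz = _state_path_cov(psi.G, psi.Sigma_eta, P1, obs.T)
    Ho = psi.K[network.stacked_pollutant_index()][rows]
    c, low = cho_factor(Sigma + 1e-12 * np.eye(mu.size))
    w = cho_solve((c, low), (yv - mu))
    T, p = obs.T, psi.p
    zs = np.zeros((T, p))
    Ps = np.zeros((T, p, p))
    for t in range(T):
        # Cov(z_t, y_obs_m) = Vz[t, day_m] @ Ho[m]
        C_zy = np.einsum("mjk,mk->jm", Vz[t, days], Ho)
        zs[t] = C_zy @ w
        Ps[t] = Vz[t, t] - C_zy @ cho_solve((c, low), C_zy.T)
    return zs, Ps
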