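"""Plug-in dynamic kriging over a prediction grid, with block aggregation.

The per-day prediction at a target (pollutant i, location s*) is the exact
conditional expectation of the noise-free field

    y*_i(s*, t) = x'(s*,t) beta + [K z(t)]_i + alpha_i u_i + sum_j lam w_i^j

given *all* observed data, evaluated at the plugged-in parameter
estimates.  Writing B_t = C_cross Sigma_t^{-1} (the day-t simple-kriging
weights on the residuals) and M_t = K_i - B_t H_t, the smoother identity
E[v_t|Y] = Sigma_t^{-1}(y_t - X_t b - H_t zhat_t) gives

    mean  = x'b + K_i zhat^T(t) + B_t (y_t - X_t b - H_t zhat^T(t))
    var   = C** - B_t C_cross' + M_t P^T(t) M_t'

which accounts for the latent-state uncertainty and its correlation with
the spatial interpolation error, and excludes the measurement-error
nugget.  At an observed station with zero nugget the prediction
interpolates the observation with zero variance; far from all stations it
collapses to x'b + K zhat with the full prior spatial variance.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Dict, List, Optional, Sequence

import numpy as np

from .datamodel import CovariateField, GridSpec, ObservationSet, TransformRecord
from .dcm_core import ParameterSet, cross_covariance, residual_covariance_full
from .estimation import FitResult, SmootherOutput


@dataclass
class DynamicMap:
    """Per-pollutant gridded daily predictions with uncertainty.

    ``mean``/``sd`` have shape (T, n_cells) on the transformed (model)
    scale; ``transform`` back-transforms to concentration units.
    """

    pollutant: str
    grid: GridSpec
    time_index: object
    mean: np.ndarray
    sd: np.ndarray
    transform: Optional[TransformRecord] = None

    def __post_init__(self) -> None:
        if np.nanmin(self.sd) < -1e-12:
            raise ValueError("prediction standard deviations must be >= 0")
        self.sd = np.clip(self.sd, 0.0, None)

    @property
    def T(self) -> int:
        return self.mean.shape[0]

    def values_original(self, mode: str = "lognormal") -> np.ndarray:
        """Back-transformed predictions on the original concentration scale.

        ``mode='lognormal'`` applies the lognormal mean correction
        exp(mu + sigma^2/2) for log-transformed variables (the default);
        ``mode='naive'`` is the plain inverse transform of the mean.
        """
        if self.transform is None:
            return self.mean.copy()
        if mode == "lognormal":
            return self.transform.invert_mean(self.pollutant, self.mean, self.sd)
        if mode == "naive":
            return self.transform.invert(self.pollutant, self.mean)
        raise ValueError(f"unknown back-transform mode {mode!r}")


def _krige_points(
    obs: ObservationSet,
    covariates: CovariateField,
    psi: ParameterSet,
    sm: SmootherOutput,
    target_pol: np.ndarray,
    target_coords: np.ndarray,
    target_mean: np.ndarray,
    days: Optional[Sequence[int]] = None,
):
    """Exact conditional mean/variance of the noise-free field at targets.

    ``target_mean`` is the fixed-effects mean x'beta, shape (n_targets, T).
    Returns (pred, var), each (n_targets, T_sel) over the requested days.
    """
    network = obs.network
    T = obs.T
    if days is None:
        days = range(T)
    days = list(days)
    target_pol = np.asarray(target_pol, int)
    target_coords = np.asarray(target_coords, float)
    nt = target_pol.size

    Y = obs.stacked()
    pol = network.stacked_pollutant_index()
    xy = network.stacked_coords()
    from .dcm_core import stack_covariates
    X = stack_covariates(network, covariates, T)
    mean_st = np.einsum("ntk,nk->nt", X, psi.beta[pol])
    H = psi.K[pol]
    Ktar = psi.K[target_pol]
    Sigma = residual_covariance_full(network, psi)
    C_cr_full = cross_covariance(network, psi, target_pol, target_coords, pol, xy)

    # prior spatial-latent variance at the targets (h = 0)
    prior_var = np.zeros(nt)
    if psi.has_u:
        prior_var += psi.alpha[target_pol] ** 2
    for comp in psi.lcm:
        prior_var += comp.lam[target_pol] ** 2

    pred = np.empty((nt, len(days)))
    var = np.empty((nt, len(days)))
    for jt, t in enumerate(days):
        o = np.isfinite(Y[:, t])
        zs = sm.z_smooth[t]
        Ps = sm.P_smooth[t]
        base = target_mean[:, t] + Ktar @ zs
        if not o.any():
            pred[:, jt] = base
            var[:, jt] = prior_var + np.einsum("aj,jk,ak->a", Ktar, Ps, Ktar)
            continue
        So = Sigma[np.ix_(o, o)]
        C_cr = C_cr_full[:, o]
        r = Y[o, t] - mean_st[o, t] - H[o] @ zs
        L = np.linalg.cholesky(So)
        B = np.linalg.solve(L.T, np.linalg.solve(L, C_cr.T)).T     # (nt, n_obs)
        pred[:, jt] = base + B @ r
        M = Ktar - B @ H[o]
        var[:, jt] = (
            prior_var
            - np.einsum("am,am->a", B, C_cr)
            + np.einsum("aj,jk,ak->a", M, Ps, M)
        )
    return pred, np.clip(var, 0.0, None)


def krige(
    fit: FitResult,
    grid_covariates: CovariateField,
    grid: GridSpec,
    days: Optional[Sequence[int]] = None,
    pollutants: Optional[Sequence[str]] = None,
    transform: Optional[TransformRecord] = None,
) -> Dict[str, DynamicMap]:
    """Dynamic kriging maps for each pollutant over a prediction grid.

    ``grid_covariates.grid`` must hold the covariates at every grid cell
    (shape (n_cells, T, k) or (n_cells, k) if time invariant); cells with
    missing covariates are masked (NaN) in the output.
    """
    obs, psi, sm = fit.obs, fit.psi, fit.smoother
    network = obs.network
    if pollutants is None:
        pollutants = network.pollutants
    T = obs.T
    if days is None:
        days = list(range(T))
    centres = grid.cell_centres()
    ncell = centres.shape[0]
    if transform is None:
        transform = obs.transform

    out: Dict[str, DynamicMap] = {}
    for polname in pollutants:
        ip = network.pollutants.index(polname)
        gx = grid_covariates.grid
        if gx is None:
            raise ValueError("grid covariates are required for kriging")
        if gx.ndim == 2:
            Xg = np.broadcast_to(gx[:, None, :], (ncell, T, gx.shape[1]))
        else:
            Xg = gx
        bad = ~np.isfinite(Xg).all(axis=(1, 2))
        mean_t = np.einsum("ctk,k->ct", np.where(np.isfinite(Xg), Xg, 0.0),
                           psi.beta[ip])
        pred, var = _krige_points(
            obs, fit.covariates, psi, sm,
            np.full(ncell, ip), centres, mean_t, days=days,
        )
        pred = pred.T.copy()        # (T_sel, ncell)
        sd = np.sqrt(var).T.copy()
        if bad.any():
            pred[:, bad] = np.nan
            sd[:, bad] = np.nan
        ti = (obs.time_index[list(days)]
              if hasattr(obs.time_index, "__getitem__") else list(days))
        out[polname] = DynamicMap(
            pollutant=polname, grid=grid, time_index=ti,
            mean=pred, sd=sd, transform=transform,
        )
    return out


def block_aggregate(
    field: Callable[[np.ndarray], np.ndarray],
    tessellation: GridSpec,
    mode: str = "centre",
    k: int = 4,
) -> np.ndarray:
    """Block (change-of-support) values of a point-level field.

    ``field`` evaluates the point field at an (m, 2) coordinate array.
    ``mode='centre'`` uses the pixel-centre approximation, valid when
    blocks are small relative to the spatial correlation range;
    ``mode='subsample'`` averages a k x k regular sub-sampling of each
    block.  Returns one value per masked block.
    """
    centres = tessellation.cell_centres()
    if mode == "centre":
        return np.asarray(field(centres), dtype=float)
    if mode != "subsample":
        raise ValueError(f"unknown mode {mode!r}")
    dx = float(np.diff(tessellation.lons).mean()) if tessellation.lons.size > 1 else 1.0
    dy = float(np.diff(tessellation.lats).mean()) if tessellation.lats.size > 1 else dx
    offs = (np.arange(k) + 0.5) / k - 0.5
    out = np.zeros(centres.shape[0])
    pts = []
    for ox in offs:
        for oy in offs:
            pts.append(centres + np.array([ox * dx, oy * dy]))
    pts = np.concatenate(pts, axis=0)
    vals = np.asarray(field(pts), dtype=float).reshape(k * k, -1)
    return vals.mean(axis=0)


def temporal_average_map(
    dmap: DynamicMap,
    day_set: Sequence[int],
    mode: str = "lognormal",
) -> np.ndarray:
    """Per-cell temporal average of back-transformed daily predictions.

    ``day_set`` indexes days of the map (e.g. a month or the whole year);
    the average is the arithmetic mean of the original-scale predictions,
    returned as one value per grid cell.
    """
    day_set = list(day_set)
    if len(day_set) == 0:
        raise ValueError("day_set must be non-empty")
    if min(day_set) < 0 or max(day_set) >= dmap.T:
        raise ValueError("day_set outside the map's days")
    vals = dmap.values_original(mode=mode)
    return vals[day_set].mean(axis=0)
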