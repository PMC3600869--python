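import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize

from airdcm import (
    CovariateField,
    LCMComponent,
    ModelConfig,
    ObservationSet,
    ParameterSet,
    StationNetwork,
    em_fit,
    fisher_information,
    kalman_smooth,
    loso_crossval,
    simulate_dcm,
)
from airdcm.dcm_core import dense_joint, stack_covariates
from airdcm.estimation import beta_information, kalman_loglik


def _scalar_model(ns=3, T=30, seed=2, k=2):
    rng = np.random.default_rng(seed)
    net = StationNetwork(
        pollutants=["A"],
        site_ids={"A": [f"s{i}" for i in range(ns)]},
        coords={"A": rng.uniform(0, 100, (ns, 2))},
        distance="planar",
    )
    cov = CovariateField(names=[f"x{j}" for j in range(k)],
                         station={"A": rng.standard_normal((ns, T, k))})
    psi = ParameterSet(
        beta=np.array([[0.5, -0.3][:k]]), K=np.ones((1, 1)),
        G=np.array([[0.7]]), Sigma_eta=np.array([[0.3]]),
        sigma2_eps=np.array([0.2]),
    )
    return net, cov, psi


class TestSmoother:
    def test_single_day_equals_conditional_normal(self):
        # T=1: posterior of z given y is the Gaussian conditional update
        net, cov, psi = _scalar_model(ns=2, T=1, k=1)
        obs, _ = simulate_dcm(psi, net, cov, T=1, seed=4)
        sm = kalman_smooth(obs, cov, psi)
        P0 = psi.stationary_state_cov()[0, 0]
        H = np.ones(2)
        y = obs.stacked()[:, 0]
        mean = np.einsum("ntk,k->nt", cov.station["A"], psi.beta[0])[:, 0]
        S = P0 * np.outer(H, H) + np.diag(psi.sigma2_eps[[0, 0]])
        gain = P0 * H @ np.linalg.inv(S)
        z_post = gain @ (y - mean)
        P_post = P0 - gain @ (P0 * H)
        assert sm.z_smooth[0, 0] == pytest.approx(z_post, abs=1e-10)
        assert sm.P_smooth[0, 0, 0] == pytest.approx(P_post, abs=1e-10)

    def test_all_missing_day_keeps_prior_variance(self):
        net, cov, psi = _scalar_model(ns=3, T=7, k=1)
        obs, _ = simulate_dcm(psi, net, cov, T=7, seed=5)
        obs.values["A"][:, 3] = np.nan
        sm = kalman_smooth(obs, cov, psi)
        # an information-free day cannot have smaller smoothed variance
        # than its observed neighbours
        assert sm.P_smooth[3, 0, 0] >= sm.P_smooth[2, 0, 0] - 1e-12
        assert sm.P_smooth[3, 0, 0] >= sm.P_smooth[4, 0, 0] - 1e-12

    def test_rejects_non_psd_innovation_covariance(self):
        net, cov, psi = _scalar_model(T=4, k=1)
        obs, _ = simulate_dcm(psi, net, cov, T=4, seed=6)
        psi_bad = psi.copy()
        psi_bad.Sigma_eta = np.array([[-0.1]])
        with pytest.raises(ValueError):
            kalman_smooth(obs, cov, psi_bad)


class TestEMFit:
    def test_z_only_model_matches_direct_mle(self):
        # no spatial latents, no missing: EM must land on the global MLE
        net, cov, psi_true = _scalar_model(ns=3, T=40, seed=2, k=2)
        obs, _ = simulate_dcm(psi_true, net, cov, T=40, seed=4)
        config = ModelConfig(p=1, include_u=False, include_lcm=False)
        res = em_fit(obs, cov, config, tol=1e-12, max_iter=3000)
        P1 = res.init_state_cov
        ll_em = kalman_loglik(obs, cov, res.psi, init_state_cov=P1)
        x0 = res.psi.pack_unconstrained()
        neg = lambda x: -kalman_loglik(obs, cov, res.psi.unpack_unconstrained(x),
                                       init_state_cov=P1)
        direct = minimize(neg, x0, method="Nelder-Mead",
                          options={"maxiter": 4000, "fatol": 1e-12, "xatol": 1e-10})
        assert -direct.fun - ll_em <= 1e-6
        # and beta is the GLS fixed point: gradient of the loglik in beta ~ 0
        g = np.zeros(2)
        for j in range(2):
            e = np.zeros_like(x0)
            e[j] = 1e-5
            g[j] = (neg(x0 + e) - neg(x0 - e)) / 2e-5
        assert np.abs(g).max() < 1e-3

    def test_monotone_trace_with_spatial_block(self, fit120):
        d = np.diff(fit120.loglik_trace)
        assert d.min() >= -1e-6 * np.abs(fit120.loglik_trace[:-1]).max()

    def test_nonconvergence_flagged_best_iterate_returned(self):
        net, cov, psi_true = _scalar_model(ns=3, T=20, k=1)
        obs, _ = simulate_dcm(psi_true, net, cov, T=20, seed=8)
        config = ModelConfig(p=1, include_u=False, include_lcm=False)
        with pytest.warns(UserWarning, match="did not converge"):
            res = em_fit(obs, cov, config, tol=1e-14, max_iter=2)
        assert not res.converged
        assert res.psi is not None and np.isfinite(res.loglik)


class TestFisherInformation:
    def test_scalar_mean_information_closed_form(self):
        # y = beta + eps with variance sigma2: information n / sigma2
        rng = np.random.default_rng(3)
        ns, T, s2 = 4, 25, 0.3
        net = StationNetwork(
            pollutants=["A"], site_ids={"A": [f"s{i}" for i in range(ns)]},
            coords={"A": rng.uniform(0, 100, (ns, 2))}, distance="planar",
        )
        cov = CovariateField(names=["one"], station={"A": np.ones((ns, T, 1))})
        psi = ParameterSet(
            beta=np.array([[0.4]]), K=np.zeros((1, 1)), G=np.array([[0.5]]),
            Sigma_eta=np.array([[0.1]]), sigma2_eps=np.array([s2]),
        )
        obs, _ = simulate_dcm(psi, net, cov, T=T, seed=5)
        with pytest.warns(UserWarning):   # K = 0 leaves the state unidentified
            info = fisher_information(psi, obs, cov)
        assert info.matrix[0, 0] == pytest.approx(ns * T / s2, rel=1e-4)
        np.testing.assert_allclose(info.matrix, info.matrix.T, atol=1e-8)

    def test_beta_block_equals_dense_gls_information(self, micro):
        obs, cov, psi = micro.obs, micro.covariates, micro.psi_true
        Ib = beta_information(psi, obs, cov)
        mu, Sigma, rows, days = dense_joint(obs, cov, psi)
        X = stack_covariates(obs.network, cov, obs.T)
        pol = obs.network.stacked_pollutant_index()
        k, q, m = X.shape[2], obs.network.q, rows.size
        R = np.zeros((m, q * k))
        for a in range(m):
            i = pol[rows[a]]
            R[a, i * k:(i + 1) * k] = X[rows[a], days[a]]
        Id = R.T @ np.linalg.solve(Sigma, R)
        np.testing.assert_allclose(Ib, Id, atol=1e-10)


class TestLOSO:
    def test_duplicate_station_zero_nugget_gives_tiny_residual(self):
        # a perfect co-located neighbour with (almost) no measurement noise
        xy = np.array([[10.0, 10.0], [10.0, 10.0], [80.0, 80.0]])
        net = StationNetwork(
            pollutants=["A"], site_ids={"A": ["s1", "s2", "s3"]},
            coords={"A": xy}, distance="planar",
        )
        T = 20
        cov = CovariateField(names=["x"], station={"A": np.zeros((3, T, 1))})
        psi = ParameterSet(
            beta=np.zeros((1, 1)), K=np.ones((1, 1)), G=np.array([[0.5]]),
            Sigma_eta=np.array([[0.2]]), sigma2_eps=np.array([1e-8]),
            lcm=[LCMComponent(lam=np.array([1.0]), V=np.eye(1), range_km=50.0)],
        )
        obs, _ = simulate_dcm(psi, net, cov, T=T, seed=7)
        cv = loso_crossval(obs, cov, psi)
        # held-out s1 is predicted through its duplicate s2
        assert np.nanmax(np.abs(cv.residual["A"][0])) < 1e-3

    def test_single_station_pollutant_flagged(self):
        rng = np.random.default_rng(4)
        net = StationNetwork(
            pollutants=["A", "B"],
            site_ids={"A": ["a1", "a2"], "B": ["b1"]},
            coords={"A": rng.uniform(0, 50, (2, 2)),
                    "B": rng.uniform(0, 50, (1, 2))},
            distance="planar",
        )
        T = 15
        cov = CovariateField(names=["x"],
                             station={p: np.zeros((net.n_sites(p), T, 1))
                                      for p in net.pollutants})
        V = np.array([[1.0, 0.5], [0.5, 1.0]])
        psi = ParameterSet(
            beta=np.zeros((2, 1)), K=np.eye(2), G=0.4 * np.eye(2),
            Sigma_eta=0.1 * np.eye(2), sigma2_eps=np.array([0.1, 0.1]),
            lcm=[LCMComponent(lam=np.array([0.8, 0.8]), V=V, range_km=60.0)],
        )
        obs, _ = simulate_dcm(psi, net, cov, T=T, seed=9)
        cv = loso_crossval(obs, cov, psi)
        assert cv.single_station_pollutants == ["B"]
        assert np.isfinite(cv.residual["B"]).any()

    def test_cmse_exceeds_insample_mse(self, loso120):
        for pol in loso120.cmse:
            assert loso120.cmse[pol] > loso120.insample_mse[pol]
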