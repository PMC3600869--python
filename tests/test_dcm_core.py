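import numpy as np
import pandas as pd
import pytest

from airdcm import (
    CovariateField,
    LCMComponent,
    ObservationSet,
    ParameterSet,
    StationNetwork,
    build_residual_covariance,
    exp_correlation,
    loglik_exact,
    simulate_dcm,
)
from airdcm.dcm_core import residual_covariance_full, stacked_mean


def _network(counts, seed=0, pollutants=None):
    rng = np.random.default_rng(seed)
    pollutants = pollutants or [f"p{i}" for i in range(len(counts))]
    return StationNetwork(
        pollutants=list(pollutants),
        site_ids={p: [f"{p}s{j}" for j in range(counts[i])]
                  for i, p in enumerate(pollutants)},
        coords={p: rng.uniform(0, 200, (counts[i], 2))
                for i, p in enumerate(pollutants)},
        distance="planar",
    )


def _random_psi(q, rng, include_u=True, c=1, k=1):
    A = rng.standard_normal((q, q))
    V = A @ A.T + 0.1 * np.eye(q)
    d = np.sqrt(np.diag(V))
    V = V / np.outer(d, d)
    return ParameterSet(
        beta=np.zeros((q, k)),
        K=np.eye(q),
        G=0.5 * np.eye(q),
        Sigma_eta=np.eye(q),
        sigma2_eps=rng.uniform(0.01, 1.0, q),
        alpha=rng.uniform(0.1, 2.0, q) if include_u else None,
        theta=rng.uniform(5, 300, q) if include_u else None,
        lcm=[LCMComponent(lam=rng.uniform(0.1, 2.0, q), V=V,
                          range_km=float(rng.uniform(5, 300)))
             for _ in range(c)],
    )


class TestExpCorrelation:
    def test_unit_at_zero_distance(self):
        assert exp_correlation(0.0, 37.0) == 1.0

    def test_value_at_three_ranges(self):
        # correlation between points 3 ranges apart is about 0.05
        assert round(exp_correlation(3 * 80.0, 80.0), 2) == 0.05

    def test_closed_form_at_one_range(self):
        assert exp_correlation(50.0, 50.0) == pytest.approx(np.exp(-1.0))

    def test_strictly_decreasing_in_distance(self):
        h = np.linspace(0, 500, 100)
        v = exp_correlation(h, 60.0)
        assert np.all(np.diff(v) < 0)

    def test_invalid_range_rejected(self):
        with pytest.raises(ValueError):
            exp_correlation(1.0, 0.0)
        with pytest.raises(ValueError):
            exp_correlation(-1.0, 10.0)


class TestResidualCovariance:
    def test_single_site_direct_only_variance(self):
        net = _network([1])
        psi = ParameterSet(
            beta=np.zeros((1, 1)), K=np.eye(1), G=0.5 * np.eye(1),
            Sigma_eta=np.eye(1), sigma2_eps=np.array([0.3]),
            alpha=np.array([0.9]), theta=np.array([40.0]),
        )
        C = build_residual_covariance(net, np.array([True]), psi)
        assert C[0, 0] == pytest.approx(0.9 ** 2 + 0.3)

    def test_colocated_cross_pollutant_lcm_covariance(self):
        xy = np.array([[10.0, 20.0]])
        net = StationNetwork(
            pollutants=["a", "b"],
            site_ids={"a": ["s"], "b": ["s"]},
            coords={"a": xy.copy(), "b": xy.copy()},
            distance="planar",
        )
        lam = np.array([0.7, 0.5])
        V = np.array([[1.0, 0.6], [0.6, 1.0]])
        psi = ParameterSet(
            beta=np.zeros((2, 1)), K=np.eye(2), G=0.5 * np.eye(2),
            Sigma_eta=np.eye(2), sigma2_eps=np.array([0.1, 0.1]),
            lcm=[LCMComponent(lam=lam, V=V, range_km=50.0)],
        )
        C = build_residual_covariance(net, np.ones(2, bool), psi)
        assert C[0, 1] == pytest.approx(lam[0] * lam[1] * V[0, 1])

    def test_pattern_validation(self):
        net = _network([2])
        psi = _random_psi(1, np.random.default_rng(0))
        with pytest.raises(ValueError):
            build_residual_covariance(net, np.zeros(2, bool), psi)
        with pytest.raises(ValueError):
            build_residual_covariance(net, np.ones(3, bool), psi)

    def test_symmetric_psd_under_fuzzing(self):
        # 1000 random configurations: symmetric, eigenvalues >= -1e-10
        rng = np.random.default_rng(42)
        for _ in range(1000):
            q = int(rng.integers(1, 4))
            counts = rng.integers(1, 4, q)
            net = _network(counts, seed=int(rng.integers(1 << 31)))
            psi = _random_psi(q, rng, include_u=bool(rng.integers(2)),
                              c=int(rng.integers(1, 3)))
            C = residual_covariance_full(net, psi)
            assert np.allclose(C, C.T)
            assert np.linalg.eigvalsh(C).min() >= -1e-10


class TestSimulation:
    def _setup(self, q=2, counts=(2, 2), T=6, seed=0):
        net = _network(counts, seed=seed)
        rng = np.random.default_rng(seed + 1)
        cov = CovariateField(
            names=["x1"],
            station={p: rng.standard_normal((net.n_sites(p), T, 1))
                     for p in net.pollutants},
        )
        return net, cov

    def test_zero_variances_reduce_to_fixed_effects(self):
        net, cov = self._setup()
        psi = ParameterSet(
            beta=np.array([[0.7], [-0.4]]), K=np.eye(2), G=0.5 * np.eye(2),
            Sigma_eta=np.zeros((2, 2)), sigma2_eps=np.zeros(2),
            lcm=[LCMComponent(lam=np.zeros(2), V=np.eye(2), range_km=50.0)],
        )
        obs, lat = simulate_dcm(psi, net, cov, T=6, seed=3)
        expect = stacked_mean(net, cov, psi, 6)
        np.testing.assert_allclose(obs.stacked(), expect, atol=1e-12)
        np.testing.assert_allclose(lat.z, 0.0, atol=1e-12)

    def test_same_seed_reproduces_identically(self):
        net, cov = self._setup()
        psi = _random_psi(2, np.random.default_rng(5), k=1)
        a, _ = simulate_dcm(psi, net, cov, T=6, missing_prob=0.2, seed=11)
        b, _ = simulate_dcm(psi, net, cov, T=6, missing_prob=0.2, seed=11)
        for p in net.pollutants:
            np.testing.assert_array_equal(a.values[p], b.values[p])

    def test_unstable_transition_rejected(self):
        net, cov = self._setup()
        psi = _random_psi(2, np.random.default_rng(6), k=1)
        psi.G = 1.05 * np.eye(2)
        with pytest.raises(ValueError, match="stable"):
            simulate_dcm(psi, net, cov, T=4, seed=0)

    def test_sample_covariance_matches_analytic(self):
        # long-run per-day covariance across entries: K P K' + spatial + nugget
        net, _ = self._setup(counts=(2, 2))
        T = 5000
        cov = CovariateField(
            names=["x1"],
            station={p: np.zeros((net.n_sites(p), T, 1)) for p in net.pollutants},
        )
        psi = _random_psi(2, np.random.default_rng(7), include_u=False, k=1)
        psi.G = np.diag([0.6, 0.4])
        psi.Sigma_eta = np.diag([0.2, 0.3])
        obs, _ = simulate_dcm(psi, net, cov, T=T, seed=9)
        S_emp = np.cov(obs.stacked())
        H = psi.K[net.stacked_pollutant_index()]
        S_an = H @ psi.stationary_state_cov() @ H.T + residual_covariance_full(net, psi)
        mc_se = np.sqrt((S_an ** 2 + np.outer(np.diag(S_an), np.diag(S_an))) / T)
        assert np.all(np.abs(S_emp - S_an) <= 3 * mc_se)


class TestExactLikelihood:
    def test_single_observation_closed_form(self):
        net = _network([1])
        cov = CovariateField(names=["x"], station={"p0": np.full((1, 1, 1), 2.0)})
        psi = ParameterSet(
            beta=np.array([[0.5]]), K=np.zeros((1, 1)), G=np.array([[0.5]]),
            Sigma_eta=np.array([[1e-12]]), sigma2_eps=np.array([0.4]),
        )
        y = 1.7
        obs = ObservationSet(network=net, time_index=pd.RangeIndex(1),
                             values={"p0": np.array([[y]])})
        ll = loglik_exact(obs, cov, psi)
        expect = -0.5 * (np.log(2 * np.pi * 0.4) + (y - 1.0) ** 2 / 0.4)
        assert ll == pytest.approx(expect, abs=1e-8)

    def test_station_order_invariance(self, micro):
        obs, cov, psi = micro.obs, micro.covariates, micro.psi_true
        ll = loglik_exact(obs, cov, psi)
        # reverse the station order of pollutant A
        net = obs.network
        net2 = StationNetwork(
            pollutants=list(net.pollutants),
            site_ids={"A": net.site_ids["A"][::-1], "B": list(net.site_ids["B"])},
            coords={"A": net.coords["A"][::-1].copy(), "B": net.coords["B"].copy()},
            distance="planar",
        )
        obs2 = ObservationSet(network=net2, time_index=obs.time_index,
                              values={"A": obs.values["A"][::-1].copy(),
                                      "B": obs.values["B"].copy()})
        cov2 = CovariateField(names=cov.names,
                              station={"A": cov.station["A"][::-1].copy(),
                                       "B": cov.station["B"].copy()})
        assert loglik_exact(obs2, cov2, psi) == pytest.approx(ll, abs=1e-10)


def test_stationary_cov_solves_lyapunov_identity():
    psi = _random_psi(3, np.random.default_rng(12), k=1)
    psi.G = np.array([[0.5, 0.2, 0.0], [0.0, 0.4, 0.1], [0.1, 0.0, 0.3]])
    P = psi.stationary_state_cov()
    np.testing.assert_allclose(P, psi.G @ P @ psi.G.T + psi.Sigma_eta, atol=1e-10)


def test_unconstrained_packing_round_trip():
    psi = _random_psi(3, np.random.default_rng(8), include_u=True, c=2, k=2)
    psi.beta = np.random.default_rng(9).standard_normal((3, 2))
    x = psi.pack_unconstrained()
    back = psi.unpack_unconstrained(x)
    np.testing.assert_allclose(back.beta, psi.beta, atol=1e-10)
    np.testing.assert_allclose(back.G, psi.G, atol=1e-10)
    np.testing.assert_allclose(back.Sigma_eta, psi.Sigma_eta, atol=1e-8)
    np.testing.assert_allclose(back.alpha, psi.alpha, rtol=1e-8)
    np.testing.assert_allclose(back.theta, psi.theta, rtol=1e-8)
    for a, b in zip(back.lcm, psi.lcm):
        np.testing.assert_allclose(a.lam, b.lam, rtol=1e-8)
        np.testing.assert_allclose(a.V, b.V, atol=1e-7)
        assert a.range_km == pytest.approx(b.range_km, rel=1e-8)
    np.testing.assert_allclose(back.sigma2_eps, psi.sigma2_eps, rtol=1e-8)
    assert len(psi.pack_names()) == x.size
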