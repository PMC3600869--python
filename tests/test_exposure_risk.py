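import itertools

import numpy as np
import pytest
from scipy.stats import norm

from airdcm import (
    GridSpec,
    PopulationRaster,
    aggregated_risk_series,
    cumulative_exposure,
    daily_exceedance_population,
    day_count_distribution,
    exceedance_probability,
    exposure_index,
    fit_residual_cdf,
)
from airdcm.datamodel import TransformRecord
from airdcm.mapping import DynamicMap


def _raster(counts):
    n = len(counts)
    grid = GridSpec(lons=np.arange(n, dtype=float), lats=np.array([0.0]))
    return PopulationRaster(grid=grid, counts=np.asarray(counts, float))


class TestExposure:
    def test_population_weighted_region_average(self):
        summ = exposure_index(np.array([10.0, 20.0]), _raster([100, 300]))
        assert summ.region_average == pytest.approx(17.5)

    def test_uniform_population_gives_unweighted_mean(self):
        vals = np.array([3.0, 5.0, 10.0])
        summ = exposure_index(vals, _raster([7, 7, 7]))
        assert summ.region_average == pytest.approx(vals.mean())

    def test_zero_population_blocks_ignored(self):
        summ = exposure_index(np.array([10.0, 999.0]), _raster([50, 0]))
        assert summ.region_average == pytest.approx(10.0)

    def test_grid_mismatch_rejected(self):
        with pytest.raises(ValueError):
            exposure_index(np.array([1.0, 2.0, 3.0]), _raster([10, 10]))

    def test_block_reindexing_invariance(self):
        vals = np.array([4.0, 9.0, 1.0, 6.0])
        pop = [10, 40, 25, 5]
        perm = [2, 0, 3, 1]
        a = exposure_index(vals, _raster(pop)).region_average
        b = exposure_index(vals[perm], _raster([pop[i] for i in perm])).region_average
        assert a == pytest.approx(b)

    def test_cumulative_distribution_step_values(self):
        summ = cumulative_exposure(np.array([10.0, 20.0]), _raster([100, 100]))
        assert summ.cdf(15.0) == pytest.approx(0.5)
        assert summ.cdf(9.0) == pytest.approx(0.0)
        assert summ.cdf(20.0) == pytest.approx(1.0)   # right-continuous at max

    def test_mean_of_distribution_equals_region_average(self):
        rng = np.random.default_rng(3)
        vals = rng.uniform(5, 50, 40)
        pop = rng.uniform(0, 1000, 40)
        summ = cumulative_exposure(vals, _raster(pop))
        mean_from_cdf = float(np.sum(summ.concentrations * summ.weights)
                              / summ.weights.sum())
        assert mean_from_cdf == pytest.approx(summ.region_average, abs=1e-9)

    def test_zero_total_population_rejected(self):
        with pytest.raises(ValueError):
            exposure_index(np.array([1.0]), _raster([0]))


class TestDailyExceedancePopulation:
    def _map(self, vals):
        grid = GridSpec(lons=np.arange(vals.shape[1], dtype=float),
                        lats=np.array([0.0]))
        return DynamicMap(pollutant="PM10", grid=grid,
                          time_index=list(range(vals.shape[0])),
                          mean=vals, sd=np.zeros_like(vals))

    def test_counts_population_above_threshold(self):
        pop = _raster([100, 500, 250])
        vals = np.array([[10.0, 60.0, 10.0],     # only middle block above
                         [10.0, 10.0, 10.0],     # none
                         [60.0, 60.0, 60.0]])    # all
        counts = daily_exceedance_population(self._map(vals), pop, 50.0)
        np.testing.assert_allclose(counts, [500.0, 0.0, 850.0])


class TestResidualCdf:
    def test_symmetry_at_zero(self):
        f = fit_residual_cdf(np.concatenate([np.full(30, -1.0), np.full(30, 1.0)]))
        assert f(0.0) == pytest.approx(0.5)

    def test_monotone_with_limits(self):
        rng = np.random.default_rng(2)
        f = fit_residual_cdf(rng.standard_normal(200))
        grid = np.linspace(-8, 8, 1000)
        vals = f(grid)
        assert np.all(np.diff(vals) >= 0)
        assert vals[0] < 1e-6 and vals[-1] > 1 - 1e-6

    def test_glivenko_cantelli_against_normal(self):
        rng = np.random.default_rng(7)
        f = fit_residual_cdf(rng.standard_normal(5000))
        grid = np.linspace(-4, 4, 400)
        assert np.max(np.abs(f(grid) - norm.cdf(grid))) < 0.03

    def test_too_few_residuals_rejected(self):
        with pytest.raises(ValueError):
            fit_residual_cdf(np.ones(10) + np.arange(10))


class TestExceedanceProbability:
    def _map(self, mean, sd, transform=None):
        grid = GridSpec(lons=np.arange(mean.shape[1], dtype=float),
                        lats=np.array([0.0]))
        return DynamicMap(pollutant="PM10", grid=grid,
                          time_index=list(range(mean.shape[0])),
                          mean=mean, sd=sd, transform=transform)

    def test_half_when_prediction_at_threshold(self):
        tr = TransformRecord(log_applied={"PM10": True},
                             centers={"PM10": np.log(16.6)}, scales={"PM10": 0.5})
        L = 50.0
        L_t = tr.apply("PM10", L)
        dm = self._map(np.full((2, 3), L_t), np.full((2, 3), 0.7), transform=tr)
        pi = exceedance_probability(dm, L, norm.cdf)
        np.testing.assert_allclose(pi, 0.5, atol=1e-12)

    def test_monotone_nonincreasing_in_threshold(self):
        tr = TransformRecord(log_applied={"PM10": True},
                             centers={"PM10": np.log(16.6)}, scales={"PM10": 0.5})
        rng = np.random.default_rng(1)
        dm = self._map(rng.standard_normal((4, 5)),
                       rng.uniform(0.2, 1.0, (4, 5)), transform=tr)
        pis = [exceedance_probability(dm, L, norm.cdf) for L in (30.0, 50.0, 80.0)]
        assert np.all(pis[0] >= pis[1]) and np.all(pis[1] >= pis[2])

    def test_zero_sd_cells_compare_directly(self):
        dm = self._map(np.array([[1.0, -1.0]]), np.zeros((1, 2)))
        pi = exceedance_probability(dm, 0.0, norm.cdf)   # threshold on model scale
        np.testing.assert_array_equal(pi, [[1.0, 0.0]])


class TestDayCounts:
    def test_certain_exceedance_every_day(self):
        d = day_count_distribution(np.ones(6), M=3)
        assert d.pmf[-1] == pytest.approx(1.0)
        assert d.p_exceed == pytest.approx(1.0)

    def test_two_half_days_enumeration(self):
        d = day_count_distribution(np.array([0.5, 0.5]), M=0)
        np.testing.assert_allclose(d.pmf, [0.25, 0.5, 0.25])
        assert 1 - d.pmf[0] == pytest.approx(0.75)      # P(N >= 1)

    def test_dp_equals_full_enumeration(self):
        rng = np.random.default_rng(4)
        for T in (5, 9, 12):
            pi = rng.uniform(0, 1, T)
            d = day_count_distribution(pi, M=2)
            pmf = np.zeros(T + 1)
            for outcome in itertools.product([0, 1], repeat=T):
                prob = np.prod(np.where(outcome, pi, 1 - pi))
                pmf[sum(outcome)] += prob
            np.testing.assert_allclose(d.pmf, pmf, atol=1e-12)

    def test_monte_carlo_agrees_with_exact(self):
        rng = np.random.default_rng(8)
        pi = rng.uniform(0, 1, 30)
        exact = day_count_distribution(pi, M=7, method="exact")
        mc = day_count_distribution(pi, M=7, method="montecarlo", nsim=500, seed=1)
        se = np.sqrt(exact.p_exceed * (1 - exact.p_exceed) / 500)
        assert abs(mc.p_exceed - exact.p_exceed) <= 3 * se

    def test_mean_equals_sum_of_probabilities(self):
        rng = np.random.default_rng(5)
        pi = rng.uniform(0, 1, 40)
        d = day_count_distribution(pi, M=7)
        assert d.mean == pytest.approx(pi.sum(), abs=1e-9)

    def test_p_exceed_matches_cdf_and_decreases_in_M(self):
        rng = np.random.default_rng(6)
        pi = rng.uniform(0, 1, 15)
        prev = 1.1
        for M in range(0, 15):
            d = day_count_distribution(pi, M=M)
            assert d.p_exceed == pytest.approx(1.0 - d.cdf(M), abs=1e-12)
            assert d.p_exceed <= prev + 1e-12
            prev = d.p_exceed

    def test_invalid_probabilities_rejected(self):
        with pytest.raises(ValueError):
            day_count_distribution(np.array([0.2, 1.4]))


class TestAggregatedRisk:
    def test_constant_surface(self):
        pi = np.full((3, 4), 0.2)
        out = aggregated_risk_series(pi, _raster([1, 2, 3, 4]))
        np.testing.assert_allclose(out, 0.2)

    def test_concentrated_weights_pick_one_block(self):
        pi = np.array([[0.1, 0.9], [0.4, 0.6]])
        out = aggregated_risk_series(pi, _raster([0, 100]))
        np.testing.assert_allclose(out, [0.9, 0.6])

    def test_bounded_by_daily_extremes(self):
        rng = np.random.default_rng(2)
        pi = rng.uniform(0, 1, (10, 6))
        out = aggregated_risk_series(pi, _raster(rng.uniform(1, 100, 6)))
        assert np.all(out >= pi.min(axis=1)) and np.all(out <= pi.max(axis=1))

    def test_unweighted_mode(self):
        pi = np.array([[0.0, 1.0]])
        out = aggregated_risk_series(pi, weighted=False)
        np.testing.assert_allclose(out, [0.5])
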