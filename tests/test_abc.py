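import numpy as np
import pytest

from natfert.abc import (
    ASFRSchedule,
    PriorBox,
    ReferenceTable,
    RFSettings,
    build_reference_table,
    estimate,
    euclidean_distance,
    posterior_predictive,
    reject,
    rf_adjust,
    sample_prior,
    simulate_reference_table,
    summarize_posterior,
)
from natfert.fecundability import peak_values
from natfert.simulate import ParameterVector, SimulationConfig, simulate_asfr

GRID = tuple(range(15, 50))


@pytest.fixture(scope="module")
def box():
    return PriorBox()


@pytest.fixture(scope="module")
def obs_and_truth(box):
    rng = np.random.default_rng(99)
    theta0 = ParameterVector.from_array(sample_prior(box, 1, rng)[0])
    cfg = SimulationConfig(n_women=2000, age_grid=GRID)
    return simulate_asfr(theta0, cfg, rng), theta0


@pytest.fixture(scope="module")
def small_table(box, obs_and_truth):
    obs, _ = obs_and_truth
    cfg = SimulationConfig(n_women=300, age_grid=GRID)
    return build_reference_table(obs, box, 400, cfg, seed=17)


class TestPriorBox:
    def test_bounds_must_be_ordered(self):
        with pytest.raises(ValueError):
            PriorBox(mu_m=(27.0, 19.0))

    def test_delta_bounds_respected(self, box, rng):
        draws = sample_prior(box, 100_000, rng)
        assert draws[:, 4].min() >= 6.0
        assert draws[:, 4].max() <= 18.0

    def test_mu_m_uniform_mean(self, box, rng):
        draws = sample_prior(box, 100_000, rng)
        se = (27 - 19) / np.sqrt(12) / np.sqrt(draws.shape[0])
        assert abs(draws[:, 0].mean() - 23.0) < 3 * se

    def test_peak_band_holds_exactly(self, box, rng):
        draws = sample_prior(box, 20_000, rng)
        peaks = peak_values(draws[:, 2], draws[:, 3])
        assert peaks.min() >= 0.12
        assert peaks.max() <= 0.35

    def test_degenerate_coordinate_is_constant(self, rng):
        nearly = PriorBox(delta=(12.0, 12.0 + 1e-9))
        draws = sample_prior(nearly, 1000, rng)
        np.testing.assert_allclose(draws[:, 4], 12.0, atol=1e-6)

    def test_zero_draws(self, box, rng):
        assert sample_prior(box, 0, rng).shape == (0, 5)


class TestEuclideanDistance:
    def test_identical_is_zero(self):
        a = ASFRSchedule(ages=np.array([20, 21]), rates=np.array([0.1, 0.2]))
        assert euclidean_distance(a, a) == 0.0

    def test_three_four_five(self):
        a = ASFRSchedule(ages=np.array([20, 21]), rates=np.array([0.0, 0.0]))
        b = ASFRSchedule(ages=np.array([20, 21]), rates=np.array([0.03, 0.04]))
        assert euclidean_distance(a, b) == pytest.approx(0.05)

    def test_order_sensitive(self):
        a = ASFRSchedule(ages=np.array([20, 21]), rates=np.array([0.1, 0.3]))
        b = ASFRSchedule(ages=np.array([20, 21]), rates=np.array([0.1, 0.1]))
        b_swapped = ASFRSchedule(ages=np.array([20, 21]), rates=np.array([0.1, 0.3][::-1]))
        assert euclidean_distance(a, b) != euclidean_distance(a, b_swapped)

    def test_grid_mismatch_raises(self):
        a = ASFRSchedule(ages=np.array([20, 21]), rates=np.zeros(2))
        b = ASFRSchedule(ages=np.array([21, 22]), rates=np.zeros(2))
        with pytest.raises(ValueError):
            euclidean_distance(a, b)


class TestReferenceTable:
    def test_rows_aligned(self, small_table):
        assert len(small_table) == 400
        assert small_table.summaries.shape == (400, len(GRID))
        assert np.all(small_table.distances >= 0)

    def test_parallel_contract_same_seed_same_table(self, box, obs_and_truth):
        obs, _ = obs_and_truth
        cfg = SimulationConfig(n_women=100, age_grid=GRID)
        t1 = build_reference_table(obs, box, 50, cfg, seed=5)
        t2 = build_reference_table(obs, box, 50, cfg, seed=5)
        np.testing.assert_array_equal(t1.params, t2.params)
        np.testing.assert_array_equal(t1.summaries, t2.summaries)

    def test_best_row_is_near_truth(self, small_table, obs_and_truth, box):
        # recovery property: the distance-minimising row's mu_m falls in
        # the middle-50%-width band around the generating value
        _, theta0 = obs_and_truth
        best = small_table.params[np.argmin(small_table.distances)]
        lo, hi = box.mu_m
        assert abs(best[0] - theta0.mu_m) <= (hi - lo) / 4

    def test_csv_round_trip(self, small_table, tmp_path):
        path = tmp_path / "table.csv"
        small_table.save(path)
        back = ReferenceTable.load(path)
        np.testing.assert_allclose(back.params, small_table.params)
        np.testing.assert_allclose(back.summaries, small_table.summaries)
        np.testing.assert_allclose(back.distances, small_table.distances)


class TestReject:
    def _table(self, distances):
        n = len(distances)
        return ReferenceTable(
            params=np.arange(n * 5, dtype=float).reshape(n, 5),
            summaries=np.zeros((n, 3)),
            ages=np.array([20, 21, 22]),
            config=SimulationConfig(n_women=10),
            distances=np.asarray(distances, dtype=float),
        )

    def test_keeps_minimum(self):
        t = self._table([5.0, 1.0, 3.0])
        kept = reject(t, 1 / 3)
        assert len(kept) == 1
        np.testing.assert_array_equal(kept.params[0], t.params[1])

    def test_fraction_one_keeps_all(self):
        t = self._table([5.0, 1.0, 3.0])
        assert len(reject(t, 1.0)) == 3

    def test_tie_break_by_row_index(self):
        t = self._table([2.0, 2.0, 2.0, 1.0])
        kept = reject(t, 0.5)
        # distance-1 row, then the earliest of the tied distance-2 rows
        np.testing.assert_array_equal(kept.params, t.params[[0, 3]])

    def test_bad_fraction(self):
        t = self._table([1.0])
        with pytest.raises(ValueError):
            reject(t, 0.0)

    def test_empty_table(self):
        t = self._table([])
        with pytest.raises(ValueError):
            reject(t, 0.5)


class TestRFAdjust:
    def test_constant_surface_leaves_draws_unchanged(self, box, rng):
        # theta independent of summaries: the two regression terms cancel
        n = 120
        params = sample_prior(box, n, rng)
        summaries = np.tile(rng.random(10), (n, 1))
        table = ReferenceTable(
            params=params,
            summaries=summaries,
            ages=np.arange(20, 30),
            config=SimulationConfig(n_women=10),
        )
        obs = ASFRSchedule(ages=np.arange(20, 30), rates=summaries[0])
        post = rf_adjust(table, obs, box, RFSettings(n_trees=100), seed=0)
        # the two regression terms cancel up to out-of-bag noise, which
        # shrinks with the accepted-set size; allow a small fraction of
        # each parameter's spread
        diff = np.abs(post.adjusted - params)
        assert np.all(diff.max(axis=0) <= 0.35 * params.std(axis=0))

    def test_adjusted_inside_prior_box(self, small_table, obs_and_truth, box):
        obs, _ = obs_and_truth
        accepted = reject(small_table, 0.25)
        post = rf_adjust(accepted, obs, box, RFSettings(n_trees=50), seed=1)
        assert np.all(box.contains(post.adjusted))

    def test_refuses_tiny_accepted_set(self, small_table, obs_and_truth, box):
        obs, _ = obs_and_truth
        accepted = reject(small_table, 10 / len(small_table))
        with pytest.raises(ValueError, match="accept"):
            rf_adjust(accepted, obs, box, RFSettings(min_accepted=50))

    def test_nearest_neighbour_oracle_direction(self, box, rng):
        # With obs equal to one accepted row's summary, a 1-NN regression
        # oracle predicts that row's theta at obs; hand-compute the
        # adjustment it implies and check the forest moves the same way
        # for a strongly informative, monotone summary.
        n = 200
        mu = np.sort(rng.uniform(19, 27, n))
        params = sample_prior(box, n, rng)
        params[:, 0] = mu
        summaries = mu.reshape(-1, 1) + rng.normal(0, 0.01, (n, 1))
        table = ReferenceTable(
            params=params,
            summaries=summaries,
            ages=np.array([20]),
            config=SimulationConfig(n_women=10),
        )
        target = 50
        obs = ASFRSchedule(ages=np.array([20]), rates=summaries[target])
        post = rf_adjust(table, obs, box, RFSettings(n_trees=200), seed=2)
        # adjusted draws concentrate around the target row's mu_m
        assert abs(np.median(post.adjusted[:, 0]) - mu[target]) < abs(
            np.median(params[:, 0]) - mu[target]
        )


class TestSummarizePosterior:
    def test_tiny(self):
        df = summarize_posterior(np.array([[1.0], [2.0], [3.0]]), ["x"])
        assert df.loc["x", "mean"] == 2.0
        assert df.loc["x", "median"] == 2.0

    def test_uniform_quantiles(self, rng):
        draws = rng.random((10_000, 1))
        df = summarize_posterior(draws, ["u"])
        assert df.loc["u", "q2.5"] == pytest.approx(0.025, abs=0.01)
        assert df.loc["u", "q97.5"] == pytest.approx(0.975, abs=0.01)

    def test_single_draw_degenerate(self):
        df = summarize_posterior(np.array([[2.0, 3.0]]), ["a", "b"])
        assert df.loc["a", "q2.5"] == df.loc["a", "q97.5"] == 2.0


class TestPosteriorPredictive:
    def test_envelope_ordering(self, obs_and_truth, rng):
        _, theta0 = obs_and_truth
        draws = np.tile(theta0.to_array(), (30, 1))
        draws += rng.normal(0, 0.01, draws.shape) * [1, 1, 0, 0, 1]
        cfg = SimulationConfig(n_women=200, age_grid=GRID)
        env = posterior_predictive(draws, cfg, 40, rng)
        assert np.all(env.lower <= env.median + 1e-12)
        assert np.all(env.median <= env.upper + 1e-12)

    def test_degenerate_posterior_collapses(self, obs_and_truth, rng):
        _, theta0 = obs_and_truth
        draws = theta0.to_array().reshape(1, -1)
        cfg = SimulationConfig(n_women=4000, age_grid=GRID)
        env = posterior_predictive(draws, cfg, 25, rng)
        assert np.max(env.upper - env.lower) < 0.05


class TestEndToEnd:
    def test_recovery_smoke(self, box, obs_and_truth):
        obs, theta0 = obs_and_truth
        cfg = SimulationConfig(n_women=1000, age_grid=GRID)
        post = estimate(
            obs, box, cfg, n_draws=600, accept_fraction=0.1,
            rf=RFSettings(n_trees=100, min_accepted=20), seed=21,
        )
        df = post.summary()
        # mu_m is the best-identified parameter; CI should cover truth
        assert df.loc["mu_m", "q2.5"] <= theta0.mu_m <= df.loc["mu_m", "q97.5"]
        # and the accepted spread is narrower than the prior
        assert (
            df.loc["mu_m", "q97.5"] - df.loc["mu_m", "q2.5"]
            < box.mu_m[1] - box.mu_m[0]
        )
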