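import numpy as np
import pytest

from harrierpva import demography as dem
from harrierpva import pva
from harrierpva.data_model import ModelParams, PopulationVector, VitalRates
from harrierpva.published import POSTERIOR_SUMMARY


def zero_sd_summary():
    return {k: (mean, 0.0) for k, (mean, sd) in POSTERIOR_SUMMARY.items()}


def mean_params():
    m = {k: v[0] for k, v in POSTERIOR_SUMMARY.items()}
    return ModelParams(
        r=m["r"], mu0=m["mu0"], psi=m["psi"],
        vital=VitalRates(m["phi1"], m["phi2"], m["beta0"], m["beta1"], m["sigma_gamma"]),
    )


class TestSampleParams:
    def test_zero_sd_returns_means_exactly(self):
        p = pva.sample_params(zero_sd_summary(), 1, seed=0)[0]
        assert p.mu0 == 1.277
        assert p.vital.phi2 == 0.704
        assert p.vital.phi1 == 0.502

    def test_survival_rates_stay_in_unit_interval(self):
        draws = pva.sample_params(POSTERIOR_SUMMARY, 2000, seed=1)
        for p in draws:
            assert 0 < p.vital.phi1 < p.vital.phi2 < 1
            assert 0 < p.r < 1
            assert p.psi > 0 and p.mu0 > 0

    def test_sample_means_match_summary(self):
        draws = pva.sample_params(POSTERIOR_SUMMARY, 10_000, seed=2)
        beta0 = np.array([p.vital.beta0 for p in draws])
        mean, sd = POSTERIOR_SUMMARY["beta0"]
        assert abs(beta0.mean() - mean) < 3 * sd / np.sqrt(len(beta0))

    def test_resampling_from_posterior_draw_arrays(self):
        source = {
            "r": np.full(100, 0.06), "mu0": np.full(100, 1.2),
            "psi": np.full(100, 1.4), "phi1": np.full(100, 0.5),
            "phi2": np.full(100, 0.7), "beta0": np.full(100, 0.1),
            "beta1": np.full(100, 0.9), "sigma_gamma": np.full(100, 0.3),
        }
        p = pva.sample_params(source, 3, seed=3)[1]
        assert p.mu0 == 1.2 and p.vital.phi2 == 0.7


class TestSimulateTrajectory:
    def test_declining_population_without_removals_never_extinct(self):
        scenario = pva.ScenarioConfig(
            removals_per_year=0, horizon_years=100, n_trajectories=1,
            initial_population=1367.0, seed=0,
        )
        totals, extinct = pva.simulate_trajectory(mean_params(), scenario, seed=0)
        assert extinct == -1
        assert totals[-1] > 0
        assert totals[-1] < totals[0]  # posterior-mean rates imply decline

    def test_removals_exceeding_population_extinct_in_year_one(self):
        scenario = pva.ScenarioConfig(
            removals_per_year=5000, horizon_years=10, n_trajectories=1,
            initial_population=1367.0, seed=0,
        )
        totals, extinct = pva.simulate_trajectory(mean_params(), scenario, seed=0)
        assert extinct == 1
        assert np.all(totals[1:] == 0)

    def test_one_step_projection_minus_removals(self):
        a = dem.build_matrix(0.783, 0.502, 0.704)
        projected = dem.project(PopulationVector(0, 0, 100), a).as_array()
        projected[2] -= 5
        assert projected == pytest.approx([55.12, 0.0, 65.4], abs=0.01)

    def test_extinction_is_absorbing(self):
        scenario = pva.ScenarioConfig(
            removals_per_year=40, horizon_years=50, n_trajectories=1,
            initial_population=100.0, seed=0,
        )
        totals, extinct = pva.simulate_trajectory(mean_params(), scenario, seed=0)
        assert extinct > 0
        assert np.all(totals[extinct:] == 0)
        assert np.all(totals >= 0)


class TestRunScenario:
    def run(self, removals, stage="adult", n=150, seed=9):
        scenario = pva.ScenarioConfig(
            removals_per_year=removals, removed_stage=stage,
            n_trajectories=n, seed=seed,
        )
        return pva.run_scenario(POSTERIOR_SUMMARY, scenario)

    def test_extinction_monotone_in_removals_on_matched_seeds(self):
        probs = [self.run(k).extinction_probability for k in (0, 1, 3, 5)]
        assert probs[0] == 0.0
        assert probs == sorted(probs)
        assert probs[1] < probs[3]  # strictly increasing somewhere

    def test_matched_seed_curves_monotone_year_by_year(self):
        c1 = pva.extinction_curve(self.run(1))
        c5 = pva.extinction_curve(self.run(5))
        assert np.all(c5 >= c1)

    def test_removing_subadults_identical_to_adults(self):
        adults = self.run(3, "adult")
        subs = self.run(3, "subadult")
        assert np.array_equal(adults.totals, subs.totals)
        assert np.array_equal(adults.extinct_year, subs.extinct_year)

    def test_removing_fledglings_is_less_harmful(self):
        adults = self.run(3, "adult")
        fled = self.run(3, "fledgling")
        assert fled.extinction_probability <= adults.extinction_probability

    def test_reproducible_under_seed(self):
        a, b = self.run(3, n=40), self.run(3, n=40)
        assert np.array_equal(a.totals, b.totals)

    def test_monte_carlo_error_scales_as_binomial(self):
        small = self.run(3, n=200, seed=17)
        big = self.run(3, n=400, seed=17)
        p = big.extinction_probability
        se = np.sqrt(p * (1 - p) / 200)
        assert abs(small.extinction_probability - p) < 3 * se + 1e-9


class TestExtinctionCurve:
    def test_no_extinctions_all_zero(self):
        ens = pva.TrajectoryEnsemble(
            totals=np.ones((4, 11)), extinct_year=np.full(4, -1), params=[]
        )
        assert np.all(pva.extinction_curve(ens) == 0)

    def test_all_extinct_at_year_one(self):
        totals = np.zeros((3, 11))
        totals[:, 0] = 5.0
        ens = pva.TrajectoryEnsemble(
            totals=totals, extinct_year=np.full(3, 1), params=[]
        )
        curve = pva.extinction_curve(ens)
        assert curve[0] == 0 and np.all(curve[1:] == 1)

    def test_terminal_value_is_extinct_fraction(self):
        ens = pva.TrajectoryEnsemble(
            totals=np.ones((5, 11)),
            extinct_year=np.array([-1, 2, 7, -1, 10]),
            params=[],
        )
        curve = pva.extinction_curve(ens)
        assert curve[-1] == pytest.approx(3 / 5)
        assert np.all(np.diff(curve) >= 0)


class TestPosteriorElasticities:
    def test_single_draw_at_posterior_means(self):
        report = pva.posterior_elasticities([mean_params()])
        assert report["phi2"][0] == pytest.approx(0.556, abs=0.001)
        assert report["phi1"][0] == pytest.approx(0.222, abs=0.001)
        assert report["rho"][0] == pytest.approx(0.222, abs=0.001)

    def test_fledgling_and_fecundity_elasticities_identical(self):
        draws = pva.sample_params(POSTERIOR_SUMMARY, 200, seed=4)
        rep = pva.posterior_elasticities(draws, include_random_effect=True, seed=5)
        assert rep["phi1"][0] == pytest.approx(rep["rho"][0], abs=1e-9)
        assert rep["phi1"][1] == pytest.approx(rep["rho"][1], abs=1e-9)

    def test_stage_elasticities_partition_unity_in_expectation(self):
        draws = pva.sample_params(POSTERIOR_SUMMARY, 200, seed=6)
        rep = pva.posterior_elasticities(draws, seed=7)
        total = rep["phi2"][0] + rep["phi1"][0] + rep["rho"][0]
        assert total == pytest.approx(1.0, abs=1e-9)
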