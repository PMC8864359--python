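import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from harrierpva import demography as dem
from harrierpva.data_model import PopulationVector, TrackingRecord


def valid_rates():
    """Strategy for (rho, phi1, phi2) respecting the life-cycle constraints."""
    return st.tuples(
        st.floats(0.01, 1.49),
        st.floats(0.05, 0.90),
        st.floats(0.05, 0.95),
    ).map(lambda t: (t[0], min(t[1], t[2]) * 0.99, max(t[1], t[2])))


class TestFecundity:
    def test_matches_published_posterior_mean(self):
        assert dem.fecundity(0.092, 0.862, 0.0, 0.0) == pytest.approx(0.783, abs=0.005)

    def test_neutral_logit_gives_three_quarters(self):
        assert dem.fecundity(0.0, 0.0, 0.0, 0.0) == pytest.approx(0.75)

    def test_one_sd_of_rain_boosts_fecundity_38_percent(self):
        ratio = dem.fecundity(0.092, 0.862, 1.0) / dem.fecundity(0.092, 0.862, 0.0)
        assert ratio - 1 == pytest.approx(0.38, abs=0.005)

    def test_bounded_by_zero_and_three_per_pair(self):
        assert dem.fecundity(50, 0, 0, 0) <= 1.5
        assert dem.fecundity(-50, 0, 0, 0) >= 0.0


class TestTransitionMatrix:
    def test_layout_at_posterior_means(self):
        a = dem.build_matrix(0.783, 0.502, 0.704)
        assert a[0, 1] == pytest.approx(0.5512, abs=1e-4)
        assert a[0, 2] == a[0, 1]
        assert a[1, 0] == 0.502
        assert np.all(a[1, 1:] == 0)
        assert a[0, 0] == 0

    def test_zero_fecundity_zeroes_first_row(self):
        a = dem.build_matrix(0.0, 0.3, 0.6)
        assert np.all(a[0] == 0)

    @given(valid_rates())
    @settings(deadline=None, max_examples=50)
    def test_subadult_and_adult_columns_identical(self, rates):
        a = dem.build_matrix(*rates)
        assert np.array_equal(a[:, 1], a[:, 2])

    def test_invalid_rates_rejected(self):
        with pytest.raises(ValueError):
            dem.build_matrix(2.0, 0.3, 0.6)
        with pytest.raises(ValueError):
            dem.build_matrix(0.5, 0.7, 0.6)


class TestProjection:
    def test_empty_population_stays_empty(self):
        a = dem.build_matrix(0.783, 0.502, 0.704)
        out = dem.project(PopulationVector(0, 0, 0), a)
        assert out.as_array().tolist() == [0, 0, 0]

    def test_hundred_adults_one_step(self):
        a = dem.build_matrix(0.783, 0.502, 0.704)
        out = dem.project(PopulationVector(0, 0, 100), a)
        assert out.n_fledgling == pytest.approx(55.12, abs=0.01)
        assert out.n_subadult == 0
        assert out.n_adult == pytest.approx(70.4, abs=0.01)

    def test_fledglings_only_mature_to_subadults(self):
        a = dem.build_matrix(0.0, 0.502, 0.704)
        out = dem.project(PopulationVector(100, 0, 0), a)
        assert out.as_array() == pytest.approx([0.0, 50.2, 0.0])

    def test_removing_subadult_equals_removing_adult(self):
        # structural consequence of identical columns 2 and 3
        a = dem.build_matrix(0.9, 0.4, 0.7)
        minus_sub = dem.project(PopulationVector(10, 19, 30), a).as_array()
        minus_ad = dem.project(PopulationVector(10, 20, 29), a).as_array()
        assert minus_sub == pytest.approx(minus_ad)


class TestGrowthRate:
    def test_posterior_mean_growth_rate(self):
        a = dem.build_matrix(0.783, 0.502, 0.704)
        assert dem.growth_rate(a) == pytest.approx(0.985, abs=1e-3)

    def test_zero_fecundity_collapses_to_adult_survival(self):
        a = dem.build_matrix(0.0, 0.3, 0.6)
        assert dem.growth_rate(a) == pytest.approx(0.6, abs=1e-12)

    @given(valid_rates())
    @settings(deadline=None, max_examples=1000)
    def test_eigensolver_matches_closed_form(self, rates):
        a = dem.build_matrix(*rates)
        assert abs(dem.growth_rate(a) - dem.growth_rate_closed_form(a)) < 1e-10

    @given(valid_rates())
    @settings(deadline=None, max_examples=50)
    def test_growth_rate_monotone_in_each_rate(self, rates):
        rho, phi1, phi2 = rates
        lam = dem.growth_rate_closed_form(dem.build_matrix(rho, phi1, phi2))
        up = [
            (min(rho * 1.01, 1.5), phi1, phi2),
            (rho, min(phi1 * 1.01, phi2 * 0.999), phi2),
            (rho, phi1, min(phi2 * 1.01, 0.999)),
        ]
        for rates_up in up:
            assert dem.growth_rate_closed_form(dem.build_matrix(*rates_up)) >= lam - 1e-12


class TestElasticities:
    def test_values_at_posterior_means(self):
        rep = dem.elasticities(dem.build_matrix(0.783, 0.502, 0.704))
        assert rep.phi2 == pytest.approx(0.556, abs=0.001)
        assert rep.phi1 == pytest.approx(0.222, abs=0.001)
        assert rep.rho == pytest.approx(0.222, abs=0.001)

    @given(valid_rates())
    @settings(deadline=None, max_examples=100)
    def test_entrywise_sum_to_one_and_nonnegative(self, rates):
        rep = dem.elasticities(dem.build_matrix(*rates))
        assert rep.entrywise.sum() == pytest.approx(1.0, abs=1e-10)
        assert np.all(rep.entrywise >= -1e-12)

    @given(valid_rates())
    @settings(deadline=None, max_examples=100)
    def test_loop_identity_fledgling_equals_fecundity(self, rates):
        rep = dem.elasticities(dem.build_matrix(*rates))
        assert rep.phi1 == pytest.approx(rep.rho, abs=1e-9)

    def test_stage_groups_partition_total(self):
        rep = dem.elasticities(dem.build_matrix(0.9, 0.4, 0.7))
        assert rep.phi2 + rep.phi1 + rep.rho == pytest.approx(1.0, abs=1e-10)


class TestStableStage:
    def test_is_eigenvector_with_dominant_eigenvalue(self):
        a = dem.build_matrix(0.783, 0.502, 0.704)
        w = dem.stable_stage_distribution(a)
        lam = dem.growth_rate(a)
        assert a @ w == pytest.approx(lam * w, abs=1e-12)
        assert w.sum() == pytest.approx(1.0)


class TestExponentialSurvival:
    def test_mle_matches_deaths_over_exposure(self, tracking_fixture):
        h = dem.fit_hazard_mle(tracking_fixture)
        assert h == pytest.approx(4 / 13, abs=1e-12)
        assert dem.annual_survival(h) == pytest.approx(np.exp(-4 / 13), abs=1e-12)

    def test_loglik_maximized_at_closed_form(self, tracking_fixture):
        h = dem.fit_hazard_mle(tracking_fixture)
        at_mle = dem.survival_loglik(tracking_fixture, h)
        for other in (h * 0.8, h * 1.2):
            assert dem.survival_loglik(tracking_fixture, other) < at_mle

    def test_no_deaths_pushes_hazard_to_zero(self):
        recs = [TrackingRecord(f"b{i}", 365.0, False) for i in range(5)]
        hs = [0.01, 0.1, 1.0]
        lls = [dem.survival_loglik(recs, h) for h in hs]
        assert lls == sorted(lls, reverse=True)
        with pytest.raises(ValueError):
            dem.fit_hazard_mle(recs)

    def test_doubling_exposure_halves_mle(self, tracking_fixture):
        doubled = [
            TrackingRecord(r.bird_id, r.exposure_days * 2, r.died)
            for r in tracking_fixture
        ]
        assert dem.fit_hazard_mle(doubled) == pytest.approx(
            dem.fit_hazard_mle(tracking_fixture) / 2
        )

    @pytest.mark.parametrize(
        "hazard,expected", [(0.0, 1.0), (4 / 13, 0.7352), (np.log(2), 0.5)]
    )
    def test_annual_survival_values(self, hazard, expected):
        assert dem.annual_survival(hazard) == pytest.approx(expected, abs=1e-4)
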