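"""Cohort-survival forecasting: trend fits, cohort advancement, projections."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from agetech.demography import (
    AgeBand,
    MigrationAssumption,
    MortalitySchedule,
    PopulationTable,
    advance_cohort,
    fit_linear_trend,
    forecast_population,
    growth_percent,
)


class TestAgeBand:
    @pytest.mark.parametrize(
        "label, lower, upper",
        [("65-69", 65, 69), ("85+", 85, None), ("90 and over", 90, None)],
    )
    def test_parse(self, label, lower, upper):
        band = AgeBand.parse(label)
        assert (band.lower, band.upper) == (lower, upper)

    def test_rejects_inverted_bounds(self):
        with pytest.raises(ValueError):
            AgeBand(label="x", lower=70, upper=65)


class TestLinearTrend:
    def test_constant_series_has_zero_slope(self):
        m = fit_linear_trend([(2006, 5.0), (2011, 5.0), (2016, 5.0)])
        assert m.slope == pytest.approx(0.0)
        assert m.predict(2030) == pytest.approx(5.0)

    def test_three_point_death_rate_trend(self):
        # closed form on centered points: slope = sum(xy)/sum(x^2) = -1.5/50
        m = fit_linear_trend([(2006, 4.40), (2011, 4.20), (2016, 4.10)])
        assert m.slope == pytest.approx(-0.03)
        assert m.predict(2016) == pytest.approx(4.0833, abs=1e-4)
        assert m.predict(2021) == pytest.approx(3.9333, abs=1e-4)

    def test_two_point_line(self):
        m = fit_linear_trend([(2006, 0.0), (2016, 10.0)])
        assert m.slope == pytest.approx(1.0)
        assert m.predict(2021) == pytest.approx(15.0)

    def test_single_year_rejected(self):
        with pytest.raises(ValueError):
            fit_linear_trend([(2016, 1.0), (2016, 2.0)])

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(
        values=st.lists(
            st.floats(min_value=-100, max_value=100), min_size=3, max_size=6
        )
    )
    def test_agrees_with_grid_search_minimizer(self, values):
        """OLS beats every line on a fine slope/intercept grid to 1e-6."""
        years = list(range(2000, 2000 + len(values)))
        pts = list(zip(years, values))
        m = fit_linear_trend(pts)

        def sse(intercept, slope, ref):
            return sum((v - (intercept + slope * (y - ref))) ** 2 for y, v in pts)

        best = sse(m.intercept, m.slope, m.reference_year)
        for di in np.linspace(-0.5, 0.5, 21):
            for ds in np.linspace(-0.5, 0.5, 21):
                assert (
                    best
                    <= sse(m.intercept + di, m.slope + ds, m.reference_year) + 1e-6
                )

    def test_residuals_orthogonal_to_year(self):
        pts = [(2006, 3.1), (2011, 4.7), (2016, 4.0), (2021, 6.2)]
        m = fit_linear_trend(pts)
        resid = [v - m.predict(y) for y, v in pts]
        years = [y for y, _ in pts]
        assert abs(np.dot(resid, np.array(years) - np.mean(years))) < 1e-8


class TestAdvanceCohort:
    def test_zero_mortality_identity(self):
        assert advance_cohort(1000, 0, 5, 0) == pytest.approx(1000)

    def test_compounds_annually(self):
        assert advance_cohort(1000, 10, 5, 0) == pytest.approx(1000 * 0.99**5)

    def test_migration_offsets_mortality_at_fixed_point(self):
        assert advance_cohort(1000, 10, 5, 10) == pytest.approx(1000)

    def test_clamped_at_zero(self):
        assert advance_cohort(10, 100, 3, -50) == 0.0

    @pytest.mark.parametrize("bad", [(-1, 5, 1, 0), (100, -2, 1, 0), (100, 5, -1, 0)])
    def test_rejects_negative_inputs(self, bad):
        with pytest.raises(ValueError):
            advance_cohort(*bad)

    @settings(deadline=None, derandomize=True, max_examples=40)
    @given(
        count=st.floats(min_value=0, max_value=1e6),
        r1=st.floats(min_value=0, max_value=500),
        r2=st.floats(min_value=0, max_value=500),
        mig=st.floats(min_value=-100, max_value=100),
    )
    def test_monotone_in_death_rate_and_migration(self, count, r1, r2, mig):
        lo, hi = sorted((r1, r2))
        assert advance_cohort(count, hi, 5, mig) <= advance_cohort(count, lo, 5, mig)
        assert advance_cohort(count, r1, 5, mig) <= advance_cohort(
            count, r1, 5, mig + 1
        )


def _toy_schedule(rate=0.0, years=(2016, 2021, 2026)):
    sched = MortalitySchedule()
    for y in years:
        for band in ("55-59", "60-64", "65-69", "70-74", "75-79", "80-84", "85-89", "90-94"):
            sched.set(y, band, rate)
    return sched


class TestForecast:
    def test_zero_rates_and_migration_conserve_total(self):
        base = PopulationTable()
        for band, n in [("55-59", 100), ("60-64", 200), ("65-69", 300), ("85+", 50)]:
            base.set(2016, band, n)
        base.set(2016, "70-74", 10)
        base.set(2016, "75-79", 20)
        base.set(2016, "80-84", 30)
        fc = forecast_population(
            base, _toy_schedule(0.0), MigrationAssumption(0, 0), 10, base_year=2016
        )
        # every person in the closed system is still there after the step
        assert fc.total(2021, min_age=0) == pytest.approx(base.total(2016, min_age=0))

    def test_pure_advancement_two_band_toy(self):
        base = PopulationTable()
        base.set(2016, "60-64", 1000)
        base.set(2016, "65-69", 0)
        fc = forecast_population(
            base, _toy_schedule(0.0), MigrationAssumption(0, 0), 5, base_year=2016
        )
        assert fc.get(2021, "65-69") == pytest.approx(1000)

    def test_missing_feeder_band_is_a_coverage_error(self):
        base = PopulationTable()
        base.set(2016, "65-69", 100)  # nothing feeds 65-69
        with pytest.raises(KeyError, match="feeder"):
            forecast_population(
                base, _toy_schedule(), MigrationAssumption(0, 0), 5, base_year=2016
            )

    def test_never_negative(self):
        base = PopulationTable()
        base.set(2016, "60-64", 5)
        base.set(2016, "65-69", 5)
        fc = forecast_population(
            base,
            _toy_schedule(999.0),
            MigrationAssumption(0, 0),
            10,
            base_year=2016,
        )
        assert all(v >= 0 for v in fc.counts.values())

    def test_regional_case_study_direction(self, population, mortality):
        """65+ grows from 30,314 toward the published ~43,824 over 10 years."""
        from agetech.datasets import FCW_MIGRATION, load_regional_totals

        fc = forecast_population(
            population,
            mortality,
            FCW_MIGRATION,
            10,
            base_year=2016,
            regional_population=load_regional_totals("fcw"),
        )
        start = population.total(2016, min_age=65)
        end = fc.total(2026, min_age=65)
        assert start == pytest.approx(30314)
        assert 38000 < end < 48000  # strong growth of the right order
        assert fc.total(2021, min_age=65) < end


class TestGrowthPercent:
    def test_no_change(self):
        assert growth_percent(100, 100) == 0.0

    def test_published_65plus_totals(self):
        assert growth_percent(30314, 43824) == pytest.approx(44.57, abs=0.01)

    def test_state_population_growth(self):
        assert growth_percent(4848877, 5835658) == pytest.approx(20.35, abs=0.01)

    def test_zero_initial_rejected(self):
        with pytest.raises(ZeroDivisionError):
            growth_percent(0, 10)


def test_schedule_projects_missing_years_by_trend():
    sched = MortalitySchedule()
    for y, r in [(2006, 11.8), (2011, 10.3), (2016, 9.6)]:
        sched.set(y, "65-69", r)
    m_expected = fit_linear_trend([(2006, 11.8), (2011, 10.3), (2016, 9.6)])
    assert sched.rate(2021, "65-69") == pytest.approx(m_expected.predict(2021))


def test_schedule_open_band_falls_back_to_containing_band():
    sched = MortalitySchedule()
    sched.set(2016, "85-89", 94.5)
    assert sched.rate(2016, "85+") == 94.5


def test_schedule_warns_on_non_monotone_rates():
    sched = MortalitySchedule()
    sched.set(2016, "65-69", 10.0)
    sched.set(2016, "70-74", 5.0)
    with pytest.warns(UserWarning, match="decreases with age"):
        sched.check_monotone(2016)
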