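"""Log-log multistage fit: OLS oracle, filtering rules, step conversion."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from multistage import (
    BandFilterConfig,
    CohortTable,
    DegenerateDesignError,
    InsufficientDataError,
    Participant,
    SlopeDomainError,
    UndefinedRateError,
    band_incidence,
    filter_bands,
    fit_cohort,
    fit_loglog,
    steps_from_slope,
)
from multistage.persontime import AgeBand, BandTable


def _bands(rows, width=5.0):
    """rows: (lower, person_years, events)."""
    bands = [AgeBand(lo, lo + width, py, ev) for lo, py, ev in rows]
    return BandTable(bands, width, bands[0].lower % width)


def _closed_form_ols(x, y):
    x, y = np.asarray(x), np.asarray(y)
    xb, yb = x.mean(), y.mean()
    slope = ((x - xb) * (y - yb)).sum() / ((x - xb) ** 2).sum()
    return slope, yb - slope * xb


class TestBandIncidence:
    def test_rate(self):
        assert band_incidence(AgeBand(60, 65, 5000.0, 10)) == pytest.approx(0.002)

    def test_zero_events(self):
        assert band_incidence(AgeBand(60, 65, 800.0, 0)) == 0.0

    def test_zero_person_years_is_error(self):
        with pytest.raises(UndefinedRateError):
            band_incidence(AgeBand(60, 65, 0.0, 1))


class TestFilterBands:
    def test_person_year_threshold_exclusive_below(self):
        table = _bands([(50, 499.0, 1), (55, 600, 2), (60, 700, 3), (65, 800, 4)])
        retained, report = filter_bands(table, BandFilterConfig())
        assert [b.lower for b in retained] == [55, 60, 65]
        assert report.excluded_bands == 1
        assert report.excluded_person_years == pytest.approx(499.0)

    def test_rate_threshold_exclusive_below(self):
        # 10,000 py with 9 events: rate 0.0009 < 1 per 1000 py -> excluded
        table = _bands([(50, 10_000.0, 9), (55, 600, 2), (60, 700, 3), (65, 800, 4)])
        retained, _ = filter_bands(table, BandFilterConfig())
        assert [b.lower for b in retained] == [55, 60, 65]

    def test_thresholds_are_inclusive_at_boundary(self):
        """Exactly 500 py and exactly 1 per 1000 py is retained."""
        table = _bands([(50, 500.0, 1), (55, 1000, 1), (60, 700, 3), (65, 800, 4)])
        # band [50,55): 500 py, rate 1/500 = 0.002 >= 0.001; [55,60): rate exactly 0.001
        retained, _ = filter_bands(table, BandFilterConfig())
        assert [b.lower for b in retained] == [50, 55, 60, 65]

    def test_insufficient_bands_raises(self):
        table = _bands([(50, 100.0, 1), (55, 100, 1), (60, 700, 3)])
        with pytest.raises(InsufficientDataError):
            filter_bands(table, BandFilterConfig())

    def test_excluded_participants_below_first_retained_band(self):
        table = _bands([(50, 10.0, 0), (55, 600, 2), (60, 700, 3), (65, 800, 4)])
        cohort = CohortTable.from_participants(
            [
                Participant("a", 50.0, 53.0, False),  # exits below 55 -> excluded
                Participant("b", 50.0, 67.0, True),
            ]
        )
        _, report = filter_bands(table, BandFilterConfig(), cohort)
        assert report.first_retained_lower == 55
        assert report.excluded_participants == 1


class TestFitLoglog:
    def test_exact_power_law_recovered(self):
        """Bands with rate = exp(c) t^6 at midpoints: slope 6, adjusted R^2 = 1."""
        rows = []
        c = -30.0
        for lo in (55, 60, 65, 70, 75, 80):
            t = lo + 2.5
            rate = math.exp(c) * t**6
            py = 10_000.0
            rows.append(AgeBand(lo, lo + 5, py, rate * py))
        fit = fit_loglog(rows)
        assert fit.slope == pytest.approx(6.0, abs=1e-9)
        assert fit.intercept == pytest.approx(c, abs=1e-7)
        assert fit.adjusted_r2 == pytest.approx(1.0, abs=1e-12)
        assert fit.n_steps == 7

    def test_constant_rate_gives_slope_zero_one_step(self):
        rows = [AgeBand(lo, lo + 5, 1000.0, 5) for lo in (55, 60, 65, 70)]
        fit = fit_loglog(rows)
        assert fit.slope == pytest.approx(0.0, abs=1e-12)
        assert fit.n_steps == 1

    def test_three_point_hand_computation(self):
        """(0,0),(1,1),(2,3) has closed-form slope 1.5."""
        # abscissae exp(0), exp(1), exp(2); rates exp(0), exp(1), exp(3)
        rows = [
            AgeBand(math.exp(x) - 1, math.exp(x) + 1, 1000.0, 1000.0 * math.exp(y))
            for x, y in [(0, 0), (1, 1), (2, 3)]
        ]
        fit = fit_loglog(rows)
        assert fit.slope == pytest.approx(1.5, rel=1e-9)

    def test_degenerate_design(self):
        rows = [AgeBand(60, 65, 1000.0, k) for k in (1, 2, 3)]
        with pytest.raises(DegenerateDesignError):
            fit_loglog(rows)

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(st.integers(0, 10_000))
    def test_ols_matches_closed_form_normal_equations(self, seed):
        """Slope/intercept agree with Σ(x-x̄)(y-ȳ)/Σ(x-x̄)² to 1e-12 relative."""
        rng = np.random.default_rng(seed)
        k = rng.integers(3, 12)
        lowers = 40 + 5 * np.arange(k)
        # rising rates keep the fitted slope in the multistage domain
        rates = np.sort(rng.uniform(1e-4, 1e-1, size=k))
        rows = [AgeBand(lo, lo + 5, 1000.0, 1000.0 * r) for lo, r in zip(lowers, rates)]
        fit = fit_loglog(rows)
        x = [math.log(b.midpoint) for b in rows]
        y = [math.log(band_incidence(b)) for b in rows]
        slope, intercept = _closed_form_ols(x, y)
        assert fit.slope == pytest.approx(slope, rel=1e-12)
        assert fit.intercept == pytest.approx(intercept, rel=1e-12)

    def test_rate_scaling_moves_only_intercept(self):
        rng = np.random.default_rng(0)
        rates = np.sort(rng.uniform(1e-4, 1e-1, size=6))
        rows = [AgeBand(50 + 5 * i, 55 + 5 * i, 1000.0, 1000.0 * r) for i, r in enumerate(rates)]
        scaled = [AgeBand(b.lower, b.upper, b.person_years, b.events * 7.5) for b in rows]
        f1, f2 = fit_loglog(rows), fit_loglog(scaled)
        assert f2.slope == pytest.approx(f1.slope, rel=1e-12)
        assert f2.intercept - f1.intercept == pytest.approx(math.log(7.5), rel=1e-9)

    def test_age_point_conventions_differ(self):
        rows = [AgeBand(50 + 5 * i, 55 + 5 * i, 1000.0, (i + 1) ** 3) for i in range(5)]
        s_mid = fit_loglog(rows, age_point="midpoint").slope
        s_low = fit_loglog(rows, age_point="lower").slope
        assert s_mid != s_low

    def test_poisson_mode_close_to_ols_on_clean_data(self):
        rows = []
        for lo in (60, 65, 70, 75, 80, 85):
            t = lo + 2.5
            py = 50_000.0
            rows.append(AgeBand(lo, lo + 5, py, round(math.exp(-28.0) * t**6 * py)))
        s_ols = fit_loglog(rows, method="ols").slope
        s_poi = fit_loglog(rows, method="poisson").slope
        assert s_poi == pytest.approx(s_ols, abs=0.2)


class TestStepsFromSlope:
    @pytest.mark.parametrize(
        "slope,steps",
        [
            (12.82, 14),
            (8.92, 10),
            (11.72, 13),
            (10.56, 12),
            (15.02, 16),
            (14.93, 16),
            (15.3, 16),
            (8.93, 10),
            (0.0, 1),
            (0.5, 2),  # half rounds away from zero
            (-0.5, 1),
        ],
    )
    def test_rounding_convention(self, slope, steps):
        assert steps_from_slope(slope) == steps

    def test_slope_at_or_below_minus_one_is_domain_error(self):
        with pytest.raises(SlopeDomainError):
            steps_from_slope(-1.0)
        with pytest.raises(SlopeDomainError):
            steps_from_slope(-2.5)


class TestFitCohort:
    def test_all_censored_cohort_is_insufficient(self):
        cohort = CohortTable.from_participants(
            [Participant(f"p{i}", 50.0, 70.0, False) for i in range(100)]
        )
        with pytest.raises(InsufficientDataError):
            fit_cohort(cohort, BandFilterConfig(min_person_years=100))

    def test_permutation_invariance(self, powerlaw_cohort):
        """Reordering participants changes no output bit."""
        f1 = fit_cohort(powerlaw_cohort)
        rng = np.random.default_rng(3)
        perm = rng.permutation(len(powerlaw_cohort))
        shuffled = powerlaw_cohort.subset(powerlaw_cohort.frame.index[perm])
        f2 = fit_cohort(shuffled)
        assert f2.slope == f1.slope
        assert f2.intercept == f1.intercept
        assert f2.points == f1.points

    def test_recovery_on_simulated_cohort(self, powerlaw_cohort):
        """A 6-step power-law cohort fits back to about 6 steps."""
        fit = fit_cohort(powerlaw_cohort)
        assert abs(fit.slope - 5.0) < 1.0
        assert fit.adjusted_r2 > 0.9
        assert fit.n_participants + fit.excluded_participants == len(powerlaw_cohort)

    def test_exclusion_bookkeeping_attached(self, powerlaw_cohort):
        fit = fit_cohort(powerlaw_cohort)
        assert fit.excluded_person_years > 0
        assert fit.excluded_participants > 0
        d = fit.to_dict()
        assert d["k_points"] == len(fit.points)
        assert d["n_steps"] == fit.n_steps
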