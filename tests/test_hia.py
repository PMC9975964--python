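import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cobenefits import ahmedabad
from cobenefits.exposure import population_weighted_mean
from cobenefits.grids import AnnualSurface, GridSpec, PopulationSurface
from cobenefits.hia import (
    DEFAULT_TARGETS,
    GEMM_NONACCIDENTAL,
    POPE_ALL_CAUSE,
    TURNER_ALL_CAUSE,
    AttainmentTarget,
    BaselineMortality,
    CIUnavailableError,
    GemmERF,
    LogLinearERF,
    attainment_benefit,
    attributable_deaths_loglinear,
    attributable_deaths_rr_ratio,
    beta_from_rr,
    cellwise_hia,
    confidence_interval,
    gemm_rr,
    mortality_rate_change,
    rollback_to_target,
)

from conftest import uniform_population, uniform_surface

Y0 = ahmedabad.BASELINE_MORTALITY
POP30 = ahmedabad.POPULATION["2030"].total_30_99   # 7 116 333
POP25 = ahmedabad.POPULATION["2030"].total_25_99   # 7 488 672
PW = ahmedabad.POPULATION_WEIGHTED_MEAN


def gemm_oracle(c, theta=0.143, alpha=1.6, mu=15.5, nu=36.8, c0=2.4):
    """Independent spreadsheet-style evaluation of the GEMM hazard."""
    z = max(0.0, c - c0)
    omega = 1.0 / (1.0 + math.exp(-(z - mu) / nu))
    return math.exp(theta * math.log(1.0 + z / alpha) * omega)


class TestBetaFromRR:
    def test_null_risk_gives_zero_slope(self):
        assert beta_from_rr(1.0) == 0.0

    def test_turner_slope(self):
        assert beta_from_rr(1.06) == pytest.approx(0.0058269, abs=1e-7)

    @given(rr=st.floats(0.8, 1.5))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_round_trip_recovers_rr(self, rr):
        assert math.exp(10 * beta_from_rr(rr)) == pytest.approx(rr, rel=1e-14)

    def test_non_positive_rr_rejected(self):
        with pytest.raises(ValueError):
            beta_from_rr(0.0)


class TestGemmRR:
    def test_counterfactual_anchor(self):
        assert gemm_rr(GEMM_NONACCIDENTAL.c0, GEMM_NONACCIDENTAL) == 1.0
        assert gemm_rr(0.0, GEMM_NONACCIDENTAL) == 1.0
        assert gemm_rr(1.0, GEMM_NONACCIDENTAL) == 1.0  # below counterfactual

    def test_against_independent_oracle(self):
        for c in (2.4, 10.0, 40.0, 71.04, 84.0, 150.0):
            assert gemm_rr(c, GEMM_NONACCIDENTAL) == pytest.approx(
                gemm_oracle(c), rel=1e-12
            )

    def test_adult_parameters_at_baseline_exposure(self):
        # RR at the 2018 population-weighted mean with the default adult
        # parameters is about 1.55
        assert gemm_rr(71.04, GEMM_NONACCIDENTAL) == pytest.approx(1.549, abs=0.002)

    def test_monotone_over_sweep(self):
        sweep = np.linspace(0.0, 150.0, 601)
        rr = gemm_rr(sweep, GEMM_NONACCIDENTAL)
        assert np.all(np.diff(rr) >= 0)
        assert rr[0] == 1.0


class TestAggregateFormulas:
    def test_zero_delta_gives_zero_deaths(self):
        assert attributable_deaths_loglinear(Y0, POP30, 0.0, TURNER_ALL_CAUSE) == 0.0
        assert attributable_deaths_rr_ratio(Y0, POP25, 60.0, 60.0, GEMM_NONACCIDENTAL) == 0.0

    def test_loglinear_closed_form_value(self):
        # y0=684.21, pop=7 116 333, dC=4.14, RR10=1.06 -> about 1160 deaths
        deaths = attributable_deaths_loglinear(Y0, POP30, 4.14, TURNER_ALL_CAUSE)
        expected = (684.21 / 1e5) * POP30 * (1 - math.exp(-math.log(1.06) / 10 * 4.14))
        assert deaths == pytest.approx(expected, rel=1e-12)
        assert deaths == pytest.approx(1160.4, abs=1.0)

    def test_linear_limit(self):
        beta = TURNER_ALL_CAUSE.beta
        delta = 0.1  # beta*delta ~ 6e-4 << 1
        deaths = attributable_deaths_loglinear(Y0, POP30, delta, TURNER_ALL_CAUSE)
        linear = (684.21 / 1e5) * POP30 * beta * delta
        assert deaths == pytest.approx(linear, rel=0.01)

    def test_gemm_aggregate_bau_pair(self):
        # aggregate evaluation at the published population-weighted means is
        # the same order as the published cellwise result (870)
        deaths = attributable_deaths_rr_ratio(
            Y0, POP25, PW["bau_2030"], PW["baseline_2018"], GEMM_NONACCIDENTAL
        )
        assert deaths == pytest.approx(800, abs=10)

    def test_negative_delta_gives_avoided_deaths(self):
        assert attributable_deaths_loglinear(Y0, POP30, -4.0, TURNER_ALL_CAUSE) < 0


def brute_force_hia(reference, scenario, pop, y0, erf):
    """Per-cell loop oracle for the cellwise assessment."""
    frac = pop.age_structure.fraction(erf.age_band)
    total = 0.0
    for r in range(reference.grid.n_rows):
        for c in range(reference.grid.n_cols):
            p = pop.persons[r, c] * frac
            if isinstance(erf, LogLinearERF):
                d = scenario.values[r, c] - reference.values[r, c]
                total += (y0.rate_per_100k / 1e5) * p * (1 - math.exp(-erf.beta * d))
            else:
                rr_s = gemm_oracle(
                    scenario.values[r, c], erf.theta, erf.alpha, erf.mu, erf.nu, erf.c0
                )
                rr_r = gemm_oracle(
                    reference.values[r, c], erf.theta, erf.alpha, erf.mu, erf.nu, erf.c0
                )
                total += (y0.rate_per_100k / 1e5) * p * (rr_s - rr_r) / rr_s
    return total


class TestCellwiseHIA:
    def test_no_change_no_deaths(self, grid5, pop_2030):
        surface = uniform_surface(grid5, 70.0)
        pop = uniform_population(grid5, pop_2030)
        res = cellwise_hia(surface, surface, pop, Y0, TURNER_ALL_CAUSE)
        assert res.excess_deaths == 0.0
        assert res.attributable_fraction == 0.0

    @pytest.mark.parametrize("erf", [TURNER_ALL_CAUSE, GEMM_NONACCIDENTAL])
    def test_uniform_surfaces_equal_aggregate_formula(self, grid5, pop_2030, erf):
        ref = uniform_surface(grid5, PW["baseline_2018"])
        scen = uniform_surface(grid5, PW["bau_2030"])
        pop = uniform_population(grid5, pop_2030)
        res = cellwise_hia(ref, scen, pop, Y0, erf)
        band = pop_2030.total(erf.age_band)
        if isinstance(erf, LogLinearERF):
            agg = attributable_deaths_loglinear(
                Y0, band, PW["bau_2030"] - PW["baseline_2018"], erf
            )
        else:
            agg = attributable_deaths_rr_ratio(
                Y0, band, PW["bau_2030"], PW["baseline_2018"], erf
            )
        assert res.excess_deaths == pytest.approx(agg, rel=1e-12)

    @pytest.mark.parametrize("erf", [POPE_ALL_CAUSE, GEMM_NONACCIDENTAL])
    def test_heterogeneous_matches_brute_force(
        self, random_surface_pair, random_population, erf
    ):
        ref, scen = random_surface_pair
        res = cellwise_hia(ref, scen, random_population, Y0, erf)
        oracle = brute_force_hia(ref, scen, random_population, Y0, erf)
        assert res.excess_deaths == pytest.approx(oracle, rel=1e-9)

    def test_af_bounded_for_exposure_reduction(self, grid8, pop_2030):
        pop = uniform_population(grid8, pop_2030)
        ref = uniform_surface(grid8, 80.0)
        scen = uniform_surface(grid8, 40.0)
        res = cellwise_hia(scen, ref, pop, Y0, TURNER_ALL_CAUSE)  # reduction vs ref
        af = -cellwise_hia(ref, scen, pop, Y0, TURNER_ALL_CAUSE).attributable_fraction
        assert 0.0 <= af < 1.0
        assert -1.0 < res.attributable_fraction < 1.0

    def test_deaths_scale_linearly_with_population_and_rate(self, grid5, pop_2030):
        ref = uniform_surface(grid5, 70.0)
        scen = uniform_surface(grid5, 75.0)
        pop = uniform_population(grid5, pop_2030)
        base = cellwise_hia(ref, scen, pop, Y0, TURNER_ALL_CAUSE).excess_deaths
        double_pop = PopulationSurface(grid5, pop.persons * 2, pop_2030)
        assert cellwise_hia(
            ref, scen, double_pop, Y0, TURNER_ALL_CAUSE
        ).excess_deaths == pytest.approx(2 * base, rel=1e-12)
        double_rate = BaselineMortality(Y0.rate_per_100k * 2, Y0.age_band)
        assert cellwise_hia(
            ref, scen, pop, double_rate, TURNER_ALL_CAUSE
        ).excess_deaths == pytest.approx(2 * base, rel=1e-12)

    def test_jensen_direction_for_concave_loglinear_response(self, grid8, pop_2030):
        """1 − e^{−βΔC} is concave in ΔC, so with equal cell populations the
        cellwise sum over heterogeneous positive deltas cannot exceed the
        aggregate evaluated at the mean delta."""
        rng = np.random.default_rng(17)
        deltas = rng.uniform(0.0, 20.0, grid8.shape)
        ref = uniform_surface(grid8, 50.0)
        scen = AnnualSurface(grid8, 50.0 + deltas)
        pop = uniform_population(grid8, pop_2030)
        cellwise = cellwise_hia(ref, scen, pop, Y0, TURNER_ALL_CAUSE).excess_deaths
        aggregate = attributable_deaths_loglinear(
            Y0, pop_2030.total_30_99, float(deltas.mean()), TURNER_ALL_CAUSE
        )
        assert cellwise <= aggregate + 1e-9

    def test_approximate_scenario_antisymmetry(self, grid5, pop_2030):
        ref = uniform_surface(grid5, 71.0)
        scen = uniform_surface(grid5, 75.0)
        pop = uniform_population(grid5, pop_2030)
        fwd = cellwise_hia(ref, scen, pop, Y0, TURNER_ALL_CAUSE).excess_deaths
        bwd = cellwise_hia(scen, ref, pop, Y0, TURNER_ALL_CAUSE).excess_deaths
        beta, dc = TURNER_ALL_CAUSE.beta, 4.0
        assert abs(fwd + bwd) / abs(fwd) <= math.exp(beta * dc) - 1 + 1e-12


class TestConfidenceInterval:
    def setup_case(self, grid5, pop_2030, hi=True):
        ref = uniform_surface(grid5, PW["baseline_2018"])
        scen = uniform_surface(grid5, PW["bau_2030"] if hi else PW["ma_2030"])
        pop = uniform_population(grid5, pop_2030)
        return ref, scen, pop

    def test_interval_brackets_central_for_positive_delta(self, grid5, pop_2030):
        ref, scen, pop = self.setup_case(grid5, pop_2030)
        res = cellwise_hia(ref, scen, pop, Y0, TURNER_ALL_CAUSE)
        lo, hi = confidence_interval(res)
        assert lo < res.excess_deaths < hi

    def test_order_reversed_for_negative_delta(self, grid5, pop_2030):
        ref, scen, pop = self.setup_case(grid5, pop_2030, hi=False)
        res = cellwise_hia(ref, scen, pop, Y0, TURNER_ALL_CAUSE)
        lo, hi = res.ci
        # all bounds negative, larger risk -> larger avoided magnitude
        assert res.excess_deaths < 0 and lo < 0 and hi < 0
        assert hi < res.excess_deaths < lo

    def test_degenerate_ci_zero_width(self, grid5, pop_2030):
        erf = LogLinearERF("flat", 1.06, 1.06, 1.06)
        ref, scen, pop = self.setup_case(grid5, pop_2030)
        res = cellwise_hia(ref, scen, pop, Y0, erf)
        lo, hi = confidence_interval(res)
        assert lo == res.excess_deaths == hi

    def test_missing_ci_raises(self, grid5, pop_2030):
        erf = LogLinearERF("noci", 1.06)
        ref, scen, pop = self.setup_case(grid5, pop_2030)
        res = cellwise_hia(ref, scen, pop, Y0, erf)
        with pytest.raises(CIUnavailableError):
            confidence_interval(res)

    def test_gemm_ci_uses_theta_bounds(self, grid5, pop_2030):
        ref, scen, pop = self.setup_case(grid5, pop_2030)
        res = cellwise_hia(ref, scen, pop, Y0, GEMM_NONACCIDENTAL)
        lo, hi = confidence_interval(res)
        assert lo < res.excess_deaths < hi


class TestMortalityRateChange:
    def test_zero_excess(self):
        rate, pct = mortality_rate_change(0.0, POP30, Y0)
        assert rate == Y0.rate_per_100k and pct == 0.0

    def test_printed_rate_pair_is_internally_consistent(self):
        # 707.95 vs 684.21 is +3.47%
        pct = 100 * (707.95 - 684.21) / 684.21
        assert pct == pytest.approx(3.47, abs=0.005)

    def test_rate_increment_from_death_count(self):
        rate, _ = mortality_rate_change(1389.0, POP30, Y0)
        assert rate - Y0.rate_per_100k == pytest.approx(19.52, abs=0.01)


class TestRollback:
    def test_surface_already_attaining_is_unchanged(self, grid5, pop_2030):
        surface = uniform_surface(grid5, 30.0)
        pop = uniform_population(grid5, pop_2030)
        target = AttainmentTarget("NAAQS", level=40.0)
        assert rollback_to_target(surface, pop, target) is surface

    def test_ncap_goal_arithmetic(self):
        target = AttainmentTarget("NCAP", percent_reduction=30.0)
        assert target.goal(71.04) == pytest.approx(49.728)

    def test_who_goal_ignores_baseline(self):
        target = AttainmentTarget("WHO_AQG", level=5.0)
        assert target.goal(71.04) == 5.0
        assert target.goal() == 5.0

    def test_proportional_rollback_hits_goal_exactly(self, grid8, random_population):
        rng = np.random.default_rng(23)
        surface = AnnualSurface(grid8, rng.uniform(50, 100, grid8.shape))
        target = AttainmentTarget("NAAQS", level=40.0)
        rolled = rollback_to_target(surface, random_population, target)
        assert population_weighted_mean(rolled, random_population) == pytest.approx(
            40.0, abs=1e-9
        )

    def test_cap_method_truncates_cells(self, grid5, pop_2030):
        surface = uniform_surface(grid5, 70.0)
        pop = uniform_population(grid5, pop_2030)
        rolled = rollback_to_target(
            surface, pop, AttainmentTarget("NAAQS", level=40.0), method="cap"
        )
        assert rolled.values.max() == 40.0


class TestAttainmentBenefit:
    def test_target_above_current_mean_avoids_nothing(self, grid5, pop_2030):
        surface = uniform_surface(grid5, 30.0)
        pop = uniform_population(grid5, pop_2030)
        ben = attainment_benefit(
            surface, AttainmentTarget("NAAQS", level=40.0), pop, Y0,
            [TURNER_ALL_CAUSE, GEMM_NONACCIDENTAL],
        )
        assert ben.max_avoided == 0.0

    def test_deeper_targets_avoid_strictly_more(self, grid8, random_population):
        """WHO guideline > national standard > national programme, for every
        exposure-response function, at the published exposure levels."""
        rng = np.random.default_rng(29)
        values = rng.uniform(60, 95, grid8.shape)
        surface = AnnualSurface(grid8, values, scenario="bau")
        benefits = {
            t.name: attainment_benefit(
                surface, t, random_population, Y0,
                [POPE_ALL_CAUSE, TURNER_ALL_CAUSE, GEMM_NONACCIDENTAL],
                baseline_mean=71.04,
            )
            for t in DEFAULT_TARGETS
        }
        for erf in ("pope_all_cause", "turner_all_cause", "gemm_non_accidental"):
            who = benefits["WHO_AQG"].avoided_by_erf[erf]
            naaqs = benefits["NAAQS"].avoided_by_erf[erf]
            ncap = benefits["NCAP"].avoided_by_erf[erf]
            assert who > naaqs > ncap > 0

    def test_matches_two_scenario_hia_oracle(self, grid5, pop_2030):
        rng = np.random.default_rng(31)
        surface = AnnualSurface(grid5, rng.uniform(55, 90, (5, 5)))
        pop = uniform_population(grid5, pop_2030)
        target = AttainmentTarget("NAAQS", level=40.0)
        ben = attainment_benefit(surface, target, pop, Y0, [TURNER_ALL_CAUSE])
        rolled = rollback_to_target(surface, pop, target)
        direct = brute_force_hia(surface, rolled, pop, Y0, TURNER_ALL_CAUSE)
        assert ben.avoided_by_erf["turner_all_cause"] == pytest.approx(
            -direct, rel=1e-9
        )
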