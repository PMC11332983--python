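import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hdtfc.engine import (
    STATE_COLUMNS,
    CohortTrace,
    LifeTable,
    accumulate_outcomes,
    median_survival,
    run_cohort,
    run_pfd_cohort,
)
from hdtfc.exceptions import DataError, ValidationError
from hdtfc.onset import OnsetSchedule
from hdtfc.parameters import DMTScenario, TrajectoryObservation, load_parameters
from hdtfc.progression import build_transition_matrix

TFC_COLS = slice(1, 14)
DEAD_PROG = STATE_COLUMNS.index("dead_progression")
DEAD_BG = STATE_COLUMNS.index("dead_background")


def params_with_rate(population, p, **overrides):
    """Parameter set whose fitted slope is exactly -p (collinear points)."""
    traj = [{"time_years": 0.0, "mean_delta": 0.0},
            {"time_years": 1.0, "mean_delta": -p},
            {"time_years": 2.0, "mean_delta": -2 * p}]
    return load_parameters({"trajectories": traj, **overrides},
                           population=population)


class TestLifeTable:
    def test_contiguity_enforced(self):
        with pytest.raises(DataError, match="contiguous"):
            LifeTable(np.array([40, 42]), np.array([0.01, 0.01]))

    def test_q_out_of_range_names_age(self):
        with pytest.raises(DataError, match="41"):
            LifeTable(np.array([40, 41]), np.array([0.01, 1.5]))

    def test_coverage_gap(self, life_table):
        with pytest.raises(DataError, match="covers"):
            life_table.require_coverage(30, 100)

    def test_lookup(self, life_table):
        assert 0.001 < life_table.q(40) < 0.01


class TestRunCohort:
    def test_deterministic_stepping_p1(self, zero_mortality_table):
        params = params_with_rate("SF2", 1.0, start_tfc=10, max_age=140)
        # TFC 10 -> 9 -> ... but from TFC 3 onward: state 3,2,1 then death at t=...
        params = params.replace(start_tfc=7)
        trace = run_cohort(params, zero_mortality_table)
        # start TFC 7: after 7 cycles the whole cohort is dead from progression
        assert trace.occupancy[7, DEAD_PROG] == pytest.approx(1.0)
        assert trace.survival[6] == pytest.approx(1.0)

    def test_p0_constant_occupancy(self, zero_mortality_table):
        params = params_with_rate("SF1", 0.0, max_age=120)
        trace = run_cohort(params, zero_mortality_table)
        assert np.allclose(trace.occupancy, trace.occupancy[0])

    def test_pfd_population_rejected(self, life_table, pfd_params):
        with pytest.raises(ValidationError):
            run_cohort(pfd_params, life_table)

    def test_mass_conservation(self, sf1_params, life_table):
        trace = run_cohort(sf1_params, life_table)
        assert np.abs(trace.occupancy.sum(axis=1) - 1.0).max() < 1e-12

    def test_survival_monotone_dead_nondecreasing(self, sf1_params, life_table):
        trace = run_cohort(sf1_params, life_table)
        assert (np.diff(trace.survival) <= 1e-15).all()
        assert (np.diff(trace.occupancy[:, DEAD_PROG]) >= -1e-15).all()
        assert (np.diff(trace.occupancy[:, DEAD_BG]) >= -1e-15).all()

    @settings(max_examples=25, deadline=None)
    @given(p=st.floats(0.05, 1.0), q=st.floats(0.0, 0.2))
    def test_mass_conservation_property(self, p, q):
        lt = LifeTable(np.arange(40, 100), np.full(60, q))
        params = params_with_rate("SF1", p)
        trace = run_cohort(params, lt)
        assert np.abs(trace.occupancy.sum(axis=1) - 1.0).max() < 1e-12
        assert (np.diff(trace.survival) <= 1e-15).all()

    def test_matches_matrix_propagation_oracle(self, sf2_params, life_table):
        """Independent route: propagate with explicit transition matrices."""
        from hdtfc.progression import ProgressionModel

        trace = run_cohort(sf2_params, life_table)
        p = ProgressionModel.from_observations(
            sf2_params.trajectories).annual_transition_probability
        state = np.zeros(14)
        state[13 - sf2_params.start_tfc] = 1.0
        for t in range(sf2_params.horizon):
            m = build_transition_matrix(p, life_table.q(40 + t))
            state = state @ m
            alive = trace.occupancy[t + 1, TFC_COLS]
            assert np.allclose(state[:13], alive, atol=1e-12)
            dead = trace.occupancy[t + 1, DEAD_PROG] + trace.occupancy[t + 1, DEAD_BG]
            assert state[13] == pytest.approx(dead, abs=1e-12)

    def test_expected_time_to_death_negative_binomial(self, zero_mortality_table):
        # q=0, RR=1: expected cycles from TFC k to death is k/p
        k, p = 5, 0.4
        params = params_with_rate("SF2", p, start_tfc=7, max_age=350,
                                  start_age=0)
        params = params.replace(start_tfc=7)
        k = 7
        trace = run_cohort(params, zero_mortality_table)
        expected_cycles = trace.survival[:-1].sum()
        assert expected_cycles == pytest.approx(k / p, rel=1e-6)

    def test_median_matches_monte_carlo_negative_binomial(self, zero_mortality_table,
                                                          rng):
        k, p = 9, 0.55
        params = params_with_rate("SF2", p, start_tfc=9, start_age=0, max_age=200)
        trace = run_cohort(params, zero_mortality_table)
        model_median = median_survival(trace)
        sim = rng.negative_binomial(k, p, size=100_000) + k
        mc_median = np.median(sim)
        assert abs(model_median - mc_median) <= 1.0  # interpolation width

    def test_dmt_identity_reproduces_natural_history(self, sf1_params, life_table):
        natural = run_cohort(sf1_params, life_table)
        identity = run_cohort(
            sf1_params.replace(dmt=DMTScenario(0, 1.0)), life_table)
        assert (natural.occupancy == identity.occupancy).all()

    def test_dmt_delay_arrests_progression(self, life_table):
        params = params_with_rate("SF1", 0.6).replace(dmt=DMTScenario(3, 1.0))
        trace = run_cohort(params, life_table)
        # during the delay only background death moves mass
        assert trace.occupancy[3, DEAD_PROG] == 0.0
        start_col = 1 + (13 - params.start_tfc)
        assert trace.occupancy[3, start_col] == pytest.approx(
            np.prod([1 - life_table.q(40 + t) for t in range(3)]))


class TestRunPfdCohort:
    def test_single_subcohort_collapses_to_sf1_trace(self, pfd_params, life_table):
        w = np.zeros(60)
        w[0] = 1.0
        schedule = OnsetSchedule(40, w)
        pooled = run_pfd_cohort(pfd_params, schedule, life_table)
        sf1_like = pfd_params.replace(population="SF1", start_tfc=13)
        direct = run_cohort(sf1_like, life_table)
        assert np.allclose(pooled.occupancy, direct.occupancy, atol=1e-12)

    def test_residual_only_is_background_mortality(self, pfd_params, life_table):
        schedule = OnsetSchedule(40, np.zeros(60), residual_weight=1.0)
        pooled = run_pfd_cohort(pfd_params, schedule, life_table)
        expected = np.cumprod([1 - life_table.q(40 + t) for t in range(60)])
        assert np.allclose(pooled.survival[1:], expected, atol=1e-12)
        assert pooled.occupancy[:, DEAD_PROG].max() == 0.0

    def test_two_point_mixture_oracle(self, pfd_params, life_table):
        w = np.zeros(60)
        w[0] = w[5] = 0.5
        pooled = run_pfd_cohort(pfd_params, OnsetSchedule(40, w), life_table)
        w0 = np.zeros(60); w0[0] = 1.0
        w5 = np.zeros(60); w5[5] = 1.0
        t0 = run_pfd_cohort(pfd_params, OnsetSchedule(40, w0), life_table)
        t5 = run_pfd_cohort(pfd_params, OnsetSchedule(40, w5), life_table)
        assert np.allclose(pooled.occupancy,
                           0.5 * t0.occupancy + 0.5 * t5.occupancy, atol=1e-12)

    def test_horizon_mismatch_rejected(self, pfd_params, life_table):
        w = np.full(80, 1 / 80)
        with pytest.raises(DataError, match="horizon"):
            run_pfd_cohort(pfd_params, OnsetSchedule(40, w), life_table)

    def test_packaged_schedule_mass_conserved(self, pfd_params, cag40_schedule,
                                              life_table):
        trace = run_pfd_cohort(pfd_params, cag40_schedule, life_table)
        assert np.abs(trace.occupancy.sum(axis=1) - 1.0).max() < 1e-9


class TestMedianSurvival:
    def test_forced_interpolation_example(self):
        occ = np.zeros((11, len(STATE_COLUMNS)))
        occ[:10, 1] = 1.0  # fully alive through t=9
        occ[10, 1] = 0.4
        occ[10, DEAD_BG] = 0.6
        trace = CohortTrace(40, occ, np.zeros(11))
        assert median_survival(trace) == pytest.approx(9 + 0.5 / 0.6)

    def test_never_crossed_is_inf(self, zero_mortality_table):
        params = params_with_rate("SF1", 0.0, max_age=120)
        trace = run_cohort(params, zero_mortality_table)
        assert median_survival(trace) == float("inf")


class TestAccumulateOutcomes:
    def test_unit_utilities_zero_discount(self, sf1_params, life_table):
        params = load_parameters(
            {"utilities": {"PFD": 1.0, "SF1": 1.0, "SF2": 1.0, "SF3": 1.0,
                           "SF4": 1.0},
             "discount_rate": 0.0},
            population="SF1")
        trace = run_cohort(params, life_table)
        o = accumulate_outcomes(trace, params.payoffs, 0.0)
        assert o.qalys.discounted == pytest.approx(o.life_years.discounted)
        assert o.qalys.undiscounted == pytest.approx(o.life_years.undiscounted)

    def test_zero_discount_equalizes(self, sf1_params, life_table):
        trace = run_cohort(sf1_params, life_table)
        o = accumulate_outcomes(trace, sf1_params.payoffs, 0.0)
        assert o.life_years.discounted == pytest.approx(o.life_years.undiscounted)
        assert o.total_cost.discounted == pytest.approx(o.total_cost.undiscounted)

    def test_discounted_le_undiscounted(self, sf2_params, life_table):
        trace = run_cohort(sf2_params, life_table)
        o = accumulate_outcomes(trace, sf2_params.payoffs, 0.03)
        assert o.life_years.discounted <= o.life_years.undiscounted
        assert o.qalys.discounted <= o.qalys.undiscounted
        for v in o.cost.values():
            assert v.discounted <= v.undiscounted + 1e-12

    def test_qalys_le_life_years(self, sf1_params, life_table):
        trace = run_cohort(sf1_params, life_table)
        o = accumulate_outcomes(trace, sf1_params.payoffs, 0.03)
        assert o.qalys.discounted <= o.life_years.discounted
        assert o.qalys.undiscounted <= o.life_years.undiscounted

    def test_stage_time_utility_identity(self, sf1_params, life_table):
        """Stage-s discounted person-years equal stage-s QALYs / utility and
        also the direct occupancy sum - the internal consistency identity."""
        trace = run_cohort(sf1_params, life_table)
        o = accumulate_outcomes(trace, sf1_params.payoffs, 0.03)
        disc = 1.03 ** (-np.arange(trace.n_cycles))
        tfc_occ = trace.alive_tfc()[:trace.n_cycles]
        sf1_time = (tfc_occ[:, 0:3] * disc[:, None]).sum()
        assert o.qalys_by_stage["SF1"].discounted / 0.78 == pytest.approx(
            sf1_time, rel=1e-12)

    def test_total_cost_is_sum_of_cells(self, sf2_params, life_table):
        trace = run_cohort(sf2_params, life_table)
        o = accumulate_outcomes(trace, sf2_params.payoffs, 0.03)
        total = sum(v.discounted for v in o.cost.values())
        assert o.total_cost.discounted == pytest.approx(total, rel=1e-9)

    def test_terminal_cost_option(self, sf1_params, life_table):
        trace = run_cohort(sf1_params, life_table)
        base = accumulate_outcomes(trace, sf1_params.payoffs, 0.03)
        assert base.cost[("direct", "SF5")].discounted == 0.0
        params = load_parameters({"apply_sf5_terminal_cost": True},
                                 population="SF1")
        with_term = accumulate_outcomes(trace, params.payoffs, 0.03)
        disc = 1.03 ** (-np.arange(trace.n_cycles + 1))
        expected = (trace.entry_to_death * disc).sum() * 25217.0
        assert with_term.cost[("direct", "SF5")].discounted == pytest.approx(expected)

    def test_pfd_utility_and_zero_cost(self, pfd_params, life_table):
        # residual-only schedule: all person-time in PFD at utility 0.86, no cost
        schedule = OnsetSchedule(40, np.zeros(60), residual_weight=1.0)
        trace = run_pfd_cohort(pfd_params, schedule, life_table)
        o = accumulate_outcomes(trace, pfd_params.payoffs, 0.03, "PFD")
        assert o.qalys.discounted == pytest.approx(
            0.86 * o.life_years.discounted, rel=1e-12)
        assert o.total_cost.discounted == 0.0
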