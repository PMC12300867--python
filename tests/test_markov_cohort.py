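"""Cohort engine: transition construction, tracing, flows, conservation."""

import numpy as np
import pytest

from dietmarkov import (build_transition_matrix, cumulative_incidence,
                        cumulative_t2d_deaths, initial_occupancy, run_cohort)
from dietmarkov.errors import ModelError
from dietmarkov.markov_cohort import CHRONIC, DEATH_OTHER, DEATH_T2D, HEALTHY

from conftest import make_stratum


class TestInitialOccupancy:
    def test_prevalence_split(self, japan):
        occ = initial_occupancy(japan.stratum("men", "40-49"))
        assert occ[CHRONIC] == pytest.approx(535_864.71)
        assert occ[HEALTHY] == pytest.approx(8_838_135.29)
        assert occ[DEATH_T2D] == occ[DEATH_OTHER] == 0.0

    def test_degenerate_prevalence(self):
        all_healthy = initial_occupancy(make_stratum(prevalence=0.0))
        assert all_healthy[HEALTHY] == 1_000_000.0
        assert all_healthy[CHRONIC] == 0.0
        all_chronic = initial_occupancy(
            make_stratum(prevalence=99_999.999999))
        assert all_chronic[CHRONIC] == pytest.approx(1_000_000.0)


class TestBuildTransitionMatrix:
    def test_published_rates_become_probabilities(self, japan):
        m = build_transition_matrix(japan.stratum("men", "70-79"), 1.0)
        assert m[HEALTHY, CHRONIC] == pytest.approx(0.003177)
        assert m[HEALTHY, DEATH_OTHER] == pytest.approx(0.025622)
        assert m[HEALTHY, DEATH_T2D] == 0.0
        assert m[CHRONIC, DEATH_T2D] == pytest.approx(0.000170)
        assert m[CHRONIC, HEALTHY] == 0.0  # no remission

    @pytest.mark.parametrize("rr", [0.0, 0.5, 1.0, 2.0])
    def test_rows_stochastic_and_deaths_absorbing(self, japan, rr):
        for s in japan.strata:
            m = build_transition_matrix(s, rr)
            np.testing.assert_allclose(m.sum(axis=1), 1.0, atol=1e-12)
            assert (m >= 0).all() and (m <= 1).all()
            np.testing.assert_array_equal(m[DEATH_T2D],
                                          np.eye(4)[DEATH_T2D])
            np.testing.assert_array_equal(m[DEATH_OTHER],
                                          np.eye(4)[DEATH_OTHER])

    def test_zero_rates_give_identity(self):
        s = make_stratum(incidence=0, prevalence=0, t2d_mortality=0,
                         all_cause_mortality=0)
        np.testing.assert_array_equal(build_transition_matrix(s, 1.0),
                                      np.eye(4))

    def test_excess_incidence_is_parameterization_error(self):
        s = make_stratum(incidence=90_000.0)
        with pytest.raises(ModelError, match="healthy"):
            build_transition_matrix(s, 1.5)


class TestRunCohort:
    def test_zero_horizon_is_initial_row_only(self, japan):
        trace = run_cohort(japan.stratum("men", "40-49"), 1.0, 0)
        assert trace.occupancy.shape == (1, 4)
        assert cumulative_incidence(trace) == 0.0
        assert cumulative_t2d_deaths(trace) == 0.0

    def test_identity_dynamics_are_constant(self):
        s = make_stratum(incidence=0, t2d_mortality=0, all_cause_mortality=0)
        trace = run_cohort(s, 1.0, 10)
        for row in trace.occupancy:
            np.testing.assert_array_equal(row, trace.occupancy[0])

    def test_conservation_every_cycle(self, japan):
        for s in japan.strata:
            for rr in (1.0, 0.8214644823300881):
                trace = run_cohort(s, rr, japan.horizon)
                np.testing.assert_allclose(trace.occupancy.sum(axis=1),
                                           s.population, atol=1e-6)

    def test_cumulative_incidence_matches_geometric_closed_form(self, japan):
        # independent oracle: healthy pool decays geometrically, so the
        # summed incident flow is H0 * p * (1 - r**h) / (1 - r)
        for s in japan.strata:
            p_inc = s.incidence.value / 1e5
            p_do = (s.all_cause_mortality.value - s.t2d_mortality.value) / 1e5
            r = 1.0 - p_inc - p_do
            h0 = s.population * (1.0 - s.prevalence.value / 1e5)
            closed_form = h0 * p_inc * (1.0 - r ** 10) / (1.0 - r)
            trace = run_cohort(s, 1.0, 10)
            assert cumulative_incidence(trace) == pytest.approx(
                closed_form, rel=1e-12)

    def test_flows_equal_absorbing_and_chronic_balance(self, japan):
        s = japan.stratum("women", "60-69")
        trace = run_cohort(s, 1.0, 10)
        # every T2D death lands in the absorbing DeathT2D state
        assert trace.occupancy[-1, DEATH_T2D] == pytest.approx(
            cumulative_t2d_deaths(trace), rel=1e-12)
        # chronic balance: inflow - outflows = net occupancy change
        p_do = (s.all_cause_mortality.value - s.t2d_mortality.value) / 1e5
        other_deaths = (trace.occupancy[:-1, CHRONIC] * p_do).sum()
        net = trace.occupancy[-1, CHRONIC] - trace.occupancy[0, CHRONIC]
        assert cumulative_incidence(trace) - cumulative_t2d_deaths(trace) \
            - other_deaths == pytest.approx(net, rel=1e-9)

    def test_absorbing_states_never_lose_mass(self, japan):
        trace = run_cohort(japan.stratum("men", "70-79"), 1.0, 10)
        for state in (DEATH_T2D, DEATH_OTHER):
            assert (np.diff(trace.occupancy[:, state]) >= 0).all()

    def test_outcomes_monotone_in_rr_multiplier(self, japan):
        s = japan.stratum("men", "50-59")
        rr_grid = [0.2, 0.5, 0.8, 1.0]
        incidences = []
        deaths = []
        for rr in rr_grid:
            trace = run_cohort(s, rr, 10)
            incidences.append(cumulative_incidence(trace))
            deaths.append(cumulative_t2d_deaths(trace))
        assert incidences == sorted(incidences)
        assert deaths == sorted(deaths)
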