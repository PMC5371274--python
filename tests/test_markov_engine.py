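"""Lifetime Markov cohort engine: structure, dynamics, closed forms."""

import math

import numpy as np
import pytest

from quitcea.errors import ValidationError
from quitcea.markov_engine import (
    StateSpace,
    accumulate,
    annual_quit_dynamics,
    build_state_space,
    compare_strategies,
    cvd_event_outcome,
    lc_rr_exsmoker,
    relapse_hazard,
    run_cohort,
)
from quitcea.parameters import UncertainValue


def zero_risk_params(params):
    """All disease and mortality risks off, equal utilities in both arms."""
    p = params.copy()
    for group in (p.background_mortality, p.lc_incidence, p.cvd_incidence):
        for sex in group:
            group[sex] = group[sex].scaled(0.0)
    p.utility_well_quit = p.utility_well_smoking
    return p


class TestStateSpace:
    def test_tunnel_and_quit_expansion_counts(self):
        sp = build_state_space(tunnel_years=5, quit_memory_years=15)
        lc_states = [n for n in sp.names if n.startswith("lc_")]
        assert len(lc_states) == 10  # 2 stages x 5 tunnel years
        quit_states = [n for n in sp.names if n.startswith("well_quit")]
        assert len(quit_states) == 15
        assert sp.names.count("cvd") == 1  # exactly one living CVD state
        assert [n for n in sp.names if n.startswith("dead")] == [
            "dead_other", "dead_lung_cancer", "dead_cvd",
        ]

    def test_degenerate_tunnel_collapses_to_single_year_states(self):
        sp = build_state_space(tunnel_years=1)
        assert sum(n.startswith("lc_") for n in sp.names) == 2

    def test_invalid_depths_rejected(self):
        with pytest.raises(ValidationError):
            build_state_space(tunnel_years=0)
        with pytest.raises(ValidationError):
            build_state_space(quit_memory_years=10)


class TestQuitAndRelapseDynamics:
    def test_cycle_zero_quit_then_21pct_relapse(self):
        quit_flow, relapse = annual_quit_dynamics(0, smoker_share=2000.0, quit_prob=0.5)
        assert quit_flow == 1000.0
        assert relapse == pytest.approx(210.0)

    def test_three_year_hazard_matches_30pct_cumulative(self):
        h = relapse_hazard(0.30, 3)
        assert h == pytest.approx(0.1121, abs=5e-5)
        assert (1 - h) ** 3 == pytest.approx(0.70, rel=1e-12)
        _, relapse = annual_quit_dynamics(1, 0.0, quitter_share=1000.0)
        assert 1000.0 - relapse == pytest.approx(887.9, abs=0.05)

    def test_no_relapse_beyond_three_years(self):
        assert annual_quit_dynamics(5, 0.0, quitter_share=1000.0) == (0.0, 0.0)

    def test_negative_cycle_rejected(self):
        with pytest.raises(ValidationError):
            annual_quit_dynamics(-1, 1.0)


class TestRelativeRiskDecay:
    @pytest.mark.parametrize(
        "years,expected",
        [(0.0, 1.771), (7.5, 1.3855), (15.0, 1.0), (40.0, 1.0)],
    )
    def test_linear_decay_to_unity_at_fifteen_years(self, years, expected):
        assert lc_rr_exsmoker(years, 1.771) == pytest.approx(expected)


class TestCvdEventOutcome:
    def test_fatality_composition(self):
        out = cvd_event_outcome(1.0)
        total_fatal = out["instant_death_share"] + out["early_death_share"]
        assert total_fatal == pytest.approx(0.181 + 0.819 * 0.071)  # ~0.2392
        assert out["survivor_share"] == pytest.approx(1.0 - total_fatal)

    def test_no_events_no_shares(self):
        out = cvd_event_outcome(0.0)
        assert all(v == 0.0 for v in out.values())

    def test_survivors_never_leave_cvd_state(self, params):
        trace = run_cohort(params, "usual_care", "male", 60)
        sp = trace.space
        # once anyone occupies CVD, outflow only to death: occupancy can
        # only fall by the mortality applied that cycle
        occ = trace.occupancy
        mort = params.background_mortality["male"].slice(60, params.horizon_age)
        for t in range(trace.n_cycles):
            inflow_free_min = occ[t, sp.CVD] * (1 - mort[t])
            assert occ[t + 1, sp.CVD] >= inflow_free_min - 1e-12


class TestCohortClosedForms:
    def test_closed_system_with_no_risks(self, params):
        p = zero_risk_params(params)
        trace = run_cohort(p, "intervention", "male", 40)
        well = trace.occupancy[:, : trace.space.QUIT.stop].sum(axis=1)
        assert np.allclose(well, 1.0, atol=1e-12)

    def test_certain_mortality_flushes_cohort(self, params):
        p = params.copy()
        for sex in p.background_mortality:
            p.background_mortality[sex] = p.background_mortality[sex].scaled(0.0)
        p.background_mortality["male"].values[:] = 1.0
        trace = run_cohort(p, "usual_care", "male", 40)
        assert trace.occupancy[1, trace.space.LIVING].sum() == 0.0
        assert trace.occupancy[-1, trace.space.DEAD].sum() == pytest.approx(1.0)

    def test_constant_mortality_matches_geometric_closed_form(self, params):
        """Well/dead reduction: occupancy_well(t) = (1 - m)^t to 1e-12."""
        m = 0.0123
        p = zero_risk_params(params)
        for sex in p.background_mortality:
            p.background_mortality[sex].values[:] = m
        trace = run_cohort(p, "usual_care", "female", 40)
        living = trace.occupancy[:, trace.space.LIVING].sum(axis=1)
        expected = (1 - m) ** np.arange(trace.n_cycles + 1)
        assert np.max(np.abs(living - expected)) < 1e-12

    def test_discounted_qalys_match_geometric_sum(self, params):
        """Ten cycles of perfect survival at utility 1 discount to the
        closed-form annuity sum 8.6077 at 3.5%."""
        p = zero_risk_params(params)
        p.utility_well_smoking = 1.0
        p.utility_well_quit = 1.0
        p.horizon_age = 50
        trace = run_cohort(p, "usual_care", "male", 40)
        res = accumulate(trace, p)
        expected = sum(1.035 ** -t for t in range(10))
        assert expected == pytest.approx(8.6077, abs=5e-5)
        assert res.discounted_qalys == pytest.approx(expected, rel=1e-12)
        res0 = accumulate(trace, zero_risk_params(params))  # utility 0.8, 10 cycles
        assert res0.undiscounted_qalys == pytest.approx(8.0, rel=1e-12)

    def test_quit_gain_matches_hand_closed_form(self, params):
        """With no risks, no relapse and no discounting, dQALY = d*g*T."""
        p = zero_risk_params(params)
        p.discount_rate = 0.0
        p.relapse_24wk_to_12mo = 0.0
        p.relapse_after_12mo_cumulative = 0.0
        p.utility_well_quit = 0.830
        p.horizon_age = 60
        ce = compare_strategies(p, "male", 40)
        d = 0.352 - 0.242
        g = 0.830 - 0.800
        T = 60 - 40 - 1  # utility gain starts the first post-quit cycle
        assert ce.delta_effect == pytest.approx(d * g * T, rel=1e-12)

    def test_zero_risk_limit_gives_programme_cost_only(self, params):
        p = zero_risk_params(params)
        ce = compare_strategies(p, "male", 40)
        assert ce.delta_effect == pytest.approx(0.0, abs=1e-12)
        assert ce.delta_cost == pytest.approx(622.91 - 195.33, abs=1e-9)
        assert ce.classification == "undefined"


class TestTraceInvariants:
    @pytest.mark.parametrize("sex", ["male", "female"])
    @pytest.mark.parametrize("strategy", ["intervention", "usual_care"])
    def test_conservation_and_monotone_death(self, params, sex, strategy):
        trace = run_cohort(params, strategy, sex, 40)
        sums = trace.occupancy.sum(axis=1)
        assert np.max(np.abs(sums - 1.0)) < 1e-9
        dead = trace.occupancy[:, trace.space.DEAD].sum(axis=1)
        assert np.all(np.diff(dead) >= -1e-15)
        assert trace.occupancy.min() >= 0.0

    def test_discounting_never_increases_qalys(self, params):
        trace = run_cohort(params, "intervention", "male", 40)
        base = accumulate(trace, params)
        assert base.discounted_qalys <= base.undiscounted_qalys
        higher = params.copy()
        higher.discount_rate = 0.05
        assert accumulate(trace, higher).discounted_qalys < base.discounted_qalys

    def test_higher_quit_rate_never_lowers_incremental_qalys(self, params):
        gains = []
        for q in (0.30, 0.36, 0.42):
            p = params.copy()
            p.quit_rate[("adherent_intervention", "male")] = UncertainValue(
                q, 0.047, "beta"
            )
            gains.append(compare_strategies(p, "male", 40).delta_effect)
        assert gains == sorted(gains)

    def test_start_age_beyond_horizon_rejected(self, params):
        with pytest.raises(ValidationError):
            run_cohort(params, "usual_care", "male", 100)


class TestMicrosimulationOracle:
    def test_cohort_trace_matches_individual_simulation(self, params, microsim):
        """Occupancy from 10^5 simulated individuals agrees with the cohort
        trace within 4 binomial standard errors at every cycle (20-year run)."""
        p = params.copy()
        p.horizon_age = 80
        n = 100_000
        space = StateSpace(p.lc_tunnel.years)
        trace = run_cohort(p, "intervention", "male", 60, space)
        sim = microsim(p, "intervention", "male", 60, n, seed=123, space=space)
        expected = trace.occupancy
        se = np.sqrt(np.clip(expected * (1 - expected), 0, None) / n)
        assert np.all(np.abs(sim - expected) <= 4 * se + 1e-4)
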