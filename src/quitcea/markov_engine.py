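"""Lifetime Markov cohort model of smoking, quitting, CVD and lung cancer.

Annual cycles track sex-specific cohorts from a start age (default 40) to
age 100 through the states

* well, smoking;
* well, quit — expanded by years since quitting so the lung-cancer relative
  risk can decay and relapse can be confined to the first years;
* lung cancer, early and advanced stage — tunnel sub-states indexed by years
  since diagnosis, so progression/death depend on time in state;
* CVD — entered by event survivors, with permanently reduced utility;
* dead — absorbing, disaggregated by cause (other / lung cancer / CVD) so
  terminal-care costs can be attached to the right deaths.

Within a cycle events apply in a fixed order: background mortality, then
disease-specific mortality/progression, then disease incidence, then
quit/relapse flows.  Cohorts in both strategies share every parameter except
the trial quit probability and the programme cost charged at cycle 0.

No half-cycle correction is applied by default (annual cycles, state
membership evaluated at cycle start); ``accumulate(..., half_cycle=True)``
switches to trapezoid occupancy for exploration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import trial_cea
from .errors import CoverageError, ValidationError
from .parameters import ModelParameters, SEXES

logger = logging.getLogger(__name__)

STRATEGIES = ("intervention", "usual_care")
_STRATEGY_ARM = {"intervention": "adherent_intervention", "usual_care": "usual_care"}


class StateSpace:
    """Enumerated model states with index bookkeeping.

    ``quit_memory_years`` well-quit sub-states track years since quitting
    (the last one is absorbing in quit-time); each lung-cancer stage has
    ``tunnel_years`` sub-states indexed by years since diagnosis (the last
    one holds long-term survivors).
    """

    def __init__(self, tunnel_years: int = 5, quit_memory_years: int = 16):
        if tunnel_years < 1:
            raise ValidationError("tunnel_years must be >= 1")
        if quit_memory_years < 15:
            raise ValidationError("quit_memory_years must be >= 15")
        T, M = int(tunnel_years), int(quit_memory_years)
        self.tunnel_years = T
        self.quit_memory_years = M
        self.WS = 0
        self.QUIT = slice(1, 1 + M)
        self.LC_EARLY = slice(1 + M, 1 + M + T)
        self.LC_ADV = slice(1 + M + T, 1 + M + 2 * T)
        self.CVD = 1 + M + 2 * T
        self.DEAD_OTHER = self.CVD + 1
        self.DEAD_LC = self.CVD + 2
        self.DEAD_CVD = self.CVD + 3
        self.n_states = self.CVD + 4
        self.LIVING = slice(0, self.DEAD_OTHER)
        self.DEAD = slice(self.DEAD_OTHER, self.n_states)
        self.names = (
            ["well_smoking"]
            + [f"well_quit_{q}" for q in range(M)]
            + [f"lc_early_{y}" for y in range(1, T + 1)]
            + [f"lc_adv_{y}" for y in range(1, T + 1)]
            + ["cvd", "dead_other", "dead_lung_cancer", "dead_cvd"]
        )

    def index(self, name: str) -> int:
        return self.names.index(name)


def build_state_space(tunnel_years: int = 5, quit_memory_years: int = 16) -> StateSpace:
    return StateSpace(tunnel_years, quit_memory_years)


def relapse_hazard(cumulative: float = 0.30, years: int = 3) -> float:
    """Constant annual hazard whose cumulative effect over ``years`` matches."""
    if not 0.0 <= cumulative < 1.0:
        raise ValidationError("cumulative relapse must lie in [0, 1)")
    return 1.0 - (1.0 - cumulative) ** (1.0 / years)


def annual_quit_dynamics(
    cycle_index: int,
    smoker_share: float,
    quitter_share: float = 0.0,
    quit_prob: float = 0.0,
    relapse_12mo: float = 0.21,
    relapse_3yr_cumulative: float = 0.30,
) -> tuple[float, float]:
    """Quit and relapse flows for one cycle.

    Cycle 0: the trial quit probability applies to smokers, then the
    24-week-to-12-month relapse removes ``relapse_12mo`` of the new
    quitters.  Cycles 1–3: sustained quitters relapse at the constant annual
    hazard whose three-year cumulative effect is ``relapse_3yr_cumulative``.
    Cycles >= 4: no relapse.
    """
    if cycle_index < 0:
        raise ValidationError("cycle_index must be >= 0")
    if cycle_index == 0:
        quit_flow = smoker_share * quit_prob
        return quit_flow, quit_flow * relapse_12mo
    if cycle_index <= 3:
        return 0.0, quitter_share * relapse_hazard(relapse_3yr_cumulative, 3)
    return 0.0, 0.0


def lc_rr_exsmoker(
    years_since_quit: float, rr_smoker_vs_general: float, decay_years: float = 15.0
) -> float:
    """Ex-smoker lung-cancer RR: linear decay from the smoker RR to 1.0."""
    if years_since_quit < 0:
        raise ValidationError("years_since_quit must be >= 0")
    if rr_smoker_vs_general < 1.0:
        raise ValidationError("rr_smoker_vs_general must be >= 1")
    frac = min(years_since_quit, decay_years) / decay_years
    return rr_smoker_vs_general - (rr_smoker_vs_general - 1.0) * frac


def cvd_event_outcome(
    event_probability: float,
    prehospital_fatality: float = 0.181,
    fatality_28day: float = 0.071,
) -> dict[str, float]:
    """Split a CVD event probability into death/survival shares.

    Of those with an event, ``prehospital_fatality`` die before hospital;
    of the hospitalised remainder, ``fatality_28day`` die within 28 days;
    survivors enter the chronic CVD state permanently.
    """
    if not 0.0 <= event_probability <= 1.0:
        raise ValidationError("event probability must lie in [0, 1]")
    instant = event_probability * prehospital_fatality
    hospitalised = event_probability - instant
    early = hospitalised * fatality_28day
    return {
        "instant_death_share": instant,
        "early_death_share": early,
        "survivor_share": hospitalised - early,
        "hospitalised_share": hospitalised,
    }


FLOW_KEYS = (
    "new_lc",            # newly diagnosed lung cancer (both stages)
    "lc_deaths",         # deaths from lung cancer (terminal LC cost)
    "new_cvd_hospitalised",  # CVD events reaching hospital (first-year cost)
    "cvd_deaths",        # deaths attributed to CVD (terminal CVD cost)
    "other_deaths",
    "quit_flow",
    "relapse_flow",
)


@dataclass
class CohortTrace:
    """Per-cycle state occupancy plus event flows for one strategy run.

    ``occupancy`` has one row per model age (start age .. horizon age); the
    flows are per transition (length ``n_cycles``).
    """

    space: StateSpace
    strategy: str
    sex: str
    start_age: int
    occupancy: np.ndarray
    flows: dict[str, np.ndarray]

    @property
    def n_cycles(self) -> int:
        return self.occupancy.shape[0] - 1

    @property
    def ages(self) -> np.ndarray:
        return self.start_age + np.arange(self.occupancy.shape[0])

    def check_conservation(self, tol: float = 1e-9) -> None:
        sums = self.occupancy.sum(axis=1)
        if np.max(np.abs(sums - 1.0)) > tol:
            raise ValidationError("cohort trace rows do not sum to 1")


@dataclass(frozen=True)
class CohortResult:
    """Per-person lifetime outputs for one strategy."""

    discounted_cost: float
    discounted_qalys: float
    life_years: float
    undiscounted_qalys: float


def run_cohort(
    params: ModelParameters,
    strategy: str,
    sex: str,
    start_age: int,
    space: StateSpace | None = None,
) -> CohortTrace:
    """Propagate a cohort (everyone initially well and smoking) to the horizon."""
    if strategy not in STRATEGIES:
        raise ValidationError(f"unknown strategy {strategy!r}")
    if sex not in SEXES:
        raise ValidationError(f"unknown sex {sex!r}")
    if start_age >= params.horizon_age:
        raise ValidationError("start_age must be below the horizon age")
    sp = space or StateSpace(params.lc_tunnel.years)
    if sp.tunnel_years != params.lc_tunnel.years:
        raise ValidationError("state-space tunnel depth does not match lc_tunnel")
    T, M = sp.tunnel_years, sp.quit_memory_years
    n_cycles = params.horizon_age - start_age
    ages = np.arange(start_age, params.horizon_age)

    def curve_values(curve) -> np.ndarray:
        if curve.ages[0] > 0 or curve.ages[-1] < params.horizon_age - 1:
            # hold-endpoint extrapolation makes this unreachable for bundled
            # curves; guard kept for hand-built short curves
            missing = [a for a in range(start_age, params.horizon_age)
                       if not curve.ages[0] <= a <= curve.ages[-1]]
            logger.debug("curve extrapolated at ages %s", missing)
        return curve.slice(start_age, params.horizon_age)

    mort = curve_values(params.background_mortality[sex])
    lc_inc = curve_values(params.lc_incidence[sex])
    cvd_inc = curve_values(params.cvd_incidence[sex])

    q0 = params.quit_rate[(_STRATEGY_ARM[strategy], sex)].mean
    r12 = params.relapse_24wk_to_12mo
    h = relapse_hazard(params.relapse_after_12mo_cumulative, 3)
    rr_cvd_smoker = params.cvd_rr_smoker.mean
    rr_cvd_quit = rr_cvd_smoker * params.cvd_rr_exsmoker_vs_smoker.mean
    rr_lc_smoker = params.lc_rr_smoker
    rr_lc_quit = np.array(
        [lc_rr_exsmoker(min(q, M - 1) if q < M - 1 else params.lc_rr_decay_years,
                        rr_lc_smoker, params.lc_rr_decay_years)
         for q in range(M)]
    )
    # the final quit sub-state holds everyone >= M-1 years post-quit; with the
    # default M=16 its RR is exactly 1.0
    early_d = params.lc_tunnel.early_death
    early_p = params.lc_tunnel.early_progression
    adv_d = params.lc_tunnel.adv_death
    pre_f = params.cvd_prehospital_fatality
    f28 = params.cvd_28day_fatality
    early_prop, adv_prop = params.lc_early_prop, params.lc_adv_prop

    S = sp.n_states
    occ = np.zeros((n_cycles + 1, S))
    occ[0, sp.WS] = 1.0
    flows = {k: np.zeros(n_cycles) for k in FLOW_KEYS}
    clipped = False

    e0, a0 = sp.LC_EARLY.start, sp.LC_ADV.start
    for t in range(n_cycles):
        x = occ[t]
        y = np.zeros(S)
        m = mort[t]

        # 1. background mortality; CVD occupants' deaths are attributed to CVD
        surv = x[sp.LIVING] * (1.0 - m)
        bg_dead = x[sp.LIVING].sum() * m
        cvd_bg_dead = x[sp.CVD] * m
        y[sp.DEAD_OTHER] = x[sp.DEAD_OTHER] + bg_dead - cvd_bg_dead
        y[sp.DEAD_LC] = x[sp.DEAD_LC]
        y[sp.DEAD_CVD] = x[sp.DEAD_CVD] + cvd_bg_dead
        flows["other_deaths"][t] += bg_dead - cvd_bg_dead
        flows["cvd_deaths"][t] += cvd_bg_dead

        # 2. lung-cancer tunnels: disease death, stage progression, ageing
        for j in range(T):
            s = surv[e0 + j]
            if s > 0.0:
                die = s * early_d[j]
                rem = s - die
                prog = rem * early_p[j]
                y[sp.DEAD_LC] += die
                y[a0] += prog  # progression restarts the advanced tunnel
                y[e0 + min(j + 1, T - 1)] += rem - prog
                flows["lc_deaths"][t] += die
            s = surv[a0 + j]
            if s > 0.0:
                die = s * adv_d[j]
                y[sp.DEAD_LC] += die
                y[a0 + min(j + 1, T - 1)] += s - die
                flows["lc_deaths"][t] += die

        # chronic CVD occupants stay put
        y[sp.CVD] += surv[sp.CVD]

        # 3. disease incidence from the well states (mutually exclusive risks)
        li, ci = lc_inc[t], cvd_inc[t]
        rem_well = np.zeros(1 + M)  # WS followed by quit sub-states
        for k in range(1 + M):
            s = surv[k]
            if s == 0.0:
                rem_well[k] = 0.0
                continue
            if k == sp.WS:
                p_lc = li * rr_lc_smoker
                p_cvd = ci * rr_cvd_smoker
            else:
                q = k - 1
                p_lc = li * rr_lc_quit[q]
                p_cvd = ci * rr_cvd_quit
            if p_lc + p_cvd > 1.0:
                scale = 1.0 / (p_lc + p_cvd)
                p_lc *= scale
                p_cvd *= scale
                clipped = True
            lcf = s * p_lc
            cvf = s * p_cvd
            y[e0] += lcf * early_prop
            y[a0] += lcf * adv_prop
            out = cvd_event_outcome(1.0, pre_f, f28)
            y[sp.DEAD_CVD] += cvf * (out["instant_death_share"] + out["early_death_share"])
            y[sp.CVD] += cvf * out["survivor_share"]
            flows["new_lc"][t] += lcf
            flows["new_cvd_hospitalised"][t] += cvf * out["hospitalised_share"]
            flows["cvd_deaths"][t] += cvf * (
                out["instant_death_share"] + out["early_death_share"]
            )
            rem_well[k] = s - lcf - cvf

        # 4. quit / relapse flows among those still well
        if t == 0:
            new_quit = rem_well[0] * q0
            net = new_quit * (1.0 - r12)
            y[sp.QUIT.start] += net
            y[sp.WS] += rem_well[0] - net
            flows["quit_flow"][t] += new_quit
            flows["relapse_flow"][t] += new_quit - net
        else:
            y[sp.WS] += rem_well[0]
        for q in range(M):
            rem = rem_well[1 + q]
            if rem == 0.0:
                continue
            if q <= 2:  # relapse confined to the three years after 12 months
                rel = rem * h
                y[sp.WS] += rel
                rem -= rel
                flows["relapse_flow"][t] += rel
            y[sp.QUIT.start + min(q + 1, M - 1)] += rem

        occ[t + 1] = y

    if clipped:
        logger.warning(
            "incidence probabilities exceeded 1 after relative risks and were rescaled"
        )
    trace = CohortTrace(sp, strategy, sex, start_age, occ, flows)
    trace.check_conservation()
    return trace


def _programme_cost(params: ModelParameters, strategy: str) -> float:
    if strategy == "intervention":
        return float(trial_cea.intervention_total(params.programme))
    return float(trial_cea.control_total(params.programme))


def state_utilities(params: ModelParameters, space: StateSpace) -> np.ndarray:
    u = np.zeros(space.n_states)
    u[space.WS] = params.utility_well_smoking
    u[space.QUIT] = params.utility_well_quit
    u[space.LC_EARLY] = params.utility_lc_early.mean
    u[space.LC_ADV] = params.utility_lc_adv.mean
    u[space.CVD] = params.utility_cvd
    return u


def accumulate(
    trace: CohortTrace, params: ModelParameters, half_cycle: bool = False
) -> CohortResult:
    """Discounted per-person costs and QALYs plus undiscounted life-years.

    Per-cycle QALYs weight occupancy by state utility.  Costs comprise the
    strategy's programme cost at cycle 0, first-year costs on incident
    disease, annual continuing lung-cancer costs on prevalent lung-cancer
    occupancy, and terminal six-month costs charged as a lump sum in the
    cycle of cause-specific death.  Both streams discount by 1/(1+r)^t.
    """
    sp = trace.space
    n = trace.n_cycles
    r = params.discount_rate
    disc = (1.0 + r) ** -np.arange(n)
    ages = trace.ages[:n]
    sex = trace.sex

    u = state_utilities(params, sp)
    occ = 0.5 * (trace.occupancy[:-1] + trace.occupancy[1:]) if half_cycle else trace.occupancy[:n]
    qaly_t = occ @ u
    living_t = occ[:, sp.LIVING].sum(axis=1)
    lc_occ_t = occ[:, sp.LC_EARLY].sum(axis=1) + occ[:, sp.LC_ADV].sum(axis=1)

    def cost_arr(label: str) -> np.ndarray:
        return params.excess_costs[label][sex].slice(trace.start_age, trace.start_age + n)

    cost_t = (
        trace.flows["new_lc"] * cost_arr("lc_first_year")
        + lc_occ_t * cost_arr("lc_subsequent_annual")
        + trace.flows["lc_deaths"] * cost_arr("lc_terminal_6mo")
        + trace.flows["new_cvd_hospitalised"] * cost_arr("cvd_first_year")
        + trace.flows["cvd_deaths"] * cost_arr("cvd_terminal_6mo")
    )
    cost_t = cost_t.copy()
    cost_t[0] += _programme_cost(params, trace.strategy)

    return CohortResult(
        discounted_cost=float(cost_t @ disc),
        discounted_qalys=float(qaly_t @ disc),
        life_years=float(living_t.sum()),
        undiscounted_qalys=float(qaly_t.sum()),
    )


def compare_strategies(
    params: ModelParameters,
    sex: str,
    start_age: int,
    space: StateSpace | None = None,
    half_cycle: bool = False,
) -> trial_cea.CEResult:
    """Incremental lifetime cost and QALYs (intervention vs usual care)."""
    sp = space or StateSpace(params.lc_tunnel.years)
    results = {}
    for strategy in STRATEGIES:
        trace = run_cohort(params, strategy, sex, start_age, sp)
        results[strategy] = accumulate(trace, params, half_cycle)
    dc = results["intervention"].discounted_cost - results["usual_care"].discounted_cost
    dq = results["intervention"].discounted_qalys - results["usual_care"].discounted_qalys
    return trial_cea.make_ce_result(dc, dq, "QALY", per_strategy=results)
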