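"""Shared fixtures: default parameters and an independent microsimulation.

The microsimulation replays the annual model rules for individual people
with explicit random draws.  It shares nothing with the cohort engine's
occupancy arithmetic, so agreement between the two is a genuine
cross-check of the transition structure.
"""

from __future__ import annotations

import numpy as np
import pytest

from quitcea.markov_engine import StateSpace, cvd_event_outcome, relapse_hazard
from quitcea.parameters import default_parameters


@pytest.fixture(scope="session")
def params():
    return default_parameters()


def run_microsim(
    params,
    strategy: str,
    sex: str,
    start_age: int,
    n_individuals: int,
    seed: int,
    space: StateSpace | None = None,
) -> np.ndarray:
    """Individual-level simulation of the annual rules; returns occupancy
    fractions with the same (cycles+1, states) shape as a cohort trace."""
    sp = space or StateSpace(params.lc_tunnel.years)
    T, M = sp.tunnel_years, sp.quit_memory_years
    rng = np.random.default_rng(seed)
    n_cycles = params.horizon_age - start_age

    arm = "adherent_intervention" if strategy == "intervention" else "usual_care"
    q0 = params.quit_rate[(arm, sex)].mean
    r12 = params.relapse_24wk_to_12mo
    h = relapse_hazard(params.relapse_after_12mo_cumulative, 3)
    rr_cvd_s = params.cvd_rr_smoker.mean
    rr_cvd_q = rr_cvd_s * params.cvd_rr_exsmoker_vs_smoker.mean
    rr_lc_s = params.lc_rr_smoker
    decay = params.lc_rr_decay_years

    def rr_lc_quit(q: int) -> float:
        years = decay if q >= M - 1 else q
        frac = min(years, decay) / decay
        return rr_lc_s - (rr_lc_s - 1.0) * frac

    state = np.zeros(n_individuals, dtype=int)  # everyone well & smoking
    occ = np.zeros((n_cycles + 1, sp.n_states))
    occ[0] = np.bincount(state, minlength=sp.n_states) / n_individuals

    e0, a0 = sp.LC_EARLY.start, sp.LC_ADV.start
    mort = params.background_mortality[sex].slice(start_age, params.horizon_age)
    lc_inc = params.lc_incidence[sex].slice(start_age, params.horizon_age)
    cvd_inc = params.cvd_incidence[sex].slice(start_age, params.horizon_age)
    out = cvd_event_outcome(1.0, params.cvd_prehospital_fatality, params.cvd_28day_fatality)
    p_cvd_death = out["instant_death_share"] + out["early_death_share"]

    for t in range(n_cycles):
        new = state.copy()
        alive = state < sp.DEAD_OTHER
        # background mortality; CVD occupants' deaths attributed to CVD
        die = alive & (rng.random(n_individuals) < mort[t])
        new[die & (state == sp.CVD)] = sp.DEAD_CVD
        new[die & (state != sp.CVD)] = sp.DEAD_OTHER
        ok = alive & ~die

        # lung-cancer tunnels
        for j in range(T):
            for base, d in ((e0, params.lc_tunnel.early_death[j]),
                            (a0, params.lc_tunnel.adv_death[j])):
                mask = ok & (state == base + j)
                if not mask.any():
                    continue
                u = rng.random(n_individuals)
                new[mask & (u < d)] = sp.DEAD_LC
                survivors = mask & (u >= d)
                if base == e0:
                    u2 = rng.random(n_individuals)
                    prog = survivors & (u2 < params.lc_tunnel.early_progression[j])
                    new[prog] = a0
                    new[survivors & ~prog] = e0 + min(j + 1, T - 1)
                else:
                    new[survivors] = a0 + min(j + 1, T - 1)

        # incidence + smoking flows for the well states
        for k in range(1 + M):
            mask = ok & (state == k)
            if not mask.any():
                continue
            if k == sp.WS:
                p_lc, p_cvd = lc_inc[t] * rr_lc_s, cvd_inc[t] * rr_cvd_s
            else:
                p_lc, p_cvd = lc_inc[t] * rr_lc_quit(k - 1), cvd_inc[t] * rr_cvd_q
            u = rng.random(n_individuals)
            got_lc = mask & (u < p_lc)
            got_cvd = mask & (u >= p_lc) & (u < p_lc + p_cvd)
            stage = rng.random(n_individuals)
            new[got_lc & (stage < params.lc_early_prop)] = e0
            new[got_lc & (stage >= params.lc_early_prop)] = a0
            fate = rng.random(n_individuals)
            new[got_cvd & (fate < p_cvd_death)] = sp.DEAD_CVD
            new[got_cvd & (fate >= p_cvd_death)] = sp.CVD
            stay = mask & ~got_lc & ~got_cvd
            if k == sp.WS:
                if t == 0:
                    uq = rng.random(n_individuals)
                    new[stay & (uq < q0 * (1.0 - r12))] = sp.QUIT.start
            else:
                q = k - 1
                if q <= 2:
                    ur = rng.random(n_individuals)
                    rel = stay & (ur < h)
                    new[rel] = sp.WS
                    stay = stay & ~rel
                new[stay] = sp.QUIT.start + min(q + 1, M - 1)
        state = new
        occ[t + 1] = np.bincount(state, minlength=sp.n_states) / n_individuals
    return occ


@pytest.fixture(scope="session")
def microsim():
    return run_microsim
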