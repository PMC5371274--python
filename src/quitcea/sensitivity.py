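"""Probabilistic, one-way, and scenario sensitivity analyses.

The PSA redraws every uncertain scalar independently from its fitted
distribution (beta for probabilities, lognormal for relative risks, gamma
for costs), reruns the two-strategy comparison, and summarises the draws as
mean incrementals and a cost-effectiveness acceptability curve (CEAC): the
fraction of draws with positive net monetary benefit, lambda * dQALY - dCost,
at each willingness-to-pay threshold.  One root seed spawns per-repetition
child streams, so changing the repetition count never reshuffles earlier
draws.  Age curves are not sampled by default; ``curve_cv`` applies a common
multiplicative gamma factor per curve group for exploration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import markov_engine
from .errors import InsufficientDataError, ValidationError
from .parameters import (
    ARMS,
    COST_LABELS,
    SEXES,
    ModelParameters,
    UncertainValue,
    fit_distribution,
)
from .trial_cea import CEResult

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLDS = (0.0, 5_000.0, 10_000.0, 15_000.0, 20_000.0, 30_000.0, 50_000.0)


def _draw_uv(uv: UncertainValue, rng: np.random.Generator) -> UncertainValue:
    """Replace the point estimate with one draw; fixed values pass through."""
    if uv.is_fixed:
        return uv
    value = float(fit_distribution(uv).rvs(random_state=rng))
    if uv.family == "beta" and not 0.0 < value < 1.0:  # numerically degenerate draw
        clipped = min(max(value, 1e-12), 1.0 - 1e-12)
        logger.warning("clipped beta draw %s -> %s", value, clipped)
        value = clipped
    return uv.with_mean(value)


def draw_parameters(
    params: ModelParameters,
    rng: np.random.Generator,
    curve_cv: float = 0.0,
) -> ModelParameters:
    """One PSA parameter draw: independent sampling of uncertain scalars.

    With ``curve_cv > 0`` each incidence/mortality/cost curve group is also
    perturbed by a gamma-distributed common factor (mean 1, cv ``curve_cv``);
    probability curves are clipped to [0, 1] after scaling.
    """
    p = params.copy()
    p.quit_rate = {key: _draw_uv(uv, rng) for key, uv in params.quit_rate.items()}
    p.cvd_rr_smoker = _draw_uv(params.cvd_rr_smoker, rng)
    p.cvd_rr_exsmoker_vs_smoker = _draw_uv(params.cvd_rr_exsmoker_vs_smoker, rng)
    p.utility_lc_early = _draw_uv(params.utility_lc_early, rng)
    p.utility_lc_adv = _draw_uv(params.utility_lc_adv, rng)
    if curve_cv > 0.0:
        shape = 1.0 / (curve_cv * curve_cv)
        def factor() -> float:
            return float(rng.gamma(shape, 1.0 / shape))
        for group in (p.background_mortality, p.lc_incidence, p.cvd_incidence):
            f = factor()
            for sex in SEXES:
                group[sex] = group[sex].scaled(f)
        for label in COST_LABELS:
            f = factor()
            for sex in SEXES:
                p.excess_costs[label][sex] = p.excess_costs[label][sex].scaled(f)
    return p


def ceac(draws: np.ndarray, thresholds) -> dict[float, float]:
    """Probability cost-effective per threshold from (dCost, dQALY) draws."""
    draws = np.asarray(draws, dtype=float)
    if draws.size == 0:
        raise InsufficientDataError("CEAC needs at least one draw")
    dc, dq = draws[:, 0], draws[:, 1]
    return {
        float(lam): float(np.mean(lam * dq - dc > 0.0)) for lam in thresholds
    }


@dataclass
class PSAResult:
    """Monte-Carlo draws of incremental (cost, QALY) pairs plus the CEAC."""

    draws: np.ndarray  # shape (n, 2): columns delta_cost, delta_qaly
    n_draws: int
    seed: int
    sex: str
    start_age: int
    thresholds: tuple[float, ...]
    ceac: dict[float, float]
    n_excluded: int = 0

    @property
    def mean_delta_cost(self) -> float:
        return float(self.draws[:, 0].mean())

    @property
    def mean_delta_qaly(self) -> float:
        return float(self.draws[:, 1].mean())

    def prob_cost_effective(self, threshold: float) -> float:
        dc, dq = self.draws[:, 0], self.draws[:, 1]
        return float(np.mean(threshold * dq - dc > 0.0))


def run_psa(
    params: ModelParameters,
    sex: str,
    start_age: int,
    n_reps: int,
    seed: int,
    thresholds=DEFAULT_THRESHOLDS,
    curve_cv: float = 0.0,
) -> PSAResult:
    """Monte-Carlo PSA over the two-strategy lifetime comparison."""
    if n_reps < 1:
        raise ValidationError("n_reps must be >= 1")
    space = markov_engine.StateSpace(params.lc_tunnel.years)
    children = np.random.SeedSequence(seed).spawn(n_reps)
    rows, n_excluded = [], 0
    for child in children:
        rng = np.random.default_rng(child)
        try:
            drawn = draw_parameters(params, rng, curve_cv=curve_cv)
            ce = markov_engine.compare_strategies(drawn, sex, start_age, space)
        except ValidationError as exc:
            n_excluded += 1
            logger.warning("PSA draw excluded: %s", exc)
            continue
        rows.append((ce.delta_cost, ce.delta_effect))
    if not rows:
        raise InsufficientDataError("all PSA draws failed model preconditions")
    draws = np.array(rows)
    return PSAResult(
        draws=draws,
        n_draws=len(rows),
        seed=seed,
        sex=sex,
        start_age=start_age,
        thresholds=tuple(float(t) for t in thresholds),
        ceac=ceac(draws, thresholds),
        n_excluded=n_excluded,
    )


# ---------------------------------------------------------------------------
# One-way sensitivity analysis
# ---------------------------------------------------------------------------

def _quit_setter(arm: str, sex: str):
    def get(p: ModelParameters) -> UncertainValue:
        return p.quit_rate[(arm, sex)]

    def set_(p: ModelParameters, value: float) -> None:
        p.quit_rate[(arm, sex)] = p.quit_rate[(arm, sex)].with_mean(value)

    return get, set_


def _uv_attr(name: str):
    def get(p: ModelParameters) -> UncertainValue:
        return getattr(p, name)

    def set_(p: ModelParameters, value: float) -> None:
        setattr(p, name, getattr(p, name).with_mean(value))

    return get, set_


def _float_attr(name: str):
    def get(p: ModelParameters) -> UncertainValue:
        return UncertainValue(getattr(p, name))

    def set_(p: ModelParameters, value: float) -> None:
        setattr(p, name, value)

    return get, set_


def _one_way_registry() -> dict:
    reg = {}
    for arm in ARMS:
        for sex in SEXES:
            reg[f"quit_rate.{arm}.{sex}"] = _quit_setter(arm, sex)
    for name in ("cvd_rr_smoker", "cvd_rr_exsmoker_vs_smoker",
                 "utility_lc_early", "utility_lc_adv"):
        reg[name] = _uv_attr(name)
    for name in ("relapse_24wk_to_12mo", "relapse_after_12mo_cumulative",
                 "lc_rr_smoker", "utility_well_quit"):
        reg[name] = _float_attr(name)
    return reg


ONE_WAY_PARAMETER_IDS = tuple(_one_way_registry().keys())


@dataclass(frozen=True)
class OneWayEntry:
    """Low/high inputs for one parameter and the resulting comparisons."""

    parameter: str
    base_value: float
    low_value: float
    high_value: float
    low: CEResult
    high: CEResult

    def icer_range(self) -> float:
        """Spread of the signed cost-per-QALY ratio across the two inputs."""
        vals = [r.icer for r in (self.low, self.high) if r.icer is not None]
        if len(vals) < 2:
            return float("inf")
        return abs(vals[1] - vals[0])


def one_way(
    params: ModelParameters, parameter_id: str, sex: str, start_age: int
) -> OneWayEntry:
    """Recompute the comparison at mean +/- 2 se (se known) or mean x 0.8/1.2."""
    registry = _one_way_registry()
    if parameter_id not in registry:
        raise LookupError(f"unknown one-way parameter {parameter_id!r}")
    get, set_ = registry[parameter_id]
    uv = get(params)
    if uv.se:
        low, high = uv.mean - 2.0 * uv.se, uv.mean + 2.0 * uv.se
    else:
        low, high = 0.8 * uv.mean, 1.2 * uv.mean
    results = {}
    for label, value in (("low", low), ("high", high)):
        p = params.copy()
        set_(p, value)
        results[label] = markov_engine.compare_strategies(p, sex, start_age)
    return OneWayEntry(
        parameter=parameter_id,
        base_value=uv.mean,
        low_value=low,
        high_value=high,
        low=results["low"],
        high=results["high"],
    )


def tornado(
    params: ModelParameters,
    sex: str,
    start_age: int,
    parameter_ids=None,
) -> list[OneWayEntry]:
    """One-way entries for every registered parameter, widest range first."""
    ids = parameter_ids or ONE_WAY_PARAMETER_IDS
    entries = [one_way(params, pid, sex, start_age) for pid in ids]
    entries.sort(key=lambda e: e.icer_range(), reverse=True)
    return entries


# ---------------------------------------------------------------------------
# Scenario analysis
# ---------------------------------------------------------------------------

DEFAULT_SCENARIOS = (
    ("base", 0.035, 40),
    ("discount_0pct", 0.0, 40),
    ("discount_5pct", 0.05, 40),
    ("age_30", 0.035, 30),
    ("age_50", 0.035, 50),
    ("age_60", 0.035, 60),
)


def run_scenarios(
    params: ModelParameters,
    sexes=SEXES,
    scenarios=DEFAULT_SCENARIOS,
    psa_reps: int = 0,
    seed: int | None = None,
) -> pd.DataFrame:
    """Deterministic comparison per (sex, scenario); optional PSA per cell.

    Scenarios vary the discount rate (0 / 3.5 / 5%) and the cohort start age
    (30 / 40 / 50 / 60).  With ``psa_reps > 0`` the probability
    cost-effective at the configured threshold is added per cell.
    """
    rows = []
    for sex in sexes:
        for i, (label, discount, start_age) in enumerate(scenarios):
            p = params.copy()
            p.discount_rate = discount
            ce = markov_engine.compare_strategies(p, sex, start_age)
            row = {
                "sex": sex,
                "scenario": label,
                "discount_rate": discount,
                "start_age": start_age,
                "delta_cost": ce.delta_cost,
                "delta_qaly": ce.delta_effect,
                "icer": ce.icer,
                "classification": ce.classification,
                "cost_intervention": ce.per_strategy["intervention"].discounted_cost,
                "cost_usual_care": ce.per_strategy["usual_care"].discounted_cost,
                "qalys_intervention": ce.per_strategy["intervention"].discounted_qalys,
                "qalys_usual_care": ce.per_strategy["usual_care"].discounted_qalys,
            }
            if psa_reps > 0:
                if seed is None:
                    raise ValidationError("scenario PSA requires a seed")
                psa = run_psa(p, sex, start_age, psa_reps, seed + 1000 * i)
                row["prob_cost_effective"] = psa.prob_cost_effective(p.wtp_threshold)
            rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Plots (optional outputs)
# ---------------------------------------------------------------------------

def plot_ceac(result: PSAResult, path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    lams = sorted(result.ceac)
    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.plot(lams, [result.ceac[l] for l in lams], marker="o")
    ax.set_xlabel("Willingness to pay (NZ$/QALY)")
    ax.set_ylabel("Probability cost-effective")
    ax.set_ylim(0, 1)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_ce_plane(result: PSAResult, path, threshold: float | None = None) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(result.draws[:, 1], result.draws[:, 0], s=6, alpha=0.4)
    ax.axhline(0, lw=0.5, color="k")
    ax.axvline(0, lw=0.5, color="k")
    if threshold is not None:
        q = np.linspace(*ax.get_xlim(), 10)
        ax.plot(q, threshold * q, ls="--", lw=0.8, color="grey")
    ax.set_xlabel("Incremental QALYs")
    ax.set_ylabel("Incremental cost (NZ$)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
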