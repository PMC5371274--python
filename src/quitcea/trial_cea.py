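"""Within-trial (24-week) economic evaluation.

Programme costing to the cent, incremental cost, cost per additional
quitter, QALYs from EQ-5D utilities, and the baseline-adjusted between-arm
QALY difference.  Only programme costs enter the 24-week ICERs: wider
health-sector costs were not collected during the trial, so there are no
cost offsets at this stage.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import InsufficientDataError, ValidationError
from .parameters import ProgrammeCosts

CENT = Decimal("0.01")
EQ5D_MIN, EQ5D_MAX = -0.59, 1.0
TRIAL_DURATION_YEARS = 24 / 52  # 24-week follow-up window


def _to_cents(x) -> Decimal:
    return Decimal(str(x)).quantize(CENT, rounding=ROUND_HALF_UP)


def amortise(total_cost, n_participants: int) -> Decimal:
    """Spread a one-off cost over participants, reported to the cent."""
    if n_participants < 1:
        raise ValidationError("cannot amortise over zero participants")
    total = Decimal(str(total_cost))
    if total < 0:
        raise ValidationError("cost must be >= 0")
    return (total / n_participants).quantize(CENT, rounding=ROUND_HALF_UP)


@dataclass(frozen=True)
class ArmCostSummary:
    """Per-participant cost components and their exact total for one arm."""

    arm: str
    components: tuple[tuple[str, Decimal], ...]

    @property
    def total(self) -> Decimal:
        return sum((c for _, c in self.components), Decimal("0.00"))

    def as_dict(self) -> dict[str, float]:
        return {label: float(c) for label, c in self.components}


def arm_total(components: Mapping[str, object], arm: str = "intervention") -> ArmCostSummary:
    """Exact (decimal) per-participant costing for one arm."""
    items = []
    for label, value in components.items():
        c = _to_cents(value)
        if c < 0:
            raise ValidationError(f"negative cost component {label!r}: {c}")
        items.append((label, c))
    return ArmCostSummary(arm=arm, components=tuple(items))


def intervention_components(pc: ProgrammeCosts) -> dict[str, Decimal]:
    """Default intervention per-participant components.

    Training and salary are amortised over the whole intervention arm.
    """
    return {
        "psp_training": amortise(pc.trainer_hours * pc.trainer_rate, pc.n_intervention),
        "psp_salary": amortise(pc.psp_salary_total, pc.n_intervention),
        "gp_visit": _to_cents(pc.gp_visit),
        "pedometer": _to_cents(pc.pedometer),
        "quitline": _to_cents(pc.quitline_per_participant),
    }


def control_components(pc: ProgrammeCosts) -> dict[str, Decimal]:
    return {"quitline": _to_cents(pc.quitline_per_participant)}


def intervention_total(pc: ProgrammeCosts) -> Decimal:
    return arm_total(intervention_components(pc), "intervention").total


def control_total(pc: ProgrammeCosts) -> Decimal:
    return arm_total(control_components(pc), "control").total


def incremental_cost(intervention: ArmCostSummary, control: ArmCostSummary) -> Decimal:
    """Intervention minus control per-participant cost (sign preserved)."""
    return intervention.total - control.total


@dataclass(frozen=True)
class CEResult:
    """Incremental cost and effect for a strategy pair, with classification.

    ``classification`` is ``"icer"`` when the ratio is meaningful,
    ``"dominant"`` (cheaper and more effective), ``"dominated"`` (costlier
    and less effective), or ``"undefined"`` (zero effect difference).  When
    both increments are negative the ratio is reported with
    ``southwest=True`` (savings per unit of health forgone).
    """

    delta_cost: float
    delta_effect: float
    effect_units: str
    icer: float | None
    classification: str
    southwest: bool = False
    per_strategy: dict | None = field(default=None, compare=False)


def make_ce_result(
    delta_cost: float,
    delta_effect: float,
    effect_units: str,
    per_strategy: dict | None = None,
) -> CEResult:
    dc, de = float(delta_cost), float(delta_effect)
    if de == 0.0:
        cls, ratio, sw = "undefined", None, False
    elif de > 0:
        ratio = dc / de
        cls, sw = ("icer", False) if dc >= 0 else ("dominant", False)
    else:
        ratio = dc / de
        cls, sw = ("dominated", False) if dc > 0 else ("icer", True)
    return CEResult(dc, de, effect_units, ratio, cls, sw, per_strategy)


def icer(delta_cost, effect_intervention: float, effect_control: float,
         effect_units: str = "quitter") -> CEResult:
    """ICER from an incremental cost and two absolute effect levels."""
    return make_ce_result(
        float(delta_cost), float(effect_intervention) - float(effect_control), effect_units
    )


def qaly_accrual(u_start: float, u_end: float, duration_years: float) -> float:
    """Trapezoid QALYs: mean utility over the interval times its length."""
    if duration_years < 0:
        raise ValidationError("duration must be >= 0")
    for u in (u_start, u_end):
        if not EQ5D_MIN <= u <= EQ5D_MAX:
            raise ValidationError(f"utility {u} outside the EQ-5D range [{EQ5D_MIN}, {EQ5D_MAX}]")
    return 0.5 * (u_start + u_end) * duration_years


def adjusted_qaly_difference(
    trial_records: pd.DataFrame,
    duration_years: float = TRIAL_DURATION_YEARS,
) -> tuple[float, tuple[float, float]]:
    """Between-arm 24-week QALY difference adjusted for baseline utility.

    Individual QALYs are the trapezoid of the baseline and follow-up
    utilities over the follow-up window; the arm contrast comes from an
    ANCOVA-style linear model with baseline utility as covariate.  Records
    missing either utility are excluded (listwise deletion).  Returns the
    intervention-minus-control difference with a normal-approximation 95% CI.
    """
    df = trial_records.dropna(subset=["eq5d_baseline", "eq5d_24wk"]).copy()
    counts = df["arm"].value_counts()
    for arm in ("intervention", "control"):
        if counts.get(arm, 0) < 2:
            raise InsufficientDataError(
                f"arm {arm!r} has {counts.get(arm, 0)} usable records (< 2)"
            )
    qaly = df.apply(
        lambda r: qaly_accrual(r["eq5d_baseline"], r["eq5d_24wk"], duration_years), axis=1
    )
    X = sm.add_constant(
        pd.DataFrame(
            {
                "intervention": (df["arm"] == "intervention").astype(float),
                "baseline": df["eq5d_baseline"].astype(float),
            }
        )
    )
    fit = sm.OLS(qaly.astype(float), X).fit()
    delta = float(fit.params["intervention"])
    lo, hi = (float(v) for v in fit.conf_int().loc["intervention"])
    return delta, (lo, hi)


@dataclass(frozen=True)
class WithinTrialReport:
    """All within-trial results in one place (costs in 2012 NZ$)."""

    intervention_costs: ArmCostSummary
    control_costs: ArmCostSummary
    incremental_cost: Decimal
    icer_per_quitter_itt: CEResult
    icer_per_quitter_adherent: CEResult
    icer_per_qaly: CEResult | None
    delta_qaly: float | None
    delta_qaly_ci: tuple[float, float] | None


def within_trial_analysis(
    programme: ProgrammeCosts,
    quit_rate_itt: tuple[float, float],
    quit_rate_adherent: tuple[float, float] | None = None,
    trial_records: pd.DataFrame | None = None,
) -> WithinTrialReport:
    """Run the full 24-week evaluation from summaries (and optional records).

    ``quit_rate_itt`` is (intervention, control); ``quit_rate_adherent`` is
    (adherent-intervention, control).  When individual records are supplied
    the baseline-adjusted QALY difference and cost-per-QALY are included.
    """
    inter = arm_total(intervention_components(programme), "intervention")
    ctrl = arm_total(control_components(programme), "control")
    dcost = incremental_cost(inter, ctrl)
    itt = icer(dcost, *quit_rate_itt, effect_units="quitter")
    adh = (
        icer(dcost, *quit_rate_adherent, effect_units="quitter")
        if quit_rate_adherent is not None
        else itt
    )
    dq = ci = per_qaly = None
    if trial_records is not None:
        dq, ci = adjusted_qaly_difference(trial_records)
        per_qaly = make_ce_result(float(dcost), dq, "QALY")
    return WithinTrialReport(
        intervention_costs=inter,
        control_costs=ctrl,
        incremental_cost=dcost,
        icer_per_quitter_itt=itt,
        icer_per_quitter_adherent=adh,
        icer_per_qaly=per_qaly,
        delta_qaly=dq,
        delta_qaly_ci=ci,
    )
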