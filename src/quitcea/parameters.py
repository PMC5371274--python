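"""Model inputs: uncertain scalars, age–sex curves, and the full parameter set.

Every quantity the decision model consumes lives here: trial quit rates,
relapse proportions, disease incidence and background-mortality curves,
relative risks for current and former smokers, health-state utilities, excess
health-system costs, discounting and threshold settings, and the programme
costing inputs.  Uncertain scalars carry a (mean, se) pair plus a
distribution family (beta for probabilities, gamma for costs, lognormal for
relative risks) fitted by method of moments on the natural scale, which is
how the source estimates are reported.

Configuration is plain text: one YAML file for scalars plus one CSV per age
curve with columns ``age,sex,value``.  The in-code defaults reproduce the
published point estimates; age curves default to synthetic shapes anchored at
the published age-65 example values (see :mod:`quitcea.synthetic_data`).
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .errors import (
    ConfigurationError,
    InfeasibleMomentsError,
    ValidationError,
)

SEXES = ("male", "female")
ARMS = ("adherent_intervention", "usual_care")
FAMILIES = ("beta", "gamma", "lognormal", "fixed")
COST_LABELS = (
    "lc_first_year",
    "lc_subsequent_annual",
    "lc_terminal_6mo",
    "cvd_first_year",
    "cvd_terminal_6mo",
)


# ---------------------------------------------------------------------------
# Uncertain scalars
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class UncertainValue:
    """A scalar with sampling uncertainty: natural-scale mean, se, family."""

    mean: float
    se: float | None = None
    family: str = "fixed"

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValidationError(f"unknown distribution family {self.family!r}")
        if self.se is not None and self.se < 0:
            raise ValidationError("se must be >= 0")
        fixed = self.se is None or self.se == 0
        if fixed != (self.family == "fixed"):
            raise ValidationError(
                "family='fixed' exactly when se is absent or zero "
                f"(got family={self.family!r}, se={self.se!r})"
            )
        if self.family == "beta" and not 0.0 < self.mean < 1.0:
            raise ValidationError(f"beta family requires 0 < mean < 1, got {self.mean}")
        if self.family in ("gamma", "lognormal") and self.mean <= 0:
            raise ValidationError(f"{self.family} family requires mean > 0, got {self.mean}")

    @property
    def is_fixed(self) -> bool:
        return self.family == "fixed"

    def with_mean(self, mean: float) -> "UncertainValue":
        """Same uncertainty structure with the point estimate replaced."""
        return UncertainValue(mean=mean, se=self.se, family=self.family)

    def as_fixed(self, mean: float | None = None) -> "UncertainValue":
        return UncertainValue(mean=self.mean if mean is None else mean)


class _PointMass:
    """Degenerate sampler for fixed parameters (scipy-like surface)."""

    def __init__(self, value: float):
        self.value = float(value)

    def rvs(self, size=None, random_state=None):
        if size is None:
            return self.value
        return np.full(size, self.value)

    def mean(self) -> float:
        return self.value

    def std(self) -> float:
        return 0.0


def fit_distribution(uv: UncertainValue):
    """Method-of-moments sampler for an :class:`UncertainValue`.

    Returns a frozen scipy distribution (or a point mass for fixed values)
    whose analytic mean and standard deviation equal ``uv.mean`` and
    ``uv.se``.  Lognormal parameters are recovered from natural-scale
    moments: sigma^2 = ln(1 + cv^2), mu = ln(mean) - sigma^2 / 2.
    """
    if uv.is_fixed:
        return _PointMass(uv.mean)
    m, s = uv.mean, float(uv.se)
    var = s * s
    if uv.family == "beta":
        if var >= m * (1.0 - m):
            raise InfeasibleMomentsError(
                f"beta moments infeasible: se^2={var:.6g} >= mean(1-mean)={m * (1 - m):.6g}"
            )
        nu = m * (1.0 - m) / var - 1.0
        return stats.beta(m * nu, (1.0 - m) * nu)
    if uv.family == "gamma":
        return stats.gamma(a=m * m / var, scale=var / m)
    if uv.family == "lognormal":
        sigma2 = math.log1p(var / (m * m))
        mu = math.log(m) - sigma2 / 2.0
        return stats.lognorm(s=math.sqrt(sigma2), scale=math.exp(mu))
    raise ValidationError(f"cannot fit family {uv.family!r}")  # pragma: no cover


# ---------------------------------------------------------------------------
# Age curves
# ---------------------------------------------------------------------------

@dataclass(eq=False)
class AgeCurve:
    """Sex-specific value-by-integer-age lookup (probability/year or NZ$).

    Ages outside the tabulated range hold the nearest endpoint value
    constant, so a curve tabulated over 0–100 never has coverage gaps.
    """

    sex: str
    ages: np.ndarray
    values: np.ndarray
    kind: str = "probability"  # or "cost"

    def __post_init__(self) -> None:
        self.ages = np.asarray(self.ages, dtype=int)
        self.values = np.asarray(self.values, dtype=float)
        if self.sex not in SEXES:
            raise ValidationError(f"unknown sex {self.sex!r}")
        if self.kind not in ("probability", "cost"):
            raise ValidationError(f"unknown curve kind {self.kind!r}")
        if self.ages.size == 0 or self.ages.size != self.values.size:
            raise ValidationError("ages and values must be equal-length and non-empty")
        if not np.array_equal(self.ages, np.arange(self.ages[0], self.ages[-1] + 1)):
            missing = sorted(set(range(self.ages[0], self.ages[-1] + 1)) - set(self.ages.tolist()))
            raise ValidationError(f"curve must cover consecutive integer ages; missing {missing}")
        if self.kind == "probability":
            if np.any(self.values < 0) or np.any(self.values > 1):
                raise ValidationError("probability curve values must lie in [0, 1]")
        elif np.any(self.values < 0):
            raise ValidationError("cost curve values must be >= 0")

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, AgeCurve)
            and self.sex == other.sex
            and self.kind == other.kind
            and np.array_equal(self.ages, other.ages)
            and np.array_equal(self.values, other.values)
        )

    def value_at(self, age: int) -> float:
        idx = int(np.clip(age, self.ages[0], self.ages[-1])) - int(self.ages[0])
        return float(self.values[idx])

    def slice(self, start_age: int, stop_age: int) -> np.ndarray:
        """Values for ages ``start_age .. stop_age - 1`` (endpoint-held)."""
        ages = np.clip(np.arange(start_age, stop_age), self.ages[0], self.ages[-1])
        return self.values[ages - int(self.ages[0])]

    def scaled(self, factor: float) -> "AgeCurve":
        vals = self.values * factor
        if self.kind == "probability":
            vals = np.clip(vals, 0.0, 1.0)
        return AgeCurve(self.sex, self.ages.copy(), vals, self.kind)


# ---------------------------------------------------------------------------
# Composite CVD utility
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CVDUtilityComponents:
    """Condition-level utilities with admission-share weights (percent)."""

    components: tuple[tuple[str, float, float], ...]  # (name, utility, weight %)

    def weight_sum(self) -> float:
        return sum(w for _, _, w in self.components)


DEFAULT_CVD_COMPONENTS = CVDUtilityComponents(
    components=(
        ("coronary_artery_disease", 0.629, 54.9),
        ("cerebrovascular_disease_stroke", 0.649, 21.9),
        ("congestive_heart_failure", 0.493, 17.6),
        ("peripheral_vascular_disease", 0.657, 5.6),
    )
)


def composite_cvd_utility(components: CVDUtilityComponents) -> float:
    """Incidence-weighted mean utility across CVD conditions, 3 dp.

    Weights are hospital-admission shares in percent and must sum to
    100 +/- 0.1.
    """
    total = components.weight_sum()
    if not 99.9 <= total <= 100.1:
        raise ValidationError(f"CVD utility weights must sum to 100% +/- 0.1, got {total}")
    value = sum(u * w for _, u, w in components.components) / total
    return round(value, 3)


# ---------------------------------------------------------------------------
# Programme costs and trial summaries
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ProgrammeCosts:
    """Inputs to the intervention/control per-participant programme costing."""

    trainer_hours: float = 9.0
    trainer_rate: float = 125.0          # NZ$/hour
    psp_salary_total: float = 150_000.0  # incl. 25% overhead
    gp_visit: float = 65.0
    pedometer: float = 30.44
    quitline_per_participant: float = 195.33
    n_intervention: int = 455
    n_control: int = 451

    def __post_init__(self) -> None:
        for name in ("trainer_hours", "trainer_rate", "psp_salary_total",
                     "gp_visit", "pedometer", "quitline_per_participant"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be > 0")
        for name in ("n_intervention", "n_control"):
            n = getattr(self, name)
            if not (isinstance(n, int) and n >= 1):
                raise ValidationError(f"{name} must be a positive integer")


@dataclass(frozen=True)
class TrialArmSummary:
    """Published arm-level summary: n, quit rate, EQ-5D means (mean, se)."""

    n: int
    quit_rate: UncertainValue
    eq5d_baseline: tuple[float, float]
    eq5d_24wk: tuple[float, float]


# ---------------------------------------------------------------------------
# Lung-cancer tunnel parameterisation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LCTunnel:
    """Stage-specific annual progression/death inside the tunnel states.

    One entry per tunnel year; occupants of the final sub-state keep its
    rates (long-term survivors).  Defaults are synthetic, chosen so 5-year
    survival is clearly worse for the advanced stage.
    """

    years: int = 5
    early_death: tuple[float, ...] = (0.10, 0.08, 0.06, 0.05, 0.04)
    early_progression: tuple[float, ...] = (0.05, 0.05, 0.05, 0.05, 0.05)
    adv_death: tuple[float, ...] = (0.45, 0.35, 0.25, 0.20, 0.15)

    def __post_init__(self) -> None:
        if self.years < 1:
            raise ValidationError("tunnel depth must be >= 1 year")
        for name in ("early_death", "early_progression", "adv_death"):
            v = getattr(self, name)
            if len(v) != self.years:
                raise ValidationError(f"{name} needs one value per tunnel year")
            if any(not 0.0 <= p <= 1.0 for p in v):
                raise ValidationError(f"{name} entries must be probabilities in [0, 1]")


# ---------------------------------------------------------------------------
# The full parameter set
# ---------------------------------------------------------------------------

@dataclass
class ModelParameters:
    """Everything the trial-stage and lifetime analyses consume.

    Monetary values are 2012 NZ$ throughout; currency conversion is a
    display-layer concern (:func:`quitcea.report.convert_currency`).
    """

    quit_rate: dict  # (arm, sex) -> UncertainValue
    relapse_24wk_to_12mo: float
    relapse_after_12mo_cumulative: float
    lc_incidence: dict  # sex -> AgeCurve
    lc_early_prop: float
    lc_adv_prop: float
    lc_rr_smoker: float
    lc_rr_decay_years: float
    lc_tunnel: LCTunnel
    cvd_incidence: dict
    cvd_rr_smoker: UncertainValue
    cvd_rr_exsmoker_vs_smoker: UncertainValue
    cvd_prehospital_fatality: float
    cvd_28day_fatality: float
    background_mortality: dict
    utility_well_smoking: float
    utility_well_quit: float
    utility_lc_early: UncertainValue
    utility_lc_adv: UncertainValue
    cvd_utility_components: CVDUtilityComponents
    excess_costs: dict  # label -> sex -> AgeCurve
    discount_rate: float
    wtp_threshold: float
    horizon_age: int
    ppp_rates: dict
    programme: ProgrammeCosts
    trial: dict  # arm label -> TrialArmSummary

    @property
    def utility_cvd(self) -> float:
        return composite_cvd_utility(self.cvd_utility_components)

    def copy(self) -> "ModelParameters":
        return copy.deepcopy(self)

    def validate(self) -> None:
        for arm in ARMS:
            for sex in SEXES:
                if (arm, sex) not in self.quit_rate:
                    raise ConfigurationError(f"missing quit_rate[{arm}, {sex}]")
        for p, name in (
            (self.relapse_24wk_to_12mo, "relapse_24wk_to_12mo"),
            (self.relapse_after_12mo_cumulative, "relapse_after_12mo_cumulative"),
            (self.lc_early_prop, "lc_early_prop"),
            (self.lc_adv_prop, "lc_adv_prop"),
            (self.cvd_prehospital_fatality, "cvd_prehospital_fatality"),
            (self.cvd_28day_fatality, "cvd_28day_fatality"),
            (self.utility_well_smoking, "utility_well_smoking"),
            (self.utility_well_quit, "utility_well_quit"),
        ):
            if not 0.0 <= p <= 1.0:
                raise ValidationError(f"{name} must lie in [0, 1], got {p}")
        if abs(self.lc_early_prop + self.lc_adv_prop - 1.0) > 1e-9:
            raise ValidationError(
                "lc_early_prop + lc_adv_prop must equal 1, got "
                f"{self.lc_early_prop} + {self.lc_adv_prop}"
            )
        for rr, name in (
            (self.lc_rr_smoker, "lc_rr_smoker"),
            (self.cvd_rr_smoker.mean, "cvd_rr_smoker"),
            (self.cvd_rr_exsmoker_vs_smoker.mean, "cvd_rr_exsmoker_vs_smoker"),
        ):
            if rr <= 0:
                raise ValidationError(f"{name} must be > 0")
        if self.lc_rr_decay_years <= 0:
            raise ValidationError("lc_rr_decay_years must be > 0")
        if not 0.0 <= self.discount_rate < 1.0:
            raise ValidationError("discount_rate must lie in [0, 1)")
        for group in (self.lc_incidence, self.cvd_incidence, self.background_mortality):
            for sex in SEXES:
                if sex not in group:
                    raise ConfigurationError(f"missing {sex} curve")
        for label in COST_LABELS:
            if label not in self.excess_costs:
                raise ConfigurationError(f"missing excess cost curve {label!r}")
        composite_cvd_utility(self.cvd_utility_components)

    # -- serialisation ------------------------------------------------------

    def to_config_dict(self) -> dict:
        def uv(u: UncertainValue) -> dict:
            d = {"mean": u.mean, "family": u.family}
            if u.se is not None:
                d["se"] = u.se
            return d

        return {
            "quit_rate": {
                arm: {sex: uv(self.quit_rate[(arm, sex)]) for sex in SEXES} for arm in ARMS
            },
            "relapse": {
                "to_12_months": self.relapse_24wk_to_12mo,
                "after_12_months_cumulative": self.relapse_after_12mo_cumulative,
            },
            "lung_cancer": {
                "early_stage_proportion": self.lc_early_prop,
                "advanced_stage_proportion": self.lc_adv_prop,
                "rr_smoker": self.lc_rr_smoker,
                "rr_decay_years": self.lc_rr_decay_years,
                "tunnel": {
                    "years": self.lc_tunnel.years,
                    "early_death": list(self.lc_tunnel.early_death),
                    "early_progression": list(self.lc_tunnel.early_progression),
                    "advanced_death": list(self.lc_tunnel.adv_death),
                },
            },
            "cvd": {
                "rr_smoker": uv(self.cvd_rr_smoker),
                "rr_exsmoker_vs_smoker": uv(self.cvd_rr_exsmoker_vs_smoker),
                "prehospital_fatality": self.cvd_prehospital_fatality,
                "fatality_28day": self.cvd_28day_fatality,
            },
            "utilities": {
                "well_smoking": self.utility_well_smoking,
                "well_quit": self.utility_well_quit,
                "lc_early": uv(self.utility_lc_early),
                "lc_adv": uv(self.utility_lc_adv),
                "cvd_components": [
                    {"name": n, "utility": u, "weight_percent": w}
                    for n, u, w in self.cvd_utility_components.components
                ],
            },
            "economics": {
                "discount_rate": self.discount_rate,
                "wtp_threshold": self.wtp_threshold,
                "horizon_age": self.horizon_age,
                "ppp_rates": dict(self.ppp_rates),
            },
            "programme": {
                "trainer_hours": self.programme.trainer_hours,
                "trainer_rate": self.programme.trainer_rate,
                "psp_salary_total": self.programme.psp_salary_total,
                "gp_visit": self.programme.gp_visit,
                "pedometer": self.programme.pedometer,
                "quitline_per_participant": self.programme.quitline_per_participant,
                "n_intervention": self.programme.n_intervention,
                "n_control": self.programme.n_control,
            },
            "trial": {
                arm: {
                    "n": s.n,
                    "quit_rate": uv(s.quit_rate),
                    "eq5d_baseline": list(s.eq5d_baseline),
                    "eq5d_24wk": list(s.eq5d_24wk),
                }
                for arm, s in self.trial.items()
            },
        }


_CURVE_FILES = {
    "background_mortality": "probability",
    "lc_incidence": "probability",
    "cvd_incidence": "probability",
    "cost_lc_first_year": "cost",
    "cost_lc_subsequent_annual": "cost",
    "cost_lc_terminal_6mo": "cost",
    "cost_cvd_first_year": "cost",
    "cost_cvd_terminal_6mo": "cost",
}


def save_parameters(params: ModelParameters, directory: str | Path) -> Path:
    """Write ``params.yaml`` plus one ``curves/<name>.csv`` per age curve."""
    directory = Path(directory)
    (directory / "curves").mkdir(parents=True, exist_ok=True)
    with open(directory / "params.yaml", "w") as fh:
        yaml.safe_dump(params.to_config_dict(), fh, sort_keys=False)

    curve_groups = {
        "background_mortality": params.background_mortality,
        "lc_incidence": params.lc_incidence,
        "cvd_incidence": params.cvd_incidence,
    }
    for label in COST_LABELS:
        curve_groups[f"cost_{label}"] = params.excess_costs[label]
    for name, group in curve_groups.items():
        frames = []
        for sex in SEXES:
            c = group[sex]
            frames.append(pd.DataFrame({"age": c.ages, "sex": sex, "value": c.values}))
        pd.concat(frames).to_csv(
            directory / "curves" / f"{name}.csv", index=False, float_format="%.17g"
        )
    return directory


def _require(mapping: Mapping, key: str, context: str):
    if key not in mapping:
        raise ConfigurationError(f"missing required configuration key {context}.{key}")
    return mapping[key]


def _load_uv(d, context: str) -> UncertainValue:
    if isinstance(d, (int, float)):
        return UncertainValue(float(d))
    mean = _require(d, "mean", context)
    return UncertainValue(float(mean), d.get("se"), d.get("family", "fixed"))


def load_parameters(directory: str | Path) -> ModelParameters:
    """Load a parameter bundle written by :func:`save_parameters`.

    Raises :class:`ConfigurationError` naming the first missing key and
    :class:`ValidationError` for out-of-range values.
    """
    directory = Path(directory)
    path = directory / "params.yaml"
    if not path.exists():
        raise ConfigurationError(f"no params.yaml under {directory}")
    with open(path) as fh:
        cfg = yaml.safe_load(fh)

    curves: dict[str, dict[str, AgeCurve]] = {}
    for name, kind in _CURVE_FILES.items():
        fpath = directory / "curves" / f"{name}.csv"
        if not fpath.exists():
            raise ConfigurationError(f"missing curve file curves/{name}.csv")
        df = pd.read_csv(fpath, float_precision="round_trip")
        group = {}
        for sex in SEXES:
            sub = df[df["sex"] == sex].sort_values("age")
            if sub.empty:
                raise ConfigurationError(f"curve {name} has no rows for sex={sex}")
            group[sex] = AgeCurve(sex, sub["age"].to_numpy(), sub["value"].to_numpy(), kind)
        curves[name] = group

    qr = _require(cfg, "quit_rate", "")
    quit_rate = {}
    for arm in ARMS:
        arm_cfg = _require(qr, arm, "quit_rate")
        for sex in SEXES:
            quit_rate[(arm, sex)] = _load_uv(
                _require(arm_cfg, sex, f"quit_rate.{arm}"), f"quit_rate.{arm}.{sex}"
            )

    relapse = _require(cfg, "relapse", "")
    lc = _require(cfg, "lung_cancer", "")
    tunnel_cfg = _require(lc, "tunnel", "lung_cancer")
    cvd = _require(cfg, "cvd", "")
    util = _require(cfg, "utilities", "")
    econ = _require(cfg, "economics", "")
    prog = _require(cfg, "programme", "")
    trial_cfg = _require(cfg, "trial", "")

    comps = CVDUtilityComponents(
        components=tuple(
            (c["name"], float(c["utility"]), float(c["weight_percent"]))
            for c in _require(util, "cvd_components", "utilities")
        )
    )
    params = ModelParameters(
        quit_rate=quit_rate,
        relapse_24wk_to_12mo=float(_require(relapse, "to_12_months", "relapse")),
        relapse_after_12mo_cumulative=float(
            _require(relapse, "after_12_months_cumulative", "relapse")
        ),
        lc_incidence=curves["lc_incidence"],
        lc_early_prop=float(_require(lc, "early_stage_proportion", "lung_cancer")),
        lc_adv_prop=float(_require(lc, "advanced_stage_proportion", "lung_cancer")),
        lc_rr_smoker=float(_require(lc, "rr_smoker", "lung_cancer")),
        lc_rr_decay_years=float(_require(lc, "rr_decay_years", "lung_cancer")),
        lc_tunnel=LCTunnel(
            years=int(_require(tunnel_cfg, "years", "lung_cancer.tunnel")),
            early_death=tuple(_require(tunnel_cfg, "early_death", "lung_cancer.tunnel")),
            early_progression=tuple(
                _require(tunnel_cfg, "early_progression", "lung_cancer.tunnel")
            ),
            adv_death=tuple(_require(tunnel_cfg, "advanced_death", "lung_cancer.tunnel")),
        ),
        cvd_incidence=curves["cvd_incidence"],
        cvd_rr_smoker=_load_uv(_require(cvd, "rr_smoker", "cvd"), "cvd.rr_smoker"),
        cvd_rr_exsmoker_vs_smoker=_load_uv(
            _require(cvd, "rr_exsmoker_vs_smoker", "cvd"), "cvd.rr_exsmoker_vs_smoker"
        ),
        cvd_prehospital_fatality=float(_require(cvd, "prehospital_fatality", "cvd")),
        cvd_28day_fatality=float(_require(cvd, "fatality_28day", "cvd")),
        background_mortality=curves["background_mortality"],
        utility_well_smoking=float(_require(util, "well_smoking", "utilities")),
        utility_well_quit=float(_require(util, "well_quit", "utilities")),
        utility_lc_early=_load_uv(_require(util, "lc_early", "utilities"), "utilities.lc_early"),
        utility_lc_adv=_load_uv(_require(util, "lc_adv", "utilities"), "utilities.lc_adv"),
        cvd_utility_components=comps,
        excess_costs={label: curves[f"cost_{label}"] for label in COST_LABELS},
        discount_rate=float(_require(econ, "discount_rate", "economics")),
        wtp_threshold=float(_require(econ, "wtp_threshold", "economics")),
        horizon_age=int(_require(econ, "horizon_age", "economics")),
        ppp_rates=dict(_require(econ, "ppp_rates", "economics")),
        programme=ProgrammeCosts(
            trainer_hours=float(_require(prog, "trainer_hours", "programme")),
            trainer_rate=float(_require(prog, "trainer_rate", "programme")),
            psp_salary_total=float(_require(prog, "psp_salary_total", "programme")),
            gp_visit=float(_require(prog, "gp_visit", "programme")),
            pedometer=float(_require(prog, "pedometer", "programme")),
            quitline_per_participant=float(
                _require(prog, "quitline_per_participant", "programme")
            ),
            n_intervention=int(_require(prog, "n_intervention", "programme")),
            n_control=int(_require(prog, "n_control", "programme")),
        ),
        trial={
            arm: TrialArmSummary(
                n=int(_require(s, "n", f"trial.{arm}")),
                quit_rate=_load_uv(_require(s, "quit_rate", f"trial.{arm}"), f"trial.{arm}"),
                eq5d_baseline=tuple(_require(s, "eq5d_baseline", f"trial.{arm}")),
                eq5d_24wk=tuple(_require(s, "eq5d_24wk", f"trial.{arm}")),
            )
            for arm, s in trial_cfg.items()
        },
    )
    params.validate()
    return params


def default_parameters() -> ModelParameters:
    """The bundled defaults: published scalars plus synthetic age curves."""
    from . import synthetic_data  # local import to avoid a cycle

    curves = synthetic_data.default_curves()
    params = ModelParameters(
        quit_rate={
            ("adherent_intervention", "male"): UncertainValue(0.352, 0.047, "beta"),
            ("adherent_intervention", "female"): UncertainValue(0.298, 0.040, "beta"),
            ("usual_care", "male"): UncertainValue(0.242, 0.030, "beta"),
            ("usual_care", "female"): UncertainValue(0.197, 0.025, "beta"),
        },
        relapse_24wk_to_12mo=0.21,
        relapse_after_12mo_cumulative=0.30,
        lc_incidence=curves["lc_incidence"],
        lc_early_prop=0.20,
        lc_adv_prop=0.80,
        lc_rr_smoker=1.771,
        lc_rr_decay_years=15.0,
        lc_tunnel=LCTunnel(),
        cvd_incidence=curves["cvd_incidence"],
        cvd_rr_smoker=UncertainValue(1.42, 0.031, "lognormal"),
        cvd_rr_exsmoker_vs_smoker=UncertainValue(0.71, 0.036, "lognormal"),
        cvd_prehospital_fatality=0.181,
        cvd_28day_fatality=0.071,
        background_mortality=curves["background_mortality"],
        utility_well_smoking=0.800,
        utility_well_quit=0.830,
        utility_lc_early=UncertainValue(0.73, 0.020, "beta"),
        utility_lc_adv=UncertainValue(0.56, 0.043, "beta"),
        cvd_utility_components=DEFAULT_CVD_COMPONENTS,
        excess_costs={label: curves[f"cost_{label}"] for label in COST_LABELS},
        discount_rate=0.035,
        wtp_threshold=20_000.0,
        horizon_age=100,
        ppp_rates={"USD": 0.68, "EUR": 0.53},
        programme=ProgrammeCosts(),
        trial={
            "intervention": TrialArmSummary(
                n=455,
                quit_rate=UncertainValue(0.231, 0.020, "beta"),
                eq5d_baseline=(0.792, 0.01),
                eq5d_24wk=(0.800, 0.01),
            ),
            "control": TrialArmSummary(
                n=451,
                quit_rate=UncertainValue(0.217, 0.019, "beta"),
                eq5d_baseline=(0.800, 0.01),
                eq5d_24wk=(0.803, 0.01),
            ),
            "adherent": TrialArmSummary(
                n=236,
                quit_rate=UncertainValue(0.322, 0.030, "beta"),
                eq5d_baseline=(0.792, 0.01),
                eq5d_24wk=(0.800, 0.01),
            ),
        },
    )
    params.validate()
    return params
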