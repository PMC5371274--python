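"""Synthetic inputs: age–sex curves and individual-level trial records.

The published analysis draws its age-dependent inputs (disease incidence,
background mortality, excess health-system costs) from national New Zealand
data sources that only print example values for a 65-year-old.  This module
generates full 0–100 curves anchored exactly at those age-65 values, with a
Gompertz-like exponential age trend for mortality/incidence and flat curves
for costs.  It also simulates individual trial records (quit status and
EQ-5D utilities at baseline and 24 weeks) whose arm-level means and standard
errors match the published summaries, so every downstream analysis is
runnable and testable without any external download.

The curves are anchored fixtures, not estimates of the real NZ curves; the
log-slopes (mortality 0.09/yr, lung-cancer incidence 0.085/yr, CVD incidence
0.07/yr) were picked once for demographic plausibility.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError
from .parameters import (
    SEXES,
    AgeCurve,
    TrialArmSummary,
    UncertainValue,
)

EQ5D_MIN, EQ5D_MAX = -0.59, 1.0

# Within-person correlation between baseline and 24-week EQ-5D (Gaussian
# copula scale).  Repeated HRQoL measures are strongly correlated; 0.75 is a
# typical test–retest figure for EQ-5D index values.
DEFAULT_UTILITY_RHO = 0.75
DEFAULT_MALE_FRACTION = 0.46       # trial arms were ~46% male
DEFAULT_ADHERENT_FRACTION = 236 / 455


@dataclass(frozen=True)
class CurveShapeSpec:
    """Shape of a synthetic age curve: exponential-in-age or flat.

    ``value(age) = anchor * exp(log_slope * (age - anchor_age))`` for the
    exponential family; probability curves are clipped to [0, 1], so the
    anchor is reproduced exactly and the curve is monotone wherever the clip
    is inactive.
    """

    family: str                      # "exponential" or "flat"
    anchors: Mapping[str, float]     # per-sex value at anchor_age
    anchor_age: int = 65
    log_slope: float = 0.0

    def __post_init__(self) -> None:
        if self.family not in ("exponential", "flat"):
            raise ValidationError(f"unknown curve family {self.family!r}")


def gen_age_curve(
    spec: CurveShapeSpec,
    sex: str,
    kind: str = "probability",
    age_min: int = 0,
    age_max: int = 100,
) -> AgeCurve:
    """Materialise one sex's curve from a :class:`CurveShapeSpec`."""
    if sex not in spec.anchors:
        raise ValidationError(f"spec has no anchor for sex {sex!r}")
    anchor = float(spec.anchors[sex])
    if kind == "probability" and not 0.0 <= anchor <= 1.0:
        raise ValidationError(f"probability anchor must lie in [0, 1], got {anchor}")
    if kind == "cost" and anchor < 0:
        raise ValidationError(f"cost anchor must be >= 0, got {anchor}")
    ages = np.arange(age_min, age_max + 1)
    if spec.family == "flat":
        values = np.full(ages.shape, anchor, dtype=float)
    else:
        values = anchor * np.exp(spec.log_slope * (ages - spec.anchor_age))
    if kind == "probability":
        values = np.clip(values, 0.0, 1.0)
    return AgeCurve(sex=sex, ages=ages, values=values, kind=kind)


def default_curve_specs() -> dict[str, tuple[CurveShapeSpec, str]]:
    """Default (spec, kind) per curve, anchored at the published age-65 values."""
    return {
        "background_mortality": (
            CurveShapeSpec("exponential", {"male": 0.01071, "female": 0.00715}, 65, 0.09),
            "probability",
        ),
        "lc_incidence": (
            CurveShapeSpec("exponential", {"male": 0.00180, "female": 0.00165}, 65, 0.085),
            "probability",
        ),
        "cvd_incidence": (
            CurveShapeSpec("exponential", {"male": 0.03095, "female": 0.01843}, 65, 0.07),
            "probability",
        ),
        "cost_lc_first_year": (
            CurveShapeSpec("flat", {"male": 23_970.0, "female": 22_256.0}),
            "cost",
        ),
        "cost_lc_subsequent_annual": (
            CurveShapeSpec("flat", {"male": 5_375.0, "female": 4_341.0}),
            "cost",
        ),
        "cost_lc_terminal_6mo": (
            CurveShapeSpec("flat", {"male": 16_615.0, "female": 20_300.0}),
            "cost",
        ),
        "cost_cvd_first_year": (
            CurveShapeSpec("flat", {"male": 11_327.0, "female": 10_189.0}),
            "cost",
        ),
        "cost_cvd_terminal_6mo": (
            CurveShapeSpec("flat", {"male": 17_573.0, "female": 11_048.0}),
            "cost",
        ),
    }


def default_curves() -> dict[str, dict[str, AgeCurve]]:
    """All default curves, keyed by name then sex."""
    out: dict[str, dict[str, AgeCurve]] = {}
    for name, (spec, kind) in default_curve_specs().items():
        out[name] = {sex: gen_age_curve(spec, sex, kind) for sex in SEXES}
    return out


# ---------------------------------------------------------------------------
# Individual-level trial records
# ---------------------------------------------------------------------------

def _beta_params(mean: float, sd: float) -> tuple[float, float]:
    var = sd * sd
    if var >= mean * (1.0 - mean):
        raise ValidationError(
            f"cannot match utility mean {mean} / sd {sd} with a beta on [0, 1]"
        )
    nu = mean * (1.0 - mean) / var - 1.0
    return mean * nu, (1.0 - mean) * nu


def _utility_pair(
    rng: np.random.Generator,
    n: int,
    baseline: tuple[float, float],
    followup: tuple[float, float],
    n_summary: int,
    rho: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Correlated (baseline, follow-up) utilities via a Gaussian copula.

    Marginals are betas on [0, 1] matched to the arm mean and an individual-
    level sd of se * sqrt(n_summary); EQ-5D states below 0 are not generated
    (cohort-level simplification).
    """
    ab_b = _beta_params(baseline[0], baseline[1] * np.sqrt(n_summary))
    ab_f = _beta_params(followup[0], followup[1] * np.sqrt(n_summary))
    z1 = rng.standard_normal(n)
    z2 = rho * z1 + np.sqrt(1.0 - rho * rho) * rng.standard_normal(n)
    u_base = stats.beta.ppf(stats.norm.cdf(z1), *ab_b)
    u_fup = stats.beta.ppf(stats.norm.cdf(z2), *ab_f)
    return u_base, u_fup


def gen_trial_cohort(
    n_per_arm: int,
    arm_summaries: Mapping[str, TrialArmSummary],
    seed: int,
    rho: float = DEFAULT_UTILITY_RHO,
    male_fraction: float = DEFAULT_MALE_FRACTION,
    adherent_fraction: float = DEFAULT_ADHERENT_FRACTION,
) -> pd.DataFrame:
    """Simulate individual trial records matching published arm summaries.

    ``arm_summaries`` must carry keys ``intervention``, ``control`` and
    ``adherent`` (the adherent subset of the intervention arm).  Quit
    indicators are Bernoulli at the arm rate; within the intervention arm
    the adherent subgroup quits at its own (higher) rate and the
    non-adherent rate is solved so the arm-level rate is preserved.
    Identical seeds give byte-identical record tables.
    """
    if n_per_arm < 1:
        raise ValidationError("n_per_arm must be >= 1")
    for key in ("intervention", "control", "adherent"):
        if key not in arm_summaries:
            raise ValidationError(f"arm_summaries missing {key!r}")
    rng = np.random.default_rng(seed)

    p_int = arm_summaries["intervention"].quit_rate.mean
    p_ctl = arm_summaries["control"].quit_rate.mean
    p_adh = arm_summaries["adherent"].quit_rate.mean
    for p, name in ((p_int, "intervention"), (p_ctl, "control"), (p_adh, "adherent")):
        if not 0.0 <= p <= 1.0:
            raise ValidationError(f"{name} quit rate must lie in [0, 1], got {p}")
    f = adherent_fraction
    p_non = (p_int - f * p_adh) / (1.0 - f) if f < 1.0 else p_int
    if not 0.0 <= p_non <= 1.0:
        raise ValidationError(
            "implied non-adherent quit rate outside [0, 1]; "
            "check intervention/adherent summaries"
        )

    frames = []
    for arm in ("intervention", "control"):
        s = arm_summaries[arm]
        sex = np.where(rng.random(n_per_arm) < male_fraction, "male", "female")
        if arm == "intervention":
            adherent = rng.random(n_per_arm) < f
            p_quit = np.where(adherent, p_adh, p_non)
        else:
            adherent = np.zeros(n_per_arm, dtype=bool)
            p_quit = np.full(n_per_arm, p_ctl)
        quit = rng.random(n_per_arm) < p_quit
        u_base, u_fup = _utility_pair(
            rng, n_per_arm, s.eq5d_baseline, s.eq5d_24wk, s.n, rho
        )
        frames.append(
            pd.DataFrame(
                {
                    "arm": arm,
                    "adherent": adherent,
                    "sex": sex,
                    "quit_24wk": quit,
                    "eq5d_baseline": u_base,
                    "eq5d_24wk": u_fup,
                }
            )
        )
    df = pd.concat(frames, ignore_index=True)
    df.insert(0, "id", np.arange(1, len(df) + 1))
    return df


def write_trial_records(records: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    records.to_csv(path, index=False)
    return path


def read_trial_records(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
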