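"""Display-layer helpers: currency conversion, report tables, run manifests.

All model arithmetic stays in 2012 NZ$; purchasing-power-parity conversion
to US$/€ happens only here, when results are rendered.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd

from .errors import ValidationError
from .trial_cea import CEResult, WithinTrialReport

DEFAULT_PPP = {"USD": 0.68, "EUR": 0.53}
PRICE_YEAR_NOTE = "2012 NZ$"


def convert_currency(nzd_amount: float, target: str, rates=None, whole: bool = True):
    """PPP-convert an NZ$ amount for display (rounded to whole units)."""
    rates = DEFAULT_PPP if rates is None else rates
    if target not in rates:
        raise LookupError(f"no PPP rate configured for currency {target!r}")
    value = float(nzd_amount) * rates[target]
    return round(value) if whole else value


def _fmt_money(x: float | None) -> str:
    return "—" if x is None else f"{x:,.0f}"


def _fmt_icer(ce: CEResult | None) -> str:
    if ce is None:
        return "—"
    if ce.classification == "dominant":
        return "Dominant"
    if ce.classification == "dominated":
        return "Dominated"
    if ce.classification == "undefined" or ce.icer is None:
        return "undefined"
    return f"{ce.icer:,.0f}"


def render_within_trial(report: WithinTrialReport) -> str:
    """Text report of the 24-week evaluation (costs in 2012 NZ$)."""
    lines = [f"Within-trial (24-week) cost-effectiveness [{PRICE_YEAR_NOTE}]", ""]
    for summary in (report.intervention_costs, report.control_costs):
        lines.append(f"{summary.arm} cost per participant:")
        for label, value in summary.components:
            lines.append(f"  {label:<22} {value:>10}")
        lines.append(f"  {'total':<22} {summary.total:>10}")
        lines.append("")
    lines.append(f"Incremental programme cost: {report.incremental_cost}")
    lines.append(f"ICER per quitter (ITT):      {_fmt_icer(report.icer_per_quitter_itt)}")
    lines.append(f"ICER per quitter (adherent): {_fmt_icer(report.icer_per_quitter_adherent)}")
    if report.delta_qaly is not None:
        lo, hi = report.delta_qaly_ci
        lines.append(
            f"Adjusted QALY gain: {report.delta_qaly:.4f} (95% CI {lo:.4f} to {hi:.4f})"
        )
        lines.append(f"ICER per QALY:               {_fmt_icer(report.icer_per_qaly)}")
    return "\n".join(lines)


def render_table4(
    base_results: dict,
    scenarios: pd.DataFrame | None = None,
    threshold: float = 20_000.0,
) -> str:
    """Lifetime results formatted like the published summary table.

    ``base_results`` maps sex -> dict with optional keys ``intervention`` /
    ``usual_care`` (CohortResult), ``ce`` (CEResult), ``prob_ce`` (float).
    Missing cells render as an em-dash gap marker rather than failing.
    """
    sexes = list(base_results) or ["male", "female"]
    if not base_results:
        header = "Lifetime cost-effectiveness (no results supplied — empty report)"
    else:
        header = f"Lifetime cost-effectiveness, adherent subgroup [{PRICE_YEAR_NOTE}]"
    lines = [header, ""]
    colw = 16
    lines.append("".ljust(34) + "".join(s.ljust(colw) for s in sexes))

    def cell(sex: str, key: str, fmt):
        entry = base_results.get(sex, {})
        value = entry.get(key)
        return "—" if value is None else fmt(value)

    rows = [
        ("Mean cost, intervention (NZ$)", "intervention",
         lambda r: _fmt_money(r.discounted_cost)),
        ("Mean cost, usual care (NZ$)", "usual_care",
         lambda r: _fmt_money(r.discounted_cost)),
        ("QALYs, intervention", "intervention", lambda r: f"{r.discounted_qalys:.3f}"),
        ("QALYs, usual care", "usual_care", lambda r: f"{r.discounted_qalys:.3f}"),
        ("Incremental cost (NZ$)", "ce", lambda ce: _fmt_money(ce.delta_cost)),
        ("Incremental QALYs", "ce", lambda ce: f"{ce.delta_effect:.3f}"),
        ("ICER per QALY (NZ$)", "ce", _fmt_icer),
        (f"Probability cost-effective at {threshold:,.0f}", "prob_ce",
         lambda p: f"{p:.3f}"),
    ]
    for label, key, fmt in rows:
        lines.append(label.ljust(34) + "".join(cell(s, key, fmt).ljust(colw) for s in sexes))

    if scenarios is not None and len(scenarios):
        lines += ["", "Scenarios:"]
        lines.append(
            f"{'sex':<8}{'scenario':<16}{'Incr. cost':>12}{'Incr. QALYs':>13}"
            f"{'ICER':>12}{'P(CE)':>8}"
        )
        for _, row in scenarios.iterrows():
            ce_txt = (
                "Dominant" if row["classification"] == "dominant"
                else "Dominated" if row["classification"] == "dominated"
                else "undefined" if row["classification"] == "undefined"
                else f"{row['icer']:,.0f}"
            )
            prob = row.get("prob_cost_effective")
            prob_txt = "—" if prob is None or pd.isna(prob) else f"{prob:.3f}"
            lines.append(
                f"{row['sex']:<8}{row['scenario']:<16}{row['delta_cost']:>12,.0f}"
                f"{row['delta_qaly']:>13.3f}{ce_txt:>12}{prob_txt:>8}"
            )
    elif not base_results:
        lines.append("  (all cells empty — supply base-case results)")
    return "\n".join(lines)


@dataclass(frozen=True)
class RunManifest:
    """Provenance stamp written next to every CLI output."""

    subcommand: str
    params_path: str | None
    seed: int | None
    timestamp: str
    package_version: str
    parameter_checksum: str | None


def parameter_checksum(directory: str | Path | None) -> str | None:
    if directory is None:
        return None
    directory = Path(directory)
    digest = hashlib.sha256()
    for path in sorted(directory.rglob("*")):
        if path.is_file():
            digest.update(path.name.encode())
            digest.update(path.read_bytes())
    return digest.hexdigest()


def write_manifest(
    out_dir: str | Path,
    subcommand: str,
    params_path: str | Path | None = None,
    seed: int | None = None,
) -> Path:
    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        subcommand=subcommand,
        params_path=str(params_path) if params_path else None,
        seed=seed,
        timestamp=datetime.now(timezone.utc).isoformat(),
        package_version=__version__,
        parameter_checksum=parameter_checksum(params_path),
    )
    path = out_dir / "manifest.json"
    with open(path, "w") as fh:
        json.dump(asdict(manifest), fh, indent=2)
    return path
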