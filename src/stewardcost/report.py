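"""Report writers: delimited tables and a human-readable markdown summary.

Stored results keep full floating precision; these writers are the only
place figures are rounded (half away from zero, to whole currency units),
and every monetary figure is presented in both the base currency and USD.
Outputs are deterministic: fixed row order, no timestamps.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .cbna import CostBenefitResult, CurrencyConfig, qar_to_usd, round_half_away
from .costing import PeriodSummary
from .sensitivity import SensitivityResult

__all__ = [
    "period_summary_frame",
    "cost_benefit_frame",
    "write_period_summaries",
    "write_cost_benefit",
    "write_sensitivity",
    "write_markdown_report",
]


def _pair(amount: float, cfg: CurrencyConfig) -> tuple[int, int]:
    return round_half_away(amount), round_half_away(qar_to_usd(amount, cfg))


def period_summary_frame(
    summaries: list[PeriodSummary], cfg: CurrencyConfig | None = None
) -> pd.DataFrame:
    """Itemized per-phase resource table (one column pair per phase)."""
    cfg = cfg or CurrencyConfig()
    rows: dict[str, dict[str, float]] = {}
    for s in summaries:
        led = s.ledger
        items = {
            "n_patients": s.n_patients,
            "ddd_total": round(led.ddd_total, 1),
            "antimicrobial_cost": led.antimicrobial_ddd_cost,
            "resource.cultures_before": led.resource.cultures_before,
            "resource.labs_before": led.resource.labs_before,
            "resource.biopsies_before": led.resource.biopsies_before,
            "resource.cultures_after": led.resource.cultures_after,
            "resource.labs_after": led.resource.labs_after,
            "resource.biopsies_after": led.resource.biopsies_after,
            "resource.iv_to_oral": led.resource.iv_to_oral,
            "resource.total": led.resource_total,
            "resource.per_patient": led.resource_total / s.n_patients,
            "avoidance.hospitalization": led.avoidance.hospitalization,
            "avoidance.cdi": led.avoidance.cdi,
            "avoidance.readmission": led.avoidance.readmission,
            "avoidance.ade": led.avoidance.ade,
            "avoidance.total": led.avoidance_total,
            "avoidance.per_patient": led.avoidance_total / s.n_patients,
            "operational": led.operational,
        }
        for item, value in items.items():
            row = rows.setdefault(item, {"item": item})
            if item in ("n_patients", "ddd_total"):
                row[s.period] = value
            else:
                qar, usd = _pair(value, cfg)
                row[f"{s.period}_qar"] = qar
                row[f"{s.period}_usd"] = usd
    return pd.DataFrame(list(rows.values()))


def cost_benefit_frame(
    result: CostBenefitResult, cfg: CurrencyConfig | None = None
) -> pd.DataFrame:
    """Cost-benefit table: each category difference, total and per patient."""
    cfg = cfg or CurrencyConfig()
    rows = []
    for label, total, pp in [
        ("saving_ddd", result.saving_ddd, result.saving_ddd_per_patient),
        ("saving_resource", result.saving_resource, result.saving_resource_per_patient),
        ("saving_total", result.saving_total, result.saving_total_per_patient),
        ("avoidance", result.avoidance, result.avoidance_per_patient),
        ("operational_saving", result.operational_saving,
         result.operational_saving_per_patient),
        ("net_reduction", result.net_reduction, result.net_reduction_per_patient),
    ]:
        t_qar, t_usd = _pair(total, cfg)
        p_qar, p_usd = _pair(pp, cfg)
        rows.append(
            {
                "parameter": label,
                "total_qar": t_qar,
                "total_usd": t_usd,
                "per_patient_qar": p_qar,
                "per_patient_usd": p_usd,
            }
        )
    return pd.DataFrame(rows)


def _to_csv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False, lineterminator="\n")


def write_period_summaries(
    summaries: list[PeriodSummary], path: str | Path, cfg: CurrencyConfig | None = None
) -> None:
    _to_csv(period_summary_frame(summaries, cfg), path)


def write_cost_benefit(
    result: CostBenefitResult, path: str | Path, cfg: CurrencyConfig | None = None
) -> None:
    _to_csv(cost_benefit_frame(result, cfg), path)


def write_sensitivity(
    result: SensitivityResult,
    draws_path: str | Path,
    tornado_path: str | Path,
) -> None:
    """Write the draws/outcome table and the tornado ranking as CSV."""
    draws = pd.DataFrame(result.draws, columns=result.input_names)
    draws.insert(0, "iteration", range(1, result.n_iterations + 1))
    draws["net_reduction"] = result.outcomes
    _to_csv(draws, draws_path)

    tornado = pd.DataFrame(
        result.tornado, columns=["input", "standardized_coefficient"]
    )
    tornado.insert(0, "rank", range(1, len(result.tornado) + 1))
    _to_csv(tornado, tornado_path)


def write_markdown_report(
    summaries: list[PeriodSummary],
    result: CostBenefitResult,
    sensitivity: SensitivityResult | None,
    stats_table: pd.DataFrame | None,
    path: str | Path,
    cfg: CurrencyConfig | None = None,
) -> None:
    """Human-readable summary of the full comparison, in both currencies."""
    cfg = cfg or CurrencyConfig()
    lines = ["# Stewardship cost of resource use", ""]
    lines.append("## Phase totals")
    lines.append("")
    lines.append("```\n" + period_summary_frame(summaries, cfg).to_string(index=False) + "\n```")
    lines.append("")
    lines.append("## Cost-benefit (positive favors the developed phase)")
    lines.append("")
    lines.append("```\n" + cost_benefit_frame(result, cfg).to_string(index=False) + "\n```")
    lines.append("")
    net_qar, net_usd = _pair(result.net_reduction, cfg)
    pp_qar, pp_usd = _pair(result.net_reduction_per_patient, cfg)
    lines.append(
        f"Net reduction in monetary spending: QAR {net_qar:,} (USD {net_usd:,}); "
        f"QAR {pp_qar:,} (USD {pp_usd:,}) per patient."
    )
    if sensitivity is not None:
        lines.append("")
        lines.append("## Sensitivity")
        lines.append("")
        lines.append(
            f"Probability the developed phase is favored (net reduction > 0) over "
            f"{sensitivity.n_iterations} iterations (seed {sensitivity.seed}): "
            f"{100 * sensitivity.probability_in_favor:.1f}%."
        )
        lines.append("")
        for rank, (name, coef) in enumerate(sensitivity.tornado, start=1):
            lines.append(f"{rank}. {name}: standardized coefficient {coef:+.3f}")
    if stats_table is not None:
        lines.append("")
        lines.append("## Cohort comparison")
        lines.append("")
        lines.append("```\n" + stats_table.to_string(index=False) + "\n```")
    lines.append("")
    Path(path).write_text("\n".join(lines), encoding="utf-8")
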