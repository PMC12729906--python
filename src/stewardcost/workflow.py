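"""End-to-end analysis workflow: config, logging, report bundle.

`run_analysis` ties the stages together in the study's order — read,
filter for eligibility, cost each phase, compare, test, propagate
uncertainty — and writes a deterministic report bundle.  The thin CLI in
:mod:`stewardcost.cli` is a wrapper around these functions.
"""

from __future__ import annotations

import logging
from importlib.metadata import version
from pathlib import Path
from typing import Any

import yaml
from pydantic import BaseModel, Field

from . import cbna, costing, io, records, report, sensitivity, stats

logger = logging.getLogger("stewardcost")

__all__ = ["RunConfig", "load_run_config", "run_analysis"]


class RunConfig(BaseModel):
    """Paths and knobs for one full analysis run."""

    cohort_preliminary: Path
    cohort_developed: Path
    unit_costs: Path
    ddd_reference: Path
    staffing: Path
    output_dir: Path
    seed: int = 0
    iterations: int = Field(default=1000, ge=1)
    pct: float = Field(default=0.10, ge=0)
    utilization_scope: sensitivity.UtilizationScope = "developed"
    qar_per_usd: float = Field(default=3.64, gt=0)
    log_level: str = "INFO"


def load_run_config(
    path: str | Path | None = None, **overrides: Any
) -> RunConfig:
    """Build a :class:`RunConfig` from a YAML file; keyword flags win."""
    payload: dict[str, Any] = {}
    if path is not None:
        payload = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
    payload.update({k: v for k, v in overrides.items() if v is not None})
    return RunConfig(**payload)


def _require(path: Path, what: str) -> Path:
    if not path.exists():
        raise FileNotFoundError(f"{what}: {path}")
    return path


def run_analysis(config: RunConfig) -> dict[str, Path]:
    """Run the full comparison and write the report bundle.

    Outputs in ``config.output_dir``: ``period_summaries.csv``,
    ``cost_benefit.csv``, ``statistics.csv``, ``sensitivity_draws.csv``,
    ``tornado.csv`` and ``report.md``.  Deterministic for a fixed config
    and seed.  Raises on missing inputs or an empty eligible cohort.
    """
    logging.basicConfig(level=config.log_level)
    logger.info("stewardcost %s", version("stewardcost"))
    logger.info("config: %s", config.model_dump())

    costs = io.read_unit_costs(_require(config.unit_costs, "unit-cost table"))
    reference = io.read_ddd_reference(_require(config.ddd_reference, "DDD reference"))
    rosters = io.read_staffing(_require(config.staffing, "staffing rosters"))

    policy = records.EligibilityPolicy()
    summaries = []
    cohorts: dict[str, list[records.PatientEpisode]] = {}
    for label, directory in [
        ("preliminary", config.cohort_preliminary),
        ("developed", config.cohort_developed),
    ]:
        cohort = io.read_cohort(_require(Path(directory), f"{label} cohort"))
        eligible = records.filter_eligible(cohort, policy)
        logger.info("%s: %d episodes read, %d eligible", label, len(cohort), len(eligible))
        if not eligible:
            raise costing.EmptyCohortError(f"no eligible episodes in {label} cohort")
        cohorts[label] = eligible
        operational = (
            costing.annual_operational_cost(rosters[label]) if label in rosters else 0.0
        )
        summaries.append(
            costing.period_totals(eligible, reference, costs, label, operational)
        )

    pre_summary, dev_summary = summaries
    result = cbna.compare_periods(pre_summary, dev_summary)
    stats_table = stats.compare_cohorts(cohorts["preliminary"], cohorts["developed"])

    model = sensitivity.net_reduction_model(
        pre_summary, dev_summary, utilization_scope=config.utilization_scope
    )
    psa = sensitivity.multivariate(
        model,
        sensitivity.default_uncertain_inputs(config.pct),
        n_iterations=config.iterations,
        seed=config.seed,
    )

    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = cbna.CurrencyConfig(qar_per_usd=config.qar_per_usd)
    paths = {
        "period_summaries": out / "period_summaries.csv",
        "cost_benefit": out / "cost_benefit.csv",
        "statistics": out / "statistics.csv",
        "sensitivity_draws": out / "sensitivity_draws.csv",
        "tornado": out / "tornado.csv",
        "report": out / "report.md",
    }
    report.write_period_summaries(summaries, paths["period_summaries"], cfg)
    report.write_cost_benefit(result, paths["cost_benefit"], cfg)
    stats_table.to_csv(paths["statistics"], index=False, lineterminator="\n")
    report.write_sensitivity(psa, paths["sensitivity_draws"], paths["tornado"])
    report.write_markdown_report(
        summaries, result, psa, stats_table, paths["report"], cfg
    )
    logger.info("wrote %d report files to %s", len(paths), out)
    return paths
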