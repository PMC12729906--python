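"""Cost-benefit aggregation of two program phases, with currency handling.

The comparison differences the two phases' ledgers category by category —
antimicrobial (DDD) cost, resource micro-costs, cost avoidance and
operational cost — under a fixed sign convention: **positive favors the
developed phase** (the preliminary phase spent more).  Per-patient figures
divide each phase's totals by that phase's own patient count *before*
differencing, so a phase with fewer patients is not penalized; the
per-patient net is the sum of per-patient category differences, never the
net total divided by a pooled n.

The decomposition identity ``net = saving + avoidance + operational`` is
asserted on construction.
"""

from __future__ import annotations

import math

from pydantic import BaseModel, ConfigDict, Field, model_validator

from .costing import PeriodSummary

__all__ = [
    "SIGN_CONVENTION",
    "CurrencyConfig",
    "CostBenefitResult",
    "per_patient",
    "compare_periods",
    "qar_to_usd",
    "usd_to_qar",
    "cpi_adjust",
    "percent_reduction",
    "round_half_away",
]

SIGN_CONVENTION = "positive favors developed period"

_DECOMPOSITION_TOL = 1e-6


class CurrencyConfig(BaseModel):
    """Exchange rate and consumer-price-index table.

    The default 3.64 riyal per US dollar is the riyal's long-standing peg.
    ``cpi_index`` maps calendar years to a health CPI level used to restate
    amounts at ``target_year`` prices.
    """

    model_config = ConfigDict(frozen=True)

    qar_per_usd: float = Field(default=3.64, gt=0)
    cpi_index: dict[int, float] = Field(default_factory=dict)
    target_year: int = 2023

    @model_validator(mode="after")
    def _positive_indices(self) -> "CurrencyConfig":
        for year, index in self.cpi_index.items():
            if index <= 0:
                raise ValueError(f"CPI index for {year} must be > 0")
        return self


class CostBenefitResult(BaseModel):
    """Differences between two phases, total and per patient.

    ``saving_resource`` may be negative (the developed phase can spend more
    on diagnostics in total yet less per patient).
    """

    model_config = ConfigDict(frozen=True)

    period_pre: str
    period_dev: str
    n_pre: int = Field(ge=1)
    n_dev: int = Field(ge=1)

    saving_ddd: float
    saving_resource: float
    saving_total: float
    avoidance: float
    operational_saving: float
    net_reduction: float

    saving_ddd_per_patient: float
    saving_resource_per_patient: float
    saving_total_per_patient: float
    avoidance_per_patient: float
    operational_saving_per_patient: float
    net_reduction_per_patient: float

    sign_convention: str = SIGN_CONVENTION

    @model_validator(mode="after")
    def _decomposition(self) -> "CostBenefitResult":
        if not math.isclose(
            self.saving_total,
            self.saving_ddd + self.saving_resource,
            abs_tol=_DECOMPOSITION_TOL,
        ):
            raise ValueError("saving_total must equal saving_ddd + saving_resource")
        if not math.isclose(
            self.net_reduction,
            self.saving_total + self.avoidance + self.operational_saving,
            abs_tol=_DECOMPOSITION_TOL,
        ):
            raise ValueError(
                "net_reduction must equal saving_total + avoidance + operational_saving"
            )
        return self


def per_patient(amount: float, n: int) -> float:
    """Divide a phase total by its patient count, at full precision."""
    if n < 1:
        raise ZeroDivisionError("per-patient value undefined for n < 1")
    return amount / n


def compare_periods(pre: PeriodSummary, dev: PeriodSummary) -> CostBenefitResult:
    """Difference two phase summaries into a cost-benefit result.

    Every field is ``preliminary - developed``, so positive values favor
    the developed phase.
    """
    if pre.period == dev.period:
        raise ValueError("the two summaries must carry distinct period labels")

    saving_ddd = pre.ledger.antimicrobial_ddd_cost - dev.ledger.antimicrobial_ddd_cost
    saving_resource = pre.ledger.resource_total - dev.ledger.resource_total
    saving_total = saving_ddd + saving_resource
    avoidance = pre.ledger.avoidance_total - dev.ledger.avoidance_total
    operational_saving = pre.ledger.operational - dev.ledger.operational
    net_reduction = saving_total + avoidance + operational_saving

    def pp(pre_amount: float, dev_amount: float) -> float:
        return per_patient(pre_amount, pre.n_patients) - per_patient(
            dev_amount, dev.n_patients
        )

    saving_ddd_pp = pp(pre.ledger.antimicrobial_ddd_cost, dev.ledger.antimicrobial_ddd_cost)
    saving_resource_pp = pp(pre.ledger.resource_total, dev.ledger.resource_total)
    avoidance_pp = pp(pre.ledger.avoidance_total, dev.ledger.avoidance_total)
    operational_pp = pp(pre.ledger.operational, dev.ledger.operational)

    return CostBenefitResult(
        period_pre=pre.period,
        period_dev=dev.period,
        n_pre=pre.n_patients,
        n_dev=dev.n_patients,
        saving_ddd=saving_ddd,
        saving_resource=saving_resource,
        saving_total=saving_total,
        avoidance=avoidance,
        operational_saving=operational_saving,
        net_reduction=net_reduction,
        saving_ddd_per_patient=saving_ddd_pp,
        saving_resource_per_patient=saving_resource_pp,
        saving_total_per_patient=saving_ddd_pp + saving_resource_pp,
        avoidance_per_patient=avoidance_pp,
        operational_saving_per_patient=operational_pp,
        net_reduction_per_patient=saving_ddd_pp
        + saving_resource_pp
        + avoidance_pp
        + operational_pp,
    )


def qar_to_usd(amount: float, cfg: CurrencyConfig | None = None) -> float:
    """Convert riyal to US dollars at the configured rate."""
    cfg = cfg or CurrencyConfig()
    return amount / cfg.qar_per_usd


def usd_to_qar(amount: float, cfg: CurrencyConfig | None = None) -> float:
    cfg = cfg or CurrencyConfig()
    return amount * cfg.qar_per_usd


def cpi_adjust(amount: float, source_year: int, cfg: CurrencyConfig) -> float:
    """Restate an amount at target-year price levels via the CPI table."""
    for year in (source_year, cfg.target_year):
        if year not in cfg.cpi_index:
            raise KeyError(f"CPI index has no entry for year {year}")
    return amount * cfg.cpi_index[cfg.target_year] / cfg.cpi_index[source_year]


def percent_reduction(before: float, after: float) -> float:
    """Percentage reduction from ``before`` to ``after`` (positive = lower)."""
    if before == 0:
        raise ZeroDivisionError("percent reduction undefined for a zero baseline")
    return 100.0 * (1.0 - after / before)


def round_half_away(value: float) -> int:
    """Round half away from zero, as whole-currency reports present figures."""
    return int(math.floor(abs(value) + 0.5)) * (1 if value >= 0 else -1)
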