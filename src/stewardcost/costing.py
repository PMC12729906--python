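"""Costing engine: DDD consumption, micro-costing, cost avoidance, operations.

Four cost categories are computed per episode and summed per program phase:

* **antimicrobial consumption** — grams administered converted to defined
  daily doses (DDDs) and priced per DDD (or, optionally, summed pharmacy
  acquisition costs);
* **resource micro-costing** — unit cost x observed frequency for cultures,
  laboratory tests, biopsies and early IV-to-oral switches;
* **cost avoidance** — the monetized value of adverse outcomes: bed-days of
  the initial stay, the fixed oral-vancomycin CDI recipe, readmission
  bed-days, and ADE-attributable extra stay (2 bed-days for an injectable
  agent, 1 for an oral one);
* **operational cost** — stewardship staffing time (data collection,
  rounds, committee meetings) valued at hourly rates and annualized.

All arithmetic runs at full floating precision; rounding to whole currency
units happens only in report writers.
"""

from __future__ import annotations

from typing import Iterable, Literal, Mapping

from pydantic import BaseModel, ConfigDict, Field, model_validator

from .records import (
    AntimicrobialCourse,
    DDDReference,
    PatientEpisode,
    Route,
    UnitCostTable,
)

__all__ = [
    "CDI_DOSES_PER_DAY",
    "CDI_TREATMENT_DAYS",
    "DEFAULT_ADE_EXTRA_DAYS",
    "ResourceCostBreakdown",
    "AvoidanceBreakdown",
    "CostLedger",
    "StaffingRole",
    "StaffingConfig",
    "PeriodSummary",
    "EmptyCohortError",
    "course_ddd",
    "episode_ddd",
    "period_consumption",
    "episode_resource_cost",
    "episode_avoidance_cost",
    "episode_ledger",
    "period_totals",
    "annual_operational_cost",
]

#: CDI treatment recipe: vancomycin 125 mg orally four times daily for ten
#: days, plus one diagnostic culture per case.
CDI_DOSES_PER_DAY = 4
CDI_TREATMENT_DAYS = 10

#: Extra bed-days attributed to an adverse drug event, by implicated route.
DEFAULT_ADE_EXTRA_DAYS: Mapping[Route, float] = {
    Route.injectable: 2.0,
    Route.oral: 1.0,
}

ConsumptionMode = Literal["price_per_ddd", "acquisition"]


class EmptyCohortError(ValueError):
    """Period totals are undefined on an empty cohort (per-patient division)."""


class ResourceCostBreakdown(BaseModel):
    """Micro-costing components in currency units; total is their sum."""

    model_config = ConfigDict(frozen=True)

    cultures_before: float = Field(ge=0, default=0.0)
    labs_before: float = Field(ge=0, default=0.0)
    biopsies_before: float = Field(ge=0, default=0.0)
    cultures_after: float = Field(ge=0, default=0.0)
    labs_after: float = Field(ge=0, default=0.0)
    biopsies_after: float = Field(ge=0, default=0.0)
    iv_to_oral: float = Field(ge=0, default=0.0)

    @property
    def total(self) -> float:
        return (
            self.cultures_before
            + self.labs_before
            + self.biopsies_before
            + self.cultures_after
            + self.labs_after
            + self.biopsies_after
            + self.iv_to_oral
        )

    def __add__(self, other: "ResourceCostBreakdown") -> "ResourceCostBreakdown":
        return ResourceCostBreakdown(
            **{k: getattr(self, k) + getattr(other, k) for k in type(self).model_fields}
        )


class AvoidanceBreakdown(BaseModel):
    """Cost-avoidance components in currency units; total is their sum."""

    model_config = ConfigDict(frozen=True)

    hospitalization: float = Field(ge=0, default=0.0)
    cdi: float = Field(ge=0, default=0.0)
    readmission: float = Field(ge=0, default=0.0)
    ade: float = Field(ge=0, default=0.0)

    @property
    def total(self) -> float:
        return self.hospitalization + self.cdi + self.readmission + self.ade

    def __add__(self, other: "AvoidanceBreakdown") -> "AvoidanceBreakdown":
        return AvoidanceBreakdown(
            **{k: getattr(self, k) + getattr(other, k) for k in type(self).model_fields}
        )


class CostLedger(BaseModel):
    """Itemized costs of one episode or one program phase.

    Category totals are derived properties, so the conservation identity
    (total = sum of components) holds by construction; ``check_conservation``
    re-asserts it explicitly for externally constructed ledgers.
    """

    model_config = ConfigDict(frozen=True)

    ddd_total: float = Field(ge=0, default=0.0)
    antimicrobial_ddd_cost: float = Field(ge=0, default=0.0)
    resource: ResourceCostBreakdown = Field(default_factory=ResourceCostBreakdown)
    avoidance: AvoidanceBreakdown = Field(default_factory=AvoidanceBreakdown)
    operational: float = Field(ge=0, default=0.0)

    @property
    def resource_total(self) -> float:
        return self.resource.total

    @property
    def avoidance_total(self) -> float:
        return self.avoidance.total

    def check_conservation(self, tol: float = 1e-6) -> None:
        """Assert each stored category total equals the sum of its components."""
        resource_parts = [getattr(self.resource, k) for k in ResourceCostBreakdown.model_fields]
        if abs(self.resource.total - sum(resource_parts)) > tol:
            raise AssertionError("resource total violates conservation")
        avoid_parts = [getattr(self.avoidance, k) for k in AvoidanceBreakdown.model_fields]
        if abs(self.avoidance.total - sum(avoid_parts)) > tol:
            raise AssertionError("avoidance total violates conservation")

    def __add__(self, other: "CostLedger") -> "CostLedger":
        return CostLedger(
            ddd_total=self.ddd_total + other.ddd_total,
            antimicrobial_ddd_cost=self.antimicrobial_ddd_cost
            + other.antimicrobial_ddd_cost,
            resource=self.resource + other.resource,
            avoidance=self.avoidance + other.avoidance,
            operational=self.operational + other.operational,
        )


class StaffingRole(BaseModel):
    """One stewardship role's time commitment and hourly rate."""

    model_config = ConfigDict(frozen=True)

    name: str
    headcount: int = Field(ge=0, default=1)
    hourly_rate: float = Field(ge=0)
    data_collection_hours_per_day: float = Field(ge=0, default=0.0)
    rounds_hours_per_day: float = Field(ge=0, default=0.0)
    meeting_hours_per_month: float = Field(ge=0, default=0.0)


class StaffingConfig(BaseModel):
    """A phase's staffing roster.

    ``working_days_per_year`` defaults to 365 because data collection and
    rounds are daily activities; weekday-only sites can lower it.
    """

    roles: list[StaffingRole] = Field(default_factory=list)
    working_days_per_year: int = Field(ge=0, default=365)
    months_per_year: Literal[12] = 12


class PeriodSummary(BaseModel):
    """A program phase: its label, patient count and cost ledger."""

    model_config = ConfigDict(frozen=True)

    period: str
    n_patients: int = Field(ge=1)
    ledger: CostLedger


def course_ddd(course: AntimicrobialCourse, ref: DDDReference) -> float:
    """DDDs consumed by one course: grams administered / grams per DDD."""
    if course.duration_days == 0:
        return 0.0
    grams = course.daily_dose_grams * course.duration_days
    return grams / ref.ddd_grams(course.drug_name, course.route)


def episode_ddd(episode: PatientEpisode, ref: DDDReference) -> float:
    """Total DDDs over an episode's courses."""
    return sum(course_ddd(c, ref) for c in episode.courses)


def period_consumption(
    cohort: Iterable[PatientEpisode],
    ref: DDDReference,
    costs: UnitCostTable,
    mode: ConsumptionMode = "price_per_ddd",
) -> tuple[float, float]:
    """Antimicrobial consumption (DDDs) and its cost over a cohort.

    In ``price_per_ddd`` mode (default) the cost of each course is its DDD
    count times the drug's per-DDD price; in ``acquisition`` mode the
    course's recorded pharmacy acquisition cost is summed instead.
    """
    ddd_total = 0.0
    cost_total = 0.0
    for episode in cohort:
        for course in episode.courses:
            ddd = course_ddd(course, ref)
            ddd_total += ddd
            if mode == "price_per_ddd":
                cost_total += ddd * costs.price_per_ddd(course.drug_name)
            else:
                if course.acquisition_cost is None:
                    raise ValueError(
                        f"course of {course.drug_name!r} has no acquisition_cost"
                    )
                cost_total += course.acquisition_cost
    return ddd_total, cost_total


def episode_resource_cost(
    episode: PatientEpisode, costs: UnitCostTable
) -> ResourceCostBreakdown:
    """Micro-costing: each resource count times its unit cost."""
    r = episode.resources
    return ResourceCostBreakdown(
        cultures_before=r.cultures_before * costs.culture_test,
        labs_before=r.labs_before * costs.lab_test,
        biopsies_before=r.biopsies_before * costs.biopsy,
        cultures_after=r.cultures_after * costs.culture_test,
        labs_after=r.labs_after * costs.lab_test,
        biopsies_after=r.biopsies_after * costs.biopsy,
        iv_to_oral=r.iv_to_oral_switches * costs.iv_to_oral_switch_event,
    )


def episode_avoidance_cost(
    episode: PatientEpisode,
    costs: UnitCostTable,
    ade_extra_days: Mapping[Route, float] = DEFAULT_ADE_EXTRA_DAYS,
    bed_day: float | None = None,
) -> AvoidanceBreakdown:
    """Monetized adverse outcomes of one episode.

    ``bed_day`` overrides the table's bed-day rate, for sites whose ADE
    extra-stay is valued at the episode's own ward rate.
    """
    rate = costs.bed_day if bed_day is None else bed_day
    hospitalization = episode.los_initial_days * rate
    readmission = (
        episode.los_readmission_days * rate if episode.readmitted_30d else 0.0
    )
    cdi = (
        CDI_DOSES_PER_DAY * CDI_TREATMENT_DAYS * costs.vancomycin_125mg_dose
        + costs.cdi_diagnostic_culture
        if episode.cdi
        else 0.0
    )
    ade = sum(
        ade_extra_days[event.implicated_route] * rate for event in episode.ade_events
    )
    return AvoidanceBreakdown(
        hospitalization=hospitalization,
        cdi=cdi,
        readmission=readmission,
        ade=ade,
    )


def episode_ledger(
    episode: PatientEpisode,
    ref: DDDReference,
    costs: UnitCostTable,
    mode: ConsumptionMode = "price_per_ddd",
    ade_extra_days: Mapping[Route, float] = DEFAULT_ADE_EXTRA_DAYS,
) -> CostLedger:
    """All cost components of a single episode (operational excluded)."""
    ddd, am_cost = period_consumption([episode], ref, costs, mode=mode)
    return CostLedger(
        ddd_total=ddd,
        antimicrobial_ddd_cost=am_cost,
        resource=episode_resource_cost(episode, costs),
        avoidance=episode_avoidance_cost(episode, costs, ade_extra_days),
    )


def period_totals(
    cohort: list[PatientEpisode],
    ref: DDDReference,
    costs: UnitCostTable,
    label: str,
    operational: float = 0.0,
    mode: ConsumptionMode = "price_per_ddd",
    ade_extra_days: Mapping[Route, float] = DEFAULT_ADE_EXTRA_DAYS,
) -> PeriodSummary:
    """Component-wise sum of episode ledgers for one program phase.

    Raises :class:`EmptyCohortError` on an empty cohort, where the
    per-patient quantities used downstream are undefined.
    """
    if not cohort:
        raise EmptyCohortError(f"period {label!r} has no eligible episodes")
    total = CostLedger(operational=operational)
    for episode in cohort:
        total = total + episode_ledger(
            episode, ref, costs, mode=mode, ade_extra_days=ade_extra_days
        )
    return PeriodSummary(period=label, n_patients=len(cohort), ledger=total)


def annual_operational_cost(staffing: StaffingConfig) -> float:
    """Annual staffing cost of running the program.

    Per role: headcount x hourly rate x [(daily data-collection + rounds
    hours) x working days + monthly meeting hours x 12].
    """
    total = 0.0
    for role in staffing.roles:
        daily_hours = (
            role.data_collection_hours_per_day + role.rounds_hours_per_day
        ) * staffing.working_days_per_year
        meeting_hours = role.meeting_hours_per_month * staffing.months_per_year
        total += role.headcount * role.hourly_rate * (daily_hours + meeting_hours)
    return total
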