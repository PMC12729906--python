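"""Domain records for stewardship cost analysis.

The atomic unit of analysis is the :class:`PatientEpisode` — a single
admission with its antimicrobial courses, clinical outcome flags and
countable resource events.  Episodes belong to one of two program phases
("preliminary" vs "developed" stewardship), and enter the costing pipeline
only after passing the eligibility filter implemented here: treatment with
a targeted agent, started early in the admission, sustained for a minimum
continuous duration, outside intensive care.

All monetary denominators (unit costs, price per defined daily dose) live
in :class:`UnitCostTable` and :class:`DDDReference`; costing code reads
them from these tables, never from literals.
"""

from __future__ import annotations

import enum
from typing import Optional

from pydantic import BaseModel, ConfigDict, Field, model_validator

__all__ = [
    "Route",
    "Period",
    "Sex",
    "TARGETED_DRUGS",
    "AntimicrobialCourse",
    "AdeEvent",
    "ResourceEvents",
    "PatientEpisode",
    "DDDReference",
    "UnitCostTable",
    "EligibilityPolicy",
    "EligibilityDecision",
    "DrugLookupError",
    "PricingError",
    "is_eligible",
    "filter_eligible",
]


class Route(str, enum.Enum):
    """Administration route of a course; drives the ADE extra-stay rule."""

    injectable = "injectable"
    oral = "oral"


class Period(str, enum.Enum):
    """Program phase an episode belongs to."""

    preliminary = "preliminary"
    developed = "developed"


class Sex(str, enum.Enum):
    male = "male"
    female = "female"


#: The 18 agents targeted by the stewardship program.
TARGETED_DRUGS: frozenset[str] = frozenset(
    {
        "cefepime",
        "linezolid",
        "teicoplanin",
        "tigecycline",
        "ertapenem",
        "amikacin",
        "colistin",
        "ciprofloxacin",
        "moxifloxacin",
        "aztreonam",
        "ceftazidime",
        "daptomycin",
        "anidulafungin",
        "fluconazole",
        "amphotericin",
        "caspofungin",
        "posaconazole",
        "voriconazole",
    }
)


class DrugLookupError(KeyError):
    """A drug is absent from the defined-daily-dose reference."""


class PricingError(KeyError):
    """A drug has no price in the unit-cost table."""


class AntimicrobialCourse(BaseModel):
    """One drug course within an admission.

    ``start_day`` counts days since admission with admission itself as
    day 0.  ``acquisition_cost`` is the total pharmacy cost of the course
    and is optional when costing goes through a per-DDD price instead.
    """

    model_config = ConfigDict(frozen=True)

    drug_name: str = Field(min_length=1)
    route: Route
    daily_dose_grams: float = Field(ge=0)
    duration_days: float = Field(ge=0)
    start_day: int = Field(ge=0, default=0)
    acquisition_cost: Optional[float] = Field(default=None, ge=0)


class AdeEvent(BaseModel):
    """An adverse drug event, attributed to an injectable or oral agent."""

    model_config = ConfigDict(frozen=True)

    implicated_route: Route


class ResourceEvents(BaseModel):
    """Countable resource use around therapy, for micro-costing.

    ``iv_to_oral_switches`` counts switches from intravenous to oral
    medication within the first three days of antibiotic therapy.
    """

    model_config = ConfigDict(frozen=True)

    cultures_before: int = Field(ge=0, default=0)
    labs_before: int = Field(ge=0, default=0)
    biopsies_before: int = Field(ge=0, default=0)
    cultures_after: int = Field(ge=0, default=0)
    labs_after: int = Field(ge=0, default=0)
    biopsies_after: int = Field(ge=0, default=0)
    iv_to_oral_switches: int = Field(ge=0, default=0)


class PatientEpisode(BaseModel):
    """A single admission: demographics, courses, outcomes, resource events."""

    id: str = Field(min_length=1)
    period: Period
    age_years: float = Field(ge=0)
    sex: Sex
    icu_flag: bool = False
    los_initial_days: float = Field(ge=0)
    readmitted_30d: bool = False
    los_readmission_days: float = Field(ge=0, default=0.0)
    cdi: bool = False
    ade_events: list[AdeEvent] = Field(default_factory=list)
    courses: list[AntimicrobialCourse] = Field(default_factory=list)
    resources: ResourceEvents = Field(default_factory=ResourceEvents)
    death_30d: bool = False
    infection_related_death: bool = False
    resistance_developed: bool = False

    @model_validator(mode="after")
    def _readmission_consistency(self) -> "PatientEpisode":
        if not self.readmitted_30d and self.los_readmission_days != 0:
            raise ValueError(
                "los_readmission_days must be 0 when readmitted_30d is False"
            )
        return self


class DDDReference(BaseModel):
    """Grams per defined daily dose (DDD), the WHO-style consumption unit.

    The DDD is the assumed average maintenance dose per day for a drug's
    main adult indication.  Optional per-route overrides cover agents whose
    oral and parenteral DDDs differ (e.g. ciprofloxacin).
    """

    values: dict[str, float]
    route_overrides: dict[str, dict[Route, float]] = Field(default_factory=dict)

    @model_validator(mode="after")
    def _positive(self) -> "DDDReference":
        for drug, g in self.values.items():
            if g <= 0:
                raise ValueError(f"ddd_grams for {drug!r} must be > 0")
        for drug, per_route in self.route_overrides.items():
            for g in per_route.values():
                if g <= 0:
                    raise ValueError(f"route override for {drug!r} must be > 0")
        return self

    def ddd_grams(self, drug: str, route: Route | None = None) -> float:
        if route is not None and drug in self.route_overrides:
            override = self.route_overrides[drug]
            if route in override:
                return override[route]
        try:
            return self.values[drug]
        except KeyError:
            raise DrugLookupError(drug) from None


class UnitCostTable(BaseModel):
    """Unit costs of resources and drugs; every monetary output reads from here.

    Amounts are in ``currency_code`` (Qatari Riyal by default) at
    ``price_year`` price levels.
    """

    bed_day: float = Field(ge=0)
    culture_test: float = Field(ge=0)
    lab_test: float = Field(ge=0)
    biopsy: float = Field(ge=0)
    iv_to_oral_switch_event: float = Field(ge=0)
    cdi_diagnostic_culture: float = Field(ge=0)
    vancomycin_125mg_dose: float = Field(ge=0)
    cost_per_ddd: dict[str, float] = Field(default_factory=dict)
    currency_code: str = "QAR"
    price_year: int = 2023

    @model_validator(mode="after")
    def _nonnegative_prices(self) -> "UnitCostTable":
        for drug, price in self.cost_per_ddd.items():
            if price < 0:
                raise ValueError(f"cost_per_ddd for {drug!r} must be >= 0")
        return self

    def price_per_ddd(self, drug: str) -> float:
        try:
            return self.cost_per_ddd[drug]
        except KeyError:
            raise PricingError(drug) from None


class EligibilityPolicy(BaseModel):
    """Inclusion rules for the costed population.

    Defaults encode the study design: a targeted agent started within
    3 days of admission (admission = day 0, so start days 0–3 qualify),
    given for at least 48 consecutive hours, with intensive-care
    admissions excluded.
    """

    model_config = ConfigDict(frozen=True)

    targeted_drugs: frozenset[str] = TARGETED_DRUGS
    max_start_day: int = Field(default=3, ge=0)
    min_continuous_hours: float = Field(default=48.0, gt=0)
    exclude_icu: bool = True


class EligibilityDecision(BaseModel):
    """Outcome of the eligibility filter; ``reason`` names the first failed rule."""

    model_config = ConfigDict(frozen=True)

    eligible: bool
    reason: Optional[str] = None

    def __bool__(self) -> bool:  # allows `if is_eligible(ep):`
        return self.eligible


def is_eligible(
    episode: PatientEpisode, policy: EligibilityPolicy | None = None
) -> EligibilityDecision:
    """Decide whether an admission enters the costed cohort.

    Rules are applied in a fixed order and the first failure is reported:
    ICU exclusion, presence of a targeted course, treatment start within
    ``max_start_day`` of admission, and a continuous duration of at least
    ``min_continuous_hours`` (a single course record of >= 2 days under the
    defaults; split administrations are not merged).
    """
    policy = policy or EligibilityPolicy()

    if policy.exclude_icu and episode.icu_flag:
        return EligibilityDecision(eligible=False, reason="icu_excluded")

    targeted = [c for c in episode.courses if c.drug_name in policy.targeted_drugs]
    if not targeted:
        return EligibilityDecision(eligible=False, reason="no_targeted_course")

    timely = [c for c in targeted if c.start_day <= policy.max_start_day]
    if not timely:
        return EligibilityDecision(eligible=False, reason="max_start_day")

    if any(c.duration_days * 24.0 >= policy.min_continuous_hours for c in timely):
        return EligibilityDecision(eligible=True)
    return EligibilityDecision(eligible=False, reason="min_continuous_hours")


def filter_eligible(
    episodes: list[PatientEpisode], policy: EligibilityPolicy | None = None
) -> list[PatientEpisode]:
    """Return the episodes passing :func:`is_eligible`, preserving order."""
    policy = policy or EligibilityPolicy()
    return [ep for ep in episodes if is_eligible(ep, policy).eligible]
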