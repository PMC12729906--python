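"""Seeded synthetic two-phase cohorts with the published summary structure.

The real cohorts are site-internal hospital records, so testing the
pipeline requires a generator that emulates their published statistical
shape: a small antifungal-heavy preliminary phase (n = 81, long skewed
stays, high CDI incidence) against a larger antibacterial-heavy developed
phase (n = 105, short stays, lower CDI incidence), with zero readmissions
in both.

Length of stay is lognormal.  Because published stays have standard
deviations larger than their means, the family must be right-skewed, and a
hard floor of 2 days keeps every generated episode eligible (a course must
run 48 h).  Naive truncation of a moment-matched lognormal would inflate
the short-stay arm's mean by about two days, so the generator instead
solves for the lognormal parameters whose *floored* (resampled-below-2)
distribution reproduces the target mean and SD exactly.

Default unit costs are synthetic but internally consistent with the scale
of the published aggregates (e.g. a bed-day near QAR 6,107); see
``docs/methods.md``.  Adverse-drug-event probabilities default to zero, as
reported, but are adjustable so the ADE costing path stays testable.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path
from typing import Literal

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, model_validator
from scipy import optimize
from scipy.stats import norm

from .costing import StaffingConfig, StaffingRole
from .io import (
    write_cohort,
    write_ddd_reference,
    write_staffing,
    write_unit_costs,
)
from .records import (
    AdeEvent,
    AntimicrobialCourse,
    DDDReference,
    PatientEpisode,
    Period,
    ResourceEvents,
    Route,
    Sex,
    UnitCostTable,
)

__all__ = [
    "DrugProfile",
    "ResourceRates",
    "CohortProfile",
    "default_profiles",
    "generate_cohort",
    "default_unit_costs",
    "make_fixture_workspace",
]

#: Minimum generated stay, matching the 48-hour eligibility floor.
LOS_FLOOR_DAYS = 2.0


class DrugProfile(BaseModel):
    """One row of a phase's drug frequency table."""

    model_config = ConfigDict(frozen=True)

    drug: str
    route: Route
    drug_class: Literal["antibacterial", "antifungal"]
    daily_dose_grams: float = Field(gt=0)
    duration_mean_days: float = Field(gt=0)
    weight: float = Field(gt=0)


class ResourceRates(BaseModel):
    """Mean resource-event counts per episode (Poisson rates)."""

    model_config = ConfigDict(frozen=True)

    cultures_before: float = Field(ge=0, default=0.0)
    labs_before: float = Field(ge=0, default=0.0)
    biopsies_before: float = Field(ge=0, default=0.0)
    cultures_after: float = Field(ge=0, default=0.0)
    labs_after: float = Field(ge=0, default=0.0)
    biopsies_after: float = Field(ge=0, default=0.0)
    iv_to_oral_switches: float = Field(ge=0, default=0.0)


class CohortProfile(BaseModel):
    """Distributional description of one program phase's cohort."""

    model_config = ConfigDict(frozen=True)

    period: Period
    n: int = Field(ge=1)
    antibacterial_fraction: float = Field(ge=0, le=1)
    drugs: list[DrugProfile]
    los_mean: float = Field(gt=0)
    los_sd: float = Field(ge=0)
    cdi_prob: float = Field(ge=0, le=1)
    ade_prob_injectable: float = Field(ge=0, le=1, default=0.0)
    ade_prob_oral: float = Field(ge=0, le=1, default=0.0)
    readmission_prob: float = Field(ge=0, le=1, default=0.0)
    readmission_los_mean: float = Field(gt=0, default=5.0)
    death_prob: float = Field(ge=0, le=1, default=0.0)
    age_mean: float = Field(gt=0)
    age_sd: float = Field(ge=0)
    male_fraction: float = Field(ge=0, le=1)
    n_courses_probs: tuple[float, float, float] = (1.0, 0.0, 0.0)
    resource_rates: ResourceRates = Field(default_factory=ResourceRates)

    @model_validator(mode="after")
    def _consistent(self) -> "CohortProfile":
        if not self.drugs:
            raise ValueError("profile needs at least one drug")
        if abs(sum(self.n_courses_probs) - 1.0) > 1e-9:
            raise ValueError("n_courses_probs must sum to 1")
        return self


def default_profiles() -> tuple[CohortProfile, CohortProfile]:
    """The two published phases as generator profiles.

    Preliminary: n = 81, 8.6% antibacterial, stay 34.02 +/- 51.21 days,
    30.9% CDI.  Developed: n = 105, 94.3% antibacterial, stay
    7.12 +/- 10.47 days, 15.2% CDI.  Neither phase recorded readmissions.
    Drug mixes weight the reported leading agents (fluconazole/caspofungin
    vs ertapenem/ciprofloxacin).
    """
    preliminary = CohortProfile(
        period=Period.preliminary,
        n=81,
        antibacterial_fraction=0.086,
        drugs=[
            DrugProfile(drug="fluconazole", route=Route.oral, drug_class="antifungal",
                        daily_dose_grams=0.4, duration_mean_days=12, weight=0.573),
            DrugProfile(drug="caspofungin", route=Route.injectable, drug_class="antifungal",
                        daily_dose_grams=0.05, duration_mean_days=14, weight=0.146),
            DrugProfile(drug="voriconazole", route=Route.oral, drug_class="antifungal",
                        daily_dose_grams=0.4, duration_mean_days=14, weight=0.090),
            DrugProfile(drug="posaconazole", route=Route.oral, drug_class="antifungal",
                        daily_dose_grams=0.3, duration_mean_days=14, weight=0.060),
            DrugProfile(drug="amphotericin", route=Route.injectable, drug_class="antifungal",
                        daily_dose_grams=0.05, duration_mean_days=12, weight=0.045),
            DrugProfile(drug="cefepime", route=Route.injectable, drug_class="antibacterial",
                        daily_dose_grams=6.0, duration_mean_days=7, weight=0.040),
            DrugProfile(drug="ciprofloxacin", route=Route.oral, drug_class="antibacterial",
                        daily_dose_grams=1.0, duration_mean_days=7, weight=0.046),
        ],
        los_mean=34.02,
        los_sd=51.21,
        cdi_prob=0.309,
        readmission_prob=0.0,
        death_prob=0.012,
        age_mean=47.8,
        age_sd=17.62,
        male_fraction=0.667,
        n_courses_probs=(0.691, 0.247, 0.062),
        resource_rates=ResourceRates(
            cultures_before=0.05, labs_before=3.05, cultures_after=0.22,
            labs_after=3.6, iv_to_oral_switches=1.2,
        ),
    )
    developed = CohortProfile(
        period=Period.developed,
        n=105,
        antibacterial_fraction=0.943,
        drugs=[
            DrugProfile(drug="ertapenem", route=Route.injectable, drug_class="antibacterial",
                        daily_dose_grams=1.0, duration_mean_days=7, weight=0.324),
            DrugProfile(drug="ciprofloxacin", route=Route.oral, drug_class="antibacterial",
                        daily_dose_grams=1.0, duration_mean_days=7, weight=0.295),
            DrugProfile(drug="cefepime", route=Route.injectable, drug_class="antibacterial",
                        daily_dose_grams=6.0, duration_mean_days=6, weight=0.120),
            DrugProfile(drug="linezolid", route=Route.oral, drug_class="antibacterial",
                        daily_dose_grams=1.2, duration_mean_days=10, weight=0.080),
            DrugProfile(drug="amikacin", route=Route.injectable, drug_class="antibacterial",
                        daily_dose_grams=1.0, duration_mean_days=5, weight=0.064),
            DrugProfile(drug="moxifloxacin", route=Route.oral, drug_class="antibacterial",
                        daily_dose_grams=0.4, duration_mean_days=7, weight=0.060),
            DrugProfile(drug="fluconazole", route=Route.oral, drug_class="antifungal",
                        daily_dose_grams=0.4, duration_mean_days=10, weight=0.040),
            DrugProfile(drug="caspofungin", route=Route.injectable, drug_class="antifungal",
                        daily_dose_grams=0.05, duration_mean_days=12, weight=0.017),
        ],
        los_mean=7.12,
        los_sd=10.47,
        cdi_prob=0.152,
        readmission_prob=0.0,
        death_prob=0.027,
        age_mean=54.7,
        age_sd=19.89,
        male_fraction=0.467,
        n_courses_probs=(0.962, 0.019, 0.019),
        resource_rates=ResourceRates(
            cultures_before=0.045, labs_before=2.75, cultures_after=0.175,
            labs_after=3.6, iv_to_oral_switches=1.03,
        ),
    )
    return preliminary, developed


def _floored_lognormal_params(
    mean: float, sd: float, floor: float = LOS_FLOOR_DAYS
) -> tuple[float, float]:
    """Lognormal (mu, sigma) whose >= floor conditional matches (mean, sd).

    Solves the two truncated-moment equations so that resampling draws
    below ``floor`` leaves the target moments intact.
    """
    if sd == 0:
        if mean < floor:
            raise ValueError(f"constant stay {mean} below the {floor}-day floor")
        return np.log(mean), 0.0

    log_floor = np.log(floor)

    def conditional_moments(mu: float, sigma: float) -> tuple[float, float]:
        p = norm.sf((log_floor - mu) / sigma)
        m1 = np.exp(mu + sigma**2 / 2) * norm.sf((log_floor - mu - sigma**2) / sigma) / p
        m2 = (
            np.exp(2 * mu + 2 * sigma**2)
            * norm.sf((log_floor - mu - 2 * sigma**2) / sigma)
            / p
        )
        return m1, np.sqrt(max(m2 - m1**2, 0.0))

    s2 = np.log(1 + (sd / mean) ** 2)
    x0 = np.array([np.log(mean) - s2 / 2, np.sqrt(s2)])

    def equations(x: np.ndarray) -> list[float]:
        m, s = conditional_moments(x[0], abs(x[1]))
        return [m - mean, s - sd]

    solution, _, ier, msg = optimize.fsolve(equations, x0, full_output=True)
    if ier != 1:
        raise RuntimeError(f"stay-distribution moment matching failed: {msg}")
    return float(solution[0]), float(abs(solution[1]))


def _draw_floored_lognormal(
    rng: np.random.Generator, mu: float, sigma: float, floor: float = LOS_FLOOR_DAYS
) -> float:
    if sigma == 0:
        return float(np.exp(mu))
    value = rng.lognormal(mu, sigma)
    while value < floor:
        value = rng.lognormal(mu, sigma)
    return float(value)


_START_DAYS = np.array([0, 1, 2, 3])
_START_DAY_WEIGHTS = np.array([0.55, 0.25, 0.12, 0.08])


def generate_cohort(profile: CohortProfile, seed: int) -> list[PatientEpisode]:
    """Draw exactly ``profile.n`` episodes, reproducibly for a given seed.

    Every episode passes the default eligibility policy: the first course
    is a targeted agent, starts on day 0-3 and runs at least 2 days.
    """
    rng = np.random.default_rng(seed)
    mu, sigma = _floored_lognormal_params(profile.los_mean, profile.los_sd)

    weights = np.array([d.weight for d in profile.drugs], dtype=float)
    weights = weights / weights.sum()

    episodes: list[PatientEpisode] = []
    for i in range(profile.n):
        los = _draw_floored_lognormal(rng, mu, sigma)
        n_courses = 1 + rng.choice(3, p=np.asarray(profile.n_courses_probs))

        courses = []
        for k in range(n_courses):
            drug = profile.drugs[rng.choice(len(profile.drugs), p=weights)]
            if k == 0:
                start = int(rng.choice(_START_DAYS, p=_START_DAY_WEIGHTS))
                duration = max(2.0, rng.gamma(4.0, drug.duration_mean_days / 4.0))
            else:
                start = int(rng.integers(1, 8))
                duration = max(1.0, rng.gamma(4.0, drug.duration_mean_days / 4.0))
            courses.append(
                AntimicrobialCourse(
                    drug_name=drug.drug,
                    route=drug.route,
                    daily_dose_grams=drug.daily_dose_grams,
                    duration_days=round(float(duration), 2),
                    start_day=start,
                )
            )

        ade_events = []
        if rng.random() < profile.ade_prob_injectable:
            ade_events.append(AdeEvent(implicated_route=Route.injectable))
        if rng.random() < profile.ade_prob_oral:
            ade_events.append(AdeEvent(implicated_route=Route.oral))

        readmitted = rng.random() < profile.readmission_prob
        r = profile.resource_rates
        episodes.append(
            PatientEpisode(
                id=f"{profile.period.value[:3]}-{i + 1:05d}",
                period=profile.period,
                age_years=round(float(np.clip(rng.normal(profile.age_mean, profile.age_sd), 18.0, 100.0)), 1),
                sex=Sex.male if rng.random() < profile.male_fraction else Sex.female,
                icu_flag=False,
                los_initial_days=round(los, 2),
                readmitted_30d=readmitted,
                los_readmission_days=(
                    round(float(max(1.0, rng.exponential(profile.readmission_los_mean))), 2)
                    if readmitted
                    else 0.0
                ),
                cdi=bool(rng.random() < profile.cdi_prob),
                ade_events=ade_events,
                courses=courses,
                resources=ResourceEvents(
                    cultures_before=int(rng.poisson(r.cultures_before)),
                    labs_before=int(rng.poisson(r.labs_before)),
                    biopsies_before=int(rng.poisson(r.biopsies_before)),
                    cultures_after=int(rng.poisson(r.cultures_after)),
                    labs_after=int(rng.poisson(r.labs_after)),
                    biopsies_after=int(rng.poisson(r.biopsies_after)),
                    iv_to_oral_switches=int(rng.poisson(r.iv_to_oral_switches)),
                ),
                death_30d=bool(rng.random() < profile.death_prob),
            )
        )
    return episodes


def _bundled_ddd_reference() -> DDDReference:
    from .io import read_ddd_reference

    with resources.as_file(
        resources.files("stewardcost.data") / "ddd_reference.csv"
    ) as path:
        return read_ddd_reference(path)


def default_unit_costs() -> tuple[UnitCostTable, DDDReference, dict[str, StaffingConfig]]:
    """Internally consistent synthetic prices, DDD reference and rosters.

    Prices are fixed (no randomness): a QAR 6,107 bed-day and a QAR 202
    CDI recipe sit at the scale implied by the published aggregates; the
    remaining unit costs and hourly rates are realistic synthetic choices.
    Staffing hours follow the two published rosters; rates are synthetic.
    """
    costs = UnitCostTable(
        bed_day=6107.0,
        culture_test=160.0,
        lab_test=100.0,
        biopsy=450.0,
        iv_to_oral_switch_event=700.0,
        cdi_diagnostic_culture=30.0,
        vancomycin_125mg_dose=4.3,
        cost_per_ddd={
            "amikacin": 18.0,
            "amphotericin": 850.0,
            "anidulafungin": 1200.0,
            "aztreonam": 130.0,
            "caspofungin": 1450.0,
            "cefepime": 45.0,
            "ceftazidime": 30.0,
            "ciprofloxacin": 12.0,
            "colistin": 260.0,
            "daptomycin": 560.0,
            "ertapenem": 210.0,
            "fluconazole": 25.0,
            "linezolid": 320.0,
            "moxifloxacin": 40.0,
            "posaconazole": 700.0,
            "teicoplanin": 95.0,
            "tigecycline": 480.0,
            "voriconazole": 420.0,
        },
        currency_code="QAR",
        price_year=2023,
    )
    reference = _bundled_ddd_reference()
    rosters = {
        "preliminary": StaffingConfig(
            working_days_per_year=365,
            roles=[
                StaffingRole(name="physician", hourly_rate=45.0,
                             data_collection_hours_per_day=3.0,
                             rounds_hours_per_day=1.0,
                             meeting_hours_per_month=5.0),
                StaffingRole(name="clinical_pharmacist", hourly_rate=20.0,
                             data_collection_hours_per_day=3.0,
                             meeting_hours_per_month=5.0),
            ],
        ),
        "developed": StaffingConfig(
            working_days_per_year=365,
            roles=[
                StaffingRole(name="id_consultant", hourly_rate=45.0,
                             meeting_hours_per_month=10.0),
                StaffingRole(name="clinical_pharmacist", hourly_rate=20.0,
                             data_collection_hours_per_day=3.0,
                             rounds_hours_per_day=1.0,
                             meeting_hours_per_month=10.0),
                StaffingRole(name="clinical_microbiologist", hourly_rate=30.0,
                             meeting_hours_per_month=10.0),
                StaffingRole(name="infection_control_practitioner", hourly_rate=18.0,
                             meeting_hours_per_month=10.0),
                StaffingRole(name="stewardship_nurse", hourly_rate=14.0,
                             meeting_hours_per_month=10.0),
                StaffingRole(name="physician_fellow", hourly_rate=22.0,
                             data_collection_hours_per_day=3.0,
                             rounds_hours_per_day=1.0),
            ],
        ),
    }
    return costs, reference, rosters


def make_fixture_workspace(directory: str | Path, seed: int = 0) -> dict[str, Path]:
    """Materialize a complete demo workspace of delimited-text inputs.

    Writes both phase cohorts (each as episodes/courses/ade_events CSVs),
    ``unit_costs.csv``, ``ddd_reference.csv`` and ``staffing.yaml``; every
    file re-reads into value-identical objects.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    preliminary, developed = default_profiles()
    costs, reference, rosters = default_unit_costs()

    paths: dict[str, Path] = {}
    for profile, offset in [(preliminary, 0), (developed, 1)]:
        cohort_dir = directory / profile.period.value
        write_cohort(generate_cohort(profile, seed + offset), cohort_dir)
        paths[profile.period.value] = cohort_dir
    paths["unit_costs"] = directory / "unit_costs.csv"
    write_unit_costs(costs, paths["unit_costs"])
    paths["ddd_reference"] = directory / "ddd_reference.csv"
    write_ddd_reference(reference, paths["ddd_reference"])
    paths["staffing"] = directory / "staffing.yaml"
    write_staffing(rosters, paths["staffing"])
    return paths
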