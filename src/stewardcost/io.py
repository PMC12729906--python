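"""Delimited-text persistence for cohorts, cost tables and staffing rosters.

A cohort on disk is three UTF-8 comma-delimited files in one directory:
``episodes.csv`` (one row per admission, resource counts inlined),
``courses.csv`` and ``ade_events.csv`` (child rows keyed by ``episode_id``).
Column dictionaries are documented in ``docs/file_formats.md``.  Writing is
deterministic — fixed column order, ``\\n`` line endings, lowercase
booleans — so two writes of the same cohort are byte-identical.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Any

import pandas as pd
import yaml
from pydantic import ValidationError

from .costing import StaffingConfig
from .records import (
    AdeEvent,
    AntimicrobialCourse,
    DDDReference,
    PatientEpisode,
    ResourceEvents,
    Route,
    UnitCostTable,
)

__all__ = [
    "SchemaError",
    "CohortValidationError",
    "read_cohort",
    "write_cohort",
    "read_unit_costs",
    "write_unit_costs",
    "read_ddd_reference",
    "write_ddd_reference",
    "read_staffing",
    "write_staffing",
]

EPISODE_COLUMNS = [
    "id",
    "period",
    "age_years",
    "sex",
    "icu_flag",
    "los_initial_days",
    "readmitted_30d",
    "los_readmission_days",
    "cdi",
    "death_30d",
    "infection_related_death",
    "resistance_developed",
    "cultures_before",
    "labs_before",
    "biopsies_before",
    "cultures_after",
    "labs_after",
    "biopsies_after",
    "iv_to_oral_switches",
]
COURSE_COLUMNS = [
    "episode_id",
    "drug_name",
    "route",
    "daily_dose_grams",
    "duration_days",
    "start_day",
    "acquisition_cost",
]
ADE_COLUMNS = ["episode_id", "implicated_route"]

_RESOURCE_FIELDS = list(ResourceEvents.model_fields)
_BOOL_FIELDS = [
    "icu_flag",
    "readmitted_30d",
    "cdi",
    "death_30d",
    "infection_related_death",
    "resistance_developed",
]


class SchemaError(ValueError):
    """A cohort file is missing a mandatory column."""


class CohortValidationError(ValueError):
    """One or more rows violate a record invariant; lines are reported."""

    def __init__(self, errors: list[str]):
        self.errors = errors
        super().__init__("; ".join(errors))


def _check_columns(df: pd.DataFrame, required: list[str], filename: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{filename}: missing column(s) {', '.join(missing)}")


def _fmt(value: Any) -> str:
    if isinstance(value, bool):
        return "true" if value else "false"
    if value is None:
        return ""
    if isinstance(value, float):
        if math.isnan(value):
            return ""
        return repr(value)
    return str(value)


def _parse_bool(raw: Any, field: str, line: int) -> bool:
    text = str(raw).strip().lower()
    if text in {"true", "1"}:
        return True
    if text in {"false", "0"}:
        return False
    raise ValueError(f"line {line}: {field}: cannot parse boolean from {raw!r}")


def write_cohort(episodes: list[PatientEpisode], directory: str | Path) -> None:
    """Write a cohort to ``episodes.csv``/``courses.csv``/``ade_events.csv``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)

    ep_rows, course_rows, ade_rows = [], [], []
    for ep in episodes:
        row = {c: getattr(ep, c) for c in EPISODE_COLUMNS if c not in _RESOURCE_FIELDS}
        row["period"] = ep.period.value
        row["sex"] = ep.sex.value
        for field in _RESOURCE_FIELDS:
            row[field] = getattr(ep.resources, field)
        ep_rows.append(row)
        for course in ep.courses:
            course_rows.append(
                {
                    "episode_id": ep.id,
                    "drug_name": course.drug_name,
                    "route": course.route.value,
                    "daily_dose_grams": course.daily_dose_grams,
                    "duration_days": course.duration_days,
                    "start_day": course.start_day,
                    "acquisition_cost": course.acquisition_cost,
                }
            )
        for event in ep.ade_events:
            ade_rows.append(
                {"episode_id": ep.id, "implicated_route": event.implicated_route.value}
            )

    for filename, columns, rows in [
        ("episodes.csv", EPISODE_COLUMNS, ep_rows),
        ("courses.csv", COURSE_COLUMNS, course_rows),
        ("ade_events.csv", ADE_COLUMNS, ade_rows),
    ]:
        lines = [",".join(columns)]
        for row in rows:
            lines.append(",".join(_fmt(row[c]) for c in columns))
        (directory / filename).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_cohort(directory: str | Path) -> list[PatientEpisode]:
    """Read a cohort written by :func:`write_cohort`.

    Rows violating a record invariant are collected and reported together
    with their CSV line numbers (header = line 1).
    """
    directory = Path(directory)
    ep_path = directory / "episodes.csv"
    if not ep_path.exists():
        raise FileNotFoundError(str(ep_path))
    episodes_df = pd.read_csv(ep_path, dtype=str, keep_default_na=False)
    _check_columns(episodes_df, EPISODE_COLUMNS, "episodes.csv")

    courses_by_ep: dict[str, list[tuple[int, dict]]] = {}
    course_path = directory / "courses.csv"
    if course_path.exists():
        courses_df = pd.read_csv(course_path, dtype=str, keep_default_na=False)
        _check_columns(courses_df, COURSE_COLUMNS, "courses.csv")
        for i, row in enumerate(courses_df.to_dict("records")):
            courses_by_ep.setdefault(row["episode_id"], []).append((i + 2, row))

    ades_by_ep: dict[str, list[tuple[int, dict]]] = {}
    ade_path = directory / "ade_events.csv"
    if ade_path.exists():
        ades_df = pd.read_csv(ade_path, dtype=str, keep_default_na=False)
        _check_columns(ades_df, ADE_COLUMNS, "ade_events.csv")
        for i, row in enumerate(ades_df.to_dict("records")):
            ades_by_ep.setdefault(row["episode_id"], []).append((i + 2, row))

    episodes: list[PatientEpisode] = []
    errors: list[str] = []
    for i, row in enumerate(episodes_df.to_dict("records")):
        line = i + 2
        try:
            courses = []
            for course_line, c in courses_by_ep.get(row["id"], []):
                acquisition = c["acquisition_cost"].strip()
                try:
                    courses.append(
                        AntimicrobialCourse(
                            drug_name=c["drug_name"],
                            route=Route(c["route"]),
                            daily_dose_grams=float(c["daily_dose_grams"]),
                            duration_days=float(c["duration_days"]),
                            start_day=int(c["start_day"]),
                            acquisition_cost=float(acquisition) if acquisition else None,
                        )
                    )
                except (ValidationError, ValueError) as exc:
                    raise ValueError(f"courses.csv line {course_line}: {exc}") from None
            ade_events = [
                AdeEvent(implicated_route=Route(a["implicated_route"]))
                for _, a in ades_by_ep.get(row["id"], [])
            ]
            episodes.append(
                PatientEpisode(
                    id=row["id"],
                    period=row["period"],
                    age_years=float(row["age_years"]),
                    sex=row["sex"],
                    icu_flag=_parse_bool(row["icu_flag"], "icu_flag", line),
                    los_initial_days=float(row["los_initial_days"]),
                    readmitted_30d=_parse_bool(
                        row["readmitted_30d"], "readmitted_30d", line
                    ),
                    los_readmission_days=float(row["los_readmission_days"]),
                    cdi=_parse_bool(row["cdi"], "cdi", line),
                    death_30d=_parse_bool(row["death_30d"], "death_30d", line),
                    infection_related_death=_parse_bool(
                        row["infection_related_death"], "infection_related_death", line
                    ),
                    resistance_developed=_parse_bool(
                        row["resistance_developed"], "resistance_developed", line
                    ),
                    ade_events=ade_events,
                    courses=courses,
                    resources=ResourceEvents(
                        **{f: int(row[f]) for f in _RESOURCE_FIELDS}
                    ),
                )
            )
        except (ValidationError, ValueError) as exc:
            errors.append(f"episodes.csv line {line}: {exc}")
    if errors:
        raise CohortValidationError(errors)
    return episodes


def write_unit_costs(costs: UnitCostTable, path: str | Path) -> None:
    """Write a unit-cost table as ``component,drug,amount,currency,year``."""
    lines = ["component,drug,amount,currency,year"]
    scalar_fields = [
        "bed_day",
        "culture_test",
        "lab_test",
        "biopsy",
        "iv_to_oral_switch_event",
        "cdi_diagnostic_culture",
        "vancomycin_125mg_dose",
    ]
    for field in scalar_fields:
        lines.append(
            f"{field},,{_fmt(getattr(costs, field))},{costs.currency_code},{costs.price_year}"
        )
    for drug in sorted(costs.cost_per_ddd):
        lines.append(
            f"cost_per_ddd,{drug},{_fmt(costs.cost_per_ddd[drug])},"
            f"{costs.currency_code},{costs.price_year}"
        )
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_unit_costs(path: str | Path) -> UnitCostTable:
    df = pd.read_csv(path, dtype=str, keep_default_na=False, comment="#")
    _check_columns(df, ["component", "drug", "amount"], Path(path).name)
    scalars: dict[str, float] = {}
    per_ddd: dict[str, float] = {}
    currency, year = "QAR", 2023
    for row in df.to_dict("records"):
        if row.get("currency"):
            currency = row["currency"]
        if row.get("year"):
            year = int(row["year"])
        if row["component"] == "cost_per_ddd":
            per_ddd[row["drug"]] = float(row["amount"])
        else:
            scalars[row["component"]] = float(row["amount"])
    return UnitCostTable(
        **scalars, cost_per_ddd=per_ddd, currency_code=currency, price_year=year
    )


def write_ddd_reference(ref: DDDReference, path: str | Path) -> None:
    """Write a DDD reference as ``drug,route,ddd_grams`` (blank route = default)."""
    lines = ["drug,route,ddd_grams"]
    for drug in sorted(ref.values):
        lines.append(f"{drug},,{_fmt(ref.values[drug])}")
    for drug in sorted(ref.route_overrides):
        for route, grams in sorted(ref.route_overrides[drug].items()):
            lines.append(f"{drug},{route.value},{_fmt(grams)}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_ddd_reference(path: str | Path) -> DDDReference:
    df = pd.read_csv(path, dtype=str, keep_default_na=False, comment="#")
    _check_columns(df, ["drug", "route", "ddd_grams"], Path(path).name)
    values: dict[str, float] = {}
    overrides: dict[str, dict[Route, float]] = {}
    for row in df.to_dict("records"):
        grams = float(row["ddd_grams"])
        if row["route"].strip():
            overrides.setdefault(row["drug"], {})[Route(row["route"])] = grams
        else:
            values[row["drug"]] = grams
    return DDDReference(values=values, route_overrides=overrides)


def write_staffing(rosters: dict[str, StaffingConfig], path: str | Path) -> None:
    """Write staffing rosters (one per program phase) to YAML."""
    payload = {
        label: config.model_dump(mode="json") for label, config in rosters.items()
    }
    Path(path).write_text(
        yaml.safe_dump(payload, sort_keys=True), encoding="utf-8"
    )


def read_staffing(path: str | Path) -> dict[str, StaffingConfig]:
    payload = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    return {label: StaffingConfig(**config) for label, config in payload.items()}
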