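"""Filter admissions into the costed population.

An admission qualifies when a targeted antimicrobial was started within
3 days of admission (day 0 = admission), ran for at least 48 consecutive
hours, and the patient never entered intensive care.
"""

from stewardcost import (
    AntimicrobialCourse,
    PatientEpisode,
    Route,
    is_eligible,
)


def episode(label, *, icu=False, drug="fluconazole", start=0, duration=5.0):
    return PatientEpisode(
        id=label, period="preliminary", age_years=52, sex="female",
        icu_flag=icu, los_initial_days=12.0,
        courses=[AntimicrobialCourse(
            drug_name=drug, route=Route.oral,
            daily_dose_grams=0.4, duration_days=duration, start_day=start,
        )],
    )


candidates = [
    episode("qualifying course"),
    episode("36 h of therapy only", duration=1.5),
    episode("ICU admission", icu=True),
    episode("non-targeted agent", drug="metronidazole"),
    episode("started on day 5", start=5),
]

for ep in candidates:
    decision = is_eligible(ep)
    verdict = "eligible" if decision.eligible else f"ineligible ({decision.reason})"
    print(f"{ep.id:24s} -> {verdict}")

print()
print("The reason code names the first failed rule, so a site can see which")
print("inclusion criterion removed each admission from the costed cohort.")
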