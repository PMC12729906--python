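"""Cost one phase's antimicrobial consumption and resource use.

Consumption is measured in defined daily doses (DDD = grams administered /
grams per DDD) and priced per DDD; diagnostics are micro-costed as
unit cost x frequency; avoided outcomes are monetized by fixed rules
(bed-days, the 40-dose oral-vancomycin CDI recipe, ADE extra stay).
"""

from stewardcost import (
    default_profiles,
    default_unit_costs,
    generate_cohort,
    period_totals,
)

costs, ddd_reference, rosters = default_unit_costs()
preliminary_profile, _ = default_profiles()
cohort = generate_cohort(preliminary_profile, seed=1)

summary = period_totals(cohort, ddd_reference, costs, "preliminary")
ledger = summary.ledger

print(f"episodes costed:        {summary.n_patients}")
print(f"antimicrobial DDDs:     {ledger.ddd_total:,.1f}")
print(f"antimicrobial cost:     QAR {ledger.antimicrobial_ddd_cost:,.0f}")
print(f"resource micro-costs:   QAR {ledger.resource_total:,.0f}")
print(f"  of which IV-to-oral:  QAR {ledger.resource.iv_to_oral:,.0f}")
print(f"cost avoidance value:   QAR {ledger.avoidance_total:,.0f}")
print(f"  of which bed-days:    QAR {ledger.avoidance.hospitalization:,.0f}")
print(f"  of which CDI recipe:  QAR {ledger.avoidance.cdi:,.0f}")
print()
print("Every figure is count x unit-cost arithmetic over the episode table;")
print("the category totals equal the sum of their components by construction.")
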