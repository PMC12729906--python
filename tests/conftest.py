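import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from stewardcost import (
    default_profiles,
    default_unit_costs,
    generate_cohort,
)
from stewardcost.costing import (
    AvoidanceBreakdown,
    CostLedger,
    PeriodSummary,
    ResourceCostBreakdown,
)

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def cost_tables():
    """Default synthetic unit costs, DDD reference and staffing rosters."""
    return default_unit_costs()


@pytest.fixture(scope="session")
def profiles():
    return default_profiles()


@pytest.fixture(scope="session")
def small_cohorts(profiles):
    """One seeded cohort per phase at the published sample sizes."""
    pre_profile, dev_profile = profiles
    return generate_cohort(pre_profile, 11), generate_cohort(dev_profile, 12)


def published_period_summaries() -> tuple[PeriodSummary, PeriodSummary]:
    """The two phases reconstructed from the published aggregate tables.

    Line items are inputs here: antimicrobial cost, the seven resource
    micro-cost lines, the four avoidance components, and the annual
    operational cost of each phase.
    """
    preliminary = PeriodSummary(
        period="preliminary",
        n_patients=81,
        ledger=CostLedger(
            antimicrobial_ddd_cost=1_569_699,
            resource=ResourceCostBreakdown(
                cultures_before=640,
                labs_before=24_730,
                biopsies_before=0,
                cultures_after=2_880,
                labs_after=28_994,
                biopsies_after=0,
                iv_to_oral=68_001,
            ),
            avoidance=AvoidanceBreakdown(
                hospitalization=16_827_888, cdi=5_050, readmission=0, ade=1_086_868
            ),
            operational=74_190,
        ),
    )
    developed = PeriodSummary(
        period="developed",
        n_patients=105,
        ledger=CostLedger(
            antimicrobial_ddd_cost=300_321,
            resource=ResourceCostBreakdown(
                cultures_before=720,
                labs_before=28_892,
                biopsies_before=0,
                cultures_after=2_943,
                labs_after=37_641,
                biopsies_after=0,
                iv_to_oral=75_760,
            ),
            avoidance=AvoidanceBreakdown(
                hospitalization=4_567_221, cdi=3_536, readmission=0, ade=1_379_108
            ),
            operational=61_714,
        ),
    )
    return preliminary, developed


@pytest.fixture(scope="session")
def printed_summaries():
    return published_period_summaries()
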