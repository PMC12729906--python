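"""Between-phase comparative statistics for cohort tables.

Continuous variables are gated on normality: Shapiro-Wilk on each sample
(at the same alpha as the main test, by default) chooses between the
two-sample Student t-test and the Mann-Whitney U test.  Categorical
variables use the chi-square test, substituting Fisher's exact test for
2x2 tables with any expected count below 5.  All tests are two-sided at
alpha = 0.05 by default.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, model_validator
from scipy import stats as sps

from .records import PatientEpisode, Sex

__all__ = [
    "TestResult",
    "SampleSizeError",
    "DegenerateTableError",
    "compare_continuous",
    "compare_categorical",
    "compare_cohorts",
]


class SampleSizeError(ValueError):
    """Too few observations to run (and gate) a two-sample test."""


class DegenerateTableError(ValueError):
    """A contingency table with an empty margin has no defined test."""


class TestResult(BaseModel):
    """One hypothesis test: which test ran, its statistic and decision."""

    model_config = ConfigDict(frozen=True)

    test_name: str
    statistic: float
    p_value: float = Field(ge=0, le=1)
    alpha: float = 0.05
    significant: bool
    normality_p_values: Optional[tuple[float, float]] = None
    expected_counts: Optional[list[list[float]]] = None

    @model_validator(mode="after")
    def _decision_consistent(self) -> "TestResult":
        if self.significant != (self.p_value < self.alpha):
            raise ValueError("significant must equal p_value < alpha")
        return self


def compare_continuous(
    sample_a: Sequence[float],
    sample_b: Sequence[float],
    alpha: float = 0.05,
    equal_var: bool = True,
    normality_alpha: float | None = None,
) -> TestResult:
    """Normality-gated two-sample comparison of a continuous variable.

    Both samples must pass Shapiro-Wilk (each at ``normality_alpha``,
    defaulting to ``alpha``) for the t-test to be used; otherwise the
    Mann-Whitney U test runs.  ``equal_var=False`` switches the t-test to
    Welch's form.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size < 3 or b.size < 3:
        raise SampleSizeError("each sample needs at least 3 observations")
    gate_alpha = alpha if normality_alpha is None else normality_alpha

    sw_a = sps.shapiro(a).pvalue
    sw_b = sps.shapiro(b).pvalue
    normal = sw_a > gate_alpha and sw_b > gate_alpha

    if normal:
        res = sps.ttest_ind(a, b, equal_var=equal_var)
        name = "t_test" if equal_var else "welch_t_test"
    else:
        res = sps.mannwhitneyu(a, b, alternative="two-sided")
        name = "mann_whitney_u"
    p = float(min(res.pvalue, 1.0))
    return TestResult(
        test_name=name,
        statistic=float(res.statistic),
        p_value=p,
        alpha=alpha,
        significant=bool(p < alpha),
        normality_p_values=(float(sw_a), float(sw_b)),
    )


def compare_categorical(
    table: Sequence[Sequence[int]],
    alpha: float = 0.05,
    correction: bool = False,
) -> TestResult:
    """Chi-square (or Fisher's exact) test on a 2xk contingency table.

    Fisher's exact test substitutes for 2x2 tables when any expected count
    falls below 5.  Yates' continuity correction is off by default; it only
    moves borderline chi-square p-values.
    """
    counts = np.asarray(table, dtype=float)
    if counts.ndim != 2 or (counts < 0).any() or (counts != np.round(counts)).any():
        raise ValueError("table must be a 2-D array of nonnegative integer counts")
    if counts.sum() == 0:
        raise DegenerateTableError("all-zero contingency table")
    if (counts.sum(axis=1) == 0).any() or (counts.sum(axis=0) == 0).any():
        raise DegenerateTableError("contingency table has an empty row or column")

    expected = sps.contingency.expected_freq(counts)
    if counts.shape == (2, 2) and (expected < 5).any():
        odds, p = sps.fisher_exact(counts)
        name, statistic = "fisher_exact", float(odds)
    else:
        chi2, p, _, _ = sps.chi2_contingency(counts, correction=correction)
        name, statistic = "chi_square", float(chi2)
    p = float(min(p, 1.0))
    return TestResult(
        test_name=name,
        statistic=statistic,
        p_value=p,
        alpha=alpha,
        significant=bool(p < alpha),
        expected_counts=expected.tolist(),
    )


def compare_cohorts(
    pre: list[PatientEpisode],
    dev: list[PatientEpisode],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Demographics/outcomes comparison table for two cohorts.

    One row per variable: the test chosen, its statistic, p-value and the
    significance decision — the shape of a published baseline table.
    """
    rows = []

    def continuous(variable: str, va: list[float], vb: list[float]) -> None:
        res = compare_continuous(va, vb, alpha=alpha)
        rows.append(
            {
                "variable": variable,
                "test": res.test_name,
                "statistic": res.statistic,
                "p_value": res.p_value,
                "significant": res.significant,
            }
        )

    def categorical(variable: str, table: list[list[int]]) -> None:
        res = compare_categorical(table, alpha=alpha)
        rows.append(
            {
                "variable": variable,
                "test": res.test_name,
                "statistic": res.statistic,
                "p_value": res.p_value,
                "significant": res.significant,
            }
        )

    continuous("age_years", [e.age_years for e in pre], [e.age_years for e in dev])
    continuous(
        "los_initial_days",
        [e.los_initial_days for e in pre],
        [e.los_initial_days for e in dev],
    )

    def two_by_two(flag) -> list[list[int]]:
        return [
            [sum(1 for e in pre if flag(e)), sum(1 for e in pre if not flag(e))],
            [sum(1 for e in dev if flag(e)), sum(1 for e in dev if not flag(e))],
        ]

    categorical("sex_male", two_by_two(lambda e: e.sex == Sex.male))
    categorical("cdi", two_by_two(lambda e: e.cdi))
    categorical("death_30d", two_by_two(lambda e: e.death_30d))
    return pd.DataFrame(rows)
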