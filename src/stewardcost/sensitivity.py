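"""One-way and multivariate Monte Carlo sensitivity analysis.

Input uncertainty is triangular — Triangular(base x (1 - pct), base,
base x (1 + pct)) — the bounded, mode-centered distribution conventional in
health-economic models.  Both the one-way and the multivariate analyses
propagate draws through a deterministic cost model over 1000 iterations by
default, summarizing the outcome vector as a probability-in-favor (share of
iterations with net reduction > 0; exact ties count as not-in-favor) and a
tornado ranking of standardized least-squares regression coefficients.

The shipped default input set mirrors the study design: the bed-day price
("hospitalization_cost"), the initial length of stay ("initial_los") and
the ADE extra-stay day multipliers ("ade_extra_days"), each expressed as a
multiplicative factor with base 1.  The bed-day price is a shared unit cost
and scales every bed-day-valued term in both phases; the two utilization
factors scale the phase named by ``utilization_scope`` (the developed phase
by default — the comparator phase is treated as the fixed historical
baseline; see docs/methods.md for the rationale and alternatives).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Literal, Mapping, Sequence

import numpy as np
from pydantic import BaseModel, ConfigDict, Field

from .costing import PeriodSummary

__all__ = [
    "HOSPITALIZATION_COST",
    "INITIAL_LOS",
    "ADE_EXTRA_DAYS",
    "UncertainInput",
    "SensitivityResult",
    "sample_triangular",
    "one_way",
    "multivariate",
    "tornado",
    "net_reduction_model",
    "default_uncertain_inputs",
]

HOSPITALIZATION_COST = "hospitalization_cost"
INITIAL_LOS = "initial_los"
ADE_EXTRA_DAYS = "ade_extra_days"

CostModel = Callable[[Mapping[str, float]], float]
UtilizationScope = Literal["developed", "preliminary", "both"]


class UncertainInput(BaseModel):
    """An uncertain model input: base value and fractional half-width."""

    model_config = ConfigDict(frozen=True)

    name: str
    base_value: float
    pct_range: float = Field(ge=0)


@dataclass
class SensitivityResult:
    """Draws, outcomes and summaries of one sensitivity run."""

    input_names: list[str]
    draws: np.ndarray  # (n_iterations, n_inputs)
    outcomes: np.ndarray  # (n_iterations,)
    base_outcome: float
    probability_in_favor: float
    outcome_mean: float
    outcome_p2_5: float
    outcome_p97_5: float
    tornado: list[tuple[str, float]] = field(default_factory=list)
    conclusion_stable: bool = False
    seed: int = 0
    n_iterations: int = 0


def sample_triangular(
    base: float,
    pct: float,
    count: int,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Draw i.i.d. Triangular(base(1-pct), base, base(1+pct)) values.

    ``pct = 0`` degenerates to the constant ``base``.  A negative base is
    handled by ordering the endpoints.
    """
    if count < 1:
        raise ValueError("count must be >= 1")
    if pct < 0:
        raise ValueError("pct must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if pct == 0 or base == 0:
        return np.full(count, float(base))
    lo, hi = base * (1 - pct), base * (1 + pct)
    left, right = min(lo, hi), max(lo, hi)
    return rng.triangular(left, base, right, size=count)


def _summarize(
    input_names: list[str],
    draws: np.ndarray,
    outcomes: np.ndarray,
    base_outcome: float,
    seed: int,
) -> SensitivityResult:
    result = SensitivityResult(
        input_names=input_names,
        draws=draws,
        outcomes=outcomes,
        base_outcome=base_outcome,
        probability_in_favor=float(np.mean(outcomes > 0)),
        outcome_mean=float(np.mean(outcomes)),
        outcome_p2_5=float(np.percentile(outcomes, 2.5)),
        outcome_p97_5=float(np.percentile(outcomes, 97.5)),
        conclusion_stable=bool(np.all((outcomes > 0) == (base_outcome > 0))),
        seed=seed,
        n_iterations=outcomes.shape[0],
    )
    result.tornado = tornado(result)
    return result


def one_way(
    model: CostModel,
    inputs: Sequence[UncertainInput],
    vary: str,
    n_iterations: int = 1000,
    seed: int = 0,
    pct: float | None = None,
    mode: Literal["monte_carlo", "endpoints"] = "monte_carlo",
) -> SensitivityResult:
    """Vary one input, pinning every other input at its base value.

    ``pct`` overrides the varied input's own half-width (the study used
    20% for one-way runs against 10% for the multivariate run).  The
    default propagates Monte Carlo draws; ``mode="endpoints"`` evaluates
    the two deterministic range endpoints instead.
    """
    by_name = {inp.name: inp for inp in inputs}
    if vary not in by_name:
        raise LookupError(f"unknown input {vary!r}")
    target = by_name[vary]
    half_width = target.pct_range if pct is None else pct

    base_assignment = {inp.name: inp.base_value for inp in inputs}
    base_outcome = model(base_assignment)

    if mode == "endpoints":
        values = np.array(
            [target.base_value * (1 - half_width), target.base_value * (1 + half_width)]
        )
    else:
        values = sample_triangular(target.base_value, half_width, n_iterations, seed)

    outcomes = np.empty(values.shape[0])
    for i, value in enumerate(values):
        outcomes[i] = model({**base_assignment, vary: value})
    return _summarize([vary], values.reshape(-1, 1), outcomes, base_outcome, seed)


def multivariate(
    model: CostModel,
    inputs: Sequence[UncertainInput],
    n_iterations: int = 1000,
    seed: int = 0,
) -> SensitivityResult:
    """Joint independent triangular draws over all inputs.

    Deterministic given ``seed``: one named generator drives all columns,
    sampled in declaration order.
    """
    if not inputs:
        raise ValueError("multivariate analysis requires at least one input")
    if n_iterations < 1:
        raise ValueError("n_iterations must be >= 1")
    rng = np.random.default_rng(seed)
    names = [inp.name for inp in inputs]
    draws = np.column_stack(
        [
            sample_triangular(inp.base_value, inp.pct_range, n_iterations, rng)
            for inp in inputs
        ]
    )
    base_outcome = model({inp.name: inp.base_value for inp in inputs})
    outcomes = np.empty(n_iterations)
    for i in range(n_iterations):
        outcomes[i] = model(dict(zip(names, draws[i])))
    return _summarize(names, draws, outcomes, base_outcome, seed)


def tornado(result: SensitivityResult) -> list[tuple[str, float]]:
    """Standardized-regression influence ranking of the inputs.

    Outcomes and draws are z-scored and regressed by least squares; inputs
    are ordered by decreasing coefficient magnitude (ties broken by name).
    A zero-variance input column gets a coefficient of 0 with a warning.
    """
    if result.outcomes.shape[0] < 2 or result.draws.shape[1] < 1:
        raise ValueError("tornado requires >= 2 iterations and >= 1 input")
    X = np.asarray(result.draws, dtype=float)
    y = np.asarray(result.outcomes, dtype=float)

    x_sd = X.std(axis=0)
    y_sd = y.std()
    degenerate = x_sd == 0
    if degenerate.any():
        names = [n for n, d in zip(result.input_names, degenerate) if d]
        warnings.warn(
            f"zero-variance input column(s) {names}; coefficient set to 0",
            stacklevel=2,
        )

    coefs = np.zeros(X.shape[1])
    active = ~degenerate
    if y_sd > 0 and active.any():
        Xz = (X[:, active] - X[:, active].mean(axis=0)) / x_sd[active]
        yz = (y - y.mean()) / y_sd
        beta, *_ = np.linalg.lstsq(Xz, yz, rcond=None)
        coefs[active] = beta

    ranked = sorted(
        zip(result.input_names, coefs), key=lambda item: (-abs(item[1]), item[0])
    )
    return [(name, float(coef)) for name, coef in ranked]


def default_uncertain_inputs(pct: float = 0.10) -> list[UncertainInput]:
    """The study's three targeted inputs as relative factors with base 1."""
    return [
        UncertainInput(name=HOSPITALIZATION_COST, base_value=1.0, pct_range=pct),
        UncertainInput(name=INITIAL_LOS, base_value=1.0, pct_range=pct),
        UncertainInput(name=ADE_EXTRA_DAYS, base_value=1.0, pct_range=pct),
    ]


def net_reduction_model(
    pre: PeriodSummary,
    dev: PeriodSummary,
    utilization_scope: UtilizationScope = "developed",
    per_patient: bool = False,
) -> CostModel:
    """Build the deterministic net-reduction model from two phase summaries.

    The returned callable maps an assignment of the three named factors to
    the net reduction in monetary spending (positive favors the developed
    phase).  ``hospitalization_cost`` rescales every bed-day-valued
    avoidance term (hospitalization, readmission, ADE extra stay) in both
    phases; ``initial_los`` and ``ade_extra_days`` rescale the utilization
    of the phase(s) selected by ``utilization_scope``.  Factors absent from
    an assignment default to 1.  With ``per_patient`` the outcome is the
    sum of per-patient category differences instead of the total.
    """
    pre_l, dev_l = pre.ledger, dev.ledger
    w_pre = 1.0 / pre.n_patients if per_patient else 1.0
    w_dev = 1.0 / dev.n_patients if per_patient else 1.0

    on_pre = utilization_scope in ("preliminary", "both")
    on_dev = utilization_scope in ("developed", "both")

    fixed = (
        w_pre * pre_l.antimicrobial_ddd_cost
        - w_dev * dev_l.antimicrobial_ddd_cost
        + w_pre * pre_l.resource_total
        - w_dev * dev_l.resource_total
        + w_pre * pre_l.operational
        - w_dev * dev_l.operational
        + w_pre * pre_l.avoidance.cdi
        - w_dev * dev_l.avoidance.cdi
    )

    def model(assignment: Mapping[str, float]) -> float:
        f_bed = assignment.get(HOSPITALIZATION_COST, 1.0)
        f_los = assignment.get(INITIAL_LOS, 1.0)
        f_ade = assignment.get(ADE_EXTRA_DAYS, 1.0)
        hosp = (
            w_pre * pre_l.avoidance.hospitalization * (f_los if on_pre else 1.0)
            - w_dev * dev_l.avoidance.hospitalization * (f_los if on_dev else 1.0)
        )
        readm = w_pre * pre_l.avoidance.readmission - w_dev * dev_l.avoidance.readmission
        ade = (
            w_pre * pre_l.avoidance.ade * (f_ade if on_pre else 1.0)
            - w_dev * dev_l.avoidance.ade * (f_ade if on_dev else 1.0)
        )
        return fixed + f_bed * (hosp + readm + ade)

    return model
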