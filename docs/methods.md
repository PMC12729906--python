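# Methods

`stewardcost` compares two phases of a hospital antimicrobial stewardship
program (ASP) — an early "preliminary" phase and a mature "developed"
phase — on the monetary value of resource use, from the hospital
perspective, direct medical costs only. This note documents the model,
its parameters, the synthetic-data generator, the numerical choices and
the limitations.

## The cost model

Each admission (a *patient episode*) enters the analysis if it passes the
eligibility filter: at least one course of a targeted antimicrobial (the
18-agent stewardship list), started within `max_start_day = 3` days of
admission with admission counted as day 0 (so start days 0–3 qualify),
running at least `min_continuous_hours = 48` hours, and no intensive-care
stay (`exclude_icu = True`). The 48-hour rule is operationalized on a
single course record — a course of duration ≥ 2 days — because the data
model stores courses, not individual administrations; split records are
not merged. Whether the continuity rule should apply per drug or per
regimen when agents are switched is not settled by the study design; the
per-course reading is this package's choice and can be tightened by
supplying a custom `EligibilityPolicy`.

Four cost categories are computed per episode and summed per phase:

1. **Antimicrobial consumption.** Consumption is measured in defined
   daily doses, DDD = (daily dose in g × duration in days) / (g per DDD),
   and costed as DDD × price-per-DDD. An alternative mode sums recorded
   per-course pharmacy acquisition costs; price-per-DDD is the default
   because consumption is reported in DDDs while acquisition prices are
   site-internal. DDD denominators are configuration, not code: a bundled
   reference CSV carries WHO-style illustrative values (synthetic; the
   WHO index is versioned and sites should pin the version they report
   against), with optional per-route overrides.

2. **Resource micro-costing.** Cultures, laboratory tests and biopsies
   before/after therapy start, and IV-to-oral switches within the first
   three days of antibiotic therapy, each valued as count × unit cost.
   The monetary meaning of the switch line is modelled as a per-event
   cost supplied in the unit-cost table; the package does not assert any
   particular internal accounting for it.

3. **Cost avoidance** — the monetized value of adverse outcomes:
   * hospitalization: initial length of stay × bed-day cost;
   * readmission: readmission stay × bed-day cost, when readmitted
     within 30 days;
   * CDI: a fixed recipe per case — oral vancomycin 125 mg four times
     daily for ten days (40 doses) plus one diagnostic culture. Bed-days
     attributable to CDI are *not* added; only the drug-plus-culture
     recipe is modelled.
   * adverse drug events: 2 extra bed-days per injectable-implicated
     event, 1 per oral-implicated event, valued at the bed-day rate. A
     per-episode rate override supports sites that value the extra stay
     at the ward's own rate; by default one bed-day rate covers a cohort.

4. **Operational cost.** Per staffing role: headcount × hourly rate ×
   [(data-collection + rounds hours per day) × working days per year +
   meeting hours per month × 12]. `working_days_per_year` defaults to 365
   because collection and rounds are daily activities; weekday-only sites
   can configure 260.

All arithmetic runs at full floating precision. Whole-currency rounding
(half away from zero) happens only in report writers.

## Cost–benefit aggregation

`compare_periods` differences the phase ledgers with a fixed sign
convention, positive favors the developed phase:

* saving = preliminary − developed, separately for antimicrobial cost and
  resource micro-costs (the resource saving may be negative);
* avoidance = preliminary avoidance total − developed avoidance total;
* operational saving = preliminary − developed operational cost;
* **net reduction = saving + avoidance + operational saving**, asserted
  as a validation invariant on every result (tolerance 1e-6 QAR).

Per-patient figures divide each phase by its *own* patient count before
differencing; the per-patient net is the sum of per-patient category
differences, never the net total divided by a pooled n. Amounts are kept
in Qatari Riyal (QAR) and presented also in USD at the configurable peg
rate 3.64 QAR/USD; a consumer-price-index table supports restating
amounts at a target price year (default 2023) when sources differ.

Note that the aggregate tables this model was validated against are not
perfectly self-consistent: the developed phase's avoidance components sum
to 290 QAR less than its printed total, and the printed net totals differ
from the sum of their own printed components by ~25k QAR (total) and
~658 QAR (per patient). The package therefore treats its decomposition
identity as the source of truth and leaves such printed nets to the
reader; report writers always emit internally consistent tables.

## Sensitivity analysis

Input uncertainty is triangular: Triangular(base(1−pct), base,
base(1+pct)). Both the one-way analysis (default half-width 20%) and the
multivariate analysis (default 10%) propagate Monte Carlo draws through
the deterministic cost model, 1000 iterations by default, with one named
seeded generator; a deterministic endpoint mode is available for one-way
runs but is not the default. Summaries: the probability-in-favor (share
of iterations with net reduction > 0; an exact 0 counts as not in favor),
mean and 2.5th/97.5th percentiles, a conclusion-stability flag (all
outcomes share the base-case sign), and a tornado ranking.

The tornado regresses z-scored outcomes on z-scored draws by least
squares and orders inputs by decreasing |coefficient|, ties broken
alphabetically by input name. A zero-variance input column is assigned
coefficient 0 with a warning rather than entering the regression.

**Default input set and scope.** The three shipped inputs are relative
factors with base 1: the bed-day price (`hospitalization_cost`), the
initial length of stay (`initial_los`) and the ADE extra-stay day
multipliers (`ade_extra_days`). The ADE uncertainty varies the 2/1 day
multipliers, not the resulting cost directly. The bed-day price is a
shared unit cost, so it scales every bed-day-valued avoidance term
(hospitalization, readmission, ADE stay) in *both* phases. The two
utilization factors scale the developed phase by default
(`utilization_scope="developed"`): the comparison treats the preliminary
phase as the fixed historical baseline and asks whether the conclusion
survives error in the developed phase's measured utilization together
with the shared price. This mapping reproduces the expected dominance
structure — the bed-day price is the strongest driver and the ADE
extra-stay the weakest. Scoping the utilization factors to both phases
jointly is available (`utilization_scope="both"`); under it the LOS
factor's influence becomes nearly collinear with the price factor's
(their effect magnitudes differ only by the ADE difference term), so the
top two ranks can swap — a consequence of the model algebra worth knowing
before interpreting a tornado under that scope.

Sampling is independent across inputs; correlated sampling and
non-triangular distributions are out of scope.

## Comparative statistics

Continuous variables: Shapiro–Wilk on each sample gates between the
two-sample Student t-test (both pass) and the Mann–Whitney U test. The
gate's alpha defaults to the test alpha (0.05) since no separate gate
level is conventional; it is a parameter. The t-test is equal-variance by
default, with Welch available by flag. Categorical variables: chi-square
without continuity correction by default (correction by flag; it only
moves borderline p-values), replaced by Fisher's exact test for 2×2
tables with any expected count below 5. Expected counts are returned with
the result. No multiplicity adjustment is applied.

## Synthetic cohort generator

`default_profiles()` encodes the two phases' published structure:

| parameter | preliminary | developed |
|---|---|---|
| n | 81 | 105 |
| antibacterial fraction | 0.086 | 0.943 |
| stay mean ± SD (days) | 34.02 ± 51.21 | 7.12 ± 10.47 |
| CDI probability | 0.309 | 0.152 |
| readmission probability | 0 | 0 |
| age mean ± SD | 47.8 ± 17.62 | 54.7 ± 19.89 |
| male fraction | 0.667 | 0.467 |

Drug frequency tables weight the reported leading agents (fluconazole
57.3% and caspofungin 14.6% of the preliminary mix; ertapenem 32.4% and
ciprofloxacin 29.5% of the developed mix), with class weights matching
the antibacterial/antifungal split. Course counts per episode follow the
published 1/2/3+ distribution. Resource-event counts are Poisson with
means chosen once so that phase-level micro-costs sit at the scale of the
published line items under the default unit costs. ADE probabilities
default to 0 (zero events were reported) but are profile parameters so
the ADE costing path is exercised in tests.

**Length of stay.** Stays are lognormal — SD > mean forces a
right-skewed family — with a hard floor of 2 days so every generated
episode can satisfy the 48-hour rule. Draws below the floor are
resampled, and the lognormal parameters are solved (two truncated-moment
equations, `scipy.optimize.fsolve`) so that the *floored* distribution
matches the target mean and SD exactly; naive truncation of an
unconditionally moment-matched lognormal would inflate the developed
phase's mean by roughly two days. First-course durations are gamma
(shape 4) around the drug's typical duration, clipped below at 2 days; a
course may outlast the stay (oral continuation after discharge).

**Default unit costs** are synthetic but anchored to internal consistency
of the published aggregates: bed-day 6,107 QAR (both phases' printed
hospitalization values divided by their total bed-days give ≈ 6,106–6,109),
CDI recipe 202 QAR/case (printed preliminary CDI cost over 25 cases:
vancomycin dose 4.3 × 40 + culture 30). Diagnostic unit costs (culture
160, lab 100, biopsy 450, switch event 700 QAR), per-DDD prices
(antifungals expensive, e.g. caspofungin 1,450 QAR/DDD; antibacterials
cheap, e.g. ciprofloxacin 12 QAR/DDD) and staffing hourly rates are
realistic synthetic choices, fixed once. The staffing rosters carry the
published hours exactly — preliminary: 2 roles × 5 meeting-h/month,
2 roles × 3 h/day data collection, 1 role × 1 h/day rounds; developed:
5 roles × 10 meeting-h/month plus 2 roles × (3 h/day collection +
1 h/day rounds) — with rates chosen so the developed phase's annual cost
comes out below the preliminary phase's, matching the reported direction.

**What the generator does not emulate**, and hence what passing tests do
not show about real data: no correlation between comorbidity and stay,
between drug class and stay, or between CDI and stay; no seasonal or
calendar structure; resource counts independent of stay length;
demographics (nationality, comorbidity index, infection site) beyond
age/sex are not generated. Published rows whose counts are inconsistent
with the group sizes (allergy, all-cause death) are not parameterized.

## Numerical choices

* Moment matching of the floored lognormal uses `fsolve` seeded at the
  unconditional moment-matched parameters; failure to converge raises.
* Eligibility reasons are evaluated in a fixed order (ICU → targeted
  course → start day → duration) and the first failure is reported.
* Ledger conservation tolerance: 1e-6 QAR; decomposition identity
  tolerance: 1e-6 QAR.
* Triangular sampling with `pct = 0` (or base 0) short-circuits to the
  constant base rather than calling the sampler with a degenerate
  support.
* Reports round half away from zero to whole currency units; stored
  values are never rounded.
* Cohort CSVs are written with fixed column order, `\n` line endings,
  lowercase booleans and `repr` floats, making writes byte-reproducible.

## Problem sizes used by the test suite

Parameter-recovery and sampler-moment checks run at n = 10,000 draws
(3-standard-error bands); test-calibration checks run 1,000 null
simulations at group size 30 (rejection rate 0.05 ± 0.02); brute-force
oracle comparisons use cohorts of ≤ 5 episodes; pipeline and determinism
checks run at the published sample sizes (81/105) with 200–1000 Monte
Carlo iterations. The full suite completes in well under a minute on one
CPU.

## Limitations

* Unit costs, per-DDD prices and hourly rates are inputs; the package
  ships only synthetic defaults and makes no claim about any site's
  actual prices.
* The CDI cost is the fixed recipe only; attributable bed-days, isolation
  and recurrence costs are not modelled.
* No discounting, no incremental cost-effectiveness ratios, no indirect
  or productivity costs (hospital perspective).
* ADE causality and infection-relatedness flags are taken as given; no
  clinical adjudication is modelled.
* The sensitivity model varies three named inputs; structural uncertainty
  (e.g. the CDI recipe itself) is not propagated.
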