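# stewardcost

Cost of resource use under an antimicrobial stewardship program (ASP):
a tested, reusable pipeline for comparing two program phases — an early
"preliminary" phase and a mature "developed" phase — on what the hospital
actually spent and avoided spending.

Hospital stewardship teams routinely must show that a maturing ASP pays
for itself. `stewardcost` implements that evaluation end to end for
pharmacists, infectious-disease teams and health economists: eligibility
filtering of admissions, antimicrobial consumption costing in defined
daily doses, bottom-up micro-costing of diagnostics, rule-based cost
avoidance, operational staffing cost, cost–benefit aggregation in two
currencies, and probabilistic sensitivity analysis with a tornado
ranking. A seeded synthetic-cohort generator reproduces the statistical
structure of a published two-phase oncology/hematology evaluation
(n = 81 vs n = 105), so every stage is testable without any patient data.

## The model

For each eligible admission *i* and phase *P*:

* **Consumption**: DDDᵢ = Σ over courses of (daily dose g × days) / (g per
  DDD); antimicrobial cost = Σ DDD × price-per-DDD.
* **Micro-costing**: Σ countᵢⱼ × unit costⱼ over cultures, labs, biopsies
  (before/after therapy) and early IV→oral switches.
* **Cost avoidance**: LOSᵢ × bed-day cost + readmission days × bed-day
  cost + 1{CDI}·(40 × vancomycin-125 mg dose + diagnostic culture) +
  Σ ADE (2 days injectable / 1 day oral) × bed-day cost.
* **Operational**: Σ roles headcount × rate × [(collection + rounds
  h/day) × working days + meeting h/month × 12].

The phases are differenced category-wise (positive favors the developed
phase), per-patient values divide each phase by its own n, and

net reduction = (antimicrobial + resource saving) + cost avoidance + operational saving

is enforced as an invariant. Uncertainty is propagated by Monte Carlo
with triangular inputs, Triangular(0.9·base, base, 1.1·base) by default,
over the bed-day price, the initial length of stay and the ADE extra-stay
multipliers; results are summarized as a probability-in-favor and a
standardized-regression tornado. See `docs/methods.md` for assumptions
and `docs/file_formats.md` for the on-disk schemas.

## Worked example

Feeding in the published period aggregates of the two-phase evaluation
(antimicrobial costs, resource line items, avoidance components,
operational totals) and differencing them:

```sh
python examples/03_cost_benefit.py
```

```
antimicrobial (DDD) saving   QAR     1,269,378 (USD    348,730)   per patient QAR   16,518.8
resource saving              QAR       -20,711 (USD     -5,690)   per patient QAR      156.2
cost avoidance               QAR    11,969,941 (USD  3,288,445)   per patient QAR  164,566.8
operational saving           QAR        12,476 (USD      3,427)   per patient QAR      328.2
net reduction                QAR    13,231,084 (USD  3,634,913)   per patient QAR  181,569.9
```

The developed phase spends 80.9% less on antimicrobials; total diagnostic
spending rises (negative resource saving) yet falls per patient; the net
reduction is the exact sum of the three category results. The sensitivity
analysis on the same base case:

```sh
python examples/04_sensitivity_tornado.py
```

```
base-case net reduction: QAR 13,231,084
probability in favor of the developed phase: 100%
95% interval: QAR 12,234,505 .. QAR 14,207,795

tornado (standardized regression coefficients):
  1. hospitalization_cost   +0.934
  2. initial_los            -0.353
  3. ade_extra_days         -0.108
```

No draw of the 1000 overturns the conclusion; the bed-day price dominates
and the ADE extra-stay days matter least. The other examples cover
eligibility filtering, DDD costing on synthetic cohorts, the comparative
statistics and the file-based workflow; the same workflow runs from the
shell:

```sh
stewardcost simulate --out demo --seed 7
stewardcost analyze --workspace demo --out demo_reports --seed 7
```

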