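# File formats

All inputs are UTF-8, comma-delimited, `.` decimal separator. Lines
beginning with `#` are comments in the unit-cost and DDD tables.

## Cohort directory

A cohort is a directory with three files; child rows join on episode id.

### episodes.csv

| column | type | meaning |
|---|---|---|
| id | text | unique episode (admission) identifier |
| period | `preliminary` \| `developed` | program phase |
| age_years | real ≥ 0 | age at admission |
| sex | `male` \| `female` | |
| icu_flag | bool | any ICU stay during antimicrobial treatment |
| los_initial_days | real ≥ 0 | initial admission length of stay |
| readmitted_30d | bool | infection-related readmission within 30 days |
| los_readmission_days | real ≥ 0 | readmission stay; must be 0 when not readmitted |
| cdi | bool | hospital-onset C. difficile infection |
| death_30d | bool | all-cause death within 30 days |
| infection_related_death | bool | |
| resistance_developed | bool | resistance emerged during hospitalization |
| cultures_before, labs_before, biopsies_before | int ≥ 0 | tests before therapy start |
| cultures_after, labs_after, biopsies_after | int ≥ 0 | tests after therapy start |
| iv_to_oral_switches | int ≥ 0 | IV→oral switches within the first 3 days of antibiotic therapy |

Booleans are written `true`/`false` (`1`/`0` accepted on read).

### courses.csv

| column | type | meaning |
|---|---|---|
| episode_id | text | parent episode id |
| drug_name | text | lowercase agent name |
| route | `injectable` \| `oral` | |
| daily_dose_grams | real ≥ 0 | g/day |
| duration_days | real ≥ 0 | |
| start_day | int ≥ 0 | days since admission; admission = day 0 |
| acquisition_cost | real ≥ 0, blank allowed | total pharmacy cost of the course (only needed in acquisition costing mode) |

### ade_events.csv

| column | type | meaning |
|---|---|---|
| episode_id | text | parent episode id |
| implicated_route | `injectable` \| `oral` | drives the 2-day/1-day extra-stay rule |

## unit_costs.csv

`component,drug,amount,currency,year`. Scalar components: `bed_day`,
`culture_test`, `lab_test`, `biopsy`, `iv_to_oral_switch_event`,
`cdi_diagnostic_culture`, `vancomycin_125mg_dose` (drug column blank).
Per-DDD drug prices use component `cost_per_ddd` with the drug named.
Amounts are QAR per unit (per day, per test, per event, per dose, per
DDD) at the stated price year.

## ddd_reference.csv

`drug,route,ddd_grams` — grams per defined daily dose. A blank route is
the drug's default; a named route overrides it (e.g. ciprofloxacin oral
1.0 g vs injectable 0.8 g).

## staffing.yaml

One mapping per phase label:

```yaml
preliminary:
  working_days_per_year: 365
  months_per_year: 12
  roles:
    - name: physician
      headcount: 1
      hourly_rate: 45.0
      data_collection_hours_per_day: 3.0
      rounds_hours_per_day: 1.0
      meeting_hours_per_month: 5.0
```

## Run config (YAML, for `stewardcost analyze --config`)

Keys: `cohort_preliminary`, `cohort_developed` (cohort directories),
`unit_costs`, `ddd_reference`, `staffing` (files), `output_dir`, `seed`,
`iterations`, `pct`, `utilization_scope`, `qar_per_usd`, `log_level`.
Command-line flags override config values.
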