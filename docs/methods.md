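# Methods

## The transformation model

`i2omop` treats an i2b2 ontology as an *information model*: a hierarchy
whose leaves enumerate exactly the codes a repository may contain, each
leaf carrying a prefixed basecode (`ICD9:250`, `CPT:99213`,
`RXNORM:860975`, `LOINC:2345-7`) and, after annotation, the integer
OMOP concept number of that code in the concept dictionary. The
transformation is then a pure function of four inputs: the star-schema
repository, the annotated ontology, the vocabulary subset (`concept` +
`concept_relationship` restricted to "Maps to" rows), and the valueset
crosswalks for demographics, encounters and vitals.

Resolution of a source code proceeds source code → (vocabulary, code)
via the prefix map → source concept id → all "Maps to" successors, each
tagged with its domain and routed to the domain's table:
Condition→`condition_occurrence`, Procedure→`procedure_occurrence`,
Drug→`drug_exposure`, Measurement→`measurement`,
Observation→`observation`, Device→`device_exposure`. Unknown domains
fall back to the `observation` catch-all with a logged warning rather
than dropping data. A standard source concept with no explicit mapping
rows resolves to itself. Targets are ordered by ascending standard
concept id so output is reproducible; where a source code has both a
self-mapping and external "Maps to" rows, all targets are kept.

Value fields (`value_as_number`, `value_as_string`,
`unit_source_value`) are carried only onto measurement and observation
rows, where they are meaningful. Modifier facts (duplicated fact rows
with a non-`@` modifier code) never seed standalone rows: the three
modifiers equivalent across models — refills, quantity, days supply —
populate the corresponding `drug_exposure` columns of their parent
fact's rows; modifiers whose parent fact is unmapped are counted as
orphans in the report.

### Pass accounting

The engine runs once per (source tree, target table) pair. To make row
conservation exact under 1:n splitting, each primary fact is *homed* to
one pass: the table of its lowest-id resolved target, or its tree's
conventional table (Diagnosis→condition, Procedure→procedure,
Medication→drug, Labs→measurement) when unmapped. With this
convention, for every pass `rows_in = contributing facts +
rows_unmapped`, `rows_out ≥ rows_in − rows_unmapped` (splits inflate
output), and the `rows_in` of a tree's passes sum exactly to the
tree's primary fact count. The test suite verifies both identities by
exhaustive enumeration of fact × resolution targets.

### Computed tables

`observation_period` holds one row per person with at least one dated
event, spanning the person's earliest to latest event date across all
event tables (visit, condition, procedure, drug, device, measurement,
observation; end dates included when present).

Eras merge per-(person, concept) intervals: sort by start date, then
merge while the next start is within `gap_days` of the running end
(missing end dates count as the start date). The era end is the
maximum merged end; `occurrence_count` is the number of merged source
rows. The persistence gap defaults to 30 days — the common OHDSI
convention — and is configurable. Drug eras group by the exposure's
standard concept id as-is; ingredient roll-up would require the
`concept_ancestor` table and is out of scope. Tests compare the merge
against an independent brute-force oracle that marks every covered day
extended by the gap and unions intervals whose day sets intersect; the
two constructions are exactly equivalent for the `≤` merge rule.

## QA checklist thresholds

The five checks quantify qualitative review guidance; every threshold
is a `QAConfig` field.

| check | rule | default |
|---|---|---|
| data_density | per-table monthly counts have Theil–Sen slope ≥ 0 over the trailing window, and per-table totals sit within a ratio of each other | 24 months, ratio ≤ 10 |
| age_first_obs | modal age (ages ≥ 1) in the 20s–30s; 5-year rolling mean of counts non-increasing from the peak to age 80; age-0 spike permitted | peak ∈ [20, 39] |
| treemap_variety | distinct concept ids in condition / measurement / drug / procedure tables | ≥ 20 each |
| person_balance | female share near one half; every expected race present | share ∈ [0.4, 0.6] |
| recency | latest visit start per visit type within a window of the refresh date | 90 days |

`observation_period` is excluded from the magnitude comparison since it
has one row per patient by construction. A robust slope rather than
strict monotonicity tolerates ordinary monthly noise. Rendering plots
is optional; pass/fail never depends on it.

## The synthetic population

The generator emulates only what the checklist inspects, at the demo
scale of 133 patients over a 2016-01 → 2018-12 horizon:

* **Ages at first observation** follow a deterministic unimodal
  histogram: counts are allocated by largest remainder against a
  normal(28, 8) density mixed with a uniform elder tail (15%) and an
  age-0 point mass (12%), then laid out as a tent around the mode so
  the decline past the peak is monotone for any population size.
* **Visit volume** grows 4% per month, allocated by largest remainder
  across months; each patient enters in the first year and every
  patient's first visit is their entry visit, so everyone has ≥ 1
  event. Each visit carries a fixed recipe of facts (two diagnoses,
  usually a procedure and a medication, two labs, one vital); the
  first pass through each tree cycles its full code catalog so every
  concept is represented.
* **Demographics**: exact female share (default 0.5), races and
  ethnicities allocated by largest remainder so all categories are
  present; 4% of patients receive death dates after their last event.
* Each code catalog holds ≥ 20 mapped codes per event tree, plus three
  planted codes absent from the concept dictionary (an OTC drug
  combination, a retired procedure code, a local E-code) to exercise
  unmapped accounting.

Independent random streams drive each aspect (ages, sex, race, entry,
visits, types, codes, values, deaths), so an adversarial variant
perturbs exactly one aspect and fails exactly one check:
`uniform_ages` (cyclic ages 0–79), `all_male`, `missing_race` (one
race reassigned), `stale_visits` (emergency visits confined to the
early horizon, so the ER stream goes quiet two years before refresh),
and `empty_drug` (the medication catalog collapses to a single
product, preserving exposure volume while variety vanishes — a fully
empty drug table would also trip the density magnitude check).

What the population does **not** emulate: clinical plausibility
(comorbidity structure, code co-occurrence, realistic lab values),
coding drift over time, missingness patterns, or the scale and term
diversity of a production warehouse with the full three-million-term
dictionary. Passing the checklist on this fixture demonstrates the
mechanics of the transformation and of the checks, not data quality of
any real site.

## Numerical and design choices

* Problem sizes: the default test and acceptance runs use the
  133-patient demo population (~3,200 visits, ~24,000 facts) and 1,000
  random interval sets for the era oracle; the whole suite runs in well
  under a minute.
* All files are UTF-8 CSV with ISO-8601 dates and a mandatory header;
  headers are case-insensitive, values case-preserved. The empty
  modifier is normalized to the i2b2 sentinel `@`. Missing visit end
  dates are stored empty and imputed to the start date only at
  transform time, preserving provenance.
* `person_id` / `visit_occurrence_id` reuse the source
  `patient_num` / `encounter_num` (already pseudonymous integers) for
  auditability; event-row ids are assigned sequentially after a
  deterministic sort, so two runs on identical inputs are
  byte-identical.
* Provenance (`type_concept_id`) defaults to the single "EHR record"
  constant 32817, configurable.
* Lenient reads drop and count orphan facts (facts whose patient or
  encounter is missing from the dimensions); strict reads abort. On a
  clean repository the two modes agree exactly.
* Synthetic concept ids are drawn from a reserved range
  (> 2,000,000,000) so fixture ids can never collide with real OMOP
  concept ids; the two published reference ids (44833365, 44821975)
  are the only real source-concept numbers embedded.
* The medication target table is `drug_exposure` throughout; HCPCS
  ontology entries ship disabled, and only the eight modifiers
  mappable across models are active in the fixture ontology.
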