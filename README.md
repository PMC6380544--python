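# i2omop

Ontology-driven transformation of i2b2 clinical repositories into the
OMOP Common Data Model, with built-in synthetic fixtures and an
Achilles-style data-quality checklist.

## The problem

Research networks increasingly require EHR data in the OMOP CDM: domain
tables (`condition_occurrence`, `drug_exposure`, `measurement`, …) keyed
to a central concept dictionary of integer "OMOP numbers". Many
institutions instead run i2b2, which stores every observation in a
single narrow `observation_fact` table (patient, encounter, prefixed
code such as `ICD9:250`, modifier, dates, value) with hierarchical
ontologies supplying the semantic layer. Because an i2b2 ontology can
exactly enumerate the permissible codes of a target model, it can also
*drive* the transformation into that model — no site-specific
programming per concept.

`i2omop` implements that approach end to end:

1. **OMOP-number annotation.** Every active ontology leaf's basecode is
   cross-referenced into the OMOP concept dictionary (`ICD9:250` →
   concept 44833365); codes absent from the dictionary are collected in
   an unmapped-code report.
2. **Dynamic 1:n standard-concept resolution.** At transform time each
   source concept is mapped through the `concept_relationship` "Maps to"
   rows to its *standard* analytic concepts. The mapping is one-to-many
   and may cross domains: `ICD9:V37.0` resolves to three SNOMED
   concepts; a childhood-obesity code lands in both the condition and
   observation tables; vaccine diagnosis codes are routed to the
   procedure table.
3. **Domain routing and multi-pass materialization.** Each resolved
   target is written to the table of its *domain*
   (Condition→`condition_occurrence`, Drug→`drug_exposure`, …), with the
   engine running once per (source tree, target table) pair and
   reporting rows in / rows out / rows unmapped for every pass.
4. **Computed tables.** `observation_period` (one row per person,
   spanning first to last event) and `drug_era` / `condition_era`
   (per-person per-concept intervals merged under a 30-day persistence
   gap).
5. **Five-point QA checklist.** Data density, age at first observation,
   treemap variety, demographic balance, and data recency — pass/fail
   rules distilled from OHDSI's Achilles characterization reports.

A deterministic fixture generator produces every input the pipeline
needs (a 133-patient demo population, a mini ARCH-style ontology, a mini
OMOP vocabulary carrying the reference mappings above, and valueset
crosswalks), so the whole pipeline runs with no external data.

## Worked example

```python
import i2omop as m

bundle = m.generate_vocabulary_fixture()

# 1:n cross-domain resolution of a childhood-obesity diagnosis code
res = m.resolve_standard_concepts("ICD9:V85.54",
                                  bundle.concepts, bundle.mappings)
for cid, domain, table in res.targets:
    print(f"  -> {cid}  {domain:<12} {table}")
```

```
  -> 2000000004  Condition    condition_occurrence
  -> 2000000005  Observation  observation
```

One source code, two rows in two OMOP tables. Running the full demo
transform and checklist:

```python
ontology, unmapped = m.annotate_omop_codes(bundle.ontology, bundle.concepts)
repo = m.generate_population(m.FixtureConfig(), bundle)     # 133 patients
tables, report = m.run_transform(repo, ontology, bundle.concepts,
                                 bundle.mappings, bundle.crosswalks)
qa = m.run_checklist(tables, m.QAConfig(refresh_date="2018-12-31",
                     expected_race_concepts=m.fixtures.RACE_NAMES))
```

prints (via the row counts in `report.row_counts`):

```
person                    133 rows
visit_occurrence         3192 rows
condition_occurrence     4689 rows
observation              1888 rows
drug_era                 2600 rows
observation_period        133 rows
unmapped facts: 492
QA overall: True
```

`person` and `observation_period` carry exactly one row per patient;
the 492 unmapped facts are the observations coded with the three
planted codes missing from the concept dictionary — counted and logged,
never silently dropped. The mapping-multiplicity report shows how each
source tree fans out across target tables:

```
source_tree  condition_occurrence  drug_exposure  measurement  observation  procedure_occurrence  total
  Diagnosis                    20              0            0            6                     1     26
       Labs                     0              0           20            0                     0     20
 Medication                     0             21            0            0                     0     21
  Procedure                     0              0            0            0                    19     19
```

(The Diagnosis row spans three tables: conditions, status observations,
and the vaccine code routed to procedures.)

## Command line

```bash
i2omop generate-fixtures --output-dir fix/
i2omop transform --input-dir fix/ --output-dir omop/
i2omop qa --input-dir omop/ --output-dir qa/ --refresh-date 2018-12-31
i2omop report-unmapped --input-dir fix/ --output-dir reports/
i2omop report-multiplicity --input-dir fix/ --output-dir reports/
```

Exit codes: 0 success, 1 validation/QA failure, 2 usage error. Every
run writes a `run_manifest.json` with the resolved configuration and a
pass/fail summary.

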