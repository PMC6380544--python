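import numpy as np
import pandas as pd
import pytest

import i2omop as m
from i2omop.star_schema import NO_MODIFIER
from i2omop.transform import (compute_observation_period,
                              copy_dimension_tables, map_coded_facts,
                              map_person, map_visits)


CODED_TREES = ("Diagnosis", "Procedure", "Medication", "Labs")


class TestTableCopies:
    def test_death_rows_match_deceased_patients(self, repo):
        tables = copy_dimension_tables(repo)
        expected = repo.patients["death_date"].notna().sum()
        assert len(tables["death"]) == expected == 5

    def test_death_after_birth(self, repo):
        tables = copy_dimension_tables(repo)
        birth = repo.patients.set_index("patient_num")["birth_date"]
        for row in tables["death"].itertuples():
            assert row.death_date >= birth[row.person_id]

    def test_care_sites_from_distinct_locations(self, repo):
        tables = copy_dimension_tables(repo)
        assert sorted(tables["care_site"]["care_site_source_value"]) == \
            sorted(set(repo.visits["location_cd"]))

    def test_no_providers_gives_empty_table(self, repo):
        empty = repo.copy()
        empty.providers = empty.providers.iloc[:0]
        assert copy_dimension_tables(empty)["provider"].empty


class TestPerson:
    def test_one_row_per_patient(self, transformed):
        tables, _ = transformed
        assert len(tables["person"]) == 133
        assert tables["person"]["person_id"].is_unique

    def test_crosswalk_lookup_and_fallback(self, mini_repo, bundle):
        person = map_person(mini_repo.patients, bundle.crosswalks)
        assert person.loc[0, "gender_concept_id"] == 8532  # F
        # unmapped race code preserved with concept 0
        assert person.loc[1, "race_concept_id"] == 0
        assert person.loc[1, "race_source_value"] == "X9"


class TestVisits:
    def test_row_count_and_end_imputation(self, mini_repo, bundle):
        vo = map_visits(mini_repo.visits, bundle.crosswalks)
        assert len(vo) == len(mini_repo.visits)
        assert vo.loc[0, "end_date"] == vo.loc[0, "start_date"]

    def test_unmapped_inout_gets_concept_zero(self, mini_repo, bundle):
        visits = mini_repo.visits.assign(inout_cd="Z")
        vo = map_visits(visits, bundle.crosswalks)
        assert (vo["concept_id"] == 0).all()
        assert (vo["source_value"] == "Z").all()


class TestCodedFacts:
    def test_childhood_obesity_splits_into_two_domains(self, mini_repo,
                                                       bundle, annotated):
        ontology, _ = annotated
        tables, passes, unmapped, _ = map_coded_facts(
            mini_repo.facts, "Diagnosis", ontology, bundle.concepts,
            bundle.mappings)
        obesity_cond = [r for r in tables["condition_occurrence"]
                        if r["source_value"] == "ICD9:V85.54"]
        obesity_obs = [r for r in tables["observation"]
                       if r["source_value"] == "ICD9:V85.54"]
        assert len(obesity_cond) == 1 and len(obesity_obs) == 1

    def test_vaccine_diagnosis_routes_to_procedure_table(self, mini_repo,
                                                         bundle,
                                                         annotated):
        ontology, _ = annotated
        tables, _, _, _ = map_coded_facts(
            mini_repo.facts, "Diagnosis", ontology, bundle.concepts,
            bundle.mappings)
        vaccine = [r for r in tables.get("procedure_occurrence", [])
                   if r["source_value"] == "ICD9:V04.81"]
        assert len(vaccine) == 1

    def test_unmapped_fact_counted_not_written(self, mini_repo, bundle,
                                               annotated):
        ontology, _ = annotated
        tables, passes, unmapped, _ = map_coded_facts(
            mini_repo.facts, "Diagnosis", ontology, bundle.concepts,
            bundle.mappings)
        assert unmapped == {"ICD9:E849.7": 1}
        for rows in tables.values():
            assert all(r["source_value"] != "ICD9:E849.7" for r in rows)

    def test_conservation_against_exhaustive_enumeration(self, repo,
                                                         bundle,
                                                         annotated,
                                                         transformed):
        """Per-table outputs equal brute-force fact x targets counts."""
        ontology, _ = annotated
        tables, report = transformed
        leaves = ontology[(ontology["basecode"] != "") &
                          ontology["active"] & ~ontology["is_modifier"]]
        tree_by_code = {b: p.split("\\")[1]
                        for p, b in zip(leaves["path"], leaves["basecode"])}
        primary = repo.facts[repo.facts["modifier_cd"] == NO_MODIFIER]
        expected_rows: dict[str, int] = {}
        n_coded = 0
        for code, count in primary["concept_cd"].value_counts().items():
            tree = tree_by_code.get(code)
            if tree not in CODED_TREES:
                continue
            n_coded += count
            res = m.resolve_standard_concepts(code, bundle.concepts,
                                              bundle.mappings)
            for _, _, table in res.targets:
                expected_rows[table] = expected_rows.get(table, 0) + count
        coded_passes = [p for p in report.passes
                        if p.source_tree in CODED_TREES]
        assert sum(p.rows_in for p in coded_passes) == n_coded
        for p in coded_passes:
            assert p.rows_out >= p.rows_in - p.rows_unmapped
        by_table: dict[str, int] = {}
        for p in coded_passes:
            by_table[p.target_table] = by_table.get(p.target_table, 0) + \
                p.rows_out
        assert by_table == expected_rows

    def test_per_fact_splitting_bound(self, repo, bundle):
        for code in set(repo.facts["concept_cd"]):
            res = m.resolve_standard_concepts(code, bundle.concepts,
                                              bundle.mappings)
            assert len(res.targets) <= 5

    def test_values_carried_for_measurement_targets(self, transformed):
        tables, _ = transformed
        labs = tables["measurement"]
        lab_rows = labs[labs["source_value"].str.startswith("LOINC:")]
        assert lab_rows["value_as_number"].notna().all()

    def test_modifiers_attach_to_drug_rows(self, transformed):
        tables, report = transformed
        drugs = tables["drug_exposure"]
        assert drugs["refills"].notna().any()
        assert (drugs.loc[drugs["days_supply"].notna(),
                          "days_supply"] == 30).all()
        assert report.orphan_modifiers > 0  # modifiers of unmapped drugs


class TestObservationPeriod:
    def test_one_row_per_person_with_events(self, transformed):
        tables, _ = transformed
        op = tables["observation_period"]
        assert len(op) == 133
        assert op["person_id"].is_unique

    def test_single_event_spans_single_day(self):
        tables = {"measurement": pd.DataFrame({
            "person_id": [7], "start_date": [pd.Timestamp("2018-05-05")],
            "end_date": [pd.NaT]})}
        op = compute_observation_period(tables)
        assert op.iloc[0]["start_date"] == op.iloc[0]["end_date"] == \
            pd.Timestamp("2018-05-05")

    def test_minmax_matches_brute_force_scan(self, transformed):
        tables, _ = transformed
        op = tables["observation_period"].set_index("person_id")
        dates: dict[int, list] = {}
        for name in ("visit_occurrence", "condition_occurrence",
                     "procedure_occurrence", "drug_exposure",
                     "measurement", "observation"):
            df = tables[name]
            for pid, s, e in zip(df["person_id"], df["start_date"],
                                 df.get("end_date", df["start_date"])):
                dates.setdefault(pid, []).append(s)
                if pd.notna(e):
                    dates[pid].append(e)
        for pid, ds in dates.items():
            assert op.loc[pid, "start_date"] == min(ds)
            assert op.loc[pid, "end_date"] == max(ds)

    def test_every_event_within_period(self, transformed):
        tables, _ = transformed
        op = tables["observation_period"].set_index("person_id")
        for name in ("condition_occurrence", "measurement"):
            df = tables[name]
            starts = op.loc[df["person_id"], "start_date"].to_numpy()
            ends = op.loc[df["person_id"], "end_date"].to_numpy()
            assert (df["start_date"].to_numpy() >= starts).all()
            assert (df["start_date"].to_numpy() <= ends).all()


def test_empty_repository_transforms_to_empty_tables(mini_repo, bundle,
                                                     annotated):
    ontology, _ = annotated
    empty = mini_repo.copy()
    empty.facts = empty.facts.iloc[:0]
    empty.patients = empty.patients.iloc[:0]
    empty.visits = empty.visits.iloc[:0]
    empty.providers = empty.providers.iloc[:0]
    tables, report = m.run_transform(empty, ontology, bundle.concepts,
                                     bundle.mappings, bundle.crosswalks)
    assert all(df.empty for df in tables.values())
    assert sum(report.unmapped_codes.values()) == 0


def test_transform_is_deterministic(repo, bundle, annotated, transformed):
    ontology, _ = annotated
    tables1, _ = transformed
    tables2, _ = m.run_transform(repo, ontology, bundle.concepts,
                                 bundle.mappings, bundle.crosswalks)
    for name, df in tables1.items():
        pd.testing.assert_frame_equal(df, tables2[name])
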