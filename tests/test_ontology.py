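import pandas as pd
import pytest

import i2omop as m
from i2omop.fixtures import (CONCEPT_FILE, ONTOLOGY_FILE,
                             RELATIONSHIP_FILE, write_fixture_bundle)
from i2omop.ontology import OntologyError, route_domain, tree_of


@pytest.fixture(scope="module")
def bundle_dir(tmp_path_factory):
    d = tmp_path_factory.mktemp("bundle")
    write_fixture_bundle(d, m.FixtureConfig(n_patients=5))
    return d


class TestLoadOntology:
    def test_fixture_has_eight_active_modifiers(self, bundle_dir):
        ont = m.load_ontology(bundle_dir / ONTOLOGY_FILE)
        active_mods = ont[ont["is_modifier"] & ont["active"]]
        assert len(active_mods) == 8

    def test_toy_two_level_file(self, tmp_path):
        f = tmp_path / "ont.csv"
        f.write_text(
            "path,basecode,name,level,omop_concept_id,active,is_modifier,"
            "modifier_applied_path\n"
            '\\Diagnosis\\,,Diagnosis,0,,true,false,\n'
            '\\Diagnosis\\Leaf\\,ICD9:250,Leaf,1,,true,false,\n')
        ont = m.load_ontology(f)
        assert len(ont) == 2
        assert ont["level"].tolist() == [0, 1]

    def test_orphan_path_rejected(self, tmp_path):
        f = tmp_path / "ont.csv"
        f.write_text(
            "path,basecode,name,level,omop_concept_id,active,is_modifier,"
            "modifier_applied_path\n"
            '\\Diagnosis\\Missing\\Leaf\\,ICD9:250,Leaf,2,,true,false,\n')
        with pytest.raises(OntologyError, match="orphan path"):
            m.load_ontology(f)

    def test_duplicate_path_rejected(self, tmp_path):
        f = tmp_path / "ont.csv"
        f.write_text(
            "path,basecode,name,level,omop_concept_id,active,is_modifier,"
            "modifier_applied_path\n"
            '\\Diagnosis\\,,Diagnosis,0,,true,false,\n'
            '\\Diagnosis\\,,Diagnosis,0,,true,false,\n')
        with pytest.raises(OntologyError, match="duplicate"):
            m.load_ontology(f)


class TestAnnotate:
    def test_reference_codes_get_their_omop_numbers(self, annotated):
        ontology, _ = annotated
        by_code = ontology.set_index("basecode")["omop_concept_id"]
        assert by_code["ICD9:250"] == 44833365
        assert by_code["ICD9:463"] == 44821975

    def test_unmapped_report_lists_planted_codes_once(self, bundle,
                                                      annotated):
        _, report = annotated
        assert sorted(report["basecode"]) == sorted(bundle.planted_unmapped)
        assert not report["basecode"].duplicated().any()

    def test_idempotent(self, bundle, annotated):
        ontology, report = annotated
        again, report2 = m.annotate_omop_codes(ontology, bundle.concepts)
        pd.testing.assert_frame_equal(ontology, again)
        pd.testing.assert_frame_equal(report, report2)

    def test_annotated_and_unmapped_partition_active_leaves(self, bundle,
                                                            annotated):
        ontology, report = annotated
        leaves = ontology[(ontology["basecode"] != "") & ontology["active"]
                          & ~ontology["is_modifier"]]
        dict_leaves = leaves[[tree_of(p) in
                              {"Diagnosis", "Procedure", "Medication",
                               "Labs"} for p in leaves["path"]]]
        annotated_codes = set(
            dict_leaves.loc[dict_leaves["omop_concept_id"].notna(),
                            "basecode"])
        unmapped_codes = set(report["basecode"])
        assert annotated_codes | unmapped_codes == set(
            dict_leaves["basecode"])
        assert not annotated_codes & unmapped_codes

    def test_empty_ontology_unchanged(self, bundle):
        empty = bundle.ontology.iloc[:0]
        out, report = m.annotate_omop_codes(empty, bundle.concepts)
        assert out.empty and report.empty


class TestResolve:
    def test_v37_resolves_to_three_standard_targets(self, bundle):
        res = m.resolve_standard_concepts("ICD9:V37.0", bundle.concepts,
                                          bundle.mappings)
        assert len(res.targets) == 3
        assert [t[0] for t in res.targets] == sorted(t[0]
                                                     for t in res.targets)

    def test_standard_source_resolves_to_itself(self, bundle):
        res = m.resolve_standard_concepts("CPT:99213", bundle.concepts,
                                          bundle.mappings)
        assert len(res.targets) == 1
        assert res.targets[0][0] == res.source_concept_id

    def test_unknown_code_is_unmapped(self, bundle):
        res = m.resolve_standard_concepts("ICD9:000.0", bundle.concepts,
                                          bundle.mappings)
        assert res.unmapped and res.targets == ()

    def test_resolution_matches_brute_force_scan(self, bundle):
        """Every fixture code against an exhaustive mapping-table scan."""
        concepts, mappings = bundle.concepts, bundle.mappings
        by_key = {(v, c): (i, s) for v, c, i, s in zip(
            concepts["vocabulary_id"], concepts["concept_code"],
            concepts["concept_id"], concepts["standard"])}
        for tree, codes in bundle.catalogs.items():
            if tree == "Vitals":
                continue
            for code in codes:
                res = m.resolve_standard_concepts(code, concepts, mappings)
                prefix, _, raw = code.partition(":")
                vocab = {"ICD9": "ICD9CM", "CPT": "CPT4",
                         "RXNORM": "RxNorm", "NDC": "NDC",
                         "LOINC": "LOINC"}[prefix]
                if (vocab, raw) not in by_key:
                    assert res.unmapped
                    continue
                sid, standard = by_key[(vocab, raw)]
                expected = sorted(
                    t for s, t in zip(mappings["source_concept_id"],
                                      mappings["target_concept_id"])
                    if s == sid)
                if not expected and standard:
                    expected = [sid]
                assert [t[0] for t in res.targets] == expected, code

    def test_multiplicity_bound_on_fixture(self, bundle):
        for tree, codes in bundle.catalogs.items():
            if tree == "Vitals":
                continue
            for code in codes:
                res = m.resolve_standard_concepts(code, bundle.concepts,
                                                  bundle.mappings)
                if not res.unmapped:
                    assert 1 <= len(res.targets) <= 5


class TestRouting:
    @pytest.mark.parametrize("domain,tree,table", [
        ("Condition", "Diagnosis", "condition_occurrence"),
        ("Drug", "Procedure", "drug_exposure"),
        ("Procedure", "Diagnosis", "procedure_occurrence"),
        ("Measurement", "Labs", "measurement"),
        ("Observation", "Diagnosis", "observation"),
        ("Device", "Procedure", "device_exposure"),
    ])
    def test_domain_routing_map(self, domain, tree, table):
        assert route_domain(domain, tree) == table

    def test_unknown_domain_falls_back_to_observation(self, caplog):
        assert route_domain("Specimen", "Labs") == "observation"


class TestMultiplicityReport:
    def test_diagnosis_spans_multiple_target_tables(self, annotated,
                                                    bundle):
        ontology, _ = annotated
        report = m.multiplicity_report(ontology, bundle.concepts,
                                       bundle.mappings)
        diag = report[report["source_tree"] == "Diagnosis"].iloc[0]
        tables = [c for c in report.columns
                  if c not in ("source_tree", "total")]
        assert sum(diag[t] > 0 for t in tables) >= 2

    def test_cell_counts_match_per_code_enumeration(self, annotated,
                                                    bundle):
        ontology, _ = annotated
        report = m.multiplicity_report(ontology, bundle.concepts,
                                       bundle.mappings).set_index(
            "source_tree")
        leaves = ontology[(ontology["basecode"] != "") & ontology["active"]
                          & ~ontology["is_modifier"]]
        expected: dict[tuple[str, str], set] = {}
        totals: dict[str, set] = {}
        for path, code in zip(leaves["path"], leaves["basecode"]):
            res = m.resolve_standard_concepts(code, bundle.concepts,
                                              bundle.mappings)
            if res.unmapped:
                continue
            totals.setdefault(tree_of(path), set()).add(code)
            for _, _, table in res.targets:
                expected.setdefault((tree_of(path), table),
                                    set()).add(code)
        for (tree, table), codes in expected.items():
            assert report.loc[tree, table] == len(codes)
        for tree, codes in totals.items():
            assert report.loc[tree, "total"] == len(codes)

    def test_empty_mapping_table_gives_empty_report(self, annotated,
                                                    bundle):
        ontology, _ = annotated
        nonstandard = bundle.concepts.assign(
            standard=False)  # no identity fallback either
        report = m.multiplicity_report(ontology, nonstandard,
                                       bundle.mappings.iloc[:0])
        assert report.empty or (report.drop(
            columns="source_tree").to_numpy() == 0).all()


def test_modifier_crosswalk_counts(bundle):
    counts = m.modifier_crosswalk_summary(bundle.modifier_crosswalk)
    assert counts == {"equivalent": 3, "valueset_differs": 4,
                      "single_model": 18}


class TestLoadVocabulary:
    def test_fixture_files_load(self, bundle_dir, bundle):
        concepts, mappings = m.load_vocabulary(
            bundle_dir / CONCEPT_FILE, bundle_dir / RELATIONSHIP_FILE)
        assert len(concepts) == len(bundle.concepts)
        assert len(mappings) == len(bundle.mappings)

    def test_unknown_relationship_target_rejected(self, bundle_dir,
                                                  tmp_path):
        rel = pd.read_csv(bundle_dir / RELATIONSHIP_FILE)
        rel.loc[0, "concept_id_2"] = 123456789
        bad = tmp_path / "rel.csv"
        rel.to_csv(bad, index=False)
        with pytest.raises(OntologyError, match="123456789"):
            m.load_vocabulary(bundle_dir / CONCEPT_FILE, bad)

    def test_duplicate_concept_id_rejected(self, bundle_dir, tmp_path):
        con = pd.read_csv(bundle_dir / CONCEPT_FILE)
        bad = tmp_path / "con.csv"
        pd.concat([con, con.iloc[[0]]]).to_csv(bad, index=False)
        with pytest.raises(OntologyError, match="duplicate concept_id"):
            m.load_vocabulary(bad, bundle_dir / RELATIONSHIP_FILE)

    def test_non_maps_to_rows_dropped(self, bundle_dir, tmp_path):
        rel = pd.read_csv(bundle_dir / RELATIONSHIP_FILE)
        extra = rel.iloc[[0]].assign(relationship_id="Subsumes")
        f = tmp_path / "rel.csv"
        pd.concat([rel, extra]).to_csv(f, index=False)
        _, mappings = m.load_vocabulary(bundle_dir / CONCEPT_FILE, f)
        assert len(mappings) == len(rel)
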