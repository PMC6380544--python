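import pandas as pd
import pytest

import i2omop as m
from i2omop.fixtures import RACE_NAMES


@pytest.fixture(scope="session")
def bundle():
    return m.generate_vocabulary_fixture()


@pytest.fixture(scope="session")
def annotated(bundle):
    ontology, report = m.annotate_omop_codes(bundle.ontology,
                                             bundle.concepts)
    return ontology, report


@pytest.fixture(scope="session")
def repo(bundle):
    return m.generate_population(m.FixtureConfig(), bundle)


@pytest.fixture(scope="session")
def transformed(repo, bundle, annotated):
    ontology, _ = annotated
    return m.run_transform(repo, ontology, bundle.concepts,
                           bundle.mappings, bundle.crosswalks)


@pytest.fixture(scope="session")
def qa_config():
    return m.QAConfig(refresh_date="2018-12-31",
                      expected_race_concepts=dict(RACE_NAMES))


@pytest.fixture()
def mini_repo():
    """Two patients, two visits, hand-sized for targeted assertions."""
    facts = pd.DataFrame([
        dict(patient_num=1, encounter_num=1, concept_cd="ICD9:V85.54",
             modifier_cd="@", provider_id="P1",
             start_date=pd.Timestamp("2018-03-01"), end_date=pd.NaT,
             valtype_cd="", nval_num=float("nan"), tval_char="",
             units_cd="", instance_num=1),
        dict(patient_num=2, encounter_num=2, concept_cd="ICD9:V04.81",
             modifier_cd="@", provider_id="P1",
             start_date=pd.Timestamp("2018-04-01"), end_date=pd.NaT,
             valtype_cd="", nval_num=float("nan"), tval_char="",
             units_cd="", instance_num=1),
        dict(patient_num=2, encounter_num=2, concept_cd="ICD9:E849.7",
             modifier_cd="@", provider_id="P1",
             start_date=pd.Timestamp("2018-04-01"), end_date=pd.NaT,
             valtype_cd="", nval_num=float("nan"), tval_char="",
             units_cd="", instance_num=2),
    ])
    patients = pd.DataFrame([
        dict(patient_num=1, birth_date=pd.Timestamp("2000-01-01"),
             death_date=pd.NaT, sex_cd="F", race_cd="WH",
             ethnicity_cd="N"),
        dict(patient_num=2, birth_date=pd.Timestamp("1990-06-15"),
             death_date=pd.NaT, sex_cd="M", race_cd="X9",
             ethnicity_cd="H"),
    ])
    visits = pd.DataFrame([
        dict(encounter_num=1, patient_num=1,
             start_date=pd.Timestamp("2018-03-01"), end_date=pd.NaT,
             inout_cd="O", location_cd="SITE_A"),
        dict(encounter_num=2, patient_num=2,
             start_date=pd.Timestamp("2018-04-01"),
             end_date=pd.Timestamp("2018-04-03"), inout_cd="I",
             location_cd="SITE_B"),
    ])
    providers = pd.DataFrame([
        dict(provider_id="P1", provider_name="Provider 1",
             provider_path="\\Providers\\P1\\"),
    ])
    return m.I2b2Repository(facts, patients, visits, providers)
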