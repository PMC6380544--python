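"""Deterministic synthetic inputs: vocabulary, ontology, crosswalks and a
demo patient population.

No deposited dataset is required to run the pipeline: this module
generates every input it needs. The vocabulary fixture embeds the known
reference mappings (ICD-9 250 is OMOP concept 44833365; ICD-9 463 is
44821975; ICD-9 V37.0 maps to three SNOMED concepts for multiple birth,
live birth and stillbirth; childhood obesity splits across the condition
and observation domains; a vaccine diagnosis code routes to the procedure
table) plus planted codes with no mapping, so the unmapped report and
1:n splitting behaviour are exercised end to end. Synthetic concept ids
live in a reserved range (>= 2,000,000,000) so they cannot collide with
real OMOP ids.

The demo population emulates the shape of an i2b2 demo database: 133
fake patients whose age at first observation peaks in the late 20s with
an age-0 newborn cohort, balanced sexes, all races represented, monthly
event volume growing to the refresh date, and every patient carrying at
least one event — i.e. exactly the features the QA checklist inspects.
Adversarial variants each break one and only one checklist item.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .star_schema import (I2b2Repository, write_repository)
from .transform import Crosswalks, crosswalks_to_frame

SYNTHETIC_ID_BASE = 2_000_000_000

VARIANTS = ("uniform_ages", "all_male", "missing_race", "stale_visits",
            "empty_drug")

RACE_NAMES = {8527: "White", 8516: "Black or African American",
              8515: "Asian", 8657: "American Indian or Alaska Native"}


@dataclass
class FixtureConfig:
    """Study conditions of the synthetic demo population."""

    n_patients: int = 133
    seed: int = 20190212
    start_year: int = 2016
    refresh_date: str = "2018-12-31"
    monthly_growth: float = 0.04
    female_share: float = 0.5
    race_distribution: dict[str, float] = field(default_factory=lambda: {
        "WH": 0.60, "BL": 0.20, "AS": 0.12, "AI": 0.08})
    ethnicity_distribution: dict[str, float] = field(default_factory=lambda: {
        "N": 0.85, "H": 0.15})
    visits_per_patient: float = 24.0
    death_fraction: float = 0.04
    infant_share: float = 0.12
    age_mode: int = 28
    age_sd: float = 8.0
    elder_share: float = 0.15

    def validate(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        for name in ("female_share", "death_fraction", "infant_share",
                     "elder_share", "monthly_growth"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for dist in (self.race_distribution, self.ethnicity_distribution):
            if abs(sum(dist.values()) - 1.0) > 1e-9:
                raise ValueError("category weights must sum to 1")


@dataclass
class VocabularyBundle:
    """Everything besides the patient data: concept dictionary, mapping
    table, ARCH-style ontology, valueset and modifier crosswalks."""

    concepts: pd.DataFrame
    mappings: pd.DataFrame
    ontology: pd.DataFrame
    crosswalks: Crosswalks
    modifier_crosswalk: pd.DataFrame
    catalogs: dict[str, list[str]]       # tree -> fact-generation basecodes
    planted_unmapped: list[str]


# ---------------------------------------------------------------------------
# vocabulary / ontology fixture

_GENERIC_CONDITIONS = [
    ("401.9", "Essential hypertension"),
    ("272.4", "Hyperlipidemia"),
    ("530.81", "Esophageal reflux"),
    ("493.90", "Asthma, unspecified"),
    ("311", "Depressive disorder"),
    ("244.9", "Hypothyroidism"),
    ("285.9", "Anemia, unspecified"),
    ("300.00", "Anxiety state"),
    ("414.01", "Coronary atherosclerosis"),
    ("427.31", "Atrial fibrillation"),
    ("486", "Pneumonia, organism unspecified"),
    ("599.0", "Urinary tract infection"),
    ("715.90", "Osteoarthrosis, unspecified"),
    ("780.79", "Malaise and fatigue"),
    ("723.1", "Cervicalgia"),
    ("724.2", "Lumbago"),
    ("786.2", "Cough"),
]

_OBSERVATION_VCODES = [
    ("V15.82", "History of tobacco use"),
    ("V58.69", "Long-term use of other medications"),
    ("V70.0", "Routine general medical examination"),
    ("V16.3", "Family history of malignant neoplasm of breast"),
]

_CPT_PROCEDURES = [
    ("99213", "Office visit, established patient, level 3"),
    ("99214", "Office visit, established patient, level 4"),
    ("93000", "Electrocardiogram, routine"),
    ("71020", "Chest X-ray, two views"),
    ("80053", "Comprehensive metabolic panel collection"),
    ("36415", "Routine venipuncture"),
    ("45378", "Colonoscopy, diagnostic"),
    ("77067", "Screening mammography, bilateral"),
    ("29881", "Knee arthroscopy with meniscectomy"),
    ("66984", "Cataract extraction with IOL insertion"),
    ("43239", "Upper GI endoscopy with biopsy"),
    ("20610", "Arthrocentesis, major joint"),
    ("12001", "Simple wound repair, 2.5 cm or less"),
    ("94010", "Spirometry"),
    ("92557", "Comprehensive audiometry"),
    ("59400", "Routine obstetric care, vaginal delivery"),
    ("27447", "Total knee arthroplasty"),
    ("47562", "Laparoscopic cholecystectomy"),
    ("10060", "Incision and drainage of abscess"),
]

_RXNORM_DRUGS = [
    ("617314", "atorvastatin 20 MG Oral Tablet"),
    ("197361", "lisinopril 10 MG Oral Tablet"),
    ("860975", "metformin 500 MG Oral Tablet"),
    ("197517", "levothyroxine 50 UG Oral Tablet"),
    ("308136", "amlodipine 5 MG Oral Tablet"),
    ("312961", "simvastatin 20 MG Oral Tablet"),
    ("310965", "ibuprofen 200 MG Oral Tablet"),
    ("198440", "omeprazole 20 MG Oral Capsule"),
    ("312615", "sertraline 50 MG Oral Tablet"),
    ("197696", "metoprolol 50 MG Oral Tablet"),
    ("308182", "amoxicillin 500 MG Oral Capsule"),
    ("197885", "losartan 50 MG Oral Tablet"),
    ("199026", "gabapentin 300 MG Oral Capsule"),
    ("567645", "albuterol 0.09 MG/ACTUAT inhaler"),
    ("855332", "warfarin 5 MG Oral Tablet"),
    ("309362", "clopidogrel 75 MG Oral Tablet"),
    ("311671", "prednisone 10 MG Oral Tablet"),
    ("313782", "tramadol 50 MG Oral Tablet"),
]

_NDC_DRUGS = [  # non-standard NDC packages mapping to RxNorm products
    ("00093505698", "hydrochlorothiazide 25 MG package",
     "310798", "hydrochlorothiazide 25 MG Oral Tablet"),
    ("00378395205", "furosemide 40 MG package",
     "310429", "furosemide 40 MG Oral Tablet"),
    ("68180051301", "escitalopram 10 MG package",
     "351250", "escitalopram 10 MG Oral Tablet"),
]

_LOINC_LABS = [
    ("2345-7", "Glucose, serum"),
    ("2160-0", "Creatinine, serum"),
    ("718-7", "Hemoglobin"),
    ("4544-3", "Hematocrit"),
    ("6690-2", "Leukocytes"),
    ("777-3", "Platelets"),
    ("2951-2", "Sodium, serum"),
    ("2823-3", "Potassium, serum"),
    ("2075-0", "Chloride, serum"),
    ("2028-9", "Carbon dioxide, serum"),
    ("3094-0", "Urea nitrogen, serum"),
    ("1742-6", "Alanine aminotransferase"),
    ("1920-8", "Aspartate aminotransferase"),
    ("1975-2", "Bilirubin, total"),
    ("2885-2", "Protein, total"),
    ("1751-7", "Albumin, serum"),
    ("2093-3", "Cholesterol, total"),
    ("2571-8", "Triglycerides"),
    ("2085-9", "HDL cholesterol"),
    ("13457-7", "LDL cholesterol, calculated"),
]

_VITALS = [
    ("VITAL:HT", "Body height", 3036277, "cm"),
    ("VITAL:WT", "Body weight", 3025315, "kg"),
    ("VITAL:SBP", "Systolic blood pressure", 3004249, "mmHg"),
    ("VITAL:DBP", "Diastolic blood pressure", 3012888, "mmHg"),
]

#: planted codes absent from the concept dictionary, in the spirit of an
#: unmapped-code report: an over-the-counter drug combination, a retired
#: procedure code, a local E-code
_PLANTED_UNMAPPED = [
    ("Diagnosis", "ICD9:E849.7", "Accident, residential institution "
                                 "(local extension)"),
    ("Procedure", "CPT:0058T", "Cryopreservation of ovarian tissue "
                               "(retired)"),
    ("Medication", "NDC:99999000101", "Cold-and-flu combination, "
                                      "over-the-counter"),
]

_ACTIVE_MODIFIERS = [
    ("MOD:REFILLS", "Medication refills"),
    ("MOD:QUANTITY", "Quantity"),
    ("MOD:SUPPLY", "Days supply"),
    ("MOD:RXSOURCE", "Prescribed vs dispensed vs administered"),
    ("MOD:ROUTE", "Route of administration"),
    ("MOD:FREQUENCY", "Dose frequency"),
    ("MOD:DOSEUNIT", "Dose unit"),
    ("MOD:DOSEFORM", "Dose form"),
]
_INACTIVE_MODIFIERS = [
    ("MOD:INFUSIONRATE", "Infusion rate"),
    ("MOD:STRENGTH", "Drug strength"),
]

_MODIFIER_CROSSWALK = (
    [("Medication", m, "equivalent")
     for m in ("Medication refill", "Quantity", "Supply")] +
    [("Medication", m, "valueset_differs")
     for m in ("Prescribing vs dispensed source", "Route of administration",
               "Dose frequency", "Dose unit")] +
    [("Medication", m, "single_model")
     for m in ("Dispensed through mail order", "Physician administered drug",
               "Drug strength", "Infusion rate", "Lot number",
               "Stop reason", "Sig text", "Refills authorized vs dispensed",
               "Brand vs generic indicator", "Pharmacy identifier")] +
    [("Diagnosis", m, "single_model")
     for m in ("Condition status", "Stop reason", "Provider attribution")] +
    [("Labs", m, "single_model")
     for m in ("Specimen source", "Result operator", "Normal range low",
               "Normal range high", "Abnormal flag")]
)


def generate_vocabulary_fixture() -> VocabularyBundle:
    """Build the deterministic mini vocabulary, ontology and crosswalks."""
    concepts: list[dict] = []
    mappings: list[dict] = []
    counter = [SYNTHETIC_ID_BASE]

    def new_id() -> int:
        counter[0] += 1
        return counter[0]

    def add_concept(concept_id, code, vocab, domain, name, standard):
        concepts.append({
            "concept_id": concept_id, "concept_code": code,
            "vocabulary_id": vocab, "domain_id": domain,
            "concept_name": name,
            "standard_concept": "S" if standard else ""})
        return concept_id

    def add_source_with_targets(code, vocab, src_domain, name,
                                targets, source_id=None):
        sid = add_concept(source_id or new_id(), code, vocab, src_domain,
                          name, False)
        for t_domain, t_name in targets:
            tid = add_concept(new_id(), f"SCT-{counter[0]}", "SNOMED",
                              t_domain, t_name, True)
            mappings.append({"source_concept_id": sid,
                             "target_concept_id": tid})
        return sid

    def add_standard(code, vocab, domain, name):
        sid = add_concept(new_id(), code, vocab, domain, name, True)
        mappings.append({"source_concept_id": sid,
                         "target_concept_id": sid})
        return sid

    # reference anchors with their published OMOP concept numbers
    add_source_with_targets("250", "ICD9CM", "Condition",
                            "Diabetes mellitus",
                            [("Condition", "Diabetes mellitus (disorder)")],
                            source_id=44833365)
    add_source_with_targets("463", "ICD9CM", "Condition",
                            "Acute tonsillitis",
                            [("Condition", "Acute tonsillitis (disorder)")],
                            source_id=44821975)
    add_source_with_targets(
        "V85.54", "ICD9CM", "Condition",
        "BMI, pediatric, >=95th percentile (childhood obesity)",
        [("Condition", "Childhood obesity (disorder)"),
         ("Observation", "Weight greater than 97th percentile for age")])
    add_source_with_targets(
        "V37.0", "ICD9CM", "Condition",
        "Other multiple, mates liveborn and stillborn, born in hospital",
        [("Observation", "Multiple birth"),
         ("Observation", "Live birth"),
         ("Observation", "Stillbirth")])
    add_source_with_targets(
        "V04.81", "ICD9CM", "Condition",
        "Need for prophylactic vaccination, influenza",
        [("Procedure", "Influenza vaccination")])
    for code, name in _GENERIC_CONDITIONS:
        add_source_with_targets(code, "ICD9CM", "Condition", name,
                                [("Condition", f"{name} (disorder)")])
    for code, name in _OBSERVATION_VCODES:
        add_source_with_targets(code, "ICD9CM", "Condition", name,
                                [("Observation", name)])
    for code, name in _CPT_PROCEDURES:
        add_standard(code, "CPT4", "Procedure", name)
    for code, name in _RXNORM_DRUGS:
        add_standard(code, "RxNorm", "Drug", name)
    for ndc, ndc_name, rx_code, rx_name in _NDC_DRUGS:
        rx_id = add_standard(rx_code, "RxNorm", "Drug", rx_name)
        ndc_id = add_concept(new_id(), ndc, "NDC", "Drug", ndc_name, False)
        mappings.append({"source_concept_id": ndc_id,
                         "target_concept_id": rx_id})
    for code, name in _LOINC_LABS:
        add_standard(code, "LOINC", "Measurement", name)

    # valueset-crosswalk targets (standard demographic/visit/vital concepts)
    for cid, code, vocab, domain, name in [
            (8507, "M", "Gender", "Gender", "MALE"),
            (8532, "F", "Gender", "Gender", "FEMALE"),
            (8527, "5", "Race", "Race", RACE_NAMES[8527]),
            (8516, "3", "Race", "Race", RACE_NAMES[8516]),
            (8515, "2", "Race", "Race", RACE_NAMES[8515]),
            (8657, "1", "Race", "Race", RACE_NAMES[8657]),
            (38003563, "Hispanic", "Ethnicity", "Ethnicity", "Hispanic"),
            (38003564, "Not Hispanic", "Ethnicity", "Ethnicity",
             "Not Hispanic"),
            (9201, "IP", "Visit", "Visit", "Inpatient Visit"),
            (9202, "OP", "Visit", "Visit", "Outpatient Visit"),
            (9203, "ER", "Visit", "Visit", "Emergency Room Visit"),
            (3036277, "8302-2", "LOINC", "Measurement", "Body height"),
            (3025315, "29463-7", "LOINC", "Measurement", "Body weight"),
            (3004249, "8480-6", "LOINC", "Measurement",
             "Systolic blood pressure"),
            (3012888, "8462-4", "LOINC", "Measurement",
             "Diastolic blood pressure")]:
        add_concept(cid, code, vocab, domain, name, True)

    concepts_df = pd.DataFrame(concepts)
    concepts_df["standard"] = concepts_df["standard_concept"].eq("S")
    mappings_df = pd.DataFrame(mappings)

    ontology = _build_ontology()
    crosswalks = Crosswalks(
        sex={"F": 8532, "M": 8507},
        race={"WH": 8527, "BL": 8516, "AS": 8515, "AI": 8657},
        ethnicity={"H": 38003563, "N": 38003564},
        encounter={"I": 9201, "O": 9202, "E": 9203},
        vitals={code: cid for code, _, cid, _ in _VITALS},
    )
    modifier_crosswalk = pd.DataFrame(
        _MODIFIER_CROSSWALK, columns=["domain", "modifier_name", "status"])

    catalogs = {
        "Diagnosis": (["ICD9:250", "ICD9:463", "ICD9:V85.54", "ICD9:V37.0",
                       "ICD9:V04.81"]
                      + [f"ICD9:{c}" for c, _ in _GENERIC_CONDITIONS]
                      + [f"ICD9:{c}" for c, _ in _OBSERVATION_VCODES]
                      + ["ICD9:E849.7"]),
        "Procedure": [f"CPT:{c}" for c, _ in _CPT_PROCEDURES]
                     + ["CPT:0058T"],
        "Medication": [f"RXNORM:{c}" for c, _ in _RXNORM_DRUGS]
                      + [f"NDC:{c}" for c, *_ in _NDC_DRUGS]
                      + ["NDC:99999000101"],
        "Labs": [f"LOINC:{c}" for c, _ in _LOINC_LABS],
        "Vitals": [code for code, *_ in _VITALS],
    }
    return VocabularyBundle(
        concepts=concepts_df, mappings=mappings_df, ontology=ontology,
        crosswalks=crosswalks, modifier_crosswalk=modifier_crosswalk,
        catalogs=catalogs,
        planted_unmapped=[c for _, c, _ in _PLANTED_UNMAPPED])


def _build_ontology() -> pd.DataFrame:
    rows: list[dict] = []

    def add(path, basecode="", name="", active=True, is_modifier=False,
            applied_path=""):
        parts = [p for p in path.split("\\") if p]
        rows.append({"path": path, "basecode": basecode,
                     "name": name or parts[-1], "level": len(parts) - 1,
                     "omop_concept_id": "", "active": str(active).lower(),
                     "is_modifier": str(is_modifier).lower(),
                     "modifier_applied_path": applied_path})

    add("\\Diagnosis\\")
    add("\\Diagnosis\\Reference\\")
    add("\\Diagnosis\\Reference\\ICD9 250\\", "ICD9:250",
        "Diabetes mellitus")
    add("\\Diagnosis\\Reference\\ICD9 463\\", "ICD9:463",
        "Acute tonsillitis")
    add("\\Diagnosis\\Reference\\ICD9 V85.54\\", "ICD9:V85.54",
        "Childhood obesity")
    add("\\Diagnosis\\Reference\\ICD9 V37.0\\", "ICD9:V37.0",
        "Other multiple, mates liveborn and stillborn")
    add("\\Diagnosis\\Reference\\ICD9 V04.81\\", "ICD9:V04.81",
        "Need for prophylactic vaccination, influenza")
    add("\\Diagnosis\\Conditions\\")
    for code, name in _GENERIC_CONDITIONS:
        add(f"\\Diagnosis\\Conditions\\ICD9 {code}\\", f"ICD9:{code}", name)
    add("\\Diagnosis\\Status\\")
    for code, name in _OBSERVATION_VCODES:
        add(f"\\Diagnosis\\Status\\ICD9 {code}\\", f"ICD9:{code}", name)
    add("\\Diagnosis\\Local\\")
    add("\\Diagnosis\\Local\\ICD9 E849.7\\", "ICD9:E849.7",
        _PLANTED_UNMAPPED[0][2])

    add("\\Procedure\\")
    add("\\Procedure\\CPT\\")
    for code, name in _CPT_PROCEDURES:
        add(f"\\Procedure\\CPT\\CPT {code}\\", f"CPT:{code}", name)
    add("\\Procedure\\CPT\\CPT 0058T\\", "CPT:0058T",
        _PLANTED_UNMAPPED[1][2])
    add("\\Procedure\\HCPCS\\", active=False)
    add("\\Procedure\\HCPCS\\HCPCS E0601\\", "HCPCS:E0601",
        "CPAP device", active=False)
    add("\\Procedure\\HCPCS\\HCPCS A4253\\", "HCPCS:A4253",
        "Blood glucose test strips", active=False)

    add("\\Medication\\")
    add("\\Medication\\RxNorm\\")
    for code, name in _RXNORM_DRUGS:
        add(f"\\Medication\\RxNorm\\RXNORM {code}\\", f"RXNORM:{code}", name)
    add("\\Medication\\NDC\\")
    for ndc, ndc_name, *_ in _NDC_DRUGS:
        add(f"\\Medication\\NDC\\NDC {ndc}\\", f"NDC:{ndc}", ndc_name)
    add("\\Medication\\NDC\\NDC 99999000101\\", "NDC:99999000101",
        _PLANTED_UNMAPPED[2][2])
    add("\\Medication\\Modifiers\\")
    for basecode, name in _ACTIVE_MODIFIERS:
        add(f"\\Medication\\Modifiers\\{name}\\", basecode, name,
            is_modifier=True, applied_path="\\Medication\\")
    for basecode, name in _INACTIVE_MODIFIERS:
        add(f"\\Medication\\Modifiers\\{name}\\", basecode, name,
            active=False, is_modifier=True, applied_path="\\Medication\\")

    add("\\Labs\\")
    add("\\Labs\\LOINC\\")
    for code, name in _LOINC_LABS:
        add(f"\\Labs\\LOINC\\LOINC {code}\\", f"LOINC:{code}", name)

    add("\\Vitals\\")
    for code, name, _, _ in _VITALS:
        add(f"\\Vitals\\{name}\\", code, name)
    add("\\Demographics\\")
    add("\\Encounter\\")

    df = pd.DataFrame(rows)
    df["active"] = df["active"].eq("true")
    df["is_modifier"] = df["is_modifier"].eq("true")
    df["omop_concept_id"] = pd.Series([pd.NA] * len(df), dtype="Int64")
    return df


# ---------------------------------------------------------------------------
# population generator

def _largest_remainder(weights: np.ndarray, total: int) -> np.ndarray:
    """Integer allocation of ``total`` proportional to ``weights``."""
    weights = np.asarray(weights, dtype=float)
    if weights.sum() == 0 or total == 0:
        return np.zeros(len(weights), dtype=int)
    quota = weights / weights.sum() * total
    counts = np.floor(quota).astype(int)
    short = total - counts.sum()
    order = np.argsort(-(quota - counts), kind="stable")
    counts[order[:short]] += 1
    return counts


def _age_histogram(config: FixtureConfig, n_adults: int) -> np.ndarray:
    """Unimodal adult age histogram peaking at ``age_mode``.

    Counts are allocated by largest remainder against a normal-plus-
    elder-tail density, then laid out as a tent around the mode
    (largest count at the mode, alternating outward), which guarantees
    the decline past the peak is monotone — the shape the QA age check
    expects — for any n.
    """
    ages = np.arange(1, 86)
    density = np.exp(-0.5 * ((ages - config.age_mode) / config.age_sd) ** 2)
    density = ((1 - config.elder_share) * density / density.sum()
               + config.elder_share * ((ages >= 40) & (ages <= 85))
               / 46.0)
    counts = np.sort(_largest_remainder(density, n_adults))[::-1]
    hist = np.zeros(111, dtype=int)
    left, right = config.age_mode - 1, config.age_mode
    for c in counts:
        if c == 0:
            break
        if right <= 110 and (right - config.age_mode <=
                             config.age_mode - left or left < 1):
            hist[right] += c
            right += 1
        else:
            hist[left] += c
            left -= 1
    return hist


def _spawn(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng([seed & 0x7FFFFFFF, stream])


def generate_population(config: FixtureConfig | None = None,
                        bundle: VocabularyBundle | None = None,
                        variant: str | None = None) -> I2b2Repository:
    """Generate the demo i2b2 repository (133 fake patients by default).

    Fully reproducible from ``config.seed``; independent random streams
    drive each aspect (ages, sex, race, visits, codes, values, deaths) so
    an adversarial ``variant`` perturbs exactly one aspect.
    """
    config = config or FixtureConfig()
    config.validate()
    if variant is not None and variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}; "
                         f"choose from {VARIANTS}")
    bundle = bundle or generate_vocabulary_fixture()
    n = config.n_patients
    seed = config.seed
    refresh = pd.Timestamp(config.refresh_date)
    start = pd.Timestamp(year=config.start_year, month=1, day=1)
    months = pd.period_range(start, refresh, freq="M")
    n_months = len(months)

    # --- ages -------------------------------------------------------------
    rng_ages = _spawn(seed, 1)
    if variant == "uniform_ages":
        age_list = [a % 80 for a in range(n)]
    else:
        n_infants = int(round(n * config.infant_share)) if n > 1 else 0
        hist = _age_histogram(config, n - n_infants)
        age_list = [0] * n_infants + [a for a in range(111)
                                      for _ in range(hist[a])]
    ages = np.array(age_list)
    rng_ages.shuffle(ages)

    # --- sex / race / ethnicity -------------------------------------------
    rng_sex = _spawn(seed, 2)
    n_female = int(round(n * config.female_share))
    sexes = np.array(["F"] * n_female + ["M"] * (n - n_female))
    rng_sex.shuffle(sexes)
    if variant == "all_male":
        sexes = np.array(["M"] * n)

    rng_race = _spawn(seed, 3)
    race_codes = list(config.race_distribution)
    race_counts = _largest_remainder(
        np.array(list(config.race_distribution.values())), n)
    races = np.array([c for c, k in zip(race_codes, race_counts)
                      for _ in range(k)])
    rng_race.shuffle(races)
    if variant == "missing_race":
        races = np.where(races == "AI", "WH", races)

    eth_codes = list(config.ethnicity_distribution)
    eth_counts = _largest_remainder(
        np.array(list(config.ethnicity_distribution.values())), n)
    ethnicities = np.array([c for c, k in zip(eth_codes, eth_counts)
                            for _ in range(k)])
    rng_race.shuffle(ethnicities)

    # --- patient entry dates and births -----------------------------------
    rng_entry = _spawn(seed, 4)
    entry_months = rng_entry.integers(0, min(12, n_months), size=n)
    entry_months[0] = 0  # the enrollment window always opens with a patient
    entry_days = rng_entry.integers(1, 29, size=n)
    entry_dates = [months[m].to_timestamp()
                   + pd.Timedelta(days=int(d) - 1)
                   for m, d in zip(entry_months, entry_days)]
    birth_offsets = rng_entry.integers(20, 341, size=n)
    births = [e - pd.Timedelta(days=int(round(365.25 * a)) + int(u))
              for e, a, u in zip(entry_dates, ages, birth_offsets)]

    # --- visits ------------------------------------------------------------
    rng_visits = _spawn(seed, 5)
    rng_types = _spawn(seed, 6)
    total_visits = max(n, int(round(n * config.visits_per_patient)))
    growth = (1.0 + config.monthly_growth) ** np.arange(n_months)
    month_quota = _largest_remainder(growth, total_visits)
    providers = [f"PRV{i:03d}" for i in range(1, 6)]
    locations = ["SITE_A", "SITE_B", "SITE_C"]

    visit_rows: list[dict] = []
    encounter = 0
    stale_cutoff = max(0, n_months - 25)  # variant: no recent ER visits
    for m in range(n_months):
        entrants = [i for i in range(n) if entry_months[i] == m]
        k = max(int(month_quota[m]), len(entrants))
        extra = rng_visits.integers(0, n, size=max(k - len(entrants), 0))
        entered = np.flatnonzero(entry_months <= m)
        patients_m = entrants + [int(entered[j % len(entered)])
                                 for j in extra]
        for slot, i in enumerate(patients_m):
            encounter += 1
            month_start = months[m].to_timestamp()
            if slot < len(entrants):
                date = entry_dates[i]
            else:
                lo = int(entry_days[i]) if entry_months[i] == m else 1
                day = int(rng_visits.integers(lo, 29))
                date = month_start + pd.Timedelta(days=day - 1)
            inout = str(rng_types.choice(["O", "I", "E"],
                                         p=[0.70, 0.15, 0.15]))
            if variant == "stale_visits" and inout == "E" \
                    and m >= stale_cutoff:
                inout = "O"
            end = (date + pd.Timedelta(days=int(rng_types.integers(1, 6)))
                   if inout == "I" else pd.NaT)
            visit_rows.append({
                "encounter_num": encounter, "patient_num": i + 1,
                "start_date": date, "end_date": end, "inout_cd": inout,
                "location_cd": locations[encounter % len(locations)],
                "provider_id": providers[encounter % len(providers)],
            })
    # make sure every non-stale visit type reaches the refresh month
    recent_types = ["O", "I"] if variant == "stale_visits" \
        else ["O", "I", "E"]
    for j, inout in enumerate(recent_types):
        visit_rows[-1 - j]["inout_cd"] = inout
        visit_rows[-1 - j]["end_date"] = pd.NaT
    if variant == "stale_visits":
        # the ER stream exists but went quiet two years before the refresh
        visit_rows[0]["inout_cd"] = "E"

    # --- facts -------------------------------------------------------------
    rng_codes = _spawn(seed, 7)
    rng_values = _spawn(seed, 8)
    catalogs = {t: list(v) for t, v in bundle.catalogs.items()}
    if variant == "empty_drug":
        catalogs["Medication"] = [catalogs["Medication"][0]]
    counters = {t: 0 for t in catalogs}

    def next_code(tree: str) -> str:
        cat = catalogs[tree]
        i = counters[tree]
        counters[tree] += 1
        if i < len(cat):
            return cat[i]           # coverage pass: cycle the catalog once
        return str(rng_codes.choice(cat))

    fact_rows: list[dict] = []

    def add_fact(visit, code, instance, modifier="@", valtype="",
                 nval=None, units="", end=pd.NaT):
        fact_rows.append({
            "patient_num": visit["patient_num"],
            "encounter_num": visit["encounter_num"],
            "concept_cd": code, "modifier_cd": modifier,
            "provider_id": visit["provider_id"],
            "start_date": visit["start_date"], "end_date": end,
            "valtype_cd": valtype, "nval_num": nval, "tval_char": "",
            "units_cd": units, "instance_num": instance,
        })

    vital_values = {"VITAL:HT": (168.0, 10.0, "cm"),
                    "VITAL:WT": (75.0, 15.0, "kg"),
                    "VITAL:SBP": (122.0, 14.0, "mmHg"),
                    "VITAL:DBP": (78.0, 9.0, "mmHg")}
    for v_index, visit in enumerate(visit_rows):
        instance = 0
        for _ in range(2):
            instance += 1
            add_fact(visit, next_code("Diagnosis"), instance)
        if rng_codes.random() < 0.85:
            instance += 1
            add_fact(visit, next_code("Procedure"), instance)
        if rng_codes.random() < 0.90:
            instance += 1
            med = next_code("Medication")
            med_end = visit["start_date"] + pd.Timedelta(
                days=int(rng_values.integers(5, 31)))
            add_fact(visit, med, instance, end=med_end)
            if rng_codes.random() < 0.5:
                add_fact(visit, med, instance, modifier="MOD:REFILLS",
                         valtype="N",
                         nval=float(rng_values.integers(0, 6)), end=med_end)
                add_fact(visit, med, instance, modifier="MOD:SUPPLY",
                         valtype="N", nval=30.0, end=med_end)
        for _ in range(2):
            instance += 1
            add_fact(visit, next_code("Labs"), instance, valtype="N",
                     nval=float(np.round(rng_values.lognormal(3.0, 0.6), 1)),
                     units="U/L")
        instance += 1
        vital = next_code("Vitals")
        mean, sd, unit = vital_values[vital]
        add_fact(visit, vital, instance, valtype="N",
                 nval=float(np.round(rng_values.normal(mean, sd), 1)),
                 units=unit)

    facts = pd.DataFrame(fact_rows)
    facts["nval_num"] = facts["nval_num"].astype(float)

    # --- deaths ------------------------------------------------------------
    rng_death = _spawn(seed, 9)
    n_dead = int(round(n * config.death_fraction))
    dead = sorted(rng_death.choice(n, size=n_dead, replace=False))
    last_event = facts.groupby("patient_num")["start_date"].max()
    death_dates = [pd.NaT] * n
    for i in dead:
        death_dates[i] = (last_event[i + 1]
                          + pd.Timedelta(days=int(rng_death.integers(1, 61))))

    patients = pd.DataFrame({
        "patient_num": np.arange(1, n + 1, dtype="int64"),
        "birth_date": births,
        "death_date": death_dates,
        "sex_cd": sexes, "race_cd": races, "ethnicity_cd": ethnicities,
    })
    visits = pd.DataFrame(visit_rows)[
        ["encounter_num", "patient_num", "start_date", "end_date",
         "inout_cd", "location_cd"]]
    visits = visits.astype({"encounter_num": "int64",
                            "patient_num": "int64"})
    provider_dim = pd.DataFrame({
        "provider_id": providers,
        "provider_name": [f"Provider {p[-3:]}" for p in providers],
        "provider_path": [f"\\Providers\\{p}\\" for p in providers],
    })
    return I2b2Repository(facts=facts, patients=patients, visits=visits,
                          providers=provider_dim)


def generate_adversarial_variants(config: FixtureConfig,
                                  variant: str) -> I2b2Repository:
    """Default population with exactly one planted QA defect."""
    return generate_population(config, variant=variant)


# ---------------------------------------------------------------------------
# bundle writer

ONTOLOGY_FILE = "ontology.csv"
CONCEPT_FILE = "concept.csv"
RELATIONSHIP_FILE = "concept_relationship.csv"
CROSSWALK_FILE = "valueset_crosswalks.csv"
MODIFIER_FILE = "modifier_crosswalk.csv"


def write_fixture_bundle(directory: str | Path,
                         config: FixtureConfig | None = None,
                         variant: str | None = None) -> dict:
    """Write population + vocabulary + ontology + crosswalk files.

    Emits exactly the CSV dialects the reader modules expect; returns a
    manifest of files and row counts (also stored as JSON).
    """
    config = config or FixtureConfig()
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    bundle = generate_vocabulary_fixture()
    repo = generate_population(config, bundle, variant=variant)

    manifest = write_repository(repo, directory)
    ont = bundle.ontology.copy()
    ont["active"] = ont["active"].map({True: "true", False: "false"})
    ont["is_modifier"] = ont["is_modifier"].map({True: "true",
                                                 False: "false"})
    ont["omop_concept_id"] = ont["omop_concept_id"].astype(object).fillna("")
    ont.to_csv(directory / ONTOLOGY_FILE, index=False, lineterminator="\n")
    manifest[ONTOLOGY_FILE] = len(ont)

    concepts = bundle.concepts.drop(columns=["standard"])
    concepts.to_csv(directory / CONCEPT_FILE, index=False,
                    lineterminator="\n")
    manifest[CONCEPT_FILE] = len(concepts)

    rel = bundle.mappings.rename(columns={
        "source_concept_id": "concept_id_1",
        "target_concept_id": "concept_id_2"})
    rel["relationship_id"] = "Maps to"
    rel.to_csv(directory / RELATIONSHIP_FILE, index=False,
               lineterminator="\n")
    manifest[RELATIONSHIP_FILE] = len(rel)

    xw = crosswalks_to_frame(bundle.crosswalks)
    xw.to_csv(directory / CROSSWALK_FILE, index=False, lineterminator="\n")
    manifest[CROSSWALK_FILE] = len(xw)

    bundle.modifier_crosswalk.to_csv(directory / MODIFIER_FILE, index=False,
                                     lineterminator="\n")
    manifest[MODIFIER_FILE] = len(bundle.modifier_crosswalk)

    with open(directory / "fixture_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
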