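"""Multi-pass i2b2-to-OMOP transformation.

The engine materializes the All Of Us subset of OMOP CDM tables from an
i2b2 star schema in a fixed order: direct table copies (provider,
care_site, death), valueset-mapped tables (person, visit_occurrence,
vitals), concept-dictionary-mapped coded passes (Diagnosis, Procedure,
Medication, Labs trees), then the computed tables (observation_period,
drug_era, condition_era). Coded facts are routed by the *domain* of each
resolved standard concept, so a single source code may write rows to
several tables (1:n cross-domain splitting).

Pass accounting: the engine runs once per (source tree, target table)
pair. Each primary fact is homed to exactly one pass — the table of its
lowest-id resolved target, or the tree's conventional table when
unmapped — so per-pass conservation (rows_in = contributing + unmapped)
holds and the rows_in of a tree's passes sum to its primary fact count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .ontology import (DEFAULT_TREE_TABLE, MappingResolution,
                       resolve_standard_concepts, tree_of)
from .star_schema import NO_MODIFIER, I2b2Repository

log = logging.getLogger(__name__)

#: OMOP "EHR" record-provenance concept
EHR_TYPE_CONCEPT = 32817

CODED_TREES = ["Diagnosis", "Procedure", "Medication", "Labs"]

EVENT_COLUMNS = ["row_id", "person_id", "visit_occurrence_id", "concept_id",
                 "source_concept_id", "source_value", "start_date",
                 "end_date", "type_concept_id", "value_as_number",
                 "value_as_string", "unit_source_value"]
DRUG_COLUMNS = EVENT_COLUMNS + ["refills", "quantity", "days_supply"]

#: modifier basecode -> drug_exposure column it populates (the three
#: modifiers that are equivalent between the ARCH and OMOP models)
MODIFIER_COLUMNS = {
    "MOD:REFILLS": "refills",
    "MOD:QUANTITY": "quantity",
    "MOD:SUPPLY": "days_supply",
}


@dataclass
class TransformConfig:
    """Tunable knobs of the transformation."""

    gap_days: int = 30              # era persistence window
    type_concept_id: int = EHR_TYPE_CONCEPT
    strict: bool = True


@dataclass
class TransformPass:
    """Row accounting for one (source tree, target table) pass."""

    source_tree: str
    target_table: str
    rows_in: int
    rows_out: int
    rows_unmapped: int


@dataclass
class TransformReport:
    passes: list[TransformPass] = field(default_factory=list)
    unmapped_codes: dict[str, int] = field(default_factory=dict)
    orphan_modifiers: int = 0
    row_counts: dict[str, int] = field(default_factory=dict)


@dataclass
class Crosswalks:
    """All Of Us-style valueset crosswalks for demographics, encounters
    and vitals (site code -> standard concept id)."""

    sex: dict[str, int]
    race: dict[str, int]
    ethnicity: dict[str, int]
    encounter: dict[str, int]
    vitals: dict[str, int]


def load_crosswalks(file: str | Path) -> Crosswalks:
    df = pd.read_csv(file, dtype=str, keep_default_na=False)
    df.columns = [c.strip().lower() for c in df.columns]
    out = {"sex": {}, "race": {}, "ethnicity": {}, "encounter": {},
           "vitals": {}}
    for _, row in df.iterrows():
        fld = row["field"]
        if fld not in out:
            raise ValueError(f"unknown crosswalk field {fld!r}")
        out[fld][row["source_value"]] = int(row["concept_id"])
    return Crosswalks(**out)


def crosswalks_to_frame(xw: Crosswalks) -> pd.DataFrame:
    rows = []
    for fld in ("sex", "race", "ethnicity", "encounter", "vitals"):
        for src, cid in getattr(xw, fld).items():
            rows.append({"field": fld, "source_value": src,
                         "concept_id": cid})
    return pd.DataFrame(rows, columns=["field", "source_value", "concept_id"])


def copy_dimension_tables(repo: I2b2Repository
                          ) -> dict[str, pd.DataFrame]:
    """Tables copied from i2b2 with no concept mapping.

    care_site rows come from the distinct visit locations, provider rows
    1:1 from provider_dimension, and death rows exactly from patients
    whose death_date is present.
    """
    locations = sorted({loc for loc in repo.visits["location_cd"] if loc})
    care_site = pd.DataFrame({
        "care_site_id": range(1, len(locations) + 1),
        "care_site_source_value": locations,
    })
    provider = repo.providers.rename(columns={
        "provider_path": "provider_source_value"})[
        ["provider_id", "provider_name", "provider_source_value"]].copy()
    dead = repo.patients[repo.patients["death_date"].notna()]
    death = pd.DataFrame({
        "person_id": dead["patient_num"].astype("int64"),
        "death_date": dead["death_date"],
    }).sort_values("person_id").reset_index(drop=True)
    return {"care_site": care_site, "provider": provider, "death": death}


def map_person(patients: pd.DataFrame, xw: Crosswalks) -> pd.DataFrame:
    """One person row per patient via the demographics valueset crosswalk.

    Site codes absent from the crosswalk get concept id 0 with the source
    value preserved (no silent data loss).
    """
    p = patients.sort_values("patient_num")
    person = pd.DataFrame({
        "person_id": p["patient_num"].astype("int64").values,
        "gender_concept_id": [xw.sex.get(c, 0) for c in p["sex_cd"]],
        "birth_datetime": p["birth_date"].values,
        "race_concept_id": [xw.race.get(c, 0) for c in p["race_cd"]],
        "ethnicity_concept_id": [xw.ethnicity.get(c, 0)
                                 for c in p["ethnicity_cd"]],
        "gender_source_value": p["sex_cd"].values,
        "race_source_value": p["race_cd"].values,
        "ethnicity_source_value": p["ethnicity_cd"].values,
    })
    return person.reset_index(drop=True)


def map_visits(visits: pd.DataFrame, xw: Crosswalks,
               config: TransformConfig | None = None) -> pd.DataFrame:
    """One visit_occurrence row per visit; missing end dates impute to
    the start date at transform time (the source file keeps them empty)."""
    config = config or TransformConfig()
    v = visits.sort_values("encounter_num")
    end = v["end_date"].fillna(v["start_date"])
    return pd.DataFrame({
        "visit_occurrence_id": v["encounter_num"].astype("int64").values,
        "person_id": v["patient_num"].astype("int64").values,
        "concept_id": [xw.encounter.get(c, 0) for c in v["inout_cd"]],
        "source_value": v["inout_cd"].values,
        "start_date": v["start_date"].values,
        "end_date": end.values,
        "type_concept_id": config.type_concept_id,
        "care_site_source_value": v["location_cd"].values,
    }).reset_index(drop=True)


def map_vitals(facts: pd.DataFrame, xw: Crosswalks,
               config: TransformConfig | None = None
               ) -> tuple[pd.DataFrame, TransformPass]:
    """Vitals facts -> measurement rows via the LOINC-equivalent crosswalk."""
    config = config or TransformConfig()
    sub = facts[(facts["modifier_cd"] == NO_MODIFIER) &
                facts["concept_cd"].str.startswith("VITAL:")]
    rows, unmapped = [], 0
    for f in sub.itertuples():
        concept = xw.vitals.get(f.concept_cd)
        if concept is None:
            unmapped += 1
            continue
        rows.append({
            "person_id": f.patient_num,
            "visit_occurrence_id": f.encounter_num,
            "concept_id": concept,
            "source_concept_id": 0,
            "source_value": f.concept_cd,
            "start_date": f.start_date,
            "end_date": f.end_date,
            "type_concept_id": config.type_concept_id,
            "value_as_number": f.nval_num,
            "value_as_string": f.tval_char or None,
            "unit_source_value": f.units_cd or None,
        })
    df = pd.DataFrame(rows, columns=[c for c in EVENT_COLUMNS
                                     if c != "row_id"])
    record = TransformPass("Vitals", "measurement", len(sub), len(df),
                           unmapped)
    return df, record


def _tree_basecodes(ontology: pd.DataFrame, tree: str) -> set[str]:
    leaves = ontology[(ontology["basecode"] != "") & ontology["active"] &
                      ~ontology["is_modifier"]]
    return {b for p, b in zip(leaves["path"], leaves["basecode"])
            if tree_of(p) == tree}


def map_coded_facts(facts: pd.DataFrame, tree: str, ontology: pd.DataFrame,
                    concepts: pd.DataFrame, mappings: pd.DataFrame,
                    config: TransformConfig | None = None
                    ) -> tuple[dict[str, list[dict]], list[TransformPass],
                               dict[str, int], int]:
    """One coded pass family: all facts of one source tree.

    Primary facts (modifier ``@``) seed one output row per resolved
    standard target; mapped modifier facts attach attributes to the rows
    of their parent fact; unmapped facts are counted and excluded.
    Returns (rows per table, pass records, unmapped tally, orphan
    modifier count).
    """
    config = config or TransformConfig()
    codes = _tree_basecodes(ontology, tree)
    sub = facts[facts["concept_cd"].isin(codes)]
    primary = sub[sub["modifier_cd"] == NO_MODIFIER]
    modifiers = sub[sub["modifier_cd"] != NO_MODIFIER]

    resolution: dict[str, MappingResolution] = {
        code: resolve_standard_concepts(code, concepts, mappings)
        for code in sorted(set(primary["concept_cd"]))}

    tables: dict[str, list[dict]] = {}
    homed_in: dict[str, int] = {}
    homed_unmapped: dict[str, int] = {}
    out_counts: dict[str, int] = {}
    unmapped_codes: dict[str, int] = {}
    fact_rows: dict[tuple, list[dict]] = {}

    for f in primary.itertuples():
        res = resolution[f.concept_cd]
        if res.unmapped:
            home = DEFAULT_TREE_TABLE.get(tree, "observation")
            homed_in[home] = homed_in.get(home, 0) + 1
            homed_unmapped[home] = homed_unmapped.get(home, 0) + 1
            unmapped_codes[f.concept_cd] = \
                unmapped_codes.get(f.concept_cd, 0) + 1
            continue
        home = res.targets[0][2]
        homed_in[home] = homed_in.get(home, 0) + 1
        key = (f.patient_num, f.encounter_num, f.concept_cd, f.provider_id,
               f.start_date, f.instance_num)
        for concept_id, domain, table in res.targets:
            row = {
                "person_id": f.patient_num,
                "visit_occurrence_id": f.encounter_num,
                "concept_id": concept_id,
                "source_concept_id": res.source_concept_id,
                "source_value": f.concept_cd,
                "start_date": f.start_date,
                "end_date": f.end_date,
                "type_concept_id": config.type_concept_id,
                "value_as_number": f.nval_num
                if table in ("measurement", "observation") else None,
                "value_as_string": (f.tval_char or None)
                if table in ("measurement", "observation") else None,
                "unit_source_value": (f.units_cd or None)
                if table in ("measurement", "observation") else None,
            }
            if table == "drug_exposure":
                row.update({"refills": None, "quantity": None,
                            "days_supply": None})
            tables.setdefault(table, []).append(row)
            fact_rows.setdefault(key, []).append(row)
            out_counts[table] = out_counts.get(table, 0) + 1

    orphans = 0
    for m in modifiers.itertuples():
        column = MODIFIER_COLUMNS.get(m.modifier_cd)
        key = (m.patient_num, m.encounter_num, m.concept_cd, m.provider_id,
               m.start_date, m.instance_num)
        parents = fact_rows.get(key)
        if parents is None:
            orphans += 1
            continue
        if column is None:
            continue  # modifier mapped in the model but carrying no column
        for row in parents:
            if column in row:
                row[column] = m.nval_num
    del fact_rows

    records = []
    for table in sorted(set(homed_in) | set(out_counts)):
        records.append(TransformPass(
            tree, table, homed_in.get(table, 0), out_counts.get(table, 0),
            homed_unmapped.get(table, 0)))
    return tables, records, unmapped_codes, orphans


def _finalize_event_table(rows: list[dict], name: str) -> pd.DataFrame:
    columns = DRUG_COLUMNS if name == "drug_exposure" else EVENT_COLUMNS
    df = pd.DataFrame(rows, columns=[c for c in columns if c != "row_id"])
    if df.empty:
        return pd.DataFrame(columns=columns)
    df = df.sort_values(
        ["person_id", "start_date", "source_value", "concept_id",
         "visit_occurrence_id"], kind="mergesort").reset_index(drop=True)
    df.insert(0, "row_id", np.arange(1, len(df) + 1))
    # normalize NA representation so CSV round trips are faithful
    for col in ("start_date", "end_date"):
        df[col] = pd.to_datetime(df[col])
    for col in ("value_as_number", "refills", "quantity", "days_supply"):
        if col in df.columns:
            df[col] = pd.to_numeric(df[col])
    for col in ("value_as_string", "unit_source_value"):
        df[col] = df[col].fillna("").astype(str)
    return df


def compute_observation_period(tables: dict[str, pd.DataFrame]
                               ) -> pd.DataFrame:
    """One row per person with events, spanning min to max event date."""
    event_tables = ["visit_occurrence", "condition_occurrence",
                    "procedure_occurrence", "drug_exposure",
                    "device_exposure", "measurement", "observation"]
    pieces = []
    for name in event_tables:
        df = tables.get(name)
        if df is None or df.empty:
            continue
        pieces.append(df[["person_id", "start_date"]]
                      .rename(columns={"start_date": "date"}))
        if "end_date" in df.columns:
            end = df[["person_id", "end_date"]].dropna(subset=["end_date"])
            pieces.append(end.rename(columns={"end_date": "date"}))
    if not pieces:
        return pd.DataFrame(columns=["person_id", "start_date", "end_date"])
    events = pd.concat(pieces, ignore_index=True)
    agg = events.groupby("person_id")["date"].agg(["min", "max"])
    out = agg.reset_index().rename(columns={"min": "start_date",
                                            "max": "end_date"})
    return out.sort_values("person_id").reset_index(drop=True)


def compute_eras(rows: pd.DataFrame, gap_days: int = 30) -> pd.DataFrame:
    """Merge per-(person, concept) intervals into eras.

    Intervals are sorted by start; consecutive intervals merge while the
    next start is within ``gap_days`` of the running end. Missing end
    dates count as the start date. ``occurrence_count`` is the number of
    source rows merged into the era.
    """
    if rows.empty:
        return pd.DataFrame(columns=["person_id", "era_concept_id",
                                     "start_date", "end_date",
                                     "occurrence_count"])
    gap = pd.Timedelta(days=gap_days)
    df = rows[["person_id", "concept_id", "start_date", "end_date"]].copy()
    df["end_date"] = df["end_date"].fillna(df["start_date"])
    df = df.sort_values(["person_id", "concept_id", "start_date",
                         "end_date"], kind="mergesort")
    eras = []
    for (person, concept), grp in df.groupby(["person_id", "concept_id"],
                                             sort=True):
        cur_start = cur_end = None
        count = 0
        for s, e in zip(grp["start_date"], grp["end_date"]):
            if cur_start is None:
                cur_start, cur_end, count = s, e, 1
            elif s <= cur_end + gap:
                cur_end = max(cur_end, e)
                count += 1
            else:
                eras.append((person, concept, cur_start, cur_end, count))
                cur_start, cur_end, count = s, e, 1
        eras.append((person, concept, cur_start, cur_end, count))
    return pd.DataFrame(eras, columns=["person_id", "era_concept_id",
                                       "start_date", "end_date",
                                       "occurrence_count"])


def run_transform(repo: I2b2Repository, ontology: pd.DataFrame,
                  concepts: pd.DataFrame, mappings: pd.DataFrame,
                  crosswalks: Crosswalks,
                  config: TransformConfig | None = None
                  ) -> tuple[dict[str, pd.DataFrame], TransformReport]:
    """Execute the full transformation and return (tables, report).

    Deterministic: two runs on the same inputs produce identical tables,
    row ids included.
    """
    config = config or TransformConfig()
    report = TransformReport()
    tables = copy_dimension_tables(repo)
    tables["person"] = map_person(repo.patients, crosswalks)
    tables["visit_occurrence"] = map_visits(repo.visits, crosswalks, config)

    event_rows: dict[str, list[dict]] = {}
    vitals, vitals_pass = map_vitals(repo.facts, crosswalks, config)
    report.passes.append(vitals_pass)
    event_rows["measurement"] = vitals.to_dict("records")

    for tree in CODED_TREES:
        tree_tables, records, unmapped, orphans = map_coded_facts(
            repo.facts, tree, ontology, concepts, mappings, config)
        report.passes.extend(records)
        report.orphan_modifiers += orphans
        for code, n in unmapped.items():
            report.unmapped_codes[code] = \
                report.unmapped_codes.get(code, 0) + n
        for table, rows in tree_tables.items():
            event_rows.setdefault(table, []).extend(rows)

    for name in ("condition_occurrence", "procedure_occurrence",
                 "drug_exposure", "device_exposure", "measurement",
                 "observation"):
        tables[name] = _finalize_event_table(event_rows.get(name, []), name)

    tables["observation_period"] = compute_observation_period(tables)
    tables["drug_era"] = compute_eras(tables["drug_exposure"],
                                      config.gap_days)
    tables["condition_era"] = compute_eras(tables["condition_occurrence"],
                                           config.gap_days)
    report.row_counts = {name: len(df) for name, df in tables.items()}
    return tables, report
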