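"""ARCH-style information model and OMOP vocabulary handling.

An i2b2 ontology that exactly enumerates the permissible codes of a target
data model can drive transformation into that model. Here each ontology
leaf carries a prefixed *basecode* (e.g. ``ICD9:250``) and an annotated
OMOP concept number cross-referencing the OMOP concept dictionary. Source
concepts are resolved to their *standard* analytic concepts through the
``Maps to`` rows of the concept_relationship table; the resolution is 1:n
and may cross domains, so a single source code can land in several OMOP
tables (domain routing).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

log = logging.getLogger(__name__)

ONTOLOGY_ROOTS = {"Diagnosis", "Procedure", "Medication", "Labs", "Vitals",
                  "Demographics", "Encounter"}

#: basecode prefix -> OMOP vocabulary_id
PREFIX_VOCABULARY = {
    "ICD9": "ICD9CM",
    "ICD10": "ICD10CM",
    "CPT": "CPT4",
    "RXNORM": "RxNorm",
    "NDC": "NDC",
    "LOINC": "LOINC",
    "HCPCS": "HCPCS",
    "SNOMED": "SNOMED",
}

#: OMOP domain_id -> CDM target table (domain routing)
DOMAIN_TABLE = {
    "Condition": "condition_occurrence",
    "Procedure": "procedure_occurrence",
    "Drug": "drug_exposure",
    "Measurement": "measurement",
    "Observation": "observation",
    "Device": "device_exposure",
}

#: conventional table of each source tree, used when a fact has no mapping
DEFAULT_TREE_TABLE = {
    "Diagnosis": "condition_occurrence",
    "Procedure": "procedure_occurrence",
    "Medication": "drug_exposure",
    "Labs": "measurement",
    "Vitals": "measurement",
}

ONTOLOGY_COLUMNS = ["path", "basecode", "name", "level", "omop_concept_id",
                    "active", "is_modifier", "modifier_applied_path"]

MODIFIER_STATUSES = ("equivalent", "valueset_differs", "single_model")


class OntologyError(ValueError):
    """Raised for malformed ontology or vocabulary inputs."""


@dataclass(frozen=True)
class MappingResolution:
    """A source code resolved to its standard concepts and target tables.

    ``targets`` holds ``(standard_concept_id, domain_id, target_table)``
    triples in ascending concept-id order; ``unmapped`` is true iff the
    code has no source concept or no standard targets.
    """

    source_code: str
    source_concept_id: int | None
    targets: tuple[tuple[int, str, str], ...]

    @property
    def unmapped(self) -> bool:
        return self.source_concept_id is None or not self.targets


def split_basecode(basecode: str) -> tuple[str, str] | None:
    """``"ICD9:250"`` -> ``("ICD9CM", "250")``; None if prefix unknown."""
    prefix, sep, code = basecode.partition(":")
    if not sep:
        return None
    vocab = PREFIX_VOCABULARY.get(prefix.upper())
    if vocab is None:
        return None
    return vocab, code


def load_ontology(file: str | Path) -> pd.DataFrame:
    """Load an ontology CSV and check hierarchy closure.

    Every entry's parent path must itself be an entry or a tree root;
    duplicate paths are rejected. Disabled entries are kept but flagged
    inactive so they are excluded from transformation.
    """
    df = pd.read_csv(file, dtype=str, keep_default_na=False)
    df.columns = [c.strip().lower() for c in df.columns]
    missing = [c for c in ONTOLOGY_COLUMNS if c not in df.columns]
    if missing:
        raise OntologyError(f"ontology file missing column(s) {missing}")
    df = df[ONTOLOGY_COLUMNS].copy()
    df["level"] = df["level"].astype(int)
    df["omop_concept_id"] = pd.to_numeric(
        df["omop_concept_id"].replace("", pd.NA)).astype("Int64")
    df["active"] = df["active"].str.lower().isin({"1", "true", "y", "yes"})
    df["is_modifier"] = df["is_modifier"].str.lower().isin(
        {"1", "true", "y", "yes"})

    dup = df["path"].duplicated()
    if dup.any():
        raise OntologyError(
            f"duplicate ontology path: {df['path'][dup.idxmax()]!r}")
    paths = set(df["path"])
    for path, level in zip(df["path"], df["level"]):
        parts = [p for p in path.split("\\") if p]
        if not parts or parts[0] not in ONTOLOGY_ROOTS:
            raise OntologyError(f"path not rooted in a known tree: {path!r}")
        if level != len(parts) - 1:
            raise OntologyError(
                f"level {level} inconsistent with path depth: {path!r}")
        if len(parts) > 1:
            parent = "\\" + "\\".join(parts[:-1]) + "\\"
            if parent not in paths:
                raise OntologyError(f"orphan path (missing parent): {path!r}")
    return df


def tree_of(path: str) -> str:
    return [p for p in path.split("\\") if p][0]


def load_vocabulary(concept_file: str | Path,
                    relationship_file: str | Path
                    ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Load OMOP CONCEPT / CONCEPT_RELATIONSHIP subsets from CSV.

    Only ``Maps to`` rows are retained from the relationship file, and
    every relationship endpoint must exist in the concept table with a
    standard target.
    """
    concepts = pd.read_csv(concept_file, dtype=str, keep_default_na=False)
    concepts.columns = [c.strip().lower() for c in concepts.columns]
    need = ["concept_id", "concept_code", "vocabulary_id", "domain_id",
            "concept_name", "standard_concept"]
    missing = [c for c in need if c not in concepts.columns]
    if missing:
        raise OntologyError(f"concept file missing column(s) {missing}")
    concepts = concepts[need].copy()
    concepts["concept_id"] = concepts["concept_id"].astype("int64")
    concepts["standard"] = concepts["standard_concept"].eq("S")
    dup = concepts["concept_id"].duplicated()
    if dup.any():
        raise OntologyError(
            f"duplicate concept_id {concepts['concept_id'][dup.idxmax()]}")
    dup = concepts.duplicated(subset=["vocabulary_id", "concept_code"])
    if dup.any():
        i = dup.idxmax()
        raise OntologyError(
            "duplicate (vocabulary_id, concept_code): "
            f"{concepts['vocabulary_id'][i]}:{concepts['concept_code'][i]}")

    rel = pd.read_csv(relationship_file, dtype=str, keep_default_na=False)
    rel.columns = [c.strip().lower() for c in rel.columns]
    need = ["concept_id_1", "concept_id_2", "relationship_id"]
    missing = [c for c in need if c not in rel.columns]
    if missing:
        raise OntologyError(f"relationship file missing column(s) {missing}")
    rel = rel[rel["relationship_id"] == "Maps to"][need].copy()
    rel["concept_id_1"] = rel["concept_id_1"].astype("int64")
    rel["concept_id_2"] = rel["concept_id_2"].astype("int64")
    known = set(concepts["concept_id"])
    for col in ("concept_id_1", "concept_id_2"):
        unknown = rel.loc[~rel[col].isin(known), col]
        if len(unknown):
            raise OntologyError(
                f"relationship references unknown concept_id(s) "
                f"{sorted(unknown.unique())[:5]}")
    std = dict(zip(concepts["concept_id"], concepts["standard"]))
    nonstd = [t for t in rel["concept_id_2"] if not std[t]]
    if nonstd:
        raise OntologyError(
            f"'Maps to' target(s) not standard: {sorted(set(nonstd))[:5]}")
    rel = rel.drop_duplicates(subset=["concept_id_1", "concept_id_2"])
    mappings = rel.rename(columns={"concept_id_1": "source_concept_id",
                                   "concept_id_2": "target_concept_id"})
    mappings = mappings[["source_concept_id", "target_concept_id"]]
    return concepts, mappings.reset_index(drop=True)


def annotate_omop_codes(ontology: pd.DataFrame, concepts: pd.DataFrame
                        ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Fill the OMOP-code column of every active leaf; report the rest.

    Returns the annotated ontology and an unmapped report with columns
    ``basecode, code_type, name`` listing active leaves whose code is not
    in the concept dictionary. Idempotent: annotating an already-annotated
    ontology changes nothing. Valueset-mapped trees (Vitals, Demographics,
    Encounter) are not dictionary-mapped and are skipped.
    """
    ontology = ontology.copy()
    valueset_trees = {"Vitals", "Demographics", "Encounter"}
    lookup = {(v, c): i for v, c, i in zip(concepts["vocabulary_id"],
                                           concepts["concept_code"],
                                           concepts["concept_id"])}
    unmapped = []
    for idx, row in ontology.iterrows():
        if not row["basecode"] or row["is_modifier"] or not row["active"]:
            continue
        if tree_of(row["path"]) in valueset_trees:
            continue
        parsed = split_basecode(row["basecode"])
        if parsed is None:
            log.warning("unrecognized code prefix in basecode %r",
                        row["basecode"])
            continue
        concept_id = lookup.get(parsed)
        if concept_id is None:
            unmapped.append({"basecode": row["basecode"],
                             "code_type": parsed[0], "name": row["name"]})
        else:
            ontology.at[idx, "omop_concept_id"] = concept_id
    report = pd.DataFrame(unmapped, columns=["basecode", "code_type", "name"])
    return ontology, report.drop_duplicates().reset_index(drop=True)


def route_domain(domain_id: str, source_tree: str = "") -> str:
    """Target table for a standard concept's domain (pure routing map).

    Routing follows the concept's *domain*, not the source tree — this is
    how e.g. a vaccine ICD diagnosis code ends up in procedure_occurrence.
    Unknown domains fall back to the observation catch-all with a warning.
    """
    table = DOMAIN_TABLE.get(domain_id)
    if table is None:
        log.warning("unknown domain %r (source tree %r); routing to "
                    "observation", domain_id, source_tree)
        return "observation"
    return table


def resolve_standard_concepts(code: str, concepts: pd.DataFrame,
                              mappings: pd.DataFrame) -> MappingResolution:
    """Resolve one prefixed source code to its standard concepts.

    Targets are all ``Maps to`` successors of the code's source concept,
    in ascending standard-concept-id order, each tagged with its domain
    and target table. A standard source with no explicit mapping rows
    resolves to itself. Absence at any step yields an unmapped resolution.
    """
    parsed = split_basecode(code)
    if parsed is None:
        return MappingResolution(code, None, ())
    row = concepts[(concepts["vocabulary_id"] == parsed[0]) &
                   (concepts["concept_code"] == parsed[1])]
    if row.empty:
        return MappingResolution(code, None, ())
    source_id = int(row["concept_id"].iloc[0])
    target_ids = sorted(
        mappings.loc[mappings["source_concept_id"] == source_id,
                     "target_concept_id"])
    if not target_ids and bool(row["standard"].iloc[0]):
        target_ids = [source_id]
    domain = dict(zip(concepts["concept_id"], concepts["domain_id"]))
    targets = tuple((t, domain[t], route_domain(domain[t]))
                    for t in target_ids)
    return MappingResolution(code, source_id, targets)


def multiplicity_report(ontology: pd.DataFrame, concepts: pd.DataFrame,
                        mappings: pd.DataFrame) -> pd.DataFrame:
    """Mapping distribution from source trees to OMOP tables.

    One row per source tree, one column per target table; each cell counts
    the distinct mapped basecodes of that tree contributing at least one
    standard target routed to that table, plus a ``total`` column counting
    the tree's mapped codes.
    """
    leaves = ontology[(ontology["basecode"] != "") & ontology["active"] &
                      ~ontology["is_modifier"]]
    tables = sorted(set(DOMAIN_TABLE.values()))
    trees: dict[str, dict[str, set]] = {}
    totals: dict[str, set] = {}
    for path, basecode in zip(leaves["path"], leaves["basecode"]):
        res = resolve_standard_concepts(basecode, concepts, mappings)
        if res.unmapped:
            continue
        tree = tree_of(path)
        totals.setdefault(tree, set()).add(basecode)
        cell = trees.setdefault(tree, {t: set() for t in tables})
        for _, _, table in res.targets:
            cell[table].add(basecode)
    rows = []
    for tree in sorted(trees):
        row = {"source_tree": tree}
        row.update({t: len(trees[tree][t]) for t in tables})
        row["total"] = len(totals[tree])
        rows.append(row)
    return pd.DataFrame(rows, columns=["source_tree"] + tables + ["total"])


def load_modifier_crosswalk(file: str | Path) -> pd.DataFrame:
    """Load the modifier crosswalk (domain, modifier_name, status)."""
    df = pd.read_csv(file, dtype=str, keep_default_na=False)
    df.columns = [c.strip().lower() for c in df.columns]
    bad = set(df["status"]) - set(MODIFIER_STATUSES)
    if bad:
        raise OntologyError(f"unknown modifier crosswalk status(es): {bad}")
    return df


def modifier_crosswalk_summary(crosswalk: pd.DataFrame) -> dict[str, int]:
    """Counts of crosswalk entries per status."""
    counts = crosswalk["status"].value_counts()
    return {s: int(counts.get(s, 0)) for s in MODIFIER_STATUSES}
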