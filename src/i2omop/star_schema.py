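"""Read, validate and write i2b2 star-schema tables and OMOP output tables.

The i2b2 star schema keeps all clinical observations in one narrow
``observation_fact`` table (patient, encounter, coded concept, modifier,
dates, value), with ``patient_dimension``, ``visit_dimension`` and
``provider_dimension`` supplying demographics, encounters and providers.
Everything is exchanged as UTF-8 CSV with a mandatory header row and
ISO-8601 dates, so fixtures stay diff-able and round-trips are exact.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

log = logging.getLogger(__name__)

NO_MODIFIER = "@"

FACT_FILE = "observation_fact.csv"
PATIENT_FILE = "patient_dimension.csv"
VISIT_FILE = "visit_dimension.csv"
PROVIDER_FILE = "provider_dimension.csv"

FACT_COLUMNS = [
    "patient_num", "encounter_num", "concept_cd", "modifier_cd",
    "provider_id", "start_date", "end_date", "valtype_cd", "nval_num",
    "tval_char", "units_cd", "instance_num",
]
PATIENT_COLUMNS = [
    "patient_num", "birth_date", "death_date", "sex_cd", "race_cd",
    "ethnicity_cd",
]
VISIT_COLUMNS = [
    "encounter_num", "patient_num", "start_date", "end_date", "inout_cd",
    "location_cd",
]
PROVIDER_COLUMNS = ["provider_id", "provider_name", "provider_path"]

FACT_KEY = [
    "patient_num", "encounter_num", "concept_cd", "modifier_cd",
    "provider_id", "start_date", "instance_num",
]

#: OMOP CDM tables in the All Of Us subset that this pipeline materializes.
OMOP_TABLES = [
    "person", "visit_occurrence", "condition_occurrence",
    "procedure_occurrence", "drug_exposure", "device_exposure",
    "measurement", "observation", "death", "provider", "care_site",
    "observation_period", "drug_era", "condition_era",
]

_DATE_COLUMNS = {
    "observation_fact": ["start_date", "end_date"],
    "patient_dimension": ["birth_date", "death_date"],
    "visit_dimension": ["start_date", "end_date"],
    "provider_dimension": [],
}
_INT_COLUMNS = {
    "observation_fact": ["patient_num", "encounter_num", "instance_num"],
    "patient_dimension": ["patient_num"],
    "visit_dimension": ["encounter_num", "patient_num"],
    "provider_dimension": [],
}


class RepositoryError(ValueError):
    """Raised when an i2b2 repository cannot be read or fails validation."""


@dataclass
class Violation:
    """One invariant violation found in a repository."""

    kind: str
    table: str
    key: str
    message: str


@dataclass
class I2b2Repository:
    """In-memory i2b2 star schema: one fact table plus three dimensions."""

    facts: pd.DataFrame
    patients: pd.DataFrame
    visits: pd.DataFrame
    providers: pd.DataFrame
    dropped_orphans: int = 0

    def copy(self) -> "I2b2Repository":
        return I2b2Repository(
            self.facts.copy(), self.patients.copy(), self.visits.copy(),
            self.providers.copy(), self.dropped_orphans,
        )


def _read_table(path: Path, name: str, required: list[str]) -> pd.DataFrame:
    if not path.exists():
        raise RepositoryError(f"missing file: {path}")
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    df.columns = [c.strip().lower() for c in df.columns]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise RepositoryError(
            f"{name}: missing required column(s) {missing} in {path}"
        )
    df = df[required].copy()
    for col in _DATE_COLUMNS[name]:
        raw = df[col]
        parsed = pd.to_datetime(raw.replace("", pd.NA), format="%Y-%m-%d",
                                errors="coerce")
        bad = raw.ne("") & parsed.isna()
        if bad.any():
            row = int(bad.idxmax())
            raise RepositoryError(
                f"{name}: unparseable date {raw[row]!r} in column {col}, "
                f"line {row + 2} of {path}"
            )
        df[col] = parsed
    for col in _INT_COLUMNS[name]:
        try:
            df[col] = df[col].astype("int64")
        except ValueError as exc:
            raise RepositoryError(f"{name}: non-integer {col}: {exc}") from exc
    return df


def read_repository(directory: str | Path, strict: bool = True,
                    paths: dict[str, Path] | None = None) -> I2b2Repository:
    """Read the four star-schema CSVs from ``directory``.

    In strict mode any referential-integrity violation aborts with
    :class:`RepositoryError`; in lenient mode orphan facts (facts whose
    patient or encounter is missing from the dimensions) are dropped and
    counted in ``dropped_orphans``.
    """
    directory = Path(directory)
    paths = paths or {}
    facts = _read_table(paths.get("facts", directory / FACT_FILE),
                        "observation_fact", FACT_COLUMNS)
    patients = _read_table(paths.get("patients", directory / PATIENT_FILE),
                           "patient_dimension", PATIENT_COLUMNS)
    visits = _read_table(paths.get("visits", directory / VISIT_FILE),
                         "visit_dimension", VISIT_COLUMNS)
    providers = _read_table(paths.get("providers", directory / PROVIDER_FILE),
                            "provider_dimension", PROVIDER_COLUMNS)

    # normalize "no modifier" sentinel
    facts["modifier_cd"] = facts["modifier_cd"].replace("", NO_MODIFIER)
    facts["nval_num"] = pd.to_numeric(facts["nval_num"].replace("", pd.NA))

    orphan = ~facts["patient_num"].isin(patients["patient_num"]) | \
        ~facts["encounter_num"].isin(visits["encounter_num"])
    n_orphans = int(orphan.sum())
    if n_orphans:
        if strict:
            row = int(orphan.idxmax())
            raise RepositoryError(
                "referential-integrity error: fact row "
                f"{row + 2} (patient_num={facts['patient_num'][row]}, "
                f"encounter_num={facts['encounter_num'][row]}) does not "
                "resolve against the dimension tables"
            )
        log.warning("dropping %d orphan fact(s) without dimension rows",
                    n_orphans)
        facts = facts[~orphan].reset_index(drop=True)
    return I2b2Repository(facts, patients, visits, providers,
                          dropped_orphans=n_orphans)


def validate_repository(repo: I2b2Repository) -> list[Violation]:
    """Return every invariant violation; empty list iff the repository is clean."""
    out: list[Violation] = []
    f = repo.facts

    bad = f["end_date"].notna() & (f["end_date"] < f["start_date"])
    for i in f.index[bad]:
        out.append(Violation("date_order", "observation_fact",
                             _fact_key(f.loc[i]),
                             "end_date precedes start_date"))
    dup = f.duplicated(subset=FACT_KEY, keep="first")
    for i in f.index[dup]:
        out.append(Violation("duplicate_key", "observation_fact",
                             _fact_key(f.loc[i]), "duplicate fact key"))
    miss_n = f["valtype_cd"].eq("N") & f["nval_num"].isna()
    for i in f.index[miss_n]:
        out.append(Violation("missing_value", "observation_fact",
                             _fact_key(f.loc[i]),
                             "valtype_cd 'N' without nval_num"))
    miss_t = f["valtype_cd"].eq("T") & f["tval_char"].eq("")
    for i in f.index[miss_t]:
        out.append(Violation("missing_value", "observation_fact",
                             _fact_key(f.loc[i]),
                             "valtype_cd 'T' without tval_char"))

    p = repo.patients
    for i in p.index[p.duplicated("patient_num", keep="first")]:
        out.append(Violation("duplicate_key", "patient_dimension",
                             str(p["patient_num"][i]),
                             "duplicate patient_num"))
    bad = p["death_date"].notna() & (p["death_date"] < p["birth_date"])
    for i in p.index[bad]:
        out.append(Violation("date_order", "patient_dimension",
                             str(p["patient_num"][i]),
                             "death_date precedes birth_date"))

    v = repo.visits
    for i in v.index[v.duplicated("encounter_num", keep="first")]:
        out.append(Violation("duplicate_key", "visit_dimension",
                             str(v["encounter_num"][i]),
                             "duplicate encounter_num"))
    orphan_v = ~v["patient_num"].isin(p["patient_num"])
    for i in v.index[orphan_v]:
        out.append(Violation("orphan", "visit_dimension",
                             str(v["encounter_num"][i]),
                             "visit references unknown patient_num"))

    pr = repo.providers
    for i in pr.index[pr.duplicated("provider_id", keep="first")]:
        out.append(Violation("duplicate_key", "provider_dimension",
                             str(pr["provider_id"][i]),
                             "duplicate provider_id"))

    orphan_f = ~f["patient_num"].isin(p["patient_num"]) | \
        ~f["encounter_num"].isin(v["encounter_num"])
    for i in f.index[orphan_f]:
        out.append(Violation("orphan", "observation_fact",
                             _fact_key(f.loc[i]),
                             "fact does not resolve against dimensions"))
    return out


def _fact_key(row: pd.Series) -> str:
    return "|".join(str(row[c]) for c in FACT_KEY)


def _format_dates(df: pd.DataFrame) -> pd.DataFrame:
    out = df.copy()
    for col in out.columns:
        if pd.api.types.is_datetime64_any_dtype(out[col]):
            out[col] = out[col].dt.strftime("%Y-%m-%d").fillna("")
    return out


def write_repository(repo: I2b2Repository, directory: str | Path) -> dict:
    """Write the four star-schema CSVs; returns {filename: row count}."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = {}
    for name, df in [(FACT_FILE, repo.facts), (PATIENT_FILE, repo.patients),
                     (VISIT_FILE, repo.visits),
                     (PROVIDER_FILE, repo.providers)]:
        _format_dates(df).to_csv(directory / name, index=False,
                                 lineterminator="\n")
        manifest[name] = len(df)
    return manifest


def write_omop_tables(tables: dict[str, pd.DataFrame],
                      directory: str | Path) -> dict:
    """Write one CSV per non-empty OMOP table; returns {filename: row count}.

    Table names must come from the All Of Us subset (:data:`OMOP_TABLES`).
    Re-reading with :func:`read_omop_tables` reproduces the rows exactly.
    """
    directory = Path(directory)
    unknown = sorted(set(tables) - set(OMOP_TABLES))
    if unknown:
        raise ValueError(f"not in the supported OMOP table subset: {unknown}")
    directory.mkdir(parents=True, exist_ok=True)
    manifest = {}
    for name in OMOP_TABLES:
        df = tables.get(name)
        if df is None or df.empty:
            continue
        _format_dates(df).to_csv(directory / f"{name}.csv", index=False,
                                 lineterminator="\n")
        manifest[f"{name}.csv"] = len(df)
    with open(directory / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def read_omop_tables(directory: str | Path) -> dict[str, pd.DataFrame]:
    """Read back every OMOP table CSV present in ``directory``."""
    directory = Path(directory)
    out = {}
    for name in OMOP_TABLES:
        path = directory / f"{name}.csv"
        if not path.exists():
            continue
        df = pd.read_csv(path, keep_default_na=False)
        for col in df.columns:
            if col.endswith("_date") or col == "birth_datetime":
                df[col] = pd.to_datetime(df[col].replace("", pd.NA),
                                         format="%Y-%m-%d")
            elif col in ("value_as_number", "refills", "quantity",
                         "days_supply"):
                df[col] = pd.to_numeric(
                    df[col].replace("", pd.NA) if df[col].dtype == object
                    else df[col])
        out[name] = df
    return out
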