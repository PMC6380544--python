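"""Achilles-style five-point QA checklist over a materialized OMOP table set.

The checks interpret OHDSI's descriptive data-characterization reports as
pass/fail rules suitable for running at every data refresh:

* **data_density** — monthly row counts per event table should trend
  upward (robust Theil–Sen slope over the recent window) and per-table
  totals should sit within one order of magnitude of each other.
  observation_period is excluded: it has one entry per patient by
  construction.
* **age_first_obs** — age at first observation should peak in the 20s or
  30s and decline gradually toward old age; a spike at age 0 (babies
  born without follow-up care) is permitted.
* **treemap_variety** — the condition, measurement, drug and procedure
  treemaps should show a variety of concepts, not a handful of boxes.
* **person_balance** — the male/female ratio should be near 50/50 and
  every expected race should be represented.
* **recency** — every visit type should run to within a window of the
  data refresh date.

Thresholds quantify qualitative guidance and are all configurable:
"same magnitude" -> ratio <= 10, "~50/50" -> female share in [0.4, 0.6],
"ending close to the refresh date" -> 90 days, "many boxes" -> >= 20
distinct concepts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

FEMALE_CONCEPT = 8532

CHECK_IDS = ["data_density", "age_first_obs", "treemap_variety",
             "person_balance", "recency"]

DENSITY_TABLES = ["visit_occurrence", "condition_occurrence",
                  "procedure_occurrence", "drug_exposure", "measurement",
                  "observation"]
TREEMAP_TABLES = ["condition_occurrence", "measurement", "drug_exposure",
                  "procedure_occurrence"]


@dataclass
class QAConfig:
    refresh_date: pd.Timestamp | str | None = None
    magnitude_ratio: float = 10.0
    trend_months: int = 24
    female_share_range: tuple[float, float] = (0.4, 0.6)
    expected_race_concepts: dict[int, str] = field(default_factory=dict)
    min_distinct: int = 20
    window_days: int = 90
    density_tables: list[str] = field(
        default_factory=lambda: list(DENSITY_TABLES))

    def __post_init__(self):
        if self.refresh_date is not None:
            self.refresh_date = pd.Timestamp(self.refresh_date)


@dataclass
class QACheckResult:
    check_id: str
    passed: bool
    metrics: dict
    message: str


@dataclass
class QAReport:
    checks: list[QACheckResult]
    overall_pass: bool

    def check(self, check_id: str) -> QACheckResult:
        return next(c for c in self.checks if c.check_id == check_id)

    def to_json(self) -> str:
        return json.dumps({
            "overall_pass": self.overall_pass,
            "checks": [{"check_id": c.check_id, "passed": c.passed,
                        "metrics": c.metrics, "message": c.message}
                       for c in self.checks]}, indent=2, default=str)

    @classmethod
    def from_json(cls, text: str) -> "QAReport":
        obj = json.loads(text)
        checks = [QACheckResult(c["check_id"], c["passed"], c["metrics"],
                                c["message"]) for c in obj["checks"]]
        return cls(checks, obj["overall_pass"])


def monthly_density(tables: dict[str, pd.DataFrame],
                    table_names: list[str] | None = None) -> pd.DataFrame:
    """Per-table monthly row counts (contiguous months, zero-filled).

    Columns: table, month (period start timestamp), row_count.
    """
    table_names = table_names or DENSITY_TABLES
    frames = []
    for name in table_names:
        df = tables.get(name)
        if df is None or df.empty:
            frames.append(pd.DataFrame(
                {"table": name, "month": pd.Series(dtype="datetime64[ns]"),
                 "row_count": pd.Series(dtype="int64")}))
            continue
        months = pd.to_datetime(df["start_date"]).dt.to_period("M")
        counts = months.value_counts().sort_index()
        full = pd.period_range(counts.index.min(), counts.index.max(),
                               freq="M")
        counts = counts.reindex(full, fill_value=0)
        frames.append(pd.DataFrame({
            "table": name,
            "month": counts.index.to_timestamp(),
            "row_count": counts.values.astype("int64")}))
    return pd.concat(frames, ignore_index=True)


def compute_data_density(tables: dict[str, pd.DataFrame],
                         config: QAConfig | None = None
                         ) -> tuple[pd.DataFrame, QACheckResult]:
    """Data-density check: growth per event table, comparable totals."""
    config = config or QAConfig()
    density = monthly_density(tables, config.density_tables)
    slopes, totals, failures = {}, {}, []
    for name in config.density_tables:
        series = density[density["table"] == name]
        total = int(series["row_count"].sum())
        totals[name] = total
        if total == 0:
            failures.append(f"{name} is empty")
            continue
        recent = series.tail(config.trend_months)["row_count"].to_numpy()
        if len(recent) >= 2 and np.ptp(recent) > 0:
            slope = stats.theilslopes(recent, np.arange(len(recent)))[0]
        else:
            slope = 0.0
        slopes[name] = float(slope)
        if slope < 0:
            failures.append(f"{name} monthly volume is decreasing "
                            f"(slope {slope:.2f})")
    nonzero = [t for t, n in totals.items() if n > 0]
    if len(nonzero) >= 2:
        ratio = max(totals[t] for t in nonzero) / min(totals[t]
                                                      for t in nonzero)
        if ratio > config.magnitude_ratio:
            failures.append(
                f"per-table totals span more than {config.magnitude_ratio}x "
                f"(ratio {ratio:.1f})")
    else:
        ratio = float("inf") if failures else 1.0
    result = QACheckResult(
        "data_density", not failures,
        {"totals": totals, "slopes": slopes, "magnitude_ratio": ratio},
        "; ".join(failures) or "all event tables growing and comparable")
    return density, result


def age_at_first_observation(person: pd.DataFrame,
                             tables: dict[str, pd.DataFrame]) -> pd.Series:
    """Whole-year age of each person at their earliest event."""
    pieces = []
    for name in DENSITY_TABLES:
        df = tables.get(name)
        if df is None or df.empty:
            continue
        pieces.append(df[["person_id", "start_date"]])
    if not pieces:
        return pd.Series(dtype="int64")
    first = (pd.concat(pieces, ignore_index=True)
             .groupby("person_id")["start_date"].min())
    birth = person.set_index("person_id")["birth_datetime"]
    delta = (first - birth.reindex(first.index)).dt.days
    return np.floor(delta / 365.25).astype("int64")


def compute_age_first_observation(person: pd.DataFrame,
                                  tables: dict[str, pd.DataFrame],
                                  config: QAConfig | None = None
                                  ) -> tuple[pd.Series, QACheckResult]:
    """Age-at-first-observation histogram and its shape check.

    Passes iff the modal age over ages >= 1 falls in [20, 39] and the
    5-year rolling mean of the counts is non-increasing from that peak
    out to age 80. An age-0 spike is permitted, not required.
    """
    config = config or QAConfig()
    ages = age_at_first_observation(person, tables)
    hist = ages.value_counts().reindex(range(0, 111), fill_value=0)
    if hist.sum() == 0:
        result = QACheckResult("age_first_obs", False, {"n": 0},
                               "no persons with events")
        return hist, result
    adult = hist.loc[1:]
    peak = int(adult.idxmax())
    metrics = {"peak_age": peak, "n": int(hist.sum())}
    if not 20 <= peak <= 39:
        result = QACheckResult(
            "age_first_obs", False, metrics,
            f"no peak in the 20s-30s (modal age {peak})")
        return hist, result
    smooth = hist.loc[peak:80].rolling(5, min_periods=1).mean().to_numpy()
    rising = np.diff(smooth) > 1e-9
    if rising.any():
        age = peak + int(np.argmax(rising)) + 1
        result = QACheckResult(
            "age_first_obs", False, metrics,
            f"counts rise again near age {age} instead of declining")
        return hist, result
    result = QACheckResult(
        "age_first_obs", True, metrics,
        f"peak at age {peak} with gradual decline to age 80")
    return hist, result


def compute_treemap_variety(tables: dict[str, pd.DataFrame],
                            config: QAConfig | None = None) -> QACheckResult:
    """Variety check: enough distinct concepts per treemap table."""
    config = config or QAConfig()
    distinct, failures = {}, []
    for name in TREEMAP_TABLES:
        df = tables.get(name)
        n = 0 if df is None or df.empty else int(df["concept_id"].nunique())
        distinct[name] = n
        if n < config.min_distinct:
            failures.append(f"{name} has {n} distinct concepts "
                            f"(< {config.min_distinct})")
    return QACheckResult(
        "treemap_variety", not failures, {"distinct_concepts": distinct},
        "; ".join(failures) or "all treemaps varied")


def compute_person_balance(person: pd.DataFrame,
                           config: QAConfig | None = None) -> QACheckResult:
    """Demographic balance: ~50/50 sex ratio, all races represented."""
    config = config or QAConfig()
    failures = []
    n = len(person)
    share = (float((person["gender_concept_id"] == FEMALE_CONCEPT).mean())
             if n else 0.0)
    lo, hi = config.female_share_range
    if not lo <= share <= hi:
        failures.append(f"female share {share:.2f} outside [{lo}, {hi}]")
    present = set(person["race_concept_id"]) if n else set()
    missing = [name for cid, name in
               sorted(config.expected_race_concepts.items())
               if cid not in present]
    if missing:
        failures.append(f"race(s) not represented: {', '.join(missing)}")
    return QACheckResult(
        "person_balance", not failures,
        {"female_share": share, "n_persons": n,
         "missing_races": missing},
        "; ".join(failures) or "sexes balanced and all races represented")


def compute_recency(visit_occurrence: pd.DataFrame,
                    config: QAConfig | None = None) -> QACheckResult:
    """Every visit type must run to within window_days of the refresh."""
    config = config or QAConfig()
    if config.refresh_date is None:
        raise ValueError("QAConfig.refresh_date is required for recency")
    if visit_occurrence is None or visit_occurrence.empty:
        return QACheckResult("recency", False, {"latest_by_type": {}},
                             "visit table is empty")
    latest = (visit_occurrence.groupby("source_value")["start_date"].max())
    cutoff = config.refresh_date - pd.Timedelta(days=config.window_days)
    stale = sorted(latest.index[latest < cutoff])
    metrics = {"latest_by_type": {k: str(v.date())
                                  for k, v in latest.items()},
               "cutoff": str(cutoff.date())}
    if stale:
        return QACheckResult(
            "recency", False, metrics,
            f"visit type(s) ending before {cutoff.date()}: "
            f"{', '.join(stale)}")
    return QACheckResult("recency", True, metrics,
                         "all visit types run to the refresh date")


def run_checklist(tables: dict[str, pd.DataFrame],
                  config: QAConfig) -> QAReport:
    """All five checks; overall pass iff every check passes."""
    _, density = compute_data_density(tables, config)
    _, age = compute_age_first_observation(tables["person"], tables, config)
    checks = [
        density,
        age,
        compute_treemap_variety(tables, config),
        compute_person_balance(tables["person"], config),
        compute_recency(tables.get("visit_occurrence"), config),
    ]
    return QAReport(checks, all(c.passed for c in checks))
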