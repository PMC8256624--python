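"""Reading, validating and writing the study-level dose-outcome database.

One row per study-dose.  Canonical interchange format is CSV (UTF-8,
header required); an Excel workbook with the same columns on its first
sheet is accepted through the same schema.  Missing outcome counts are
empty cells, never zero: zero events is information, absence is not.

Columns::

    study_id, year, design_class, disease_class, disease, treatment_class,
    contains_chemotherapy, dose_label, dose_components, n_evaluable_dlt,
    n_dlt, n_evaluable_or, n_or

``dose_components`` holds semicolon-separated ``agent=amount`` pairs,
e.g. ``"cisplatin=50;erlotinib=100"``.  A ``series_id`` column, if
present, is accepted: files storing pre-formed series can be read here
as raw dose rows, or consumed directly by the series-level fitting CLI
(``dosemono fit``); otherwise series are built from the partial order by
:mod:`dosemono.series`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd

__all__ = [
    "StudyMeta",
    "DoseOutcomeRecord",
    "Database",
    "SchemaError",
    "ValidationError",
    "read_database",
    "write_database",
    "characteristics_table",
    "render_characteristics",
]

DESIGN_CLASSES = ("rule_based", "model_based")
DISEASE_CLASSES = ("haematological", "non_haematological", "both", "undisclosed")

COLUMNS = [
    "study_id", "year", "design_class", "disease_class", "disease",
    "treatment_class", "contains_chemotherapy", "dose_label",
    "dose_components", "n_evaluable_dlt", "n_dlt", "n_evaluable_or", "n_or",
]
OPTIONAL_COLUMNS = ["series_id"]


class SchemaError(ValueError):
    """The file does not carry the documented column schema."""


class ValidationError(ValueError):
    """Rows violate the database invariants; offending rows are listed."""

    def __init__(self, problems: list[str]):
        self.problems = problems
        super().__init__(
            "invalid database rows:\n" + "\n".join(f"  - {p}" for p in problems)
        )


@dataclass(frozen=True)
class StudyMeta:
    """Study-level metadata for one dose-finding manuscript."""

    study_id: str
    year: int
    design_class: str  # rule_based | model_based
    disease_class: str  # haematological | non_haematological | both | undisclosed
    disease: str
    treatment_class: str
    contains_chemotherapy: bool

    def __post_init__(self) -> None:
        if not (1990 <= self.year <= 2030):
            raise ValueError(f"year {self.year} outside [1990, 2030]")
        if self.design_class not in DESIGN_CLASSES:
            raise ValueError(f"design_class must be one of {DESIGN_CLASSES}")
        if self.disease_class not in DISEASE_CLASSES:
            raise ValueError(f"disease_class must be one of {DISEASE_CLASSES}")


@dataclass(frozen=True)
class DoseOutcomeRecord:
    """Outcome counts at one dose-level of one study.

    ``n_dlt`` / ``n_or`` of None mean the count was not reported; at least
    one of the two outcome pairs must be present.
    """

    study_id: str
    dose_label: str
    dose_components: dict[str, float]
    n_evaluable_dlt: int | None = None
    n_dlt: int | None = None
    n_evaluable_or: int | None = None
    n_or: int | None = None

    def __post_init__(self) -> None:
        probs = self.problems()
        if probs:
            raise ValueError("; ".join(probs))

    def problems(self) -> list[str]:
        out = []
        if not self.dose_components:
            out.append("dose has no components")
        for agent, amt in self.dose_components.items():
            if not (np.isfinite(amt) and amt >= 0):
                out.append(f"component {agent!r} amount must be finite and >= 0")
        has_dlt = self.n_evaluable_dlt is not None and self.n_dlt is not None
        has_or = self.n_evaluable_or is not None and self.n_or is not None
        if not has_dlt and not has_or:
            out.append("record reports neither DLT nor OR counts")
        if has_dlt and not (0 <= self.n_dlt <= self.n_evaluable_dlt):
            out.append(
                f"n_dlt={self.n_dlt} exceeds n_evaluable_dlt={self.n_evaluable_dlt}"
            )
        if has_or and not (0 <= self.n_or <= self.n_evaluable_or):
            out.append(f"n_or={self.n_or} exceeds n_evaluable_or={self.n_evaluable_or}")
        return out


@dataclass
class Database:
    """A validated collection of studies and their dose-outcome rows."""

    studies: list[StudyMeta] = field(default_factory=list)
    records: list[DoseOutcomeRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [s.study_id for s in self.studies]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate study_id in studies")
        known = set(ids)
        orphan = {r.study_id for r in self.records} - known
        if orphan:
            raise ValueError(f"records reference unknown studies: {sorted(orphan)}")

    def study(self, study_id: str) -> StudyMeta:
        for s in self.studies:
            if s.study_id == study_id:
                return s
        raise KeyError(study_id)

    def records_for(self, study_id: str) -> list[DoseOutcomeRecord]:
        return [r for r in self.records if r.study_id == study_id]

    def __eq__(self, other) -> bool:
        if not isinstance(other, Database):
            return NotImplemented
        return self.studies == other.studies and self.records == other.records


# ---------------------------------------------------------------------------
# serialisation


def _format_components(components: dict[str, float]) -> str:
    return ";".join(f"{a}={float(v)!r}" for a, v in sorted(components.items()))


def _parse_components(text: str) -> dict[str, float]:
    out: dict[str, float] = {}
    for pair in str(text).split(";"):
        if not pair.strip():
            continue
        agent, _, amount = pair.partition("=")
        out[agent.strip()] = float(amount)
    return out


def _opt_int(value) -> int | None:
    if value is None or (isinstance(value, float) and np.isnan(value)) or value == "":
        return None
    return int(value)


def read_database(path: str | Path, format: Literal["csv", "xlsx"] | None = None) -> Database:
    """Read and validate a dose-outcome database from CSV or Excel.

    Rows violating invariants are collected and reported together in a
    :class:`ValidationError`, never silently dropped.
    """
    path = Path(path)
    if format is None:
        format = "xlsx" if path.suffix.lower() in (".xlsx", ".xls") else "csv"
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "xlsx":
        frame = pd.read_excel(path, sheet_name=0)
    else:
        frame = pd.read_csv(path)

    missing = [c for c in COLUMNS if c not in frame.columns]
    unknown = [c for c in frame.columns if c not in COLUMNS + OPTIONAL_COLUMNS]
    if missing or unknown:
        raise SchemaError(
            f"schema mismatch: missing columns {missing}, unknown columns {unknown}"
        )

    problems: list[str] = []
    studies: dict[str, StudyMeta] = {}
    records: list[DoseOutcomeRecord] = []
    for idx, row in frame.iterrows():
        sid = str(row["study_id"])
        try:
            meta = StudyMeta(
                study_id=sid,
                year=int(row["year"]),
                design_class=str(row["design_class"]),
                disease_class=str(row["disease_class"]),
                disease=str(row["disease"]),
                treatment_class=str(row["treatment_class"]),
                contains_chemotherapy=_parse_bool(row["contains_chemotherapy"]),
            )
            if sid in studies:
                if studies[sid] != meta:
                    problems.append(f"row {idx}: study {sid} metadata inconsistent")
            else:
                studies[sid] = meta
        except (ValueError, TypeError) as exc:
            problems.append(f"row {idx} (study {sid}): {exc}")
            continue
        try:
            rec = DoseOutcomeRecord(
                study_id=sid,
                dose_label=str(row["dose_label"]),
                dose_components=_parse_components(row["dose_components"]),
                n_evaluable_dlt=_opt_int(row["n_evaluable_dlt"]),
                n_dlt=_opt_int(row["n_dlt"]),
                n_evaluable_or=_opt_int(row["n_evaluable_or"]),
                n_or=_opt_int(row["n_or"]),
            )
            records.append(rec)
        except (ValueError, TypeError) as exc:
            problems.append(f"row {idx} (study {sid}, dose {row['dose_label']!r}): {exc}")
    if problems:
        raise ValidationError(problems)
    return Database(studies=list(studies.values()), records=records)


def _parse_bool(value) -> bool:
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    text = str(value).strip().lower()
    if text in ("true", "1", "yes"):
        return True
    if text in ("false", "0", "no"):
        return False
    raise ValueError(f"cannot interpret {value!r} as a boolean")


def to_frame(db: Database) -> pd.DataFrame:
    """Flatten a Database to the canonical one-row-per-study-dose table."""
    meta = {s.study_id: s for s in db.studies}
    rows = []
    seen = set()
    for r in db.records:
        s = meta[r.study_id]
        seen.add(r.study_id)
        rows.append({
            "study_id": s.study_id,
            "year": s.year,
            "design_class": s.design_class,
            "disease_class": s.disease_class,
            "disease": s.disease,
            "treatment_class": s.treatment_class,
            "contains_chemotherapy": s.contains_chemotherapy,
            "dose_label": r.dose_label,
            "dose_components": _format_components(r.dose_components),
            "n_evaluable_dlt": r.n_evaluable_dlt,
            "n_dlt": r.n_dlt,
            "n_evaluable_or": r.n_evaluable_or,
            "n_or": r.n_or,
        })
    return pd.DataFrame(rows, columns=COLUMNS)


def write_database(db: Database, path: str | Path, format: Literal["csv", "xlsx"] = "csv") -> None:
    """Write a Database; the file re-reads to an equal Database.

    Studies without records are not representable in the flat schema and
    are rejected.
    """
    dangling = {s.study_id for s in db.studies} - {r.study_id for r in db.records}
    if dangling:
        raise ValueError(
            f"studies with no dose rows cannot be serialised: {sorted(dangling)}"
        )
    frame = to_frame(db)
    # pandas writes Int64 NA as empty cell, preserving the missing-vs-zero
    # distinction
    for col in ("n_evaluable_dlt", "n_dlt", "n_evaluable_or", "n_or"):
        frame[col] = frame[col].astype("Int64")
    if format == "xlsx":
        frame.to_excel(path, index=False)
    else:
        frame.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# characteristics summary


def characteristics_table(db: Database, series_dlt, series_or) -> pd.DataFrame:
    """Counts and within-column percentages of manuscripts and DLT/OR
    series by year, design class, disease class, disease label and
    treatment class, plus the median and IQR of dose-levels per series.

    Returns a tidy frame with columns ``block``, ``category``, and a
    ``"<count> (<pct>)"`` cell per column (manuscripts / DLT series / OR
    series), the layout of a trial-characteristics table.  Empty inputs
    yield zero counts, not an error.
    """
    meta = {s.study_id: s for s in db.studies}

    def col(values: list, total: int) -> dict:
        counts = pd.Series(values).value_counts() if values else pd.Series(dtype=int)
        return {"counts": counts, "total": total}

    def block(name: str, getter) -> list[dict]:
        mans = [getter(s) for s in db.studies]
        dlt = [getter(meta[s.study_id]) for s in series_dlt]
        orr = [getter(meta[s.study_id]) for s in series_or]
        cats = sorted(set(mans) | set(dlt) | set(orr), key=str)
        rows = []
        for cat in cats:
            rows.append({
                "block": name,
                "category": str(cat),
                "manuscripts": _cell(mans.count(cat), len(mans)),
                "dlt_series": _cell(dlt.count(cat), len(dlt)),
                "or_series": _cell(orr.count(cat), len(orr)),
                "n_manuscripts": mans.count(cat),
                "n_dlt_series": dlt.count(cat),
                "n_or_series": orr.count(cat),
            })
        return rows

    rows: list[dict] = []
    rows.append({
        "block": "totals", "category": "N",
        "manuscripts": str(len(db.studies)),
        "dlt_series": str(len(series_dlt)),
        "or_series": str(len(series_or)),
        "n_manuscripts": len(db.studies),
        "n_dlt_series": len(series_dlt),
        "n_or_series": len(series_or),
    })
    rows += block("year", lambda s: s.year)
    rows += block("design_class", lambda s: s.design_class)
    rows += block("disease_class", lambda s: s.disease_class)
    rows += block("disease", lambda s: s.disease)
    rows += block("treatment_class", lambda s: s.treatment_class)
    rows += block("contains_chemotherapy", lambda s: s.contains_chemotherapy)

    rows.append({
        "block": "dose_levels", "category": "median (IQR)",
        "manuscripts": "",
        "dlt_series": _median_iqr([s.n_levels for s in series_dlt]),
        "or_series": _median_iqr([s.n_levels for s in series_or]),
        "n_manuscripts": 0,
        "n_dlt_series": len(series_dlt),
        "n_or_series": len(series_or),
    })
    return pd.DataFrame(rows)


def _cell(count: int, total: int) -> str:
    pct = 0.0 if total == 0 else 100.0 * count / total
    return f"{count} ({pct:.0f}%)"


def _median_iqr(values: list[int]) -> str:
    """``"median (q1, q3)"`` with linear-interpolation (type-7) quantiles."""
    if not values:
        return "- (-, -)"
    arr = np.asarray(values, dtype=float)
    med, q1, q3 = (np.quantile(arr, q, method="linear") for q in (0.5, 0.25, 0.75))
    return f"{_num(med)} ({_num(q1)}, {_num(q3)})"


def _num(x: float) -> str:
    return f"{x:g}"


def render_characteristics(table: pd.DataFrame) -> str:
    """Plain-text rendering of the characteristics table."""
    lines = []
    width = max(len(str(c)) for c in table["category"]) + 2
    header = f"{'':{width}}  {'Manuscripts':>14}  {'DLT series':>14}  {'OR series':>14}"
    lines.append(header)
    for blockname, chunk in table.groupby("block", sort=False):
        lines.append(f"-- {blockname} --")
        for _, row in chunk.iterrows():
            lines.append(
                f"{row['category']:{width}}  {row['manuscripts']:>14}  "
                f"{row['dlt_series']:>14}  {row['or_series']:>14}"
            )
    return "\n".join(lines)
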