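"""CSV ingest for curated study/compound collections.

The curated corpus travels as four UTF-8 CSV files, one logical record per
row:

* ``compounds.csv`` — ingredient identity (id, names, CAS/EC, SMILES,
  use category, polymer/placeholder flags)
* ``opinions.csv``  — scientific opinions (number, year, covered compounds)
* ``studies.csv``   — one study per row; the guideline-profiled field map is
  linearized into a single cell (see below) to keep the row-per-record shape
* ``effects.csv``   — liver-parameter findings (compound, parameter,
  direction, qualifier flags, source)

Embedded tables and field maps are linearized with a fixed dialect: cells
separated by ``;``, rows by ``|``; literal separators are backslash-escaped.
Invalid rows are flagged, never dropped — violations ride along as a JSON
report so curator-visible discrepancies stay visible downstream.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field, replace
from pathlib import Path

import pandas as pd

from .errors import IngestError, UndefinedMetricError
from .liver_filter import EffectEntry, ParameterLexicon, default_lexicon
from .study_model import (
    CompoundRecord,
    NON_OECD,
    ProfileRegistry,
    ReliabilityBlock,
    StudyRecord,
    Violation,
    cas_checksum_ok,
    validate_record,
)


@dataclass(frozen=True)
class LinearDialect:
    """Delimiters for tables flattened to linear text inside one CSV cell."""

    cell: str = ";"
    row: str = "|"


DIALECT = LinearDialect()


def _lin_escape(text: str, dialect: LinearDialect = DIALECT) -> str:
    return (
        str(text)
        .replace("\\", "\\\\")
        .replace(dialect.cell, "\\" + dialect.cell)
        .replace(dialect.row, "\\" + dialect.row)
    )


def _lin_split(text: str, sep: str) -> list[str]:
    parts = re.split(r"(?<!\\)" + re.escape(sep), text)
    return [p.replace("\\" + sep, sep) for p in parts]


def _lin_unescape(text: str) -> str:
    return text.replace("\\\\", "\\")


@dataclass
class OpinionRecord:
    """One scientific opinion and the ingredients it covers."""

    sccs_number: str
    year: int
    compound_ids: list[str] = field(default_factory=list)


@dataclass
class Dataset:
    """The in-memory corpus every downstream module consumes."""

    compounds: list[CompoundRecord] = field(default_factory=list)
    opinions: list[OpinionRecord] = field(default_factory=list)
    studies: list[StudyRecord] = field(default_factory=list)
    effects: list[EffectEntry] = field(default_factory=list)

    def compound_by_id(self, compound_id: str) -> CompoundRecord | None:
        return next((c for c in self.compounds if c.compound_id == compound_id), None)

    def compound_by_name(self, name: str) -> CompoundRecord | None:
        low = name.strip().lower()
        return next(
            (c for c in self.compounds if c.ingredient_name.lower() == low), None
        )

    def latest_opinion(self, compound_id: str) -> OpinionRecord | None:
        """Conclusions attach to the most recent opinion for an ingredient."""
        covering = [o for o in self.opinions if compound_id in o.compound_ids]
        return max(covering, key=lambda o: o.year, default=None)

    def sorted_copy(self) -> "Dataset":
        return Dataset(
            compounds=sorted(self.compounds, key=lambda c: c.compound_id),
            opinions=sorted(self.opinions, key=lambda o: o.sccs_number),
            studies=sorted(self.studies, key=lambda s: (s.compound_id, s.study_id)),
            effects=sorted(
                self.effects,
                key=lambda e: (e.compound_id, e.parameter, e.direction, e.source),
            ),
        )


# -- readers -------------------------------------------------------------

_COMPOUND_COLUMNS = {"compound_id", "ingredient_name"}
_STUDY_COLUMNS = {"study_id", "compound_id"}


def _read_csv(path: Path) -> pd.DataFrame:
    try:
        return pd.read_csv(path, dtype=str, keep_default_na=False, encoding="utf-8")
    except OSError as err:
        raise IngestError(f"cannot read {path}: {err}") from err
    except pd.errors.ParserError as err:
        raise IngestError(f"malformed CSV {path}: {err}") from err


def _bool(text: str) -> bool:
    return str(text).strip().lower() in ("true", "yes", "1")


def parse_fields_cell(
    cell: str, dialect: LinearDialect = DIALECT
) -> list[tuple[str, str, str]]:
    """Parse a linearized field map into (path, value, provenance) triples."""
    triples: list[tuple[str, str, str]] = []
    if not cell.strip():
        return triples
    for row in _lin_split(cell, dialect.row):
        if not row.strip():
            continue
        parts = _lin_split(row, dialect.cell)
        if len(parts) < 2:
            raise IngestError(f"field row {row!r} lacks a path;value pair")
        path = _lin_unescape(parts[0].strip())
        value = _lin_unescape(parts[1])
        provenance = _lin_unescape(parts[2].strip()) if len(parts) > 2 else "paper"
        triples.append((path, value, provenance or "paper"))
    return triples


def render_fields_cell(
    record: StudyRecord, dialect: LinearDialect = DIALECT
) -> str:
    rows = []
    for path in sorted(record.fields):
        values = record.fields[path]
        for value in values if isinstance(values, list) else [values]:
            prov = record.provenance.get(path, "paper")
            rows.append(
                dialect.cell.join(
                    _lin_escape(x, dialect) for x in (path, value, prov)
                )
            )
    return dialect.row.join(rows)


def _study_from_row(row: dict, dialect: LinearDialect) -> StudyRecord:
    year = row.get("study_year", "").strip()
    glp = row.get("glp_status", "").strip()
    reliability = ReliabilityBlock(
        sccs_comments=row.get("sccs_comments", ""),
        study_year=int(year) if year else None,
        glp_status=_bool(glp) if glp else None,
        ref_in_dossier=row.get("ref_in_dossier", ""),
        additional_information=row.get("additional_information", ""),
        own_comments=row.get("own_comments", ""),
        control_recovery_group=row.get("control_recovery_group", "").strip() or None,
    )
    record = StudyRecord(
        study_id=row["study_id"].strip(),
        compound_id=row["compound_id"].strip(),
        guideline_id=row.get("guideline_id", "").strip() or NON_OECD,
        reliability=reliability,
    )
    for path, value, provenance in parse_fields_cell(row.get("fields", ""), dialect):
        existing = record.fields.get(path)
        if existing is None:
            record.fields[path] = value
        elif isinstance(existing, list):
            existing.append(value)
        else:
            record.fields[path] = [existing, value]
        record.provenance[path] = provenance
    return record


def read_dataset(
    data_dir: str | Path,
    profiles: ProfileRegistry | None = None,
    lexicon: ParameterLexicon | None = None,
    dialect: LinearDialect = DIALECT,
) -> tuple[Dataset, list[Violation]]:
    """Read the CSV corpus under *data_dir* with validation and provenance.

    Rows failing validation are retained but flagged.  Missing files yield
    empty collections; unreadable files and missing identifier columns are
    fatal.
    """
    data_dir = Path(data_dir)
    profiles = profiles or ProfileRegistry.builtin()
    lexicon = lexicon or default_lexicon()
    dataset = Dataset()
    violations: list[Violation] = []

    compounds_path = data_dir / "compounds.csv"
    if compounds_path.exists():
        frame = _read_csv(compounds_path)
        missing = _COMPOUND_COLUMNS - set(frame.columns)
        if missing:
            raise IngestError(f"{compounds_path}: missing columns {sorted(missing)}")
        for row in frame.to_dict("records"):
            record = CompoundRecord(
                compound_id=row["compound_id"].strip(),
                ingredient_name=row["ingredient_name"].strip(),
                inci_name=row.get("inci_name", ""),
                cas_number=row.get("cas_number", "").strip(),
                ec_number=row.get("ec_number", ""),
                smiles=row.get("smiles", ""),
                canonical_smiles=row.get("canonical_smiles", ""),
                use_category=row.get("use_category", "other").strip() or "other",
                function=row.get("function", ""),
                is_polymer=_bool(row.get("is_polymer", "")),
                is_placeholder=_bool(row.get("is_placeholder", "")),
            )
            if record.cas_number and not cas_checksum_ok(record.cas_number):
                # legacy registry numbers occur in source data: warn, keep
                violations.append(
                    Violation("", record.compound_id, "cas-checksum",
                              f"CAS {record.cas_number!r} fails the check-digit rule")
                )
            dataset.compounds.append(record)

    opinions_path = data_dir / "opinions.csv"
    if opinions_path.exists():
        frame = _read_csv(opinions_path)
        if "sccs_number" not in frame.columns:
            raise IngestError(f"{opinions_path}: missing column sccs_number")
        for row in frame.to_dict("records"):
            dataset.opinions.append(
                OpinionRecord(
                    sccs_number=row["sccs_number"].strip(),
                    year=int(row["year"]) if row.get("year", "").strip() else 0,
                    compound_ids=[
                        c.strip()
                        for c in row.get("compound_ids", "").split(";")
                        if c.strip()
                    ],
                )
            )

    studies_path = data_dir / "studies.csv"
    if studies_path.exists():
        frame = _read_csv(studies_path)
        missing = _STUDY_COLUMNS - set(frame.columns)
        if missing:
            raise IngestError(f"{studies_path}: missing columns {sorted(missing)}")
        seen: set[tuple[str, str]] = set()
        for row in frame.to_dict("records"):
            record = _study_from_row(row, dialect)
            key = (record.compound_id, record.study_id)
            if key in seen:
                violations.append(
                    Violation(record.study_id, "", "uniqueness",
                              f"duplicate (compound, study) pair {key}")
                )
            seen.add(key)
            dataset.studies.append(record)

    effects_path = data_dir / "effects.csv"
    if effects_path.exists():
        frame = _read_csv(effects_path)
        if "compound_id" not in frame.columns or "parameter" not in frame.columns:
            raise IngestError(f"{effects_path}: missing identifier columns")
        for row in frame.to_dict("records"):
            raw_param = row["parameter"].strip()
            canonical = lexicon.normalize_parameter(raw_param)
            if canonical is None:
                violations.append(
                    Violation("", row["compound_id"], "parameter",
                              f"unknown liver parameter {raw_param!r}")
                )
                canonical = raw_param  # retained, flagged
            raw_direction = row.get("direction", "").strip()
            if raw_direction in ("increase", "decrease", "change", "mixed"):
                direction = raw_direction  # already canonical
            else:
                direction = lexicon.normalize_direction(raw_direction) or "change"
            qualifiers = frozenset(
                q.strip() for q in row.get("qualifiers", "").split(";") if q.strip()
            )
            try:
                entry = EffectEntry(
                    compound_id=row["compound_id"].strip(),
                    parameter=canonical,
                    direction=direction,
                    qualifiers=qualifiers,
                    source=row.get("source", ""),
                )
            except Exception as err:  # bad flag/direction: flag, keep going
                violations.append(
                    Violation("", row["compound_id"], "parameter", str(err))
                )
                continue
            dataset.effects.append(entry)

    # referential integrity
    known = {c.compound_id for c in dataset.compounds}
    for study in dataset.studies:
        if dataset.compounds and study.compound_id not in known:
            violations.append(
                Violation(study.study_id, "", "reference",
                          f"unknown compound {study.compound_id!r}")
            )
    dataset.studies = dedupe_redundant_fields(dataset.studies)
    for study in dataset.studies:
        violations.extend(validate_record(study, profiles))
        for flag in study.conflicts:
            violations.append(Violation(study.study_id, flag, "conflict",
                                        "conflicting repeated values retained"))
    return dataset, violations


# -- redundancy handling -------------------------------------------------


def dedupe_redundant_fields(records: list[StudyRecord]) -> list[StudyRecord]:
    """Collapse repeated identical field mentions within each study.

    Dosages, routes and test-substance specifications are often restated
    across opinion sections; identical repeats collapse to one field while
    conflicting repeats are kept side by side and flagged, never silently
    merged.
    """
    out: list[StudyRecord] = []
    for record in records:
        fields: dict[str, object] = {}
        conflicts: list[str] = []
        for path, value in record.fields.items():
            if isinstance(value, list):
                distinct: list[str] = []
                for v in value:
                    if v not in distinct:
                        distinct.append(v)
                if len(distinct) == 1:
                    fields[path] = distinct[0]
                else:
                    fields[path] = distinct
                    conflicts.append(path)
            else:
                fields[path] = value
        out.append(replace(record, fields=fields, conflicts=sorted(conflicts)))
    return out


# -- write-back ----------------------------------------------------------


def write_dataset(
    dataset: Dataset, data_dir: str | Path, dialect: LinearDialect = DIALECT
) -> None:
    """Canonical CSV write-back (sorted rows; re-ingest yields an identical
    dataset)."""
    data_dir = Path(data_dir)
    data_dir.mkdir(parents=True, exist_ok=True)
    ds = dataset.sorted_copy()

    pd.DataFrame(
        [
            {
                "compound_id": c.compound_id,
                "ingredient_name": c.ingredient_name,
                "inci_name": c.inci_name,
                "cas_number": c.cas_number,
                "ec_number": c.ec_number,
                "smiles": c.smiles,
                "canonical_smiles": c.canonical_smiles,
                "use_category": c.use_category,
                "function": c.function,
                "is_polymer": str(c.is_polymer).lower(),
                "is_placeholder": str(c.is_placeholder).lower(),
            }
            for c in ds.compounds
        ],
        columns=["compound_id", "ingredient_name", "inci_name", "cas_number",
                 "ec_number", "smiles", "canonical_smiles", "use_category",
                 "function", "is_polymer", "is_placeholder"],
    ).to_csv(data_dir / "compounds.csv", index=False)

    pd.DataFrame(
        [
            {
                "sccs_number": o.sccs_number,
                "year": o.year,
                "compound_ids": ";".join(o.compound_ids),
            }
            for o in ds.opinions
        ],
        columns=["sccs_number", "year", "compound_ids"],
    ).to_csv(data_dir / "opinions.csv", index=False)

    pd.DataFrame(
        [
            {
                "study_id": s.study_id,
                "compound_id": s.compound_id,
                "guideline_id": s.guideline_id,
                "fields": render_fields_cell(s, dialect),
                "sccs_comments": s.reliability.sccs_comments,
                "study_year": s.reliability.study_year or "",
                "glp_status": ""
                if s.reliability.glp_status is None
                else str(s.reliability.glp_status).lower(),
                "ref_in_dossier": s.reliability.ref_in_dossier,
                "additional_information": s.reliability.additional_information,
                "own_comments": s.reliability.own_comments,
                "control_recovery_group": s.reliability.control_recovery_group or "",
            }
            for s in ds.studies
        ],
        columns=["study_id", "compound_id", "guideline_id", "fields",
                 "sccs_comments", "study_year", "glp_status", "ref_in_dossier",
                 "additional_information", "own_comments",
                 "control_recovery_group"],
    ).to_csv(data_dir / "studies.csv", index=False)

    pd.DataFrame(
        [
            {
                "compound_id": e.compound_id,
                "parameter": e.parameter,
                "direction": e.direction,
                "qualifiers": ";".join(sorted(e.qualifiers)),
                "source": e.source,
            }
            for e in ds.effects
        ],
        columns=["compound_id", "parameter", "direction", "qualifiers",
                 "source"],
    ).to_csv(data_dir / "effects.csv", index=False)


# -- JSON round trip -----------------------------------------------------


def dataset_to_dict(dataset: Dataset) -> dict:
    ds = dataset.sorted_copy()
    return {
        "compounds": [
            {
                "compound_id": c.compound_id,
                "ingredient_name": c.ingredient_name,
                "inci_name": c.inci_name,
                "cas_number": c.cas_number,
                "ec_number": c.ec_number,
                "smiles": c.smiles,
                "canonical_smiles": c.canonical_smiles,
                "use_category": c.use_category,
                "function": c.function,
                "is_polymer": c.is_polymer,
                "is_placeholder": c.is_placeholder,
            }
            for c in ds.compounds
        ],
        "opinions": [
            {"sccs_number": o.sccs_number, "year": o.year,
             "compound_ids": o.compound_ids}
            for o in ds.opinions
        ],
        "studies": [
            {
                "study_id": s.study_id,
                "compound_id": s.compound_id,
                "guideline_id": s.guideline_id,
                "fields": s.fields,
                "provenance": s.provenance,
                "conflicts": s.conflicts,
                "reliability": {
                    "sccs_comments": s.reliability.sccs_comments,
                    "study_year": s.reliability.study_year,
                    "glp_status": s.reliability.glp_status,
                    "ref_in_dossier": s.reliability.ref_in_dossier,
                    "additional_information": s.reliability.additional_information,
                    "own_comments": s.reliability.own_comments,
                    "control_recovery_group": s.reliability.control_recovery_group,
                },
            }
            for s in ds.studies
        ],
        "effects": [
            {
                "compound_id": e.compound_id,
                "parameter": e.parameter,
                "direction": e.direction,
                "qualifiers": sorted(e.qualifiers),
                "source": e.source,
            }
            for e in ds.effects
        ],
    }


def dataset_from_dict(data: dict) -> Dataset:
    return Dataset(
        compounds=[CompoundRecord(**c) for c in data.get("compounds", ())],
        opinions=[OpinionRecord(**o) for o in data.get("opinions", ())],
        studies=[
            StudyRecord(
                study_id=s["study_id"],
                compound_id=s["compound_id"],
                guideline_id=s.get("guideline_id", NON_OECD),
                fields=dict(s.get("fields", {})),
                provenance=dict(s.get("provenance", {})),
                conflicts=list(s.get("conflicts", ())),
                reliability=ReliabilityBlock(**s.get("reliability", {})),
            )
            for s in data.get("studies", ())
        ],
        effects=[
            EffectEntry(
                compound_id=e["compound_id"],
                parameter=e["parameter"],
                direction=e["direction"],
                qualifiers=frozenset(e.get("qualifiers", ())),
                source=e.get("source", ""),
            )
            for e in data.get("effects", ())
        ],
    )


# -- metrics -------------------------------------------------------------


def curation_accuracy(correct: int, total: int) -> int:
    """Percentage of correct entries, rounded to the nearest integer.

    E.g. 948 correct of 990 reviewed entries -> 96.
    """
    if total <= 0:
        raise UndefinedMetricError("accuracy is undefined for zero total entries")
    if not 0 <= correct <= total:
        raise UndefinedMetricError(
            f"correct count {correct} outside 0..{total}"
        )
    return int(math.floor(correct * 100 / total + 0.5))
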