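"""Reading and validation of activity-record and drug-annotation tables.

Two tabular inputs drive the whole analysis:

* an *activity table* — one row per dated compound→target measurement,
  carrying the assay-confidence metadata (relationship type, confidence
  score), the measurement type (Ki, IC50, ...), the relation operator,
  the potency value with its unit, and the release year;
* a *drug table* — one row per approved-drug annotation, where a single
  annotation may name a whole group of related protein accessions (e.g.
  a receptor with several subunits).

All structures are standardized to canonical SMILES at ingest so that
downstream drug↔compound matching is plain string equality.  All
concentration values are converted to nM so a single internal unit feeds
the measurement-consistency rule and the p-scale conversion.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml
from rdkit import Chem, RDLogger
from rdkit.Chem.MolStandardize import rdMolStandardize

RDLogger.DisableLog("rdApp.*")

__all__ = [
    "ActivityRecord",
    "DrugAnnotation",
    "Dialect",
    "standardize_structure",
    "read_activity_table",
    "read_drug_table",
    "expand_target_groups",
    "write_rejection_log",
]

#: measurement types whose values are concentrations (convertible to nM)
CONCENTRATION_TYPES = frozenset({"Ki", "IC50", "EC50", "Kd"})

#: conversion factors to nM
UNIT_TO_NM = {"nM": 1.0, "uM": 1e3, "µM": 1e3, "um": 1e3, "M": 1e9}

VALID_RELATIONS = frozenset({"=", ">", "<", "~"})


@dataclass(frozen=True)
class ActivityRecord:
    """One dated compound→target measurement with confidence metadata.

    ``value`` is the magnitude as reported; ``value_nM`` is the same
    quantity converted to nM when the measurement is a concentration
    (None for unitless types such as ``%max``).
    """

    compound_id: str
    structure: str  # canonical SMILES
    target_id: str
    target_family: str
    relationship_type: str
    confidence_score: int
    measurement_type: str
    relation: str
    value: float
    units: str
    year: int
    value_nM: float | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.confidence_score <= 9:
            raise ValueError(f"confidence score {self.confidence_score} outside [0, 9]")
        if self.value < 0:
            raise ValueError("potency magnitude must be non-negative")
        if not 1000 <= self.year <= 9999:
            raise ValueError(f"year {self.year} is not a 4-digit integer")


@dataclass(frozen=True)
class DrugAnnotation:
    """An approved-drug annotation with its group-expanded accession set."""

    drug_id: str
    name: str
    structure: str  # canonical SMILES
    category: str  # drug-action target / metabolizing enzyme / transporter / carrier
    target_ids: frozenset[str]

    def __post_init__(self) -> None:
        if not self.target_ids:
            raise ValueError("target_ids must be non-empty")


# --------------------------------------------------------------------------
# dialect (column-mapping) configuration
# --------------------------------------------------------------------------

ACTIVITY_FIELDS = (
    "compound_id",
    "smiles",
    "target_id",
    "target_family",
    "relationship_type",
    "confidence_score",
    "measurement_type",
    "relation",
    "value",
    "units",
    "year",
)
DRUG_FIELDS = ("drug_id", "name", "smiles", "category", "target_group")

#: columns that may be absent/blank without rejecting the row
OPTIONAL_ACTIVITY_FIELDS = frozenset({"target_family", "relation", "units"})


@dataclass(frozen=True)
class Dialect:
    """Maps the logical field names to the column names of a concrete file.

    The default dialect expects columns named exactly like the logical
    fields; a YAML/JSON config may override any subset, e.g.
    ``{"smiles": "canonical_smiles", "year": "release_year"}``.
    """

    activity: Mapping[str, str] = field(default_factory=dict)
    drug: Mapping[str, str] = field(default_factory=dict)

    def activity_column(self, logical: str) -> str:
        return self.activity.get(logical, logical)

    def drug_column(self, logical: str) -> str:
        return self.drug.get(logical, logical)

    @classmethod
    def from_file(cls, path: str | Path) -> "Dialect":
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        data = data or {}
        return cls(activity=data.get("activity", {}), drug=data.get("drug", {}))


# --------------------------------------------------------------------------
# structure standardization
# --------------------------------------------------------------------------

_FRAGMENT_CHOOSER = rdMolStandardize.LargestFragmentChooser(preferOrganic=True)
_UNCHARGER = rdMolStandardize.Uncharger()


def standardize_structure(smiles: str) -> str | None:
    """Standardize a SMILES string and return its canonical form.

    Recipe: parse → keep the largest organic fragment (salt/counter-ion
    stripping) → neutralize common charges → canonical SMILES.  The
    result is idempotent and independent of the input atom ordering;
    stereochemistry is preserved, so stereoisomers remain distinct.

    Returns None for unparsable input (the structure is flagged invalid
    and excluded downstream).
    """
    if smiles is None or not str(smiles).strip():
        return None
    mol = Chem.MolFromSmiles(str(smiles))
    if mol is None:
        return None
    try:
        mol = _FRAGMENT_CHOOSER.choose(mol)
        mol = _UNCHARGER.uncharge(mol)
    except Exception:  # pragma: no cover - defensive, RDKit edge cases
        return None
    return Chem.MolToSmiles(mol)


# --------------------------------------------------------------------------
# table readers
# --------------------------------------------------------------------------


def _read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    frame = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    if frame.empty:
        raise ValueError(f"{path}: empty table")
    return frame


def _require_columns(frame: pd.DataFrame, columns: Iterable[str], path: Path) -> None:
    missing = [c for c in columns if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s): {', '.join(missing)}")


def read_activity_table(
    path: str | Path, dialect: Dialect | None = None
) -> tuple[list[ActivityRecord], pd.DataFrame]:
    """Read an activity table into validated :class:`ActivityRecord` objects.

    Rows with an unparsable year or value, or an unparsable structure,
    are dropped and reported in the returned rejection log, a DataFrame
    with columns ``row_number`` (1-based data row) and ``reason``.
    Blank relations are treated as "=" (explicit values dominate source
    exports); concentration values are converted to nM.
    """
    dialect = dialect or Dialect()
    path = Path(path)
    frame = _read_table(path)
    required = [
        dialect.activity_column(f)
        for f in ACTIVITY_FIELDS
        if f not in OPTIONAL_ACTIVITY_FIELDS
    ]
    _require_columns(frame, required, path)

    records: list[ActivityRecord] = []
    rejections: list[tuple[int, str]] = []
    canon_cache: dict[str, str | None] = {}

    def col(row, logical, default=""):
        name = dialect.activity_column(logical)
        return str(row.get(name, default)).strip()

    for i, row in enumerate(frame.to_dict("records"), start=1):
        try:
            year = int(col(row, "year"))
        except ValueError:
            rejections.append((i, "unparsable year"))
            continue
        try:
            value = float(col(row, "value"))
        except ValueError:
            rejections.append((i, "unparsable value"))
            continue
        try:
            score = int(col(row, "confidence_score"))
        except ValueError:
            rejections.append((i, "unparsable confidence score"))
            continue
        raw_smiles = col(row, "smiles")
        if raw_smiles not in canon_cache:
            canon_cache[raw_smiles] = standardize_structure(raw_smiles)
        canonical = canon_cache[raw_smiles]
        if canonical is None:
            rejections.append((i, "invalid structure"))
            continue
        relation = col(row, "relation") or "="
        if relation not in VALID_RELATIONS:
            rejections.append((i, f"unknown relation {relation!r}"))
            continue
        mtype = col(row, "measurement_type")
        units = col(row, "units")
        value_nM: float | None = None
        if mtype in CONCENTRATION_TYPES:
            factor = UNIT_TO_NM.get(units)
            if factor is None:
                rejections.append((i, f"unknown concentration unit {units!r}"))
                continue
            value_nM = value * factor
        try:
            record = ActivityRecord(
                compound_id=col(row, "compound_id"),
                structure=canonical,
                target_id=col(row, "target_id"),
                target_family=col(row, "target_family"),
                relationship_type=col(row, "relationship_type"),
                confidence_score=score,
                measurement_type=mtype,
                relation=relation,
                value=value,
                units=units,
                year=year,
                value_nM=value_nM,
            )
        except ValueError as exc:
            rejections.append((i, str(exc)))
            continue
        records.append(record)

    log = pd.DataFrame(rejections, columns=["row_number", "reason"])
    return records, log


def expand_target_groups(
    drug_id: str,
    name: str,
    structure: str,
    category: str,
    target_group: Sequence[str] | str,
) -> DrugAnnotation | None:
    """Expand a grouped target annotation into one accession per member.

    ``target_group`` may be an iterable of accessions or a single string
    with members separated by ``|`` or ``;`` (how receptor groups such
    as an NMDA receptor with seven subunit accessions arrive in exports).
    Duplicates are removed.  An empty group yields None (annotation
    dropped; the caller logs a warning).
    """
    if isinstance(target_group, str):
        members = [t.strip() for t in target_group.replace(";", "|").split("|")]
    else:
        members = [str(t).strip() for t in target_group]
    accessions = frozenset(t for t in members if t)
    if not accessions:
        return None
    return DrugAnnotation(
        drug_id=drug_id,
        name=name,
        structure=structure,
        category=category,
        target_ids=accessions,
    )


def read_drug_table(
    path: str | Path, dialect: Dialect | None = None
) -> tuple[list[DrugAnnotation], pd.DataFrame]:
    """Read a drug-annotation table (one row per drug/category/group).

    Structures are standardized to canonical SMILES; rows with an
    unparsable structure or an empty target group are dropped and
    logged.  Each surviving row becomes one :class:`DrugAnnotation`
    with its accession group expanded and de-duplicated.
    """
    dialect = dialect or Dialect()
    path = Path(path)
    frame = _read_table(path)
    required = [dialect.drug_column(f) for f in DRUG_FIELDS]
    _require_columns(frame, required, path)

    annotations: list[DrugAnnotation] = []
    rejections: list[tuple[int, str]] = []
    canon_cache: dict[str, str | None] = {}
    for i, row in enumerate(frame.to_dict("records"), start=1):
        raw_smiles = str(row[dialect.drug_column("smiles")]).strip()
        if raw_smiles not in canon_cache:
            canon_cache[raw_smiles] = standardize_structure(raw_smiles)
        canonical = canon_cache[raw_smiles]
        if canonical is None:
            rejections.append((i, "invalid structure"))
            continue
        annotation = expand_target_groups(
            drug_id=str(row[dialect.drug_column("drug_id")]).strip(),
            name=str(row[dialect.drug_column("name")]).strip(),
            structure=canonical,
            category=str(row[dialect.drug_column("category")]).strip(),
            target_group=str(row[dialect.drug_column("target_group")]),
        )
        if annotation is None:
            rejections.append((i, "empty target group"))
            continue
        annotations.append(annotation)

    log = pd.DataFrame(rejections, columns=["row_number", "reason"])
    return annotations, log


def write_rejection_log(log: pd.DataFrame, path: str | Path) -> None:
    log.to_csv(path, sep="\t", index=False)
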