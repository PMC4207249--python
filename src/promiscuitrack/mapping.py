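"""Structure-based mapping of approved drugs to bioactive compounds.

Drug names differ between annotation databases and activity databases,
so matching is by exact canonical-SMILES equality only.  A drug may
match several compound entries (duplicate registrations of the same
structure); their curated interactions are pooled, keeping the earliest
first-report year per target.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

from .curation import CuratedInteraction
from .ingest import DrugAnnotation

__all__ = ["DrugCompoundMatch", "match_drugs_to_compounds", "drug_structures"]


@dataclass(frozen=True)
class DrugCompoundMatch:
    """A drug with all compound entries sharing its canonical structure
    and the union of their curated interactions."""

    drug_id: str
    structure: str
    compound_ids: frozenset[str]
    interactions: tuple[CuratedInteraction, ...]
    #: per target, the earliest release year across all matched compounds
    target_first_years: Mapping[str, int]
    #: per target, a family label (first non-empty seen)
    target_families: Mapping[str, str]


def drug_structures(drugs: Iterable[DrugAnnotation]) -> dict[str, str]:
    """Canonical structure per drug id (annotations of one drug agree)."""
    structures: dict[str, str] = {}
    for annotation in drugs:
        previous = structures.setdefault(annotation.drug_id, annotation.structure)
        if previous != annotation.structure:
            raise ValueError(
                f"drug {annotation.drug_id} has conflicting structures"
            )
    return structures


def match_drugs_to_compounds(
    drugs: Iterable[DrugAnnotation],
    interactions: Iterable[CuratedInteraction],
) -> tuple[list[DrugCompoundMatch], list[str]]:
    """Match drugs to compounds by canonical-SMILES identity.

    Returns the matches (sorted by drug id) and the list of unmatched
    drug ids; unmatched drugs are excluded from the temporal analysis.
    Matching is deterministic and independent of input order.
    """
    structures = drug_structures(drugs)

    by_structure: dict[str, list[CuratedInteraction]] = {}
    for interaction in interactions:
        by_structure.setdefault(interaction.structure, []).append(interaction)

    matches: list[DrugCompoundMatch] = []
    unmatched: list[str] = []
    for drug_id in sorted(structures):
        structure = structures[drug_id]
        pooled = by_structure.get(structure)
        if not pooled:
            unmatched.append(drug_id)
            continue
        first_years: dict[str, int] = {}
        families: dict[str, str] = {}
        for interaction in pooled:
            t = interaction.target_id
            if t not in first_years or interaction.first_year < first_years[t]:
                first_years[t] = interaction.first_year
            if interaction.target_family and not families.get(t):
                families[t] = interaction.target_family
        matches.append(
            DrugCompoundMatch(
                drug_id=drug_id,
                structure=structure,
                compound_ids=frozenset(i.compound_id for i in pooled),
                interactions=tuple(
                    sorted(pooled, key=lambda i: (i.compound_id, i.target_id))
                ),
                target_first_years=first_years,
                target_families=families,
            )
        )
    return matches, unmatched
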