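"""Confidence-tier curation and measurement consolidation.

Activity records are retained at three nested stringency levels:

``high``
    direct assays (relationship type "D") at confidence score 9, only
    explicit ("=") Ki or IC50 measurements; multiple measurements of the
    same type for one (compound, target) pair must agree within one
    order of magnitude or the pair is dropped.
``low1``
    relationship "D" / score 9 kept, but any measurement type and any
    relation operator qualifies and measurement consistency is ignored.
``low2``
    every record qualifies (confidence metadata ignored too).

By construction the retained interaction sets nest:
high ⊆ low1 ⊆ low2.  A (compound, target) pair counts as a single
interaction regardless of how many records support it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from typing import Iterable, Mapping, Sequence

from scipy.stats import gmean

from .ingest import ActivityRecord, CONCENTRATION_TYPES

__all__ = [
    "TIERS",
    "CuratedInteraction",
    "DatasetSummary",
    "filter_tier",
    "values_consistent",
    "consolidate_measurements",
    "curate",
    "potency_to_pscale",
    "summarize_dataset",
    "summarize_interactions",
    "summarize_annotations",
]

TIERS = ("high", "low1", "low2")

#: measurement types admitted to the high-confidence tier
HIGH_TIER_TYPES = frozenset({"Ki", "IC50"})

#: inclusive "same order of magnitude" ratio bound
_CONSISTENCY_RATIO = 10.0
_RATIO_EPS = 1e-12


@dataclass(frozen=True)
class CuratedInteraction:
    """A retained (compound, target) pair in a given confidence tier.

    ``potency_nM`` is the consolidated (geometric-mean) potency over the
    contributing concentration-type measurements, present only when such
    measurements exist; ``potency_by_type`` holds the per-measurement-type
    geometric means used by potency-distribution reports.
    """

    compound_id: str
    structure: str
    target_id: str
    target_family: str
    tier: str
    first_year: int
    measurement_type: str
    potency_nM: float | None = None
    potency_by_type: Mapping[str, float] = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.tier not in TIERS:
            raise ValueError(f"unknown tier {self.tier!r}")
        if self.potency_nM is not None and not self.potency_nM > 0:
            raise ValueError("consolidated potency must be positive")
        if self.potency_by_type is None:
            object.__setattr__(self, "potency_by_type", {})


def filter_tier(records: Iterable[ActivityRecord], tier: str) -> list[ActivityRecord]:
    """Return the records admissible at a confidence tier.

    The three tiers are nested record-wise: every record passing
    ``high`` passes ``low1``, and every record passes ``low2``.
    """
    if tier not in TIERS:
        raise ValueError(f"unknown tier {tier!r}; expected one of {TIERS}")
    records = list(records)
    if tier == "low2":
        return records
    direct = [
        r for r in records if r.relationship_type == "D" and r.confidence_score == 9
    ]
    if tier == "low1":
        return direct
    return [
        r
        for r in direct
        if r.measurement_type in HIGH_TIER_TYPES and r.relation == "="
    ]


def values_consistent(values: Sequence[float]) -> bool:
    """Do the potency values fall within the same order of magnitude?

    Operationalized as max/min ≤ 10 (log10 range ≤ 1), boundary
    inclusive, with a tiny epsilon so the boundary is deterministic
    under floating-point round-off.
    """
    if not values:
        raise ValueError("no values to check")
    lo, hi = min(values), max(values)
    if lo <= 0:
        raise ValueError("potency values must be positive")
    return hi / lo <= _CONSISTENCY_RATIO * (1.0 + _RATIO_EPS)


def consolidate_measurements(
    records: Sequence[ActivityRecord], tier: str
) -> CuratedInteraction | None:
    """Consolidate all records of one (compound, target) pair into one
    interaction, or return None when the pair is rejected.

    High tier: each measurement type (Ki, IC50) is consistency-checked
    separately; the pair is retained if at least one type has all its
    values within one order of magnitude, and the consolidated potency
    is the geometric mean over the passing types' values.  Low tiers:
    the pair is always retained and the potency (when concentration-type
    measurements exist) is the geometric mean of their nM values.
    """
    if not records:
        raise ValueError("no records for pair")
    if tier not in TIERS:
        raise ValueError(f"unknown tier {tier!r}")
    keys = {(r.compound_id, r.target_id) for r in records}
    if len(keys) != 1:
        raise ValueError("records span more than one (compound, target) pair")

    by_type: dict[str, list[ActivityRecord]] = {}
    for r in records:
        by_type.setdefault(r.measurement_type, []).append(r)

    if tier == "high":
        passing: dict[str, list[ActivityRecord]] = {}
        for mtype, group in by_type.items():
            values = sorted({r.value_nM for r in group})
            if values_consistent(values):
                passing[mtype] = group
        if not passing:
            return None
        contributing = [r for group in passing.values() for r in group]
        potency_by_type = {
            mtype: float(gmean(sorted({r.value_nM for r in group})))
            for mtype, group in passing.items()
        }
        all_values = sorted({r.value_nM for r in contributing})
        potency = float(gmean(all_values))
        mtypes = sorted(passing)
    else:
        contributing = list(records)
        conc = {
            mtype: sorted({r.value_nM for r in group if r.value_nM and r.value_nM > 0})
            for mtype, group in by_type.items()
            if mtype in CONCENTRATION_TYPES
        }
        conc = {m: v for m, v in conc.items() if v}
        potency_by_type = {m: float(gmean(v)) for m, v in conc.items()}
        all_values = sorted(v for vs in conc.values() for v in vs)
        potency = float(gmean(all_values)) if all_values else None
        mtypes = sorted(by_type)

    first = min(contributing, key=lambda r: r.year)
    family = next((r.target_family for r in contributing if r.target_family), "")
    return CuratedInteraction(
        compound_id=first.compound_id,
        structure=first.structure,
        target_id=first.target_id,
        target_family=family,
        tier=tier,
        first_year=min(r.year for r in contributing),
        measurement_type="+".join(mtypes),
        potency_nM=potency,
        potency_by_type=potency_by_type,
    )


def curate(
    records: Iterable[ActivityRecord], tier: str
) -> tuple[list[CuratedInteraction], list[tuple[str, str, str]]]:
    """Filter records to a tier and consolidate per (compound, target).

    Returns the curated interactions and a rejection list of
    ``(compound_id, target_id, reason)`` tuples (pairs whose potency
    measurements disagreed by more than an order of magnitude in the
    high tier).
    """
    admitted = filter_tier(records, tier)
    pairs: dict[tuple[str, str], list[ActivityRecord]] = {}
    for r in admitted:
        pairs.setdefault((r.compound_id, r.target_id), []).append(r)
    interactions: list[CuratedInteraction] = []
    rejected: list[tuple[str, str, str]] = []
    for (compound, target) in sorted(pairs):
        result = consolidate_measurements(pairs[(compound, target)], tier)
        if result is None:
            rejected.append((compound, target, "inconsistent potency measurements"))
        else:
            interactions.append(result)
    return interactions, rejected


def potency_to_pscale(value_nM: float) -> float:
    """Convert a concentration in nM to the p-scale (−log10 molar).

    100 nM → 7.0; 32 µM (32 000 nM) → ≈4.49; 1 M → 0.0.
    """
    if not value_nM > 0:
        raise ValueError("concentration must be positive")
    return -math.log10(value_nM * 1e-9)


def _round_half_up(x: float, digits: int = 1) -> float:
    q = Decimal(10) ** -digits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class DatasetSummary:
    """Corpus-level counts: entities, distinct targets, interactions,
    and the mean number of targets per entity (one decimal)."""

    n_entities: int
    n_targets: int
    n_interactions: int
    mean_targets_per_entity: float


def summarize_dataset(pairs: Iterable[tuple[str, str]]) -> DatasetSummary:
    """Summarize a set of (entity, target) interaction pairs.

    The mean targets-per-entity is interactions/entities rounded
    half-up to one decimal (the convention of corpus summary tables).
    """
    pairs = list(pairs)
    entities = {e for e, _ in pairs}
    if not entities:
        raise ValueError("no entities to summarize")
    targets = {t for _, t in pairs}
    n_interactions = len(set(pairs))
    return DatasetSummary(
        n_entities=len(entities),
        n_targets=len(targets),
        n_interactions=n_interactions,
        mean_targets_per_entity=_round_half_up(n_interactions / len(entities)),
    )


def summarize_interactions(interactions: Iterable[CuratedInteraction]) -> DatasetSummary:
    return summarize_dataset((i.compound_id, i.target_id) for i in interactions)


def summarize_annotations(annotations) -> DatasetSummary:
    """Summarize drug annotations (accession sets pooled per drug)."""
    pairs = [
        (a.drug_id, t) for a in annotations for t in a.target_ids
    ]
    return summarize_dataset(pairs)
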