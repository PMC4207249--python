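"""Promiscuity statistics over cumulative profiles.

Covers: per-interval five-number summaries of promiscuity rates,
per-drug increases and their histogram, target-family promiscuity,
annotation comparison between the two database kinds, and Tukey box
statistics of p-scale potencies per confidence tier.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from typing import Iterable, Mapping, Sequence

import numpy as np

from .curation import CuratedInteraction, potency_to_pscale
from .temporal import (
    N_INTERVALS,
    INTERVAL_LABELS,
    CumulativeProfile,
    interval_index,
)

__all__ = [
    "PromiscuitySummary",
    "IncreaseHistogram",
    "CrossDbComparison",
    "FamilyProfile",
    "PotencyDistribution",
    "interval_distribution",
    "promiscuity_increase",
    "increase_histogram",
    "increase_histogram_from_values",
    "family_promiscuity",
    "compare_profiles",
    "potency_distribution",
    "top_increases",
]


def _round_half_up(x: float, digits: int = 1) -> float:
    q = Decimal(10) ** -digits
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class PromiscuitySummary:
    """Five-number summary plus mean of per-drug promiscuity rates at
    one interval, over the drugs that have entered by that interval."""

    interval: str
    n_drugs: int
    min: float
    lower_quartile: float
    median: float
    upper_quartile: float
    max: float
    mean: float


def interval_distribution(
    profiles: Iterable[CumulativeProfile], interval: int | str
) -> PromiscuitySummary:
    """Distribution of promiscuity rates at one interval.

    Only drugs that entered at or before the interval contribute (a
    drug is absent, not zero, before its first record).  Quartiles use
    linear interpolation between order statistics.
    """
    i = interval if isinstance(interval, int) else interval_index(interval)
    rates = [p.rate(i) for p in profiles if p.rate(i) is not None]
    if not rates:
        raise ValueError(f"no drugs entered by interval {INTERVAL_LABELS[i]!r}")
    arr = np.asarray(rates, dtype=float)
    q1, med, q3 = np.percentile(arr, [25, 50, 75])
    return PromiscuitySummary(
        interval=INTERVAL_LABELS[i],
        n_drugs=len(rates),
        min=float(arr.min()),
        lower_quartile=float(q1),
        median=float(med),
        upper_quartile=float(q3),
        max=float(arr.max()),
        mean=float(arr.mean()),
    )


def promiscuity_increase(profile: CumulativeProfile) -> int:
    """Increase in cumulative rate from the drug's first to its most
    recent records: rate(last interval) − rate(entry interval); ≥ 0
    because the profile is cumulative."""
    return profile.final_rate - profile.entry_rate


@dataclass(frozen=True)
class IncreaseHistogram:
    """Counts and percentages of drugs per increase value, with values
    above ``upper`` pooled into one ">upper" bin."""

    bins: tuple[str, ...]
    counts: tuple[int, ...]
    percentages: tuple[float, ...]
    n: int

    def as_mapping(self) -> dict[str, tuple[int, float]]:
        return {
            b: (c, p) for b, c, p in zip(self.bins, self.counts, self.percentages)
        }


def increase_histogram_from_values(
    increases: Sequence[int], upper: int = 10
) -> IncreaseHistogram:
    """Histogram of per-drug increase values with a pooled ">upper" bin.

    Percentages are rounded half-up to one decimal; counts always sum
    to the number of drugs.
    """
    increases = list(increases)
    if not increases:
        raise ValueError("no increase values")
    n = len(increases)
    labels = [str(v) for v in range(upper + 1)] + [f">{upper}"]
    counts = [0] * (upper + 2)
    for v in increases:
        if v < 0:
            raise ValueError("increase values must be non-negative")
        counts[min(v, upper + 1)] += 1
    percentages = [_round_half_up(100.0 * c / n) for c in counts]
    return IncreaseHistogram(
        bins=tuple(labels), counts=tuple(counts), percentages=tuple(percentages), n=n
    )


def increase_histogram(
    profiles: Iterable[CumulativeProfile], upper: int = 10
) -> IncreaseHistogram:
    return increase_histogram_from_values(
        [promiscuity_increase(p) for p in profiles], upper=upper
    )


@dataclass(frozen=True)
class FamilyProfile:
    """Target-family view of one drug's cumulative profile."""

    drug_id: str
    family_counts: tuple[int, ...]  # distinct families per interval (0 before entry)
    family_increase: int
    first_record_families: frozenset[str]
    final_families: frozenset[str]


def family_promiscuity(
    profile: CumulativeProfile, family_map: Mapping[str, str]
) -> FamilyProfile:
    """Follow a drug's distinct target-family count over time.

    Targets missing from ``family_map`` (or mapped to an empty label)
    fall into the "unassigned" family.  The family count can never
    exceed the target count at any interval.
    """

    def families(targets: frozenset[str]) -> frozenset[str]:
        return frozenset(family_map.get(t) or "unassigned" for t in targets)

    counts = tuple(len(families(s)) for s in profile.target_sets)
    first = families(profile.target_sets[profile.entry_index])
    final = families(profile.target_sets[-1])
    return FamilyProfile(
        drug_id=profile.drug_id,
        family_counts=counts,
        family_increase=len(final) - len(first),
        first_record_families=first,
        final_families=final,
    )


@dataclass(frozen=True)
class CrossDbComparison:
    """Annotation-count comparison for one drug between the drug
    database (annotation-derived) and the activity database
    (record-derived) target sets."""

    drug_id: str
    n_db_targets: int
    n_activity_targets: int
    delta: int  # n_db − n_activity; may be negative
    n_common: int


def compare_profiles(
    drug_id: str,
    db_targets: Iterable[str],
    activity_targets: Iterable[str],
) -> CrossDbComparison:
    """Compare a drug's two accession sets (same namespace on both sides)."""
    db = frozenset(db_targets)
    act = frozenset(activity_targets)
    return CrossDbComparison(
        drug_id=drug_id,
        n_db_targets=len(db),
        n_activity_targets=len(act),
        delta=len(db) - len(act),
        n_common=len(db & act),
    )


@dataclass(frozen=True)
class PotencyDistribution:
    """Tukey box statistics of p-scale (−log10 M) potencies.

    Whisker ends are the extreme data points within 1.5×IQR of the
    quartiles; values outside are listed as outliers.
    """

    tier: str
    n: int
    lower_whisker: float
    lower_quartile: float
    median: float
    upper_quartile: float
    upper_whisker: float
    outliers: tuple[float, ...] = field(default_factory=tuple)


def potency_distribution(
    interactions: Iterable[CuratedInteraction], tier: str = ""
) -> PotencyDistribution:
    """Box statistics of pKi/pIC50 values for a set of interactions.

    Only Ki- and IC50-typed consolidated potencies contribute in every
    tier (other measurement types carry no p-scale value even where
    they count as interactions).
    """
    values: list[float] = []
    for interaction in interactions:
        for mtype in ("Ki", "IC50"):
            nm = interaction.potency_by_type.get(mtype)
            if nm is not None:
                values.append(potency_to_pscale(nm))
    if not values:
        raise ValueError("no Ki/IC50 potency values")
    arr = np.sort(np.asarray(values, dtype=float))
    q1, med, q3 = np.percentile(arr, [25, 50, 75])
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = arr[(arr >= lo_fence) & (arr <= hi_fence)]
    outliers = arr[(arr < lo_fence) | (arr > hi_fence)]
    return PotencyDistribution(
        tier=tier,
        n=len(arr),
        lower_whisker=float(inside.min()),
        lower_quartile=float(q1),
        median=float(med),
        upper_quartile=float(q3),
        upper_whisker=float(inside.max()),
        outliers=tuple(float(v) for v in outliers),
    )


def top_increases(
    profiles: Iterable[CumulativeProfile], k: int = 5
) -> list[tuple[str, int, int]]:
    """The k drugs with the largest promiscuity increase, as
    (drug_id, increase, final_rate), ties broken by drug id."""
    ranked = sorted(
        ((p.drug_id, promiscuity_increase(p), p.final_rate) for p in profiles),
        key=lambda t: (-t[1], t[0]),
    )
    return ranked[:k]
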