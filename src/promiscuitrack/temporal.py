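"""Time-interval binning and cumulative per-drug activity profiles.

Activity records are organized into 14 ordered intervals: "2000"
(absorbing everything reported up to and including 2000), the twelve
individual years "2001" … "2012", and ">2012" for everything later.
For each drug, the cumulative profile records, per interval, the set of
targets first reported at or before that interval; its size is the
drug's promiscuity rate at that interval.  A drug enters the statistics
at the interval of its first record and is absent (not zero) before.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .mapping import DrugCompoundMatch

__all__ = [
    "INTERVAL_LABELS",
    "N_INTERVALS",
    "assign_interval",
    "interval_index",
    "CumulativeProfile",
    "build_cumulative_profile",
    "record_span",
    "cumulative_drug_counts",
]

INTERVAL_LABELS: tuple[str, ...] = tuple(str(y) for y in range(2000, 2013)) + (">2012",)
N_INTERVALS = len(INTERVAL_LABELS)  # 14
_INDEX: dict[str, int] = {label: i for i, label in enumerate(INTERVAL_LABELS)}


def assign_interval(year: int) -> str:
    """Bin a release year into its time-interval label.

    Years up to 2000 collapse into "2000" (the start of the analysis);
    years after 2012 collapse into ">2012".
    """
    year = int(year)
    if year <= 2000:
        return "2000"
    if year > 2012:
        return ">2012"
    return str(year)


def interval_index(label: str) -> int:
    """Ordinal position (0–13) of an interval label."""
    try:
        return _INDEX[label]
    except KeyError:
        raise ValueError(f"unknown interval label {label!r}") from None


@dataclass(frozen=True)
class CumulativeProfile:
    """Per-drug monotone interval → target-set map.

    ``target_sets[i]`` is the set of targets first reported at or before
    interval ``i``; it is empty before the drug's entry interval and
    non-decreasing under inclusion afterwards.  ``raw_first_year`` and
    ``raw_last_year`` keep the uncollapsed years for span computation.
    """

    drug_id: str
    target_sets: tuple[frozenset[str], ...]
    entry_index: int
    raw_first_year: int
    raw_last_year: int

    @property
    def entry_interval(self) -> str:
        return INTERVAL_LABELS[self.entry_index]

    def rate(self, interval: int | str) -> int | None:
        """Promiscuity rate at an interval; None before the drug entered."""
        i = interval if isinstance(interval, int) else interval_index(interval)
        if i < self.entry_index:
            return None
        return len(self.target_sets[i])

    @property
    def final_rate(self) -> int:
        return len(self.target_sets[-1])

    @property
    def entry_rate(self) -> int:
        return len(self.target_sets[self.entry_index])


def build_cumulative_profile(
    match: DrugCompoundMatch | None = None,
    *,
    drug_id: str | None = None,
    target_first_years: Mapping[str, int] | None = None,
) -> CumulativeProfile:
    """Build the cumulative activity profile of one drug.

    Accepts either a :class:`~promiscuitrack.mapping.DrugCompoundMatch`
    or an explicit ``target → first year`` mapping.  Each target first
    appears at ``assign_interval`` of its earliest record year; the
    interval set is the union of all targets first appearing at or
    before that interval.
    """
    if match is not None:
        drug_id = match.drug_id
        target_first_years = dict(match.target_first_years)
    if not target_first_years:
        raise ValueError(f"drug {drug_id!r} has no dated interactions")

    first_index = {
        target: interval_index(assign_interval(year))
        for target, year in target_first_years.items()
    }
    sets: list[frozenset[str]] = []
    for i in range(N_INTERVALS):
        sets.append(frozenset(t for t, fi in first_index.items() if fi <= i))
    return CumulativeProfile(
        drug_id=str(drug_id),
        target_sets=tuple(sets),
        entry_index=min(first_index.values()),
        raw_first_year=min(target_first_years.values()),
        raw_last_year=max(target_first_years.values()),
    )


def record_span(profile: CumulativeProfile) -> int:
    """Years between the first and last raw record years.

    Raw years are used even though binning collapses everything before
    2000 — a drug first reported in 1981 and last in 2005 spans 24
    years, which the interval labels cannot express.
    """
    return profile.raw_last_year - profile.raw_first_year


def cumulative_drug_counts(profiles: Iterable[CumulativeProfile]) -> list[int]:
    """Per-interval count of drugs whose entry interval is ≤ t.

    The result has one entry per interval and is non-decreasing.
    """
    entries = [p.entry_index for p in profiles]
    return [sum(1 for e in entries if e <= i) for i in range(N_INTERVALS)]
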