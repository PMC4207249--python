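"""PAINS substructure screening of drug structures.

Pan-assay interference compounds (PAINS) carry substructure motifs —
rhodanines, catechols, quinones, hydrazones, azo bridges, ... — that
produce non-specific hits across many assay technologies.  Drugs
containing such motifs are flagged and their promiscuity trend is
compared against the full drug set.

The pattern list is data, not code: a two-column SMARTS file can be
supplied; the packaged default covers the classic PAINS motif classes.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from rdkit import Chem

from .temporal import N_INTERVALS, INTERVAL_LABELS, CumulativeProfile

__all__ = [
    "PainsPattern",
    "PainsScreenResult",
    "load_patterns",
    "default_patterns",
    "screen_structures",
    "pains_trend_comparison",
]


@dataclass(frozen=True)
class PainsPattern:
    pattern_id: str
    smarts: str
    description: str = ""

    def query(self) -> Chem.Mol:
        mol = Chem.MolFromSmarts(self.smarts)
        if mol is None:
            raise ValueError(
                f"pattern {self.pattern_id!r}: unparsable SMARTS {self.smarts!r}"
            )
        return mol


@dataclass(frozen=True)
class PainsScreenResult:
    drug_id: str
    matched_pattern_ids: frozenset[str]

    @property
    def positive(self) -> bool:
        return bool(self.matched_pattern_ids)


def load_patterns(path: str | Path) -> list[PainsPattern]:
    """Load a SMARTS pattern table (pattern_id, smarts[, description]).

    Every pattern must parse; an unparsable SMARTS is fatal at load.
    """
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    patterns = [
        PainsPattern(
            pattern_id=row["pattern_id"],
            smarts=row["smarts"],
            description=row.get("description", ""),
        )
        for row in frame.to_dict("records")
    ]
    for p in patterns:
        p.query()  # fail fast
    return patterns


def default_patterns() -> list[PainsPattern]:
    """The packaged default PAINS motif collection."""
    ref = resources.files("promiscuitrack.data") / "pains_default.tsv"
    with resources.as_file(ref) as path:
        return load_patterns(path)


def screen_structures(
    structures: Mapping[str, str],
    patterns: Iterable[PainsPattern] | None = None,
) -> list[PainsScreenResult]:
    """Screen drug structures (drug_id → SMILES) against the patterns.

    A drug is positive iff at least one pattern matches as a
    substructure.  Unparsable structures are skipped (with no result
    entry); screening is deterministic and order-independent.
    """
    patterns = list(default_patterns() if patterns is None else patterns)
    queries = [(p.pattern_id, p.query()) for p in patterns]
    results: list[PainsScreenResult] = []
    for drug_id in sorted(structures):
        mol = Chem.MolFromSmiles(structures[drug_id])
        if mol is None:
            continue
        matched = frozenset(
            pid for pid, query in queries if mol.HasSubstructMatch(query)
        )
        results.append(PainsScreenResult(drug_id=drug_id, matched_pattern_ids=matched))
    return results


def pains_trend_comparison(
    profiles: Iterable[CumulativeProfile],
    screen_results: Iterable[PainsScreenResult],
) -> pd.DataFrame:
    """Per-interval mean promiscuity of PAINS-positive drugs vs all drugs.

    Returns a frame with one row per interval: the number and mean rate
    of all entered drugs, and of the PAINS-positive subset (NaN where no
    positive drug has entered yet).  Restriction to the subset is a pure
    projection — it never changes any individual drug's rate.
    """
    profiles = list(profiles)
    positive_ids = {r.drug_id for r in screen_results if r.positive}
    rows = []
    for i in range(N_INTERVALS):
        all_rates = [p.rate(i) for p in profiles if p.rate(i) is not None]
        pains_rates = [
            p.rate(i)
            for p in profiles
            if p.drug_id in positive_ids and p.rate(i) is not None
        ]
        rows.append(
            {
                "interval": INTERVAL_LABELS[i],
                "n_all": len(all_rates),
                "mean_all": float(pd.Series(all_rates, dtype=float).mean())
                if all_rates
                else float("nan"),
                "n_pains": len(pains_rates),
                "mean_pains": float(pd.Series(pains_rates, dtype=float).mean())
                if pains_rates
                else float("nan"),
            }
        )
    return pd.DataFrame(rows)
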