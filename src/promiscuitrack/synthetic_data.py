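"""Synthetic activity / annotation tables with known ground truth.

The generator emulates the shape of the real inputs — dated activity
releases across the 14 analysis intervals, three nested confidence
tiers, heavy-tailed per-drug target counts with a small highly
promiscuous subset, partially discordant annotation sets between the
drug table and the activity table, and a minority of PAINS-bearing
structures — so that every pipeline stage can be exercised against a
recorded ground truth without any external download.

Per-drug final target counts come from a two-component mixture: most
drugs draw 1 + Poisson(λ) targets (λ derived from the configured mean),
while a small tail fraction draws uniformly from a high range, mirroring
the small subset of highly promiscuous drugs that dominates average
rates.  A configurable fraction of multi-measurement pairs receives
potency values spread by more than an order of magnitude, exercising
the high-tier rejection path.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from rdkit import Chem

from .temporal import N_INTERVALS, INTERVAL_LABELS

__all__ = ["SyntheticConfig", "generate_dataset", "write_dataset"]

_PAINS_CORE = "O=C1CSC(=S)N1"  # rhodanine scaffold grafted onto positives
_CHAIN_ATOMS = "CNO"

#: entry-interval weights: a sizable backlog by 2000, then a roughly
#: even flow of newly covered drugs per interval
_DEFAULT_ENTRY_WEIGHTS = (0.15,) + (0.85 / 13,) * 13

_LOW1_TYPES = ("EC50", "Kd", "%max", "Efficacy", "Residual Activity")
_ANNOTATION_CATEGORIES = (
    "drug-action target",
    "metabolizing enzyme",
    "transporter",
    "carrier",
)


@dataclass(frozen=True)
class SyntheticConfig:
    """Ground-truth parameters of the generated landscape."""

    n_drugs: int = 500
    n_decoy_compounds: int = 200
    #: mean of the per-drug final (high-tier, pre-noise) target count
    mean_final_promiscuity: float = 3.0
    #: fraction of drugs in the highly promiscuous tail …
    tail_fraction: float = 0.05
    #: … drawing their target count uniformly from this inclusive range
    tail_range: tuple[int, int] = (12, 30)
    #: per-interval probability of a drug's first high-confidence record
    entry_weights: tuple[float, ...] = _DEFAULT_ENTRY_WEIGHTS
    #: fraction of drugs present only in the annotation table
    unmatched_fraction: float = 0.1
    #: fraction of matched drugs registered under two compound ids
    duplicate_compound_fraction: float = 0.05
    #: expected extra low1-only / low2-only targets per drug
    low1_extra_rate: float = 15.0
    low2_extra_rate: float = 10.0
    #: expected annotation-only (drug-table) targets per drug
    db_only_rate: float = 7.0
    #: fraction of a drug's activity targets missing from its annotations
    db_missing_fraction: float = 0.2
    #: fraction of drugs whose structure carries a PAINS motif
    pains_fraction: float = 0.05
    #: probability that an annotation row groups several accessions
    group_annotation_prob: float = 0.15
    #: P(1, 2, 3 measurements) for a high-tier pair
    measurements_per_pair_probs: tuple[float, ...] = (0.5, 0.3, 0.2)
    #: probability that a pair's measurements disagree by >1 order of
    #: magnitude (forces ≥2 measurements; high-tier rejection path)
    inconsistency_prob: float = 0.05
    n_target_pool: int = 400
    n_families: int = 12
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "tail_fraction",
            "unmatched_fraction",
            "duplicate_compound_fraction",
            "db_missing_fraction",
            "pains_fraction",
            "group_annotation_prob",
            "inconsistency_prob",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if len(self.entry_weights) != N_INTERVALS:
            raise ValueError(f"entry_weights must have {N_INTERVALS} entries")
        if abs(sum(self.entry_weights) - 1.0) > 1e-9:
            raise ValueError("entry_weights must sum to 1")
        if abs(sum(self.measurements_per_pair_probs) - 1.0) > 1e-9:
            raise ValueError("measurements_per_pair_probs must sum to 1")
        if self.base_poisson_lambda() < 0:
            raise ValueError(
                "mean_final_promiscuity too small for the configured tail"
            )

    def base_poisson_lambda(self) -> float:
        """λ of the non-tail component so the mixture mean equals
        ``mean_final_promiscuity`` (counts are 1 + Poisson(λ))."""
        tail_mean = (self.tail_range[0] + self.tail_range[1]) / 2.0
        p = self.tail_fraction
        return (self.mean_final_promiscuity - p * tail_mean) / (1.0 - p) - 1.0


# --------------------------------------------------------------------------
# deterministic unique-structure factory
# --------------------------------------------------------------------------


class _StructureFactory:
    """Yields unique canonical SMILES: heteroatom-substituted carbon
    chains, optionally grafted onto the rhodanine PAINS scaffold."""

    def __init__(self) -> None:
        self._seen: set[str] = set()
        self._counter = 0

    def _chain(self, index: int) -> str:
        digits = []
        index += 3  # skip degenerate tiny chains
        while index:
            index, d = divmod(index, len(_CHAIN_ATOMS))
            digits.append(_CHAIN_ATOMS[d])
        return "CC" + "".join(digits)

    def next(self, pains: bool = False) -> str:
        while True:
            chain = self._chain(self._counter)
            self._counter += 1
            smiles = (_PAINS_CORE + chain) if pains else chain
            mol = Chem.MolFromSmiles(smiles)
            if mol is None:  # pragma: no cover - chains always parse
                continue
            canonical = Chem.MolToSmiles(mol)
            if canonical not in self._seen:
                self._seen.add(canonical)
                return canonical


def _interval_year(rng: np.random.Generator, interval: int) -> int:
    """A concrete release year inside an interval (the first interval
    reaches back before 2000, the last beyond 2012)."""
    if interval == 0:
        return int(rng.integers(1981, 2001))
    if interval == N_INTERVALS - 1:
        return int(rng.integers(2013, 2015))
    return 2000 + interval


# --------------------------------------------------------------------------
# generation
# --------------------------------------------------------------------------


def generate_dataset(
    config: SyntheticConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate (activity table, drug table, ground-truth table).

    All randomness flows from ``config.seed``; the same config yields
    byte-identical tables.  Ground truth records, per drug, the drawn
    target count, tier-wise final counts after noise injection, entry
    interval, promiscuity increase, PAINS status and annotation counts.
    """
    rng = np.random.default_rng(config.seed)
    factory = _StructureFactory()

    pool = [f"P{i:05d}" for i in range(config.n_target_pool)]
    families = {
        t: f"FAM{int(rng.integers(1, config.n_families + 1)):02d}" for t in pool
    }
    lam = config.base_poisson_lambda()
    n_meas_choices = np.arange(1, len(config.measurements_per_pair_probs) + 1)

    activity_rows: list[dict] = []
    drug_rows: list[dict] = []
    truth_rows: list[dict] = []

    def add_record(
        compound_id: str,
        smiles: str,
        target: str,
        mtype: str,
        relation: str,
        value_nm: float | None,
        year: int,
        rel_type: str = "D",
        score: int = 9,
        raw_value: float | None = None,
        units: str | None = None,
    ) -> None:
        if value_nm is not None:
            # occasionally report in µM to exercise unit conversion
            if value_nm >= 1000 and rng.random() < 0.3:
                raw_value, units = value_nm / 1000.0, "uM"
            else:
                raw_value, units = value_nm, "nM"
        activity_rows.append(
            {
                "compound_id": compound_id,
                "smiles": smiles,
                "target_id": target,
                "target_family": families.get(target, ""),
                "relationship_type": rel_type,
                "confidence_score": score,
                "measurement_type": mtype,
                "relation": relation,
                "value": round(float(raw_value), 6),
                "units": units if units is not None else "",
                "year": int(year),
            }
        )

    def emit_pair_measurements(
        compound_id: str, smiles: str, target: str, year: int
    ) -> bool:
        """Emit Ki/IC50 measurements for one pair; returns True when the
        values stay within one order of magnitude (high-tier valid)."""
        mtype = "Ki" if rng.random() < 0.5 else "IC50"
        inconsistent = rng.random() < config.inconsistency_prob
        n_meas = int(rng.choice(n_meas_choices, p=config.measurements_per_pair_probs))
        if inconsistent:
            n_meas = max(2, n_meas)
        base = 10.0 ** rng.uniform(0.5, 4.0)  # ~3 nM – 10 µM
        values = [base * 10.0 ** rng.uniform(-0.4, 0.4) for _ in range(n_meas)]
        if inconsistent:
            values[-1] *= 10.0 ** rng.uniform(2.0, 3.0)  # spread ratio > 10
        years = [year] + [
            min(2014, year + int(rng.integers(0, 4))) for _ in values[1:]
        ]
        for v, y in zip(values, years):
            add_record(compound_id, smiles, target, mtype, "=", v, y)
        return not inconsistent

    def sample_targets(k: int, exclude: set[str]) -> list[str]:
        candidates = [t for t in pool if t not in exclude]
        k = min(k, len(candidates))
        idx = rng.choice(len(candidates), size=k, replace=False) if k else []
        return [candidates[i] for i in idx]

    for d in range(config.n_drugs):
        drug_id = f"DRG{d:05d}"
        is_pains = bool(rng.random() < config.pains_fraction)
        smiles = factory.next(pains=is_pains)
        matched = rng.random() >= config.unmatched_fraction

        if rng.random() < config.tail_fraction:
            n_targets = int(rng.integers(config.tail_range[0], config.tail_range[1] + 1))
        else:
            n_targets = 1 + int(rng.poisson(lam))
        entry = int(rng.choice(N_INTERVALS, p=config.entry_weights))

        targets = sample_targets(n_targets, exclude=set())
        first_intervals = {targets[0]: entry} if targets else {}
        for t in targets[1:]:
            first_intervals[t] = int(rng.integers(entry, N_INTERVALS))
        first_years = {
            t: _interval_year(rng, iv) for t, iv in first_intervals.items()
        }

        high_valid: set[str] = set()
        low1_extra: list[str] = []
        low2_extra: list[str] = []
        if matched:
            compound_id = f"CPD{d:05d}"
            for t in targets:
                if emit_pair_measurements(compound_id, smiles, t, first_years[t]):
                    high_valid.add(t)

            # a second registration of the same structure for some drugs:
            # duplicate records, no new targets (union must not change
            # counts) — only high-valid targets are re-reported so a
            # rejected pair cannot re-enter the high tier via the twin
            if high_valid and rng.random() < config.duplicate_compound_fraction:
                dup_id = f"CPD{d:05d}b"
                for t in sorted(high_valid)[: max(1, len(high_valid) // 2)]:
                    add_record(
                        dup_id, smiles, t, "Ki", "=",
                        10.0 ** rng.uniform(1.0, 3.0),
                        min(2014, first_years[t] + int(rng.integers(0, 3))),
                    )

            # tier-1 noise: direct/score-9 records of other measurement
            # types (or approximate relations) on additional targets
            k1 = int(rng.poisson(config.low1_extra_rate))
            low1_extra = sample_targets(k1, exclude=set(targets))
            for t in low1_extra:
                year = _interval_year(rng, int(rng.integers(0, N_INTERVALS)))
                if rng.random() < 0.3:
                    add_record(compound_id, smiles, t, "Ki", ">",
                               10.0 ** rng.uniform(2.0, 5.0), year)
                else:
                    mtype = str(rng.choice(_LOW1_TYPES))
                    if mtype in ("EC50", "Kd"):
                        add_record(compound_id, smiles, t, mtype, "=",
                                   10.0 ** rng.uniform(0.5, 4.0), year)
                    else:
                        add_record(compound_id, smiles, t, mtype, "=", None, year,
                                   raw_value=float(rng.uniform(10, 100)), units="")

            # tier-2 noise: records below the direct/score-9 bar
            k2 = int(rng.poisson(config.low2_extra_rate))
            low2_extra = sample_targets(k2, exclude=set(targets) | set(low1_extra))
            for t in low2_extra:
                year = _interval_year(rng, int(rng.integers(0, N_INTERVALS)))
                rel_type = str(rng.choice(["H", "S", "U"]))
                add_record(compound_id, smiles, t, str(rng.choice(["Ki", "IC50", "EC50"])),
                           "=", 10.0 ** rng.uniform(0.5, 4.0), year,
                           rel_type=rel_type, score=int(rng.integers(0, 9)))

        # annotation (drug-table) side: drop some activity targets,
        # add annotation-only accessions — discordant by construction
        kept = [t for t in targets if rng.random() >= config.db_missing_fraction]
        n_db_only = int(rng.poisson(config.db_only_rate))
        db_only = [f"Q{d:04d}x{j:02d}" for j in range(n_db_only)]
        db_targets = kept + db_only
        if not db_targets:
            db_targets = [f"Q{d:04d}x00"]
        name = f"drug-{d:05d}"
        remaining = list(db_targets)
        while remaining:
            if len(remaining) > 1 and rng.random() < config.group_annotation_prob:
                size = int(rng.integers(2, min(4, len(remaining)) + 1))
            else:
                size = 1
            group, remaining = remaining[:size], remaining[size:]
            drug_rows.append(
                {
                    "drug_id": drug_id,
                    "name": name,
                    "smiles": smiles,
                    "category": str(rng.choice(_ANNOTATION_CATEGORIES)),
                    "target_group": "|".join(group),
                }
            )

        valid_intervals = [first_intervals[t] for t in high_valid]
        if matched and valid_intervals:
            entry_valid = min(valid_intervals)
            entry_rate = sum(1 for iv in valid_intervals if iv == entry_valid)
            entry_label = INTERVAL_LABELS[entry_valid]
            increase = len(high_valid) - entry_rate
        else:
            entry_label, increase = "", 0
        truth_rows.append(
            {
                "drug_id": drug_id,
                "smiles": smiles,
                "matched": matched,
                "pains_positive": is_pains,
                "n_targets_drawn": n_targets,
                "final_high": len(high_valid) if matched else 0,
                "final_low1": len(targets) + len(low1_extra) if matched else 0,
                "final_low2": (
                    len(targets) + len(low1_extra) + len(low2_extra) if matched else 0
                ),
                "entry_interval_high": entry_label,
                "increase_high": increase,
                "n_db_targets": len(set(db_targets)),
                "n_common_high": len(set(kept) & high_valid),
            }
        )

    # decoy compounds: activity-table-only structures, never drug-matched
    for c in range(config.n_decoy_compounds):
        compound_id = f"DEC{c:05d}"
        smiles = factory.next(pains=False)
        for t in sample_targets(1 + int(rng.poisson(0.5)), exclude=set()):
            year = _interval_year(rng, int(rng.integers(0, N_INTERVALS)))
            emit_pair_measurements(compound_id, smiles, t, year)

    activities = pd.DataFrame(activity_rows)
    drugs = pd.DataFrame(drug_rows)
    truth = pd.DataFrame(truth_rows)
    return activities, drugs, truth


def write_dataset(config: SyntheticConfig, out_dir: str | Path) -> dict[str, Path]:
    """Generate and write activities.tsv, drugs.tsv, ground_truth.tsv
    plus the config used (config.yaml); returns the paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    activities, drugs, truth = generate_dataset(config)
    paths = {
        "activities": out / "activities.tsv",
        "drugs": out / "drugs.tsv",
        "ground_truth": out / "ground_truth.tsv",
        "config": out / "config.yaml",
    }
    activities.to_csv(paths["activities"], sep="\t", index=False)
    drugs.to_csv(paths["drugs"], sep="\t", index=False)
    truth.to_csv(paths["ground_truth"], sep="\t", index=False)
    cfg = asdict(config)
    cfg["entry_weights"] = list(map(float, cfg["entry_weights"]))
    cfg["measurements_per_pair_probs"] = list(
        map(float, cfg["measurements_per_pair_probs"])
    )
    cfg["tail_range"] = list(cfg["tail_range"])
    paths["config"].write_text(yaml.safe_dump(cfg, sort_keys=False))
    return paths
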