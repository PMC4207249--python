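"""End-to-end orchestration: ingest → curation → mapping → temporal →
statistics → PAINS, with every report emitted as an inspectable TSV.

Each requested confidence tier gets its own sub-directory of reports;
a run manifest (inputs, parameters, package version) is written at the
top level.  Re-running with identical config and inputs reproduces
byte-identical reports (the manifest timestamp aside).
"""

from __future__ import annotations

import json
import logging
import sys
from dataclasses import dataclass, field, asdict
from datetime import datetime, timezone
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from . import __version__
from .ingest import Dialect, read_activity_table, read_drug_table
from .curation import (
    TIERS,
    curate,
    summarize_annotations,
    summarize_interactions,
)
from .mapping import match_drugs_to_compounds
from .temporal import (
    INTERVAL_LABELS,
    N_INTERVALS,
    CumulativeProfile,
    build_cumulative_profile,
    cumulative_drug_counts,
    record_span,
)
from . import stats as st
from .pains import (
    PainsScreenResult,
    default_patterns,
    load_patterns,
    pains_trend_comparison,
    screen_structures,
)

__all__ = ["RunConfig", "TierResult", "AnalysisResult", "run_analysis"]

log = logging.getLogger("promiscuitrack")


@dataclass(frozen=True)
class RunConfig:
    """Inputs and parameters of one analysis run."""

    activities_path: str | Path
    drugs_path: str | Path
    out_dir: str | Path
    tiers: Sequence[str] = ("high",)
    dialect_path: str | Path | None = None
    pains_path: str | Path | None = None
    increase_upper: int = 10
    family_upper: int = 5
    top_k: int = 5

    def __post_init__(self) -> None:
        for tier in self.tiers:
            if tier not in TIERS:
                raise ValueError(f"unknown tier {tier!r}")


@dataclass
class TierResult:
    """In-memory results for one confidence tier."""

    tier: str
    interactions: list
    curation_rejections: list
    matches: list
    unmatched_drugs: list[str]
    profiles: list[CumulativeProfile]
    drug_counts: list[int]
    interval_summaries: list[st.PromiscuitySummary]
    increase_histogram: st.IncreaseHistogram | None
    family_histogram: st.IncreaseHistogram | None
    top_increases: list[tuple[str, int, int]]
    crossdb: list[st.CrossDbComparison]
    potency: st.PotencyDistribution | None
    pains_trend: pd.DataFrame


@dataclass
class AnalysisResult:
    config: RunConfig
    activity_rejections: pd.DataFrame
    drug_rejections: pd.DataFrame
    screen_results: list[PainsScreenResult]
    tiers: dict[str, TierResult] = field(default_factory=dict)


def _write(frame: pd.DataFrame, path: Path) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, sep="\t", index=False)


def _stage(name: str, message: str) -> None:
    log.info("[%s] %s", name, message)


def run_analysis(config: RunConfig) -> AnalysisResult:
    """Run the full analysis and write all report tables.

    Any stage failure raises with a stage-tagged message.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    dialect = (
        Dialect.from_file(config.dialect_path) if config.dialect_path else Dialect()
    )

    try:
        _stage("ingest", f"reading {config.activities_path}")
        records, activity_rejections = read_activity_table(
            config.activities_path, dialect
        )
        drugs, drug_rejections = read_drug_table(config.drugs_path, dialect)
    except Exception as exc:
        raise RuntimeError(f"[ingest] {exc}") from exc
    _stage(
        "ingest",
        f"{len(records)} activity records ({len(activity_rejections)} rejected), "
        f"{len(drugs)} drug annotations ({len(drug_rejections)} rejected)",
    )
    _write(activity_rejections, out / "activity_rejections.tsv")
    _write(drug_rejections, out / "drug_rejections.tsv")

    # annotation-side target sets per drug (group-expanded, pooled)
    db_targets: dict[str, set[str]] = {}
    drug_structure: dict[str, str] = {}
    for a in drugs:
        db_targets.setdefault(a.drug_id, set()).update(a.target_ids)
        drug_structure.setdefault(a.drug_id, a.structure)

    try:
        _stage("pains", "screening drug structures")
        patterns = (
            load_patterns(config.pains_path) if config.pains_path else default_patterns()
        )
        screen_results = screen_structures(drug_structure, patterns)
    except Exception as exc:
        raise RuntimeError(f"[pains] {exc}") from exc
    _write(
        pd.DataFrame(
            {
                "drug_id": r.drug_id,
                "positive": r.positive,
                "matched_ids": ",".join(sorted(r.matched_pattern_ids)),
            }
            for r in screen_results
        ),
        out / "pains_screen.tsv",
    )

    result = AnalysisResult(
        config=config,
        activity_rejections=activity_rejections,
        drug_rejections=drug_rejections,
        screen_results=screen_results,
    )

    for tier in config.tiers:
        tier_out = out / tier
        try:
            result.tiers[tier] = _run_tier(
                tier, records, drugs, db_targets, screen_results, config, tier_out
            )
        except Exception as exc:
            raise RuntimeError(f"[{tier}] {exc}") from exc

    manifest = {
        "package": "promiscuitrack",
        "version": __version__,
        "generated_at": datetime.now(timezone.utc).isoformat(),
        "inputs": {
            "activities": str(config.activities_path),
            "drugs": str(config.drugs_path),
            "dialect": str(config.dialect_path) if config.dialect_path else None,
            "pains_patterns": str(config.pains_path) if config.pains_path else "default",
        },
        "parameters": {
            "tiers": list(config.tiers),
            "increase_upper": config.increase_upper,
            "family_upper": config.family_upper,
            "top_k": config.top_k,
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return result


def _run_tier(
    tier: str,
    records,
    drugs,
    db_targets: dict[str, set[str]],
    screen_results: list[PainsScreenResult],
    config: RunConfig,
    out: Path,
) -> TierResult:
    _stage(tier, "curating")
    interactions, rejections = curate(records, tier)
    _write(
        pd.DataFrame(
            [
                {
                    "compound_id": i.compound_id,
                    "smiles": i.structure,
                    "target_id": i.target_id,
                    "family": i.target_family,
                    "tier": i.tier,
                    "first_year": i.first_year,
                    "potency_nM": "" if i.potency_nM is None else round(i.potency_nM, 4),
                    "measurement_type": i.measurement_type,
                }
                for i in interactions
            ]
        ),
        out / "curated_interactions.tsv",
    )
    _write(
        pd.DataFrame(rejections, columns=["compound_id", "target_id", "reason"]),
        out / "curation_rejections.tsv",
    )

    summary_rows = []
    if interactions:
        s = summarize_interactions(interactions)
        summary_rows.append({"side": "compounds", **asdict(s)})
    if drugs:
        s = summarize_annotations(drugs)
        summary_rows.append({"side": "drug_annotations", **asdict(s)})
    _write(pd.DataFrame(summary_rows), out / "dataset_summary.tsv")

    _stage(tier, "matching drugs to compounds")
    matches, unmatched = match_drugs_to_compounds(drugs, interactions)
    _write(
        pd.DataFrame(
            {
                "drug_id": m.drug_id,
                "n_compounds": len(m.compound_ids),
                "n_interactions": len(m.interactions),
            }
            for m in matches
        ),
        out / "matches.tsv",
    )
    _write(pd.DataFrame({"drug_id": unmatched}), out / "unmatched_drugs.tsv")

    _stage(tier, "building cumulative profiles")
    profiles = [build_cumulative_profile(m) for m in matches]
    _write(
        pd.DataFrame(
            {"drug_id": p.drug_id, "interval": INTERVAL_LABELS[i], "n_targets": p.rate(i)}
            for p in profiles
            for i in range(p.entry_index, N_INTERVALS)
        ),
        out / "profiles_long.tsv",
    )
    _write(
        pd.DataFrame(
            {
                "drug_id": p.drug_id,
                "entry_interval": p.entry_interval,
                "span_years": record_span(p),
                "final_rate": p.final_rate,
                "increase": st.promiscuity_increase(p),
            }
            for p in profiles
        ),
        out / "drug_summary.tsv",
    )

    drug_counts = cumulative_drug_counts(profiles)
    _write(
        pd.DataFrame({"interval": INTERVAL_LABELS, "n_drugs": drug_counts}),
        out / "cumulative_drug_counts.tsv",
    )

    _stage(tier, "computing statistics")
    interval_summaries = [
        st.interval_distribution(profiles, i)
        for i in range(N_INTERVALS)
        if any(p.entry_index <= i for p in profiles)
    ]
    _write(
        pd.DataFrame([asdict(s) for s in interval_summaries]),
        out / "interval_summary.tsv",
    )

    histogram = st.increase_histogram(profiles, upper=config.increase_upper) if profiles else None
    if histogram:
        _write(
            pd.DataFrame(
                {
                    "increase": histogram.bins,
                    "n_drugs": histogram.counts,
                    "percent": histogram.percentages,
                }
            ),
            out / "increase_histogram.tsv",
        )

    family_map = {t: f for m in matches for t, f in m.target_families.items()}
    family_profiles = [st.family_promiscuity(p, family_map) for p in profiles]
    family_histogram = (
        st.increase_histogram_from_values(
            [fp.family_increase for fp in family_profiles], upper=config.family_upper
        )
        if family_profiles
        else None
    )
    if family_histogram:
        _write(
            pd.DataFrame(
                {
                    "family_increase": family_histogram.bins,
                    "n_drugs": family_histogram.counts,
                    "percent": family_histogram.percentages,
                }
            ),
            out / "family_increase_histogram.tsv",
        )

    top = st.top_increases(profiles, k=config.top_k)
    _write(
        pd.DataFrame(top, columns=["drug_id", "increase", "final_rate"]),
        out / "top_increases.tsv",
    )

    by_drug = {p.drug_id: p for p in profiles}
    crossdb = [
        st.compare_profiles(
            drug_id,
            db_targets.get(drug_id, set()),
            by_drug[drug_id].target_sets[-1],
        )
        for drug_id in sorted(by_drug)
    ]
    _write(pd.DataFrame([asdict(c) for c in crossdb]), out / "crossdb.tsv")

    potency = None
    if any(
        i.potency_by_type.get(m) for i in interactions for m in ("Ki", "IC50")
    ):
        potency = st.potency_distribution(interactions, tier=tier)
        row = asdict(potency)
        row["outliers"] = ",".join(f"{v:.4f}" for v in potency.outliers)
        _write(pd.DataFrame([row]), out / "potency_boxstats.tsv")

    trend = pains_trend_comparison(profiles, screen_results)
    _write(trend, out / "pains_trend.tsv")

    return TierResult(
        tier=tier,
        interactions=interactions,
        curation_rejections=rejections,
        matches=matches,
        unmatched_drugs=unmatched,
        profiles=profiles,
        drug_counts=drug_counts,
        interval_summaries=interval_summaries,
        increase_histogram=histogram,
        family_histogram=family_histogram,
        top_increases=top,
        crossdb=crossdb,
        potency=potency,
        pains_trend=trend,
    )
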