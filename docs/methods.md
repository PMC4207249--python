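# Methods

## Model and assumptions

The pipeline treats a drug's promiscuity rate as the cardinality of its
cumulative target set over dated activity records. Underlying assumptions:

* **One structure, one string.** Drug↔compound identity is exact equality of
  canonical SMILES after standardization. Tautomers and stereoisomers remain
  distinct; name-based matching is never used (names differ between
  annotation and activity databases).
* **A pair is one interaction.** However many records support a
  (compound, target) pair, it contributes a single interaction; the target's
  first year is the minimum release year over all contributing records in
  the active tier, pooled across all compounds matching the drug's structure.
* **Cumulative, never forgetting.** Target sets only grow over intervals;
  retractions or later re-curation of records are not modeled.
* **Entry-conditional statistics.** A drug is *absent* (not zero-valued)
  from interval statistics before its first record: distributions at
  interval *t* are over drugs whose data had become available by *t*.

## Curation rules and numerical choices

* **Tier definitions.** `high` = relationship "D", confidence score 9,
  explicit ("=") Ki/IC50 only, with the order-of-magnitude consistency rule;
  `low1` drops the measurement-type/relation/consistency requirements;
  `low2` additionally drops the confidence requirements. Record-wise and
  interaction-wise nesting holds by construction.
* **"Same order of magnitude"** is max/min ≤ 10 (equivalently a log10 range
  ≤ 1), boundary inclusive, with a 1e−12 relative epsilon so the boundary is
  deterministic under floating-point round-off. Ki and IC50 values for the
  same pair are checked separately per type; the pair survives if at least
  one type passes. Whether a historical analysis would have dropped the
  whole pair when one type failed is not documented anywhere we could rely
  on; the per-type rule is our choice and is flagged as such.
* **Consolidated potency** is the geometric mean (potencies are
  log-distributed); duplicated records cannot change decisions because
  consistency checks and means run over the distinct value set.
* **Units.** All concentrations are converted to nM at ingest (µM × 10³,
  M × 10⁹); p-scale values are −log10 of molar concentration. Unitless
  measurement types (%max, Efficacy, Residual Activity) carry no p-scale
  value and are excluded from potency distributions while still counting as
  interactions in the low tiers.
* **Quartiles** use linear interpolation between order statistics
  (numpy's default, the "type 7" convention). Interval box summaries report
  min/max extremes; potency box statistics use Tukey whiskers at 1.5×IQR
  with explicit outliers. Percentages are rounded half-up to one decimal.
* **Interval scheme.** 14 ordered bins: "2000" absorbs every year ≤ 2000,
  ">2012" every year > 2012. Record *spans* use raw years (a drug first
  reported 1981 and last 2005 spans 24 years) because binning collapses the
  pre-2000 era.
* **Standardization recipe.** RDKit parse → largest organic fragment
  (salt/counter-ion stripping) → neutralize common charges → canonical
  SMILES. Idempotent and atom-order independent. Stereochemistry is
  preserved — the safest default under an exact-string matching rule.
* **Blank relations** are read as "=" (explicit values dominate real
  exports); rows with unparsable years, values or structures are dropped
  into a rejection log, so `rows in = records out + rejections` always.

## Synthetic landscape generator

`synthetic_data` emulates the *shape* of curated activity exports, not their
chemistry:

* **Promiscuity mixture.** Per-drug final target counts are
  1 + Poisson(λ) for most drugs, with a `tail_fraction` (default 0.05)
  drawing uniformly from 12–30 targets; λ is derived so the mixture mean
  equals `mean_final_promiscuity` (default 3.0 targets per drug, the scale
  reported for high-confidence curation of real corpora). The tail mirrors
  the small highly promiscuous subset that dominates average rates.
* **Timing.** Entry intervals follow a weight vector defaulting to a 15%
  pre-2000 backlog and a uniform flow afterwards; later targets accrue
  uniformly over the remaining intervals. Concrete years are drawn inside
  each interval (1981–2000 for the first, 2013–2014 for the last).
* **Measurements.** 1–3 Ki/IC50 values per pair, log-jittered within a
  factor ~6; with `inconsistency_prob` (default 0.05) a pair's values are
  spread by a factor > 100, guaranteeing high-tier rejection while the low
  tiers retain the pair — the ground truth records tier membership *after*
  this injection. About 30% of µM-range values are written in µM units to
  exercise conversion.
* **Noise tiers.** Extra low1-only targets (default mean 15/drug) carry
  non-Ki/IC50 measurement types or approximate relations at full confidence;
  low2-only targets (default mean 10/drug) carry degraded relationship
  types/scores, echoing the order-of-magnitude inflation of interaction
  counts seen when stringency is relaxed.
* **Annotation discordance.** The drug table drops ~20% of each drug's
  activity targets and adds annotation-only accessions (mean 7/drug,
  separate namespace), so annotation-derived counts systematically exceed
  record-derived ones; some rows group several accessions to exercise group
  expansion.
* **PAINS positives** are built by grafting a rhodanine core onto the
  drug's scaffold chain (default 5% of drugs), guaranteeing a screening
  positive control. Structures are heteroatom-substituted carbon chains —
  valid, unique, and chemically trivial on purpose.

What the generator does **not** emulate: realistic medicinal chemistry,
assay biology, correlated target panels, name/synonym noise, or
species mixing. Passing tests therefore demonstrate the correctness of the
bookkeeping and statistics on data of the right shape, not performance on
any real database release.

## PAINS screening

The default pattern file ships ten hand-written SMARTS for classic PAINS
motif classes (rhodanine, catechol, ortho/para-quinones, phenolic
hydrazone, aromatic azo, isothiazolone, alkylidene barbiturate,
cross-conjugated dienone, β-nitrostyrene). The historical "26 substructures"
filter could not be reconstructed unambiguously from public sources, so the
pattern list is deliberately data, not code: any two-column SMARTS TSV can
be supplied with `--pains`. Tests cross-check screening calls against
RDKit's independent PAINS filter catalog.

## Problem sizes

Unit and property tests run on landscapes of 10–100 drugs; the parameter
recovery test uses the 500-drug default with fixed seeds — large enough that
three-standard-error recovery bands are meaningful, small enough for a
single-CPU suite in well under a minute. The acceptance script runs the
three-record worked example only.

## Known limitations

* No significance testing between tiers (none is defined for these
  descriptive statistics).
* The family taxonomy is an input column, not a built-in ontology; targets
  without a label fall into "unassigned".
* Reports are TSV only; plotting is left to downstream notebooks.
* Sub-year resolution, tautomer canonicalization, InChIKey or fuzzy
  structural matching are out of scope.
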