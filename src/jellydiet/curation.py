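"""Feature-table curation: the multi-rule refinement cascade.

Raw two-marker feature tables from stomach-content metabarcoding carry
laboratory contamination (visible in extraction blanks), low-confidence and
ecologically implausible taxonomic assignments, sub-threshold noise counts,
the predator's own DNA, and tag-switched reads.  The cascade applies, in a
fixed and audited order:

1. lineage reassignments from a user-supplied override table,
2. blank correction (drop features over-represented in extraction controls),
3. taxonomy filters (confidence thresholds and excluded groups, per marker),
4. per-cell minimum-read zeroing,
5. predator-read removal (species-level per stomach for COI; order-level in
   every sample for 18S, guarding against tag-switching),
6. regional-plausibility filter,
7. minimum per-sample read-depth filter.

Every rule reports exactly which features, cells, reads and samples it
removed; the report satisfies exact integer read conservation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .io import (
    ContractError,
    FeatureTable,
    RANKS,
    SampleMetadata,
    TaxonomyTable,
)

#: predator orders of the studied demersal/pelagic fish assemblage; 18S-mode
#: predator removal strips these orders from every sample.
DEFAULT_PREDATOR_ORDERS = (
    "Pleuronectiformes",
    "Gadiformes",
    "Perciformes",
    "Argentiniformes",
)


class ConfigError(ValueError):
    """A curation-config field is out of range or inconsistent."""


@dataclass
class CurationConfig:
    """Thresholds and modes of the refinement cascade.

    Defaults follow the strict threshold readings: features are dropped when
    their blank share *exceeds* ``blank_fraction_threshold``; COI features
    with best identity *below* ``min_best_identity`` and 18S features with
    phylum bootstrap *below* ``min_phylum_bootstrap`` are dropped (equality
    retains); cells with *fewer than* ``min_reads_per_cell`` reads are
    zeroed; samples with *at least* ``min_sample_reads`` reads are kept.
    """

    blank_fraction_threshold: float = 0.10
    min_best_identity: float = 0.85
    min_phylum_bootstrap: int = 70
    min_reads_per_cell: int = 5
    min_sample_reads: int = 1000
    predator_removal_coi: str = "species"  # per-sample, the focal predator only
    predator_removal_18s: str = "order"  # order-level, across all samples
    predator_orders: tuple[str, ...] = DEFAULT_PREDATOR_ORDERS
    regional_filter: bool = True
    blanks_include_pcr_negatives: bool = False
    reassignments: dict[str, dict[str, str]] = field(default_factory=dict)
    defaults_applied: tuple[str, ...] = ()

    _FIELDS = (
        "blank_fraction_threshold",
        "min_best_identity",
        "min_phylum_bootstrap",
        "min_reads_per_cell",
        "min_sample_reads",
        "predator_removal_coi",
        "predator_removal_18s",
        "predator_orders",
        "regional_filter",
        "blanks_include_pcr_negatives",
        "reassignments",
    )

    def __post_init__(self) -> None:
        if not 0 <= self.blank_fraction_threshold <= 1:
            raise ConfigError("blank_fraction_threshold must lie in [0, 1]")
        if not 0 <= self.min_best_identity <= 1:
            raise ConfigError("min_best_identity must lie in [0, 1]")
        if not 0 <= self.min_phylum_bootstrap <= 100:
            raise ConfigError("min_phylum_bootstrap must lie in [0, 100]")
        if self.min_reads_per_cell < 0:
            raise ConfigError("min_reads_per_cell must be non-negative")
        if self.min_sample_reads < 0:
            raise ConfigError("min_sample_reads must be non-negative")
        if self.predator_removal_coi not in {"species", "order"}:
            raise ConfigError("predator_removal_coi must be 'species' or 'order'")
        if self.predator_removal_18s not in {"species", "order"}:
            raise ConfigError("predator_removal_18s must be 'species' or 'order'")
        self.predator_orders = tuple(self.predator_orders)

    @classmethod
    def from_dict(cls, data: dict) -> "CurationConfig":
        unknown = sorted(set(data) - set(cls._FIELDS))
        if unknown:
            raise ConfigError(f"unknown config fields: {unknown}")
        defaults = tuple(f for f in cls._FIELDS if f not in data)
        return cls(**data, defaults_applied=defaults)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["predator_orders"] = list(self.predator_orders)
        d["defaults_applied"] = list(self.defaults_applied)
        return d


@dataclass
class RuleRecord:
    """Audit record for one cascade rule."""

    rule: str
    applied: bool
    features_removed: list[str] = field(default_factory=list)
    reads_removed: int = 0
    cells_zeroed: int = 0
    samples_dropped: list[str] = field(default_factory=list)
    detail: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class CurationReport:
    """Ordered audit trail of the cascade, with exact read conservation."""

    marker: str
    reads_in: int
    reads_out: int
    rules: list[RuleRecord]
    retained_samples: list[str]

    def check_conservation(self) -> None:
        removed = sum(r.reads_removed for r in self.rules)
        if self.reads_in - removed != self.reads_out:
            raise AssertionError(
                f"read conservation violated: {self.reads_in} - {removed} "
                f"!= {self.reads_out}"
            )

    def to_dict(self) -> dict:
        return {
            "marker": self.marker,
            "reads_in": self.reads_in,
            "reads_out": self.reads_out,
            "rules": [r.to_dict() for r in self.rules],
            "retained_samples": self.retained_samples,
        }


# ---------------------------------------------------------------------------
# individual rules
# ---------------------------------------------------------------------------


def apply_reassignments(
    tax: TaxonomyTable, overrides: dict[str, dict[str, str]]
) -> TaxonomyTable:
    """Replace lineages for selected features (e.g. curated re-identifications).

    ``overrides`` maps feature id to a partial or full lineage; ranks absent
    from an override are blanked, so demoting a species-level call to family
    level removes it from species-level summaries while keeping it at family
    level.
    """
    if not overrides:
        return tax
    unknown = [f for f in overrides if f not in tax.table.index]
    if unknown:
        raise ContractError(f"reassignment for unknown feature ids: {sorted(unknown)}")
    out = tax.table.copy()
    for fid, lineage in overrides.items():
        bad = sorted(set(lineage) - set(RANKS))
        if bad:
            raise ContractError(f"reassignment for {fid!r} uses unknown ranks: {bad}")
        for rank in RANKS:
            out.loc[fid, rank] = lineage.get(rank, "")
    return TaxonomyTable(tax.marker, out)


def blank_correct(
    table: FeatureTable,
    meta: SampleMetadata,
    threshold: float,
    include_pcr_negatives: bool = False,
) -> tuple[FeatureTable, RuleRecord]:
    """Drop features over-represented in no-template controls.

    A feature is removed iff the share of its total reads (across all
    samples, controls included) that falls in extraction blanks — optionally
    pooled with PCR negatives — strictly exceeds ``threshold``.  With no
    control sample present the rule is skipped and logged as such.
    """
    blank_ids = [s for s in meta.samples_of_type("extraction_blank") if s in table.sample_ids]
    if include_pcr_negatives:
        blank_ids += [s for s in meta.samples_of_type("pcr_negative") if s in table.sample_ids]
    rec = RuleRecord(rule="blank_correct", applied=bool(blank_ids))
    if not blank_ids:
        rec.detail["skipped"] = "no control samples present"
        return table, rec
    totals = table.counts.sum(axis=1)
    in_blanks = table.counts[blank_ids].sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        share = in_blanks / totals.replace(0, np.nan)
    removed = list(table.counts.index[share.fillna(0.0) > threshold])
    kept = table.counts.drop(index=removed)
    rec.features_removed = removed
    rec.reads_removed = int(totals.loc[removed].sum())
    rec.detail["control_samples"] = blank_ids
    return FeatureTable(table.marker, kept), rec


def filter_taxonomy(
    table: FeatureTable,
    tax: TaxonomyTable,
    config: CurationConfig,
    marker: str,
) -> tuple[FeatureTable, RuleRecord]:
    """Drop low-confidence and excluded-group features, per marker.

    COI: best identity below the threshold, terrestrial taxa, and the
    excluded groups (fungi / algae / rotifers, flagged upstream as likely
    secondary predation).  18S: features not assigned to Animalia, or with
    phylum-level bootstrap below the threshold.
    """
    tax.require_features(table.feature_ids)
    t = tax.table.loc[table.feature_ids]
    reasons: dict[str, str] = {}
    if marker == "COI":
        if t["best_identity"].isna().any():
            bad = list(t.index[t["best_identity"].isna()])
            raise ContractError(f"COI features lacking best_identity: {bad}")
        for fid, row in t.iterrows():
            if row["best_identity"] < config.min_best_identity:
                reasons[fid] = "identity"
            elif row["is_terrestrial"]:
                reasons[fid] = "terrestrial"
            elif row["excluded_group"]:
                reasons[fid] = "excluded_group"
    else:
        if t["phylum_bootstrap"].isna().any():
            bad = list(t.index[t["phylum_bootstrap"].isna()])
            raise ContractError(f"18S features lacking phylum_bootstrap: {bad}")
        for fid, row in t.iterrows():
            if row["kingdom"] != "Animalia":
                reasons[fid] = "non_animalia"
            elif row["phylum_bootstrap"] < config.min_phylum_bootstrap:
                reasons[fid] = "bootstrap"
    removed = [f for f in table.feature_ids if f in reasons]
    rec = RuleRecord(rule="filter_taxonomy", applied=True)
    rec.features_removed = removed
    rec.reads_removed = int(table.counts.loc[removed].to_numpy().sum())
    rec.detail["reasons"] = {f: reasons[f] for f in removed}
    return FeatureTable(marker, table.counts.drop(index=removed)), rec


def zero_low_cells(
    table: FeatureTable, min_reads: int
) -> tuple[FeatureTable, RuleRecord]:
    """Zero cells with fewer than ``min_reads`` reads; features emptied by
    the zeroing are dropped (features that were already all-zero stay)."""
    counts = table.counts.copy()
    nonzero_before = counts.sum(axis=1) > 0
    mask = (counts > 0) & (counts < min_reads)
    rec = RuleRecord(rule="zero_low_cells", applied=True)
    rec.cells_zeroed = int(mask.to_numpy().sum())
    rec.reads_removed = int(counts.where(mask, 0).to_numpy().sum())
    counts[mask] = 0
    if counts.size:
        empty = list(counts.index[(counts.sum(axis=1) == 0) & nonzero_before])
    else:
        empty = []
    rec.features_removed = empty
    counts = counts.drop(index=empty)
    return FeatureTable(table.marker, counts), rec


def remove_predator_reads(
    table: FeatureTable,
    tax: TaxonomyTable,
    meta: SampleMetadata,
    mode: str,
    predator_orders: tuple[str, ...] = DEFAULT_PREDATOR_ORDERS,
) -> tuple[FeatureTable, RuleRecord]:
    """Zero reads attributable to the predators themselves.

    ``mode='species'`` (COI): in each stomach, zero features whose
    species-level assignment equals that stomach's predator species.
    ``mode='order'`` (18S): zero features assigned to any configured predator
    order in *every* sample — reads of those orders found in other samples
    may be tag-switched predator DNA and cannot be trusted as prey.
    """
    tax.require_features(table.feature_ids)
    counts = table.counts.copy()
    t = tax.table.loc[table.feature_ids]
    rec = RuleRecord(rule="remove_predator_reads", applied=True)
    removed_per_sample: dict[str, int] = {}
    if mode == "species":
        for sid in meta.stomach_ids:
            if sid not in counts.columns:
                continue
            species = meta.table.loc[sid, "predator_species"]
            feats = list(t.index[t["species"] == species])
            if not feats:
                continue
            reads = int(counts.loc[feats, sid].sum())
            if reads:
                removed_per_sample[sid] = reads
            counts.loc[feats, sid] = 0
    elif mode == "order":
        if not predator_orders:
            raise ContractError("order-level predator removal needs a non-empty order list")
        feats = list(t.index[t["order"].isin(predator_orders)])
        for sid in counts.columns:
            reads = int(counts.loc[feats, sid].sum())
            if reads:
                removed_per_sample[sid] = reads
        counts.loc[feats, :] = 0
    else:
        raise ContractError(f"unknown predator-removal mode {mode!r}")
    rec.reads_removed = sum(removed_per_sample.values())
    rec.detail["reads_removed_per_sample"] = removed_per_sample
    empty = list(counts.index[counts.sum(axis=1) == 0]) if counts.size else []
    emptied = [f for f in empty if f not in table.counts.index[table.counts.sum(axis=1) == 0]]
    rec.features_removed = emptied
    counts = counts.drop(index=emptied)
    return FeatureTable(table.marker, counts), rec


def filter_regional(
    table: FeatureTable, tax: TaxonomyTable
) -> tuple[FeatureTable, RuleRecord]:
    """Drop features flagged implausible for the target geographic region."""
    tax.require_features(table.feature_ids)
    t = tax.table.loc[table.feature_ids]
    removed = list(t.index[~t["regionally_plausible"]])
    rec = RuleRecord(rule="filter_regional", applied=True)
    rec.features_removed = removed
    rec.reads_removed = int(table.counts.loc[removed].to_numpy().sum())
    return FeatureTable(table.marker, table.counts.drop(index=removed)), rec


def drop_low_depth_samples(
    table: FeatureTable, min_sample_reads: int
) -> tuple[FeatureTable, RuleRecord]:
    """Drop samples (controls included) whose remaining depth is below the
    minimum; a sample at exactly the minimum is kept."""
    depths = table.counts.sum(axis=0)
    dropped = list(depths.index[depths < min_sample_reads])
    rec = RuleRecord(rule="drop_low_depth_samples", applied=True)
    rec.samples_dropped = dropped
    rec.reads_removed = int(depths.loc[dropped].sum())
    return FeatureTable(table.marker, table.counts.drop(columns=dropped)), rec


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------


def curate(
    table: FeatureTable,
    tax: TaxonomyTable,
    meta: SampleMetadata,
    config: CurationConfig | None = None,
) -> tuple[FeatureTable, CurationReport]:
    """Run the full refinement cascade and return the audited result.

    The step order is fixed: reassignments, blank correction, taxonomy
    filters, per-cell zeroing, predator removal, regional plausibility, and
    finally the per-sample depth filter.  Cheap whole-feature filters run
    before cell-level edits; the depth rule is last so it sees fully curated
    depths.  The report satisfies exact read conservation and the cascade is
    idempotent on its own output under study-like conditions (controls fall
    below the depth threshold and are dropped in the first pass).
    """
    if config is None:
        config = CurationConfig()
    meta.require_samples(table.sample_ids)
    tax.require_features(table.feature_ids)
    marker = table.marker
    reads_in = table.total_reads
    rules: list[RuleRecord] = []

    tax = apply_reassignments(tax, config.reassignments)

    table, rec = blank_correct(
        table, meta, config.blank_fraction_threshold, config.blanks_include_pcr_negatives
    )
    rules.append(rec)

    table, rec = filter_taxonomy(table, tax, config, marker)
    rules.append(rec)

    table, rec = zero_low_cells(table, config.min_reads_per_cell)
    rules.append(rec)

    mode = config.predator_removal_coi if marker == "COI" else config.predator_removal_18s
    table, rec = remove_predator_reads(table, tax, meta, mode, config.predator_orders)
    rules.append(rec)

    if config.regional_filter:
        table, rec = filter_regional(table, tax)
        rules.append(rec)

    table, rec = drop_low_depth_samples(table, config.min_sample_reads)
    rules.append(rec)

    report = CurationReport(
        marker=marker,
        reads_in=reads_in,
        reads_out=table.total_reads,
        rules=rules,
        retained_samples=table.sample_ids,
    )
    report.check_conservation()
    return table, report
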