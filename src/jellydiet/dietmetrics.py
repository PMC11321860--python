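"""Diet composition metrics from curated feature tables.

Given a curated feature table (predator reads already removed), this module
computes the standard descriptors of metabarcoding diet studies:

- per-sample and per-species relative read abundance (RRA, in percent),
- absolute and percentage frequency of occurrence (FOO, %FOO),
- rank-level aggregation (e.g. family-level summaries for the
  low-resolution 18S marker), rolling unassigned features up to their
  deepest assigned rank,
- the gelatinous-zooplankton (GZP) fraction: overall RRA renormalized over
  gelatinous features only,
- the prey-importance index: GZP-fraction RRA (percent) x FOO, banded into
  low / medium / high importance.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .io import ContractError, FeatureTable, RANKS, SampleMetadata, TaxonomyTable

#: importance-band edges: importance <= low_max is "low", >= high_min is
#: "high", strictly between is "medium".  The bands close the integer-phrased
#: convention (<100 low, 101-499 medium, >500 high) so they partition [0, inf).
LOW_MAX = 100.0
HIGH_MIN = 500.0


def rra_per_sample(table: FeatureTable) -> pd.DataFrame:
    """Per-sample relative read abundance, in percent.

    Each sample's counts are divided by its column total and scaled to 100.
    All-zero samples yield all-zero columns (flagged via the ``empty_samples``
    attribute on the result) rather than NaN.
    """
    counts = table.counts.astype(float)
    totals = counts.sum(axis=0)
    empty = list(totals.index[totals == 0])
    safe = totals.replace(0, np.nan)
    out = counts.div(safe, axis=1).fillna(0.0) * 100.0
    out.attrs["empty_samples"] = empty
    return out


def overall_rra(
    table: FeatureTable,
    meta: SampleMetadata,
    species: str,
    method: str = "pooled",
) -> pd.Series:
    """Species-level overall RRA (percent) across a predator's stomachs.

    ``method='pooled'`` (default) sums reads over the species' retained
    stomachs and normalizes — each read counts equally, so deep samples
    weigh more.  ``method='mean'`` averages per-sample RRAs — each stomach
    counts equally.  Both sum to 100 when any reads exist.
    """
    stomachs = [s for s in meta.stomachs_of_species(species) if s in table.sample_ids]
    if not stomachs:
        raise ContractError(f"no retained stomach samples for species {species!r}")
    if method == "pooled":
        pooled = table.counts[stomachs].sum(axis=1).astype(float)
        total = pooled.sum()
        return pooled / total * 100.0 if total > 0 else pooled * 0.0
    if method == "mean":
        per_sample = rra_per_sample(FeatureTable(table.marker, table.counts[stomachs]))
        nonempty = [s for s in stomachs if s not in per_sample.attrs["empty_samples"]]
        if not nonempty:
            return pd.Series(0.0, index=table.counts.index)
        return per_sample[nonempty].mean(axis=1)
    raise ContractError(f"unknown overall_rra method {method!r}")


def foo(table: FeatureTable, meta: SampleMetadata, species: str) -> pd.DataFrame:
    """Frequency of occurrence per feature for one predator species.

    Returns a DataFrame with columns ``foo`` (number of the species'
    retained stomachs containing >= 1 read) and ``pct_foo``
    (= 100 * foo / n stomachs), plus ``n_samples``.
    """
    stomachs = [s for s in meta.stomachs_of_species(species) if s in table.sample_ids]
    if not stomachs:
        raise ContractError(f"no retained stomach samples for species {species!r}")
    n = len(stomachs)
    present = (table.counts[stomachs] >= 1).sum(axis=1).astype(int)
    return pd.DataFrame(
        {"foo": present, "pct_foo": 100.0 * present / n, "n_samples": n}
    )


def aggregate_rank(
    table: FeatureTable, tax: TaxonomyTable, rank: str
) -> tuple[FeatureTable, TaxonomyTable]:
    """Aggregate features to a lineage rank, conserving total reads exactly.

    Features unassigned at ``rank`` are rolled up to their deepest assigned
    rank and labelled with it, e.g. ``"Tentaculata (class)"``; fully
    unassigned features are grouped as ``"unassigned"``.  Trait flags of an
    aggregated group are the OR over its members; confidence scores are the
    member maximum (the group is at least as trustworthy as its best member).
    """
    if rank not in RANKS:
        raise ContractError(f"unknown rank {rank!r}; expected one of {RANKS}")
    tax.require_features(table.feature_ids)
    t = tax.table.loc[table.feature_ids]
    rank_pos = RANKS.index(rank)

    labels = {}
    for fid, row in t.iterrows():
        if row[rank] != "":
            labels[fid] = row[rank]
            continue
        rolled = "unassigned"
        for r in reversed(RANKS[:rank_pos]):
            if row[r] != "":
                rolled = f"{row[r]} ({r})"
                break
        labels[fid] = rolled

    lab = pd.Series(labels)
    agg_counts = table.counts.groupby(lab).sum()
    agg_counts.index.name = "feature_id"

    rows = []
    for label, members in t.groupby(lab.loc[t.index]):
        lineage = {}
        for i, r in enumerate(RANKS):
            vals = set(members[r]) - {""}
            lineage[r] = vals.pop() if len(vals) == 1 and i <= rank_pos else ""
        rows.append({
            "feature_id": label, **lineage,
            "best_identity": members["best_identity"].max(),
            "phylum_bootstrap": members["phylum_bootstrap"].max(),
            "is_gelatinous": bool(members["is_gelatinous"].any()),
            "is_benthic_gelatinous": bool(members["is_benthic_gelatinous"].any()),
            "is_terrestrial": bool(members["is_terrestrial"].any()),
            "excluded_group": bool(members["excluded_group"].any()),
            "regionally_plausible": bool(members["regionally_plausible"].all()),
        })
    agg_tax = TaxonomyTable(tax.marker, pd.DataFrame(rows).set_index("feature_id"))
    return FeatureTable(table.marker, agg_counts), agg_tax


def gzp_fraction_rra(
    table: FeatureTable,
    tax: TaxonomyTable,
    meta: SampleMetadata,
    species: str,
    method: str = "pooled",
    include_benthic: bool = True,
) -> pd.Series:
    """Overall RRA renormalized over the gelatinous fraction of the reads.

    Zooms into gelatinous features (optionally including benthic gelatinous
    invertebrates) and recomputes overall RRA over them alone, so the
    gelatinous composition is comparable across predators regardless of how
    much non-gelatinous prey they ate.  Returns an empty Series when the
    species has no gelatinous reads.
    """
    tax.require_features(table.feature_ids)
    t = tax.table.loc[table.feature_ids]
    gel = t["is_gelatinous"] | (t["is_benthic_gelatinous"] if include_benthic else False)
    gel_ids = list(t.index[gel])
    if not gel_ids:
        return pd.Series(dtype=float, name="gzp_rra_pct")
    sub = FeatureTable(table.marker, table.counts.loc[gel_ids])
    stomachs = [s for s in meta.stomachs_of_species(species) if s in table.sample_ids]
    if not stomachs:
        raise ContractError(f"no retained stomach samples for species {species!r}")
    if sub.counts[stomachs].to_numpy().sum() == 0:
        return pd.Series(dtype=float, name="gzp_rra_pct")
    out = overall_rra(sub, meta, species, method=method)
    out.name = "gzp_rra_pct"
    return out


@dataclass
class ImportanceRecord:
    """Prey-importance of one gelatinous taxon for one predator."""

    taxon: str
    predator_species: str
    marker: str
    gzp_rra_pct: float
    foo: int
    importance: float
    category: str

    def to_dict(self) -> dict:
        return asdict(self)


def importance(
    gzp_rra_pct: float,
    foo: int,
    taxon: str = "",
    predator_species: str = "",
    marker: str = "COI",
    low_max: float = LOW_MAX,
    high_min: float = HIGH_MIN,
) -> ImportanceRecord:
    """Importance index: GZP-fraction RRA (percent) x FOO, banded.

    ``importance <= low_max`` -> low; ``importance >= high_min`` -> high;
    strictly between -> medium.  The closed bands partition [0, inf).
    """
    if gzp_rra_pct < 0 or foo < 0:
        raise ContractError("importance inputs must be non-negative")
    value = float(gzp_rra_pct) * int(foo)
    if value <= low_max:
        category = "low"
    elif value >= high_min:
        category = "high"
    else:
        category = "medium"
    return ImportanceRecord(
        taxon=taxon, predator_species=predator_species, marker=marker,
        gzp_rra_pct=float(gzp_rra_pct), foo=int(foo),
        importance=value, category=category,
    )


def diet_table(
    table: FeatureTable,
    tax: TaxonomyTable,
    meta: SampleMetadata,
    rank: str | None = None,
    method: str = "pooled",
) -> "DietTable":
    """Per-(species, taxon) diet summary: overall RRA, FOO and %FOO.

    With ``rank`` set, the table is aggregated to that rank first (the usual
    choice for 18S is family).
    """
    if rank is not None:
        table, tax = aggregate_rank(table, tax, rank)
    frames = []
    for species in meta.predator_species:
        stomachs = [s for s in meta.stomachs_of_species(species) if s in table.sample_ids]
        if not stomachs:
            continue
        rra = overall_rra(table, meta, species, method=method)
        occ = foo(table, meta, species)
        df = pd.DataFrame({
            "predator_species": species,
            "overall_rra_pct": rra,
            "foo": occ["foo"],
            "pct_foo": occ["pct_foo"],
            "n_samples": occ["n_samples"],
        })
        df.index.name = "taxon"
        frames.append(df.reset_index())
    if frames:
        data = pd.concat(frames, ignore_index=True)
    else:
        data = pd.DataFrame(
            columns=["taxon", "predator_species", "overall_rra_pct", "foo",
                     "pct_foo", "n_samples"]
        )
    return DietTable(marker=table.marker, rank=rank, table=data)


@dataclass
class DietTable:
    """Diet summary rows for one marker at one (optional) aggregation rank."""

    marker: str
    rank: str | None
    table: pd.DataFrame

    def for_species(self, species: str) -> pd.DataFrame:
        t = self.table
        return t[t["predator_species"] == species].set_index("taxon")


def gzp_importance_table(
    table: FeatureTable,
    tax: TaxonomyTable,
    meta: SampleMetadata,
    rank: str | None = None,
    method: str = "pooled",
    include_benthic: bool = True,
) -> list[ImportanceRecord]:
    """Importance records for every (predator, gelatinous taxon) pair with
    at least one read, computed from the GZP-fraction RRA and FOO."""
    if rank is not None:
        table, tax = aggregate_rank(table, tax, rank)
    records: list[ImportanceRecord] = []
    for species in meta.predator_species:
        stomachs = [s for s in meta.stomachs_of_species(species) if s in table.sample_ids]
        if not stomachs:
            continue
        gzp = gzp_fraction_rra(table, tax, meta, species, method=method,
                               include_benthic=include_benthic)
        if gzp.empty:
            continue
        occ = foo(table, meta, species)
        for taxon, rra_pct in gzp.items():
            if table.counts.loc[taxon, stomachs].sum() == 0:
                continue
            records.append(importance(
                rra_pct, int(occ.loc[taxon, "foo"]), taxon=taxon,
                predator_species=species, marker=table.marker,
            ))
    return records
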