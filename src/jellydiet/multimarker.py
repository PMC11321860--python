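"""Reconcile prey detections between the COI and 18S markers.

Primer affinity and reference-database coverage differ between a
mitochondrial and a nuclear ribosomal marker, so each recovers prey taxa
the other misses (pelagic tunicates essentially only with 18S; cephalopods
and some parasites only with COI).  This module outer-joins per-species
diet tables harmonized to a common rank (family by default, because
species-level 18S calls are unreliable) and reports which taxa are shared
and which are single-marker.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .dietmetrics import DietTable
from .io import ContractError


@dataclass
class MarkerCongruence:
    """Outer join of two per-species diet tables on (species, taxon).

    Every row has at least one marker detecting the taxon (FOO >= 1).
    ``summary`` counts shared / COI-only / 18S-only taxa per predator.
    """

    rank: str | None
    table: pd.DataFrame
    summary: pd.DataFrame

    def for_species(self, species: str) -> pd.DataFrame:
        t = self.table
        return t[t["predator_species"] == species]


def harmonize(diet_coi: DietTable, diet_18s: DietTable, rank: str | None = "family") -> MarkerCongruence:
    """Join COI and 18S diet tables at a common aggregation rank.

    Both inputs must already be aggregated to ``rank`` (pass the same rank
    to :func:`jellydiet.dietmetrics.diet_table`); a mismatch is an error
    rather than a silent re-aggregation.
    """
    if diet_coi.marker != "COI" or diet_18s.marker != "18S":
        raise ContractError(
            f"expected (COI, 18S) diet tables, got ({diet_coi.marker}, {diet_18s.marker})"
        )
    if diet_coi.rank != rank or diet_18s.rank != rank:
        raise ContractError(
            f"rank mismatch: harmonizing at {rank!r} but tables are at "
            f"{diet_coi.rank!r} (COI) and {diet_18s.rank!r} (18S)"
        )

    def _prep(dt: DietTable, suffix: str) -> pd.DataFrame:
        t = dt.table[dt.table["foo"] >= 1]
        t = t[["predator_species", "taxon", "overall_rra_pct", "foo"]].copy()
        return t.rename(columns={
            "overall_rra_pct": f"rra_pct_{suffix}", "foo": f"foo_{suffix}",
        })

    merged = pd.merge(
        _prep(diet_coi, "coi"), _prep(diet_18s, "18s"),
        on=["predator_species", "taxon"], how="outer",
    )
    merged["detected_coi"] = merged["foo_coi"].notna()
    merged["detected_18s"] = merged["foo_18s"].notna()
    for col in ("foo_coi", "foo_18s"):
        merged[col] = pd.to_numeric(merged[col]).fillna(0).astype(int)
    for col in ("rra_pct_coi", "rra_pct_18s"):
        merged[col] = pd.to_numeric(merged[col]).fillna(0.0)
    merged = merged.sort_values(["predator_species", "taxon"]).reset_index(drop=True)

    rows = []
    for species, grp in merged.groupby("predator_species"):
        shared = int((grp["detected_coi"] & grp["detected_18s"]).sum())
        coi_only = int((grp["detected_coi"] & ~grp["detected_18s"]).sum())
        ssu_only = int((~grp["detected_coi"] & grp["detected_18s"]).sum())
        rows.append({
            "predator_species": species, "shared": shared,
            "coi_only": coi_only, "ssu_only": ssu_only,
            "union": shared + coi_only + ssu_only,
        })
    summary = pd.DataFrame(
        rows, columns=["predator_species", "shared", "coi_only", "ssu_only", "union"]
    )
    return MarkerCongruence(rank=rank, table=merged, summary=summary)
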