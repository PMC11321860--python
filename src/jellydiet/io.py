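"""Tabular I/O and validated in-memory containers.

The pipeline's interchange boundary is plain TSV: feature tables (features as
rows, samples as columns, integer read counts), per-feature taxonomy tables
with rank-column lineages, and sample metadata.  Upstream clustering /
denoising tools (MOTU pipelines for COI, ASV denoisers for 18S) export such
tables; everything downstream consumes the validated containers defined here.

Conventions: UTF-8 TSV; an empty string means "unassigned" at a lineage rank;
boolean trait flags are stored as 0/1; count cells are never missing.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

MARKERS = ("COI", "18S")
RANKS = ("kingdom", "phylum", "class", "order", "family", "genus", "species")
SAMPLE_TYPES = ("stomach", "extraction_blank", "pcr_negative")
REGIONS = ("west", "east", "south")

#: trait-flag columns carried by every taxonomy table
FLAG_COLUMNS = (
    "is_gelatinous",
    "is_benthic_gelatinous",
    "is_terrestrial",
    "excluded_group",
    "regionally_plausible",
)


class FormatError(ValueError):
    """A file or table violates the documented format contract."""


class ContractError(ValueError):
    """Inputs violate a precondition of an operation."""


def _check_marker(marker: str) -> str:
    if marker not in MARKERS:
        raise ContractError(f"unknown marker {marker!r}; expected one of {MARKERS}")
    return marker


# ---------------------------------------------------------------------------
# FeatureTable
# ---------------------------------------------------------------------------


@dataclass
class FeatureTable:
    """Integer read-count matrix (features x samples) for one marker.

    ``counts`` is a DataFrame indexed by feature id with sample ids as
    columns.  All counts are non-negative integers; duplicate feature or
    sample ids are rejected.
    """

    marker: str
    counts: pd.DataFrame

    def __post_init__(self) -> None:
        _check_marker(self.marker)
        counts = self.counts
        if counts.index.has_duplicates:
            dups = counts.index[counts.index.duplicated()].unique().tolist()
            raise FormatError(f"duplicate feature ids: {dups}")
        if counts.columns.has_duplicates:
            dups = counts.columns[counts.columns.duplicated()].unique().tolist()
            raise FormatError(f"duplicate sample ids: {dups}")
        if counts.size:
            arr = counts.to_numpy()
            if not np.issubdtype(arr.dtype, np.integer):
                frac = arr != np.floor(arr)
                if np.any(frac) or not np.all(np.isfinite(arr)):
                    i, j = np.argwhere(frac | ~np.isfinite(arr))[0]
                    raise FormatError(
                        f"non-integer count {arr[i, j]!r} at feature "
                        f"{counts.index[i]!r}, sample {counts.columns[j]!r}"
                    )
                counts = counts.astype(np.int64)
            if (counts.to_numpy() < 0).any():
                i, j = np.argwhere(counts.to_numpy() < 0)[0]
                raise FormatError(
                    f"negative count at feature {counts.index[i]!r}, "
                    f"sample {counts.columns[j]!r}"
                )
        counts = counts.astype(np.int64)
        counts.index = counts.index.astype(str)
        counts.columns = counts.columns.astype(str)
        counts.index.name = "feature_id"
        self.counts = counts

    @property
    def feature_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def total_reads(self) -> int:
        return int(self.counts.to_numpy().sum()) if self.counts.size else 0

    def copy(self) -> "FeatureTable":
        return FeatureTable(self.marker, self.counts.copy())

    def subset_samples(self, sample_ids) -> "FeatureTable":
        return FeatureTable(self.marker, self.counts[list(sample_ids)].copy())

    def equals(self, other: "FeatureTable") -> bool:
        return self.marker == other.marker and self.counts.equals(other.counts)


# ---------------------------------------------------------------------------
# TaxonomyTable
# ---------------------------------------------------------------------------


@dataclass
class TaxonomyTable:
    """Per-feature lineage plus assignment confidence and trait flags.

    COI rows carry ``best_identity`` (fraction in [0, 1], from best-hit
    identity to a reference sequence); 18S rows carry ``phylum_bootstrap``
    (0-100 classifier bootstrap at phylum rank).  The unused column may be
    absent or NaN.
    """

    marker: str
    table: pd.DataFrame

    def __post_init__(self) -> None:
        _check_marker(self.marker)
        df = self.table.copy()
        if df.index.name != "feature_id" and "feature_id" in df.columns:
            df = df.set_index("feature_id")
        if df.index.has_duplicates:
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise FormatError(f"duplicate taxonomy rows for features: {dups}")
        for rank in RANKS:
            if rank not in df.columns:
                raise FormatError(f"taxonomy table missing rank column {rank!r}")
            df[rank] = df[rank].fillna("").astype(str)
        for flag in FLAG_COLUMNS:
            if flag not in df.columns:
                raise FormatError(f"taxonomy table missing flag column {flag!r}")
            df[flag] = df[flag].astype(float).astype(bool)
        for col in ("best_identity", "phylum_bootstrap"):
            if col not in df.columns:
                df[col] = np.nan
            df[col] = pd.to_numeric(df[col], errors="raise")
        bi = df["best_identity"].dropna()
        if ((bi < 0) | (bi > 1)).any():
            raise FormatError("best_identity values must lie in [0, 1]")
        pb = df["phylum_bootstrap"].dropna()
        if ((pb < 0) | (pb > 100)).any():
            raise FormatError("phylum_bootstrap values must lie in [0, 100]")
        df.index.name = "feature_id"
        self.table = df

    def require_features(self, feature_ids) -> None:
        """Raise unless every feature id has exactly one taxonomy row."""
        missing = [f for f in feature_ids if f not in self.table.index]
        if missing:
            raise ContractError(f"taxonomy rows missing for features: {missing}")

    def lineage(self, feature_id: str) -> dict[str, str]:
        row = self.table.loc[feature_id]
        return {rank: row[rank] for rank in RANKS}

    def copy(self) -> "TaxonomyTable":
        return TaxonomyTable(self.marker, self.table.copy())


# ---------------------------------------------------------------------------
# SampleMetadata
# ---------------------------------------------------------------------------


@dataclass
class SampleMetadata:
    """Sample roles and grouping factors.

    Stomach samples carry predator species/order, sampling region and
    station; control samples (extraction blanks, PCR negatives) have empty
    predator fields.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.table.copy()
        if df.index.name != "sample_id" and "sample_id" in df.columns:
            df = df.set_index("sample_id")
        if df.index.has_duplicates:
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise FormatError(f"duplicate metadata rows for samples: {dups}")
        required = ["sample_type", "predator_species", "predator_order", "region", "station"]
        for col in required:
            if col not in df.columns:
                raise FormatError(f"metadata missing mandatory column {col!r}")
            df[col] = df[col].fillna("").astype(str)
        bad = sorted(set(df["sample_type"]) - set(SAMPLE_TYPES))
        if bad:
            raise FormatError(
                f"unknown sample_type values {bad}; expected one of {SAMPLE_TYPES}"
            )
        stomachs = df[df["sample_type"] == "stomach"]
        incomplete = stomachs[
            (stomachs["predator_species"] == "") | (stomachs["predator_order"] == "")
        ]
        if len(incomplete):
            raise FormatError(
                "stomach samples lacking predator species/order: "
                f"{list(incomplete.index)}"
            )
        controls = df[df["sample_type"] != "stomach"]
        nonempty = controls[
            (controls["predator_species"] != "") | (controls["predator_order"] != "")
        ]
        if len(nonempty):
            raise FormatError(
                f"control samples with predator fields set: {list(nonempty.index)}"
            )
        df.index.name = "sample_id"
        self.table = df[required]

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    def samples_of_type(self, sample_type: str) -> list[str]:
        if sample_type not in SAMPLE_TYPES:
            raise ContractError(f"unknown sample_type {sample_type!r}")
        return list(self.table.index[self.table["sample_type"] == sample_type])

    @property
    def stomach_ids(self) -> list[str]:
        return self.samples_of_type("stomach")

    def stomachs_of_species(self, species: str) -> list[str]:
        t = self.table
        mask = (t["sample_type"] == "stomach") & (t["predator_species"] == species)
        return list(t.index[mask])

    @property
    def predator_species(self) -> list[str]:
        t = self.table
        return sorted(set(t.loc[t["sample_type"] == "stomach", "predator_species"]))

    def require_samples(self, sample_ids) -> None:
        missing = [s for s in sample_ids if s not in self.table.index]
        if missing:
            raise ContractError(f"samples absent from metadata: {missing}")

    def copy(self) -> "SampleMetadata":
        return SampleMetadata(self.table.copy())


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def read_feature_table(path, marker: str) -> FeatureTable:
    """Read a features-x-samples TSV of integer read counts."""
    _check_marker(marker)
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    if df.index.name is None:
        df.index.name = "feature_id"
    parsed = pd.DataFrame(index=df.index.astype(str))
    for col in df.columns:
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            bad = df.index[vals.isna()][0]
            raise FormatError(
                f"{path.name}: non-numeric count at feature {bad!r}, sample {col!r}"
            )
        frac = vals != np.floor(vals)
        if frac.any():
            bad = df.index[frac][0]
            raise FormatError(
                f"{path.name}: non-integer count {df.loc[bad, col]!r} at feature "
                f"{bad!r}, sample {col!r}"
            )
        parsed[col] = vals.astype(np.int64)
    return FeatureTable(marker, parsed)


def write_feature_table(table: FeatureTable, path) -> None:
    table.counts.to_csv(path, sep="\t")


def read_taxonomy(path, marker: str) -> TaxonomyTable:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if "feature_id" not in df.columns:
        raise FormatError(f"{Path(path).name}: missing feature_id column")
    df = df.set_index("feature_id")
    for col in ("best_identity", "phylum_bootstrap"):
        if col in df.columns:
            df[col] = pd.to_numeric(df[col].mask(df[col] == "", np.nan))
    for flag in FLAG_COLUMNS:
        if flag in df.columns:
            df[flag] = pd.to_numeric(df[flag], errors="raise")
    return TaxonomyTable(marker, df)


def write_taxonomy(tax: TaxonomyTable, path) -> None:
    df = tax.table.copy()
    for flag in FLAG_COLUMNS:
        df[flag] = df[flag].astype(int)
    df.to_csv(path, sep="\t")


def read_metadata(path) -> SampleMetadata:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if "sample_id" not in df.columns:
        raise FormatError(f"{Path(path).name}: missing sample_id column")
    return SampleMetadata(df.set_index("sample_id"))


def write_metadata(meta: SampleMetadata, path) -> None:
    meta.table.to_csv(path, sep="\t")


def read_config(path):
    """Load a curation config from YAML or JSON, applying documented defaults.

    Returns a :class:`jellydiet.curation.CurationConfig`; fields absent from
    the file take the defaults recorded on that class, and the loaded object
    lists them in ``defaults_applied`` so audit logs can report which
    thresholds were user-supplied.
    """
    from .curation import CurationConfig

    path = Path(path)
    text = path.read_text()
    data = yaml.safe_load(text) if path.suffix in {".yml", ".yaml"} else json.loads(text)
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise FormatError(f"{path.name}: config must be a mapping")
    return CurationConfig.from_dict(data)


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
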