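"""Core in-memory containers for IgA-seq cohorts.

The common currency of the pipeline is a taxon-by-sample integer count
matrix (:class:`CountTable`) aligned with per-sample metadata
(:class:`SampleMetadata`) that records, for every sample, which subject it
came from, the subject's group (``control`` or ``celiac``), the collection
age (2.5 or 5 years), and the sorted fraction (``presort`` — the unsorted
fecal suspension; ``igapos`` — IgA-coated bacteria captured on anti-IgA
beads; ``iganeg`` — the flow-through).

All containers wrap pandas objects and validate their invariants on
construction, so downstream code can assume well-formed inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import FormatError, JoinError, ParameterError

GROUPS = ("control", "celiac")
AGES = (2.5, 5.0)
FRACTIONS = ("presort", "igapos", "iganeg")

#: Canonical taxonomy ranks, coarsest to finest.
RANKS = ("kingdom", "phylum", "class", "order", "family", "genus", "species")

METADATA_COLUMNS = ("sample_id", "subject_id", "group", "age", "fraction")


@dataclass
class CountTable:
    """Integer taxon x sample read-count matrix.

    Parameters
    ----------
    counts
        DataFrame with taxa as the index and samples as the columns.
        Entries must be non-negative integers (reads).
    """

    counts: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.counts
        if df.index.has_duplicates:
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise FormatError(f"duplicated taxon ids: {dups}")
        if df.columns.has_duplicates:
            dups = df.columns[df.columns.duplicated()].unique().tolist()
            raise FormatError(f"duplicated sample ids: {dups}")
        values = df.to_numpy()
        if values.size:
            if not np.issubdtype(values.dtype, np.integer):
                # floats are accepted only if they are exact integers
                rounded = np.rint(values)
                bad = ~np.isfinite(values) | (values != rounded)
                if bad.any():
                    i, j = np.argwhere(bad)[0]
                    raise FormatError(
                        f"non-integer count at taxon {df.index[i]!r}, "
                        f"sample {df.columns[j]!r}: {values[i, j]!r}"
                    )
                df = df.astype(np.int64)
                self.counts = df
                values = df.to_numpy()
            if (values < 0).any():
                i, j = np.argwhere(values < 0)[0]
                raise FormatError(
                    f"negative count at taxon {df.index[i]!r}, "
                    f"sample {df.columns[j]!r}: {values[i, j]}"
                )
        else:
            self.counts = df.astype(np.int64)
        self.counts.index.name = "taxon_id"

    @property
    def taxon_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns

    @property
    def n_taxa(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def depths(self) -> pd.Series:
        """Per-sample total read count."""
        return self.counts.sum(axis=0)

    def select(self, sample_ids) -> "CountTable":
        return CountTable(self.counts.loc[:, list(sample_ids)].copy())

    def equals(self, other: "CountTable") -> bool:
        return self.counts.equals(other.counts)


@dataclass
class SampleMetadata:
    """Per-sample design information for a sorted cohort.

    Enforces the cohort structure the sorting experiment implies: every
    subject-age has exactly one presort sample, and sorted fractions come
    as complete igapos/iganeg pairs or not at all.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.table
        missing = [c for c in METADATA_COLUMNS if c not in df.columns]
        if missing:
            raise FormatError(f"metadata missing columns: {missing}")
        df = df.copy()
        df["age"] = df["age"].astype(float)
        bad_group = set(df["group"]) - set(GROUPS)
        if bad_group:
            raise FormatError(f"unknown group labels: {sorted(bad_group)}")
        bad_frac = set(df["fraction"]) - set(FRACTIONS)
        if bad_frac:
            raise FormatError(f"unknown fraction labels: {sorted(bad_frac)}")
        if df["sample_id"].duplicated().any():
            dups = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
            raise FormatError(f"duplicated sample ids in metadata: {dups}")
        key = df[["subject_id", "age", "fraction"]]
        if key.duplicated().any():
            dup = key[key.duplicated()].iloc[0]
            raise FormatError(
                "duplicate (subject_id, age, fraction): "
                f"({dup['subject_id']}, {dup['age']}, {dup['fraction']})"
            )
        for (subj, age), grp in df.groupby(["subject_id", "age"]):
            fracs = set(grp["fraction"])
            if "presort" not in fracs:
                raise FormatError(
                    f"subject {subj!r} at age {age} lacks a presort sample"
                )
            if ("igapos" in fracs) != ("iganeg" in fracs):
                raise FormatError(
                    f"subject {subj!r} at age {age} has an unpaired sorted "
                    "fraction (igapos/iganeg must occur together)"
                )
        self.table = df.reset_index(drop=True)

    @property
    def sample_ids(self) -> pd.Index:
        return pd.Index(self.table["sample_id"])

    def select_ids(self, *, fraction=None, age=None, group=None) -> list:
        """Sample ids matching the given design slice, in table order."""
        df = self.table
        mask = pd.Series(True, index=df.index)
        if fraction is not None:
            mask &= df["fraction"] == fraction
        if age is not None:
            mask &= df["age"] == float(age)
        if group is not None:
            mask &= df["group"] == group
        return df.loc[mask, "sample_id"].tolist()

    def groups_of(self, sample_ids) -> pd.Series:
        lookup = self.table.set_index("sample_id")["group"]
        return lookup.loc[list(sample_ids)]


@dataclass
class Cohort:
    """A count table joined with its sample metadata."""

    counts: CountTable
    metadata: SampleMetadata

    def __post_init__(self) -> None:
        table_ids = set(self.counts.sample_ids)
        meta_ids = set(self.metadata.sample_ids)
        only_meta = sorted(meta_ids - table_ids)
        only_table = sorted(table_ids - meta_ids)
        if only_meta or only_table:
            parts = []
            if only_meta:
                parts.append(f"samples in metadata but not counts: {only_meta}")
            if only_table:
                parts.append(f"samples in counts but not metadata: {only_table}")
            raise JoinError("; ".join(parts))

    def select(self, *, fraction=None, age=None, group=None) -> CountTable:
        ids = self.metadata.select_ids(fraction=fraction, age=age, group=group)
        return self.counts.select(ids)


@dataclass
class TaxonomyTable:
    """Per-taxon rank-labeled lineage (kingdom through species).

    ``lineages`` is a DataFrame indexed by taxon_id with one column per
    rank in :data:`RANKS`; unassigned ranks are empty strings.
    """

    lineages: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.lineages
        if df.index.has_duplicates:
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise FormatError(f"duplicated taxon ids in taxonomy: {dups}")
        for rank in RANKS:
            if rank not in df.columns:
                df[rank] = ""
        df = df[list(RANKS)].fillna("").astype(str)
        df.index.name = "taxon_id"
        self.lineages = df

    def labels_at(self, rank: str) -> pd.Series:
        if rank not in RANKS:
            raise ParameterError(
                f"unknown rank {rank!r}; valid ranks: {list(RANKS)}"
            )
        return self.lineages[rank]

    def check_covers(self, table: CountTable) -> None:
        missing = sorted(set(table.taxon_ids) - set(self.lineages.index))
        if missing:
            raise JoinError(f"taxa without a taxonomy row: {missing}")


@dataclass
class FeatureTable:
    """Non-negative real feature x sample matrix (metabolites, cytokines).

    Values are normalized intensities; the sorted-fraction field of any
    joined metadata is irrelevant for these assays and ignored.
    """

    values: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.values.astype(float)
        if df.index.has_duplicates:
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise FormatError(f"duplicated feature ids: {dups}")
        if df.columns.has_duplicates:
            dups = df.columns[df.columns.duplicated()].unique().tolist()
            raise FormatError(f"duplicated sample ids: {dups}")
        arr = df.to_numpy()
        if arr.size and ((arr < 0).any() or ~np.isfinite(arr).all()):
            bad = np.argwhere((arr < 0) | ~np.isfinite(arr))[0]
            raise FormatError(
                f"negative or non-finite value at feature "
                f"{df.index[bad[0]]!r}, sample {df.columns[bad[1]]!r}"
            )
        df.index.name = "feature_id"
        self.values = df

    @property
    def feature_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns
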