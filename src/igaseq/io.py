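"""Readers and writers for the tabular formats the pipeline consumes.

The canonical dialect is UTF-8, tab-separated, with the first header cell
``taxon_id`` (or ``feature_id`` / ``sample_id`` for the other tables) and
``#``-prefixed comment lines ignored — the de facto ASV-table convention,
diff-friendly and round-trip exact for integer counts.

A read-only BIOM reader (JSON 1.0 profile and HDF5 2.1 layout) is provided
behind the same interface; TSV remains canonical.
"""

from __future__ import annotations

import io as _io
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import (
    Cohort,
    CountTable,
    FeatureTable,
    RANKS,
    SampleMetadata,
    TaxonomyTable,
)
from .errors import FormatError, ParameterError


def _read_tsv(path) -> pd.DataFrame:
    with open(path, "r", encoding="utf-8") as fh:
        lines = [ln for ln in fh if not ln.startswith("#")]
    if not lines:
        raise FormatError(f"{path}: empty file")
    return pd.read_csv(_io.StringIO("".join(lines)), sep="\t", dtype=str)


def read_count_table(path, metadata_path=None):
    """Read a taxon x sample count matrix, optionally joined to metadata.

    Returns a :class:`CountTable`, or a :class:`Cohort` when
    ``metadata_path`` is given (the join is validated both ways).
    """
    raw = _read_tsv(path)
    first = raw.columns[0]
    if first != "taxon_id":
        raise FormatError(
            f"{path}: first column header must be 'taxon_id', got {first!r}"
        )
    raw = raw.set_index("taxon_id")
    cols = {}
    for col in raw.columns:
        try:
            cols[col] = raw[col].astype(np.int64)
        except (ValueError, TypeError):
            numeric = pd.to_numeric(raw[col], errors="coerce")
            bad = raw.index[numeric.isna() | (numeric % 1 != 0)]
            taxon = bad[0] if len(bad) else raw.index[0]
            raise FormatError(
                f"{path}: non-integer count at taxon {taxon!r}, sample {col!r}"
            ) from None
    counts = pd.DataFrame(cols, index=raw.index)
    table = CountTable(counts)
    if metadata_path is None:
        return table
    metadata = read_sample_metadata(metadata_path)
    return Cohort(table, metadata)


def write_count_table(table: CountTable, path) -> None:
    table.counts.to_csv(path, sep="\t", index_label="taxon_id")


def read_sample_metadata(path) -> SampleMetadata:
    df = _read_tsv(path)
    return SampleMetadata(df)


def write_sample_metadata(metadata: SampleMetadata, path) -> None:
    df = metadata.table.copy()
    # keep ages as '2.5'/'5.0' text so round-trips are exact
    df["age"] = df["age"].map(lambda a: format(float(a), "g"))
    df.to_csv(path, sep="\t", index=False)


def read_taxonomy(path) -> TaxonomyTable:
    """Read a two-column TSV: taxon_id, semicolon-delimited lineage."""
    df = _read_tsv(path)
    if "taxon_id" not in df.columns or "lineage" not in df.columns:
        raise FormatError(f"{path}: taxonomy needs columns taxon_id, lineage")
    rows = {}
    for _, rec in df.iterrows():
        raw = "" if pd.isna(rec["lineage"]) else str(rec["lineage"])
        parts = [p.strip() for p in raw.split(";")]
        parts = (parts + [""] * len(RANKS))[: len(RANKS)]
        rows[rec["taxon_id"]] = parts
    lineages = pd.DataFrame.from_dict(rows, orient="index", columns=list(RANKS))
    return TaxonomyTable(lineages)


def write_taxonomy(taxonomy: TaxonomyTable, path) -> None:
    lineage = taxonomy.lineages.apply(
        lambda row: ";".join(row).rstrip(";"), axis=1
    )
    out = pd.DataFrame({"taxon_id": taxonomy.lineages.index, "lineage": lineage})
    out.to_csv(path, sep="\t", index=False)


def read_feature_table(path) -> FeatureTable:
    raw = _read_tsv(path)
    if raw.columns[0] != "feature_id":
        raise FormatError(
            f"{path}: first column header must be 'feature_id', "
            f"got {raw.columns[0]!r}"
        )
    raw = raw.set_index("feature_id")
    try:
        values = raw.astype(float)
    except (ValueError, TypeError):
        raise FormatError(f"{path}: non-numeric feature value") from None
    return FeatureTable(values)


def write_feature_table(features: FeatureTable, path) -> None:
    features.values.to_csv(
        path, sep="\t", index_label="feature_id", float_format="%.10g"
    )


# ---------------------------------------------------------------------------
# BIOM (read-only, optional)

def read_biom(path) -> CountTable:
    """Read a BIOM observation x sample table (JSON 1.0 or HDF5 2.1)."""
    path = Path(path)
    with open(path, "rb") as fh:
        magic = fh.read(8)
    if magic.startswith(b"\x89HDF"):
        return _read_biom_hdf5(path)
    return _read_biom_json(path)


def _read_biom_json(path) -> CountTable:
    with open(path, "r", encoding="utf-8") as fh:
        doc = json.load(fh)
    try:
        taxa = [r["id"] for r in doc["rows"]]
        samples = [c["id"] for c in doc["columns"]]
        matrix_type = doc["matrix_type"]
        data = doc["data"]
    except (KeyError, TypeError) as exc:
        raise FormatError(f"{path}: not a BIOM JSON table ({exc})") from None
    counts = np.zeros((len(taxa), len(samples)), dtype=np.int64)
    if matrix_type == "sparse":
        for i, j, v in data:
            counts[int(i), int(j)] = int(v)
    elif matrix_type == "dense":
        counts[:] = np.asarray(data, dtype=np.int64)
    else:
        raise FormatError(f"{path}: unknown BIOM matrix_type {matrix_type!r}")
    return CountTable(pd.DataFrame(counts, index=taxa, columns=samples))


def _read_biom_hdf5(path) -> CountTable:
    import h5py

    with h5py.File(path, "r") as h5:
        taxa = [t.decode() if isinstance(t, bytes) else str(t)
                for t in h5["observation/ids"][:]]
        samples = [s.decode() if isinstance(s, bytes) else str(s)
                   for s in h5["sample/ids"][:]]
        grp = h5["observation/matrix"]  # CSR over observations
        data = grp["data"][:]
        indices = grp["indices"][:]
        indptr = grp["indptr"][:]
    counts = np.zeros((len(taxa), len(samples)), dtype=np.int64)
    for i in range(len(taxa)):
        cols = indices[indptr[i]:indptr[i + 1]]
        counts[i, cols] = np.rint(data[indptr[i]:indptr[i + 1]]).astype(np.int64)
    return CountTable(pd.DataFrame(counts, index=taxa, columns=samples))


# ---------------------------------------------------------------------------
# Taxa agglomeration

def agglomerate(table: CountTable, taxonomy: TaxonomyTable,
                rank: str) -> CountTable:
    """Sum counts of taxa sharing the same label at ``rank``.

    Taxa with an empty label at that rank are pooled into ``"unclassified"``
    rather than dropped, so per-sample totals are conserved exactly —
    downstream relative abundances depend on that.
    """
    if rank not in RANKS:
        raise ParameterError(
            f"unknown rank {rank!r}; valid ranks: {list(RANKS)}"
        )
    taxonomy.check_covers(table)
    labels = taxonomy.labels_at(rank).reindex(table.taxon_ids)
    labels = labels.where(labels.str.len() > 0, "unclassified")
    grouped = table.counts.groupby(labels.values, sort=False).sum()
    grouped.index.name = "taxon_id"
    return CountTable(grouped)
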