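"""The IgA coating index (ICI) and its retention, normalization, and
high-coater rules.

For each taxon, the ICI is the ratio of its relative abundance in the
IgA-positive fraction to its relative abundance in the IgA-negative
fraction: values well above 1 mark taxa preferentially targeted by the
mucosal antibody response, values near 1 taxa the sort does not separate.

Group-level indices (ICI_control, ICI_celiac) are computed per age from
group-aggregated relative abundances. Taxa with both group indices below 1
are discarded for the heatmap, except discordant taxa — coated in one
group but not the other (one index < 1, the other > 1) — which are kept.
A taxon with a group index above 10 is a "high coater" in that group.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import Cohort, CountTable
from .errors import (
    DegenerateSampleError,
    InsufficientDataError,
    ParameterError,
)

HIGH_COATER_THRESHOLD = 10.0
DEFAULT_PSEUDOCOUNT = 1.0


@dataclass
class RelativeAbundanceTable:
    """Per-sample proportions (columns sum to 1) plus the pseudocount used."""

    proportions: pd.DataFrame
    pseudocount: float


def relative_abundance(table, pseudocount: float = 0.0) -> RelativeAbundanceTable:
    """Column-normalize counts to proportions after adding a pseudocount.

    A pseudocount of 1 read per cell (the pipeline default downstream)
    keeps every proportion strictly positive so ratios stay finite.
    """
    if pseudocount < 0:
        raise ParameterError(f"pseudocount must be >= 0, got {pseudocount}")
    counts = table.counts if isinstance(table, CountTable) else table
    shifted = counts.astype(float) + pseudocount
    totals = shifted.sum(axis=0)
    if (totals <= 0).any():
        bad = totals.index[totals <= 0].tolist()
        raise DegenerateSampleError(
            f"samples with zero total counts and pseudocount 0: {bad}; "
            "set a positive pseudocount or drop these samples"
        )
    return RelativeAbundanceTable(shifted / totals, float(pseudocount))


def ici_per_taxon(rel_pos, rel_neg) -> pd.Series:
    """ICI_t = rel_pos_t / rel_neg_t for matched proportion vectors."""
    pos = pd.Series(rel_pos, dtype=float)
    neg = pd.Series(rel_neg, dtype=float)
    if len(pos) != len(neg):
        raise ParameterError("rel_pos and rel_neg must have equal length")
    if (neg.to_numpy() == 0).any():
        raise ParameterError(
            "zero relative abundance in the IgA- fraction makes the ICI "
            "undefined; recompute relative abundances with a positive "
            "pseudocount"
        )
    out = pos.to_numpy() / neg.to_numpy()
    return pd.Series(out, index=pos.index, name="ici")


def group_ici(cohort: Cohort, group: str, age,
              aggregation: str = "mean",
              pseudocount: float = DEFAULT_PSEUDOCOUNT) -> pd.Series:
    """Per-taxon group-level ICI for one group at one age.

    ``aggregation="mean"`` (default): ratio of the group's mean IgA+
    relative abundance to its mean IgA- relative abundance.
    ``aggregation="median"``: per-subject ICI first, then the median
    across subjects. The published per-group index does not state its
    estimator; both are offered and labeled.
    """
    pos_ids = cohort.metadata.select_ids(fraction="igapos", age=age, group=group)
    neg_ids = cohort.metadata.select_ids(fraction="iganeg", age=age, group=group)
    if not pos_ids or not neg_ids:
        raise InsufficientDataError(
            f"group {group!r} at age {age} has no sorted igapos/iganeg pairs"
        )
    rel_pos = relative_abundance(cohort.counts.select(pos_ids), pseudocount)
    rel_neg = relative_abundance(cohort.counts.select(neg_ids), pseudocount)
    if aggregation == "mean":
        return ici_per_taxon(rel_pos.proportions.mean(axis=1),
                             rel_neg.proportions.mean(axis=1))
    if aggregation == "median":
        # match sorted pairs subject by subject
        meta = cohort.metadata.table.set_index("sample_id")
        per_subject = []
        for pos_id in pos_ids:
            subj = meta.loc[pos_id, "subject_id"]
            neg_match = [s for s in neg_ids
                         if meta.loc[s, "subject_id"] == subj]
            per_subject.append(ici_per_taxon(
                rel_pos.proportions[pos_id],
                rel_neg.proportions[neg_match[0]],
            ))
        return pd.concat(per_subject, axis=1).median(axis=1).rename("ici")
    raise ParameterError(
        f"unknown aggregation {aggregation!r} (use 'mean' or 'median')"
    )


def retention_filter(ici_control, ici_celiac):
    """Apply the heatmap retention rule.

    Taxa with ICI values lower than 1 in both groups are discarded, except
    discordant taxa: (ICI_control < 1 and ICI_celiac > 1) or
    (ICI_control > 1 and ICI_celiac < 1). A boundary value of exactly 1 is
    not "lower than 1", so a taxon at (1, 1) is retained.

    Returns
    -------
    (retained, discordant) : two aligned boolean Series.
    """
    c = pd.Series(ici_control, dtype=float)
    e = pd.Series(ici_celiac, dtype=float)
    if not c.index.equals(e.index):
        raise ParameterError("ici_control and ici_celiac must share an index")
    discordant = ((c < 1) & (e > 1)) | ((c > 1) & (e < 1))
    retained = (np.minimum(c, e) >= 1) | discordant
    return retained.rename("retained"), discordant.rename("discordant")


def normalize_rows(matrix: pd.DataFrame) -> pd.DataFrame:
    """Row z-scores for the heatmap: (x - row mean) / row sd (ddof=1).

    Constant rows map to all-zeros instead of NaN.
    """
    if matrix.shape[1] < 2:
        raise ParameterError("row normalization needs >= 2 columns")
    arr = matrix.to_numpy(dtype=float)
    mean = arr.mean(axis=1, keepdims=True)
    sd = arr.std(axis=1, ddof=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (arr - mean) / sd
    z[np.broadcast_to(sd == 0, z.shape)] = 0.0
    return pd.DataFrame(z, index=matrix.index, columns=matrix.columns)


def high_coaters(ici_table: pd.DataFrame,
                 threshold: float = HIGH_COATER_THRESHOLD) -> dict:
    """Taxa with group ICI strictly above ``threshold``, per group.

    ``ici_table`` must carry columns ``ici_control`` and ``ici_celiac``
    (as produced by :func:`compute_ici_table`).
    """
    out = {}
    for group in ("control", "celiac"):
        col = f"ici_{group}"
        if col not in ici_table.columns:
            raise ParameterError(f"ici table lacks column {col!r}")
        flagged = ici_table.index[ici_table[col] > threshold]
        out[group] = set(flagged)
    return out


def compute_ici_table(cohort: Cohort, age,
                      aggregation: str = "mean",
                      pseudocount: float = DEFAULT_PSEUDOCOUNT,
                      high_coater_threshold: float = HIGH_COATER_THRESHOLD,
                      include_relabund: bool = True) -> pd.DataFrame:
    """Full per-taxon ICI report for one age.

    Columns: ici_control, ici_celiac, retained, discordant,
    high_coater_control, high_coater_celiac, and one ``heatmap_*`` z-score
    column per heatmap input column. The heatmap matrix is the row-
    normalized (ICI_control, ICI_celiac) pair, augmented with the group
    mean IgA+ relative abundances when ``include_relabund``.
    """
    icis = {
        g: group_ici(cohort, g, age, aggregation=aggregation,
                     pseudocount=pseudocount)
        for g in ("control", "celiac")
    }
    table = pd.DataFrame({
        "ici_control": icis["control"],
        "ici_celiac": icis["celiac"],
    })
    retained, discordant = retention_filter(table["ici_control"],
                                            table["ici_celiac"])
    table["retained"] = retained
    table["discordant"] = discordant
    table["high_coater_control"] = table["ici_control"] > high_coater_threshold
    table["high_coater_celiac"] = table["ici_celiac"] > high_coater_threshold

    heat_cols = {"ici_control": table["ici_control"],
                 "ici_celiac": table["ici_celiac"]}
    if include_relabund:
        for group in ("control", "celiac"):
            ids = cohort.metadata.select_ids(fraction="igapos", age=age,
                                             group=group)
            rel = relative_abundance(cohort.counts.select(ids), pseudocount)
            heat_cols[f"relabund_{group}"] = rel.proportions.mean(axis=1)
    heatmap = normalize_rows(pd.DataFrame(heat_cols))
    for col in heatmap.columns:
        table[f"heatmap_{col}"] = heatmap[col]
    return table


def heatmap_matrix(ici_table: pd.DataFrame) -> pd.DataFrame:
    """Row-normalized heatmap restricted to retained taxa."""
    heat = ici_table.loc[ici_table["retained"],
                         [c for c in ici_table.columns
                          if c.startswith("heatmap_")]]
    return heat.rename(columns=lambda c: c[len("heatmap_"):])
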