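"""Two-group screens: differential abundance, differential IgA targeting,
and the plasma-analyte volcano screen.

The built-in test engine for taxon screens is a label-permutation test on
per-sample relative abundances (|difference of group means|, exhaustive
when feasible). Significance for taxon screens is conjunctive — BH-adjusted
q below ``q_max`` AND raw p below ``p_max`` — the stringent double
threshold under which the differential ASV tallies were reported.

The composite "differentially targeted" call flags taxa whose presort
abundance is statistically comparable between groups (screen q at or above
a comparability floor) while their IgA-coated abundance differs
(significant on the IgA+ fraction, or on the IgA- fraction or per-subject
ICI values, selectable).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from ._permute import two_group_mean_diff_pvalues
from .datatypes import Cohort, FeatureTable, TaxonomyTable
from .errors import InsufficientDataError, ParameterError, SelectionError
from .ici import ici_per_taxon, relative_abundance
from .io import agglomerate

DEFAULT_Q_MAX = 0.05
DEFAULT_P_MAX = 0.01


@dataclass
class DifferentialResult:
    """Per-feature two-group screen result.

    ``table`` columns: log2fc (celiac over control), p, q, significant,
    plus screen-specific extras. Significance is conjunctive:
    q < q_max AND p < p_max.
    """

    table: pd.DataFrame
    q_max: float
    p_max: float
    test: str
    notes: dict = field(default_factory=dict)

    @property
    def significant_features(self) -> list:
        return self.table.index[self.table["significant"]].tolist()

    @property
    def n_significant(self) -> int:
        return int(self.table["significant"].sum())


@dataclass
class TargetingCall:
    """Composite differential-targeting call per taxon."""

    table: pd.DataFrame           # presort_comparable, coating_differential,
                                  # differentially_targeted
    presort: DifferentialResult
    coating: DifferentialResult
    comparability_q_floor: float

    @property
    def targeted_taxa(self) -> list:
        return self.table.index[self.table["differentially_targeted"]].tolist()


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (clipped to 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ParameterError("p-values must lie in [0, 1]")
    return multipletests(p.ravel(), method="fdr_bh")[1].reshape(p.shape)


def permutation_group_test(values, labels, n_perm: int = 999,
                           seed=None, exhaustive_if_feasible: bool = True,
                           return_details: bool = False):
    """Two-group |difference of means| permutation test.

    ``values`` is a 1-D sample vector or a (features x samples) matrix;
    ``labels`` holds exactly two distinct group labels. Exhaustive
    enumeration is used when the number of distinct label splits is at
    most 20,000 (p is then the exact tail fraction); otherwise ``n_perm``
    sampled permutations with the (1 + extreme) / (1 + B) convention.
    """
    labels = np.asarray(labels)
    uniq = pd.unique(labels)
    if len(uniq) != 2:
        raise ParameterError(f"need exactly 2 group labels, got {list(uniq)}")
    values = np.asarray(values, dtype=float)
    one_dim = values.ndim == 1
    p, obs, mode, n_used = two_group_mean_diff_pvalues(
        np.atleast_2d(values), labels == uniq[1],
        n_perm=n_perm, seed=seed,
        exhaustive_if_feasible=exhaustive_if_feasible,
    )
    if one_dim:
        p, obs = float(p[0]), float(obs[0])
    if return_details:
        return p, obs, mode, n_used
    return p


def _fraction_values(cohort: Cohort, fraction: str, age,
                     pseudocount: float):
    """(values matrix, is_celiac mask, sample ids) for one fraction/age."""
    ids_ctrl = cohort.metadata.select_ids(fraction=fraction, age=age,
                                          group="control")
    ids_cel = cohort.metadata.select_ids(fraction=fraction, age=age,
                                         group="celiac")
    if not ids_ctrl or not ids_cel:
        raise SelectionError(
            f"fraction {fraction!r} at age {age} is missing for "
            f"{'control' if not ids_ctrl else 'celiac'} samples"
        )
    ids = ids_ctrl + ids_cel
    rel = relative_abundance(cohort.counts.select(ids), pseudocount)
    is_celiac = np.array([False] * len(ids_ctrl) + [True] * len(ids_cel))
    return rel.proportions, is_celiac, ids


def differential_abundance(cohort: Cohort, fraction: str, age,
                           q_max: float = DEFAULT_Q_MAX,
                           p_max: float = DEFAULT_P_MAX,
                           pseudocount: float = 1.0,
                           n_perm: int = 999,
                           seed=0) -> DifferentialResult:
    """Per-taxon two-group screen on one fraction at one age.

    log2 fold-changes are celiac over control on pseudocounted group mean
    relative abundances (hence always finite); p-values come from the
    permutation engine and q-values from BH.
    """
    rel, is_celiac, _ = _fraction_values(cohort, fraction, age, pseudocount)
    values = rel.to_numpy()
    if is_celiac.sum() < 2 or (~is_celiac).sum() < 2:
        raise InsufficientDataError("each group needs >= 2 samples")
    p, obs, mode, n_used = two_group_mean_diff_pvalues(
        values, is_celiac, n_perm=n_perm, seed=seed)
    mean_cel = values[:, is_celiac].mean(axis=1)
    mean_ctrl = values[:, ~is_celiac].mean(axis=1)
    log2fc = np.log2(mean_cel / mean_ctrl)
    q = bh_fdr(p)
    table = pd.DataFrame({
        "log2fc": log2fc, "p": p, "q": q,
        "significant": (q < q_max) & (p < p_max),
    }, index=rel.index)
    return DifferentialResult(
        table, q_max, p_max,
        test=f"permutation|{mode}|n={n_used}",
        notes={"fraction": fraction, "age": float(age),
               "pseudocount": pseudocount, "seed": seed},
    )


def _per_subject_ici(cohort: Cohort, age, pseudocount: float):
    """Per-subject per-taxon ICI matrix (taxa x subjects) and group mask."""
    meta = cohort.metadata.table
    sel = meta[(meta["age"] == float(age)) & (meta["fraction"] != "presort")]
    subjects = sel[["subject_id", "group"]].drop_duplicates("subject_id")
    cols, groups = {}, []
    for _, row in subjects.iterrows():
        subj = row["subject_id"]
        pos = sel[(sel["subject_id"] == subj) & (sel["fraction"] == "igapos")]
        neg = sel[(sel["subject_id"] == subj) & (sel["fraction"] == "iganeg")]
        if pos.empty or neg.empty:
            continue
        rel = relative_abundance(
            cohort.counts.select([pos["sample_id"].iloc[0],
                                  neg["sample_id"].iloc[0]]),
            pseudocount)
        cols[subj] = ici_per_taxon(rel.proportions.iloc[:, 0],
                                   rel.proportions.iloc[:, 1])
        groups.append(row["group"])
    if not cols:
        raise SelectionError(f"no sorted pairs at age {age}")
    return pd.DataFrame(cols), np.array(groups) == "celiac"


def differential_targeting(cohort: Cohort, age,
                           comparability_q_floor: float = 0.05,
                           coating_on: str = "igapos",
                           q_max: float = DEFAULT_Q_MAX,
                           p_max: float = DEFAULT_P_MAX,
                           pseudocount: float = 1.0,
                           n_perm: int = 999,
                           seed=0) -> TargetingCall:
    """Taxa comparable in presort abundance but differentially IgA-coated.

    ``coating_on`` selects where the coating difference is assessed:
    the IgA+ fraction (default), the IgA- fraction, or per-subject ICI
    values ("ici"). "Comparable" is operationalized as non-significance
    of the presort screen at q >= ``comparability_q_floor``.
    """
    presort = differential_abundance(
        cohort, "presort", age, q_max=q_max, p_max=p_max,
        pseudocount=pseudocount, n_perm=n_perm, seed=seed)
    if coating_on in ("igapos", "iganeg"):
        coating = differential_abundance(
            cohort, coating_on, age, q_max=q_max, p_max=p_max,
            pseudocount=pseudocount, n_perm=n_perm, seed=seed)
    elif coating_on == "ici":
        ici_mat, is_celiac = _per_subject_ici(cohort, age, pseudocount)
        values = ici_mat.to_numpy()
        p, obs, mode, n_used = two_group_mean_diff_pvalues(
            values, is_celiac, n_perm=n_perm, seed=seed)
        mean_cel = values[:, is_celiac].mean(axis=1)
        mean_ctrl = values[:, ~is_celiac].mean(axis=1)
        q = bh_fdr(p)
        coating = DifferentialResult(
            pd.DataFrame({
                "log2fc": np.log2(mean_cel / mean_ctrl),
                "p": p, "q": q,
                "significant": (q < q_max) & (p < p_max),
            }, index=ici_mat.index),
            q_max, p_max, test=f"permutation|{mode}|n={n_used}",
            notes={"on": "per-subject ICI", "age": float(age)},
        )
    else:
        raise ParameterError(
            f"coating_on must be 'igapos', 'iganeg' or 'ici', got {coating_on!r}"
        )
    presort_comparable = presort.table["q"] >= comparability_q_floor
    coating_differential = coating.table["significant"]
    table = pd.DataFrame({
        "presort_comparable": presort_comparable,
        "coating_differential": coating_differential,
        "differentially_targeted": presort_comparable & coating_differential,
    })
    return TargetingCall(table, presort, coating, comparability_q_floor)


def volcano_screen(features: FeatureTable, groups,
                   fc_threshold: float = 1.2,
                   neglog10_p_threshold: float = 0.1,
                   q_max: float = 0.05) -> DifferentialResult:
    """Plasma-analyte volcano screen (Welch t-test per feature).

    A feature is volcano-significant when |log2 FC| exceeds
    ``fc_threshold`` and -log10(p) exceeds ``neglog10_p_threshold`` (the
    published volcano gates). BH q-values are also reported for the
    separate FDR tally. Features constant across all samples get p = 1
    and a warning flag.
    """
    groups = pd.Series(groups)
    values = features.values[groups.index].to_numpy()
    is_celiac = (groups == "celiac").to_numpy()
    if is_celiac.sum() < 2 or (~is_celiac).sum() < 2:
        raise InsufficientDataError("each group needs >= 2 samples")
    cel = values[:, is_celiac]
    ctrl = values[:, ~is_celiac]
    with np.errstate(divide="ignore", invalid="ignore"):
        t, p = sps.ttest_ind(cel, ctrl, axis=1, equal_var=False)
        log2fc = np.log2(cel.mean(axis=1) / ctrl.mean(axis=1))
    constant = np.ptp(values, axis=1) == 0
    flagged = constant | ~np.isfinite(p)
    p = np.where(flagged, 1.0, p)
    q = bh_fdr(p)
    volcano_sig = (np.abs(log2fc) > fc_threshold) & \
        (-np.log10(np.maximum(p, np.finfo(float).tiny))
         > neglog10_p_threshold)
    volcano_class = np.where(~volcano_sig, "ns",
                             np.where(log2fc > 0, "up", "down"))
    table = pd.DataFrame({
        "log2fc": log2fc, "p": p, "q": q,
        "significant": q < q_max,
        "volcano_significant": volcano_sig,
        "volcano_class": volcano_class,
        "constant_flag": flagged,
    }, index=features.feature_ids)
    return DifferentialResult(
        table, q_max, p_max=1.0, test="welch-t",
        notes={"fc_threshold": fc_threshold,
               "neglog10_p_threshold": neglog10_p_threshold},
    )


def group_mean_relabund_screen(cohort: Cohort, taxonomy: TaxonomyTable,
                               rank: str, fraction: str = "presort",
                               age=None,
                               min_mean_abundance: float = 0.01,
                               q_max: float = 0.05) -> DifferentialResult:
    """Rank-level >1% relative-abundance screen (Welch t + BH).

    Taxa are agglomerated at ``rank``; only taxa whose overall mean
    relative abundance strictly exceeds ``min_mean_abundance`` are tested
    (two-tailed t tests with BH correction — the phylum/genus bar-plot
    comparisons).
    """
    agg = agglomerate(cohort.counts, taxonomy, rank)
    agg_cohort = Cohort(agg, cohort.metadata)
    rel, is_celiac, _ = _fraction_values(agg_cohort, fraction, age,
                                         pseudocount=0.0)
    keep = rel.mean(axis=1) > min_mean_abundance
    rel = rel.loc[keep]
    if rel.empty:
        empty = pd.DataFrame(
            columns=["log2fc", "p", "q", "significant"], dtype=float)
        return DifferentialResult(
            empty, q_max, p_max=1.0, test="welch-t",
            notes={"notice": "no taxa pass the abundance filter",
                   "rank": rank})
    values = rel.to_numpy()
    cel = values[:, is_celiac]
    ctrl = values[:, ~is_celiac]
    with np.errstate(divide="ignore", invalid="ignore"):
        _, p = sps.ttest_ind(cel, ctrl, axis=1, equal_var=False)
        log2fc = np.log2(cel.mean(axis=1) / ctrl.mean(axis=1))
    p = np.where(np.isfinite(p), p, 1.0)
    q = bh_fdr(p)
    table = pd.DataFrame({
        "log2fc": log2fc, "p": p, "q": q, "significant": q < q_max,
    }, index=rel.index)
    return DifferentialResult(
        table, q_max, p_max=1.0, test="welch-t",
        notes={"rank": rank, "fraction": fraction,
               "min_mean_abundance": min_mean_abundance},
    )
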