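"""Community-level statistics: observed richness, Bray-Curtis
dissimilarity, PERMANOVA, PCA ordination, and one-/two-way ANOVA.

Bray-Curtis between samples x and y is

    BC(x, y) = 1 - 2 * sum_t min(x_t, y_t) / (sum_t x_t + sum_t y_t)

computed on relative abundances by default, so per-sample sequencing
depth does not leak into beta diversity. PERMANOVA partitions the squared
distances into among- and within-group sums of squares (Anderson's
pseudo-F) and assesses it by label permutation, exhaustively when the
number of distinct arrangements is at most 20,000.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import f_oneway
from skbio import DistanceMatrix

from ._permute import n_arrangements, permuted_label_matrix, tail_count
from .datatypes import CountTable
from .errors import (
    DesignError,
    InsufficientDataError,
    ParameterError,
)
from .ici import relative_abundance


@dataclass
class PermanovaResult:
    pseudo_F: float
    R2: float
    p_value: float
    n_permutations: int
    mode: str
    seed: object = None


def observed_richness(table: CountTable) -> pd.Series:
    """Per-sample number of taxa with at least one read (observed ASVs)."""
    counts = table.counts if isinstance(table, CountTable) else table
    return (counts > 0).sum(axis=0).rename("observed_richness")


def bray_curtis(x, y) -> float:
    """Bray-Curtis dissimilarity between two non-negative vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ParameterError("vectors must have equal length")
    if (x < 0).any() or (y < 0).any():
        raise ParameterError("Bray-Curtis requires non-negative vectors")
    total = x.sum() + y.sum()
    if total == 0:
        raise ParameterError(
            "Bray-Curtis is undefined for two all-zero vectors")
    return float(1.0 - 2.0 * np.minimum(x, y).sum() / total)


def bray_curtis_matrix(table, on: str = "relabund") -> DistanceMatrix:
    """Pairwise Bray-Curtis distances between samples.

    ``on="relabund"`` (default) normalizes each sample to proportions
    first; ``on="counts"`` uses raw counts.
    """
    counts = table.counts if isinstance(table, CountTable) else table
    if on == "relabund":
        data = relative_abundance(counts, pseudocount=0.0).proportions
    elif on == "counts":
        data = counts.astype(float)
    else:
        raise ParameterError(f"on must be 'relabund' or 'counts', got {on!r}")
    condensed = pdist(data.to_numpy().T, metric="braycurtis")
    return DistanceMatrix(squareform(condensed), ids=list(counts.columns))


def _permanova_stat(d2: np.ndarray, labels: np.ndarray) -> tuple:
    """(pseudo-F, R2) from a squared-distance matrix and group labels."""
    n = d2.shape[0]
    ss_total = d2[np.triu_indices(n, 1)].sum() / n
    ss_within = 0.0
    groups = pd.unique(labels)
    for g in groups:
        idx = np.flatnonzero(labels == g)
        sub = d2[np.ix_(idx, idx)]
        ss_within += sub[np.triu_indices(len(idx), 1)].sum() / len(idx)
    ss_among = ss_total - ss_within
    a = len(groups)
    if ss_total <= 1e-300:
        # all points coincide: no variance to partition; F := 0 so that
        # permutation ties give p = 1
        return 0.0, 0.0
    with np.errstate(divide="ignore"):
        f = (ss_among / (a - 1)) / (ss_within / (n - a))
    r2 = ss_among / ss_total
    return f, r2


def permanova(dm: DistanceMatrix, grouping, n_perm: int = 999,
              seed=None, exhaustive_if_feasible: bool = True
              ) -> PermanovaResult:
    """Permutational multivariate ANOVA on a distance matrix.

    Exhaustive enumeration (exact p, ties as extreme) when the number of
    distinct label arrangements is at most 20,000, else ``n_perm`` sampled
    permutations with the (1 + extreme) / (1 + B) convention.
    """
    labels = np.asarray(list(grouping))
    if labels.size != dm.shape[0]:
        raise ParameterError("grouping length must match the distance matrix")
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2:
        raise InsufficientDataError("PERMANOVA needs >= 2 groups")
    if counts.min() < 2:
        small = uniq[counts.argmin()]
        raise InsufficientDataError(
            f"group {small!r} has fewer than 2 samples")
    d2 = np.asarray(dm.data, dtype=float) ** 2
    observed, r2 = _permanova_stat(d2, labels)
    perms, mode = permuted_label_matrix(
        labels, n_perm, seed=seed,
        exhaustive_if_feasible=exhaustive_if_feasible)
    stats = np.array([_permanova_stat(d2, perm)[0] for perm in perms])
    count = int(tail_count(stats[None, :], np.array([observed]))[0])
    if mode == "exhaustive":
        p = count / len(perms)
        n_used = len(perms)
    else:
        p = (1.0 + count) / (1.0 + n_perm)
        n_used = n_perm
    return PermanovaResult(float(observed), float(r2), float(p),
                           n_used, mode, seed)


def pca(data: pd.DataFrame, n_components: int = 2,
        hellinger: bool = False):
    """PCA ordination of samples.

    ``data`` is a taxa x samples (or feature x sample) proportion table;
    samples are the observations. Columns are centered, not scaled; the
    Hellinger option square-root transforms proportions first. Axis signs
    are made deterministic.

    Returns
    -------
    (coordinates, explained_variance_ratio)
        ``coordinates`` is a samples x PC DataFrame.
    """
    from sklearn.decomposition import PCA

    X = data.to_numpy(dtype=float).T    # samples x features
    n_samples, n_features = X.shape
    if n_samples < 2:
        raise InsufficientDataError("PCA needs >= 2 samples")
    if n_components > min(n_samples, n_features):
        raise ParameterError(
            f"n_components={n_components} exceeds min(n_samples, n_features)"
            f"={min(n_samples, n_features)}")
    if hellinger:
        X = np.sqrt(np.maximum(X, 0.0))
    model = PCA(n_components=n_components, svd_solver="full")
    coords = model.fit_transform(X)
    cols = [f"PC{i + 1}" for i in range(coords.shape[1])]
    return (pd.DataFrame(coords, index=data.columns, columns=cols),
            model.explained_variance_ratio_)


def anova_oneway(values, factor) -> tuple:
    """Classical one-way ANOVA F and p across the levels of ``factor``."""
    values = pd.Series(values).reset_index(drop=True)
    factor = pd.Series(list(factor))
    levels = factor.unique()
    if len(levels) < 2:
        raise InsufficientDataError("one-way ANOVA needs >= 2 levels")
    groups = [values[factor.values == lv].to_numpy() for lv in levels]
    res = f_oneway(*groups)
    return float(res.statistic), float(res.pvalue)


def anova_twoway(values, factor_a, factor_b) -> pd.DataFrame:
    """Two-way ANOVA with Type II sums of squares.

    Appropriate for the unbalanced group x age design; requires at least
    two observations in every factor cell. Returns a DataFrame indexed by
    effect (factor_a, factor_b, interaction) with F and p columns.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    df = pd.DataFrame({
        "y": np.asarray(list(values), dtype=float),
        "a": [str(x) for x in factor_a],
        "b": [str(x) for x in factor_b],
    })
    for fac in ("a", "b"):
        if df[fac].nunique() < 2:
            raise InsufficientDataError(
                f"two-way ANOVA needs >= 2 levels per factor ({fac})")
    cell_sizes = df.groupby(["a", "b"]).size()
    full = pd.MultiIndex.from_product(
        [df["a"].unique(), df["b"].unique()], names=["a", "b"])
    cell_sizes = cell_sizes.reindex(full, fill_value=0)
    thin = cell_sizes[cell_sizes < 2]
    if not thin.empty:
        cell = thin.index[0]
        raise DesignError(
            f"design cell (a={cell[0]!r}, b={cell[1]!r}) has "
            f"{int(thin.iloc[0])} observations (need >= 2)")
    model = smf.ols("y ~ C(a) * C(b)", data=df).fit()
    tab = sm.stats.anova_lm(model, typ=2)
    out = tab.loc[["C(a)", "C(b)", "C(a):C(b)"], ["sum_sq", "F", "PR(>F)"]]
    out.index = ["factor_a", "factor_b", "interaction"]
    return out.rename(columns={"PR(>F)": "p"})
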