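"""Shared label-permutation machinery.

Two conventions are pinned here and used by every permutation statistic in
the package:

* exhaustive mode — when the number of distinct label arrangements is at
  most ``MAX_EXHAUSTIVE`` (20,000), all arrangements are enumerated and the
  p-value is the exact fraction with a statistic at least as extreme as the
  observed one (the identity arrangement is part of the enumeration);
* sampled mode — ``B`` random permutations, p = (1 + #extreme) / (1 + B),
  so a sampled p is never exactly zero.

Ties count as extreme (>= with a small numerical tolerance).
"""

from __future__ import annotations

from itertools import combinations
from math import comb, factorial, prod

import numpy as np

MAX_EXHAUSTIVE = 20_000

_TIE_TOL = 1e-12


def n_arrangements(labels) -> int:
    """Number of distinct label arrangements (multinomial coefficient)."""
    labels = np.asarray(labels)
    _, counts = np.unique(labels, return_counts=True)
    return factorial(len(labels)) // prod(factorial(int(c)) for c in counts)


def tail_count(stats: np.ndarray, observed) -> np.ndarray:
    """#{arrangements with statistic >= observed}, ties counted as extreme."""
    observed = np.asarray(observed, dtype=float)
    tol = _TIE_TOL * np.maximum(1.0, np.abs(observed))
    return (stats >= (observed - tol)[..., None]).sum(axis=-1)


def two_group_mean_diff_pvalues(values: np.ndarray, is_group_b: np.ndarray,
                                n_perm: int = 999, seed=None,
                                exhaustive_if_feasible: bool = True):
    """Vectorized two-group |difference of means| permutation test.

    Parameters
    ----------
    values : (n_features, n_samples) array
    is_group_b : boolean array over samples

    Returns
    -------
    (p, observed, mode, n_used)
        ``p`` and ``observed`` are per-feature arrays; ``mode`` is
        ``"exhaustive"`` or ``"sampled"``; ``n_used`` the arrangement or
        permutation count.
    """
    values = np.atleast_2d(np.asarray(values, dtype=float))
    is_b = np.asarray(is_group_b, dtype=bool)
    n = is_b.size
    n_b = int(is_b.sum())
    n_a = n - n_b
    if n_a < 2 or n_b < 2:
        from .errors import InsufficientDataError
        raise InsufficientDataError(
            f"each group needs >= 2 samples (got {n_a} and {n_b})"
        )
    totals = values.sum(axis=1)

    def stat_for(sum_b, k_b):
        mean_b = sum_b / k_b
        mean_a = (totals[:, None] - sum_b) / (n - k_b)
        return np.abs(mean_b - mean_a)

    observed = stat_for(values[:, is_b].sum(axis=1)[:, None], n_b)[:, 0]

    if exhaustive_if_feasible and comb(n, n_b) <= MAX_EXHAUSTIVE:
        combos = np.fromiter(
            (i for c in combinations(range(n), n_b) for i in c),
            dtype=np.intp,
        ).reshape(-1, n_b)
        member = np.zeros((combos.shape[0], n), dtype=float)
        np.put_along_axis(member, combos, 1.0, axis=1)
        sums_b = values @ member.T           # (features, arrangements)
        stats = stat_for(sums_b, n_b)
        count = tail_count(stats, observed)
        total = combos.shape[0]
        return count / total, observed, "exhaustive", total

    rng = np.random.default_rng(seed)
    count = np.zeros(values.shape[0], dtype=np.int64)
    # permute in blocks to bound memory at cohort scale
    block = max(1, min(n_perm, 512))
    done = 0
    while done < n_perm:
        b = min(block, n_perm - done)
        member = np.zeros((b, n), dtype=float)
        idx = np.argsort(rng.random((b, n)), axis=1)[:, :n_b]
        np.put_along_axis(member, idx, 1.0, axis=1)
        stats = stat_for(values @ member.T, n_b)
        count += tail_count(stats, observed)
        done += b
    p = (1.0 + count) / (1.0 + n_perm)
    return p, observed, "sampled", n_perm


def permuted_label_matrix(labels, n_perm: int, seed=None,
                          exhaustive_if_feasible: bool = True):
    """Label arrangements for a generic permutation statistic.

    Returns (matrix of label arrays, mode). In exhaustive mode the matrix
    enumerates every distinct arrangement once (identity included);
    otherwise it holds ``n_perm`` random permutations (identity excluded —
    the caller applies the +1/(B+1) convention).
    """
    labels = np.asarray(labels)
    if exhaustive_if_feasible and n_arrangements(labels) <= MAX_EXHAUSTIVE:
        from sympy.utilities.iterables import multiset_permutations

        arr = np.array(list(multiset_permutations(list(labels))))
        return arr, "exhaustive"
    rng = np.random.default_rng(seed)
    perms = np.empty((n_perm, labels.size), dtype=labels.dtype)
    for i in range(n_perm):
        perms[i] = labels[rng.permutation(labels.size)]
    return perms, "sampled"
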