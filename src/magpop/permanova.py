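"""Permutation-based multivariate tests of population structure (PERMANOVA).

Implemented from first principles on a distance matrix, following Anderson's
pseudo-F decomposition:

    SS_total  = sum_{i<j} d_ij^2 / n
    SS_within = sum_g sum_{i<j in g} d_ij^2 / n_g
    pseudo-F  = (SS_between / (k - 1)) / (SS_within / (n - k))

with SS_between = SS_total - SS_within. Significance comes from random label
permutations with the add-one rule p = (1 + #{F_perm >= F_obs}) /
(1 + n_permutations), which keeps p > 0 and bounds it below by
1/(n_permutations + 1).

F_ST estimates can dip slightly below zero under sampling noise; distances
are floored at 0 for the squared-distance decomposition only (and the
flooring is logged), since sums of squares require non-negative distances.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from statsmodels.stats.multitest import multipletests

from .exceptions import ValidationError
from .io import logger


@dataclass
class PermanovaResult:
    factor: str
    pseudo_F: float
    p_value: float
    n_permutations: int
    df_between: int
    df_within: int
    n_samples: int
    groups: tuple[str, ...]
    adjusted_p: float | None = None


def _as_distance_array(matrix) -> np.ndarray:
    values = np.asarray(getattr(matrix, "values", matrix), dtype=float)
    if values.ndim != 2 or values.shape[0] != values.shape[1]:
        raise ValidationError("PERMANOVA needs a square distance matrix")
    if np.isnan(values).any():
        raise ValidationError("PERMANOVA needs a complete distance matrix")
    if (values < 0).any():
        logger.info(
            "permanova: flooring %d negative distance entries at 0",
            int((values < 0).sum() // 2),
        )
        values = np.maximum(values, 0.0)
    return values


def _pseudo_f(d2: np.ndarray, codes: np.ndarray, k: int, ss_total: float) -> float:
    n = d2.shape[0]
    ss_within = 0.0
    for g in range(k):
        idx = np.flatnonzero(codes == g)
        if idx.size > 1:
            ss_within += d2[np.ix_(idx, idx)].sum() / (2.0 * idx.size)
    ss_between = ss_total - ss_within
    df_between = k - 1
    df_within = n - k
    if ss_within == 0.0:
        return np.inf if ss_between > 0 else 0.0
    return (ss_between / df_between) / (ss_within / df_within)


def permanova(
    matrix,
    grouping,
    n_permutations: int = 999,
    seed: int = 0,
    factor: str = "factor",
) -> PermanovaResult:
    """Single-factor PERMANOVA on a distance matrix.

    Parameters
    ----------
    matrix
        An FstMatrix (or any square array-like of distances).
    grouping
        Mapping sample_id -> group label, or a sequence of labels aligned
        with the matrix's sample order.
    n_permutations, seed
        Number of label permutations and the RNG seed; results are
        reproducible bit-for-bit given both.
    """
    values = _as_distance_array(matrix)
    n = values.shape[0]
    sample_ids = list(getattr(matrix, "sample_ids", range(n)))
    if hasattr(grouping, "get") and not isinstance(grouping, (list, tuple, np.ndarray)):
        labels = [grouping[s] for s in sample_ids]
    else:
        labels = list(grouping)
    if len(labels) != n:
        raise ValidationError("grouping length does not match matrix size")
    group_names = sorted(set(labels))
    k = len(group_names)
    if k < 2:
        raise ValidationError("PERMANOVA needs at least 2 groups")
    code_of = {g: i for i, g in enumerate(group_names)}
    codes = np.array([code_of[l] for l in labels], dtype=np.int64)

    d2 = values**2
    ss_total = d2.sum() / (2.0 * n)
    f_obs = _pseudo_f(d2, codes, k, ss_total)

    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_permutations):
        perm = rng.permutation(codes)
        if _pseudo_f(d2, perm, k, ss_total) >= f_obs:
            exceed += 1
    p_value = (1.0 + exceed) / (1.0 + n_permutations)
    return PermanovaResult(
        factor=factor,
        pseudo_F=float(f_obs),
        p_value=float(p_value),
        n_permutations=int(n_permutations),
        df_between=k - 1,
        df_within=n - k,
        n_samples=n,
        groups=tuple(group_names),
    )


def benjamini_hochberg(p_values) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (step-up FDR)."""
    p_values = np.asarray(p_values, dtype=float)
    return multipletests(p_values, method="fdr_bh")[1]


def pairwise_permanova(
    matrix,
    grouping,
    n_permutations: int = 999,
    seed: int = 0,
    factor: str = "factor",
) -> list[PermanovaResult]:
    """One PERMANOVA per group pair with BH adjustment across pairs.

    A post-hoc decomposition for a significant >= 3-group test; with only
    2 groups use :func:`permanova` directly.
    """
    values = _as_distance_array(matrix)
    sample_ids = list(getattr(matrix, "sample_ids", range(values.shape[0])))
    if hasattr(grouping, "get") and not isinstance(grouping, (list, tuple, np.ndarray)):
        labels = [grouping[s] for s in sample_ids]
    else:
        labels = list(grouping)
    group_names = sorted(set(labels))
    if len(group_names) < 3:
        raise ValidationError("pairwise PERMANOVA needs >= 3 groups")
    labels = np.array(labels, dtype=object)
    results = []
    # one child seed per pair so each sub-test is independently reproducible
    seeds = np.random.SeedSequence(seed).generate_state(
        len(list(itertools.combinations(group_names, 2)))
    )
    for (ga, gb), sub_seed in zip(itertools.combinations(group_names, 2), seeds):
        idx = np.flatnonzero((labels == ga) | (labels == gb))
        sub = values[np.ix_(idx, idx)]
        sub_labels = list(labels[idx])
        res = permanova(
            sub,
            sub_labels,
            n_permutations=n_permutations,
            seed=int(sub_seed % (2**31)),
            factor=f"{factor}:{ga}-vs-{gb}",
        )
        results.append(res)
    adjusted = benjamini_hochberg([r.p_value for r in results])
    for res, adj in zip(results, adjusted):
        res.adjusted_p = float(adj)
    return results
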