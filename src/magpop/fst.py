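"""Fixation-index (F_ST) distances between metagenome samples.

Following the genome-wide estimator of Schloissnig et al. (2013), a site's
within-sample heterozygosity from read-derived allele frequencies
``f = (f_A, f_C, f_G, f_T)`` is ``pi = 1 - sum_a f_a^2`` and the
between-sample heterozygosity of two frequency vectors x, y is
``pi_xy = 1 - sum_a x_a * y_a``. For a pair of samples, over a shared set of
positions,

    F_ST = 1 - (mean(pi_x) + mean(pi_y)) / (2 * mean(pi_xy))

with the means taken over the same position set (a ratio of averages, not an
average of per-site ratios, which are unstable at low heterozygosity).

Read frequencies are used as-is, with no small-sample (n/(n-1)) correction;
this matches the cited estimator and leaves an upward bias of order
1/coverage in F_ST, which the null-calibration tests quantify rather than
correct. Estimates may come out slightly negative under sampling noise and
are reported unclamped.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .exceptions import MatrixIncompleteError, NoOverlapError, ValidationError

BASES = ("A", "C", "G", "T")

SITE_SETS = ("snv-union", "all-covered")


@dataclass
class FstMatrix:
    """Symmetric between-sample distance matrix for one MAG.

    ``values[i, j]`` is the pairwise F_ST between ``sample_ids[i]`` and
    ``sample_ids[j]``; ``n_positions[i, j]`` counts the sites each pair used.
    Missing pairs (no shared usable sites) are NaN.
    """

    sample_ids: list[str]
    values: np.ndarray
    n_positions: np.ndarray | None = None
    mag_id: str | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.sample_ids), len(self.sample_ids)):
            raise ValidationError("FstMatrix: values shape does not match sample_ids")

    def is_complete(self) -> bool:
        return not np.isnan(self.values).any()

    def missing_pairs(self) -> list[tuple[str, str]]:
        i, j = np.where(np.isnan(np.triu(self.values, k=1)))
        nan_mask = np.isnan(self.values)
        out = []
        for a in range(len(self.sample_ids)):
            for b in range(a + 1, len(self.sample_ids)):
                if nan_mask[a, b]:
                    out.append((self.sample_ids[a], self.sample_ids[b]))
        return out

    def pair_value(self, sample_x: str, sample_y: str) -> float:
        i = self.sample_ids.index(sample_x)
        j = self.sample_ids.index(sample_y)
        return float(self.values[i, j])

    def reordered(self, sample_ids) -> "FstMatrix":
        """Same matrix with rows/columns permuted to the given label order."""
        idx = [self.sample_ids.index(s) for s in sample_ids]
        npos = None if self.n_positions is None else self.n_positions[np.ix_(idx, idx)]
        return FstMatrix(
            sample_ids=list(sample_ids),
            values=self.values[np.ix_(idx, idx)],
            n_positions=npos,
            mag_id=self.mag_id,
        )


def allele_frequencies(counts: pd.DataFrame) -> np.ndarray:
    """Per-row frequency 4-vectors (A, C, G, T) from read counts."""
    arr = counts[list(BASES)].to_numpy(dtype=float)
    coverage = arr.sum(axis=1, keepdims=True)
    if (coverage <= 0).any():
        raise ValidationError("allele frequencies undefined at zero coverage")
    return arr / coverage


def site_heterozygosity_within(freqs) -> np.ndarray | float:
    """pi = 1 - sum_a f_a^2; 0 iff monomorphic, at most 0.75 for 4 alleles."""
    freqs = np.asarray(freqs, dtype=float)
    return 1.0 - (freqs**2).sum(axis=-1)


def site_heterozygosity_between(freqs_x, freqs_y) -> np.ndarray | float:
    """pi_xy = 1 - sum_a x_a * y_a; symmetric; equals within-pi when x == y."""
    x = np.asarray(freqs_x, dtype=float)
    y = np.asarray(freqs_y, dtype=float)
    return 1.0 - (x * y).sum(axis=-1)


def fst_pair(freqs_x, freqs_y) -> tuple[float, int]:
    """Genome-wide F_ST between two samples from aligned frequency arrays.

    ``freqs_x`` and ``freqs_y`` are (n_positions, 4) arrays already
    restricted to the pair's usable position set (covered in both samples
    and, under the default site policy, variable in at least one).

    Returns ``(fst, n_positions)``. Raises NoOverlapError when the position
    set is empty. When every site is monomorphic and identical in both
    samples the denominator is zero and F_ST is defined as 0.
    """
    x = np.atleast_2d(np.asarray(freqs_x, dtype=float))
    y = np.atleast_2d(np.asarray(freqs_y, dtype=float))
    if x.shape != y.shape:
        raise ValidationError("fst_pair: frequency arrays must have equal shapes")
    n = x.shape[0]
    if n == 0:
        raise NoOverlapError("fst_pair: no shared positions")
    mean_pi_x = float(site_heterozygosity_within(x).mean())
    mean_pi_y = float(site_heterozygosity_within(y).mean())
    mean_pi_xy = float(site_heterozygosity_between(x, y).mean())
    denom = 2.0 * mean_pi_xy
    if denom == 0.0:
        return 0.0, n
    return 1.0 - (mean_pi_x + mean_pi_y) / denom, n


def pairwise_fst_from_arrays(
    freqs: np.ndarray,
    coverage: np.ndarray,
    snv_mask: np.ndarray | None,
    min_coverage: int = 10,
    site_set: str = "snv-union",
) -> tuple[np.ndarray, np.ndarray]:
    """All pairwise F_ST values from stacked per-sample arrays.

    Parameters
    ----------
    freqs : (n_samples, n_positions, 4) allele-frequency array (rows with
        zero coverage may hold zeros; they are excluded by the coverage mask).
    coverage : (n_samples, n_positions) read depth.
    snv_mask : (n_samples, n_positions) boolean, True where the position is
        an SNV record in that sample; required for site_set="snv-union".
    site_set : "snv-union" restricts each pair to positions variable in at
        least one of the two samples; "all-covered" uses every position
        covered in both.

    Returns (values, n_positions) square arrays; missing pairs are NaN/0.
    """
    if site_set not in SITE_SETS:
        raise ValidationError(f"unknown site_set {site_set!r}")
    if site_set == "snv-union" and snv_mask is None:
        raise ValidationError("snv-union site set requires an SNV mask")
    n_samples = freqs.shape[0]
    covered = coverage >= min_coverage
    pi_within = 1.0 - (freqs**2).sum(axis=-1)  # (S, P)
    values = np.zeros((n_samples, n_samples), dtype=float)
    n_positions = np.zeros((n_samples, n_samples), dtype=np.int64)
    for i in range(n_samples):
        for j in range(i + 1, n_samples):
            mask = covered[i] & covered[j]
            if site_set == "snv-union":
                mask &= snv_mask[i] | snv_mask[j]
            n = int(mask.sum())
            n_positions[i, j] = n_positions[j, i] = n
            if n == 0:
                values[i, j] = values[j, i] = np.nan
                continue
            mpx = pi_within[i, mask].mean()
            mpy = pi_within[j, mask].mean()
            mpxy = (1.0 - (freqs[i, mask] * freqs[j, mask]).sum(axis=-1)).mean()
            denom = 2.0 * mpxy
            fst = 0.0 if denom == 0.0 else 1.0 - (mpx + mpy) / denom
            values[i, j] = values[j, i] = fst
    return values, n_positions


def _stack_arrays(counts: pd.DataFrame, snvs: pd.DataFrame, sample_ids: list[str]):
    """Pivot count/SNV tables into (samples x positions) arrays."""
    key_cols = ["contig_id", "position"]
    wide = counts.pivot_table(
        index=key_cols, columns="sample_id", values=list(BASES), fill_value=0, aggfunc="sum"
    )
    positions = wide.index
    n_pos = len(positions)
    n_samp = len(sample_ids)
    count_arr = np.zeros((n_samp, n_pos, 4), dtype=float)
    for b, base in enumerate(BASES):
        block = wide[base].reindex(columns=sample_ids, fill_value=0)
        count_arr[:, :, b] = block.to_numpy(dtype=float).T
    cov = count_arr.sum(axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        freqs = np.where(cov[..., None] > 0, count_arr / np.maximum(cov[..., None], 1), 0.0)
    snv_mask = np.zeros((n_samp, n_pos), dtype=bool)
    if snvs is not None and len(snvs):
        pos_lookup = {k: idx for idx, k in enumerate(positions)}
        samp_lookup = {s: idx for idx, s in enumerate(sample_ids)}
        for contig, pos, sample in snvs[["contig_id", "position", "sample_id"]].itertuples(index=False):
            pi = pos_lookup.get((contig, pos))
            si = samp_lookup.get(sample)
            if pi is not None and si is not None:
                snv_mask[si, pi] = True
    return freqs, cov, snv_mask, positions


def fst_matrix(
    counts: pd.DataFrame,
    snvs: pd.DataFrame,
    sample_ids,
    min_coverage: int = 10,
    site_set: str = "snv-union",
    mag_id: str | None = None,
    on_missing: str = "error",
) -> FstMatrix:
    """Pairwise F_ST matrix for one MAG across the given samples.

    Each unordered pair uses its own position set: sites covered >=
    min_coverage in both samples and (default policy) an SNV record in at
    least one of the two. Pairs with an empty set are missing; with
    ``on_missing="error"`` (the default, suitable before clustering) a
    MatrixIncompleteError lists them, with ``on_missing="nan"`` they are
    kept as NaN.
    """
    sample_ids = list(sample_ids)
    if len(sample_ids) < 2:
        raise ValidationError("fst_matrix needs at least 2 samples")
    if mag_id is not None:
        counts = counts[counts["mag_id"] == mag_id]
        if snvs is not None:
            snvs = snvs[snvs["mag_id"] == mag_id]
    present = set(counts["sample_id"].unique())
    absent = [s for s in sample_ids if s not in present]
    if absent:
        raise ValidationError(f"sample(s) absent from count table: {absent}")
    counts = counts[counts["sample_id"].isin(sample_ids)]
    freqs, cov, snv_mask, _ = _stack_arrays(counts, snvs, sample_ids)
    values, n_positions = pairwise_fst_from_arrays(
        freqs, cov, snv_mask, min_coverage=min_coverage, site_set=site_set
    )
    matrix = FstMatrix(sample_ids=sample_ids, values=values, n_positions=n_positions, mag_id=mag_id)
    if on_missing == "error" and not matrix.is_complete():
        pairs = matrix.missing_pairs()
        raise MatrixIncompleteError(
            f"F_ST matrix incomplete: {len(pairs)} pair(s) share no usable positions", pairs
        )
    return matrix


# ---------------------------------------------------------------------------
# hierarchical clustering
# ---------------------------------------------------------------------------


@dataclass
class Dendrogram:
    """Binary agglomerative tree over samples (scipy linkage encoding)."""

    linkage: np.ndarray
    labels: list[str]

    def to_newick(self) -> str:
        """Newick string; a branch's length is the height drop to its parent.

        Leaves sit at height 0 and an internal node at its merge height, so
        two leaves merged at height h render as ``(a:h,b:h);``.
        """
        tree = hierarchy.to_tree(self.linkage)

        def render(node, parent_height: float) -> str:
            height = 0.0 if node.is_leaf() else node.dist
            length = parent_height - height
            if node.is_leaf():
                return f"{self.labels[node.id]}:{length:.10g}"
            left = render(node.left, height)
            right = render(node.right, height)
            return f"({left},{right}):{length:.10g}"

        if tree.is_leaf():
            return f"{self.labels[tree.id]}:0;"
        left = render(tree.left, tree.dist)
        right = render(tree.right, tree.dist)
        return f"({left},{right});"

    def first_bipartition(self) -> tuple[frozenset, frozenset]:
        """Leaf labels on either side of the root (the coarsest 2-cut)."""
        assignments = hierarchy.fcluster(self.linkage, t=2, criterion="maxclust")
        a = frozenset(l for l, c in zip(self.labels, assignments) if c == 1)
        b = frozenset(l for l, c in zip(self.labels, assignments) if c != 1)
        return a, b


def ward_cluster(matrix: FstMatrix) -> Dendrogram:
    """Ward-linkage dendrogram of samples from an F_ST matrix.

    Uses the Ward.D2 convention (scipy's ``ward`` on the distances directly):
    each merge minimizes the increase in within-cluster sum of squared
    distances. Requires a complete matrix.
    """
    if not matrix.is_complete():
        raise MatrixIncompleteError(
            "cannot cluster an incomplete matrix", matrix.missing_pairs()
        )
    condensed = squareform(matrix.values, checks=False)
    linkage = hierarchy.linkage(condensed, method="ward")
    return Dendrogram(linkage=linkage, labels=list(matrix.sample_ids))
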