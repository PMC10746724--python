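from fractions import Fraction

import numpy as np
import pytest
from scipy.cluster import hierarchy

from magpop import (
    FstMatrix,
    MatrixIncompleteError,
    NoOverlapError,
    fst_matrix,
    fst_pair,
    ward_cluster,
)
from magpop.fst import (
    allele_frequencies,
    pairwise_fst_from_arrays,
    site_heterozygosity_between,
    site_heterozygosity_within,
)

from conftest import make_counts, random_count_fixture


def fst_fraction_oracle(counts_x, counts_y):
    """Exact-rational reimplementation of the estimator, independent of
    the numpy code path: ratio of averages over the given aligned sites."""
    n = len(counts_x)
    pi_x = pi_y = pi_xy = Fraction(0)
    for cx, cy in zip(counts_x, counts_y):
        tx, ty = int(sum(cx)), int(sum(cy))
        fx = [Fraction(int(c), tx) for c in cx]
        fy = [Fraction(int(c), ty) for c in cy]
        pi_x += 1 - sum(f * f for f in fx)
        pi_y += 1 - sum(f * f for f in fy)
        pi_xy += 1 - sum(a * b for a, b in zip(fx, fy))
    if pi_xy == 0:
        return 0.0
    return float(1 - (pi_x + pi_y) / (2 * pi_xy))


class TestHeterozygosity:
    def test_hand_values(self):
        assert site_heterozygosity_within([0.9, 0.1, 0, 0]) == pytest.approx(0.18)
        assert site_heterozygosity_within([0.5, 0.5, 0, 0]) == pytest.approx(0.5)
        assert site_heterozygosity_within([1, 0, 0, 0]) == 0.0
        assert site_heterozygosity_between(
            [0.9, 0.1, 0, 0], [0.1, 0.9, 0, 0]
        ) == pytest.approx(0.82)

    def test_between_reduces_to_within_on_identical_input(self):
        f = np.array([0.3, 0.2, 0.5, 0.0])
        assert site_heterozygosity_between(f, f) == pytest.approx(
            site_heterozygosity_within(f)
        )

    def test_allele_frequencies_rows_sum_to_one(self, tiny_counts):
        freqs = allele_frequencies(tiny_counts)
        np.testing.assert_allclose(freqs.sum(axis=1), 1.0)


class TestFstPair:
    def test_single_site_hand_value(self):
        # pi_x = pi_y = 0.18, pi_xy = 0.82 -> F_ST = 1 - 0.36/1.64 = 32/41
        x = np.array([[0.9, 0.1, 0.0, 0.0]])
        y = np.array([[0.1, 0.9, 0.0, 0.0]])
        fst, n = fst_pair(x, y)
        assert n == 1
        assert fst == pytest.approx(32 / 41, abs=1e-12)

    def test_identical_samples_give_zero(self):
        rng = np.random.default_rng(2)
        f = rng.dirichlet(np.ones(4), size=30)
        fst, n = fst_pair(f, f)
        assert fst == 0.0
        assert n == 30

    def test_monomorphic_identical_sites_define_zero(self):
        f = np.tile([1.0, 0.0, 0.0, 0.0], (5, 1))
        assert fst_pair(f, f) == (0.0, 5)

    def test_empty_site_set_raises(self):
        with pytest.raises(NoOverlapError):
            fst_pair(np.empty((0, 4)), np.empty((0, 4)))

    def test_pairwise_estimator_is_nonnegative(self):
        # per site 2*pi_xy - pi_x - pi_y = sum_a (x_a - y_a)^2 >= 0, so the
        # ratio-of-averages between two samples never goes negative and no
        # clamping is applied anywhere
        rng = np.random.default_rng(6)
        for _ in range(20):
            x = rng.dirichlet(np.full(4, 0.4), size=8)
            y = rng.dirichlet(np.full(4, 0.4), size=8)
            fst, _ = fst_pair(x, y)
            assert -1e-15 <= fst <= 1.0

    def test_matches_exact_rational_oracle(self):
        rng = np.random.default_rng(9)
        for _ in range(10):
            n_sites = int(rng.integers(1, 21))
            counts = random_count_fixture(rng, n_sites, 2)
            fx = counts[0] / counts[0].sum(axis=1, keepdims=True)
            fy = counts[1] / counts[1].sum(axis=1, keepdims=True)
            fst, _ = fst_pair(fx, fy)
            expected = fst_fraction_oracle(counts[0], counts[1])
            assert fst == pytest.approx(expected, abs=1e-12)


class TestFstMatrixConstruction:
    @staticmethod
    def _counts_for(samples, per_sample_rows):
        rows = []
        for s, sample_rows in zip(samples, per_sample_rows):
            for pos, acgt in sample_rows:
                rows.append(("M", "c", pos, s, *acgt))
        return make_counts(rows)

    def test_identical_samples_give_zero_matrix(self):
        site_rows = [(p, (30, 10, 0, 0)) for p in range(4)]
        counts = self._counts_for(["s1", "s2", "s3"], [site_rows] * 3)
        snvs = counts.assign(departure=0.25)
        m = fst_matrix(counts, snvs, ["s1", "s2", "s3"])
        np.testing.assert_allclose(m.values, 0.0, atol=1e-15)
        assert (m.n_positions[~np.eye(3, dtype=bool)] == 4).all()

    def test_label_equivariance_under_sample_permutation(self):
        rng = np.random.default_rng(4)
        samples = ["s1", "s2", "s3", "s4"]
        arr = random_count_fixture(rng, 12, 4)
        per_sample = [[(p, tuple(arr[s, p])) for p in range(12)] for s in range(4)]
        counts = self._counts_for(samples, per_sample)
        snvs = counts.assign(departure=0.2)
        m1 = fst_matrix(counts, snvs, samples)
        perm = ["s3", "s1", "s4", "s2"]
        m2 = fst_matrix(counts, snvs, perm)
        for a in samples:
            for b in samples:
                if a != b:
                    assert m2.pair_value(a, b) == pytest.approx(m1.pair_value(a, b))

    def test_disjoint_coverage_raises_incomplete(self):
        counts = self._counts_for(
            ["s1", "s2"],
            [[(0, (20, 5, 0, 0))], [(1, (20, 5, 0, 0))]],
        )
        snvs = counts.assign(departure=0.2)
        with pytest.raises(MatrixIncompleteError) as exc:
            fst_matrix(counts, snvs, ["s1", "s2"])
        assert ("s1", "s2") in exc.value.pairs

    def test_on_missing_nan_keeps_pair(self):
        counts = self._counts_for(
            ["s1", "s2"],
            [[(0, (20, 5, 0, 0))], [(1, (20, 5, 0, 0))]],
        )
        snvs = counts.assign(departure=0.2)
        m = fst_matrix(counts, snvs, ["s1", "s2"], on_missing="nan")
        assert np.isnan(m.pair_value("s1", "s2"))
        assert not m.is_complete()

    def test_jointly_monomorphic_identical_site_changes_nothing(self):
        # an identical fixed site adds zero to every heterozygosity sum, so
        # the ratio-of-averages value is unchanged; only the site count grows
        per_sample = [
            [(0, (30, 10, 0, 0)), (1, (40, 0, 0, 0))],
            [(0, (10, 30, 0, 0)), (1, (40, 0, 0, 0))],
        ]
        counts = self._counts_for(["s1", "s2"], per_sample)
        snvs = counts[counts["position"] == 0].assign(departure=0.25)
        m_union = fst_matrix(counts, snvs, ["s1", "s2"], site_set="snv-union")
        m_all = fst_matrix(counts, snvs, ["s1", "s2"], site_set="all-covered")
        assert m_union.n_positions[0, 1] == 1
        assert m_all.n_positions[0, 1] == 2
        assert m_all.pair_value("s1", "s2") == pytest.approx(
            m_union.pair_value("s1", "s2")
        )

    def test_fixed_difference_site_counts_only_under_all_covered(self):
        # a site fixed for different alleles has departure 0 in both samples
        # (not an SNV) yet maximal between-sample heterozygosity: the two
        # site policies disagree on it, and including it raises F_ST
        per_sample = [
            [(0, (30, 10, 0, 0)), (1, (40, 0, 0, 0))],
            [(0, (10, 30, 0, 0)), (1, (0, 40, 0, 0))],
        ]
        counts = self._counts_for(["s1", "s2"], per_sample)
        snvs = counts[counts["position"] == 0].assign(departure=0.25)
        m_union = fst_matrix(counts, snvs, ["s1", "s2"], site_set="snv-union")
        m_all = fst_matrix(counts, snvs, ["s1", "s2"], site_set="all-covered")
        assert m_union.n_positions[0, 1] == 1
        assert m_all.n_positions[0, 1] == 2
        assert m_all.pair_value("s1", "s2") > m_union.pair_value("s1", "s2")

    def test_array_path_matches_rational_oracle_pairwise(self):
        rng = np.random.default_rng(17)
        counts = random_count_fixture(rng, 15, 4)
        cov = counts.sum(axis=-1).astype(float)
        freqs = counts / counts.sum(axis=-1, keepdims=True)
        values, n_pos = pairwise_fst_from_arrays(
            freqs, cov, snv_mask=None, min_coverage=10, site_set="all-covered"
        )
        for i in range(4):
            for j in range(i + 1, 4):
                expected = fst_fraction_oracle(counts[i], counts[j])
                assert values[i, j] == pytest.approx(expected, abs=1e-12)
                assert n_pos[i, j] == 15


def naive_ward_cophenetic(dist):
    """O(n^3) Ward.D2 agglomeration via the Lance-Williams update, returning
    the cophenetic distance matrix. Independent oracle for scipy's linkage."""
    n = dist.shape[0]
    members = {i: {i} for i in range(n)}
    sizes = {i: 1 for i in range(n)}
    d = {(i, j): float(dist[i, j]) for i in range(n) for j in range(i + 1, n)}
    coph = np.zeros((n, n))
    next_id = n
    while len(members) > 1:
        (a, b) = min(d, key=d.get)
        height = d[(a, b)]
        for x in members[a]:
            for y in members[b]:
                coph[x, y] = coph[y, x] = height
        # Lance-Williams update for Ward.D2 (squared-distance recurrence)
        na, nb = sizes[a], sizes[b]
        new = {}
        for k in members:
            if k in (a, b):
                continue
            nk = sizes[k]
            dka = d[tuple(sorted((k, a)))]
            dkb = d[tuple(sorted((k, b)))]
            dab = d[(a, b)]
            sq = (
                (na + nk) * dka**2 + (nb + nk) * dkb**2 - nk * dab**2
            ) / (na + nb + nk)
            new[k] = np.sqrt(sq)
        merged = members.pop(a) | members.pop(b)
        del sizes[a], sizes[b]
        d = {
            key: val
            for key, val in d.items()
            if a not in key and b not in key
        }
        members[next_id] = merged
        sizes[next_id] = na + nb
        for k, val in new.items():
            d[tuple(sorted((k, next_id)))] = val
        next_id += 1
    return coph


def random_distance_matrix(rng, n):
    raw = rng.uniform(0.05, 1.0, (n, n))
    vals = (raw + raw.T) / 2
    np.fill_diagonal(vals, 0.0)
    return vals


class TestWardClustering:
    def test_two_samples_merge_at_their_distance(self):
        m = FstMatrix(sample_ids=["a", "b"], values=np.array([[0.0, 0.3], [0.3, 0.0]]))
        tree = ward_cluster(m)
        assert tree.linkage.shape == (1, 4)
        assert tree.linkage[0, 2] == pytest.approx(0.3)

    def test_two_deme_structure_recovered_in_first_bipartition(self):
        # 6 samples: {a,b,c} mutually close, {d,e,f} mutually close, far apart
        ids = list("abcdef")
        vals = np.full((6, 6), 0.5)
        for group in ((0, 1, 2), (3, 4, 5)):
            for i in group:
                for j in group:
                    vals[i, j] = 0.02 if i != j else 0.0
        tree = ward_cluster(FstMatrix(sample_ids=ids, values=vals))
        left, right = tree.first_bipartition()
        assert {left, right} == {frozenset("abc"), frozenset("def")}

    def test_matches_naive_lance_williams_oracle(self):
        rng = np.random.default_rng(21)
        for _ in range(5):
            vals = random_distance_matrix(rng, 6)
            tree = ward_cluster(FstMatrix(sample_ids=list("abcdef"), values=vals))
            coph_scipy = hierarchy.cophenet(tree.linkage)
            from scipy.spatial.distance import squareform

            coph_naive = squareform(naive_ward_cophenetic(vals), checks=False)
            np.testing.assert_allclose(coph_scipy, coph_naive, rtol=1e-10)

    def test_incomplete_matrix_rejected(self):
        vals = np.array([[0.0, np.nan], [np.nan, 0.0]])
        m = FstMatrix(sample_ids=["a", "b"], values=vals)
        with pytest.raises(MatrixIncompleteError):
            ward_cluster(m)
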