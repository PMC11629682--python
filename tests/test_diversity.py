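"""Hill decomposition, PCoA, Mantel test, prevalence curves."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform

from mecphage.diversity import (
    DissimilarityMatrix,
    correlate_dissimilarities,
    dissimilarity_matrix,
    pairwise_dissimilarity,
    pcoa,
    prevalence_by_completeness,
    shared_fraction,
)
from mecphage.errors import (
    EmptySampleError,
    InsufficientSamplesError,
    InvalidInputError,
)

QS = (0.0, 1.0, 2.0)


class TestPairwiseDissimilarity:
    @pytest.mark.parametrize("q", QS)
    def test_identical_samples(self, q):
        p = [0.2, 0.3, 0.5]
        decomp, d = pairwise_dissimilarity(p, p, q)
        assert d == pytest.approx(0.0, abs=1e-12)
        assert decomp.beta == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("q", QS)
    def test_disjoint_supports(self, q):
        _, d = pairwise_dissimilarity([1.0, 0.0], [0.0, 1.0], q)
        assert d == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("q", QS)
    def test_half_overlap_closed_form(self, q):
        # closed form: q=0 beta=1.5 d=0.5; q=1 beta=sqrt2 d=0.5; q=2 beta=4/3 d=0.5
        decomp, d = pairwise_dissimilarity([0.5, 0.5, 0.0], [0.0, 0.5, 0.5], q)
        assert d == pytest.approx(0.5, abs=1e-12)
        expected_beta = {0.0: 1.5, 1.0: np.sqrt(2.0), 2.0: 4.0 / 3.0}[q]
        assert decomp.beta == pytest.approx(expected_beta, abs=1e-12)

    def test_q1_limit(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            n = int(rng.integers(2, 10))
            p1 = rng.dirichlet(np.ones(n))
            p2 = rng.dirichlet(np.ones(n))
            _, d1 = pairwise_dissimilarity(p1, p2, 1.0)
            _, lo = pairwise_dissimilarity(p1, p2, 1.0 - 1e-6)
            _, hi = pairwise_dissimilarity(p1, p2, 1.0 + 1e-6)
            assert abs(lo - d1) < 1e-4 and abs(hi - d1) < 1e-4

    @pytest.mark.parametrize("q", QS)
    def test_relabeling_and_zero_padding_invariance(self, q):
        rng = np.random.default_rng(1)
        p1, p2 = rng.dirichlet(np.ones(5)), rng.dirichlet(np.ones(5))
        _, d = pairwise_dissimilarity(p1, p2, q)
        perm = rng.permutation(5)
        _, d_perm = pairwise_dissimilarity(p1[perm], p2[perm], q)
        _, d_pad = pairwise_dissimilarity(
            np.concatenate([p1, [0.0, 0.0]]), np.concatenate([p2, [0.0, 0.0]]), q
        )
        assert d_perm == pytest.approx(d, abs=1e-12)
        assert d_pad == pytest.approx(d, abs=1e-12)

    def test_beta_bounded_property(self):
        rng = np.random.default_rng(2)
        for _ in range(200):
            n = int(rng.integers(2, 8))
            q = float(rng.choice([0.0, 0.5, 1.0, 2.0, 3.0]))
            decomp, d = pairwise_dissimilarity(
                rng.dirichlet(np.ones(n)), rng.dirichlet(np.ones(n)), q
            )
            assert 1.0 - 1e-9 <= decomp.beta <= 2.0 + 1e-9
            assert 0.0 <= d <= 1.0

    def test_invalid_inputs(self):
        with pytest.raises(InvalidInputError):
            pairwise_dissimilarity([0.5, 0.5], [0.5, 0.5], -1.0)
        with pytest.raises(InvalidInputError):
            pairwise_dissimilarity([0.0, 0.0], [0.5, 0.5], 1.0)


class TestDissimilarityMatrix:
    def test_identical_columns_zero(self):
        t = pd.DataFrame({"s1": [1, 2, 3], "s2": [1, 2, 3]}, index=list("abc"))
        m = dissimilarity_matrix(t, 1.0)
        assert np.allclose(m.values, 0.0)

    def test_symmetry_and_diagonal(self):
        rng = np.random.default_rng(3)
        t = pd.DataFrame(
            rng.uniform(0, 10, size=(6, 4)), columns=[f"s{i}" for i in range(4)]
        )
        m = dissimilarity_matrix(t, 2.0)
        assert np.allclose(m.values, m.values.T)
        assert np.allclose(np.diag(m.values), 0.0)

    def test_median_matches_bruteforce_pairs(self):
        rng = np.random.default_rng(4)
        t = pd.DataFrame(
            rng.uniform(0, 5, size=(8, 5)), columns=[f"s{i}" for i in range(5)]
        )
        m = dissimilarity_matrix(t, 1.0)
        brute = []
        cols = list(t.columns)
        for i in range(len(cols)):
            for j in range(i + 1, len(cols)):
                _, dij = pairwise_dissimilarity(
                    t[cols[i]].to_numpy(), t[cols[j]].to_numpy(), 1.0
                )
                brute.append(dij)
        assert np.median(m.condensed()) == pytest.approx(np.median(brute), abs=1e-12)

    def test_empty_column_signals(self):
        t = pd.DataFrame({"s1": [1, 2], "s2": [0, 0]})
        with pytest.raises(EmptySampleError):
            dissimilarity_matrix(t, 0.0)


class TestPcoa:
    def test_equilateral_triangle(self):
        m = DissimilarityMatrix(["a", "b", "c"], 0.0, np.array(
            [[0.0, 0.5, 0.5], [0.5, 0.0, 0.5], [0.5, 0.5, 0.0]]
        ))
        res = pcoa(m)
        assert res.eigenvalues[0] == pytest.approx(res.eigenvalues[1], abs=1e-10)
        emb = squareform(pdist(res.coordinates[:, :2]))
        assert np.allclose(emb[np.triu_indices(3, 1)], 0.5, atol=1e-10)

    def test_zero_matrix(self):
        m = DissimilarityMatrix(["a", "b", "c"], 0.0, np.zeros((3, 3)))
        res = pcoa(m)
        assert np.allclose(res.eigenvalues, 0.0)
        assert res.coordinates.shape[1] == 0

    def test_euclidean_reconstruction(self):
        rng = np.random.default_rng(5)
        pts = rng.normal(size=(7, 3))
        d = squareform(pdist(pts))
        res = pcoa(DissimilarityMatrix([f"s{i}" for i in range(7)], 0.0, d))
        emb = squareform(pdist(res.coordinates))
        assert np.allclose(emb, d, atol=1e-8)

    def test_eigenvalue_sum_equals_gower_trace(self):
        rng = np.random.default_rng(6)
        pts = rng.normal(size=(6, 4))
        d = squareform(pdist(pts))
        res = pcoa(DissimilarityMatrix([f"s{i}" for i in range(6)], 0.0, d))
        a = -0.5 * d**2
        c = np.eye(6) - np.ones((6, 6)) / 6
        g = c @ a @ c
        assert res.eigenvalues.sum() == pytest.approx(np.trace(g), abs=1e-8)

    def test_axes_ordered_descending(self):
        rng = np.random.default_rng(7)
        pts = rng.normal(size=(8, 5))
        d = squareform(pdist(pts))
        res = pcoa(DissimilarityMatrix([f"s{i}" for i in range(8)], 0.0, d))
        assert np.all(np.diff(res.eigenvalues) <= 1e-12)


class TestMantel:
    def _random_matrix(self, rng, n):
        pts = rng.normal(size=(n, 3))
        return DissimilarityMatrix(
            [f"s{i}" for i in range(n)], 0.0, squareform(pdist(pts))
        )

    def test_self_correlation(self):
        rng = np.random.default_rng(8)
        m = self._random_matrix(rng, 6)
        r, p = correlate_dissimilarities(m, m, n_perm=99, seed=0)
        assert r == pytest.approx(1.0)

    def test_affine_invariance(self):
        rng = np.random.default_rng(9)
        m = self._random_matrix(rng, 6)
        m2 = DissimilarityMatrix(m.sample_ids, 0.0, 0.3 * m.values + 0.1 * (m.values > 0))
        r, _ = correlate_dissimilarities(m, m2, n_perm=99, seed=0)
        assert r == pytest.approx(1.0, abs=1e-9)

    def test_simultaneous_relabeling_invariance(self):
        rng = np.random.default_rng(10)
        a = self._random_matrix(rng, 7)
        b = self._random_matrix(rng, 7)
        r0, p0 = correlate_dissimilarities(a, b, n_perm=499, seed=3)
        perm = rng.permutation(7)
        ap = DissimilarityMatrix(a.sample_ids, 0.0, a.values[np.ix_(perm, perm)])
        bp = DissimilarityMatrix(b.sample_ids, 0.0, b.values[np.ix_(perm, perm)])
        r1, p1 = correlate_dissimilarities(ap, bp, n_perm=499, seed=3)
        assert r0 == pytest.approx(r1, abs=1e-12)
        assert p0 == pytest.approx(p1, abs=0.05)  # same null up to permutation draws

    def test_insufficient_samples(self):
        rng = np.random.default_rng(11)
        m = self._random_matrix(rng, 3)
        with pytest.raises(InsufficientSamplesError):
            correlate_dissimilarities(m, m, n_perm=9, seed=0)


class TestPrevalenceByCompleteness:
    def _bins(self, n, flagged=None):
        rng = np.random.default_rng(12)
        return pd.DataFrame(
            {
                "bin_id": [f"b{i:03d}" for i in range(n)],
                "completeness": rng.uniform(50, 100, size=n),
                "feat": [True] * n if flagged is None else flagged,
            }
        )

    def test_72_bins_two_groups(self):
        curve = prevalence_by_completeness(self._bins(72), "feat", 36)
        assert len(curve.groups) == 2
        assert not curve.groups["partial"].any()
        assert (curve.groups["n_bins"] == 36).all()

    def test_all_flagged(self):
        curve = prevalence_by_completeness(self._bins(50), "feat", 36)
        assert (curve.groups["fraction"] == 1.0).all()

    def test_partial_group_flagged(self):
        curve = prevalence_by_completeness(self._bins(40), "feat", 36)
        assert list(curve.groups["n_bins"]) == [36, 4]
        assert list(curve.groups["partial"]) == [False, True]

    def test_groups_ordered_by_completeness(self):
        curve = prevalence_by_completeness(self._bins(80), "feat", 36)
        mins = curve.groups["completeness_min"].to_numpy()
        maxs = curve.groups["completeness_max"].to_numpy()
        assert np.all(mins[1:] >= maxs[:-1])


class TestSharedFraction:
    def test_median_example(self):
        assert shared_fraction(0.62) == 38

    def test_zero(self):
        assert shared_fraction(0.0) == 100

    def test_fifth_percentile_example(self):
        assert shared_fraction(0.36) == 64

    def test_out_of_range(self):
        with pytest.raises(InvalidInputError):
            shared_fraction(1.5)
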