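import itertools
import math

import numpy as np
import pytest

from invasionscape.core_io import DistanceMatrix, GenotypeMatrix, MISSING
from invasionscape.popgen_stats import (
    allele_frequencies,
    amova,
    chord_distance,
    heterozygosity,
    impute_mean,
    mantel,
    pairwise_fst,
    pcoa,
    prevosti_distance,
    prevosti_distance_individuals,
)


def matrix(calls, n_localities=1, loc_sizes=None):
    calls = np.asarray(calls, dtype=np.int8)
    n = calls.shape[0]
    inds = [f"i{k}" for k in range(n)]
    if loc_sizes is None:
        loc_sizes = [n]
    loc_of, start = {}, 0
    for li, size in enumerate(loc_sizes, start=1):
        for k in range(start, start + size):
            loc_of[inds[k]] = li
        start += size
    return GenotypeMatrix(inds, [f"l{j}" for j in range(calls.shape[1])],
                          calls, loc_of)


class TestHeterozygosity:
    def test_all_heterozygous_locus(self):
        G = matrix([[1], [1], [1]])
        assert heterozygosity(G).loc[1, "ho"] == pytest.approx(1.0)

    def test_monomorphic_locus_excluded_from_fis(self):
        G = matrix([[0, 1], [0, 1], [0, 1], [0, 1]])
        stats = heterozygosity(G)
        # locus 1 monomorphic: He = 0, dropped from F_IS; locus 2 all het
        assert stats.loc[1, "he"] == pytest.approx((0 + 2 * 0.5 * 0.5 * 8 / 7) / 2)
        p = 0.5
        he2 = 2 * p * (1 - p) * 8 / 7
        assert stats.loc[1, "fis"] == pytest.approx(1 - 1.0 / he2)

    def test_hand_tallied_toy(self):
        # locality of 4 individuals, 2 loci, worked by hand
        G = matrix([[0, 1], [1, 2], [2, 1], [1, MISSING]])
        stats = heterozygosity(G)
        # locus 1: het 2/4; p = 4/8; He = 2*.5*.5*(8/7)
        # locus 2: het 2/3;  p = 4/6; He = 2*(2/3)*(1/3)*(6/5)
        ho1, he1 = 0.5, 2 * 0.5 * 0.5 * 8 / 7
        ho2, he2 = 2 / 3, 2 * (2 / 3) * (1 / 3) * (6 / 5)
        assert stats.loc[1, "ho"] == pytest.approx((ho1 + ho2) / 2, abs=1e-12)
        assert stats.loc[1, "he"] == pytest.approx((he1 + he2) / 2, abs=1e-12)
        assert stats.loc[1, "fis"] == pytest.approx(
            1 - (ho1 + ho2) / (he1 + he2), abs=1e-12)

    def test_small_locality_carries_no_statistics(self):
        G = matrix([[0, 1], [1, 1], [2, 0]], loc_sizes=[2, 1])
        stats = heterozygosity(G)
        assert np.isnan(stats.loc[2, "ho"])
        assert stats.loc[2, "n"] == 1

    def test_he_unbiasedness_over_wright_fisher_replicates(self):
        rng = np.random.default_rng(4)
        p_true = 0.3
        he_hat = []
        for _ in range(500):
            calls = rng.binomial(2, p_true, size=(8, 1)).astype(np.int8)
            if len(np.unique(calls)) == 1:
                continue
            G = matrix(calls.tolist() + [[1]] * 0)
            he_hat.append(heterozygosity(G).loc[1, "he"])
        # conditional on polymorphism the unbiased estimator tracks 2p(1-p)
        assert np.mean(he_hat) == pytest.approx(2 * p_true * (1 - p_true),
                                                abs=0.03)


class TestPairwiseFst:
    def test_unbiased_for_samples_from_one_pool(self):
        # the WC84 point estimate for two *identical* samples is slightly
        # negative (the finite-sample correction); the estimator's defining
        # property is zero expectation over independent same-pool samples
        rng = np.random.default_rng(5)
        block = rng.integers(0, 3, size=(6, 40))
        G = matrix(np.vstack([block, block]), loc_sizes=[6, 6])
        assert pairwise_fst(G).get(1, 2) <= 0.0
        vals = []
        for s in range(200):
            r = np.random.default_rng(s)
            p = r.uniform(0.2, 0.8, 40)
            calls = np.vstack([r.binomial(2, p, (6, 40)),
                               r.binomial(2, p, (6, 40))])
            vals.append(pairwise_fst(matrix(calls, loc_sizes=[6, 6])).get(1, 2))
        assert abs(np.mean(vals)) < 0.01

    def test_fixed_difference_is_one(self):
        G = matrix([[0] * 5] * 4 + [[2] * 5] * 4, loc_sizes=[4, 4])
        assert pairwise_fst(G).get(1, 2) == pytest.approx(1.0)

    def test_two_pop_two_locus_hand_oracle(self):
        # Weir & Cockerham components evaluated step by step in the oracle
        G = matrix([[0, 1], [1, 1], [1, 0], [2, 1], [2, 2], [1, 2]],
                   loc_sizes=[3, 3])
        theta = pairwise_fst(G).get(1, 2)
        assert theta == pytest.approx(_wc_theta_oracle(G), abs=1e-12)


def _wc_theta_oracle(G):
    """Direct transcription of the WC84 two-population component formulas."""
    by = G.by_locality()
    calls1, calls2 = by[1], by[2]
    num = den = 0.0
    r = 2
    for l in range(calls1.shape[1]):
        c1, c2 = calls1[:, l], calls2[:, l]
        n1, n2 = len(c1), len(c2)
        p1, p2 = c1.sum() / (2 * n1), c2.sum() / (2 * n2)
        h1, h2 = (c1 == 1).mean(), (c2 == 1).mean()
        nbar = (n1 + n2) / 2
        nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1)
        pbar = (n1 * p1 + n2 * p2) / (r * nbar)
        if pbar in (0.0, 1.0):
            continue
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
        hbar = (n1 * h1 + n2 * h2) / (r * nbar)
        a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - s2 * (r - 1) / r
                                 - hbar / 4) / (nbar - 1))
        b = (nbar / (nbar - 1)) * (pbar * (1 - pbar) - s2 * (r - 1) / r
                                   - hbar * (2 * nbar - 1) / (4 * nbar))
        c = hbar / 2
        num += a
        den += a + b + c
    return num / den


class TestGeneticDistances:
    def test_identical_frequencies_zero(self):
        freqs = {1: np.array([0.2, 0.7]), 2: np.array([0.2, 0.7])}
        assert chord_distance(freqs).get(1, 2) == pytest.approx(0.0)
        assert prevosti_distance(freqs).get(1, 2) == pytest.approx(0.0)

    def test_opposite_fixation_single_locus(self):
        freqs = {1: np.array([0.0]), 2: np.array([1.0])}
        assert prevosti_distance(freqs).get(1, 2) == pytest.approx(1.0)
        assert chord_distance(freqs).get(1, 2) == pytest.approx(
            (2 / math.pi) * math.sqrt(2))

    def test_missing_locus_dropped_pairwise(self):
        freqs = {1: np.array([0.0, np.nan]), 2: np.array([1.0, 0.5])}
        assert prevosti_distance(freqs).get(1, 2) == pytest.approx(1.0)

    def test_individual_prevosti_matches_allele_sharing(self):
        G = matrix([[0, 2, 1], [2, 2, 1]])
        d = prevosti_distance_individuals(G)
        # |0-2| + |2-2| + |1-1| over 2L = 2/6
        assert d.get("i0", "i1") == pytest.approx(2 / 6)


class TestAmova:
    def test_two_fixed_clusters_phi_one(self):
        G = matrix([[0] * 6] * 5 + [[2] * 6] * 5, loc_sizes=[5, 5])
        res = amova(G, {1: "A", 2: "B"}, n_perm=199, seed=0)
        assert res.phi_st == pytest.approx(1.0)
        # only the observed partition (or its mirror) reaches phi = 1
        assert res.p_value <= 0.05

    def test_null_data_phi_near_zero(self):
        rng = np.random.default_rng(6)
        phis = []
        for s in range(10):
            calls = rng.binomial(2, 0.4, size=(12, 60)).astype(np.int8)
            G = matrix(calls, loc_sizes=[6, 6])
            phis.append(amova(G, {1: "A", 2: "B"}, n_perm=19, seed=s).phi_st)
        assert abs(np.mean(phis)) < 0.02

    def test_variance_components_match_enumeration_oracle(self):
        G = matrix([[0, 1, 2], [1, 1, 0], [2, 0, 1],
                    [0, 2, 2], [1, 0, 1], [2, 2, 0]], loc_sizes=[3, 3])
        res = amova(G, {1: "A", 2: "B"}, n_perm=9, seed=0)
        # brute-force sums of squares from pairwise squared distances
        calls = G.calls.astype(float)
        d2 = ((calls[:, None, :] - calls[None, :, :]) ** 2).sum(axis=2)
        N, g, n_per = 6, 2, 3
        ss_total = d2[np.triu_indices(N, 1)].sum() / N
        ss_within = sum(
            d2[np.ix_(idx, idx)][np.triu_indices(n_per, 1)].sum() / n_per
            for idx in ([0, 1, 2], [3, 4, 5]))
        ms_a = (ss_total - ss_within) / (g - 1)
        ms_w = ss_within / (N - g)
        sigma_w = ms_w
        sigma_a = (ms_a - ms_w) / n_per
        assert res.sigma2_within == pytest.approx(sigma_w, abs=1e-10)
        assert res.sigma2_among == pytest.approx(sigma_a, abs=1e-10)
        assert res.phi_st == pytest.approx(sigma_a / (sigma_a + sigma_w),
                                           abs=1e-10)

    def test_singleton_cluster_rejected(self):
        G = matrix([[0, 1], [1, 1], [2, 0]], loc_sizes=[2, 1])
        with pytest.raises(ValueError, match="2 individuals"):
            amova(G, {1: "A", 2: "B"}, n_perm=9, seed=0)


class TestPcoa:
    def test_distances_preserved_without_missing_data(self):
        rng = np.random.default_rng(7)
        calls = rng.integers(0, 3, size=(6, 20)).astype(np.int8)
        G = matrix(calls)
        coords, _ = pcoa(G)
        orig = np.sqrt(((calls[:, None].astype(float)
                         - calls[None]) ** 2).sum(axis=2))
        emb = np.sqrt(((coords[:, None] - coords[None]) ** 2).sum(axis=2))
        assert np.allclose(orig, emb, atol=1e-8)

    def test_duplicate_individuals_coincide(self):
        calls = np.array([[0, 1, 2], [0, 1, 2], [2, 0, 1], [1, 1, 1]],
                         dtype=np.int8)
        coords, _ = pcoa(matrix(calls))
        assert np.allclose(coords[0], coords[1], atol=1e-8)

    def test_eigenvalues_match_direct_decomposition(self):
        calls = np.array([[0, 1], [1, 2], [2, 0], [1, 1]], dtype=np.int8)
        G = matrix(calls)
        coords, pct = pcoa(G)
        X = calls.astype(float)
        sq = ((X[:, None] - X[None]) ** 2).sum(axis=2)
        J = np.eye(4) - np.ones((4, 4)) / 4
        evals = np.sort(np.linalg.eigvalsh(-0.5 * J @ sq @ J))[::-1]
        evals = evals[evals > 1e-9]
        axis_vars = (coords**2).sum(axis=0)
        assert np.allclose(np.sort(axis_vars)[::-1], evals, atol=1e-8)

    def test_mean_imputation_uses_locus_mean(self):
        calls = np.array([[0, MISSING], [2, 2], [0, 0], [2, 2]], dtype=np.int8)
        X = impute_mean(matrix(calls))
        assert X[0, 1] == pytest.approx(4 / 3)


class TestMantel:
    def _dm(self, m, labels=None):
        m = np.asarray(m, dtype=float)
        return DistanceMatrix(labels=labels or list(range(len(m))), d=m)

    def test_self_correlation_is_one(self):
        rng = np.random.default_rng(8)
        m = rng.random((6, 6))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 0)
        res = mantel(self._dm(m), self._dm(m), n_perm=99, seed=0)
        assert res.r == pytest.approx(1.0)

    def test_affine_invariance(self):
        rng = np.random.default_rng(9)
        m = rng.random((6, 6))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 0)
        m2 = 3.0 * m + 1.0
        np.fill_diagonal(m2, 0)
        res = mantel(self._dm(m), self._dm(m2), n_perm=9, seed=0)
        assert res.r == pytest.approx(1.0)

    def test_constant_matrix_rejected(self):
        c = np.ones((4, 4)) - np.eye(4)
        rng = np.random.default_rng(10)
        m = rng.random((4, 4))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 0)
        with pytest.raises(ValueError, match="constant"):
            mantel(self._dm(m), self._dm(c), n_perm=9, seed=0)

    def test_permutation_p_matches_exhaustive_null(self):
        rng = np.random.default_rng(11)
        m1 = rng.random((4, 4)); m1 = (m1 + m1.T) / 2; np.fill_diagonal(m1, 0)
        m2 = rng.random((4, 4)); m2 = (m2 + m2.T) / 2; np.fill_diagonal(m2, 0)
        iu = np.triu_indices(4, 1)

        def corr(a, b):
            x, y = a[iu], b[iu]
            return np.corrcoef(x, y)[0, 1]

        r_obs = corr(m1, m2)
        exhaustive = [
            corr(m1, m2[np.ix_(p, p)])
            for p in itertools.permutations(range(4))
        ]
        p_exact = np.mean([r >= r_obs - 1e-12 for r in exhaustive])
        res = mantel(self._dm(m1), self._dm(m2), n_perm=999, seed=1)
        # the add-one Monte-Carlo p converges on the exhaustive null value
        assert res.p == pytest.approx(p_exact, abs=0.08)

    def test_agrees_with_skbio(self):
        pytest.importorskip("skbio")
        from skbio.stats.distance import DistanceMatrix as SkDM
        from skbio.stats.distance import mantel as sk_mantel

        rng = np.random.default_rng(12)
        xy = rng.random((7, 2))
        geo = np.sqrt(((xy[:, None] - xy[None]) ** 2).sum(axis=2))
        gen = geo * 0.5 + rng.random((7, 7)) * 0.05
        gen = (gen + gen.T) / 2
        np.fill_diagonal(gen, 0)
        ours = mantel(self._dm(geo), self._dm(gen), n_perm=999, seed=0)
        sk_r, sk_p, _ = sk_mantel(SkDM(geo), SkDM(gen), method="pearson",
                                  permutations=999, alternative="greater")
        assert ours.r == pytest.approx(sk_r, abs=1e-12)
        assert ours.p == pytest.approx(sk_p, abs=0.05)
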