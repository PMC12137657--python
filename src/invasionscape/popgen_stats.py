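"""Diversity, differentiation, ordination, AMOVA and isolation-by-distance.

All estimators operate on the 0/1/2 alternate-allele coding of
:class:`~invasionscape.core_io.GenotypeMatrix`; -1 marks missing calls.
Conventions:

* He is the unbiased (small-sample corrected) expected heterozygosity
  2p(1-p) * 2n/(2n-1).
* F_IS = 1 - sum(Ho) / sum(He) over polymorphic loci (ratio of multilocus
  sums, hierfstat-style); monomorphic loci are excluded.
* Pairwise F_ST is Weir & Cockerham's theta, combined over loci as a ratio
  of summed variance components; negative estimates are reported as computed.
* Permutation p-values use the add-one convention (never exactly 0).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import DistanceMatrix, GenotypeMatrix, MISSING

logger = logging.getLogger("invasionscape")


@dataclass
class AmovaResult:
    phi_st: float
    sigma2_among: float
    sigma2_within: float
    p_value: float
    n_perm: int


@dataclass
class MantelResult:
    r: float
    p: float
    n_perm: int


# ---------------------------------------------------------------------------
# Allele frequencies and diversity
# ---------------------------------------------------------------------------

def allele_frequencies(G: GenotypeMatrix) -> dict[int, np.ndarray]:
    """Per-locality alternate-allele frequencies (NaN where a locus has no calls)."""
    out = {}
    for loc, calls in G.by_locality().items():
        valid = calls != MISSING
        n = valid.sum(axis=0)
        alt = np.where(valid, calls, 0).sum(axis=0)
        with np.errstate(invalid="ignore"):
            out[loc] = np.where(n > 0, alt / (2 * n), np.nan)
    return out


def heterozygosity(G: GenotypeMatrix) -> pd.DataFrame:
    """Per-locality Ho, He (unbiased) and F_IS.

    Returns a DataFrame indexed by locality_id with columns ho, he, fis, n.
    Localities with fewer than 2 individuals carry NaN statistics. Loci with
    no calls in a locality are excluded from that locality's means (logged);
    monomorphic loci are excluded from F_IS.
    """
    rows = []
    for loc, calls in G.by_locality().items():
        n_ind = calls.shape[0]
        if n_ind < 2:
            rows.append((loc, np.nan, np.nan, np.nan, n_ind))
            continue
        valid = calls != MISSING
        n = valid.sum(axis=0).astype(float)
        usable = n >= 2
        n_dropped = int((~usable).sum())
        if n_dropped:
            logger.info("locality %s: %d loci without enough calls excluded",
                        loc, n_dropped)
        het = np.where(valid, calls == 1, False).sum(axis=0)
        alt = np.where(valid, calls, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = alt / (2 * n)
            ho_l = het / n
            he_l = 2 * p * (1 - p) * (2 * n) / (2 * n - 1)
        ho_l, he_l = ho_l[usable], he_l[usable]
        poly = he_l > 0
        ho, he = float(np.mean(ho_l)), float(np.mean(he_l))
        fis = 1.0 - ho_l[poly].sum() / he_l[poly].sum() if poly.any() else np.nan
        rows.append((loc, ho, he, fis, n_ind))
    return pd.DataFrame(rows, columns=["locality_id", "ho", "he", "fis", "n"]
                        ).set_index("locality_id")


# ---------------------------------------------------------------------------
# Weir & Cockerham pairwise F_ST
# ---------------------------------------------------------------------------

def _wc_components(calls_a: np.ndarray, calls_b: np.ndarray):
    """Per-locus WC84 variance components (a, b, c) for two samples."""
    comps = []
    for calls in (calls_a, calls_b):
        valid = calls != MISSING
        n = valid.sum(axis=0).astype(float)
        alt = np.where(valid, calls, 0).sum(axis=0)
        het = np.where(valid, calls == 1, False).sum(axis=0)
        comps.append((n, alt, het))
    (n1, alt1, het1), (n2, alt2, het2) = comps
    ok = (n1 >= 1) & (n2 >= 1) & (n1 + n2 >= 3)
    r = 2.0
    with np.errstate(invalid="ignore", divide="ignore"):
        p1, p2 = alt1 / (2 * n1), alt2 / (2 * n2)
        h1, h2 = het1 / n1, het2 / n2
        nbar = (n1 + n2) / r
        nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1)
        pbar = (n1 * p1 + n2 * p2) / (r * nbar)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
        hbar = (n1 * h1 + n2 * h2) / (r * nbar)
        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - s2 * (r - 1) / r - hbar / 4) / (nbar - 1)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - s2 * (r - 1) / r - hbar * (2 * nbar - 1) / (4 * nbar)
        )
        c = hbar / 2
    poly = ok & (pbar > 0) & (pbar < 1)
    return a[poly], b[poly], c[poly]


def pairwise_fst(G: GenotypeMatrix) -> DistanceMatrix:
    """Multilocus Weir–Cockerham theta between every pair of localities.

    Ratio-of-sums over loci; negative estimates are kept. A pair with no
    shared polymorphic locus gets NaN (flagged via log).
    """
    by_loc = G.by_locality()
    locs = [l for l, calls in by_loc.items() if calls.shape[0] >= 2]
    if len(locs) < 2:
        raise ValueError("need >= 2 localities with >= 2 individuals")
    n = len(locs)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            a, b, c = _wc_components(by_loc[locs[i]], by_loc[locs[j]])
            denom = (a + b + c).sum()
            if len(a) == 0 or denom == 0:
                logger.warning("F_ST undefined for pair (%s, %s)", locs[i], locs[j])
                theta = np.nan
            else:
                theta = a.sum() / denom
            d[i, j] = d[j, i] = theta
    # a symmetric matrix with possibly negative entries is still a valid
    # "distance" container here; DistanceMatrix only enforces symmetry
    return DistanceMatrix(labels=locs, d=d)


# ---------------------------------------------------------------------------
# Genetic distances
# ---------------------------------------------------------------------------

def chord_distance(freqs: dict[int, np.ndarray]) -> DistanceMatrix:
    """Cavalli-Sforza & Edwards chord distance D_c between localities.

    D_c = (2/(pi*L)) * sum_l sqrt(2 * (1 - sum_a sqrt(p1a * p2a))); loci with
    a missing frequency in either locality are dropped pairwise.
    """
    locs = list(freqs)
    n = len(locs)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            p, q = freqs[locs[i]], freqs[locs[j]]
            ok = ~(np.isnan(p) | np.isnan(q))
            L = int(ok.sum())
            if L == 0:
                d[i, j] = d[j, i] = np.nan
                continue
            cos_theta = np.sqrt(p[ok] * q[ok]) + np.sqrt((1 - p[ok]) * (1 - q[ok]))
            val = (2.0 / (np.pi * L)) * np.sqrt(
                2.0 * np.clip(1.0 - cos_theta, 0.0, None)
            ).sum()
            d[i, j] = d[j, i] = val
    return DistanceMatrix(labels=locs, d=d)


def prevosti_distance(freqs: dict[int, np.ndarray]) -> DistanceMatrix:
    """Prevosti distance (1/(2L)) sum_l sum_a |p1a - p2a| between localities."""
    locs = list(freqs)
    n = len(locs)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            p, q = freqs[locs[i]], freqs[locs[j]]
            ok = ~(np.isnan(p) | np.isnan(q))
            L = int(ok.sum())
            if L == 0:
                d[i, j] = d[j, i] = np.nan
                continue
            d[i, j] = d[j, i] = float(np.abs(p[ok] - q[ok]).sum() * 2 / (2 * L))
    return DistanceMatrix(labels=locs, d=d)


def prevosti_distance_individuals(G: GenotypeMatrix) -> DistanceMatrix:
    """Prevosti distance between individuals: (1/(2L)) sum_l |g1 - g2|.

    An individual's two alleles are treated as a frequency vector (g/2,
    1-g/2), which reduces the per-locus allele-frequency difference sum to
    |g1 - g2|. Missing loci are dropped pairwise, with L adjusted.
    """
    calls = G.calls.astype(float)
    calls[G.calls == MISSING] = np.nan
    n = calls.shape[0]
    d = np.zeros((n, n))
    for i in range(n):
        diff = np.abs(calls[i] - calls)
        L = (~np.isnan(diff)).sum(axis=1)
        s = np.nansum(diff, axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            d[i] = np.where(L > 0, s / (2 * L), np.nan)
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(labels=list(G.individuals), d=d)


# ---------------------------------------------------------------------------
# AMOVA
# ---------------------------------------------------------------------------

def _pairwise_sq_genotype_distance(G: GenotypeMatrix) -> np.ndarray:
    """Squared Euclidean genotype distances, rescaled for pairwise missingness."""
    calls = G.calls.astype(float)
    calls[G.calls == MISSING] = np.nan
    n, L = calls.shape
    d2 = np.zeros((n, n))
    for i in range(n):
        diff2 = (calls[i] - calls) ** 2
        shared = (~np.isnan(diff2)).sum(axis=1)
        s = np.nansum(diff2, axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            d2[i] = np.where(shared > 0, s * L / shared, np.nan)
    np.fill_diagonal(d2, 0.0)
    return d2


def _amova_phi(d2: np.ndarray, groups: np.ndarray):
    """Variance components for a two-level AMOVA from squared distances."""
    N = d2.shape[0]
    labels = np.unique(groups)
    G_n = len(labels)
    ss_total = d2[np.triu_indices(N, 1)].sum() / N
    ss_within = 0.0
    sizes = []
    for g in labels:
        idx = np.flatnonzero(groups == g)
        sizes.append(len(idx))
        sub = d2[np.ix_(idx, idx)]
        ss_within += sub[np.triu_indices(len(idx), 1)].sum() / len(idx)
    sizes = np.asarray(sizes, dtype=float)
    ss_among = ss_total - ss_within
    df_a, df_w = G_n - 1, N - G_n
    ms_a, ms_w = ss_among / df_a, ss_within / df_w
    n0 = (N - (sizes**2).sum() / N) / df_a
    sigma_w = ms_w
    sigma_a = (ms_a - ms_w) / n0
    denom = sigma_a + sigma_w
    phi = sigma_a / denom if denom != 0 else np.nan
    return phi, sigma_a, sigma_w


def amova(
    G: GenotypeMatrix,
    cluster_of: dict[int, str],
    n_perm: int = 1000,
    seed: int = 0,
) -> AmovaResult:
    """Two-level AMOVA (among/within clusters) on squared genotype distances.

    Phi_ST = sigma2_among / (sigma2_among + sigma2_within); significance by
    permuting individuals across clusters, p = (1 + #{perm >= obs}) /
    (n_perm + 1).
    """
    groups = np.array([cluster_of[G.locality_of[i]] for i in G.individuals])
    labels, counts = np.unique(groups, return_counts=True)
    if len(labels) < 2:
        raise ValueError("need >= 2 clusters")
    if (counts < 2).any():
        raise ValueError("every cluster needs >= 2 individuals")
    d2 = _pairwise_sq_genotype_distance(G)
    phi, s_a, s_w = _amova_phi(d2, groups)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(groups)
        phi_p, _, _ = _amova_phi(d2, perm)
        if phi_p >= phi:
            count += 1
    p = (1 + count) / (n_perm + 1)
    return AmovaResult(phi_st=float(phi), sigma2_among=float(s_a),
                       sigma2_within=float(s_w), p_value=float(p), n_perm=n_perm)


# ---------------------------------------------------------------------------
# PCoA
# ---------------------------------------------------------------------------

def impute_mean(G: GenotypeMatrix) -> np.ndarray:
    """0/1/2 matrix with missing calls replaced by the locus mean allele value.

    Loci missing in every individual are dropped.
    """
    calls = G.calls.astype(float)
    calls[G.calls == MISSING] = np.nan
    keep = ~np.isnan(calls).all(axis=0)
    calls = calls[:, keep]
    means = np.nanmean(calls, axis=0)
    idx = np.where(np.isnan(calls))
    calls[idx] = means[idx[1]]
    return calls


def pcoa(G: GenotypeMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Principal coordinate analysis of mean-imputed genotypes.

    Euclidean distances, Gower double-centring, eigendecomposition. Returns
    (coordinates ordered by eigenvalue, percent variance per retained axis);
    only axes with positive eigenvalues are kept.
    """
    if G.n_individuals < 3:
        raise ValueError("need >= 3 individuals")
    X = impute_mean(G)
    sq = ((X[:, None, :] - X[None, :, :]) ** 2).sum(axis=2)
    n = sq.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ sq @ J
    evals, evecs = np.linalg.eigh(B)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    pos = evals > 1e-9 * max(evals.max(), 1.0)
    coords = evecs[:, pos] * np.sqrt(evals[pos])
    pct = 100.0 * evals[pos] / evals[pos].sum()
    return coords, pct


# ---------------------------------------------------------------------------
# Mantel test
# ---------------------------------------------------------------------------

def mantel(
    D1: DistanceMatrix,
    D2: DistanceMatrix,
    n_perm: int = 999,
    seed: int = 0,
) -> MantelResult:
    """Mantel correlation of two distance matrices with the same labels.

    r is the Pearson correlation of upper-triangle entries; the null permutes
    rows/columns of D2 simultaneously; one-sided p for positive association
    with the add-one convention.
    """
    if list(D1.labels) != list(D2.labels):
        raise ValueError("distance matrices must share labels in the same order")
    n = len(D1.labels)
    iu = np.triu_indices(n, 1)
    x = D1.d[iu]
    if np.std(x) == 0 or np.std(D2.d[iu]) == 0:
        raise ValueError("constant distance matrix: Mantel r undefined")
    xc = (x - x.mean()) / x.std()

    def corr(mat):
        y = mat[iu]
        yc = (y - y.mean()) / y.std()
        return float((xc * yc).mean())

    r_obs = corr(D2.d)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        if corr(D2.d[np.ix_(perm, perm)]) >= r_obs:
            count += 1
    p = (1 + count) / (n_perm + 1)
    return MantelResult(r=r_obs, p=float(p), n_perm=n_perm)
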