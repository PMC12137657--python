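"""Directional relative migration, kinship, and source-sink summaries.

The kinship estimator is Wang's (2002) moment estimator. Per locus, a pair of
diploid genotypes falls into one of four mutually exclusive similarity
classes: identical (P1), three-of-four alleles shared (P2), exactly one
allele shared between otherwise different genotypes (P3; requires three
alleles, so it never occurs at a biallelic locus), or no allele shared (P4).
Writing phi and Delta for the probabilities that the pair shares exactly one
or both allele pairs identical-by-descent, the class probabilities are linear
in (phi, Delta):

    E P1 = b + c*phi + (1-b)*Delta
    E P2 = d + e*phi - d*Delta
    E P3 = f + g*phi - f*Delta

with b..g polynomial in the allele-frequency moments a2, a3, a4 (sums of
squared/cubed/fourth powers of frequencies), bias-corrected with
falling-factorial estimators from the sample counts. The relatedness is
r = phi/2 + Delta, estimated per pair by weighted least squares over the
three moment equations, loci weighted by 1/(2*a2 - a3) as in Wang (2002).

Directional relative migration follows the divMigrate construction: for an
ordered locality pair, a hypothetical pool averages their allele frequencies;
the rate into a locality derives from that locality's differentiation from
the pool, converted to an Nm value combining G_ST and Jost's D, and the
whole matrix is scaled so its maximum is 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import GenotypeMatrix, Locality, MISSING
from .popgen_stats import allele_frequencies

logger = logging.getLogger("invasionscape")

MIN_INFORMATIVE_LOCI = 20
FULL_SIB_THRESHOLD = 0.5
EDGE_THRESHOLD = 0.35


@dataclass
class KinshipMatrix:
    individuals: list[str]
    r: np.ndarray            # symmetric pairwise relatedness
    reliable: np.ndarray     # False where < MIN_INFORMATIVE_LOCI shared loci

    def get(self, a: str, b: str) -> float:
        return float(self.r[self.individuals.index(a), self.individuals.index(b)])


@dataclass
class MigrationMatrix:
    labels: list[int]
    m: np.ndarray            # directed rates, max-normalised to 1
    statistic: str = "Nm_Alcala"


@dataclass
class LinearTrendResult:
    slope: float
    intercept: float
    t: float
    p: float
    cooks_distance: dict[int, float]
    n: int


# ---------------------------------------------------------------------------
# Wang relatedness
# ---------------------------------------------------------------------------

def _frequency_moments(G: GenotypeMatrix, freqs: np.ndarray | None = None):
    """Bias-corrected a2, a3, a4 and weights per locus from the full sample.

    When the true population frequencies are known (``freqs``), exact moments
    are used instead of the sample estimators.
    """
    if freqs is not None:
        p = np.asarray(freqs, dtype=float)
        a2 = p**2 + (1 - p) ** 2
        a3 = p**3 + (1 - p) ** 3
        a4 = p**4 + (1 - p) ** 4
        usable = (p > 0) & (p < 1)
        return _coefficients(a2, a3, a4, usable)
    calls = G.calls
    valid = calls != MISSING
    n_genes = 2 * valid.sum(axis=0).astype(float)
    alt = np.where(valid, calls, 0).sum(axis=0).astype(float)
    ref = n_genes - alt

    def falling(x, k):
        out = np.ones_like(x)
        for i in range(k):
            out = out * (x - i)
        return out

    with np.errstate(invalid="ignore", divide="ignore"):
        a2 = (falling(alt, 2) + falling(ref, 2)) / falling(n_genes, 2)
        a3 = (falling(alt, 3) + falling(ref, 3)) / falling(n_genes, 3)
        a4 = (falling(alt, 4) + falling(ref, 4)) / falling(n_genes, 4)
    usable = (n_genes >= 4) & (alt > 0) & (ref > 0)
    return _coefficients(a2, a3, a4, usable)


def _coefficients(a2, a3, a4, usable):
    b = 2 * a2**2 - a4
    c = a2 - 2 * a2**2 + a4
    d = 4 * (a3 - a4)
    e = 2 * (a2 - 3 * a3 + 2 * a4)
    f = 4 * (a2 - a2**2 - 2 * a3 + 2 * a4)
    g = 1 - 7 * a2 + 4 * a2**2 + 10 * a3 - 8 * a4
    with np.errstate(invalid="ignore", divide="ignore"):
        w = 1.0 / (2 * a2 - a3)
    return usable, w, np.stack([b, c, d, e, f, g])


def wang_relatedness(G: GenotypeMatrix, freqs: np.ndarray | None = None) -> KinshipMatrix:
    """Pairwise Wang (2002) relatedness from the full-sample frequencies.

    Loci with a missing call in either member are skipped pairwise; pairs with
    fewer than 20 informative loci are flagged unreliable. Pass ``freqs`` to
    use known (true) population allele frequencies instead of sample ones.
    """
    usable, w, coef = _frequency_moments(G, freqs)
    calls = G.calls
    n, L = calls.shape
    valid = (calls != MISSING) & usable[None, :]

    # per-locus similarity classes for all pairs, computed per pair below
    r_mat = np.zeros((n, n))
    reliable = np.ones((n, n), dtype=bool)
    b, c, d, e, f, g = coef

    for i in range(n):
        for j in range(i + 1, n):
            ok = valid[i] & valid[j]
            if ok.sum() < MIN_INFORMATIVE_LOCI:
                reliable[i, j] = reliable[j, i] = False
            if not ok.any():
                r_mat[i, j] = r_mat[j, i] = np.nan
                continue
            gi, gj = calls[i, ok].astype(int), calls[j, ok].astype(int)
            p1 = gi == gj
            p4 = np.abs(gi - gj) == 2
            p2 = ~p1 & ~p4          # homo vs het sharing one allele
            p3 = np.zeros_like(p1)  # needs a third allele; never at SNPs

            wk = w[ok]
            W = wk.sum()
            P = np.array([(wk * p1).sum(), (wk * p2).sum(), (wk * p3).sum()]) / W
            bb, cc, dd, ee, ff, gg = (np.array([x[ok] * wk for x in (b, c, d, e, f, g)]
                                               ).sum(axis=1) / W)
            # least squares for (phi, Delta):  P - const = A @ (phi, Delta)
            A = np.array([[cc, 1 - bb], [ee, -dd], [gg, -ff]])
            y = P - np.array([bb, dd, ff])
            phi, delta = np.linalg.lstsq(A, y, rcond=None)[0]
            r_mat[i, j] = r_mat[j, i] = phi / 2 + delta

    return KinshipMatrix(individuals=list(G.individuals), r=r_mat, reliable=reliable)


def filter_fullsibs(
    K: KinshipMatrix,
    locality_of: dict[str, int],
    threshold: float = FULL_SIB_THRESHOLD,
    seed: int = 0,
) -> tuple[list[str], list[tuple[str, str, str]]]:
    """Iteratively discard one random member per same-locality full-sib pair.

    Returns (retained individual ids, removal log of (kept, removed, reason)).
    Post-condition: no retained same-locality pair has relatedness >= threshold.
    """
    rng = np.random.default_rng(seed)
    retained = list(K.individuals)
    log: list[tuple[str, str, str]] = []
    while True:
        pair = None
        for ai in range(len(retained)):
            for bi in range(ai + 1, len(retained)):
                a, b = retained[ai], retained[bi]
                if locality_of[a] != locality_of[b]:
                    continue
                if K.get(a, b) >= threshold:
                    pair = (a, b)
                    break
            if pair:
                break
        if pair is None:
            return retained, log
        drop = pair[rng.integers(0, 2)]
        keep = pair[0] if drop == pair[1] else pair[1]
        retained.remove(drop)
        log.append((keep, drop, f"full-sib pair r={K.get(*pair):.3f}"))


def crosslocality_edges(
    K: KinshipMatrix,
    locality_of: dict[str, int],
    threshold: float = EDGE_THRESHOLD,
) -> list[tuple[str, str, float]]:
    """Cross-locality pairs with relatedness >= threshold (likely dispersers)."""
    edges = []
    for i, a in enumerate(K.individuals):
        for j in range(i + 1, len(K.individuals)):
            b = K.individuals[j]
            if locality_of[a] == locality_of[b]:
                continue
            r = K.r[i, j]
            if np.isfinite(r) and r >= threshold:
                edges.append((a, b, float(r)))
    return edges


# ---------------------------------------------------------------------------
# Directional relative migration
# ---------------------------------------------------------------------------

def _pool_differentiation(p_deme, p_pool):
    """Multilocus (G_ST, Jost D) between one deme and a pooled frequency set."""
    ok = ~(np.isnan(p_deme) | np.isnan(p_pool))
    p1, p2 = p_deme[ok], p_pool[ok]
    hs = (2 * p1 * (1 - p1) + 2 * p2 * (1 - p2)) / 2
    pbar = (p1 + p2) / 2
    ht = 2 * pbar * (1 - pbar)
    mhs, mht = hs.mean(), ht.mean()
    if mht <= 0:
        return np.nan, np.nan
    gst = (mht - mhs) / mht
    d = 2 * (mht - mhs) / (1 - mhs) if mhs < 1 else np.nan
    return gst, d


def _nm_alcala(gst: float, d: float) -> float:
    """Migration estimate combining G_ST and Jost's D (geometric mean of the
    island-model Nm implied by each statistic)."""
    if not (np.isfinite(gst) and np.isfinite(d)):
        return np.nan
    gst = min(max(gst, 1e-6), 1 - 1e-12)
    d = min(max(d, 1e-6), 1 - 1e-12)
    nm_g = (1 - gst) / (4 * gst)
    nm_d = (1 - d) / (4 * d)
    return float(np.sqrt(nm_g * nm_d))


def directional_migration(G: GenotypeMatrix, stat: str = "Nm_Alcala") -> MigrationMatrix:
    """Directed relative migration rates between localities (divMigrate-style).

    For each ordered pair (a, b): pool frequencies = mean of a's and b's;
    m[a->b] derives from b's differentiation from the pool; the full matrix is
    divided by its maximum so rates lie in (0, 1].
    """
    if stat != "Nm_Alcala":
        raise ValueError(f"unsupported statistic {stat!r}")
    freqs = allele_frequencies(G)
    sizes = {loc: calls.shape[0] for loc, calls in G.by_locality().items()}
    locs = [l for l in freqs if sizes[l] >= 2]
    if len(locs) < 2:
        raise ValueError("need >= 2 localities with >= 2 individuals")
    n = len(locs)
    m = np.full((n, n), np.nan)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            pool = (freqs[locs[i]] + freqs[locs[j]]) / 2
            gst_b, d_b = _pool_differentiation(freqs[locs[j]], pool)
            m[i, j] = _nm_alcala(gst_b, d_b)
    if np.isnan(m[~np.eye(n, dtype=bool)]).all():
        logger.warning("all migration rates undefined (monomorphic data?)")
        return MigrationMatrix(labels=locs, m=m, statistic=stat)
    mx = np.nanmax(m)
    if mx > 0:
        m = m / mx
    return MigrationMatrix(labels=locs, m=m, statistic=stat)


def migration_summary(M: MigrationMatrix) -> pd.DataFrame:
    """Mean relative immigration (I), emigration (E) and their ratio per locality.

    I(a) averages the rates into a, E(a) the rates out of a; R_I/E is NaN when
    E = 0.
    """
    n = len(M.labels)
    off = ~np.eye(n, dtype=bool)
    I = np.array([np.nanmean(M.m[:, a][off[:, a]]) for a in range(n)])
    E = np.array([np.nanmean(M.m[a, :][off[a, :]]) for a in range(n)])
    with np.errstate(invalid="ignore", divide="ignore"):
        R = np.where(E > 0, I / E, np.nan)
    return pd.DataFrame({"locality_id": M.labels, "I": I, "E": E, "R_IE": R}
                        ).set_index("locality_id")


# ---------------------------------------------------------------------------
# Downstream comparisons
# ---------------------------------------------------------------------------

def compare_clusters(
    values: dict[int, float],
    cluster_of: dict[int, str],
) -> tuple[float, float]:
    """Two-sided Mann-Whitney U between the two clusters' per-locality values.

    Exact enumeration for combined n <= 20 without ties; tie-corrected normal
    approximation otherwise. Returns (U, p).
    """
    groups: dict[str, list[float]] = {}
    for loc, v in values.items():
        if np.isfinite(v):
            groups.setdefault(cluster_of[loc], []).append(v)
    if len(groups) != 2:
        raise ValueError("need exactly two clusters with data")
    a, b = groups.values()
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs n >= 2")
    combined = len(a) + len(b)
    no_ties = len(set(a) | set(b)) == combined
    method = "exact" if (combined <= 20 and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def ratio_vs_source_distance(
    values: dict[int, float],
    localities: list[Locality],
    sources: list[tuple[float, float]],
    drop: list[int] | None = None,
) -> LinearTrendResult:
    """OLS of per-locality R_I/E on Euclidean distance to the nearest source.

    Cook's distance is reported per locality so influential points can be
    identified (and passed back through ``drop``).
    """
    import statsmodels.api as sm
    from statsmodels.stats.outliers_influence import OLSInfluence

    drop = set(drop or [])
    loc_by_id = {l.locality_id: l for l in localities}
    ids, y, x = [], [], []
    for loc_id, v in values.items():
        if loc_id in drop or not np.isfinite(v):
            continue
        loc = loc_by_id[loc_id]
        dist = min(np.hypot(loc.x - sx, loc.y - sy) for sx, sy in sources)
        ids.append(loc_id)
        y.append(v)
        x.append(dist)
    if len(ids) < 3:
        raise ValueError("need >= 3 localities after drops")
    x = np.asarray(x)
    if np.ptp(x) == 0:
        raise ValueError("all distances equal: slope undefined")
    X = sm.add_constant(x)
    fit = sm.OLS(np.asarray(y), X).fit()
    cooks = OLSInfluence(fit).cooks_distance[0]
    return LinearTrendResult(
        slope=float(fit.params[1]),
        intercept=float(fit.params[0]),
        t=float(fit.tvalues[1]),
        p=float(fit.pvalues[1]),
        cooks_distance={i: float(cd) for i, cd in zip(ids, cooks)},
        n=len(ids),
    )
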