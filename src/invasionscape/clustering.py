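"""Bayesian admixture clustering with Evanno model choice.

A STRUCTURE-style Gibbs sampler under the admixture model with uncorrelated
allele frequencies: cluster allele frequencies carry Beta(1, 1) priors, each
of an individual's two allele copies per locus carries a latent cluster
assignment, and individual admixture proportions carry a symmetric
Dirichlet(alpha) prior with alpha = 1. Replicate runs are consolidated by
greedy label alignment (exhaustive over cluster permutations for K <= 8),
the number of clusters is chosen by the Evanno delta-K criterion, and the
analysis is reapplied within each inferred cluster to expose hierarchical
substructure, assigning a locality to a cluster when its individuals' mean
admixture proportion is >= 0.6.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_io import GenotypeMatrix, MISSING

logger = logging.getLogger("invasionscape")

Q_THRESHOLD = 0.6
DIRICHLET_ALPHA = 1.0


@dataclass
class QMatrix:
    individuals: list[str]
    q: np.ndarray              # (n, K) admixture proportions, rows sum to 1
    log_likelihood: float      # mean ln P(X | p, q) over sampled iterations
    k: int


@dataclass
class ClusterNode:
    """One level of the hierarchical clustering tree."""

    localities: list[int]
    n_individuals: int
    best_k: int | None               # None = indeterminate
    assignment: dict[int, object]    # locality -> cluster index or "unassigned"
    q_matrix: QMatrix | None
    children: dict[int, "ClusterNode"]

    def depth(self) -> int:
        if not self.children:
            return 1
        return 1 + max(c.depth() for c in self.children.values())

    def to_dict(self) -> dict:
        return {
            "localities": self.localities,
            "n_individuals": self.n_individuals,
            "best_k": self.best_k,
            "assignment": {str(k): v for k, v in self.assignment.items()},
            "children": {str(k): c.to_dict() for k, c in self.children.items()},
        }


# ---------------------------------------------------------------------------
# Gibbs sampler
# ---------------------------------------------------------------------------

def admixture_mcmc(
    G: GenotypeMatrix,
    K: int,
    n_burn: int = 10_000,
    n_iter: int = 100_000,
    seed: int = 0,
) -> QMatrix:
    """Posterior-mean admixture proportions and mean ln-likelihood at fixed K.

    Deterministic under ``seed``. For K = 1 the result is exact (all q = 1)
    and only the likelihood is sampled.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    if K > G.n_individuals:
        raise ValueError("K exceeds the number of individuals")
    rng = np.random.default_rng(seed)
    calls = G.calls
    n, L = calls.shape
    observed = calls != MISSING
    # two exchangeable allele copies per genotype
    alleles = np.stack([
        np.where(observed, (calls >= 1), False),
        np.where(observed, (calls == 2), False),
    ]).astype(bool)                      # (2, n, L)

    p = np.full((K, L), 0.5)
    q = np.full((n, K), 1.0 / K)
    q_sum = np.zeros((n, K))
    ll_sum, ll_n = 0.0, 0

    for it in range(n_burn + n_iter):
        # (i) sample copy assignments z | p, q
        counts_k = np.zeros((n, K))
        alt_k = np.zeros((K, L))
        tot_k = np.zeros((K, L))
        for copy in range(2):
            a = alleles[copy]            # (n, L) allele values
            f = np.where(a[:, None, :], p[None, :, :], 1.0 - p[None, :, :])
            w = q[:, :, None] * f        # (n, K, L)
            w_sum = w.sum(axis=1, keepdims=True)
            u = rng.random((n, 1, L)) * w_sum
            z = (w.cumsum(axis=1) < u).sum(axis=1)   # (n, L) in 0..K-1
            z = np.minimum(z, K - 1)
            # accumulate counts (only observed calls)
            for k in range(K):
                sel = (z == k) & observed
                counts_k[:, k] += sel.sum(axis=1)
                alt_k[k] += (sel & a).sum(axis=0)
                tot_k[k] += sel.sum(axis=0)
        # (ii) p | z  ~ Beta(1 + alt, 1 + ref)
        p = rng.beta(1.0 + alt_k, 1.0 + (tot_k - alt_k))
        # (iii) q | z ~ Dirichlet(alpha + counts)
        gam = rng.gamma(DIRICHLET_ALPHA + counts_k)
        q = gam / gam.sum(axis=1, keepdims=True)

        if it >= n_burn:
            q_sum += q
            pi = q @ p                   # (n, L) expected alt-copy frequency
            pi = np.clip(pi, 1e-12, 1 - 1e-12)
            ll = np.where(calls == 0, 2 * np.log(1 - pi),
                 np.where(calls == 2, 2 * np.log(pi),
                 np.where(calls == 1, np.log(2 * pi * (1 - pi)), 0.0)))
            ll_sum += ll[observed].sum()
            ll_n += 1

    q_mean = q_sum / max(ll_n, 1)
    q_mean = q_mean / q_mean.sum(axis=1, keepdims=True)
    return QMatrix(individuals=list(G.individuals), q=q_mean,
                   log_likelihood=ll_sum / max(ll_n, 1), k=K)


# ---------------------------------------------------------------------------
# Run consolidation
# ---------------------------------------------------------------------------

def align_to(reference: np.ndarray, q: np.ndarray) -> tuple[np.ndarray, tuple]:
    """Permute columns of q to best match the reference (max summed correlation)."""
    K = q.shape[1]
    if K == 1:
        return q, (0,)
    best_perm, best_score = None, -np.inf
    for perm in itertools.permutations(range(K)):
        score = 0.0
        for k in range(K):
            a, b = reference[:, k], q[:, perm[k]]
            if a.std() > 0 and b.std() > 0:
                score += float(np.corrcoef(a, b)[0, 1])
            else:
                score += float(-np.abs(a - b).mean())
        if score > best_score:
            best_perm, best_score = perm, score
    return q[:, best_perm], best_perm


def consolidate_runs(runs: list[QMatrix]) -> QMatrix:
    """Label-align replicate runs to the first and average element-wise.

    Exhaustive permutation search (K <= 8 in practice); rows renormalised.
    A single run is returned unchanged.
    """
    if not runs:
        raise ValueError("no runs")
    if len(runs) == 1:
        return runs[0]
    ref = runs[0]
    K = ref.k
    for run in runs[1:]:
        if run.k != K or run.individuals != ref.individuals:
            raise ValueError("runs have inconsistent dimensions")
    if K > 8:
        raise ValueError("exhaustive alignment limited to K <= 8")
    acc = ref.q.copy()
    for run in runs[1:]:
        aligned, _ = align_to(ref.q, run.q)
        acc += aligned
    acc /= len(runs)
    acc /= acc.sum(axis=1, keepdims=True)
    return QMatrix(individuals=list(ref.individuals), q=acc,
                   log_likelihood=float(np.mean([r.log_likelihood for r in runs])),
                   k=K)


# ---------------------------------------------------------------------------
# Evanno delta-K
# ---------------------------------------------------------------------------

def evanno_delta_k(replicates: dict[int, list[float]]) -> tuple[pd.DataFrame, int | None]:
    """Evanno table and the best K (argmax delta-K over interior K).

    ``replicates`` maps K to the replicate ln-likelihoods. Needs >= 3
    consecutive K values with >= 2 replicates each. Returns (table, best_k);
    best_k is None when no interior K has a positive curvature signal
    (indeterminate).
    """
    ks = sorted(replicates)
    if len(ks) < 3 or any(k2 - k1 != 1 for k1, k2 in zip(ks[:-1], ks[1:])):
        raise ValueError("need >= 3 consecutive K values")
    if any(len(replicates[k]) < 2 for k in ks):
        raise ValueError("need >= 2 replicates per K")
    mean = {k: float(np.mean(replicates[k])) for k in ks}
    sd = {k: float(np.std(replicates[k], ddof=1)) for k in ks}
    rows = []
    for k in ks:
        lp = mean[k] - mean[k - 1] if k - 1 in mean else np.nan
        lpp = (
            abs((mean[k + 1] - mean[k]) - lp)
            if (k + 1 in mean and k - 1 in mean)
            else np.nan
        )
        if np.isnan(lpp):
            dk = np.nan
        elif sd[k] == 0:
            logger.warning("zero SD of ln-likelihood at K=%d; delta-K undefined", k)
            dk = np.nan
        else:
            dk = lpp / sd[k]
        rows.append((k, mean[k], sd[k], lp, lpp, dk))
    table = pd.DataFrame(
        rows, columns=["K", "mean_lnL", "sd_lnL", "Lprime", "Lsecond", "deltaK"]
    ).set_index("K")
    valid = table.deltaK.dropna()
    if valid.empty or (table.Lsecond.dropna() == 0).all():
        return table, None
    return table, int(valid.idxmax())


# ---------------------------------------------------------------------------
# Hierarchical application
# ---------------------------------------------------------------------------

def locality_mean_q(Q: QMatrix, locality_of: dict[str, int]) -> pd.DataFrame:
    """Mean admixture proportion per locality (rows) and cluster (columns)."""
    locs = sorted({locality_of[i] for i in Q.individuals})
    out = np.zeros((len(locs), Q.q.shape[1]))
    for li, loc in enumerate(locs):
        rows = [i for i, ind in enumerate(Q.individuals) if locality_of[ind] == loc]
        out[li] = Q.q[rows].mean(axis=0)
    return pd.DataFrame(out, index=locs)


def hierarchical_clustering(
    G: GenotypeMatrix,
    q_threshold: float = Q_THRESHOLD,
    max_k: int = 20,
    replicates: int = 10,
    n_burn: int = 10_000,
    n_iter: int = 100_000,
    seed: int = 0,
    _depth: int = 0,
) -> ClusterNode:
    """Recursive admixture clustering with the >= 0.6 locality assignment rule.

    At each level, K = 1..min(max_k, n_localities + 1) is explored with
    ``replicates`` runs per K, the level's K is chosen by Evanno, and every
    level-1 cluster containing >= 2 assigned localities with >= 4 individuals
    is re-analysed for substructure. Recursion stops when the best K is 1 or
    indeterminate.
    """
    locs = G.locality_ids()
    node = ClusterNode(localities=sorted(locs), n_individuals=G.n_individuals,
                       best_k=None, assignment={}, q_matrix=None, children={})
    k_hi = min(max_k, G.n_individuals - 1, len(locs) + 1)
    if k_hi < 3 or _depth > 4:
        return node

    rng = np.random.default_rng(seed)
    lnls: dict[int, list[float]] = {}
    runs_by_k: dict[int, list[QMatrix]] = {}
    for k in range(1, k_hi + 1):
        runs = [
            admixture_mcmc(G, k, n_burn=n_burn, n_iter=n_iter,
                           seed=int(rng.integers(2**31)))
            for _ in range(max(replicates, 2))
        ]
        lnls[k] = [r.log_likelihood for r in runs]
        runs_by_k[k] = runs
    _, best_k = evanno_delta_k(lnls)
    node.best_k = best_k
    if best_k is None or best_k == 1:
        return node

    Q = consolidate_runs(runs_by_k[best_k])
    node.q_matrix = Q
    mean_q = locality_mean_q(Q, G.locality_of)
    for loc in mean_q.index:
        row = mean_q.loc[loc]
        k_best = int(row.idxmax())
        node.assignment[loc] = k_best if row[k_best] >= q_threshold else "unassigned"

    # Evanno's delta-K cannot point at K = 1, so a diffuse-q level (most
    # localities unassignable at the threshold) is declared unstructured
    n_assigned = sum(1 for a in node.assignment.values() if a != "unassigned")
    if n_assigned < max(2, len(locs) // 2):
        logger.info("level with best_k=%d left unstructured: only %d/%d "
                    "localities assignable at q >= %.2f",
                    best_k, n_assigned, len(locs), q_threshold)
        node.best_k = 1
        node.assignment = {}
        return node

    for k in range(best_k):
        members = [l for l, a in node.assignment.items() if a == k]
        if len(members) < 2:
            continue
        keep = [i for i in G.individuals if G.locality_of[i] in members]
        if len(keep) < 4:
            continue
        sub = G.subset_individuals(keep)
        node.children[k] = hierarchical_clustering(
            sub, q_threshold=q_threshold, max_k=max_k, replicates=replicates,
            n_burn=n_burn, n_iter=n_iter, seed=int(rng.integers(2**31)),
            _depth=_depth + 1,
        )
    return node
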