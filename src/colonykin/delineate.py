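"""Colony delineation from field samples via pairwise genotypic differentiation.

Field samples (collection points, each a set of workers) are compared pairwise
with a multilocus log-likelihood G-statistic; P-values come from permuting
whole multilocus genotypes between the two samples.  Samples that never differ
significantly (after Bonferroni correction over all pairs) are chained into
one colony by connected components.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

from .genotypes import GenotypeTable

logger = logging.getLogger(__name__)

__all__ = ["PairTestResult", "ColonyPartition", "pairwise_g",
           "differentiation_test", "delineate", "multilocus_g_counts"]


@dataclass
class PairTestResult:
    pair: tuple
    G_obs: float
    p_value: float
    n_permutations: int
    significant_after_correction: bool = False


@dataclass
class ColonyPartition:
    colony_of: dict  # sample_id -> colony id
    group_colony: dict  # sampling-point label -> colony id
    evidence: list = field(default_factory=list)  # PairTestResult per pair

    @property
    def n_colonies(self) -> int:
        return len(set(self.group_colony.values()))


def _g_2xk(counts_a: np.ndarray, counts_b: np.ndarray) -> np.ndarray:
    """G = 2 sum O ln(O/E) for 2 x K contingency tables (vectorised over the
    leading axis); expected counts from row/column margins, 0*ln0 = 0."""
    ca = counts_a.astype(float)
    cb = counts_b.astype(float)
    na = ca.sum(axis=-1, keepdims=True)
    nb = cb.sum(axis=-1, keepdims=True)
    col = ca + cb
    n = na + nb
    with np.errstate(divide="ignore", invalid="ignore"):
        ea = na * col / n
        eb = nb * col / n
        ga = np.where(ca > 0, ca * np.log(ca / ea), 0.0)
        gb = np.where(cb > 0, cb * np.log(cb / eb), 0.0)
    return 2.0 * (np.nansum(ga, axis=-1) + np.nansum(gb, axis=-1))


def multilocus_g_counts(onehots: list[np.ndarray],
                        in_a: np.ndarray) -> np.ndarray:
    """Multilocus G for membership vectors.

    ``onehots``: per locus an (n_pool, K_l) one-hot genotype-class matrix with
    all-zero rows for missing genotypes.  ``in_a``: boolean (n_splits, n_pool).
    Returns G summed over loci for each split.
    """
    g = np.zeros(in_a.shape[0])
    a = in_a.astype(float)
    for oh in onehots:
        tot = oh.sum(axis=0)
        ca = a @ oh
        cb = tot[None, :] - ca
        g += _g_2xk(ca, cb)
    return g


def _pooled_onehots(t: GenotypeTable, pool: np.ndarray) -> list[np.ndarray]:
    """Per-locus one-hot genotype-class matrices over the pooled samples."""
    sub = t.subset(pool)
    out = []
    for l in range(sub.n_loci):
        codes, k = sub.genotype_codes(l)
        if k == 0:
            continue
        oh = np.zeros((len(pool), k))
        ok = codes >= 0
        oh[np.flatnonzero(ok), codes[ok]] = 1.0
        out.append(oh)
    return out


def pairwise_g(t: GenotypeTable, a, b) -> float:
    """Observed multilocus G between sample sets ``a`` and ``b`` (index arrays):
    per locus, the genotype-class x set contingency G, summed over loci with
    data in both sets."""
    a = np.asarray(a, dtype=np.intp)
    b = np.asarray(b, dtype=np.intp)
    if a.size == 0 or b.size == 0:
        raise ValueError("both sample sets must be non-empty")
    pool = np.concatenate([a, b])
    onehots = _pooled_onehots(t, pool)
    in_a = np.zeros((1, len(pool)), dtype=bool)
    in_a[0, : len(a)] = True
    # keep only loci informative in both sets
    kept = []
    for oh in onehots:
        has_a = oh[: len(a)].sum() > 0
        has_b = oh[len(a):].sum() > 0
        if has_a and has_b:
            kept.append(oh)
    if not kept:
        raise ValueError("no locus with data in both sample sets")
    return float(multilocus_g_counts(kept, in_a)[0])


def differentiation_test(
    t: GenotypeTable, a, b, n_perm: int = 2000,
    seed: int | np.random.Generator = 0,
) -> PairTestResult:
    """Permutation test of genotypic differentiation between two sample sets.

    Whole multilocus genotypes are permuted between the sets (set sizes
    fixed); p = (1 + #{G_perm >= G_obs}) / (n_perm + 1).
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    a = np.asarray(a, dtype=np.intp)
    b = np.asarray(b, dtype=np.intp)
    g_obs = pairwise_g(t, a, b)
    pool = np.concatenate([a, b])
    onehots = _pooled_onehots(t, pool)
    n = len(pool)
    order = np.argsort(rng.random((n_perm, n)), axis=1)
    in_a = np.zeros((n_perm, n), dtype=bool)
    np.put_along_axis(in_a, order[:, : len(a)], True, axis=1)
    g_perm = multilocus_g_counts(onehots, in_a)
    p = (1 + int((g_perm >= g_obs - 1e-12).sum())) / (n_perm + 1)
    return PairTestResult(pair=(tuple(a), tuple(b)), G_obs=g_obs,
                          p_value=float(min(p, 1.0)), n_permutations=n_perm)


class _UnionFind:
    def __init__(self, items):
        self.parent = {x: x for x in items}

    def find(self, x):
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, x, y):
        self.parent[self.find(x)] = self.find(y)


def delineate(
    t: GenotypeTable,
    alpha: float = 0.05,
    correction: str = "bonferroni",
    n_perm: int = 2000,
    seed: int | np.random.Generator = 0,
) -> ColonyPartition:
    """Partition sampling points (``t.groups``) into colonies.

    Pairs NOT significant after correction are edges; connected components are
    colonies (single-linkage).  Intransitive triples — a pair significant yet
    chained into one component — are logged.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    gix = t.group_indices()
    points = list(gix)
    if len(points) < 2:
        raise ValueError("need at least two sampling points")
    pairs = list(combinations(points, 2))
    level = alpha / len(pairs) if correction == "bonferroni" else alpha
    # the permutation p floor is 1/(n_perm+1): raise n_perm when it cannot
    # resolve the corrected level, otherwise nothing can ever be significant
    needed = int(np.ceil(1.0 / level))
    if n_perm < needed:
        logger.info("raising n_perm from %d to %d to resolve the "
                    "Bonferroni-corrected level %.2g", n_perm, needed, level)
        n_perm = needed
    uf = _UnionFind(points)
    evidence = []
    for u, v in pairs:
        res = differentiation_test(t, gix[u], gix[v], n_perm=n_perm, seed=rng)
        res.pair = (u, v)
        res.significant_after_correction = res.p_value < level
        evidence.append(res)
        if not res.significant_after_correction:
            uf.union(u, v)
    roots: dict = {}
    group_colony = {}
    for pt in points:
        root = uf.find(pt)
        if root not in roots:
            roots[root] = f"colony_{len(roots) + 1:03d}"
        group_colony[pt] = roots[root]
    intransitive = sum(
        1 for r in evidence
        if r.significant_after_correction
        and group_colony[r.pair[0]] == group_colony[r.pair[1]]
    )
    if intransitive:
        logger.warning(
            "%d significant pair(s) ended up inside one colony "
            "(intransitive differentiation; single-linkage merging applied)",
            intransitive,
        )
    colony_of = {s: group_colony[g] for s, g in zip(t.sample_ids, t.groups)}
    return ColonyPartition(colony_of, group_colony, evidence)
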