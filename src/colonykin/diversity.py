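"""Population-level summary statistics and marker quality control.

All population-level statistics operate on one randomly chosen worker per
colony (colony members are close kin; using them all would pseudo-replicate),
drawn with an explicit seed that the caller shares across stages so every
population-level analysis sees the same representatives.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

from .genotypes import MISSING, GenotypeTable

__all__ = [
    "PopulationSummary", "NullAlleleReport", "one_per_colony",
    "summarize", "hwe_test", "ld_test", "null_allele_estimate",
    "private_alleles", "unbiased_he",
]


@dataclass
class PopulationSummary:
    population: str
    n_colonies: int
    N_A: float  # mean alleles per locus
    H_E: float  # unbiased expected heterozygosity, mean over loci
    H_O: float  # observed heterozygosity, mean over loci
    F_IS: float


@dataclass
class NullAlleleReport:
    locus: str
    estimator: str
    estimated_null_freq: float
    hwe_p: float | None = None


def one_per_colony(t: GenotypeTable, colonies=None,
                   seed: int | np.random.Generator = 0) -> np.ndarray:
    """Indices of one randomly chosen sample per colony (seeded)."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    labels = t.groups if colonies is None else np.array(
        [colonies[s] for s in t.sample_ids], dtype=object)
    out = []
    for g in pd.unique(labels):
        ix = np.flatnonzero(labels == g)
        out.append(int(rng.choice(ix)))
    return np.asarray(out, dtype=np.intp)


def unbiased_he(counts: np.ndarray) -> float:
    """Nei's unbiased gene diversity (2n/(2n-1)) (1 - sum p^2) from allele
    counts at one locus."""
    n_genes = counts.sum()
    if n_genes < 2:
        return float("nan")
    p = counts / n_genes
    return float(n_genes / (n_genes - 1) * (1.0 - (p ** 2).sum()))


def _locus_counts(t: GenotypeTable, ix: np.ndarray, l: int):
    pairs = t.alleles[ix, l, :]
    ok = pairs[:, 0] != MISSING
    genes = pairs[ok].ravel()
    if genes.size == 0:
        return None
    alleles, counts = np.unique(genes, return_counts=True)
    het = (pairs[ok, 0] != pairs[ok, 1])
    return alleles, counts.astype(float), het, int(ok.sum())


def summarize(t: GenotypeTable, populations=None, colonies=None,
              seed: int | np.random.Generator = 0) -> pd.DataFrame:
    """Per-population summary (one worker per colony): N_A, H_E, H_O, F_IS.

    ``populations``: map colony_id -> population (default: one population,
    "all").  ``colonies``: per-sample colony labels (default ``t.groups``).
    F_IS = 1 - sum_l H_O,l / sum_l H_E,l (ratio of sums over loci).
    """
    labels = t.groups if colonies is None else np.array(
        [colonies[s] for s in t.sample_ids], dtype=object)
    reps = one_per_colony(t, colonies, seed)
    pop_of = (lambda c: "all") if populations is None else \
        (lambda c: populations[c])
    rows = []
    by_pop: dict[str, list[int]] = {}
    for i in reps:
        by_pop.setdefault(pop_of(labels[i]), []).append(i)
    for pop, ix in by_pop.items():
        ix = np.asarray(ix, dtype=np.intp)
        na, he, ho = [], [], []
        for l in range(t.n_loci):
            lc = _locus_counts(t, ix, l)
            if lc is None:
                warnings.warn(f"locus {t.locus_names[l]} missing in {pop}; dropped")
                continue
            alleles, counts, het, n = lc
            na.append(len(alleles))
            he.append(unbiased_he(counts))
            ho.append(het.mean())
        he_a, ho_a = np.asarray(he), np.asarray(ho)
        f_is = 1.0 - ho_a.sum() / he_a.sum() if he_a.sum() > 0 else float("nan")
        rows.append(dict(population=pop, n_colonies=len(ix),
                         N_A=float(np.mean(na)), H_E=float(he_a.mean()),
                         H_O=float(ho_a.mean()), F_IS=float(f_is)))
    return pd.DataFrame(rows)


def hwe_test(t: GenotypeTable, samples, locus: int,
             n_shuffles: int = 3200,
             seed: int | np.random.Generator = 0) -> float:
    """Monte-Carlo Hardy–Weinberg test at one locus.

    Allele copies are permuted among the genotyped individuals (keeping
    allele frequencies fixed), the statistic is |F_IS| = |1 - H_O/H_E|, and
    p = (1 + #{|F_perm| >= |F_obs|}) / (n_shuffles + 1).  Monomorphic locus
    -> p = 1.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    ix = np.asarray(samples, dtype=np.intp)
    pairs = t.alleles[ix, locus, :]
    pairs = pairs[pairs[:, 0] != MISSING]
    n = len(pairs)
    if n < 5:
        raise ValueError("need >= 5 genotyped individuals")
    genes = pairs.ravel()
    if np.unique(genes).size < 2:
        return 1.0
    he = 1.0 - ((np.bincount(genes) / genes.size) ** 2).sum()
    ho_obs = (pairs[:, 0] != pairs[:, 1]).mean()
    f_obs = abs(1.0 - ho_obs / he)
    # vectorised shuffles: each row an independent permutation of the copies
    mat = np.tile(genes, (n_shuffles, 1))
    mat = rng.permuted(mat, axis=1)
    ho_perm = (mat[:, 0::2] != mat[:, 1::2]).mean(axis=1)
    f_perm = np.abs(1.0 - ho_perm / he)
    p = (1 + int((f_perm >= f_obs - 1e-12).sum())) / (n_shuffles + 1)
    return float(min(p, 1.0))


def ld_test(t: GenotypeTable, samples, locus_pair: tuple[int, int],
            n_shuffles: int = 3200,
            seed: int | np.random.Generator = 0) -> float:
    """Monte-Carlo linkage-disequilibrium test for a locus pair.

    Statistic: log-likelihood G of the two-locus genotype-class contingency
    table; null distribution by permuting one locus's genotypes among the
    individuals (complete cases only).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    ix = np.asarray(samples, dtype=np.intp)
    l1, l2 = locus_pair
    sub = t.subset(ix)
    c1, k1 = sub.genotype_codes(l1)
    c2, k2 = sub.genotype_codes(l2)
    ok = (c1 >= 0) & (c2 >= 0)
    c1, c2 = c1[ok], c2[ok]
    if len(c1) < 2:
        raise ValueError("need >= 2 complete two-locus genotypes")
    if k1 < 2 or k2 < 2 or np.unique(c1).size < 2 or np.unique(c2).size < 2:
        raise ValueError("both loci must be polymorphic among complete cases")

    def g_of(a: np.ndarray, b: np.ndarray) -> float:
        tab = np.zeros((k1, k2))
        np.add.at(tab, (a, b), 1.0)
        rowt = tab.sum(axis=1, keepdims=True)
        colt = tab.sum(axis=0, keepdims=True)
        with np.errstate(divide="ignore", invalid="ignore"):
            e = rowt * colt / tab.sum()
            term = np.where(tab > 0, tab * np.log(tab / e), 0.0)
        return float(2.0 * np.nansum(term))

    g_obs = g_of(c1, c2)
    count = 0
    for _ in range(n_shuffles):
        count += g_of(c1, rng.permutation(c2)) >= g_obs - 1e-12
    return float(min((1 + count) / (n_shuffles + 1), 1.0))


def null_allele_estimate(t: GenotypeTable, samples, locus: int,
                         estimator: str = "brookfield1",
                         hwe_p: float | None = None) -> NullAlleleReport | None:
    """Null-allele frequency estimate at a heterozygote-deficient locus.

    * ``brookfield1``: r = (He - Ho) / (1 + He);
    * ``chakraborty``: r = (He - Ho) / (He + Ho);
    * ``oosterhout``: maximum-likelihood fit of a single null allele to the
      apparent genotype frequencies (numerical; see docs/methods.md).

    Returns None when Ho >= He (no deficit, estimators not applicable).
    """
    ix = np.asarray(samples, dtype=np.intp)
    lc = _locus_counts(t, ix, locus)
    if lc is None:
        raise ValueError("locus entirely missing")
    alleles, counts, het, n = lc
    he = unbiased_he(counts)
    ho = float(het.mean())
    if ho > he:
        return None
    name = t.locus_names[locus]
    if ho == he:  # boundary: no deficit, null frequency exactly zero
        return NullAlleleReport(name, estimator, 0.0, hwe_p)
    if estimator == "brookfield1":
        r = (he - ho) / (1.0 + he)
    elif estimator == "chakraborty":
        r = (he - ho) / (he + ho)
    elif estimator == "oosterhout":
        r = _ml_null_freq(counts, int(het.sum()), n)
    else:
        raise ValueError(f"unknown estimator '{estimator}'")
    return NullAlleleReport(name, estimator, float(np.clip(r, 0.0, 1.0)), hwe_p)


def _ml_null_freq(counts: np.ndarray, n_het: int, n: int) -> float:
    """ML estimate of a single null-allele frequency from apparent genotype
    data: with null frequency r and visible-allele diversity He_v, amplified
    individuals are heterozygous with probability (1-r) He_v / (1 + r(1-...))
    -- maximised numerically over r with He_v profiled from the counts."""
    p_vis = counts / counts.sum()
    he_v = 1.0 - (p_vis ** 2).sum()

    def negll(r: float) -> float:
        r = min(max(r, 1e-9), 0.999)
        # among amplified individuals (prob 1 - r^2):
        #   apparent het: (1-r)^2 He_v ; apparent hom: rest
        p_het = (1.0 - r) ** 2 * he_v / (1.0 - r ** 2)
        p_het = min(max(p_het, 1e-12), 1 - 1e-12)
        return -(n_het * np.log(p_het) + (n - n_het) * np.log(1.0 - p_het))

    res = optimize.minimize_scalar(negll, bounds=(1e-9, 0.999), method="bounded")
    return float(res.x)


def private_alleles(t: GenotypeTable, group_a, group_b) -> tuple[int, int]:
    """(alleles seen in a but not b, alleles seen in b but not a), summed over
    loci.  ``group_a``/``group_b``: sample index arrays."""
    a = np.asarray(group_a, dtype=np.intp)
    b = np.asarray(group_b, dtype=np.intp)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    only_a = only_b = 0
    for l in range(t.n_loci):
        ga = t.alleles[a, l, :].ravel()
        gb = t.alleles[b, l, :].ravel()
        sa = set(ga[ga != MISSING].tolist())
        sb = set(gb[gb != MISSING].tolist())
        only_a += len(sa - sb)
        only_b += len(sb - sa)
    return only_a, only_b
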