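"""Bottleneck detection by heterozygosity excess.

After a recent reduction in effective population size, allele number drops
faster than gene diversity, so the observed gene diversity He exceeds the
equilibrium diversity Heq expected for the observed allele count.  For each
locus, samples of the same size are simulated at mutation–drift equilibrium
(coalescent genealogy + mutations) conditional on the observed allele count,
giving the null Heq distribution; the standardised differences
DH = (He_obs - mean Heq)/sd Heq are combined across loci with a one-sided
Wilcoxon signed-rank test.

Mutation models: IAM (every mutation a novel allele; simulated by the Hoppe
urn, i.e. the Ewens sampling distribution), SMM (mutations step +-1 on the
repeat-score lattice) and TPM (single-step with probability
``tpm_single_step_prob``, otherwise a symmetric geometric multi-step with the
stated variance).  The mutation parameter theta is tuned by bisection so the
expected allele count matches the observed one, then samples are retained by
rejection on the exact allele count.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genotypes import MISSING, GenotypeTable
from .diversity import unbiased_he

__all__ = ["MutationModel", "LocusEquilibrium", "simulate_heq",
           "locus_excess", "wilcoxon_excess", "bottleneck_test"]


@dataclass(frozen=True)
class MutationModel:
    kind: str = "IAM"  # IAM | SMM | TPM
    tpm_single_step_prob: float = 0.95
    tpm_variance: float = 12.0  # variance of the multi-step geometric component

    def __post_init__(self) -> None:
        if self.kind not in ("IAM", "SMM", "TPM"):
            raise ValueError("kind must be IAM, SMM or TPM")
        if not 0.0 < self.tpm_single_step_prob <= 1.0:
            raise ValueError("tpm_single_step_prob must be in (0, 1]")


@dataclass
class LocusEquilibrium:
    locus: str
    k_obs: int
    n_genes: int
    He_obs: float
    Heq_mean: float
    Heq_sd: float
    DH: float
    p_excess: float  # null quantile of He_obs (fraction of Heq draws <= He_obs)


# ---------------------------------------------------------------------------
# Equilibrium samplers
# ---------------------------------------------------------------------------

def _iam_expected_k(theta: float, n: int) -> float:
    i = np.arange(n, dtype=float)
    return float((theta / (theta + i)).sum())


def _hoppe_urn(theta: float, n: int, rng: np.random.Generator) -> np.ndarray:
    """One Ewens-distributed allele-count configuration for n genes."""
    counts = [1]
    for i in range(1, n):
        if rng.random() < theta / (theta + i):
            counts.append(1)
        else:
            # join an existing allele with probability proportional to count
            j = rng.choice(len(counts), p=np.asarray(counts) / i)
            counts[j] += 1
    return np.asarray(counts, dtype=float)


def _coalescent_lattice(theta: float, n: int, model: MutationModel,
                        rng: np.random.Generator) -> np.ndarray:
    """Allele counts for one coalescent sample under a stepwise model.

    Simulates the n-coalescent genealogy, drops Poisson(theta/2 * length)
    mutations per branch, applies lattice steps, reads leaf states."""
    total = 2 * n - 1
    birth = np.zeros(total)  # node creation times (leaves at 0)
    parent = np.full(total, -1, dtype=np.int64)
    active = list(range(n))
    t = 0.0
    nxt = n
    while len(active) > 1:
        j = len(active)
        t += rng.exponential(2.0 / (j * (j - 1)))
        i1, i2 = rng.choice(j, 2, replace=False)
        a, b = active[i1], active[i2]
        birth[nxt] = t
        parent[a] = parent[b] = nxt
        for idx in sorted((i1, i2), reverse=True):
            active.pop(idx)
        active.append(nxt)
        nxt += 1
    # accumulate mutation offsets root -> leaves (nodes are created in
    # increasing time order, so iterate from the root downwards)
    state = np.zeros(total)
    if model.kind == "TPM":
        p_single = model.tpm_single_step_prob
        # symmetric geometric multi-step; match the requested variance:
        # for a geometric(+1-shifted? ) magnitude m >= 1 with P(m)= (1-q) q^(m-1),
        # Var(step) = E[m^2] = (1+q)/(1-q)^2  (mean-zero symmetric sign)
        v = max(model.tpm_variance, 1.0)
        # solve (1+q)/(1-q)^2 = v for q in [0,1)
        q = 1.0 + (1.0 - math.sqrt(1.0 + 8.0 * v)) / (2.0 * v)
    for node in range(total - 2, -1, -1):
        length = birth[parent[node]] - birth[node]
        n_mut = rng.poisson(theta / 2.0 * length)
        offset = 0.0
        if n_mut:
            if model.kind == "SMM":
                steps = rng.choice([-1, 1], n_mut)
            else:  # TPM
                mag = np.ones(n_mut)
                multi = rng.random(n_mut) >= p_single
                if multi.any():
                    mag[multi] = rng.geometric(1.0 - q, int(multi.sum()))
                steps = mag * rng.choice([-1, 1], n_mut)
            offset = steps.sum()
        state[node] = state[parent[node]] + offset
    leaf_states = np.round(state[:n]).astype(np.int64)
    _, counts = np.unique(leaf_states, return_counts=True)
    return counts.astype(float)


def _draw_config(theta: float, n: int, model: MutationModel,
                 rng: np.random.Generator) -> np.ndarray:
    if model.kind == "IAM":
        return _hoppe_urn(theta, n, rng)
    return _coalescent_lattice(theta, n, model, rng)


def _tune_theta(model: MutationModel, n: int, k_obs: int,
                rng: np.random.Generator, n_eval: int = 200) -> float:
    """Bisect theta so that E[number of alleles] ~ k_obs."""
    if model.kind == "IAM":
        lo, hi = 1e-4, 1e4
        for _ in range(80):
            mid = math.sqrt(lo * hi)
            if _iam_expected_k(mid, n) < k_obs:
                lo = mid
            else:
                hi = mid
        return math.sqrt(lo * hi)

    def mean_k(theta: float) -> float:
        return float(np.mean([
            len(_draw_config(theta, n, model, rng)) for _ in range(n_eval)]))

    lo, hi = 1e-3, 1e3
    for _ in range(18):
        mid = math.sqrt(lo * hi)
        if mean_k(mid) < k_obs:
            lo = mid
        else:
            hi = mid
    return math.sqrt(lo * hi)


def simulate_heq(model: MutationModel, n_genes: int, k_obs: int,
                 n_sim: int = 1000,
                 seed: int | np.random.Generator = 0,
                 max_batches: int = 400) -> tuple[float, float, np.ndarray]:
    """Null distribution of gene diversity conditional on the allele count.

    Simulates equilibrium samples of ``n_genes`` genes, keeps those with
    exactly ``k_obs`` alleles until ``n_sim`` are retained, and returns
    (mean, sd, retained He draws).  He is the unbiased gene diversity, the
    same statistic used on the data.
    """
    if not 2 <= k_obs <= n_genes:
        raise ValueError("need 2 <= k_obs <= n_genes")
    if n_sim < 1000:
        raise ValueError("n_sim must be >= 1000 for a stable null distribution")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    theta = _tune_theta(model, n_genes, k_obs, rng)
    kept: list[float] = []
    batch = max(n_sim // 2, 200)
    for _ in range(max_batches):
        for _ in range(batch):
            counts = _draw_config(theta, n_genes, model, rng)
            if len(counts) == k_obs:
                kept.append(unbiased_he(counts))
                if len(kept) == n_sim:
                    break
        if len(kept) == n_sim:
            break
    if len(kept) < n_sim:
        raise RuntimeError(
            f"could not reach {n_sim} equilibrium samples with k={k_obs} "
            f"(n={n_genes}, {model.kind}); got {len(kept)}")
    draws = np.asarray(kept)
    return float(draws.mean()), float(draws.std(ddof=1)), draws


_HEQ_CACHE: dict = {}


def _heq_cached(model: MutationModel, n_genes: int, k_obs: int,
                n_sim: int, seed: int) -> tuple[float, float, np.ndarray]:
    """Deterministic cached wrapper: the null distribution for a given
    (model, n, k, n_sim, seed) is computed once per process."""
    key = (model, n_genes, k_obs, n_sim, seed)
    if key not in _HEQ_CACHE:
        _HEQ_CACHE[key] = simulate_heq(
            model, n_genes, k_obs, n_sim,
            np.random.default_rng([seed, n_genes, k_obs]))
    return _HEQ_CACHE[key]


def locus_excess(t: GenotypeTable, samples, locus: int,
                 model: MutationModel, n_sim: int = 1000,
                 seed: int = 0, use_cache: bool = True) -> LocusEquilibrium:
    """He_obs vs the conditional equilibrium distribution at one locus."""
    ix = np.asarray(samples, dtype=np.intp)
    pairs = t.alleles[ix, locus, :]
    genes = pairs[pairs[:, 0] != MISSING].ravel()
    alleles, counts = np.unique(genes, return_counts=True)
    if alleles.size < 2:
        raise ValueError("monomorphic locus: excluded from the bottleneck test")
    he_obs = unbiased_he(counts.astype(float))
    n_genes, k_obs = int(genes.size), int(alleles.size)
    if use_cache:
        mean, sd, draws = _heq_cached(model, n_genes, k_obs, n_sim, seed)
    else:
        mean, sd, draws = simulate_heq(
            model, n_genes, k_obs, n_sim,
            np.random.default_rng([seed, n_genes, k_obs]))
    dh = (he_obs - mean) / sd if sd > 0 else 0.0
    p_exc = float((draws <= he_obs).mean())
    return LocusEquilibrium(t.locus_names[locus], k_obs, n_genes, he_obs,
                            mean, sd, float(dh), p_exc)


def wilcoxon_excess(locus_results) -> float:
    """One-sided Wilcoxon signed-rank p-value for heterozygosity excess
    across loci (exact null distribution for <= 25 informative loci)."""
    dh = np.asarray([r.DH if isinstance(r, LocusEquilibrium) else float(r)
                     for r in locus_results], dtype=float)
    dh = dh[dh != 0.0]
    if dh.size == 0:
        return 1.0
    if np.asarray(locus_results).size < 4:
        raise ValueError("need >= 4 informative loci")
    method = "exact" if dh.size <= 25 else "approx"
    res = stats.wilcoxon(dh, alternative="greater", method=method)
    return float(res.pvalue)


def bottleneck_test(t: GenotypeTable, samples,
                    models=("IAM", "TPM", "SMM"),
                    n_sim: int = 1000, seed: int = 0
                    ) -> tuple[pd.DataFrame, dict]:
    """Per-locus DH table and Wilcoxon excess p-value per mutation model."""
    out_rows = []
    pvals = {}
    for kind in models:
        model = kind if isinstance(kind, MutationModel) else MutationModel(kind)
        per_locus = []
        for l in range(t.n_loci):
            try:
                res = locus_excess(t, samples, l, model, n_sim=n_sim, seed=seed)
            except ValueError:
                continue
            per_locus.append(res)
            out_rows.append(dict(model=model.kind, locus=res.locus,
                                 k=res.k_obs, n_genes=res.n_genes,
                                 He_obs=res.He_obs, Heq_mean=res.Heq_mean,
                                 Heq_sd=res.Heq_sd, DH=res.DH,
                                 p_excess=res.p_excess))
        pvals[model.kind] = wilcoxon_excess(per_locus) if len(per_locus) >= 4 \
            else float("nan")
    return pd.DataFrame(out_rows), pvals
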