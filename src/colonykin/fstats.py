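"""Hierarchical Weir–Cockerham F-statistics for colony-structured samples.

The hierarchy is individual < colony < total sample.  Per locus and allele the
method-of-moments variance components are

* ``a`` — among colonies,
* ``b`` — among individuals within colonies,
* ``c`` — between the two gene copies within individuals,

with the unequal-sample-size corrections of the classical estimator.  Ratio-
of-sums estimators over all loci and alleles give

    F_CT = sum(a) / sum(a+b+c)        (colony vs total; "theta" at two levels)
    F_IT = sum(a+b) / sum(a+b+c)
    F_IC = sum(b) / sum(b+c)

and nestmate relatedness via Pamilo's identity r = 2*F_CT / (1 + F_IT).
Standard errors are delete-one jackknives over colonies (over loci when three
or fewer colonies are available).  Per-colony values — needed for one-sample
t-tests against breeding-system expectations — use an identity-probability
(gene-identity) estimator with the cross-colony baseline held fixed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .delineate import _pooled_onehots, multilocus_g_counts
from .genotypes import MISSING, GenotypeTable

__all__ = [
    "Components", "HierFStats", "ReferenceRow", "REFERENCE_ROWS",
    "variance_components", "hier_estimates", "jackknife_se",
    "per_colony_values", "compare_to_reference", "pairwise_fst",
]


@dataclass
class Components:
    """Per-locus variance components (arrays over alleles)."""

    locus_names: list[str]
    a: list[np.ndarray]
    b: list[np.ndarray]
    c: list[np.ndarray]

    def sums(self) -> tuple[float, float, float]:
        return (
            float(sum(x.sum() for x in self.a)),
            float(sum(x.sum() for x in self.b)),
            float(sum(x.sum() for x in self.c)),
        )

    def drop_locus(self, i: int) -> "Components":
        keep = [j for j in range(len(self.locus_names)) if j != i]
        return Components(
            [self.locus_names[j] for j in keep],
            [self.a[j] for j in keep],
            [self.b[j] for j in keep],
            [self.c[j] for j in keep],
        )


@dataclass
class HierFStats:
    F_IT: float
    F_CT: float
    F_IC: float
    r: float
    se_F_IT: float = float("nan")
    se_F_CT: float = float("nan")
    se_F_IC: float = float("nan")
    se_r: float = float("nan")
    jackknife_unit: str | None = None

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in
                ("F_IT", "F_CT", "F_IC", "r",
                 "se_F_IT", "se_F_CT", "se_F_IC", "se_r")}


def _resolve_labels(t: GenotypeTable, colonies) -> np.ndarray:
    if colonies is None:
        return t.groups
    if isinstance(colonies, dict):
        return np.array([colonies[s] for s in t.sample_ids], dtype=object)
    return np.asarray(colonies, dtype=object)


def variance_components(t: GenotypeTable, colonies=None) -> Components:
    """Weir–Cockerham (method-of-moments) components per locus and allele.

    ``colonies``: per-sample labels (defaults to ``t.groups``).  Per locus,
    colonies without genotyped individuals are dropped; a locus with fewer
    than two such colonies, or average sample size of one, contributes zero
    components (it carries no information at this hierarchy level).
    Monomorphic loci yield zero components and are retained.
    """
    labels = _resolve_labels(t, colonies)
    uniq = pd.unique(labels)
    a_out, b_out, c_out = [], [], []
    for l in range(t.n_loci):
        pairs = t.alleles[:, l, :]
        ok = pairs[:, 0] != MISSING
        # per-colony sample sizes, allele freqs, het freqs
        alleles = np.unique(pairs[ok])
        if alleles.size <= 1 or ok.sum() == 0:
            z = np.zeros(max(alleles.size, 1))
            a_out.append(z.copy()); b_out.append(z.copy()); c_out.append(z.copy())
            continue
        ni, pi, hi = [], [], []
        for g in uniq:
            ix = (labels == g) & ok
            n_i = int(ix.sum())
            if n_i == 0:
                continue
            gp = pairs[ix]
            ni.append(n_i)
            # p_i[k]: allele freq; h_i[k]: freq of heterozygotes carrying k
            het = gp[:, 0] != gp[:, 1]
            pi.append([(gp == al).sum() / (2 * n_i) for al in alleles])
            hi.append([((gp == al).any(axis=1) & het).sum() / n_i for al in alleles])
        ni = np.asarray(ni, dtype=float)
        r = len(ni)
        if r < 2 or ni.mean() <= 1:
            z = np.zeros(alleles.size)
            a_out.append(z.copy()); b_out.append(z.copy()); c_out.append(z.copy())
            continue
        pi = np.asarray(pi)  # (r, K)
        hi = np.asarray(hi)
        nbar = ni.mean()
        nsum = ni.sum()
        nc = (nsum - (ni ** 2).sum() / nsum) / (r - 1)
        pbar = (ni[:, None] * pi).sum(axis=0) / nsum
        s2 = (ni[:, None] * (pi - pbar) ** 2).sum(axis=0) / ((r - 1) * nbar)
        hbar = (ni[:, None] * hi).sum(axis=0) / nsum
        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
        )
        c = hbar / 2
        a_out.append(a); b_out.append(b); c_out.append(c)
    return Components(list(t.locus_names), a_out, b_out, c_out)


def hier_estimates(components: Components) -> HierFStats:
    """Ratio-of-sums F-statistics from shared variance components.

    By construction the algebraic identities (1-F_IT) = (1-F_CT)(1-F_IC) and
    r = 2 F_CT / (1+F_IT) hold exactly.
    """
    sa, sb, sc = components.sums()
    tot = sa + sb + sc
    if tot == 0:
        raise ValueError("all loci monomorphic: F-statistics undefined")
    f_ct = sa / tot
    f_it = (sa + sb) / tot
    f_ic = sb / (sb + sc) if (sb + sc) != 0 else float("nan")
    # r undefined in the degenerate F_IT -> -1 limit (every gene copy pair
    # within individuals maximally dissimilar)
    r = 2 * f_ct / (1 + f_it) if (1 + f_it) != 0 else float("nan")
    return HierFStats(F_IT=f_it, F_CT=f_ct, F_IC=f_ic, r=r)


def _jack_se(values: np.ndarray) -> np.ndarray:
    n = values.shape[0]
    mean = values.mean(axis=0)
    return np.sqrt((n - 1) / n * ((values - mean) ** 2).sum(axis=0))


def jackknife_se(t: GenotypeTable, colonies=None, unit: str = "auto") -> HierFStats:
    """Point estimates plus delete-one jackknife SEs.

    ``unit``: 'colonies', 'loci' or 'auto' (colonies, switching to loci when
    three or fewer colonies are available).
    """
    labels = _resolve_labels(t, colonies)
    uniq = list(pd.unique(labels))
    if unit == "auto":
        unit = "colonies" if len(uniq) > 3 else "loci"
    full = hier_estimates(variance_components(t, labels))
    if unit == "colonies":
        if len(uniq) < 2:
            raise ValueError("jackknife over colonies needs >= 2 colonies")
        reps = []
        for g in uniq:
            keep = np.flatnonzero(labels != g)
            est = hier_estimates(
                variance_components(t.subset(keep), labels[keep]))
            reps.append([est.F_IT, est.F_CT, est.F_IC, est.r])
    elif unit == "loci":
        comp = variance_components(t, labels)
        if len(comp.locus_names) < 2:
            raise ValueError("jackknife over loci needs >= 2 loci")
        reps = []
        for i in range(len(comp.locus_names)):
            est = hier_estimates(comp.drop_locus(i))
            reps.append([est.F_IT, est.F_CT, est.F_IC, est.r])
    else:
        raise ValueError("unit must be 'colonies', 'loci' or 'auto'")
    se = _jack_se(np.asarray(reps))
    return HierFStats(full.F_IT, full.F_CT, full.F_IC, full.r,
                      *map(float, se), jackknife_unit=unit)


# ---------------------------------------------------------------------------
# Per-colony values (replicates for one-sample t-tests)
# ---------------------------------------------------------------------------

def per_colony_values(
    t: GenotypeTable, colonies=None, mode: str = "colony_vs_total"
) -> pd.DataFrame:
    """Per-colony F_IT, F_CT, F_IC and r with the cross-colony baseline fixed.

    Gene-identity estimator: per locus, Q1 = identity of the two gene copies
    within an individual, Q2 = identity of genes in different individuals of
    the colony, Q3 = identity of genes in different colonies (over the whole
    sample in ``colony_vs_total`` mode, or excluding the focal colony in
    ``colony_vs_rest``).  F-statistics are ratio-of-sums over loci of
    (Q - Q3)/(1 - Q3) terms; r = 2 F_CT/(1 + F_IT).  Colonies with fewer than
    two genotyped workers at every locus are excluded with a warning.
    """
    if mode not in ("colony_vs_total", "colony_vs_rest"):
        raise ValueError("mode must be 'colony_vs_total' or 'colony_vs_rest'")
    labels = _resolve_labels(t, colonies)
    uniq = list(pd.unique(labels))
    # per locus: per-colony allele count vectors
    locus_data = []
    for l in range(t.n_loci):
        pairs = t.alleles[:, l, :]
        ok = pairs[:, 0] != MISSING
        alleles = np.unique(pairs[ok]) if ok.any() else np.array([])
        per_colony = {}
        for g in uniq:
            ix = (labels == g) & ok
            gp = pairs[ix]
            counts = np.array([(gp == al).sum() for al in alleles], dtype=float)
            n_hom = int(((gp[:, 0] == gp[:, 1])).sum()) if len(gp) else 0
            per_colony[g] = (len(gp), counts, n_hom)
        locus_data.append(per_colony)

    rows = []
    for g in uniq:
        num_it = den_it = num_ct = num_ic = den_ic = 0.0
        n_loci_used = 0
        for per_colony in locus_data:
            n_i, counts, n_hom = per_colony[g]
            if n_i < 2 or counts.size == 0:
                continue
            # Q3: identity of two genes drawn from DIFFERENT colonies of the
            # baseline set (whole sample, or all other colonies).
            base = [c_j for k, (n_j, c_j, _) in per_colony.items()
                    if c_j.size and (mode == "colony_vs_total" or k != g)]
            if len(base) < 2:
                continue
            cmat = np.stack(base)  # (J, K)
            m = cmat.sum(axis=1)  # gene counts per colony
            cross_tot = (m.sum() ** 2 - (m ** 2).sum()) / 2
            if cross_tot <= 0:
                continue
            cross_same = ((cmat.sum(axis=0) ** 2).sum()
                          - (cmat ** 2).sum()) / 2
            q3 = cross_same / cross_tot
            # Q1: identity within individuals; Q2: within colony, across
            # individuals (same-allele pairs excluding within-individual ones)
            q1 = n_hom / n_i
            same_within = (counts * (counts - 1)).sum() / 2 - n_hom
            q2 = same_within / (2 * n_i * (n_i - 1))
            num_it += q1 - q3
            num_ct += q2 - q3
            den_it += 1 - q3
            num_ic += q1 - q2
            den_ic += 1 - q2
            n_loci_used += 1
        if n_loci_used == 0 or den_it == 0:
            warnings.warn(f"colony {g} has too few genotyped workers; excluded")
            continue
        f_it = num_it / den_it
        f_ct = num_ct / den_it
        f_ic = num_ic / den_ic if den_ic else float("nan")
        rows.append(dict(colony=g, n_loci=n_loci_used, F_IT=f_it, F_CT=f_ct,
                         F_IC=f_ic, r=2 * f_ct / (1 + f_it)))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Reference rows and one-sample t-tests
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ReferenceRow:
    case: str
    F_IT: float
    F_CT: float
    F_IC: float
    r: float


#: Expected F-statistics for classical termite breeding systems (from the
#: simulation literature on subterranean-termite colony genetics).  Case b1's
#: printed values are internally inconsistent with the ratio identities and
#: are kept verbatim; see docs/methods.md.
REFERENCE_ROWS: dict[str, ReferenceRow] = {
    "a1": ReferenceRow("a1", 0.00, 0.25, -0.33, 0.50),
    "a2": ReferenceRow("a2", 0.33, 0.42, -0.14, 0.62),
    "b1": ReferenceRow("b1", 0.26, 0.65, -0.14, 0.55),
    "b2": ReferenceRow("b2", 0.52, 0.59, -0.17, 0.78),
    "b3": ReferenceRow("b3", 0.33, 0.34, -0.01, 0.51),
    "b4": ReferenceRow("b4", 0.33, 0.34, 0.00, 0.50),
    "c": ReferenceRow("c", 0.57, 0.43, 0.25, 0.55),
    "d": ReferenceRow("d", 0.66, 0.64, 0.04, 0.77),
    "e1": ReferenceRow("e1", 0.00, 0.19, -0.23, 0.38),
    "e2": ReferenceRow("e2", 0.27, 0.29, -0.03, 0.45),
    "e3": ReferenceRow("e3", 0.10, 0.12, -0.02, 0.22),
}


def compare_to_reference(values, row: ReferenceRow | float,
                         parameters=("F_IT", "F_IC", "r")) -> pd.DataFrame:
    """One-sample t-tests of per-colony values against reference expectations.

    ``values``: DataFrame from :func:`per_colony_values` (or, with a scalar
    ``row``, a plain sequence tested against that value).  Two-sided p; when
    the per-colony values have zero variance the test degenerates — p = 1 on
    exact match, p = 0 flagged otherwise.
    """
    def one(v: np.ndarray, expected: float, name: str) -> dict:
        v = np.asarray(v, dtype=float)
        v = v[~np.isnan(v)]
        if v.size < 2:
            raise ValueError("need >= 2 colonies for a t-test")
        if np.allclose(v.std(ddof=1), 0):
            equal = np.allclose(v.mean(), expected)
            return dict(parameter=name, mean=float(v.mean()), expected=expected,
                        t=0.0 if equal else float("inf"),
                        p=1.0 if equal else 0.0, n=int(v.size),
                        zero_variance=True)
        t_stat, p = stats.ttest_1samp(v, expected)
        return dict(parameter=name, mean=float(v.mean()), expected=expected,
                    t=float(t_stat), p=float(p), n=int(v.size),
                    zero_variance=False)

    if isinstance(row, ReferenceRow):
        return pd.DataFrame(
            [one(values[p].to_numpy(), getattr(row, p), p) for p in parameters])
    return pd.DataFrame([one(np.asarray(values), float(row), "value")])


# ---------------------------------------------------------------------------
# Pairwise F_ST between groups (populations) + global differentiation test
# ---------------------------------------------------------------------------

def pairwise_fst(
    t: GenotypeTable, groups=None, n_perm: int = 6000,
    seed: int | np.random.Generator = 0,
) -> tuple[pd.DataFrame, float]:
    """Pairwise two-level Weir–Cockerham theta between groups, plus a global
    permutation test (multilocus G over genotype classes, group labels
    permuted among individuals).

    Groups of size < 2 are excluded with a warning.  Returns (theta matrix as
    a symmetric DataFrame, global p-value).
    """
    labels = _resolve_labels(t, groups)
    gix = {g: np.flatnonzero(labels == g) for g in pd.unique(labels)}
    small = [g for g, ix in gix.items() if len(ix) < 2]
    for g in small:
        warnings.warn(f"group {g} has <2 individuals; excluded from F_ST")
        del gix[g]
    names = list(gix)
    if len(names) < 2:
        raise ValueError("need >= 2 groups of size >= 2")
    mat = pd.DataFrame(0.0, index=names, columns=names)
    for u, v in combinations(names, 2):
        ix = np.concatenate([gix[u], gix[v]])
        sub = t.subset(ix)
        est = variance_components(sub, labels[ix])
        sa, sb, sc = est.sums()
        theta = sa / (sa + sb + sc) if (sa + sb + sc) else float("nan")
        mat.loc[u, v] = mat.loc[v, u] = theta

    # global test: permute group labels of individuals
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    keep = np.concatenate([gix[g] for g in names])
    onehots = _pooled_onehots(t, keep)
    memb = np.concatenate([np.full(len(gix[g]), i) for i, g in enumerate(names)])
    g_obs = _multigroup_g(onehots, memb, len(names))
    count = 0
    for _ in range(n_perm):
        count += _multigroup_g(onehots, rng.permutation(memb), len(names)) \
            >= g_obs - 1e-12
    p = (1 + count) / (n_perm + 1)
    return mat, float(p)


def _multigroup_g(onehots: list[np.ndarray], memb: np.ndarray,
                  n_groups: int) -> float:
    """Multilocus G for an R x K genotype-class contingency table."""
    g = 0.0
    for oh in onehots:
        counts = np.zeros((n_groups, oh.shape[1]))
        np.add.at(counts, memb, oh)
        rowtot = counts.sum(axis=1, keepdims=True)
        coltot = counts.sum(axis=0, keepdims=True)
        n = counts.sum()
        if n == 0:
            continue
        with np.errstate(divide="ignore", invalid="ignore"):
            e = rowtot * coltot / n
            term = np.where(counts > 0, counts * np.log(counts / e), 0.0)
        g += 2.0 * np.nansum(term)
    return float(g)
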