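"""Simple / extended / mixed family classification of colonies.

A colony of workers is classified from its genotype array by the classical
rule set for subterranean termites:

* **mixed** — more than four alleles at one or more loci (impossible for the
  offspring of any two diploid parents);
* **extended** — not mixed, but some locus shows more than four genotypic
  classes, or no monogamous parent pair is compatible with the observed
  genotypes, or the genotype frequencies deviate from Mendelian expectations
  (G-test summed over loci, P < alpha);
* **simple** — otherwise: consistent with offspring of one monogamous pair.

Parent-pair ambiguity at a locus is resolved in favour of the pair minimising
G, which makes "extended" calls conservative.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations_with_replacement

import numpy as np
import pandas as pd
from scipy import stats

from .genotypes import MISSING, GenotypeTable

__all__ = ["LocusDiagnosis", "FamilyCall", "enumerate_parent_pairs",
           "mendelian_gtest", "classify_family", "family_census",
           "classify_table"]


@dataclass
class LocusDiagnosis:
    locus: str
    n_alleles: int
    n_genotypes: int
    n_workers: int
    pair_compatible: bool
    best_parent_pair: tuple | None
    G_contribution: float
    df: int
    used_in_gtest: bool


@dataclass
class FamilyCall:
    colony_id: str
    family_type: str  # simple | extended | mixed
    G_total: float
    df_total: int
    p_value: float
    diagnoses: list = field(default_factory=list)
    low_confidence: bool = False
    reasons: list = field(default_factory=list)


def _offspring_classes(pair) -> dict[tuple, float]:
    """Mendelian offspring genotype classes and probabilities for a parent
    pair ((a,b), (c,d)): each parent transmits either allele with prob 1/2."""
    (a, b), (c, d) = pair
    out: dict[tuple, float] = {}
    for x in (a, b):
        for y in (c, d):
            g = (x, y) if x <= y else (y, x)
            out[g] = out.get(g, 0.0) + 0.25
    return out


def enumerate_parent_pairs(genotypes) -> list[tuple]:
    """All unordered diploid parent pairs over the observed alleles whose
    Mendelian offspring set contains every observed genotype.

    ``genotypes``: iterable of (a1, a2) tuples (non-missing).  Empty list when
    no pair is compatible (e.g. more than four alleles: pigeonhole).
    """
    obs = {tuple(sorted(g)) for g in genotypes}
    if not obs:
        raise ValueError("need at least one non-missing genotype")
    alleles = sorted({a for g in obs for a in g})
    if len(alleles) > 4:
        return []
    possible_parents = list(combinations_with_replacement(alleles, 2))
    out = []
    for p1, p2 in combinations_with_replacement(possible_parents, 2):
        if obs <= set(_offspring_classes((p1, p2))):
            out.append((p1, p2))
    return out


def mendelian_gtest(genotypes, parent_pair) -> tuple[float, int]:
    """G-test of observed genotype counts against Mendelian expectations for
    ``parent_pair``.  Returns (G, df) with df = #offspring classes - 1; an
    observed genotype outside the pair's offspring set raises (use
    :func:`enumerate_parent_pairs` first)."""
    classes = _offspring_classes(parent_pair)
    obs_list = [tuple(sorted(g)) for g in genotypes]
    n = len(obs_list)
    counts = {g: 0 for g in classes}
    for g in obs_list:
        if g not in counts:
            raise ValueError(f"genotype {g} incompatible with pair {parent_pair}")
        counts[g] += 1
    g_stat = 0.0
    for cls, prob in classes.items():
        o = counts[cls]
        e = n * prob
        if o > 0:
            g_stat += 2.0 * o * np.log(o / e)
    return float(g_stat), len(classes) - 1


def classify_family(
    genotypes: np.ndarray,
    alpha: float = 0.05,
    colony_id: str = "colony",
    locus_names=None,
    min_workers: int = 10,
    min_per_locus: int = 5,
    gtest_mode: str = "summed",
) -> FamilyCall:
    """Classify one colony from its (n_workers, n_loci, 2) genotype array.

    Missing genotypes are excluded per locus; loci with fewer than
    ``min_per_locus`` genotyped workers contribute no G (small-count G is
    unstable).  ``gtest_mode``: 'summed' pools G and df across loci into one
    test per colony; 'per_locus' flags the colony extended if any single
    locus rejects at ``alpha``.
    """
    genotypes = np.asarray(genotypes)
    n_workers, n_loci, _ = genotypes.shape
    names = locus_names or [f"L{l + 1}" for l in range(n_loci)]
    diagnoses = []
    reasons = []
    mixed = False
    extended = False
    g_total, df_total = 0.0, 0
    per_locus_reject = False
    for l in range(n_loci):
        pairs = genotypes[:, l, :]
        ok = (pairs != MISSING).all(axis=1)
        gl = [tuple(sorted(p)) for p in pairs[ok]]
        if not gl:
            diagnoses.append(LocusDiagnosis(names[l], 0, 0, 0, False, None,
                                            0.0, 0, False))
            continue
        alleles = {a for g in gl for a in g}
        classes = set(gl)
        if len(alleles) > 4:
            mixed = True
            reasons.append(f"{names[l]}: {len(alleles)} alleles (>4)")
            diagnoses.append(LocusDiagnosis(names[l], len(alleles), len(classes),
                                            len(gl), False, None, 0.0, 0, False))
            continue
        candidates = enumerate_parent_pairs(gl)
        if len(classes) > 4 or not candidates:
            extended = True
            why = ">4 genotypic classes" if len(classes) > 4 \
                else "no compatible monogamous pair"
            reasons.append(f"{names[l]}: {why}")
            diagnoses.append(LocusDiagnosis(names[l], len(alleles), len(classes),
                                            len(gl), False, None, 0.0, 0, False))
            continue
        best = min(candidates, key=lambda pr: mendelian_gtest(gl, pr)[0])
        g_stat, df = mendelian_gtest(gl, best)
        use = len(gl) >= min_per_locus and df > 0
        if use:
            g_total += g_stat
            df_total += df
            if gtest_mode == "per_locus" and \
                    stats.chi2.sf(g_stat, df) < alpha:
                per_locus_reject = True
                reasons.append(f"{names[l]}: Mendelian G-test rejected")
        diagnoses.append(LocusDiagnosis(names[l], len(alleles), len(classes),
                                        len(gl), True, best, g_stat, df, use))

    p = float(stats.chi2.sf(g_total, df_total)) if df_total > 0 else 1.0
    if mixed:
        family = "mixed"
    elif extended or (gtest_mode == "summed" and p < alpha) or \
            (gtest_mode == "per_locus" and per_locus_reject):
        family = "extended"
        if not extended and not per_locus_reject:
            reasons.append(f"summed Mendelian G-test: p={p:.4g} < {alpha}")
    else:
        family = "simple"
    return FamilyCall(colony_id, family, g_total, df_total, p, diagnoses,
                      low_confidence=n_workers < min_workers, reasons=reasons)


def classify_table(t: GenotypeTable, colonies=None, alpha: float = 0.05,
                   **kwargs) -> list[FamilyCall]:
    """Classify every colony of a genotype table (labels from ``colonies`` or
    ``t.groups``)."""
    labels = t.groups if colonies is None else np.array(
        [colonies[s] for s in t.sample_ids], dtype=object)
    calls = []
    for g in pd.unique(labels):
        ix = np.flatnonzero(labels == g)
        calls.append(classify_family(t.alleles[ix], alpha=alpha,
                                     colony_id=str(g),
                                     locus_names=t.locus_names, **kwargs))
    return calls


def family_census(calls, by=None) -> pd.DataFrame:
    """Counts and percentages of simple/extended/mixed calls.

    ``by``: optional map colony_id -> population label; a pooled row is always
    included."""
    rows = []
    groups: dict[str, list] = {"all": list(calls)}
    if by is not None:
        for c in calls:
            groups.setdefault(by[c.colony_id], []).append(c)
    for name, cs in groups.items():
        n = len(cs)
        if n == 0:
            continue
        row = {"population": name, "n_colonies": n}
        for ft in ("simple", "extended", "mixed"):
            k = sum(1 for c in cs if c.family_type == ft)
            row[f"n_{ft}"] = k
            row[f"pct_{ft}"] = round(100.0 * k / n, 2)
        rows.append(row)
    return pd.DataFrame(rows)
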