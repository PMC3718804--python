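"""Isolation by distance: colony-pair F_ST versus geographic distance.

Pairwise Weir–Cockerham theta between colonies (all workers of the two
colonies) is linearised as F_ST/(1-F_ST) and regressed on the natural log of
great-circle distance (metres) between colony centroids; the matrix
correlation is tested with a one-sided Mantel permutation test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations, permutations

import numpy as np
import pandas as pd

from .fstats import _resolve_labels, variance_components
from .genotypes import GenotypeTable

EARTH_RADIUS_M = 6_371_000.0

__all__ = ["MantelResult", "haversine_m", "colony_pair_fst", "mantel",
           "ibd_analysis"]


@dataclass
class MantelResult:
    r: float
    p: float
    n_permutations: int


def haversine_m(lat1: float, lon1: float, lat2: float, lon2: float) -> float:
    """Great-circle distance in metres between WGS84 decimal-degree points."""
    phi1, phi2 = np.radians(lat1), np.radians(lat2)
    dphi = phi2 - phi1
    dlam = np.radians(lon2 - lon1)
    a = np.sin(dphi / 2) ** 2 + np.cos(phi1) * np.cos(phi2) * np.sin(dlam / 2) ** 2
    return float(2 * EARTH_RADIUS_M * np.arcsin(np.sqrt(a)))


def colony_pair_fst(t: GenotypeTable, colonies=None) -> pd.DataFrame:
    """Symmetric matrix of pairwise two-level Weir–Cockerham theta between
    colonies, using all workers of each pair.  Negative estimates are kept
    as-is (they are legitimate method-of-moments outcomes)."""
    labels = _resolve_labels(t, colonies)
    gix = {g: np.flatnonzero(labels == g) for g in pd.unique(labels)}
    usable = {g: ix for g, ix in gix.items() if len(ix) >= 2}
    dropped = set(gix) - set(usable)
    if dropped:
        warnings.warn(f"colonies with <2 workers dropped: {sorted(map(str, dropped))}")
    names = list(usable)
    mat = pd.DataFrame(0.0, index=names, columns=names)
    for u, v in combinations(names, 2):
        ix = np.concatenate([usable[u], usable[v]])
        comp = variance_components(t.subset(ix), labels[ix])
        sa, sb, sc = comp.sums()
        theta = sa / (sa + sb + sc) if (sa + sb + sc) else float("nan")
        mat.loc[u, v] = mat.loc[v, u] = theta
    return mat


def _upper(m: np.ndarray) -> np.ndarray:
    iu = np.triu_indices_from(m, k=1)
    return m[iu]


def mantel(m1, m2, n_perm: int = 10_000,
           seed: int | np.random.Generator = 0) -> MantelResult:
    """Mantel matrix correlation with a one-sided permutation test.

    r is the Pearson correlation over the off-diagonal upper triangle; the
    permutation simultaneously reorders rows and columns of ``m2``; p is
    one-sided for positive association.
    """
    a = np.asarray(m1, dtype=float)
    b = np.asarray(m2, dtype=float)
    if a.shape != b.shape or a.shape[0] != a.shape[1]:
        raise ValueError("matrices must be square and of equal size")
    n = a.shape[0]
    if n < 4:
        raise ValueError("need >= 4 objects")
    if not (np.allclose(a, a.T, equal_nan=True) and np.allclose(b, b.T, equal_nan=True)):
        raise ValueError("matrices must be symmetric")
    x = _upper(a)
    if x.std() == 0 or _upper(b).std() == 0:
        raise ValueError("zero variance in a distance matrix")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    def corr(perm: np.ndarray) -> float:
        y = _upper(b[np.ix_(perm, perm)])
        return float(np.corrcoef(x, y)[0, 1])

    r_obs = corr(np.arange(n))
    count = 0
    for _ in range(n_perm):
        count += corr(rng.permutation(n)) >= r_obs - 1e-12
    p = (1 + count) / (n_perm + 1)
    return MantelResult(r=r_obs, p=float(min(p, 1.0)), n_permutations=n_perm)


def mantel_exact(m1, m2) -> MantelResult:
    """Exhaustive-relabeling Mantel p (reference for small n)."""
    a = np.asarray(m1, dtype=float)
    b = np.asarray(m2, dtype=float)
    n = a.shape[0]
    x = _upper(a)

    def corr(perm) -> float:
        perm = np.asarray(perm)
        return float(np.corrcoef(x, _upper(b[np.ix_(perm, perm)]))[0, 1])

    r_obs = corr(range(n))
    vals = [corr(p) for p in permutations(range(n))]
    p = sum(v >= r_obs - 1e-12 for v in vals) / len(vals)
    return MantelResult(r=r_obs, p=float(p), n_permutations=len(vals))


def colony_centroids(t: GenotypeTable, colonies=None) -> dict:
    """Colony coordinate = centroid of its member samples' coordinates."""
    if t.coords is None:
        raise ValueError("genotype table carries no coordinates")
    labels = _resolve_labels(t, colonies)
    out = {}
    for g in pd.unique(labels):
        ix = np.flatnonzero(labels == g)
        pts = [t.coords[t.sample_ids[i]] for i in ix
               if t.sample_ids[i] in t.coords]
        if pts:
            arr = np.asarray(pts)
            out[g] = (float(arr[:, 0].mean()), float(arr[:, 1].mean()))
    return out


def ibd_analysis(t: GenotypeTable, colonies=None, coords=None,
                 n_perm: int = 10_000,
                 seed: int | np.random.Generator = 0
                 ) -> tuple[MantelResult, pd.DataFrame]:
    """Mantel test of linearised colony-pair F_ST against ln distance (m).

    ``coords``: optional map colony -> (lat, lon); defaults to centroids of
    member sample coordinates.  Colonies at coincident coordinates with some
    partner are excluded pairwise (ln 0 undefined) by removing the offending
    colony with a warning.
    """
    fst = colony_pair_fst(t, colonies)
    cents = coords or colony_centroids(t, colonies)
    names = [c for c in fst.index if c in cents]
    if len(names) < 4:
        raise ValueError("need >= 4 colonies with coordinates")
    # drop colonies involved in zero-distance pairs
    keep = list(names)
    changed = True
    while changed:
        changed = False
        for u, v in combinations(keep, 2):
            if haversine_m(*cents[u], *cents[v]) <= 0:
                warnings.warn(f"colonies {u}/{v} share coordinates; {v} dropped")
                keep.remove(v)
                changed = True
                break
    names = keep
    n = len(names)
    lin = np.zeros((n, n))
    lng = np.zeros((n, n))
    rows = []
    for i, j in combinations(range(n), 2):
        f = float(fst.loc[names[i], names[j]])
        if f >= 1 - 1e-9:
            warnings.warn(f"F_ST at ceiling for {names[i]}/{names[j]}; capped")
            f = 1 - 1e-9
        linear = f / (1 - f)
        d = haversine_m(*cents[names[i]], *cents[names[j]])
        lin[i, j] = lin[j, i] = linear
        lng[i, j] = lng[j, i] = np.log(d)
        rows.append(dict(colony_a=str(names[i]), colony_b=str(names[j]),
                         fst=f, linearized=linear, geo_m=d, ln_geo=np.log(d)))
    res = mantel(lng, lin, n_perm=n_perm, seed=seed)
    return res, pd.DataFrame(rows)
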