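"""Independent scalar evaluation of the Weir–Cockerham variance components.

Deliberately written as plain per-allele arithmetic (no vectorisation, no
shared code with the package) so it can serve as an oracle for toy tables.
"""

from __future__ import annotations


def wc_components_single_locus(colonies: list[list[tuple[int, int]]]):
    """``colonies``: genotype pair lists, one list per colony; no missing data.

    Returns dict allele -> (a, b, c).
    """
    r = len(colonies)
    ns = [len(c) for c in colonies]
    nbar = sum(ns) / r
    nsum = sum(ns)
    nc = (nsum - sum(n * n for n in ns) / nsum) / (r - 1)
    alleles = sorted({a for col in colonies for g in col for a in g})
    out = {}
    for al in alleles:
        ps, hs = [], []
        for col in colonies:
            n = len(col)
            copies = sum((g[0] == al) + (g[1] == al) for g in col)
            hets = sum(1 for g in col if g[0] != g[1] and al in g)
            ps.append(copies / (2 * n))
            hs.append(hets / n)
        pbar = sum(n * p for n, p in zip(ns, ps)) / nsum
        s2 = sum(n * (p - pbar) ** 2 for n, p in zip(ns, ps)) / ((r - 1) * nbar)
        hbar = sum(n * h for n, h in zip(ns, hs)) / nsum
        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1))
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - (r - 1) / r * s2
            - (2 * nbar - 1) / (4 * nbar) * hbar)
        c = hbar / 2
        out[al] = (a, b, c)
    return out
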