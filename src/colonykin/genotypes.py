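"""Diploid microsatellite genotype tables and the file formats that carry them.

Alleles are opaque positive-integer labels (fragment sizes or bin codes — the
statistics downstream never do arithmetic on them, except the stepwise mutation
models which treat labels as repeat scores).  The missing sentinel is 0: a
genotype with either allele missing is treated as wholly missing, because every
downstream statistic assumes complete diploid genotypes.
"""

from __future__ import annotations

import io
import re
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

MISSING = 0

__all__ = [
    "MISSING",
    "GenotypeTable",
    "AlleleFrequencyTable",
    "read_genepop",
    "write_genepop",
    "read_table",
    "read_coords",
    "allele_frequencies",
]


def _canonicalize(alleles: np.ndarray) -> np.ndarray:
    """Sort each allele pair and blank half-missing genotypes.

    Canonical storage (a1 <= a2, half-missing -> fully missing) makes
    heterozygote counts independent of the order alleles appear in the input.
    """
    a = np.asarray(alleles, dtype=np.int32).copy()
    if a.ndim != 3 or a.shape[2] != 2:
        raise ValueError("allele array must have shape (n_samples, n_loci, 2)")
    if (a < 0).any():
        raise ValueError("allele labels must be positive (0 = missing)")
    half_missing = (a == MISSING).any(axis=2)
    a.sort(axis=2)
    a[half_missing] = MISSING
    return a


@dataclass
class GenotypeTable:
    """Samples x loci matrix of diploid genotypes with group labels.

    ``groups`` is a single-level label per sample (collection site, colony or
    population depending on the analysis stage); the colony-within-population
    hierarchy is expressed by handing two different labelings to the
    F-statistics module rather than by nesting here, so one table can flow
    through every stage.
    """

    alleles: np.ndarray  # (n_samples, n_loci, 2) int32, 0 = missing
    sample_ids: list[str]
    locus_names: list[str]
    groups: np.ndarray  # (n_samples,) object
    coords: dict[str, tuple[float, float]] | None = None

    def __post_init__(self) -> None:
        self.alleles = _canonicalize(self.alleles)
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.locus_names = [str(l) for l in self.locus_names]
        self.groups = np.asarray(self.groups, dtype=object)
        n, l, _ = self.alleles.shape
        if len(self.sample_ids) != n:
            raise ValueError("sample_ids length does not match allele matrix")
        if len(self.locus_names) != l:
            raise ValueError("locus_names length does not match allele matrix")
        if len(self.groups) != n:
            raise ValueError("every sample needs a group label")
        if len(set(self.sample_ids)) != n:
            raise ValueError("duplicate sample ids")
        if len(set(self.locus_names)) != l:
            raise ValueError("duplicate locus names")

    # -- basic views ---------------------------------------------------

    @property
    def n_samples(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_loci(self) -> int:
        return self.alleles.shape[1]

    @property
    def missing(self) -> np.ndarray:
        """Boolean (n_samples, n_loci): genotype wholly missing."""
        return self.alleles[:, :, 0] == MISSING

    @property
    def heterozygous(self) -> np.ndarray:
        """Boolean (n_samples, n_loci): non-missing and a1 != a2."""
        return (~self.missing) & (self.alleles[:, :, 0] != self.alleles[:, :, 1])

    def group_indices(self) -> dict:
        """Map group label -> sample index array, in first-seen order."""
        out: dict = {}
        for i, g in enumerate(self.groups):
            out.setdefault(g, []).append(i)
        return {g: np.asarray(ix, dtype=np.intp) for g, ix in out.items()}

    def subset(self, sample_idx: Sequence[int]) -> "GenotypeTable":
        ix = np.asarray(sample_idx, dtype=np.intp)
        ids = [self.sample_ids[i] for i in ix]
        coords = None
        if self.coords is not None:
            coords = {s: self.coords[s] for s in ids if s in self.coords}
        return GenotypeTable(
            self.alleles[ix], ids, list(self.locus_names), self.groups[ix], coords
        )

    def with_groups(self, labels: Mapping[str, object] | np.ndarray) -> "GenotypeTable":
        """Return a copy relabeled by sample (e.g. site labels -> colony ids)."""
        if isinstance(labels, Mapping):
            g = np.array([labels[s] for s in self.sample_ids], dtype=object)
        else:
            g = np.asarray(labels, dtype=object)
        return GenotypeTable(self.alleles, list(self.sample_ids),
                             list(self.locus_names), g, self.coords)

    def genotype_codes(self, locus: int) -> tuple[np.ndarray, int]:
        """Encode each sample's genotype at ``locus`` as a small integer.

        Returns (codes, n_classes); missing genotypes get code -1.  Codes are
        assigned by sorted (a1, a2) pair so they are input-order invariant.
        """
        pairs = self.alleles[:, locus, :]
        ok = pairs[:, 0] != MISSING
        codes = np.full(self.n_samples, -1, dtype=np.int64)
        if ok.any():
            uniq, inv = np.unique(pairs[ok], axis=0, return_inverse=True)
            codes[ok] = inv
            return codes, len(uniq)
        return codes, 0

    def __eq__(self, other: object) -> bool:  # full structural equality
        if not isinstance(other, GenotypeTable):
            return NotImplemented
        return (
            self.sample_ids == other.sample_ids
            and self.locus_names == other.locus_names
            and np.array_equal(self.alleles, other.alleles)
            and list(self.groups) == list(other.groups)
            and (self.coords or {}) == (other.coords or {})
        )


@dataclass
class AlleleFrequencyTable:
    """Per-locus allele frequencies over non-missing gene copies."""

    freqs: dict[str, "pd.Series"]  # locus -> Series(freq, index=allele label)
    gene_counts: dict[str, int]
    excluded: list[str] = field(default_factory=list)  # loci with no data in scope

    def __post_init__(self) -> None:
        for locus, s in self.freqs.items():
            total = float(s.sum())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"frequencies at {locus} sum to {total}, not 1")
            if (s <= 0).any():
                raise ValueError(f"zero/negative frequency listed at {locus}")


def allele_frequencies(
    t: GenotypeTable, samples: Sequence[int] | None = None
) -> AlleleFrequencyTable:
    """Count-based allele frequencies; each non-missing gene copy counted once.

    ``samples`` restricts the scope (e.g. one group); default is all samples.
    A locus entirely missing in scope is excluded and reported in ``excluded``.
    """
    ix = np.arange(t.n_samples) if samples is None else np.asarray(samples, dtype=np.intp)
    freqs: dict[str, pd.Series] = {}
    counts: dict[str, int] = {}
    excluded: list[str] = []
    for l, locus in enumerate(t.locus_names):
        genes = t.alleles[ix, l, :].ravel()
        genes = genes[genes != MISSING]
        if genes.size == 0:
            excluded.append(locus)
            warnings.warn(f"locus {locus} has no data in scope; excluded")
            continue
        lab, cnt = np.unique(genes, return_counts=True)
        freqs[locus] = pd.Series(cnt / genes.size, index=lab)
        counts[locus] = int(genes.size)
    return AlleleFrequencyTable(freqs, counts, excluded)


def group_allele_frequencies(t: GenotypeTable) -> dict:
    """AlleleFrequencyTable per group label."""
    return {g: allele_frequencies(t, ix) for g, ix in t.group_indices().items()}


# ---------------------------------------------------------------------------
# GenePop dialect
# ---------------------------------------------------------------------------

def _genepop_width(field_chars: int) -> int:
    if field_chars % 2 or field_chars not in (4, 6):
        raise ValueError(f"cannot infer allele width from field of {field_chars} chars")
    return field_chars // 2


def read_genepop(path, dialect: str = "auto") -> GenotypeTable:
    """Read a GenePop file (2- or 3-digit allele encoding, POP-separated).

    Allele 0 (``00``/``000``) encodes missing.  One group label per POP block
    (``pop1``, ``pop2``, ... or the block's last sample id convention is NOT
    used — labels are positional to stay deterministic).
    """
    if dialect not in ("auto", "2-digit", "3-digit"):
        raise ValueError("dialect must be 'auto', '2-digit' or '3-digit'")
    if hasattr(path, "read"):
        lines = path.read().splitlines()
    else:
        with open(path, "r", encoding="utf-8") as fh:
            lines = fh.read().splitlines()
    lines = [l.rstrip() for l in lines]
    if not lines:
        raise ValueError("empty GenePop file")
    # title line, then locus names (one per line, or comma-separated on one line)
    body_start = 1
    locus_names: list[str] = []
    i = 1
    while i < len(lines) and lines[i].strip().lower() != "pop":
        chunk = lines[i].strip()
        if chunk:
            locus_names.extend(x.strip() for x in chunk.split(",") if x.strip())
        i += 1
    if i == len(lines):
        raise ValueError("no POP separator found")
    width = {"2-digit": 2, "3-digit": 3, "auto": None}[dialect]

    sample_ids: list[str] = []
    groups: list[str] = []
    rows: list[list[tuple[int, int]]] = []
    pop_no = 0
    for lineno in range(i, len(lines)):
        line = lines[lineno]
        if not line.strip():
            continue
        if line.strip().lower() == "pop":
            pop_no += 1
            continue
        if "," not in line:
            raise ValueError(f"line {lineno + 1}: expected 'sample_id ,' separator")
        sid, rest = line.split(",", 1)
        sid = sid.strip()
        fields = rest.split()
        if len(fields) != len(locus_names):
            raise ValueError(
                f"line {lineno + 1}: {len(fields)} genotype fields for "
                f"{len(locus_names)} loci"
            )
        if width is None:
            width = _genepop_width(len(fields[0]))
        row = []
        for f in fields:
            if len(f) != 2 * width or not f.isdigit():
                raise ValueError(f"line {lineno + 1}: malformed genotype field '{f}'")
            row.append((int(f[:width]), int(f[width:])))
        if sid in sample_ids:
            raise ValueError(f"duplicate sample id '{sid}'")
        sample_ids.append(sid)
        groups.append(f"pop{pop_no}")
        rows.append(row)
    alleles = np.array(rows, dtype=np.int32)
    return GenotypeTable(alleles, sample_ids, locus_names,
                         np.array(groups, dtype=object))


def write_genepop(t: GenotypeTable, path, dialect: str = "3-digit",
                  title: str = "colonykin export") -> None:
    """Write ``t`` as GenePop; samples sharing a group label form one POP block."""
    width = {"2-digit": 2, "3-digit": 3}[dialect]
    if t.alleles.max(initial=0) >= 10 ** width:
        raise ValueError(f"allele labels exceed {dialect} encoding")

    def fmt(pair) -> str:
        return f"{pair[0]:0{width}d}{pair[1]:0{width}d}"

    buf = io.StringIO()
    buf.write(title + "\n")
    for locus in t.locus_names:
        buf.write(locus + "\n")
    for g, ix in t.group_indices().items():
        buf.write("POP\n")
        for i in ix:
            fields = " ".join(fmt(t.alleles[i, l]) for l in range(t.n_loci))
            buf.write(f"{t.sample_ids[i]} , {fields}\n")
    text = buf.getvalue()
    if hasattr(path, "write"):
        path.write(text)
    else:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(text)


# ---------------------------------------------------------------------------
# Delimited tables (spreadsheet-style: one row per sample, two columns/locus)
# ---------------------------------------------------------------------------

_NA_STRINGS = {"", "na", "n/a", "nan", "none", "?", "0"}


def read_table(path, schema: Mapping, sep: str | None = None) -> GenotypeTable:
    """Read a delimited genotype table.

    ``schema`` maps the file's columns onto the model::

        {"sample_id": "id", "group": "site",
         "loci": {"Rf21-1": ("Rf21-1_a", "Rf21-1_b"), ...},
         "lat": "latitude", "lon": "longitude"}   # lat/lon optional

    Blank, 'na' or 0 cells are missing.  A locus listed with only one of its
    two allele columns present in the file is an error.
    """
    df = pd.read_csv(path, sep=sep, engine="python")
    df.columns = [str(c).strip() for c in df.columns]
    loci = schema["loci"]
    for locus, cols in loci.items():
        if len(cols) != 2:
            raise ValueError(f"locus {locus} must name exactly two allele columns")
        missing_cols = [c for c in cols if c not in df.columns]
        if len(missing_cols) == 1:
            raise ValueError(
                f"locus {locus}: only one allele column present "
                f"(missing {missing_cols[0]})"
            )
        if missing_cols:
            raise ValueError(f"locus {locus}: columns {missing_cols} absent")

    def parse_allele(v) -> int:
        if pd.isna(v) or str(v).strip().lower() in _NA_STRINGS:
            return MISSING
        return int(float(v))

    sample_ids = [str(s).strip() for s in df[schema["sample_id"]]]
    groups = np.array([str(g).strip() for g in df[schema["group"]]], dtype=object)
    locus_names = list(loci)
    alleles = np.zeros((len(df), len(locus_names), 2), dtype=np.int32)
    for l, locus in enumerate(locus_names):
        c1, c2 = loci[locus]
        alleles[:, l, 0] = [parse_allele(v) for v in df[c1]]
        alleles[:, l, 1] = [parse_allele(v) for v in df[c2]]
    coords = None
    if schema.get("lat") and schema.get("lon"):
        coords = {
            sid: (float(lat), float(lon))
            for sid, lat, lon in zip(sample_ids, df[schema["lat"]], df[schema["lon"]])
        }
    return GenotypeTable(alleles, sample_ids, locus_names, groups, coords)


def read_coords(path, sep: str | None = None) -> dict[str, tuple[float, float]]:
    """Read a sample_id / latitude / longitude table (decimal degrees WGS84)."""
    df = pd.read_csv(path, sep=sep, engine="python")
    df.columns = [str(c).strip().lower() for c in df.columns]
    id_col = df.columns[0]
    lat_col = next(c for c in df.columns if c.startswith("lat"))
    lon_col = next(c for c in df.columns if c.startswith("lon"))
    return {
        str(r[id_col]).strip(): (float(r[lat_col]), float(r[lon_col]))
        for _, r in df.iterrows()
    }
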