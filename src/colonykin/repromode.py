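"""Sexual versus parthenogenetic origin of neotenic reproductives.

Under automictic parthenogenesis, offspring are homozygous at every locus; a
neotenic heterozygous at one or more loci is therefore sexually produced,
while one homozygous at all typed loci is a parthenogenesis candidate
(asexual queen succession, AQS).  With few typed loci an all-homozygous
genotype is weak evidence, so candidates require at least ``min_loci`` typed
loci; otherwise the call is indeterminate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .family import FamilyCall, classify_family
from .genotypes import MISSING, GenotypeTable, read_table

__all__ = ["ReproductiveRecord", "ModeCall", "classify_mode", "census_modes",
           "infer_parental_family", "records_from_table"]


@dataclass
class ReproductiveRecord:
    individual_id: str
    colony_id: str
    sex: str  # female | male
    caste: str  # primary | nymphoid_neotenic | ergatoid_neotenic
    genotypes: np.ndarray  # (n_loci, 2); 0 = missing

    @property
    def n_typed_loci(self) -> int:
        return int((self.genotypes[:, 0] != MISSING).sum())

    @property
    def n_heterozygous_loci(self) -> int:
        ok = self.genotypes[:, 0] != MISSING
        return int((self.genotypes[ok, 0] != self.genotypes[ok, 1]).sum())


@dataclass
class ModeCall:
    individual_id: str
    mode: str  # sexual | parthenogenetic_candidate | indeterminate
    n_heterozygous_loci: int
    n_typed_loci: int


def classify_mode(rec: ReproductiveRecord, min_loci: int = 4) -> ModeCall:
    """Sexual if heterozygous anywhere; parthenogenetic candidate if
    homozygous at all of >= min_loci typed loci; indeterminate otherwise."""
    if rec.n_typed_loci < 1:
        raise ValueError(f"{rec.individual_id}: no typed loci")
    if rec.n_heterozygous_loci >= 1:
        mode = "sexual"
    elif rec.n_typed_loci >= min_loci:
        mode = "parthenogenetic_candidate"
    else:
        mode = "indeterminate"
    return ModeCall(rec.individual_id, mode, rec.n_heterozygous_loci,
                    rec.n_typed_loci)


def census_modes(records, min_loci: int = 4) -> pd.DataFrame:
    """Counts of sexual / candidate / indeterminate calls per colony, sex and
    caste, plus a pooled row and a per-colony AQS verdict (no evidence of AQS
    when no female candidate exists)."""
    calls = [(r, classify_mode(r, min_loci)) for r in records]
    rows = []
    colonies = sorted({r.colony_id for r in records})
    for colony in colonies + ["all"]:
        sub = [rc for rc in calls if colony == "all" or rc[0].colony_id == colony]
        for sex in ("female", "male"):
            for caste in sorted({r.caste for r, _ in sub}):
                grp = [c for r, c in sub if r.sex == sex and r.caste == caste]
                if not grp:
                    continue
                rows.append(dict(
                    colony=colony, sex=sex, caste=caste, n=len(grp),
                    sexual=sum(c.mode == "sexual" for c in grp),
                    parthenogenetic_candidate=sum(
                        c.mode == "parthenogenetic_candidate" for c in grp),
                    indeterminate=sum(c.mode == "indeterminate" for c in grp),
                ))
    df = pd.DataFrame(rows)
    verdicts = {}
    for colony in colonies:
        fem = [c for r, c in calls if r.colony_id == colony and r.sex == "female"]
        verdicts[colony] = "no evidence of AQS" if not any(
            c.mode == "parthenogenetic_candidate" for c in fem) \
            else "candidate AQS"
    df.attrs["aqs_verdict"] = verdicts
    return df


def infer_parental_family(records, alpha: float = 0.05,
                          min_individuals: int = 5, **kwargs) -> FamilyCall:
    """Family type of the colony that produced these neotenics: the family
    classifier applied to the neotenic genotypes."""
    records = list(records)
    if len(records) < min_individuals:
        raise ValueError(f"need >= {min_individuals} genotyped neotenics")
    colony = records[0].colony_id
    genos = np.stack([r.genotypes for r in records])
    return classify_family(genos, alpha=alpha, colony_id=colony,
                           min_workers=min_individuals, **kwargs)


def records_from_table(t: GenotypeTable, sex: dict, caste: dict
                       ) -> list[ReproductiveRecord]:
    """Build reproductive records from a genotype table plus per-sample sex
    and caste annotations (``t.groups`` are colony ids)."""
    out = []
    for i, sid in enumerate(t.sample_ids):
        out.append(ReproductiveRecord(sid, str(t.groups[i]), sex[sid],
                                      caste[sid], t.alleles[i]))
    return out
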