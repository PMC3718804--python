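"""Reproductive mode of neotenics and the family type of their parents.

Simulates dissected field colonies: five colonies headed by sexually produced
neotenics (drawn from extended-family broods) and, for contrast, one colony
practising asexual queen succession (automictic, fully homozygous replacement
queens).  Each neotenic is classified sexual / parthenogenetic candidate by
the all-loci homozygosity rule, and each colony's neotenic set is fed to the
family classifier to infer the parental family type.
"""

import numpy as np
import pandas as pd

from colonykin.repromode import (ReproductiveRecord, census_modes,
                                 infer_parental_family)
from colonykin.simulate import (BreedingSystemSpec, SourcePopulationModel,
                                run_colony)

from common import RESULTS

model = SourcePopulationModel()
rng = np.random.default_rng(9)
records = []

# five sexually reproducing colonies: neotenics are brood of extended families
plan = [("col1", 20, 3), ("col2", 20, 20), ("col3", 8, 4), ("col4", 6, 1),
        ("col5", 5, 1)]
for name, n_q, n_k in plan:
    col = run_colony(BreedingSystemSpec(N_f=10, N_m=10, X=1), model,
                     n_q + n_k, rng)
    for i, g in enumerate(col.workers):
        sex = "female" if i < n_q else "male"
        records.append(ReproductiveRecord(f"{name}_n{i}", name, sex,
                                          "nymphoid_neotenic", g))

# one AQS colony: replacement queens are automictic clones of the queen
aqs = run_colony(BreedingSystemSpec(N_f=5, N_m=5, X=1,
                                    parthenogenetic_neotenics=True),
                 model, 10, rng)
for i, neo in enumerate(aqs.neotenics):
    records.append(ReproductiveRecord(f"aqs_n{i}", "col_aqs", neo["sex"],
                                      "nymphoid_neotenic", neo["genotype"]))

census = census_modes(records)
census.to_csv(RESULTS / "reproductive_census.tsv", sep="\t", index=False)
pooled = census[census["colony"] == "all"]
print(pooled.to_string(index=False))
print("\ncolony verdicts:")
for colony, verdict in census.attrs["aqs_verdict"].items():
    print(f"  {colony}: {verdict}")

rows = []
for colony in sorted({r.colony_id for r in records}):
    recs = [r for r in records if r.colony_id == colony]
    try:
        call = infer_parental_family(recs, alpha=0.05)
    except ValueError as e:
        print(f"{colony}: {e}")
        continue
    rows.append(dict(colony=colony, parental_family=call.family_type,
                     G=round(call.G_total, 2), df=call.df_total,
                     p=round(call.p_value, 4)))
fam = pd.DataFrame(rows)
fam.to_csv(RESULTS / "parental_family.tsv", sep="\t", index=False)
print("\nparental family types:")
print(fam.to_string(index=False))
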