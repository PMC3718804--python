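"""Population summary statistics and marker QC on one worker per colony:
alleles per locus, expected/observed heterozygosity, F_IS; Hardy-Weinberg
tests (3200 shufflings) with null-allele frequency estimates at deficit loci;
pairwise population F_ST with a global permutation test; private alleles.
"""

import warnings

import numpy as np
import pandas as pd

from colonykin import diversity as dv
from colonykin.fstats import pairwise_fst

from common import RESULTS, colony_populations, load_colonies, load_study

warnings.filterwarnings("ignore", category=UserWarning)

t, truth, point_pop = load_study()
colony_of = load_colonies()
colony_pop = colony_populations(t, colony_of, point_pop)

summary = dv.summarize(t, populations=colony_pop, colonies=colony_of, seed=2)
summary.round(3).to_csv(RESULTS / "population_summary.tsv", sep="\t",
                        index=False)
print(summary.round(3).to_string(index=False))

reps = dv.one_per_colony(t, colony_of, seed=2)
rep_pop = np.array([colony_pop[colony_of[t.sample_ids[i]]] for i in reps])

qc = []
rng = np.random.default_rng(3)
for pop in sorted(set(rep_pop)):
    ix = reps[rep_pop == pop]
    for l, locus in enumerate(t.locus_names):
        try:
            p = dv.hwe_test(t, ix, l, n_shuffles=3200, seed=rng)
        except ValueError:
            continue
        rep = dv.null_allele_estimate(t, ix, l, "brookfield1", p)
        qc.append(dict(population=pop, locus=locus, hwe_p=round(p, 4),
                       null_freq=(round(rep.estimated_null_freq, 3)
                                  if rep else np.nan)))
qc_df = pd.DataFrame(qc)
qc_df.to_csv(RESULTS / "locus_qc.tsv", sep="\t", index=False)
n_sig = (qc_df["hwe_p"] <= 0.05).sum()
print(f"\nHWE: {n_sig}/{len(qc_df)} population x locus tests significant "
      "at 0.05 (before correction)")

sub = t.subset(reps)
mat, p_glob = pairwise_fst(sub, rep_pop, n_perm=6000, seed=4)
mat.round(4).to_csv(RESULTS / "population_fst.tsv", sep="\t")
print(f"\nPairwise population F_ST (global permutation p = {p_glob:.4g}):")
print(mat.round(4).to_string())

pops = sorted(set(rep_pop))
for i in range(len(pops)):
    for j in range(i + 1, len(pops)):
        a = reps[rep_pop == pops[i]]
        b = reps[rep_pop == pops[j]]
        pa, pb = dv.private_alleles(t, a, b)
        print(f"private alleles {pops[i]} vs {pops[j]}: {pa} / {pb}")
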