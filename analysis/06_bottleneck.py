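"""Heterozygosity-excess bottleneck tests per population under the three
mutation models (IAM, TPM with 95% single-step steps and variance 12, SMM),
one worker per colony, 1000 conditional equilibrium simulations per locus,
combined across loci with a one-sided Wilcoxon signed-rank test.

Expect rejections here and read them as a property of the generator, not of
any demography: the synthetic source population uses equifrequent allele
spectra, the maximal-evenness state, so its gene diversity exceeds the
mutation-drift-equilibrium expectation for the observed allele counts —
exactly the signature this test screens for.  (The test's calibration against
genuinely equilibrium and bottlenecked histories lives in the test suite,
which simulates those histories coalescently.)  Stepwise models are the more
conservative, matching their known ordering Heq(IAM) < Heq(TPM) < Heq(SMM).
"""

import warnings

import numpy as np
import pandas as pd

from colonykin import diversity as dv
from colonykin.bottleneck import bottleneck_test

from common import RESULTS, colony_populations, load_colonies, load_study

warnings.filterwarnings("ignore", category=UserWarning)

t, truth, point_pop = load_study()
colony_of = load_colonies()
colony_pop = colony_populations(t, colony_of, point_pop)
reps = dv.one_per_colony(t, colony_of, seed=2)
rep_pop = np.array([colony_pop[colony_of[t.sample_ids[i]]] for i in reps])

rows, pvals = [], []
for pop in sorted(set(rep_pop)):
    ix = reps[rep_pop == pop]
    if len(ix) < 5:
        print(f"{pop}: fewer than 5 colonies, skipped")
        continue
    df, pv = bottleneck_test(t, ix, models=("IAM", "TPM", "SMM"),
                             n_sim=1000, seed=5)
    df.insert(0, "population", pop)
    rows.append(df)
    for m, p in pv.items():
        pvals.append(dict(population=pop, model=m, wilcoxon_p=round(p, 4)))
    print(f"{pop}: " + ", ".join(f"{m} p={p:.3f}" for m, p in pv.items()))

pd.concat(rows, ignore_index=True).round(4).to_csv(
    RESULTS / "bottleneck_loci.tsv", sep="\t", index=False)
pd.DataFrame(pvals).to_csv(RESULTS / "bottleneck_p.tsv", sep="\t", index=False)
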