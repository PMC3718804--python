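# Methods

This note records the models, estimators, numerical conventions and design
choices behind each stage, and what validation on simulated data does and
does not establish.

## Data model

Alleles are opaque positive integers (fragment sizes or bin codes — the
package never does arithmetic on labels, except the stepwise mutation models,
which treat them as repeat scores on an unbounded integer lattice). The
missing sentinel is 0, and a genotype with either copy missing is wholly
missing: every downstream statistic assumes complete diploid genotypes.
Genotypes are stored canonically (a1 ≤ a2) so heterozygote counts cannot
depend on input order. Group labels are single-level; the
population > colony > individual hierarchy is expressed by passing different
labelings (sampling points, delineated colonies, populations) to each stage,
which lets one table flow through the whole chain. Coordinates are WGS84
decimal degrees; distances are haversine great-circle metres.

## Gene-dropping simulator

Colonies are founded by `n_founding_queens` + `n_founding_kings`
reproductives drawn from an infinite outbred source population (independent
Hardy–Weinberg draws from per-locus spectra; default 8 loci × 10 equifrequent
alleles). Each brood offspring draws a dam uniformly among current females
and a sire uniformly among males, independently per offspring, then one
allele per locus from each parent. For each of `X` neotenic generations,
`N_f` females and `N_m` males are drawn uniformly without replacement from
the brood (sexes assigned Bernoulli(1/2) beforehand; sexes are redrawn, with
a bounded retry, if one sex falls short) and become the next breeding set.
Workers are sampled from the final brood only — a single cohort, which is
what drives the strongly negative within-colony F_IC of the reference cases.
Mixing replaces a fraction 1−p of the worker sample with workers of a second
colony (founders of both colonies are nestmates of one hidden outbred pair
in the "related" variant). Automictic parthenogenesis makes each replacement
female fully homozygous for one uniformly chosen maternal allele per locus;
no cytological mechanism is modelled beyond that operational rule, because
the all-loci-homozygosity rule is also how candidates are diagnosed.

Null alleles segregate through the pedigree as a real allele at the stated
source frequency: null homozygotes fail to amplify (missing), null
heterozygotes appear homozygous for the visible allele.
Missing-at-random erasure is applied after that. Defaults for reference
runs are 200–500 colonies × 20 workers, which keeps estimator noise near
±0.005 and runtimes in seconds.

Pedigree closed forms used to verify the engine: a monogamous outbred pair
gives worker coancestry 1/4, hence F_CT = 1/4, F_IC = −1/3, r = 1/2; two
queens sharing one king give coancestry 3/16 (half full sibs, half paternal
half sibs), hence F_CT = 0.1875, F_IC = −3/13 ≈ −0.231, r = 0.375; 10+10
first-generation neotenics give worker inbreeding 1/4 and coancestry 0.2625,
hence F_IC ≈ −0.017.

### The reference table and its under-specified rows

The classical breeding-system expectations this package regenerates come
from earlier simulation studies that did not publish every founder pedigree.
Gene-dropping reproduces the monogamous-outbred (A1) and pleometrosis rows
(E1, E3) to ±0.02, and the within-colony coefficient F_IC of the
multi-neotenic rows (B3: −0.011 vs −0.01; B4: −0.009 vs 0). It does not
reproduce the published F_IT/F_CT of the inbred-pair row A2 (0.33/0.42) —
full-sib founders of an outbred pair give 0.25, sibs of a sib-mated pair
0.50, and both recipes are provided as registered pedigree tags
(`sib_line_1..3`, default `sib_line_1`) — nor the B/C/D rows exactly, whose
deeper ancestries are similarly unrecoverable. One published row (B1) is
internally inconsistent with the ratio identities
(1−F_IT) = (1−F_CT)(1−F_IC) and r = 2F_CT/(1+F_IT) that all other rows
satisfy to rounding, and cannot be matched by any estimator that computes
all four quantities from shared variance components. `analysis/04` writes
the regenerated-vs-published comparison to
`results/reference_table_regenerated.tsv` rather than forcing agreement.

## Colony delineation

Observed statistic: per locus, the genotype-class × sample-pair contingency
G = 2ΣO·ln(O/E) (0·ln 0 ≡ 0, expecteds from margins), summed over loci with
data in both samples. The null permutes whole multilocus genotypes between
the two samples with set sizes fixed; p = (1+#{G* ≥ G})/(n_perm+1). The
nominal level is α = 0.05 with Bonferroni over all pairs within a region.
Because the permutation p floor is 1/(n_perm+1), the requested n_perm is
automatically raised to ⌈n_pairs/α⌉ when it cannot resolve the corrected
level (e.g. 6000 permutations for 300 pairs) — otherwise no pair could ever
be significant and all points would merge. Non-significant pairs are edges;
colonies are connected components (single linkage). Intransitive triples
(a~b, b~c, a≁c) are possible in principle; they are merged, counted and
logged. Geographic distance is deliberately not used: colony membership is
decided genetically only.

## Family classification

Precedence is fixed: the >4-alleles rule (mixed) is checked first, per
locus, because no two diploid parents can carry more than four alleles. The
extended rules follow: >4 genotypic classes at a locus, no compatible
monogamous parent pair (exhaustive enumeration over the observed alleles),
or Mendelian G-test rejection. Parent-pair ambiguity is resolved by the
pair minimising G — the choice most favourable to "simple" — so extended
calls are conservative; on simulated simple families the false-extended rate
measures ≈7% at α = 0.05 (the G-test level plus the selection slack). G and
df are summed across loci into one test per colony (likelihood-ratio
additivity); a per-locus mode is available. Loci with fewer than 5 genotyped
workers contribute no G (small-count G is unstable), and colonies with fewer
than `min_workers` (default 10) are called but flagged low-confidence.

## Hierarchical F-statistics

Per locus and allele the Weir–Cockerham method-of-moments components a
(among colonies), b (among individuals within colonies) and c (within
individuals) are computed with the unequal-sample-size corrections; per
locus, colonies with no genotyped individuals are dropped, and monomorphic
loci contribute exact zeros (kept, so estimates are continuous as
polymorphism vanishes). Ratio-of-sums estimators over all loci and alleles
give F_CT, F_IT, F_IC; relatedness uses the F-statistics identity
r = 2F_CT/(1+F_IT), so the ratio identities hold exactly by construction.
Standard errors are delete-one jackknives over colonies, switching to loci
when three or fewer colonies are available. Degenerate limits are defined:
all-monomorphic data raise an error, and r is NaN at the F_IT → −1 boundary.

Per-colony replicates (for one-sample t-tests against reference rows) use a
gene-identity estimator: Q1 (within-individual identity), Q2 (within-colony,
cross-individual, with within-individual pairs excluded) and Q3 (cross-
colony baseline, held fixed across colonies), combined as ratio-of-sums of
(Q−Q3)/(1−Q3) terms over loci. The baseline includes all colonies by
default (`colony_vs_total`); a `colony_vs_rest` mode excludes the focal
colony. Colony means track the pooled estimator on balanced simulated data.
The t-test is the ordinary one-sample test (a "not assuming equal variances"
qualifier only applies to two-sample settings); zero-variance inputs
short-circuit to p = 1 on exact match.

Population-level F_ST uses one randomly chosen worker per colony (a seeded
choice shared with the diversity stage, so every population-level analysis
sees the same representatives), two-level Weir–Cockerham θ per population
pair, and a global permutation test of the multilocus genotype-class G with
individual labels permuted (default 6000 permutations).

## Diversity and QC

N_A is the mean observed allele count; H_E is Nei's unbiased gene diversity
(2n/(2n−1))(1−Σp²) averaged over loci; H_O is the heterozygote fraction;
F_IS = 1 − ΣH_O/ΣH_E (ratio of sums). The Hardy–Weinberg test permutes
allele copies among individuals (3200 shufflings by default) with statistic
|F_IS|; this is a Monte-Carlo "shuffling" test, not a full-enumeration exact
test, and it scales to arbitrarily many alleles. The LD test permutes one
locus's genotypes among complete cases with the two-locus contingency G as
statistic. Both are slightly conservative under heavy ties (discrete
genotype tables), as permutation tests are; their measured levels sit inside
±2 SE of 0.05 on 500 null replicates of 200 individuals at 2-allele loci.
Null-allele frequency is estimated only at heterozygote-deficit loci:
Brookfield-1 r = (H_E−H_O)/(1+H_E), Chakraborty r = (H_E−H_O)/(H_E+H_O), and
an `oosterhout` mode implemented as a numerical maximum-likelihood fit of a
single null allele to the apparent heterozygote fraction among amplified
individuals (the original software's iterative algorithm has no published
closed form). All recover a simulated true null frequency of 0.2 within
±0.08.

## Bottleneck test

For each polymorphic locus, samples of the same gene count are simulated at
mutation–drift equilibrium conditional on the observed allele count k:
under IAM by the Hoppe urn (Ewens sampling distribution) with θ solved
exactly from E[k] = Σθ/(θ+i); under SMM/TPM by simulating the n-coalescent
genealogy, dropping Poisson(θℓ/2) mutations per branch and stepping on the
integer lattice (TPM: single step with probability 0.95, else a symmetric
geometric step whose variance parameter defaults to 12 — the common settings
of this test's standard software, config-exposed because the choice
matters), with θ tuned by stochastic bisection on the simulated mean allele
count and samples retained by rejection on k. DH = (He_obs − mean Heq)/sd
Heq; the per-locus `p_excess` field is the null quantile of He_obs (the
fraction of null draws ≤ the observation). Loci are combined by a one-sided
Wilcoxon signed-rank test on DH (exact null for ≤25 loci). Null
distributions are cached per (model, n, k, n_sim, seed) with the stream seed
derived deterministically from (seed, n, k).

Verification uses an independent data-generating process (msprime
coalescent with infinite-alleles mutations): the conditional Heq means agree
with the urn to <0.02 across k; on 100 equilibrium populations the Wilcoxon
rejection rate is 0.07 ≤ α+2SE; against a 10-fold crash (5000 → 500 diploids
100 generations ago, θ appropriate for 6–12 alleles per locus) power is
≈0.9. The model ordering Heq(IAM) < Heq(TPM) < Heq(SMM) at equal (n, k) —
the homoplasy effect that makes stepwise-model bottleneck tests more
conservative — is asserted in the tests.

## Isolation by distance

Pairwise colony θ uses all workers of the two colonies (within-colony
variance is the information here, unlike the one-per-colony population
analyses); negative estimates are retained, and linearisation F/(1−F) caps
F at 1−10⁻⁹ with a warning. Colony coordinates are centroids of member
sampling points (a colony can span two points). Pairs at literally
coincident coordinates are excluded (ln 0), by dropping the second colony
with a warning, rather than jittered. The Mantel statistic is the Pearson
correlation over upper-triangle entries; the null simultaneously reorders
rows and columns of one matrix; p is one-sided for positive association
(10,000 permutations by default), and the Monte-Carlo p matches exhaustive
relabeling for ≤6 objects to ±0.02.

## Reproductive mode

A neotenic heterozygous at ≥1 typed locus is sexually produced; one
homozygous at every typed locus is a parthenogenesis candidate only when at
least 4 loci are typed (with fewer, the call is indeterminate — an
all-homozygous profile over 2 diverse loci arises by chance ~1% of the time,
over 8 loci ~10⁻⁸). Candidates whose homozygosity involves loci flagged for
null alleles should be read with the QC output at hand, since null alleles
mimic homozygosity. Parental family type is the family classifier applied
to the neotenic set (≥5 individuals).

## The synthetic study and what the tests show

`make_synthetic_study` emulates the sampling design the pipeline targets:
populations of 9–24 colonies (69 total; 51 extended / 14 simple / 4 mixed),
25 workers per sampling point, a few colonies sampled at two points, and an
optional 1-D stepping-stone layout in which colonies are founded from demes
of a drifted Wright–Fisher lattice, producing a genuine spatial correlation
of allele frequencies. Same spec + seed ⇒ byte-identical files.

What it does **not** emulate: mutation–drift-equilibrium allele spectra
(the equifrequent source is a maximal-evenness state, which the bottleneck
test rightly flags as heterozygosity excess — bottleneck calibration
therefore uses coalescent data instead), genotyping artefacts beyond null
alleles and missingness (no stutter, no large-allele dropout, no binning
error), overlapping worker cohorts within colonies, and any real dispersal
biology behind the spatial layout. Green tests on this generator show the
estimators and decision rules are correct under their own assumptions; they
do not show robustness to the artefacts real gels produce.

Scales used by the shipped runs (chosen as reasonable trade-offs between
Monte-Carlo error and wall time): 500 colonies × 20 workers for reference
F-statistics; 500 null replicates for HWE/LD calibration; 100 equilibrium +
12 crash replicates for the bottleneck test; 2000–6000 permutations per
delineation pair; 10,000 Mantel permutations.
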