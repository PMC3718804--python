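"""Generate the synthetic field study every later script analyses.

Four populations whose colony counts and family-type composition mirror the
empirical design (69 colonies: 51 extended / 14 simple / 4 mixed; 25 workers
per sampling point; a few colonies sampled at two points), laid out on a
stepping-stone lattice so colonies close in space share drifted allele
frequencies (an isolation-by-distance signal).
"""

from colonykin.pipeline import DEFAULT_STUDY, make_synthetic_study

from common import STUDY, STUDY_SEED

res = make_synthetic_study(DEFAULT_STUDY, seed=STUDY_SEED, outdir=STUDY)
truth = res["truth"]
print(f"wrote {', '.join(res['paths'].values())}")
print(f"{truth['colony'].nunique()} colonies over "
      f"{truth['point'].nunique()} sampling points in "
      f"{truth['population'].nunique()} populations")
print(truth.drop_duplicates('colony')
      .groupby(['population', 'family_type']).size().unstack(fill_value=0))
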