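"""Shared paths and loaders for the numbered analysis scripts.

Run the scripts in order from the repository root:

    python analysis/01_simulate_study.py
    python analysis/02_delineate_colonies.py
    ...

Every script reads its inputs from ``results/`` (written by earlier steps)
and appends its own tables there.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from colonykin.genotypes import GenotypeTable, read_coords, read_genepop

RESULTS = Path("results")
STUDY = RESULTS / "synthetic_study"
STUDY_SEED = 7


def load_study() -> tuple[GenotypeTable, pd.DataFrame, dict]:
    """Genotype table (with coordinates), truth labels, point->population."""
    t = read_genepop(STUDY / "genotypes.gen")
    t.coords = read_coords(STUDY / "coords.tsv")
    truth = pd.read_csv(STUDY / "truth.tsv", sep="\t")
    pp = pd.read_csv(STUDY / "point_populations.tsv", sep="\t")
    point_pop = dict(zip(pp["point"].astype(str), pp["population"].astype(str)))
    return t, truth, point_pop


def load_colonies() -> dict[str, str]:
    """sample_id -> colony, as delineated by script 02."""
    df = pd.read_csv(RESULTS / "colonies.tsv", sep="\t")
    return dict(zip(df["sample_id"].astype(str), df["colony"].astype(str)))


def colony_populations(t: GenotypeTable, colony_of: dict,
                       point_pop: dict) -> dict[str, str]:
    return {colony_of[s]: point_pop[str(g)]
            for s, g in zip(t.sample_ids, t.groups)}
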