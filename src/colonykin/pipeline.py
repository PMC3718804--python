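"""Study-level orchestration: synthetic study generation and the full
delineate -> classify -> F-stats -> QC -> bottleneck -> IBD -> reproductive-mode
chain driven by a single config.

Every stochastic stage has an explicit seed in the config; re-running a config
reproduces every output byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import bottleneck as bn
from . import diversity as dv
from .delineate import delineate
from .family import classify_table, family_census
from .fstats import (REFERENCE_ROWS, compare_to_reference, jackknife_se,
                     pairwise_fst, per_colony_values)
from .genotypes import GenotypeTable, read_coords, read_genepop, write_genepop
from .ibd import ibd_analysis
from .repromode import census_modes, infer_parental_family, records_from_table
from .simulate import (BreedingSystemSpec, SourcePopulationModel, run_colony,
                       simulate_population, stepping_stone_frequencies,
                       breeding_system, _mask_observation)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "RunReport", "run_pipeline", "make_synthetic_study",
           "DEFAULT_STUDY"]

ALL_STAGES = ("delineate", "classify", "fstats", "qc", "bottleneck", "ibd",
              "repromode")


@dataclass
class RunConfig:
    genotypes: str = "genotypes.gen"  # GenePop; one POP block per sampling point
    point_populations: str | None = None  # TSV point->population (default: one pop)
    coords: str | None = None  # TSV sample_id, latitude, longitude
    reproductives: str | None = None  # TSV for the repromode stage
    outdir: str = "results"
    stages: tuple = ALL_STAGES
    alpha: float = 0.05
    n_perm_pairwise: int = 2000
    hwe_shuffles: int = 3200
    global_perm: int = 6000
    mantel_perm: int = 10_000
    bottleneck_models: tuple = ("IAM", "TPM", "SMM")
    bottleneck_sims: int = 1000
    seeds: dict = field(default_factory=lambda: {
        "delineate": 1, "subsample": 2, "qc": 3, "bottleneck": 4, "ibd": 5})

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["stages"] = list(self.stages)
        d["bottleneck_models"] = list(self.bottleneck_models)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text())
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(d) - known
        if bad:
            raise ValueError(f"unknown config keys: {sorted(bad)}")
        for k in ("stages", "bottleneck_models"):
            if k in d:
                d[k] = tuple(d[k])
        return cls(**d)


@dataclass
class RunReport:
    outputs: dict = field(default_factory=dict)  # stage -> list of paths
    tables: dict = field(default_factory=dict)  # name -> DataFrame
    skipped: dict = field(default_factory=dict)  # stage -> reason
    seeds: dict = field(default_factory=dict)


def _write(df: pd.DataFrame, path: Path) -> Path:
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)
    return path


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute the enabled stages in dependency order.

    ``delineate`` and ``classify`` feed every later stage; optional stages
    that lack their inputs (e.g. IBD without coordinates) are skipped with a
    logged reason.
    """
    bad = set(config.stages) - set(ALL_STAGES)
    if bad:
        raise ValueError(f"unknown stages: {sorted(bad)}")
    out = Path(config.outdir)
    report = RunReport(seeds=dict(config.seeds))
    t = read_genepop(config.genotypes)
    if config.coords:
        t.coords = read_coords(config.coords)
    if config.point_populations:
        pp = pd.read_csv(config.point_populations, sep="\t")
        point_pop = dict(zip(pp.iloc[:, 0].astype(str), pp.iloc[:, 1].astype(str)))
    else:
        point_pop = {str(g): "all" for g in pd.unique(t.groups)}
    populations = sorted(set(point_pop.values()))

    # ---- colony delineation (within each population) --------------------
    colony_of: dict[str, str] = {}
    if "delineate" in config.stages:
        rows = []
        for pop in populations:
            pts = [g for g in pd.unique(t.groups) if point_pop[str(g)] == pop]
            ix = np.flatnonzero(np.isin(t.groups, pts))
            sub = t.subset(ix)
            part = delineate(sub, alpha=config.alpha,
                             n_perm=config.n_perm_pairwise,
                             seed=config.seeds.get("delineate", 1))
            for s, c in part.colony_of.items():
                colony_of[s] = f"{pop}:{c}"
            rows.extend(dict(population=pop, point=str(u), other=str(v),
                             G=e.G_obs, p=e.p_value,
                             significant=e.significant_after_correction)
                        for e in part.evidence for u, v in [e.pair])
        report.tables["colonies"] = pd.DataFrame(
            dict(sample_id=list(colony_of), colony=list(colony_of.values())))
        report.outputs["delineate"] = [
            _write(report.tables["colonies"], out / "colonies.tsv"),
            _write(pd.DataFrame(rows), out / "delineation_evidence.tsv")]
    else:
        colony_of = {s: str(g) for s, g in zip(t.sample_ids, t.groups)}

    colony_pop = {c: point_pop.get(str(g), "all")
                  for s, g in zip(t.sample_ids, t.groups)
                  for c in [colony_of[s]]}

    # ---- family classification ------------------------------------------
    calls = None
    if "classify" in config.stages:
        calls = classify_table(t, colony_of, alpha=config.alpha)
        fam = pd.DataFrame([
            dict(colony=c.colony_id, population=colony_pop[c.colony_id],
                 family_type=c.family_type, G=c.G_total, df=c.df_total,
                 p=c.p_value, low_confidence=c.low_confidence,
                 reasons="; ".join(c.reasons)) for c in calls])
        census = family_census(calls, by=colony_pop)
        report.tables["families"] = fam
        report.tables["family_census"] = census
        report.outputs["classify"] = [
            _write(fam, out / "families.tsv"),
            _write(census, out / "family_census.tsv")]

    # ---- hierarchical F-statistics vs reference breeding systems --------
    if "fstats" in config.stages:
        if calls is None:
            report.skipped["fstats"] = "classify stage disabled"
        else:
            ftype = {c.colony_id: c.family_type for c in calls}
            rows, trows = [], []
            for pop in populations:
                for fam_t in ("simple", "extended", "mixed"):
                    cols = [c for c in ftype
                            if colony_pop[c] == pop and ftype[c] == fam_t]
                    samples = [i for i, s in enumerate(t.sample_ids)
                               if colony_of[s] in cols]
                    if len(cols) < 2:
                        continue
                    sub = t.subset(samples)
                    labels = np.array([colony_of[s] for s in sub.sample_ids],
                                      dtype=object)
                    est = jackknife_se(sub, labels)
                    rows.append(dict(population=pop, family_type=fam_t,
                                     n_colonies=len(cols), **est.as_dict(),
                                     jackknife_unit=est.jackknife_unit))
                    vals = per_colony_values(sub, labels)
                    for case, ref in REFERENCE_ROWS.items():
                        tt = compare_to_reference(vals, ref)
                        for _, r in tt.iterrows():
                            trows.append(dict(population=pop, family_type=fam_t,
                                              case=case, **r.to_dict()))
            report.tables["fstats"] = pd.DataFrame(rows)
            report.tables["reference_ttests"] = pd.DataFrame(trows)
            report.outputs["fstats"] = [
                _write(report.tables["fstats"], out / "fstats_by_family.tsv"),
                _write(report.tables["reference_ttests"],
                       out / "reference_ttests.tsv")]

    # one worker per colony, shared by the population-level stages
    reps = dv.one_per_colony(t, colony_of, seed=config.seeds.get("subsample", 2))
    rep_pop = np.array([colony_pop[colony_of[t.sample_ids[i]]] for i in reps])

    # ---- diversity / QC ---------------------------------------------------
    if "qc" in config.stages:
        summary = dv.summarize(t, populations=colony_pop, colonies=colony_of,
                               seed=config.seeds.get("subsample", 2))
        qc_rows = []
        rng = np.random.default_rng(config.seeds.get("qc", 3))
        for pop in populations:
            ix = reps[rep_pop == pop]
            if len(ix) < 5:
                continue
            for l in range(t.n_loci):
                try:
                    p_hwe = dv.hwe_test(t, ix, l, n_shuffles=config.hwe_shuffles,
                                        seed=rng)
                except ValueError:
                    continue
                rep = dv.null_allele_estimate(t, ix, l, "brookfield1", p_hwe)
                qc_rows.append(dict(
                    population=pop, locus=t.locus_names[l], hwe_p=p_hwe,
                    null_freq_brookfield1=(rep.estimated_null_freq
                                           if rep else float("nan"))))
        report.tables["summary"] = summary
        report.tables["locus_qc"] = pd.DataFrame(qc_rows)
        outputs = [_write(summary, out / "population_summary.tsv"),
                   _write(report.tables["locus_qc"], out / "locus_qc.tsv")]
        if len(populations) >= 2:
            sub = t.subset(reps)
            mat, p_glob = pairwise_fst(sub, rep_pop,
                                       n_perm=config.global_perm,
                                       seed=config.seeds.get("qc", 3))
            mat.index.name = "population"
            mat.to_csv(out / "population_fst.tsv", sep="\t")
            (out / "population_fst_test.json").write_text(
                json.dumps({"global_p": p_glob,
                            "n_perm": config.global_perm}))
            report.tables["population_fst"] = mat
            outputs.append(out / "population_fst.tsv")
        report.outputs["qc"] = outputs

    # ---- bottleneck --------------------------------------------------------
    if "bottleneck" in config.stages:
        rows, prows = [], []
        for pop in populations:
            ix = reps[rep_pop == pop]
            if len(ix) < 5:
                report.skipped[f"bottleneck:{pop}"] = "fewer than 5 colonies"
                continue
            df, pv = bn.bottleneck_test(
                t, ix, models=config.bottleneck_models,
                n_sim=config.bottleneck_sims,
                seed=config.seeds.get("bottleneck", 4))
            df.insert(0, "population", pop)
            rows.append(df)
            prows.extend(dict(population=pop, model=m, wilcoxon_p=p)
                         for m, p in pv.items())
        if rows:
            report.tables["bottleneck"] = pd.concat(rows, ignore_index=True)
            report.tables["bottleneck_p"] = pd.DataFrame(prows)
            report.outputs["bottleneck"] = [
                _write(report.tables["bottleneck"], out / "bottleneck_loci.tsv"),
                _write(report.tables["bottleneck_p"], out / "bottleneck_p.tsv")]

    # ---- isolation by distance --------------------------------------------
    if "ibd" in config.stages:
        if t.coords is None:
            report.skipped["ibd"] = "no coordinates provided"
            logger.info("IBD skipped: no coordinates")
        else:
            rows, pair_tabs = [], []
            for pop in populations:
                samples = [i for i, s in enumerate(t.sample_ids)
                           if colony_pop[colony_of[s]] == pop]
                sub = t.subset(samples)
                labels = np.array([colony_of[s] for s in sub.sample_ids],
                                  dtype=object)
                try:
                    res, pairs = ibd_analysis(
                        sub, labels, n_perm=config.mantel_perm,
                        seed=config.seeds.get("ibd", 5))
                except ValueError as e:
                    report.skipped[f"ibd:{pop}"] = str(e)
                    continue
                rows.append(dict(population=pop, mantel_r=res.r, p=res.p,
                                 n_perm=res.n_permutations))
                pairs.insert(0, "population", pop)
                pair_tabs.append(pairs)
            if rows:
                report.tables["ibd"] = pd.DataFrame(rows)
                report.outputs["ibd"] = [
                    _write(report.tables["ibd"], out / "ibd_mantel.tsv"),
                    _write(pd.concat(pair_tabs, ignore_index=True),
                           out / "ibd_pairs.tsv")]

    # ---- reproductive mode -------------------------------------------------
    if "repromode" in config.stages:
        if not config.reproductives:
            report.skipped["repromode"] = "no reproductive table provided"
        else:
            df = pd.read_csv(config.reproductives, sep="\t")
            loci = [c[:-3] for c in df.columns if c.endswith("_a1")]
            from .genotypes import read_table as _rt
            schema = dict(sample_id="id", group="colony",
                          loci={l: (f"{l}_a1", f"{l}_a2") for l in loci})
            rt = _rt(config.reproductives, schema, sep="\t")
            sex = dict(zip(df["id"].astype(str), df["sex"]))
            caste = dict(zip(df["id"].astype(str), df["caste"]))
            records = records_from_table(rt, sex, caste)
            census = census_modes(records)
            fam_rows = []
            for colony in sorted({r.colony_id for r in records}):
                recs = [r for r in records if r.colony_id == colony]
                try:
                    call = infer_parental_family(recs, alpha=config.alpha)
                except ValueError as e:
                    report.skipped[f"repromode:{colony}"] = str(e)
                    continue
                fam_rows.append(dict(colony=colony,
                                     parental_family=call.family_type,
                                     G=call.G_total, df=call.df_total,
                                     p=call.p_value))
            report.tables["reproductive_census"] = census
            report.tables["parental_family"] = pd.DataFrame(fam_rows)
            report.outputs["repromode"] = [
                _write(census, out / "reproductive_census.tsv"),
                _write(report.tables["parental_family"],
                       out / "parental_family.tsv")]
    return report


# ---------------------------------------------------------------------------
# Synthetic study generation
# ---------------------------------------------------------------------------

#: Default synthetic study: four populations whose colony counts and family
#: composition mirror the empirical design this pipeline targets
#: (69 colonies: 51 extended / 14 simple / 4 mixed).
DEFAULT_STUDY = {
    "populations": [
        {"name": "popA", "n_simple": 4, "n_extended": 20, "n_mixed": 0,
         "n_duplicate_points": 1, "origin": (30.45, 114.87)},
        {"name": "popB", "n_simple": 4, "n_extended": 18, "n_mixed": 1,
         "n_duplicate_points": 2, "origin": (28.24, 112.98)},
        {"name": "popC", "n_simple": 4, "n_extended": 8, "n_mixed": 1,
         "n_duplicate_points": 0, "origin": (29.53, 106.61)},
        {"name": "popD", "n_simple": 2, "n_extended": 5, "n_mixed": 2,
         "n_duplicate_points": 0, "origin": (29.55, 106.63)},
    ],
    "workers_per_point": 25,
    "spatial": "stepping_stone",  # or "none"
    "extent_m": 500.0,  # spatial span of each population
    "specs": {"simple": "a1", "extended": "b3", "mixed": "e1"},
}


def make_synthetic_study(study: dict | None = None, seed: int = 0,
                         outdir: str | Path = "synthetic_study",
                         model: SourcePopulationModel | None = None) -> dict:
    """Write a complete synthetic study to disk: GenePop genotypes (one POP
    block per sampling point), coordinates TSV, point->population TSV and a
    truth-labels TSV.  Returns the file paths plus the truth DataFrame.

    Under the ``stepping_stone`` layout, colonies within a population are
    founded from demes of a drifted 1-D lattice matched to their position,
    so genetic and geographic distance correlate (isolation by distance).
    """
    study = study or DEFAULT_STUDY
    model = model or SourcePopulationModel()
    rng = np.random.default_rng(seed)
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    nw = study["workers_per_point"]
    specs = {k: breeding_system(v) for k, v in study["specs"].items()}

    blocks, ids, groups, coords, truth, point_pop = [], [], [], {}, [], []
    pt_counter = 0  # GenePop POP blocks are positional: labels pop1, pop2, ...
    for p, pop in enumerate(study["populations"]):
        plan = (["simple"] * pop["n_simple"] + ["extended"] * pop["n_extended"]
                + ["mixed"] * pop["n_mixed"])
        rng.shuffle(plan)
        n_col = len(plan)
        ndup = pop.get("n_duplicate_points", 0)
        lat0, lon0 = pop["origin"]
        extent = study.get("extent_m", 500.0)
        pos_m = np.sort(rng.uniform(0, extent, n_col))
        if study.get("spatial") == "stepping_stone":
            demes = stepping_stone_frequencies(
                10, model, seed=np.random.default_rng([seed, 17 + p]))
            deme_of = np.minimum((pos_m / extent * 10).astype(int), 9)
        # colony j is sampled at 1 point, plus a second point for j < ndup
        visits = [2 if j < ndup else 1 for j in range(n_col)]
        for j, fam in enumerate(plan):
            m = demes[deme_of[j]] if study.get("spatial") == "stepping_stone" \
                else model
            colony = run_colony(specs[fam], m, nw * visits[j], rng)
            cid = f"{pop['name']}_col{j:02d}"
            for visit in range(visits[j]):
                pt_counter += 1
                pname = f"pop{pt_counter}"
                workers = colony.workers[visit * nw:(visit + 1) * nw]
                blocks.append(_mask_observation(workers, m.missing_rate, rng))
                # two points of one colony sit a few metres apart
                x = pos_m[j] + visit * rng.uniform(3.0, 8.0)
                lat = lat0 + x / 111_320.0
                for w in range(nw):
                    sid = f"{pname}_w{w:02d}"
                    ids.append(sid)
                    groups.append(pname)
                    coords[sid] = (lat, lon0)
                truth.append(dict(point=pname, colony=cid,
                                  population=pop["name"], family_type=fam))
                point_pop.append(dict(point=pname, population=pop["name"]))

    table = GenotypeTable(np.concatenate(blocks), ids,
                          [f"L{l + 1}" for l in range(model.n_loci)],
                          np.array(groups, dtype=object), coords)
    paths = {
        "genotypes": out / "genotypes.gen",
        "coords": out / "coords.tsv",
        "point_populations": out / "point_populations.tsv",
        "truth": out / "truth.tsv",
    }
    write_genepop(table, paths["genotypes"], title=f"synthetic study seed={seed}")
    pd.DataFrame([dict(sample_id=s, latitude=c[0], longitude=c[1])
                  for s, c in coords.items()]).to_csv(
        paths["coords"], sep="\t", index=False)
    pd.DataFrame(point_pop).to_csv(paths["point_populations"], sep="\t",
                                   index=False)
    truth_df = pd.DataFrame(truth)
    truth_df.to_csv(paths["truth"], sep="\t", index=False)
    return {"paths": {k: str(v) for k, v in paths.items()}, "truth": truth_df,
            "table": table}
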