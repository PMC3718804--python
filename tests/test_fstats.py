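import numpy as np
import pandas as pd
import pytest

from colonykin.fstats import (REFERENCE_ROWS, compare_to_reference,
                              hier_estimates, jackknife_se, pairwise_fst,
                              per_colony_values, variance_components)
from colonykin.genotypes import GenotypeTable
from colonykin.simulate import (SourcePopulationModel, simulate_population,
                                breeding_system)

from conftest import table_from_genotypes
from wc_oracle import wc_components_single_locus


class TestVarianceComponents:
    def test_matches_hand_evaluated_formulas(self):
        colonies = {
            "c1": [[(1, 1)], [(1, 2)], [(2, 2)], [(1, 2)]],
            "c2": [[(2, 2)], [(2, 3)], [(3, 3)]],
            "c3": [[(1, 3)], [(1, 1)], [(3, 3)], [(1, 3)], [(1, 1)]],
        }
        t = table_from_genotypes(colonies)
        comp = variance_components(t)
        oracle = wc_components_single_locus(
            [[member[0] for member in col] for col in colonies.values()])
        alleles = sorted(oracle)
        for k, al in enumerate(alleles):
            a, b, c = oracle[al]
            assert comp.a[0][k] == pytest.approx(a, abs=1e-10)
            assert comp.b[0][k] == pytest.approx(b, abs=1e-10)
            assert comp.c[0][k] == pytest.approx(c, abs=1e-10)

    def test_fixed_colonies_maximal_differentiation(self):
        t = table_from_genotypes({"c1": [[(1, 1)]] * 5, "c2": [[(2, 2)]] * 5})
        comp = variance_components(t)
        est = hier_estimates(comp)
        assert sum(x.sum() for x in comp.c) == 0.0
        assert est.F_CT == pytest.approx(1.0)

    def test_all_heterozygous_excess_limit(self):
        t = table_from_genotypes({"c1": [[(1, 2)]] * 5, "c2": [[(1, 2)]] * 5})
        est = hier_estimates(variance_components(t))
        assert est.F_IT == pytest.approx(-1.0)

    def test_monomorphic_locus_contributes_zeros(self):
        t = table_from_genotypes({
            "c1": [[(1, 1), (1, 2)], [(1, 1), (2, 2)]],
            "c2": [[(1, 1), (1, 1)], [(1, 1), (1, 2)]],
        })
        comp = variance_components(t)
        assert comp.a[0].sum() == comp.b[0].sum() == comp.c[0].sum() == 0.0

    def test_all_monomorphic_errors(self):
        t = table_from_genotypes({"c1": [[(1, 1)]] * 3, "c2": [[(1, 1)]] * 3})
        with pytest.raises(ValueError, match="monomorphic"):
            hier_estimates(variance_components(t))


class TestHierEstimates:
    def test_algebraic_identities_exact(self, model):
        table, _ = simulate_population(breeding_system("b1"), model, 30, 15, 4)
        est = hier_estimates(variance_components(table))
        assert est.F_IC == pytest.approx(
            (est.F_IT - est.F_CT) / (1 - est.F_CT), abs=1e-12)
        assert est.r == pytest.approx(2 * est.F_CT / (1 + est.F_IT), abs=1e-15)

    def test_invariant_to_allele_relabeling(self, model):
        table, _ = simulate_population(breeding_system("a1"), model, 20, 10, 8)
        est1 = hier_estimates(variance_components(table))
        relab = table.alleles.copy()
        relab[relab > 0] = 11 - relab[relab > 0]  # bijection on 1..10
        t2 = GenotypeTable(relab, table.sample_ids, table.locus_names,
                           table.groups)
        est2 = hier_estimates(variance_components(t2))
        assert est1.F_CT == pytest.approx(est2.F_CT, abs=1e-12)
        assert est1.F_IT == pytest.approx(est2.F_IT, abs=1e-12)

    def test_panmictic_near_zero(self, model, rng):
        # no colony structure: random individuals labeled into fake colonies
        draws = model.draw_genotypes(400, rng)
        groups = np.repeat([f"c{i}" for i in range(20)], 20)
        t = GenotypeTable(draws, [f"s{i}" for i in range(400)],
                          [f"L{l+1}" for l in range(8)],
                          groups.astype(object))
        est = hier_estimates(variance_components(t))
        assert abs(est.F_CT) < 0.02 and abs(est.F_IT) < 0.03


class TestJackknife:
    def test_duplicated_colonies_near_zero_se(self, model, rng):
        draws = model.draw_genotypes(10, rng)
        block = np.tile(draws, (6, 1, 1))
        groups = np.repeat([f"c{i}" for i in range(6)], 10)
        t = GenotypeTable(block, [f"s{i}" for i in range(60)],
                          [f"L{l+1}" for l in range(8)], groups.astype(object))
        est = jackknife_se(t)
        assert est.se_F_CT == pytest.approx(0.0, abs=1e-9)

    def test_three_colonies_switch_to_loci(self, model):
        table, _ = simulate_population(breeding_system("a1"), model, 3, 10, 2)
        est = jackknife_se(table)
        assert est.jackknife_unit == "loci"

    def test_se_tracks_monte_carlo_sd(self, model):
        """Jackknife SE over 20 colonies within 2x of the replicate SD of the
        pooled estimator across independent populations."""
        reps = []
        for seed in range(12):
            table, _ = simulate_population(breeding_system("a1"), model, 20, 20,
                                           100 + seed)
            reps.append(hier_estimates(variance_components(table)).F_CT)
        mc_sd = np.std(reps, ddof=1)
        table, _ = simulate_population(breeding_system("a1"), model, 20, 20, 100)
        jk = jackknife_se(table).se_F_CT
        assert mc_sd / 2 < jk < mc_sd * 2


class TestPerColony:
    def test_clonal_colony_r_near_one(self, model, rng):
        draws = model.draw_genotypes(30, rng)
        clone = np.tile(model.draw_genotypes(1, rng), (10, 1, 1))
        # force the clone heterozygous everywhere so identity is visible
        clone[:, :, 0] = 1
        clone[:, :, 1] = 2
        alleles = np.concatenate([draws, clone])
        groups = np.array(["bg"] * 30 + ["clonal"] * 10, dtype=object)
        t = GenotypeTable(alleles, [f"s{i}" for i in range(40)],
                          [f"L{l+1}" for l in range(8)], groups)
        vals = per_colony_values(t).set_index("colony")
        assert vals.loc["clonal", "r"] > 0.8

    def test_mean_tracks_pooled_estimate(self, model):
        table, _ = simulate_population(breeding_system("a1"), model, 40, 20, 6)
        pooled = hier_estimates(variance_components(table))
        vals = per_colony_values(table)
        assert vals["F_CT"].mean() == pytest.approx(pooled.F_CT, abs=0.03)
        assert vals["r"].mean() == pytest.approx(pooled.r, abs=0.05)

    def test_pleometrosis_r_centered_near_reference(self, model):
        table, _ = simulate_population(breeding_system("e1"), model, 80, 20, 13)
        vals = per_colony_values(table)
        assert vals["r"].mean() == pytest.approx(0.38, abs=0.03)

    def test_single_worker_colony_excluded(self, model, rng):
        draws = model.draw_genotypes(21, rng)
        groups = np.array(["c1"] * 10 + ["c2"] * 10 + ["lone"], dtype=object)
        t = GenotypeTable(draws, [f"s{i}" for i in range(21)],
                          [f"L{l+1}" for l in range(8)], groups)
        with pytest.warns(UserWarning, match="lone"):
            vals = per_colony_values(t)
        assert "lone" not in set(vals["colony"])


class TestCompareToReference:
    def test_exact_match_degenerate(self):
        res = compare_to_reference([0.5, 0.5, 0.5], 0.5)
        assert res.iloc[0]["t"] == 0.0 and res.iloc[0]["p"] == 1.0

    def test_level_against_true_value(self, model):
        ns = 0
        for seed in range(20):
            table, _ = simulate_population(breeding_system("a1"), model, 20, 20,
                                           300 + seed)
            vals = per_colony_values(table)
            res = compare_to_reference(vals["F_IC"].to_numpy(), -1 / 3)
            ns += res.iloc[0]["p"] >= 0.05
        assert ns >= 17  # nominal level: expect ~1 rejection in 20

    def test_power_against_wrong_row(self, model):
        table, _ = simulate_population(breeding_system("a1"), model, 20, 20, 77)
        vals = per_colony_values(table)
        res = compare_to_reference(vals, REFERENCE_ROWS["a2"],
                                   parameters=("F_IC",))
        assert res.iloc[0]["p"] < 0.05  # -0.33 colonies vs the -0.14 row


class TestPairwiseFst:
    def test_identical_frequencies_near_zero(self, model, rng):
        draws = model.draw_genotypes(200, rng)
        groups = np.array(["p1"] * 100 + ["p2"] * 100, dtype=object)
        t = GenotypeTable(draws, [f"s{i}" for i in range(200)],
                          [f"L{l+1}" for l in range(8)], groups)
        mat, p = pairwise_fst(t, n_perm=200, seed=1)
        assert abs(mat.loc["p1", "p2"]) < 0.01
        assert p > 0.05

    def test_fixed_difference_theta_one(self):
        t = table_from_genotypes({"p1": [[(1, 1)]] * 6, "p2": [[(2, 2)]] * 6})
        mat, p = pairwise_fst(t, n_perm=200, seed=1)
        assert mat.loc["p1", "p2"] == pytest.approx(1.0)
        assert p < 0.05

    def test_recovers_island_model_divergence(self, rng):
        """Balding–Nichols draw: per-population allele frequencies Dirichlet
        around the ancestral spectrum with concentration (1-F)/F recovers
        theta ~ F."""
        F = 0.10
        n_loci, n_per = 10, 150
        anc = np.full(10, 0.1)
        blocks = []
        for _ in range(2):
            g = np.zeros((n_per, n_loci, 2), dtype=np.int32)
            for l in range(n_loci):
                p = rng.dirichlet(anc * (1 - F) / F)
                g[:, l, :] = rng.choice(np.arange(1, 11), (n_per, 2), p=p)
            blocks.append(g)
        groups = np.array(["p1"] * n_per + ["p2"] * n_per, dtype=object)
        t = GenotypeTable(np.concatenate(blocks),
                          [f"s{i}" for i in range(2 * n_per)],
                          [f"L{l+1}" for l in range(n_loci)], groups)
        mat, _ = pairwise_fst(t, n_perm=100, seed=0)
        assert mat.loc["p1", "p2"] == pytest.approx(F, abs=0.05)

    def test_small_group_excluded(self, model, rng):
        draws = model.draw_genotypes(21, rng)
        groups = np.array(["p1"] * 10 + ["p2"] * 10 + ["tiny"], dtype=object)
        t = GenotypeTable(draws, [f"s{i}" for i in range(21)],
                          [f"L{l+1}" for l in range(8)], groups)
        with pytest.warns(UserWarning, match="tiny"):
            mat, _ = pairwise_fst(t, n_perm=100, seed=0)
        assert "tiny" not in mat.index
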