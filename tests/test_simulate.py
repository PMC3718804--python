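import numpy as np
import pytest
from scipy import stats

from colonykin.simulate import (BreedingSystemSpec, MixSpec,
                                SourcePopulationModel, automictic_offspring,
                                breed_generation, draw_founders, run_colony,
                                simulate_population, breeding_system)
from colonykin.genotypes import MISSING


class TestFounders:
    def test_outbred_pair_shapes(self, model, rng):
        q, k = draw_founders(BreedingSystemSpec(), model, rng)
        assert q.shape == (1, 8, 2) and k.shape == (1, 8, 2)

    def test_pleometrosis_founder_count(self, model, rng):
        spec = BreedingSystemSpec(n_founding_queens=2, n_founding_kings=1)
        q, k = draw_founders(spec, model, rng)
        assert len(q) == 2 and len(k) == 1

    def test_nestmate_sib_coancestry(self, model, rng):
        # pedigree coancestry of full sibs is 1/4: with 10 equifrequent
        # alleles, P(two random gene copies identical in state)
        # = theta + (1-theta) * 0.1 = 0.325
        hits = tot = 0
        for _ in range(400):
            q, k = draw_founders(
                BreedingSystemSpec(founder_relation="nestmate_sibs"), model, rng)
            pick_q = q[0, np.arange(8), rng.integers(0, 2, 8)]
            pick_k = k[0, np.arange(8), rng.integers(0, 2, 8)]
            hits += (pick_q == pick_k).sum()
            tot += 8
        assert hits / tot == pytest.approx(0.325, abs=0.03)

    def test_unknown_pedigree_tag_lists_registered(self, model, rng):
        with pytest.raises(ValueError, match="sib_line_1"):
            draw_founders(BreedingSystemSpec(founder_relation="nope"),
                          model, rng)


class TestBreeding:
    def test_forced_heterozygosity(self, rng):
        dams = np.full((1, 4, 2), 1, dtype=np.int32)
        sires = np.full((1, 4, 2), 2, dtype=np.int32)
        off, _, _ = breed_generation(dams, sires, 50, rng)
        assert np.all(np.sort(off, axis=2) == [1, 2])

    def test_mendelian_ratio_1_2_1(self, rng):
        dams = np.array([[[1, 2]]], dtype=np.int32)
        sires = np.array([[[1, 2]]], dtype=np.int32)
        off, _, _ = breed_generation(dams, sires, 10_000, rng)
        pairs = np.sort(off[:, 0, :], axis=1)
        counts = [int(((pairs == [a, b]).all(axis=1)).sum())
                  for a, b in [(1, 1), (1, 2), (2, 2)]]
        chi2, p = stats.chisquare(counts, f_exp=[2500, 5000, 2500])
        assert p > 0.001

    def test_uniform_dam_choice(self, rng):
        dams = np.zeros((2, 1, 2), dtype=np.int32) + 1
        sires = np.zeros((1, 1, 2), dtype=np.int32) + 2
        _, di, _ = breed_generation(dams, sires, 20_000, rng)
        # fraction of offspring pairs sharing a dam ~ 1/2
        frac_same = (di[:10_000] == di[10_000:]).mean()
        assert frac_same == pytest.approx(0.5, abs=0.02)

    def test_no_males_errors(self, rng):
        with pytest.raises(ValueError, match="each sex"):
            breed_generation(np.ones((1, 2, 2), np.int32),
                             np.empty((0, 2, 2), np.int32), 5, rng)


class TestColony:
    def test_simple_family_workers_are_full_sibs(self, model, rng):
        col = run_colony(breeding_system("a1"), model, 20, rng)
        assert len(col.workers) == 20
        assert np.all(col.worker_parents == 0)  # single dam, single sire
        # gene-dropping audit: every worker allele traces to a founder allele
        for l in range(8):
            assert set(col.workers[:, l, :].ravel()) <= \
                set(col.founders[:, l, :].ravel())

    def test_extended_family_audit(self, model, rng):
        col = run_colony(breeding_system("b3"), model, 20, rng)
        assert len(col.neotenics) == 20  # 10 females + 10 males, X=1
        for l in range(8):
            assert set(col.workers[:, l, :].ravel()) <= \
                set(col.founders[:, l, :].ravel())

    def test_brood_smaller_than_replacements_errors(self, model, rng):
        with pytest.raises(ValueError, match="brood smaller"):
            run_colony(breeding_system("b3"), model, 10, rng, brood_size=5)

    def test_parthenogenetic_females_always_fully_homozygous(self, model, rng):
        spec = BreedingSystemSpec(N_f=5, N_m=5, X=2,
                                  parthenogenetic_neotenics=True)
        col = run_colony(spec, model, 10, rng)
        females = [n for n in col.neotenics if n["sex"] == "female"]
        assert len(females) == 10
        for n in females:
            g = n["genotype"]
            assert np.all(g[:, 0] == g[:, 1])

    def test_automixis_draws_one_maternal_allele(self, rng):
        dam = np.array([[[3, 7]]] , dtype=np.int32)
        off = automictic_offspring(dam, 200, rng)
        assert set(off[:, 0, 0]) == {3, 7}
        assert np.all(off[:, 0, 0] == off[:, 0, 1])

    def test_mixing_draws_from_two_colonies(self, model, rng):
        spec = breeding_system("c")  # unrelated mixing, p = 0.8
        col = run_colony(spec, model, 20, rng)
        assert len(col.workers) == 20
        assert col.spec.family_type == "mixed"


class TestPopulation:
    def test_truth_labels(self, model):
        table, truth = simulate_population(breeding_system("a1"), model, 10, 5, 3)
        assert table.n_samples == 50
        assert set(truth["family_type"]) == {"simple"}
        assert truth.shape[0] == 10

    def test_seed_determinism(self, model):
        t1, _ = simulate_population(breeding_system("e2"), model, 5, 10, 42)
        t2, _ = simulate_population(breeding_system("e2"), model, 5, 10, 42)
        assert np.array_equal(t1.alleles, t2.alleles)
        assert t1.sample_ids == t2.sample_ids

    def test_null_alleles_inflate_homozygosity(self):
        model = SourcePopulationModel(null_allele_freq=0.2)
        table, _ = simulate_population(breeding_system("a1"), model, 150, 10, 11)
        reps = np.arange(0, table.n_samples, 10)  # one worker per colony
        pairs = table.alleles[reps, 0, :]
        ok = pairs[:, 0] != MISSING
        assert ok.mean() < 1.0  # null homozygotes went missing
        ho = (pairs[ok, 0] != pairs[ok, 1]).mean()
        genes = pairs[ok].ravel()
        p = np.bincount(genes) / genes.size
        he = 1 - (p ** 2).sum()
        assert ho < he - 0.05  # apparent-homozygote inflation

    def test_missing_at_random(self):
        model = SourcePopulationModel(missing_rate=0.3)
        table, _ = simulate_population(breeding_system("a1"), model, 10, 10, 1)
        assert 0.2 < table.missing.mean() < 0.4

    def test_mixed_truth_label(self, model):
        _, truth = simulate_population(breeding_system("c"), model, 3, 5, 0)
        assert set(truth["family_type"]) == {"mixed"}

    def test_too_few_colonies(self, model):
        with pytest.raises(ValueError, match="two colonies"):
            simulate_population(breeding_system("a1"), model, 1, 5, 0)
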