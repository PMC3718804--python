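import numpy as np
import pytest

from colonykin.diversity import (hwe_test, ld_test, null_allele_estimate,
                                 one_per_colony, private_alleles, summarize,
                                 unbiased_he)
from colonykin.genotypes import GenotypeTable
from colonykin.simulate import (SourcePopulationModel, simulate_population,
                                breeding_system)

from conftest import table_from_genotypes


def _single_pop(genos):
    return table_from_genotypes({"p": genos})


class TestSummarize:
    def test_unbiased_he_hand_value(self):
        # allele counts {5, 5} in 5 diploids: He = (10/9)(1 - 0.5) = 0.5556
        assert unbiased_he(np.array([5.0, 5.0])) == pytest.approx(10 / 18)

    def test_all_homozygous_population(self):
        t = table_from_genotypes({
            "c1": [[(1, 1)]] * 2, "c2": [[(2, 2)]] * 2, "c3": [[(1, 1)]] * 2})
        s = summarize(t).iloc[0]
        assert s["H_O"] == 0.0 and s["n_colonies"] == 3

    def test_one_per_colony_is_seeded(self, model):
        table, _ = simulate_population(breeding_system("a1"), model, 10, 10, 3)
        assert np.array_equal(one_per_colony(table, seed=5),
                              one_per_colony(table, seed=5))
        s1 = summarize(table, seed=5)
        s2 = summarize(table, seed=5)
        assert s1.equals(s2)

    def test_diversity_of_outbred_source(self, model, rng):
        # one random worker per colony from outbred founders: H_E near the
        # source value (10 equifrequent alleles -> 0.9), F_IS near 0
        table, _ = simulate_population(breeding_system("a1"), model, 150, 5, 17)
        s = summarize(table, seed=1).iloc[0]
        assert s["H_E"] == pytest.approx(0.9, abs=0.03)
        assert abs(s["F_IS"]) < 0.06


class TestHWE:
    def test_perfect_proportions_not_rejected(self):
        genos = [[(1, 1)]] * 25 + [[(1, 2)]] * 50 + [[(2, 2)]] * 25
        t = _single_pop(genos)
        p = hwe_test(t, np.arange(100), 0, n_shuffles=300, seed=0)
        assert p > 0.5

    def test_all_heterozygotes_rejected(self):
        t = _single_pop([[(1, 2)]] * 40)
        p = hwe_test(t, np.arange(40), 0, n_shuffles=300, seed=0)
        assert p < 0.02

    def test_monomorphic_p_one(self):
        t = _single_pop([[(1, 1)]] * 10)
        assert hwe_test(t, np.arange(10), 0, n_shuffles=300, seed=0) == 1.0

    def test_too_few_individuals(self):
        t = _single_pop([[(1, 2)]] * 3)
        with pytest.raises(ValueError, match=">= 5"):
            hwe_test(t, np.arange(3), 0)

    def test_null_allele_locus_rejected_often(self):
        model = SourcePopulationModel(null_allele_freq=0.2)
        rej = trials = 0
        for seed in range(15):
            table, _ = simulate_population(breeding_system("a1"), model, 60, 5,
                                           400 + seed)
            reps = one_per_colony(table, seed=seed)
            try:
                p = hwe_test(table, reps, 0, n_shuffles=300, seed=seed)
            except ValueError:
                continue
            rej += p <= 0.05
            trials += 1
        assert rej / trials > 0.5  # heterozygote deficit: far above the 5% level


class TestLD:
    def test_duplicated_locus_floor(self, model, rng):
        draws = model.draw_genotypes(40, rng)[:, :1, :]
        dup = np.concatenate([draws, draws], axis=1)
        t = GenotypeTable(dup, [f"s{i}" for i in range(40)], ["L1", "L2"],
                          np.array(["p"] * 40, dtype=object))
        p = ld_test(t, np.arange(40), (0, 1), n_shuffles=300, seed=0)
        assert p == pytest.approx(1 / 301, abs=1e-9)

    def test_independent_loci_uniform_p(self, rng):
        ps = []
        for rep in range(80):
            genes = rng.integers(1, 3, size=(60, 2, 2)).astype(np.int32)
            t = GenotypeTable(genes, [f"s{i}" for i in range(60)],
                              ["L1", "L2"], np.array(["p"] * 60, dtype=object))
            ps.append(ld_test(t, np.arange(60), (0, 1), n_shuffles=150,
                              seed=rng))
        from scipy import stats
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_single_individual_errors(self):
        t = _single_pop([[(1, 2), (1, 2)]])
        with pytest.raises(ValueError):
            ld_test(t, [0], (0, 1))


class TestNullAlleles:
    def _deficit_table(self):
        # He ~ 0.66, Ho = 0.3: clear heterozygote deficit
        genos = ([[(1, 1)]] * 14 + [[(2, 2)]] * 14 + [[(3, 3)]] * 7
                 + [[(1, 2)]] * 9 + [[(1, 3)]] * 3 + [[(2, 3)]] * 3)
        return _single_pop(genos), len(genos)

    def test_brookfield_formula(self):
        t, n = self._deficit_table()
        rep = null_allele_estimate(t, np.arange(n), 0, "brookfield1")
        pairs = t.alleles[:, 0, :]
        counts = np.bincount(pairs.ravel())[1:].astype(float)
        he = unbiased_he(counts)
        ho = (pairs[:, 0] != pairs[:, 1]).mean()
        assert rep.estimated_null_freq == pytest.approx((he - ho) / (1 + he))

    def test_chakraborty_formula(self):
        t, n = self._deficit_table()
        rep = null_allele_estimate(t, np.arange(n), 0, "chakraborty")
        pairs = t.alleles[:, 0, :]
        counts = np.bincount(pairs.ravel())[1:].astype(float)
        he = unbiased_he(counts)
        ho = (pairs[:, 0] != pairs[:, 1]).mean()
        assert rep.estimated_null_freq == pytest.approx((he - ho) / (he + ho))

    def test_no_deficit_no_report(self):
        t = _single_pop([[(1, 2)]] * 10 + [[(1, 1)]] * 2)
        assert null_allele_estimate(t, np.arange(12), 0, "brookfield1") is None

    @pytest.mark.parametrize("estimator",
                             ["brookfield1", "chakraborty", "oosterhout"])
    def test_recovers_simulated_null_frequency(self, estimator):
        model = SourcePopulationModel(null_allele_freq=0.2)
        ests = []
        for seed in range(10):
            table, _ = simulate_population(breeding_system("a1"), model, 120, 5,
                                           700 + seed)
            reps = one_per_colony(table, seed=seed)
            rep = null_allele_estimate(table, reps, 0, estimator)
            if rep is not None:
                ests.append(rep.estimated_null_freq)
        assert np.mean(ests) == pytest.approx(0.2, abs=0.08)


class TestPrivateAlleles:
    def test_identical_sets(self):
        t = _single_pop([[(1, 2)]] * 4)
        assert private_alleles(t, [0, 1], [2, 3]) == (0, 0)

    def test_disjoint_single_allele_loci(self):
        t = table_from_genotypes({
            "a": [[(1, 1), (3, 3)]] * 2, "b": [[(2, 2), (4, 4)]] * 2})
        assert private_alleles(t, [0, 1], [2, 3]) == (2, 2)

    def test_matches_manual_set_difference(self, model, rng):
        table, _ = simulate_population(breeding_system("a1"), model, 10, 5, 31)
        a = np.arange(0, 25)
        b = np.arange(25, 50)
        got = private_alleles(table, a, b)
        exp_a = exp_b = 0
        for l in range(table.n_loci):
            sa, sb = set(), set()
            for i in a:
                for al in table.alleles[i, l]:
                    if al:
                        sa.add(int(al))
            for i in b:
                for al in table.alleles[i, l]:
                    if al:
                        sb.add(int(al))
            exp_a += len(sa - sb)
            exp_b += len(sb - sa)
        assert got == (exp_a, exp_b)
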