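from itertools import combinations, permutations

import numpy as np
import pytest

from colonykin.genotypes import GenotypeTable
from colonykin.ibd import (colony_pair_fst, haversine_m, ibd_analysis, mantel)
from colonykin.simulate import (SourcePopulationModel, simulate_population,
                                stepping_stone_frequencies, breeding_system)

from conftest import table_from_genotypes
from wc_oracle import wc_components_single_locus


def test_haversine_reference_distance():
    # one degree of latitude is ~111.2 km everywhere
    assert haversine_m(30.0, 114.0, 31.0, 114.0) == pytest.approx(111_195, rel=0.01)
    assert haversine_m(30.0, 114.0, 30.0, 114.0) == 0.0


class TestMantel:
    def _random_sym(self, n, rng):
        m = rng.random((n, n))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 0)
        return m

    def test_affine_transform_perfect_correlation(self, rng):
        m1 = self._random_sym(6, rng)
        m2 = 3.0 * m1 + 1.0
        np.fill_diagonal(m2, 0)
        res = mantel(m1, m2, n_perm=400, seed=0)
        assert res.r == pytest.approx(1.0)
        assert res.p == pytest.approx(1 / 401, abs=1e-9)

    @pytest.mark.parametrize("n", [4, 5])
    def test_matches_exhaustive_relabeling(self, n, rng):
        m1 = self._random_sym(n, rng)
        m2 = self._random_sym(n, rng)

        def corr(perm):
            iu = np.triu_indices(n, 1)
            return np.corrcoef(m1[iu], m2[np.ix_(perm, perm)][iu])[0, 1]

        r_obs = corr(list(range(n)))
        vals = [corr(list(p)) for p in permutations(range(n))]
        exact = sum(v >= r_obs - 1e-12 for v in vals) / len(vals)
        res = mantel(m1, m2, n_perm=8000, seed=1)
        assert res.r == pytest.approx(r_obs, abs=1e-12)
        assert res.p == pytest.approx(exact, abs=0.02)

    def test_requires_symmetric_square(self):
        with pytest.raises(ValueError):
            mantel(np.zeros((4, 3)), np.zeros((4, 3)))
        bad = np.arange(16).reshape(4, 4).astype(float)
        with pytest.raises(ValueError, match="symmetric"):
            mantel(bad, bad)

    def test_zero_variance_errors(self, rng):
        flat = np.ones((5, 5)) - np.eye(5)
        with pytest.raises(ValueError, match="variance"):
            mantel(flat, self._random_sym(5, rng))

    def test_too_few_objects(self):
        m = np.zeros((3, 3))
        with pytest.raises(ValueError, match=">= 4"):
            mantel(m, m)


class TestColonyPairFst:
    def test_same_source_colonies_near_zero(self, model, rng):
        # two samples from one panmictic source: theta centred on 0 (literal
        # duplication would bias slightly negative, as the estimator removes
        # the expected sampling variance)
        alleles = model.draw_genotypes(80, rng)
        groups = np.array(["c1"] * 40 + ["c2"] * 40, dtype=object)
        t = GenotypeTable(alleles, [f"s{i}" for i in range(80)],
                          [f"L{l+1}" for l in range(8)], groups)
        mat = colony_pair_fst(t)
        assert abs(mat.loc["c1", "c2"]) < 0.02

    def test_matches_component_oracle_on_toy_pair(self):
        colonies = {"c1": [[(1, 1)], [(1, 2)], [(2, 2)]],
                    "c2": [[(2, 2)], [(2, 3)], [(3, 3)], [(2, 3)]]}
        t = table_from_genotypes(colonies)
        mat = colony_pair_fst(t)
        oracle = wc_components_single_locus(
            [[m[0] for m in col] for col in colonies.values()])
        sa = sum(v[0] for v in oracle.values())
        tot = sum(sum(v) for v in oracle.values())
        assert mat.loc["c1", "c2"] == pytest.approx(sa / tot, abs=1e-10)

    def test_negative_estimates_retained(self, model):
        table, _ = simulate_population(breeding_system("a1"), model, 6, 10, 12)
        mat = colony_pair_fst(table)
        # same-source colonies: estimates scatter around their expectation and
        # are not truncated at zero from below across all pairs
        off = mat.to_numpy()[np.triu_indices(6, 1)]
        assert np.isfinite(off).all()


class TestIbdAnalysis:
    def _spatial_population(self, seed, shuffle_coords=False):
        model = SourcePopulationModel(k_alleles=8)
        demes = stepping_stone_frequencies(10, model, deme_size=60,
                                           migration=0.03, generations=80,
                                           seed=seed)
        rng = np.random.default_rng(seed + 1)
        n_col = 12
        pos = np.linspace(0, 500, n_col)
        deme_of = np.minimum((pos / 500 * 10).astype(int), 9)
        specs = [breeding_system("a1")] * n_col
        models = [demes[d] for d in deme_of]
        table, _ = simulate_population(specs, models, n_col, 10, seed + 2)
        order = rng.permutation(n_col) if shuffle_coords else np.arange(n_col)
        coords = {f"c{j:04d}": (30.0 + pos[order[j]] / 111_320.0, 114.0)
                  for j in range(n_col)}
        return table, coords

    def test_stepping_stone_positive_signal(self):
        table, coords = self._spatial_population(seed=5)
        res, pairs = ibd_analysis(table, coords=coords, n_perm=500, seed=0)
        assert res.r > 0
        assert res.p < 0.05
        assert len(pairs) == 12 * 11 // 2

    def test_shuffling_coordinates_destroys_signal(self):
        rs = []
        for seed in (5, 6, 7):
            table, coords = self._spatial_population(seed=seed,
                                                     shuffle_coords=True)
            res, _ = ibd_analysis(table, coords=coords, n_perm=300, seed=1)
            rs.append(res.p)
        assert min(rs) > 0.001 and max(rs) > 0.1

    def test_island_model_nominal_level(self, model):
        """With no spatial structure the Mantel test rejects at ~alpha."""
        rej = 0
        for seed in range(15):
            table, _ = simulate_population(breeding_system("a1"), model, 8, 10,
                                           800 + seed)
            rng = np.random.default_rng(seed)
            coords = {f"c{j:04d}": (30.0 + rng.uniform(0, 0.005), 114.0)
                      for j in range(8)}
            res, _ = ibd_analysis(table, coords=coords, n_perm=300, seed=2)
            rej += res.p <= 0.05
        assert rej <= 4  # 15 null tests at the 5% level

    def test_coincident_coordinates_dropped(self, model):
        table, _ = simulate_population(breeding_system("a1"), model, 5, 10, 3)
        coords = {f"c{j:04d}": (30.0 + j * 1e-4, 114.0) for j in range(5)}
        coords["c0001"] = coords["c0000"]  # duplicate position
        with pytest.warns(UserWarning, match="share coordinates"):
            res, pairs = ibd_analysis(table, coords=coords, n_perm=300, seed=0)
        assert len(pairs) == 4 * 3 // 2
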