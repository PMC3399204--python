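"""Heterozygosity, rarefied allelic richness, signed-rank comparison."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats

from islandgen.core import GenotypeMatrix, allele_frequencies
from islandgen.diversity import (
    allelic_richness,
    expected_heterozygosity,
    observed_heterozygosity,
    population_summary,
    wilcoxon_richness_test,
)
from islandgen.synth import PopScenario, generate_genotypes

from conftest import random_genotype_matrix


def _single_locus(genotypes):
    calls = np.array(genotypes).reshape(-1, 1, 2)
    n = calls.shape[0]
    return GenotypeMatrix(
        [f"i{k}" for k in range(n)], ["L"], ["p"] * n, calls
    )


class TestHeterozygosity:
    def test_all_heterozygous(self):
        gm = _single_locus([(1, 2), (1, 2)])
        assert observed_heterozygosity(gm, "p").mean == 1.0

    def test_all_homozygous(self):
        gm = _single_locus([(1, 1), (2, 2)])
        assert observed_heterozygosity(gm, "p").mean == 0.0

    def test_observed_matches_direct_count(self):
        gm = random_genotype_matrix(7, n_per_pop=25)
        res = observed_heterozygosity(gm, "pop1")
        for j, locus in enumerate(gm.loci):
            idx = [i for i, p in enumerate(gm.populations) if p == "pop1"]
            g = gm.calls[idx, j, :]
            g = g[(g != 0).all(axis=1)]
            assert res.per_locus[locus] == pytest.approx(
                (g[:, 0] != g[:, 1]).mean()
            )

    def test_expected_monomorphic_is_zero(self):
        gm = _single_locus([(1, 1), (1, 1)])
        assert expected_heterozygosity(gm, "p").mean == 0.0

    def test_expected_unbiased_small_sample(self):
        # n=2, p=(0.5,0.5): (4/3) * 0.5 = 2/3
        gm = _single_locus([(1, 2), (1, 2)])
        assert expected_heterozygosity(gm, "p").mean == pytest.approx(2 / 3)

    def test_expected_converges_to_gene_diversity(self):
        rng = np.random.default_rng(11)
        genotypes = rng.integers(1, 3, size=(5000, 2))
        gm = _single_locus(list(map(tuple, genotypes)))
        assert expected_heterozygosity(gm, "p").mean == pytest.approx(
            0.5, abs=0.02
        )


class TestAllelicRichness:
    def test_full_sample_equals_allele_count(self):
        gm = _single_locus([(1, 2), (3, 3)])
        assert allelic_richness(gm, "p", g=4).mean == pytest.approx(3.0)

    def test_monomorphic_is_one_for_any_g(self):
        gm = _single_locus([(1, 1), (1, 1), (1, 1)])
        for g in (2, 4, 6):
            assert allelic_richness(gm, "p", g=g).mean == pytest.approx(1.0)

    @pytest.mark.parametrize(
        "genotypes", [[(1, 2), (1, 3), (1, 1)], [(1, 1), (2, 2), (3, 4)]]
    )
    @pytest.mark.parametrize("g", [2, 3, 4, 5])
    def test_matches_exhaustive_subsampling(self, genotypes, g):
        # 6-gene toy locus: average allele count over all C(6, g) subsamples
        gm = _single_locus(genotypes)
        genes = [a for pair in genotypes for a in pair]
        brute = np.mean(
            [len(set(sub)) for sub in itertools.combinations(genes, g)]
        )
        assert allelic_richness(gm, "p", g=g).mean == pytest.approx(brute)

    def test_non_decreasing_in_g(self):
        gm = random_genotype_matrix(3, n_per_pop=15)
        values = [allelic_richness(gm, "pop1", g=g).mean for g in range(2, 20)]
        assert all(b >= a - 1e-12 for a, b in zip(values, values[1:]))

    def test_g_exceeding_gene_count_names_locus(self):
        gm = _single_locus([(1, 2), (1, 3)])
        with pytest.raises(ValueError, match="L"):
            allelic_richness(gm, "p", g=6)


class TestWilcoxonRichness:
    def test_identical_vectors_not_applicable(self):
        x = np.arange(13, dtype=float)
        assert wilcoxon_richness_test(x, x) is None

    def test_uniform_shift_gives_smallest_exact_p(self):
        x = np.linspace(1, 5, 13)
        p = wilcoxon_richness_test(x + 1, x)
        assert p == pytest.approx(2 / 2**13)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=10)
        y = rng.normal(size=10)
        p = wilcoxon_richness_test(x, y)
        # enumerate all sign patterns of the rank sum
        d = x - y
        d = d[d != 0]
        ranks = stats.rankdata(np.abs(d))
        w_obs = ranks[d > 0].sum()
        ws = [
            sum(r for r, s in zip(ranks, signs) if s)
            for signs in itertools.product([0, 1], repeat=len(d))
        ]
        ws = np.array(ws)
        lower = (ws <= w_obs + 1e-9).mean()
        upper = (ws >= w_obs - 1e-9).mean()
        assert p == pytest.approx(min(1.0, 2 * min(lower, upper)))

    @pytest.mark.parametrize("seed", range(3))
    def test_agrees_with_scipy_exact_when_tie_free(self, seed):
        rng = np.random.default_rng(seed + 100)
        x = rng.normal(size=12)
        y = rng.normal(size=12)
        expected = stats.wilcoxon(x, y, method="exact").pvalue
        assert wilcoxon_richness_test(x, y) == pytest.approx(expected)


class TestPopulationSummary:
    def test_population_of_clones_degenerates(self):
        calls = np.tile([[1, 1], [2, 2]], (6, 1)).reshape(6, 2, 2)
        gm = GenotypeMatrix(
            [f"i{k}" for k in range(6)], ["L1", "L2"], ["p"] * 6, calls
        )
        s = population_summary(gm, "p", g=2, seed=0)
        assert s.a == 1.0
        assert s.r == pytest.approx(1.0)
        assert s.H_O == 0.0
        assert s.H_E == 0.0
        assert s.F_IS is None
        assert s.hwe_p is None

    def test_hwe_population_has_matching_ho_he(self, source_frequencies):
        sc = PopScenario(
            ["p"], [400], {"p": source_frequencies}, F_IS=0.0, seed=5
        )
        gm = generate_genotypes(sc)
        s = population_summary(gm, "p", seed=1, hwe_steps=2000)
        assert s.H_O == pytest.approx(s.H_E, abs=0.03)
        assert abs(s.F_IS) < 0.03

    def test_mostly_fixed_panel_reports_monomorphic_count(self):
        # 8 of 13 loci fixed, like a long-isolated island population
        rng = np.random.default_rng(9)
        calls = np.empty((20, 13, 2), dtype=np.int64)
        for j in range(13):
            if j < 8:
                calls[:, j, :] = 1
            else:
                calls[:, j, :] = rng.integers(1, 3, size=(20, 2))
        gm = GenotypeMatrix(
            [f"i{k}" for k in range(20)],
            [f"L{j}" for j in range(13)],
            ["island"] * 20,
            calls,
        )
        s = population_summary(gm, "island", seed=0)
        assert len(s.monomorphic) == 8


class TestOrderingInvariance:
    def test_statistics_invariant_to_individual_order(self):
        gm = random_genotype_matrix(21, n_per_pop=10)
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(gm.individuals))
        shuffled = GenotypeMatrix(
            [gm.individuals[i] for i in perm],
            gm.loci,
            [gm.populations[i] for i in perm],
            gm.calls[perm],
        )
        a = observed_heterozygosity(gm, "pop2").mean
        b = observed_heterozygosity(shuffled, "pop2").mean
        assert a == b
        assert expected_heterozygosity(gm, "pop2").mean == pytest.approx(
            expected_heterozygosity(shuffled, "pop2").mean
        )

    def test_statistics_invariant_to_allele_relabeling(self):
        gm = random_genotype_matrix(22, n_per_pop=10, max_allele=5)
        relabel = {0: 0, 1: 11, 2: 7, 3: 29, 4: 5, 5: 13}
        calls = np.vectorize(relabel.get)(gm.calls)
        renamed = GenotypeMatrix(
            gm.individuals, gm.loci, gm.populations, calls
        )
        for pop in gm.population_set:
            assert expected_heterozygosity(gm, pop).mean == pytest.approx(
                expected_heterozygosity(renamed, pop).mean
            )
            assert allelic_richness(gm, pop, g=6).mean == pytest.approx(
                allelic_richness(renamed, pop, g=6).mean
            )
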