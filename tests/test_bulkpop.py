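"""Meiosis, mating, and population propagation."""
import numpy as np
import pytest
from scipy import stats

from cexqtl.bulkpop import (
    FEMALE,
    MALE,
    ExtinctionError,
    Haplotype,
    Individual,
    Population,
    SimConfig,
    _join_at,
    _transmit,
    expand_pool,
    make_gamete,
    mate,
    propagate,
    simulate_cross,
)
from cexqtl.genome import ALLELE_A, ALLELE_B, ChromosomeMap, GeneticMap, MarkerGrid
from cexqtl.selection import FitnessLocus


def het_female(gmap):
    return Individual(Haplotype.pure(ALLELE_A, gmap), Haplotype.pure(ALLELE_B, gmap), FEMALE)


def het_male(gmap):
    x = gmap.x_name
    autos = [c for c in gmap.names if c != x]
    return Individual(Haplotype.pure(ALLELE_A, gmap),
                      Haplotype.pure(ALLELE_B, gmap, autos), MALE)


class TestMakeGamete:
    def test_breakpoint_fraction_is_half(self, gmap, rng):
        parent = het_female(gmap)
        n = 10_000
        hits = sum(make_gamete(parent, gmap, rng).n_breakpoints("chr1") > 0
                   for _ in range(n))
        sd = np.sqrt(0.25 / n)
        assert abs(hits / n - 0.5) < 3 * sd

    def test_homozygous_parent_transmits_identically(self, gmap, rng):
        parent = Individual(Haplotype.pure(ALLELE_A, gmap),
                            Haplotype.pure(ALLELE_A, gmap), FEMALE)
        for _ in range(50):
            gam = make_gamete(parent, gmap, rng)
            for chrom in gmap.names:
                assert gam.segments[chrom] == parent.hap1.segments[chrom]

    def test_recombinant_fraction_matches_map_distance(self, rng):
        # two markers 10 cM apart on a 50 cM chromosome: under a single
        # uniform crossover at rate 0.5, recombinant fraction = 0.5 * 10/50
        gmap = GeneticMap({"c": ChromosomeMap("c", [1, 1_000_000], [0.0, 50.0])})
        bp = [gmap["c"].cm_to_bp(20.0), gmap["c"].cm_to_bp(30.0)]
        n = 100_000
        start, xo = rng.integers(0, 2, n).astype(np.int8), np.where(
            rng.random(n) < 0.5, rng.random(n) * 50.0, np.inf)
        haps = np.tile(np.array([[0, 0], [1, 1]], dtype=np.int8), (n, 1, 1))
        gam = _transmit(haps, start, xo, np.array([20.0, 30.0]))
        rec = np.mean(gam[:, 0] != gam[:, 1])
        sd = np.sqrt(0.1 * 0.9 / n)
        assert abs(rec - 0.10) < 3 * sd

    def test_object_and_vector_meiosis_agree_given_same_draws(self, gmap, markers, rng):
        parent = het_female(gmap)
        sl = markers.chrom_slices()["chr1"]
        cm = markers.cm[sl]
        for _ in range(25):
            start = int(rng.integers(2))
            xo_cm = float(rng.uniform(*gmap["chr1"].cm_span))
            xo_bp = gmap["chr1"].cm_to_bp(xo_cm)
            haps = [parent.hap1, parent.hap2]
            segs = _join_at(haps[start], haps[1 - start], "chr1", xo_bp)
            obj = Haplotype({"chr1": segs}, gmap).to_vector(markers)[sl]
            parent_arr = np.stack([np.zeros(len(cm), np.int8),
                                   np.ones(len(cm), np.int8)])[None]
            vec = _transmit(parent_arr, np.array([start], np.int8),
                            np.array([xo_cm]), cm)[0]
            np.testing.assert_array_equal(obj, vec)

    def test_segments_tile_chromosome_after_meiosis(self, gmap, rng):
        parent = het_female(gmap)
        for _ in range(200):
            gam = make_gamete(parent, gmap, rng)
            gam.validate()  # raises if segments do not tile the span

    def test_unknown_chromosome_is_config_error(self, gmap, rng):
        parent = het_female(gmap)
        parent.hap1.segments["chrZ"] = [(100, ALLELE_A)]
        with pytest.raises(KeyError, match="chrZ"):
            make_gamete(parent, gmap, rng, chroms=["chrZ"])


class TestMate:
    def test_f1_cross_is_fully_heterozygous_on_autosomes(self, gmap, markers, rng):
        mother = Individual(Haplotype.pure(ALLELE_A, gmap),
                            Haplotype.pure(ALLELE_A, gmap), FEMALE)
        x = gmap.x_name
        father = Individual(Haplotype.pure(ALLELE_B, gmap),
                            Haplotype.pure(ALLELE_B, gmap, [c for c in gmap.names if c != x]),
                            MALE)
        progeny = mate(mother, father, 20, gmap, rng)
        sl = markers.chrom_slices()
        for child in progeny:
            for chrom in gmap.names:
                if chrom == x:
                    continue
                v1 = child.hap1.to_vector(markers)[sl[chrom]]
                v2 = child.hap2.to_vector(markers)[sl[chrom]]
                assert np.all(v1 == ALLELE_A) and np.all(v2 == ALLELE_B)

    def test_sex_ratio_is_mendelian(self, gmap, rng):
        mother, father = het_female(gmap), het_male(gmap)
        n = 10_000
        females = sum(c.sex == FEMALE for c in mate(mother, father, n, gmap, rng))
        assert abs(females / n - 0.5) < 3 * np.sqrt(0.25 / n)

    def test_males_receive_x_only_from_mother(self, gmap, rng):
        mother = Individual(Haplotype.pure(ALLELE_A, gmap),
                            Haplotype.pure(ALLELE_A, gmap), FEMALE)
        father = het_male(gmap)
        x = gmap.x_name
        for child in mate(mother, father, 50, gmap, rng):
            if child.sex == MALE:
                assert x not in child.hap2.segments
                assert child.hap1.origin_at(x, 1000) == ALLELE_A

    def test_same_sex_pairing_rejected(self, gmap, rng):
        with pytest.raises(ValueError, match="female mother and a male father"):
            mate(het_female(gmap), het_female(gmap), 1, gmap, rng)

    def test_f2_genotypes_are_one_two_one(self, gmap, markers, rng):
        # F1 x F1 (vectorised engine): autosomal genotype counts ~ 1:2:1
        pop = Population.f1_founders(2_000, markers, rng)
        cfg = SimConfig(pop_cap=10_000, f1_founders=2_000, progeny_per_female=10)
        f2 = propagate(pop, cfg, gmap, rng)
        j = markers.chrom_slices()["chr3"].start
        g = f2.dosage(j)
        counts = np.bincount(g, minlength=3)
        chi2 = stats.chisquare(counts, len(f2) * np.array([0.25, 0.5, 0.25]))
        assert chi2.pvalue > 0.001


class TestPropagate:
    def test_cap_contract(self, gmap, markers, rng):
        pop = Population.f1_founders(400, markers, rng)
        cfg = SimConfig(pop_cap=1_000, f1_founders=400, progeny_per_female=10)
        nxt = propagate(pop, cfg, gmap, rng)
        assert len(nxt) == 1_000

    def test_single_sex_population_is_extinct(self, gmap, markers, rng):
        pop = Population.f1_founders(50, markers, rng)
        females = pop.subset(np.flatnonzero(pop.sex == FEMALE))
        with pytest.raises(ExtinctionError):
            propagate(females, SimConfig(pop_cap=100, f1_founders=50), gmap, rng)

    def test_male_fitness_locus_drives_allele_up(self, gmap, markers, rng):
        j = markers.chrom_slices()["chr2"].start + 10
        locus = FitnessLocus("chr2", int(markers.pos[j]), w_aa=1.0, w_ab=1.5, w_bb=2.0)
        cfg = SimConfig(pop_cap=800, f1_founders=400, generations=6,
                        fitness_loci=[locus])
        gains = []
        for rep in range(30):
            rep_rng = np.random.default_rng(1_000 + rep)
            traj, _ = simulate_cross(cfg, gmap, markers, rng=rep_rng)
            f = traj[(traj["chrom"] == "chr2") & (traj["pos"] == markers.pos[j])]
            f = f.sort_values("generation")["freq_b"].to_numpy()
            gains.append(f[-1] - f[0])
        assert np.mean(gains) > 0.02  # B allele rises under 2:1 male weighting

    def test_determinism_with_fixed_seed(self, gmap, markers):
        cfg = SimConfig(pop_cap=500, f1_founders=200, generations=5, seed=99)
        traj1, pop1 = simulate_cross(cfg, gmap, markers)
        traj2, pop2 = simulate_cross(cfg, gmap, markers)
        assert traj1.equals(traj2)
        np.testing.assert_array_equal(pop1.haps, pop2.haps)

    def test_f1_autosomal_frequencies_exactly_half(self, gmap, markers):
        cfg = SimConfig(pop_cap=1_000, f1_founders=300, generations=1, seed=1)
        traj, _ = simulate_cross(cfg, gmap, markers)
        auto = traj[traj["chrom"] != gmap.x_name]
        np.testing.assert_allclose(auto["freq_b"], 0.5)

    def test_linkage_decays_with_map_distance(self, gmap, markers):
        cfg = SimConfig(pop_cap=2_000, f1_founders=500, generations=8, seed=5)
        _, pop = simulate_cross(cfg, gmap, markers, record_generations=False)
        sl = markers.chrom_slices()["chr1"]
        cm = markers.cm[sl]
        origins = pop.haps[:, 0, sl].astype(float)
        j0 = 0
        corr = np.array([np.corrcoef(origins[:, j0], origins[:, j])[0, 1]
                         for j in range(len(cm))])
        assert corr[j0] == pytest.approx(1.0)
        near = corr[np.abs(cm - cm[j0]) < 5.0].mean()
        far = corr[np.abs(cm - cm[j0]) > 30.0].mean()
        assert near > far


class TestSnapshots:
    def test_population_text_roundtrip(self, gmap, markers, rng, tmp_path):
        from cexqtl import io

        cfg = SimConfig(pop_cap=150, f1_founders=80, generations=3)
        _, pop = simulate_cross(cfg, gmap, markers, rng=rng, record_generations=False)
        path = tmp_path / "pop.tsv"
        io.write_population(pop, path)
        back = io.read_population(path, markers)
        np.testing.assert_array_equal(back.haps, pop.haps)
        np.testing.assert_array_equal(back.sex, pop.sex)


class TestExpandPool:
    def test_expansion_reaches_target_size(self, gmap, markers, rng):
        cfg = SimConfig(pop_cap=500, f1_founders=200, generations=4)
        _, pop = simulate_cross(cfg, gmap, markers, rng=rng, record_generations=False)
        big = expand_pool(pop, 5_000, cfg, gmap, rng)
        assert len(big) == 5_000

    def test_expansion_preserves_frequencies(self, gmap, markers, rng):
        cfg = SimConfig(pop_cap=1_000, f1_founders=500, generations=4)
        _, pop = simulate_cross(cfg, gmap, markers, rng=rng, record_generations=False)
        big = expand_pool(pop, 10_000, cfg, gmap, rng)
        auto = markers.chrom != gmap.x_name
        diff = big.freq_b()[auto] - pop.freq_b()[auto]
        assert np.abs(diff).mean() < 0.03

    def test_different_seeds_differ(self, gmap, markers):
        cfg = SimConfig(pop_cap=300, f1_founders=100, generations=3, seed=2)
        _, pop = simulate_cross(cfg, gmap, markers, record_generations=False)
        a = expand_pool(pop, 1_000, cfg, gmap, np.random.default_rng(1))
        b = expand_pool(pop, 1_000, cfg, gmap, np.random.default_rng(2))
        assert not np.array_equal(a.haps, b.haps)
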