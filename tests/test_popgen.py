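"""Unit tests for the microsatellite summary statistics."""

import math

import numpy as np
import pytest

from landqgen import popgen

from conftest import dataset_from_sites, random_dataset
from oracles import (brute_gst_prime, brute_he, brute_jost_d, brute_rst,
                     brute_wc, gene_copies)


def _mono(site_n, allele=100, n_loci=1):
    return np.full((site_n, n_loci, 2), allele, dtype=np.int64)


class TestExpectedHeterozygosity:
    def test_identical_homozygotes_give_zero(self):
        ds = dataset_from_sites({"S1": _mono(5)})
        assert popgen.expected_heterozygosity(ds, "S1", 0) == 0.0

    def test_two_diploids_two_alleles(self):
        # gene copies {A,A,B,B}: (4/3)(1 - 0.5) = 2/3
        ds = dataset_from_sites({"S1": [[[100, 100]], [[102, 102]]]})
        he = popgen.expected_heterozygosity(ds, "S1", 0)
        assert he == pytest.approx(2.0 / 3.0, abs=1e-12)

    def test_matches_direct_summation(self, rng):
        for _ in range(20):
            ds = random_dataset(rng)
            for site in ds.sites:
                for l in range(ds.n_loci):
                    copies = gene_copies(ds, site, l)
                    assert popgen.expected_heterozygosity(ds, site, l) == \
                        pytest.approx(brute_he(copies), abs=1e-12)

    def test_insufficient_copies_rejected(self):
        ds = dataset_from_sites({"S1": [[[100, 0]]]})
        with pytest.raises(ValueError):
            popgen.expected_heterozygosity(ds, "S1", 0)


class TestAllelicRichness:
    def test_small_counts_example(self):
        # counts {A:3, B:1}, g=2: (1-0) + (1 - C(3,2)/C(4,2)) = 1.5
        ds = dataset_from_sites({"S1": [[[100, 100]], [[100, 102]]]})
        assert popgen.allelic_richness(ds, "S1", 0, g=2) == pytest.approx(1.5)

    def test_g_equals_n_gives_observed_count(self, rng):
        ds = random_dataset(rng, n_sites=1)
        for l in range(ds.n_loci):
            copies = gene_copies(ds, "S1", l)
            ar = popgen.allelic_richness(ds, "S1", l, g=len(copies))
            assert ar == pytest.approx(len(set(copies)), abs=1e-12)

    def test_monomorphic_gives_one(self):
        ds = dataset_from_sites({"S1": _mono(6)})
        for g in (1, 4, 12):
            assert popgen.allelic_richness(ds, "S1", 0, g=g) == pytest.approx(1.0)

    def test_g_larger_than_n_rejected(self):
        ds = dataset_from_sites({"S1": _mono(3)})
        with pytest.raises(ValueError):
            popgen.allelic_richness(ds, "S1", 0, g=7)

    def test_default_g_is_global_minimum(self):
        ds = dataset_from_sites({"S1": _mono(5), "S2": _mono(3, allele=102)})
        assert popgen.default_rarefaction_g(ds) == 6


class TestWeirCockerham:
    def test_fixed_different_alleles_gives_one(self):
        ds = dataset_from_sites({"S1": _mono(8, 100), "S2": _mono(8, 110)})
        fst, _, fit = popgen.wc_f_statistics(ds)
        assert fst == pytest.approx(1.0)
        assert fit == pytest.approx(1.0)

    def test_matches_brute_force_anova(self, rng):
        for _ in range(25):
            ds = random_dataset(rng, max_ind=8, n_sites=rng.integers(2, 4))
            got = popgen.wc_f_statistics(ds)
            want = brute_wc(ds, ds.sites)
            assert got == pytest.approx(want, abs=1e-10)

    def test_identical_frequencies_near_zero(self):
        rng = np.random.default_rng(5)
        sizes = 100 + 2 * np.arange(10)
        geno = {s: rng.choice(sizes, size=(500, 3, 2)) for s in ("S1", "S2")}
        ds = dataset_from_sites(geno)
        fst, _, _ = popgen.wc_f_statistics(ds)
        assert abs(fst) < 0.02

    def test_single_site_rejected(self):
        ds = dataset_from_sites({"S1": _mono(5)})
        with pytest.raises(ValueError):
            popgen.wc_f_statistics(ds)


class TestInbreeding:
    def test_all_homozygotes_two_allele_locus(self):
        geno = np.array([[[100, 100]]] * 5 + [[[102, 102]]] * 5)
        ds = dataset_from_sites({"S1": geno})
        f, p = popgen.inbreeding_with_test(ds, "S1", n_perm=99, rng=0)
        assert f == pytest.approx(1.0)
        assert p < 0.05

    def test_hardy_weinberg_site_near_zero(self):
        rng = np.random.default_rng(7)
        sizes = 100 + 2 * np.arange(8)
        ds = dataset_from_sites({"S1": rng.choice(sizes, size=(500, 4, 2))})
        f, p = popgen.inbreeding_with_test(ds, "S1", n_perm=99, rng=1)
        assert abs(f) < 0.03
        assert p > 0.05

    def test_pvalue_invariant_to_individual_order(self, rng):
        geno = rng.choice([100, 102, 104], size=(12, 2, 2))
        ds1 = dataset_from_sites({"S1": geno})
        ds2 = dataset_from_sites({"S1": geno[::-1]})
        f1, p1 = popgen.inbreeding_with_test(ds1, "S1", n_perm=199, rng=3)
        f2, p2 = popgen.inbreeding_with_test(ds2, "S1", n_perm=199, rng=3)
        assert f1 == pytest.approx(f2, abs=1e-12)
        assert p1 == pytest.approx(p2, abs=0.05)

    def test_per_locus_results_available(self, rng):
        geno = rng.choice([100, 102, 104], size=(10, 3, 2))
        ds = dataset_from_sites({"S1": geno})
        f, p, locus_results = popgen.inbreeding_with_test(
            ds, "S1", n_perm=49, rng=0, per_locus=True)
        assert len(locus_results) == 3


class TestDifferentiationMeasures:
    def test_disjoint_fixed_sites(self):
        ds = dataset_from_sites({"S1": _mono(10, 100), "S2": _mono(10, 110)})
        assert popgen.hedrick_gst_prime(ds, ["S1", "S2"]) == pytest.approx(1.0)
        assert popgen.jost_d(ds, ["S1", "S2"]) == pytest.approx(1.0)

    def test_duplicated_sites_near_zero(self, rng):
        geno = rng.choice([100, 102, 104, 106], size=(50, 2, 2))
        ds = dataset_from_sites({"S1": geno, "S2": geno})
        # unbiased estimators may dip slightly negative for identical sites;
        # G'_ST divides by G_ST(max), which is small at high diversity, so its
        # sampling wiggle is wider than F_ST's or D's
        assert abs(popgen.hedrick_gst_prime(ds, ["S1", "S2"])) < 0.15
        assert abs(popgen.jost_d(ds, ["S1", "S2"])) < 0.05
        fst, _, _ = popgen.wc_f_statistics(ds)
        assert abs(fst) < 0.05

    def test_matches_brute_oracles(self, rng):
        for _ in range(25):
            ds = random_dataset(rng, max_ind=10)
            pair = ds.sites[:2]
            assert popgen.hedrick_gst_prime(ds, pair) == \
                pytest.approx(brute_gst_prime(ds, pair), abs=1e-10)
            assert popgen.jost_d(ds, pair) == \
                pytest.approx(brute_jost_d(ds, pair), abs=1e-10)

    def test_toy_frequency_pair_hand_value(self):
        # p1 = (0.7, 0.3), p2 = (0.3, 0.7) realized exactly in 10 diploids
        g1 = [[100, 100]] * 7 + [[102, 102]] * 3
        g2 = [[100, 100]] * 3 + [[102, 102]] * 7
        ds = dataset_from_sites({"S1": np.array(g1)[:, None, :],
                                 "S2": np.array(g2)[:, None, :]})
        got = popgen.hedrick_gst_prime(ds, ["S1", "S2"])
        want = brute_gst_prime(ds, ["S1", "S2"])
        assert got == pytest.approx(want, abs=1e-12)
        assert 0 < got < 1


class TestRst:
    def test_fixed_size_difference_gives_one(self):
        ds = dataset_from_sites({"S1": _mono(8, 10), "S2": _mono(8, 20)})
        rst, se, p = popgen.slatkin_rst_with_test(ds, n_perm=19, rng=0)
        assert rst == pytest.approx(1.0)

    def test_matches_brute_anova(self, rng):
        for _ in range(25):
            ds = random_dataset(rng, max_ind=10)
            rst, _, _ = popgen.slatkin_rst_with_test(ds, n_perm=0, rng=0)
            assert rst == pytest.approx(brute_rst(ds, ds.sites), abs=1e-10)

    def test_no_size_variation_rejected(self):
        ds = dataset_from_sites({"S1": _mono(5), "S2": _mono(5)})
        with pytest.raises(ValueError):
            popgen.slatkin_rst_with_test(ds, n_perm=9)


class TestNeCoancestry:
    def test_identical_homozygotes_lower_bound(self):
        ds = dataset_from_sites({"S1": _mono(4, 100, n_loci=3)})
        ne, fhat = popgen.ne_coancestry(ds, "S1")
        assert fhat == pytest.approx(1.0)
        assert ne == pytest.approx(0.5)

    def test_disjoint_alleles_not_estimable(self):
        ds = dataset_from_sites({"S1": np.array([[[100, 102]], [[104, 106]]])})
        ne, fhat = popgen.ne_coancestry(ds, "S1")
        assert fhat == 0.0
        assert math.isinf(ne)

    def test_bottleneck_reduces_ne(self, rng):
        # a site built from few founder genotypes has higher coancestry
        sizes = 100 + 2 * np.arange(12)
        wide = rng.choice(sizes, size=(60, 5, 2))
        founders = rng.choice(sizes, size=(4, 5, 2))
        narrow = founders[rng.integers(0, 4, 60)]
        ds = dataset_from_sites({"wide": wide, "narrow": narrow})
        ne_wide, _ = popgen.ne_coancestry(ds, "wide")
        ne_narrow, _ = popgen.ne_coancestry(ds, "narrow")
        assert ne_narrow < ne_wide


class TestMonotonicity:
    def test_fst_increases_with_divergence(self):
        from landqgen.simulate import GenotypeSimSpec, simulate_genotypes
        means = []
        for F in (0.01, 0.05, 0.2):
            vals = []
            for seed in range(3):
                ds = simulate_genotypes(GenotypeSimSpec(
                    n_landscapes=5, sites_per_landscape=1,
                    n_individuals_per_site=30, n_loci=5, alleles_per_locus=10,
                    target_Fst=F, rng_seed=seed))
                vals.append(popgen.wc_f_statistics(ds)[0])
            means.append(np.mean(vals))
        assert means[0] < means[1] < means[2]
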