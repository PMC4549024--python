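"""Simulator: design calculators, meiosis, population structure, traits."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import addomgs as A


class TestDesignCalculators:
    @pytest.mark.parametrize(
        "theta,pa1,pa2,pb1,pb2,expected",
        [
            (0.0, 1.0, 0.0, 1.0, 0.0, 0.25),   # maximal coupling LD
            (0.2, 0.6, 0.6, 0.9, 0.1, 0.0),    # equal parental frequencies
            (0.5, 0.9, 0.1, 0.8, 0.2, 0.0),    # free recombination
            (0.0, 1.0, 0.0, 0.0, 1.0, -0.25),  # repulsion: negative sign
        ],
    )
    def test_expected_composite_ld(self, theta, pa1, pa2, pb1, pb2, expected):
        assert A.expected_composite_ld(theta, pa1, pa2, pb1, pb2) == pytest.approx(expected)

    def test_ld_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            A.expected_composite_ld(0.7, 0.5, 0.5, 0.5, 0.5)
        with pytest.raises(ValueError):
            A.expected_composite_ld(0.1, 1.2, 0.5, 0.5, 0.5)

    @given(
        theta=st.floats(0, 0.5),
        p=st.tuples(*[st.floats(0, 1)] * 4),
    )
    @settings(max_examples=50, deadline=None)
    def test_ld_bounded_by_quarter(self, theta, p):
        assert abs(A.expected_composite_ld(theta, *p)) <= 0.25 + 1e-12

    @pytest.mark.parametrize(
        "n,n_qtl,expected",
        [(2000, 100, 0.95), (2000, 2 * 39.22 * 2, 0.93), (500, 0, 1.0)],
    )
    def test_marker_capture_ratio(self, n, n_qtl, expected):
        assert A.marker_capture_ratio(n, n_qtl) == pytest.approx(expected, abs=5e-3)

    def test_marker_capture_ratio_rejects_zero_markers(self):
        with pytest.raises(ValueError):
            A.marker_capture_ratio(0, 10)

    @pytest.mark.parametrize(
        "ne,s,expected",
        [(39.22, 0.001, 0.86), (100.0, 0.0, 1.0), (250.0, 0.001, 0.5)],
    )
    def test_marker_capture_from_spacing(self, ne, s, expected):
        assert A.marker_capture_from_spacing(ne, s) == pytest.approx(expected, abs=5e-3)


class TestMeiosis:
    def test_unlinked_loci_assort_independently(self):
        gmap = A.GenomeMap(np.array([0.0, 0.0]), np.array([0, 1]), np.array([], int))
        rng = np.random.default_rng(0)
        parent = np.array([[[1, 1], [0, 0]]], dtype=np.uint8)
        n = 200_000
        g = A.sample_gametes(np.repeat(parent, n, axis=0), gmap, rng)
        recomb = np.mean(g[:, 0] != g[:, 1])
        assert recomb == pytest.approx(0.5, abs=0.005)

    def test_zero_distance_never_recombines(self):
        gmap = A.GenomeMap(np.array([3.0, 3.0]), np.array([0, 0]), np.array([], int))
        rng = np.random.default_rng(1)
        parent = np.array([[[1, 1], [0, 0]]], dtype=np.uint8)
        g = A.sample_gametes(np.repeat(parent, 50_000, axis=0), gmap, rng)
        assert np.all(g[:, 0] == g[:, 1])

    def test_short_distance_matches_haldane(self):
        # 0.1 cM apart: Monte-Carlo recombination fraction vs (1-e^-0.002)/2
        gmap = A.GenomeMap(np.array([0.0, 0.1]), np.array([0, 0]), np.array([], int))
        rng = np.random.default_rng(2)
        parent = np.array([[[1, 1], [0, 0]]], dtype=np.uint8)
        n = 2_000_000
        g = A.sample_gametes(np.repeat(parent, n, axis=0), gmap, rng)
        c_hat = np.mean(g[:, 0] != g[:, 1])
        c = A.haldane(0.001)
        assert c_hat == pytest.approx(c, abs=3 * np.sqrt(c / n))

    def test_single_gamete_wrapper_shape(self, small_map):
        hap = np.zeros((2, small_map.n_loci), dtype=np.uint8)
        hap[0] = 1
        g = A.sample_gamete(hap, small_map, seed=3)
        assert g.shape == (small_map.n_loci,)
        assert set(np.unique(g)) <= {0, 1}


class TestComposite:
    def test_max_divergence_gives_quarter_ld_when_tightly_linked(self):
        # theta = 0 between adjacent loci (same position), |p1 - p2| = 1
        pos = np.repeat(np.arange(5.0), 2)
        gmap = A.GenomeMap(pos, np.zeros(10, int), np.array([], int))
        founders = A.FounderSpec(np.full(10, 1 - 1e-9), np.full(10, 1e-9))
        pop = A.simulate_composite(founders, gmap, n_generations=5,
                                   pop_size=4000, seed=4)
        pairs = np.array([[2 * k, 2 * k + 1] for k in range(5)])
        dd = A.estimate_ld(pop, pairs)
        assert np.mean(np.abs(dd)) == pytest.approx(0.25, abs=0.01)

    def test_equal_founder_frequencies_give_no_ld(self, small_map):
        rng = np.random.default_rng(5)
        p = rng.uniform(0.2, 0.8, small_map.n_loci)
        founders = A.FounderSpec(p, p.copy())
        pop = A.simulate_composite(founders, small_map, 5, 3000, seed=6)
        pairs = np.column_stack([np.arange(0, 19), np.arange(1, 20)])
        dd = A.estimate_ld(pop, pairs)
        assert abs(np.mean(dd)) < 0.01

    def test_ld_decays_with_distance_and_matches_expectation(self, small_map):
        rng = np.random.default_rng(8)
        founders = A.FounderSpec.draw(small_map, rng)
        pop = A.simulate_composite(founders, small_map, 5, 6000, seed=9)
        seps = [1, 4, 10]  # 0.5, 2, 5 cM
        observed, expected = [], []
        for s in seps:
            i = np.arange(0, 20 - s)
            pairs = np.column_stack([i, i + s])
            dd = A.estimate_ld(pop, pairs)
            # sign-aligned mean against theory, 5 rounds of decay
            theta = A.haldane(s * 0.5 / 100)
            th = A.expected_composite_ld(
                theta, founders.p1[i], founders.p2[i],
                founders.p1[i + s], founders.p2[i + s],
            ) * (1 - theta) ** 4
            observed.append(np.mean(np.abs(dd)))
            expected.append(np.mean(np.abs(th)))
        assert observed[0] > observed[1] > observed[2]
        for o, e in zip(observed, expected):
            assert o == pytest.approx(e, abs=0.03)

    def test_hardy_weinberg_in_composite(self, small_map):
        from scipy import stats

        rng = np.random.default_rng(10)
        founders = A.FounderSpec.draw(small_map, rng)
        pop = A.simulate_composite(founders, small_map, 5, 4000, seed=12)
        x = pop.dosages()
        p = pop.allele_freq()
        n = pop.n
        rejected = 0
        for j in range(pop.n_loci):
            obs = np.bincount(x[:, j], minlength=3)
            exp = n * np.array([(1 - p[j]) ** 2, 2 * p[j] * (1 - p[j]), p[j] ** 2])
            chi2 = np.sum((obs - exp) ** 2 / exp)
            if chi2 > stats.chi2.ppf(0.99, df=1):
                rejected += 1
        assert rejected <= max(3, 0.05 * pop.n_loci)

    def test_seed_determinism(self, small_map):
        rng = np.random.default_rng(13)
        founders = A.FounderSpec.draw(small_map, rng)
        p1 = A.simulate_composite(founders, small_map, 3, 500, seed=99)
        p2 = A.simulate_composite(founders, small_map, 3, 500, seed=99)
        assert np.array_equal(p1.haplotypes, p2.haplotypes)

    def test_degenerate_inputs_rejected(self, small_map):
        founders = A.FounderSpec(np.full(small_map.n_loci, 0.5),
                                 np.full(small_map.n_loci, 0.5))
        with pytest.raises(ValueError):
            A.simulate_composite(founders, small_map, 0, 100)
        with pytest.raises(ValueError):
            A.simulate_composite(founders, small_map, 5, 1)


class TestFamilies:
    def test_family_structure(self, small_dataset):
        c = small_dataset.cohort
        assert c.n == 100
        assert c.n_families == 5
        fam_sizes = np.bincount(c.family_id)
        assert np.all(fam_sizes == 20)
        # full sibs share both parents
        for f in range(5):
            m = c.family_id == f
            assert np.unique(c.sire[m]).size == 1
            assert np.unique(c.dam[m]).size == 1

    def test_dosage_haplotype_consistency(self, small_dataset):
        c = small_dataset.cohort
        assert np.array_equal(c.dosages(), c.haplotypes.sum(axis=1))
        assert set(np.unique(c.dosages())) <= {0, 1, 2}

    def test_within_family_additive_relationship(self, small_dataset):
        # pedigree oracle: mean within-family off-diagonal A = 0.5
        c = small_dataset.cohort
        sire, dam = c.pedigree()
        Afull = A.build_A(sire, dam)
        idx = np.arange(c.n_founders, sire.size)
        Ac = Afull[np.ix_(idx, idx)]
        same_fam = c.family_id[:, None] == c.family_id[None, :]
        off = ~np.eye(c.n, dtype=bool)
        assert Ac[same_fam & off].mean() == pytest.approx(0.5, abs=1e-12)

    def test_too_few_parents_rejected(self, small_map):
        founders = A.FounderSpec(np.full(small_map.n_loci, 0.4),
                                 np.full(small_map.n_loci, 0.6))
        pop = A.simulate_composite(founders, small_map, 2, 50, seed=14)
        with pytest.raises(ValueError):
            A.make_families(pop, small_map, n_families=10, family_size=5,
                            n_parents=10, seed=15)

    def test_two_full_sibs(self, small_map):
        founders = A.FounderSpec(np.full(small_map.n_loci, 0.4),
                                 np.full(small_map.n_loci, 0.6))
        pop = A.simulate_composite(founders, small_map, 2, 50, seed=16)
        c = A.make_families(pop, small_map, 1, 2, 2, seed=17)
        assert c.n == 2
        assert c.sire[0] == c.sire[1] and c.dam[0] == c.dam[1]


class TestTrait:
    def test_heritability_targeting_across_seeds(self, small_map):
        # realized broad-sense h2 within +-0.02 of target over seeds
        for seed in range(10):
            ds = A.simulate_dataset(gmap=small_map, pop_size=200, n_families=5,
                                    family_size=20, n_parents=10, seed=seed)
            vg = np.var(ds.g)
            h2 = vg / (vg + ds.trait.sigma_e2)
            assert h2 == pytest.approx(0.30, abs=0.02)

    def test_major_genes_variance_share(self, small_map):
        ds = A.simulate_dataset(gmap=small_map, architecture="major_genes",
                                pop_size=200, n_families=5, family_size=20,
                                n_parents=10, seed=21)
        tr = ds.trait
        assert tr.major_indices.size == 5
        a_maj = np.where(np.isin(np.arange(tr.a.size), tr.major_indices), tr.a, 0)
        d_maj = np.where(np.isin(np.arange(tr.a.size), tr.major_indices), tr.d, 0)
        tr_maj = A.TraitArchitecture("major_genes", tr.qtl_indices, a_maj, d_maj,
                                     0.0, 0.0, 0.3, 0.2)
        ua_m, ud_m = tr_maj.true_components(ds.dosages)
        share = (np.var(ua_m) + np.var(ud_m)) / (np.var(ds.u_a) + np.var(ds.u_d))
        assert share == pytest.approx(0.5, abs=0.05)

    def test_no_dominance_equalizes_heritabilities(self, small_map, small_dataset):
        tr = small_dataset.trait
        tr0 = A.TraitArchitecture(tr.architecture, tr.qtl_indices, tr.a,
                                  np.zeros_like(tr.d), tr.mean_m, tr.sigma_e2,
                                  tr.h2_broad, tr.h2_narrow)
        g = tr0.genotypic_values(small_dataset.dosages)
        u_a, u_d = tr0.true_components(small_dataset.dosages)
        assert np.allclose(u_d, 0)
        assert np.var(g) == pytest.approx(np.var(u_a), rel=1e-9)

    def test_phenotype_is_genotype_plus_noise(self, small_dataset):
        tr = small_dataset.trait
        tr_noiseless = A.TraitArchitecture(
            tr.architecture, tr.qtl_indices, tr.a, tr.d, tr.mean_m, 0.0,
            tr.h2_broad, tr.h2_narrow, tr.major_indices)
        y0 = A.simulate_phenotypes(small_dataset.cohort, tr_noiseless, seed=22)
        assert np.allclose(y0, small_dataset.g)
        # var(y) ~ var(g) / h2_broad
        y = A.simulate_phenotypes(small_dataset.cohort, tr, seed=23)
        assert np.var(y) == pytest.approx(np.var(small_dataset.g) / 0.30, rel=0.25)

    def test_complete_homozygote_bounded_by_gmax(self, small_dataset):
        tr = small_dataset.trait
        best = np.full((1, small_dataset.dosages.shape[1]), 0, dtype=np.uint8)
        best[0, tr.qtl_indices] = np.where(tr.a > 0, 2, 0)
        g_best = tr.genotypic_values(best)[0]
        assert g_best <= tr.gmax + 1e-9
        assert tr.gmin <= g_best

    def test_invalid_targets_rejected(self, small_dataset, small_map):
        with pytest.raises(ValueError):
            A.assign_trait(small_dataset.cohort, small_map,
                           h2_broad=0.2, h2_narrow=0.3)

    def test_degree_of_dominance_near_one(self, small_dataset):
        assert small_dataset.trait.degree_of_dominance == pytest.approx(1.0, abs=0.45)


class TestMAF:
    def test_threshold_filters_rare_alleles(self):
        hap = np.zeros((50, 2, 3), dtype=np.uint8)
        hap[:2, :, 0] = 1          # p = 0.04
        hap[:25, 0, 1] = 1         # p = 0.25
        hap[:, :, 2] = 1           # p = 1 (monomorphic)
        pop = A.Population(hap)
        keep = A.enforce_maf(pop, 0.05)
        assert keep.tolist() == [False, True, False]
        keep0 = A.enforce_maf(pop, 0.0)
        assert keep0.tolist() == [True, True, False]

    def test_default_pipeline_keeps_full_panel(self, small_dataset):
        keep = A.enforce_maf(small_dataset.cohort, 0.05)
        assert keep.all()
        assert small_dataset.dosages.shape[1] == small_dataset.gmap.n_loci
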