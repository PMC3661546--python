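import itertools

import numpy as np
import pytest

from popgendiff.genotype_io import MISSING, GeneRegion
from popgendiff.ld_haplotype import (
    block_features,
    em_block_haplotypes,
    em_two_locus,
    four_gamete_blocks,
    gene_ld_features,
    haplotype_diversity,
    ld_stats,
    pairwise_ld,
    HaplotypeBlock,
)
from popgendiff.synthetic_data import SimulationConfig, simulate

from conftest import make_table
from oracles import (
    brute_force_partition,
    grid_max_loglik,
    spectrum_loglik,
    support_haplotypes,
)


def hap_matrix(f00, f01, f10, f11):
    return np.array([[f00, f01], [f10, f11]])


class TestEmTwoLocus:
    def test_unambiguous_phase(self):
        # only AABB and aabb style samples: spectrum {AB: f, ab: 1-f}, r2 = 1
        a = np.array([0, 0, 0, 2, 2, 1])
        b = np.array([0, 0, 0, 2, 2, 1])
        f = em_two_locus(a, b)
        # 12 chromosomes: 7 carry ref-ref, 5 alt-alt (double het resolves cis)
        assert f[0, 0] == pytest.approx(7 / 12, abs=1e-6)
        assert f[1, 1] == pytest.approx(5 / 12, abs=1e-6)
        r2, dp = ld_stats(f)
        assert r2 == pytest.approx(1.0, abs=1e-6)
        assert dp == pytest.approx(1.0, abs=1e-6)

    def test_double_heterozygote_beats_grid(self):
        # one AaBb sample plus anchors: EM reaches a stationary point whose
        # likelihood is at least the best exhaustive grid value
        rng = np.random.default_rng(0)
        for _ in range(5):
            a = rng.integers(0, 3, size=12)
            b = rng.integers(0, 3, size=12)
            a[0] = b[0] = 1
            f = em_two_locus(a, b)
            genos = list(zip((int(x) for x in a), (int(x) for x in b)))
            spectrum = {
                (0, 0): f[0, 0], (0, 1): f[0, 1], (1, 0): f[1, 0], (1, 1): f[1, 1]
            }
            ll_em = spectrum_loglik(genos, spectrum)
            ll_grid = grid_max_loglik(genos, sorted(spectrum))
            assert ll_em >= ll_grid - 1e-8

    def test_linkage_equilibrium_simulation(self):
        rng = np.random.default_rng(123)
        a = rng.binomial(2, 0.4, size=500)
        b = rng.binomial(2, 0.6, size=500)
        r2, _ = ld_stats(em_two_locus(a, b))
        assert r2 < 0.05

    def test_missing_pairs_dropped(self):
        a = np.array([0, 0, 2, 2, MISSING, 1])
        b = np.array([0, 0, 2, 2, 1, MISSING])
        f = em_two_locus(a, b)
        assert f.sum() == pytest.approx(1.0)

    def test_marginals_match_allele_frequencies(self):
        rng = np.random.default_rng(5)
        a = rng.integers(0, 3, 40)
        b = rng.integers(0, 3, 40)
        f = em_two_locus(a, b)
        assert f[1, :].sum() == pytest.approx(a.mean() / 2, abs=1e-6)
        assert f[:, 1].sum() == pytest.approx(b.mean() / 2, abs=1e-6)


class TestLdStats:
    def test_independence_gives_zero(self):
        r2, dp = ld_stats(hap_matrix(0.25, 0.25, 0.25, 0.25))
        assert r2 == 0.0 and dp == 0.0

    def test_absent_class_gives_dprime_one(self):
        r2, dp = ld_stats(hap_matrix(0.5, 0.3, 0.0, 0.2))
        assert dp == pytest.approx(1.0)
        assert r2 < 1.0

    def test_hand_evaluated_closed_form(self):
        # D = 0.4 - 0.5*0.5 = 0.15; r2 = 0.36; D' = 0.15/0.25 = 0.6
        r2, dp = ld_stats(hap_matrix(0.4, 0.1, 0.1, 0.4))
        assert r2 == pytest.approx(0.36)
        assert dp == pytest.approx(0.6)

    def test_monomorphic_marginal_undefined(self):
        r2, dp = ld_stats(hap_matrix(0.6, 0.4, 0.0, 0.0))
        assert np.isnan(r2) and np.isnan(dp)

    def test_label_and_allele_swap_invariance(self):
        f = hap_matrix(0.4, 0.1, 0.2, 0.3)
        r2, dp = ld_stats(f)
        assert ld_stats(f.T) == pytest.approx((r2, dp))  # swap SNP order
        assert ld_stats(f[::-1, :]) == pytest.approx((r2, dp))  # relabel locus A
        assert ld_stats(f[:, ::-1]) == pytest.approx((r2, dp))  # relabel locus B

    def test_r2_le_dprime_at_half_frequencies(self):
        # algebraic consequence when both marginals are 0.5
        for d in (0.05, 0.1, 0.2, 0.25):
            f = hap_matrix(0.25 + d, 0.25 - d, 0.25 - d, 0.25 + d)
            r2, dp = ld_stats(f)
            assert r2 <= dp + 1e-12


class TestFourGameteBlocks:
    def _vt_two_snp(self, all_four):
        if all_four:
            g = [[0, 0], [0, 2], [2, 0], [2, 2], [0, 0], [2, 2], [0, 2], [2, 0]]
        else:
            g = [[0, 0], [0, 0], [1, 1], [2, 2], [2, 2], [0, 0], [1, 1], [2, 2]]
        return make_table(g)

    def test_three_gametes_form_block(self):
        vt = self._vt_two_snp(all_four=False)
        gene = GeneRegion("g", "1", 0, 1000, snp_indices=[0, 1])
        blocks = four_gamete_blocks(vt, np.arange(8), gene)
        assert len(blocks) == 1
        assert blocks[0].snp_indices.tolist() == [0, 1]

    def test_four_gametes_break_block(self):
        vt = self._vt_two_snp(all_four=True)
        gene = GeneRegion("g", "1", 0, 1000, snp_indices=[0, 1])
        assert four_gamete_blocks(vt, np.arange(8), gene) == []

    def test_matches_brute_force_partitioner(self):
        rng_seeds = range(40)
        checked = 0
        for seed in rng_seeds:
            cfg = SimulationConfig(
                n_populations=2,
                samples_per_population=25,
                n_genes=1,
                snps_per_gene=8,
                block_length=3,
                haplotypes_per_block=4,
                missing_rate=0.02,
                seed=seed,
            )
            vt, panel, cat = simulate(cfg)
            gene = GeneRegion("g", cat.genes[0].chrom, cat.genes[0].start,
                              cat.genes[0].end, snp_indices=np.arange(8))
            rows = panel.sample_indices(vt)["POP1"]
            ld = pairwise_ld(vt, rows, gene.snp_indices)
            blocks = four_gamete_blocks(vt, rows, gene, ld=ld)

            def passes(i, j):
                pair = ld[(min(i, j), max(i, j))]
                return int(np.sum(pair.hap_freqs >= 0.01)) < 4

            expected = brute_force_partition(passes, 8)
            assert [b.snp_indices.tolist() for b in blocks] == expected
            checked += 1
        assert checked == 40

    def test_partition_properties(self, small_sim):
        _, vt, panel, catalogue = small_sim
        rows = panel.sample_indices(vt)
        for gene in catalogue:
            for pop in panel.populations:
                blocks = four_gamete_blocks(vt, rows[pop], gene)
                seen = []
                for b in blocks:
                    assert b.n_snps >= 2
                    assert np.all(np.diff(b.snp_indices) > 0)
                    seen.extend(b.snp_indices.tolist())
                assert len(seen) == len(set(seen))  # disjoint
                assert seen == sorted(seen)  # ordered


class TestBlockFeatures:
    def blk(self, start, end, n_snps):
        return HaplotypeBlock(
            snp_indices=np.arange(n_snps),
            start_bp=start,
            end_bp=end,
            hap_spectrum={(0,) * n_snps: 1.0},
            n_chromosomes=20,
        )

    def test_single_block_arithmetic(self):
        n, size, dens = block_features([self.blk(1, 10_000, 5)])
        assert (n, size) == (1, 10_000.0)
        assert dens == pytest.approx(0.5)

    def test_mean_of_two_blocks(self):
        _, size, _ = block_features([self.blk(1, 1000, 2), self.blk(1, 3000, 2)])
        assert size == pytest.approx(2000.0)

    def test_zero_blocks_missing(self):
        n, size, dens = block_features([])
        assert np.isnan(n) and np.isnan(size) and np.isnan(dens)


class TestBlockEM:
    def test_three_snp_block_beats_grid(self):
        rng = np.random.default_rng(21)
        for _ in range(8):
            g = rng.integers(0, 3, size=(20, 3))
            spectrum, _ = em_block_haplotypes(g)
            genos = [tuple(int(x) for x in row) for row in g]
            support = support_haplotypes(genos)
            full = dict.fromkeys(support, 0.0) | spectrum
            assert spectrum_loglik(genos, full) >= grid_max_loglik(genos, support) - 1e-8

    def test_spectrum_sums_to_one(self, small_sim):
        _, vt, panel, catalogue = small_sim
        rows = panel.sample_indices(vt)["POP1"]
        gene = catalogue.genes[0]
        spectrum, n_chrom = em_block_haplotypes(
            vt.genotypes[np.ix_(rows, gene.snp_indices[:5])]
        )
        assert sum(spectrum.values()) == pytest.approx(1.0, abs=1e-6)
        assert n_chrom % 2 == 0

    def test_unambiguous_phase_counting(self):
        # homozygous-only individuals: spectrum = direct haplotype counting
        g = np.array([[0, 0, 0]] * 6 + [[2, 2, 2]] * 4)
        spectrum, n = em_block_haplotypes(g)
        assert spectrum[(0, 0, 0)] == pytest.approx(0.6)
        assert spectrum[(1, 1, 1)] == pytest.approx(0.4)
        assert n == 20

    def test_partition_ligation_matches_direct_em(self):
        # 10-SNP block built from two founder haplotypes: PL must find them
        rng = np.random.default_rng(3)
        h1 = rng.integers(0, 2, 10)
        h2 = 1 - h1
        picks = rng.integers(0, 2, size=(30, 2))
        pool = np.stack([h1, h2])
        g = pool[picks[:, 0]] + pool[picks[:, 1]]
        spectrum, _ = em_block_haplotypes(g.astype(np.int8), pl_threshold=4)
        top = sorted(spectrum, key=spectrum.get, reverse=True)[:2]
        assert set(top) == {tuple(h1), tuple(h2)}
        assert sum(spectrum[t] for t in top) == pytest.approx(1.0, abs=1e-3)


class TestDiversity:
    def test_single_haplotype_zero(self):
        assert haplotype_diversity({(0, 1): 1.0}, 40) == 0.0

    def test_two_equal_haplotypes(self):
        h = haplotype_diversity({(0,): 0.5, (1,): 0.5}, 10)
        assert h == pytest.approx(10 / 9 * 0.5)

    def test_bounds_and_split_monotonicity(self):
        n = 30
        spectrum = {(0, 0): 0.5, (1, 1): 0.5}
        h = haplotype_diversity(spectrum, n)
        split = {(0, 0): 0.25, (0, 1): 0.25, (1, 1): 0.5}
        assert 0 <= h < n / (n - 1)
        assert haplotype_diversity(split, n) > h


class TestGeneLDFeatures:
    def test_full_feature_bundle(self, small_sim):
        _, vt, panel, catalogue = small_sim
        rows = panel.sample_indices(vt)
        feats = gene_ld_features(vt, rows["POP1"], catalogue.genes[0], "POP1")
        n_pairs = len(list(itertools.combinations(range(catalogue.genes[0].n_snps), 2)))
        assert len(feats.pair_r2) == n_pairs
        if np.isfinite(feats.block_number):
            assert feats.block_number >= 1
            assert feats.haplotype_diversity >= 0

    def test_max_pair_distance_limits_pairs(self, small_sim):
        _, vt, panel, catalogue = small_sim
        rows = panel.sample_indices(vt)
        gene = catalogue.genes[0]
        near = pairwise_ld(vt, rows["POP1"], gene.snp_indices, max_pair_distance=2000)
        all_pairs = pairwise_ld(vt, rows["POP1"], gene.snp_indices)
        assert set(near) <= set(all_pairs)
        assert len(near) < len(all_pairs)
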