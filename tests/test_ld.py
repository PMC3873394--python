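import numpy as np
import pytest

from daughterqtl.io import MISSING, GenotypeMatrix
from daughterqtl.ld import (BlockPartition, HaplotypeSet, all_pairwise_ld,
                            detect_blocks, dprime_confidence_interval,
                            em_haplotype_frequencies, pairwise_ld,
                            pool_rare_haplotypes)
from daughterqtl.simulate import BlockSpec, SimulationConfig, simulate_genotypes, simulate_pedigree


def _gm(codes):
    codes = np.asarray(codes, dtype=np.int8)
    return GenotypeMatrix(ids=[f"i{k}" for k in range(codes.shape[0])],
                          codes=codes)


def _gm_from_haplotype_pairs(pairs):
    """Genotypes from explicit haplotype pairs (each haplotype a 0/1 tuple)."""
    codes = np.array([[a + b for a, b in zip(h1, h2)] for h1, h2 in pairs])
    return _gm(codes)


class TestEm:
    def test_homozygous_individuals_are_phase_certain(self):
        gm = _gm([[0, 0, 0], [2, 2, 2], [2, 2, 2], [0, 0, 0]])
        hs = em_haplotype_frequencies(gm, range(3), seed=0)
        assert sorted(zip(hs.hap_bits, hs.frequencies)) == [
            ((0, 0, 0), pytest.approx(0.5)), ((1, 1, 1), pytest.approx(0.5))]
        # every dosage entry integral: no phase ambiguity
        assert np.allclose(hs.dosages, np.round(hs.dosages))

    def test_double_heterozygotes_match_grid_search_oracle(self):
        """With only double-het 2-SNP genotypes the likelihood is a
        one-parameter family p(00)=p(11)=t/... ; EM must reach the global
        maximum found by brute-force grid search."""
        gm = _gm([[1, 1]] * 20)
        hs = em_haplotype_frequencies(gm, (0, 1), n_restarts=8, seed=1)
        # brute force over t = freq(00) = freq(11), freq(01)=freq(10)=0.5-t
        ts = np.linspace(0, 0.5, 2001)
        ll = 20 * np.log(2 * ts ** 2 + 2 * (0.5 - ts) ** 2)
        assert hs.log_likelihood == pytest.approx(ll.max(), abs=1e-6)

    def test_recovers_generating_pool_at_study_scale(self):
        # unrelated founders: binomial SE applies (family clustering would
        # inflate the sampling variance of the realised frequencies)
        from daughterqtl.io import Pedigree
        config = SimulationConfig()
        ped = Pedigree.from_records([(f"F{k}", "0", "0") for k in range(638)])
        gm, smap, _ = simulate_genotypes(ped, config, seed=31)
        hs = em_haplotype_frequencies(gm, range(3, 8), seed=0, snp_map=smap)
        n = 2 * len(ped)
        spec = config.block_specs[3]
        est = dict(zip(hs.hap_bits, hs.frequencies))
        # minor-allele coding may flip bits per SNP, so match either parity
        for hap, f_true in zip(spec.haplotypes, spec.frequencies):
            bits = tuple(int(c) for c in hap)
            match = [f for b, f in est.items() if b == bits or
                     b == tuple(1 - x for x in bits)]
            se = np.sqrt(f_true * (1 - f_true) / n)
            assert any(abs(f - f_true) < 3 * se for f in match), \
                f"haplotype {hap}: estimated {match} vs {f_true}"

    def test_loglik_trace_monotone(self, rng):
        for _ in range(10):
            codes = rng.integers(0, 3, size=(30, 4))
            codes[rng.random(codes.shape) < 0.05] = MISSING
            hs = em_haplotype_frequencies(_gm(codes), range(4), seed=3)
            diffs = np.diff(hs.ll_trace)
            assert (diffs > -1e-9).all()

    def test_frequencies_and_dosages_normalised(self, rng):
        codes = rng.integers(0, 3, size=(50, 5))
        hs = em_haplotype_frequencies(_gm(codes), range(5), seed=0)
        assert hs.frequencies.sum() == pytest.approx(1.0, abs=1e-9)
        np.testing.assert_allclose(hs.dosages.sum(axis=1), 2.0, atol=1e-9)

    def test_oversized_window_rejected(self):
        gm = _gm(np.zeros((4, 13), dtype=int))
        with pytest.raises(ValueError, match="[Ss]plit into blocks"):
            em_haplotype_frequencies(gm, range(13))


class TestPooling:
    def _hs(self, freqs):
        freqs = np.asarray(freqs, dtype=float)
        dosages = np.tile(2 * freqs, (3, 1))
        return HaplotypeSet(snp_indices=(0, 1),
                            haplotypes=[f"H{k}" for k in range(len(freqs))],
                            hap_bits=[(k,) for k in range(len(freqs))],
                            frequencies=freqs, dosages=dosages,
                            log_likelihood=0.0, ll_trace=[0.0])

    def test_pools_tail_into_single_group(self):
        # common classes 33.5/33.1/25.6 %, seven rare sharing 7.8 %
        freqs = [0.335, 0.331, 0.256] + [0.078 / 7] * 7
        pooled = pool_rare_haplotypes(self._hs(freqs), 0.05)
        assert pooled.haplotypes[-1] == "pooled"
        assert pooled.frequencies[-1] == pytest.approx(0.078)
        assert pooled.frequencies.sum() == pytest.approx(1.0)
        np.testing.assert_allclose(pooled.dosages.sum(axis=1), 2.0, atol=1e-9)

    def test_identity_when_nothing_rare(self):
        hs = self._hs([0.5, 0.3, 0.2])
        pooled = pool_rare_haplotypes(hs, 0.05)
        np.testing.assert_array_equal(pooled.frequencies, hs.frequencies)
        assert pooled.haplotypes == hs.haplotypes

    def test_boundary_frequency_kept(self):
        pooled = pool_rare_haplotypes(self._hs([0.6, 0.3, 0.06, 0.04]), 0.05)
        assert pooled.frequencies[-1] == pytest.approx(0.04)
        assert 0.06 in np.round(pooled.frequencies, 9)

    def test_all_rare_rejected(self):
        with pytest.raises(ValueError, match="threshold"):
            pool_rare_haplotypes(self._hs([0.04] * 25), 0.05)


class TestPairwiseLd:
    def test_complete_coupling(self):
        pairs = [((0, 0), (0, 0))] * 4 + [((1, 1), (0, 0))] * 4 + [((1, 1), (1, 1))] * 2
        res = pairwise_ld(_gm_from_haplotype_pairs(pairs), 0, 1)
        assert res.dprime == pytest.approx(1.0)
        assert res.r2 == pytest.approx(1.0)

    def test_independent_loci_near_zero(self, rng):
        n = 2000
        codes = np.column_stack([rng.binomial(2, 0.4, n), rng.binomial(2, 0.3, n)])
        res = pairwise_ld(_gm(codes), 0, 1)
        assert res.dprime < 0.15

    def test_phase_known_toy_table_oracle(self):
        # haplotype counts 4 AB, 1 Ab, 1 aB, 4 ab paired without double hets
        pairs = [((1, 1), (1, 1)), ((1, 1), (1, 0)), ((1, 1), (0, 1)),
                 ((0, 0), (0, 0)), ((0, 0), (0, 0))]
        res = pairwise_ld(_gm_from_haplotype_pairs(pairs), 0, 1)
        pAB, pA, pB = 0.4, 0.5, 0.5
        D = pAB - pA * pB
        dmax = min(pA * (1 - pB), (1 - pA) * pB)
        assert res.dprime == pytest.approx(D / dmax, abs=1e-6)
        assert res.r2 == pytest.approx(D ** 2 / (pA * pB * 0.5 * 0.5), abs=1e-6)

    def test_monomorphic_rejected(self):
        gm = _gm([[0, 1], [0, 1], [0, 0]])
        with pytest.raises(ValueError, match="monomorphic"):
            pairwise_ld(gm, 0, 1)


class TestDprimeCi:
    def test_perfect_ld_tight_lower_bound(self, rng):
        n = 500
        h = rng.random(2 * n) < 0.4
        pairs = [((int(h[2 * k]),) * 2, (int(h[2 * k + 1]),) * 2) for k in range(n)]
        gm = _gm_from_haplotype_pairs(pairs)
        lo, hi = dprime_confidence_interval(gm, 0, 1)
        assert lo >= 0.98

    def test_point_estimate_inside_interval(self, rng):
        for _ in range(5):
            codes = rng.integers(0, 3, size=(60, 2))
            gm = _gm(codes)
            try:
                res = pairwise_ld(gm, 0, 1)
                lo, hi = dprime_confidence_interval(gm, 0, 1)
            except ValueError:
                continue
            assert lo <= res.dprime <= hi

    def test_interval_narrows_with_sample_size(self, rng):
        def width(n, seed):
            ped = simulate_pedigree(1, n, seed)
            config = SimulationConfig(block_specs=[BlockSpec(
                haplotypes=("00", "10", "01"), frequencies=(0.5, 0.3, 0.2))])
            gm, _, _ = simulate_genotypes(ped, config, seed)
            lo, hi = dprime_confidence_interval(gm, 0, 1)
            return hi - lo
        assert width(1000, 5) < width(10, 5)


class TestBlockDetection:
    def test_recovers_planted_two_block_structure(self, study_dataset):
        _, gm, smap, _, _ = study_dataset
        ld = all_pairwise_ld(gm, seed=0)
        blocks = detect_blocks(ld, smap)
        assert blocks.blocks == [(3, 7), (9, 10)]

    def test_free_recombination_yields_no_blocks(self, rng):
        n = 600
        codes = np.column_stack([rng.binomial(2, p, n)
                                 for p in (0.4, 0.3, 0.45, 0.35)])
        gm = _gm(codes)
        from daughterqtl.io import SnpMap
        smap = SnpMap(snp_id=[f"M{j}" for j in range(4)], chromosome=["1"] * 4,
                      position=np.arange(1, 5) * 1000,
                      ref_allele=["A"] * 4, alt_allele=["G"] * 4)
        blocks = detect_blocks(all_pairwise_ld(gm, seed=0), smap)
        assert len(blocks) == 0

    def test_single_perfect_pair_forms_block(self, rng):
        n = 500
        h = rng.random(2 * n) < 0.4
        pairs = [((int(h[2 * k]),) * 2, (int(h[2 * k + 1]),) * 2) for k in range(n)]
        gm = _gm_from_haplotype_pairs(pairs)
        from daughterqtl.io import SnpMap
        smap = SnpMap(snp_id=["M0", "M1"], chromosome=["1", "1"],
                      position=np.array([1000, 2000]),
                      ref_allele=["A", "A"], alt_allele=["G", "G"])
        blocks = detect_blocks(all_pairwise_ld(gm, seed=0), smap)
        assert blocks.blocks == [(0, 1)]

    def test_partition_validation(self):
        with pytest.raises(ValueError):
            BlockPartition(blocks=[(0, 0)])
        with pytest.raises(ValueError):
            BlockPartition(blocks=[(0, 2), (2, 4)])
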