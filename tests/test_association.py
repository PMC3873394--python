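import numpy as np
import pytest
from scipy import stats

from daughterqtl.association import (block_association_test,
                                     genotype_class_lsm, htr_design_matrix,
                                     single_snp_scan, variance_explained)
from daughterqtl.io import GenotypeMatrix
from daughterqtl.ld import em_haplotype_frequencies, pool_rare_haplotypes
from daughterqtl.mixed_model import VarianceComponents
from daughterqtl.simulate import (BlockSpec, SimulationConfig,
                                  simulate_dataset, simulate_ebv_phenotypes)


class TestVarianceExplained:
    @pytest.mark.parametrize("p,a,vp,expected", [
        (0.5, 0.0, 1.0, 0.0),
        (0.5, 1.0, 1.0, 0.5),
        (0.38, 0.2, 4.0, 2 * 0.38 * 0.62 * 0.04 / 4),  # = 0.004712
    ])
    def test_arithmetic(self, p, a, vp, expected):
        assert variance_explained(p, a, vp) == pytest.approx(expected)

    def test_invalid_frequency(self):
        with pytest.raises(ValueError):
            variance_explained(0.0, 1.0, 1.0)


class TestSingleSnpScan:
    def test_detects_causal_snp(self, study_dataset, study_a_inv, vc):
        ped, gm, smap, phen, truth = study_dataset
        res = single_snp_scan(gm, phen, ped, vc, "MY", snp_map=smap,
                              a_inv=study_a_inv)
        assert len(res) == 13
        causal = res[truth.causal_snp]
        assert causal.significant
        # estimate should be in the neighbourhood of the simulated effect
        assert abs(causal.effect - truth.alpha_true) < 4 * causal.se

    def test_var_explained_consistent_with_own_outputs(self, study_dataset,
                                                       study_a_inv, vc):
        ped, gm, smap, phen, _ = study_dataset
        res = single_snp_scan(gm, phen, ped, vc, "MY", snp_map=smap,
                              a_inv=study_a_inv)
        for j, r in enumerate(res):
            col = gm.codes[:, j].astype(float)
            maf = col[col >= 0].mean() / 2
            if 0 < maf < 1:
                assert r.var_explained == pytest.approx(
                    2 * maf * (1 - maf) * r.effect ** 2 / vc.var_p)

    def test_dosage_recode_flips_sign_only(self, small_dataset, vc):
        ped, gm, smap, phen, _ = small_dataset
        res = single_snp_scan(gm, phen, ped, vc, "MY", snps=[0])
        flipped = GenotypeMatrix(ids=gm.ids, codes=np.where(
            gm.codes < 0, gm.codes, 2 - gm.codes))
        res2 = single_snp_scan(flipped, phen, ped, vc, "MY", snps=[0])
        assert res[0].effect == pytest.approx(-res2[0].effect)
        assert res[0].p_raw == pytest.approx(res2[0].p_raw, abs=1e-10)

    def test_monomorphic_snp_soft_path(self, small_dataset, vc):
        ped, gm, _, phen, _ = small_dataset
        mono = GenotypeMatrix(ids=gm.ids,
                              codes=np.zeros_like(gm.codes[:, :1]))
        res = single_snp_scan(mono, phen, ped, vc, "MY")
        assert res[0].p_raw == 1.0 and not res[0].significant

    def test_permuted_phenotypes_give_uniform_p(self, small_dataset, vc, rng):
        """Permutation destroys the association; the p-value distribution
        must be indistinguishable from uniform (KS at alpha = 0.01)."""
        ped, gm, smap, phen, _ = small_dataset
        pvals = []
        base = phen.for_trait("MY")
        from daughterqtl.io import PhenotypeTable
        for _ in range(150):
            perm = base.copy()
            perm["ebv"] = rng.permutation(perm["ebv"].to_numpy())
            res = single_snp_scan(gm, PhenotypeTable(perm), ped, vc, "MY",
                                  snps=[0])
            pvals.append(res[0].p_raw)
        assert stats.kstest(pvals, "uniform").pvalue > 0.01


class TestGenotypeClassLsm:
    def test_monotone_means_for_strong_additive_snp(self, vc):
        config = SimulationConfig(alpha_true=2.0)
        ped, gm, smap, phen, truth = simulate_dataset(config, seed=5)
        lsm = genotype_class_lsm(gm, phen, ped, vc, "MY", truth.causal_snp,
                                 snp_map=smap)
        means = lsm.table["lsm"].to_numpy()
        assert (np.diff(means) > 0).all()
        # extreme classes clearly separated at the 0.01 level
        top, bottom = lsm.table.iloc[-1], lsm.table.iloc[0]
        assert set(top["letters_01"]).isdisjoint(set(bottom["letters_01"]))

    def test_single_class_snp_errors(self, small_dataset, vc):
        ped, gm, _, phen, _ = small_dataset
        mono = GenotypeMatrix(ids=gm.ids, codes=np.ones_like(gm.codes[:, :1]))
        with pytest.raises(ValueError, match="classes"):
            genotype_class_lsm(mono, phen, ped, vc, "MY", 0)

    def test_null_classes_mostly_share_letters(self, vc):
        config = SimulationConfig(alpha_true=0.0, n_sires=6,
                                  daughters_per_sire=40)
        ped, gm, smap, phen, truth = simulate_dataset(config, seed=9)
        lsm = genotype_class_lsm(gm, phen, ped, vc, "MY", 0, snp_map=smap)
        letters = lsm.table["letters_01"]
        shared = set.intersection(*[set(x) for x in letters if x])
        assert shared  # no class pair separated at the 0.01 level


class TestHaplotypeTrendRegression:
    def test_two_haplotype_block_equals_single_snp_test(self, vc):
        """A k=2 block's joint test must reduce to the single-SNP dosage
        test on the non-reference haplotype."""
        spec = BlockSpec(haplotypes=("00", "11"), frequencies=(0.6, 0.4))
        config = SimulationConfig(block_specs=[spec], causal_snp=0,
                                  alpha_true=0.4, n_sires=6,
                                  daughters_per_sire=40)
        ped, gm, smap, phen, _ = simulate_dataset(config, seed=3)
        hs = em_haplotype_frequencies(gm, (0, 1), seed=0, snp_map=smap)
        pooled = pool_rare_haplotypes(hs)
        design = htr_design_matrix(pooled, gm.ids)
        r = block_association_test(design, phen, ped, vc, "MY")
        snp = single_snp_scan(gm, phen, ped, vc, "MY", snps=[0])[0]
        assert r.df == 1
        assert r.p_raw == pytest.approx(snp.p_raw, abs=1e-9)

    def test_reference_choice_invariance(self, study_dataset, study_a_inv, vc):
        ped, gm, smap, phen, _ = study_dataset
        hs = em_haplotype_frequencies(gm, range(3, 8), seed=0, snp_map=smap)
        pooled = pool_rare_haplotypes(hs)
        design = htr_design_matrix(pooled, gm.ids)
        stats_ = []
        for ref in pooled.haplotypes:
            r = block_association_test(design, phen, ped, vc, "MY",
                                       a_inv=study_a_inv, reference=ref)
            stats_.append(r.wald_chisq)
            assert r.df == len(pooled.haplotypes) - 1
        assert np.ptp(stats_) < 1e-6

    def test_phase_certain_dosages_match_true_phases(self, vc):
        """When phase is unambiguous, EM posterior dosages equal the true
        phase counts, so both give identical block tests."""
        spec = BlockSpec(haplotypes=("00", "11"), frequencies=(0.5, 0.5))
        config = SimulationConfig(block_specs=[spec], causal_snp=None,
                                  n_sires=5, daughters_per_sire=30)
        ped, gm, smap, phen, truth = simulate_dataset(config, seed=13)
        hs = em_haplotype_frequencies(gm, (0, 1), seed=0)
        pooled = pool_rare_haplotypes(hs)
        # true dosage of each haplotype from the generator's phases
        ph = truth.phases[0]
        bits = spec.bits
        true_dos = np.zeros((len(ped), 2))
        order = [hs.hap_bits.index(tuple(b)) for b in bits]
        for i in range(len(ped)):
            for m in range(2):
                true_dos[i, order[ph[i, m]]] += 1
        np.testing.assert_allclose(pooled.dosages, true_dos, atol=1e-9)

    def test_joint_test_finds_block_effect(self, study_dataset, study_a_inv, vc):
        ped, gm, smap, phen, _ = study_dataset
        hs = em_haplotype_frequencies(gm, range(3, 8), seed=0, snp_map=smap)
        design = htr_design_matrix(pool_rare_haplotypes(hs), gm.ids)
        r = block_association_test(design, phen, ped, vc, "MY",
                                   a_inv=study_a_inv, n_blocks=2)
        assert r.p_raw < 0.05 / 2
        assert r.significant
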