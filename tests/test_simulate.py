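"""Generator contracts: design shape, Mendelian consistency, variance targets."""

import numpy as np
import pytest

from gsq.io import adjust_phenotypes
from gsq.simulate import (SimConfig, TraitArchitecture, simulate_genotypes,
                          simulate_phenotypes)


class TestConfig:
    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(n_markers=5, n_chromosomes=11)
        with pytest.raises(ValueError):
            SimConfig(selfing_rate=1.5)
        with pytest.raises(ValueError):
            SimConfig(n_families=0)
        with pytest.raises(ValueError):
            TraitArchitecture("t", 2, (0.6, 0.6))

    def test_design_shape(self):
        cfg = SimConfig(n_families=49, offspring_per_family=10, n_markers=500,
                        n_chromosomes=11, seed=1)
        sim = simulate_genotypes(cfg)
        assert sim.geno.n_individuals == 490
        assert sim.founders.n_individuals == 49
        assert len(sim.pedigree) == 49 + 490
        # markers spread over chromosomes with sorted positions
        meta = sim.geno.marker_meta
        assert meta["chrom"].nunique() == 11
        for _, grp in meta.groupby("chrom"):
            assert (np.diff(grp["pos"]) >= 0).all()

    def test_same_seed_bit_identical(self):
        cfg = SimConfig(n_families=8, offspring_per_family=4, n_markers=100,
                        n_chromosomes=2, seed=7)
        a = simulate_genotypes(cfg)
        b = simulate_genotypes(cfg)
        np.testing.assert_array_equal(a.geno.codes, b.geno.codes)
        arch = TraitArchitecture("t", 2, (0.05, 0.05), 0.2, 0.1)
        pa, ta = simulate_phenotypes(a.geno, a.pedigree, arch, seed=3)
        pb, tb = simulate_phenotypes(b.geno, b.pedigree, arch, seed=3)
        assert pa.equals(pb)
        np.testing.assert_array_equal(ta.true_breeding_values,
                                      tb.true_breeding_values)


class TestMendelianConsistency:
    def test_selfed_offspring_inherit_only_dam_alleles(self):
        cfg = SimConfig(n_families=10, offspring_per_family=10, n_markers=300,
                        n_chromosomes=3, selfing_rate=1.0, seed=11)
        sim = simulate_genotypes(cfg)
        dams = sim.founders.codes
        for f in range(10):
            fam = sim.geno.codes[f * 10:(f + 1) * 10]
            dam = dams[f]
            # dam hom-ref -> no alt allele in offspring; hom-alt -> no ref
            assert (fam[:, dam == 0] == 0).all()
            assert (fam[:, dam == 2] == 2).all()


class TestPhenotypes:
    def test_zero_signal_variance_is_block_plus_residual(self):
        cfg = SimConfig(n_families=49, offspring_per_family=10, n_markers=60,
                        n_chromosomes=2, n_subpops=1, target_fst=0.0,
                        block_variance=0.4, seed=21)
        sim = simulate_genotypes(cfg)
        arch = TraitArchitecture("t", 0, (), 0.0, 0.0)
        pheno, _ = simulate_phenotypes(sim.geno, sim.pedigree, arch,
                                       block_variance=0.4, seed=22)
        v = pheno["t"].var()
        assert v == pytest.approx(0.4 + 1.0, rel=0.15)

    def test_ordinal_values_in_level_set(self):
        cfg = SimConfig(n_families=10, offspring_per_family=6, n_markers=80,
                        n_chromosomes=2, seed=31)
        sim = simulate_genotypes(cfg)
        arch = TraitArchitecture("t", 0, (), 0.3, 0.0, scale="ordinal",
                                 ordinal_levels=4, ordinal_start=0)
        pheno, _ = simulate_phenotypes(sim.geno, sim.pedigree, arch, seed=32)
        assert set(pheno["t"]) <= {0.0, 1.0, 2.0, 3.0}
        arch5 = TraitArchitecture("t", 0, (), 0.3, 0.0, scale="ordinal",
                                  ordinal_levels=5, ordinal_start=1)
        pheno5, _ = simulate_phenotypes(sim.geno, sim.pedigree, arch5, seed=33)
        assert set(pheno5["t"]) <= {1.0, 2.0, 3.0, 4.0, 5.0}

    def test_qtl_count_exceeding_markers_rejected(self):
        cfg = SimConfig(n_families=5, offspring_per_family=4, n_markers=10,
                        n_chromosomes=2, seed=41)
        sim = simulate_genotypes(cfg)
        arch = TraitArchitecture("t", 11, tuple([0.01] * 11), 0.0, 0.0)
        with pytest.raises(ValueError, match="exceeds marker count"):
            simulate_phenotypes(sim.geno, sim.pedigree, arch, seed=1)

    def test_realized_per_qtl_variance_tracks_target(self):
        # averaged over 50 phenotype seeds, each QTL's realized share is
        # within 30% relative error of its architecture target
        cfg = SimConfig(n_families=30, offspring_per_family=8, n_markers=150,
                        n_chromosomes=3, n_subpops=1, target_fst=0.0,
                        block_variance=0.0, seed=51)
        sim = simulate_genotypes(cfg)
        targets = (0.10, 0.05)
        arch = TraitArchitecture("t", 2, targets, 0.1, 0.1)
        realized = []
        for s in range(50):
            _, truth = simulate_phenotypes(sim.geno, sim.pedigree, arch,
                                           seed=1000 + s)
            realized.append(truth.realized_h2_components["per_qtl"])
        mean_realized = np.mean(realized, axis=0)
        np.testing.assert_allclose(mean_realized, targets, rtol=0.30)

    def test_block_effects_removed_by_adjustment(self):
        cfg = SimConfig(n_families=20, offspring_per_family=8, n_markers=60,
                        n_chromosomes=2, block_variance=2.0, seed=61)
        sim = simulate_genotypes(cfg)
        arch = TraitArchitecture("t", 0, (), 0.0, 0.0)
        pheno, _ = simulate_phenotypes(sim.geno, sim.pedigree, arch,
                                       n_blocks=10, block_variance=2.0, seed=62)
        adj = adjust_phenotypes(pheno, "t")
        assert adj.y_star.var() < pheno["t"].var()
        assert abs(adj.y_star.mean()) < 1e-10
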