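"""Heritability partition, DIC, the DIC-difference rule and cross-validation."""

import numpy as np
import pytest

from gsq.evaluate import (cross_validate, delta_dic, dic, heritabilities,
                          make_folds, predictive_ability)
from gsq.io import adjust_phenotypes
from gsq.kinship import pedigree_A
from gsq.simulate import SimConfig, TraitArchitecture, simulate_genotypes, \
    simulate_phenotypes
from gsq.wgr import MCMCSettings, ModelSpec


class TestHeritabilities:
    @pytest.mark.parametrize("draws,expected", [
        ((1, 1, 1, 1), (0.25, 0.25, 0.25)),
        ((2, 1, 1, 4), (0.25, 0.125, 0.125)),
        ((1, 1, 0, 2), (0.25, 0.25, 0.0)),     # GS: sigma_q^2 = 0
    ])
    def test_constant_draw_instances(self, draws, expected):
        h = heritabilities(*[np.array([v], dtype=float) for v in draws])
        assert (h.h2_a, h.h2_m, h.h2_q) == pytest.approx(expected)

    def test_scale_invariance(self):
        rng = np.random.default_rng(7)
        draws = [rng.gamma(2, 1, 100) for _ in range(4)]
        h1 = heritabilities(*draws)
        h2 = heritabilities(*[3.7 * d for d in draws])
        assert (h1.h2_a, h1.h2_m, h1.h2_q) == pytest.approx(
            (h2.h2_a, h2.h2_m, h2.h2_q))

    def test_ratio_of_draws_not_ratio_of_means(self):
        sa = np.array([1.0, 9.0])
        se = np.array([9.0, 1.0])
        z = np.zeros(2)
        h = heritabilities(sa, z, z, se)
        assert h.h2_a == pytest.approx(0.5)  # per-draw 0.1 and 0.9 averaged

    def test_zero_denominator_rejected(self):
        with pytest.raises(ValueError):
            heritabilities(np.zeros(2), np.zeros(2), np.zeros(2), np.zeros(2))


class TestDic:
    def test_degenerate_posterior(self):
        r = dic(np.array([5.0, 5.0]), 5.0)
        assert (r.dic, r.p_d) == (5.0, 0.0)

    def test_arithmetic_instance(self):
        r = dic(np.array([10.0, 12.0]), 9.0)
        assert (r.d_bar, r.p_d, r.dic) == (11.0, 2.0, 13.0)
        assert r.dic == r.d_bar + r.p_d

    def test_order_invariance(self):
        draws = np.array([3.0, 9.0, 4.5, 7.5])
        assert dic(draws, 2.0).dic == dic(draws[::-1], 2.0).dic

    def test_conjugate_normal_mean_pd(self):
        # y_i ~ N(theta, s2) known s2, theta ~ N(0, t2): the effective
        # parameter count is the shrinkage factor n t2 / (n t2 + s2)
        rng = np.random.default_rng(11)
        n, s2, t2 = 25, 2.0, 1.5
        y = rng.normal(1.0, np.sqrt(s2), n)
        post_var = 1.0 / (n / s2 + 1 / t2)
        post_mean = post_var * y.sum() / s2
        thetas = rng.normal(post_mean, np.sqrt(post_var), 40_000)
        dev = np.array([n * np.log(2 * np.pi * s2)
                        + np.sum((y - th) ** 2) / s2 for th in thetas])
        d_at_mean = n * np.log(2 * np.pi * s2) + np.sum((y - post_mean) ** 2) / s2
        r = dic(dev, d_at_mean)
        expected_pd = n * t2 / (n * t2 + s2)
        assert r.p_d == pytest.approx(expected_pd, abs=0.1)

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            dic(np.array([1.0, np.inf]), 1.0)


class TestDeltaDic:
    @pytest.mark.parametrize("gs,gsq,delta,verdict", [
        (1968.9, 1951.2, 17.7, "strong"),
        (947.7, 947.0, 0.7, "not significant"),
        (2042.0, 2070.3, -28.3, "strong"),
        (1300.0, 1292.5, 7.5, "substantial"),
    ])
    def test_rule(self, gs, gsq, delta, verdict):
        d, v = delta_dic(gs, gsq)
        assert d == pytest.approx(delta)
        assert v == verdict


class TestPredictiveAbility:
    def test_perfect_and_anti(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        assert predictive_ability(y, y) == pytest.approx(1.0)
        assert predictive_ability(y, -y) == pytest.approx(-1.0)

    def test_hand_pearson(self):
        assert predictive_ability([1, 2, 3, 4], [1, 3, 2, 4]) == pytest.approx(0.8)

    def test_zero_variance_missing(self):
        assert np.isnan(predictive_ability([1, 2, 3], [5, 5, 5]))


class TestCrossValidation:
    def test_fold_partition_arithmetic(self):
        folds = make_folds(480, 20, seed=1)
        counts = np.bincount(folds)
        assert len(counts) == 20 and (counts == 24).all()

    def test_fold_determinism(self):
        np.testing.assert_array_equal(make_folds(100, 5, 3), make_folds(100, 5, 3))

    def test_oracle_predictor_pa_near_h(self):
        # feeding the true breeding values as predictor bounds PA at
        # corr(y, g) ~ h = sqrt(0.4)
        cfg = SimConfig(n_families=49, offspring_per_family=10, n_markers=200,
                        n_chromosomes=2, n_subpops=1, target_fst=0.0,
                        block_variance=0.0, seed=13)
        sim = simulate_genotypes(cfg)
        arch = TraitArchitecture("t", 4, (0.05,) * 4, 0.1, 0.1)  # h2 = 0.4
        pas = []
        for s in range(5):
            pheno, truth = simulate_phenotypes(sim.geno, sim.pedigree, arch,
                                               seed=1400 + s)
            y = adjust_phenotypes(pheno, "t")
            pas.append(predictive_ability(y.y_star, truth.true_breeding_values))
        assert np.mean(pas) == pytest.approx(np.sqrt(0.4), abs=0.1)

    def test_cv_refit_deterministic_and_sane(self):
        cfg = SimConfig(n_families=15, offspring_per_family=6, n_markers=120,
                        n_chromosomes=2, n_subpops=1, target_fst=0.0, seed=17)
        sim = simulate_genotypes(cfg)
        arch = TraitArchitecture("t", 2, (0.15, 0.15), 0.2, 0.0)
        pheno, _ = simulate_phenotypes(sim.geno, sim.pedigree, arch, seed=18)
        y = adjust_phenotypes(pheno, "t")
        A = pedigree_A(sim.pedigree)
        spec = ModelSpec("BRR", "GS", None, [("A", A)],
                         MCMCSettings(800, 200, 2, seed=19))
        cv1 = cross_validate(y, sim.geno, spec, n_folds=5, seed=20)
        cv2 = cross_validate(y, sim.geno, spec, n_folds=5, seed=20)
        np.testing.assert_array_equal(cv1.fold_assignment, cv2.fold_assignment)
        np.testing.assert_array_equal(cv1.per_fold_pa, cv2.per_fold_pa)
        assert -1 <= cv1.mean_pa <= 1

    def test_tiny_fold_rejected(self):
        cfg = SimConfig(n_families=4, offspring_per_family=2, n_markers=20,
                        n_chromosomes=2, seed=23)
        sim = simulate_genotypes(cfg)
        arch = TraitArchitecture("t", 0, (), 0.2, 0.0)
        pheno, _ = simulate_phenotypes(sim.geno, sim.pedigree, arch, seed=24)
        y = adjust_phenotypes(pheno, "t")
        spec = ModelSpec("BRR", "GS", None, [], MCMCSettings(100, 10, 1, 1))
        with pytest.raises(ValueError, match="fewer than 3"):
            cross_validate(y, sim.geno, spec, n_folds=4, seed=25)
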