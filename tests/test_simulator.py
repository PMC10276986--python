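"""Calibration and arithmetic tests for the genotype/phenotype simulator."""

import dataclasses

import numpy as np
import pytest
from scipy.special import expit

from wbha import SimulationDesign, simulate_study
from wbha.simulate import (
    CAUSAL_MAF_RANGES,
    EFFECT_TABLE,
    GROUPS,
    assign_effects,
    assign_mafs,
    calibrate_intercept,
    causal_group_sizes,
    residual_variance,
    simulate_binary_trait,
    simulate_genotypes,
    simulate_quantitative_trait,
)


class TestMafAssignment:
    @pytest.mark.parametrize("m1", [5, 10, 15, 20, 25, 50, 100, 150])
    def test_group_sizes_follow_euclidean_rule(self, m1):
        q, r = divmod(m1, 4)
        assert causal_group_sizes(m1) == (q, q, q, q + r)

    def test_remainder_goes_to_common_group(self):
        assert causal_group_sizes(10) == (2, 2, 2, 4)
        assert causal_group_sizes(4) == (1, 1, 1, 1)

    def test_no_causal_markers(self):
        design = SimulationDesign(m=500, m1=0, seed=0)
        maf, causal, labels = assign_mafs(design)
        assert causal.size == 0
        assert np.all(labels == "null")
        assert maf.min() >= 0.01 and maf.max() <= 0.5

    def test_causal_mafs_lie_in_group_ranges(self):
        design = SimulationDesign(m=2000, m1=100, seed=3)
        maf, causal, labels = assign_mafs(design)
        assert causal.size == 100
        for group, (lo, hi) in CAUSAL_MAF_RANGES.items():
            members = maf[labels == group]
            assert members.size == causal_group_sizes(100)[GROUPS.index(group)]
            assert np.all((members >= lo) & (members <= hi))

    def test_m1_exceeding_m_rejected(self):
        with pytest.raises(ValueError):
            SimulationDesign(m=10, m1=11)


class TestGenotypes:
    @pytest.mark.parametrize("p", [0.01, 0.05, 0.1, 0.25, 0.5])
    def test_hwe_frequency_recovery(self, p):
        """Empirical genotype frequencies match (q^2, 2pq, p^2) within 4 SE
        at n = 20000."""
        n = 20000
        design = SimulationDesign(n=n, m=1, m1=0, rho=0.0, seed=17)
        G = simulate_genotypes(design, [p], rng=np.random.default_rng(17))
        q = 1.0 - p
        expected = {0: q**2, 1: 2 * p * q, 2: p**2}
        for g, freq in expected.items():
            observed = np.mean(G[:, 0] == g)
            se = np.sqrt(freq * (1 - freq) / n)
            assert abs(observed - freq) <= 4 * se + 1e-12

    def test_block_latent_correlation(self):
        design = SimulationDesign(n=20000, m=2, m1=0, rho=0.75, block_size=2, seed=5)
        G, latent = simulate_genotypes(
            design, [0.3, 0.3], rng=np.random.default_rng(5), return_latent=True
        )
        r_latent = np.corrcoef(latent.T)[0, 1]
        assert abs(r_latent - 0.75) < 0.02
        assert np.corrcoef(G.T.astype(float))[0, 1] > 0.4

    def test_independent_markers_uncorrelated_across_blocks(self):
        design = SimulationDesign(n=2000, m=200, m1=0, rho=0.0, seed=9)
        maf = np.full(200, 0.3)
        G = simulate_genotypes(design, maf, rng=np.random.default_rng(9))
        corr = np.corrcoef(G.T.astype(float))
        off = np.abs(corr[np.triu_indices(200, k=1)])
        assert np.quantile(off, 0.99) < 0.1

    def test_invalid_maf_rejected(self):
        design = SimulationDesign(n=100, m=2, m1=0)
        with pytest.raises(ValueError):
            simulate_genotypes(design, [0.0, 0.3], rng=np.random.default_rng(0))
        with pytest.raises(ValueError):
            simulate_genotypes(design, [0.3, 0.6], rng=np.random.default_rng(0))


class TestEffects:
    @pytest.mark.parametrize(
        "trait, scenario, expected",
        [
            ("quantitative", 1, (4, 3, 2, 1)),
            ("quantitative", 2, (1, 2, 3, 4)),
            ("quantitative", 3, (2, 2, 2, 2)),
            ("binary", 1, tuple(np.log([2.2, 1.8, 1.5, 1.3]))),
            ("binary", 2, tuple(np.log([1.3, 1.5, 1.8, 2.2]))),
            ("binary", 3, tuple(np.log([1.5] * 4))),
        ],
    )
    def test_scenario_table(self, trait, scenario, expected):
        design = SimulationDesign(trait=trait, scenario=scenario)
        labels = np.array(list(GROUPS) + ["null"], dtype=object)
        beta = assign_effects(design, labels)
        np.testing.assert_allclose(beta[:4], expected)
        assert beta[4] == 0.0

    def test_unknown_scenario_rejected(self):
        with pytest.raises(ValueError):
            SimulationDesign(scenario=4)


class TestQuantitativeTrait:
    def test_residual_variance_hand_example(self):
        # score (0,1,2,3): SS = 5, n-2 = 2, R^2 = 0.2 -> (0.8*5)/(0.2*2) = 10
        assert residual_variance([0.0, 1.0, 2.0, 3.0], 0.2) == pytest.approx(10.0)

    def test_high_r_squared_limit_recovers_score(self, rng):
        G = rng.integers(0, 3, size=(50, 4)).astype(np.int8)
        beta = np.array([1.0, 0.0, 2.0, 0.0])
        y = simulate_quantitative_trait(G, beta, r_squared=1 - 1e-9, rng=rng)
        score = G[:, [0, 2]].astype(float) @ np.array([1.0, 2.0])
        np.testing.assert_allclose(y, score, atol=1e-3)

    def test_empirical_r_squared_recovery(self):
        """Regressing y on the genetic score recovers the target R^2 = 0.2
        within 0.02 on average."""
        r2s = []
        for seed in range(10):
            design = SimulationDesign(n=5000, m=100, m1=8, rho=0.0, seed=seed)
            study = simulate_study(design)
            score = study.G[:, study.beta != 0].astype(float) @ study.beta[study.beta != 0]
            r = np.corrcoef(score, study.y)[0, 1]
            r2s.append(r**2)
        assert abs(np.mean(r2s) - 0.2) < 0.02

    def test_all_null_betas_fall_back_to_unit_noise(self, rng):
        G = rng.integers(0, 3, size=(100, 5)).astype(np.int8)
        with pytest.warns(UserWarning, match="constant genetic score"):
            y = simulate_quantitative_trait(G, np.zeros(5), 0.2, rng=rng)
        assert y.std() == pytest.approx(1.0, abs=0.3)


class TestBinaryTrait:
    def test_intercept_calibration_is_exact(self, rng):
        score = rng.normal(2.0, 3.0, size=1000)
        b0 = calibrate_intercept(score)
        assert abs(expit(b0 + score).mean() - 0.5) < 1e-8

    def test_null_model_gives_fair_coin(self, rng):
        G = rng.integers(0, 3, size=(5000, 3)).astype(np.int8)
        assert calibrate_intercept(np.zeros(5000)) == pytest.approx(0.0, abs=1e-10)
        y = simulate_binary_trait(G, np.zeros(3), rng=rng)
        assert set(np.unique(y)) <= {0, 1}

    def test_balanced_case_fraction_at_scale(self):
        design = SimulationDesign(
            n=20000, m=400, m1=20, rho=0.0, trait="binary", scenario=1, seed=23
        )
        study = simulate_study(design)
        assert 0.47 <= study.y.mean() <= 0.53


class TestStudyComposition:
    def test_default_design_shapes_and_group_sizes(self):
        design = SimulationDesign(n=200, m=800, m1=25, rho=0.0, seed=1)
        study = simulate_study(design)
        assert study.G.shape == (200, 800)
        assert np.count_nonzero(study.beta) == 25
        sizes = [np.count_nonzero(study.maf_group == g) for g in GROUPS]
        assert sizes == [6, 6, 6, 7]

    def test_bit_identical_given_seed(self):
        design = SimulationDesign(n=150, m=300, m1=8, rho=0.35, seed=99)
        s1, s2 = simulate_study(design), simulate_study(design)
        assert np.array_equal(s1.G, s2.G)
        assert np.array_equal(s1.y, s2.y)
        assert np.array_equal(s1.maf, s2.maf)
        assert np.array_equal(s1.is_causal, s2.is_causal)

    def test_large_m_path_shape_correctness(self):
        """The larger-m settings run through the same code path; check
        shapes and group arithmetic at m = 20000."""
        design = SimulationDesign(n=100, m=20000, m1=100, rho=0.0, seed=2)
        study = simulate_study(design)
        assert study.G.shape == (100, 20000)
        assert study.is_causal.sum() == 100

    def test_plugin_genotype_matrix(self):
        base = simulate_study(SimulationDesign(n=300, m=500, m1=0, rho=0.0, seed=7))
        design = SimulationDesign(n=300, m=500, m1=8, rho=0.0, seed=11)
        study = simulate_study(design, genotypes=base.G)
        assert np.array_equal(study.G, base.G)
        assert study.is_causal.sum() == 8
        # causal markers must sit in their observed-MAF bins
        for group, size in zip(GROUPS, (2, 2, 2, 2)):
            assert np.count_nonzero(study.maf_group == group) == size

    def test_plugin_matrix_without_rare_markers_errors(self, rng):
        # all markers common: no marker can serve as a rare causal variant
        G = rng.integers(0, 3, size=(200, 50)).astype(np.int8)
        design = SimulationDesign(n=200, m=50, m1=8, seed=0)
        with pytest.raises(ValueError, match="MAF"):
            simulate_study(design, genotypes=G)

    def test_plugin_matrix_shape_mismatch_errors(self, rng):
        G = rng.integers(0, 3, size=(50, 20)).astype(np.int8)
        with pytest.raises(ValueError, match="shape"):
            simulate_study(SimulationDesign(n=60, m=20, m1=0), genotypes=G)

    def test_design_validation(self):
        for kwargs in (
            dict(rho=1.0),
            dict(r_squared=0.0),
            dict(trait="ordinal"),
            dict(block_size=0),
        ):
            with pytest.raises(ValueError):
                SimulationDesign(**kwargs)

    def test_scenario_effects_attached_to_groups(self):
        design = SimulationDesign(n=100, m=400, m1=8, scenario=1, seed=4)
        study = simulate_study(design)
        for group, expected in zip(GROUPS, EFFECT_TABLE["quantitative"][1]):
            np.testing.assert_allclose(study.beta[study.maf_group == group], expected)
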