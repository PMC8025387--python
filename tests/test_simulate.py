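"""Synthetic-cohort generator: copula treatment correlation, mixture
methylation with injected effects, outcomes, genotypes, reproducibility."""

import numpy as np
import pandas as pd
import pytest

from ewasmed.simulate import (
    OutcomeModel,
    SimulationConfig,
    generate_genotypes,
    generate_methylation,
    generate_outcomes,
    generate_treatments,
    phi_to_latent_rho,
    simulate_cohort,
)


def _phi(x, y):
    return np.corrcoef(x, y)[0, 1]


class TestTreatments:
    def test_independent_treatments_have_near_zero_phi(self):
        cfg = SimulationConfig(
            n_samples=5000, treatments=[("a", 0.5), ("b", 0.5)], seed=7
        )
        T = generate_treatments(cfg)
        assert abs(_phi(T["a"], T["b"])) < 0.05

    def test_target_phi_recovered_via_copula_inversion(self):
        # Monte-Carlo check of the tetrachoric conversion: simulate at the
        # solved latent rho and confirm the empirical phi hits the target.
        cfg = SimulationConfig(
            n_samples=5000,
            treatments=[("a", 0.5), ("b", 0.5)],
            phi_targets=np.array([[1.0, 0.6], [0.6, 1.0]]),
            seed=11,
        )
        T = generate_treatments(cfg)
        assert _phi(T["a"], T["b"]) == pytest.approx(0.6, abs=0.05)
        # for equal 50/50 margins the tetrachoric rho = sin(pi/2 * phi)
        assert phi_to_latent_rho(0.6, 0.5, 0.5) == pytest.approx(
            np.sin(np.pi / 2 * 0.6), abs=1e-6
        )

    def test_column_means_match_prevalences(self):
        cfg = SimulationConfig(
            n_samples=8000, treatments=[("a", 0.2), ("b", 0.7)], seed=3
        )
        T = generate_treatments(cfg)
        assert T["a"].mean() == pytest.approx(0.2, abs=0.02)
        assert T["b"].mean() == pytest.approx(0.7, abs=0.02)

    def test_same_seed_reproduces_matrix(self):
        cfg = SimulationConfig(n_samples=200, seed=5)
        pd.testing.assert_frame_equal(generate_treatments(cfg), generate_treatments(cfg))

    def test_infeasible_phi_structure_names_a_pair(self):
        phi = np.array(
            [[1.0, 0.9, -0.9], [0.9, 1.0, 0.9], [-0.9, 0.9, 1.0]]
        )
        cfg = SimulationConfig(
            n_samples=100,
            treatments=[("a", 0.5), ("b", 0.5), ("c", 0.5)],
            phi_targets=phi,
        )
        with pytest.raises(ValueError, match="positive semidefinite.*'"):
            generate_treatments(cfg)


class TestMethylation:
    def test_single_cell_type_no_noise_reproduces_reference(self, rng):
        ref = rng.uniform(0.2, 0.8, size=(1, 30))
        cfg = SimulationConfig(
            n_samples=5, n_cpgs=30, n_cell_types=1,
            reference_profiles=ref, dirichlet_alpha=np.array([1.0]),
            noise_sd=0.0, seed=1,
        )
        T = generate_treatments(cfg, np.random.default_rng(1))
        props = np.ones((5, 1))
        mm, _, _ = generate_methylation(cfg, T, props, np.random.default_rng(2))
        np.testing.assert_allclose(mm.values, np.tile(ref.T, (1, 5)), atol=1e-9)

    def test_injected_delta_is_exact_without_noise(self, rng):
        ref = rng.uniform(0.3, 0.7, size=(1, 10))
        cfg = SimulationConfig(
            n_samples=200, n_cpgs=10, n_cell_types=1,
            reference_profiles=ref, dirichlet_alpha=np.array([1.0]),
            noise_sd=0.0, causal_cpgs={"chemo": [(4, 1.0)]},
            treatments=[("chemo", 0.5)], seed=2,
        )
        T = generate_treatments(cfg)
        mm, _, _ = generate_methylation(cfg, T, np.ones((200, 1)), np.random.default_rng(3))
        M = mm.to_m().values
        exposed = T["chemo"].values == 1
        diff = M[4, exposed].mean() - M[4, ~exposed].mean()
        assert diff == pytest.approx(1.0, abs=1e-9)

    def test_detection_failure_rate_binomial(self):
        cfg = SimulationConfig(
            n_samples=1000, n_cpgs=100, detection_fail_rate=0.02, seed=9,
            treatments=[("t", 0.5)],
        )
        T = generate_treatments(cfg)
        rng = np.random.default_rng(9)
        props = np.random.default_rng(1).dirichlet(np.ones(6), size=1000)
        from ewasmed.simulate import default_reference_profiles

        ref = default_reference_profiles(6, 100, np.random.default_rng(0))
        cfg.reference_profiles = ref
        _, det, _ = generate_methylation(cfg, T, props, rng)
        frac = (det > 0.01).mean()
        assert frac == pytest.approx(0.02, abs=0.005)

    def test_reference_shape_mismatch_raises(self, rng):
        cfg = SimulationConfig(n_samples=5, n_cpgs=10, n_cell_types=2,
                               reference_profiles=rng.uniform(0.2, 0.8, (2, 7)))
        T = generate_treatments(cfg, np.random.default_rng(0))
        with pytest.raises(ValueError, match="reference profile shape"):
            generate_methylation(cfg, T, np.full((5, 2), 0.5), np.random.default_rng(0))


class TestOutcomes:
    def _cohort_bits(self, n, cfg_extra, seed=0):
        cfg = SimulationConfig(
            n_samples=n, n_cpgs=20, treatments=[("t", 0.5)], seed=seed, **cfg_extra
        )
        return cfg, simulate_cohort(cfg)

    def test_zero_model_gives_half_prevalence(self):
        _, co = self._cohort_bits(4000, {"outcome_models": {"x": OutcomeModel()}})
        assert co.sample_sheet["chc_x"].mean() == pytest.approx(0.5, abs=0.03)

    def test_intercept_minus_two_gives_logistic_prevalence(self):
        _, co = self._cohort_bits(
            10000, {"outcome_models": {"x": OutcomeModel(intercept=-2.0)}}
        )
        assert co.sample_sheet["chc_x"].mean() == pytest.approx(0.1192, abs=0.02)

    def test_mediated_effect_raises_exposed_prevalence(self):
        _, co = self._cohort_bits(
            4000,
            {
                "causal_cpgs": {"t": [(0, 1.0)]},
                "noise_sd": 0.3,
                "outcome_models": {
                    "x": OutcomeModel(mediator_coefs={0: 1.0})
                },
            },
        )
        sheet = co.sample_sheet
        p1 = sheet.loc[sheet["t"] == 1, "chc_x"].mean()
        p0 = sheet.loc[sheet["t"] == 0, "chc_x"].mean()
        assert p1 > p0 + 0.05

    def test_unknown_mediator_cpg_rejected(self):
        with pytest.raises(ValueError, match="unknown CpG"):
            self._cohort_bits(
                50, {"outcome_models": {"x": OutcomeModel(mediator_coefs={99: 1.0})}}
            )

    def test_prevalent_fraction_flagged(self):
        _, co = self._cohort_bits(
            6000,
            {"outcome_models": {"x": OutcomeModel(prevalent_frac=0.1)}},
        )
        sheet = co.sample_sheet
        cases = sheet["chc_x"] == 1
        frac = sheet.loc[cases, "prevalent_x"].mean()
        assert frac == pytest.approx(0.1, abs=0.02)


class TestGenotypes:
    def test_mean_dosage_at_half_maf(self):
        cfg = SimulationConfig(n_samples=10000, maf=np.array([0.5]), seed=4)
        G = generate_genotypes(cfg)
        assert G.iloc[:, 0].mean() == pytest.approx(1.0, abs=0.03)

    def test_hardy_weinberg_homozygote_frequency(self):
        cfg = SimulationConfig(n_samples=10000, maf=np.array([0.1]), seed=5)
        G = generate_genotypes(cfg)
        assert (G.iloc[:, 0] == 2).mean() == pytest.approx(0.01, abs=0.01)

    def test_seeded_reproducibility(self):
        cfg = SimulationConfig(n_samples=500, n_snps=10, seed=6)
        pd.testing.assert_frame_equal(generate_genotypes(cfg), generate_genotypes(cfg))

    def test_maf_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="0, 0.5"):
            SimulationConfig(n_samples=10, maf=np.array([0.7]))

    def test_correlated_pair_has_high_r2(self):
        cfg = SimulationConfig(
            n_samples=4000, n_snps=3, maf=np.array([0.3, 0.3, 0.3]),
            correlated_snp_pairs=[(0, 1, 0.05)], seed=8,
        )
        G = generate_genotypes(cfg)
        r = np.corrcoef(G.iloc[:, 0], G.iloc[:, 1])[0, 1]
        assert r**2 > 0.8


class TestCohortBundle:
    def test_full_simulation_is_seed_deterministic(self):
        cfg = SimulationConfig(
            n_samples=80, n_cpgs=40,
            causal_cpgs={"chemo": [(0, 0.8)]},
            outcome_models={"x": OutcomeModel(treatment_coefs={"chemo": 0.4})},
            treatments=[("chemo", 0.5), ("radio", 0.3)],
            prs_panels={"x": [0, 1]}, seed=12,
        )
        a, b = simulate_cohort(cfg), simulate_cohort(cfg)
        pd.testing.assert_frame_equal(a.sample_sheet, b.sample_sheet)
        np.testing.assert_array_equal(a.beta.values, b.beta.values)
        np.testing.assert_array_equal(a.genotypes.values, b.genotypes.values)

    def test_ground_truth_designed_proportion(self):
        # delta * b / (delta * b + c) on the linear-probability scale
        cfg = SimulationConfig(
            n_samples=50, n_cpgs=10,
            treatments=[("t", 0.5)],
            causal_cpgs={"t": [(2, 0.8)]},
            outcome_models={
                "x": OutcomeModel(treatment_coefs={"t": 0.3}, mediator_coefs={2: 0.875})
            },
            seed=13,
        )
        co = simulate_cohort(cfg)
        triples = co.ground_truth.mediator_triples
        assert len(triples) == 1
        t, idx, chc, prop = triples[0]
        assert (t, idx, chc) == ("t", 2, "x")
        assert prop == pytest.approx(0.7, abs=1e-12)
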