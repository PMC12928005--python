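"""Generators: HWE genotypes, noise families, exposures, outcomes, LD blocks."""

import numpy as np
import pytest
from scipy import stats
from scipy.integrate import quad

from ganiv.synthetic import (
    CausalFunctionSpec,
    NoiseSpec,
    causal_effect,
    draw_noise,
    make_linear_exposure,
    make_outcome,
    make_pleiotropy_dataset,
    make_simulation1_dataset,
    simulate_genotypes,
    simulate_ld_block,
)


class TestGenotypes:
    def test_degenerate_maf_gives_all_zero_dosages(self):
        Z = simulate_genotypes(100, 2, 1e-12, seed=0)
        assert np.all(Z == 0)

    def test_mean_dosage_matches_hwe_closed_form(self):
        Z = simulate_genotypes(100_000, 1, 0.2, seed=1)
        assert abs(Z.mean() - 0.4) < 0.01  # mean = 2 * maf

    def test_seed_determinism(self):
        a = simulate_genotypes(50, 5, 0.3, seed=7)
        b = simulate_genotypes(50, 5, 0.3, seed=7)
        assert np.array_equal(a, b)

    @pytest.mark.parametrize("maf", [0.0, 1.0, -0.1, 1.5])
    def test_invalid_maf_rejected(self, maf):
        with pytest.raises(ValueError):
            simulate_genotypes(10, 1, maf, seed=0)

    def test_genotype_frequencies_pass_hwe_goodness_of_fit(self):
        maf = 0.2
        Z = simulate_genotypes(100_000, 1, maf, seed=3).ravel()
        obs = np.bincount(Z.astype(int), minlength=3)
        exp = len(Z) * np.array(
            [(1 - maf) ** 2, 2 * maf * (1 - maf), maf**2]
        )
        chi2 = ((obs - exp) ** 2 / exp).sum()
        assert chi2 < stats.chi2.ppf(0.99, df=2)


class TestLdBlock:
    def test_perfect_ld_copies_partner_columns(self):
        Z_E, Z_U, pairs = simulate_ld_block(500, 4, 1.0, 1.0, seed=0)
        assert pairs.all()
        assert np.array_equal(Z_E, Z_U)

    def test_pairwise_correlation_near_target(self):
        Z_E, Z_U, _ = simulate_ld_block(5000, 10, 0.8, 1.0, seed=1)
        for j in range(10):
            r = np.corrcoef(Z_E[:, j], Z_U[:, j])[0, 1]
            assert abs(r - 0.8) < 0.1

    def test_half_proportion_flags_exactly_half_the_columns(self):
        _, _, pairs = simulate_ld_block(200, 10, 0.8, 0.5, seed=2)
        assert pairs.sum() == 5

    def test_invalid_r_target_rejected(self):
        with pytest.raises(ValueError):
            simulate_ld_block(100, 2, 0.0, 1.0, seed=0)
        with pytest.raises(ValueError):
            simulate_ld_block(100, 2, 1.1, 1.0, seed=0)


class TestNoise:
    def test_normal_default_mean_near_zero(self):
        x = draw_noise(NoiseSpec("normal"), 100_000, seed=0)
        assert abs(x.mean()) < 0.02

    def test_centered_gamma_mean_zero_and_right_skewed(self):
        spec = NoiseSpec("gamma", {"shape": 2.0, "scale": 1.0}, center=True)
        x = draw_noise(spec, 100_000, seed=1)
        assert abs(x.mean()) < 0.03  # shape*scale = 2 subtracted
        assert stats.skew(x) > 0.5

    def test_unknown_family_rejected(self):
        with pytest.raises(ValueError):
            NoiseSpec("beta")

    @pytest.mark.parametrize("family", ["normal", "laplace", "gamma",
                                        "mixture_normal"])
    def test_centered_sample_mean_scales_as_root_n(self, family):
        spec = NoiseSpec(family, center=True).scaled_to_unit_variance()
        x = draw_noise(spec, 100_000, seed=5)
        assert abs(x.mean()) < 5 * x.std() / np.sqrt(len(x))
        assert abs(x.var() - 1.0) < 0.05  # variance-matched families

    @pytest.mark.parametrize("family", ["normal", "laplace", "gamma",
                                        "mixture_normal"])
    def test_logpdf_integrates_to_one(self, family):
        spec = NoiseSpec(family, center=True)
        total, _ = quad(lambda t: np.exp(spec.logpdf(t)), -30, 30, limit=200)
        assert abs(total - 1.0) < 1e-6

    def test_logpdf_matches_empirical_histogram_mode(self):
        spec = NoiseSpec("mixture_normal", center=True)
        x = draw_noise(spec, 200_000, seed=9)
        # two modes near +-2 for the default mixture
        dens_at_modes = np.exp(spec.logpdf([-2.0, 2.0]))
        dens_at_zero = np.exp(spec.logpdf(0.0))
        assert (dens_at_modes > dens_at_zero).all()
        assert abs(np.mean(x < 0) - 0.5) < 0.01


class TestExposure:
    def test_noiseless_exposure_equals_h(self):
        Z = simulate_genotypes(20, 2, 0.3, seed=0)
        G, h = make_linear_exposure(Z, 1.0, [2.0, -1.0], np.zeros(20))
        assert np.array_equal(G, h)

    def test_single_snp_arithmetic(self):
        G, h = make_linear_exposure(np.array([[1.0]]), 1.0, [2.0], np.zeros(1))
        assert G[0] == 3.0

    def test_ols_recovers_coefficients(self):
        rng = np.random.default_rng(0)
        Z = simulate_genotypes(100_000, 3, 0.2, seed=1)
        G, _ = make_linear_exposure(Z, 0.5, [1.0, -0.5, 2.0],
                                    rng.standard_normal(100_000))
        X = np.column_stack([np.ones(len(G)), Z])
        coef, *_ = np.linalg.lstsq(X, G, rcond=None)
        assert np.allclose(coef, [0.5, 1.0, -0.5, 2.0], atol=0.05)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            make_linear_exposure(np.ones((5, 2)), 0.0, [1.0], np.zeros(5))
        with pytest.raises(ValueError):
            make_linear_exposure(np.ones((5, 2)), 0.0, [1.0, 1.0], np.zeros(4))


class TestCausalForms:
    def test_linear_identity(self):
        spec = CausalFunctionSpec("linear", (0.0, 1.0))
        assert np.array_equal(causal_effect(spec, [1.0, 2.0]), [1.0, 2.0])

    def test_cos_default_at_zero(self):
        assert causal_effect(CausalFunctionSpec("cos"), [0.0])[0] == 2.0

    def test_two_way_threshold_caps_interaction(self):
        # documented form: g + (g+1) + min(g*(g+1), tau); large g hits the cap
        spec = CausalFunctionSpec("two_way_thres", threshold=2.0)
        g = 5.0
        assert causal_effect(spec, [g])[0] == g + (g + 1) + 2.0
        # below the cap the raw interaction passes through
        g = 0.5
        assert causal_effect(spec, [g])[0] == pytest.approx(g + (g + 1) + g * (g + 1))

    def test_all_forms_finite(self):
        g = np.linspace(-50, 50, 101)
        for name in ("linear", "cos", "poly", "two_way_thres", "three_way_thres"):
            assert np.all(np.isfinite(causal_effect(CausalFunctionSpec(name), g)))

    def test_unknown_name_rejected(self):
        with pytest.raises(ValueError):
            CausalFunctionSpec("sigmoid")


class TestOutcome:
    def test_confounder_correlation_matches_rho(self):
        rng = np.random.default_rng(0)
        G = rng.standard_normal(100_000)
        noise = rng.standard_normal(100_000)
        _, U, _ = make_outcome(G, CausalFunctionSpec("linear"), 0.5, noise,
                               np.zeros(100_000), seed=1)
        assert abs(np.corrcoef(U, noise)[0, 1] - 0.5) < 0.02

    def test_noiseless_unconfounded_outcome_equals_y0(self):
        G = np.linspace(-1, 1, 50)
        Y, _, y0 = make_outcome(G, CausalFunctionSpec("poly"), 0.0,
                                np.zeros(50), np.zeros(50), seed=2, gamma=0.0)
        assert np.array_equal(Y, y0)

    def test_zero_rho_leaves_outcome_residual_unconfounded(self):
        rng = np.random.default_rng(3)
        noise = rng.standard_normal(50_000)
        G = 2.0 + noise
        Y, U, y0 = make_outcome(G, CausalFunctionSpec("linear"), 0.0, noise,
                                np.zeros(50_000), seed=4)
        assert abs(np.corrcoef(Y - y0, noise)[0, 1]) < 0.02

    def test_endogeneity_present_with_nonzero_rho(self):
        ds = make_simulation1_dataset(n=10_000, seed=11)
        r = np.corrcoef(ds.Y - ds.y0, ds.G)[0, 1]
        # significantly nonzero: |r| >> 3/sqrt(n)
        assert abs(r) > 3 / np.sqrt(ds.n)


class TestSimulation1Oracles:
    def test_oracles_mutually_consistent(self):
        ds = make_simulation1_dataset(n=5000, seed=0)
        assert abs(np.mean(ds.G - ds.h_vals)) < 5 / np.sqrt(ds.n)
        assert np.array_equal(ds.y0, ds.causal_spec(ds.G))

    @pytest.mark.parametrize("family", ["normal", "gamma", "mixture_normal"])
    def test_true_logdensity_integrates_to_one(self, family):
        ds = make_simulation1_dataset(n=100, noise_family=family, seed=1)
        for z in (ds.Z[0], ds.Z[1], ds.Z[2]):
            total, _ = quad(
                lambda g: np.exp(ds.true_logdensity(np.array([g]), z))[0],
                -40, 40, limit=300,
            )
            assert abs(total - 1.0) < 1e-3


class TestPleiotropy:
    def test_default_cohort_sizes(self):
        ds = make_pleiotropy_dataset(seed=0)
        labels, counts = np.unique(ds.cohort, return_counts=True)
        assert dict(zip(labels, counts)) == {
            "exposure": 500, "reference": 500, "outcome": 500
        }

    def test_full_proportion_partners_all_ivs(self):
        ds = make_pleiotropy_dataset(pleiotropic_proportion=1.0, seed=1)
        assert ds.ld_pairs.sum() == 10

    def test_noiseless_linear_outcome_is_exact_in_G_E(self):
        ds = make_pleiotropy_dataset(
            noise_sd=0.0, beta_U=0.0, linear=True, seed=2
        )
        X = np.column_stack([np.ones(len(ds.Y)), ds.G_E])
        coef, *_ = np.linalg.lstsq(X, ds.Y, rcond=None)
        assert np.abs(ds.Y - X @ coef).max() < 1e-8

    def test_inconsistent_cohort_sizes_rejected(self):
        with pytest.raises(ValueError):
            make_pleiotropy_dataset(n_total=1000, cohort_sizes=(500, 500, 500))
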