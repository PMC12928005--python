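"""Conditional GAN: losses, analytic optima, training behavior, sampler."""

import numpy as np
import pytest

from ganiv.gan import (
    ConditionalSampler,
    GanConfig,
    discriminator_loss,
    generator_loss,
    optimal_discriminator,
    sample_conditional,
    train_conditional_gan,
)
from ganiv.synthetic import simulate_genotypes


class TestGeneratorLoss:
    def test_perfectly_fooled_discriminator_gives_zero(self):
        assert generator_loss([1.0, 1.0, 1.0]) == pytest.approx(0.0, abs=1e-6)

    def test_half_probability_gives_log_two(self):
        assert generator_loss([0.5]) == pytest.approx(np.log(2), abs=1e-4)

    def test_monotone_decreasing_in_probability(self):
        losses = [generator_loss([d]) for d in (1e-6, 0.1, 0.5, 0.9)]
        assert losses == sorted(losses, reverse=True)
        assert losses[0] > 10  # blows up as d -> 0+

    def test_empty_batch_rejected(self):
        with pytest.raises(ValueError):
            generator_loss([])


class TestDiscriminatorLoss:
    def test_coin_flip_discriminator_at_log_two(self):
        out = discriminator_loss([0.5, 0.5], [0.5, 0.5], [0.0, 0.0], 0.0)
        assert out["total"] == pytest.approx(np.log(2), abs=1e-4)

    def test_perfect_discriminator_loss_vanishes(self):
        eps = 1e-6
        out = discriminator_loss([1 - eps], [eps], [0.0], 0.0)
        assert out["total"] < 1e-4

    def test_zero_gradients_contribute_no_penalty(self):
        out = discriminator_loss([0.7], [0.2], [0.0, 0.0], 10.0)
        assert out["r1"] == 0.0

    def test_component_identity(self):
        rng = np.random.default_rng(0)
        out = discriminator_loss(
            rng.uniform(0.1, 0.9, 10), rng.uniform(0.1, 0.9, 10),
            rng.uniform(0, 2, 10), 3.0,
        )
        assert out["total"] == pytest.approx(
            0.5 * (out["real"] + out["fake"]) + out["r1"], abs=1e-12
        )

    def test_negative_lambda_rejected(self):
        with pytest.raises(ValueError):
            discriminator_loss([0.5], [0.5], [0.0], -1.0)


class TestOptimalDiscriminator:
    def test_equal_densities_give_half(self):
        p = np.array([0.2, 0.5, 0.3])
        assert np.allclose(optimal_discriminator(p, p), 0.5)

    def test_real_only_support_gives_one(self):
        assert optimal_discriminator([0.4], [0.0])[0] == 1.0

    def test_arithmetic(self):
        assert optimal_discriminator([0.2], [0.6])[0] == pytest.approx(0.25)

    def test_undefined_where_both_vanish(self):
        with pytest.raises(ValueError):
            optimal_discriminator([0.0], [0.0])

    def test_matched_distributions_attain_minus_log4(self):
        """Exact-summation value of the adversarial objective at the optimum.

        On a discrete toy conditional distribution with the generated law
        equal to the data law, plugging the analytic optimal discriminator
        into E[log D] + E[log(1-D)] gives -log 4.
        """
        rng = np.random.default_rng(0)
        for z in range(3):  # three conditioning values, 10-point support each
            p = rng.dirichlet(np.ones(10))
            d_star = optimal_discriminator(p, p)
            value = np.sum(p * np.log(d_star)) + np.sum(p * np.log(1 - d_star))
            assert value == pytest.approx(-np.log(4), abs=1e-10)


@pytest.fixture(scope="module")
def linear_toy_sampler():
    """GAN trained briefly on G = 2 Z + N(0, 0.5^2) with scalar dosage Z."""
    rng = np.random.default_rng(0)
    Z = simulate_genotypes(400, 1, 0.3, seed=1)
    G = 2.0 * Z[:, 0] + 0.5 * rng.standard_normal(400)
    cfg = GanConfig(
        epochs=1800, batch_size=400, lr_gen=3e-3, lr_disc=3e-3, seed=0,
        stop_on_convergence=False,
    )
    sampler, diag = train_conditional_gan(Z, G, cfg)
    return Z, G, sampler, diag


class TestTraining:
    def test_constant_exposure_learned_as_point_mass(self):
        c = 3.0
        Z = simulate_genotypes(200, 1, 0.3, seed=2)
        G = np.full(200, c)
        cfg = GanConfig(epochs=150, batch_size=200, lr_gen=2e-3, lr_disc=2e-3,
                        seed=0, stop_on_convergence=False)
        sampler, _ = train_conditional_gan(Z, G, cfg)
        for z in (0.0, 1.0, 2.0):
            assert abs(sampler.conditional_mean([z], 200) - c) < 0.05 * (1 + abs(c))

    def test_conditional_mean_beats_constant_predictor(self, linear_toy_sampler):
        Z, G, sampler, _ = linear_toy_sampler
        h = 2.0 * Z[:, 0]
        gan_err = np.mean(np.abs(sampler.conditional_mean(Z, 300, seed=5) - h))
        const_err = np.mean(np.abs(G.mean() - h))
        assert gan_err < const_err

    def test_logged_loss_identity(self, linear_toy_sampler):
        _, _, _, diag = linear_toy_sampler
        for t in range(len(diag.steps)):
            lhs = diag.loss_d[t]
            rhs = 0.5 * (diag.loss_d_real[t] + diag.loss_d_fake[t]) + diag.loss_d_r1[t]
            assert lhs == pytest.approx(rhs, abs=1e-6)

    def test_accuracies_within_unit_interval(self, linear_toy_sampler):
        _, _, _, diag = linear_toy_sampler
        assert all(0.0 <= a <= 1.0 for a in diag.accuracy)

    def test_conditional_variance_within_factor_of_truth(self, linear_toy_sampler):
        # anti-mode-collapse: generated spread comparable to true sd 0.5
        _, _, sampler, _ = linear_toy_sampler
        draws = sampler.sample([1.0], 1000, seed=3)
        ratio = draws.var() / 0.25
        assert 0.3 < ratio < 3.0

    def test_batch_size_larger_than_n_rejected(self):
        Z = np.zeros((10, 1))
        with pytest.raises(ValueError):
            train_conditional_gan(Z, np.zeros(10), GanConfig(batch_size=64))


class TestSampler:
    def test_seeded_draws_are_reproducible(self, linear_toy_sampler):
        _, _, sampler, _ = linear_toy_sampler
        a = sample_conditional(sampler, [1.0], 50, seed=9)
        b = sample_conditional(sampler, [1.0], 50, seed=9)
        assert np.array_equal(a, b)

    def test_single_draw_boundary(self, linear_toy_sampler):
        _, _, sampler, _ = linear_toy_sampler
        assert sample_conditional(sampler, [1.0], 1, seed=0).shape == (1,)
        with pytest.raises(ValueError):
            sample_conditional(sampler, [1.0], 0, seed=0)

    def test_conditional_mean_is_mean_of_draws(self, linear_toy_sampler):
        _, _, sampler, _ = linear_toy_sampler
        draws = sampler.sample([2.0], 100, seed=4)
        assert sampler.conditional_mean([2.0], 100, seed=4) == draws.mean()

    def test_zero_weight_generator_outputs_its_bias(self, linear_toy_sampler):
        import copy

        _, _, sampler, _ = linear_toy_sampler
        s = copy.deepcopy(sampler)
        for w in s.generator.weights:
            w.data[...] = 0.0
        for b in s.generator.biases:
            b.data[...] = 0.0
        s.generator.biases[-1].data[...] = 0.7
        draws = s.sample([1.0], 20, seed=0)
        assert np.allclose(draws, 0.7 * s.g_std + s.g_mean)

    def test_monte_carlo_error_shrinks_as_root_m(self, linear_toy_sampler):
        _, _, sampler, _ = linear_toy_sampler
        small = [sampler.conditional_mean([1.0], 100, seed=s) for s in range(40)]
        large = [sampler.conditional_mean([1.0], 10_000, seed=s) for s in range(40)]
        ratio = np.std(small) / np.std(large)
        assert 5 < ratio < 20  # theoretical factor 10

    def test_serialization_roundtrip(self, linear_toy_sampler, tmp_path):
        _, _, sampler, _ = linear_toy_sampler
        path = tmp_path / "sampler.json"
        sampler.save(path)
        loaded = ConditionalSampler.load(path)
        a = sampler.sample([1.0, 0.0], 25, seed=1)
        b = loaded.sample([1.0, 0.0], 25, seed=1)
        assert np.allclose(a, b)
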