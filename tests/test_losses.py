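"""Loss algebra: analytic values, brute-force oracles, gradient checks,
and numerical guards."""

import math

import numpy as np
import pytest

from fusegan.losses import (
    FrozenContractError,
    LossWeights,
    adversarial_loss,
    adversarial_loss_logits,
    classification_objective,
    fusion_loss,
    generator_objective,
    l1_loss,
    softmax_probabilities,
)
from fusegan.networks import FusionSpec, GeneratorSpec, build_fusion_classifier, build_generator
from fusegan.nn import Tensor, freeze


class TestAdversarial:
    def test_uninformative_discriminator_gives_log_quarter(self):
        d = np.full(4, 0.5)
        loss_d, _ = adversarial_loss(d, d)
        # minimax value log(1/2) + log(1/2) = -1.3863; loss_D is its negation
        assert float(loss_d.data) == pytest.approx(-math.log(0.25), abs=1e-6)

    def test_perfect_discriminator_limit(self):
        loss_d, _ = adversarial_loss(np.full(4, 1 - 1e-9), np.full(4, 1e-9))
        assert float(loss_d.data) == pytest.approx(0.0, abs=1e-5)

    def test_matches_elementwise_oracle(self, rng):
        d_real = rng.uniform(0.05, 0.95, 8)
        d_fake = rng.uniform(0.05, 0.95, 8)
        loss_d, loss_g_ns = adversarial_loss(d_real, d_fake)
        _, loss_g_sat = adversarial_loss(d_real, d_fake, saturating=True)
        oracle_d = -np.mean([math.log(p) for p in d_real]) - np.mean(
            [math.log(1 - p) for p in d_fake]
        )
        assert float(loss_d.data) == pytest.approx(oracle_d, abs=1e-6)
        assert float(loss_g_ns.data) == pytest.approx(
            -np.mean([math.log(p) for p in d_fake]), abs=1e-6
        )
        assert float(loss_g_sat.data) == pytest.approx(
            np.mean([math.log(1 - p) for p in d_fake]), abs=1e-6
        )

    def test_clamped_probabilities_never_nan(self):
        for probs in ([0.0, 1.0], [1e-12, 1 - 1e-12]):
            loss_d, loss_g = adversarial_loss(np.array(probs), np.array(probs))
            assert np.isfinite(loss_d.data).all()
            assert np.isfinite(loss_g.data).all()

    def test_logit_form_agrees_with_probability_form(self, rng):
        z_real = rng.normal(size=6)
        z_fake = rng.normal(size=6)
        ld_z, lg_z = adversarial_loss_logits(z_real, z_fake)
        sig = lambda z: 1 / (1 + np.exp(-z))
        ld_p, lg_p = adversarial_loss(sig(z_real), sig(z_fake))
        assert float(ld_z.data) == pytest.approx(float(ld_p.data), abs=1e-9)
        assert float(lg_z.data) == pytest.approx(float(lg_p.data), abs=1e-9)


class TestL1:
    def test_identity_zero(self, rng):
        y = rng.random((4, 4, 4))
        assert float(l1_loss(y, y).data) == 0.0

    def test_unit_range_maximum(self):
        assert float(l1_loss(np.ones((3, 3, 3)), np.zeros((3, 3, 3))).data) == 1.0

    def test_matches_brute_force_mean(self, rng):
        y, g = rng.random((4, 4, 4)), rng.random((4, 4, 4))
        oracle = np.mean([abs(a - b) for a, b in zip(y.ravel(), g.ravel())])
        assert float(l1_loss(y, g).data) == pytest.approx(oracle, abs=1e-12)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            l1_loss(np.zeros((2, 2, 2)), np.zeros((3, 3, 3)))


class _IdentityFusion:
    """Stub fusion model: features = flattened concatenation of both inputs."""

    def parameters(self):
        return []

    def features(self, x, y):
        from fusegan.nn import concat

        return concat([x, y], axis=1).reshape(x.shape[0], -1)


FUSION_SPEC = FusionSpec(branch_blocks=2, trunk_blocks=1, base_channels=4, input_edge=16)


class TestFusionLoss:
    def test_zero_when_synthesis_equals_real(self, rng):
        model = freeze(build_fusion_classifier(FUSION_SPEC, seed=0)).eval()
        x = rng.random((1, 1, 16, 16, 16))
        y = rng.random((1, 1, 16, 16, 16))
        assert float(fusion_loss(model, x, y, y).data) == 0.0

    def test_identity_stub_reduces_to_pet_slot_l1(self, rng):
        x = rng.random((1, 1, 4, 4, 4))
        y = rng.random((1, 1, 4, 4, 4))
        g = rng.random((1, 1, 4, 4, 4))
        loss = fusion_loss(_IdentityFusion(), x, y, g)
        # |(x,y) - (x,g)| averages |y - g| over the PET half and 0 over the MRI half
        assert float(loss.data) == pytest.approx(float(l1_loss(y, g).data) / 2, abs=1e-12)

    def test_matches_two_forward_pass_oracle(self, rng):
        model = freeze(build_fusion_classifier(FUSION_SPEC, seed=0)).eval()
        x = rng.random((1, 1, 16, 16, 16))
        y = rng.random((1, 1, 16, 16, 16))
        g = rng.random((1, 1, 16, 16, 16))
        f_real = model.features(Tensor(x), Tensor(y)).data
        f_fake = model.features(Tensor(x), Tensor(g)).data
        oracle = np.abs(f_real - f_fake).mean()
        assert float(fusion_loss(model, x, y, g).data) == pytest.approx(oracle, abs=1e-9)

    def test_unfrozen_model_rejected(self, rng):
        model = build_fusion_classifier(FUSION_SPEC, seed=0).eval()
        x = rng.random((1, 1, 16, 16, 16))
        with pytest.raises(FrozenContractError):
            fusion_loss(model, x, x, x)

    def test_nonnegative_and_zero_iff_features_match(self, rng):
        model = freeze(build_fusion_classifier(FUSION_SPEC, seed=0)).eval()
        x = rng.random((1, 1, 16, 16, 16))
        y = rng.random((1, 1, 16, 16, 16))
        g = y + 0.1 * rng.random((1, 1, 16, 16, 16))
        assert float(fusion_loss(model, x, y, g).data) > 0.0


class TestGeneratorObjective:
    def test_zero_weights_reduce_to_adversarial(self):
        out = generator_objective(-0.7, 0.3, 0.9, LossWeights(0.0, 0.0))
        assert float(out.data) == pytest.approx(-0.7)

    def test_zero_reconstruction_terms(self):
        out = generator_objective(-0.7, 0.0, 0.0, LossWeights(100.0, 100.0))
        assert float(out.data) == pytest.approx(-0.7)

    def test_hand_arithmetic(self):
        out = generator_objective(-0.7, 0.01, 0.002, LossWeights(100.0, 100.0))
        assert float(out.data) == pytest.approx(0.5, abs=1e-12)

    def test_negative_weights_rejected(self):
        with pytest.raises(ValueError):
            LossWeights(-1.0, 0.0)


class TestClassificationObjective:
    def test_uniform_scores_give_log_two(self):
        scores = Tensor(np.zeros((4, 2)))
        loss = classification_objective(scores, [0, 1, 0, 1])
        assert float(loss.data) == pytest.approx(math.log(2), abs=1e-9)

    def test_confident_correct_scores_vanish(self):
        scores = Tensor(np.array([[20.0, -20.0], [-20.0, 20.0]]))
        loss = classification_objective(scores, [0, 1], l2_coeff=0.0)
        assert float(loss.data) == pytest.approx(0.0, abs=1e-9)

    def test_matches_elementwise_oracle_with_l2(self, rng):
        scores_np = rng.normal(size=(8, 2))
        labels = rng.integers(0, 2, 8)
        params = [Tensor(rng.normal(size=(3, 3)), requires_grad=True)]
        loss = classification_objective(Tensor(scores_np), labels, params, l2_coeff=0.001)
        probs = softmax_probabilities(scores_np)
        oracle = -np.mean(np.log(probs[np.arange(8), labels])) + 0.001 * np.sum(
            params[0].data ** 2
        )
        assert float(loss.data) == pytest.approx(oracle, abs=1e-9)


GEN_SPEC = GeneratorSpec(encoder_channels=[4, 8], decoder_channels=[8, 1])


def test_generator_objective_gradient_passes_directional_fd_check(rng):
    """d(objective)/d(theta_G) along 5 random directions agrees with central
    finite differences to 0.1% relative error on a width-scaled model."""
    from fusegan.networks import DiscriminatorSpec, build_discriminator

    gen = build_generator(GEN_SPEC, seed=1)
    disc = build_discriminator(DiscriminatorSpec(channels=[2, 4], input_edge=8), seed=2)
    fusion = freeze(
        build_fusion_classifier(
            FusionSpec(branch_blocks=1, trunk_blocks=1, base_channels=2, input_edge=8),
            seed=3,
        )
    ).eval()
    x_np = rng.random((1, 1, 8, 8, 8))
    y_np = rng.random((1, 1, 8, 8, 8))
    weights = LossWeights(100.0, 100.0)

    def objective():
        g_x = gen(Tensor(x_np))
        _, adv_g = adversarial_loss(Tensor(np.full((1, 1), 0.5)), disc(g_x))
        return generator_objective(
            adv_g, l1_loss(Tensor(y_np), g_x), fusion_loss(fusion, x_np, y_np, g_x), weights
        )

    loss = objective()
    for p in gen.parameters():
        p.grad = None
    loss.backward()
    params = gen.parameters()
    grads = [p.grad if p.grad is not None else np.zeros_like(p.data) for p in params]

    probe_rng = np.random.default_rng(42)
    eps = 1e-5
    for _ in range(5):
        direction = [probe_rng.normal(size=p.data.shape) for p in params]
        norm = math.sqrt(sum(float((d * d).sum()) for d in direction))
        direction = [d / norm for d in direction]
        analytic = sum(float((g * d).sum()) for g, d in zip(grads, direction))
        originals = [p.data.copy() for p in params]
        for p, d in zip(params, direction):
            p.data = p.data + eps * d
        lp = float(objective().data)
        for p, o, d in zip(params, originals, direction):
            p.data = o - eps * d
        lm = float(objective().data)
        for p, o in zip(params, originals):
            p.data = o
        fd = (lp - lm) / (2 * eps)
        assert analytic == pytest.approx(fd, rel=1e-3, abs=1e-8)
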