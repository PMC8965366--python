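"""Loss algebra for the feature-fusion GAN and the fusion classifier.

All norms are per-element means rather than sums, so the default weights
lambda1 = lambda2 = 100 keep their meaning across patch and feature sizes.
Probabilities are clamped at 1e-7 before any logarithm; no loss here can
return NaN or Inf on clamped inputs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import Module, Tensor

__all__ = [
    "LossWeights",
    "FrozenContractError",
    "adversarial_loss",
    "adversarial_loss_logits",
    "l1_loss",
    "fusion_loss",
    "generator_objective",
    "classification_objective",
    "softmax_probabilities",
]

_EPS = 1e-7


class FrozenContractError(RuntimeError):
    """The fusion model must be frozen while it defines the feature loss."""


@dataclass
class LossWeights:
    lambda1: float = 100.0  # L1 estimation-error weight
    lambda2: float = 100.0  # feature-fusion weight

    def __post_init__(self):
        if self.lambda1 < 0 or self.lambda2 < 0:
            raise ValueError("loss weights must be non-negative")


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float64))


def adversarial_loss(
    d_real, d_fake, saturating: bool = False
) -> tuple[Tensor, Tensor]:
    """Minimax adversarial losses from discriminator probabilities.

    loss_D = -mean(log D(real)) - mean(log(1 - D(fake))): the discriminator
    descends this to ascend the minimax value. The generator term defaults
    to the non-saturating form -mean(log D(fake)); ``saturating=True``
    selects the literal minimax term +mean(log(1 - D(fake))). Both share
    the same fixed point.
    """
    d_real = _as_tensor(d_real).clip(_EPS, 1.0 - _EPS)
    d_fake = _as_tensor(d_fake).clip(_EPS, 1.0 - _EPS)
    loss_d = -(d_real.log().mean()) - (1.0 - d_fake).log().mean()
    if saturating:
        loss_g = (1.0 - d_fake).log().mean()
    else:
        loss_g = -(d_fake.log().mean())
    return loss_d, loss_g


def adversarial_loss_logits(
    z_real, z_fake, saturating: bool = False
) -> tuple[Tensor, Tensor]:
    """:func:`adversarial_loss` evaluated from discriminator logits.

    Identical objective (probabilities are sigmoid(z)) but computed via
    softplus, so the generator's adversarial gradient stays bounded even
    when the discriminator saturates.  Used by the training loop; the
    probability form remains the module's reference definition.
    """
    z_real, z_fake = _as_tensor(z_real), _as_tensor(z_fake)
    # -log sigmoid(z) = softplus(-z); -log(1 - sigmoid(z)) = softplus(z)
    loss_d = (-z_real).softplus().mean() + z_fake.softplus().mean()
    if saturating:
        loss_g = -(z_fake.softplus().mean())
    else:
        loss_g = (-z_fake).softplus().mean()
    return loss_d, loss_g


def l1_loss(y, g_x) -> Tensor:
    """Mean absolute voxel difference between a real and a synthesized patch."""
    y, g_x = _as_tensor(y), _as_tensor(g_x)
    if y.shape != g_x.shape:
        raise ValueError(f"shape mismatch: {y.shape} vs {g_x.shape}")
    return (y - g_x).abs().mean()


def fusion_loss(
    fusion_model: Module, x, y, g_x, check_frozen: bool = True
) -> Tensor:
    """Mean absolute difference of fused features F(x, y) vs F(x, G(x)).

    ``fusion_model`` must expose ``features(mri, pet)`` and, in a training
    context, must be frozen (no parameter receives gradients) — the loss
    shapes the generator in the classifier's feature space without moving
    the classifier.
    """
    if check_frozen and any(p.requires_grad for p in fusion_model.parameters()):
        raise FrozenContractError(
            "fusion model has trainable parameters; freeze it before computing "
            "the feature-fusion loss in a training context"
        )
    x, y, g_x = _as_tensor(x), _as_tensor(y), _as_tensor(g_x)
    f_real = fusion_model.features(x, y)
    f_fake = fusion_model.features(x, g_x)
    return (f_real - f_fake).abs().mean()


def generator_objective(adv_g, l1, fusion, weights: LossWeights) -> Tensor:
    """adv_G + lambda1 * L1 + lambda2 * L_fusion."""
    return (
        _as_tensor(adv_g)
        + weights.lambda1 * _as_tensor(l1)
        + weights.lambda2 * _as_tensor(fusion)
    )


def classification_objective(
    scores: Tensor, labels, parameters=None, l2_coeff: float = 0.0
) -> Tensor:
    """Mean two-class softmax cross-entropy plus l2_coeff * sum(param^2)."""
    labels = np.asarray(labels, dtype=np.int64)
    if not np.isin(labels, (0, 1)).all():
        raise ValueError("labels must be binary (0/1)")
    scores = _as_tensor(scores)
    shift = Tensor(scores.data.max(axis=1, keepdims=True))  # stability constant
    z = scores - shift
    log_norm = z.exp().sum(axis=1).log()
    data_term = (log_norm - z.take_column(labels)).mean()
    if l2_coeff and parameters:
        reg = None
        for p in parameters:
            term = p.square().sum()
            reg = term if reg is None else reg + term
        return data_term + l2_coeff * reg
    return data_term


def softmax_probabilities(scores: np.ndarray) -> np.ndarray:
    """Class probabilities from raw scores (rows sum to 1)."""
    scores = np.asarray(scores, dtype=np.float64)
    z = scores - scores.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)
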