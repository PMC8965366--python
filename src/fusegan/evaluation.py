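"""Evaluation: classification metrics, image-quality metrics, Grad-CAM.

Conventions, fixed here because they matter for comparability:

* the positive class for sensitivity is class 1 (the LMCI-like class);
  specificity is the true-negative rate of class 0;
* AUC uses the rank (Mann-Whitney) formulation with ties counted 1/2 —
  exact for small samples, invariant under monotone transforms;
* PSNR uses peak 1.0 (volumes are min-max normalized to [0, 1]) and is
  reported as +inf when MSE is exactly 0;
* SSIM uses K1=0.01, K2=0.03, a 7-voxel window and data range 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.metrics import structural_similarity

from .networks import FusionClassifier
from .nn import Tensor
from .synthetic import Volume

__all__ = [
    "MetricsReport",
    "ImageQuality",
    "GradCamResult",
    "classification_metrics",
    "image_metrics",
    "grad_cam",
    "auc_mann_whitney",
]


@dataclass
class MetricsReport:
    acc: float  # percent
    sen: float  # percent, recall of class 1
    spe: float  # percent, recall of class 0
    auc: float  # fraction in [0, 1]
    n_subjects: int
    threshold: float = 0.5
    split_tag: str | None = None

    def as_dict(self) -> dict:
        return {
            "acc": self.acc,
            "sen": self.sen,
            "spe": self.spe,
            "auc": self.auc,
            "n_subjects": self.n_subjects,
            "threshold": self.threshold,
            "split_tag": self.split_tag,
        }


def auc_mann_whitney(labels: np.ndarray, scores: np.ndarray) -> float:
    """P(random positive outranks random negative), ties counted 1/2."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    if pos.size == 0 or neg.size == 0:
        raise ValueError("AUC undefined: both classes must be present")
    greater = (pos[:, None] > neg[None, :]).sum()
    ties = (pos[:, None] == neg[None, :]).sum()
    return float((greater + 0.5 * ties) / (pos.size * neg.size))


def classification_metrics(
    labels,
    predicted_probabilities,
    threshold: float = 0.5,
    split_tag: str | None = None,
) -> MetricsReport:
    labels = np.asarray(labels, dtype=np.int64)
    probs = np.asarray(predicted_probabilities, dtype=np.float64)
    if labels.shape != probs.shape:
        raise ValueError("labels and probabilities must have matching shapes")
    if not np.isin(labels, (0, 1)).all():
        raise ValueError("labels must be binary (0/1)")
    if ((probs < 0) | (probs > 1)).any():
        raise ValueError("probabilities must lie in [0, 1]")
    pred = (probs >= threshold).astype(np.int64)
    tp = int(((pred == 1) & (labels == 1)).sum())
    tn = int(((pred == 0) & (labels == 0)).sum())
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    acc = 100.0 * (tp + tn) / labels.size
    sen = 100.0 * tp / n_pos if n_pos else float("nan")
    spe = 100.0 * tn / n_neg if n_neg else float("nan")
    auc = auc_mann_whitney(labels, probs)
    return MetricsReport(
        acc=acc, sen=sen, spe=spe, auc=auc,
        n_subjects=int(labels.size), threshold=threshold, split_tag=split_tag,
    )


@dataclass
class ImageQuality:
    mse: float
    psnr: float  # dB; +inf when mse == 0
    ssim: float

    def as_dict(self) -> dict:
        return {"mse": self.mse, "psnr": self.psnr, "ssim": self.ssim}


def image_metrics(reference: Volume, synthesized: Volume) -> ImageQuality:
    ref = np.asarray(reference.data, dtype=np.float64)
    syn = np.asarray(synthesized.data, dtype=np.float64)
    if ref.shape != syn.shape:
        raise ValueError(f"shape mismatch: {ref.shape} vs {syn.shape}")
    mse = float(np.mean((ref - syn) ** 2))
    psnr = math.inf if mse == 0.0 else 10.0 * math.log10(1.0 / mse)
    win = min(7, ref.shape[0] - (1 - ref.shape[0] % 2))  # odd, <= edge
    ssim = float(
        structural_similarity(
            ref, syn, data_range=1.0, win_size=win, K1=0.01, K2=0.03,
            gaussian_weights=False,
        )
    )
    return ImageQuality(mse=mse, psnr=psnr, ssim=ssim)


@dataclass
class GradCamResult:
    saliency: dict[str, Volume]  # per modality, values in [0, 1]
    all_zero: dict[str, bool] = field(default_factory=dict)


def _cam_from_activation(act: Tensor, target_shape: tuple[int, ...]) -> tuple[np.ndarray, bool]:
    grads = act.grad  # (N, C, d, h, w); N == 1 here
    if grads is None:
        grads = np.zeros_like(act.data)
    weights = grads.mean(axis=(2, 3, 4), keepdims=True)  # spatial-average per channel
    cam = np.maximum((weights * act.data).sum(axis=1)[0], 0.0)
    factors = [t / s for t, s in zip(target_shape, cam.shape)]
    cam = ndimage.zoom(cam, factors, order=1, grid_mode=True, mode="grid-constant")
    cam = cam[tuple(slice(0, t) for t in target_shape)]
    peak = cam.max()
    if peak <= 0.0:
        return np.zeros(target_shape), True
    return cam / peak, False


def grad_cam(
    model: FusionClassifier,
    mri: Volume,
    pet: Volume,
    target_class: int = 1,
) -> GradCamResult:
    """Gradient-weighted class-activation maps for both modality branches.

    The target layer is the last convolutional block of each branch (its
    activation just before modality fusion).  Channel weights are the
    spatial means of the target-class score gradient; the weighted sum is
    rectified at 0, trilinearly upsampled to the input shape and
    max-normalized to [0, 1].  All-zero gradients yield an all-zero map
    with a warning flag rather than an error.
    """
    model.eval()
    x = Tensor(np.asarray(mri.data, dtype=np.float64)[None, None], requires_grad=True)
    y = Tensor(np.asarray(pet.data, dtype=np.float64)[None, None], requires_grad=True)
    capture: dict[str, Tensor] = {}
    scores = model(x, y, capture=capture)
    score = scores.take_column([target_class]).sum()
    score.backward()

    shape = mri.data.shape
    saliency: dict[str, Volume] = {}
    flags: dict[str, bool] = {}
    for name in ("mri", "pet"):
        cam, zero = _cam_from_activation(capture[name], shape)
        saliency[name] = Volume(cam, "MRI" if name == "mri" else "PET")
        flags[name] = zero
    return GradCamResult(saliency=saliency, all_zero=flags)
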