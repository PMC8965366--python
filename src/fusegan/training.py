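"""The three-stage hybrid schedule.

Stage 1 pretrains the dual-branch fusion classifier on paired whole
volumes.  Stage 2 trains the MRI-to-PET generator adversarially with the
L1 estimation error and the feature-fusion loss computed through the
frozen fusion feature extractor F (the classifier minus its affine head),
alternating five discriminator steps per generator step; each iteration
consumes every patch of one subject pair.  Stage 3 replaces the training
PET volumes with synthesized ones and fine-tunes the classifier so it
adapts to synthesis artifacts.  Stages 2 and 3 are cycled, and the model
with the best validation accuracy across cycles is selected.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .losses import (
    FrozenContractError,
    LossWeights,
    adversarial_loss_logits,
    classification_objective,
    fusion_loss,
    generator_objective,
    l1_loss,
    softmax_probabilities,
)
from .networks import (
    DiscriminatorSpec,
    FusionClassifier,
    FusionSpec,
    GeneratorSpec,
    build_discriminator,
    build_fusion_classifier,
    build_generator,
)
from .nn import Adam, Tensor, freeze, save_checkpoint, state_bytes_equal
from .nn.optim import clip_grad_norm
from .preprocessing import extract_patches, reassemble
from .synthetic import Cohort, Subject, Volume

__all__ = [
    "Stage1Config",
    "Stage2Config",
    "Stage3Config",
    "StageConfig",
    "StageArtifacts",
    "HybridResult",
    "pretrain_classifier",
    "train_ffgan",
    "synthesize_pet",
    "finetune_classifier",
    "run_hybrid",
    "predict_probabilities",
    "clone_classifier",
]


@dataclass
class Stage1Config:
    lr: float = 0.0005
    batch: int = 8
    l2: float = 0.001
    epochs: int = 30


@dataclass
class Stage2Config:
    lr: float = 0.00001
    d_steps_per_g_step: int = 5
    weights: LossWeights = field(default_factory=LossWeights)
    epochs: int = 200
    saturating: bool = False
    resume_generator: bool = True
    grad_clip: float = 0.0  # global-norm clip on the generator step; 0 = off
    d_lr: float = 0.0  # discriminator learning rate; 0 = same as lr


@dataclass
class Stage3Config:
    lr: float = 0.0001
    batch: int = 8
    l2: float = 0.001
    epochs: int = 20


@dataclass
class StageConfig:
    stage1: Stage1Config = field(default_factory=Stage1Config)
    stage2: Stage2Config = field(default_factory=Stage2Config)
    stage3: Stage3Config = field(default_factory=Stage3Config)
    cycles: int = 3
    seed: int = 0

    def __post_init__(self):
        if self.cycles < 1:
            raise ValueError("cycles must be at least 1")
        if self.stage2.d_steps_per_g_step < 1:
            raise ValueError("need at least one discriminator step per generator step")
        for lr in (self.stage1.lr, self.stage2.lr, self.stage3.lr):
            if lr <= 0:
                raise ValueError("learning rates must be positive")


@dataclass
class StageArtifacts:
    stage: int
    cycle: int
    seed: int
    classifier: FusionClassifier | None = None
    generator: object | None = None
    discriminator: object | None = None
    metrics_history: list[dict] = field(default_factory=list)
    extras: dict = field(default_factory=dict)

    def save(self, directory: str | Path) -> Path:
        states = {}
        if self.classifier is not None:
            states["classifier"] = self.classifier.state_dict()
        if self.generator is not None and hasattr(self.generator, "state_dict"):
            states["generator"] = self.generator.state_dict()
        if self.discriminator is not None and hasattr(self.discriminator, "state_dict"):
            states["discriminator"] = self.discriminator.state_dict()
        meta = {
            "stage": self.stage,
            "cycle": self.cycle,
            "seed": self.seed,
            "metrics_history": self.metrics_history,
            "extras": {k: v for k, v in self.extras.items() if np.isscalar(v)},
        }
        return save_checkpoint(Path(directory) / f"stage{self.stage}_cycle{self.cycle}", states, meta)


def _batch(subjects: list[Subject], which: str) -> np.ndarray:
    vols = []
    for s in subjects:
        vol = getattr(s, which)
        if vol is None:
            raise ValueError(f"subject {s.subject_id} has no {which} volume")
        vols.append(np.asarray(vol.data, dtype=np.float64)[None])
    return np.stack(vols)


def clone_classifier(classifier: FusionClassifier) -> FusionClassifier:
    clone = build_fusion_classifier(copy.deepcopy(classifier.spec), seed=0)
    clone.load_state_dict(classifier.state_dict())
    return clone


def _train_classifier_epochs(
    classifier: FusionClassifier,
    mri: np.ndarray,
    pet: np.ndarray,
    labels: np.ndarray,
    lr: float,
    batch: int,
    l2: float,
    epochs: int,
    rng: np.random.Generator,
    val_subjects: list[Subject] | None = None,
) -> list[dict]:
    optimizer = Adam(classifier.parameters(), lr=lr)
    params = classifier.parameters()
    history: list[dict] = []
    n = mri.shape[0]
    for epoch in range(epochs):
        classifier.train()
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, batch):
            idx = order[start : start + batch]
            scores = classifier(Tensor(mri[idx]), Tensor(pet[idx]))
            loss = classification_objective(scores, labels[idx], params, l2)
            optimizer.zero_grad()
            loss.backward()
            optimizer.step()
            losses.append(float(loss.data))
        record = {"epoch": epoch, "train_loss": float(np.mean(losses))}
        if val_subjects:
            from .evaluation import classification_metrics

            probs = predict_probabilities(classifier, val_subjects, pet_source="real")
            report = classification_metrics([s.label for s in val_subjects], probs)
            record["val_acc"] = report.acc
            record["val_auc"] = report.auc
        history.append(record)
    return history


def pretrain_classifier(
    train_subjects: list[Subject] | Cohort,
    fusion_spec: FusionSpec,
    config: Stage1Config,
    seed: int,
    val_subjects: list[Subject] | None = None,
) -> StageArtifacts:
    """Stage 1: train (F, head) on paired whole volumes with Adam + L2."""
    subjects = list(train_subjects)
    missing = [s.subject_id for s in subjects if not s.has_pet]
    if missing:
        raise ValueError(
            f"stage 1 requires paired data; subjects without PET: {missing}"
        )
    if not subjects:
        raise ValueError("stage 1 requires at least one training subject")
    ss = np.random.SeedSequence([seed, 1])
    build_seed, loop_seed = (int(s) for s in ss.generate_state(2) % (2**31))
    classifier = build_fusion_classifier(fusion_spec, seed=build_seed)
    history = _train_classifier_epochs(
        classifier,
        _batch(subjects, "mri"),
        _batch(subjects, "pet"),
        np.array([s.label for s in subjects]),
        config.lr,
        config.batch,
        config.l2,
        config.epochs,
        np.random.default_rng(loop_seed),
        val_subjects,
    )
    return StageArtifacts(
        stage=1, cycle=0, seed=seed, classifier=classifier, metrics_history=history
    )


def train_ffgan(
    paired_train: list[Subject] | Cohort,
    frozen_fusion: FusionClassifier,
    generator_spec: GeneratorSpec,
    discriminator_spec: DiscriminatorSpec,
    config: Stage2Config,
    patch_size: int,
    stride: int,
    seed: int,
    generator=None,
    discriminator=None,
    cycle: int = 1,
) -> StageArtifacts:
    """Stage 2: adversarial training of G against D with L1 and fusion terms.

    Each iteration draws all patches of one MRI/PET subject pair, runs
    ``d_steps_per_g_step`` discriminator updates against a fixed generator,
    then one generator update against the combined objective.  F must be
    frozen and is verified bit-identical afterwards.
    """
    subjects = [s for s in paired_train if s.has_pet]
    if not subjects:
        raise ValueError("stage 2 requires paired training subjects")
    if any(p.requires_grad for p in frozen_fusion.parameters()):
        raise FrozenContractError(
            "fusion model must be frozen before stage-2 training"
        )
    frozen_fusion.eval()
    f_before = frozen_fusion.state_dict()

    ss = np.random.SeedSequence([seed, 2])
    g_seed, d_seed, loop_seed = (int(s) for s in ss.generate_state(3) % (2**31))
    if generator is None:
        generator = build_generator(generator_spec, seed=g_seed)
    if discriminator is None:
        discriminator = build_discriminator(discriminator_spec, seed=d_seed)
    adam_g = Adam(generator.parameters(), lr=config.lr)
    adam_d = Adam(discriminator.parameters(), lr=config.d_lr or config.lr)
    rng = np.random.default_rng(loop_seed)

    patch_cache = {
        s.subject_id: (
            np.stack([p[None] for p in extract_patches(s.mri, patch_size, stride).patches]),
            np.stack([p[None] for p in extract_patches(s.pet, patch_size, stride).patches]),
        )
        for s in subjects
    }

    history: list[dict] = []
    d_steps = g_steps = fusion_evals = 0
    for epoch in range(config.epochs):
        order = rng.permutation(len(subjects))
        for si in order:
            x_np, y_np = patch_cache[subjects[si].subject_id]
            x, y = Tensor(x_np), Tensor(y_np)
            fake_const = Tensor(generator(x).data)
            for _ in range(config.d_steps_per_g_step):
                z_real = discriminator.logit(y)
                z_fake = discriminator.logit(fake_const)
                loss_d, _ = adversarial_loss_logits(z_real, z_fake, config.saturating)
                adam_d.zero_grad()
                loss_d.backward()
                adam_d.step()
                d_steps += 1
            g_x = generator(x)
            z_fake = discriminator.logit(g_x)
            _, adv_g = adversarial_loss_logits(
                z_real.detach(), z_fake, config.saturating
            )
            l1 = l1_loss(y, g_x)
            if config.weights.lambda2 > 0:
                fus = fusion_loss(frozen_fusion, x, y, g_x)
                fusion_evals += 1
            else:
                fus = Tensor(0.0)
            objective = generator_objective(adv_g, l1, fus, config.weights)
            adam_g.zero_grad()
            adam_d.zero_grad()
            objective.backward()
            if config.grad_clip > 0:
                clip_grad_norm(generator.parameters(), config.grad_clip)
            adam_g.step()
            g_steps += 1
            history.append(
                {
                    "epoch": epoch,
                    "loss_d": float(loss_d.data),
                    "adv_g": float(adv_g.data),
                    "l1": float(l1.data),
                    "fusion": float(fus.data),
                    "objective": float(objective.data),
                }
            )

    if not state_bytes_equal(f_before, frozen_fusion.state_dict()):
        raise FrozenContractError("fusion model parameters changed during stage 2")
    return StageArtifacts(
        stage=2,
        cycle=cycle,
        seed=seed,
        generator=generator,
        discriminator=discriminator,
        metrics_history=history,
        extras={"d_steps": d_steps, "g_steps": g_steps, "fusion_evals": fusion_evals},
    )


def synthesize_pet(mri: Volume, generator, patch_size: int, stride: int) -> Volume:
    """Whole-volume synthesis: patch -> generator -> overlap-averaged volume."""
    patchset = extract_patches(mri, patch_size, stride)
    batch = Tensor(np.stack([p[None] for p in patchset.patches]))
    out = generator(batch).data[:, 0]
    synthesized = type(patchset)(
        patches=[np.asarray(p) for p in out],
        origins=patchset.origins,
        patch_size=patch_size,
        source_shape=patchset.source_shape,
        modality="PET",
    )
    vol = reassemble(synthesized)
    return Volume(vol.data, "PET")


def finetune_classifier(
    train_subjects: list[Subject] | Cohort,
    generator,
    stage1_artifacts: StageArtifacts,
    config: Stage3Config,
    patch_size: int,
    stride: int,
    seed: int,
    val_subjects: list[Subject] | None = None,
    cycle: int = 1,
) -> StageArtifacts:
    """Stage 3: fine-tune the pretrained classifier on real MRI + synthesized
    PET; the generator is treated as missing-data imputer and never updated."""
    if stage1_artifacts.classifier is None:
        raise ValueError("stage-1 artifacts carry no classifier checkpoint")
    subjects = list(train_subjects)
    classifier = clone_classifier(stage1_artifacts.classifier)
    if config.epochs == 0:
        return StageArtifacts(
            stage=3, cycle=cycle, seed=seed, classifier=classifier, generator=generator
        )
    g_before = (
        generator.state_dict() if hasattr(generator, "state_dict") else None
    )
    synth = np.stack(
        [
            np.asarray(
                synthesize_pet(s.mri, generator, patch_size, stride).data,
                dtype=np.float64,
            )[None]
            for s in subjects
        ]
    )
    ss = np.random.SeedSequence([seed, 3])
    loop_seed = int(ss.generate_state(1)[0] % (2**31))
    history = _train_classifier_epochs(
        classifier,
        _batch(subjects, "mri"),
        synth,
        np.array([s.label for s in subjects]),
        config.lr,
        config.batch,
        config.l2,
        config.epochs,
        np.random.default_rng(loop_seed),
        val_subjects,
    )
    if g_before is not None and not state_bytes_equal(g_before, generator.state_dict()):
        raise FrozenContractError("generator parameters changed during stage 3")
    return StageArtifacts(
        stage=3,
        cycle=cycle,
        seed=seed,
        classifier=classifier,
        generator=generator,
        metrics_history=history,
    )


def predict_probabilities(
    classifier: FusionClassifier,
    subjects: list[Subject],
    generator=None,
    patch_size: int | None = None,
    stride: int | None = None,
    pet_source: str = "real",
) -> np.ndarray:
    """Class-1 probabilities for a subject list.

    pet_source: 'real' uses each subject's PET; 'synthesized' imputes PET
    from MRI through the generator (required for MRI-only subjects).
    """
    classifier.eval()
    mri = _batch(subjects, "mri")
    if pet_source == "real":
        pet = _batch(subjects, "pet")
    elif pet_source == "synthesized":
        if generator is None or patch_size is None or stride is None:
            raise ValueError("synthesized PET requires generator, patch_size, stride")
        pet = np.stack(
            [
                np.asarray(
                    synthesize_pet(s.mri, generator, patch_size, stride).data,
                    dtype=np.float64,
                )[None]
                for s in subjects
            ]
        )
    else:
        raise ValueError(f"unknown pet_source {pet_source!r}")
    scores = classifier(Tensor(mri), Tensor(pet)).data
    return softmax_probabilities(scores)[:, 1]


@dataclass
class HybridResult:
    stage1: StageArtifacts
    checkpoints: dict[tuple[int, int], StageArtifacts]
    best: StageArtifacts
    best_cycle: int
    history: list[dict]


def run_hybrid(
    cohort: Cohort,
    fusion_spec: FusionSpec,
    generator_spec: GeneratorSpec,
    discriminator_spec: DiscriminatorSpec,
    config: StageConfig,
    patch_size: int,
    stride: int,
    out_dir: str | Path | None = None,
) -> HybridResult:
    """Full schedule: stage 1, then `cycles` repetitions of stage 2 -> stage 3.

    The cohort must carry split tags (train/validation/test).  Validation
    uses real MRI + real PET; model selection is best validation accuracy
    across cycles, ties broken by validation AUC.
    """
    from .evaluation import classification_metrics

    train = [s for s in cohort if s.split_tag == "train" and s.has_pet]
    val = [s for s in cohort if s.split_tag == "validation" and s.has_pet]
    if not train:
        raise ValueError("cohort has no paired training subjects (split tags set?)")

    seed = config.seed
    stage1 = pretrain_classifier(
        train, fusion_spec, config.stage1, seed, val_subjects=None
    )
    checkpoints: dict[tuple[int, int], StageArtifacts] = {(1, 0): stage1}
    history: list[dict] = []

    current = stage1
    generator = discriminator = None
    best: StageArtifacts | None = None
    best_key: tuple[float, float] = (-1.0, -1.0)
    best_cycle = 0

    for cycle in range(1, config.cycles + 1):
        frozen = freeze(clone_classifier(current.classifier))
        art2 = train_ffgan(
            train,
            frozen,
            generator_spec,
            discriminator_spec,
            config.stage2,
            patch_size,
            stride,
            seed=seed + cycle,
            generator=generator if config.stage2.resume_generator else None,
            discriminator=discriminator if config.stage2.resume_generator else None,
            cycle=cycle,
        )
        generator, discriminator = art2.generator, art2.discriminator
        checkpoints[(2, cycle)] = art2

        art3 = finetune_classifier(
            train,
            generator,
            StageArtifacts(stage=1, cycle=cycle, seed=seed, classifier=current.classifier),
            config.stage3,
            patch_size,
            stride,
            seed=seed + cycle,
            cycle=cycle,
        )
        checkpoints[(3, cycle)] = art3
        current = art3

        record = {"cycle": cycle}
        if val:
            probs = predict_probabilities(art3.classifier, val, pet_source="real")
            report = classification_metrics([s.label for s in val], probs)
            record.update({"val_acc": report.acc, "val_auc": report.auc})
            key = (report.acc, report.auc)
        else:
            key = (0.0, 0.0)
        history.append(record)
        if best is None or key > best_key:
            best, best_key, best_cycle = art3, key, cycle

    if out_dir is not None:
        out_dir = Path(out_dir)
        for art in checkpoints.values():
            art.save(out_dir)

    return HybridResult(
        stage1=stage1,
        checkpoints=checkpoints,
        best=best,
        best_cycle=best_cycle,
        history=history,
    )
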