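"""End-to-end orchestration used by the CLI, the examples and the
acceptance script: cohort preparation, the three-stage run, and evaluation
of every arm on the standard splits."""

from __future__ import annotations

import json

from pathlib import Path

import numpy as np

from .config import RunConfig, save_config
from .evaluation import classification_metrics, image_metrics
from .preprocessing import assign_split_tags, make_folds, normalize_cohort
from .synthetic import Cohort, generate_cohort, read_cohort
from .training import (
    HybridResult,
    predict_probabilities,
    run_hybrid,
    synthesize_pet,
)

__all__ = ["prepare_cohort", "evaluate_run", "run_pipeline"]


def prepare_cohort(config: RunConfig) -> Cohort:
    """Load or simulate, then normalize and split the cohort."""
    if config.cohort_dir is not None:
        cohort = read_cohort(config.cohort_dir)
    else:
        cohort = generate_cohort(config.synthetic)
    normalize_cohort(cohort)
    plan = make_folds(cohort, config.folds, config.protocol, config.seed)
    assign_split_tags(cohort, plan, validation_fold=config.validation_fold)
    return cohort


def evaluate_run(
    cohort: Cohort, result: HybridResult, config: RunConfig
) -> dict:
    """Metrics for the selected model and its ablation arms.

    Validation uses real MRI + real PET; the test split (MRI-only
    subjects) uses real MRI + synthesized PET.  Image quality of the
    generator is measured against real PET on the validation split.
    """
    val = [s for s in cohort if s.split_tag == "validation" and s.has_pet]
    test = [s for s in cohort if s.split_tag == "test"]
    generator = result.best.generator
    ps, st = config.patch_size, config.patch_stride
    out: dict = {"best_cycle": result.best_cycle}

    if val:
        probs = predict_probabilities(result.best.classifier, val, pet_source="real")
        out["validation"] = classification_metrics(
            [s.label for s in val], probs, split_tag="validation"
        ).as_dict()
        quality = [
            image_metrics(s.pet, synthesize_pet(s.mri, generator, ps, st)) for s in val
        ]
        out["synthesis"] = {
            "mse": float(np.mean([q.mse for q in quality])),
            "psnr": float(np.mean([q.psnr for q in quality])),
            "ssim": float(np.mean([q.ssim for q in quality])),
            "n_subjects": len(quality),
        }
    if test:
        for name, classifier in (
            ("test", result.best.classifier),
            ("test_no_finetune", result.stage1.classifier),
        ):
            probs = predict_probabilities(
                classifier, test, generator=generator, patch_size=ps, stride=st,
                pet_source="synthesized",
            )
            out[name] = classification_metrics(
                [s.label for s in test], probs, split_tag="test"
            ).as_dict()
    return out


def run_pipeline(config: RunConfig, save_artifacts: bool = True) -> dict:
    """Prepare the cohort, run the hybrid schedule, evaluate, and (optionally)
    persist config snapshot, checkpoints and metrics under the output dir."""
    cohort = prepare_cohort(config)
    out_dir = Path(config.output_dir)
    if save_artifacts:
        out_dir.mkdir(parents=True, exist_ok=True)
        save_config(config, out_dir / "config.yaml")
    result = run_hybrid(
        cohort,
        config.fusion,
        config.generator,
        config.discriminator,
        config.stages,
        config.patch_size,
        config.patch_stride,
        out_dir=out_dir if save_artifacts else None,
    )
    metrics = evaluate_run(cohort, result, config)
    metrics["cycles"] = [dict(r) for r in result.history]
    if save_artifacts:
        (out_dir / "metrics.json").write_text(json.dumps(metrics, indent=2))
    return metrics
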