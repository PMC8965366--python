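"""Three-stage schedule: contracts, schedules, freeze guarantees and
determinism — exercised at micro scale so every test stays fast."""

import dataclasses

import numpy as np
import pytest

from fusegan.losses import FrozenContractError, LossWeights
from fusegan.networks import (
    DiscriminatorSpec,
    FusionSpec,
    GeneratorSpec,
    build_generator,
)
from fusegan.nn import Tensor, freeze, state_bytes_equal
from fusegan.preprocessing import assign_split_tags, make_folds, normalize_cohort
from fusegan.synthetic import SyntheticConfig, Volume, generate_cohort
from fusegan.training import (
    Stage1Config,
    Stage2Config,
    Stage3Config,
    StageConfig,
    clone_classifier,
    finetune_classifier,
    pretrain_classifier,
    run_hybrid,
    synthesize_pet,
    train_ffgan,
)

GEN = GeneratorSpec(encoder_channels=[4, 8], decoder_channels=[8, 1])
DISC = DiscriminatorSpec(channels=[2, 4, 8], input_edge=16)
FUSION = FusionSpec(branch_blocks=2, trunk_blocks=1, base_channels=4, input_edge=16)


@pytest.fixture(scope="module")
def micro_cohort():
    cohort = generate_cohort(
        SyntheticConfig(
            volume_size=16, n_paired_per_class=3, n_unpaired_per_class=1,
            noise_sd=0.05, effect_size=0.4, seed=21,
        )
    )
    normalize_cohort(cohort)
    plan = make_folds(cohort, 3, "incomplete", seed=21)
    assign_split_tags(cohort, plan, validation_fold=0)
    return cohort


@pytest.fixture(scope="module")
def micro_train(micro_cohort):
    return [s for s in micro_cohort if s.split_tag == "train"]


@pytest.fixture(scope="module")
def stage1(micro_train):
    return pretrain_classifier(
        micro_train, FUSION, Stage1Config(lr=5e-3, epochs=8), seed=1
    )


class TestPretrain:
    def test_missing_pet_rejected(self, micro_cohort):
        with pytest.raises(ValueError, match="U0"):
            pretrain_classifier(
                list(micro_cohort), FUSION, Stage1Config(epochs=1), seed=0
            )

    def test_loss_decreases(self, stage1):
        hist = stage1.metrics_history
        assert hist[-1]["train_loss"] < hist[0]["train_loss"]

    def test_same_seed_identical_parameters(self, micro_train):
        cfg = Stage1Config(lr=5e-3, epochs=2)
        a = pretrain_classifier(micro_train, FUSION, cfg, seed=7)
        b = pretrain_classifier(micro_train, FUSION, cfg, seed=7)
        assert state_bytes_equal(
            a.classifier.state_dict(), b.classifier.state_dict()
        )


class TestFfgan:
    def test_unfrozen_fusion_rejected(self, micro_train, stage1):
        with pytest.raises(FrozenContractError):
            train_ffgan(
                micro_train, clone_classifier(stage1.classifier), GEN, DISC,
                Stage2Config(lr=1e-3, epochs=1), 16, 8, seed=0,
            )

    def test_schedule_arithmetic_and_freeze(self, micro_train, stage1):
        frozen = freeze(clone_classifier(stage1.classifier))
        before = frozen.state_dict()
        art = train_ffgan(
            micro_train, frozen, GEN, DISC,
            Stage2Config(lr=1e-3, epochs=2), 16, 8, seed=0,
        )
        n_iter = 2 * len(micro_train)
        assert art.extras["d_steps"] == 5 * n_iter
        assert art.extras["g_steps"] == n_iter
        assert art.extras["fusion_evals"] == n_iter
        assert state_bytes_equal(before, frozen.state_dict())

    def test_lambda2_zero_never_evaluates_fusion_loss(self, micro_train, stage1):
        frozen = freeze(clone_classifier(stage1.classifier))
        art = train_ffgan(
            micro_train, frozen, GEN, DISC,
            Stage2Config(lr=1e-3, epochs=1, weights=LossWeights(100.0, 0.0)),
            16, 8, seed=0,
        )
        assert art.extras["fusion_evals"] == 0
        assert all(r["fusion"] == 0.0 for r in art.metrics_history)


class _IdentityGenerator:
    """Stub with the generator's call signature returning its input."""

    def __call__(self, x):
        return Tensor(x.data.copy())


class TestSynthesize:
    def test_identity_generator_roundtrip(self, rng):
        vol = Volume(rng.random((16, 16, 16)), "MRI")
        out = synthesize_pet(vol, _IdentityGenerator(), 16, 8)
        np.testing.assert_array_equal(out.data, vol.data)
        assert out.modality == "PET"

    def test_output_range_contract(self, rng):
        gen = build_generator(GEN, seed=0)
        vol = Volume(rng.random((16, 16, 16)), "MRI")
        out = synthesize_pet(vol, gen, 16, 8)
        assert out.data.shape == (16, 16, 16)
        assert out.data.min() >= 0.0 and out.data.max() <= 1.0

    def test_geometry_error_propagates(self, rng):
        gen = build_generator(GEN, seed=0)
        vol = Volume(rng.random((16, 16, 16)), "MRI")
        from fusegan.preprocessing import GeometryError

        with pytest.raises(GeometryError):
            synthesize_pet(vol, gen, 12, 5)


class TestFinetune:
    def test_zero_epochs_is_noop(self, micro_train, stage1):
        gen = build_generator(GEN, seed=0)
        art = finetune_classifier(
            micro_train, gen, stage1, Stage3Config(epochs=0), 16, 8, seed=0
        )
        assert state_bytes_equal(
            art.classifier.state_dict(), stage1.classifier.state_dict()
        )

    def test_generator_unchanged_and_loss_decreases(self, micro_train, stage1):
        gen = build_generator(GEN, seed=0)
        before = gen.state_dict()
        art = finetune_classifier(
            micro_train, gen, stage1, Stage3Config(lr=1e-3, epochs=4), 16, 8, seed=0
        )
        assert state_bytes_equal(before, gen.state_dict())
        hist = art.metrics_history
        assert hist[-1]["train_loss"] < hist[0]["train_loss"]

    def test_missing_stage1_checkpoint_rejected(self, micro_train):
        from fusegan.training import StageArtifacts

        empty = StageArtifacts(stage=1, cycle=0, seed=0, classifier=None)
        with pytest.raises(ValueError):
            finetune_classifier(
                micro_train, build_generator(GEN, seed=0), empty,
                Stage3Config(epochs=1), 16, 8, seed=0,
            )


def _short_stages(seed=0, cycles=1):
    return StageConfig(
        stage1=Stage1Config(lr=5e-3, epochs=2),
        stage2=Stage2Config(lr=1e-3, d_lr=2.5e-4, epochs=2),
        stage3=Stage3Config(lr=1e-3, epochs=2),
        cycles=cycles,
        seed=seed,
    )


class TestHybrid:
    def test_single_cycle_runs_all_three_stages(self, micro_cohort):
        res = run_hybrid(micro_cohort, FUSION, GEN, DISC, _short_stages(), 16, 8)
        assert set(res.checkpoints) == {(1, 0), (2, 1), (3, 1)}
        assert res.best_cycle == 1

    def test_per_cycle_checkpoints_retrievable(self, micro_cohort):
        res = run_hybrid(
            micro_cohort, FUSION, GEN, DISC, _short_stages(cycles=2), 16, 8
        )
        assert set(res.checkpoints) == {(1, 0), (2, 1), (3, 1), (2, 2), (3, 2)}
        for (stage, cycle), art in res.checkpoints.items():
            assert art.stage == stage and art.cycle == cycle

    def test_identical_seed_identical_artifacts(self, micro_cohort):
        a = run_hybrid(micro_cohort, FUSION, GEN, DISC, _short_stages(seed=3), 16, 8)
        b = run_hybrid(micro_cohort, FUSION, GEN, DISC, _short_stages(seed=3), 16, 8)
        assert state_bytes_equal(
            a.best.classifier.state_dict(), b.best.classifier.state_dict()
        )
        assert state_bytes_equal(
            a.best.generator.state_dict(), b.best.generator.state_dict()
        )
        assert a.history == b.history

    def test_checkpoints_written_to_disk(self, micro_cohort, tmp_path):
        run_hybrid(
            micro_cohort, FUSION, GEN, DISC, _short_stages(), 16, 8,
            out_dir=tmp_path,
        )
        names = {p.name for p in tmp_path.glob("*.npz")}
        assert {"stage1_cycle0.npz", "stage2_cycle1.npz", "stage3_cycle1.npz"} <= names
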