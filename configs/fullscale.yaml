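cohort_dir: null
output_dir: runs/run0
synthetic:
  volume_size: 128
  n_paired_per_class: 128
  n_unpaired_per_class: 52
  smoothness: 2.0
  crossmodal_gain: 1.0
  crossmodal_offset: 0.0
  crossmodal_fn: smoothstep
  effect_size: 0.4
  mri_effect_fraction: 0.25
  lesion_regions: null
  noise_sd: 0.05
  missing_label_policy: imbalanced
  seed: 0
stages:
  stage1:
    lr: 0.0005
    batch: 8
    l2: 0.001
    epochs: 30
  stage2:
    lr: 1.0e-05
    d_steps_per_g_step: 5
    weights:
      lambda1: 100.0
      lambda2: 100.0
    epochs: 200
    saturating: false
    resume_generator: true
    grad_clip: 0.0
    d_lr: 0.0
  stage3:
    lr: 0.0001
    batch: 8
    l2: 0.001
    epochs: 20
  cycles: 3
  seed: 0
generator:
  encoder_channels:
  - 64
  - 128
  - 256
  - 512
  - 1024
  - 1024
  decoder_channels:
  - 1024
  - 512
  - 256
  - 128
  - 64
  - 1
  kernel: 3
  stride: 2
  output_activation: sigmoid
  width_scale: 1.0
  leaky_slope: 0.2
discriminator:
  channels:
  - 32
  - 64
  - 128
  - 256
  - 512
  - 1024
  input_edge: 64
  kernel: 3
  stride: 2
  leaky_slope: 0.2
  width_scale: 1.0
fusion:
  branch_blocks: 3
  trunk_blocks: 2
  base_channels: 8
  input_edge: 128
  dropout_rate: 0.5
  n_classes: 2
protocol: incomplete
folds: 10
validation_fold: 0
patch_size: 64
patch_stride: 32
seed: 0
deterministic: true
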