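"""The three-stage hybrid schedule end to end at desk scale (~30 s on CPU).

Stage 1 pretrains the fusion classifier on paired volumes; stage 2 trains
the MRI->PET generator with adversarial + L1 + feature-fusion losses
through the frozen fusion model; stage 3 fine-tunes the classifier on
synthesized PET.  MRI-only test subjects are then diagnosed from real MRI
plus imputed PET.
"""

import json

from fusegan import desk_profile, run_pipeline

config = desk_profile(seed=7)
config.output_dir = "runs/example"
metrics = run_pipeline(config)

print(json.dumps(metrics, indent=2))
print()
print("validation = paired subjects judged on real MRI + real PET;")
print("test       = MRI-only subjects judged on real MRI + synthesized PET;")
print("'test_no_finetune' is the stage-1 classifier on the same inputs —")
print("the gap to 'test' is what stage-3 adaptation buys.")
print("'synthesis' reports generator quality (MSE/PSNR/SSIM vs real PET).")
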