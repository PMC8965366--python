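"""Grad-CAM saliency volumes from a trained fusion classifier.

Trains stage 1 briefly on a small cohort, then computes gradient-weighted
class-activation maps for one subject of the late-impairment-like class
and reports how much saliency mass falls inside the planted lesion regions.
"""

import numpy as np

from fusegan import desk_profile, grad_cam, prepare_cohort, pretrain_classifier
from fusegan.synthetic import lesion_mask

config = desk_profile(seed=3)
cohort = prepare_cohort(config)
train = [s for s in cohort if s.split_tag == "train" and s.has_pet]
artifacts = pretrain_classifier(train, config.fusion, config.stages.stage1, seed=3)

subject = next(s for s in train if s.label == 1)
result = grad_cam(artifacts.classifier, subject.mri, subject.pet, target_class=1)

mask = lesion_mask(config.synthetic.volume_size, config.synthetic.resolved_lesions())
for name in ("mri", "pet"):
    cam = result.saliency[name].data
    if result.all_zero[name]:
        print(f"{name}: zero gradients — no saliency for this subject")
        continue
    inside = cam[mask].mean()
    outside = cam[~mask].mean()
    print(f"{name}: mean saliency inside lesions {inside:.3f}, outside {outside:.3f}")
# At this miniature scale the target layer is only 4^3, so maps are coarse:
# treat them as qualitative overlays, not quantitative localization.
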