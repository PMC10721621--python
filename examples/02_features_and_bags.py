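"""From a pose sequence to distance features, MIL instances, and clip labels.

Each frame becomes three 17x17 matrices of per-dimension joint distances;
the video tensor is split into 9.6-s instances stepped by 6 s, and expert
FMs intervals label each clip by the strict >0.5-coverage rule.
"""

import numpy as np

from mam.bags import label_clip_from_annotation, split_into_instances
from mam.features import sequence_features
from mam.skeleton_io import preprocess
from mam.synthetic import SyntheticConfig, simulate_infant

rng = np.random.default_rng(1)
infant = simulate_infant(SyntheticConfig(duration_s=60.0), "normal", rng)
seq = preprocess(infant.pose)

features = sequence_features(seq)
print(f"feature tensor [T*, C, V, V] = {features.tensor.shape}")
print(f"slice symmetry check: "
      f"{np.allclose(features.tensor[0], np.swapaxes(features.tensor[0], 1, 2))}")

bag = split_into_instances(features, T=240, step=150)
print(f"bag of {len(bag)} instances of 240 frames (9.6 s), step 150 (6 s)")

for instance in bag.instances:
    label = label_clip_from_annotation(
        infant.annotation, instance.start_frame, T=240, fps=25.0
    )
    window = (instance.start_frame / 25.0, (instance.start_frame + 240) / 25.0)
    print(f"  clip [{window[0]:5.1f}, {window[1]:5.1f}) s -> {label}")
# Clips are FMs when more than half of the window lies inside an annotated
# FMs interval — these latent labels are what the model must recover.
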