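"""Simulate an annotated creature and encode its training targets.

Builds the small 5-keypoint test creature, samples one pose, renders the
image, and draws the confidence-map stack: one Gaussian peak per keypoint
plus the four-level posture graph (edge maps, limb maps, the whole graph,
and the graph fused with the peaks).
"""

import numpy as np

from posekit import render_targets, sample_pose
from posekit.synthetic import render, toy_creature

spec = toy_creature(64, noise_level=0.02)
rng = np.random.default_rng(0)
kp = sample_pose(spec, rng)
image = render(spec, kp, rng)

stack = render_targets(kp, spec.skeleton, spec.image_size, stride=2, sigma=5.0)

print(f"image: {image.shape} uint8, intensities {image.min()}..{image.max()}")
print(f"keypoints: {kp.n_keypoints}, all visible: {kp.visible.all()}")
print(f"target stack: {stack.maps.shape} (K={stack.n_keypoints} keypoint maps "
      f"+ G={stack.n_graph_maps} graph maps) at stride {stack.stride}")
for level in range(1, 5):
    print(f"  graph level {level}: {stack.graph_level(level).shape[0]} map(s)")
print(f"all map values in [0, 1]: {stack.maps.min() >= 0 and stack.maps.max() <= 1}")
# Levels 1-2 decompose the skeleton into segments and limbs; levels 3-4 are
# single integrated maps the model must reproduce at every scale.
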