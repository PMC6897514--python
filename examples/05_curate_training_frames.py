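"""Curate a training set: diverse frame sampling and egocentric alignment.

k-means sampling picks frames that span distinct postures instead of
consecutive near-duplicates; egocentric alignment rotates each image so the
body axis is vertical and centred, standardising the data before annotation.
"""

import numpy as np

from posekit.curation import egocentric_align, kmeans_sample
from posekit.synthetic import make_dataset, render, sample_pose, toy_creature

spec = toy_creature(64, jitter=25.0, noise_level=0.02)
ds = make_dataset(spec, 60, seed=4)

picked = kmeans_sample(ds.images, k=10, n=8, seed=0)
print(f"selected frames (k=10 clusters): {sorted(picked.tolist())}")

head = spec.skeleton.index("head")
tail = spec.skeleton.index("tail")
rng = np.random.default_rng(2)
kp = sample_pose(spec, rng)
image = render(spec, kp, rng)
v = kp.coords[head] - kp.coords[tail]
angle_before = np.degrees(np.arctan2(v[0], -v[1]))

_, kp_aligned = egocentric_align(image, kp, axis=(tail, head))
v2 = kp_aligned.coords[head] - kp_aligned.coords[tail]
angle_after = np.degrees(np.arctan2(v2[0], -v2[1]))
print(f"body-axis angle before: {angle_before:+.1f} deg, "
      f"after alignment: {angle_after:+.1f} deg")
mid = (kp_aligned.coords[head] + kp_aligned.coords[tail]) / 2
print(f"axis midpoint after alignment: ({mid[0]:.1f}, {mid[1]:.1f}) "
      f"(image centre is (31.5, 31.5))")
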