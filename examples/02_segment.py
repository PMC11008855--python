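"""Segment nuclei with the thresholding-initialized level set.

Builds a phantom with known nuclei, runs the competitive-weight adaptive
threshold and the distance-regularized level-set evolution, and reports the
Dice overlap with the ground-truth mask (1.0 = perfect agreement).
"""

import hybridpath as hp
from hybridpath.segmentation import mean_gradient_magnitude, init_sdf, binarize

img, true_mask, _ = hp.make_phantom(hp.PhantomSpec(seed=3, n_nuclei=5))

thr = hp.adaptive_threshold(img)
mask = hp.segment(img)

phi = init_sdf(binarize(img, thr))
print(f"adaptive threshold       {thr:6.1f}  (background ~60, nuclei ~190)")
print(f"initial SDF mean |grad|  {mean_gradient_magnitude(phi):6.3f}  (~1 for a distance field)")
print(f"Dice vs true nuclei      {hp.dice(mask, true_mask):6.3f}")
print(f"nuclei pixels segmented  {int(mask.sum())} / {int(true_mask.sum())} true")
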