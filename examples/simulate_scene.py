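"""Generate one synthetic desert-farmland scene and describe it.

A scene is a sandy low-saturation background with smooth brightness
variation, sparse green vegetation blobs carrying canopy speckle, soft
shadows, and sensor noise — plus an exact ground-truth vegetation mask.
"""

import numpy as np

from desertveg import SceneParams, generate_scene, rgb_to_hsv

params = SceneParams(size=(256, 256), vegetation_fraction_target=0.2, seed=11)
rgb, mask, meta = generate_scene(params)

hsv = rgb_to_hsv(rgb)
print(f"scene size          : {rgb.shape[0]}x{rgb.shape[1]}")
print(f"vegetation fraction : {mask.mean():.3f} (target {params.vegetation_fraction_target})")
print(f"vegetation hue (deg): median {np.median(hsv[..., 0][mask]):.1f}")
print(f"soil hue (deg)      : median {np.median(hsv[..., 0][~mask]):.1f}")
print(f"shadowed pixels     : {meta['shadow_mask'].mean():.3f} of the image")

# The hue gap between the two medians is what color-based segmentation
# exploits; the shadow fraction shows how much of the image has had its
# brightness (but not its hue) reduced.
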