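"""Generate one synthetic adipocyte scene and inspect its ground truth.

Builds a 128x128 scene with the default study conditions (5 nuclei, 12
lipid droplets, 30% defective) and prints what the generator guarantees:
exact object counts, registration, and the faintness of nuclei in
bright-field relative to their fluorescence contrast.
"""

import numpy as np

from virtustain.imaging_io import Channel
from virtustain.synthetic_data import SceneSpec, generate_scene

spec = SceneSpec(seed=7)
stack, channels, truth = generate_scene(spec)

print(f"bright-field stack: {stack.n_planes} planes of {stack.plane_shape}")
print(f"nuclei in truth:    {truth.nuclei_labels.max()} (centers {truth.nuclei_centers})")
print(f"lipids in truth:    {truth.lipid_labels.max()}, "
      f"defective ids {truth.defective_lipid_ids}")

nuc = truth.nuclei_labels > 0
focus = stack.planes[stack.n_planes // 2]
bf_contrast = abs(focus[nuc].mean() - focus[~nuc].mean())
fl = channels[Channel.NUCLEI].pixels
fl_contrast = abs(fl[nuc].mean() - fl[~nuc].mean())
print(f"nucleus contrast:   {bf_contrast:.3f} in bright-field vs "
      f"{fl_contrast:.3f} in fluorescence")
print("-> the virtual-staining task is hard exactly where it should be:")
print("   nuclei are an order of magnitude fainter in transmitted light.")
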