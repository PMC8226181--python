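"""Build a synthetic implanted-lead CT volume with known ground truth.

Creates a gently bowed electrode trajectory (exact cubic, so the downstream
model is identifiable), rasterizes it at the emulated scanner resolution
(0.488 x 0.488 x 0.625 mm), and reports the voxel classes produced.
"""

import numpy as np

from dbsdeform import make_ground_truth_curve, rasterize_case
from dbsdeform.synthetic import LABEL

curve = make_ground_truth_curve(
    electrode_type="directional",
    hemisphere="left",
    deviation_amplitudes=(0.8, -0.4, 0.2),  # mm, max per-axis bow vs the chord
    chord_length=68.0,                      # mm, proximal point to tip
    seed=42,
)
case = rasterize_case(curve, seed=42)

print(f"volume shape {case.volume.data.shape}, voxel size "
      f"{np.round(case.volume.voxel_size, 3)} mm")
for name, code in LABEL.items():
    print(f"  {name:10s} {int((case.class_labels == code).sum()):8d} voxels")
print(f"electrode voxels: {case.electrode_voxels['left']}")
print(f"sampled frontiers (mm from proximal point): "
      f"cortex {case.frontiers['left'].cortex_entry:.2f}, "
      f"gyration/WMS {case.frontiers['left'].gyration_wms:.2f}, "
      f"WMS/deep {case.frontiers['left'].wms_deep:.2f}")
# The electrode class is everything a CT thresholding step at the default
# threshold would call metal; frontier distances position the three tissue
# layers the lead crosses.
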