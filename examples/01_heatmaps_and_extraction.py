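"""Gaussian heatmap targets and landmark recovery.

Builds the regression target for one landmark, shows the peak value and
its one-voxel neighbours, and recovers the landmark position with the
argmax / score-S extractor.
"""

import numpy as np

from landmarknet import HeatmapConfig, extract_landmark, make_heatmap

grid = (33, 64, 64)          # head output grid: 33 slices, 64x64 in-plane
landmark = (16, 30, 34)      # voxel position of the landmark on that grid

hm = make_heatmap(landmark, grid, HeatmapConfig())
print(f"peak temperature at the landmark voxel : {hm.values[landmark]:.1f}")
print(f"one voxel away along x                 : {hm.values[16, 30, 35]:.4f}")
print(f"analytic k*exp(-1/2)                   : {1000 * np.exp(-0.5):.4f}")

recovered = extract_landmark(hm)
print(f"recovered landmark position            : {recovered}")
# The peak equals k = 1000, the neighbour k*exp(-1/2) (sigma = one voxel),
# and extraction returns the planted voxel exactly.
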