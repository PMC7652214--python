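"""Segment the cornea band and extract its medial axis.

Runs Otsu thresholding + morphological cleanup on the green channel,
then the three-stage centerline estimate (cubic fit, normal-line
midpoint refinement, smoothing spline), and scores both against the
generator's analytic ground truth.
"""

import numpy as np
from scipy.spatial import cKDTree

from corneaquant import (
    SynthParams,
    extract_centerline,
    extract_green,
    generate_section,
    otsu_threshold,
    segment_cornea,
)
from corneaquant.centerline import centerline_from_points
from corneaquant.synthetic import _arc_geometry

params = SynthParams(seed=1)
section = generate_section(params)
green = extract_green(section.image)

t = otsu_threshold(green)
print(f"Otsu threshold: {t} (tissue = green <= {t})")

mask = segment_cornea(green)
inter = (mask & section.mask).sum()
union = (mask | section.mask).sum()
print(f"mask: {int(mask.sum())} px, Jaccard vs ground truth "
      f"{inter / union:.4f} (1.0 = perfect overlap)")

line = extract_centerline(mask)
*_, truth_pts = _arc_geometry(params)
truth = centerline_from_points(truth_pts, n_out=20000)
d, _ = cKDTree(truth.points).query(line.points)
print(f"centerline: {len(line)} points, length {line.total_length:.1f} px, "
      f"RMS error vs true medial arc {np.sqrt((d**2).mean()):.2f} px")
print("sub-pixel agreement means the 24-ROI grid lands where the "
      "anatomy says it should.")
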