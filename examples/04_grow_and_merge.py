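"""Segment one crop window by multi-seed region growing and hull merging.

Inside the crop window of the first detected circle, five seeds (centre
plus a half-radius ring) each grow a region by absorbing the adjacent
pixel closest to the region's running mean, within a grey tolerance.
The grown fragments of the body are then merged by their convex hull.
The printed areas show fragments vs. the merged mask.
"""

import numpy as np

from archseg import fusion, hough, regiongrow, scenes, separation
from archseg.denoise import Neighborhood, median_filter, wiener_filter

truth = scenes.build_height_map(scenes.SceneSpec())
fused = fusion.fuse_standard_set(scenes.render_standard_set(truth))
work = median_filter(wiener_filter(fused, Neighborhood(3, 3)), Neighborhood(3, 3))
circles = hough.detect_circles(work, 10, 30, max_circles=14, min_center_sep=20)

(win, labelmap), = regiongrow.segment_all_windows(work, circles[:1], tolerance=0.06, margin=0.35)
print(f"window rows {win.top}..{win.bottom}, cols {win.left}..{win.right}")
print(f"{labelmap.n_regions} regions grown, areas: {list(labelmap.areas())}")

fragments = [labelmap.region_mask(k) for k in range(1, labelmap.n_regions + 1)]
merged = separation.convex_hull_merge(fragments).hull_mask
print(f"convex hull of all fragments: {merged.sum()} px "
      f"(vs {sum(f.sum() for f in fragments)} px of fragment area; the hull "
      "bridges the shading-induced gaps between fragments of one body)")
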