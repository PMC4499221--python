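"""Separate two fused discs by the boundary-curvature algorithm.

Two overlapping discs form a single mask with a neck.  The boundary is
traced, smoothed, and its cyclic second derivative computed; along
convex arcs the second derivative points into the object, at the neck
corners it flips outward.  The two strongest concave zones mark the
intersection points, and a straight cut between them splits the mask.
The printed errors compare the found cut points with the closed-form
circle-intersection points.
"""

import numpy as np

from archseg import separation

rr = np.arange(140)[:, None]
cc = np.arange(200)[None, :]
c1, c2, radius = (70, 60), (70, 95), 20
mask = ((rr - c1[0]) ** 2 + (cc - c1[1]) ** 2 <= radius**2) | (
    (rr - c2[0]) ** 2 + (cc - c2[1]) ** 2 <= radius**2
)

parts = separation.separate_pipeline([mask])
print(f"separate_pipeline returned {len(parts)} masks "
      f"(areas {[int(p.sum()) for p in parts]})")

prepared = separation.morphological_prepare(mask)
contour = separation.second_derivative(
    separation.smooth_contour(separation.trace_boundary(prepared), window=9)
)
cuts = separation.find_cut_points(contour, prepared)
d = np.linalg.norm(np.array(c2) - c1)
a = d / 2  # equal radii: the chord is centred between the discs
h = np.sqrt(radius**2 - a**2)
expected = [(c1[0] + h, (c1[1] + c2[1]) / 2), (c1[0] - h, (c1[1] + c2[1]) / 2)]
for p in cuts:
    err = min(np.hypot(p[0] - e[0], p[1] - e[1]) for e in expected)
    print(f"cut point {p}: {err:.2f} px from the analytic circle intersection")
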