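"""Consistency checks on the bundled reference measurements.

The per-tooth similarity table carries both a Jaccard index and a Dice
coefficient; the two are algebraically linked (D = 2J/(1+J)), so one can
be recomputed from the other.  The arch-distance table carries manual
and camera-based distances; the percent errors and their mean quantify
how closely the camera-based segmentation reproduces the manual
measurement.
"""

from archseg import metrics, reference
from archseg.metrics import dice_from_jaccard

print("Dice recomputed from the tabulated Jaccard index:")
for label, row in reference.TOOTH_SIMILARITY.items():
    d = dice_from_jaccard(row["jaccard"])
    print(f"  {label}: J={row['jaccard']:.4f} -> D={d:.4f} (tabulated {row['dice']:.4f})")

manual = {k: v[0] for k, v in reference.ARCH_DISTANCES_MM.items()}
proposed = {k: v[1] for k, v in reference.ARCH_DISTANCES_MM.items()}
rep = metrics.error_vs_reference(
    metrics.ArchReport(pair_distances_mm=proposed, pixel_scale=1.0), manual
)
print("\nmirrored-pair distances, camera-based vs manual:")
for k in sorted(manual):
    print(f"  pair {k}-{k}: {manual[k]:7.2f} vs {proposed[k]:7.2f} mm  "
          f"-> {rep.errors_mm[k]:.2f} mm, {rep.errors_pct[k]:.2f}%")
print(f"mean percent error: {rep.mean_percent_error:.2f}%")
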