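"""Run the complete pipeline on the default synthetic scene.

Simulate, fuse, denoise, detect, grow+merge, separate, evaluate.  The
summary reports, per tooth, the pixel-agreement of the recovered mask
with the ground truth (Dice near 1 = near-perfect recovery), and the
distances between mass centres of mirrored teeth compared with the
generator's geometry (mean percent error well under 1% on clean runs).
"""

import json

from archseg import pipeline

config = pipeline.validate_config({"seed": 0})
summary = pipeline.run_pipeline(config)

print(f"bodies recovered: {summary['n_detected']} / {summary['n_truth_bodies']}")
print(f"median per-tooth Dice: {summary['median_dice']:.4f}")
print("per-tooth Dice:")
for label, rep in summary["per_tooth"].items():
    print(f"  {label}: dice={rep['dice']:.4f} jaccard={rep['jaccard']:.4f} "
          f"accuracy={rep['accuracy']:.4f}")
print("mirrored-pair distances (measured vs truth, mm):")
for k in sorted(summary["pair_distances_mm"]):
    print(f"  pair {k}-{k}: {summary['pair_distances_mm'][k]:7.2f} vs "
          f"{summary['truth_pair_distances_mm'][k]:7.2f}  "
          f"({summary['pair_errors_pct'][k]:.2f}% error)")
print(f"mean percent error: {summary['mean_percent_error']:.2f}%")
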