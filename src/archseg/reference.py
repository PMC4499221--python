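"""Bundled reference measurements of an adult dental arch plaster cast.

Used by the worked examples and the regression checks: manual-calliper and
camera-based estimates of the distance (mm) between mass centres of
mirrored teeth for positions 1 (central incisor) through 7 (second molar),
and per-tooth segmentation similarity scores for the same cast.  Tooth
labels combine the position index with the arch side, e.g. ``"3L"``.
"""

from __future__ import annotations

__all__ = ["ARCH_DISTANCES_MM", "TOOTH_SIMILARITY", "ARCH_SIMILARITY"]

#: Per position index: (manual segmentation distance, proposed/camera
#: segmentation distance), both in millimetres.
ARCH_DISTANCES_MM: dict[int, tuple[float, float]] = {
    1: (32.68, 32.14),
    2: (85.86, 84.69),
    3: (124.15, 121.38),
    4: (147.82, 145.39),
    5: (168.63, 166.44),
    6: (206.01, 203.77),
    7: (227.72, 226.87),
}

#: Per tooth label: Jaccard index, Dice coefficient, accuracy,
#: false-positive rate and false-negative rate of the camera-based
#: segmentation against manually drawn boundaries.
TOOTH_SIMILARITY: dict[str, dict[str, float]] = {
    "1R": {"jaccard": 0.9330, "dice": 0.9653, "accuracy": 0.9993, "fpr": 0.0627, "fnr": 0.0086},
    "2R": {"jaccard": 0.9211, "dice": 0.9589, "accuracy": 0.9994, "fpr": 0.0649, "fnr": 0.0192},
    "3R": {"jaccard": 0.9606, "dice": 0.9799, "accuracy": 0.9996, "fpr": 0.0285, "fnr": 0.0120},
    "4R": {"jaccard": 0.9344, "dice": 0.9661, "accuracy": 0.9994, "fpr": 0.0512, "fnr": 0.0178},
    "5R": {"jaccard": 0.9466, "dice": 0.9726, "accuracy": 0.9989, "fpr": 0.0363, "fnr": 0.0190},
    "6R": {"jaccard": 0.9217, "dice": 0.9593, "accuracy": 0.9986, "fpr": 0.0308, "fnr": 0.0499},
    "7R": {"jaccard": 0.8933, "dice": 0.9436, "accuracy": 0.9988, "fpr": 0.0198, "fnr": 0.0891},
    "1L": {"jaccard": 0.8786, "dice": 0.9354, "accuracy": 0.9998, "fpr": 0.0611, "fnr": 0.0677},
    "2L": {"jaccard": 0.8224, "dice": 0.9025, "accuracy": 0.9998, "fpr": 0.0146, "fnr": 0.1656},
    "3L": {"jaccard": 0.7285, "dice": 0.8429, "accuracy": 0.9974, "fpr": 0.0654, "fnr": 0.2238},
    "4L": {"jaccard": 0.8360, "dice": 0.9106, "accuracy": 0.9983, "fpr": 0.0455, "fnr": 0.1261},
    "5L": {"jaccard": 0.8593, "dice": 0.9243, "accuracy": 0.9971, "fpr": 0.0427, "fnr": 0.1040},
    "6L": {"jaccard": 0.8964, "dice": 0.9454, "accuracy": 0.9983, "fpr": 0.0248, "fnr": 0.0813},
    "7L": {"jaccard": 0.8986, "dice": 0.9466, "accuracy": 0.9990, "fpr": 0.0309, "fnr": 0.0737},
}

#: Whole-arch agreement of the same segmentation.
ARCH_SIMILARITY: dict[str, float] = {
    "jaccard": 0.8931,
    "dice": 0.9436,
    "accuracy": 0.9828,
    "fpr": 0.0381,
    "fnr": 0.0728,
}
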