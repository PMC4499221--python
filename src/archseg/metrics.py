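"""Segmentation evaluation and dental-arch morphometry.

Pixel-level agreement between a segmentation result and ground truth is
summarised by the confusion counts TP/FP/FN/TN and the derived rates

    TPR = TP/(TP+FN)            TNR = TN/(FP+TN)
    FNR = FN/(TP+FN)            FPR = FP/(FP+TN)
    Accuracy = (TP+TN)/total
    Jaccard  = TP/(TP+FP+FN)    Dice = 2 TP/((FP+TP)+(TP+FN))

with the algebraic identity Dice = 2 J / (1 + J).  Because per-tooth
evaluation frames are dominated by true negatives, FPR on the full frame
is tiny even for poor masks; an object-relative false-positive measure
FP/(FP+TP) is therefore reported alongside the frame-relative FPR.

Arch morphometry reduces each tooth mask to its mass centre and measures,
for every position index, the distance in millimetres between the left and
right mass centres; the per-pair absolute and percent errors against a
reference set of distances and their mean summarise geometric fidelity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ConfusionCounts",
    "SimilarityReport",
    "ToothMeasurement",
    "ArchReport",
    "confusion_counts",
    "similarity_report",
    "dice_from_jaccard",
    "mass_center",
    "pair_distances",
    "error_vs_reference",
]


@dataclass(frozen=True)
class ConfusionCounts:
    """Pixel classification counts over one evaluation frame."""

    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class SimilarityReport:
    """Agreement rates for one object; degenerate ratios are NaN."""

    tpr: float
    tnr: float
    fnr: float
    fpr: float
    accuracy: float
    jaccard: float
    dice: float
    #: object-relative false positives FP/(FP+TP) -- the share of the
    #: predicted mask lying outside the truth; more informative than the
    #: frame-relative FPR when the frame is dominated by background.
    fpr_object: float = float("nan")


@dataclass(frozen=True)
class ToothMeasurement:
    """One labelled tooth mask reduced to its mass centre."""

    side: str
    index: int
    mask: np.ndarray
    mass_center_rc: tuple[float, float] = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "mass_center_rc", mass_center(self.mask))

    @property
    def label(self) -> str:
        return f"{self.index}{self.side}"


@dataclass
class ArchReport:
    """Per-index L-R mass-centre distances (mm) and errors vs a reference."""

    pair_distances_mm: dict[int, float]
    pixel_scale: float
    errors_mm: dict[int, float] = field(default_factory=dict)
    errors_pct: dict[int, float] = field(default_factory=dict)
    mean_percent_error: float = float("nan")
    invalid_pairs: list[int] = field(default_factory=list)


def _as_mask(mask: np.ndarray) -> np.ndarray:
    mask = np.asarray(mask)
    if mask.ndim != 2:
        raise ValueError("mask must be 2-D")
    return mask.astype(bool)


def confusion_counts(result_mask: np.ndarray, truth_mask: np.ndarray) -> ConfusionCounts:
    """TP/FP/FN/TN pixel counts of a result mask against a truth mask."""
    result = _as_mask(result_mask)
    truth = _as_mask(truth_mask)
    if result.shape != truth.shape:
        raise ValueError("masks must share dimensions")
    tp = int(np.count_nonzero(result & truth))
    fp = int(np.count_nonzero(result & ~truth))
    fn = int(np.count_nonzero(~result & truth))
    tn = result.size - tp - fp - fn
    return ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=tn)


def _ratio(num: int, den: int, name: str) -> float:
    if den == 0:
        warnings.warn(f"{name} undefined: empty denominator", stacklevel=3)
        return float("nan")
    return num / den


def similarity_report(c: ConfusionCounts) -> SimilarityReport:
    """All agreement rates from one set of confusion counts."""
    pos = c.tp + c.fn
    neg = c.fp + c.tn
    return SimilarityReport(
        tpr=_ratio(c.tp, pos, "TPR"),
        tnr=_ratio(c.tn, neg, "TNR"),
        fnr=_ratio(c.fn, pos, "FNR"),
        fpr=_ratio(c.fp, neg, "FPR"),
        accuracy=_ratio(c.tp + c.tn, c.total, "accuracy"),
        jaccard=_ratio(c.tp, c.fp + c.tp + c.fn, "Jaccard"),
        dice=_ratio(2 * c.tp, (c.fp + c.tp) + (c.tp + c.fn), "Dice"),
        fpr_object=_ratio(c.fp, c.fp + c.tp, "object-relative FPR"),
    )


def dice_from_jaccard(jaccard: float) -> float:
    """Dice coefficient implied by a Jaccard index: D = 2J / (1 + J)."""
    if not (0.0 <= jaccard <= 1.0):
        raise ValueError("Jaccard index must lie in [0, 1]")
    return 2.0 * jaccard / (1.0 + jaccard)


def mass_center(mask: np.ndarray) -> tuple[float, float]:
    """Centroid (row, col) of the foreground pixels, uniform density."""
    mask = _as_mask(mask)
    pts = np.argwhere(mask)
    if pts.shape[0] == 0:
        raise ValueError("empty mask has no mass centre")
    r, c = pts.mean(axis=0)
    return float(r), float(c)


def pair_distances(teeth: list[ToothMeasurement], pixel_scale: float) -> ArchReport:
    """Euclidean distance (mm) between the L and R mass centres per index.

    Every index present must appear on both sides.  A zero distance
    (coincident centres) is physically invalid and flagged in
    ``invalid_pairs``.
    """
    if pixel_scale <= 0:
        raise ValueError("pixel_scale must be > 0")
    by_key = {(t.side, t.index): t for t in teeth}
    indices = sorted({t.index for t in teeth})
    dists: dict[int, float] = {}
    invalid: list[int] = []
    for k in indices:
        if ("L", k) not in by_key or ("R", k) not in by_key:
            raise ValueError(f"index {k} missing on one side")
        left = np.array(by_key[("L", k)].mass_center_rc)
        right = np.array(by_key[("R", k)].mass_center_rc)
        d = float(np.linalg.norm(left - right)) * pixel_scale
        dists[k] = d
        if d == 0.0:
            invalid.append(k)
            warnings.warn(f"pair {k}-{k}: coincident mass centres (distance 0)", stacklevel=2)
    return ArchReport(pair_distances_mm=dists, pixel_scale=pixel_scale, invalid_pairs=invalid)


def error_vs_reference(measured: ArchReport, reference_distances_mm: dict[int, float]) -> ArchReport:
    """Fill per-pair absolute (mm) and percent errors against a reference.

    percent error = |reference - measured| / reference * 100; the mean
    percent error is the arithmetic mean over pairs.  All arithmetic is at
    full precision; rounding is a presentation concern.
    """
    if set(reference_distances_mm) != set(measured.pair_distances_mm):
        raise ValueError("reference and measured index sets differ")
    errors_mm: dict[int, float] = {}
    errors_pct: dict[int, float] = {}
    for k, ref in reference_distances_mm.items():
        if ref <= 0:
            raise ValueError(f"reference distance for pair {k} must be > 0")
        err = abs(ref - measured.pair_distances_mm[k])
        errors_mm[k] = err
        errors_pct[k] = err / ref * 100.0
    return ArchReport(
        pair_distances_mm=dict(measured.pair_distances_mm),
        pixel_scale=measured.pixel_scale,
        errors_mm=errors_mm,
        errors_pct=errors_pct,
        mean_percent_error=float(np.mean(list(errors_pct.values()))),
        invalid_pairs=list(measured.invalid_pairs),
    )
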