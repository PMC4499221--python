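"""End-to-end pipeline: simulate, fuse, denoise, detect, grow, separate, evaluate.

The pipeline renders (or is given) a four-capture illumination set, fuses
it, denoises the fused image (Wiener then median), localizes candidate
bodies with the circular Hough transform, grows regions inside each crop
window, merges each window's fragments with a convex hull, repairs
heavily overlapping neighbour masks with the curvature split, and
evaluates the resulting per-tooth masks against ground truth.  All
randomness flows from a single root seed split deterministically per
stage, so identical configuration and seed reproduce identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.optimize import linear_sum_assignment

from . import fusion, hough, metrics, regiongrow, scenes, separation
from .denoise import Neighborhood, median_filter, wiener_filter

__all__ = [
    "DenoiseParams",
    "HoughParams",
    "GrowParams",
    "SeparateParams",
    "PipelineConfig",
    "validate_config",
    "run_pipeline",
]

log = logging.getLogger("archseg")


@dataclass(frozen=True)
class DenoiseParams:
    wiener_window: int = 3
    median_window: int = 3
    noise_var: float | None = None

    def validate(self, errors: list[str]) -> None:
        for name in ("wiener_window", "median_window"):
            v = getattr(self, name)
            if v < 1 or v % 2 == 0:
                errors.append(f"denoise.{name} must be odd and >= 1 (got {v})")
        if self.noise_var is not None and self.noise_var < 0:
            errors.append(f"denoise.noise_var must be >= 0 (got {self.noise_var})")


@dataclass(frozen=True)
class HoughParams:
    r_min: int = 10
    r_max: int = 30
    grad_threshold: float | None = None
    max_circles: int = 14
    min_center_sep: float | None = 20.0
    window_margin: float = 0.35

    def validate(self, errors: list[str]) -> None:
        if self.r_min <= 0:
            errors.append(f"hough.r_min must be > 0 (got {self.r_min})")
        if self.r_max < self.r_min:
            errors.append("hough.r_max must be >= hough.r_min")
        if self.max_circles < 1:
            errors.append(f"hough.max_circles must be >= 1 (got {self.max_circles})")
        if self.window_margin < 0:
            errors.append(f"hough.window_margin must be >= 0 (got {self.window_margin})")


@dataclass(frozen=True)
class GrowParams:
    tolerance: float = 0.06
    connectivity: int = 8
    seeds_per_circle: int = 5
    max_area_factor: float = 4.0

    def validate(self, errors: list[str]) -> None:
        if self.tolerance < 0:
            errors.append(f"region_grow.tolerance must be >= 0 (got {self.tolerance})")
        if self.connectivity not in (4, 8):
            errors.append(f"region_grow.connectivity must be 4 or 8 (got {self.connectivity})")
        if self.seeds_per_circle < 1:
            errors.append("region_grow.seeds_per_circle must be >= 1")
        if self.max_area_factor <= 0:
            errors.append("region_grow.max_area_factor must be > 0")


@dataclass(frozen=True)
class SeparateParams:
    smooth_window: int = 9
    noise_floor_pct: float = 25.0
    overlap_iou_gate: float = 0.3

    def validate(self, errors: list[str]) -> None:
        if self.smooth_window < 1 or self.smooth_window % 2 == 0:
            errors.append("separate.smooth_window must be odd and >= 1")
        if not (0 <= self.noise_floor_pct < 100):
            errors.append("separate.noise_floor_pct must lie in [0, 100)")
        if not (0 < self.overlap_iou_gate <= 1):
            errors.append("separate.overlap_iou_gate must lie in (0, 1]")


@dataclass(frozen=True)
class PipelineConfig:
    scene: scenes.SceneSpec = field(default_factory=scenes.SceneSpec)
    denoise: DenoiseParams = field(default_factory=DenoiseParams)
    hough: HoughParams = field(default_factory=HoughParams)
    grow: GrowParams = field(default_factory=GrowParams)
    separate: SeparateParams = field(default_factory=SeparateParams)
    seed: int = 0
    log_level: str = "INFO"
    apply_denoise: bool = True


#: config block name -> (PipelineConfig field, parameter class)
_BLOCKS = {
    "scene": ("scene", scenes.SceneSpec),
    "denoise": ("denoise", DenoiseParams),
    "hough": ("hough", HoughParams),
    "region_grow": ("grow", GrowParams),
    "separate": ("separate", SeparateParams),
}


def validate_config(raw: dict) -> PipelineConfig:
    """Build a :class:`PipelineConfig` from a plain key/value tree.

    Unknown keys are rejected; every violation is collected and reported
    together, not just the first.
    """
    errors: list[str] = []
    kwargs: dict = {}
    raw = dict(raw or {})
    for name, (attr, cls) in _BLOCKS.items():
        block = raw.pop(name, {})
        if not isinstance(block, dict):
            errors.append(f"{name} must be a mapping")
            continue
        valid_fields = {f.name for f in dataclasses.fields(cls)}
        unknown = set(block) - valid_fields
        if unknown:
            errors.append(f"{name}: unknown keys {sorted(unknown)}")
        block = {k: v for k, v in block.items() if k in valid_fields}
        if name == "scene" and "noise" in block and isinstance(block["noise"], dict):
            block["noise"] = scenes.NoiseSpec(**block["noise"])
        if name == "scene" and "image_shape" in block:
            block["image_shape"] = tuple(block["image_shape"])
        if name == "scene" and "body_radii" in block:
            block["body_radii"] = tuple(block["body_radii"])
        try:
            kwargs[attr] = cls(**block)
        except (TypeError, ValueError) as exc:
            errors.append(f"{name}: {exc}")
    for key in ("seed", "log_level", "apply_denoise"):
        if key in raw:
            kwargs[key] = raw.pop(key)
    if raw:
        errors.append(f"unknown top-level keys {sorted(raw)}")
    if not errors:
        try:
            cfg = PipelineConfig(**kwargs)
        except (TypeError, ValueError) as exc:
            errors.append(str(exc))
        else:
            try:
                cfg.scene.validate()
            except ValueError as exc:
                errors.append(f"scene: {exc}")
            for name in ("denoise", "hough", "grow", "separate"):
                getattr(cfg, name).validate(errors)
            if not errors:
                return cfg
    raise ValueError("invalid pipeline configuration:\n  " + "\n  ".join(errors))


def _place_full(mask: np.ndarray, window: hough.Window, shape: tuple[int, int]) -> np.ndarray:
    full = np.zeros(shape, dtype=bool)
    full[window.slices] = mask
    return full


def _iou(a: np.ndarray, b: np.ndarray) -> float:
    inter = np.count_nonzero(a & b)
    union = np.count_nonzero(a | b)
    return inter / union if union else 0.0


def complete_to_valley(
    image: np.ndarray,
    masks: list[np.ndarray],
    radii: list[float],
    rise_tol: float = 0.02,
    extend_frac: float = 0.35,
) -> list[np.ndarray]:
    """Extend each mask downhill through its dark rim to the intensity valley.

    A convex body lit from above/aside shows a bright plateau and a dark
    shading ring at its rim; intensity-similarity growth stops at the top
    of the ring, so the recovered mask underestimates the body support.
    This completion admits, in order of decreasing image intensity, every
    unclaimed pixel adjacent to a mask whose intensity does not exceed its
    brightest claimed neighbour by more than ``rise_tol`` -- i.e. the
    expansion may only descend (or stay level within noise).  It therefore
    follows the ring down to the surrounding intensity valley and stops
    where intensity rises again toward the base or a neighbouring body.
    Expansion is capped at ``extend_frac`` times the body radius beyond
    the original mask.  Deterministic: the queue is ordered by
    (-intensity, row, col) and ties between claiming masks go to the
    lower mask index.
    """
    import heapq

    image = np.asarray(image, dtype=float)
    M, N = image.shape
    labels = np.zeros((M, N), dtype=np.int32)
    for i, m in enumerate(masks):
        labels[m & (labels == 0)] = i + 1
    from scipy.ndimage import distance_transform_edt

    allowed = []
    for m, r in zip(masks, radii):
        if m.any():
            allowed.append(distance_transform_edt(~m) <= extend_frac * r)
        else:
            allowed.append(np.zeros((M, N), dtype=bool))

    heap: list[tuple[float, int, int]] = []
    queued = np.zeros((M, N), dtype=bool)

    def enqueue_neighbors(r0: int, c0: int) -> None:
        for dr, dc in _OFFS8:
            rr, cc = r0 + dr, c0 + dc
            if 0 <= rr < M and 0 <= cc < N and labels[rr, cc] == 0 and not queued[rr, cc]:
                queued[rr, cc] = True
                heapq.heappush(heap, (-image[rr, cc], rr, cc))

    for r0, c0 in np.argwhere(labels > 0):
        enqueue_neighbors(int(r0), int(c0))

    while heap:
        neg, r0, c0 = heapq.heappop(heap)
        if labels[r0, c0] != 0:
            continue
        best = None  # (intensity, -label) of brightest claimed neighbour
        for dr, dc in _OFFS8:
            rr, cc = r0 + dr, c0 + dc
            if 0 <= rr < M and 0 <= cc < N and labels[rr, cc] != 0:
                key = (image[rr, cc], -labels[rr, cc])
                if best is None or key > best:
                    best = key
        if best is None:
            continue
        lab = -best[1]
        if image[r0, c0] <= best[0] + rise_tol and allowed[lab - 1][r0, c0]:
            labels[r0, c0] = lab
            enqueue_neighbors(r0, c0)
    return [m | (labels == i + 1) for i, m in enumerate(masks)]


_OFFS8 = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


def segment_scene(
    image: np.ndarray,
    circles: list[hough.CircleHypothesis],
    grow: GrowParams,
    sep: SeparateParams,
    window_margin: float,
) -> list[np.ndarray]:
    """Detected circles -> one full-frame mask per circle.

    Each circle's crop window is segmented by multi-seed growth; the kept
    regions are merged by convex hull into a candidate body mask.  When two
    neighbouring candidate masks overlap beyond the IoU gate, the
    curvature-split pipeline re-separates their union and the parts are
    reassigned to the nearer circle.
    """
    results = regiongrow.segment_all_windows(
        image,
        circles,
        tolerance=grow.tolerance,
        connectivity=grow.connectivity,
        seeds_per_circle=grow.seeds_per_circle,
        margin=window_margin,
        max_area_factor=grow.max_area_factor,
    )
    masks: list[np.ndarray] = []
    for (win, lm), circle in zip(results, circles):
        comps = [lm.region_mask(k) for k in range(1, lm.n_regions + 1) if lm.region_mask(k).any()]
        if not comps:
            masks.append(np.zeros(image.shape, dtype=bool))
            continue
        hull = separation.convex_hull_merge(comps).hull_mask
        masks.append(_place_full(hull, win, image.shape))
    masks = complete_to_valley(image, masks, [c.radius for c in circles])
    # repair pass: strongly overlapping neighbour masks get re-split
    for i in range(len(masks)):
        for j in range(i + 1, len(masks)):
            if not masks[i].any() or not masks[j].any():
                continue
            if _iou(masks[i], masks[j]) < sep.overlap_iou_gate:
                continue
            parts = separation.separate_pipeline(
                [masks[i], masks[j]],
                smooth_window=sep.smooth_window,
                noise_floor_pct=sep.noise_floor_pct,
            )
            if len(parts) != 2:
                continue
            ci = np.array([circles[i].row, circles[i].col], float)
            cj = np.array([circles[j].row, circles[j].col], float)
            c0 = np.array(metrics.mass_center(parts[0]))
            if np.linalg.norm(c0 - ci) <= np.linalg.norm(c0 - cj):
                masks[i], masks[j] = parts[0], parts[1]
            else:
                masks[i], masks[j] = parts[1], parts[0]
    return masks


def _match_to_truth(
    masks: list[np.ndarray], truth: scenes.SceneTruth
) -> list[tuple[scenes.Body, np.ndarray]]:
    """Bijective centroid assignment of predicted masks to truth bodies."""
    pred_centers = np.array([metrics.mass_center(m) if m.any() else (1e9, 1e9) for m in masks])
    true_centers = np.array([b.center for b in truth.bodies])
    cost = np.linalg.norm(pred_centers[:, None, :] - true_centers[None, :, :], axis=2)
    rows, cols = linear_sum_assignment(cost)
    return [(truth.bodies[c], masks[r]) for r, c in zip(rows, cols)]


def run_pipeline(config: PipelineConfig, out_dir: str | Path | None = None) -> dict:
    """Execute all stages and return (and optionally write) the summary.

    The summary holds the per-tooth similarity reports, the measured
    mirrored-pair distances with errors against the generator geometry,
    and bookkeeping (stage timings, parameters, seed).  With ``out_dir``
    given, intermediate images, masks and the summary JSON are written
    with stage-tagged filenames.
    """
    t_all = time.perf_counter()
    timings: dict[str, float] = {}

    def tick(stage: str, t0: float) -> None:
        timings[stage] = round(time.perf_counter() - t0, 3)
        log.info("stage %-10s %6.2f s", stage, timings[stage])

    # 1. simulate
    t0 = time.perf_counter()
    spec = dataclasses.replace(config.scene, seed=config.seed)
    truth = scenes.build_height_map(spec)
    captures = scenes.render_standard_set(truth)
    tick("simulate", t0)

    # 2. fuse
    t0 = time.perf_counter()
    fused = fusion.fuse_standard_set(captures)
    tick("fuse", t0)

    # 3. denoise
    t0 = time.perf_counter()
    if config.apply_denoise:
        dn = config.denoise
        work = wiener_filter(fused, Neighborhood(dn.wiener_window, dn.wiener_window), dn.noise_var)
        work = median_filter(work, Neighborhood(dn.median_window, dn.median_window))
    else:
        work = fused
    tick("denoise", t0)

    # 4. detect
    t0 = time.perf_counter()
    hp = config.hough
    circles = hough.detect_circles(
        work, hp.r_min, hp.r_max, hp.grad_threshold, hp.max_circles, hp.min_center_sep
    )
    tick("detect", t0)

    # 5+6. grow and separate
    t0 = time.perf_counter()
    masks = segment_scene(work, circles, config.grow, config.separate, hp.window_margin)
    tick("segment", t0)

    # 7. evaluate against truth
    t0 = time.perf_counter()
    matched = _match_to_truth(masks, truth)
    per_tooth = {}
    teeth_pred, teeth_true = [], []
    for body, mask in matched:
        rep = metrics.similarity_report(metrics.confusion_counts(mask, body.mask))
        per_tooth[body.label] = {
            "jaccard": rep.jaccard,
            "dice": rep.dice,
            "accuracy": rep.accuracy,
            "fpr": rep.fpr,
            "fnr": rep.fnr,
            "fpr_object": rep.fpr_object,
            "detected": bool(mask.any()),
        }
        if mask.any():
            teeth_pred.append(metrics.ToothMeasurement(side=body.side, index=body.index, mask=mask))
        teeth_true.append(metrics.ToothMeasurement(side=body.side, index=body.index, mask=body.mask))
    truth_report = metrics.pair_distances(teeth_true, truth.pixel_scale)
    arch = None
    if len(teeth_pred) == len(teeth_true):
        measured = metrics.pair_distances(teeth_pred, truth.pixel_scale)
        arch = metrics.error_vs_reference(
            measured, {k: v for k, v in truth_report.pair_distances_mm.items()}
        )
    tick("evaluate", t0)

    dices = sorted(v["dice"] for v in per_tooth.values())
    summary = {
        "seed": config.seed,
        "n_truth_bodies": len(truth.bodies),
        "n_detected": sum(1 for m in masks if m.any()),
        "per_tooth": {k: per_tooth[k] for k in sorted(per_tooth)},
        "median_dice": float(np.median(dices)) if dices else float("nan"),
        "pair_distances_mm": (
            {str(k): v for k, v in arch.pair_distances_mm.items()} if arch else None
        ),
        "truth_pair_distances_mm": {str(k): v for k, v in truth_report.pair_distances_mm.items()},
        "pair_errors_pct": ({str(k): v for k, v in arch.errors_pct.items()} if arch else None),
        "mean_percent_error": arch.mean_percent_error if arch else float("nan"),
    }
    log.info("pipeline finished in %.1f s (stage timings: %s)", time.perf_counter() - t_all, timings)

    if out_dir is not None:
        _write_outputs(Path(out_dir), fused, work, masks, matched, summary)
    return summary


def _write_outputs(out_dir, fused, denoised, masks, matched, summary) -> None:
    import imageio.v3 as iio

    out_dir.mkdir(parents=True, exist_ok=True)
    iio.imwrite(out_dir / "stage2_fused.png", (np.clip(fused, 0, 1) * 255).astype(np.uint8))
    iio.imwrite(out_dir / "stage3_denoised.png", (np.clip(denoised, 0, 1) * 255).astype(np.uint8))
    for body, mask in matched:
        iio.imwrite(out_dir / f"stage6_mask_{body.label}.png", mask.astype(np.uint8) * 255)
    with open(out_dir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
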