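"""Multi-seed region growing with dynamic region means.

Growth is globally best-candidate-first: at every step, among all
unlabelled pixels adjacent to a region, the pixel/region pair with the
smallest absolute difference between the pixel grey value and the region's
*current* mean is assigned, provided the difference does not exceed the
tolerance; the region mean is then updated incrementally.  Ties are broken
by (difference, row, col, region id) ascending, which makes the result
independent of processing order and fully deterministic.  Growth stops
when no adjacent pixel is admissible under any region.  Seeds whose grown
regions touch remain separate labels; reconciling fragments of one body is
the job of the convex-hull merging stage.

Implementation note: a lazy priority queue is used where every frontier
entry is stamped with its region's mean version; whenever a region's mean
changes, all of that region's frontier pixels are re-pushed with fresh
priorities and stale entries are discarded on pop.  This reproduces the
naive "rescan everything each step" semantics exactly.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field

import numpy as np

from .hough import CircleHypothesis, Window, crop_windows

__all__ = ["SeedSet", "LabelMap", "seeds_from_circles", "region_grow", "segment_all_windows"]

_OFFSETS_8 = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
_OFFSETS_4 = [(-1, 0), (0, -1), (0, 1), (1, 0)]


@dataclass(frozen=True)
class SeedSet:
    """Seed pixels plus the admission tolerance and pixel connectivity."""

    seeds: tuple[tuple[int, int], ...]
    tolerance: float = 0.12
    connectivity: int = 8

    def __post_init__(self) -> None:
        if self.tolerance < 0:
            raise ValueError("tolerance must be >= 0")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")


@dataclass
class LabelMap:
    """Disjoint-region partition: 0 = unassigned, 1..K = grown regions."""

    labels: np.ndarray
    n_regions: int
    window: Window | None = None

    def region_mask(self, k: int) -> np.ndarray:
        return self.labels == k

    def areas(self) -> np.ndarray:
        return np.bincount(self.labels.ravel(), minlength=self.n_regions + 1)[1:]


def seeds_from_circles(
    circles: list[CircleHypothesis],
    per_circle: int = 5,
    image_shape: tuple[int, int] | None = None,
) -> list[tuple[int, int]]:
    """Circle centres plus ``per_circle - 1`` points on a half-radius ring.

    Ring points are evenly spaced starting at angle 0 (toward +row); all
    seeds are clipped into the image when a shape is given.
    """
    if per_circle < 1:
        raise ValueError("per_circle must be >= 1")
    seeds: list[tuple[int, int]] = []
    for c in circles:
        pts = [(float(c.row), float(c.col))]
        n_ring = per_circle - 1
        for i in range(n_ring):
            ang = 2.0 * np.pi * i / n_ring
            pts.append((c.row + 0.5 * c.radius * np.cos(ang), c.col + 0.5 * c.radius * np.sin(ang)))
        for r, col in pts:
            ri, ci = int(round(r)), int(round(col))
            if image_shape is not None:
                ri = min(max(ri, 0), image_shape[0] - 1)
                ci = min(max(ci, 0), image_shape[1] - 1)
            seeds.append((ri, ci))
    return seeds


def region_grow(image: np.ndarray, seedset: SeedSet) -> LabelMap:
    """Grow one region per seed under the best-candidate-first rule."""
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError("image must be 2-D")
    if not seedset.seeds:
        raise ValueError("seed list is empty")
    M, N = image.shape
    offsets = _OFFSETS_8 if seedset.connectivity == 8 else _OFFSETS_4
    labels = np.zeros((M, N), dtype=np.int32)

    sums: list[float] = [0.0]
    counts: list[int] = [0]
    versions: list[int] = [0]
    frontiers: list[set[tuple[int, int]]] = [set()]

    for r, c in seedset.seeds:
        if not (0 <= r < M and 0 <= c < N):
            raise ValueError(f"seed ({r}, {c}) lies outside the image")

    heap: list[tuple[float, int, int, int, int]] = []

    def push_frontier(k: int) -> None:
        mean_k = sums[k] / counts[k]
        ver = versions[k]
        for (r, c) in frontiers[k]:
            heapq.heappush(heap, (abs(image[r, c] - mean_k), r, c, k, ver))

    def assign(r: int, c: int, k: int) -> None:
        labels[r, c] = k
        sums[k] += image[r, c]
        counts[k] += 1
        versions[k] += 1
        for fr in frontiers[1:]:
            fr.discard((r, c))
        for dr, dc in offsets:
            rr, cc = r + dr, c + dc
            if 0 <= rr < M and 0 <= cc < N and labels[rr, cc] == 0:
                frontiers[k].add((rr, cc))
        push_frontier(k)

    n_regions = 0
    for r, c in seedset.seeds:
        if labels[r, c] != 0:
            continue  # duplicate seed position: first seed wins
        n_regions += 1
        sums.append(0.0)
        counts.append(0)
        versions.append(0)
        frontiers.append(set())
        assign(r, c, n_regions)

    while heap:
        delta, r, c, k, ver = heapq.heappop(heap)
        if labels[r, c] != 0 or ver != versions[k]:
            continue
        if delta > seedset.tolerance:
            break  # heap minimum among current entries: nothing admissible
        assign(r, c, k)

    return LabelMap(labels=labels, n_regions=n_regions)


def segment_all_windows(
    image: np.ndarray,
    circles: list[CircleHypothesis],
    tolerance: float = 0.12,
    connectivity: int = 8,
    seeds_per_circle: int = 5,
    margin: float = 0.2,
    max_area_factor: float = 4.0,
) -> list[tuple[Window, LabelMap]]:
    """Run seeded growth inside the crop window of each circle.

    Seeds come from :func:`seeds_from_circles` mapped into window
    coordinates.  A grown region larger than ``max_area_factor`` times the
    circle's disc area is discarded (set back to 0) as having escaped the
    body.  Each returned :class:`LabelMap` carries its window so masks can
    be placed back into full-image coordinates.
    """
    if not circles:
        raise ValueError("need at least one circle")
    image = np.asarray(image, dtype=float)
    windows = crop_windows(circles, margin, image.shape)
    out: list[tuple[Window, LabelMap]] = []
    for circle, win in zip(circles, windows):
        sub = image[win.slices]
        seeds = seeds_from_circles([circle], per_circle=seeds_per_circle, image_shape=image.shape)
        local = []
        for r, c in seeds:
            rr = min(max(r - win.top, 0), sub.shape[0] - 1)
            cc = min(max(c - win.left, 0), sub.shape[1] - 1)
            local.append((rr, cc))
        lm = region_grow(sub, SeedSet(seeds=tuple(local), tolerance=tolerance, connectivity=connectivity))
        max_area = max_area_factor * np.pi * circle.radius**2
        for k, area in enumerate(lm.areas(), start=1):
            if area > max_area:
                lm.labels[lm.labels == k] = 0
        lm.window = win
        out.append((win, lm))
    return out
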