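"""Merging fragmented regions and splitting touching convex bodies.

Region growing applied to one body typically yields several sub-regions;
their convex hull reconstitutes the body.  When two neighbouring bodies
are connected in a single mask, the common boundary is recovered from the
shape of the outline: the mask boundary is traced (Moore neighbourhood,
clockwise), smoothed by a circular moving average, and its discrete second
derivative computed at every point.  Along a convex outline the second
derivative is centripetal -- it points toward the local centre of
curvature, inside the object; at the neck between two fused convex bodies
the centre of curvature flips to the outside.  Maximal runs of such
concave points form zones, the two strongest zones mark the two
intersection points of the body outlines, and a straight one-pixel cut
between those points separates the mask into its two constituents.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage.draw import line as draw_line
from skimage.morphology import convex_hull_image

__all__ = [
    "ConvexObject",
    "ClosedContour",
    "SplitResult",
    "NoOverlapError",
    "inward_curvature",
    "convex_hull_merge",
    "morphological_prepare",
    "trace_boundary",
    "smooth_contour",
    "second_derivative",
    "find_cut_points",
    "split_object",
    "separate_pipeline",
]

_S8 = np.ones((3, 3), dtype=bool)
# Moore neighbourhood in clockwise order for row-down image coordinates,
# starting East: E, SE, S, SW, W, NW, N, NE.
_MOORE = [(0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1), (-1, 0), (-1, 1)]


class NoOverlapError(Exception):
    """Raised when fewer than two concave zones exist: the object shows no
    neck, so no overlap is detected and the caller keeps it whole."""


@dataclass(frozen=True)
class ConvexObject:
    """Component masks of one object together with their convex hull mask."""

    components: tuple[np.ndarray, ...]
    hull_mask: np.ndarray


@dataclass
class ClosedContour:
    """Cyclically ordered boundary of a mask.

    ``points`` are the raw traced pixels (consecutive points are
    8-neighbours; the successor of the last point is the first);
    ``smoothed`` holds the moving-average coordinates and ``d2`` the
    per-point second-derivative vectors once computed.
    """

    points: np.ndarray                 # (n, 2) int
    smoothed: np.ndarray | None = None  # (n, 2) float
    d2: np.ndarray | None = None        # (n, 2) float

    def __len__(self) -> int:
        return len(self.points)


@dataclass(frozen=True)
class SplitResult:
    """Two cut points and the two separated parts of a mask."""

    cut_points: tuple[tuple[int, int], tuple[int, int]]
    parts: tuple[np.ndarray, np.ndarray]


def _as_mask(mask: np.ndarray) -> np.ndarray:
    mask = np.asarray(mask)
    if mask.ndim != 2:
        raise ValueError("mask must be 2-D")
    return mask.astype(bool)


def convex_hull_merge(components: list[np.ndarray]) -> ConvexObject:
    """Rasterized convex hull of the union of all component pixels.

    Degenerate inputs (a single pixel, collinear pixels) yield the point
    or the digital line segment between the extreme points.
    """
    if not components:
        raise ValueError("no components given")
    comps = tuple(_as_mask(c) for c in components)
    union = np.zeros(comps[0].shape, dtype=bool)
    for c in comps:
        if c.shape != union.shape:
            raise ValueError("components must share dimensions")
        union |= c
    pts = np.argwhere(union)
    if pts.shape[0] == 0:
        raise ValueError("all components are empty")
    if pts.shape[0] == 1:
        return ConvexObject(components=comps, hull_mask=union.copy())
    centered = pts - pts.mean(axis=0)
    sv = np.linalg.svd(centered.astype(float), compute_uv=False)
    if sv[1] < 1e-9:  # collinear: hull degenerates to a segment
        direction = centered[np.argmax(np.abs(centered).sum(axis=1))].astype(float)
        proj = centered @ direction
        p0, p1 = pts[np.argmin(proj)], pts[np.argmax(proj)]
        hull = np.zeros_like(union)
        rr, cc = draw_line(p0[0], p0[1], p1[0], p1[1])
        hull[rr, cc] = True
        return ConvexObject(components=comps, hull_mask=hull)
    return ConvexObject(components=comps, hull_mask=convex_hull_image(union))


def morphological_prepare(mask: np.ndarray) -> np.ndarray:
    """Hole-fill, open with a 3x3 element to remove spurs, keep the largest
    connected component; the result is a single hole-free component."""
    mask = _as_mask(mask)
    if not mask.any():
        raise ValueError("empty mask")
    filled = ndi.binary_fill_holes(mask)
    opened = ndi.binary_opening(filled, structure=_S8)
    if not opened.any():
        opened = filled  # object thinner than the structuring element
    lbl, n = ndi.label(opened, structure=_S8)
    if n > 1:
        areas = np.bincount(lbl.ravel())[1:]
        opened = lbl == (int(np.argmax(areas)) + 1)
    return ndi.binary_fill_holes(opened)


def trace_boundary(mask: np.ndarray) -> ClosedContour:
    """Clockwise Moore-neighbour boundary trace of a single-component mask.

    Starts from the top-most then left-most foreground pixel.  Every traced
    pixel is foreground with at least one background 8-neighbour.
    """
    mask = _as_mask(mask)
    if not mask.any():
        raise ValueError("empty mask")
    _, n = ndi.label(mask, structure=_S8)
    if n != 1:
        raise ValueError(f"mask must be a single connected component (found {n})")
    M, N = mask.shape

    def fg(r: int, c: int) -> bool:
        return 0 <= r < M and 0 <= c < N and mask[r, c]

    start = tuple(int(v) for v in np.argwhere(mask)[0])  # row-major: topmost, leftmost
    b0 = (start[0], start[1] - 1)  # West neighbour, background by construction
    contour = [start]
    cur, back = start, b0
    max_steps = 4 * int(mask.sum()) + 8
    for _ in range(max_steps):
        bidx = _MOORE.index((back[0] - cur[0], back[1] - cur[1]))
        nxt = None
        for i in range(1, 9):
            dr, dc = _MOORE[(bidx + i) % 8]
            cand = (cur[0] + dr, cur[1] + dc)
            if fg(*cand):
                nxt = cand
                prev_dr, prev_dc = _MOORE[(bidx + i - 1) % 8]
                back = (cur[0] + prev_dr, cur[1] + prev_dc)
                break
        if nxt is None:  # isolated pixel
            break
        cur = nxt
        if cur == start and back == b0:
            break
        contour.append(cur)
    return ClosedContour(points=np.array(contour, dtype=int))


def smooth_contour(contour: ClosedContour, window: int = 9) -> ClosedContour:
    """Circular moving average of the boundary coordinates."""
    if window % 2 == 0:
        raise ValueError("smoothing window must be odd")
    n = len(contour)
    if window > n:
        raise ValueError("smoothing window exceeds contour length")
    sm = ndi.uniform_filter1d(contour.points.astype(float), size=window, axis=0, mode="wrap")
    return ClosedContour(points=contour.points, smoothed=sm)


def second_derivative(contour: ClosedContour) -> ClosedContour:
    """Cyclic discrete second derivative of the smoothed boundary:
    d2[k] = s[k+1] - 2 s[k] + s[k-1]."""
    if contour.smoothed is None:
        raise ValueError("smooth the contour first")
    if len(contour) < 3:
        raise ValueError("contour must have at least 3 points")
    s = contour.smoothed
    d2 = np.roll(s, -1, axis=0) + np.roll(s, 1, axis=0) - 2.0 * s
    return ClosedContour(points=contour.points, smoothed=s, d2=d2)


def _cyclic_runs(flags: np.ndarray) -> list[list[int]]:
    """Maximal cyclic runs of True indices."""
    n = flags.size
    if flags.all():
        return [list(range(n))]
    runs, current = [], []
    for i in range(n):
        if flags[i]:
            current.append(i)
        elif current:
            runs.append(current)
            current = []
    if current:
        if runs and flags[0] and runs[0][0] == 0:
            runs[0] = current + runs[0]  # wrap-around run
        else:
            runs.append(current)
    return runs


def inward_curvature(contour: ClosedContour) -> np.ndarray:
    """Signed concavity: the component of d2 along the inward normal.

    The contour is traced clockwise in row-down image coordinates, so the
    object interior lies to the right of the direction of travel; rotating
    the tangent ``t = (t_r, t_c)`` to ``(t_c, -t_r)`` gives the inward
    normal.  Along a convex arc the second difference is centripetal --
    it points toward the local centre of curvature, which lies inside the
    object -- so the value is positive.  At a neck between two fused
    convex bodies the centre of curvature lies outside the object and the
    value turns negative: negative inward curvature marks a concavity.
    """
    if contour.d2 is None:
        raise ValueError("compute the second derivative first")
    s = contour.smoothed
    tangent = np.roll(s, -1, axis=0) - np.roll(s, 1, axis=0)
    n_in = np.stack([tangent[:, 1], -tangent[:, 0]], axis=1)
    norm = np.linalg.norm(n_in, axis=1)
    norm[norm == 0] = 1.0
    return np.sum(contour.d2 * n_in, axis=1) / norm


def find_cut_points(
    contour: ClosedContour,
    mask: np.ndarray,
    noise_floor_pct: float = 25.0,
    min_corner_turn: float = 0.35,
) -> tuple[tuple[int, int], tuple[int, int]]:
    """Locate the two intersection points of two fused convex bodies.

    A contour point is concave when its inward curvature (see
    :func:`inward_curvature`) is *negative* beyond a noise floor set at a
    low percentile of the nonzero absolute curvatures -- the boundary
    locally turns away from the object.  Maximal cyclic runs of concave
    points form zones; a zone only counts as a neck corner when its total
    inward turn (the summed concave curvature, roughly the exterior angle
    of the corner in radians) exceeds ``min_corner_turn`` -- rasterization
    dips on a convex outline stay an order of magnitude below a real
    corner.  The two strongest zones are selected and their extreme
    points, refined to the narrowest crossing of the neck, mark the
    intersection points.  Raises :class:`NoOverlapError` when fewer than
    two qualifying zones exist.
    """
    mask = _as_mask(mask)
    curv = inward_curvature(contour)
    nz = np.abs(curv)[np.abs(curv) > 1e-12]
    if nz.size == 0:
        raise NoOverlapError("boundary has no curvature")
    floor = np.percentile(nz, noise_floor_pct)
    M, N = mask.shape
    concave = curv < -floor
    zones = [
        z for z in _cyclic_runs(concave) if -sum(curv[i] for i in z) >= min_corner_turn
    ]
    if len(zones) < 2:
        raise NoOverlapError(f"no overlap detected ({len(zones)} concave zone(s))")
    zones.sort(key=lambda z: (sum(curv[i] for i in z), z[0]))
    peaks = [min(zone, key=lambda i: (curv[i], i)) for zone in zones[:2]]
    # Smoothing spreads the neck corner's curvature over neighbouring
    # points, so the |d2| peak localizes the corner only to within a few
    # pixels.  The two corners are the narrowest crossing of the neck:
    # refine by choosing, within a half-window of each peak, the pair of
    # boundary points with minimal mutual distance.
    n = len(contour)
    halo = 4
    cand = [
        [(peaks[z] + off) % n for off in range(-halo, halo + 1)] for z in (0, 1)
    ]
    best_pair = None
    for i in cand[0]:
        for j in cand[1]:
            sep_idx = min((i - j) % n, (j - i) % n)
            if sep_idx <= 2 * halo:
                continue  # same stretch of boundary: not a neck crossing
            mid = 0.5 * (contour.points[i] + contour.points[j])
            mr, mc = int(round(mid[0])), int(round(mid[1]))
            if not (0 <= mr < M and 0 <= mc < N and mask[mr, mc]):
                continue  # the cut must pass through the object
            d = float(np.hypot(*(contour.points[i] - contour.points[j])))
            key = (d, i, j)
            if best_pair is None or key < best_pair:
                best_pair = key
    if best_pair is None:
        i, j = peaks
    else:
        _, i, j = best_pair
    picks = (
        tuple(int(v) for v in contour.points[i]),
        tuple(int(v) for v in contour.points[j]),
    )
    if picks[0] == picks[1]:
        raise NoOverlapError("concave zones collapse onto one point")
    return picks


def split_object(mask: np.ndarray, cut_points) -> SplitResult:
    """Cut the mask along the straight segment between the two cut points.

    Pixels on the one-pixel rasterized segment are cleared; the two
    largest remaining 4-connected components become the parts (the
    8-connected digital segment blocks every 4-path across the cut).
    """
    mask = _as_mask(mask)
    (r0, c0), (r1, c1) = cut_points
    if (r0, c0) == (r1, c1):
        raise ValueError("cut points coincide: degenerate segment")
    cut = mask.copy()
    rr, cc = draw_line(int(r0), int(c0), int(r1), int(c1))
    keep = (rr >= 0) & (rr < mask.shape[0]) & (cc >= 0) & (cc < mask.shape[1])
    cut[rr[keep], cc[keep]] = False
    lbl, n = ndi.label(cut, structure=np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], bool))
    if n < 2:
        raise ValueError("cut did not separate the mask into two components")
    areas = np.bincount(lbl.ravel())[1:]
    order = np.argsort(areas)[::-1]
    parts = (lbl == order[0] + 1, lbl == order[1] + 1)
    return SplitResult(cut_points=((int(r0), int(c0)), (int(r1), int(c1))), parts=parts)


def separate_pipeline(
    components: list[np.ndarray],
    smooth_window: int = 9,
    noise_floor_pct: float = 25.0,
) -> list[np.ndarray]:
    """Merge the fragments of one or two adjacent bodies and, if their
    union shows a neck, split it into two parts.

    Disconnected fragments are first bridged by their convex hull (the
    standard repair for one body broken into sub-regions); a connected
    union is used as-is, because taking its hull would erase the very neck
    concavity the split relies on.  Returns one mask when no overlap is
    detected, otherwise the two split parts.
    """
    if not components:
        raise ValueError("no components given")
    comps = [_as_mask(c) for c in components]
    union = np.zeros(comps[0].shape, dtype=bool)
    for c in comps:
        union |= c
    if not union.any():
        raise ValueError("all components are empty")
    _, n = ndi.label(union, structure=_S8)
    work = convex_hull_merge(comps).hull_mask if n > 1 else union
    prepared = morphological_prepare(work)
    traced = trace_boundary(prepared)
    if len(traced) < max(3, smooth_window):
        return [prepared]  # too small to carry a resolvable neck
    contour = second_derivative(smooth_contour(traced, window=smooth_window))
    try:
        cuts = find_cut_points(contour, prepared, noise_floor_pct=noise_floor_pct)
    except NoOverlapError:
        return [prepared]
    try:
        result = split_object(prepared, cuts)
    except ValueError:
        return [prepared]
    return [result.parts[0], result.parts[1]]
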