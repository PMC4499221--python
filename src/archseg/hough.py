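"""Gradient-voting circular Hough transform.

Each edge pixel (image-gradient magnitude above a threshold) casts votes
into a 3-D accumulator indexed by (centre row, centre column, radius): for
every integer radius in the configured range the pixel votes at the two
positions one radius away along its gradient direction, in both
orientations, since the polarity of the bodies (bright on dark or the
converse) is not assumed.  Votes are accumulated by bulk array scatter, so
there is no per-pixel interpreted loop.  Circle hypotheses are the peaks
of the accumulator summed over the radius axis, after greedy non-maximum
suppression with a minimum centre separation; the radius of a peak is read
back as the arg-max over the radius axis at the peak position.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "CircleHypothesis",
    "GradientField",
    "Window",
    "gradient_field",
    "hough_accumulate",
    "detect_circles",
    "crop_windows",
]


@dataclass(frozen=True)
class CircleHypothesis:
    """A detected circle: centre (row, col), radius and accumulator score."""

    row: int
    col: int
    radius: int
    score: float


@dataclass(frozen=True)
class GradientField:
    """Gradient magnitude and unit direction of a grey image.

    ``direction`` has shape (M, N, 2) in (row, col) order; it is undefined
    (zero) wherever the magnitude is zero.
    """

    magnitude: np.ndarray
    direction: np.ndarray


@dataclass(frozen=True)
class Window:
    """Axis-aligned crop window with inclusive pixel bounds."""

    top: int
    bottom: int
    left: int
    right: int

    @property
    def slices(self) -> tuple[slice, slice]:
        return slice(self.top, self.bottom + 1), slice(self.left, self.right + 1)

    @property
    def offset(self) -> tuple[int, int]:
        return self.top, self.left

    def contains(self, row: float, col: float) -> bool:
        return self.top <= row <= self.bottom and self.left <= col <= self.right


def gradient_field(image: np.ndarray) -> GradientField:
    """Central-difference gradient (one-sided at borders), Euclidean norm."""
    image = np.asarray(image, dtype=float)
    gr, gc = np.gradient(image)
    mag = np.hypot(gr, gc)
    direction = np.zeros(image.shape + (2,))
    nz = mag > 0
    direction[nz, 0] = gr[nz] / mag[nz]
    direction[nz, 1] = gc[nz] / mag[nz]
    return GradientField(magnitude=mag, direction=direction)


def default_gradient_threshold(grad: GradientField, percentile: float = 95.0) -> float:
    """Adaptive edge threshold: a high percentile of the nonzero magnitudes."""
    nz = grad.magnitude[grad.magnitude > 0]
    if nz.size == 0:
        return np.inf
    return float(np.percentile(nz, percentile))


def hough_accumulate(
    grad: GradientField,
    r_min: int,
    r_max: int,
    grad_threshold: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Scatter gradient votes into the (row, col, radius) accumulator.

    Returns ``(accumulator, radii)`` where ``radii`` lists the integer
    radii of the accumulator's last axis.  Vote positions are rounded to
    the nearest pixel; votes falling outside the image are dropped.
    """
    if r_min <= 0:
        raise ValueError("r_min must be > 0")
    if r_max < r_min:
        raise ValueError("r_max must be >= r_min")
    M, N = grad.magnitude.shape
    radii = np.arange(int(r_min), int(r_max) + 1)
    acc = np.zeros((M, N, radii.size))
    sel = grad.magnitude > grad_threshold
    if not sel.any():
        return acc, radii
    rows, cols = np.nonzero(sel)
    dr = grad.direction[rows, cols, 0]
    dc = grad.direction[rows, cols, 1]
    for k, r in enumerate(radii):
        for sign in (1.0, -1.0):
            rr = np.rint(rows + sign * r * dr).astype(int)
            cc = np.rint(cols + sign * r * dc).astype(int)
            ok = (rr >= 0) & (rr < M) & (cc >= 0) & (cc < N)
            np.add.at(acc[:, :, k], (rr[ok], cc[ok]), 1.0)
    return acc, radii


def detect_circles(
    image: np.ndarray,
    r_min: int,
    r_max: int,
    grad_threshold: float | None = None,
    max_circles: int = 14,
    min_center_sep: float | None = None,
) -> list[CircleHypothesis]:
    """Locate up to ``max_circles`` circles by accumulator peak picking.

    The peak score is the accumulator summed over the radius axis (robust
    to votes splitting between neighbouring radius bins); greedy
    non-maximum suppression zeroes a disc of radius ``min_center_sep``
    (default ``r_min``) around each accepted peak.  Ties are broken
    lexicographically by (row, col, radius), so the result is
    deterministic.  Fewer than ``max_circles`` hypotheses are returned when
    the accumulator runs out of positive peaks.
    """
    if max_circles < 1:
        raise ValueError("max_circles must be >= 1")
    grad = gradient_field(image)
    if grad_threshold is None:
        grad_threshold = default_gradient_threshold(grad)
    if min_center_sep is None:
        min_center_sep = float(r_min)
    acc, radii = hough_accumulate(grad, r_min, r_max, grad_threshold)
    score2d = acc.sum(axis=2)
    M, N = score2d.shape
    rr = np.arange(M)[:, None]
    cc = np.arange(N)[None, :]
    circles: list[CircleHypothesis] = []
    for _ in range(max_circles):
        flat = int(np.argmax(score2d))
        r0, c0 = divmod(flat, N)
        score = float(score2d[r0, c0])
        if score <= 0:
            break
        radius = int(radii[int(np.argmax(acc[r0, c0, :]))])
        circles.append(CircleHypothesis(row=r0, col=c0, radius=radius, score=score))
        suppress = (rr - r0) ** 2 + (cc - c0) ** 2 < min_center_sep**2
        score2d[suppress] = 0.0
    return circles


def crop_windows(
    circles: list[CircleHypothesis],
    margin: float,
    image_shape: tuple[int, int],
) -> list[Window]:
    """Square window per circle of side ``2*radius*(1+margin)``, clipped to
    the image; each window keeps its offset for mapping back to full-image
    coordinates."""
    if margin < 0:
        raise ValueError("margin must be >= 0")
    M, N = image_shape
    windows = []
    for c in circles:
        half = int(round(c.radius * (1.0 + margin)))
        windows.append(
            Window(
                top=max(0, c.row - half),
                bottom=min(M - 1, c.row + half),
                left=max(0, c.col - half),
                right=min(N - 1, c.col + half),
            )
        )
    return windows
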