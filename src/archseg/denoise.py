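"""Adaptive Wiener filtering and rank-order median filtering.

The Wiener filter estimates each output pixel as

    b(i,j) = mu + (sigma^2 - xi^2) / sigma^2 * (a(i,j) - mu)

where ``mu`` and ``sigma^2`` are the local mean and variance over an
R-by-S window centred on the pixel and ``xi^2`` is the image noise
variance, by default estimated as the mean of all local variances.  Where
the local variance falls below the noise variance the gain is clamped to
zero, so the output is the local mean.  The median filter replaces each
pixel by the median of its window; for an even pixel count Q the two
middle order statistics are averaged.  Both filters use symmetric
reflection padding at the image borders.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi

__all__ = ["Neighborhood", "local_stats", "wiener_filter", "median_filter", "median_of_values"]


@dataclass(frozen=True)
class Neighborhood:
    """An R-by-S local window.

    The statistics filters (:func:`local_stats`, :func:`wiener_filter`)
    require odd dimensions so the window is centred on a pixel; the median
    filter additionally accepts even dimensions, averaging the two middle
    order statistics.
    """

    rows: int = 3
    cols: int = 3

    def __post_init__(self) -> None:
        if self.rows < 1 or self.cols < 1:
            raise ValueError("window dimensions must be >= 1")

    @property
    def q(self) -> int:
        return self.rows * self.cols

    @property
    def is_odd(self) -> bool:
        return self.rows % 2 == 1 and self.cols % 2 == 1


def median_of_values(values) -> float:
    """Median of a flat collection per the rank-order rule: the middle
    order statistic for odd counts, the mean of the two middle ones for
    even counts."""
    p = np.sort(np.asarray(values, dtype=float).ravel())
    q = p.size
    if q == 0:
        raise ValueError("empty value set")
    if q % 2 == 1:
        return float(p[(q - 1) // 2])
    return float(0.5 * (p[q // 2 - 1] + p[q // 2]))


def _check(image: np.ndarray, window: Neighborhood) -> np.ndarray:
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError("image must be 2-D")
    if window.rows > image.shape[0] or window.cols > image.shape[1]:
        raise ValueError("window larger than image")
    return image


def local_stats(image: np.ndarray, window: Neighborhood = Neighborhood()) -> tuple[np.ndarray, np.ndarray]:
    """Per-pixel windowed mean and variance (reflection-padded borders)."""
    image = _check(image, window)
    if not window.is_odd:
        raise ValueError("local statistics require an odd window")
    size = (window.rows, window.cols)
    mu = ndi.uniform_filter(image, size=size, mode="reflect")
    mu2 = ndi.uniform_filter(image * image, size=size, mode="reflect")
    sigma2 = np.clip(mu2 - mu * mu, 0.0, None)  # guard tiny negative round-off
    return mu, sigma2


def wiener_filter(
    image: np.ndarray,
    window: Neighborhood = Neighborhood(),
    noise_var: float | None = None,
) -> np.ndarray:
    """Adaptive Wiener filter with non-negative gain.

    When ``noise_var`` is omitted the noise variance is the mean of all
    local variances.  Where the local variance does not exceed the noise
    variance (including flat regions with zero variance) the output is the
    local mean.
    """
    image = _check(image, window)
    if noise_var is not None and noise_var < 0:
        raise ValueError("noise_var must be >= 0")
    mu, sigma2 = local_stats(image, window)
    xi2 = float(np.mean(sigma2)) if noise_var is None else float(noise_var)
    with np.errstate(divide="ignore", invalid="ignore"):
        gain = np.where(sigma2 > xi2, (sigma2 - xi2) / sigma2, 0.0)
    if xi2 == 0.0:
        gain = np.where(sigma2 > 0, 1.0, 0.0)
    return mu + gain * (image - mu)


def median_filter(image: np.ndarray, window: Neighborhood = Neighborhood()) -> np.ndarray:
    """Rank-order median over the window, averaging the two middle order
    statistics when the window pixel count is even."""
    image = _check(image, window)
    size = (window.rows, window.cols)
    q = window.q
    if q % 2 == 1:
        return ndi.rank_filter(image, rank=(q - 1) // 2, size=size, mode="reflect")
    lo = ndi.rank_filter(image, rank=q // 2 - 1, size=size, mode="reflect")
    hi = ndi.rank_filter(image, rank=q // 2, size=size, mode="reflect")
    return 0.5 * (lo + hi)
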