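"""Multi-illumination image fusion.

Four co-registered captures of one scene -- left-lit, right-lit and two
top-lit at different elevations -- are combined into a single
contrast-enhanced image.  The side-lit pair is first split along the
central vertical axis and recombined into an "outside-lit" image (each half
lit from its own side) and a "central-lit" image (each half lit from the
opposite side); these and the two top-lit captures are then multiplied
pixel by pixel.  The multiplicative combination reinforces the shadow lines
that all captures share at body boundaries while flattening the interior
shading that differs between captures.
"""

from __future__ import annotations

import numpy as np

from .scenes import IlluminatedCapture

__all__ = ["split_recombine", "multiply_images", "fuse_standard_set", "STANDARD_TAGS"]

STANDARD_TAGS = ("top_wide", "top_narrow", "left", "right")


def _check_image(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img, dtype=float)
    if img.ndim != 2 or img.shape[0] < 2 or img.shape[1] < 2:
        raise ValueError("grey image must be 2-D with at least 2 rows and 2 columns")
    if not np.all(np.isfinite(img)):
        raise ValueError("grey image must be finite")
    return img


def split_recombine(left_capture: np.ndarray, right_capture: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Swap halves of the side-lit pair about the central vertical axis.

    Returns ``(outside, central)`` where ``outside`` keeps each half lit
    from its own side (left half of the left-lit image, right half of the
    right-lit image) and ``central`` the converse.  For odd widths the left
    half takes the extra column.  Applying the operation twice returns the
    original pair.
    """
    left_capture = _check_image(left_capture)
    right_capture = _check_image(right_capture)
    if left_capture.shape != right_capture.shape:
        raise ValueError("captures must share dimensions")
    n_left = -(-left_capture.shape[1] // 2)  # ceil(N/2)
    outside = np.hstack([left_capture[:, :n_left], right_capture[:, n_left:]])
    central = np.hstack([right_capture[:, :n_left], left_capture[:, n_left:]])
    return outside, central


def multiply_images(images: list[np.ndarray], rescale: bool = True) -> np.ndarray:
    """Pixel-by-pixel product of two or more equally sized grey images.

    The product is linearly rescaled to span [0, 1] (min to 0, max to 1)
    unless it is constant, in which case it is returned unscaled; repeated
    products of sub-unity values would otherwise collapse toward zero and
    break fixed thresholds downstream.
    """
    if len(images) < 2:
        raise ValueError("need at least two images to multiply")
    imgs = [_check_image(i) for i in images]
    shape = imgs[0].shape
    if any(i.shape != shape for i in imgs):
        raise ValueError("images must share dimensions")
    prod = imgs[0].copy()
    for i in imgs[1:]:
        prod *= i
    if not rescale:
        return prod
    lo, hi = prod.min(), prod.max()
    if hi == lo:
        return prod
    return (prod - lo) / (hi - lo)


def fuse_standard_set(captures: list[IlluminatedCapture]) -> np.ndarray:
    """Fuse a standard four-capture set into one contrast-enhanced image.

    Expects exactly one capture per tag in :data:`STANDARD_TAGS`.  Computes
    the outside/central recombination of the side-lit pair, then the
    product of those two images with the two top-lit captures, rescaled
    once at the end (so the result equals the rescaled raw product of all
    four constituent images).
    """
    by_tag: dict[str, IlluminatedCapture] = {}
    for cap in captures:
        if cap.tag in by_tag:
            raise ValueError(f"duplicated capture tag {cap.tag!r}")
        by_tag[cap.tag] = cap
    missing = [t for t in STANDARD_TAGS if t not in by_tag]
    if missing or len(by_tag) != len(STANDARD_TAGS):
        raise ValueError(f"capture set must contain exactly the tags {STANDARD_TAGS}, missing {missing}")
    outside, central = split_recombine(by_tag["left"].image, by_tag["right"].image)
    return multiply_images([outside, central, by_tag["top_wide"].image, by_tag["top_narrow"].image])
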