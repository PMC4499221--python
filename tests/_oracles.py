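"""Independent naive reference implementations used as test oracles.

Everything here is deliberately written as plain loops over pixels (or
plain geometry) and shares no code with the package implementation.
"""

from __future__ import annotations

import numpy as np


def naive_local_stats(image: np.ndarray, rows: int, cols: int):
    """Windowed mean/variance with symmetric padding, double loop."""
    pr, pc = rows // 2, cols // 2
    padded = np.pad(image, ((pr, pr), (pc, pc)), mode="symmetric")
    M, N = image.shape
    mu = np.empty((M, N))
    sigma2 = np.empty((M, N))
    q = rows * cols
    for i in range(M):
        for j in range(N):
            win = padded[i : i + rows, j : j + cols]
            m = win.sum() / q
            mu[i, j] = m
            sigma2[i, j] = (win**2).sum() / q - m * m
    return mu, np.clip(sigma2, 0.0, None)


def naive_wiener(image: np.ndarray, rows: int, cols: int, noise_var=None):
    mu, sigma2 = naive_local_stats(image, rows, cols)
    xi2 = sigma2.mean() if noise_var is None else noise_var
    out = np.empty_like(mu)
    M, N = image.shape
    for i in range(M):
        for j in range(N):
            s2 = sigma2[i, j]
            if xi2 == 0.0:
                gain = 1.0 if s2 > 0 else 0.0
            elif s2 > xi2:
                gain = (s2 - xi2) / s2
            else:
                gain = 0.0
            out[i, j] = mu[i, j] + gain * (image[i, j] - mu[i, j])
    return out


def naive_median(image: np.ndarray, rows: int, cols: int):
    pr, pc = (rows - 1) // 2, (cols - 1) // 2
    # symmetric padding sized so every window fits, matching centred
    # windows for odd sizes and scipy's origin convention for even sizes
    pr2, pc2 = rows - 1 - pr, cols - 1 - pc
    padded = np.pad(image, ((pr, pr2), (pc, pc2)), mode="symmetric")
    M, N = image.shape
    out = np.empty((M, N))
    q = rows * cols
    for i in range(M):
        for j in range(N):
            vals = np.sort(padded[i : i + rows, j : j + cols].ravel())
            if q % 2 == 1:
                out[i, j] = vals[(q - 1) // 2]
            else:
                out[i, j] = 0.5 * (vals[q // 2 - 1] + vals[q // 2])
    return out


def naive_region_grow(image, seeds, tolerance, connectivity=8):
    """Literal rescan-everything-each-step best-candidate-first growth."""
    M, N = image.shape
    offs = (
        [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
        if connectivity == 8
        else [(-1, 0), (0, -1), (0, 1), (1, 0)]
    )
    labels = np.zeros((M, N), dtype=int)
    sums, counts = [0.0], [0]
    k = 0
    for r, c in seeds:
        if labels[r, c] != 0:
            continue
        k += 1
        labels[r, c] = k
        sums.append(float(image[r, c]))
        counts.append(1)
    while True:
        best = None  # (delta, r, c, k)
        for i in range(M):
            for j in range(N):
                if labels[i, j] != 0:
                    continue
                cand = None
                for dr, dc in offs:
                    rr, cc = i + dr, j + dc
                    if 0 <= rr < M and 0 <= cc < N and labels[rr, cc] != 0:
                        kk = labels[rr, cc]
                        delta = abs(image[i, j] - sums[kk] / counts[kk])
                        if cand is None or (delta, kk) < cand:
                            cand = (delta, kk)
                if cand is not None and cand[0] <= tolerance:
                    entry = (cand[0], i, j, cand[1])
                    if best is None or entry < best:
                        best = entry
        if best is None:
            break
        delta, i, j, kk = best
        labels[i, j] = kk
        sums[kk] += float(image[i, j])
        counts[kk] += 1
    return labels


def naive_confusion(result, truth):
    tp = fp = fn = tn = 0
    for i in range(result.shape[0]):
        for j in range(result.shape[1]):
            r, t = bool(result[i, j]), bool(truth[i, j])
            if r and t:
                tp += 1
            elif r:
                fp += 1
            elif t:
                fn += 1
            else:
                tn += 1
    return tp, fp, fn, tn


def naive_mass_center(mask):
    rs, cs, n = 0.0, 0.0, 0
    for i in range(mask.shape[0]):
        for j in range(mask.shape[1]):
            if mask[i, j]:
                rs += i
                cs += j
                n += 1
    return rs / n, cs / n


def brute_force_hull_vertices(points: np.ndarray) -> set[tuple[int, int]]:
    """O(n^3) hull: (p, q) is a hull edge iff all points lie on one side."""
    pts = [tuple(map(int, p)) for p in points]
    unique = list(dict.fromkeys(pts))
    n = len(unique)
    vertices: set[tuple[int, int]] = set()
    for a in range(n):
        for b in range(n):
            if a == b:
                continue
            p, q = unique[a], unique[b]
            pos = neg = False
            for r in unique:
                if r == p or r == q:
                    continue
                cross = (q[0] - p[0]) * (r[1] - p[1]) - (q[1] - p[1]) * (r[0] - p[0])
                if cross > 0:
                    pos = True
                elif cross < 0:
                    neg = True
            if not (pos and neg):
                vertices.add(p)
                vertices.add(q)
    return vertices


def naive_hough_accumulate(magnitude, direction, r_min, r_max, threshold):
    M, N = magnitude.shape
    radii = list(range(r_min, r_max + 1))
    acc = np.zeros((M, N, len(radii)))
    for i in range(M):
        for j in range(N):
            if magnitude[i, j] <= threshold:
                continue
            for k, r in enumerate(radii):
                for sign in (1.0, -1.0):
                    rr = int(np.rint(i + sign * r * direction[i, j, 0]))
                    cc = int(np.rint(j + sign * r * direction[i, j, 1]))
                    if 0 <= rr < M and 0 <= cc < N:
                        acc[rr, cc, k] += 1.0
    return acc
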