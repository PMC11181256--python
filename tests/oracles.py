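"""Independent brute-force oracles used by the test suite.

Everything here is written as direct loops over definitions, deliberately
sharing no code with the package implementation.
"""

from __future__ import annotations

import math

import numpy as np

GLCM_OFFSETS = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}


def brute_glcm(
    image: np.ndarray, mask: np.ndarray, d: int, theta: int, levels: int
) -> np.ndarray:
    """Co-occurrence counts by explicit enumeration of every pixel pair."""
    h, w = image.shape
    dr, dc = GLCM_OFFSETS[theta]
    dr, dc = dr * d, dc * d
    counts = np.zeros((levels, levels), dtype=np.int64)
    for r in range(h):
        for c in range(w):
            r2, c2 = r + dr, c + dc
            if 0 <= r2 < h and 0 <= c2 < w and mask[r, c] and mask[r2, c2]:
                a, b = int(image[r, c]), int(image[r2, c2])
                if a >= levels or b >= levels:
                    a, b = a * levels // 256, b * levels // 256
                counts[a, b] += 1
    return counts


def brute_glcm_descriptors(counts: np.ndarray) -> tuple[float, float, float, float]:
    """Contrast/correlation/energy/homogeneity by double loops."""
    n = counts.sum()
    L = counts.shape[0]
    contrast = energy = homogeneity = 0.0
    mu_r = mu_c = 0.0
    for a in range(L):
        for b in range(L):
            p = counts[a, b] / n
            contrast += (a - b) ** 2 * p
            energy += p * p
            homogeneity += p / (1 + abs(a - b))
            mu_r += a * p
            mu_c += b * p
    var_r = var_c = cov = 0.0
    for a in range(L):
        for b in range(L):
            p = counts[a, b] / n
            var_r += (a - mu_r) ** 2 * p
            var_c += (b - mu_c) ** 2 * p
            cov += (a - mu_r) * (b - mu_c) * p
    sd = math.sqrt(var_r * var_c)
    correlation = 0.0 if sd == 0 else cov / sd
    return contrast, correlation, energy, homogeneity


def brute_interior(mask: np.ndarray) -> np.ndarray:
    """Pixels whose full 8-neighborhood (and themselves) are in the mask."""
    h, w = mask.shape
    out = np.zeros_like(mask)
    for r in range(h):
        for c in range(w):
            ok = True
            for dr in (-1, 0, 1):
                for dc in (-1, 0, 1):
                    r2, c2 = r + dr, c + dc
                    if not (0 <= r2 < h and 0 <= c2 < w and mask[r2, c2]):
                        ok = False
            out[r, c] = ok
    return out


def brute_point_in_polygon(
    vertices: list[tuple[float, float]], shape: tuple[int, int]
) -> np.ndarray:
    """Even-odd rasterization with boundary-inclusive centers, by ray casting
    plus an explicit on-segment check for every pixel center."""

    def on_segment(pr, pc, r1, c1, r2, c2) -> bool:
        cross = (c2 - c1) * (pr - r1) - (r2 - r1) * (pc - c1)
        if abs(cross) > 1e-9:
            return False
        dot = (pc - c1) * (c2 - c1) + (pr - r1) * (r2 - r1)
        sq = (c2 - c1) ** 2 + (r2 - r1) ** 2
        return -1e-9 <= dot <= sq + 1e-9

    h, w = shape
    n = len(vertices)
    out = np.zeros(shape, dtype=bool)
    for pr in range(h):
        for pc in range(w):
            boundary = False
            inside = False
            for k in range(n):
                r1, c1 = vertices[k]
                r2, c2 = vertices[(k + 1) % n]
                if on_segment(pr, pc, r1, c1, r2, c2):
                    boundary = True
                    break
                # even-odd ray cast along +col
                if (r1 > pr) != (r2 > pr):
                    c_at = c1 + (pr - r1) * (c2 - c1) / (r2 - r1)
                    if c_at > pc:
                        inside = not inside
            out[pr, pc] = boundary or inside
    return out


def brute_ggcm_features(H: np.ndarray) -> list[float]:
    """The 15 GGCM descriptors by direct double loops over the matrix."""
    T = H.sum()
    ng, ns = H.shape
    rowsum = [sum(H[i, j] for j in range(ns)) for i in range(ng)]
    colsum = [sum(H[i, j] for i in range(ng)) for j in range(ns)]
    small = sum(colsum[j] / (j + 1) ** 2 for j in range(ns)) / T
    large = sum(j * j * colsum[j] for j in range(ns)) / T
    gray_het = sum(rowsum[i] ** 2 for i in range(ng)) / T
    grad_het = sum(colsum[j] ** 2 for j in range(ns)) / T
    energy = sum((H[i, j] / T) ** 2 for i in range(ng) for j in range(ns))
    mu_g = sum(i * rowsum[i] for i in range(ng)) / T
    mu_s = sum(j * colsum[j] for j in range(ns)) / T
    sd_g = math.sqrt(sum((i - mu_g) ** 2 * rowsum[i] for i in range(ng)) / T)
    sd_s = math.sqrt(sum((j - mu_s) ** 2 * colsum[j] for j in range(ns)) / T)
    corr = sum(
        (i - mu_g) * (j - mu_s) * H[i, j] / T for i in range(ng) for j in range(ns)
    )
    gray_ent = -sum(
        (rowsum[i] / T) * math.log(rowsum[i] / T) for i in range(ng) if rowsum[i] > 0
    )
    grad_ent = -sum(
        (colsum[j] / T) * math.log(colsum[j] / T) for j in range(ns) if colsum[j] > 0
    )
    hybrid = -sum(
        (H[i, j] / T) * math.log(H[i, j] / T)
        for i in range(ng)
        for j in range(ns)
        if H[i, j] > 0
    )
    inertia = sum((i - j) ** 2 * H[i, j] / T for i in range(ng) for j in range(ns))
    idm = sum(
        H[i, j] / T / (1 + (i - j) ** 2) for i in range(ng) for j in range(ns)
    )
    return [
        small, large, gray_het, grad_het, energy, mu_g, mu_s, sd_g, sd_s,
        corr, gray_ent, grad_ent, hybrid, inertia, idm,
    ]


def brute_auc(pos: np.ndarray, neg: np.ndarray) -> float:
    """Concordant-pair fraction with ties counted one half."""
    wins = 0.0
    for x in pos:
        for y in neg:
            if x > y:
                wins += 1.0
            elif x == y:
                wins += 0.5
    return wins / (len(pos) * len(neg))
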