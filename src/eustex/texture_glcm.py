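"""Gray-level co-occurrence matrix (GLCM) texture features.

Two feature combinations are built here:

* ``GLCM48`` — for each of 3 pixel distances (d = 1, 2, 3) and 4 directions
  (0, 45, 90, 135 degrees) a co-occurrence matrix is accumulated over
  ordered pixel pairs lying entirely inside the ROI mask, and four Haralick
  descriptors (contrast, correlation, energy, homogeneity) are computed,
  giving 3 x 4 x 4 = 48 features.
* ``GLCM48_PLUS_GLOBAL3`` — the 48 features plus three first-order global
  gray statistics of the ROI (entropy of the 256-bin histogram in nats,
  mean intensity, population SD).

Direction-to-offset convention (pinned; 45/135-degree signs differ across
libraries): 0 deg -> (0, +d), 45 deg -> (-d, +d), 90 deg -> (-d, 0),
135 deg -> (-d, -d), in (row, col) with row 0 at the top.

The matrix is *asymmetric*: each (d, theta) counts one displacement
direction only. Gray levels default to 256; images whose values already
lie in [0, levels) are used as level indices directly, otherwise values
are rebinned by ``floor(g * levels / 256)`` (order-preserving).
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import NamedTuple

import numpy as np

from .features import FeatureVector
from .image_io import AnnotatedLesion

__all__ = [
    "GlcmConfig",
    "CoocMatrix",
    "GlcmError",
    "quantize_gray",
    "compute_glcm",
    "glcm_descriptors",
    "glcm48",
    "global_gray_features",
    "glcm51",
]

#: (row, col) unit offsets per direction, scaled by the distance d.
OFFSETS = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}

_VALID_LEVELS = (8, 16, 32, 64, 128, 256)

_DESCRIPTOR_NAMES = ("contrast", "correlation", "energy", "homogeneity")


class GlcmError(ValueError):
    """Raised when a co-occurrence matrix cannot be formed."""


@dataclass(frozen=True)
class GlcmConfig:
    """GLCM extraction settings.

    ``homogeneity_kernel`` selects the weighting 1/(1+|a-b|) (``"abs"``,
    the default) or 1/(1+(a-b)^2) (``"square"``); both are standard in the
    literature.
    """

    distances: tuple[int, ...] = (1, 2, 3)
    angles: tuple[int, ...] = (0, 45, 90, 135)
    levels: int = 256
    homogeneity_kernel: str = "abs"

    def __post_init__(self) -> None:
        if any(d < 1 for d in self.distances):
            raise ValueError("distances must be >= 1")
        if any(a not in OFFSETS for a in self.angles):
            raise ValueError(f"angles must be in {sorted(OFFSETS)}")
        if self.levels not in _VALID_LEVELS:
            raise ValueError(f"levels must be one of {_VALID_LEVELS}")
        if self.homogeneity_kernel not in ("abs", "square"):
            raise ValueError("homogeneity_kernel must be 'abs' or 'square'")


@dataclass(frozen=True)
class CoocMatrix:
    """Co-occurrence counts at one (distance, direction)."""

    counts: np.ndarray
    d: int
    theta: int
    n_pairs: int


class GlcmDescriptors(NamedTuple):
    contrast: float
    correlation: float
    energy: float
    homogeneity: float


def quantize_gray(values: np.ndarray, levels: int) -> np.ndarray:
    """Rebin 8-bit gray values to ``levels`` bins: floor(g * levels / 256)."""
    return (values.astype(np.int64) * levels) // 256


def compute_glcm(
    lesion: AnnotatedLesion, d: int, theta: int, levels: int = 256
) -> CoocMatrix:
    """Accumulate the co-occurrence matrix over in-mask ordered pixel pairs.

    ``counts[a, b]`` is the number of ordered pairs (p, q) with q displaced
    from p by distance ``d`` along ``theta`` where both p and q lie inside
    the ROI mask and have (quantized) gray levels a and b.
    """
    if d < 1:
        raise ValueError("distance must be >= 1")
    if theta not in OFFSETS:
        raise ValueError(f"direction must be in {sorted(OFFSETS)}")
    img = lesion.image.astype(np.int64)
    if img.max(initial=0) >= levels:
        img = quantize_gray(img, levels)
    mask = lesion.roi.mask
    h, w = img.shape
    dr, dc = OFFSETS[theta]
    dr, dc = dr * d, dc * d

    # window of p positions whose displaced partner q stays in bounds
    r0, r1 = max(0, -dr), min(h, h - dr)
    c0, c1 = max(0, -dc), min(w, w - dc)
    if r0 >= r1 or c0 >= c1:
        raise GlcmError(f"no valid pixel pairs for d={d}, theta={theta}")
    p_mask = mask[r0:r1, c0:c1]
    q_mask = mask[r0 + dr : r1 + dr, c0 + dc : c1 + dc]
    valid = p_mask & q_mask
    a = img[r0:r1, c0:c1][valid]
    b = img[r0 + dr : r1 + dr, c0 + dc : c1 + dc][valid]
    if a.size == 0:
        raise GlcmError(f"ROI too thin: no in-mask pairs for d={d}, theta={theta}")
    counts = np.bincount(a * levels + b, minlength=levels * levels).reshape(
        levels, levels
    )
    return CoocMatrix(counts=counts, d=d, theta=theta, n_pairs=int(a.size))


@lru_cache(maxsize=8)
def _level_grids(levels: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    idx = np.arange(levels, dtype=np.float64)
    diff = idx[:, None] - idx[None, :]
    return idx, diff * diff, np.abs(diff)


def glcm_descriptors(
    m: CoocMatrix, homogeneity_kernel: str = "abs"
) -> GlcmDescriptors:
    """Contrast, correlation, energy and homogeneity of one GLCM.

    With p(a,b) = counts/n_pairs: contrast = sum (a-b)^2 p; energy = sum p^2;
    homogeneity = sum p / (1 + |a-b|) (or squared difference, by kernel);
    correlation = sum (a-mu_r)(b-mu_c) p / (sigma_r sigma_c), defined as 0
    when either marginal variance vanishes.
    """
    if m.n_pairs < 1:
        raise ValueError("empty co-occurrence matrix")
    levels = m.counts.shape[0]
    idx, sqdiff, absdiff = _level_grids(levels)
    p = m.counts / m.n_pairs
    contrast = float((sqdiff * p).sum())
    energy = float((p * p).sum())
    denom = 1.0 + (absdiff if homogeneity_kernel == "abs" else sqdiff)
    homogeneity = float((p / denom).sum())
    pr, pc = p.sum(axis=1), p.sum(axis=0)
    mu_r, mu_c = float(idx @ pr), float(idx @ pc)
    var_r = float((idx - mu_r) ** 2 @ pr)
    var_c = float((idx - mu_c) ** 2 @ pc)
    sd = np.sqrt(var_r * var_c)
    if sd == 0:
        correlation = 0.0
    else:
        cov = float(idx @ p @ idx) - mu_r * mu_c
        correlation = cov / sd
    return GlcmDescriptors(contrast, correlation, energy, homogeneity)


def glcm48(lesion: AnnotatedLesion, cfg: GlcmConfig | None = None) -> FeatureVector:
    """The 48 GLCM features, ordered d ascending x theta (0,45,90,135) x
    (contrast, correlation, energy, homogeneity)."""
    cfg = cfg or GlcmConfig()
    names: list[str] = []
    values: list[float] = []
    for d in sorted(cfg.distances):
        for theta in cfg.angles:
            desc = glcm_descriptors(
                compute_glcm(lesion, d, theta, cfg.levels), cfg.homogeneity_kernel
            )
            for name, val in zip(_DESCRIPTOR_NAMES, desc):
                names.append(f"d{d}_a{theta}_{name}")
                values.append(val)
    return FeatureVector("GLCM48", tuple(names), np.asarray(values))


def global_gray_features(lesion: AnnotatedLesion) -> tuple[float, float, float]:
    """First-order global gray statistics of the ROI pixels.

    Returns (entropy, mean, sd): Shannon entropy in nats of the normalized
    256-bin gray histogram (0 ln 0 = 0), mean intensity, and population SD.
    """
    g = lesion.image[lesion.roi.mask].astype(np.float64)
    hist = np.bincount(lesion.image[lesion.roi.mask].astype(np.int64), minlength=256)
    h = hist / hist.sum()
    nz = h[h > 0]
    entropy = float(-(nz * np.log(nz)).sum())
    return entropy, float(g.mean()), float(g.std())


def glcm51(lesion: AnnotatedLesion, cfg: GlcmConfig | None = None) -> FeatureVector:
    """GLCM48 plus the 3 global gray features (entropy, mean, SD); length 51."""
    base = glcm48(lesion, cfg)
    entropy, mean, sd = global_gray_features(lesion)
    return FeatureVector(
        "GLCM48_PLUS_GLOBAL3",
        base.names + ("gray_entropy", "gray_mean", "gray_sd"),
        np.concatenate([base.values, [entropy, mean, sd]]),
    )
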