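"""Gray-gradient co-occurrence matrix (GGCM) texture features.

The GGCM pairs each pixel's gray value (full 256 levels) with its Sobel
gradient magnitude quantized to 32 levels: ``H[i, j]`` counts pixels with
gray value i and gradient level j. Fifteen classical descriptors are
extracted (small/large-gradient dominance, gray/gradient heterogeneity,
energy, gray/gradient average and mean-square error, correlation, gray /
gradient / hybrid entropy, inertia, inverse difference moment).

Gradients are computed with the standard 3x3 Sobel kernels and only at
*interior* ROI pixels — pixels whose full 3x3 neighborhood lies inside
the mask — so no gradient ever mixes lesion and background intensities.
Gradient magnitudes are normalized per lesion: the maximum magnitude in
the ROI maps to the top level. This removes dependence on absolute echo
brightness, which is not standardized across ultrasound images.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .features import FeatureVector
from .image_io import AnnotatedLesion

__all__ = [
    "GGCM_FEATURE_NAMES",
    "GradientField",
    "GGCM",
    "sobel_gradient",
    "quantize_gradient",
    "compute_ggcm",
    "ggcm_features",
    "ggcm15",
]

SOBEL_X = np.array([[-1, 0, 1], [-2, 0, 2], [-1, 0, 1]], dtype=np.float64)
SOBEL_Y = SOBEL_X.T.copy()  # sign irrelevant: only the magnitude is used

GGCM_FEATURE_NAMES = (
    "small_gradient_dominance",
    "large_gradient_dominance",
    "gray_heterogeneity",
    "gradient_heterogeneity",
    "energy",
    "gray_average",
    "gradient_average",
    "gray_mse",
    "gradient_mse",
    "correlation",
    "gray_entropy",
    "gradient_entropy",
    "hybrid_entropy",
    "inertia",
    "inverse_difference_moment",
)


@dataclass(frozen=True)
class GradientField:
    """Sobel gradient magnitudes over the ROI interior.

    ``magnitude`` and ``quantized`` are full-image arrays whose values are
    meaningful only where ``support`` (the interior mask) is true.
    """

    magnitude: np.ndarray
    support: np.ndarray
    quantized: np.ndarray | None = None


@dataclass(frozen=True)
class GGCM:
    """Gray x gradient co-occurrence counts (``levels_gray x levels_grad``)."""

    counts: np.ndarray
    n_pixels: int


def sobel_gradient(lesion: AnnotatedLesion) -> GradientField:
    """Gradient magnitude sqrt(Gx^2 + Gy^2) at every interior-mask pixel."""
    support = lesion.roi.interior_mask
    if not support.any():
        raise ValueError("empty interior mask: ROI too thin for 3x3 gradients")
    img = lesion.image.astype(np.float64)
    gx = ndimage.correlate(img, SOBEL_X, mode="constant")
    gy = ndimage.correlate(img, SOBEL_Y, mode="constant")
    magnitude = np.hypot(gx, gy)
    magnitude[~support] = 0.0
    return GradientField(magnitude=magnitude, support=support)


def quantize_gradient(field: GradientField, levels: int = 32) -> GradientField:
    """Quantize magnitudes to ``levels`` bins by per-lesion max scaling.

    ``q = floor(magnitude * levels / gmax)`` clipped to ``levels - 1``, so
    the ROI maximum lands in the top level; an all-zero field maps to 0.
    """
    if levels < 2:
        raise ValueError("levels must be >= 2")
    mag = field.magnitude
    gmax = float(mag[field.support].max()) if field.support.any() else 0.0
    if gmax == 0.0:
        q = np.zeros(mag.shape, dtype=np.int64)
    else:
        q = np.minimum((mag * levels / gmax).astype(np.int64), levels - 1)
        q[~field.support] = 0
    return GradientField(magnitude=mag, support=field.support, quantized=q)


def compute_ggcm(
    lesion: AnnotatedLesion, gray_levels: int = 256, gradient_levels: int = 32
) -> GGCM:
    """Count interior pixels by (gray value, quantized gradient level)."""
    field = quantize_gradient(sobel_gradient(lesion), gradient_levels)
    gray = lesion.image[field.support].astype(np.int64)
    if gray_levels < 256:
        gray = (gray * gray_levels) // 256
    grad = field.quantized[field.support]
    counts = np.bincount(
        gray * gradient_levels + grad, minlength=gray_levels * gradient_levels
    ).reshape(gray_levels, gradient_levels)
    return GGCM(counts=counts, n_pixels=int(counts.sum()))


def _entropy(p: np.ndarray) -> float:
    nz = p[p > 0]
    return float(-(nz * np.log(nz)).sum())


def ggcm_features(H: GGCM) -> FeatureVector:
    """The 15 GGCM descriptors (order as in :data:`GGCM_FEATURE_NAMES`).

    With T = n_pixels, p(i,j) = H(i,j)/T, gray marginal p_g, gradient
    marginal p_s and marginal moments (mu, sigma):

    1.  small-gradient dominance  = [sum_j colsum(j) / (j+1)^2] / T
    2.  large-gradient dominance  = [sum_j j^2 colsum(j)] / T
    3.  gray heterogeneity        = [sum_i rowsum(i)^2] / T
    4.  gradient heterogeneity    = [sum_j colsum(j)^2] / T
    5.  energy                    = sum p^2
    6.  gray average              = mu_g
    7.  gradient average          = mu_s
    8.  gray mean square error    = sigma_g
    9.  gradient mean square error= sigma_s
    10. correlation               = sum (i - mu_g)(j - mu_s) p(i,j)
    11. gray entropy              = -sum p_g ln p_g
    12. gradient entropy          = -sum p_s ln p_s
    13. hybrid entropy            = -sum p ln p
    14. inertia                   = sum (i - j)^2 p(i,j)
    15. inverse difference moment = sum p(i,j) / (1 + (i - j)^2)

    All entropies are in nats with 0 ln 0 = 0.
    """
    if H.n_pixels < 1:
        raise ValueError("empty GGCM")
    T = float(H.n_pixels)
    counts = H.counts.astype(np.float64)
    ng, ns = counts.shape
    i = np.arange(ng, dtype=np.float64)
    j = np.arange(ns, dtype=np.float64)
    rowsum = counts.sum(axis=1)
    colsum = counts.sum(axis=0)
    p = counts / T
    pg, ps = rowsum / T, colsum / T

    mu_g = float(i @ pg)
    mu_s = float(j @ ps)
    sd_g = float(np.sqrt((i - mu_g) ** 2 @ pg))
    sd_s = float(np.sqrt((j - mu_s) ** 2 @ ps))
    diff = i[:, None] - j[None, :]

    values = np.array(
        [
            float((colsum / (j + 1.0) ** 2).sum() / T),
            float((j**2 * colsum).sum() / T),
            float((rowsum**2).sum() / T),
            float((colsum**2).sum() / T),
            float((p * p).sum()),
            mu_g,
            mu_s,
            sd_g,
            sd_s,
            float(i @ p @ j) - mu_g * mu_s,
            _entropy(pg),
            _entropy(ps),
            _entropy(p.ravel()),
            float((diff**2 * p).sum()),
            float((p / (1.0 + diff**2)).sum()),
        ]
    )
    return FeatureVector("GGCM15", GGCM_FEATURE_NAMES, values)


def ggcm15(lesion: AnnotatedLesion) -> FeatureVector:
    """Convenience: full-resolution GGCM (256 gray x 32 gradient) features."""
    return ggcm_features(compute_ggcm(lesion))
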