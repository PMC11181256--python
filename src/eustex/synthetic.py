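"""Synthetic EUS-like lesion cohorts for end-to-end testing.

Real endoscopic-ultrasound images of gastric mesenchymal tumors are not
publicly available, so this module generates stand-in cohorts: hypoechoic
(dark, mean ~60/255) speckled textures inside randomized convex polygon
ROIs, with a binary label per lesion. Speckle is modeled as a unit-mean
multiplicative gamma field (shape k = 1/speckle_scale^2) smoothed by a
Gaussian kernel; the *only* systematic class difference is the smoothing
length (``smooth_sigma_pos`` vs ``smooth_sigma_neg``), which changes the
spatial gradient statistics — and hence second-order texture — at roughly
matched mean brightness. This mirrors the premise that gradient-based
texture separates the classes while being robust to absolute echo level.

This is a texture proxy, not an ultrasound physics simulation: there is no
point-spread function, scan geometry, or attenuation.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .image_io import MIN_ROI_PIXELS, AnnotatedLesion, RoiPolygon, rasterize, save_lesion

__all__ = ["CohortSpec", "generate_lesion", "generate_cohort", "write_cohort"]


@dataclass(frozen=True)
class CohortSpec:
    """Cohort generator settings.

    Defaults reflect the clinical study setting being emulated: 59 positive
    (GIST) and 61 negative lesions, hypoechoic (base_intensity 60 of 255).
    Image size, ROI radii and speckle dispersion are desk-scale choices:
    96-px frames with 18-30 px ROI radii give ROIs of ~1-3 thousand pixels,
    and speckle_scale 0.5 gives fully developed multiplicative speckle.
    Positives are smoother (sigma 2.0 vs 1.0 px), i.e. coarser speckle grain.
    """

    n_pos: int = 59
    n_neg: int = 61
    image_size: int = 96
    roi_radius_range: tuple[float, float] = (18.0, 30.0)
    base_intensity: float = 60.0
    speckle_scale: float = 0.5
    smooth_sigma_pos: float = 2.0
    smooth_sigma_neg: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pos < 2 or self.n_neg < 2:
            raise ValueError("need at least 2 lesions per class")
        if self.smooth_sigma_pos <= 0 or self.smooth_sigma_neg <= 0:
            raise ValueError("smoothing sigmas must be > 0")
        if not 0 < self.base_intensity < 255:
            raise ValueError("base_intensity must be in (0, 255)")
        lo, hi = self.roi_radius_range
        if not 0 < lo <= hi < self.image_size / 2:
            raise ValueError("roi_radius_range must fit inside the image")


def _random_roi(spec: CohortSpec, rng: np.random.Generator) -> RoiPolygon:
    """Randomized star-convex polygon around the (jittered) image center."""
    size = spec.image_size
    radius = rng.uniform(*spec.roi_radius_range)
    slack = size / 2.0 - 1.15 * radius - 1.0
    center = size / 2.0 + rng.uniform(-1.0, 1.0, size=2) * max(0.0, min(slack, 4.0))
    n_vert = int(rng.integers(8, 15))
    angles = np.sort(rng.uniform(0.0, 2.0 * np.pi, size=n_vert))
    radii = radius * (1.0 + rng.uniform(-0.15, 0.15, size=n_vert))
    rows = np.clip(center[0] + radii * np.sin(angles), 0.0, size - 1.0)
    cols = np.clip(center[1] + radii * np.cos(angles), 0.0, size - 1.0)
    return RoiPolygon(tuple(zip(rows.tolist(), cols.tolist())))


def generate_lesion(
    spec: CohortSpec, label: int, rng: np.random.Generator, lesion_id: str = "lesion"
) -> AnnotatedLesion:
    """Draw one speckled lesion image with a random polygon ROI.

    The texture is ``base_intensity x speckle`` where speckle is a gamma
    field with mean 1 and SD ``speckle_scale``, Gaussian-smoothed with the
    class's sigma, then rounded and clipped to 0-255.
    """
    sigma = spec.smooth_sigma_pos if label == 1 else spec.smooth_sigma_neg
    size = spec.image_size
    if spec.speckle_scale > 0:
        k = 1.0 / spec.speckle_scale**2
        speckle = rng.gamma(shape=k, scale=1.0 / k, size=(size, size))
    else:
        speckle = np.ones((size, size))
    speckle = ndimage.gaussian_filter(speckle, sigma=sigma, mode="reflect")
    image = np.clip(np.rint(spec.base_intensity * speckle), 0, 255).astype(np.uint8)
    polygon = _random_roi(spec, rng)
    roi = rasterize(polygon, image.shape)
    if roi.n_pixels < MIN_ROI_PIXELS:
        raise ValueError(f"generated ROI below minimum size ({roi.n_pixels} px)")
    return AnnotatedLesion(
        image=image, roi=roi, label=label, lesion_id=lesion_id, polygon=polygon
    )


def generate_cohort(spec: CohortSpec) -> tuple[list[AnnotatedLesion], pd.DataFrame]:
    """Generate the full labeled cohort plus an in-memory manifest.

    Every lesion uses an independent substream spawned from ``spec.seed``,
    so the cohort is fully reproducible and insensitive to generation order.
    """
    n_total = spec.n_pos + spec.n_neg
    streams = np.random.SeedSequence(spec.seed).spawn(n_total)
    lesions = []
    rows = []
    for idx in range(n_total):
        label = 1 if idx < spec.n_pos else 0
        lesion_id = f"L{idx:04d}"
        rng = np.random.default_rng(streams[idx])
        lesions.append(generate_lesion(spec, label, rng, lesion_id))
        rows.append(
            {
                "lesion_id": lesion_id,
                "image_path": f"{lesion_id}.png",
                "roi_path": f"{lesion_id}.roi.json",
                "label": "GIST" if label == 1 else "non-GIST",
            }
        )
    return lesions, pd.DataFrame(rows)


def write_cohort(spec: CohortSpec, out_dir: str | Path) -> Path:
    """Write the cohort to disk (PNG + ROI JSON per lesion + manifest.csv).

    Returns the manifest path; the layout is exactly what
    :func:`eustex.image_io.load_cohort` consumes.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    lesions, manifest = generate_cohort(spec)
    for lesion, row in zip(lesions, manifest.itertuples(index=False)):
        save_lesion(lesion, out_dir / row.image_path, out_dir / row.roi_path)
    manifest_path = out_dir / "manifest.csv"
    manifest.to_csv(manifest_path, index=False)
    return manifest_path


def null_spec(spec: CohortSpec | None = None, **overrides) -> CohortSpec:
    """A copy of ``spec`` with both classes at the positive smoothing sigma
    (zero class separation) — handy for calibration checks."""
    spec = spec or CohortSpec()
    spec = replace(spec, smooth_sigma_neg=spec.smooth_sigma_pos)
    return replace(spec, **overrides) if overrides else spec
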