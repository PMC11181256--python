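"""I/O for lesion images and polygon ROI annotations.

Conventions used throughout the package
---------------------------------------
* Pixel coordinates are ``(row, col)``, 0-based, origin at the top-left
  corner of the image.
* Images are 2-D 8-bit grayscale arrays with values in ``[0, 255]``.
  Color inputs are converted with ITU-R BT.601 luma weights
  (0.299 R + 0.587 G + 0.114 B), rounded half-up, so the conversion is
  bit-exact and deterministic.
* A pixel belongs to an ROI when its *center* lies inside or on the
  boundary of the annotation polygon (even-odd rule for simple rings).
* The *interior* of an ROI is the mask eroded by a full 3x3 structuring
  element: every interior pixel has all 8 neighbors inside the mask, so
  3x3 gradient kernels never read pixels outside the annotation.

On-disk layout
--------------
Each lesion is a grayscale PNG or BMP plus a JSON file holding the ROI
polygon as a list of ``[row, col]`` vertex pairs. A cohort manifest is a
CSV with columns ``lesion_id, image_path, roi_path, label`` (paths are
relative to the manifest's directory; label is ``GIST`` / ``non-GIST``
or ``1`` / ``0``).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import shapely
from PIL import Image
from scipy import ndimage
from shapely.geometry import Polygon as _ShapelyPolygon

__all__ = [
    "MIN_ROI_PIXELS",
    "RoiPolygon",
    "RoiMask",
    "AnnotatedLesion",
    "rasterize",
    "load_lesion",
    "save_lesion",
    "masked_pixels",
    "parse_label",
    "read_manifest",
    "load_cohort",
]

#: Minimum number of mask pixels for a usable ROI. Co-occurrence statistics
#: on smaller regions are meaningless; clinical lesions (>= 0.6 cm) are far
#: larger in pixels.
MIN_ROI_PIXELS = 64

_BT601 = np.array([0.299, 0.587, 0.114])
_STRUCT_3X3 = np.ones((3, 3), dtype=bool)


class RoiError(ValueError):
    """Raised for invalid ROI polygons or masks."""


@dataclass(frozen=True)
class RoiPolygon:
    """Closed polygonal ROI as an ordered ring of ``(row, col)`` vertices."""

    vertices: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        if len(self.vertices) < 3:
            raise RoiError(f"polygon needs >= 3 vertices, got {len(self.vertices)}")

    def within_bounds(self, shape: tuple[int, int]) -> bool:
        h, w = shape
        return all(0 <= r <= h - 1 and 0 <= c <= w - 1 for r, c in self.vertices)

    @classmethod
    def from_json(cls, path: str | Path) -> "RoiPolygon":
        data = json.loads(Path(path).read_text())
        return cls(tuple((float(r), float(c)) for r, c in data))

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps([[float(r), float(c)] for r, c in self.vertices])
        )


@dataclass(frozen=True)
class RoiMask:
    """Boolean ROI mask plus its 3x3-eroded interior."""

    mask: np.ndarray
    interior_mask: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.interior_mask is None:
            object.__setattr__(
                self,
                "interior_mask",
                ndimage.binary_erosion(self.mask, _STRUCT_3X3, border_value=0),
            )

    @property
    def n_pixels(self) -> int:
        return int(self.mask.sum())

    @property
    def n_interior(self) -> int:
        return int(self.interior_mask.sum())


@dataclass(frozen=True)
class AnnotatedLesion:
    """A grayscale lesion image, its ROI mask, and a binary label.

    ``label`` is 1 for the positive class (GIST) and 0 for the negative
    class (non-GIST: leiomyoma or schwannoma). The originating polygon is
    kept when known so that a lesion can be written back to disk losslessly.
    """

    image: np.ndarray
    roi: RoiMask
    label: int
    lesion_id: str
    polygon: RoiPolygon | None = None

    def __post_init__(self) -> None:
        if self.label not in (0, 1):
            raise ValueError(f"label must be 0 or 1, got {self.label!r}")
        if self.image.shape != self.roi.mask.shape:
            raise ValueError("image and mask shapes differ")


def rasterize(polygon: RoiPolygon, shape: tuple[int, int]) -> RoiMask:
    """Rasterize a polygon to a boolean mask on a ``(height, width)`` grid.

    A pixel is in the mask iff its center ``(row, col)`` lies inside or on
    the polygon boundary. The interior mask is the 3x3 erosion of the mask.
    """
    h, w = shape
    if not polygon.within_bounds(shape):
        raise RoiError("polygon vertex outside image bounds")
    # shapely works in (x, y) = (col, row)
    ring = _ShapelyPolygon([(c, r) for r, c in polygon.vertices])
    if ring.area == 0:
        raise RoiError("degenerate polygon (zero area)")
    cmin, rmin, cmax, rmax = ring.bounds
    r0, r1 = max(0, int(np.floor(rmin))), min(h - 1, int(np.ceil(rmax)))
    c0, c1 = max(0, int(np.floor(cmin))), min(w - 1, int(np.ceil(cmax)))
    rr, cc = np.meshgrid(np.arange(r0, r1 + 1), np.arange(c0, c1 + 1), indexing="ij")
    pts = shapely.points(cc.ravel().astype(float), rr.ravel().astype(float))
    inside = shapely.intersects(ring, pts).reshape(rr.shape)
    mask = np.zeros(shape, dtype=bool)
    mask[r0 : r1 + 1, c0 : c1 + 1] = inside
    return RoiMask(mask=mask)


def _to_gray(img: Image.Image) -> np.ndarray:
    """Decode to an 8-bit grayscale array (BT.601 luma, rounded half-up)."""
    arr = np.asarray(img)
    if arr.ndim == 2:
        if arr.dtype != np.uint8:
            raise ValueError(f"expected 8-bit image, got dtype {arr.dtype}")
        return arr
    rgb = arr[..., :3].astype(np.float64)
    luma = np.floor(rgb @ _BT601 + 0.5)
    return np.clip(luma, 0, 255).astype(np.uint8)


def load_lesion(
    image_path: str | Path,
    roi_path: str | Path,
    label: int | str,
    lesion_id: str | None = None,
    min_pixels: int = MIN_ROI_PIXELS,
) -> AnnotatedLesion:
    """Load an image + ROI polygon file into an :class:`AnnotatedLesion`.

    Raises for unreadable files, out-of-bounds polygons, and masks with
    fewer than ``min_pixels`` pixels.
    """
    with Image.open(image_path) as im:
        gray = _to_gray(im)
    polygon = RoiPolygon.from_json(roi_path)
    roi = rasterize(polygon, gray.shape)
    if roi.n_pixels < min_pixels:
        raise RoiError(
            f"ROI of {roi.n_pixels} pixels below minimum {min_pixels} "
            f"({image_path})"
        )
    return AnnotatedLesion(
        image=gray,
        roi=roi,
        label=parse_label(label),
        lesion_id=lesion_id or Path(image_path).stem,
        polygon=polygon,
    )


def save_lesion(
    lesion: AnnotatedLesion, image_path: str | Path, roi_path: str | Path
) -> None:
    """Write the lesion image (PNG/BMP by extension) and ROI polygon JSON."""
    if lesion.polygon is None:
        raise ValueError("lesion has no polygon; cannot save the ROI annotation")
    Image.fromarray(lesion.image.astype(np.uint8), mode="L").save(image_path)
    lesion.polygon.to_json(roi_path)


def masked_pixels(lesion: AnnotatedLesion) -> np.ndarray:
    """Return the in-mask pixels as an ``(n, 3)`` array of (row, col,
    intensity), in row-major order."""
    rows, cols = np.nonzero(lesion.roi.mask)  # nonzero is row-major
    return np.column_stack([rows, cols, lesion.image[rows, cols].astype(np.int64)])


_LABEL_MAP = {
    "gist": 1,
    "positive": 1,
    "1": 1,
    "non-gist": 0,
    "nongist": 0,
    "negative": 0,
    "0": 0,
}


def parse_label(label: int | str) -> int:
    if isinstance(label, (int, np.integer)) and label in (0, 1):
        return int(label)
    key = str(label).strip().lower()
    if key in _LABEL_MAP:
        return _LABEL_MAP[key]
    raise ValueError(f"unrecognized lesion label {label!r}")


def read_manifest(manifest_path: str | Path) -> pd.DataFrame:
    """Read a cohort manifest CSV (lesion_id, image_path, roi_path, label)."""
    df = pd.read_csv(manifest_path, dtype={"lesion_id": str})
    required = {"lesion_id", "image_path", "roi_path", "label"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"manifest missing columns: {sorted(missing)}")
    return df


def load_cohort(
    manifest_path: str | Path, min_pixels: int = MIN_ROI_PIXELS
) -> list[AnnotatedLesion]:
    """Load every lesion listed in a manifest (paths relative to it)."""
    manifest_path = Path(manifest_path)
    base = manifest_path.parent
    lesions = []
    for row in read_manifest(manifest_path).itertuples(index=False):
        lesions.append(
            load_lesion(
                base / row.image_path,
                base / row.roi_path,
                row.label,
                lesion_id=str(row.lesion_id),
                min_pixels=min_pixels,
            )
        )
    return lesions
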