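"""Contour-to-mask conversion and lesion sub-region derivation.

Coordinate convention, fixed package-wide: 0-based, x = column, y = row,
pixel centers at integer coordinates.  A pixel belongs to a polygon iff its
center lies inside by the even-odd rule; points exactly on the boundary are
resolved by the half-open crossing convention (left/bottom edges in, right/top
out), so an axis-aligned square with corners (10,10)-(20,20) rasterizes to
exactly 10x10 pixels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Tuple

import numpy as np
from shapely.geometry import LinearRing, Polygon
from skimage.filters import threshold_otsu


class ContourError(ValueError):
    """The polygon is open, self-intersecting, degenerate or out of bounds."""


@dataclass
class LesionMask:
    """Binary lesion region plus derived sub-regions.

    ``high_intensity`` is a subset of ``lesion``; ``reference`` (the
    rectangular band expanding outwards from the lesion) never overlaps it.
    """

    lesion: np.ndarray
    reference: np.ndarray
    high_intensity: np.ndarray
    origin_contour: Tuple[str, int, str] | None = None  # (observer, rep, modality)

    def __post_init__(self) -> None:
        if np.any(self.high_intensity & ~self.lesion):
            raise ValueError("high_intensity must be a subset of lesion")
        if np.any(self.reference & self.lesion):
            raise ValueError("reference band must be disjoint from lesion")


def _validate_polygon(contour: np.ndarray) -> np.ndarray:
    poly = np.asarray(contour, dtype=float)
    if poly.ndim != 2 or poly.shape[1] != 2 or len(poly) < 3:
        raise ContourError("contour must be an (N>=3, 2) vertex array")
    if not np.all(np.isfinite(poly)):
        raise ContourError("contour contains non-finite vertices")
    # drop an explicit closing vertex; the polygon is implicitly closed
    if np.allclose(poly[0], poly[-1]):
        poly = poly[:-1]
    if len(poly) < 3:
        raise ContourError("contour must have at least 3 distinct vertices")
    ring = LinearRing(poly)
    if not ring.is_valid or not ring.is_simple:
        raise ContourError("contour is self-intersecting or degenerate")
    if Polygon(poly).area <= 0:
        raise ContourError("contour encloses zero area (collinear vertices)")
    return poly


def contour_to_mask(contour: np.ndarray, image_dims: Tuple[int, int]) -> np.ndarray:
    """Rasterize a closed simple polygon to a boolean mask.

    A pixel (row y, col x) is True iff the point (x, y) is inside the polygon
    under the even-odd rule with half-open boundary handling.

    Parameters
    ----------
    contour : (N, 2) array of (x, y) vertices, 0-based pixel coordinates.
    image_dims : (height, width) of the target grid.
    """
    poly = _validate_polygon(contour)
    h, w = image_dims
    if poly[:, 0].min() < 0 or poly[:, 0].max() > w - 1 or poly[:, 1].min() < 0 or poly[:, 1].max() > h - 1:
        raise ContourError("contour extends outside the image bounds")

    r0 = int(np.floor(poly[:, 1].min()))
    r1 = int(np.ceil(poly[:, 1].max())) + 1
    c0 = int(np.floor(poly[:, 0].min()))
    c1 = int(np.ceil(poly[:, 0].max())) + 1
    yy, xx = np.mgrid[r0:r1, c0:c1]
    px = xx.astype(float)
    py = yy.astype(float)

    inside = np.zeros(px.shape, dtype=bool)
    x1s, y1s = poly[:, 0], poly[:, 1]
    x2s, y2s = np.roll(x1s, -1), np.roll(y1s, -1)
    for x1, y1, x2, y2 in zip(x1s, y1s, x2s, y2s):
        crosses = (y1 > py) != (y2 > py)
        if not crosses.any():
            continue
        with np.errstate(divide="ignore", invalid="ignore"):
            x_int = x1 + (py - y1) * (x2 - x1) / (y2 - y1)
        inside ^= crosses & (px < x_int)

    mask = np.zeros((h, w), dtype=bool)
    mask[r0:r1, c0:c1] = inside
    return mask


def map_to_smi(
    contour: np.ndarray,
    offset: Tuple[float, float],
    smi_dims: Tuple[int, int] | None = None,
) -> np.ndarray:
    """Translate a B-mode contour onto the co-registered SMI panel.

    The two panels of a dual-modality frame display the same section, so the
    mapping is a pure translation by ``offset`` = (dx, dy); area and perimeter
    are preserved exactly.
    """
    poly = np.asarray(contour, dtype=float)
    mapped = poly + np.asarray(offset, dtype=float)
    if smi_dims is not None:
        h, w = smi_dims
        if (
            mapped[:, 0].min() < 0
            or mapped[:, 0].max() > w - 1
            or mapped[:, 1].min() < 0
            or mapped[:, 1].max() > h - 1
        ):
            raise ContourError("mapped contour falls outside the SMI panel")
    return mapped


def reference_band(lesion_mask: np.ndarray, margin_px: int = 10) -> np.ndarray:
    """Rectangular band expanding outwards from the lesion, minus the lesion.

    The band is the lesion's bounding box dilated by ``margin_px`` on every
    side (clipped to the image) with the lesion pixels removed.
    """
    if margin_px < 1:
        raise ValueError("margin_px must be >= 1")
    rows, cols = np.nonzero(lesion_mask)
    if len(rows) == 0:
        raise ValueError("lesion mask is empty")
    h, w = lesion_mask.shape
    r0 = max(rows.min() - margin_px, 0)
    r1 = min(rows.max() + margin_px + 1, h)
    c0 = max(cols.min() - margin_px, 0)
    c1 = min(cols.max() + margin_px + 1, w)
    band = np.zeros_like(lesion_mask)
    band[r0:r1, c0:c1] = True
    band &= ~lesion_mask
    if not band.any():
        raise ValueError("reference band is empty (lesion fills the image)")
    return band


def high_intensity_region(image: np.ndarray, lesion_mask: np.ndarray) -> np.ndarray:
    """Bright sub-region of the lesion: pixels above the Otsu threshold.

    The threshold is computed from the within-lesion intensity histogram and
    follows the standard edge convention in which the threshold value itself
    belongs to the dark class (bright = intensity > threshold).  For a
    constant-intensity lesion the threshold is undefined; the whole lesion is
    returned (area ratio 1 downstream) with a warning.
    """
    values = np.asarray(image)[lesion_mask]
    if values.size == 0:
        raise ValueError("lesion mask is empty")
    if np.ptp(values) == 0:
        warnings.warn(
            "constant-intensity lesion: high-intensity region set to whole lesion",
            stacklevel=2,
        )
        return lesion_mask.copy()
    thresh = threshold_otsu(values)
    return lesion_mask & (np.asarray(image) > thresh)


def build_lesion_mask(
    image: np.ndarray,
    contour: np.ndarray,
    margin_px: int = 10,
    origin: Tuple[str, int, str] | None = None,
) -> LesionMask:
    """Rasterize a contour and derive the reference band and bright sub-region."""
    lesion = contour_to_mask(contour, image.shape)
    if lesion.sum() < 16:
        raise ContourError("lesion must cover at least 16 pixels")
    return LesionMask(
        lesion=lesion,
        reference=reference_band(lesion, margin_px),
        high_intensity=high_intensity_region(image, lesion),
        origin_contour=origin,
    )
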