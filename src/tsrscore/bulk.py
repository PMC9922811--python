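"""Tumor-bulk extraction and valid field-of-view centers.

The tumor bulk is the region enclosing all predicted tumor glands,
including the invasive edge and budding zone.  It is built from the
tumor-gland mask by morphological closing with a disc, hole filling, and
removal of small components (false-positive specks).  A field-of-view
center is valid when its circle lies wholly inside the bulk and contains
no background pixels — equivalently, a binary erosion of the bulk (and of
the non-background mask) by the disc.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.signal import fftconvolve

from .errors import EmptyBulkError
from .labelmap import LabelMap, disk_kernel, mm_to_px
from .scheme import TissueClassScheme

#: closing disc radius: one field-of-view radius (half of the 2.0 mm fov)
DEFAULT_CLOSING_RADIUS_MM = 1.0

#: minimum retained component area: one field-of-view area, pi * (1.0 mm)^2
DEFAULT_MIN_COMPONENT_AREA_MM2 = math.pi * 1.0**2


@dataclass(frozen=True)
class TumorBulkMask:
    """Binary tumor-bulk mask aligned with its label map."""

    mask: np.ndarray
    component_count: int


def _disk_counts(mask: np.ndarray, radius_px: int) -> np.ndarray:
    """Exact in-disc true-pixel count at every position (FFT + rounding).

    Out-of-grid positions contribute zero, matching morphological
    operations with border value 0.
    """
    disk = disk_kernel(radius_px).astype(np.float64)
    raw = fftconvolve(mask.astype(np.float64), disk, mode="same")
    return np.clip(np.rint(raw), 0, int(disk.sum())).astype(np.int64)


def erode_disk(mask: np.ndarray, radius_px: int,
               border_value: bool = False) -> np.ndarray:
    """Binary erosion by the disc: positions whose whole disc is inside mask.

    With ``border_value=False`` the region outside the grid counts as empty
    (a disc touching the border never survives); with ``border_value=True``
    it counts as filled, which is the convention needed inside a closing to
    avoid eating the mask back from the grid border.
    """
    if border_value:
        return _disk_counts(~mask, radius_px) == 0
    area = int(disk_kernel(radius_px).sum())
    return _disk_counts(mask, radius_px) == area


def dilate_disk(mask: np.ndarray, radius_px: int) -> np.ndarray:
    """Binary dilation by the disc."""
    return _disk_counts(mask, radius_px) > 0


def close_disk(mask: np.ndarray, radius_px: int) -> np.ndarray:
    """Binary closing (dilation then erosion) by the disc.

    The erosion treats out-of-grid as filled so that a mask reaching the
    grid border is not artificially shaved by the closing.
    """
    return erode_disk(dilate_disk(mask, radius_px), radius_px,
                      border_value=True)


def _tumor_gland_codes(scheme: TissueClassScheme) -> frozenset[int]:
    # the bulk is seeded from predicted tumor glands; schemes without that
    # class fall back to the full tumor grouping
    try:
        return frozenset({scheme.code_of("tumor glands")})
    except KeyError:
        return scheme.codes_for("tumor_full")


def extract_tumor_bulk(
    labelmap: LabelMap,
    scheme: TissueClassScheme,
    min_component_area_mm2: float = DEFAULT_MIN_COMPONENT_AREA_MM2,
    closing_radius_mm: float = DEFAULT_CLOSING_RADIUS_MM,
) -> TumorBulkMask:
    """Extract the tumor bulk from the tumor-gland pixels.

    Pipeline: binary mask of tumor-gland pixels -> morphological closing
    with a disc of ``closing_radius_mm`` -> hole filling -> removal of
    connected components smaller than ``min_component_area_mm2``.  Setting
    both parameters to 0 degrades gracefully to the filled tumor-gland
    components.

    Raises
    ------
    EmptyBulkError
        If the map contains no tumor-gland pixels, or every component is
        removed as too small.
    """
    codes = _tumor_gland_codes(scheme)
    mask = np.isin(labelmap.grid, list(codes))
    if not mask.any():
        raise EmptyBulkError("label map contains no tumor-gland pixels")

    closing_r_px = mm_to_px(closing_radius_mm, labelmap.spacing_um) \
        if closing_radius_mm > 0 else 0
    if closing_r_px >= 1:
        mask = close_disk(mask, closing_r_px)
    mask = ndimage.binary_fill_holes(mask)

    if min_component_area_mm2 > 0:
        # drop connected components with area strictly below the minimum
        min_px = min_component_area_mm2 / labelmap.pixel_area_mm2()
        labels, n = ndimage.label(mask, structure=np.ones((3, 3), bool))
        if n:
            areas = np.bincount(labels.ravel())
            keep = np.zeros(n + 1, dtype=bool)
            keep[1:] = areas[1:] >= min_px
            mask = keep[labels]
    if not mask.any():
        raise EmptyBulkError(
            "all tumor components smaller than the minimum bulk area"
        )
    _, n_components = ndimage.label(mask, structure=np.ones((3, 3), bool))
    return TumorBulkMask(mask=mask, component_count=int(n_components))


def valid_centers(
    bulk: TumorBulkMask,
    labelmap: LabelMap,
    scheme: TissueClassScheme,
    fov_radius_px: int,
) -> np.ndarray:
    """Boolean grid of admissible field-of-view centers.

    A center is valid iff its disc lies entirely inside the bulk mask and
    the disc contains no background pixels.  Computed as the intersection
    of two binary erosions by the disc (outside-grid counts as invalid).
    """
    inside_bulk = erode_disk(bulk.mask, fov_radius_px)
    not_background = labelmap.grid != scheme.background_code
    no_background = erode_disk(not_background, fov_radius_px)
    return inside_bulk & no_background
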