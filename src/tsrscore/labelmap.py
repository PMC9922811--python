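"""Spatial data model: label maps, circular regions of interest, disc kernels.

Conventions (shared by every module):

* coordinates are 0-based, row-major, pixel-center;
* physical lengths convert to pixels via ``spacing_um`` (μm/pixel) with
  round-half-up to the nearest integer;
* a circle of radius ``r`` pixels contains every pixel whose center lies at
  Euclidean distance ``<= r`` from the circle's center pixel.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass

import numpy as np
import tifffile
from PIL import Image

from .errors import FormatError, ValidationError
from .scheme import TissueClassScheme

#: default processing resolution, μm per pixel (20X magnification)
DEFAULT_SPACING_UM = 0.5

#: default circular field-of-view diameter in mm (100x microscope field)
DEFAULT_FOV_DIAMETER_MM = 2.0


def round_half_up(x: float) -> int:
    """Round to nearest integer, halves away from zero toward +inf."""
    return int(math.floor(x + 0.5))


def mm_to_px(length_mm: float, spacing_um: float) -> int:
    """Convert a physical length in mm to whole pixels (round half up)."""
    return round_half_up(length_mm * 1000.0 / spacing_um)


@dataclass(frozen=True)
class LabelMap:
    """A 2-D grid of tissue-class codes with physical pixel spacing."""

    grid: np.ndarray
    spacing_um: float = DEFAULT_SPACING_UM

    def __post_init__(self) -> None:
        if self.grid.ndim != 2 or self.grid.size == 0:
            raise ValidationError("label map grid must be a non-empty 2-D array")
        if self.spacing_um <= 0:
            raise ValidationError("spacing_um must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.grid.shape

    def pixel_area_mm2(self) -> float:
        return (self.spacing_um / 1000.0) ** 2

    def validate_against(self, scheme: TissueClassScheme) -> None:
        """Raise if any grid code is not declared in the scheme.

        The error names the offending code and the first pixel carrying it.
        """
        present = np.unique(self.grid)
        declared = scheme.codes
        for code in present:
            if int(code) not in declared:
                rr, cc = np.nonzero(self.grid == code)
                raise ValidationError(
                    f"code {int(code)} at pixel (row={int(rr[0])}, col={int(cc[0])}) "
                    "is not declared in the tissue-class scheme"
                )


@dataclass(frozen=True)
class CircularROI:
    """A circular field of view: center pixel plus physical diameter."""

    center_row: int
    center_col: int
    diameter_mm: float = DEFAULT_FOV_DIAMETER_MM

    def __post_init__(self) -> None:
        if self.diameter_mm <= 0:
            raise ValidationError("ROI diameter must be positive")

    def radius_px(self, spacing_um: float) -> int:
        """Radius in whole pixels at the given spacing (round half up, >= 1)."""
        r = round_half_up(self.diameter_mm * 1000.0 / (2.0 * spacing_um))
        if r < 1:
            raise ValidationError(
                f"ROI diameter {self.diameter_mm} mm is below one pixel at "
                f"{spacing_um} um/pixel"
            )
        return r


def disk_kernel(radius_px: int) -> np.ndarray:
    """Boolean (2r+1)² disc: pixel centers within Euclidean distance r."""
    if radius_px < 1:
        raise ValidationError("disc radius must be >= 1 pixel")
    ax = np.arange(-radius_px, radius_px + 1)
    dr2 = ax[:, None] ** 2 + ax[None, :] ** 2
    return dr2 <= radius_px * radius_px


def disk_area_px(radius_px: int) -> int:
    """Number of pixels in the disc of the given radius."""
    return int(disk_kernel(radius_px).sum())


# ---------------------------------------------------------------------------
# raster I/O

def read_labelmap(path, scheme: TissueClassScheme,
                  spacing_um: float = DEFAULT_SPACING_UM) -> LabelMap:
    """Read a single-channel indexed PNG/TIFF raster as a LabelMap.

    Grid codes are validated against the scheme; an undeclared code raises
    a :class:`ValidationError` naming the code and first offending pixel.
    """
    ext = os.path.splitext(str(path))[1].lower()
    if ext in (".tif", ".tiff"):
        arr = tifffile.imread(str(path))
    else:
        with Image.open(path) as im:
            arr = np.asarray(im)
    if arr.ndim != 2:
        raise FormatError(
            f"label raster must be single-channel, got shape {arr.shape}"
        )
    if not np.issubdtype(arr.dtype, np.integer):
        raise FormatError(f"label raster must be integer-typed, got {arr.dtype}")
    lm = LabelMap(grid=arr.astype(np.int64), spacing_um=spacing_um)
    lm.validate_against(scheme)
    return lm


def write_labelmap(labelmap: LabelMap, path) -> None:
    """Write a LabelMap grid as an indexed raster (PNG or TIFF by extension)."""
    grid = labelmap.grid
    if grid.max(initial=0) > 65535 or grid.min(initial=0) < 0:
        raise ValidationError("class codes must fit an unsigned 16-bit raster")
    dtype = np.uint8 if grid.max(initial=0) <= 255 else np.uint16
    out = grid.astype(dtype)
    ext = os.path.splitext(str(path))[1].lower()
    if ext in (".tif", ".tiff"):
        tifffile.imwrite(str(path), out)
    else:
        Image.fromarray(out).save(path)


# ---------------------------------------------------------------------------
# ROI I/O (GeoJSON FeatureCollection of Points, pixel coordinates)

def write_roi(roi: CircularROI, path) -> None:
    """Write a circular ROI as a GeoJSON Point with a diameter_mm property.

    GeoJSON coordinates are (x, y) = (col, row) in pixel units.
    """
    payload = {
        "type": "FeatureCollection",
        "features": [
            {
                "type": "Feature",
                "geometry": {
                    "type": "Point",
                    "coordinates": [roi.center_col, roi.center_row],
                },
                "properties": {"diameter_mm": roi.diameter_mm},
            }
        ],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)


def read_roi(path) -> CircularROI:
    """Read the first circular ROI from a GeoJSON FeatureCollection."""
    with open(path) as fh:
        payload = json.load(fh)
    try:
        feats = payload["features"]
        if not feats:
            raise FormatError("ROI file contains no features")
        feat = feats[0]
        geom = feat["geometry"]
        if geom["type"] != "Point":
            raise FormatError(f"ROI geometry must be Point, got {geom['type']}")
        col, row = geom["coordinates"]
        diameter = float(feat["properties"]["diameter_mm"])
    except (KeyError, TypeError, ValueError) as exc:
        raise FormatError(f"malformed ROI geometry: {exc}") from exc
    return CircularROI(center_row=int(row), center_col=int(col),
                       diameter_mm=diameter)
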