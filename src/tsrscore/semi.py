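"""Semi-automated TSR: stroma percentage inside a human-selected hot-spot.

The stroma percentage is the fraction of stromal pixels in the circular
field of view after removing mucus, necrosis and background from the
denominator.  Stromal pixels are tumor-associated stroma, lymphocytes,
erythrocytes, muscle, healthy stroma, nerve and stroma lamina propria.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import EmptyROIError, UnassessableROIError
from .labelmap import CircularROI, LabelMap
from .scheme import TissueClassScheme
from .scores import dichotomize


@dataclass(frozen=True)
class TSRResult:
    """A single TSR measurement (semi-automated ROI or automated hot-spot)."""

    stroma_percent: float
    denominator_px: int
    dichotomy: str
    mode: str  # "semi" | "full"
    class_pixel_counts: dict[int, int] = field(default_factory=dict)
    center: tuple[int, int] | None = None
    rank: int | None = None

    def rounded_to_10(self) -> int:
        """The percentage snapped to the visual 10% grid (for comparisons)."""
        return int(min(100, max(0, round(self.stroma_percent / 10.0) * 10)))


def roi_mask(labelmap: LabelMap, roi: CircularROI) -> np.ndarray:
    """Boolean in-grid mask of pixels whose centers fall inside the ROI circle."""
    rows, cols = labelmap.shape
    r = roi.radius_px(labelmap.spacing_um)
    rr = np.arange(rows) - roi.center_row
    cc = np.arange(cols) - roi.center_col
    d2 = rr[:, None].astype(np.int64) ** 2 + cc[None, :].astype(np.int64) ** 2
    mask = d2 <= r * r
    if not mask.any():
        raise EmptyROIError(
            f"ROI centered at ({roi.center_row}, {roi.center_col}) with radius "
            f"{r} px does not intersect the {rows}x{cols} grid"
        )
    return mask


def class_counts(labelmap: LabelMap, roi: CircularROI) -> dict[int, int]:
    """Per-class pixel counts over the ROI circle.

    Counts sum to the number of in-grid circle pixels.
    """
    mask = roi_mask(labelmap, roi)
    values, counts = np.unique(labelmap.grid[mask], return_counts=True)
    return {int(v): int(c) for v, c in zip(values, counts)}


def semi_auto_tsr(labelmap: LabelMap, roi: CircularROI,
                  scheme: TissueClassScheme) -> TSRResult:
    """Semi-automated stroma percentage within the circular hot-spot.

    ``stroma_percent = 100 * stroma_semi / (ROI pixels - excluded)`` where
    excluded classes are mucus, necrosis and background.  An ROI whose
    denominator is empty raises :class:`UnassessableROIError`.
    """
    counts = class_counts(labelmap, roi)
    total = sum(counts.values())
    excluded = scheme.codes_for("denominator_excluded_semi")
    stromal = scheme.codes_for("stroma_semi")
    n_excluded = sum(c for code, c in counts.items() if code in excluded)
    denominator = total - n_excluded
    if denominator <= 0:
        raise UnassessableROIError(
            "ROI contains only mucus, necrosis and/or background; "
            "stroma percentage is undefined"
        )
    n_stroma = sum(c for code, c in counts.items() if code in stromal)
    percent = 100.0 * n_stroma / denominator
    return TSRResult(
        stroma_percent=percent,
        denominator_px=denominator,
        dichotomy=dichotomize(percent),
        mode="semi",
        class_pixel_counts=counts,
        center=(roi.center_row, roi.center_col),
    )
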