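"""TSR heatmap via Fourier-domain convolution, validity rules, hot-spot ranking.

Sliding the circular field of view over the whole slide and counting
class pixels inside it at every position is a convolution of each class
indicator with the binary disc; it is evaluated with FFTs and the result
rounded back to exact integer counts.  The stroma percentage at a center is

    100 * stroma / (stroma + tumor)

with stroma = tumor-associated stroma + lymphocytes + nerve + erythrocytes
and tumor = tumor glands + healthy glands.  Fields failing the nuisance
rules (fat >= 5%, erythrocytes >= 10%, necrosis >= 30% of the disc) are
invalidated, and the top-k hot-spots (TSR-1..TSR-k) are extracted by
iterative maximum selection, zeroing a disc as large as the field of view
around each selection.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.signal import fftconvolve

from .bulk import (
    DEFAULT_CLOSING_RADIUS_MM,
    DEFAULT_MIN_COMPONENT_AREA_MM2,
    _tumor_gland_codes,
    extract_tumor_bulk,
    valid_centers,
)
from .errors import (
    CaseUnassessableError,
    EmptyBulkError,
    NumericalIntegrityError,
)
from .labelmap import (
    DEFAULT_FOV_DIAMETER_MM,
    LabelMap,
    disk_kernel,
    round_half_up,
)
from .scheme import TissueClassScheme
from .scores import dichotomize
from .semi import TSRResult

#: strict upper bounds on nuisance fractions of the field of view
DEFAULT_VALIDITY_THRESHOLDS = {
    "fat": 0.05,
    "erythrocytes": 0.10,
    "necrosis": 0.30,
}

#: tolerated deviation of an FFT count from integer, as fraction of disc area
FFT_INTEGRITY_TOL = 1e-3


@dataclass(frozen=True)
class TSRHeatmap:
    """Per-center stroma percentages with a validity mask.

    ``values`` is NaN wherever ``valid_mask`` is False.
    """

    values: np.ndarray
    valid_mask: np.ndarray
    fov_radius_px: int
    fov_diameter_mm: float
    stride: int = 1

    @property
    def n_valid(self) -> int:
        return int(self.valid_mask.sum())


@dataclass(frozen=True)
class HotSpot:
    rank: int
    center: tuple[int, int]
    stroma_percent: float

    @property
    def label(self) -> str:
        return f"TSR-{self.rank}"


def count_map(grid: np.ndarray, codes: frozenset[int] | set[int],
              radius_px: int) -> np.ndarray:
    """In-disc pixel count of the given codes at every center, via FFT.

    The real-valued convolution is rounded to exact integer counts; a
    deviation beyond ``FFT_INTEGRITY_TOL`` of the disc area raises
    :class:`NumericalIntegrityError`.
    """
    disk = disk_kernel(radius_px).astype(np.float64)
    area = int(disk.sum())
    indicator = np.isin(grid, list(codes)).astype(np.float64)
    raw = fftconvolve(indicator, disk, mode="same")
    rounded = np.rint(raw)
    deviation = np.abs(raw - rounded).max() if raw.size else 0.0
    if deviation > FFT_INTEGRITY_TOL * area:
        raise NumericalIntegrityError(
            f"FFT count deviates from integer by {deviation:.3g} "
            f"(> {FFT_INTEGRITY_TOL} of disc area {area})"
        )
    return np.clip(rounded, 0, area).astype(np.int64)


def nuisance_fraction_maps(
    labelmap: LabelMap,
    scheme: TissueClassScheme,
    radius_px: int,
) -> dict[str, np.ndarray]:
    """Disc-averaged fraction of each nuisance class at every center."""
    area = int(disk_kernel(radius_px).sum())
    out = {}
    for name in ("fat", "erythrocytes", "necrosis"):
        codes = scheme.codes_for(name)
        if codes:
            out[name] = count_map(labelmap.grid, codes, radius_px) / area
        else:
            out[name] = np.zeros(labelmap.shape, dtype=np.float64)
    return out


def tsr_heatmap(
    labelmap: LabelMap,
    centers: np.ndarray,
    scheme: TissueClassScheme,
    fov_diameter_mm: float = DEFAULT_FOV_DIAMETER_MM,
    stride: int = 1,
) -> TSRHeatmap:
    """Stroma-percentage heatmap over the admissible centers.

    ``centers`` is the boolean validity grid from :func:`~tsrscore.bulk.valid_centers`.
    Centers with an empty stroma+tumor denominator are invalidated.  A
    ``stride`` > 1 restricts evaluation to a regular sub-lattice of centers
    (efficiency knob; stride 1 is the reference semantics).
    """
    radius_px = _fov_radius_px(fov_diameter_mm, labelmap.spacing_um)
    valid = centers.copy()
    if stride > 1:
        lattice = np.zeros_like(valid)
        lattice[::stride, ::stride] = True
        valid &= lattice
    stroma = count_map(labelmap.grid, scheme.codes_for("stroma_full"), radius_px)
    tumor = count_map(labelmap.grid, scheme.codes_for("tumor_full"), radius_px)
    denom = stroma + tumor
    valid &= denom > 0
    values = np.full(labelmap.shape, np.nan)
    values[valid] = 100.0 * stroma[valid] / denom[valid]
    return TSRHeatmap(values=values, valid_mask=valid, fov_radius_px=radius_px,
                      fov_diameter_mm=fov_diameter_mm, stride=stride)


def _fov_radius_px(fov_diameter_mm: float, spacing_um: float) -> int:
    r = round_half_up(fov_diameter_mm * 1000.0 / (2.0 * spacing_um))
    if r < 1:
        raise ValueError("field of view below one pixel at this spacing")
    return r


def apply_validity_rules(
    heatmap: TSRHeatmap,
    fraction_maps: dict[str, np.ndarray],
    thresholds: dict[str, float] = DEFAULT_VALIDITY_THRESHOLDS,
) -> TSRHeatmap:
    """Invalidate centers whose nuisance fractions reach their thresholds.

    The bounds are strict: a field at exactly the threshold is invalid
    (fat >= 5%, erythrocytes >= 10%, necrosis >= 30% of the disc area).
    """
    valid = heatmap.valid_mask.copy()
    for name, threshold in thresholds.items():
        if name in fraction_maps:
            valid &= fraction_maps[name] < threshold
    values = np.where(valid, heatmap.values, np.nan)
    return replace(heatmap, values=values, valid_mask=valid)


def top_k_hotspots(heatmap: TSRHeatmap, k: int = 3) -> list[HotSpot]:
    """Iteratively select the k highest-stroma centers with disc suppression.

    Each selection zeroes (invalidates) every center within one field-of-view
    radius of it, so successive hot-spots never overlap by construction.
    Ties break toward the smallest row, then smallest column.  If fewer than
    k centers survive, the shorter list is returned.
    """
    values = heatmap.values.copy()
    valid = heatmap.valid_mask.copy()
    values[~valid] = np.nan
    r = heatmap.fov_radius_px
    rows, cols = values.shape
    spots: list[HotSpot] = []
    for rank in range(1, k + 1):
        if not np.any(valid):
            break
        best = np.nanmax(values)
        # row-major argwhere gives the smallest (row, col) tie-break for free
        br, bc = map(int, np.argwhere(values == best)[0])
        spots.append(HotSpot(rank=rank, center=(br, bc), stroma_percent=float(best)))
        r0, r1 = max(0, br - r), min(rows, br + r + 1)
        c0, c1 = max(0, bc - r), min(cols, bc + r + 1)
        rr = np.arange(r0, r1) - br
        cc = np.arange(c0, c1) - bc
        suppress = rr[:, None] ** 2 + cc[None, :] ** 2 <= r * r
        valid[r0:r1, c0:c1] &= ~suppress
        values[r0:r1, c0:c1][suppress] = np.nan
    return spots


def fully_auto_tsr(
    labelmap: LabelMap,
    scheme: TissueClassScheme,
    fov_diameter_mm: float = DEFAULT_FOV_DIAMETER_MM,
    k: int = 3,
    min_component_area_mm2: float = DEFAULT_MIN_COMPONENT_AREA_MM2,
    closing_radius_mm: float = DEFAULT_CLOSING_RADIUS_MM,
    thresholds: dict[str, float] = DEFAULT_VALIDITY_THRESHOLDS,
    stride: int = 1,
) -> list[TSRResult]:
    """Fully automated TSR: bulk -> valid centers -> heatmap -> rules -> top-k.

    Returns one :class:`~tsrscore.semi.TSRResult` (mode ``"full"``) per
    hot-spot, ranked TSR-1..TSR-k by decreasing stroma percentage.

    Raises
    ------
    EmptyBulkError
        No tumor glands on the slide.
    CaseUnassessableError
        The tumor bulk is too narrow to fit the circular field of view, or
        every candidate center fails the validity rules.
    """
    try:
        bulk = extract_tumor_bulk(labelmap, scheme,
                                  min_component_area_mm2=min_component_area_mm2,
                                  closing_radius_mm=closing_radius_mm)
    except EmptyBulkError:
        if not np.isin(labelmap.grid, list(_tumor_gland_codes(scheme))).any():
            raise  # truly no tumor on the slide
        raise CaseUnassessableError(
            "tumor area smaller than the minimum bulk area; too narrow "
            "for automated assessment"
        ) from None
    radius_px = _fov_radius_px(fov_diameter_mm, labelmap.spacing_um)
    centers = valid_centers(bulk, labelmap, scheme, radius_px)
    if not centers.any():
        raise CaseUnassessableError(
            f"tumor bulk too narrow to fit the {fov_diameter_mm} mm "
            "circular field of view"
        )
    hm = tsr_heatmap(labelmap, centers, scheme, fov_diameter_mm, stride=stride)
    fractions = nuisance_fraction_maps(labelmap, scheme, radius_px)
    hm = apply_validity_rules(hm, fractions, thresholds)
    if hm.n_valid == 0:
        raise CaseUnassessableError(
            "no field of view passes the tissue-validity rules"
        )
    spots = top_k_hotspots(hm, k=k)
    results = []
    for s in spots:
        counts = _counts_at(labelmap.grid, s.center, radius_px)
        denom = sum(c for code, c in counts.items()
                    if code in scheme.codes_for("stroma_full")
                    or code in scheme.codes_for("tumor_full"))
        results.append(TSRResult(
            stroma_percent=s.stroma_percent,
            denominator_px=denom,
            dichotomy=dichotomize(s.stroma_percent),
            mode="full",
            center=s.center,
            rank=s.rank,
            class_pixel_counts=counts,
        ))
    return results


def _counts_at(grid: np.ndarray, center: tuple[int, int],
               radius_px: int) -> dict[int, int]:
    """Exact per-class tally inside the disc at one center (direct, no FFT)."""
    br, bc = center
    rows, cols = grid.shape
    r0, r1 = max(0, br - radius_px), min(rows, br + radius_px + 1)
    c0, c1 = max(0, bc - radius_px), min(cols, bc + radius_px + 1)
    rr = np.arange(r0, r1) - br
    cc = np.arange(c0, c1) - bc
    disk = rr[:, None] ** 2 + cc[None, :] ** 2 <= radius_px * radius_px
    values, counts = np.unique(grid[r0:r1, c0:c1][disk], return_counts=True)
    return {int(v): int(c) for v, c in zip(values, counts)}
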