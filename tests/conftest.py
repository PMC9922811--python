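import numpy as np
import pytest

from tsrscore import CircularROI, LabelMap, default_scheme


@pytest.fixture(scope="session")
def scheme():
    return default_scheme()


def make_map(grid, spacing_um=20.0) -> LabelMap:
    return LabelMap(grid=np.asarray(grid, dtype=np.int64), spacing_um=spacing_um)


def uniform_map(shape, code, spacing_um=20.0) -> LabelMap:
    return make_map(np.full(shape, code, dtype=np.int64), spacing_um)


def roi_px(center_row, center_col, radius_px, spacing_um=20.0) -> CircularROI:
    """ROI whose pixel radius is exactly radius_px at the given spacing."""
    return CircularROI(center_row=center_row, center_col=center_col,
                       diameter_mm=2 * radius_px * spacing_um / 1000.0)


def brute_force_class_counts(grid, center_row, center_col, radius_px):
    """Independent per-pixel tally oracle: plain loop over the whole grid."""
    counts = {}
    r2 = radius_px * radius_px
    for row in range(grid.shape[0]):
        for col in range(grid.shape[1]):
            if (row - center_row) ** 2 + (col - center_col) ** 2 <= r2:
                code = int(grid[row, col])
                counts[code] = counts.get(code, 0) + 1
    return counts


def fill_disc_exact(grid, center, radius_px, codes_and_counts):
    """Assign disc pixels (ordered by distance, then row, col) to codes with
    exact counts; the counts must sum to the disc pixel count."""
    rows, cols = grid.shape
    cr, cc = center
    pix = []
    r2 = radius_px * radius_px
    for row in range(max(0, cr - radius_px), min(rows, cr + radius_px + 1)):
        for col in range(max(0, cc - radius_px), min(cols, cc + radius_px + 1)):
            d2 = (row - cr) ** 2 + (col - cc) ** 2
            if d2 <= r2:
                pix.append((d2, row, col))
    pix.sort()
    total = sum(n for _, n in codes_and_counts)
    assert total == len(pix), f"counts {total} != disc area {len(pix)}"
    i = 0
    for code, n in codes_and_counts:
        for _, row, col in pix[i:i + n]:
            grid[row, col] = code
        i += n
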