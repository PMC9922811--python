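"""Synthetic label maps and rater tables with analytic ground truth.

The generator emulates the structure the fully automated pipeline assumes:
a single contiguous tumor blob whose interior mixes tumor glands and
tumor-associated stroma according to a planted, spatially varying stroma
fraction (base level plus Gaussian bumps), optional nuisance patches (fat,
erythrocytes, necrosis) with exactly constructible pixel counts, and
background outside the blob.  In-blob labels are drawn per-pixel Bernoulli
from the local planted fraction, so the expected in-disc stroma fraction is
the disc mean of the analytic field and recovery tolerances are derivable.

Observer tables are simulated as truth + per-rater bias + Gaussian noise,
snapped to the visual 10% grid.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import fftconvolve

from .bulk import erode_disk
from .errors import ValidationError
from .labelmap import LabelMap, disk_kernel, mm_to_px
from .scheme import TissueClassScheme, default_scheme
from .scores import NEEDS_MEETING, ObserverTable, dichotomize
from .stats import consensus_score


@dataclass(frozen=True)
class GaussianBump:
    """A local excess of stroma: peak amplitude added at (row, col), decaying
    with Gaussian radius sigma_mm."""

    row: int
    col: int
    amplitude: float
    sigma_mm: float


@dataclass(frozen=True)
class NuisancePatch:
    """A solid patch of exactly n_pixels of one nuisance class, grown from
    (row, col) by distance order — in-disc fractions are exactly known."""

    class_name: str
    row: int
    col: int
    n_pixels: int


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of a synthetic slide.

    Defaults model a scaled-down colon-resection slide: a 4 mm square at
    16 μm/pixel working resolution with one 1.6 mm-radius tumor blob whose
    stroma fraction is 0.45 at baseline with a planted hot-spot bump.
    """

    shape: tuple[int, int] = (256, 256)
    spacing_um: float = 16.0
    blob_center: tuple[int, int] = (128, 128)
    blob_radius_mm: float = 1.6
    boundary_roughness: float = 0.04
    base_stroma_fraction: float = 0.45
    bumps: tuple[GaussianBump, ...] = (
        GaussianBump(row=100, col=104, amplitude=0.30, sigma_mm=0.60),
    )
    patches: tuple[NuisancePatch, ...] = ()
    label_noise_rate: float = 0.0
    seed: int = 0

    def blob_radius_px(self) -> int:
        return mm_to_px(self.blob_radius_mm, self.spacing_um)


@dataclass(frozen=True)
class GroundTruth:
    """Analytic truth accompanying a generated label map."""

    fraction_field: np.ndarray  # planted stroma fraction, NaN outside blob
    blob_mask: np.ndarray
    smoothed: np.ndarray  # disc-mean of the field, NaN where disc not inside
    argmax_center: tuple[int, int]
    argmax_percent: float
    fov_radius_px: int


def plant_pixels(grid: np.ndarray, center: tuple[int, int], n_pixels: int,
                 code: int) -> None:
    """Stamp exactly n_pixels of ``code`` nearest to ``center`` (in place).

    Pixels are taken in order of squared distance, then row, then column,
    so the planted count is exact and deterministic.
    """
    rows, cols = grid.shape
    r = int(math.isqrt(n_pixels)) + 2
    while True:
        r0, r1 = max(0, center[0] - r), min(rows, center[0] + r + 1)
        c0, c1 = max(0, center[1] - r), min(cols, center[1] + r + 1)
        rr, cc = np.mgrid[r0:r1, c0:c1]
        d2 = (rr - center[0]) ** 2 + (cc - center[1]) ** 2
        flat = np.stack([d2.ravel(), rr.ravel(), cc.ravel()], axis=1)
        if len(flat) >= n_pixels:
            order = np.lexsort((flat[:, 2], flat[:, 1], flat[:, 0]))
            chosen = flat[order[:n_pixels]]
            if chosen[-1, 0] < r * r or (r1 - r0) == rows and (c1 - c0) == cols:
                grid[chosen[:, 1], chosen[:, 2]] = code
                return
        if (r1 - r0) == rows and (c1 - c0) == cols:
            raise ValidationError("patch larger than the grid")
        r *= 2


def _blob_mask(spec: SyntheticSpec, rng: np.random.Generator) -> np.ndarray:
    """Roughened disc: radius modulated by a low-order Fourier series in angle."""
    rows, cols = spec.shape
    radius = spec.blob_radius_px()
    max_radius = radius * (1.0 + spec.boundary_roughness)
    cr, cc = spec.blob_center
    if (cr - max_radius < 0 or cc - max_radius < 0
            or cr + max_radius >= rows or cc + max_radius >= cols):
        raise ValidationError("tumor blob does not fit the grid")
    rr = np.arange(rows) - cr
    cc_ = np.arange(cols) - cc
    d = np.hypot(rr[:, None], cc_[None, :])
    theta = np.arctan2(rr[:, None], cc_[None, :])
    modulation = np.zeros_like(theta)
    if spec.boundary_roughness > 0:
        n_harmonics = 4
        amp = rng.normal(0.0, 1.0, size=(n_harmonics, 2))
        for h in range(n_harmonics):
            modulation += (amp[h, 0] * np.cos((h + 2) * theta)
                           + amp[h, 1] * np.sin((h + 2) * theta))
        scale = np.abs(modulation).max()
        if scale > 0:
            modulation *= spec.boundary_roughness / scale
    return d <= radius * (1.0 + modulation)


def _fraction_field(spec: SyntheticSpec) -> np.ndarray:
    rows, cols = spec.shape
    f = np.full(spec.shape, spec.base_stroma_fraction, dtype=np.float64)
    rr = np.arange(rows)
    cc = np.arange(cols)
    for bump in spec.bumps:
        sigma_px = bump.sigma_mm * 1000.0 / spec.spacing_um
        d2 = ((rr - bump.row)[:, None] ** 2 + (cc - bump.col)[None, :] ** 2)
        f += bump.amplitude * np.exp(-d2 / (2.0 * sigma_px**2))
    return np.clip(f, 0.0, 1.0)


def generate_labelmap(
    spec: SyntheticSpec,
    scheme: TissueClassScheme | None = None,
    fov_diameter_mm: float = 2.0,
) -> tuple[LabelMap, GroundTruth]:
    """Generate a label map and its analytic ground truth.

    In-blob pixels are tumor-associated stroma with probability given by
    the planted fraction field, tumor glands otherwise; nuisance patches
    are stamped afterwards; everything outside the blob is background.
    The ground truth carries the analytic field and the location/value of
    the maximum of its disc-smoothed version over centers whose disc lies
    fully inside the blob (the planted optimum the automated pipeline
    should recover).
    """
    scheme = scheme or default_scheme()
    rng = np.random.default_rng(spec.seed)
    blob = _blob_mask(spec, rng)
    f = _fraction_field(spec)

    stroma_code = scheme.code_of("tumor-associated stroma")
    tumor_code = scheme.code_of("tumor glands")
    background = scheme.background_code
    draw = rng.random(spec.shape)
    p = f
    if spec.label_noise_rate > 0:
        # a flat label-flip rate shifts the effective fraction toward 0.5
        p = f * (1 - spec.label_noise_rate) + (1 - f) * spec.label_noise_rate
    grid = np.where(blob, np.where(draw < p, stroma_code, tumor_code),
                    background).astype(np.int64)
    for patch in spec.patches:
        plant_pixels(grid, (patch.row, patch.col), patch.n_pixels,
                     scheme.code_of(patch.class_name))

    labelmap = LabelMap(grid=grid, spacing_um=spec.spacing_um)

    fov_radius = mm_to_px(fov_diameter_mm / 2.0, spec.spacing_um)
    disk = disk_kernel(fov_radius).astype(np.float64)
    area = disk.sum()
    smoothed = fftconvolve(f, disk, mode="same") / area
    inside = erode_disk(blob, fov_radius)
    smoothed = np.where(inside, smoothed, np.nan)
    if inside.any():
        best = np.nanmax(smoothed)
        argmax = tuple(int(v) for v in np.argwhere(smoothed == best)[0])
        best_pct = 100.0 * float(best)
    else:
        argmax, best_pct = (-1, -1), float("nan")
    field = np.where(blob, f, np.nan)
    truth = GroundTruth(
        fraction_field=field, blob_mask=blob, smoothed=smoothed,
        argmax_center=argmax, argmax_percent=best_pct,
        fov_radius_px=fov_radius,
    )
    return labelmap, truth


@dataclass(frozen=True)
class RaterNoiseModel:
    """Per-rater additive bias and Gaussian noise (percent scale).

    Default: 3 interchangeable raters with a 5-point scoring noise, the
    regime in which most cases reach a 2-of-3 majority but occasional
    all-distinct cases still require a consensus meeting.
    """

    biases: tuple[float, ...] = (0.0, 0.0, 0.0)
    sds: tuple[float, ...] = (5.0, 5.0, 5.0)

    def __post_init__(self) -> None:
        if len(self.biases) != len(self.sds) or len(self.biases) < 1:
            raise ValidationError("biases and sds must have equal length >= 1")

    @property
    def n_raters(self) -> int:
        return len(self.biases)


def round_to_10(value: float) -> int:
    """Snap a percentage to the visual 10% grid, clamped to [0, 100]."""
    return int(min(100, max(0, round(value / 10.0) * 10)))


def generate_observer_table(
    true_percents,
    noise: RaterNoiseModel = RaterNoiseModel(),
    seed: int = 0,
) -> ObserverTable:
    """Simulate per-case rater scores around the true stroma percentages.

    Each rater reports ``clamp(round_to_10(truth + bias + N(0, sd)))``; the
    consensus column applies the 2-of-3 majority rule and unresolved cases
    are flagged ``needs_meeting``.
    """
    rng = np.random.default_rng(seed)
    true_percents = np.asarray(true_percents, dtype=float)
    rows = []
    for i, truth in enumerate(true_percents):
        scores = [
            round_to_10(truth + noise.biases[j] + rng.normal(0.0, noise.sds[j]))
            for j in range(noise.n_raters)
        ]
        consensus = consensus_score(scores) if noise.n_raters >= 3 else scores[0]
        row = {"case_id": f"case{i + 1:03d}"}
        row.update({f"rater{j + 1}": s for j, s in enumerate(scores)})
        row["consensus"] = consensus
        row["dichotomy"] = (dichotomize(float(consensus))
                            if consensus != NEEDS_MEETING else "")
        rows.append(row)
    return ObserverTable(data=pd.DataFrame(rows))
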