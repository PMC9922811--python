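# Methods

This note documents the scoring model, the numerical conventions, the
synthetic-data model, and the design choices that were genuinely open.

## Spatial conventions

Coordinates are 0-based, row-major, pixel-center. Physical lengths convert
to pixels through the map's `spacing_um` (μm/pixel, default 0.5 — the 20×
processing resolution of whole-slide segmentation output) with
round-half-up. A circle of radius *r* pixels contains every pixel whose
center lies at Euclidean distance ≤ *r* from the center pixel; at the
default 2.0 mm field of view and 0.5 μm/px this gives *r* = 2000 px. All
examples and tests use coarser spacings (16–20 μm/px) so that slides stay a
few hundred pixels wide; every algorithm is resolution-independent, and the
tests exercise multiple spacings.

Background is a first-class tissue code, not missing data; tissue tears are
represented as background. Rasters are flat single-channel indexed images
(no pyramids); the package starts at the label map and never touches the
stained image.

## Semi-automated score

Within the pathologist's circular ROI, the stroma percentage is

    100 · Σ counts(stroma_semi) / (|ROI| − Σ counts(mucus, necrosis, background))

with the seven-class semi-mode stroma set listed in the README. Fatty
tissue stays in the denominator: the exclusion list is exactly mucus,
necrosis and background; the visual protocol's avoidance of fat-rich areas
is a field-*selection* rule, not part of the formula. An ROI whose
denominator is empty is a distinct `UnassessableROIError`. The percentage
is reported at full precision with a `rounded_to_10()` view for comparison
against visual scores (which live on the 10% grid); which of the two a
study should correlate against visual estimates is a user decision, so both
are exposed.

## Fully automated score

**Tumor bulk.** The bulk must enclose all tumor glands including the
invasive edge. No canonical "concave hull" exists for raster masks, so the
bulk is operationalized as: closing of the tumor-gland mask with a disc
(default radius 1.0 mm = one FOV radius) → hole filling → removal of
connected components (8-connectivity) with area < π·(1.0 mm)² (one FOV
area). Both parameters are configurable and degrade gracefully to plain
filled components at 0. Components smaller than the minimum are treated as
false-positive specks.

**Morphology implementation.** Disc erosions/dilations are computed as FFT
disc-count thresholds (erosion: in-disc count of the mask equals the disc
area; dilation: count > 0), which is exact after integer rounding and
orders of magnitude faster than structure-based morphology at 2 mm disc
radii. The test suite pins equality with `scipy.ndimage` morphology on
small masks. Border semantics: in `valid_centers` the outside of the grid
counts as *invalid* (a field of view must lie wholly on the slide), but the
erosion half of the bulk *closing* treats out-of-grid as filled — otherwise
a tumor reaching the slide border would be shaved back by one closing
radius, an artifact observed during development on blobs near the raster
edge.

**Heatmap.** Per-class in-disc counts at every center are convolutions of
the class indicator with the binary disc, evaluated with `fftconvolve` and
rounded to the nearest integer; a deviation from integer larger than 10⁻³
of the disc area raises a `NumericalIntegrityError` (float64 FFTs on
realistic grids deviate by ~10⁻⁹ of a count, so a trip indicates a real
defect). Negative ringing artifacts are clipped at 0, counts capped at the
disc area. The ratio uses the full-mode class sets only: stroma =
tumor-associated stroma + lymphocytes + nerve + erythrocytes, tumor =
tumor glands + healthy glands (healthy glands within a bulk are in practice
well-differentiated tumor glands). Muscle and healthy stroma are stromal in
the *semi* formula but deliberately absent here; the two groupings are kept
distinct rather than unified because each scoring mode defines its own
tissue sets. Centers whose stroma+tumor denominator is zero are invalid.
A `stride` option evaluates only a sub-lattice of centers for very large
slides; stride 1 is the reference semantics and the one all oracle tests
pin.

**Validity rules.** Fractions are relative to the full disc area (the
erosion step already guarantees no background inside a valid field).
Thresholds are strict: fat ≥ 5%, erythrocytes ≥ 10%, necrosis ≥ 30%
invalidate the field — a field at exactly a threshold is excluded.

**Ranking.** Hot-spots are selected by iterative maximum; after each pick,
all centers within one FOV radius of it are invalidated ("zeroing a region
as large as the field of view"). The zeroed region is a disc, for geometric
consistency with the field itself. Ties break to the smallest row, then
column, making outputs byte-reproducible. Fewer than *k* surviving spots is
a valid outcome, not an error. Failure paths are distinct: a slide with no
tumor glands at all raises `EmptyBulkError`; a slide whose tumor is too
small or narrow to fit the 2.0 mm field raises `CaseUnassessableError`
(the automated analogue of a case a study must exclude).

## Agreement statistics

* **Consensus**: the modal score when a strict majority of raters agrees
  (2 of 3); otherwise the case is flagged `needs_meeting` and never
  auto-resolved. Flagged cases are excluded from statistics unless a
  resolved value is supplied.
* **Dichotomy**: stroma-low iff ≤ 50%; the cut-off is configurable.
* **Cohen's κ**: unweighted, on the binary labels, implemented directly
  from the marginal-product expected agreement (cross-checked against
  scikit-learn in the tests). Degenerate marginals (pₑ = 1) are an error,
  not a NaN.
* **ICC**: no single "the ICC" exists; this package uses ICC(2,1) —
  two-way random effects, absolute agreement, single measures — the
  standard choice for interchangeable human raters where the clinical
  question is *same percentage*, not same ranking. The 95% CI uses the
  F-distribution bounds with Satterthwaite denominator degrees of freedom;
  the model name is embedded in every report. Cross-checked against
  pingouin's ICC(A,1) row, and calibration-tested: on simulated data with
  known variance components the CI covers the true ICC in ≈95% of
  replicates.
* **Spearman**: scipy's tie-aware implementation (mid-ranks, t-approximation
  p-value); appropriate at the n≈75 scale of observer studies, no exact
  permutation test.
* **Bland–Altman**: mean difference ± 1.96·SD (ddof = 1) of paired
  differences. **t-tests**: scipy paired/two-sample; a paired test with
  zero-variance differences raises rather than returning NaN.

## Synthetic-data model

A slide is a roughened disc ("tumor blob": radius modulated by a seeded
low-order Fourier series in angle, default roughness 4%) on a background
grid. Inside the blob a planted stroma-fraction field *f* (base 0.45 plus
Gaussian bumps, default one bump of amplitude 0.30 and σ = 0.6 mm) drives
per-pixel Bernoulli labels: tumor-associated stroma with probability *f*,
tumor glands otherwise. Per-pixel labeling (rather than smooth regions)
makes expected counts analytic: the expected in-field stroma share at a
center is exactly the disc mean of *f*, with binomial noise
σ ≈ √(0.25/A) ≈ 0.45 pp at the default disc area A ≈ 12 500 px. The ground
truth records the disc-smoothed field (convolution of the analytic field,
independent of the label realization) and its argmax over centers whose
disc lies inside the blob — the planted optimum the pipeline should
recover. Defaults (4.1 mm slide at 16 μm/px, blob radius 1.6 mm, hot-spot
scale comparable to the 2.0 mm field) were chosen once as a realistic
scaled-down resection slide; the generator is deterministic per seed.

Nuisance patches (fat/erythrocytes/necrosis) are stamped as exact pixel
counts grown by distance order, so validity-rule boundary cases (4% vs 6%
fat, etc.) are constructible exactly. Misclassification noise is available
only as a flat label-flip rate (shifting the effective fraction toward
0.5); the generator does not emulate structured segmentation errors, stain
variation, or tissue texture — so passing tests demonstrate correctness of
the *scoring* given a label map, not robustness to upstream segmentation
error.

Observer tables are truth + per-rater bias + Gaussian noise snapped to the
10% grid (default three unbiased raters, σ = 5 pp — a regime where most
cases reach a 2-of-3 majority and a few per 75 need a consensus meeting).

## Problem sizes

Tests and the acceptance script run on 41²–512² grids at 16–20 μm/px with
FOV radii of 10–63 px, 50-replicate recovery batches, and 500-replicate
ICC calibration at 30 cases × 3 raters; these sizes make the whole suite
run in well under a minute while keeping disc areas large enough (≥ 300 px)
for the analytic tolerances above to be meaningful.

## Known limitations

* The bulk post-processing is a deterministic morphological stand-in for
  the loosely specified "concave hull" idea; different parameters change
  which narrow tumor regions survive.
* Heatmap values are continuous; any comparison against visual scores on
  the 10% grid must choose raw or rounded values (both are exposed).
* The statistics module assumes complete case × rater matrices; missing
  scores must be handled upstream.
* No survival modelling: the package measures agreement between scoring
  methods, not prognostic value.
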