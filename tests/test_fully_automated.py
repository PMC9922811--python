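import numpy as np
import pytest
from scipy import ndimage

from tsrscore import (
    CaseUnassessableError,
    EmptyBulkError,
    NumericalIntegrityError,
    SyntheticSpec,
    TSRHeatmap,
    apply_validity_rules,
    count_map,
    disk_kernel,
    extract_tumor_bulk,
    fully_auto_tsr,
    generate_labelmap,
    nuisance_fraction_maps,
    top_k_hotspots,
    tsr_heatmap,
    valid_centers,
)
from tsrscore.bulk import close_disk, dilate_disk, erode_disk

from conftest import fill_disc_exact, make_map, uniform_map


def solid_disc_mask(shape, center, radius):
    rr = np.arange(shape[0]) - center[0]
    cc = np.arange(shape[1]) - center[1]
    return rr[:, None] ** 2 + cc[None, :] ** 2 <= radius * radius


class TestFFTMorphology:
    """The FFT disc-count morphology must agree with scipy.ndimage exactly."""

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_erode_dilate_match_ndimage(self, seed):
        rng = np.random.default_rng(seed)
        mask = rng.random((60, 70)) < 0.5
        disk = disk_kernel(4)
        np.testing.assert_array_equal(
            erode_disk(mask, 4),
            ndimage.binary_erosion(mask, structure=disk, border_value=0))
        np.testing.assert_array_equal(
            dilate_disk(mask, 4),
            ndimage.binary_dilation(mask, structure=disk, border_value=0))

    def test_close_matches_padded_ndimage(self):
        rng = np.random.default_rng(3)
        mask = rng.random((50, 50)) < 0.4
        disk = disk_kernel(3)
        dil = ndimage.binary_dilation(mask, structure=disk, border_value=0)
        ref = ndimage.binary_erosion(dil, structure=disk, border_value=1)
        np.testing.assert_array_equal(close_disk(mask, 3), ref)


class TestExtractTumorBulk:
    def test_solid_disc_closed_and_filled(self, scheme):
        """A solid 1.5 mm tumor disc comes back as (at least) that disc."""
        grid = np.zeros((200, 200), dtype=np.int64)
        disc = solid_disc_mask((200, 200), (100, 100), 75)  # 1.5mm at 20um/px
        grid[disc] = scheme.code_of("tumor glands")
        lm = make_map(grid, spacing_um=20.0)
        bulk = extract_tumor_bulk(lm, scheme, min_component_area_mm2=0.1,
                                  closing_radius_mm=0.2)
        assert bulk.component_count == 1
        assert np.all(bulk.mask[disc])

    def test_small_speck_removed(self, scheme):
        """An isolated 10-pixel tumor speck is dropped; the disc survives.

        Minimum component area is one FOV area pi*(1 mm)^2 = 7854 px at
        20 um/px, far above the speck and below the 1.5 mm disc (~17671 px).
        """
        grid = np.zeros((300, 300), dtype=np.int64)
        tumor = scheme.code_of("tumor glands")
        disc = solid_disc_mask((300, 300), (100, 100), 75)
        grid[disc] = tumor
        grid[280, 280:290] = tumor  # 10-pixel speck, far from the disc
        lm = make_map(grid, spacing_um=20.0)
        bulk = extract_tumor_bulk(lm, scheme, closing_radius_mm=0.2)
        assert bulk.component_count == 1
        assert not bulk.mask[280, 285]
        assert bulk.mask[100, 100]

    def test_annulus_hole_filled(self, scheme):
        grid = np.zeros((200, 200), dtype=np.int64)
        outer = solid_disc_mask((200, 200), (100, 100), 70)
        inner = solid_disc_mask((200, 200), (100, 100), 40)
        grid[outer & ~inner] = scheme.code_of("tumor glands")
        grid[inner] = scheme.code_of("tumor-associated stroma")
        lm = make_map(grid, spacing_um=20.0)
        bulk = extract_tumor_bulk(lm, scheme, min_component_area_mm2=0.1,
                                  closing_radius_mm=0.0)
        assert bulk.mask[100, 100]  # stroma core enclosed by the gland ring

    def test_no_tumor_raises(self, scheme):
        with pytest.raises(EmptyBulkError):
            extract_tumor_bulk(uniform_map((64, 64), 0), scheme)

    def test_zero_parameters_degrade_gracefully(self, scheme):
        grid = np.zeros((64, 64), dtype=np.int64)
        grid[10:20, 10:20] = scheme.code_of("tumor glands")
        lm = make_map(grid, spacing_um=20.0)
        bulk = extract_tumor_bulk(lm, scheme, min_component_area_mm2=0.0,
                                  closing_radius_mm=0.0)
        np.testing.assert_array_equal(bulk.mask, grid > 0)


class TestValidCenters:
    def test_erosion_identity_single_center(self, scheme):
        """Bulk = disc of exactly the FOV radius -> only its center valid."""
        stroma = scheme.code_of("tumor-associated stroma")
        lm = uniform_map((41, 41), stroma, spacing_um=20.0)
        disc = solid_disc_mask((41, 41), (20, 20), 10)
        from tsrscore import TumorBulkMask
        bulk = TumorBulkMask(mask=disc, component_count=1)
        centers = valid_centers(bulk, lm, scheme, 10)
        assert centers.sum() == 1
        assert centers[20, 20]

    def test_too_small_bulk_no_centers(self, scheme):
        stroma = scheme.code_of("tumor-associated stroma")
        lm = uniform_map((41, 41), stroma, spacing_um=20.0)
        from tsrscore import TumorBulkMask
        bulk = TumorBulkMask(mask=solid_disc_mask((41, 41), (20, 20), 8),
                             component_count=1)
        assert valid_centers(bulk, lm, scheme, 10).sum() == 0

    def test_background_in_disc_invalidates(self, scheme):
        stroma = scheme.code_of("tumor-associated stroma")
        grid = np.full((41, 41), stroma, dtype=np.int64)
        grid[20, 25] = scheme.background_code  # tissue tear inside the disc
        lm = make_map(grid, spacing_um=20.0)
        from tsrscore import TumorBulkMask
        bulk = TumorBulkMask(mask=solid_disc_mask((41, 41), (20, 20), 10),
                             component_count=1)
        assert valid_centers(bulk, lm, scheme, 10).sum() == 0

    def test_matches_brute_force(self, scheme):
        """Every center checked exhaustively against the definition."""
        rng = np.random.default_rng(9)
        blob = ndimage.binary_dilation(rng.random((48, 48)) < 0.02,
                                       structure=disk_kernel(6))
        grid = np.where(blob, scheme.code_of("tumor-associated stroma"),
                        0).astype(np.int64)
        # plant a few background tears inside the blob
        tears = rng.random((48, 48)) < 0.01
        grid[blob & tears] = 0
        lm = make_map(grid, spacing_um=20.0)
        from tsrscore import TumorBulkMask
        bulk = TumorBulkMask(mask=blob, component_count=1)
        r = 5
        centers = valid_centers(bulk, lm, scheme, r)
        disk = disk_kernel(r)
        for row in range(48):
            for col in range(48):
                ok = True
                for dr in range(-r, r + 1):
                    for dc in range(-r, r + 1):
                        if not disk[dr + r, dc + r]:
                            continue
                        rr, cc = row + dr, col + dc
                        if not (0 <= rr < 48 and 0 <= cc < 48):
                            ok = False
                        elif not blob[rr, cc] or grid[rr, cc] == 0:
                            ok = False
                        if not ok:
                            break
                    if not ok:
                        break
                assert centers[row, col] == ok, (row, col)


class TestHeatmap:
    def test_uniform_stroma_all_100(self, scheme):
        lm = uniform_map((64, 64), scheme.code_of("tumor-associated stroma"),
                         spacing_um=20.0)
        centers = np.zeros((64, 64), dtype=bool)
        centers[20:40, 20:40] = True
        hm = tsr_heatmap(lm, centers, scheme, fov_diameter_mm=0.4)  # r=10px
        assert np.all(hm.values[centers] == 100.0)

    def test_planted_70_percent_disc(self, scheme):
        """A disc whose stroma_full share among stroma+tumor is exactly 0.7
        reads 70.0 at its center."""
        area = int(disk_kernel(10).sum())  # 317
        # choose counts summing to area with an exact 0.7 ratio among a+b
        a, b = 217, 93  # a/(a+b) = 0.7, a+b=310, rest fat (not in ratio)
        assert a / (a + b) == 0.7
        grid = np.zeros((41, 41), dtype=np.int64)
        fill_disc_exact(grid, (20, 20), 10, [
            (scheme.code_of("tumor-associated stroma"), a),
            (scheme.code_of("tumor glands"), b),
            (scheme.code_of("fatty tissue"), area - a - b),
        ])
        lm = make_map(grid, spacing_um=20.0)
        centers = np.zeros((41, 41), dtype=bool)
        centers[20, 20] = True
        hm = tsr_heatmap(lm, centers, scheme, fov_diameter_mm=0.4)
        assert hm.values[20, 20] == pytest.approx(70.0)

    @pytest.mark.parametrize("seed,size,radius", [(0, 96, 5), (1, 128, 13)])
    def test_fft_equals_spatial_convolution(self, scheme, seed, size, radius):
        """The FFT counting path agrees exactly with direct spatial
        correlation for every class group and every center."""
        rng = np.random.default_rng(seed)
        grid = rng.integers(0, 13, size=(size, size))
        disk = disk_kernel(radius).astype(np.int64)
        for group in ("stroma_full", "tumor_full", "fat", "necrosis"):
            codes = scheme.codes_for(group)
            fft = count_map(grid, codes, radius)
            ref = ndimage.correlate(
                np.isin(grid, list(codes)).astype(np.int64), disk,
                mode="constant", cval=0)
            np.testing.assert_array_equal(fft, ref)

    def test_zero_denominator_invalidated(self, scheme):
        lm = uniform_map((41, 41), scheme.code_of("fatty tissue"),
                         spacing_um=20.0)
        centers = np.ones((41, 41), dtype=bool)
        hm = tsr_heatmap(lm, centers, scheme, fov_diameter_mm=0.4)
        assert hm.n_valid == 0

    def test_integrity_check_trips_on_corrupt_convolution(self, scheme,
                                                          monkeypatch):
        import tsrscore.heatmap as hmod

        def bad_conv(a, b, mode="same"):
            from scipy.signal import fftconvolve
            return fftconvolve(a, b, mode=mode) + 0.4
        monkeypatch.setattr(hmod, "fftconvolve", bad_conv)
        with pytest.raises(NumericalIntegrityError):
            count_map(np.ones((32, 32), dtype=np.int64), {1}, 5)


class TestValidityRules:
    def _heatmap(self, shape=(5, 5)):
        values = np.full(shape, 50.0)
        return TSRHeatmap(values=values, valid_mask=np.ones(shape, bool),
                          fov_radius_px=10, fov_diameter_mm=0.4)

    @pytest.mark.parametrize("name,frac,expect_valid", [
        ("fat", 0.04, True), ("fat", 0.06, False),
        ("erythrocytes", 0.09, True), ("erythrocytes", 0.11, False),
        ("necrosis", 0.29, True), ("necrosis", 0.31, False),
    ])
    def test_boundaries(self, name, frac, expect_valid):
        hm = self._heatmap()
        fractions = {k: np.zeros((5, 5)) for k in
                     ("fat", "erythrocytes", "necrosis")}
        fractions[name][:] = frac
        out = apply_validity_rules(hm, fractions)
        assert bool(out.valid_mask[2, 2]) is expect_valid

    def test_exact_threshold_is_invalid(self):
        """Strict '<' semantics: a field at exactly 30% necrosis is invalid."""
        hm = self._heatmap()
        fractions = {"fat": np.zeros((5, 5)),
                     "erythrocytes": np.zeros((5, 5)),
                     "necrosis": np.full((5, 5), 0.30)}
        out = apply_validity_rules(hm, fractions)
        assert out.n_valid == 0

    def test_all_below_thresholds_untouched(self):
        hm = self._heatmap()
        fractions = {"fat": np.full((5, 5), 0.04),
                     "erythrocytes": np.full((5, 5), 0.09),
                     "necrosis": np.full((5, 5), 0.29)}
        out = apply_validity_rules(hm, fractions)
        assert out.n_valid == 25
        np.testing.assert_array_equal(out.values, hm.values)

    def test_planted_nuisance_fraction_maps(self, scheme):
        """A patch of exactly k fat pixels in the FOV yields fraction k/area."""
        from tsrscore import plant_pixels
        area = int(disk_kernel(10).sum())
        k = round(0.06 * area)
        grid = np.full((41, 41), scheme.code_of("tumor-associated stroma"),
                       dtype=np.int64)
        plant_pixels(grid, (20, 20), k, scheme.code_of("fatty tissue"))
        lm = make_map(grid, spacing_um=20.0)
        fractions = nuisance_fraction_maps(lm, scheme, 10)
        assert fractions["fat"][20, 20] == pytest.approx(k / area)


class TestTopKHotspots:
    def _heatmap_from(self, values, fov_radius_px):
        valid = np.isfinite(values)
        return TSRHeatmap(values=values, valid_mask=valid,
                          fov_radius_px=fov_radius_px, fov_diameter_mm=1.0)

    def test_three_planted_maxima(self):
        values = np.full((100, 100), np.nan)
        values[10:90, 10:90] = 10.0
        values[20, 20] = 90.0
        values[20, 70] = 80.0
        values[70, 20] = 70.0
        spots = top_k_hotspots(self._heatmap_from(values, 10), k=3)
        assert [(s.stroma_percent, s.center) for s in spots] == [
            (90.0, (20, 20)), (80.0, (20, 70)), (70.0, (70, 20))]
        assert [s.label for s in spots] == ["TSR-1", "TSR-2", "TSR-3"]

    def test_close_maximum_suppressed(self):
        values = np.full((100, 100), np.nan)
        values[10:90, 10:90] = 10.0
        values[20, 20] = 90.0
        values[20, 28] = 85.0  # within one fov radius of the first: zeroed
        values[70, 70] = 60.0
        spots = top_k_hotspots(self._heatmap_from(values, 10), k=2)
        assert spots[0].center == (20, 20)
        assert spots[1].center == (70, 70)
        assert spots[1].stroma_percent == 60.0

    def test_constant_heatmap_tiebreak(self):
        values = np.full((30, 30), np.nan)
        values[5:25, 5:25] = 42.0
        spots = top_k_hotspots(self._heatmap_from(values, 3), k=1)
        assert spots[0].center == (5, 5)

    def test_fewer_than_k_returns_short_list(self):
        values = np.full((20, 20), np.nan)
        values[10, 10] = 55.0
        spots = top_k_hotspots(self._heatmap_from(values, 8), k=3)
        assert len(spots) == 1

    def test_ordering_and_separation_on_random_heatmaps(self):
        rng = np.random.default_rng(21)
        for _ in range(5):
            values = np.full((80, 80), np.nan)
            values[8:72, 8:72] = rng.random((64, 64)) * 100
            r = 7
            spots = top_k_hotspots(self._heatmap_from(values, r), k=3)
            percents = [s.stroma_percent for s in spots]
            assert percents == sorted(percents, reverse=True)
            for i in range(len(spots)):
                for j in range(i + 1, len(spots)):
                    d = np.hypot(spots[i].center[0] - spots[j].center[0],
                                 spots[i].center[1] - spots[j].center[1])
                    assert d > r


class TestFullyAutoTSR:
    def test_planted_65_percent_blob(self, scheme):
        """One 3.2 mm tumor blob with a flat 65% planted stroma field ->
        a hot-spot reading ~65, stroma-high."""
        spec = SyntheticSpec(base_stroma_fraction=0.65, bumps=(),
                             boundary_roughness=0.0, seed=4)
        lm, truth = generate_labelmap(spec)
        results = fully_auto_tsr(lm, scheme)
        assert results[0].stroma_percent == pytest.approx(65.0, abs=1.0)
        assert results[0].dichotomy == "stroma-high"
        assert results[0].mode == "full"

    def test_too_narrow_blob_unassessable(self, scheme):
        """A 1.5 mm tumor blob cannot fit the 2.0 mm field of view."""
        spec = SyntheticSpec(blob_radius_mm=0.75, boundary_roughness=0.0,
                             bumps=(), seed=1)
        lm, _ = generate_labelmap(spec)
        with pytest.raises(CaseUnassessableError):
            fully_auto_tsr(lm, scheme)

    def test_all_background_empty_bulk(self, scheme):
        with pytest.raises(EmptyBulkError):
            fully_auto_tsr(uniform_map((64, 64), 0), scheme)

    def test_hotspot_discs_inside_bulk_without_background(self, scheme):
        """Every reported hot-spot disc lies in the bulk and avoids background."""
        spec = SyntheticSpec(seed=12)
        lm, truth = generate_labelmap(spec)
        results = fully_auto_tsr(lm, scheme)
        bulk = extract_tumor_bulk(lm, scheme)
        r = results[0].denominator_px  # not the radius; recompute below
        from tsrscore.labelmap import mm_to_px
        radius = mm_to_px(1.0, lm.spacing_um)
        for res in results:
            br, bc = res.center
            disc = solid_disc_mask(lm.shape, (br, bc), radius)
            assert np.all(bulk.mask[disc])
            assert not np.any(lm.grid[disc] == scheme.background_code)
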