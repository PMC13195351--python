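"""Phantom generator: signal model, rasterization, cohort bookkeeping."""

import numpy as np
import pytest
from scipy import ndimage

from gastromri import (
    AreaTimeCurve,
    EmptyingTruth,
    PeristalsisTruth,
    RasterSpec,
    StudyDesign,
    generate_cohort,
    rasterize_mask_sequence,
    rasterize_volume_mask,
    simulate_area_series,
    simulate_volume_series,
)
from gastromri.motility import SliceGeometry
from gastromri.phantom import propagation_phases, record_seed


class TestAreaSeries:
    def test_noiseless_sinusoid_bounds(self, spec, clean_sinusoid_truth):
        curve = simulate_area_series(clean_sinusoid_truth, spec)
        assert len(curve) == 1123  # floor(180 * 6.24)
        assert curve.areas_mm2.min() == pytest.approx(480.0, abs=0.5)
        assert curve.areas_mm2.max() == pytest.approx(720.0, abs=0.5)

    def test_zero_amplitude_gives_constant_series(self, spec):
        truth = PeristalsisTruth(f0_cpm=3.0, mean_area_mm2=600.0, amp_mm2=0.0)
        curve = simulate_area_series(truth, spec)
        assert np.all(curve.areas_mm2 == 600.0)

    def test_autocorrelation_period_matches_frequency(self, spec, clean_sinusoid_truth):
        # independent oracle: 3 cpm -> 20 s period via direct autocorrelation
        curve = simulate_area_series(clean_sinusoid_truth, spec)
        x = curve.areas_mm2 - curve.areas_mm2.mean()
        ac = np.correlate(x, x, mode="full")[len(x) - 1:]
        lags = np.arange(len(ac)) / spec.frame_rate_fps
        search = (lags > 10) & (lags < 30)
        peak_lag = lags[search][np.argmax(ac[search])]
        assert peak_lag == pytest.approx(20.0, abs=0.5)

    def test_seed_reproduces_series_bit_identically(self, spec):
        truth = PeristalsisTruth(noise_sd_mm2=25.0, seed=42)
        a = simulate_area_series(truth, spec, slice_index=2)
        b = simulate_area_series(truth, spec, slice_index=2)
        assert np.array_equal(a.areas_mm2, b.areas_mm2)
        c = simulate_area_series(truth, spec, slice_index=1)
        assert not np.array_equal(a.areas_mm2, c.areas_mm2)

    def test_nonfinite_parameter_rejected_with_field_name(self):
        with pytest.raises(ValueError, match="f0_cpm"):
            PeristalsisTruth(f0_cpm=np.nan)
        with pytest.raises(ValueError, match="noise_sd_mm2"):
            PeristalsisTruth(noise_sd_mm2=np.inf)

    def test_amplitude_above_mean_rejected(self):
        with pytest.raises(ValueError, match="amp"):
            PeristalsisTruth(mean_area_mm2=100.0, amp_mm2=150.0)

    def test_propagation_phases_place_one_wavelength_across_extent(self):
        geom = SliceGeometry(5.0, 2.5, n_slices=3)
        phases = propagation_phases(geom)
        spacing = 5.0 + 12.5
        expected = 2 * np.pi * np.arange(3) * spacing / 40.0
        assert phases == pytest.approx(expected)


class TestRasterization:
    def test_zero_area_gives_empty_frame(self, spec):
        curve = AreaTimeCurve.from_areas([0.0], spec.frame_rate_fps)
        stack = rasterize_mask_sequence(curve, spec)
        assert stack.sum() == 0

    def test_full_grid_area_gives_all_one_frame(self, spec):
        full = spec.fov_mm[0] * spec.fov_mm[1]
        curve = AreaTimeCurve.from_areas([full], spec.frame_rate_fps)
        stack = rasterize_mask_sequence(curve, spec)
        assert stack.all()

    def test_area_beyond_grid_capacity_rejected(self, spec):
        full = spec.fov_mm[0] * spec.fov_mm[1]
        curve = AreaTimeCurve.from_areas([full * 1.01], spec.frame_rate_fps)
        with pytest.raises(ValueError, match="capacity"):
            rasterize_mask_sequence(curve, spec)

    def test_pixel_count_matches_requested_area(self, spec):
        curve = AreaTimeCurve.from_areas([100.0], spec.frame_rate_fps)
        stack = rasterize_mask_sequence(curve, spec)
        # 100 mm² / (200/140)² mm² per pixel = 49 pixels, up to a boundary ring
        assert stack[0].sum() == pytest.approx(49, abs=8)

    def test_quantization_bound_framewise(self, spec):
        # oracle: discretization error is bounded by the boundary-pixel ring
        rng = np.random.default_rng(7)
        areas = rng.uniform(50.0, 2000.0, size=24)
        curve = AreaTimeCurve.from_areas(areas, spec.frame_rate_fps)
        stack = rasterize_mask_sequence(curve, spec)
        for frame, target in zip(stack, areas):
            ring = ndimage.binary_dilation(frame) ^ ndimage.binary_erosion(frame)
            bound = ring.sum() * spec.pixel_area_mm2
            assert abs(frame.sum() * spec.pixel_area_mm2 - target) <= bound


class TestVolumeSeries:
    def test_instant_water_emptying_leaves_meal_volume(self):
        design = StudyDesign()
        truth = EmptyingTruth(v_meal0_ml=300.0, water0_ml=240.0,
                              k_water_per_min=1e6, r_meal_ml_per_min=0.0)
        series = simulate_volume_series(truth, design)
        post = series.timepoints_min > 0
        assert series.volumes_ml[post] == pytest.approx(300.0)

    def test_linear_meal_emptying_exact(self):
        design = StudyDesign()
        truth = EmptyingTruth(v_meal0_ml=500.0, water0_ml=0.0,
                              k_water_per_min=0.15, r_meal_ml_per_min=2.5)
        series = simulate_volume_series(truth, design)
        by_tp = dict(zip(series.timepoints_min, series.volumes_ml))
        assert by_tp[41] == pytest.approx(397.5)
        assert by_tp[81] == pytest.approx(297.5)

    def test_postwater_total_in_reported_range(self):
        # 298 mL meal + 240 mL water, first-order water emptying: the
        # measurement at t = 3 min should fall in the reported post-water
        # range (417 ± 70 mL) for plausible water rate constants
        design = StudyDesign()
        for k in (0.12, 0.15, 0.20):
            truth = EmptyingTruth(v_meal0_ml=298.0, water0_ml=240.0,
                                  k_water_per_min=k, r_meal_ml_per_min=2.24)
            series = simulate_volume_series(truth, design)
            v3 = dict(zip(series.timepoints_min, series.volumes_ml))[3]
            assert 347.0 <= v3 <= 487.0

    def test_baseline_required(self):
        design = StudyDesign(vol_timepoints_min=(3, 21, 41))
        with pytest.raises(ValueError, match="baseline"):
            simulate_volume_series(EmptyingTruth(), design)

    def test_late_window_exactly_affine_when_noiseless(self):
        # with the water term extinguished, V(t >= 41) is affine in t
        truth = EmptyingTruth(v_meal0_ml=400.0, water0_ml=240.0,
                              k_water_per_min=0.5, r_meal_ml_per_min=2.0)
        design = StudyDesign()
        series = simulate_volume_series(truth, design)
        late = series.timepoints_min >= 41
        t, v = series.timepoints_min[late], series.volumes_ml[late]
        assert truth.water0_ml * np.exp(-truth.k_water_per_min * 41) < 0.5
        resid = v - np.polyval(np.polyfit(t, v, 1), t)
        assert np.abs(resid).max() < 0.5


class TestVolumeMask:
    def test_zero_volume_empty_mask(self, spec):
        assert rasterize_volume_mask(0.0, spec).sum() == 0

    def test_voxel_count_exact(self, spec):
        # 100 mL at 2x2x4 mm voxels (0.016 mL) -> 6250 voxels
        assert rasterize_volume_mask(100.0, spec).sum() == 6250

    def test_round_trip_within_half_voxel(self, spec):
        from gastromri import volume_from_mask
        rng = np.random.default_rng(11)
        for v in rng.uniform(0.0, 800.0, size=100):
            mask = rasterize_volume_mask(v, spec)
            back = volume_from_mask(mask, spec.voxel_volume_ml)
            assert abs(back - v) <= spec.voxel_volume_ml / 2 + 1e-9

    def test_blob_is_single_connected_component(self, spec):
        mask = rasterize_volume_mask(350.0, spec)
        _, n = ndimage.label(mask)
        assert n == 1

    def test_capacity_error(self):
        small = RasterSpec(vol_matrix=(8, 8, 8))
        with pytest.raises(ValueError, match="capacity"):
            rasterize_volume_mask(1e6, small)


class TestCohort:
    def test_default_design_record_counts(self):
        design = StudyDesign()
        assert design.n_volumetric_records == 144
        assert design.n_dynamic_records == 360

    def test_tiny_cohort_counts(self, tmp_path):
        design = StudyDesign(n_subjects=1, arms=("solid",),
                             vol_timepoints_min=(-5, 41, 81),
                             rt_timepoints_min=(7,), n_slices=3)
        m = generate_cohort(design, 5, tmp_path / "b", write_masks=False)
        assert m["n_dynamic_records"] == 3
        assert m["n_volumetric_records"] == 3

    def test_cohort_bit_determinism(self, tmp_path, tiny_design):
        import hashlib

        def tree_hash(root):
            h = hashlib.sha256()
            for p in sorted(root.rglob("*")):
                if p.is_file() and p.suffix != ".json":  # manifests embed paths
                    h.update(p.name.encode())
                    h.update(p.read_bytes())
            return h.hexdigest()

        spec = RasterSpec(duration_s=30.0, vol_matrix=(48, 48, 48))
        generate_cohort(tiny_design, 9, tmp_path / "a", spec=spec, write_masks=True)
        generate_cohort(tiny_design, 9, tmp_path / "b", spec=spec, write_masks=True)
        assert tree_hash(tmp_path / "a") == tree_hash(tmp_path / "b")

    def test_refuses_nonempty_output_dir(self, tmp_path, tiny_design):
        out = tmp_path / "bundle"
        out.mkdir()
        (out / "stale.txt").write_text("x")
        with pytest.raises(FileExistsError):
            generate_cohort(tiny_design, 1, out, write_masks=False)

    def test_record_seed_stable_hash(self):
        # documented scheme: sha256("master|parts...")[:4] little-endian
        import hashlib
        expected = int.from_bytes(
            hashlib.sha256(b"1|sub01|solid|7").digest()[:4], "little")
        assert record_seed(1, "sub01", "solid", 7) == expected
        assert record_seed(1, "sub01", "solid", 7) < 2**32

    def test_invalid_designs_rejected(self):
        with pytest.raises(ValueError):
            StudyDesign(n_subjects=0)
        with pytest.raises(ValueError):
            StudyDesign(vol_timepoints_min=(3, 3, 41))
        with pytest.raises(ValueError):
            StudyDesign(arms=("a", "a"))


def test_spectral_purity_on_bin():
    """With noise, drift and respiration off, a generated on-bin series has a
    raw amplitude spectrum that is zero (to round-off) at every band bin
    except the true-frequency bin — checked with a direct DFT, independent
    of the analysis pipeline's detrending."""
    fs, duration = 5.0, 180.0  # 3 cpm sits exactly on bin k = 9
    raster = RasterSpec(frame_rate_fps=fs, duration_s=duration)
    truth = PeristalsisTruth(f0_cpm=3.0, mean_area_mm2=600.0, amp_mm2=120.0)
    curve = simulate_area_series(truth, raster)
    n = len(curve)
    amps = np.abs(np.fft.rfft(curve.areas_mm2 - curve.areas_mm2.mean())) * 2 / n
    freqs = np.fft.rfftfreq(n, 1 / fs)
    band = (freqs >= 0.03) & (freqs <= 0.07)
    on = np.isclose(freqs, 0.05) & band
    assert on.sum() == 1
    assert amps[on][0] == pytest.approx(120.0, rel=1e-9)
    assert np.all(amps[band & ~on] < 1e-9)
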