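"""Simulator statistics, localisation extraction, merging and drift recovery."""

import dataclasses

import numpy as np
import pytest
from scipy.special import erf
from scipy.stats import chisquare

from microqc.core_io import LocalisationTable
from microqc.fixtures import make_drift_scene
from microqc.smlm import (
    TABLE_PRESETS,
    DriftTrace,
    MergeConfig,
    SimulationParameters,
    apply_drift,
    estimate_drift,
    extract_localisations,
    merge_events,
    render_histogram,
    simulate_stack,
    _integrated_gaussian_image,
)


def union_find_tracks(table, radius_nm, max_dark):
    """Oracle track count: union-find over all linkable localisation pairs.

    Valid for well-separated emitters where linking is unambiguous.
    """
    n = len(table)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    f, x, y = table.frame, table.x_nm, table.y_nm
    for i in range(n):
        for j in range(i + 1, n):
            gap = abs(int(f[j]) - int(f[i]))
            if 1 <= gap <= 1 + max_dark and np.hypot(x[i] - x[j], y[i] - y[j]) <= radius_nm:
                parent[find(i)] = find(j)
    return len({find(i) for i in range(n)})


class TestSimulateStack:
    def test_identical_seeds_reproduce_everything(self):
        params = SimulationParameters(fov_size_nm=1600, pixel_size_nm=160, n_frames=4, seed=11)
        s1, t1 = simulate_stack(params)
        s2, t2 = simulate_stack(params)
        np.testing.assert_array_equal(s1.frames, s2.frames)
        assert t1.df.equals(t2.df)

    def test_bin4_preset_matches_published_conditions(self):
        p = TABLE_PRESETS["BIN4"]
        assert (p.fov_size_nm, p.pixel_size_nm) == (10240.0, 160.0)
        assert (p.density_mean, p.density_std) == (2.8, 0.0)
        assert p.n_frames == 20
        stack, truth = simulate_stack(dataclasses.replace(p, seed=3))
        assert stack.frames.shape == (20, 64, 64)
        # zero density spread: emitter count is the same every frame
        counts = np.bincount(truth.frame, minlength=21)[1:]
        expected = round(2.8 * (10.24) ** 2)
        assert (counts == expected).all()

    def test_photon_mean_exact_when_std_zero(self):
        params = SimulationParameters(
            fov_size_nm=3200, pixel_size_nm=160, n_frames=30,
            photons_std=0.0, psf_sigma_std_nm=0.0, seed=5,
        )
        _, truth = simulate_stack(params)
        assert (truth.photons == params.photons_mean).all()
        assert (truth.sigma_nm == params.psf_sigma_nm).all()

    def test_signal_total_conserved_within_poisson_error(self):
        # noise-free camera: stack total x conversion = in-FOV photon mass
        params = SimulationParameters(
            fov_size_nm=3200, pixel_size_nm=160, n_frames=20,
            readout_noise_adc=0.0, offset_adc=0.0, photons_std=0.0,
            psf_sigma_std_nm=0.0, density_mean=1.0, seed=9,
        )
        stack, truth = simulate_stack(params)
        # independent closed form for each emitter's in-FOV Gaussian mass
        def mass(u, sigma, extent):
            z = lambda v: 0.5 * (1 + erf(v / (sigma * np.sqrt(2))))
            return z(extent - u) - z(-u)

        expected_photons = sum(
            ph * mass(x, s, params.fov_size_nm) * mass(y, s, params.fov_size_nm)
            for x, y, ph, s in zip(truth.x_nm, truth.y_nm, truth.photons, truth.sigma_nm)
        )
        measured_photons = stack.frames.sum(dtype=np.float64) * params.adc_per_photon
        assert abs(measured_photons - expected_photons) < 4 * np.sqrt(expected_photons)

    def test_dark_frames_recover_camera_moments(self):
        params = SimulationParameters(
            fov_size_nm=10240, pixel_size_nm=160, n_frames=20,
            density_mean=1e-9, offset_adc=10550.0, readout_noise_adc=1040.0, seed=21,
        )
        stack, truth = simulate_stack(params)
        assert len(truth) == 0
        samples = stack.frames.ravel()
        se = params.readout_noise_adc / np.sqrt(samples.size)
        assert abs(samples.mean() - params.offset_adc) < 3 * se
        assert abs(samples.std() - params.readout_noise_adc) < 0.05 * params.readout_noise_adc

    def test_constant_photon_flux_moments(self, rng):
        # camera model on a constant expected-photon image S:
        # mean -> offset + S/c, var -> S/c^2 + readout^2
        S, c, offset, readout = 400.0, 16.0, 100.0, 3.0
        draws = offset + rng.poisson(S, 40000) / c + rng.normal(0, readout, 40000)
        assert abs(draws.mean() - (offset + S / c)) < 3 * np.sqrt(S / c**2 + readout**2) / 200
        assert abs(draws.var() - (S / c**2 + readout**2)) < 0.05 * (S / c**2 + readout**2)

    def test_psf_sigma_recovered_from_rendered_spot(self):
        # pixel-integrated spot second moment = sigma^2 + px^2/12 (Sheppard)
        px, sigma_nm = 160.0, 153.0
        n = 21
        img = _integrated_gaussian_image(
            n, px, np.array([n * px / 2]), np.array([n * px / 2]),
            np.array([1.0]), np.array([sigma_nm]),
        )
        centres = (np.arange(n) + 0.5) * px
        total = img.sum()
        mx = (img.sum(axis=0) * centres).sum() / total
        var = (img.sum(axis=0) * (centres - mx) ** 2).sum() / total
        sigma_est = np.sqrt(var - px**2 / 12)
        assert sigma_est == pytest.approx(sigma_nm, rel=0.02)

    def test_reciprocal_conversion_flag(self):
        base = SimulationParameters(
            fov_size_nm=1600, pixel_size_nm=160, n_frames=2, seed=2,
            readout_noise_adc=0.0, offset_adc=0.0,
        )
        lo, _ = simulate_stack(base)
        hi, _ = simulate_stack(dataclasses.replace(base, adu_per_photon=True))
        # same photon draws, scaled by factor^2 between the two conventions
        np.testing.assert_allclose(hi.frames, lo.frames * base.adc_per_photon**2)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            SimulationParameters(fov_size_nm=-1)
        with pytest.raises(ValueError):
            SimulationParameters(fov_size_nm=1000, pixel_size_nm=160)


class TestRenderHistogram:
    def test_single_localisation_single_pixel(self):
        t = LocalisationTable.from_arrays([1], [105.0], [45.0])
        img = render_histogram(t, 10.0, extent_nm=(200, 200))
        assert img.sum() == 1
        assert img[4, 10] == 1  # row = y//10, col = x//10

    def test_counts_conserved_without_blur(self, rng):
        n = 500
        t = LocalisationTable.from_arrays(
            np.ones(n, int), rng.uniform(0, 1000, n), rng.uniform(0, 1000, n)
        )
        assert render_histogram(t, 25.0).sum() == n

    def test_uniform_table_not_rejected_by_chi_square(self):
        rng = np.random.default_rng(42)
        n = 20000
        t = LocalisationTable.from_arrays(
            np.ones(n, int), rng.uniform(0, 800, n), rng.uniform(0, 800, n)
        )
        img = render_histogram(t, 100.0, extent_nm=(800, 800))
        _, p = chisquare(img.ravel())
        assert p > 0.001

    def test_empty_table_flagged_empty_raster(self):
        assert render_histogram(LocalisationTable.empty(), 10.0).sum() == 0


class TestExtractLocalisations:
    def test_subpixel_centroid_accuracy(self):
        px = 100.0
        true_x, true_y = 10.37 * px, 8.81 * px  # sub-pixel position in nm
        img = _integrated_gaussian_image(
            20, px, np.array([true_x]), np.array([true_y]), np.array([1000.0]),
            np.array([1.5 * px]),
        )
        table = extract_localisations(img, px, threshold_fraction=0.2, window_radius_px=4)
        assert len(table) == 1
        assert abs(table.x_nm[0] - true_x) < 0.1 * px
        assert abs(table.y_nm[0] - true_y) < 0.1 * px

    def test_two_separated_spots_found(self):
        px = 100.0
        img = _integrated_gaussian_image(
            24, px, np.array([5 * px, 15 * px]), np.array([12 * px, 12 * px]),
            np.array([1000.0, 800.0]), np.array([px, px]),
        )
        assert len(extract_localisations(img, px)) == 2

    def test_flat_image_below_threshold_empty(self):
        assert len(extract_localisations(np.zeros((16, 16)), 100.0)) == 0

    def test_intensity_is_window_sum(self):
        img = np.zeros((11, 11))
        img[5, 5] = 10.0
        img[5, 6] = 4.0
        table = extract_localisations(img, 1.0, threshold_fraction=0.5, window_radius_px=2)
        assert len(table) == 1
        assert table.photons[0] == pytest.approx(14.0)


class TestMergeEvents:
    def test_consecutive_frames_merge_to_one_record(self):
        t = LocalisationTable.from_arrays(
            [1, 2, 3, 4, 5], [100.0] * 5, [200.0] * 5, [10.0] * 5, [150.0] * 5
        )
        merged = merge_events(t, MergeConfig(radius_nm=40, max_dark_frames=0))
        assert len(merged) == 1
        assert merged.photons[0] == 50.0
        assert merged.frame[0] == 1

    def test_gap_breaks_track_without_dark_frames(self):
        t = LocalisationTable.from_arrays([1, 2, 4, 5], [100.0] * 4, [200.0] * 4, [10.0] * 4)
        assert len(merge_events(t, MergeConfig(40, 0))) == 2

    def test_dark_frame_allowance_bridges_gap(self):
        t = LocalisationTable.from_arrays([1, 2, 4, 5], [100.0] * 4, [200.0] * 4, [10.0] * 4)
        assert len(merge_events(t, MergeConfig(40, 1))) == 1

    def test_photon_weighted_mean_position(self):
        t = LocalisationTable.from_arrays([1, 2], [100.0, 130.0], [0.0, 0.0], [30.0, 10.0])
        merged = merge_events(t, MergeConfig(radius_nm=40))
        assert merged.x_nm[0] == pytest.approx((30 * 100 + 10 * 130) / 40)

    def test_distance_threshold_respected(self):
        t = LocalisationTable.from_arrays([1, 2], [100.0, 141.0], [0.0, 0.0], [1.0, 1.0])
        assert len(merge_events(t, MergeConfig(radius_nm=40))) == 2

    def test_tiny_radius_is_identity_on_distinct_positions(self, rng):
        n = 30
        t = LocalisationTable.from_arrays(
            rng.integers(1, 10, n), rng.uniform(0, 5000, n), rng.uniform(0, 5000, n),
            np.ones(n),
        )
        merged = merge_events(t, MergeConfig(radius_nm=1e-9))
        assert len(merged) == n

    def test_blinking_scene_matches_union_find_oracle(self):
        # 50 emitters >= 200 nm apart, 2-4 frame events, < 10 nm jitter
        rng = np.random.default_rng(77)
        grid = np.arange(10) * 500.0 + 100
        gx, gy = np.meshgrid(grid, grid)
        centres = np.column_stack([gx.ravel(), gy.ravel()])[:50]
        frames, xs, ys = [], [], []
        for k, (cx, cy) in enumerate(centres):
            start = int(rng.integers(1, 6))
            for f in range(start, start + int(rng.integers(2, 5))):
                frames.append(f)
                xs.append(cx + rng.uniform(-9, 9))
                ys.append(cy + rng.uniform(-9, 9))
        t = LocalisationTable.from_arrays(frames, xs, ys, np.ones(len(frames)))
        merged = merge_events(t, MergeConfig(radius_nm=40, max_dark_frames=0))
        assert len(merged) == union_find_tracks(t, 40, 0) == 50


class TestDrift:
    def test_zero_drift_gives_null_trace(self):
        table, _ = make_drift_scene(drift_per_frame_nm=(0.0, 0.0), seed=5)
        trace = estimate_drift(table, n_time_bins=5, render_pixel_nm=20.0)
        assert np.abs(trace.dx_nm).max() < 10.0
        assert np.abs(trace.dy_nm).max() < 10.0

    def test_trace_anchored_at_zero(self):
        table, _ = make_drift_scene(seed=6)
        trace = estimate_drift(table, n_time_bins=4, render_pixel_nm=20.0)
        assert trace.dx_nm[0] == 0.0 and trace.dy_nm[0] == 0.0

    def test_linear_drift_endpoint_recovered(self):
        # 100 nm drift in x over the stack
        table, true = make_drift_scene(drift_per_frame_nm=(100 / 199, 0.0), seed=3)
        trace = estimate_drift(table, n_time_bins=5, render_pixel_nm=20.0)
        tol = max(0.5 * 20.0, 10.0)
        assert abs(trace.dx_nm[-1] - true.dx_nm[-1]) < tol
        assert abs(trace.dy_nm[-1] - true.dy_nm[-1]) < tol

    def test_apply_then_negated_apply_is_identity(self):
        table, _ = make_drift_scene(seed=8)
        trace = estimate_drift(table, n_time_bins=4, render_pixel_nm=20.0)
        back = apply_drift(apply_drift(table, trace), trace.negated())
        np.testing.assert_allclose(back.x_nm, table.x_nm, atol=1e-9)
        np.testing.assert_allclose(back.y_nm, table.y_nm, atol=1e-9)

    def test_correction_reduces_estimated_drift(self):
        table, _ = make_drift_scene(seed=9)
        trace = estimate_drift(table, n_time_bins=5, render_pixel_nm=20.0)
        corrected = apply_drift(table, trace)
        residual = estimate_drift(corrected, n_time_bins=5, render_pixel_nm=20.0)
        assert np.hypot(residual.dx_nm[-1], residual.dy_nm[-1]) < np.hypot(
            trace.dx_nm[-1], trace.dy_nm[-1]
        )

    def test_correction_reduces_rms_to_true_positions(self):
        # pipeline property: corrected positions closer to the undrifted truth
        table, true = make_drift_scene(seed=13)
        undrifted = apply_drift(table, true)
        est = estimate_drift(table, n_time_bins=5, render_pixel_nm=20.0)
        corrected = apply_drift(table, est)
        rms_before = np.sqrt(np.mean((table.x_nm - undrifted.x_nm) ** 2 + (table.y_nm - undrifted.y_nm) ** 2))
        rms_after = np.sqrt(np.mean((corrected.x_nm - undrifted.x_nm) ** 2 + (corrected.y_nm - undrifted.y_nm) ** 2))
        assert rms_after < rms_before

    def test_frame_outside_trace_rejected(self):
        t = LocalisationTable.from_arrays([5], [0.0], [0.0])
        with pytest.raises(ValueError):
            apply_drift(t, DriftTrace(np.zeros(3), np.zeros(3)))

    def test_too_few_bins_rejected(self):
        t = LocalisationTable.from_arrays([1, 2], [0.0, 1.0], [0.0, 1.0])
        with pytest.raises(ValueError):
            estimate_drift(t, n_time_bins=1)
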