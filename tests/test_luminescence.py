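"""Grid averaging, spectra, band sums, spike correction, SP selection."""

import warnings

import numpy as np
import pytest

import radmig as rm
from radmig.luminescence import (GridSeries, SpectrumGrid, band_power,
                                 exclude_initial, grid_average, sp_row_mask,
                                 spike_correct, temporal_spectrum)


def series_from(x, dt=0.5, t0=0.0):
    """Wrap a 1-D time series as a 1x1 GridSeries."""
    x = np.asarray(x, dtype=float)
    return GridSeries(values=x[None, None, :], row_edges=np.array([0, 1]),
                      col_edges=np.array([0, 1]),
                      timestamps_h=t0 + dt * np.arange(len(x)))


def naive_dft_magnitudes(x):
    """O(N^2) direct-sum one-sided DFT magnitude (independent oracle)."""
    N = len(x)
    out = []
    for k in range(N // 2 + 1):
        acc = 0j
        for n in range(N):
            acc += x[n] * np.exp(-2j * np.pi * k * n / N)
        out.append(abs(acc))
    return np.array(out)


class TestGridAverage:
    def test_constant_image(self):
        s = rm.ImageStack(np.full((3, 20, 30), 7.0), 0.5, 1.0)
        g = grid_average(s, 4, 5)
        np.testing.assert_allclose(g.values, 7.0)

    def test_default_grid_shape(self):
        cfg = rm.RunConfig()
        s = rm.ImageStack(np.zeros((2, 56, 64)), 0.5, 1.0)
        g = grid_average(s, cfg.grid_rows, cfg.grid_cols)
        assert g.grid_shape == (14, 16)

    def test_hand_computed_block_means(self):
        img = np.arange(16, dtype=float).reshape(1, 4, 4)
        g = grid_average(rm.ImageStack(img, 1.0, 1.0), 2, 2)
        np.testing.assert_allclose(g.values[:, :, 0],
                                   [[2.5, 4.5], [10.5, 12.5]])

    def test_every_pixel_in_exactly_one_cell(self):
        # odd sizes: rounded boundaries still partition the image
        s = rm.ImageStack(np.ones((1, 23, 17)), 1.0, 1.0)
        g = grid_average(s, 5, 3)
        assert g.row_edges[0] == 0 and g.row_edges[-1] == 23
        assert np.all(np.diff(g.row_edges) > 0)
        # mean of means weighted by areas equals global mean
        areas = np.outer(np.diff(g.row_edges), np.diff(g.col_edges))
        np.testing.assert_allclose((g.values[:, :, 0] * areas).sum(),
                                   23 * 17)

    def test_grid_larger_than_image_rejected(self):
        s = rm.ImageStack(np.ones((1, 4, 4)), 1.0, 1.0)
        with pytest.raises(ValueError, match="larger than image"):
            grid_average(s, 8, 2)


class TestExcludeInitial:
    def test_cutoff_zero_identity(self):
        g = series_from(np.arange(10.0))
        out = exclude_initial(g, 0.0)
        np.testing.assert_array_equal(out.values, g.values)

    def test_boundary_frame_retained(self):
        # 0.25 h cadence: frames 0..17 start before 4.5 h, frame 18 at 4.5
        g = series_from(np.arange(40.0), dt=0.25)
        out = exclude_initial(g, 4.5)
        assert out.n_frames == 40 - 18
        assert out.timestamps_h[0] == 4.5

    def test_too_short_after_exclusion(self):
        g = series_from(np.arange(5.0), dt=0.5)
        with pytest.raises(ValueError, match="too short"):
            exclude_initial(g, 2.1)


class TestTemporalSpectrum:
    def test_constant_series(self):
        g = series_from(np.full(16, 3.0))
        spec = temporal_spectrum(g)
        assert spec.magnitudes[0, 0, 0] == pytest.approx(16 * 3.0)
        np.testing.assert_allclose(spec.magnitudes[0, 0, 1:], 0, atol=1e-10)

    def test_pure_tone(self):
        N, A = 64, 5.0
        x = A * np.cos(2 * np.pi * 3 * np.arange(N) / N)
        spec = temporal_spectrum(series_from(x))
        assert spec.magnitudes[0, 0, 3] == pytest.approx(A * N / 2)
        others = np.delete(spec.magnitudes[0, 0], 3)
        np.testing.assert_allclose(others, 0, atol=1e-9)

    def test_matches_naive_direct_sum(self):
        rng = np.random.default_rng(12)
        x = rng.normal(size=128)
        spec = temporal_spectrum(series_from(x))
        np.testing.assert_allclose(spec.magnitudes[0, 0],
                                   naive_dft_magnitudes(x), atol=1e-8)

    def test_non_uniform_timestamps_rejected(self):
        g = series_from(np.arange(8.0))
        g.timestamps_h = g.timestamps_h ** 1.1
        with pytest.raises(ValueError, match="non-uniform"):
            temporal_spectrum(g)


class TestBandPower:
    def flat_spec(self, value=1.0, n_bins=80):
        return SpectrumGrid(magnitudes=np.full((1, 1, n_bins), value),
                            n_frames_used=2 * (n_bins - 1))

    def test_inclusive_bin_count(self):
        b, n = band_power(self.flat_spec(), (2, 30))
        assert n == 29
        assert b[0, 0] == pytest.approx(29.0)

    def test_dc_band_on_constant_series(self):
        N, c = 32, 4.0
        spec = temporal_spectrum(series_from(np.full(N, c)))
        b, _ = band_power(spec, (0, 0))
        assert b[0, 0] == pytest.approx(N * c)

    def test_matches_loop_oracle(self):
        rng = np.random.default_rng(5)
        mags = rng.uniform(0, 9, size=(3, 4, 40))
        spec = SpectrumGrid(magnitudes=mags, n_frames_used=78)
        b, _ = band_power(spec, (5, 17))
        expected = np.zeros((3, 4))
        for i in range(3):
            for j in range(4):
                for k in range(5, 18):
                    expected[i, j] += mags[i, j, k]
        np.testing.assert_allclose(b, expected, rtol=1e-14)

    def test_band_clipped_with_warning(self):
        with pytest.warns(UserWarning, match="clipped"):
            b, n = band_power(self.flat_spec(n_bins=20), (2, 30))
        assert n == 18  # bins 2..19

    def test_band_above_nyquist(self):
        with pytest.raises(ValueError, match="Nyquist"):
            band_power(self.flat_spec(n_bins=20), (30, 75))
        with pytest.warns(UserWarning, match="zeros"):
            b, n = band_power(self.flat_spec(n_bins=20), (30, 75),
                              on_empty="zero")
        assert n == 0 and b[0, 0] == 0


class TestSpikeCorrect:
    def test_impulse_fully_removed(self):
        # impulse spectrum is flat: B = n_low*A, H = n_high*A, B* = 0
        A = 123.0
        B = np.array([[29 * A]])
        H = np.array([[46 * A]])
        out = spike_correct(B, H, 29, 46)
        assert out[0, 0] == pytest.approx(0.0, abs=1e-12)

    def test_zero_high_band_is_identity(self):
        B = np.array([[5.0]])
        out = spike_correct(B, np.zeros((1, 1)), 29, 46)
        np.testing.assert_array_equal(out, B)

    def test_tone_preserved(self):
        # narrow-band signal has empty high band: B* = B
        N, A = 64, 2.0
        x = A * np.cos(2 * np.pi * 3 * np.arange(N) / N)
        spec = temporal_spectrum(series_from(x))
        B, nl = band_power(spec, (2, 10))
        H, nh = band_power(spec, (12, 30))
        out = spike_correct(B, H, nl, nh)
        assert out[0, 0] == pytest.approx(A * N / 2)

    def test_mask_mode_removes_overlap_bin_only(self):
        mags = np.ones((1, 1, 80))
        spec = SpectrumGrid(magnitudes=mags, n_frames_used=158)
        B, nl = band_power(spec, (2, 30))
        H, nh = band_power(spec, (30, 75))
        out = spike_correct(B, H, nl, nh, mode="mask", spectrum=spec,
                            low_band=(2, 30), high_band=(30, 75))
        assert out[0, 0] == pytest.approx(28.0)  # bin 30 dropped

    def test_none_mode(self):
        B = np.array([[3.0]])
        np.testing.assert_array_equal(
            spike_correct(B, np.array([[9.0]]), 29, 46, mode="none"), B)

    def test_warns_when_high_band_missing(self):
        with pytest.warns(UserWarning, match="disabled"):
            out = spike_correct(np.array([[2.0]]), np.zeros((1, 1)), 29, 0)
        assert out[0, 0] == 2.0


class TestSelectSpRows:
    def grid_edges(self, n_rows=14, px_per_row=4):
        return np.arange(n_rows + 1) * px_per_row

    def test_flanking_rows_center_excluded(self):
        ann = rm.LayerAnnotation(pial_row=0, ventricular_row=55,
                                 sp_center_row=30)  # grid row 7 (28..32)
        mask = sp_row_mask(self.grid_edges(), ann, sp_half_rows=4)
        assert set(np.nonzero(mask)[0]) == {3, 4, 5, 6, 8, 9, 10, 11}

    def test_include_center_switch(self):
        ann = rm.LayerAnnotation(pial_row=0, ventricular_row=55,
                                 sp_center_row=30)
        mask = sp_row_mask(self.grid_edges(), ann, 4, include_center=True)
        assert set(np.nonzero(mask)[0]) == {3, 4, 5, 6, 7, 8, 9, 10, 11}

    def test_whole_image_selection(self):
        ann = rm.LayerAnnotation(pial_row=0, ventricular_row=55,
                                 sp_center_row=30)
        mask = sp_row_mask(self.grid_edges(), ann, 20)
        assert mask.sum() == 13  # all rows except the centre

    def test_edge_clipping_one_sided(self):
        ann = rm.LayerAnnotation(pial_row=0, ventricular_row=55,
                                 sp_center_row=2)  # grid row 0
        with pytest.warns(UserWarning, match="clipped"):
            mask = sp_row_mask(self.grid_edges(), ann, 4)
        assert set(np.nonzero(mask)[0]) == {1, 2, 3, 4}


class TestQuantifyReporter:
    def test_all_zero_stack(self):
        stack = rm.ImageStack(np.zeros((160, 56, 64)), 0.5, 8.0)
        ann = rm.LayerAnnotation(pial_row=2, ventricular_row=53,
                                 sp_center_row=26)
        g = rm.quantify_reporter(stack, ann, rm.RunConfig())
        np.testing.assert_array_equal(g.B_star, 0)

    def test_condition_label_blind(self, lum_fixture):
        _, _, lum, _, ann = lum_fixture
        cfg = rm.RunConfig()
        a = rm.quantify_reporter(lum, ann, cfg, condition="ctrl")
        b = rm.quantify_reporter(lum, ann, cfg, condition="kd")
        np.testing.assert_array_equal(a.B_star, b.B_star)

    def test_linearity_of_band_sums(self, lum_fixture):
        _, _, lum, _, ann = lum_fixture
        cfg = rm.RunConfig(use_power_spectrum=False)
        g1 = rm.quantify_reporter(lum, ann, cfg)
        scaled = rm.ImageStack(lum.frames * 3.0, lum.frame_interval_h,
                               lum.pixel_size_um)
        g3 = rm.quantify_reporter(scaled, ann, cfg)
        np.testing.assert_allclose(g3.B, 3.0 * g1.B, rtol=1e-12)
        # correction is linear too when unclamped
        np.testing.assert_allclose(g3.B_star, 3.0 * g1.B_star, rtol=1e-9)

    def test_power_mode_scales_quadratically(self, lum_fixture):
        _, _, lum, _, ann = lum_fixture
        cfg = rm.RunConfig(use_power_spectrum=True)
        g1 = rm.quantify_reporter(lum, ann, cfg)
        scaled = rm.ImageStack(lum.frames * 2.0, lum.frame_interval_h,
                               lum.pixel_size_um)
        g2 = rm.quantify_reporter(scaled, ann, cfg)
        np.testing.assert_allclose(g2.B, 4.0 * g1.B, rtol=1e-12)

    def test_errors_labeled_with_stage(self):
        stack = rm.ImageStack(np.zeros((160, 8, 8)), 0.5, 8.0)
        ann = rm.LayerAnnotation(pial_row=0, ventricular_row=7,
                                 sp_center_row=4)
        with pytest.raises(ValueError, match=r"\[grid_average\]"):
            rm.quantify_reporter(stack, ann, rm.RunConfig())

    def test_deterministic(self, lum_fixture):
        _, _, lum, _, ann = lum_fixture
        cfg = rm.RunConfig()
        a = rm.quantify_reporter(lum, ann, cfg)
        b = rm.quantify_reporter(lum, ann, cfg)
        np.testing.assert_array_equal(a.B_star, b.B_star)

    def test_single_extra_spike_barely_moves_readout(self, lum_fixture):
        # the correction's purpose, asserted as a regression on the fixture
        _, _, lum, _, ann = lum_fixture
        cfg = rm.RunConfig()
        g1 = rm.quantify_reporter(lum, ann, cfg)
        frames = lum.frames.copy()
        frames[80, 26, 32] += 250.0  # one cosmic ray inside the SP band
        g2 = rm.quantify_reporter(
            rm.ImageStack(frames, lum.frame_interval_h, lum.pixel_size_um),
            ann, cfg)
        m1 = np.median(g1.B_star[g1.sp_rows])
        m2 = np.median(g2.B_star[g2.sp_rows])
        assert abs(m2 - m1) < 0.05 * m1

    def test_long_table_schema(self, lum_fixture):
        _, _, lum, _, ann = lum_fixture
        g = rm.quantify_reporter(lum, ann, rm.RunConfig(), condition="ctrl",
                                 slice_id="s1")
        table = g.to_frame()
        assert list(table.columns) == ["condition", "slice_id", "grid_row",
                                       "grid_col", "B", "H", "B_star",
                                       "in_sp_selection"]
        assert len(table) == 14 * 16
        assert table["in_sp_selection"].sum() == 8 * 16
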