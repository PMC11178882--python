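"""Trace extraction: cropping, segmentation, weighting, detrending, metrics."""

import numpy as np
import pytest

from scanvolt.extraction import (FluorescenceTrace, NoiseFreeInputError,
                                 NoResponsiveCellError, correlation_fwhm,
                                 correlation_image, crop_roi, detrend, dff,
                                 extract_trace, initial_segment,
                                 photorecovery, photostability,
                                 pixel_weights, sbr, snr)
from scanvolt.synthetic import (AcquisitionConfig, CellModel,
                                IlluminationSpec, bleach_profile,
                                make_protocol, render_movie)

STEP_WIN = (550.0, 590.0)       # plateau of the first protocol-1 step
BASE_WIN = (50.0, 450.0)


def _weighted_dff(roi, weights, epochs=((0.0, 3000.0),)):
    tr = extract_trace(roi, weights)
    return dff(detrend(tr, [list(e) for e in epochs]), BASE_WIN)


def _plateau(d):
    sel = (d.times_ms >= STEP_WIN[0]) & (d.times_ms < STEP_WIN[1])
    return d.dff_pct[sel].mean()


class TestCropRoi:
    def test_centred_crop_round_trips_coordinates(self, p1_movie):
        movie, _ = p1_movie
        roi = crop_roi(movie, (16.0, 16.0), 40)
        assert roi.stack.shape[1:] == (40, 40)
        rng = np.random.default_rng(0)
        r = rng.integers(0, 40, 100)
        c = rng.integers(0, 40, 100)
        mr, mc = roi.to_movie_indices(r, c)
        assert np.array_equal(movie.data[:, mr, mc], roi.stack[:, r, c])

    def test_edge_crop_clips_with_warning(self, p1_movie):
        movie, _ = p1_movie
        with pytest.warns(UserWarning, match="clipped"):
            roi = crop_roi(movie, (2.0, 2.0), 40)
        assert roi.stack.shape[1] < 40

    def test_outside_centroid_rejected(self, p1_movie):
        movie, _ = p1_movie
        with pytest.raises(ValueError):
            crop_roi(movie, (100.0, 100.0), 20)


class TestSegmentation:
    def test_mask_overlaps_true_annulus(self, p1_movie):
        movie, truth = p1_movie
        roi = crop_roi(movie, (16.0, 16.0), 60)
        mask = initial_segment(roi)
        r0, c0 = roi.origin
        true_mask = truth.cell_masks[0][r0:r0 + 60, c0:c0 + 60]
        overlap = (mask & true_mask).sum() / true_mask.sum()
        assert overlap >= 0.8

    def test_pure_noise_roi_raises(self, acq_100hz):
        dark = CellModel(centroid_um=(16.0, 16.0), expression_F0=0.0)
        movie, _ = render_movie([dark], make_protocol(1),
                                IlluminationSpec(), acq_100hz, seed=2)
        with pytest.raises(NoResponsiveCellError):
            initial_segment(crop_roi(movie, (16.0, 16.0), 60))

    def test_manual_sub_region_hint_separates_cells(self, acq_100hz):
        cells = [CellModel(centroid_um=(10.0, 16.0), soma_diameter_um=10.0),
                 CellModel(centroid_um=(24.0, 16.0), soma_diameter_um=10.0)]
        movie, truth = render_movie(cells, make_protocol(1),
                                    IlluminationSpec(), acq_100hz, seed=8)
        roi = crop_roi(movie, (17.0, 16.0), 56)
        left = np.zeros(roi.stack.shape[1:], bool)
        left[:, :roi.stack.shape[2] // 2] = True
        m_left = initial_segment(roi, sub_region=left)
        m_right = initial_segment(roi, sub_region=~left)
        assert m_left.any() and m_right.any()
        assert not (m_left & m_right).any()
        half = roi.stack.shape[2] // 2
        assert np.all(~m_left[:, half:])
        assert np.all(~m_right[:, :half])


class TestPixelWeights:
    def test_identical_signal_gives_near_uniform_weights(self):
        rng = np.random.default_rng(1)
        sig = 100.0 + 20.0 * np.sin(np.linspace(0, 20, 600))
        stack = rng.poisson(sig[:, None, None] * np.ones((1, 10, 10)))
        roi = _as_roi(stack.astype(float))
        w = pixel_weights(roi, np.ones((10, 10), bool))
        used = w.weights[w.support]
        assert used.std() / used.mean() < 0.2

    def test_weight_mass_concentrates_on_signal_half(self):
        rng = np.random.default_rng(2)
        sig = 100.0 + 20.0 * np.sin(np.linspace(0, 20, 600))
        stack = np.empty((600, 10, 10))
        stack[:, :, :5] = rng.poisson(sig[:, None, None]
                                      * np.ones((1, 10, 5)))
        stack[:, :, 5:] = rng.poisson(100.0, (600, 10, 5))
        roi = _as_roi(stack)
        w = pixel_weights(roi, np.ones((10, 10), bool))
        assert w.weights[:, :5].sum() >= 0.95

    def test_weighted_dff_beats_unweighted_with_dead_pixels(self, p1_movie):
        movie, truth = p1_movie
        roi = crop_roi(movie, (16.0, 16.0), 60)
        dirty_mask = np.ones((60, 60), bool)      # annulus plus noise pixels
        w = pixel_weights(roi, dirty_mask)
        uniform = np.full((60, 60), 1.0 / 3600)
        weighted = _plateau(_weighted_dff(roi, w))
        unweighted = _plateau(_weighted_dff(roi, uniform))
        assert weighted > unweighted

    def test_support_shrinks_within_mask(self, p1_movie):
        movie, _ = p1_movie
        roi = crop_roi(movie, (16.0, 16.0), 60)
        dirty_mask = np.ones((60, 60), bool)
        w = pixel_weights(roi, dirty_mask)
        assert w.n_pixels_used < dirty_mask.sum()

    def test_constant_reference_rejected(self):
        roi = _as_roi(np.ones((200, 5, 5)))
        with pytest.raises(ValueError, match="constant"):
            pixel_weights(roi, np.ones((5, 5), bool))


class TestExtractTrace:
    def test_uniform_weights_equal_plain_mean(self, p1_movie):
        movie, _ = p1_movie
        roi = crop_roi(movie, (16.0, 16.0), 20)
        w = np.full((20, 20), 1.0 / 400)
        tr = extract_trace(roi, w)
        assert np.allclose(tr.raw, roi.stack.mean(axis=(1, 2)))

    def test_delta_weight_selects_single_pixel(self, p1_movie):
        movie, _ = p1_movie
        roi = crop_roi(movie, (16.0, 16.0), 20)
        w = np.zeros((20, 20))
        w[7, 9] = 1.0
        tr = extract_trace(roi, w)
        assert np.array_equal(tr.raw, roi.stack[:, 7, 9])

    def test_linearity_in_the_movie(self, p1_movie):
        movie, _ = p1_movie
        roi = crop_roi(movie, (16.0, 16.0), 20)
        w = np.full((20, 20), 1.0 / 400)
        doubled = _as_roi(2.0 * roi.stack)
        assert np.allclose(extract_trace(doubled, w).raw,
                           2.0 * extract_trace(roi, w).raw)


class TestDetrend:
    def test_constant_trace_unchanged(self):
        tr = FluorescenceTrace(np.arange(500) * 10.0,
                               np.full(500, 55.0), 100.0)
        out = detrend(tr)
        assert np.allclose(out.detrended, 55.0, rtol=1e-6)

    def test_pure_exponential_becomes_flat(self):
        t = np.arange(1000) / 100.0
        tr = FluorescenceTrace(t * 1000.0, 100.0 * np.exp(-t / 4.0), 100.0)
        out = detrend(tr)
        resid = out.detrended / out.detrended[0] - 1.0
        slope_per_s = abs(np.polyfit(t, resid, 1)[0])
        assert slope_per_s < 0.01

    def test_bleached_step_amplitudes_recovered(self, acq_100hz):
        """Protocol-1 trace bleaching to 0.80: the three recovered step
        amplitudes agree with the pre-bleach amplitude within 2%."""
        cell = CellModel(centroid_um=(16.0, 16.0), expression_F0=3000.0)
        movie, truth = render_movie([cell], make_protocol(1),
                                    IlluminationSpec(), acq_100hz, seed=13,
                                    background=0.0)
        roi = crop_roi(movie, (16.0, 16.0), 40)
        mask = initial_segment(roi)
        d = _weighted_dff(roi, pixel_weights(roi, mask))
        plateaus = [
            d.dff_pct[(d.times_ms >= on + 50) & (d.times_ms < on + 90)].mean()
            for on in (500.0, 1500.0, 2500.0)]
        for p in plateaus:
            assert p == pytest.approx(43.0, rel=0.02)

    def test_dff_of_flat_detrended_trace_is_idempotent(self):
        tr = FluorescenceTrace(np.arange(600) * 10.0,
                               np.full(600, 80.0), 100.0)
        once = dff(detrend(tr), (0.0, 1000.0))
        twice = dff(detrend(once), (0.0, 1000.0))
        assert np.allclose(once.dff_pct, twice.dff_pct, atol=1e-9)


class TestDff:
    def test_flat_trace_is_zero(self):
        tr = FluorescenceTrace(np.arange(200) * 10.0, np.full(200, 50.0),
                               100.0, detrended=np.full(200, 50.0))
        assert np.allclose(dff(tr, (0.0, 500.0)).dff_pct, 0.0)

    def test_half_f0_reads_fifty_percent(self):
        f = np.full(300, 100.0)
        f[150:200] = 50.0
        tr = FluorescenceTrace(np.arange(300) * 10.0, f, 100.0, detrended=f)
        d = dff(tr, (0.0, 1000.0))
        assert d.dff_pct[160] == pytest.approx(50.0)

    def test_calibrated_plateau_43pct(self, p1_movie_clean):
        movie, _ = p1_movie_clean
        roi = crop_roi(movie, (16.0, 16.0), 40)
        d = _weighted_dff(roi, pixel_weights(roi, initial_segment(roi)))
        assert _plateau(d) == pytest.approx(43.0, abs=2.0)

    def test_nonpositive_f0_rejected(self):
        tr = FluorescenceTrace(np.arange(200) * 10.0, np.full(200, -1.0),
                               100.0, detrended=np.full(200, -1.0))
        with pytest.raises(ValueError):
            dff(tr, (0.0, 500.0))


class TestSnr:
    def test_amplitude_over_noise(self):
        rng = np.random.default_rng(3)
        t = np.arange(2000.0)
        x = rng.normal(0.0, 1.0, 2000)
        x[1000:1500] += 5.0
        got = snr(x, t, (1000.0, 1500.0), (0.0, 1000.0))
        assert got == pytest.approx(5.0, rel=0.1)

    def test_noise_free_trace_raises(self):
        t = np.arange(100.0)
        x = np.zeros(100)
        x[50:] = 1.0
        with pytest.raises(NoiseFreeInputError):
            snr(x, t, (50.0, 100.0), (0.0, 50.0))


class TestPhotoMetrics:
    def test_no_bleach_both_near_one(self):
        rng = np.random.default_rng(4)
        t = np.arange(0.0, 8500.0, 10.0)
        x = rng.normal(1000.0, 5.0, t.size)
        epochs = [(0.0, 3000.0), (5500.0, 8500.0)]
        assert photostability(x, t, epochs[0]) == pytest.approx(1.0, abs=0.02)
        assert photorecovery(x, t, epochs) == pytest.approx(1.0, abs=0.02)

    def test_generator_calibration_recovered(self):
        t = np.arange(0.0, 8.5, 0.01)
        epochs_s = [(0.0, 3.0), (5.5, 8.5)]
        x = 2000.0 * bleach_profile(t, epochs_s)
        t_ms = t * 1000.0
        epochs_ms = [(a * 1000, b * 1000) for a, b in epochs_s]
        assert photostability(x, t_ms, epochs_ms[0]) == pytest.approx(
            0.80, abs=0.02)
        assert photorecovery(x, t_ms, epochs_ms) == pytest.approx(
            0.97, abs=0.02)

    def test_short_epoch_rejected(self):
        t = np.arange(0.0, 100.0, 10.0)
        with pytest.raises(ValueError):
            photostability(np.ones(10), t, (0.0, 100.0))


class TestCorrelationImage:
    def test_fwhm_matches_cell_geometry(self, p5_movie):
        movie, _ = p5_movie
        roi = crop_roi(movie, (16.0, 16.0), 60)
        w = pixel_weights(roi, initial_segment(roi))
        ref = extract_trace(roi, w).raw
        img = correlation_image(roi, ref)
        fwhm = correlation_fwhm(img, movie.pixel_size_um)
        assert fwhm == pytest.approx(14.0, abs=3.0)   # 14 um soma

    def test_noise_roi_correlations_small(self):
        rng = np.random.default_rng(5)
        stack = rng.poisson(50.0, (800, 20, 20)).astype(float)
        roi = _as_roi(stack)
        ref = rng.normal(0.0, 1.0, 800)
        img = correlation_image(roi, ref)
        assert np.percentile(np.abs(img), 95) < 0.2

    def test_fwhm_scales_with_pixel_size(self, p5_movie):
        movie, _ = p5_movie
        roi = crop_roi(movie, (16.0, 16.0), 60)
        ref = roi.stack.mean(axis=(1, 2))
        img = correlation_image(roi, ref)
        assert correlation_fwhm(img, 1.0) == pytest.approx(
            2.0 * correlation_fwhm(img, 0.5))

    def test_constant_reference_rejected(self, p5_movie):
        movie, _ = p5_movie
        roi = crop_roi(movie, (16.0, 16.0), 20)
        with pytest.raises(ValueError):
            correlation_image(roi, np.ones(roi.stack.shape[0]))


class TestSbr:
    @staticmethod
    def _roi_with_crosstalk(gain, acq):
        # crosstalk makes every pixel weakly signal-correlated, so the
        # in-target support comes from the known annulus geometry
        cell = CellModel(centroid_um=(16.0, 16.0), expression_F0=500.0)
        movie, truth = render_movie([cell], make_protocol(1),
                                    IlluminationSpec(), acq, seed=21,
                                    background=40.0, crosstalk_gain=gain)
        roi = crop_roi(movie, (16.0, 16.0), 60)
        r0, c0 = roi.origin
        annulus = truth.cell_masks[0][r0:r0 + 60, c0:c0 + 60]
        return roi, pixel_weights(roi, annulus)

    def test_sbr_inverse_in_crosstalk_gain(self, acq_100hz):
        vals = []
        for g in (0.1, 0.2, 0.4):
            roi, w = self._roi_with_crosstalk(g, acq_100hz)
            res = sbr(roi, w, signal_window=(55, 59),
                      baseline_window=(10, 45))
            vals.append(res.value)
        assert vals[0] > vals[1] > vals[2]
        # SBR ~ 1/g: halving the gain doubles the ratio (within noise)
        assert vals[0] / vals[1] == pytest.approx(2.0, rel=0.3)
        assert vals[1] / vals[2] == pytest.approx(2.0, rel=0.3)

    def test_deterministic_on_identical_movies(self, acq_100hz):
        a, wa = self._roi_with_crosstalk(0.2, acq_100hz)
        b, wb = self._roi_with_crosstalk(0.2, acq_100hz)
        ra = sbr(a, wa, signal_window=(55, 59), baseline_window=(10, 45))
        rb = sbr(b, wb, signal_window=(55, 59), baseline_window=(10, 45))
        assert ra.value == rb.value

    def test_zero_background_fluctuation_capped(self):
        stack = np.tile(np.array([[10.0, 0.0], [0.0, 0.0]]), (300, 1, 1))
        stack[150:, 0, 0] = 50.0
        roi = _as_roi(stack)
        from scanvolt.extraction import PixelWeights
        support = np.zeros((2, 2), bool)
        support[0, 0] = True
        w = PixelWeights(support.astype(float), support, 1)
        res = sbr(roi, w, signal_window=(150, 300), baseline_window=(0, 150),
                  background_annulus=~support)
        assert res.capped


def _as_roi(stack):
    from scanvolt.extraction import RoiCrop
    return RoiCrop(stack, (0, 0), (0.0, 0.0), 0.5, 100.0)
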