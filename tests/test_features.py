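"""Calibration, colour means, granularity analysis, luminance and allometry."""

import numpy as np
import pandas as pd
import pytest

from tigermoth.features import (
    GranularitySpectrum,
    allometric_ratios,
    bandpass_filters,
    build_feature_table,
    calibrate_reflectance,
    drop_correlated_features,
    granularity_bands,
    granularity_spectrum,
    luminance_band_histogram,
    pattern_summaries,
    roi_colour_means,
)
from tigermoth.simulate import generate_cohort, simulate_specimen
from tigermoth.specimen import CHANNELS, ROI_LABELS, MultichannelSpecimen

from conftest import noiseless_appearance


def flat_specimen(img: np.ndarray, spec_id: str = "s") -> MultichannelSpecimen:
    """A specimen whose single full-frame ROI (HW) carries ``img`` in every channel."""
    mask = np.full(img.shape, ROI_LABELS["HW"], dtype=np.int64)
    return MultichannelSpecimen(spec_id, {c: img.copy() for c in CHANNELS}, mask)


class TestCalibration:
    def test_standards_map_to_their_reflectances(self):
        raw = np.array([100.0, 900.0, 500.0])
        out = calibrate_reflectance(raw, 100.0, 900.0)
        np.testing.assert_allclose(out, [0.07, 0.93, 0.50], atol=1e-12)

    def test_clipping_and_validation(self):
        out = calibrate_reflectance(np.array([-1e4, 1e6]), 100.0, 900.0)
        assert out[0] == 0.0 and out[1] == 1.0
        with pytest.raises(ValueError):
            calibrate_reflectance(np.zeros(3), 5.0, 5.0)


class TestRoiColourMeans:
    def test_constant_and_split_rasters(self):
        spec = flat_specimen(np.full((10, 10), 0.4))
        means, area = roi_colour_means(spec, "HW")
        assert area == 100
        assert all(m == pytest.approx(0.4) for m in means.values())
        img = np.zeros((10, 10))
        img[:, 5:] = 1.0
        means, _ = roi_colour_means(flat_specimen(img), "HW")
        assert means["uv"] == pytest.approx(0.5)

    def test_matches_naive_pixel_loop(self):
        rng = np.random.default_rng(0)
        img = rng.random((12, 9))
        spec = flat_specimen(img)
        means, area = roi_colour_means(spec, "HW")
        total = 0.0
        for i in range(12):
            for j in range(9):
                total += img[i, j]
        assert means["lw"] == pytest.approx(total / area, rel=1e-12)

    def test_empty_roi_is_a_data_error(self):
        spec = flat_specimen(np.zeros((8, 8)))
        with pytest.raises(ValueError, match="empty"):
            roi_colour_means(spec, "FW")


class TestGranularityBands:
    def test_default_sequence(self):
        scales = granularity_bands()
        assert len(scales) == 12
        np.testing.assert_allclose(scales[:3], [2.0, 2.828, 3.999], atol=1e-3)
        assert scales[-1] == pytest.approx(2.0 * 1.414**11)
        assert scales[-1] < 100 < scales[-1] * 1.414

    def test_short_and_empty_sequences(self):
        np.testing.assert_allclose(granularity_bands(2, 4, 1.414),
                                   [2.0, 2.828, 3.998], atol=1e-2)
        assert len(granularity_bands(2, 1, 1.414)) == 0

    def test_validation(self):
        with pytest.raises(ValueError):
            granularity_bands(0.5)
        with pytest.raises(ValueError):
            granularity_bands(2, 100, 1.0)


class TestGranularitySpectrum:
    def test_constant_image_has_zero_energy_everywhere(self):
        spec = flat_specimen(np.full((64, 64), 0.3))
        gs = granularity_spectrum(spec, "HW", granularity_bands(2, 32))
        np.testing.assert_allclose(gs.energies, 0.0, atol=1e-12)

    def test_grating_peaks_at_matching_scale(self):
        # vertical square grating of period 16 px on a 128 x 128 frame
        x = np.arange(128)
        img = np.where((x // 8) % 2 == 0, 0.8, 0.2)[None, :] * np.ones((128, 1))
        spec = flat_specimen(img)
        gs = granularity_spectrum(spec, "HW")
        peak_scale = gs.scales[np.argmax(gs.energies)]
        nearest = gs.scales[np.argmin(np.abs(gs.scales - 16.0))]
        assert peak_scale == pytest.approx(nearest)

    def test_mean_invariance(self):
        rng = np.random.default_rng(1)
        img = rng.random((48, 48))
        a = granularity_spectrum(flat_specimen(img), "HW", granularity_bands(2, 16))
        b = granularity_spectrum(flat_specimen(img + 0.2), "HW", granularity_bands(2, 16))
        np.testing.assert_allclose(a.energies, b.energies, atol=1e-10)

    def test_linear_scaling_of_energies(self):
        rng = np.random.default_rng(2)
        img = rng.random((48, 48)) * 0.4
        a = granularity_spectrum(flat_specimen(img), "HW", granularity_bands(2, 16))
        b = granularity_spectrum(flat_specimen(img * 2.0), "HW", granularity_bands(2, 16))
        np.testing.assert_allclose(b.energies, 2.0 * a.energies, rtol=1e-10)
        sa, sb = pattern_summaries(a), pattern_summaries(b)
        assert sa["marking_size"] == sb["marking_size"]
        assert sa["diversity"] == pytest.approx(sb["diversity"], rel=1e-10)

    def test_matches_spatial_domain_convolution_oracle(self):
        """Fourier-path energies equal explicit circular convolution.

        The oracle builds each band's spatial kernel with explicit DFT
        matrix exponentials (no numpy FFT) and convolves by a dense
        circulant matrix product.
        """
        rng = np.random.default_rng(3)
        h = w = 64
        img = rng.random((h, w))
        scales = granularity_bands(2, 32)
        spec = flat_specimen(img)
        gs = granularity_spectrum(spec, "HW", scales)
        H = bandpass_filters((h, w), scales)
        # inverse DFT basis, built from first principles
        Eh = np.exp(2j * np.pi * np.outer(np.arange(h), np.arange(h)) / h) / h
        Ew = np.exp(2j * np.pi * np.outer(np.arange(w), np.arange(w)) / w) / w
        ii, jj = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
        for k in range(len(scales)):
            kernel = np.real(Eh @ H[k] @ Ew.T)
            # circulant operator: out[i,j] = sum_{p,q} K[(i-p)%h,(j-q)%w] img[p,q]
            K4 = kernel[(ii[:, :, None, None] - ii[None, None, :, :]) % h,
                        (jj[:, :, None, None] - jj[None, None, :, :]) % w]
            out = np.tensordot(K4, img, axes=([2, 3], [0, 1]))
            assert gs.energies[k] == pytest.approx(out.std(), abs=1e-8)

    def test_warns_when_roi_too_small_for_largest_band(self):
        spec = flat_specimen(np.zeros((32, 32)))
        with pytest.warns(UserWarning, match="largest"):
            granularity_spectrum(spec, "HW", granularity_bands(2, 100))


class TestPatternSummaries:
    @pytest.mark.parametrize(
        "energies,dominance,diversity,peak_idx",
        [
            ((0, 0, 5, 0), 5.0, 1.0, 2),
            ((1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1), 1.0, 1 / 12, 0),
            ((1, 3), 3.0, 0.75, 1),
        ],
    )
    def test_worked_examples(self, energies, dominance, diversity, peak_idx):
        scales = granularity_bands()[: len(energies)]
        s = pattern_summaries(GranularitySpectrum(scales, np.array(energies, dtype=float)))
        assert s["dominance"] == pytest.approx(dominance)
        assert s["diversity"] == pytest.approx(diversity)
        assert s["marking_size"] == pytest.approx(scales[peak_idx])

    def test_all_zero_spectrum_flagged(self):
        s = pattern_summaries(GranularitySpectrum(np.array([2.0, 4.0]), np.zeros(2)))
        assert s["diversity"] == 0.0
        assert "zero_spectrum" in s["flags"]

    def test_tie_broken_to_smallest_scale_and_flagged(self):
        s = pattern_summaries(GranularitySpectrum(np.array([2.0, 4.0, 8.0]),
                                                  np.array([3.0, 3.0, 1.0])))
        assert s["marking_size"] == 2.0
        assert "marking_size_tie" in s["flags"]

    def test_pattern_contrast_is_energy_norm(self):
        s = pattern_summaries(GranularitySpectrum(np.array([2.0, 4.0]), np.array([3.0, 4.0])))
        assert s["pattern_contrast"] == pytest.approx(5.0)


class TestLuminanceHistogram:
    def test_extremes_land_in_first_and_last_band(self):
        lo = flat_specimen(np.zeros((8, 8)))
        hi = flat_specimen(np.ones((8, 8)))
        p_lo = luminance_band_histogram(lo, "HW")
        p_hi = luminance_band_histogram(hi, "HW")
        assert p_lo[0] == 1.0 and p_lo[1:].sum() == 0.0
        assert p_hi[-1] == 1.0 and p_hi[:-1].sum() == 0.0

    def test_uniform_pixels_spread_evenly(self):
        rng = np.random.default_rng(4)
        spec = flat_specimen(rng.random((200, 200)))
        p = luminance_band_histogram(spec, "HW")
        assert p.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.all(np.abs(p - 0.05) < 3 * np.sqrt(0.05 * 0.95 / 40000))


class TestAllometry:
    def test_worked_ratios(self):
        assert allometric_ratios({"FW": 100, "HW": 100, "TH": 100, "AB": 100}) == {
            "FW_AB": 1.0, "FW_TH": 1.0, "FW_HW": 1.0, "TH_AB": 1.0}
        r = allometric_ratios({"FW": 200, "HW": 80, "TH": 50, "AB": 100})
        assert r["FW_AB"] == 2.0 and r["FW_TH"] == 4.0
        assert r["FW_HW"] == 2.5 and r["TH_AB"] == 0.5

    def test_zero_area_rejected(self):
        with pytest.raises(ValueError):
            allometric_ratios({"FW": 0, "HW": 1, "TH": 1, "AB": 1})


class TestFeatureTable:
    def test_schema_and_determinism(self):
        app = noiseless_appearance()
        cohort, _ = generate_cohort((2, 2, 2), "male", app, seed=0)
        with pytest.warns(UserWarning):
            table = build_feature_table(cohort)
        assert len(table) == 6
        metric_cols = [c for c in table.columns
                       if c not in ("id", "genotype", "sex", "clipped", "failed")]
        # 4 ROIs x (area + 4 channels + 4 pattern metrics) + 4 ratios
        assert len(metric_cols) == 4 * 9 + 4
        # identical appearance + noiseless -> identical rows within genotype
        ww = table[table["genotype"] == "WW"][metric_cols]
        assert (ww.iloc[0] == ww.iloc[1]).all()

    def test_luminance_bands_optional(self):
        app = noiseless_appearance()
        cohort, _ = generate_cohort((1, 0, 0), "male", app, seed=0)
        with pytest.warns(UserWarning):
            table = build_feature_table(cohort, include_luminance=True)
        lum_cols = [c for c in table.columns if "_lum_" in c]
        assert len(lum_cols) == 80
        for roi in ("FW", "HW", "TH", "AB"):
            s = sum(table[f"{roi}_lum_{b:02d}"].iloc[0] for b in range(20))
            assert s == pytest.approx(1.0, abs=1e-12)


class TestCorrelationFilter:
    def test_duplicate_column_dropped_once(self):
        rng = np.random.default_rng(5)
        a = rng.random(40)
        df = pd.DataFrame({"a": a, "b": a.copy(), "c": rng.random(40)})
        keep, report = drop_correlated_features(df)
        assert ("a" in keep) != ("b" in keep)
        assert "c" in keep

    def test_independent_noise_retained(self):
        rng = np.random.default_rng(6)
        df = pd.DataFrame(rng.random((200, 6)), columns=list("abcdef"))
        keep, report = drop_correlated_features(df, threshold=0.9)
        assert keep == list("abcdef")
        assert report == []

    def test_constant_column_dropped_with_reason(self):
        df = pd.DataFrame({"x": np.ones(10), "y": np.arange(10.0)})
        keep, report = drop_correlated_features(df)
        assert keep == ["y"]
        assert report[0]["reason"] == "zero variance"
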