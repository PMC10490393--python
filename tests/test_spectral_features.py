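"""Spectral preprocessing, wavelet detail reconstruction, correlation
screening, and feature-index selection."""

import numpy as np
import pytest
import pywt
from scipy.signal import savgol_coeffs

from chillspec import (WaveletConfig, continuum_removal, correlation_spectrum,
                       extract_feature_bands, first_derivative, mean_filter,
                       select_feature_set, spectral_indices, wavelet_details)
from chillspec.spectral_features import (SpectralScheme, evaluate_schemes,
                                         feature_table)
from chillspec.synthetic_cohort import reflectance_wavelengths

WL = reflectance_wavelengths()


class TestMeanFilter:
    def test_constant_unchanged(self):
        x = np.full(224, 0.3)
        np.testing.assert_allclose(mean_filter(x), x, atol=1e-12)

    def test_cubic_reproduced(self):
        t = np.linspace(-1.0, 1.0, 224)
        x = 0.4 + 0.3 * t - 0.2 * t ** 2 + 0.5 * t ** 3
        np.testing.assert_allclose(mean_filter(x), x, atol=1e-10)

    def test_spike_matches_direct_convolution(self):
        """Interior response to a unit impulse equals convolution with the
        precomputed smoothing coefficients."""
        x = np.zeros(224)
        x[100] = 1.0
        coeffs = savgol_coeffs(13, 3)
        expected = np.convolve(x, coeffs, mode="same")
        out = mean_filter(x)
        np.testing.assert_allclose(out[20:-20], expected[20:-20], atol=1e-12)

    @pytest.mark.parametrize("window, poly", [(12, 3), (3, 3), (301, 3)])
    def test_invalid_window_rejected(self, window, poly):
        with pytest.raises(ValueError):
            mean_filter(np.ones(224), window=window, poly=poly)


class TestContinuumRemoval:
    def test_concave_spectrum_all_ones(self):
        x = np.linspace(0.0, 1.0, 50)
        r = 1.0 - (x - 0.5) ** 2
        np.testing.assert_allclose(continuum_removal(x, r), 1.0, atol=1e-12)

    def test_endpoints_anchored_at_one(self, rng):
        r = 0.2 + 0.6 * rng.random(224)
        out = continuum_removal(WL, r)
        assert out[0] == 1.0 and out[-1] == 1.0
        assert np.all(out > 0) and np.all(out <= 1.0)

    def test_v_shape_matches_hand_computation(self):
        wl = np.array([400.0, 500.0, 600.0])
        r = np.array([1.0, 0.2, 1.0])
        # hull is the chord between the endpoints: value 1.0 at 500 nm
        np.testing.assert_allclose(continuum_removal(wl, r), [1.0, 0.2, 1.0])

    def test_nonpositive_reflectance_rejected(self):
        with pytest.raises(ValueError):
            continuum_removal(np.array([1.0, 2.0, 3.0]),
                              np.array([0.5, -0.1, 0.4]))


class TestFirstDerivative:
    def test_linear_spectrum_constant_slope(self):
        out = first_derivative(WL, 0.002 * WL + 1.0)
        np.testing.assert_allclose(out, 0.002, atol=1e-12)

    def test_constant_spectrum_zero(self):
        np.testing.assert_allclose(first_derivative(WL, np.full(224, 0.4)),
                                   0.0, atol=1e-15)

    def test_matches_finite_difference_oracle(self, rng):
        v = rng.random(224)
        out = first_derivative(WL, v)
        h = WL[1] - WL[0]
        interior = (v[2:] - v[:-2]) / (2 * h)
        np.testing.assert_allclose(out[1:-1], interior, atol=1e-10)
        assert out[0] == pytest.approx((v[1] - v[0]) / h)
        assert out[-1] == pytest.approx((v[-1] - v[-2]) / h)


class TestWaveletDetails:
    def test_constant_input_vanishing_details(self):
        details, _ = wavelet_details(np.full(224, 0.7))
        for series in details.values():
            assert np.max(np.abs(series)) < 1e-10

    def test_perfect_reconstruction(self, rng):
        x = rng.random(224)
        details, approx = wavelet_details(x)
        recon = approx + sum(details.values())
        np.testing.assert_allclose(recon, x, atol=1e-8)

    def test_impulse_matches_independent_reconstruction(self):
        """Unit impulse: per-level series equal an independently coded
        zero-and-reconstruct pass over the wavelet coefficients."""
        x = np.zeros(224)
        x[100] = 1.0
        details, _ = wavelet_details(x)
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            coeffs = pywt.wavedec(x, "bior1.3", mode="symmetric", level=6)
        for j in range(1, 7):
            ref = [c.copy() for c in coeffs]
            for i in range(len(ref)):
                if i != len(ref) - j:
                    ref[i][:] = 0.0
            rec = pywt.waverec(ref, "bior1.3", mode="symmetric")[:224]
            np.testing.assert_allclose(details[f"CD{j}"], rec, atol=1e-12)

    def test_too_many_levels_rejected(self):
        with pytest.raises(ValueError):
            wavelet_details(np.ones(64), WaveletConfig(n_levels=7))


class TestCorrelationSpectrum:
    def test_band_identical_to_score(self, rng):
        y = rng.normal(size=100)
        X = np.column_stack([y, -y, rng.normal(size=100)])
        r, flags = correlation_spectrum(X, y)
        assert r[0] == pytest.approx(1.0)
        assert r[1] == pytest.approx(-1.0)
        assert not flags.any()

    def test_zero_variance_band_flagged(self, rng):
        y = rng.normal(size=50)
        X = np.column_stack([np.ones(50), y])
        r, flags = correlation_spectrum(X, y)
        assert flags[0] and r[0] == 0.0

    def test_independent_band_has_small_correlation(self):
        rng = np.random.default_rng(202)
        y = rng.normal(size=432)
        X = rng.normal(size=(432, 50))
        r, _ = correlation_spectrum(X, y)
        assert np.all(np.abs(r) < 0.2)

    def test_length_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            correlation_spectrum(rng.normal(size=(10, 3)), rng.normal(size=9))


class TestExtractFeatureBands:
    def test_max_and_min_bands(self):
        r = np.array([0.1, 0.9, -0.3, 0.4, -0.7])
        ba, bb = extract_feature_bands(r)
        assert (ba, bb) == (1, 4)

    def test_all_positive_falls_to_least_positive(self):
        r = np.array([0.5, 0.2, 0.8, 0.3])
        ba, bb = extract_feature_bands(r)
        assert (ba, bb) == (2, 1)

    def test_ties_break_toward_shorter_wavelength(self):
        r = np.array([0.2, 0.9, 0.4, 0.9, -0.5, -0.5])
        ba, bb = extract_feature_bands(r)
        assert (ba, bb) == (1, 4)

    def test_all_flagged_rejected(self):
        with pytest.raises(ValueError):
            extract_feature_bands(np.zeros(4), np.ones(4, dtype=bool))


class TestSpectralIndices:
    def test_basic_arithmetic(self):
        out = spectral_indices(np.array([3.0]), np.array([1.0]))
        assert out["diff"][0] == 2.0
        assert out["ratio"][0] == 3.0
        assert out["norm"][0] == 0.5

    def test_equal_bands(self):
        out = spectral_indices(np.array([2.0]), np.array([2.0]))
        assert out["diff"][0] == 0.0
        assert out["ratio"][0] == 1.0
        assert out["norm"][0] == 0.0

    def test_vanishing_denominators_flagged(self):
        out = spectral_indices(np.array([1.0, 1.0]), np.array([0.0, -1.0]))
        assert np.isnan(out["ratio"][0])
        assert np.isnan(out["norm"][1])


def _stub_scheme(transform, level, best_r):
    """Scheme carrying only what selection needs."""
    n = 4
    vals = {f: np.zeros(n) for f in ("Ba", "Bb", "diff", "ratio", "norm")}
    return SpectralScheme(transform=transform, level=level,
                          series=np.zeros((n, 2)), r=np.zeros(2),
                          flags=np.zeros(2, bool), Ba_index=0, Bb_index=1,
                          Ba_wavelength=(0.0, 0.0), Bb_wavelength=(0.0, 0.0),
                          index_values=vals,
                          index_r={"Ba": best_r, "Bb": 0.0, "diff": 0.0,
                                   "ratio": 0.0, "norm": 0.0})


class TestSelectFeatureSet:
    def test_threshold_zero_selects_all(self, small_cohort, small_cspc):
        _, records = small_cohort
        _, result = small_cspc
        wl = records[0].reflectance.wavelength
        R = np.vstack([r.reflectance.reflectance for r in records])
        schemes = evaluate_schemes(wl, R, result["CSPC"].to_numpy())
        assert len(schemes) == 21
        assert len(select_feature_set(schemes, threshold=0.0)) == 21

    def test_impossible_threshold_falls_back_to_top_six(self):
        schemes = [_stub_scheme("mean_filter", f"CD{j}", 0.1 * j)
                   for j in range(1, 7)] + [_stub_scheme("m", "origin", 0.05)]
        with pytest.warns(UserWarning):
            chosen = select_feature_set(schemes, threshold=1.0)
        assert len(chosen) == 6
        assert chosen[0].scheme_id == "mean_filter:CD6"

    def test_planted_signal_recovered_near_882nm(self, small_cohort,
                                                 small_cspc):
        """The generator ties reflectance near 882 nm to latent stress; a
        selected scheme's Ba must land within 8 nm of it."""
        _, records = small_cohort
        _, result = small_cspc
        wl = records[0].reflectance.wavelength
        R = np.vstack([r.reflectance.reflectance for r in records])
        schemes = evaluate_schemes(wl, R, result["CSPC"].to_numpy())
        chosen = select_feature_set(schemes, threshold=0.5)
        hits = [f for f in chosen
                if any(abs(w - 882.0) <= 8.0 for w in f.Ba_wavelength)]
        assert hits

    def test_selection_deterministic(self, small_cohort, small_cspc):
        _, records = small_cohort
        _, result = small_cspc
        wl = records[0].reflectance.wavelength
        R = np.vstack([r.reflectance.reflectance for r in records])
        ids1 = [f.scheme_id for f in select_feature_set(
            evaluate_schemes(wl, R, result["CSPC"].to_numpy()))]
        ids2 = [f.scheme_id for f in select_feature_set(
            evaluate_schemes(wl, R, result["CSPC"].to_numpy()))]
        assert ids1 == ids2

    def test_feature_table_shape(self, small_cohort, small_cspc):
        _, records = small_cohort
        _, result = small_cspc
        wl = records[0].reflectance.wavelength
        R = np.vstack([r.reflectance.reflectance for r in records])
        chosen = select_feature_set(
            evaluate_schemes(wl, R, result["CSPC"].to_numpy()))
        table = feature_table(chosen, index=result.index)
        assert table.shape == (len(records), len(chosen))
        assert not table.isna().any().any()
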