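"""Complex-spectrum features: bin plan, DFT oracle, concatenation layout."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fbccnn.spectrum import (
    assemble_features,
    complex_spectrum,
    make_spectrum_spec,
)


def naive_dft(x, fft_length, bins):
    """O(N^2) DFT-sum oracle at the retained bins."""
    n = np.arange(fft_length)
    padded = np.zeros(fft_length)
    padded[: len(x)] = x
    out = []
    for k in bins:
        w = np.exp(-2j * np.pi * k * n / fft_length)
        out.append(np.sum(padded * w))
    return np.array(out)


class TestSpec:
    def test_default_plan_at_256hz(self):
        sp = make_spectrum_spec(256.0, 0.293, (3.0, 35.0))
        assert sp.fft_length == 874
        assert sp.realized_resolution == pytest.approx(256 / 874)
        assert sp.realized_resolution <= 0.293
        assert sp.n_bins == 110

    def test_single_bin_band(self):
        sp = make_spectrum_spec(256.0, 1.0, (10.0, 10.0))
        assert sp.n_bins == 1

    def test_inverted_band_rejected(self):
        with pytest.raises(ValueError, match="band"):
            make_spectrum_spec(256.0, 0.293, (40.0, 35.0))

    def test_bin_frequencies_cover_band(self):
        sp = make_spectrum_spec(256.0)
        f = sp.bin_frequencies
        assert len(f) == sp.n_bins
        df = sp.realized_resolution
        assert f[0] <= 3.0 < f[0] + df
        assert f[-1] <= 35.0 < f[-1] + df


class TestComplexSpectrum:
    def test_zero_window_all_zero(self):
        sp = make_spectrum_spec(256.0)
        out = complex_spectrum(np.zeros((3, 256)), sp)
        assert out.shape == (3, 2 * sp.n_bins)
        assert np.allclose(out, 0.0)

    def test_matches_naive_dft_on_bin_sinusoid(self):
        sp = make_spectrum_spec(256.0)
        k = sp.bin_lo + 20
        f = k * sp.realized_resolution
        t = np.arange(256) / 256.0
        x = np.sin(2 * np.pi * f * t)
        feats = complex_spectrum(x[None, :], sp)[0]
        oracle = naive_dft(x, sp.fft_length, range(sp.bin_lo, sp.bin_hi + 1))
        got = feats[: sp.n_bins] + 1j * feats[sp.n_bins :]
        scale = np.abs(oracle).max()
        assert np.abs(got - oracle).max() / scale < 1e-9
        mags = np.abs(got)
        assert mags.argmax() == k - sp.bin_lo

    def test_random_windows_match_oracle(self):
        sp = make_spectrum_spec(256.0)
        rng = np.random.default_rng(0)
        for _ in range(5):
            x = rng.standard_normal(256)
            feats = complex_spectrum(x[None, :], sp)[0]
            got = feats[: sp.n_bins] + 1j * feats[sp.n_bins :]
            oracle = naive_dft(x, sp.fft_length, range(sp.bin_lo, sp.bin_hi + 1))
            assert np.abs(got - oracle).max() / np.abs(oracle).max() < 1e-9

    def test_overlong_window_rejected(self):
        sp = make_spectrum_spec(256.0)
        with pytest.raises(ValueError, match="exceeds"):
            complex_spectrum(np.zeros((1, sp.fft_length + 1)), sp)

    def test_parseval_on_full_transform(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(874)
        spec_full = np.fft.fft(x)
        assert np.sum(np.abs(spec_full) ** 2) == pytest.approx(
            874 * np.sum(x**2), rel=1e-10
        )

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(a=st.floats(-3, 3), b=st.floats(-3, 3), seed=st.integers(0, 100))
    def test_linearity(self, a, b, seed):
        sp = make_spectrum_spec(256.0, 1.0, (5.0, 20.0))
        rng = np.random.default_rng(seed)
        x, y = rng.standard_normal((2, 2, 64))
        lhs = complex_spectrum(a * x + b * y, sp)
        rhs = a * complex_spectrum(x, sp) + b * complex_spectrum(y, sp)
        np.testing.assert_allclose(lhs, rhs, atol=1e-9)


class TestAssemble:
    @pytest.mark.parametrize("nfb", [1, 3, 7])
    def test_column_count(self, nfb):
        sp = make_spectrum_spec(256.0)
        rng = np.random.default_rng(nfb)
        bands = [rng.standard_normal((4, 8, 256)) for _ in range(nfb)]
        feats = assemble_features(bands, sp)
        assert feats.matrix.shape == (4, 8, 2 * sp.n_bins * nfb)
        assert len(feats.columns) == 2 * sp.n_bins * nfb

    def test_expected_decoder_matrix_shape(self):
        # 8 channels, NFFT=110, 3 bands -> 8 x 660
        sp = make_spectrum_spec(256.0)
        bands = [np.zeros((1, 8, 256))] * 3
        feats = assemble_features(bands, sp)
        assert feats.matrix.shape[1:] == (8, 660)

    def test_single_band_identity(self):
        sp = make_spectrum_spec(256.0)
        x = np.random.default_rng(2).standard_normal((2, 3, 256))
        feats = assemble_features([x], sp)
        np.testing.assert_array_equal(feats.matrix, complex_spectrum(x, sp))

    def test_permuted_band_order_rejected(self):
        sp = make_spectrum_spec(256.0)
        bands = [np.zeros((1, 2, 64))] * 3
        with pytest.raises(ValueError, match="ascending order"):
            assemble_features(bands, sp, band_indices=[0, 2, 1])

    def test_inconsistent_shapes_rejected(self):
        sp = make_spectrum_spec(256.0)
        with pytest.raises(ValueError, match="inconsistent"):
            assemble_features([np.zeros((1, 2, 64)), np.zeros((1, 2, 65))], sp)

    def test_layout_descriptor_roundtrip(self):
        sp = make_spectrum_spec(256.0, 1.0, (5.0, 10.0))
        bands = [np.zeros((1, 2, 64))] * 2
        feats = assemble_features(bands, sp)
        n = sp.n_bins
        for col, (band, part, freq) in enumerate(feats.columns):
            assert band == col // (2 * n)
            within = col % (2 * n)
            assert part == ("re" if within < n else "im")
            assert freq == pytest.approx(sp.bin_frequencies[within % n])
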