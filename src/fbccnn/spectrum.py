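"""Complex-spectrum feature construction.

Each band-filtered window is zero-padded to an FFT length chosen from a
target frequency resolution, transformed, and the real and imaginary
parts of the retained low-frequency bins are kept as separate features.
Bands are concatenated side by side, giving the
``Nch x (2 * NFFT * Nfb)`` input matrix of the decoder: per band, the
``NFFT`` real-part columns precede the ``NFFT`` imaginary-part columns.

Bin retention uses a coverage rule: bin ``k`` (frequency ``k*fs/nfft``)
is kept for ``floor(f_lo/df) <= k <= floor(f_hi/df)``, i.e. the bins
whose resolution cells cover the requested band. At the defaults
(0.293 Hz resolution, 3-35 Hz band, fs=256) this retains NFFT=110 bins.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .epochs import EpochSet

__all__ = [
    "SpectrumSpec",
    "ComplexSpectrumFeatures",
    "make_spectrum_spec",
    "complex_spectrum",
    "assemble_features",
    "ComplexSpectrum",
]

DEFAULT_RESOLUTION_HZ = 0.293
DEFAULT_BAND_HZ = (3.0, 35.0)


@dataclass(frozen=True)
class SpectrumSpec:
    """FFT feature-extraction plan derived from a target resolution.

    Attributes
    ----------
    fs : float
        Sampling rate in Hz.
    resolution : float
        Requested frequency resolution; the realized resolution
        ``fs / fft_length`` never exceeds it.
    band : (float, float)
        Retained frequency band (Hz).
    fft_length : int
        ``ceil(fs / resolution)`` samples.
    bin_lo, bin_hi : int
        First and last retained FFT bin indices (inclusive).
    """

    fs: float
    resolution: float
    band: tuple[float, float]
    fft_length: int
    bin_lo: int
    bin_hi: int

    @property
    def n_bins(self) -> int:
        """NFFT: number of retained frequency components per channel per band."""
        return self.bin_hi - self.bin_lo + 1

    @property
    def realized_resolution(self) -> float:
        return self.fs / self.fft_length

    @property
    def bin_frequencies(self) -> np.ndarray:
        """Center frequencies (Hz) of the retained bins."""
        return np.arange(self.bin_lo, self.bin_hi + 1) * self.realized_resolution


@dataclass
class ComplexSpectrumFeatures:
    """The ``Nch x (2*NFFT*Nfb)`` decoder input with its column layout.

    ``matrix`` stacks windows: shape ``(n_windows, Nch, 2*NFFT*Nfb)``.
    ``columns`` records, per column, ``(band_index, part, bin_frequency)``
    with ``part`` in {"re", "im"}.
    """

    matrix: np.ndarray
    columns: list[tuple[int, str, float]] = field(repr=False)
    n_bands: int = 1
    n_bins: int = 0

    def __post_init__(self) -> None:
        if self.matrix.shape[-1] != len(self.columns):
            raise ValueError("layout descriptor does not match matrix width")
        if self.matrix.shape[-1] != 2 * self.n_bins * self.n_bands:
            raise ValueError(
                f"matrix width {self.matrix.shape[-1]} != 2*NFFT*Nfb = "
                f"{2 * self.n_bins * self.n_bands}"
            )


def make_spectrum_spec(
    fs: float,
    resolution: float = DEFAULT_RESOLUTION_HZ,
    band: tuple[float, float] = DEFAULT_BAND_HZ,
) -> SpectrumSpec:
    """Derive the FFT length and retained-bin range.

    Raises
    ------
    ValueError
        For an inverted/out-of-range band or a band retaining no bins.
    """
    f_lo, f_hi = band
    if not 0 < f_lo <= f_hi or f_hi > fs / 2:
        raise ValueError(f"band must satisfy 0 < f_lo <= f_hi <= fs/2, got {band}")
    if resolution <= 0:
        raise ValueError("resolution must be positive")
    fft_length = int(np.ceil(fs / resolution))
    df = fs / fft_length
    bin_lo = int(np.floor(f_lo / df))
    bin_hi = int(np.floor(f_hi / df))
    if bin_hi < bin_lo:
        raise ValueError(f"band {band} retains no FFT bins at resolution {df}")
    return SpectrumSpec(
        fs=fs, resolution=resolution, band=(f_lo, f_hi),
        fft_length=fft_length, bin_lo=bin_lo, bin_hi=bin_hi,
    )


def complex_spectrum(window: np.ndarray, spec: SpectrumSpec) -> np.ndarray:
    """Real/imaginary FFT features of one or more windows.

    Parameters
    ----------
    window : ndarray, (..., channels, samples)
        Time-domain data; zero-padded to ``spec.fft_length``.

    Returns
    -------
    ndarray, (..., channels, 2*NFFT)
        Real parts of the retained bins followed by imaginary parts.
    """
    window = np.asarray(window, dtype=np.float64)
    n = window.shape[-1]
    if n > spec.fft_length:
        raise ValueError(
            f"window of {n} samples exceeds fft_length {spec.fft_length}"
        )
    spec_full = np.fft.rfft(window, n=spec.fft_length, axis=-1)
    kept = spec_full[..., spec.bin_lo : spec.bin_hi + 1]
    return np.concatenate([kept.real, kept.imag], axis=-1)


def assemble_features(
    band_windows: list[np.ndarray],
    spec: SpectrumSpec,
    band_indices: list[int] | None = None,
) -> ComplexSpectrumFeatures:
    """Concatenate per-band complex spectra into the decoder input matrix.

    Parameters
    ----------
    band_windows : list of ndarray, each (..., channels, samples)
        Time-domain windows of each sub-band, ascending band order.
    band_indices : list of int, optional
        Explicit 0-based band indices; must be ``0..Nfb-1`` in order
        (passing a permutation is an error: column layout is positional).

    Returns
    -------
    ComplexSpectrumFeatures
    """
    if not band_windows:
        raise ValueError("no bands given")
    shapes = {bw.shape for bw in band_windows}
    if len(shapes) != 1:
        raise ValueError(f"bands have inconsistent shapes: {sorted(shapes)}")
    n_bands = len(band_windows)
    if band_indices is not None and list(band_indices) != list(range(n_bands)):
        raise ValueError(
            f"bands must be supplied in ascending order 0..{n_bands - 1}, "
            f"got {list(band_indices)}"
        )
    blocks = [complex_spectrum(bw, spec) for bw in band_windows]
    matrix = np.concatenate(blocks, axis=-1)
    freqs = spec.bin_frequencies
    columns = [
        (b, part, float(f))
        for b in range(n_bands)
        for part in ("re", "im")
        for f in freqs
    ]
    return ComplexSpectrumFeatures(
        matrix=matrix, columns=columns, n_bands=n_bands, n_bins=spec.n_bins
    )


class ComplexSpectrum:
    """Transformer: band-filtered windows -> complex-spectrum features.

    Parameters
    ----------
    resolution_hz : float
        Target FFT resolution (Hz).
    band_hz : (float, float)
        Retained band (Hz).
    """

    def __init__(self, resolution_hz: float = DEFAULT_RESOLUTION_HZ,
                 band_hz: tuple[float, float] = DEFAULT_BAND_HZ):
        self.resolution_hz = resolution_hz
        self.band_hz = band_hz

    def get_params(self, deep: bool = True) -> dict:
        return {"resolution_hz": self.resolution_hz, "band_hz": self.band_hz}

    def set_params(self, **params) -> "ComplexSpectrum":
        for k, v in params.items():
            if not hasattr(self, k):
                raise ValueError(f"invalid parameter {k!r} for ComplexSpectrum")
            setattr(self, k, v)
        return self

    def fit(self, band_epochs: list[EpochSet] | EpochSet, y=None) -> "ComplexSpectrum":
        first = band_epochs[0] if isinstance(band_epochs, list) else band_epochs
        self.spec_ = make_spectrum_spec(first.fs, self.resolution_hz,
                                        tuple(self.band_hz))
        return self

    def transform(
        self, band_epochs: list[EpochSet] | EpochSet
    ) -> ComplexSpectrumFeatures:
        if not hasattr(self, "spec_"):
            raise RuntimeError("ComplexSpectrum is not fitted; call fit() first")
        if isinstance(band_epochs, EpochSet):
            band_epochs = [band_epochs]
        return assemble_features([e.data for e in band_epochs], self.spec_)

    def fit_transform(self, band_epochs, y=None) -> ComplexSpectrumFeatures:
        return self.fit(band_epochs).transform(band_epochs)
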