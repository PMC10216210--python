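"""Chebyshev Type I zero-phase filter bank.

Sub-band ``n`` (1-based) passes ``n*8`` to ``88`` Hz, the standard SSVEP
filter-bank plan: each band strips one more low-order harmonic region so
the network can weigh harmonic content independently. Filters are applied
forward-backward (zero phase), so the realized magnitude response is the
squared design response; the ``ripple_db`` / ``atten_db`` settings are the
end-to-end tolerances of that zero-phase realization, and each one-way
design therefore uses half of them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .epochs import EpochSet

__all__ = ["FilterBankSpec", "design_filter_bank", "apply_filter_bank", "FilterBank"]

BAND_STEP_HZ = 8.0
BAND_HIGH_HZ = 88.0
STOP_MARGIN_HZ = 6.0


@dataclass
class FilterBankSpec:
    """Designed sub-band filter bank.

    Attributes
    ----------
    n_bands : int
        Number of sub-bands ``Nfb``.
    passbands : list of (low, high) Hz pairs
        Band ``n`` spans ``(n*8, 88)`` Hz.
    fs : float
        Sampling rate the coefficients were designed for.
    ripple_db, atten_db, transition_hz : float
        End-to-end (zero-phase) passband ripple, stopband attenuation and
        lower transition width used in order selection.
    sos : list of second-order-section arrays, one per band.
    """

    n_bands: int
    passbands: list[tuple[float, float]]
    fs: float
    ripple_db: float
    atten_db: float
    transition_hz: float
    sos: list[np.ndarray] = field(repr=False, default_factory=list)


def design_filter_bank(
    n_bands: int,
    fs: float,
    *,
    ripple_db: float = 3.0,
    atten_db: float = 40.0,
    transition_hz: float = STOP_MARGIN_HZ,
) -> FilterBankSpec:
    """Design ``n_bands`` Chebyshev-I band-pass filters for zero-phase use.

    Band ``n`` (1-based) has passband ``[n*8, 88]`` Hz and stopband edges
    ``[max(n*8 - transition, 2), 88 + transition]`` Hz; the order is chosen
    by :func:`scipy.signal.cheb1ord` so the forward-backward application
    meets ``ripple_db`` / ``atten_db``.

    Raises
    ------
    ValueError
        If ``n_bands`` is non-positive, the last band would be empty, or
        88 Hz is not below Nyquist.
    """
    if n_bands <= 0:
        raise ValueError("n_bands must be positive")
    if n_bands * BAND_STEP_HZ >= BAND_HIGH_HZ:
        raise ValueError(
            f"band {n_bands} would start at {n_bands * BAND_STEP_HZ} Hz, "
            f"at or above the common 88 Hz upper edge"
        )
    if BAND_HIGH_HZ >= fs / 2:
        raise ValueError(
            f"upper band edge {BAND_HIGH_HZ} Hz requires fs > {2 * BAND_HIGH_HZ} Hz, "
            f"got fs={fs}"
        )
    nyq = fs / 2
    passbands: list[tuple[float, float]] = []
    sos_list: list[np.ndarray] = []
    for n in range(1, n_bands + 1):
        lo, hi = n * BAND_STEP_HZ, BAND_HIGH_HZ
        stop_lo = max(lo - transition_hz, 2.0)
        stop_hi = min(hi + transition_hz, nyq * 0.99)
        # one-way spec = half the end-to-end (filtfilt) tolerance
        order, wn = signal.cheb1ord(
            [lo / nyq, hi / nyq],
            [stop_lo / nyq, stop_hi / nyq],
            gpass=ripple_db / 2,
            gstop=atten_db / 2,
        )
        sos = signal.cheby1(order, ripple_db / 2, wn, btype="bandpass", output="sos")
        for section in sos:
            r = np.roots(section[3:])
            if np.any(np.abs(r) >= 1.0):
                raise RuntimeError(f"unstable filter design for band ({lo}, {hi}) Hz")
        passbands.append((lo, hi))
        sos_list.append(sos)
    return FilterBankSpec(
        n_bands=n_bands,
        passbands=passbands,
        fs=fs,
        ripple_db=ripple_db,
        atten_db=atten_db,
        transition_hz=transition_hz,
        sos=sos_list,
    )


def _padlen(sos: np.ndarray) -> int:
    # odd-symmetric edge padding of 3x the effective order
    return 3 * (2 * sos.shape[0])


def apply_filter_bank(epochs: EpochSet, spec: FilterBankSpec) -> list[EpochSet]:
    """Filter every trial/channel through each sub-band, zero phase.

    Returns one :class:`EpochSet` per band, in ascending band order, with
    shapes identical to the input.

    Raises
    ------
    ValueError
        On sampling-rate mismatch or epochs shorter than the filter
        warm-up (padding) length.
    """
    if epochs.fs != spec.fs:
        raise ValueError(
            f"epochs sampled at {epochs.fs} Hz but filters designed for {spec.fs} Hz"
        )
    out = []
    for sos in spec.sos:
        padlen = _padlen(sos)
        if epochs.n_samples <= padlen:
            raise ValueError(
                f"epoch length {epochs.n_samples} samples <= filter warm-up "
                f"padding {padlen}; epochs too short for zero-phase filtering"
            )
        filtered = signal.sosfiltfilt(sos, epochs.data, axis=-1, padtype="odd",
                                      padlen=padlen)
        out.append(epochs.with_data(filtered))
    return out


class FilterBank:
    """Transformer wrapper over the sub-band decomposition.

    scikit-learn style: ``fit`` designs the filters for the training
    sampling rate, ``transform`` maps an :class:`EpochSet` to the list of
    band-filtered EpochSets.

    Parameters
    ----------
    n_bands : int
        Number of sub-bands.
    ripple_db, atten_db, transition_hz : float
        Zero-phase design tolerances (see :func:`design_filter_bank`).
    """

    def __init__(self, n_bands: int = 3, *, ripple_db: float = 3.0,
                 atten_db: float = 40.0, transition_hz: float = STOP_MARGIN_HZ):
        self.n_bands = n_bands
        self.ripple_db = ripple_db
        self.atten_db = atten_db
        self.transition_hz = transition_hz

    def get_params(self, deep: bool = True) -> dict:
        return {
            "n_bands": self.n_bands,
            "ripple_db": self.ripple_db,
            "atten_db": self.atten_db,
            "transition_hz": self.transition_hz,
        }

    def set_params(self, **params) -> "FilterBank":
        for k, v in params.items():
            if not hasattr(self, k):
                raise ValueError(f"invalid parameter {k!r} for FilterBank")
            setattr(self, k, v)
        return self

    def fit(self, epochs: EpochSet, y=None) -> "FilterBank":
        self.spec_ = design_filter_bank(
            self.n_bands,
            epochs.fs,
            ripple_db=self.ripple_db,
            atten_db=self.atten_db,
            transition_hz=self.transition_hz,
        )
        return self

    def transform(self, epochs: EpochSet) -> list[EpochSet]:
        if not hasattr(self, "spec_"):
            raise RuntimeError("FilterBank is not fitted; call fit() first")
        return apply_filter_bank(epochs, self.spec_)

    def fit_transform(self, epochs: EpochSet, y=None) -> list[EpochSet]:
        return self.fit(epochs).transform(epochs)
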