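"""Core data containers for epoched SSVEP recordings.

An :class:`EpochSet` is the universal currency between pipeline stages:
labelled, stimulus-locked, multi-channel EEG segments together with the
sampling rate and the stimulus frequency/phase table
(:class:`StimulusLayout`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["StimulusLayout", "EpochSet"]


@dataclass(frozen=True)
class StimulusLayout:
    """Frequency/phase table of a flicker-coded stimulus matrix.

    Target ``k`` flickers at ``f0 + k*delta_f`` Hz with initial phase
    ``phi0 + k*delta_phi`` radians (phases taken mod 2*pi).

    Parameters
    ----------
    n_targets : int
        Number of stimulus targets ``N`` (>= 2).
    f0 : float
        Base stimulation frequency in Hz.
    delta_f : float
        Frequency increment between consecutive targets in Hz.
    phi0 : float
        Base stimulation phase in radians.
    delta_phi : float
        Phase increment between consecutive targets in radians.
    """

    n_targets: int
    f0: float
    delta_f: float
    phi0: float = 0.0
    delta_phi: float = 0.0

    def __post_init__(self) -> None:
        if self.n_targets < 2:
            raise ValueError(
                f"a stimulus layout needs at least 2 targets, got {self.n_targets}"
            )
        if np.any(self.frequencies <= 0):
            raise ValueError("all stimulus frequencies must be strictly positive")

    @property
    def frequencies(self) -> np.ndarray:
        """Stimulation frequencies in Hz, one per target."""
        return self.f0 + self.delta_f * np.arange(self.n_targets)

    @property
    def phases(self) -> np.ndarray:
        """Stimulation phases in radians (mod 2*pi), one per target."""
        return np.mod(self.phi0 + self.delta_phi * np.arange(self.n_targets), 2 * np.pi)

    def validate_nyquist(self, fs: float) -> None:
        """Raise if any fundamental exceeds the Nyquist frequency of ``fs``."""
        fmax = float(self.frequencies.max())
        if fmax >= fs / 2:
            raise ValueError(
                f"stimulus frequency {fmax} Hz is not below Nyquist ({fs / 2} Hz)"
            )


@dataclass
class EpochSet:
    """Labelled raw EEG epochs with sampling rate and stimulus table.

    Attributes
    ----------
    data : ndarray of shape (n_trials, n_channels, n_samples)
        Epoch amplitudes (microvolt-like arbitrary scale).
    fs : float
        Sampling rate in Hz.
    labels : ndarray of shape (n_trials,)
        Target index per trial, each in ``[0, layout.n_targets)``.
    layout : StimulusLayout
        Stimulus frequency/phase table.
    block_id : ndarray of shape (n_trials,)
        Experimental block index per trial.
    trial_id : ndarray of shape (n_trials,)
        Stable per-trial identifier, used to audit train/test leakage
        after windowing.
    """

    data: np.ndarray
    fs: float
    labels: np.ndarray
    layout: StimulusLayout
    block_id: np.ndarray
    trial_id: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        self.block_id = np.asarray(self.block_id, dtype=np.int64)
        if self.trial_id is None:
            self.trial_id = np.arange(self.n_trials, dtype=np.int64)
        else:
            self.trial_id = np.asarray(self.trial_id, dtype=np.int64)
        if self.data.ndim != 3:
            raise ValueError(
                f"data must be (trials, channels, samples), got shape {self.data.shape}"
            )
        n = self.n_trials
        for name, arr in (
            ("labels", self.labels),
            ("block_id", self.block_id),
            ("trial_id", self.trial_id),
        ):
            if arr.shape != (n,):
                raise ValueError(f"{name} must have shape ({n},), got {arr.shape}")
        if n and (self.labels.min() < 0 or self.labels.max() >= self.layout.n_targets):
            raise ValueError(
                f"labels must lie in [0, {self.layout.n_targets}), "
                f"found range [{self.labels.min()}, {self.labels.max()}]"
            )

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def select(self, idx: np.ndarray) -> "EpochSet":
        """Return a new EpochSet containing the trials in ``idx`` (in order)."""
        idx = np.asarray(idx, dtype=np.int64)
        return EpochSet(
            data=self.data[idx],
            fs=self.fs,
            labels=self.labels[idx],
            layout=self.layout,
            block_id=self.block_id[idx],
            trial_id=self.trial_id[idx],
        )

    def with_data(self, data: np.ndarray) -> "EpochSet":
        """Return a copy carrying ``data`` but the same labels/metadata."""
        data = np.asarray(data, dtype=np.float64)
        if data.shape != self.data.shape:
            raise ValueError(
                f"replacement data shape {data.shape} != {self.data.shape}"
            )
        return EpochSet(
            data=data,
            fs=self.fs,
            labels=self.labels.copy(),
            layout=self.layout,
            block_id=self.block_id.copy(),
            trial_id=self.trial_id.copy(),
        )
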