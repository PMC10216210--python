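"""Synthetic SSVEP epoch generator.

Emulates the statistical structure of flicker-evoked occipital EEG: each
trial contains a sinusoid at the attended stimulus frequency plus its
harmonics (with geometrically decaying amplitude), mixed into the channels
by per-channel gains, buried in additive noise at a controlled per-channel
SNR. Frequency/phase grids mirror the two public 12-target and 40-target
recording protocols.

The generator is fully seeded: one RNG stream per :class:`EpochSet`, so a
(layout, fs, config) triple maps to exactly one dataset.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

import numpy as np

from .epochs import EpochSet, StimulusLayout

__all__ = ["SynthConfig", "make_layout", "generate_epochs", "LAYOUT_PRESETS"]

#: Frequency/phase grids of the two public recording protocols:
#: 12 targets from 9.25 Hz in 0.5 Hz steps, and 40 targets from 8 Hz in
#: 0.2 Hz steps, both with 0.5*pi phase increments.
LAYOUT_PRESETS: dict[str, StimulusLayout] = {
    "nakanishi12": StimulusLayout(
        n_targets=12, f0=9.25, delta_f=0.5, phi0=0.0, delta_phi=0.5 * math.pi
    ),
    "benchmark40": StimulusLayout(
        n_targets=40, f0=8.0, delta_f=0.2, phi0=0.0, delta_phi=0.5 * math.pi
    ),
}


@dataclass(frozen=True)
class SynthConfig:
    """Knobs of the synthetic epoch generator.

    Parameters
    ----------
    n_channels : int
        Electrode count of the simulated montage.
    n_harmonics : int
        Harmonics per target (>= 1, fundamental included). Harmonics above
        Nyquist are silently dropped.
    harmonic_decay : float
        Amplitude ratio between consecutive harmonics.
    snr_db : float
        Per-channel signal-to-noise ratio in dB; ``math.inf`` disables noise.
    n_blocks : int
        Blocks; every block holds one trial per target.
    epoch_s : float
        Epoch duration in seconds.
    channel_gain_spread : float
        Per-channel mixing gains are drawn uniform in
        ``[1 - spread, 1 + spread]``.
    noise_color : {"white", "pink"}
        Additive noise spectrum; white keeps the SNR calibration exact.
    seed : int
        Fully determines the output.
    """

    n_channels: int = 8
    n_harmonics: int = 3
    harmonic_decay: float = 0.5
    snr_db: float = 10.0
    n_blocks: int = 15
    epoch_s: float = 4.0
    channel_gain_spread: float = 0.3
    noise_color: Literal["white", "pink"] = "white"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_harmonics < 1:
            raise ValueError("n_harmonics must be >= 1")
        if not 0 <= self.channel_gain_spread < 1:
            raise ValueError("channel_gain_spread must be in [0, 1)")
        if self.n_blocks < 1 or self.n_channels < 1:
            raise ValueError("n_blocks and n_channels must be positive")


def make_layout(
    preset: str | None = None,
    *,
    n_targets: int | None = None,
    f0: float | None = None,
    delta_f: float | None = None,
    phi0: float = 0.0,
    delta_phi: float = 0.0,
) -> StimulusLayout:
    """Build a stimulus layout from a named preset or explicit parameters.

    Parameters
    ----------
    preset : str, optional
        One of ``"nakanishi12"`` or ``"benchmark40"``. Mutually exclusive
        with the explicit parameters.

    Returns
    -------
    StimulusLayout
    """
    if preset is not None:
        try:
            return LAYOUT_PRESETS[preset]
        except KeyError:
            raise ValueError(
                f"unknown preset {preset!r}; known: {sorted(LAYOUT_PRESETS)}"
            ) from None
    if n_targets is None or f0 is None or delta_f is None:
        raise ValueError("without a preset, n_targets, f0 and delta_f are required")
    return StimulusLayout(
        n_targets=n_targets, f0=f0, delta_f=delta_f, phi0=phi0, delta_phi=delta_phi
    )


def _ssvep_waveform(
    t: np.ndarray, freq: float, phase: float, cfg: SynthConfig, fs: float
) -> np.ndarray:
    """Sum of harmonics sum_h decay^(h-1) * sin(2*pi*h*f*t + h*phi).

    Harmonics at or above Nyquist are dropped; the fundamental is
    guaranteed below Nyquist by the caller.
    """
    x = np.zeros_like(t)
    for h in range(1, cfg.n_harmonics + 1):
        if h * freq >= fs / 2:
            break
        x += cfg.harmonic_decay ** (h - 1) * np.sin(
            2 * np.pi * h * freq * t + h * phase
        )
    return x


def _pink_noise(rng: np.random.Generator, shape: tuple[int, ...]) -> np.ndarray:
    """Unit-variance 1/f-amplitude noise along the last axis."""
    white = rng.standard_normal(shape)
    spec = np.fft.rfft(white, axis=-1)
    f = np.fft.rfftfreq(shape[-1])
    scale = np.ones_like(f)
    scale[1:] = 1.0 / np.sqrt(f[1:])
    scale[0] = 0.0
    x = np.fft.irfft(spec * scale, n=shape[-1], axis=-1)
    x /= x.std(axis=-1, keepdims=True)
    return x


def generate_epochs(layout: StimulusLayout, fs: float, cfg: SynthConfig) -> EpochSet:
    """Generate one labelled epoch per target per block.

    Each trial attending target ``k`` carries the harmonic stack of
    ``f_k`` scaled by per-channel gains, plus noise calibrated so the
    empirical per-channel signal/noise power ratio equals ``cfg.snr_db``.
    Trials are ordered block-major, target-minor.

    Raises
    ------
    ValueError
        If any fundamental violates Nyquist, or the epoch duration does
        not map to an integral sample count.
    """
    layout.validate_nyquist(fs)
    n_samples_f = cfg.epoch_s * fs
    n_samples = round(n_samples_f)
    if abs(n_samples_f - n_samples) > 1e-9:
        raise ValueError(
            f"epoch_s * fs = {n_samples_f} is not an integral sample count"
        )

    rng = np.random.default_rng(cfg.seed)
    gains = rng.uniform(
        1 - cfg.channel_gain_spread, 1 + cfg.channel_gain_spread, size=cfg.n_channels
    )
    t = np.arange(n_samples) / fs
    freqs, phases = layout.frequencies, layout.phases

    n_trials = cfg.n_blocks * layout.n_targets
    data = np.empty((n_trials, cfg.n_channels, n_samples))
    labels = np.empty(n_trials, dtype=np.int64)
    block_id = np.empty(n_trials, dtype=np.int64)

    i = 0
    for b in range(cfg.n_blocks):
        for k in range(layout.n_targets):
            s = _ssvep_waveform(t, freqs[k], phases[k], cfg, fs)
            trial = gains[:, None] * s[None, :]
            if math.isfinite(cfg.snr_db):
                sig_power = np.mean(trial**2, axis=1)  # per channel
                noise_power = sig_power / 10 ** (cfg.snr_db / 10)
                if cfg.noise_color == "pink":
                    noise = _pink_noise(rng, (cfg.n_channels, n_samples))
                else:
                    noise = rng.standard_normal((cfg.n_channels, n_samples))
                trial = trial + np.sqrt(noise_power)[:, None] * noise
            data[i] = trial
            labels[i] = k
            block_id[i] = b
            i += 1

    return EpochSet(data=data, fs=fs, labels=labels, layout=layout, block_id=block_id)
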