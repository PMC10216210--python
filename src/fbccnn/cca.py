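"""Canonical correlation analysis (CCA) SSVEP classifier.

The classical frequency decoder: for each candidate stimulus frequency a
reference template of sines and cosines at the fundamental and its
harmonics is built, and the window is assigned to the frequency whose
template attains the largest canonical correlation with the data.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import linalg

from .epochs import EpochSet, StimulusLayout

__all__ = [
    "reference_templates",
    "canonical_correlation",
    "cca_classify",
    "CCAClassifier",
]

_RIDGE = 1e-8


def reference_templates(
    layout: StimulusLayout, fs: float, n_samples: int, n_harmonics: int = 5
) -> list[np.ndarray]:
    """Sin/cos harmonic templates, one ``(2*Nh_kept, Ns)`` matrix per target.

    Rows are ordered (sin h=1, cos h=1, sin h=2, ...). Harmonics at or
    above Nyquist are omitted with a warning.
    """
    t = np.arange(n_samples) / fs
    templates = []
    for f in layout.frequencies:
        rows = []
        dropped = 0
        for h in range(1, n_harmonics + 1):
            if h * f >= fs / 2:
                dropped += 1
                continue
            rows.append(np.sin(2 * np.pi * h * f * t))
            rows.append(np.cos(2 * np.pi * h * f * t))
        if dropped:
            warnings.warn(
                f"{dropped} harmonic(s) of {f} Hz at/above Nyquist omitted",
                stacklevel=2,
            )
        if not rows:
            raise ValueError(f"no template harmonics below Nyquist for {f} Hz")
        templates.append(np.asarray(rows))
    return templates


def _inv_sqrt(c: np.ndarray, label: str) -> np.ndarray:
    """Symmetric inverse square root with a ridge fallback for
    rank-deficient covariance."""
    w, v = linalg.eigh(c)
    if w.min() <= _RIDGE * max(w.max(), 1.0):
        warnings.warn(
            f"rank-deficient {label} covariance; regularizing with "
            f"ridge {_RIDGE}",
            stacklevel=3,
        )
        w = w + _RIDGE * max(w.max(), 1.0) + _RIDGE
    return v @ np.diag(1.0 / np.sqrt(w)) @ v.T


def canonical_correlation(
    x: np.ndarray, y: np.ndarray, return_weights: bool = False
):
    """Largest canonical correlation between row-variable matrices.

    Parameters
    ----------
    x : ndarray (Nx, Ns), y : ndarray (Ny, Ns)
        Multivariate signals over a common sample axis; rows are
        centered internally.
    return_weights : bool
        Also return the weight vectors ``(w_x, w_y)`` attaining the
        maximum.

    Returns
    -------
    rho : float in [0, 1]  (and optionally ``w_x``, ``w_y``)
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.ndim != 2 or y.ndim != 2 or x.shape[1] != y.shape[1]:
        raise ValueError("x and y must be 2-D with equal sample counts")
    ns = x.shape[1]
    if ns <= max(x.shape[0], y.shape[0]):
        raise ValueError(
            f"need more samples ({ns}) than variables "
            f"({x.shape[0]}, {y.shape[0]})"
        )
    xc = x - x.mean(axis=1, keepdims=True)
    yc = y - y.mean(axis=1, keepdims=True)
    cxx = xc @ xc.T / ns
    cyy = yc @ yc.T / ns
    cxy = xc @ yc.T / ns
    cxx_isqrt = _inv_sqrt(cxx, "X")
    cyy_isqrt = _inv_sqrt(cyy, "Y")
    k = cxx_isqrt @ cxy @ cyy_isqrt
    u, s, vt = linalg.svd(k, full_matrices=False)
    rho = float(np.clip(s[0], 0.0, 1.0))
    if not return_weights:
        return rho
    wx = cxx_isqrt @ u[:, 0]
    wy = cyy_isqrt @ vt[0]
    return rho, wx, wy


def cca_classify(
    window: np.ndarray,
    layout: StimulusLayout,
    fs: float,
    n_harmonics: int = 5,
    templates: list[np.ndarray] | None = None,
) -> int:
    """Predict the attended target of one ``(channels, samples)`` window.

    Argmax over targets of the canonical correlation with each
    frequency's template; ties break toward the lowest target index.
    """
    window = np.asarray(window, dtype=np.float64)
    if templates is None:
        templates = reference_templates(layout, fs, window.shape[1], n_harmonics)
    rhos = np.array([canonical_correlation(window, yk) for yk in templates])
    return int(np.argmax(rhos))


class CCAClassifier:
    """Template-matching CCA decoder, scikit-learn style.

    Needs no training: ``fit`` records the stimulus layout and sampling
    rate from the training :class:`EpochSet` (templates are built lazily
    per window length).

    Parameters
    ----------
    n_harmonics : int
        Harmonics per reference template (fundamental included).
    """

    def __init__(self, n_harmonics: int = 5):
        self.n_harmonics = n_harmonics

    def get_params(self, deep: bool = True) -> dict:
        return {"n_harmonics": self.n_harmonics}

    def set_params(self, **params) -> "CCAClassifier":
        for k, v in params.items():
            if not hasattr(self, k):
                raise ValueError(f"invalid parameter {k!r} for CCAClassifier")
            setattr(self, k, v)
        return self

    def fit(self, epochs: EpochSet, y=None) -> "CCAClassifier":
        if epochs.layout.n_targets < 1:
            raise ValueError("empty stimulus layout")
        self.layout_ = epochs.layout
        self.fs_ = epochs.fs
        self._templates: dict[int, list[np.ndarray]] = {}
        return self

    def _templates_for(self, n_samples: int) -> list[np.ndarray]:
        if n_samples not in self._templates:
            self._templates[n_samples] = reference_templates(
                self.layout_, self.fs_, n_samples, self.n_harmonics
            )
        return self._templates[n_samples]

    def predict(self, X: EpochSet | np.ndarray) -> np.ndarray:
        if not hasattr(self, "layout_"):
            raise RuntimeError("CCAClassifier is not fitted; call fit() first")
        data = X.data if isinstance(X, EpochSet) else np.asarray(X, dtype=np.float64)
        if data.ndim != 3:
            raise ValueError("X must be (n_windows, channels, samples)")
        templates = self._templates_for(data.shape[2])
        return np.array([
            cca_classify(w, self.layout_, self.fs_, self.n_harmonics, templates)
            for w in data
        ])

    def score(self, X: EpochSet | np.ndarray, y=None) -> float:
        if y is None:
            if not isinstance(X, EpochSet):
                raise ValueError("labels required when X is a bare array")
            y = X.labels
        return float(np.mean(self.predict(X) == np.asarray(y)))
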