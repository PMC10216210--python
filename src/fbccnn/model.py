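"""FB-CCNN hyperparameters and the scikit-learn-style classifier.

The decoder has five structural hyperparameters: the number of sub-bands
``Nfb``, the kernel counts of the two convolutional layers ``Nk1`` and
``Nk2``, the width ``K2`` and stride ``S2`` of the second layer's
kernels. The flattened width feeding the dense output layer is

    Nf = (floor((2*NFFT*Nfb - K2) / S2) + 1) * Nk2

which every built network is checked against.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

from .network import SpectrumCNN
from .spectrum import ComplexSpectrumFeatures

__all__ = [
    "HyperparamSet",
    "ModelSpec",
    "flatten_width",
    "build_model",
    "channel_based_hyperparams",
    "FBCCNNClassifier",
]


@dataclass(frozen=True)
class HyperparamSet:
    """The AGD search space: (Nfb, Nk1, Nk2, K2, S2), all positive ints."""

    nfb: int
    nk1: int
    nk2: int
    k2: int
    s2: int

    def __post_init__(self) -> None:
        for name in ("nfb", "nk1", "nk2", "k2", "s2"):
            v = getattr(self, name)
            if not (isinstance(v, (int, np.integer)) and v >= 1):
                raise ValueError(f"{name} must be a positive integer, got {v!r}")
        if self.s2 > self.k2:
            raise ValueError(f"S2={self.s2} may not exceed K2={self.k2}")

    def validate(self, nfft: int) -> None:
        """Check the input-width constraint K2 <= 2*NFFT*Nfb."""
        width = 2 * nfft * self.nfb
        if self.k2 > width:
            raise ValueError(
                f"K2={self.k2} exceeds the input width 2*NFFT*Nfb = {width}"
            )

    def clamped(self, nfft: int) -> "HyperparamSet":
        """Return a copy with K2 clamped to 2*NFFT*Nfb and S2 to K2."""
        k2 = min(self.k2, 2 * nfft * self.nfb)
        s2 = min(self.s2, k2)
        return replace(self, k2=k2, s2=s2)


@dataclass(frozen=True)
class ModelSpec:
    """Everything needed to instantiate the network."""

    hp: HyperparamSet
    n_channels: int
    nfft: int
    n_classes: int
    dropout: float = 0.5
    prelu_init: float = 0.25

    def __post_init__(self) -> None:
        self.hp.validate(self.nfft)


def flatten_width(hp: HyperparamSet, nfft: int) -> int:
    """Width of the flattened layer feeding the dense output.

    ``(floor((2*NFFT*Nfb - K2)/S2) + 1) * Nk2``.
    """
    hp.validate(nfft)
    return ((2 * nfft * hp.nfb - hp.k2) // hp.s2 + 1) * hp.nk2


def build_model(spec: ModelSpec, seed: int = 0) -> SpectrumCNN:
    """Instantiate the network and verify its realized flatten width."""
    net = SpectrumCNN(
        n_channels=spec.n_channels,
        width=2 * spec.nfft * spec.hp.nfb,
        n_classes=spec.n_classes,
        nk1=spec.hp.nk1,
        nk2=spec.hp.nk2,
        k2=spec.hp.k2,
        s2=spec.hp.s2,
        dropout=spec.dropout,
        prelu_init=spec.prelu_init,
        seed=seed,
    )
    expected = flatten_width(spec.hp, spec.nfft)
    assert net.flat_width == expected, (
        f"realized flatten width {net.flat_width} != formula value {expected}"
    )
    return net


def channel_based_hyperparams(
    n_channels: int,
    variant: str = "three_band",
    nfft: int | None = None,
) -> HyperparamSet:
    """Channel-number-based hyperparameter sets.

    ``one_band``: (Nfb=1, Nk1=8*Nch, Nk2=2*Nch, K2=8*Nch, S2=Nch);
    ``three_band``: (Nfb=3, all four = 8*Nch). If ``nfft`` is given the
    K2/S2 invariants are enforced by clamping, with a warning naming the
    clamped values.
    """
    if n_channels < 1:
        raise ValueError("n_channels must be >= 1")
    if variant == "one_band":
        hp = HyperparamSet(nfb=1, nk1=8 * n_channels, nk2=2 * n_channels,
                           k2=8 * n_channels, s2=n_channels)
    elif variant == "three_band":
        v = 8 * n_channels
        hp = HyperparamSet(nfb=3, nk1=v, nk2=v, k2=v, s2=v)
    else:
        raise ValueError(f"unknown variant {variant!r}")
    if nfft is not None:
        clamped = hp.clamped(nfft)
        if clamped != hp:
            warnings.warn(
                f"channel-based set {hp} clamped to {clamped} for NFFT={nfft}",
                stacklevel=2,
            )
        hp = clamped
    return hp


class FBCCNNClassifier:
    """Filter-bank complex-spectrum CNN decoder, scikit-learn style.

    Operates on pre-extracted complex-spectrum features: ``X`` is either a
    :class:`~fbccnn.spectrum.ComplexSpectrumFeatures` or an array of shape
    ``(n_windows, n_channels, 2*NFFT*Nfb)``; ``y`` holds integer class
    labels. Training is 50 epochs of Adam on mini-batches of 32 by
    default, fully determined by ``random_state``.

    Parameters
    ----------
    nfb, nk1, nk2, k2, s2 : int
        Structural hyperparameters (see module docstring).
    dropout : float
        Dropout rate after each convolutional block.
    lr : float
        Adam learning rate.
    epochs : int
        Training epochs.
    batch_size : int
        Mini-batch size.
    random_state : int
        Seeds weight initialization, dropout and batch shuffling.

    Attributes
    ----------
    classes_ : ndarray
        Sorted unique labels seen in ``fit``.
    net_ : SpectrumCNN
        The trained network.
    loss_curve_ : list of float
        Mean training loss per epoch.
    loss_ : float
        Final-epoch mean training loss.
    """

    def __init__(self, nfb: int = 3, nk1: int = 64, nk2: int = 64,
                 k2: int = 64, s2: int = 64, *, dropout: float = 0.5,
                 lr: float = 1e-3, epochs: int = 50, batch_size: int = 32,
                 random_state: int = 0):
        self.nfb = nfb
        self.nk1 = nk1
        self.nk2 = nk2
        self.k2 = k2
        self.s2 = s2
        self.dropout = dropout
        self.lr = lr
        self.epochs = epochs
        self.batch_size = batch_size
        self.random_state = random_state

    # -- sklearn plumbing ------------------------------------------------

    _param_names = ("nfb", "nk1", "nk2", "k2", "s2", "dropout", "lr",
                    "epochs", "batch_size", "random_state")

    def get_params(self, deep: bool = True) -> dict:
        return {k: getattr(self, k) for k in self._param_names}

    def set_params(self, **params) -> "FBCCNNClassifier":
        for k, v in params.items():
            if k not in self._param_names:
                raise ValueError(f"invalid parameter {k!r} for FBCCNNClassifier")
            setattr(self, k, v)
        return self

    @property
    def hyperparams(self) -> HyperparamSet:
        return HyperparamSet(nfb=self.nfb, nk1=self.nk1, nk2=self.nk2,
                             k2=self.k2, s2=self.s2)

    @staticmethod
    def _as_array(X) -> np.ndarray:
        if isinstance(X, ComplexSpectrumFeatures):
            X = X.matrix
        X = np.asarray(X, dtype=np.float64)
        if X.ndim != 3:
            raise ValueError(
                f"X must be (n_windows, n_channels, width), got shape {X.shape}"
            )
        return X

    # -- estimator API ---------------------------------------------------

    def fit(self, X, y) -> "FBCCNNClassifier":
        X = self._as_array(X)
        y = np.asarray(y, dtype=np.int64)
        if y.shape[0] != X.shape[0]:
            raise ValueError("X and y disagree on the number of windows")
        self.classes_ = np.unique(y)
        n_classes = len(self.classes_)
        if n_classes < 2:
            raise ValueError("need at least 2 classes")
        y_enc = np.searchsorted(self.classes_, y)
        width = X.shape[2]
        if width % (2 * self.nfb) != 0:
            raise ValueError(
                f"input width {width} is not divisible by 2*Nfb = {2 * self.nfb}"
            )
        nfft = width // (2 * self.nfb)
        spec = ModelSpec(hp=self.hyperparams, n_channels=X.shape[1],
                         nfft=nfft, n_classes=n_classes, dropout=self.dropout)
        self.nfft_ = nfft
        self.net_ = build_model(spec, seed=self.random_state)
        self.loss_curve_ = self.net_.fit(
            X, y_enc, epochs=self.epochs, batch_size=self.batch_size,
            lr=self.lr, seed=self.random_state,
        )
        self.loss_ = self.loss_curve_[-1]
        return self

    def decision_function(self, X) -> np.ndarray:
        self._check_fitted()
        return self.net_.predict_logits(self._as_array(X))

    def predict_proba(self, X) -> np.ndarray:
        logits = self.decision_function(X)
        z = logits - logits.max(axis=1, keepdims=True)
        e = np.exp(z)
        return e / e.sum(axis=1, keepdims=True)

    def predict(self, X) -> np.ndarray:
        logits = self.decision_function(X)
        return self.classes_[np.argmax(logits, axis=1)]

    def score(self, X, y) -> float:
        return float(np.mean(self.predict(X) == np.asarray(y)))

    def _check_fitted(self) -> None:
        if not hasattr(self, "net_"):
            raise RuntimeError("FBCCNNClassifier is not fitted; call fit() first")

    # -- checkpointing ---------------------------------------------------

    def save(self, path) -> None:
        """Write hyperparameters, weights and BN statistics to an .npz
        checkpoint so predictions are reloadable."""
        self._check_fitted()
        net = self.net_
        arrays = {f"param_{k}": v for k, v in net.params.items()}
        arrays.update(
            run_mean1=net.run_mean1, run_var1=net.run_var1,
            run_mean2=net.run_mean2, run_var2=net.run_var2,
            classes=self.classes_,
            loss_curve=np.asarray(self.loss_curve_),
            meta=np.array([net.n_channels, net.width, net.n_classes,
                           self.nfft_], dtype=np.int64),
            hp=np.array([self.nfb, self.nk1, self.nk2, self.k2, self.s2],
                        dtype=np.int64),
            train_cfg=np.array([self.dropout, self.lr, self.epochs,
                                self.batch_size, self.random_state]),
        )
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path) -> "FBCCNNClassifier":
        """Restore a checkpoint written by :meth:`save`."""
        with np.load(path) as z:
            nfb, nk1, nk2, k2, s2 = (int(v) for v in z["hp"])
            dropout, lr, epochs, batch_size, random_state = z["train_cfg"]
            clf = cls(nfb=nfb, nk1=nk1, nk2=nk2, k2=k2, s2=s2,
                      dropout=float(dropout), lr=float(lr), epochs=int(epochs),
                      batch_size=int(batch_size), random_state=int(random_state))
            n_channels, width, n_classes, nfft = (int(v) for v in z["meta"])
            net = SpectrumCNN(n_channels=n_channels, width=width,
                              n_classes=n_classes, nk1=nk1, nk2=nk2, k2=k2,
                              s2=s2, dropout=float(dropout),
                              seed=int(random_state))
            for k in net.params:
                net.params[k] = z[f"param_{k}"].copy()
            net.run_mean1 = z["run_mean1"].copy()
            net.run_var1 = z["run_var1"].copy()
            net.run_mean2 = z["run_mean2"].copy()
            net.run_var2 = z["run_var2"].copy()
            clf.net_ = net
            clf.nfft_ = nfft
            clf.classes_ = z["classes"].copy()
            clf.loss_curve_ = [float(v) for v in z["loss_curve"]]
            clf.loss_ = clf.loss_curve_[-1] if clf.loss_curve_ else float("nan")
        return clf
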