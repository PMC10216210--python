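"""Windowing, trial-level splitting, training and evaluation.

Protocol: trials are split into train/test sets at the trial level
(stratified per class) *before* any windowing, so no 1 s window of the
same trial ever appears on both sides. The filter bank runs on the full
trial (avoiding short-window edge effects), windows are then cut with a
sliding 1 s / 0.1 s grid, each window is FFT-transformed, and every
window counts as one classification when scoring.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .epochs import EpochSet
from .filterbank import apply_filter_bank, design_filter_bank
from .model import FBCCNNClassifier
from .spectrum import (
    DEFAULT_BAND_HZ,
    DEFAULT_RESOLUTION_HZ,
    assemble_features,
    make_spectrum_spec,
)

__all__ = ["TrainConfig", "EvalReport", "segment", "split_by_trials",
           "extract_features", "train"]


@dataclass(frozen=True)
class TrainConfig:
    """Training protocol parameters.

    Windows of ``window_s`` seconds are cut every ``stride_s`` seconds
    (both converted to samples by round-half-up); training runs
    ``epochs`` passes of Adam with mini-batches of ``batch_size``.
    """

    window_s: float = 1.0
    stride_s: float = 0.1
    epochs: int = 50
    batch_size: int = 32
    lr: float = 1e-3
    n_test_trials: int = 3
    resolution_hz: float = DEFAULT_RESOLUTION_HZ
    band_hz: tuple[float, float] = DEFAULT_BAND_HZ
    ripple_db: float = 3.0
    atten_db: float = 40.0
    seed: int = 0


@dataclass
class EvalReport:
    """Window-level performance summary of one trained decoder."""

    train_accuracy: float       # percent, at the final training epoch
    test_accuracy: float        # percent
    loss: float                 # final-epoch mean training loss
    per_class_accuracy: np.ndarray = field(repr=False)
    confusion: np.ndarray = field(repr=False)   # rows = true class
    n_train_windows: int = 0
    n_test_windows: int = 0

    def __post_init__(self) -> None:
        for v in (self.train_accuracy, self.test_accuracy):
            if not 0.0 <= v <= 100.0:
                raise ValueError(f"accuracy {v} outside [0, 100]")

    def to_dict(self) -> dict:
        return {
            "train_accuracy": self.train_accuracy,
            "test_accuracy": self.test_accuracy,
            "loss": self.loss,
            "per_class_accuracy": np.asarray(self.per_class_accuracy).tolist(),
            "confusion": np.asarray(self.confusion).tolist(),
            "n_train_windows": self.n_train_windows,
            "n_test_windows": self.n_test_windows,
        }


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def segment(epochs: EpochSet, window_s: float, stride_s: float) -> EpochSet:
    """Cut every trial into sliding windows with inherited labels.

    Window starts are ``0, S, 2S, ...`` samples while the window fits
    (half-open intervals), where ``W = round(window_s*fs)`` and
    ``S = round(stride_s*fs)`` with round-half-up; each trial yields
    ``floor((L - W)/S) + 1`` windows. The returned EpochSet's
    ``trial_id`` records each window's source trial, so leakage audits
    survive windowing.
    """
    w = _round_half_up(window_s * epochs.fs)
    s = _round_half_up(stride_s * epochs.fs)
    if w > epochs.n_samples:
        raise ValueError(
            f"window of {w} samples exceeds epoch length {epochs.n_samples}"
        )
    if s < 1:
        raise ValueError("stride rounds to zero samples")
    starts = np.arange(0, epochs.n_samples - w + 1, s)
    n_win = len(starts)
    data = np.stack(
        [epochs.data[:, :, st : st + w] for st in starts], axis=1
    ).reshape(epochs.n_trials * n_win, epochs.n_channels, w)
    rep = np.repeat(np.arange(epochs.n_trials), n_win)
    return EpochSet(
        data=data,
        fs=epochs.fs,
        labels=epochs.labels[rep],
        layout=epochs.layout,
        block_id=epochs.block_id[rep],
        trial_id=epochs.trial_id[rep],
    )


def split_by_trials(
    epochs: EpochSet, n_test_trials: int, seed: int = 0
) -> tuple[EpochSet, EpochSet]:
    """Stratified trial-level train/test split (before windowing).

    Per class, ``n_test_trials`` trials are drawn (seeded) for the test
    side; the remainder trains. ``n_test_trials=0`` gives an empty test
    set.
    """
    rng = np.random.default_rng(seed)
    test_idx: list[int] = []
    for k in np.unique(epochs.labels):
        idx = np.flatnonzero(epochs.labels == k)
        if n_test_trials >= len(idx):
            raise ValueError(
                f"class {k} has {len(idx)} trials, cannot hold out "
                f"{n_test_trials} for testing"
            )
        test_idx.extend(rng.choice(idx, size=n_test_trials, replace=False))
    test_mask = np.zeros(epochs.n_trials, dtype=bool)
    test_mask[np.asarray(test_idx, dtype=np.int64)] = True
    return epochs.select(np.flatnonzero(~test_mask)), epochs.select(
        np.flatnonzero(test_mask)
    )


def extract_features(epochs: EpochSet, nfb: int, cfg: TrainConfig):
    """Filter-bank -> windowing -> complex spectrum for one EpochSet.

    Returns ``(features, window_labels, window_trial_ids)`` where
    ``features.matrix`` has shape ``(n_windows, Nch, 2*NFFT*Nfb)``.
    """
    fb = design_filter_bank(nfb, epochs.fs, ripple_db=cfg.ripple_db,
                            atten_db=cfg.atten_db)
    bands = apply_filter_bank(epochs, fb)
    band_windows = [segment(b, cfg.window_s, cfg.stride_s) for b in bands]
    sp = make_spectrum_spec(epochs.fs, cfg.resolution_hz, tuple(cfg.band_hz))
    feats = assemble_features([bw.data for bw in band_windows], sp)
    ref = band_windows[0]
    return feats, ref.labels, ref.trial_id


def train(
    epochs: EpochSet,
    clf: FBCCNNClassifier | None = None,
    cfg: TrainConfig | None = None,
) -> tuple[FBCCNNClassifier, EvalReport]:
    """End-to-end protocol: split, window, featurize, train, score.

    Accuracy is per window — each window is one classification. The
    report's train accuracy is measured after the final epoch.
    """
    cfg = cfg or TrainConfig()
    clf = clf or FBCCNNClassifier(random_state=cfg.seed)
    clf.set_params(epochs=cfg.epochs, batch_size=cfg.batch_size, lr=cfg.lr)

    train_ep, test_ep = split_by_trials(epochs, cfg.n_test_trials, seed=cfg.seed)
    Xtr, ytr, tid_tr = extract_features(train_ep, clf.nfb, cfg)
    missing = set(range(epochs.layout.n_targets)) - set(np.unique(ytr))
    if missing:
        raise ValueError(f"classes {sorted(missing)} absent from training windows")
    clf.fit(Xtr, ytr)

    n_classes = epochs.layout.n_targets
    train_acc = 100.0 * clf.score(Xtr, ytr)
    if test_ep.n_trials:
        Xte, yte, tid_te = extract_features(test_ep, clf.nfb, cfg)
        leak = set(tid_tr) & set(tid_te)
        assert not leak, f"trial leakage across the split: {sorted(leak)}"
        pred = clf.predict(Xte)
        test_acc = 100.0 * float(np.mean(pred == yte))
        confusion = np.zeros((n_classes, n_classes), dtype=np.int64)
        np.add.at(confusion, (yte, pred), 1)
        with np.errstate(invalid="ignore"):
            per_class = 100.0 * np.diag(confusion) / confusion.sum(axis=1)
        n_te = len(yte)
    else:
        test_acc, n_te = 0.0, 0
        confusion = np.zeros((n_classes, n_classes), dtype=np.int64)
        per_class = np.full(n_classes, np.nan)

    report = EvalReport(
        train_accuracy=train_acc,
        test_accuracy=test_acc,
        loss=clf.loss_,
        per_class_accuracy=per_class,
        confusion=confusion,
        n_train_windows=len(ytr),
        n_test_windows=n_te,
    )
    return clf, report
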