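"""Readers for the two public SSVEP recordings and the internal archive.

Both public datasets ship as MATLAB ``.mat`` files; the readers map their
documented array layouts onto :class:`EpochSet` and fail loudly, naming
the offending dimension, on anything else. Nothing here downloads data.

Assumed layouts (the dataset releases' own conventions):

* 12-target set: variable ``eeg`` of shape
  ``(targets=12, channels=8, samples, blocks=15)`` at 256 Hz; epochs are
  trimmed by the 0.135 s visual latency after stimulus onset.
* 40-target benchmark: variable ``data`` of shape
  ``(channels=64, samples, targets=40, blocks=6)`` at 250 Hz; epochs are
  trimmed by the 0.5 s cue plus 0.14 s latency.

The internal single-file archive is a NumPy ``.npz`` holding the
EpochSet fields under the keys ``data``, ``fs``, ``labels``,
``block_id``, ``trial_id`` and the stimulus-layout scalars
``n_targets``, ``f0``, ``delta_f``, ``phi0``, ``delta_phi``.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .epochs import EpochSet, StimulusLayout
from .synth import LAYOUT_PRESETS

__all__ = [
    "DatasetDescriptor",
    "NAKANISHI",
    "BENCHMARK",
    "read_dataset",
    "save_epochs",
    "load_epochs",
    "config_hash",
]


@dataclass(frozen=True)
class DatasetDescriptor:
    """Recording-protocol facts of one public dataset."""

    name: str
    fs: float
    n_channels: int
    n_targets: int
    n_blocks: int
    epoch_s: float
    latency_s: float
    layout: StimulusLayout
    mat_key: str
    mat_order: tuple[str, ...]  # axis meaning of the stored array


NAKANISHI = DatasetDescriptor(
    name="nakanishi12",
    fs=256.0,
    n_channels=8,
    n_targets=12,
    n_blocks=15,
    epoch_s=4.0,
    latency_s=0.135,
    layout=LAYOUT_PRESETS["nakanishi12"],
    mat_key="eeg",
    mat_order=("target", "channel", "sample", "block"),
)

BENCHMARK = DatasetDescriptor(
    name="benchmark40",
    fs=250.0,
    n_channels=64,
    n_targets=40,
    n_blocks=6,
    epoch_s=5.0,
    latency_s=0.5 + 0.14,  # cue + visual latency
    layout=LAYOUT_PRESETS["benchmark40"],
    mat_key="data",
    mat_order=("channel", "sample", "target", "block"),
)


def _load_mat_array(path: Path, key: str) -> np.ndarray:
    """Load ``key`` from a .mat file (classic format, h5 fallback)."""
    try:
        from scipy.io import loadmat

        mat = loadmat(path)
        if key not in mat:
            raise KeyError(
                f"variable {key!r} missing from {path}; found "
                f"{[k for k in mat if not k.startswith('__')]}"
            )
        return np.asarray(mat[key])
    except NotImplementedError:
        # MATLAB v7.3 files are HDF5
        import h5py

        with h5py.File(path, "r") as f:
            if key not in f:
                raise KeyError(
                    f"variable {key!r} missing from {path}; found {list(f)}"
                ) from None
            # h5py stores MATLAB arrays with reversed axis order
            return np.asarray(f[key]).T


def read_dataset(path: str | Path, descriptor: DatasetDescriptor) -> EpochSet:
    """Read one subject file into an EpochSet.

    Trials are ordered block-major, target-minor; the per-dataset cue/
    latency offset is dropped from the start of every epoch and
    ``epoch_s`` seconds are kept.

    Raises
    ------
    FileNotFoundError, KeyError, ValueError
        Missing file/variable, or a dimension that contradicts the
        descriptor (the error names expected vs found).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"dataset file not found: {path}")
    arr = _load_mat_array(path, descriptor.mat_key)
    if arr.ndim != 4:
        raise ValueError(
            f"{descriptor.name}: expected a 4-D array "
            f"{descriptor.mat_order}, found {arr.ndim}-D {arr.shape}"
        )
    order = descriptor.mat_order
    expected = {
        "target": descriptor.n_targets,
        "channel": descriptor.n_channels,
        "block": descriptor.n_blocks,
    }
    for axis, meaning in enumerate(order):
        if meaning in expected and arr.shape[axis] != expected[meaning]:
            raise ValueError(
                f"{descriptor.name}: axis {axis} ({meaning}) has size "
                f"{arr.shape[axis]}, expected {expected[meaning]}"
            )
    # normalize to (block, target, channel, sample)
    perm = [order.index(m) for m in ("block", "target", "channel", "sample")]
    arr = arr.transpose(perm)

    skip = int(np.floor(descriptor.latency_s * descriptor.fs + 0.5))
    keep = int(np.floor(descriptor.epoch_s * descriptor.fs + 0.5))
    if arr.shape[3] < skip + keep:
        raise ValueError(
            f"{descriptor.name}: epochs hold {arr.shape[3]} samples, need "
            f"{skip + keep} (latency {skip} + epoch {keep})"
        )
    arr = arr[:, :, :, skip : skip + keep]

    n_blocks, n_targets = arr.shape[0], arr.shape[1]
    data = arr.reshape(n_blocks * n_targets, arr.shape[2], arr.shape[3])
    labels = np.tile(np.arange(n_targets), n_blocks)
    block_id = np.repeat(np.arange(n_blocks), n_targets)
    return EpochSet(
        data=data,
        fs=descriptor.fs,
        labels=labels,
        layout=descriptor.layout,
        block_id=block_id,
    )


def save_epochs(path: str | Path, epochs: EpochSet) -> None:
    """Write an EpochSet to the single-file .npz archive."""
    lay = epochs.layout
    np.savez(
        path,
        data=epochs.data,
        fs=np.float64(epochs.fs),
        labels=epochs.labels,
        block_id=epochs.block_id,
        trial_id=epochs.trial_id,
        n_targets=np.int64(lay.n_targets),
        f0=np.float64(lay.f0),
        delta_f=np.float64(lay.delta_f),
        phi0=np.float64(lay.phi0),
        delta_phi=np.float64(lay.delta_phi),
    )


def load_epochs(path: str | Path) -> EpochSet:
    """Read an EpochSet back from the .npz archive (bit-exact round trip)."""
    with np.load(path) as z:
        layout = StimulusLayout(
            n_targets=int(z["n_targets"]),
            f0=float(z["f0"]),
            delta_f=float(z["delta_f"]),
            phi0=float(z["phi0"]),
            delta_phi=float(z["delta_phi"]),
        )
        return EpochSet(
            data=z["data"],
            fs=float(z["fs"]),
            labels=z["labels"],
            layout=layout,
            block_id=z["block_id"],
            trial_id=z["trial_id"],
        )


def config_hash(config: dict) -> str:
    """Stable short hash of a configuration mapping, for log provenance."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]
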