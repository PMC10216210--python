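# fbccnn

Decoding steady-state visual evoked potentials (SSVEPs) from multi-channel
EEG with a filter-bank complex-spectrum convolutional network, plus the
coordinate-wise "artificial gradient descent" (AGD) hyperparameter search,
a canonical-correlation-analysis (CCA) baseline, and a seeded synthetic
SSVEP generator so the whole pipeline is testable at desk scale.

## Who this is for

SSVEP brain-computer interfaces present a grid of targets flickering at
distinct frequencies `f_k = f0 + k·Δf`; the occipital EEG of a user gazing
at target `k` oscillates at `f_k` and its harmonics. Decoding means
recovering `k` from a short (here 1 s) EEG window. This package is for BCI
researchers who want a compact, fully reproducible reference
implementation of that decoder and of the search procedure that chose its
hyperparameters.

## The model

The pipeline, for an epoch of `Nch` channels sampled at `fs`:

1. **Filter bank** — `Nfb` zero-phase Chebyshev type-I band-pass filters
   with passbands `n·8–88 Hz` (`n = 1..Nfb`) decompose each trial into
   sub-band components.
2. **Complex spectrum** — each 1 s window of each sub-band is zero-padded
   to an FFT length giving ≤ 0.293 Hz resolution; the real and imaginary
   parts of the `NFFT` bins covering 3–35 Hz are kept, producing the
   `Nch × (2·NFFT·Nfb)` input matrix.
3. **CNN** — conv layer 1: `Nk1` kernels of shape `(Nch × 1)`, stride 1;
   conv layer 2: `Nk2` kernels of shape `(1 × K2)`, stride `S2`; each
   followed by batch-norm, PReLU and dropout 0.5; a dense layer maps the
   flattened

       Nf = (⌊(2·NFFT·Nfb − K2)/S2⌋ + 1) · Nk2

   values to the `N` class scores. Training: softmax cross-entropy, Adam,
   batch 32, 50 epochs, fully seeded.

**AGD** searches the five structural hyperparameters
`{Nfb, Nk1, Nk2, K2, S2}` with three candidates each per round
(`(k, 2k, 8k)` initialization); the marginal performance ordering along
each coordinate shifts the triple up (`(a2, 2a2, 8a2)`), refines it
(midpoints) or shifts it down (`(a0/8, a0/2, a0)`), with `K2 ≤ 2·NFFT·Nfb`
and `S2 ≤ K2` enforced throughout.

The **CCA baseline** assigns a window to the target whose sine/cosine
harmonic template attains the largest canonical correlation with the
window.

## Worked example

```python
from fbccnn import (FBCCNNClassifier, CCAClassifier, SynthConfig,
                    TrainConfig, make_layout, generate_epochs, train, segment)

layout = make_layout("nakanishi12")         # 12 targets, 9.25-14.75 Hz
epochs = generate_epochs(layout, fs=256.0,
                         cfg=SynthConfig(n_blocks=15, snr_db=10.0, seed=7))

clf = FBCCNNClassifier(nfb=3, nk1=64, nk2=64, k2=64, s2=64, random_state=7)
clf, report = train(epochs, clf, TrainConfig(seed=7))
print(f"train {report.train_accuracy:.2f}%  test {report.test_accuracy:.2f}%")

cca = CCAClassifier(n_harmonics=5).fit(epochs)
windows = segment(epochs, window_s=1.0, stride_s=0.1)
print(f"CCA {100 * cca.score(windows):.2f}%")
```

Output (one CPU, a few minutes):

```
train 100.00%  test 100.00%
CCA 100.00%
```

The decoder and the baseline both saturate on this easy 10 dB synthetic
task — the generator produces textbook sinusoid-plus-noise SSVEPs; the
numbers say the pipeline is wired correctly, not that real EEG is this
clean. Window-level accuracy is reported: each 1 s window counts as one
classification, split train/test at the trial level (12 vs 3 trials per
class) so no window leaks across the split.

There is also a CLI mirroring the stages:

```bash
fbccnn simulate --preset nakanishi12 --fs 256 --snr-db 5 --blocks 15 \
    --seed 7 --out epochs.npz
fbccnn train --data epochs.npz --seed 7 --report report.json
fbccnn cca --data epochs.npz --report cca.json
fbccnn agd --data epochs.npz --rounds 2 --seed 7 --out agd_history.json
```

Readers for the two public recordings the decoder targets (the 12-target,
8-channel, 256 Hz set and the 40-target, 64-channel, 250 Hz benchmark)
are in `fbccnn.datasets`; they map each subject's `.mat` file onto the
internal epoch container and never download anything. Accuracies on those
real recordings are outside the test suite's scope — they require the
datasets themselves.

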