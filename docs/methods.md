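# Methods

This note documents the models, the numerical choices and the open design
decisions behind the package, and what the synthetic experiments do and
do not establish.

## Signal model of the synthetic generator

A trial attending target `k` (frequency `f_k`, phase `φ_k`) is

    s(t) = Σ_{h=1}^{H} d^(h-1) · sin(2π·h·f_k·t + h·φ_k)

mixed into `Nch` channels by gains drawn once per dataset from
`U[1-g, 1+g]`, plus additive noise scaled per channel so the empirical
signal-to-noise power ratio equals `snr_db`. Defaults: `H = 3` harmonics
with decay `d = 0.5` (gives non-trivial content in sub-bands up to
`Nfb = 3`), gain spread `g = 0.3` (occipital electrode-gain variation
without a head model), white Gaussian noise (keeps the SNR calibration
exact; a 1/f "pink" mode exists for qualitative checks). Stimulus grids
mirror the two public recording protocols: 12 targets at
9.25 + 0.5k Hz and 40 targets at 8 + 0.2k Hz, phases stepping by 0.5π.
One RNG stream, seeded, generates gains then per-trial noise, so a
(layout, fs, config) triple is one dataset, bit for bit.

What the generator deliberately omits: 1/f background EEG structure by
default, eye-blink/EMG artifacts, trial-to-trial amplitude and latency
variability, inter-channel noise correlation, and any forward head model.
Consequently a decoder scoring 100% here is verified *mechanically* —
correct features, correct gradients, correct bookkeeping — but nothing is
claimed about accuracy on real recordings, which the package's dataset
readers can supply but the test suite does not require.

## Filter bank

Sub-band `n` (1-based) is a Chebyshev type-I band-pass with passband
`[n·8, 88] Hz` and stopband edges `[max(n·8 - 6, 2), 94] Hz`, applied
forward-backward (zero phase) per channel per trial with odd-symmetric
edge padding of 3× the filter order. The source material for this band
plan states neither order nor ripple; we select the order with
`scipy.signal.cheb1ord` against configurable tolerances, default 3 dB
passband ripple and 40 dB stopband attenuation. Because the
forward-backward pass squares the magnitude response, each one-way design
uses half the configured decibel figures, making `ripple_db`/`atten_db`
end-to-end guarantees of the realized zero-phase filter — the convention
every test and measurement in the package uses. Sampling rates at or
below 176 Hz are an error (the 88 Hz edge would reach Nyquist), never a
silent clip.

## Complex-spectrum features

The FFT length is `ceil(fs / resolution)` with the 0.293 Hz default
resolution, i.e. 874 samples at 256 Hz (realized resolution 0.2929 Hz);
windows are zero-padded to it, rectangular (no taper), so a naive DFT sum
is an exact oracle. Retained bins are those whose resolution cells cover
the 3–35 Hz default band: `k ∈ [⌊f_lo/df⌋, ⌊f_hi/df⌋]`, which yields
`NFFT = 110` at the defaults. The retained band and the bin rule are
conventions of this package — only the resolution figure is inherited —
and both are configurable; `NFFT` is always derived, never hard-coded.
Per band the `NFFT` real parts precede the `NFFT` imaginary parts; bands
concatenate in ascending order, giving `Nch × (2·NFFT·Nfb)`. No feature
normalization is applied before the network (batch-norm inside the
network is the only normalization).

## Network and training

Layer order within each convolutional block is conv → batch-norm → PReLU
→ dropout(0.5), the conventional order; the activation slope is one
learnable scalar per layer initialized at 0.25; convolution weights are
He-uniform, the dense layer Glorot-uniform, all seeded. The loss is
softmax cross-entropy (unstated in the source material; standard for
N-way classification) and the optimizer Adam at learning rate 1e-3
(likewise the conventional default). The implementation is plain
NumPy/Numba: convolutions are BLAS matmuls over strided window views,
batch-norm and the fused PReLU+dropout run as single-pass JIT kernels,
and arithmetic is float32 with float64 accumulation for batch-norm
moments and the loss. Gradients are hand-derived and checked against
central finite differences in the test suite. Batch-norm keeps running
statistics (momentum 0.1, eps 1e-5) for inference, so single-sample and
batched predictions agree.

Protocol: the filter bank runs on full trials (avoiding 1 s-window edge
transients), trials are split train/test stratified per class *before*
windowing, then 1 s windows are cut every 0.1 s. Sample counts round
half-up: at 256 Hz the 0.1 s stride is 26 samples, giving
`⌊(1024-256)/26⌋+1 = 30` windows per 4 s trial. Every window is one
classification; reported accuracies are window-level. Train accuracy is
measured after the final (50th) epoch. Latency handling lives in the
dataset readers: the 12-target set drops 0.135 s after stimulus onset,
the 40-target benchmark drops the 0.5 s cue plus 0.14 s latency, per the
datasets' own documentation.

## AGD

Each hyperparameter holds an ordered candidate triple; a round evaluates
the Cartesian product. The stride axis is represented as fractions of K2
(initially 1/8, 1/4, 1) resolved against each combination's K2, so
`S2 ≤ K2` holds inside all 243 round-1 combinations; `K2` is clamped to
the input width `2·NFFT·Nfb`. Marginal trends along a coordinate are
classified from the three performances sharing the anchor's other
coordinates: strictly rising → shift up, strictly falling → shift down,
anything with a tie at the top or a peak → refine (midpoints); a valley
falls through to shift-down, and an increasing/decreasing oscillation
between consecutive rounds also refines. Integer axes round half-up,
enforce strict ordering by nudging collisions, and a triple collapsed by
the upper clamp freezes that coordinate. `Nfb` is searched only over its
explicit candidate list {1, 3, 7} and never ratio-updated.

The human "manual selection" step is operationalized as a deterministic
ranking — test accuracy, then train accuracy, then loss, then enumeration
order — taking the top 2 by default, with a `chooser` callback as the
interactive override; search stops when the best test accuracy improves
by under 1 percentage point between rounds. Every evaluated combination
trains with one shared seed so performance differences reflect
hyperparameters, and the evaluation subject/dataset is a caller-supplied
objective, not hard-coded. Correlation analysis reports Pearson r of each
hyperparameter against test/train accuracy and loss, with zero-variance
columns reported as undefined (NaN) rather than 0, and a pairwise table
with test accuracy min-max normalized to [0, 1].

## CCA baseline

Reference templates stack sin/cos pairs at harmonics 1..Nh of each
candidate frequency (default `Nh = 5`, the filter-bank-CCA lineage's
convention; harmonics at/above Nyquist are dropped with a warning). The
largest canonical correlation is computed by symmetric whitening + SVD;
covariance matrices falling below a 1e-8 relative eigenvalue floor are
ridge-regularized with a warning, which also gives all-zero windows a
defined (lowest-index tie-broken) prediction. The implementation is
cross-checked against an independent generalized-eigenvalue formulation
in the tests.

## Problem sizes and tolerances

The end-to-end training check uses the 12-target layout, 15 blocks,
10 dB SNR, the three-band hyperparameter set (Nfb=3, all others 64) and
the full 50-epoch protocol — about 4–5 minutes per training on one CPU,
chosen so the complete suite stays comfortably runnable at a desk. Key
tolerances: spectrum vs DFT oracle 1e-9 relative; CCA vs eigen-oracle
1e-8 absolute; float32 gradient checks 3% relative; SNR calibration
±1 dB; the shuffled-label control must lie within 3σ of the window-level
binomial chance band (windows within a trial are correlated, so this
band is approximate but conservative in practice).

## Known limitations

- The network is CPU-bound NumPy/Numba; large channel counts (the
  64-channel benchmark with channel-based hyperparameters, Nk=512) build
  but train slowly.
- The AGD oscillation guard is per-coordinate between consecutive
  rounds; the source algorithm's scoping of that clause is ambiguous and
  this is one documented reading.
- Window-level scoring is assumed throughout; no majority-vote trial
  aggregation is provided.
- The `.mat` readers implement the two public datasets' documented
  layouts and fail loudly on anything else; they are exercised against
  synthetic stand-in files, not the real downloads.
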