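"""NumPy/Numba implementation of the two-convolution-layer SSVEP decoder.

Architecture, operating on ``(batch, Nch, W)`` complex-spectrum inputs
with ``W = 2 * NFFT * Nfb``:

1. conv1 — ``Nk1`` kernels of shape ``(Nch, 1)``, stride 1: collapses the
   channel axis into ``Nk1`` learned spatial combinations, output
   ``(batch, Nk1, W)``.
2. batch-norm, PReLU (one learnable slope per layer), dropout 0.5.
3. conv2 — ``Nk2`` kernels of shape ``(1, K2)`` spanning all ``Nk1``
   feature maps, stride ``S2``: output ``(batch, Nk2, P)`` with
   ``P = floor((W - K2)/S2) + 1``.
4. batch-norm, PReLU, dropout 0.5.
5. dense — flattened ``P*Nk2`` values to ``N`` class logits; softmax
   cross-entropy loss, Adam optimizer.

Forward and backward passes are written out explicitly (no autodiff).
Convolutions reduce to BLAS matmuls in float32; batch-norm and the fused
PReLU-plus-dropout activation run as single-pass JIT kernels. Dropout
randomness is drawn from a NumPy generator, so training remains fully
seeded; the kernels themselves are deterministic.
"""

from __future__ import annotations

import numpy as np
from numba import njit
from numpy.lib.stride_tricks import as_strided

__all__ = ["SpectrumCNN"]

_BN_EPS = 1e-5
_BN_MOMENTUM = 0.1
_F32 = np.float32


# --------------------------------------------------------------------------
# fused kernels


@njit(cache=True)
def _bn_fwd_train(x, gamma, beta, eps):
    """Batch-norm forward over (batch, positions) per channel.

    Returns (y, xhat, mean, var) with float64 accumulation of the
    moments for stability.
    """
    b, c, l = x.shape
    n = b * l
    s = np.zeros(c, dtype=np.float64)
    sq = np.zeros(c, dtype=np.float64)
    for bi in range(b):
        for ci in range(c):
            for li in range(l):
                v = np.float64(x[bi, ci, li])
                s[ci] += v
                sq[ci] += v * v
    mean = (s / n).astype(np.float32)
    var = (sq / n - (s / n) ** 2).astype(np.float32)
    y = np.empty_like(x)
    xhat = np.empty_like(x)
    for ci in range(c):
        m = mean[ci]
        istd = np.float32(1.0) / np.sqrt(var[ci] + eps)
        g, be = gamma[ci], beta[ci]
        for bi in range(b):
            for li in range(l):
                xh = (x[bi, ci, li] - m) * istd
                xhat[bi, ci, li] = xh
                y[bi, ci, li] = g * xh + be
    return y, xhat, mean, var


@njit(cache=True)
def _bn_bwd(dy, xhat, istd, gamma):
    """Batch-norm backward; returns (dx, dgamma, dbeta).

    Uses sum(dxhat) = gamma*dbeta and sum(dxhat*xhat) = gamma*dgamma, so
    one reduction pass plus one elementwise pass suffice.
    """
    b, c, l = dy.shape
    n = np.float32(b * l)
    dgamma = np.zeros(c, dtype=np.float32)
    dbeta = np.zeros(c, dtype=np.float32)
    for bi in range(b):
        for ci in range(c):
            for li in range(l):
                d = dy[bi, ci, li]
                dgamma[ci] += d * xhat[bi, ci, li]
                dbeta[ci] += d
    dx = np.empty_like(dy)
    for ci in range(c):
        g = gamma[ci]
        k = istd[ci] / n
        sd = g * dbeta[ci]
        sdx = g * dgamma[ci]
        for bi in range(b):
            for li in range(l):
                dxhat = dy[bi, ci, li] * g
                dx[bi, ci, li] = k * (
                    n * dxhat - sd - xhat[bi, ci, li] * sdx
                )
    return dx, dgamma, dbeta


@njit(cache=True)
def _act_bwd(dy, mult, xneg):
    """Fused activation backward: dx = dy*mult, da = sum(dy*xneg)."""
    dx = np.empty_like(dy)
    da = 0.0
    df = dy.ravel()
    mf = mult.ravel()
    nf = xneg.ravel()
    xf = dx.ravel()
    for i in range(df.size):
        d = df[i]
        xf[i] = d * mf[i]
        da += np.float64(d * nf[i])
    return dx, np.float32(da)


@njit(cache=True)
def _act_fwd_train(x, a, rand, p_drop):
    """Fused PReLU + inverted dropout, single pass.

    Returns (y, mult, xneg_masked): ``mult`` is the exact input-gradient
    multiplier (slope times kept/scaled mask), ``xneg_masked`` carries
    the PReLU slope gradient.
    """
    keep = np.float32(1.0) - p_drop
    inv_keep = np.float32(1.0) / keep
    y = np.empty_like(x)
    mult = np.empty_like(x)
    xneg = np.empty_like(x)
    xf = x.ravel()
    yf = y.ravel()
    mf = mult.ravel()
    nf = xneg.ravel()
    rf = rand.ravel()
    for i in range(xf.size):
        v = xf[i]
        s = np.float32(1.0) if v > 0 else a
        m = inv_keep if rf[i] >= p_drop else np.float32(0.0)
        mf[i] = s * m
        yf[i] = v * s * m
        nf[i] = (v * m) if v < 0 else np.float32(0.0)
    return y, mult, xneg


class _Adam:
    """Adam over a dict of parameter arrays."""

    def __init__(self, params: dict[str, np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]):
        self.t += 1
        b1t = 1 - self.beta1**self.t
        b2t = 1 - self.beta2**self.t
        for k, g in grads.items():
            self.m[k] = self.beta1 * self.m[k] + (1 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1 - self.beta2) * g * g
            params[k] -= (self.lr * (self.m[k] / b1t)
                          / (np.sqrt(self.v[k] / b2t) + self.eps)).astype(
                              params[k].dtype)


class SpectrumCNN:
    """The raw network: parameters, forward, backward, Adam updates.

    Not a public estimator — :class:`fbccnn.model.FBCCNNClassifier` wraps
    it with the scikit-learn interface. ``seed`` fixes weight
    initialization; dropout masks come from the RNG passed to the
    training entry points.
    """

    def __init__(self, n_channels: int, width: int, n_classes: int,
                 nk1: int, nk2: int, k2: int, s2: int,
                 dropout: float = 0.5, prelu_init: float = 0.25, seed: int = 0):
        if not 1 <= k2 <= width:
            raise ValueError(f"K2={k2} must be in [1, input width {width}]")
        if not 1 <= s2 <= k2:
            raise ValueError(f"S2={s2} must be in [1, K2={k2}]")
        self.n_channels, self.width, self.n_classes = n_channels, width, n_classes
        self.nk1, self.nk2, self.k2, self.s2 = nk1, nk2, k2, s2
        self.dropout = dropout
        self.n_positions = (width - k2) // s2 + 1
        self.flat_width = self.n_positions * nk2

        rng = np.random.default_rng(seed)

        def he_uniform(shape, fan_in):
            lim = np.sqrt(6.0 / fan_in)
            return rng.uniform(-lim, lim, size=shape).astype(_F32)

        glorot_lim = np.sqrt(6.0 / (self.flat_width + n_classes))
        self.params: dict[str, np.ndarray] = {
            "W1": he_uniform((nk1, n_channels), n_channels),
            "b1": np.zeros(nk1, dtype=_F32),
            "g1": np.ones(nk1, dtype=_F32), "be1": np.zeros(nk1, dtype=_F32),
            "a1": np.float32(prelu_init),
            "W2": he_uniform((nk2, nk1 * k2), nk1 * k2),
            "b2": np.zeros(nk2, dtype=_F32),
            "g2": np.ones(nk2, dtype=_F32), "be2": np.zeros(nk2, dtype=_F32),
            "a2": np.float32(prelu_init),
            "Wd": rng.uniform(-glorot_lim, glorot_lim,
                              size=(self.flat_width, n_classes)).astype(_F32),
            "bd": np.zeros(n_classes, dtype=_F32),
        }
        # batch-norm running statistics (inference mode)
        self.run_mean1 = np.zeros(nk1, dtype=_F32)
        self.run_var1 = np.ones(nk1, dtype=_F32)
        self.run_mean2 = np.zeros(nk2, dtype=_F32)
        self.run_var2 = np.ones(nk2, dtype=_F32)

    # -- building blocks -------------------------------------------------

    def _bn(self, x, layer: int, training: bool, cache: dict | None):
        p = self.params
        gamma, beta = p[f"g{layer}"], p[f"be{layer}"]
        run_mean = getattr(self, f"run_mean{layer}")
        run_var = getattr(self, f"run_var{layer}")
        if training:
            y, xhat, mean, var = _bn_fwd_train(x, gamma, beta, _F32(_BN_EPS))
            run_mean *= _F32(1 - _BN_MOMENTUM)
            run_mean += _F32(_BN_MOMENTUM) * mean
            run_var *= _F32(1 - _BN_MOMENTUM)
            run_var += _F32(_BN_MOMENTUM) * var
            cache[f"bn{layer}"] = {
                "xhat": xhat,
                "istd": (1.0 / np.sqrt(var + _F32(_BN_EPS))).astype(_F32),
                "gamma": gamma,
            }
            return y
        istd = 1.0 / np.sqrt(run_var + _F32(_BN_EPS))
        return (gamma * istd)[None, :, None] * (
            x - run_mean[None, :, None]
        ) + beta[None, :, None]

    def _act(self, x, layer: int, training: bool,
             rng: np.random.Generator | None, cache: dict | None):
        a = self.params[f"a{layer}"]
        if training:
            if self.dropout > 0:
                rand = rng.random(x.shape, dtype=_F32)
            else:
                rand = np.ones(x.shape, dtype=_F32)  # everything kept
            y, mult, xneg = _act_fwd_train(x, a, rand, _F32(self.dropout))
            cache[f"act{layer}"] = {"mult": mult, "xneg": xneg}
            return y
        return np.where(x > 0, x, a * x)

    @staticmethod
    def _act_backward(dy, cache):
        return _act_bwd(np.ascontiguousarray(dy), cache["mult"], cache["xneg"])

    def _conv2_windows(self, h1: np.ndarray) -> np.ndarray:
        """(B*P, Nk1*K2) matrix of conv2 input windows."""
        b = h1.shape[0]
        if self.s2 == self.k2:  # non-overlapping: pure reshape/transpose
            used = h1[:, :, : self.n_positions * self.k2]
            win = used.reshape(b, self.nk1, self.n_positions, self.k2)
            win = win.transpose(0, 2, 1, 3)
        else:
            sb, sc, sw = h1.strides
            win = as_strided(
                h1,
                shape=(b, self.n_positions, self.nk1, self.k2),
                strides=(sb, sw * self.s2, sc, sw),
            )
        return np.ascontiguousarray(win).reshape(
            b * self.n_positions, self.nk1 * self.k2
        )

    # -- full passes -----------------------------------------------------

    def forward(self, x: np.ndarray, training: bool = False,
                rng: np.random.Generator | None = None):
        """Return (logits, cache). ``rng`` draws dropout masks when training."""
        p = self.params
        x = np.ascontiguousarray(x, dtype=_F32)
        cache: dict = {"x": x}

        h1 = np.matmul(p["W1"], x)       # (B, Nk1, W) batched BLAS
        h1 += p["b1"][None, :, None]
        h1 = self._bn(h1, 1, training, cache)
        h1 = self._act(h1, 1, training, rng, cache)
        cache["h1_shape"] = h1.shape

        bsz = x.shape[0]
        win_mat = self._conv2_windows(h1)
        h2 = (win_mat @ p["W2"].T).reshape(bsz, self.n_positions, self.nk2)
        h2 = np.ascontiguousarray(h2.transpose(0, 2, 1))   # (B, Nk2, P)
        h2 += p["b2"][None, :, None]
        cache["win_mat"] = win_mat
        h2 = self._bn(h2, 2, training, cache)
        h2 = self._act(h2, 2, training, rng, cache)

        flat = h2.reshape(bsz, self.flat_width)
        cache["flat"] = flat
        logits = flat @ p["Wd"] + p["bd"]
        return logits, cache

    def loss_and_grads(self, x: np.ndarray, y: np.ndarray,
                       rng: np.random.Generator):
        """Softmax cross-entropy loss and gradients for one mini-batch."""
        p = self.params
        logits, cache = self.forward(x, training=True, rng=rng)
        bsz = logits.shape[0]

        z = (logits - logits.max(axis=1, keepdims=True)).astype(np.float64)
        expz = np.exp(z)
        probs = expz / expz.sum(axis=1, keepdims=True)
        loss = -np.mean(np.log(probs[np.arange(bsz), y] + 1e-12))

        dlogits = probs.astype(_F32)
        dlogits[np.arange(bsz), y] -= _F32(1.0)
        dlogits /= _F32(bsz)

        grads: dict[str, np.ndarray] = {}
        grads["Wd"] = cache["flat"].T @ dlogits
        grads["bd"] = dlogits.sum(axis=0)
        dflat = dlogits @ p["Wd"].T
        dh2 = dflat.reshape(bsz, self.nk2, self.n_positions)

        dh2, grads["a2"] = self._act_backward(dh2, cache["act2"])
        b2c = cache["bn2"]
        dh2, grads["g2"], grads["be2"] = _bn_bwd(
            np.ascontiguousarray(dh2), b2c["xhat"], b2c["istd"], b2c["gamma"]
        )
        grads["b2"] = dh2.sum(axis=(0, 2))
        dh2_mat = np.ascontiguousarray(dh2.transpose(0, 2, 1)).reshape(
            bsz * self.n_positions, self.nk2
        )
        grads["W2"] = dh2_mat.T @ cache["win_mat"]
        dwin_mat = dh2_mat @ p["W2"]                    # (B*P, Nk1*K2)
        dwin = dwin_mat.reshape(bsz, self.n_positions, self.nk1, self.k2)
        dh1 = np.zeros(cache["h1_shape"], dtype=_F32)
        if self.s2 == self.k2:
            span = self.n_positions * self.k2
            dh1[:, :, :span] = dwin.transpose(0, 2, 1, 3).reshape(
                bsz, self.nk1, span
            )
        else:
            for pos in range(self.n_positions):         # windows overlap
                start = pos * self.s2
                dh1[:, :, start : start + self.k2] += dwin[:, pos]

        dh1, grads["a1"] = self._act_backward(dh1, cache["act1"])
        b1c = cache["bn1"]
        dh1, grads["g1"], grads["be1"] = _bn_bwd(
            np.ascontiguousarray(dh1), b1c["xhat"], b1c["istd"], b1c["gamma"]
        )
        grads["b1"] = dh1.sum(axis=(0, 2))
        # conv1 weight gradient as batched BLAS: sum_b dh1[b] @ x[b].T
        grads["W1"] = np.matmul(
            dh1, cache["x"].transpose(0, 2, 1)
        ).sum(axis=0)
        return loss, grads

    def predict_logits(self, x: np.ndarray, batch_size: int = 256) -> np.ndarray:
        """Inference-mode logits (running BN statistics, no dropout)."""
        outs = []
        for i in range(0, x.shape[0], batch_size):
            logits, _ = self.forward(x[i : i + batch_size], training=False)
            outs.append(logits)
        return np.concatenate(outs, axis=0).astype(np.float64)

    def fit(self, x: np.ndarray, y: np.ndarray, *, epochs: int = 50,
            batch_size: int = 32, lr: float = 1e-3, seed: int = 0,
            shuffle: bool = True) -> list[float]:
        """Mini-batch Adam training; returns the per-epoch mean loss curve."""
        rng = np.random.default_rng(seed)
        opt = _Adam(self.params, lr=lr)
        x = np.ascontiguousarray(x, dtype=_F32)
        y = np.asarray(y)
        n = x.shape[0]
        curve = []
        for _ in range(epochs):
            order = rng.permutation(n) if shuffle else np.arange(n)
            losses = []
            for i in range(0, n, batch_size):
                idx = order[i : i + batch_size]
                loss, grads = self.loss_and_grads(x[idx], y[idx], rng)
                opt.step(self.params, grads)
                losses.append(loss)
            curve.append(float(np.mean(losses)))
        return curve
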