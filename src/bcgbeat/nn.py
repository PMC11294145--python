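"""Minimal 1-D convolutional network engine on numpy.

Implements exactly what the sequence-to-sequence surrogate models need:
same-length Conv1d (stride 1, stride 2, and transposed stride 2), ReLU,
batch normalization, dropout, mean-squared-error loss and an Adam optimizer,
each with an explicit backward pass.  Everything runs in float32 on the CPU
and is deterministic given a seeded ``numpy.random.Generator``.

Convolutions follow the deep-learning convention (cross-correlation) with
"same" zero padding, so output length equals input length divided by the
stride.  Wide kernels are evaluated in the frequency domain (circular
correlation via ``scipy.fft`` with zero padding), which turns the dominant
O(k * n) per-channel cost into O(n log n); narrow kernels use a direct
tap-loop that maps onto BLAS matrix products.  Both paths compute the same
quantity and are cross-checked in the test suite.
"""

from __future__ import annotations

import ctypes
import sys

import numpy as np
from scipy import fft as sfft


def _tune_allocator():
    """Keep large numpy temporaries on the heap for reuse.

    Training repeatedly allocates and frees 10-100 MB scratch arrays; with
    glibc defaults these are mmap-backed, so every step pays page-fault and
    zeroing costs.  Raising the mmap/trim thresholds lets the allocator
    recycle the buffers, roughly halving the per-step wall time.  Silently a
    no-op off glibc.
    """
    if not sys.platform.startswith("linux"):
        return
    try:
        libc = ctypes.CDLL("libc.so.6")
        libc.mallopt(-1, 1 << 30)  # M_TRIM_THRESHOLD
        libc.mallopt(-3, 1 << 30)  # M_MMAP_THRESHOLD
    except OSError:
        pass


_tune_allocator()

__all__ = [
    "Param", "Conv1d", "ConvTranspose1d", "ReLU", "BatchNorm1d", "Dropout",
    "Upsample2", "Sequential", "Residual", "Adam", "mse_loss",
]

F32 = np.float32

#: kernels at least this wide go through the FFT path
FFT_KERNEL_MIN = 16


class Param:
    """A learnable tensor with its gradient accumulator."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.ascontiguousarray(value, dtype=F32)
        self.grad = np.zeros_like(self.value)

    def zero_grad(self):
        self.grad[...] = 0


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError


def _he_init(rng: np.random.Generator, out_ch: int, in_ch: int, k: int) -> np.ndarray:
    std = np.sqrt(2.0 / (in_ch * k))
    return rng.normal(0.0, std, size=(out_ch, in_ch, k))


class Conv1d(Layer):
    """Same-padded 1-D convolution, stride 1 or 2, odd kernel width."""

    def __init__(self, in_ch: int, out_ch: int, k: int, stride: int = 1,
                 rng: np.random.Generator | None = None):
        if k % 2 != 1:
            raise ValueError("kernel width must be odd for symmetric same padding")
        if stride not in (1, 2):
            raise ValueError("stride must be 1 or 2")
        rng = rng or np.random.default_rng(0)
        self.in_ch, self.out_ch, self.k, self.stride = in_ch, out_ch, k, stride
        self.W = Param(_he_init(rng, out_ch, in_ch, k))
        self.b = Param(np.zeros(out_ch))
        self._use_fft = stride == 1 and k >= FFT_KERNEL_MIN
        self._cache = None
        self._dft = None  # lazy (F, k) inverse-DFT slab for the weight gradient

    def params(self):
        return [self.W, self.b]

    # -- direct path -------------------------------------------------------
    def _forward_direct(self, x):
        B, C, n = x.shape
        k, p, s = self.k, (self.k - 1) // 2, self.stride
        if s == 2 and n % 2:
            raise ValueError("stride-2 conv needs an even input length")
        n_out = n // s
        xp = np.zeros((C, B, n + k - 1), dtype=F32)
        xp[:, :, p:p + n] = x.transpose(1, 0, 2)
        W = self.W.value
        out = np.zeros((self.out_ch, B * n_out), dtype=F32)
        for t in range(k):
            sl = xp[:, :, t:t + s * n_out:s].reshape(C, B * n_out)
            out += W[:, :, t] @ sl
        self._cache = ("direct", xp, (B, C, n, n_out))
        out = out.reshape(self.out_ch, B, n_out).transpose(1, 0, 2)
        return out + self.b.value[None, :, None]

    def _backward_direct(self, dy):
        _, xp, (B, C, n, n_out) = self._cache
        k, p, s = self.k, (self.k - 1) // 2, self.stride
        W = self.W.value
        dy2 = np.ascontiguousarray(dy.transpose(1, 0, 2)).reshape(self.out_ch, B * n_out)
        self.b.grad += dy2.sum(axis=1)
        dxp = np.zeros_like(xp)
        for t in range(k):
            sl = xp[:, :, t:t + s * n_out:s].reshape(C, B * n_out)
            self.W.grad[:, :, t] += dy2 @ sl.T
            dxp[:, :, t:t + s * n_out:s] += (W[:, :, t].T @ dy2).reshape(C, B, n_out)
        return np.ascontiguousarray(dxp[:, :, p:p + n].transpose(1, 0, 2))

    # -- FFT path (stride 1) ----------------------------------------------
    def _dft_slab(self, N: int) -> tuple[np.ndarray, np.ndarray]:
        """Real/imag (F, k) slabs evaluating an inverse rfft at the first k lags.

        ``cc[t] = sum_f w_f Re(CCf[f] e^{+2 pi i f t / N}) / N`` with the
        rfft symmetry weight ``w_f = 2`` for interior bins — a pair of sgemms
        instead of a full-length inverse FFT per (out, in) channel pair.
        """
        if self._dft is None or self._dft[0] != N:
            F = N // 2 + 1
            lags = np.arange(self.k) - (self.k - 1) // 2
            E = np.exp(2j * np.pi * np.outer(np.arange(F), lags) / N) / N
            E[1:] *= 2
            if N % 2 == 0:  # the Nyquist bin is not duplicated for even N
                E[-1] /= 2
            self._dft = (N, E.real.astype(F32), E.imag.astype(F32))
        return self._dft[1], self._dft[2]

    def _forward_fft(self, x):
        B, C, n = x.shape
        k, p = self.k, (self.k - 1) // 2
        N = sfft.next_fast_len(n + k)
        Xf = sfft.rfft(x.astype(F32, copy=False), N, axis=2)      # (B, C, F)
        Wf = sfft.rfft(self.W.value, N, axis=2)                   # (O, C, F)
        Xf_t = np.ascontiguousarray(Xf.transpose(2, 1, 0))        # (F, C, B)
        Wf_t = np.ascontiguousarray(Wf.transpose(2, 0, 1))        # (F, O, C)
        Yf = np.matmul(np.conj(Wf_t), Xf_t)                       # (F, O, B)
        c = sfft.irfft(Yf.transpose(1, 2, 0), N, axis=2)          # (O, B, N)
        if p:
            out = np.concatenate([c[:, :, N - p:], c[:, :, :n - p]], axis=2)
        else:
            out = c[:, :, :n]
        self._cache = ("fft", Xf_t, Wf_t, (B, C, n, N))
        return np.ascontiguousarray(out.transpose(1, 0, 2)) + self.b.value[None, :, None]

    def _backward_fft(self, dy):
        _, Xf_t, Wf_t, (B, C, n, N) = self._cache
        k, p = self.k, (self.k - 1) // 2
        DYf = sfft.rfft(dy.astype(F32, copy=False), N, axis=2)    # (B, O, F)
        DYf_t = np.ascontiguousarray(DYf.transpose(2, 1, 0))      # (F, O, B)
        self.b.grad += dy.sum(axis=(0, 2))
        # weight grad: circular cross-correlation of dy with x, evaluated only
        # at the k lags the kernel occupies (wrapped negatives first)
        CCf = np.matmul(np.conj(DYf_t), Xf_t.transpose(0, 2, 1))  # (F, O, C)
        Er, Ei = self._dft_slab(N)
        F = N // 2 + 1
        CC2 = CCf.transpose(1, 2, 0).reshape(self.out_ch * self.in_ch, F)
        lag = np.ascontiguousarray(CC2.real) @ Er - np.ascontiguousarray(CC2.imag) @ Ei
        self.W.grad += lag.reshape(self.out_ch, self.in_ch, k)
        # input grad: circular convolution of dy with W
        DXf = np.matmul(Wf_t.transpose(0, 2, 1), DYf_t)           # (F, C, B)
        conv = sfft.irfft(DXf.transpose(2, 1, 0), N, axis=2)      # (B, C, N)
        return np.ascontiguousarray(conv[:, :, p:p + n])

    def forward(self, x, train=False):
        x = np.ascontiguousarray(x, dtype=F32)
        if x.shape[1] != self.in_ch:
            raise ValueError(f"expected {self.in_ch} input channels, got {x.shape[1]}")
        return self._forward_fft(x) if self._use_fft else self._forward_direct(x)

    def backward(self, dy):
        dy = np.ascontiguousarray(dy, dtype=F32)
        return self._backward_fft(dy) if self._use_fft else self._backward_direct(dy)


class _ZeroStuff(Layer):
    """Insert a zero between consecutive samples (length n -> 2n)."""

    def forward(self, x, train=False):
        B, C, n = x.shape
        out = np.zeros((B, C, 2 * n), dtype=F32)
        out[:, :, ::2] = x
        return out

    def backward(self, dy):
        return np.ascontiguousarray(dy[:, :, ::2])


class ConvTranspose1d(Layer):
    """Stride-2 transposed convolution: zero-stuffing followed by a same conv."""

    def __init__(self, in_ch: int, out_ch: int, k: int,
                 rng: np.random.Generator | None = None):
        self.stuff = _ZeroStuff()
        self.conv = Conv1d(in_ch, out_ch, k, stride=1, rng=rng)

    def params(self):
        return self.conv.params()

    def forward(self, x, train=False):
        return self.conv.forward(self.stuff.forward(x, train), train)

    def backward(self, dy):
        return self.stuff.backward(self.conv.backward(dy))


class ReLU(Layer):
    def forward(self, x, train=False):
        self._mask = x > 0
        return np.where(self._mask, x, 0)

    def backward(self, dy):
        return np.where(self._mask, dy, 0)


class BatchNorm1d(Layer):
    """Per-channel normalization over (batch, time), with running statistics."""

    def __init__(self, n_ch: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Param(np.ones(n_ch))
        self.beta = Param(np.zeros(n_ch))
        self.momentum, self.eps = momentum, eps
        self.running_mean = np.zeros(n_ch, dtype=F32)
        self.running_var = np.ones(n_ch, dtype=F32)

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x, train=False):
        if train:
            mean = x.mean(axis=(0, 2))
            var = x.var(axis=(0, 2))
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mean).astype(F32)
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * var).astype(F32)
        else:
            mean, var = self.running_mean, self.running_var
        invstd = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None]) * invstd[None, :, None]
        self._cache = (xhat, invstd.astype(F32), x.shape)
        return self.gamma.value[None, :, None] * xhat + self.beta.value[None, :, None]

    def backward(self, dy):
        xhat, invstd, (B, C, n) = self._cache
        M = B * n
        self.gamma.grad += (dy * xhat).sum(axis=(0, 2))
        self.beta.grad += dy.sum(axis=(0, 2))
        dxhat = dy * self.gamma.value[None, :, None]
        s1 = dxhat.sum(axis=(0, 2), keepdims=True)
        s2 = (dxhat * xhat).sum(axis=(0, 2), keepdims=True)
        return (invstd[None, :, None] / M) * (M * dxhat - s1 - xhat * s2)


class Dropout(Layer):
    """Inverted dropout; identity outside training."""

    def __init__(self, p: float, rng: np.random.Generator | None = None):
        if not 0 <= p < 1:
            raise ValueError("dropout rate must be in [0, 1)")
        self.p = p
        self.rng = rng or np.random.default_rng(0)
        self._mask = None

    def forward(self, x, train=False):
        if not train or self.p == 0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.p).astype(F32) / (1 - self.p)
        return x * self._mask

    def backward(self, dy):
        return dy if self._mask is None else dy * self._mask


class Upsample2(Layer):
    """Nearest-neighbour doubling of the time axis (for residual skips)."""

    def forward(self, x, train=False):
        return np.repeat(x, 2, axis=2)

    def backward(self, dy):
        B, C, n2 = dy.shape
        return dy.reshape(B, C, n2 // 2, 2).sum(axis=3)


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        self.layers = list(layers)

    def params(self):
        return [p for layer in self.layers for p in layer.params()]

    def forward(self, x, train=False):
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, dy):
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy


class Residual(Layer):
    """``out = ReLU(main(x) + skip(x))`` — one residual block."""

    def __init__(self, main: Layer, skip: Layer):
        self.main, self.skip = main, skip
        self.relu = ReLU()

    def params(self):
        return self.main.params() + self.skip.params()

    def forward(self, x, train=False):
        return self.relu.forward(self.main.forward(x, train) + self.skip.forward(x, train),
                                 train)

    def backward(self, dy):
        dy = self.relu.backward(dy)
        return self.main.backward(dy) + self.skip.backward(dy)


def mse_loss(pred: np.ndarray, target: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean squared error and its gradient with respect to ``pred``."""
    diff = (pred - target).astype(F32)
    loss = float(np.mean(diff.astype(np.float64) ** 2))
    return loss, (2.0 / diff.size) * diff


class Adam:
    """Adam optimizer with bias-corrected moments and linear warm-up.

    During the first steps the bias-corrected update is close to a pure sign
    step of size ``lr`` for EVERY parameter, which at aggressive learning
    rates can swing the output wildly before the second-moment estimate is
    informative.  A short linear warm-up of the learning rate removes that
    failure mode without affecting long runs.
    """

    def __init__(self, params: list[Param], lr: float = 1e-4,
                 betas: tuple = (0.9, 0.999), eps: float = 1e-8,
                 warmup_steps: int = 10):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, betas[0], betas[1], eps
        self.warmup_steps = warmup_steps
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def step(self):
        self.t += 1
        lr = self.lr
        if self.t <= self.warmup_steps:
            lr = self.lr * self.t / (self.warmup_steps + 1)
        b1t = 1 - self.b1 ** self.t
        b2t = 1 - self.b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * p.grad
            v *= self.b2
            v += (1 - self.b2) * p.grad ** 2
            p.value -= lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.zero_grad()
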