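"""Sequence-to-sequence surrogate models: a 3-layer CNN and a residual
encoder-decoder.

Both map a normalized 3-channel BCG window ``(k=3, n)`` to an equal-length
single-channel approximation of the surrogate signal and are trained with
mean-squared error against the kernel-encoded target.

CNN
    three same-padded convolutions of 64, 128 and 1 channels with
    increasingly wide kernels (5, 65, 129) and ReLU between layers.
ResNet
    an 8-channel stem (kernel 5), two strided residual blocks down
    (8->16->32, stride 2 each), two transposed residual blocks up
    (32->16->8), batch normalization inside the blocks and 40% dropout
    between them, then a single-channel kernel-5 projection.  The two
    stride-2 stages require the input length to be divisible by 4.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import nn
from .encoding import KernelSpec, SurrogateSignal
from .types import SignalWindow

__all__ = ["ModelConfig", "TrainedModel", "build_model", "count_parameters",
           "train", "predict_surrogate", "save_checkpoint", "load_checkpoint"]


@dataclass
class ModelConfig:
    """Architecture and optimization settings."""

    arch: str = "cnn"                       # "cnn" or "resnet"
    cnn_channels: tuple = (64, 128, 1)
    cnn_kernels: tuple = (5, 65, 129)
    resnet_stem_channels: int = 8
    resnet_stem_kernel: int = 5
    resnet_block_channels: tuple = (16, 32)  # encoder plan; decoder mirrors it
    resnet_block_kernel: int = 5
    dropout: float = 0.4
    lr: float = 1e-4
    warmup_steps: int = 10
    batch_size: int = 32
    epochs: int = 40
    seed: int = 0
    best_epoch_selection: bool = True       # keep best-validation-loss weights

    def __post_init__(self):
        if self.arch not in ("cnn", "resnet"):
            raise ValueError("arch must be 'cnn' or 'resnet'")


class _CNN(nn.Sequential):
    def __init__(self, config: ModelConfig, rng: np.random.Generator):
        chans = (3,) + tuple(config.cnn_channels)
        layers: list[nn.Layer] = []
        for i, k in enumerate(config.cnn_kernels):
            layers.append(nn.Conv1d(chans[i], chans[i + 1], k, rng=rng))
            if i < len(config.cnn_kernels) - 1:
                layers.append(nn.ReLU())
        super().__init__(*layers)


def _down_block(c_in: int, c_out: int, k: int, rng) -> nn.Residual:
    main = nn.Sequential(
        nn.Conv1d(c_in, c_out, k, stride=2, rng=rng),
        nn.BatchNorm1d(c_out),
        nn.ReLU(),
        nn.Conv1d(c_out, c_out, k, rng=rng),
        nn.BatchNorm1d(c_out),
    )
    skip = nn.Conv1d(c_in, c_out, 1, stride=2, rng=rng)
    return nn.Residual(main, skip)


def _up_block(c_in: int, c_out: int, k: int, rng) -> nn.Residual:
    main = nn.Sequential(
        nn.ConvTranspose1d(c_in, c_out, k, rng=rng),
        nn.BatchNorm1d(c_out),
        nn.ReLU(),
        nn.Conv1d(c_out, c_out, k, rng=rng),
        nn.BatchNorm1d(c_out),
    )
    skip = nn.Sequential(nn.Upsample2(), nn.Conv1d(c_in, c_out, 1, rng=rng))
    return nn.Residual(main, skip)


class _ResNet(nn.Sequential):
    def __init__(self, config: ModelConfig, rng: np.random.Generator):
        stem_c = config.resnet_stem_channels
        k = config.resnet_block_kernel
        c1, c2 = config.resnet_block_channels
        drop = lambda: nn.Dropout(config.dropout, rng=rng)  # noqa: E731
        super().__init__(
            nn.Conv1d(3, stem_c, config.resnet_stem_kernel, rng=rng),
            nn.ReLU(),
            _down_block(stem_c, c1, k, rng), drop(),
            _down_block(c1, c2, k, rng), drop(),
            _up_block(c2, c1, k, rng), drop(),
            _up_block(c1, stem_c, k, rng),
            nn.Conv1d(stem_c, 1, config.resnet_stem_kernel, rng=rng),
        )

    def forward(self, x, train=False):
        if x.shape[2] % 4 != 0:
            raise ValueError("resnet input length must be divisible by 4 "
                             "(two stride-2 stages)")
        return super().forward(x, train)


def build_model(config: ModelConfig) -> nn.Sequential:
    """Instantiate an untrained model with seeded weight initialization.

    Hidden layers use He initialization; the output convolution starts at
    zero so the untrained model predicts the surrogate's zero baseline and
    the few first epochs are spent shaping beat responses rather than
    unlearning initialization noise — this matters at short training budgets.
    """
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    model = _CNN(config, rng) if config.arch == "cnn" else _ResNet(config, rng)
    model.layers[-1].W.value[...] = 0.0
    return model


def count_parameters(model: nn.Layer) -> int:
    return int(sum(p.value.size for p in model.params()))


@dataclass
class TrainedModel:
    """A fitted model with its config snapshot and loss history."""

    model: nn.Sequential
    config: ModelConfig
    history: list[dict] = field(default_factory=list)
    best_epoch: int | None = None

    @property
    def history_frame(self):
        import pandas as pd
        return pd.DataFrame(self.history)


def _batchnorm_layers(layer: nn.Layer):
    if isinstance(layer, nn.BatchNorm1d):
        yield layer
    for attr in ("layers",):
        for sub in getattr(layer, attr, []):
            yield from _batchnorm_layers(sub)
    for attr in ("main", "skip", "conv"):
        sub = getattr(layer, attr, None)
        if isinstance(sub, nn.Layer):
            yield from _batchnorm_layers(sub)


def _snapshot(model: nn.Layer):
    state = [p.value.copy() for p in model.params()]
    bn = [(l.running_mean.copy(), l.running_var.copy()) for l in _batchnorm_layers(model)]
    return state, bn


def _restore(model: nn.Layer, snap):
    state, bn = snap
    for p, v in zip(model.params(), state):
        p.value[...] = v
    for layer, (m, v) in zip(_batchnorm_layers(model), bn):
        layer.running_mean, layer.running_var = m.copy(), v.copy()


def train(
    model: nn.Sequential,
    x_train: np.ndarray,
    y_train: np.ndarray,
    x_val: np.ndarray | None = None,
    y_val: np.ndarray | None = None,
    config: ModelConfig = ModelConfig(),
    verbose: bool = False,
) -> TrainedModel:
    """Minimize the MSE between the model output and the surrogate target.

    ``x_train`` is ``(n_windows, 3, n)`` of normalized windows, ``y_train``
    ``(n_windows, n)`` of encoded surrogates.  Training is deterministic
    given ``config.seed`` (shuffling, dropout and initialization all derive
    from it).  With a validation set and ``best_epoch_selection``, the
    weights of the best validation epoch are restored at the end.
    """
    x_train = np.ascontiguousarray(x_train, dtype=nn.F32)
    y_train = np.ascontiguousarray(y_train, dtype=nn.F32)
    if y_train.ndim == 2:
        y_train = y_train[:, None, :]
    if x_val is not None:
        x_val = np.ascontiguousarray(x_val, dtype=nn.F32)
        y_val = np.ascontiguousarray(y_val, dtype=nn.F32)
        if y_val.ndim == 2:
            y_val = y_val[:, None, :]
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    opt = nn.Adam(model.params(), lr=config.lr,
                  warmup_steps=config.warmup_steps)
    n = x_train.shape[0]
    history: list[dict] = []
    best = (np.inf, None, None)
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        losses = []
        for i0 in range(0, n, config.batch_size):
            idx = order[i0:i0 + config.batch_size]
            opt.zero_grad()
            pred = model.forward(x_train[idx], train=True)
            loss, dy = nn.mse_loss(pred, y_train[idx])
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}, batch {i0 // config.batch_size} "
                    f"(lr={config.lr}, batch_size={config.batch_size})")
            model.backward(dy)
            opt.step()
            losses.append(loss)
        row = {"epoch": epoch, "train_mse": float(np.mean(losses))}
        if x_val is not None and len(x_val):
            val_pred = evaluate_in_batches(model, x_val, config.batch_size)
            row["val_mse"] = float(np.mean((val_pred - y_val) ** 2))
            if row["val_mse"] < best[0]:
                best = (row["val_mse"], _snapshot(model), epoch)
        history.append(row)
        if verbose:
            print(f"epoch {epoch}: " + ", ".join(f"{k}={v:.5f}" for k, v in row.items()
                                                 if k != "epoch"))
    best_epoch = None
    if config.best_epoch_selection and best[1] is not None:
        _restore(model, best[1])
        best_epoch = best[2]
    return TrainedModel(model, config, history, best_epoch)


def evaluate_in_batches(model: nn.Sequential, x: np.ndarray, batch_size: int = 32) -> np.ndarray:
    outs = [model.forward(x[i0:i0 + batch_size], train=False)
            for i0 in range(0, x.shape[0], batch_size)]
    return np.concatenate(outs, axis=0)


def predict_surrogate(trained: TrainedModel, win: SignalWindow,
                      kernel: KernelSpec | None = None) -> SurrogateSignal:
    """Run inference on one window; returns the raw (unsmoothed) approximation."""
    x = np.ascontiguousarray(win.samples.T[None], dtype=nn.F32)  # (1, k, n)
    out = trained.model.forward(x, train=False)
    if out.shape[-1] != win.n_samples:
        raise ValueError("model output length does not match the window")
    return SurrogateSignal(out[0, 0].astype(float), fs=win.fs, t0=win.t0, kernel=kernel)


def save_checkpoint(trained: TrainedModel, path: str | Path) -> None:
    """Weights + batchnorm statistics + config snapshot in one .npz file."""
    path = Path(path)
    arrays = {f"w{i}": p.value for i, p in enumerate(trained.model.params())}
    for i, layer in enumerate(_batchnorm_layers(trained.model)):
        arrays[f"bn{i}_mean"] = layer.running_mean
        arrays[f"bn{i}_var"] = layer.running_var
    meta = dataclasses.asdict(trained.config)
    meta["history"] = trained.history
    meta["best_epoch"] = trained.best_epoch
    arrays["meta_json"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
    np.savez(path, **arrays)


def load_checkpoint(path: str | Path) -> TrainedModel:
    z = np.load(Path(path), allow_pickle=False)
    meta = json.loads(bytes(z["meta_json"]).decode())
    history = meta.pop("history")
    best_epoch = meta.pop("best_epoch")
    for key in ("cnn_channels", "cnn_kernels", "resnet_block_channels"):
        meta[key] = tuple(meta[key])
    config = ModelConfig(**meta)
    model = build_model(config)
    for i, p in enumerate(model.params()):
        p.value[...] = z[f"w{i}"]
    for i, layer in enumerate(_batchnorm_layers(model)):
        layer.running_mean = z[f"bn{i}_mean"].copy()
        layer.running_var = z[f"bn{i}_var"].copy()
    return TrainedModel(model, config, history, best_epoch)
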