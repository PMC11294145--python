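"""Architecture contracts and training behaviour of the surrogate models."""

import numpy as np
import pytest

from bcgbeat import (KernelSpec, ModelConfig, build_model, count_parameters,
                     encode_events, load_checkpoint, predict_surrogate,
                     save_checkpoint, train)
from bcgbeat.models import TrainedModel, evaluate_in_batches
from bcgbeat.preprocessing import bandpass, iqr_normalize, segment_windows

from conftest import make_quiet_recording


def _training_crop(n_samples=1024, window_s=16.0, idx=2, seed=1, noise_sd=0.35):
    """One normalized window + triangular surrogate target from a synthetic night."""
    from bcgbeat import SubjectParams, derive_jpeaks, simulate_heartbeats, synthesize_bcg
    params = SubjectParams(movement_rate=0.0, noise_sd=noise_sd)
    r = simulate_heartbeats(params, 80.0, seed=seed)
    j = derive_jpeaks(r, params)
    rec = synthesize_bcg(j, params, fs=64.0, duration=80.0, seed=seed)
    rec = bandpass(rec, 4.0, 25.0)
    wins, evs = segment_windows(rec, r, window_s, window_s)
    w = iqr_normalize(wins[idx])
    y = encode_events(evs[idx], n_samples, 64.0, 0.0, KernelSpec("triangular", 0.8))
    return w.samples.T[None], y.values[None], w


class TestBuildModel:
    @pytest.mark.parametrize("arch", ["cnn", "resnet"])
    @pytest.mark.parametrize("n", [256, 1024, 4096])
    def test_length_preserved(self, arch, n):
        model = build_model(ModelConfig(arch=arch, seed=0))
        x = np.random.default_rng(0).normal(size=(2, 3, n)).astype(np.float32)
        assert model.forward(x).shape == (2, 1, n)

    def test_resnet_rejects_length_not_divisible_by_four(self):
        model = build_model(ModelConfig(arch="resnet", seed=0))
        x = np.zeros((1, 3, 1022), dtype=np.float32)
        with pytest.raises(ValueError, match="divisible by 4"):
            model.forward(x)

    def test_cnn_parameter_count_analytic(self):
        """Trainable parameters equal the closed-form count from layer sizes."""
        cfg = ModelConfig(arch="cnn")
        chans = (3,) + tuple(cfg.cnn_channels)
        expected = sum(chans[i] * chans[i + 1] * k + chans[i + 1]
                       for i, k in enumerate(cfg.cnn_kernels))
        assert expected == 550_145
        assert count_parameters(build_model(cfg)) == expected

    def test_seeded_init_reproducible(self):
        a = build_model(ModelConfig(arch="resnet", seed=3))
        b = build_model(ModelConfig(arch="resnet", seed=3))
        for pa, pb in zip(a.params(), b.params()):
            assert np.array_equal(pa.value, pb.value)


class TestTrain:
    def test_single_window_overfit(self):
        """Capacity sanity: one window is memorized essentially exactly."""
        X, Y, _ = _training_crop()
        cfg = ModelConfig(arch="cnn", lr=1e-3, warmup_steps=200, epochs=600,
                          batch_size=1, seed=0, best_epoch_selection=False)
        model = build_model(cfg)
        trained = train(model, X, Y, config=cfg)
        assert trained.history[-1]["train_mse"] < 1e-3

    def test_loss_decreases_on_small_set(self):
        """Epoch-mean training loss strictly decreases early in training."""
        rng = np.random.default_rng(0)
        Xs, Ys = [], []
        for i in range(6):
            X, Y, _ = _training_crop(idx=i % 4, seed=i)
            Xs.append(X[0]), Ys.append(Y[0])
        X, Y = np.stack(Xs), np.stack(Ys)
        cfg = ModelConfig(arch="cnn", epochs=6, batch_size=3, seed=0,
                          best_epoch_selection=False)
        trained = train(build_model(cfg), X, Y, config=cfg)
        losses = [h["train_mse"] for h in trained.history]
        assert losses[-1] < losses[0]

    def test_seeded_determinism(self):
        X, Y, _ = _training_crop()
        cfg = ModelConfig(arch="cnn", epochs=3, batch_size=1, seed=7,
                          best_epoch_selection=False)
        h1 = train(build_model(cfg), X, Y, config=cfg).history
        h2 = train(build_model(cfg), X, Y, config=cfg).history
        assert h1 == h2

    def test_resnet_trains(self):
        X, Y, _ = _training_crop()
        cfg = ModelConfig(arch="resnet", epochs=8, batch_size=1, seed=0,
                          lr=1e-3, best_epoch_selection=False)
        trained = train(build_model(cfg), X, Y, config=cfg)
        losses = [h["train_mse"] for h in trained.history]
        assert losses[-1] < losses[0]
        assert all(np.isfinite(l) for l in losses)


class TestPredict:
    def test_predict_surrogate_contract(self):
        X, Y, window = _training_crop()
        cfg = ModelConfig(arch="cnn", seed=0)
        trained = TrainedModel(build_model(cfg), cfg)
        y_hat = predict_surrogate(trained, window)
        assert y_hat.n_samples == window.n_samples
        assert np.all(np.isfinite(y_hat.values))

    def test_translation_covariance(self):
        """Shifting the input shifts the CNN's response (same padding, no
        pooling), up to one sample, for a beat far from the window edges."""
        cfg = ModelConfig(arch="cnn", seed=0)
        model = build_model(cfg)
        # give the zero-initialized head random weights so the output varies
        rng = np.random.default_rng(5)
        head = model.layers[-1]
        head.W.value[...] = rng.normal(0, 0.05, head.W.value.shape)
        n = 1024
        x = np.zeros((1, 3, n), dtype=np.float32)
        beat = rng.normal(size=(3, 33)).astype(np.float32)
        x[0, :, 400:433] = beat
        shift = 50
        x2 = np.zeros_like(x)
        x2[0, :, 400 + shift:433 + shift] = beat
        margin = slice(200, 800)
        a1 = int(np.argmax(model.forward(x)[0, 0, margin]))
        a2 = int(np.argmax(model.forward(x2)[0, 0, margin]))
        assert abs(a2 - a1 - shift) <= 1

    def test_checkpoint_roundtrip(self, tmp_path):
        X, Y, window = _training_crop()
        cfg = ModelConfig(arch="resnet", epochs=2, batch_size=1, seed=1)
        trained = train(build_model(cfg), X, Y, X, Y, cfg)
        out1 = evaluate_in_batches(trained.model, X.astype(np.float32))
        save_checkpoint(trained, tmp_path / "ckpt.npz")
        loaded = load_checkpoint(tmp_path / "ckpt.npz")
        out2 = evaluate_in_batches(loaded.model, X.astype(np.float32))
        assert np.allclose(out1, out2, atol=1e-6)
        assert loaded.history == trained.history
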