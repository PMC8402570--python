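import numpy as np
import pytest

from vigil import nn
from vigil.config import AEConfig, MLPConfig, TCNConfig
from vigil.models import (
    TrainingError,
    build_mlpnn,
    build_tcn,
    build_tcn_ae,
    fit_channel_state,
    predict_label,
    predict_proba,
    receptive_field,
    reconstruction_mse,
    standardize_by_channel,
    train_autoencoder,
    train_classifier,
    train_latent_classifier,
)


# ---------------------------------------------------------------------------
# receptive field

def test_receptive_field_values():
    assert receptive_field(2, 2, 32) == 128
    assert receptive_field(4, 2, 32) == 256
    assert receptive_field(2, 1, 8) == 16
    assert receptive_field(2, 2, 8) == 32


def test_receptive_field_validation():
    with pytest.raises(ValueError):
        receptive_field(0, 2, 32)
    with pytest.raises(ValueError):
        receptive_field(2, 2, 0)


# ---------------------------------------------------------------------------
# builders

def test_mlpnn_parameter_count_closed_form():
    m = build_mlpnn(MLPConfig())
    expected = (320 * 250 + 250) + (250 * 200 + 200) + (200 * 150 + 150) + (
        150 * 1 + 1
    )
    assert expected == 160_751
    assert m.n_parameters == expected


def test_mlpnn_other_width():
    m = build_mlpnn(MLPConfig(hidden_units=(10, 8, 6)), n_features=20)
    expected = (20 * 10 + 10) + (10 * 8 + 8) + (8 * 6 + 6) + (6 * 1 + 1)
    assert m.n_parameters == expected


def test_tcn_records_receptive_field_and_warns_on_cap():
    cfg = TCNConfig(dilations=(1, 2, 4, 8, 16, 32), kernel_size=2, n_blocks=2)
    m = build_tcn(cfg, n_channels=4, seq_len=250)
    assert m.extras["receptive_field"] == 128
    with pytest.warns(UserWarning, match="receptive field"):
        build_tcn(
            TCNConfig(kernel_size=4), n_channels=4, seq_len=250, rf_cap=250
        )


def test_tcn_ae_shapes():
    cfg = AEConfig()
    ae = build_tcn_ae(cfg, n_channels=16, seq_len=250)
    assert ae.latent_shape == (50, cfg.latent_filters)
    x = np.random.default_rng(0).normal(size=(3, 250, 16)).astype(np.float32)
    z = ae.encode(x)
    assert z.shape == (3, 50, cfg.latent_filters)
    r = ae.reconstruct(x)
    assert r.shape == x.shape
    with pytest.raises(ValueError, match="divisible"):
        build_tcn_ae(cfg, n_channels=4, seq_len=251)


def test_tcn_matches_hand_convolution():
    """Small-case TCN convolution equals the hand-computed values."""
    rng = np.random.default_rng(0)
    conv = nn.Conv1D(1, 1, 2, rng, dilation=2, causal=True)
    w0, w1 = 0.5, -1.0
    conv.params["W"][0, 0, 0] = w0
    conv.params["W"][1, 0, 0] = w1
    conv.params["b"][0] = 0.25
    x = np.array([[1.0, 2.0, 3.0, 4.0, 5.0]], dtype=np.float32)
    y = conv.forward(x[:, :, None])[0, :, 0]
    # causal, dilation 2: y[t] = b + w0 * x[t-2] + w1 * x[t] (x[<0] = 0)
    expected = [
        0.25 + w1 * 1,
        0.25 + w1 * 2,
        0.25 + w0 * 1 + w1 * 3,
        0.25 + w0 * 2 + w1 * 4,
        0.25 + w0 * 3 + w1 * 5,
    ]
    assert np.allclose(y, expected)


# ---------------------------------------------------------------------------
# channel standardization

def test_channel_standardization(rng):
    x = rng.normal(loc=3.0, scale=2.0, size=(20, 4, 50))
    state = fit_channel_state(x)
    z = standardize_by_channel(x, state)
    assert z.shape == (20, 50, 4)
    assert np.allclose(z.mean(axis=(0, 1)), 0.0, atol=1e-5)
    assert np.allclose(z.std(axis=(0, 1)), 1.0, atol=1e-4)
    # constant channel: SD floored, no division blowup
    x[:, 0, :] = 7.0
    z2 = standardize_by_channel(x, fit_channel_state(x))
    assert np.isfinite(z2).all()


# ---------------------------------------------------------------------------
# training

def _toy_features(rng, n=64, f=12):
    y = rng.integers(0, 2, n).astype(float)
    X = rng.normal(size=(n, f)).astype(np.float32)
    X[:, 0] += 3.0 * y  # separable
    return X, y


def test_train_classifier_learns_toy_problem(rng):
    X, y = _toy_features(rng)
    m = build_mlpnn(
        MLPConfig(hidden_units=(16, 8, 4), dropout_rate=0.0,
                  learning_rate=1e-2, epochs=60),
        n_features=X.shape[1],
    )
    train_classifier(m, X, y, seed=1)
    assert len(m.history) == 60
    assert m.history[-1] < m.history[0]
    assert (predict_label(m, X) == y).mean() > 0.95
    p = predict_proba(m, X)
    assert ((p >= 0) & (p <= 1)).all()


def test_training_is_deterministic(rng):
    X, y = _toy_features(rng)
    cfg = MLPConfig(hidden_units=(8, 6, 4), dropout_rate=0.5,
                    learning_rate=1e-3, epochs=5)
    m1 = build_mlpnn(cfg, n_features=X.shape[1], seed=3)
    m2 = build_mlpnn(cfg, n_features=X.shape[1], seed=3)
    train_classifier(m1, X, y, seed=3)
    train_classifier(m2, X, y, seed=3)
    assert m1.history == m2.history
    assert all(
        np.array_equal(a, b) for a, b in zip(m1.net.state(), m2.net.state())
    )


def test_label_validation(rng):
    X, y = _toy_features(rng)
    m = build_mlpnn(MLPConfig(hidden_units=(4, 4, 4)), n_features=X.shape[1])
    with pytest.raises(TrainingError, match="0/1"):
        train_classifier(m, X, y + 1)
    with pytest.raises(TrainingError, match="single class"):
        train_classifier(m, X, np.zeros_like(y))


def test_predict_shape_check(rng):
    m = build_mlpnn(MLPConfig(hidden_units=(4, 4, 4)), n_features=10)
    with pytest.raises(ValueError, match="shape"):
        predict_proba(m, rng.normal(size=(3, 11)).astype(np.float32))


def _small_ae():
    enc = TCNConfig(dilations=(1, 2), n_filters=6, learning_rate=1e-3)
    dec = TCNConfig(dilations=(1, 2), n_filters=6, learning_rate=1e-3,
                    use_batch_norm=False)
    return AEConfig(encoder=enc, decoder=dec, latent_filters=4,
                    ae_epochs=3, ae_learning_rate=1e-3,
                    classifier_hidden_units=(8, 4),
                    classifier_epochs=5, batch_size=16)


def test_autoencoder_trains_and_freezes_encoder(rng):
    ae = build_tcn_ae(_small_ae(), n_channels=4, seq_len=50, seed=0)
    x = rng.normal(size=(24, 4, 50))
    state = fit_channel_state(x)
    X = standardize_by_channel(x, state)
    train_autoencoder(ae, X, seed=0)
    assert len(ae.ae_history) == 3
    assert np.isfinite(ae.ae_history).all()

    # classifier training leaves the encoder bit-identical
    before = ae.encoder.state()
    y = rng.integers(0, 2, 24).astype(float)
    y[:2] = [0, 1]  # both classes present
    train_latent_classifier(ae, X, y, seed=0)
    after = ae.encoder.state()
    assert all(np.array_equal(a, b) for a, b in zip(before, after))

    mse = reconstruction_mse(ae, X)
    assert np.isfinite(mse) and mse >= 0
    # zero-epoch training is a no-op
    snap = ae.encoder.state()
    train_autoencoder(ae, X, seed=0, epochs=0)
    assert all(np.array_equal(a, b) for a, b in zip(snap, ae.encoder.state()))


def test_ae_predict_proba(rng):
    ae = build_tcn_ae(_small_ae(), n_channels=4, seq_len=50, seed=0)
    X = rng.normal(size=(6, 50, 4)).astype(np.float32)
    p = predict_proba(ae, X)
    assert p.shape == (6,)
    assert ((p >= 0) & (p <= 1)).all()
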