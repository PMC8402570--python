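"""The three classifier families for vigilance-decrement detection.

* **MLPNN** -- three ReLU hidden layers with dropout over 320 log-power
  spectral features, sigmoid output; Adam on binary cross-entropy for 300
  epochs.
* **TCN** -- a dilated causal convolution stack over the raw 250 x 64
  epoch, a kernel-1 Conv1D with 4 filters (ReLU), then a sigmoid output
  unit; Adam on binary cross-entropy for 100 epochs.
* **TCN-AE** -- a TCN autoencoder trained for signal reconstruction (MSE,
  50 epochs) on channel-standardized epochs; the frozen encoder's pooled
  50 x L latent is flattened into a two-hidden-layer classifier.

The receptive field of a TCN stack follows the product rule
``kernel_size * n_blocks * final_dilation``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from vigil.config import AEConfig, MLPConfig, TCNConfig
from vigil import nn
from vigil.nn import (
    AvgPool1D,
    Conv1D,
    Dense,
    Dropout,
    Flatten,
    NearestUpsample1D,
    ReLU,
    ResidualUnit,
    Sequential,
)


#: weight-init SD of the autoencoder's standalone kernel-1 convolutions.
#: With a linear (activation-free) decoder, variance-preserving He init
#: compounds through the residual stack and the first reconstruction loss
#: explodes; a small-normal init keeps the initial loss near the signal
#: variance so MSE training converges.
_AE_CONV_STD = 0.05


def receptive_field(k: int, b: int, d_final: int) -> int:
    """Receptive field (in timesteps) of a TCN with kernel size ``k``,
    ``b`` stacked blocks and final dilation ``d_final``."""
    if k < 1 or b < 1 or d_final < 1:
        raise ValueError("kernel size, block count and dilation must be >= 1")
    return k * b * d_final


@dataclass
class Model:
    """A (possibly trained) classifier with its network and history."""

    kind: str
    config: object
    net: Sequential
    input_shape: tuple[int, ...]
    history: list[float] = field(default_factory=list)
    #: spectral FeatureTransform for MLPNN models, set at training time
    transform: object | None = None
    extras: dict = field(default_factory=dict)

    @property
    def n_parameters(self) -> int:
        return self.net.n_parameters


def _tcn_blocks(cfg: TCNConfig, c_in: int, rng, activation: bool = True):
    """``cfg.n_blocks`` repetitions of the full dilation stack."""
    layers: list[nn.Layer] = []
    c = c_in
    for _ in range(cfg.n_blocks):
        for d in cfg.dilations:
            layers.append(
                ResidualUnit(
                    c, cfg.n_filters, cfg.kernel_size, d, rng,
                    causal=cfg.causal,
                    dropout=cfg.dropout_rate,
                    recurrent_dropout=cfg.effective_recurrent_dropout,
                    use_batch_norm=cfg.use_batch_norm,
                    activation=activation,
                )
            )
            c = cfg.n_filters
    return layers


def build_mlpnn(cfg: MLPConfig, n_features: int = 320, seed: int = 0) -> Model:
    """Untrained spectral MLPNN. Parameter count is the closed-form
    sum over the four dense layers (160,751 at the defaults)."""
    rng = np.random.default_rng([seed, 10])
    layers: list[nn.Layer] = []
    c = n_features
    for h in cfg.hidden_units:
        layers += [Dense(c, h, rng), ReLU(), Dropout(cfg.dropout_rate, rng)]
        c = h
    layers.append(Dense(c, 1, rng))
    return Model("mlpnn", cfg, Sequential(layers), (n_features,))


def build_tcn(
    cfg: TCNConfig,
    n_channels: int = 64,
    seq_len: int = 250,
    out_conv_filters: int = 4,
    seed: int = 0,
    rf_cap: int | None = None,
) -> Model:
    """Untrained raw-sequence TCN classifier.

    The model's receptive field (kernel * blocks * final dilation) is
    recorded in ``extras["receptive_field"]``; a warning is emitted when it
    exceeds ``rf_cap`` (a receptive field differing from the input length
    is tolerated by design).
    """
    rng = np.random.default_rng([seed, 11])
    rf = receptive_field(cfg.kernel_size, cfg.n_blocks, cfg.d_final)
    if rf_cap is not None and rf > rf_cap:
        warnings.warn(
            f"receptive field {rf} exceeds cap {rf_cap}", UserWarning,
            stacklevel=2,
        )
    layers = _tcn_blocks(cfg, n_channels, rng)
    layers += [
        Conv1D(cfg.n_filters, out_conv_filters, 1, rng),
        ReLU(),
        Flatten(),
        Dense(seq_len * out_conv_filters, 1, rng),
    ]
    m = Model("tcn", cfg, Sequential(layers), (seq_len, n_channels))
    m.extras["receptive_field"] = rf
    return m


@dataclass
class TCNAutoencoder:
    """Encoder, decoder and latent-feature classifier of the TCN-AE."""

    config: AEConfig
    encoder: Sequential
    decoder: Sequential
    classifier: Sequential
    input_shape: tuple[int, int]
    latent_shape: tuple[int, int]
    ae_history: list[float] = field(default_factory=list)
    clf_history: list[float] = field(default_factory=list)
    channel_state: object | None = None

    def encode(self, x: np.ndarray) -> np.ndarray:
        return self.encoder.forward(x.astype(nn.DTYPE), training=False)

    def reconstruct(self, x: np.ndarray) -> np.ndarray:
        return self.decoder.forward(self.encode(x), training=False)


def build_tcn_ae(
    cfg: AEConfig, n_channels: int = 64, seq_len: int = 250, seed: int = 0
) -> TCNAutoencoder:
    """Untrained TCN autoencoder plus classifier.

    Encoder: TCN (ReLU) -> Conv1D(k=1, L filters, ReLU) -> average pool
    of 5, latent (seq_len/5, L). Decoder: nearest-neighbor upsample x5 ->
    TCN -> Conv1D back to ``n_channels``, with no activation functions.
    Classifier: flatten -> two ReLU+dropout hidden layers -> sigmoid.
    """
    if seq_len % cfg.pool_size:
        raise ValueError(
            f"sequence length {seq_len} not divisible by pool size "
            f"{cfg.pool_size}"
        )
    rng = np.random.default_rng([seed, 12])
    L = cfg.latent_filters
    enc = Sequential(
        _tcn_blocks(cfg.encoder, n_channels, rng, activation=True)
        + [
            Conv1D(cfg.encoder.n_filters, L, 1, rng, w_init_std=_AE_CONV_STD),
            ReLU(),
            AvgPool1D(cfg.pool_size),
        ]
    )
    dec = Sequential(
        [NearestUpsample1D(cfg.pool_size)]
        + _tcn_blocks(cfg.decoder, L, rng, activation=False)
        + [Conv1D(cfg.decoder.n_filters, n_channels, 1, rng,
                  w_init_std=_AE_CONV_STD)]
    )
    latent_len = seq_len // cfg.pool_size
    clf_layers: list[nn.Layer] = [Flatten()]
    c = latent_len * L
    for h in cfg.classifier_hidden_units:
        clf_layers += [
            Dense(c, h, rng), ReLU(),
            Dropout(cfg.classifier_dropout_rate, rng),
        ]
        c = h
    clf_layers.append(Dense(c, 1, rng))
    return TCNAutoencoder(
        config=cfg,
        encoder=enc,
        decoder=dec,
        classifier=Sequential(clf_layers),
        input_shape=(seq_len, n_channels),
        latent_shape=(latent_len, L),
    )


# ---------------------------------------------------------------------------
# channel standardization for raw-sequence models

@dataclass
class ChannelState:
    mean: np.ndarray  # (n_channels,)
    sd: np.ndarray


def fit_channel_state(x: np.ndarray) -> ChannelState:
    """Per-channel mean/SD over training epochs and time;
    ``x`` is (epochs, channels, samples)."""
    mean = x.mean(axis=(0, 2))
    sd = x.std(axis=(0, 2))
    sd = np.where(sd == 0, 1.0, sd)
    return ChannelState(mean, sd)


def standardize_by_channel(x: np.ndarray, state: ChannelState) -> np.ndarray:
    """(epochs, channels, samples) -> channel-standardized
    (epochs, samples, channels) float32 sequence tensor."""
    z = (x - state.mean[None, :, None]) / state.sd[None, :, None]
    return np.transpose(z, (0, 2, 1)).astype(nn.DTYPE)


# ---------------------------------------------------------------------------
# training and inference

class TrainingError(ValueError):
    pass


def _check_labels(y: np.ndarray) -> np.ndarray:
    y = np.asarray(y, dtype=np.float64).ravel()
    if not np.isin(y, [0.0, 1.0]).all():
        raise TrainingError("labels must be 0/1")
    if len(np.unique(y)) < 2:
        raise TrainingError("training labels contain a single class")
    return y


def _minibatches(n: int, batch_size: int, rng: np.random.Generator):
    order = rng.permutation(n)
    for s in range(0, n, batch_size):
        yield order[s : s + batch_size]


def train_classifier(
    model: Model,
    X: np.ndarray,
    y: np.ndarray,
    seed: int = 0,
    epochs: int | None = None,
) -> Model:
    """Adam / binary cross-entropy training for a fixed epoch count
    (no early stopping). Reproducible for a fixed seed on one device."""
    y = _check_labels(y)
    cfg = model.config
    epochs = cfg.epochs if epochs is None else epochs
    X = np.asarray(X, dtype=nn.DTYPE)
    rng = np.random.default_rng([seed, 20])
    opt = nn.Adam(model.net, lr=cfg.learning_rate)
    for _ in range(epochs):
        losses = []
        for idx in _minibatches(len(X), cfg.batch_size, rng):
            z = model.net.forward(X[idx], training=True)
            loss, dz = nn.bce_with_logits(z.ravel(), y[idx])
            model.net.backward(dz.reshape(z.shape))
            opt.step()
            losses.append(loss)
        model.history.append(float(np.mean(losses)))
    return model


def train_latent_classifier(
    ae: TCNAutoencoder, X: np.ndarray, y: np.ndarray, seed: int = 0,
    epochs: int | None = None,
) -> TCNAutoencoder:
    """Encode ``X`` with the frozen encoder, then train the latent-feature
    classifier. Encoder parameters are untouched (bit-identical)."""
    y = _check_labels(y)
    cfg = ae.config
    epochs = cfg.classifier_epochs if epochs is None else epochs
    latents = _batched_forward(ae.encoder, np.asarray(X, dtype=nn.DTYPE))
    rng = np.random.default_rng([seed, 21])
    opt = nn.Adam(ae.classifier, lr=cfg.classifier_learning_rate)
    for _ in range(epochs):
        losses = []
        for idx in _minibatches(len(latents), cfg.batch_size, rng):
            z = ae.classifier.forward(latents[idx], training=True)
            loss, dz = nn.bce_with_logits(z.ravel(), y[idx])
            ae.classifier.backward(dz.reshape(z.shape))
            opt.step()
            losses.append(loss)
        ae.clf_history.append(float(np.mean(losses)))
    return ae


def train_autoencoder(
    ae: TCNAutoencoder,
    X: np.ndarray,
    seed: int = 0,
    epochs: int | None = None,
) -> TCNAutoencoder:
    """Train encoder + decoder for reconstruction by minimizing MSE.

    ``X`` must be channel-standardized (batch, time, channels); with
    ``epochs=0`` no parameter is updated.
    """
    cfg = ae.config
    epochs = cfg.ae_epochs if epochs is None else epochs
    X = np.asarray(X, dtype=nn.DTYPE)
    rng = np.random.default_rng([seed, 22])
    stack = Sequential([ae.encoder, ae.decoder])
    opt = nn.Adam(stack, lr=cfg.ae_learning_rate)
    for _ in range(epochs):
        losses = []
        for idx in _minibatches(len(X), cfg.batch_size, rng):
            xb = X[idx]
            r = stack.forward(xb, training=True)
            loss, dr = nn.mse_loss(r, xb)
            if not np.isfinite(loss):
                raise TrainingError("non-finite reconstruction loss")
            stack.backward(dr)
            opt.step()
            losses.append(loss)
        ae.ae_history.append(float(np.mean(losses)))
    return ae


def reconstruction_mse(ae: TCNAutoencoder, X: np.ndarray) -> float:
    """Mean squared reconstruction error on held-out standardized epochs."""
    X = np.asarray(X, dtype=nn.DTYPE)
    r = _batched_forward(Sequential([ae.encoder, ae.decoder]), X)
    return float(np.mean((r.astype(np.float64) - X) ** 2))


def _batched_forward(net: Sequential, X: np.ndarray,
                     batch_size: int = 256) -> np.ndarray:
    outs = [
        net.forward(X[s : s + batch_size], training=False)
        for s in range(0, len(X), batch_size)
    ]
    return np.concatenate(outs, axis=0)


def predict_proba(model, X: np.ndarray) -> np.ndarray:
    """Class-1 (decrement) probabilities, deterministic at inference
    (dropout off, batch norm on running statistics)."""
    X = np.asarray(X, dtype=nn.DTYPE)
    if X.shape[1:] != tuple(model.input_shape):
        raise ValueError(
            f"input shape {X.shape[1:]} != expected {tuple(model.input_shape)}"
        )
    if isinstance(model, TCNAutoencoder):
        latents = _batched_forward(model.encoder, X)
        z = _batched_forward(model.classifier, latents)
    else:
        z = _batched_forward(model.net, X)
    return nn.sigmoid(z.ravel())


def predict_label(model, X: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Hard labels: 1 iff predicted probability >= threshold."""
    return (predict_proba(model, X) >= threshold).astype(int)
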