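import numpy as np
import pytest

from vigil import nn


def _num_grad(f, x, eps=1e-2):
    g = np.zeros_like(x, dtype=np.float64)
    it = np.nditer(x, flags=["multi_index"])
    for _ in it:
        i = it.multi_index
        orig = x[i]
        x[i] = orig + eps
        fp = f()
        x[i] = orig - eps
        fm = f()
        x[i] = orig
        g[i] = (fp - fm) / (2 * eps)
    return g


def _check_param_grads(layer, x, atol=1e-2, rtol=2e-2):
    """Analytic parameter and input gradients match central differences
    for loss = sum(forward(x)). Tolerances account for float32 forward
    arithmetic under the finite-difference step."""

    def loss():
        return float(layer.forward(x.astype(nn.DTYPE), training=True).sum())

    y = layer.forward(x.astype(nn.DTYPE), training=True)
    dx = layer.backward(np.ones_like(y))
    for name, p in layer.params.items():
        num = _num_grad(lambda: loss(), p)
        assert np.allclose(layer.grads[name], num, atol=atol, rtol=rtol), name
    num_dx = _num_grad(lambda: loss(), x)
    assert np.allclose(dx, num_dx, atol=atol, rtol=rtol)


def test_dense_gradients(rng):
    layer = nn.Dense(4, 3, rng)
    _check_param_grads(layer, rng.normal(size=(5, 4)).astype(nn.DTYPE))


def test_conv1d_gradients(rng):
    layer = nn.Conv1D(3, 2, 2, rng, dilation=2, causal=True)
    _check_param_grads(layer, rng.normal(size=(2, 8, 3)).astype(nn.DTYPE))


def test_conv1d_noncausal_gradients(rng):
    layer = nn.Conv1D(2, 2, 3, rng, dilation=1, causal=False)
    _check_param_grads(layer, rng.normal(size=(2, 7, 2)).astype(nn.DTYPE))


def test_batchnorm_gradients(rng):
    layer = nn.BatchNorm1D(3)
    _check_param_grads(layer, rng.normal(size=(4, 5, 3)).astype(nn.DTYPE))


def test_conv1d_causality(rng):
    """With causal padding, output at time t ignores inputs after t."""
    layer = nn.Conv1D(2, 2, 2, rng, dilation=4, causal=True)
    x = rng.normal(size=(1, 20, 2)).astype(nn.DTYPE)
    y0 = layer.forward(x)
    x2 = x.copy()
    x2[0, 10:] += 5.0  # perturb the future
    y1 = layer.forward(x2)
    assert np.allclose(y0[0, :10], y1[0, :10])
    assert not np.allclose(y0[0, 10:], y1[0, 10:])


def test_residual_unit_causality_and_shapes(rng):
    unit = nn.ResidualUnit(3, 5, 2, 4, rng, use_batch_norm=False)
    x = rng.normal(size=(2, 16, 3)).astype(nn.DTYPE)
    y = unit.forward(x)
    assert y.shape == (2, 16, 5)
    x2 = x.copy()
    x2[:, 12:] += 3.0
    y2 = unit.forward(x2)
    assert np.allclose(y[:, :12], y2[:, :12])


def test_residual_unit_gradients(rng):
    unit = nn.ResidualUnit(2, 3, 2, 1, rng, use_batch_norm=False)
    _check_param_grads(unit, rng.normal(size=(2, 6, 2)).astype(nn.DTYPE))


def test_dropout_inference_identity(rng):
    layer = nn.Dropout(0.5, rng)
    x = rng.normal(size=(4, 6)).astype(nn.DTYPE)
    assert np.array_equal(layer.forward(x, training=False), x)
    y = layer.forward(x, training=True)
    assert not np.array_equal(y, x)
    # inverted dropout preserves the expected scale
    assert set(np.unique(np.round(y / np.where(x == 0, 1, x), 4))) <= {0.0, 2.0}


def test_channel_dropout_drops_whole_channels(rng):
    layer = nn.Dropout(0.5, rng, channel_wise=True)
    x = np.ones((3, 10, 8), dtype=nn.DTYPE)
    y = layer.forward(x, training=True)
    # each (sample, channel) is either fully kept or fully dropped
    per_channel = y.reshape(3, 10, 8)
    assert ((per_channel == per_channel[:, :1, :]).all(axis=1)).all()


def test_dropout_rate_validation(rng):
    with pytest.raises(ValueError):
        nn.Dropout(1.0, rng)


def test_batchnorm_inference_batch_invariant(rng):
    layer = nn.BatchNorm1D(3)
    for _ in range(5):
        layer.forward(rng.normal(size=(8, 4, 3)).astype(nn.DTYPE),
                      training=True)
    x = rng.normal(size=(6, 4, 3)).astype(nn.DTYPE)
    full = layer.forward(x, training=False)
    parts = np.concatenate(
        [layer.forward(x[:2], training=False),
         layer.forward(x[2:], training=False)]
    )
    assert np.allclose(full, parts)


def test_avgpool_and_upsample_roundtrip(rng):
    pool = nn.AvgPool1D(5)
    up = nn.NearestUpsample1D(5)
    x = rng.normal(size=(2, 250, 4)).astype(nn.DTYPE)
    z = pool.forward(x)
    assert z.shape == (2, 50, 4)
    assert np.allclose(z[:, 0], x[:, :5].mean(axis=1))
    y = up.forward(z)
    assert y.shape == x.shape
    with pytest.raises(ValueError):
        pool.forward(x[:, :249])
    # pool and upsample gradients are exact adjoints scaled consistently
    dy = rng.normal(size=z.shape).astype(nn.DTYPE)
    assert np.allclose(pool.backward(dy)[:, :5].sum(axis=1), dy[:, 0])


def test_adam_reduces_loss_on_toy_problem(rng):
    X = rng.normal(size=(64, 3)).astype(nn.DTYPE)
    y = (X[:, 0] - 0.5 * X[:, 1] > 0).astype(np.float64)
    net = nn.Sequential([nn.Dense(3, 8, rng), nn.ReLU(), nn.Dense(8, 1, rng)])
    opt = nn.Adam(net, lr=0.05)
    first = None
    for _ in range(150):
        z = net.forward(X, training=True)
        loss, dz = nn.bce_with_logits(z.ravel(), y)
        if first is None:
            first = loss
        net.backward(dz.reshape(z.shape))
        opt.step()
    assert loss < 0.1 < first
    pred = (nn.sigmoid(net.forward(X).ravel()) >= 0.5).astype(float)
    assert (pred == y).mean() == 1.0


def test_sigmoid_stable_and_correct():
    z = np.array([-800.0, -5.0, 0.0, 5.0, 800.0])
    s = nn.sigmoid(z)
    assert np.isfinite(s).all()
    assert s[2] == 0.5
    assert s[0] == pytest.approx(0.0, abs=1e-12)
    assert s[4] == pytest.approx(1.0)
    assert np.allclose(s[1], 1 / (1 + np.exp(5.0)))


def test_losses():
    z = np.array([0.0, 2.0, -2.0])
    y = np.array([1.0, 1.0, 0.0])
    loss, dz = nn.bce_with_logits(z, y)
    expected = np.mean(
        [-np.log(0.5), -np.log(nn.sigmoid(np.array([2.0]))[0]),
         -np.log(1 - nn.sigmoid(np.array([-2.0]))[0])]
    )
    assert loss == pytest.approx(expected)
    r = np.array([[1.0, 2.0]])
    x = np.array([[0.0, 0.0]])
    mse, dr = nn.mse_loss(r, x)
    assert mse == pytest.approx(2.5)
    assert np.allclose(dr, [[1.0, 2.0]])


def test_sequential_parameter_accounting(rng):
    net = nn.Sequential(
        [nn.Dense(4, 3, rng), nn.ReLU(),
         nn.ResidualUnit(3, 3, 2, 1, rng, use_batch_norm=False)]
    )
    manual = 4 * 3 + 3 + 2 * (2 * 3 * 3 + 3)
    assert net.n_parameters == manual
    state = net.state()
    assert sum(p.size for p in state) == manual
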