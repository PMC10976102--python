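"""Layer-level oracles and whole-model contracts for the classifier."""

import numpy as np
import pytest

from fcgru.network import (
    AttentionParams,
    CGRUModel,
    ConvBlockConfig,
    GRUParams,
    HyperParams,
    ModelVariant,
    attention_forward,
    build_model,
    conv_block_forward,
    cross_entropy_loss,
    gru_step,
    softmax,
)


# --------------------------------------------------------------- conv block


def test_all_negative_input_maps_to_zero(rng):
    """Negative map through a non-negative kernel: ReLU annihilates and
    pooling/dropout preserve zero."""
    x = -np.abs(rng.normal(size=(2, 1, 6, 6))) - 0.1
    w = np.abs(rng.normal(size=(3, 1, 3, 3)))
    out = conv_block_forward(x, ConvBlockConfig(filters=3), training=True,
                             rng=rng, weights=w, bias=np.zeros(3))
    np.testing.assert_array_equal(out, 0.0)


def test_identity_kernel_passthrough():
    x = np.abs(np.random.default_rng(0).normal(size=(1, 1, 5, 5)))
    w = np.zeros((1, 1, 3, 3))
    w[0, 0, 1, 1] = 1.0  # single 1 at the kernel centre
    cfg = ConvBlockConfig(filters=1, pool=(1, 1), dropout_rate=0.0)
    out = conv_block_forward(x, cfg, weights=w, bias=np.zeros(1))
    np.testing.assert_allclose(out, x, atol=1e-12)


def test_convolution_matches_sliding_window_oracle(rng):
    """Same-padded conv vs a brute-force dot product over the padded map."""
    x = rng.normal(size=(1, 1, 6, 6))
    w = rng.normal(size=(2, 1, 3, 3))
    b = rng.normal(size=2)
    cfg = ConvBlockConfig(filters=2, pool=(1, 1), dropout_rate=0.0)
    out = conv_block_forward(x, cfg, weights=w, bias=b)
    xp = np.pad(x[0, 0], 1)
    for o in range(2):
        for i in range(6):
            for j in range(6):
                patch = xp[i : i + 3, j : j + 3]
                expected = max(np.sum(patch * w[o, 0]) + b[o], 0.0)  # + ReLU
                assert out[0, o, i, j] == pytest.approx(expected, abs=1e-10)


def test_dropout_identity_when_not_training(rng):
    x = np.abs(rng.normal(size=(1, 1, 4, 4)))
    cfg = ConvBlockConfig(filters=1, pool=(1, 1), dropout_rate=0.9)
    w = np.zeros((1, 1, 3, 3))
    w[0, 0, 1, 1] = 1.0
    out = conv_block_forward(x, cfg, training=False, weights=w, bias=np.zeros(1))
    np.testing.assert_allclose(out, x, atol=1e-12)


def test_oversized_kernel_is_build_error():
    hyper = HyperParams(conv_blocks=(ConvBlockConfig(kernel=(9, 9)),
                                     ConvBlockConfig()))
    with pytest.raises(ValueError, match="kernel"):
        build_model((2, 4, 9), ModelVariant(), hyper)


# --------------------------------------------------------------- GRU


def _random_gru_params(rng, d_in=2, units=3, scale=0.5):
    z = lambda shape: rng.normal(scale=scale, size=shape)
    return GRUParams(
        Wz=z((d_in, units)), Uz=z((units, units)), bz=z(units),
        Wr=z((d_in, units)), Ur=z((units, units)), br=z(units),
        Wh=z((d_in, units)), Uh=z((units, units)), bh=z(units),
    )


def _gru_oracle(xt, h_prev, p):
    """Independent scalar-loop evaluation of the gate equations."""
    units = p.bz.shape[0]
    sig = lambda v: 1.0 / (1.0 + np.exp(-v))
    h = np.empty(units)
    z = np.empty(units)
    r = np.empty(units)
    hc = np.empty(units)
    for k in range(units):
        z[k] = sig(xt @ p.Wz[:, k] + h_prev @ p.Uz[:, k] + p.bz[k])
        r[k] = sig(xt @ p.Wr[:, k] + h_prev @ p.Ur[:, k] + p.br[k])
    for k in range(units):
        hc[k] = np.tanh(xt @ p.Wh[:, k] + r[k] * (h_prev @ p.Uh[:, k]) + p.bh[k])
        h[k] = (1.0 - z[k]) * h_prev[k] + z[k] * hc[k]
    return h


def test_gru_step_matches_handrolled_oracle_on_100_draws(rng):
    for _ in range(100):
        p = _random_gru_params(rng)
        xt = rng.normal(size=2)
        h_prev = rng.normal(size=3)
        np.testing.assert_allclose(
            gru_step(xt, h_prev, p)[0], _gru_oracle(xt, h_prev, p), atol=1e-6
        )


def test_gru_update_gate_saturation_limits(rng):
    p = _random_gru_params(rng)
    xt, h_prev = rng.normal(size=2), rng.normal(size=3)
    p.Wz[:] = 0.0
    p.Uz[:] = 0.0
    p.bz[:] = 50.0  # z ~ 1: new state equals the candidate
    sig = lambda v: 1.0 / (1.0 + np.exp(-v))
    r = sig(xt @ p.Wr + h_prev @ p.Ur + p.br)
    hc = np.tanh(xt @ p.Wh + r * (h_prev @ p.Uh) + p.bh)
    np.testing.assert_allclose(gru_step(xt, h_prev, p)[0], hc, atol=1e-9)
    p.bz[:] = -50.0  # z ~ 0: previous state is carried through
    np.testing.assert_allclose(gru_step(xt, h_prev, p)[0], h_prev, atol=1e-9)


def test_gru_step_shape_mismatch(rng):
    p = _random_gru_params(rng)
    with pytest.raises(ValueError, match="shape mismatch"):
        gru_step(np.zeros(5), np.zeros(3), p)


# --------------------------------------------------------------- attention


def test_attention_zero_weights_uniform(rng):
    v = rng.normal(size=7)
    out = attention_forward(v, AttentionParams(W=np.zeros((7, 7))))
    np.testing.assert_allclose(out, v / 7.0, atol=1e-12)


def test_attention_weights_form_probability_vector(rng):
    for _ in range(20):
        d = rng.integers(1, 10)
        v = rng.normal(size=d) * 5
        W = rng.normal(size=(d, d))
        out = attention_forward(v, AttentionParams(W=W))
        assert out.shape == (d,)
        w = softmax(W @ v)
        assert np.all(w >= 0) and np.isclose(w.sum(), 1.0)
        np.testing.assert_allclose(out, w * v, atol=1e-12)


def test_attention_hand_worked_three_dim_case():
    """Explicit evaluation: a = W v, w = exp(a)/sum, out = w * v."""
    v = np.array([1.0, -2.0, 0.5])
    W = np.array([[0.2, 0.0, 1.0], [-0.5, 0.3, 0.0], [0.1, 0.1, 0.1]])
    a = np.array(
        [0.2 * 1 + 0 * -2 + 1 * 0.5, -0.5 * 1 + 0.3 * -2 + 0 * 0.5,
         0.1 * 1 + 0.1 * -2 + 0.1 * 0.5]
    )
    e = np.exp(a - a.max())
    expected = (e / e.sum()) * v
    np.testing.assert_allclose(
        attention_forward(v, AttentionParams(W=W)), expected, atol=1e-6
    )


def test_attention_requires_square_weight():
    with pytest.raises(ValueError, match="square"):
        AttentionParams(W=np.zeros((3, 4)))


# --------------------------------------------------------------- model assembly


def _nodrop_hyper():
    return HyperParams(
        conv_blocks=(ConvBlockConfig(filters=2, dropout_rate=0.0),
                     ConvBlockConfig(filters=3, dropout_rate=0.0)),
        gru_units=(4, 3),
        gru_dropout=0.0,
        dense_units=5,
        head_dropout=0.0,
    )


def test_full_variant_outputs_probabilities(rng):
    model = build_model((5, 8, 13), "full", HyperParams.small(), seed=0)
    x = rng.normal(size=(3, 5, 8, 13))
    p = model.predict_proba(x)
    assert p.shape == (3, 2)
    np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-6)
    assert np.all(p >= 0)


def test_attention_adds_exactly_d_squared_parameters():
    base = build_model((3, 6, 11), ModelVariant(True, True, True, False),
                       _nodrop_hyper(), seed=0)
    with_att = build_model((3, 6, 11), ModelVariant(True, True, True, True),
                           _nodrop_hyper(), seed=0)
    d = _nodrop_hyper().gru_units[1]
    assert with_att.n_parameters - base.n_parameters == d * d


def test_eval_forward_is_deterministic(rng):
    model = build_model((3, 6, 11), "full", _nodrop_hyper(), seed=1)
    x = rng.normal(size=(2, 3, 6, 11))
    np.testing.assert_array_equal(model.forward(x), model.forward(x))


def test_variant_input_shape_validation():
    with pytest.raises(ValueError, match="feature width"):
        build_model((3, 6, 11), "model3")  # model3 expects band-only width 5
    with pytest.raises(ValueError, match="at least one"):
        ModelVariant(use_cnn=False, use_gru=False)
    with pytest.raises(ValueError, match="unknown variant"):
        ModelVariant.named("model9")


@pytest.mark.parametrize("name,width", [
    ("model1", 5), ("model2", 5), ("model3", 5),
    ("model4", 5), ("model5", 11), ("full", 11),
])
def test_all_named_variants_build_and_run(rng, name, width):
    model = build_model((3, 6, width), name, _nodrop_hyper(), seed=0)
    out = model.forward(rng.normal(size=(2, 3, 6, width)))
    assert out.shape == (2, 2)


def test_disabling_attention_reproduces_plv_cgru_variant(rng):
    """Same seed: model5 and full-without-attention give identical logits."""
    a = build_model((3, 6, 11), ModelVariant.named("model5"), _nodrop_hyper(), seed=3)
    b = build_model((3, 6, 11), ModelVariant(True, True, True, False),
                    _nodrop_hyper(), seed=3)
    x = rng.normal(size=(2, 3, 6, 11))
    np.testing.assert_array_equal(a.forward(x), b.forward(x))


def test_weight_checkpoint_roundtrip(tmp_path, rng):
    a = build_model((3, 6, 11), "full", _nodrop_hyper(), seed=0)
    b = build_model((3, 6, 11), "full", _nodrop_hyper(), seed=99)
    x = rng.normal(size=(2, 3, 6, 11))
    assert not np.allclose(a.forward(x), b.forward(x))
    ckpt = tmp_path / "model.npz"
    a.save_weights(ckpt)
    b.load_weights(ckpt)
    np.testing.assert_array_equal(a.forward(x), b.forward(x))
    wrong = build_model((3, 6, 11), "model5", _nodrop_hyper(), seed=0)
    with pytest.raises(ValueError, match="checkpoint"):
        wrong.load_weights(ckpt)


# --------------------------------------------------------------- gradients


def _loss_of(model: CGRUModel, x, y) -> float:
    logits = model.forward(x, training=True)
    return cross_entropy_loss(logits, y)[0]


@pytest.mark.parametrize("variant", ["full", "model2", "model1"])
def test_numerical_vs_analytic_gradient(rng, variant):
    """Central-difference check of backprop through the whole model."""
    width = 9 if variant in ("full", "model5") else 5
    model = build_model((2, 4, width), variant, _nodrop_hyper(), seed=0)
    x = rng.normal(size=(3, 2, 4, width))
    y = np.array([0, 1, 1])
    logits = model.forward(x, training=True)
    loss, dlogits = cross_entropy_loss(logits, y)
    model.zero_grad()
    model.backward(dlogits)
    eps = 1e-5
    check_rng = np.random.default_rng(7)
    for p, g in zip(model.params, model.grads):
        flat_idx = check_rng.choice(p.size, size=min(5, p.size), replace=False)
        for fi in flat_idx:
            idx = np.unravel_index(fi, p.shape)
            orig = p[idx]
            p[idx] = orig + eps
            lp = _loss_of(model, x, y)
            p[idx] = orig - eps
            lm = _loss_of(model, x, y)
            p[idx] = orig
            num = (lp - lm) / (2 * eps)
            assert num == pytest.approx(g[idx], abs=1e-4, rel=1e-4), (
                f"param shape {p.shape} idx {idx}"
            )
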