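"""Convolutional-recurrent classifier with attention, in pure NumPy.

The architecture stacks three stages over a ``(steps, NC, NC+5)`` fused
feature tensor:

1. **frequency-spatial stage** — two conv/ReLU/max-pool/dropout blocks
   applied time-distributed (weights shared across the step axis), each
   step's map flattened to a feature vector;
2. **temporal stage** — two gated-recurrent-unit layers, each followed
   by dropout; the second returns only its final hidden state:

       z_t = sigmoid(W_z x_t + U_z h_{t-1} + b_z)          (update gate)
       r_t = sigmoid(W_r x_t + U_r h_{t-1} + b_r)          (reset gate)
       hc_t = tanh(W_h x_t + r_t * (U_h h_{t-1}) + b_h)    (candidate)
       h_t = (1 - z_t) * h_{t-1} + z_t * hc_t

3. **attention classification head** — for a flat feature vector v of
   length d, ``out = softmax(W v) * v`` with a learnable square W
   (weights form a probability vector over the d features), then a ReLU
   dense layer, dropout and a 2-unit softmax.

Ablation variants toggle each stage: a CNN-only model convolves the
step-stacked tensor directly, a GRU-only model consumes flattened steps,
and the connectivity (PLV) columns can be dropped from the input.

Forward and backward passes are hand-written; every layer exposes
``params``/``grads`` pairs consumed by the Adam optimizer in
:mod:`fcgru.evaluation`.  All initialization and dropout randomness is
driven by a single per-model seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ConvBlockConfig",
    "GRUParams",
    "AttentionParams",
    "ModelVariant",
    "HyperParams",
    "CGRUModel",
    "conv_block_forward",
    "gru_step",
    "attention_forward",
    "build_model",
    "softmax",
]


def softmax(a: np.ndarray, axis: int = -1) -> np.ndarray:
    a = a - a.max(axis=axis, keepdims=True)
    e = np.exp(a)
    return e / e.sum(axis=axis, keepdims=True)


def _sigmoid(a: np.ndarray) -> np.ndarray:
    out = np.empty_like(a)
    pos = a >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-a[pos]))
    ea = np.exp(a[~pos])
    out[~pos] = ea / (1.0 + ea)
    return out


def _glorot(rng: np.random.Generator, shape: tuple[int, ...]) -> np.ndarray:
    fan_in = int(np.prod(shape[1:])) if len(shape) > 1 else shape[0]
    fan_out = shape[0]
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


# --------------------------------------------------------------------------
# configuration dataclasses


@dataclass
class ConvBlockConfig:
    """One conv -> ReLU -> max-pool -> dropout block."""

    filters: int = 32
    kernel: tuple[int, int] = (3, 3)
    pool: tuple[int, int] = (2, 2)
    dropout_rate: float = 0.25

    def __post_init__(self) -> None:
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError(f"dropout_rate must be in [0, 1), got {self.dropout_rate}")


@dataclass
class GRUParams:
    """Weight matrices and biases of one GRU layer (see module docstring)."""

    Wz: np.ndarray
    Uz: np.ndarray
    bz: np.ndarray
    Wr: np.ndarray
    Ur: np.ndarray
    br: np.ndarray
    Wh: np.ndarray
    Uh: np.ndarray
    bh: np.ndarray

    @property
    def hidden_size(self) -> int:
        return self.bz.shape[0]

    @classmethod
    def init(cls, rng: np.random.Generator, d_in: int, units: int) -> "GRUParams":
        return cls(
            Wz=_glorot(rng, (d_in, units)),
            Uz=_glorot(rng, (units, units)),
            bz=np.zeros(units),
            Wr=_glorot(rng, (d_in, units)),
            Ur=_glorot(rng, (units, units)),
            br=np.zeros(units),
            Wh=_glorot(rng, (d_in, units)),
            Uh=_glorot(rng, (units, units)),
            bh=np.zeros(units),
        )


@dataclass
class AttentionParams:
    """Square weight matrix of the attention layer; output keeps dimension d."""

    W: np.ndarray

    def __post_init__(self) -> None:
        if self.W.ndim != 2 or self.W.shape[0] != self.W.shape[1]:
            raise ValueError(f"attention W must be square, got {self.W.shape}")


@dataclass(frozen=True)
class ModelVariant:
    """Ablation switches.

    Named variants mirror the ablation grid: ``model1`` CNN only,
    ``model2`` GRU only, ``model3`` CNN+GRU, ``model4`` CNN+GRU+attention,
    ``model5`` PLV+CNN+GRU, ``full`` everything.
    """

    use_plv: bool = True
    use_cnn: bool = True
    use_gru: bool = True
    use_attention: bool = True

    def __post_init__(self) -> None:
        if not (self.use_cnn or self.use_gru):
            raise ValueError("at least one of use_cnn/use_gru must be enabled")

    NAMED = {
        "model1": (False, True, False, False),
        "model2": (False, False, True, False),
        "model3": (False, True, True, False),
        "model4": (False, True, True, True),
        "model5": (True, True, True, False),
        "full": (True, True, True, True),
    }

    @classmethod
    def named(cls, name: str) -> "ModelVariant":
        try:
            return cls(*cls.NAMED[name])
        except KeyError:
            raise ValueError(
                f"unknown variant {name!r}; choose from {sorted(cls.NAMED)}"
            ) from None


@dataclass
class HyperParams:
    """Layer sizes; the architecture fixes layer *counts*, sizes are tunable."""

    conv_blocks: tuple[ConvBlockConfig, ConvBlockConfig] = (
        ConvBlockConfig(filters=32),
        ConvBlockConfig(filters=64),
    )
    gru_units: tuple[int, int] = (64, 32)
    gru_dropout: float = 0.3
    dense_units: int = 128
    head_dropout: float = 0.5

    @classmethod
    def small(cls) -> "HyperParams":
        """Desk-scale sizes for fast experiments on few-channel data."""
        return cls(
            conv_blocks=(ConvBlockConfig(filters=8), ConvBlockConfig(filters=16)),
            gru_units=(32, 16),
            dense_units=32,
        )


# --------------------------------------------------------------------------
# layers


class Layer:
    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    @property
    def params(self) -> list[np.ndarray]:
        return []

    @property
    def grads(self) -> list[np.ndarray]:
        return []


class Conv2D(Layer):
    """Same-padded stride-1 2-D convolution over (B, C, H, W) maps."""

    def __init__(self, rng: np.random.Generator, c_in: int, cfg: ConvBlockConfig):
        kh, kw = cfg.kernel
        self.kh, self.kw = kh, kw
        self.W = _glorot(rng, (cfg.filters, c_in, kh, kw))
        self.b = np.zeros(cfg.filters)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        kh, kw = self.kh, self.kw
        ph, pw = kh // 2, kw // 2
        xp = np.pad(x, ((0, 0), (0, 0), (ph, kh - 1 - ph), (pw, kw - 1 - pw)))
        self._xp = xp
        B, _, H, W = x.shape
        out = np.tile(self.b[None, :, None, None], (B, 1, H, W))
        for i in range(kh):
            for j in range(kw):
                out += np.einsum(
                    "bchw,oc->bohw", xp[:, :, i : i + H, j : j + W], self.W[:, :, i, j]
                )
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        kh, kw = self.kh, self.kw
        ph, pw = kh // 2, kw // 2
        xp = self._xp
        B, _, H, W = grad.shape
        dxp = np.zeros_like(xp)
        self.db += grad.sum(axis=(0, 2, 3))
        for i in range(kh):
            for j in range(kw):
                self.dW[:, :, i, j] += np.einsum(
                    "bohw,bchw->oc", grad, xp[:, :, i : i + H, j : j + W]
                )
                dxp[:, :, i : i + H, j : j + W] += np.einsum(
                    "bohw,oc->bchw", grad, self.W[:, :, i, j]
                )
        return dxp[:, :, ph : ph + H, pw : pw + W]

    @property
    def params(self) -> list[np.ndarray]:
        return [self.W, self.b]

    @property
    def grads(self) -> list[np.ndarray]:
        return [self.dW, self.db]


class ReLU(Layer):
    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad * self._mask


class MaxPool2D(Layer):
    """Non-overlapping max pooling; trailing rows/cols that do not fill a
    pool window are discarded (and receive zero gradient)."""

    def __init__(self, pool: tuple[int, int]):
        self.ph, self.pw = pool

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        ph, pw = self.ph, self.pw
        B, C, H, W = x.shape
        Ho, Wo = max(H // ph, 1), max(W // pw, 1)
        ph_eff = min(ph, H)
        pw_eff = min(pw, W)
        self._in_shape = x.shape
        self._eff = (ph_eff, pw_eff, Ho, Wo)
        xc = x[:, :, : Ho * ph_eff, : Wo * pw_eff]
        blocks = xc.reshape(B, C, Ho, ph_eff, Wo, pw_eff).transpose(0, 1, 2, 4, 3, 5)
        flat = blocks.reshape(B, C, Ho, Wo, ph_eff * pw_eff)
        self._argmax = flat.argmax(axis=-1)
        return flat.max(axis=-1)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        B, C, H, W = self._in_shape
        ph_eff, pw_eff, Ho, Wo = self._eff
        dflat = np.zeros((B, C, Ho, Wo, ph_eff * pw_eff))
        np.put_along_axis(dflat, self._argmax[..., None], grad[..., None], axis=-1)
        dblocks = dflat.reshape(B, C, Ho, Wo, ph_eff, pw_eff).transpose(0, 1, 2, 4, 3, 5)
        dx = np.zeros(self._in_shape)
        dx[:, :, : Ho * ph_eff, : Wo * pw_eff] = dblocks.reshape(
            B, C, Ho * ph_eff, Wo * pw_eff
        )
        return dx


class Dropout(Layer):
    """Inverted dropout; identity when not training or rate is 0."""

    def __init__(self, rate: float, rng: np.random.Generator):
        if not 0.0 <= rate < 1.0:
            raise ValueError(f"dropout rate must be in [0, 1), got {rate}")
        self.rate = rate
        self.rng = rng

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return x * self._mask

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad if self._mask is None else grad * self._mask


class Flatten(Layer):
    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad.reshape(self._shape)


class ExpandChannel(Layer):
    """(B, H, W) -> (B, 1, H, W): single-channel image view for the CNN."""

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        return x[:, None, :, :]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad[:, 0, :, :]


class TimeDistributed(Layer):
    """Apply inner layers to each step of a (B, T, ...) tensor with shared
    weights by folding the step axis into the batch."""

    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        B, T = x.shape[:2]
        self._bt = (B, T)
        h = x.reshape(B * T, *x.shape[2:])
        for layer in self.layers:
            h = layer.forward(h, training)
        return h.reshape(B, T, *h.shape[1:])

    def backward(self, grad: np.ndarray) -> np.ndarray:
        B, T = self._bt
        g = grad.reshape(B * T, *grad.shape[2:])
        for layer in reversed(self.layers):
            g = layer.backward(g)
        return g.reshape(B, T, *g.shape[1:])

    @property
    def params(self) -> list[np.ndarray]:
        return [p for layer in self.layers for p in layer.params]

    @property
    def grads(self) -> list[np.ndarray]:
        return [g for layer in self.layers for g in layer.grads]


def gru_step(xt: np.ndarray, h_prev: np.ndarray, params: GRUParams) -> np.ndarray:
    """One GRU update for a batch (or single) input vector.

    Implements the gate equations in the module docstring; with the
    update gate saturated at 1 the new state equals the candidate, at 0
    the previous state is carried through unchanged.
    """
    xt = np.atleast_2d(np.asarray(xt, dtype=np.float64))
    h_prev = np.atleast_2d(np.asarray(h_prev, dtype=np.float64))
    if xt.shape[0] != h_prev.shape[0]:
        raise ValueError(f"batch mismatch: x {xt.shape} vs h {h_prev.shape}")
    if xt.shape[1] != params.Wz.shape[0] or h_prev.shape[1] != params.hidden_size:
        raise ValueError(
            f"shape mismatch: x {xt.shape}, h {h_prev.shape}, "
            f"Wz {params.Wz.shape}, hidden {params.hidden_size}"
        )
    z = _sigmoid(xt @ params.Wz + h_prev @ params.Uz + params.bz)
    r = _sigmoid(xt @ params.Wr + h_prev @ params.Ur + params.br)
    hc = np.tanh(xt @ params.Wh + r * (h_prev @ params.Uh) + params.bh)
    return (1.0 - z) * h_prev + z * hc


class GRU(Layer):
    """GRU layer over (B, T, d_in); optionally returns the full sequence."""

    def __init__(
        self,
        rng: np.random.Generator,
        d_in: int,
        units: int,
        return_sequences: bool,
    ):
        self.p = GRUParams.init(rng, d_in, units)
        self.units = units
        self.return_sequences = return_sequences
        self.g = GRUParams(
            **{k: np.zeros_like(v) for k, v in vars(self.p).items()}
        )

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        B, T, _ = x.shape
        p = self.p
        h = np.zeros((B, self.units))
        self._x = x
        self._cache = []
        hs = np.empty((B, T, self.units))
        for t in range(T):
            xt = x[:, t, :]
            z = _sigmoid(xt @ p.Wz + h @ p.Uz + p.bz)
            r = _sigmoid(xt @ p.Wr + h @ p.Ur + p.br)
            uh = h @ p.Uh
            hc = np.tanh(xt @ p.Wh + r * uh + p.bh)
            h_new = (1.0 - z) * h + z * hc
            self._cache.append((h, z, r, uh, hc))
            h = h_new
            hs[:, t, :] = h
        self._hs = hs
        return hs if self.return_sequences else h

    def backward(self, grad: np.ndarray) -> np.ndarray:
        x, p, g = self._x, self.p, self.g
        B, T, _ = x.shape
        dx = np.zeros_like(x)
        dh = np.zeros((B, self.units))
        for t in reversed(range(T)):
            if self.return_sequences:
                dh = dh + grad[:, t, :]
            elif t == T - 1:
                dh = dh + grad
            h_prev, z, r, uh, hc = self._cache[t]
            xt = x[:, t, :]
            dz = dh * (hc - h_prev)
            dhc = dh * z
            dh_prev = dh * (1.0 - z)
            da_h = dhc * (1.0 - hc * hc)
            g.Wh += xt.T @ da_h
            g.bh += da_h.sum(axis=0)
            dr = da_h * uh
            duh = da_h * r
            g.Uh += h_prev.T @ duh
            dh_prev += duh @ p.Uh.T
            da_r = dr * r * (1.0 - r)
            g.Wr += xt.T @ da_r
            g.Ur += h_prev.T @ da_r
            g.br += da_r.sum(axis=0)
            dh_prev += da_r @ p.Ur.T
            da_z = dz * z * (1.0 - z)
            g.Wz += xt.T @ da_z
            g.Uz += h_prev.T @ da_z
            g.bz += da_z.sum(axis=0)
            dh_prev += da_z @ p.Uz.T
            dx[:, t, :] = da_z @ p.Wz.T + da_r @ p.Wr.T + da_h @ p.Wh.T
            dh = dh_prev
        return dx

    @property
    def params(self) -> list[np.ndarray]:
        return [getattr(self.p, k) for k in vars(self.p)]

    @property
    def grads(self) -> list[np.ndarray]:
        return [getattr(self.g, k) for k in vars(self.g)]


def attention_forward(v: np.ndarray, params: AttentionParams) -> np.ndarray:
    """Attention re-weighting of a flat feature vector (or batch of them).

    ``out = softmax(W v) * v``: the softmax over the d components of W v
    yields non-negative weights summing to 1, applied elementwise, so
    the output keeps dimension d.  With W = 0 the weights are uniform
    and the output is v / d.
    """
    v = np.asarray(v, dtype=np.float64)
    single = v.ndim == 1
    vb = np.atleast_2d(v)
    w = softmax(vb @ params.W.T, axis=1)
    out = w * vb
    return out[0] if single else out


class Attention(Layer):
    def __init__(self, rng: np.random.Generator, d: int):
        self.W = _glorot(rng, (d, d))
        self.dW = np.zeros_like(self.W)

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        self._x = x
        self._w = softmax(x @ self.W.T, axis=1)
        return self._w * x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        x, w = self._x, self._w
        dw = grad * x
        dx = grad * w
        da = w * (dw - (dw * w).sum(axis=1, keepdims=True))
        self.dW += da.T @ x
        dx += da @ self.W
        return dx

    @property
    def params(self) -> list[np.ndarray]:
        return [self.W]

    @property
    def grads(self) -> list[np.ndarray]:
        return [self.dW]


class Dense(Layer):
    def __init__(self, rng: np.random.Generator, d_in: int, d_out: int):
        self.W = _glorot(rng, (d_in, d_out))
        self.b = np.zeros(d_out)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        self._x = x
        return x @ self.W + self.b

    def backward(self, grad: np.ndarray) -> np.ndarray:
        self.dW += self._x.T @ grad
        self.db += grad.sum(axis=0)
        return grad @ self.W.T

    @property
    def params(self) -> list[np.ndarray]:
        return [self.W, self.b]

    @property
    def grads(self) -> list[np.ndarray]:
        return [self.dW, self.db]


def conv_block_forward(
    feature_map: np.ndarray,
    cfg: ConvBlockConfig,
    training: bool = False,
    rng: np.random.Generator | None = None,
    weights: np.ndarray | None = None,
    bias: np.ndarray | None = None,
) -> np.ndarray:
    """Standalone conv -> ReLU -> max-pool -> dropout block on (B,C,H,W).

    Dropout is identity when ``training`` is False.  If ``weights``/
    ``bias`` are omitted they are Glorot-initialized from ``rng``.
    """
    rng = rng if rng is not None else np.random.default_rng(0)
    conv = Conv2D(rng, feature_map.shape[1], cfg)
    if weights is not None:
        conv.W = np.asarray(weights, dtype=np.float64)
    if bias is not None:
        conv.b = np.asarray(bias, dtype=np.float64)
    h = conv.forward(np.asarray(feature_map, dtype=np.float64), training)
    h = ReLU().forward(h, training)
    h = MaxPool2D(cfg.pool).forward(h, training)
    return Dropout(cfg.dropout_rate, rng).forward(h, training)


# --------------------------------------------------------------------------
# full model


class CGRUModel:
    """The assembled classifier; see :func:`build_model`."""

    def __init__(
        self,
        layers: list[Layer],
        input_shape: tuple[int, ...],
        variant: ModelVariant,
        hyper: HyperParams,
        seed: int,
    ):
        self.layers = layers
        self.input_shape = input_shape
        self.variant = variant
        self.hyper = hyper
        self.seed = seed

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        """Logits for a (B, steps, NC, F) batch."""
        h = np.asarray(x, dtype=np.float64)
        for layer in self.layers:
            h = layer.forward(h, training)
        return h

    def backward(self, dlogits: np.ndarray) -> None:
        g = dlogits
        for layer in reversed(self.layers):
            g = layer.backward(g)

    def zero_grad(self) -> None:
        for g in self.grads:
            g[...] = 0.0

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return softmax(self.forward(x, training=False), axis=1)

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.forward(x, training=False).argmax(axis=1)

    @property
    def params(self) -> list[np.ndarray]:
        return [p for layer in self.layers for p in layer.params]

    @property
    def grads(self) -> list[np.ndarray]:
        return [g for layer in self.layers for g in layer.grads]

    @property
    def n_parameters(self) -> int:
        return sum(p.size for p in self.params)

    def architecture(self) -> dict:
        """JSON-serializable architecture echo for audit sidecars."""
        return {
            "input_shape": list(self.input_shape),
            "variant": vars(self.variant),
            "layers": [type(layer).__name__ for layer in self.layers],
            "n_parameters": self.n_parameters,
            "seed": self.seed,
        }

    def save_weights(self, path) -> None:
        """Checkpoint all parameters to a single ``.npz`` file."""
        np.savez(path, **{f"p{i}": p for i, p in enumerate(self.params)})

    def load_weights(self, path) -> None:
        """Restore parameters saved by :meth:`save_weights` into an
        identically built model."""
        with np.load(path) as data:
            params = self.params
            if len(data.files) != len(params):
                raise ValueError(
                    f"checkpoint has {len(data.files)} arrays, model has {len(params)}"
                )
            for i, p in enumerate(params):
                saved = data[f"p{i}"]
                if saved.shape != p.shape:
                    raise ValueError(
                        f"checkpoint param {i} shape {saved.shape} != model {p.shape}"
                    )
                p[...] = saved


def _conv_stack(
    rng: np.random.Generator, c_in: int, h: int, w: int, hyper: HyperParams
) -> tuple[list[Layer], int]:
    """Two conv blocks; returns layers and the flattened output size.

    Convolutions are same-padded, so deep blocks tolerate small maps,
    but the first block's kernel must fit the incoming map.
    """
    first = hyper.conv_blocks[0]
    if h < first.kernel[0] or w < first.kernel[1]:
        raise ValueError(
            f"kernel {first.kernel} larger than incoming {h}x{w} feature map"
        )
    layers: list[Layer] = []
    for cfg in hyper.conv_blocks:
        layers += [
            Conv2D(rng, c_in, cfg),
            ReLU(),
            MaxPool2D(cfg.pool),
            Dropout(cfg.dropout_rate, rng),
        ]
        c_in = cfg.filters
        h = max(h // cfg.pool[0], 1)
        w = max(w // cfg.pool[1], 1)
    return layers, c_in * h * w


def build_model(
    input_shape: tuple[int, int, int],
    variant: ModelVariant | str = ModelVariant(),
    hyper: HyperParams | None = None,
    seed: int = 0,
) -> CGRUModel:
    """Assemble a classifier for ``input_shape = (steps, NC, F)``.

    F is NC+5 with connectivity columns, 5 without (``use_plv`` controls
    only which features the caller supplies; here it is validated against
    the shape).  Variant wiring:

    * CNN+GRU: time-distributed conv stack -> per-step flatten ->
      GRU -> dropout -> GRU (final state) -> dropout -> [attention] ->
      dense+ReLU -> dropout -> 2-unit softmax logits;
    * CNN only: the step axis becomes the conv input channels;
    * GRU only: each step is flattened to a vector before the GRU stack.
    """
    if isinstance(variant, str):
        variant = ModelVariant.named(variant)
    hyper = hyper if hyper is not None else HyperParams()
    steps, nc, f = input_shape
    expected_f = nc + 5 if variant.use_plv else 5
    if f != expected_f:
        raise ValueError(
            f"variant expects feature width {expected_f} (use_plv={variant.use_plv}), "
            f"input_shape has {f}"
        )
    if steps < 1:
        raise ValueError("need at least one step")
    rng = np.random.default_rng(seed)
    layers: list[Layer] = []
    if variant.use_cnn and variant.use_gru:
        conv_layers, feat = _conv_stack(rng, 1, nc, f, hyper)
        layers.append(TimeDistributed([ExpandChannel()] + conv_layers + [Flatten()]))
        layers.append(GRU(rng, feat, hyper.gru_units[0], return_sequences=True))
        layers.append(Dropout(hyper.gru_dropout, rng))
        layers.append(GRU(rng, hyper.gru_units[0], hyper.gru_units[1], return_sequences=False))
        layers.append(Dropout(hyper.gru_dropout, rng))
        d = hyper.gru_units[1]
    elif variant.use_cnn:
        conv_layers, feat = _conv_stack(rng, steps, nc, f, hyper)

        class _DropStep(Layer):
            """(B, T, H, W) -> (B, C=T, H, W) view for the CNN-only variant."""

            def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
                return x

            def backward(self, grad: np.ndarray) -> np.ndarray:
                return grad

        layers += [_DropStep()] + conv_layers + [Flatten()]
        d = feat
    else:  # GRU only

        class _FlattenSteps(Layer):
            def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
                self._shape = x.shape
                return x.reshape(x.shape[0], x.shape[1], -1)

            def backward(self, grad: np.ndarray) -> np.ndarray:
                return grad.reshape(self._shape)

        layers.append(_FlattenSteps())
        layers.append(GRU(rng, nc * f, hyper.gru_units[0], return_sequences=True))
        layers.append(Dropout(hyper.gru_dropout, rng))
        layers.append(GRU(rng, hyper.gru_units[0], hyper.gru_units[1], return_sequences=False))
        layers.append(Dropout(hyper.gru_dropout, rng))
        d = hyper.gru_units[1]
    if variant.use_attention:
        layers.append(Attention(rng, d))
    layers.append(Dense(rng, d, hyper.dense_units))
    layers.append(ReLU())
    layers.append(Dropout(hyper.head_dropout, rng))
    layers.append(Dense(rng, hyper.dense_units, 2))
    return CGRUModel(layers, input_shape, variant, hyper, seed)


def cross_entropy_loss(
    logits: np.ndarray, labels: np.ndarray
) -> tuple[float, np.ndarray]:
    """Mean softmax cross-entropy and its gradient w.r.t. the logits."""
    B = logits.shape[0]
    p = softmax(logits, axis=1)
    eps = 1e-12
    loss = -np.log(p[np.arange(B), labels] + eps).mean()
    dlogits = p.copy()
    dlogits[np.arange(B), labels] -= 1.0
    return float(loss), dlogits / B
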