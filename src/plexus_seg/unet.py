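"""3-D U-Net variant and generalized Dice loss, implemented in NumPy.

The architecture: an encoder of three blocks, each block two layers of
(3x3x3 conv, stride 1, pad 1 -> batch norm -> ReLU), with 64 filters in the
first block doubling per block; 2x2x2 max pooling between encoder blocks; a
decoder mirroring the encoder with filters halving per block, upsampled by
2x2x2 transposed convolutions (stride 2, no padding); concatenation skip
connections; and a 1x1x1 convolution head with a hyperbolic tangent
activation, so voxel scores live in (-1, 1).  The third encoder block acts
as the bottleneck (two pooling stages: 64^3 -> 32^3 -> 16^3).

Convolutions are direct numba kernels (see ``_kernels``) with hand-written
backward passes; training uses Adam.  Everything is float32 and fully
seeded, so two builds from the same seed are bit-identical.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np

from ._kernels import conv3_forward, conv3_grad_input, conv3_grad_weight

__all__ = [
    "UNetConfig",
    "ModelHandle",
    "UNet3D",
    "Adam",
    "build_unet",
    "forward_patch",
    "generalized_dice_loss",
    "generalized_dice_loss_grad",
    "save_model",
    "load_model",
]


@dataclasses.dataclass
class UNetConfig:
    in_channels: int = 1
    out_channels: int = 1
    base_filters: int = 64
    n_encoder_blocks: int = 3
    layers_per_block: int = 2
    batchnorm: bool = True
    skip_connections: bool = True

    def __post_init__(self) -> None:
        if self.in_channels != 1 or self.out_channels != 1:
            raise ValueError("single-channel input/output only")
        if self.n_encoder_blocks < 2:
            raise ValueError("need at least two encoder blocks")
        if self.base_filters < 1 or self.layers_per_block < 1:
            raise ValueError("invalid filter/layer counts")

    @property
    def encoder_filters(self) -> tuple[int, ...]:
        return tuple(self.base_filters * 2**b for b in range(self.n_encoder_blocks))

    @property
    def decoder_filters(self) -> tuple[int, ...]:
        return tuple(reversed(self.encoder_filters[:-1]))

    @property
    def divisor(self) -> int:
        """Input patch edges must be divisible by this (number of poolings)."""
        return 2 ** (self.n_encoder_blocks - 1)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self))

    @classmethod
    def from_json(cls, s: str) -> "UNetConfig":
        return cls(**json.loads(s))


# ---------------------------------------------------------------------------
# Layers (forward caches what backward needs; backward frees it)


class Conv3x3:
    """Stride-1, pad-1 3x3x3 convolution (direct numba kernels)."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator):
        fan_in = cin * 27
        self.W = (rng.standard_normal((cout, cin, 3, 3, 3))
                  * np.sqrt(2.0 / fan_in)).astype(np.float32)
        self.b = np.zeros(cout, dtype=np.float32)
        self.cin, self.cout = cin, cout
        self.gW = self.gb = None
        self._x = None

    def forward(self, x: np.ndarray, cache: bool) -> np.ndarray:
        y = conv3_forward(x, self.W, self.b)
        if cache:
            self._x = x
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.gW = conv3_grad_weight(self._x, dy)
        self.gb = dy.sum(axis=(0, 2, 3, 4)).astype(np.float32)
        dx = conv3_grad_input(dy, self.W)
        self._x = None
        return dx


class Conv1x1:
    def __init__(self, cin: int, cout: int, rng: np.random.Generator):
        self.W = (rng.standard_normal((cout, cin)) * np.sqrt(1.0 / cin)).astype(np.float32)
        self.b = np.zeros(cout, dtype=np.float32)
        self.cin, self.cout = cin, cout
        self.gW = self.gb = None
        self._x = None

    def forward(self, x: np.ndarray, cache: bool) -> np.ndarray:
        B, C, D, H, W = x.shape
        xf = x.reshape(B, C, -1)
        y = self.W @ xf + self.b[:, None]
        if cache:
            self._x = xf
        return y.reshape(B, self.cout, D, H, W)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        B = dy.shape[0]
        dyf = dy.reshape(B, self.cout, -1)
        self.gW = np.einsum("bfn,bcn->fc", dyf, self._x, optimize=True).astype(np.float32)
        self.gb = dyf.sum(axis=(0, 2)).astype(np.float32)
        dx = (self.W.T @ dyf).reshape(B, self.cin, *dy.shape[2:])
        self._x = None
        return dx


class BatchNorm:
    def __init__(self, c: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = np.ones(c, dtype=np.float32)
        self.beta = np.zeros(c, dtype=np.float32)
        self.running_mean = np.zeros(c, dtype=np.float32)
        self.running_var = np.ones(c, dtype=np.float32)
        self.momentum, self.eps = momentum, eps
        self.ggamma = self.gbeta = None
        self._cache = None

    def forward(self, x: np.ndarray, train: bool, cache: bool) -> np.ndarray:
        axes = (0, 2, 3, 4)
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mean).astype(np.float32)
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * var).astype(np.float32)
        else:
            mean, var = self.running_mean, self.running_var
        ivar = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None, None]) * ivar[None, :, None, None, None]
        y = self.gamma[None, :, None, None, None] * xhat + self.beta[None, :, None, None, None]
        if cache:
            self._cache = (xhat, ivar)
        return y.astype(np.float32)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, ivar = self._cache
        axes = (0, 2, 3, 4)
        m = dy.shape[0] * dy.shape[2] * dy.shape[3] * dy.shape[4]
        self.ggamma = (dy * xhat).sum(axis=axes).astype(np.float32)
        self.gbeta = dy.sum(axis=axes).astype(np.float32)
        g = self.gamma[None, :, None, None, None]
        dxhat = dy * g
        dx = (dxhat - dxhat.mean(axis=axes, keepdims=True)
              - xhat * (dxhat * xhat).mean(axis=axes, keepdims=True))
        dx *= ivar[None, :, None, None, None]
        self._cache = None
        return dx.astype(np.float32)


class ReLU:
    def __init__(self):
        self._mask = None

    def forward(self, x: np.ndarray, cache: bool) -> np.ndarray:
        y = np.maximum(x, 0)
        if cache:
            self._mask = x > 0
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dx = dy * self._mask
        self._mask = None
        return dx


class MaxPool2:
    def __init__(self):
        self._cache = None

    def forward(self, x: np.ndarray, cache: bool) -> np.ndarray:
        B, C, D, H, W = x.shape
        if D % 2 or H % 2 or W % 2:
            raise ValueError(f"spatial dims must be even for 2^3 pooling, got {(D, H, W)}")
        xb = x.reshape(B, C, D // 2, 2, H // 2, 2, W // 2, 2)
        xb = xb.transpose(0, 1, 2, 4, 6, 3, 5, 7).reshape(B, C, D // 2, H // 2, W // 2, 8)
        arg = xb.argmax(axis=-1)
        y = np.take_along_axis(xb, arg[..., None], axis=-1)[..., 0]
        if cache:
            self._cache = (arg, x.shape)
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        arg, (B, C, D, H, W) = self._cache
        blocks = np.zeros((B, C, D // 2, H // 2, W // 2, 8), dtype=dy.dtype)
        np.put_along_axis(blocks, arg[..., None], dy[..., None], axis=-1)
        dx = blocks.reshape(B, C, D // 2, H // 2, W // 2, 2, 2, 2)
        dx = dx.transpose(0, 1, 2, 5, 3, 6, 4, 7).reshape(B, C, D, H, W)
        self._cache = None
        return dx


class ConvTranspose2x2:
    """2x2x2 transposed convolution with stride 2 and no padding."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator):
        fan_in = cin
        self.W = (rng.standard_normal((cout * 8, cin)) * np.sqrt(2.0 / fan_in)).astype(np.float32)
        self.b = np.zeros(cout, dtype=np.float32)
        self.cin, self.cout = cin, cout
        self.gW = self.gb = None
        self._x = None

    def forward(self, x: np.ndarray, cache: bool) -> np.ndarray:
        B, C, D, H, W = x.shape
        xf = x.reshape(B, C, -1)
        y = (self.W @ xf).reshape(B, self.cout, 2, 2, 2, D, H, W)
        y = y.transpose(0, 1, 5, 2, 6, 3, 7, 4).reshape(B, self.cout, 2 * D, 2 * H, 2 * W)
        y = y + self.b[None, :, None, None, None]
        if cache:
            self._x = xf
        return np.ascontiguousarray(y)

    def _gather(self, dy: np.ndarray) -> np.ndarray:
        B, F, D2, H2, W2 = dy.shape
        d = dy.reshape(B, F, D2 // 2, 2, H2 // 2, 2, W2 // 2, 2)
        d = d.transpose(0, 1, 3, 5, 7, 2, 4, 6).reshape(B, F * 8, -1)
        return np.ascontiguousarray(d)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dyg = self._gather(dy)
        self.gW = np.einsum("bfn,bcn->fc", dyg, self._x, optimize=True).astype(np.float32)
        self.gb = dy.sum(axis=(0, 2, 3, 4)).astype(np.float32)
        B = dy.shape[0]
        D, H, W = dy.shape[2] // 2, dy.shape[3] // 2, dy.shape[4] // 2
        dx = (self.W.T @ dyg).reshape(B, self.cin, D, H, W)
        self._x = None
        return dx


class Tanh:
    def __init__(self):
        self._y = None

    def forward(self, x: np.ndarray, cache: bool) -> np.ndarray:
        y = np.tanh(x)
        if cache:
            self._y = y
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dx = dy * (1.0 - self._y**2)
        self._y = None
        return dx


class _ConvUnit:
    """conv -> (batch norm) -> ReLU."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator, batchnorm: bool):
        self.conv = Conv3x3(cin, cout, rng)
        self.bn = BatchNorm(cout) if batchnorm else None
        self.relu = ReLU()

    def forward(self, x, train, cache):
        x = self.conv.forward(x, cache)
        if self.bn is not None:
            x = self.bn.forward(x, train, cache)
        return self.relu.forward(x, cache)

    def backward(self, dy):
        dy = self.relu.backward(dy)
        if self.bn is not None:
            dy = self.bn.backward(dy)
        return self.conv.backward(dy)


class UNet3D:
    """The full network; ``state_dict``/``load_state_dict`` give serialization."""

    def __init__(self, config: UNetConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        enc_f = config.encoder_filters
        self.enc_blocks: list[list[_ConvUnit]] = []
        cin = config.in_channels
        for f in enc_f:
            block = []
            for layer in range(config.layers_per_block):
                block.append(_ConvUnit(cin if layer == 0 else f, f, rng, config.batchnorm))
            self.enc_blocks.append(block)
            cin = f
        self.pools = [MaxPool2() for _ in range(len(enc_f) - 1)]
        self.dec_ups: list[ConvTranspose2x2] = []
        self.dec_blocks: list[list[_ConvUnit]] = []
        cin = enc_f[-1]
        for f in config.decoder_filters:
            self.dec_ups.append(ConvTranspose2x2(cin, f, rng))
            block = []
            first_in = 2 * f if config.skip_connections else f
            for layer in range(config.layers_per_block):
                block.append(_ConvUnit(first_in if layer == 0 else f, f, rng, config.batchnorm))
            self.dec_blocks.append(block)
            cin = f
        self.head = Conv1x1(cin, config.out_channels, rng)
        self.tanh = Tanh()

    # -- parameter access ---------------------------------------------------

    def _modules(self):
        for b, block in enumerate(self.enc_blocks):
            for l, unit in enumerate(block):
                yield f"enc{b}.{l}.conv", unit.conv
                if unit.bn is not None:
                    yield f"enc{b}.{l}.bn", unit.bn
        for i, up in enumerate(self.dec_ups):
            yield f"dec{i}.up", up
        for i, block in enumerate(self.dec_blocks):
            for l, unit in enumerate(block):
                yield f"dec{i}.{l}.conv", unit.conv
                if unit.bn is not None:
                    yield f"dec{i}.{l}.bn", unit.bn
        yield "head", self.head

    _PARAM_FIELDS = {
        Conv3x3: ("W", "b"),
        Conv1x1: ("W", "b"),
        ConvTranspose2x2: ("W", "b"),
        BatchNorm: ("gamma", "beta", "running_mean", "running_var"),
    }
    _GRAD_FIELDS = {
        Conv3x3: (("W", "gW"), ("b", "gb")),
        Conv1x1: (("W", "gW"), ("b", "gb")),
        ConvTranspose2x2: (("W", "gW"), ("b", "gb")),
        BatchNorm: (("gamma", "ggamma"), ("beta", "gbeta")),
    }

    def state_dict(self) -> dict[str, np.ndarray]:
        out = {}
        for name, mod in self._modules():
            for field in self._PARAM_FIELDS[type(mod)]:
                out[f"{name}.{field}"] = getattr(mod, field).copy()
        return out

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for name, mod in self._modules():
            for field in self._PARAM_FIELDS[type(mod)]:
                key = f"{name}.{field}"
                arr = np.asarray(state[key], dtype=np.float32)
                if arr.shape != getattr(mod, field).shape:
                    raise ValueError(f"shape mismatch for {key}")
                setattr(mod, field, arr.copy())

    def trainable(self):
        """Yield (key, module, param_field, grad_field) for the optimizer."""
        for name, mod in self._modules():
            for pf, gf in self._GRAD_FIELDS[type(mod)]:
                yield f"{name}.{pf}", mod, pf, gf

    # -- forward / backward -------------------------------------------------

    def _check_input(self, x: np.ndarray) -> None:
        if x.ndim != 5:
            raise ValueError("expected a (batch, channel, D, H, W) array")
        for edge in x.shape[2:]:
            if edge % self.config.divisor:
                raise ValueError(
                    f"patch edge {edge} not divisible by {self.config.divisor} "
                    f"({self.config.n_encoder_blocks} encoder blocks)"
                )

    def forward(self, x: np.ndarray, train: bool = False, cache: bool | None = None) -> np.ndarray:
        self._check_input(x)
        cache = train if cache is None else cache
        x = np.ascontiguousarray(x, dtype=np.float32)
        skips = []
        for b, block in enumerate(self.enc_blocks):
            for unit in block:
                x = unit.forward(x, train, cache)
            if b < len(self.pools):
                skips.append(x)
                x = self.pools[b].forward(x, cache)
        for i, (up, block) in enumerate(zip(self.dec_ups, self.dec_blocks)):
            x = up.forward(x, cache)
            if self.config.skip_connections:
                x = np.concatenate([skips[-(i + 1)], x], axis=1)
            for unit in block:
                x = unit.forward(x, train, cache)
        y = self.head.forward(x, cache)
        return self.tanh.forward(y, cache)

    def backward(self, dy: np.ndarray) -> None:
        d = self.tanh.backward(dy)
        d = self.head.backward(d)
        skip_grads: dict[int, np.ndarray] = {}
        n_dec = len(self.dec_blocks)
        for i in reversed(range(n_dec)):
            for unit in reversed(self.dec_blocks[i]):
                d = unit.backward(d)
            if self.config.skip_connections:
                f = self.dec_ups[i].cout
                skip_grads[len(self.pools) - 1 - i] = d[:, :f]
                d = d[:, f:]
            d = self.dec_ups[i].backward(np.ascontiguousarray(d))
        for b in reversed(range(len(self.enc_blocks))):
            if b < len(self.pools):
                d = self.pools[b].backward(d)
                if b in skip_grads:
                    d = d + skip_grads.pop(b)
            for unit in reversed(self.enc_blocks[b]):
                d = unit.backward(d)


class Adam:
    """Adam with the standard bias-corrected moment estimates."""

    def __init__(self, net: UNet3D, lr: float = 1e-4,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.net, self.lr, self.betas, self.eps = net, lr, betas, eps
        self.t = 0
        self.m: dict[str, np.ndarray] = {}
        self.v: dict[str, np.ndarray] = {}

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.betas
        for key, mod, pf, gf in self.net.trainable():
            g = getattr(mod, gf)
            if g is None:
                continue
            p = getattr(mod, pf)
            m = self.m.setdefault(key, np.zeros_like(p))
            v = self.v.setdefault(key, np.zeros_like(p))
            m[...] = b1 * m + (1 - b1) * g
            v[...] = b2 * v + (1 - b2) * g * g
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            setattr(mod, pf, (p - self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(np.float32))


# ---------------------------------------------------------------------------
# Model handle + loss


@dataclasses.dataclass
class ModelHandle:
    """Opaque trained-network container: config, parameters, training history."""

    config: UNetConfig
    net: UNet3D
    history: list = dataclasses.field(default_factory=list)

    def forward_patch(self, patch: np.ndarray) -> np.ndarray:
        return forward_patch(self, patch)


def build_unet(config: UNetConfig, seed: int = 0) -> ModelHandle:
    """Build an untrained, seeded network."""
    return ModelHandle(config=config, net=UNet3D(config, seed=seed))


def forward_patch(model: ModelHandle, patch: np.ndarray) -> np.ndarray:
    """Run one patch through the network in evaluation mode."""
    patch = np.asarray(patch, dtype=np.float32)
    if patch.ndim != 3:
        raise ValueError(f"expected a 3-D patch, got shape {patch.shape}")
    y = model.net.forward(patch[None, None], train=False)
    return y[0, 0]


def generalized_dice_loss(scores: np.ndarray, truth: np.ndarray,
                          eps: float = 1e-6) -> float:
    """Two-class generalized Dice loss of tanh scores against a binary truth.

    Scores are mapped to foreground probabilities p = (score + 1)/2; class
    weights are the inverse squared reference volumes, w_l = 1/(sum_n r_ln + eps)^2.
    """
    loss, _ = generalized_dice_loss_grad(scores, truth, eps=eps, need_grad=False)
    return loss


def generalized_dice_loss_grad(
    scores: np.ndarray, truth: np.ndarray, eps: float = 1e-6, need_grad: bool = True
) -> tuple[float, np.ndarray | None]:
    scores = np.asarray(scores, dtype=np.float64)
    truth_arr = np.asarray(truth)
    if scores.shape != truth_arr.shape:
        raise ValueError("scores and truth must share shape")
    uniq = np.unique(truth_arr)
    if not np.all(np.isin(uniq, (0, 1))):
        raise ValueError("truth must be binary")
    r = truth_arr.astype(np.float64).ravel()
    p = (scores.ravel() + 1.0) / 2.0
    n = r.size
    rf = r.sum()
    wf = 1.0 / (rf + eps) ** 2
    wb = 1.0 / ((n - rf) + eps) ** 2
    inter = wf * (r * p).sum() + wb * ((1 - r) * (1 - p)).sum()
    denom = wf * (rf + p.sum()) + wb * ((n - rf) + (n - p.sum()))
    loss = 1.0 - 2.0 * inter / denom
    grad = None
    if need_grad:
        dinter = wf * r - wb * (1 - r)
        ddenom = wf - wb
        dp = -2.0 * (dinter * denom - inter * ddenom) / denom**2
        grad = (0.5 * dp).reshape(scores.shape).astype(np.float32)
    return float(loss), grad


# ---------------------------------------------------------------------------
# Serialization


def save_model(model: ModelHandle, path: str | Path) -> None:
    """Single-file checkpoint with the config JSON embedded."""
    state = model.net.state_dict()
    np.savez_compressed(
        path,
        __config__=np.frombuffer(model.config.to_json().encode(), dtype=np.uint8),
        __history__=np.asarray(model.history, dtype=np.float64).reshape(len(model.history), -1)
        if model.history else np.zeros((0, 2)),
        **state,
    )


def load_model(path: str | Path) -> ModelHandle:
    path = Path(path)
    if not path.exists() and path.with_name(path.name + ".npz").exists():
        path = path.with_name(path.name + ".npz")  # np.savez appends .npz
    with np.load(path) as z:
        config = UNetConfig.from_json(bytes(z["__config__"]).decode())
        history = [tuple(row) for row in z["__history__"]]
        state = {k: z[k] for k in z.files if not k.startswith("__")}
    model = build_unet(config, seed=0)
    model.net.load_state_dict(state)
    model.history = history
    return model
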