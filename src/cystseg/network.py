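"""Two-channel 2-D encoder-decoder segmentation network.

The architecture is a U-Net-style fully convolutional network operating on
256x256 (or any pool-divisible) two-channel inputs: the normalized MR slice
and the kidney mask. Each encoder block is 2-D convolution, dropout (0.1),
batch normalization, a second convolution, then 2x2 max pooling. Kernel
sizes shrink down the encoder (7x7 -> 5x5 -> 3x3) so the high-resolution
levels learn larger filters, and grow back up the decoder. Skip connections
are additive (ResNet-like): the encoder feature map is projected by a 1x1
convolution to the decoder's channel count and added after upsampling. The
head is a 1x1 convolution with a sigmoid, giving a per-pixel cyst
probability.

The whole network — convolution, batch norm, dropout, pooling, nearest
upsampling, the Adam optimizer — is implemented directly on numpy arrays
(forward and analytic backward passes), which keeps training fully
deterministic under a fixed seed on CPU. Convolutions use im2col + matmul in
float32.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "NetworkConfig",
    "SegmentationNetwork",
    "build_network",
    "predict_slices",
    "Adam",
    "save_checkpoint",
    "load_checkpoint",
]


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass
class NetworkConfig:
    """Architecture hyperparameters.

    ``kernel_schedule`` lists the per-level convolution kernel sizes down the
    encoder; the decoder uses the same schedule in reverse. ``base_filters``
    is the channel width at the highest resolution, doubling per level
    (bottleneck at ``base_filters * 2**len(schedule)``). ``input_shape`` must
    be divisible by ``pool_size ** len(kernel_schedule)``.
    """

    kernel_schedule: list[int] = field(default_factory=lambda: [7, 5, 3])
    dropout_rate: float = 0.1
    pool_size: tuple[int, int] = (2, 2)
    base_filters: int = 32
    input_shape: tuple[int, int] = (256, 256)
    in_channels: int = 2
    out_channels: int = 1

    def __post_init__(self):
        self.kernel_schedule = [int(k) for k in self.kernel_schedule]
        if any(k % 2 == 0 or k < 1 for k in self.kernel_schedule):
            raise ValueError(f"kernel sizes must be odd positive, got {self.kernel_schedule}")
        if tuple(self.pool_size) != (2, 2):
            raise ValueError("only 2x2 pooling is supported")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")
        self.input_shape = (int(self.input_shape[0]), int(self.input_shape[1]))
        div = 2 ** len(self.kernel_schedule)
        if self.input_shape[0] % div or self.input_shape[1] % div:
            raise ValueError(
                f"input_shape {self.input_shape} must be divisible by "
                f"{div} (pool 2x2 over {len(self.kernel_schedule)} levels)"
            )
        if self.in_channels != 2 or self.out_channels != 1:
            raise ValueError("the network is fixed at 2 input channels and 1 output channel")

    @property
    def n_levels(self) -> int:
        return len(self.kernel_schedule)

    def to_json(self) -> str:
        return json.dumps(
            {
                "kernel_schedule": self.kernel_schedule,
                "dropout_rate": self.dropout_rate,
                "pool_size": list(self.pool_size),
                "base_filters": self.base_filters,
                "input_shape": list(self.input_shape),
                "in_channels": self.in_channels,
                "out_channels": self.out_channels,
            }
        )

    @classmethod
    def from_json(cls, s: str) -> "NetworkConfig":
        d = json.loads(s)
        d["pool_size"] = tuple(d["pool_size"])
        d["input_shape"] = tuple(d["input_shape"])
        return cls(**d)


# ---------------------------------------------------------------------------
# layers (forward + analytic backward on float32 numpy arrays)
# ---------------------------------------------------------------------------


class Param:
    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = value.astype(np.float32)
        self.grad = np.zeros_like(self.value)


def _im2col(xp: np.ndarray, k: int) -> np.ndarray:
    """(N, C, Hp, Wp) padded input -> (N, C*k*k, H*W) columns.

    Built from k*k contiguous block copies (fast compared to a windowed
    gather) in channels-first order matching the flattened kernel layout.
    """
    N, C, Hp, Wp = xp.shape
    H, W = Hp - k + 1, Wp - k + 1
    cols = np.empty((N, C, k, k, H, W), dtype=np.float32)
    for i in range(k):
        for j in range(k):
            cols[:, :, i, j] = xp[:, :, i : i + H, j : j + W]
    return cols.reshape(N, C * k * k, H * W)


class Conv2D:
    """Same-padded 2-D convolution via im2col GEMMs (channels-first layout)."""

    def __init__(self, cin: int, cout: int, k: int, rng: np.random.Generator):
        self.cin, self.cout, self.k = cin, cout, k
        std = np.sqrt(2.0 / (cin * k * k))  # He initialization (ReLU follows)
        self.W = Param(rng.normal(0.0, std, size=(cout, cin * k * k)).astype(np.float32))
        self.b = Param(np.zeros(cout, dtype=np.float32))
        self._cache = None

    def params(self):
        return [self.W, self.b]

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        N, C, H, W_ = x.shape
        k, p = self.k, self.k // 2
        x = np.ascontiguousarray(x, dtype=np.float32)
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p))) if p else x
        cols = _im2col(xp, k)
        out = np.matmul(self.W.value, cols)  # (N, cout, H*W)
        out += self.b.value[:, None]
        if training:
            self._cache = (cols, (N, C, H, W_))
        return out.reshape(N, self.cout, H, W_)

    def backward(self, g: np.ndarray) -> np.ndarray:
        cols, (N, C, H, W_) = self._cache
        self._cache = None
        k, p = self.k, self.k // 2
        g = np.ascontiguousarray(g, dtype=np.float32)
        gm = g.reshape(N, self.cout, H * W_)
        self.W.grad += np.matmul(gm, cols.transpose(0, 2, 1)).sum(axis=0)
        self.b.grad += gm.sum(axis=(0, 2))
        # dX is the full correlation of the output gradient with the kernel
        # rotated by 180 degrees: one im2col GEMM instead of k*k scatters.
        gp = np.pad(g, ((0, 0), (0, 0), (p, p), (p, p))) if p else g
        gcols = _im2col(gp, k)  # (N, cout*k*k, H*W)
        Wrot = np.ascontiguousarray(
            self.W.value.reshape(self.cout, C, k, k)[:, :, ::-1, ::-1]
            .transpose(1, 0, 2, 3)
            .reshape(C, self.cout * k * k)
        )
        return np.matmul(Wrot, gcols).reshape(N, C, H, W_)


class BatchNorm2D:
    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Param(np.ones(channels, dtype=np.float32))
        self.beta = Param(np.zeros(channels, dtype=np.float32))
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)
        self.momentum, self.eps = momentum, eps
        self._cache = None

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        c = x.shape[1]
        if training:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        invstd = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean.reshape(1, c, 1, 1)) * invstd.reshape(1, c, 1, 1)
        if training:
            self._cache = (xhat, invstd)
        return self.gamma.value.reshape(1, c, 1, 1) * xhat + self.beta.value.reshape(1, c, 1, 1)

    def backward(self, g: np.ndarray) -> np.ndarray:
        xhat, invstd = self._cache
        self._cache = None
        N, c, H, W = g.shape
        m = N * H * W
        self.dgamma_dbeta(g, xhat)
        dxhat = g * self.gamma.value.reshape(1, c, 1, 1)
        s1 = dxhat.sum(axis=(0, 2, 3), keepdims=True)
        s2 = (dxhat * xhat).sum(axis=(0, 2, 3), keepdims=True)
        return (invstd.reshape(1, c, 1, 1) / m) * (m * dxhat - s1 - xhat * s2)

    def dgamma_dbeta(self, g, xhat):
        self.gamma.grad += (g * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += g.sum(axis=(0, 2, 3))

    def state(self):
        return {"running_mean": self.running_mean, "running_var": self.running_var}


class Dropout:
    def __init__(self, rate: float, rng: np.random.Generator):
        self.rate, self.rng = rate, rng
        self._mask = None

    def params(self):
        return []

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(np.float32) / keep
        return x * self._mask

    def backward(self, g: np.ndarray) -> np.ndarray:
        return g if self._mask is None else g * self._mask


class ReLU:
    def __init__(self):
        self._mask = None

    def params(self):
        return []

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, g: np.ndarray) -> np.ndarray:
        return g * self._mask


class MaxPool2x2:
    def __init__(self):
        self._cache = None

    def params(self):
        return []

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        N, C, H, W = x.shape
        xr = x.reshape(N, C, H // 2, 2, W // 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(
            N, C, H // 2, W // 2, 4
        )
        idx = xr.argmax(axis=-1)
        out = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]
        self._cache = (idx, (N, C, H, W))
        return out

    def backward(self, g: np.ndarray) -> np.ndarray:
        idx, (N, C, H, W) = self._cache
        self._cache = None
        dxr = np.zeros((N, C, H // 2, W // 2, 4), dtype=np.float32)
        np.put_along_axis(dxr, idx[..., None], g[..., None], axis=-1)
        return (
            dxr.reshape(N, C, H // 2, W // 2, 2, 2)
            .transpose(0, 1, 2, 4, 3, 5)
            .reshape(N, C, H, W)
        )


class UpsampleNearest2x:
    def params(self):
        return []

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        return np.repeat(np.repeat(x, 2, axis=2), 2, axis=3)

    def backward(self, g: np.ndarray) -> np.ndarray:
        N, C, H, W = g.shape
        return g.reshape(N, C, H // 2, 2, W // 2, 2).sum(axis=(3, 5))


class Sigmoid:
    def __init__(self):
        self._out = None

    def params(self):
        return []

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        out = np.empty_like(x)
        np.negative(x, out=out)
        np.exp(out, out=out)
        out += 1.0
        np.reciprocal(out, out=out)
        self._out = out
        return out

    def backward(self, g: np.ndarray) -> np.ndarray:
        return g * self._out * (1.0 - self._out)


# ---------------------------------------------------------------------------
# the network
# ---------------------------------------------------------------------------


class _Block:
    """conv -> relu -> dropout -> batchnorm -> conv -> relu."""

    def __init__(self, cin, cout, k, rate, rng):
        self.conv1 = Conv2D(cin, cout, k, rng)
        self.relu1 = ReLU()
        self.drop = Dropout(rate, rng)
        self.bn = BatchNorm2D(cout)
        self.conv2 = Conv2D(cout, cout, k, rng)
        self.relu2 = ReLU()
        self.seq = [self.conv1, self.relu1, self.drop, self.bn, self.conv2, self.relu2]

    def forward(self, x, training):
        for layer in self.seq:
            x = layer.forward(x, training)
        return x

    def backward(self, g):
        for layer in reversed(self.seq):
            g = layer.backward(g)
        return g

    def layers(self):
        return self.seq


class SegmentationNetwork:
    """Encoder-decoder with additive skips; maps (N,2,H,W) -> (N,H,W) in (0,1)."""

    def __init__(self, config: NetworkConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        rate = config.dropout_rate
        F = config.base_filters
        ks = config.kernel_schedule
        n = len(ks)
        widths = [F * 2**i for i in range(n)]

        self.enc_blocks: list[_Block] = []
        self.pools: list[MaxPool2x2] = []
        cin = config.in_channels
        for i in range(n):
            self.enc_blocks.append(_Block(cin, widths[i], ks[i], rate, rng))
            self.pools.append(MaxPool2x2())
            cin = widths[i]
        self.bottleneck = _Block(cin, F * 2**n, 3, rate, rng)

        self.ups: list[UpsampleNearest2x] = []
        self.dec_conv: list[Conv2D] = []
        self.dec_relu: list[ReLU] = []
        self.skip_proj: list[Conv2D] = []
        self.dec_blocks: list[_Block] = []
        cin = F * 2**n
        for i in reversed(range(n)):
            self.ups.append(UpsampleNearest2x())
            self.dec_conv.append(Conv2D(cin, widths[i], ks[i], rng))
            self.dec_relu.append(ReLU())
            self.skip_proj.append(Conv2D(widths[i], widths[i], 1, rng))
            self.dec_blocks.append(_Block(widths[i], widths[i], ks[i], rate, rng))
            cin = widths[i]
        self.head = Conv2D(F, config.out_channels, 1, rng)
        self.sigmoid = Sigmoid()

    # -- plumbing -----------------------------------------------------------

    def _all_layers(self):
        out = []
        for b in self.enc_blocks:
            out += b.layers()
        out += self.pools
        out += self.bottleneck.layers()
        out += self.ups + self.dec_conv + self.dec_relu + self.skip_proj
        for b in self.dec_blocks:
            out += b.layers()
        out += [self.head, self.sigmoid]
        return out

    def parameters(self) -> list[Param]:
        params = []
        for layer in self._all_layers():
            params += layer.params()
        return params

    def zero_grad(self):
        for p in self.parameters():
            p.grad[...] = 0.0

    # -- forward / backward -------------------------------------------------

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        """x: (N, 2, H, W) float32 -> per-pixel probabilities (N, H, W)."""
        x = np.ascontiguousarray(x, dtype=np.float32)
        if x.ndim != 4 or x.shape[1] != self.config.in_channels:
            raise ValueError(f"expected (N, 2, H, W) input, got shape {x.shape}")
        if tuple(x.shape[2:]) != tuple(self.config.input_shape):
            raise ValueError(
                f"input spatial shape {x.shape[2:]} does not match "
                f"configured {self.config.input_shape}"
            )
        skips = []
        for block, pool in zip(self.enc_blocks, self.pools):
            x = block.forward(x, training)
            skips.append(x)
            x = pool.forward(x, training)
        x = self.bottleneck.forward(x, training)
        n = self.config.n_levels
        for d in range(n):
            i = n - 1 - d  # encoder level this decoder stage mirrors
            x = self.ups[d].forward(x, training)
            x = self.dec_conv[d].forward(x, training)
            x = self.dec_relu[d].forward(x, training)
            x = x + self.skip_proj[d].forward(skips[i], training)
            x = self.dec_blocks[d].forward(x, training)
        x = self.head.forward(x, training)
        p = self.sigmoid.forward(x, training)
        return p[:, 0]

    def backward(self, dprob: np.ndarray) -> None:
        """Accumulate parameter gradients given dLoss/dprobability."""
        g = self.sigmoid.backward(dprob[:, None])
        g = self.head.backward(g)
        n = self.config.n_levels
        skip_grads: dict[int, np.ndarray] = {}
        for d in reversed(range(n)):
            i = n - 1 - d
            g = self.dec_blocks[d].backward(g)
            skip_grads[i] = self.skip_proj[d].backward(g)
            g = self.dec_relu[d].backward(g)
            g = self.dec_conv[d].backward(g)
            g = self.ups[d].backward(g)
        g = self.bottleneck.backward(g)
        for i in reversed(range(n)):
            g = self.pools[i].backward(g)
            g = g + skip_grads[i]
            g = self.enc_blocks[i].backward(g)

    # -- state --------------------------------------------------------------

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {}
        for idx, p in enumerate(self.parameters()):
            state[f"param_{idx:04d}"] = p.value
        bn_idx = 0
        for layer in self._all_layers():
            if isinstance(layer, BatchNorm2D):
                state[f"bn_{bn_idx:03d}_mean"] = layer.running_mean
                state[f"bn_{bn_idx:03d}_var"] = layer.running_var
                bn_idx += 1
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for idx, p in enumerate(self.parameters()):
            p.value[...] = state[f"param_{idx:04d}"]
        bn_idx = 0
        for layer in self._all_layers():
            if isinstance(layer, BatchNorm2D):
                layer.running_mean[...] = state[f"bn_{bn_idx:03d}_mean"]
                layer.running_var[...] = state[f"bn_{bn_idx:03d}_var"]
                bn_idx += 1

    def copy_state(self) -> dict[str, np.ndarray]:
        return copy.deepcopy(self.state_dict())


def build_network(config: NetworkConfig, seed: int = 0) -> SegmentationNetwork:
    """Construct a freshly initialized network (He init, seeded)."""
    return SegmentationNetwork(config, seed=seed)


# ---------------------------------------------------------------------------
# optimizer
# ---------------------------------------------------------------------------


class Adam:
    """Adam with the additive learning-rate decay lr_t = lr0 / (1 + decay * t)."""

    def __init__(self, params: list[Param], lr: float = 1e-3, decay: float = 1e-5,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-7):
        self.params = params
        self.lr, self.decay = lr, decay
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]

    def step(self):
        self.t += 1
        lr_t = self.lr / (1.0 + self.decay * self.t)
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m *= self.beta1
            m += (1.0 - self.beta1) * p.grad
            v *= self.beta2
            v += (1.0 - self.beta2) * p.grad**2
            p.value -= lr_t * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


# ---------------------------------------------------------------------------
# inference + checkpointing
# ---------------------------------------------------------------------------


def predict_slices(model: SegmentationNetwork, samples, threshold: float = 0.5,
                   batch_size: int = 8) -> list[np.ndarray]:
    """Binarize per-slice cyst probabilities at ``threshold``, input order kept."""
    if not samples:
        return []
    H, W = model.config.input_shape
    out = []
    for start in range(0, len(samples), batch_size):
        chunk = samples[start : start + batch_size]
        x = np.stack(
            [np.stack([s.input_image, s.input_kidney.astype(np.float32)]) for s in chunk]
        ).astype(np.float32)
        if x.shape[2:] != (H, W):
            raise ValueError(f"sample shape {x.shape[2:]} does not match model {H, W}")
        probs = model.forward(x, training=False)
        out.extend((probs[i] >= threshold).astype(np.uint8) for i in range(len(chunk)))
    return out


def save_checkpoint(model: SegmentationNetwork, path) -> None:
    """Weights to a single .npz; NetworkConfig to a JSON sidecar."""
    path = str(path)
    np.savez(path if path.endswith(".npz") else path + ".npz", **model.state_dict())
    base = path[: -len(".npz")] if path.endswith(".npz") else path
    with open(base + ".json", "w") as fh:
        fh.write(model.config.to_json())


def load_checkpoint(path) -> SegmentationNetwork:
    path = str(path)
    if not path.endswith(".npz"):
        path = path + ".npz"
    base = path[: -len(".npz")]
    with open(base + ".json") as fh:
        config = NetworkConfig.from_json(fh.read())
    model = SegmentationNetwork(config, seed=0)
    with np.load(path) as state:
        model.load_state_dict(dict(state))
    return model
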