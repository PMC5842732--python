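"""uResNet: u-shaped residual fully-convolutional network (numpy).

The architecture has an *analysis* (contracting) path of residual elements
(ResEle) separated by 2x2/stride-2 max-pooling, and a *synthesis*
(expanding) path of 2x2/stride-2 transposed convolutions whose outputs are
combined with the matching analysis scale by **summation** skip connections
(not concatenation), followed by one final 1x1 convolution into class
scores and a per-voxel softmax.  Under the default specification this gives
12 trainable layers -- 8 ResEle, 3 deconvolutions, 1 final convolution --
and roughly one million trainable parameters.

A ResEle computes ``ReLU(conv3x3(x)) + shortcut(x)`` where the shortcut is
the identity when the channel counts match and a trainable 1x1 linear
projection otherwise.  No batch normalization or dropout is used.  All
convolutions are same-padded so the in-plane shape is preserved, which is
what makes summation skips well-defined; the network is fully
convolutional and accepts any in-plane size divisible by 8 (three pooling
stages), so whole slices can be segmented in a single forward pass.

Layers implement explicit ``forward``/``backward`` passes (GEMM-based
convolutions via sliding windows); gradients are accumulated in
``layer.grads`` and consumed by the optimizer in :mod:`uresnet.engine`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


@dataclass
class NetworkSpec:
    """Architecture description of a uResNet instance."""

    in_channels: int = 1
    n_classes: int = 3
    channel_widths: tuple[int, ...] = (32, 64, 128, 192)
    res_per_scale: int = 2
    kernel_size: int = 3
    pool_size: int = 2
    pool_stride: int = 2
    deconv_kernel: int = 2
    deconv_stride: int = 2

    def __post_init__(self) -> None:
        self.channel_widths = tuple(int(c) for c in self.channel_widths)
        if len(self.channel_widths) != 4:
            raise ValueError("channel_widths must list exactly 4 scales")
        if any(b <= a for a, b in zip(self.channel_widths, self.channel_widths[1:])):
            raise ValueError("channel_widths must be strictly increasing")
        if self.in_channels < 1 or self.n_classes < 2:
            raise ValueError("need >=1 input channel and >=2 classes")

    def to_json(self) -> str:
        return json.dumps(
            {
                "in_channels": self.in_channels,
                "n_classes": self.n_classes,
                "channel_widths": list(self.channel_widths),
                "res_per_scale": self.res_per_scale,
            }
        )

    @classmethod
    def from_json(cls, s: str) -> "NetworkSpec":
        d = json.loads(s)
        return cls(
            in_channels=d["in_channels"],
            n_classes=d["n_classes"],
            channel_widths=tuple(d["channel_widths"]),
            res_per_scale=d["res_per_scale"],
        )


class ShapeError(ValueError):
    """Input spatial shape incompatible with the network's pooling depth."""


# ---------------------------------------------------------------------------
# layers
# ---------------------------------------------------------------------------


class Layer:
    """Minimal trainable-layer protocol: params/grads dicts + fwd/bwd."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def n_params(self) -> int:
        return sum(p.size for p in self.params.values())

    def zero_grad(self) -> None:
        for k, p in self.params.items():
            self.grads[k] = np.zeros_like(p)


def _glorot(rng: np.random.Generator, shape, fan_in: int, fan_out: int, dtype):
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(dtype)


class Conv2d(Layer):
    """Same-padded 2D convolution (square odd kernel) over (B, C, H, W)."""

    def __init__(self, c_in, c_out, k, rng, dtype=np.float32):
        super().__init__()
        self.c_in, self.c_out, self.k = c_in, c_out, k
        fan = k * k
        self.params["w"] = _glorot(rng, (c_out, c_in, k, k), c_in * fan, c_out * fan, dtype)
        self.params["b"] = np.zeros(c_out, dtype=dtype)
        self._cols = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        k, p = self.k, self.k // 2
        b, c, h, w = x.shape
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        # (B, C, H, W, k, k) view -> (B*H*W, C*k*k) design matrix
        win = sliding_window_view(xp, (k, k), axis=(2, 3))
        cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(b * h * w, c * k * k)
        self._cols, self._in_shape = cols, x.shape
        wmat = self.params["w"].reshape(self.c_out, -1)
        out = cols @ wmat.T + self.params["b"]
        return out.reshape(b, h, w, self.c_out).transpose(0, 3, 1, 2)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        k, p = self.k, self.k // 2
        b, c, h, w = self._in_shape
        dmat = dout.transpose(0, 2, 3, 1).reshape(-1, self.c_out)
        self.grads["w"] = (dmat.T @ self._cols).reshape(self.params["w"].shape)
        self.grads["b"] = dmat.sum(axis=0)
        dcols = (dmat @ self.params["w"].reshape(self.c_out, -1)).reshape(
            b, h, w, c, k, k
        )
        dxp = np.zeros((b, c, h + 2 * p, w + 2 * p), dtype=dout.dtype)
        for di in range(k):
            for dj in range(k):
                dxp[:, :, di : di + h, dj : dj + w] += dcols[:, :, :, :, di, dj].transpose(
                    0, 3, 1, 2
                )
        self._cols = None
        return dxp[:, :, p : p + h, p : p + w]


class ConvTranspose2d(Layer):
    """2x2 stride-2 transposed convolution: doubles H and W (no overlap)."""

    def __init__(self, c_in, c_out, rng, dtype=np.float32):
        super().__init__()
        self.c_in, self.c_out = c_in, c_out
        self.params["w"] = _glorot(rng, (c_in, c_out, 2, 2), c_in * 4, c_out * 4, dtype)
        self.params["b"] = np.zeros(c_out, dtype=dtype)

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        b, c, h, w = x.shape
        t = np.tensordot(x, self.params["w"], axes=([1], [0]))  # (B,H,W,Cout,2,2)
        out = t.transpose(0, 3, 1, 4, 2, 5).reshape(b, self.c_out, 2 * h, 2 * w)
        return out + self.params["b"][None, :, None, None]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        x = self._x
        b, c, h, w = x.shape
        d6 = dout.reshape(b, self.c_out, h, 2, w, 2).transpose(0, 2, 4, 1, 3, 5)
        self.grads["w"] = np.tensordot(x, d6, axes=([0, 2, 3], [0, 1, 2]))
        self.grads["b"] = dout.sum(axis=(0, 2, 3))
        dx = np.tensordot(d6, self.params["w"], axes=([3, 4, 5], [1, 2, 3]))
        self._x = None
        return dx.transpose(0, 3, 1, 2)


class MaxPool2x2(Layer):
    """2x2 stride-2 max pooling; ties broken toward the first position."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        b, c, h, w = x.shape
        r = x.reshape(b, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        r = r.reshape(b, c, h // 2, w // 2, 4)
        self._idx = r.argmax(axis=-1)
        self._in_shape = x.shape
        return np.take_along_axis(r, self._idx[..., None], axis=-1)[..., 0]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        b, c, h, w = self._in_shape
        dr = np.zeros((b, c, h // 2, w // 2, 4), dtype=dout.dtype)
        np.put_along_axis(dr, self._idx[..., None], dout[..., None], axis=-1)
        dx = dr.reshape(b, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        return dx.reshape(b, c, h, w)


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return np.where(self._mask, dout, 0)


class ResEle(Layer):
    """Residual element: ReLU(conv3x3(x)) + shortcut(x).

    The shortcut is the identity when ``c_in == c_out``, else a trainable
    1x1 projection that matches the feature-map counts.  No activation is
    applied after the summation, so a ResEle with a zeroed residual branch
    is an exact identity (when the shortcut is the identity).
    """

    def __init__(self, c_in, c_out, k, rng, dtype=np.float32):
        super().__init__()
        self.conv = Conv2d(c_in, c_out, k, rng, dtype)
        self.relu = ReLU()
        self.proj = Conv2d(c_in, c_out, 1, rng, dtype) if c_in != c_out else None

    @property
    def sublayers(self):
        return [self.conv] + ([self.proj] if self.proj is not None else [])

    def n_params(self) -> int:
        return sum(l.n_params() for l in self.sublayers)

    def forward(self, x: np.ndarray) -> np.ndarray:
        branch = self.relu.forward(self.conv.forward(x))
        shortcut = self.proj.forward(x) if self.proj is not None else x
        return branch + shortcut

    def backward(self, dout: np.ndarray) -> np.ndarray:
        dx = self.conv.backward(self.relu.backward(dout))
        if self.proj is not None:
            dx = dx + self.proj.backward(dout)
        else:
            dx = dx + dout
        return dx


# ---------------------------------------------------------------------------
# network
# ---------------------------------------------------------------------------


class Network:
    """Built uResNet with explicit forward/backward over the u-topology."""

    def __init__(self, spec: NetworkSpec, seed: int = 0, dtype=np.float32):
        self.spec = spec
        self.dtype = dtype
        rng = np.random.default_rng(seed)
        c = spec.channel_widths
        k = spec.kernel_size

        def scale(c_in, c_out):
            blocks = [ResEle(c_in, c_out, k, rng, dtype)]
            for _ in range(spec.res_per_scale - 1):
                blocks.append(ResEle(c_out, c_out, k, rng, dtype))
            return blocks

        self.scales = [
            scale(spec.in_channels, c[0]),
            scale(c[0], c[1]),
            scale(c[1], c[2]),
            scale(c[2], c[3]),
        ]
        self.pools = [MaxPool2x2(), MaxPool2x2(), MaxPool2x2()]
        self.deconvs = [
            ConvTranspose2d(c[3], c[2], rng, dtype),
            ConvTranspose2d(c[2], c[1], rng, dtype),
            ConvTranspose2d(c[1], c[0], rng, dtype),
        ]
        self.junction_relus = [ReLU(), ReLU(), ReLU()]
        self.final = Conv2d(c[0], spec.n_classes, 1, rng, dtype)

    # -- introspection ------------------------------------------------------

    @property
    def res_elements(self) -> list[ResEle]:
        return [r for s in self.scales for r in s]

    def trainable_layers(self) -> list[Layer]:
        layers: list[Layer] = []
        for r in self.res_elements:
            layers.extend(r.sublayers)
        layers.extend(self.deconvs)
        layers.append(self.final)
        return layers

    def n_residual_elements(self) -> int:
        return len(self.res_elements)

    def n_deconv_layers(self) -> int:
        return len(self.deconvs)

    # -- passes -------------------------------------------------------------

    def forward(self, x: np.ndarray) -> np.ndarray:
        """Logits (B, C, H, W) for input (B, in_channels, H, W)."""
        x = np.ascontiguousarray(x, dtype=self.dtype)
        if x.ndim != 4 or x.shape[1] != self.spec.in_channels:
            raise ValueError(
                f"expected (B, {self.spec.in_channels}, H, W) input, got {x.shape}"
            )
        if x.shape[2] % 8 or x.shape[3] % 8:
            raise ShapeError(
                "in-plane dimensions must be divisible by 8; pad the input "
                f"(got {x.shape[2]}x{x.shape[3]})"
            )
        skips = []
        h = x
        for s, blocks in enumerate(self.scales):
            for block in blocks:
                h = block.forward(h)
            if s < 3:
                skips.append(h)
                h = self.pools[s].forward(h)
        for i, deconv in enumerate(self.deconvs):
            h = self.junction_relus[i].forward(deconv.forward(h) + skips[2 - i])
        return self.final.forward(h)

    def backward(self, dlogits: np.ndarray) -> np.ndarray:
        d = self.final.backward(dlogits)
        dskips = [None, None, None]
        for i in reversed(range(3)):
            d = self.junction_relus[i].backward(d)
            dskips[2 - i] = d
            d = self.deconvs[i].backward(d)
        for s in reversed(range(4)):
            if s < 3:
                d = self.pools[s].backward(d)
                d = d + dskips[s]
            for block in reversed(self.scales[s]):
                d = block.backward(d)
        return d

    def zero_grad(self) -> None:
        for l in self.trainable_layers():
            l.zero_grad()


def build_uresnet(spec: NetworkSpec = NetworkSpec(), seed: int = 0,
                  dtype=np.float32) -> Network:
    """Construct a seeded, Glorot-initialized uResNet from its spec."""
    return Network(spec, seed=seed, dtype=dtype)


def count_parameters(net: Network) -> int:
    """Total number of trainable weights and biases."""
    return sum(l.n_params() for l in net.trainable_layers())


def softmax(logits: np.ndarray, axis: int = 1) -> np.ndarray:
    """Numerically stable per-voxel softmax into pseudo class probabilities."""
    z = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def softmax_backward(probs: np.ndarray, dprobs: np.ndarray, axis: int = 1) -> np.ndarray:
    """Chain a gradient w.r.t. probabilities back to the logits."""
    inner = (dprobs * probs).sum(axis=axis, keepdims=True)
    return probs * (dprobs - inner)


def forward(net: Network, batch: np.ndarray) -> np.ndarray:
    """Class probability maps (B, C, H, W): forward pass + softmax."""
    return softmax(net.forward(batch), axis=1)


# ---------------------------------------------------------------------------
# checkpointing
# ---------------------------------------------------------------------------


def _named_params(net: Network):
    for i, layer in enumerate(net.trainable_layers()):
        for key, val in layer.params.items():
            yield f"layer{i:02d}.{key}", layer, key, val


def save_network(net: Network, path) -> None:
    """Serialize weights plus the embedded NetworkSpec to one .npz file."""
    arrays = {name: val for name, _, _, val in _named_params(net)}
    arrays["__spec__"] = np.frombuffer(net.spec.to_json().encode(), dtype=np.uint8)
    np.savez(path, **arrays)


def load_network(path, spec: NetworkSpec | None = None) -> Network:
    """Load a checkpoint; validates spec compatibility when one is given."""
    with np.load(path) as data:
        stored = NetworkSpec.from_json(bytes(data["__spec__"].tobytes()).decode())
        if spec is not None and stored != spec:
            raise ValueError("checkpoint NetworkSpec does not match the requested spec")
        net = Network(stored)
        for name, layer, key, val in _named_params(net):
            layer.params[key] = data[name].astype(net.dtype)
    return net
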