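"""A compact dual-head (segmentation + edge) convolutional backbone.

The backbone honours the contract of an edge-guided segmentation network:
one shared convolutional encoder, an auxiliary edge head whose final hidden
feature map is concatenated into the segmentation head's input (edge
guidance), and two sigmoid outputs — a segmentation probability map and an
edge probability map — both at full input resolution.

The net is implemented directly in numpy with hand-written backpropagation
(im2col convolutions, Adam updates).  Spatial context is obtained with
dilated 3x3 convolutions instead of pooling, so every feature map keeps the
input's H x W and the output-size contract holds for any input size.  All
randomness is drawn from a caller-supplied seed; forward, backward and
updates are deterministic.

The edge head can be frozen (``net.edge_frozen = True``): gradients still
flow through its activations into the encoder, but its own parameters are
not updated — this is the mode used when training on pseudo-labels whose
derived edges are too noisy to supervise.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

CHECKPOINT_VERSION = 1


@dataclass(frozen=True)
class BackboneConfig:
    """Width/depth of the backbone.

    ``depth`` encoder convolutions with dilations 1, 2, 4, ... give a
    receptive field of a few tens of pixels at the default depth.
    """

    base_channels: int = 8
    depth: int = 3

    def __post_init__(self) -> None:
        if self.base_channels < 1 or self.depth < 1:
            raise ValueError("base_channels and depth must be positive")


class Conv2d:
    """Same-padding 2D convolution with ReLU option, on (C, H, W) arrays."""

    def __init__(
        self,
        c_in: int,
        c_out: int,
        kernel: int,
        rng: np.random.Generator,
        dilation: int = 1,
        relu: bool = True,
        dtype: np.dtype = np.float32,
        bias_init: float = 0.0,
    ) -> None:
        fan_in = c_in * kernel * kernel
        self.dtype = np.dtype(dtype)
        self.W = rng.normal(0, np.sqrt(2.0 / fan_in), (c_out, c_in, kernel, kernel)).astype(self.dtype)
        self.b = np.full(c_out, bias_init, dtype=self.dtype)
        self.kernel = kernel
        self.dilation = dilation
        self.relu = relu
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._cols: np.ndarray | None = None
        self._pre: np.ndarray | None = None
        self._in_shape: tuple[int, int, int] | None = None

    @property
    def pad(self) -> int:
        return self.dilation * (self.kernel - 1) // 2

    def _im2col(self, x: np.ndarray) -> np.ndarray:
        c, h, w = x.shape
        k, d, p = self.kernel, self.dilation, self.pad
        xp = np.pad(x, ((0, 0), (p, p), (p, p)))
        cols = np.empty((c, k, k, h, w), dtype=self.dtype)
        for i in range(k):
            for j in range(k):
                cols[:, i, j] = xp[:, i * d : i * d + h, j * d : j * d + w]
        return cols.reshape(c * k * k, h * w)

    def forward(self, x: np.ndarray) -> np.ndarray:
        c, h, w = x.shape
        cols = self._im2col(x)
        y = (self.W.reshape(self.W.shape[0], -1) @ cols + self.b[:, None]).reshape(-1, h, w)
        self._cols = cols
        self._in_shape = x.shape
        if self.relu:
            self._pre = y
            y = np.maximum(y, 0)
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        assert self._cols is not None and self._in_shape is not None
        c, h, w = self._in_shape
        k, d, p = self.kernel, self.dilation, self.pad
        dy = dy.astype(self.dtype, copy=False)
        if self.relu:
            dy = dy * (self._pre > 0)
        dy_flat = dy.reshape(dy.shape[0], -1)
        self.dW += (dy_flat @ self._cols.T).reshape(self.W.shape)
        self.db += dy_flat.sum(axis=1)
        dcols = (self.W.reshape(self.W.shape[0], -1).T @ dy_flat).reshape(c, k, k, h, w)
        dxp = np.zeros((c, h + 2 * p, w + 2 * p), dtype=self.dtype)
        for i in range(k):
            for j in range(k):
                dxp[:, i * d : i * d + h, j * d : j * d + w] += dcols[:, i, j]
        return dxp[:, p : p + h, p : p + w] if p else dxp

    def zero_grad(self) -> None:
        self.dW[...] = 0
        self.db[...] = 0


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


@dataclass
class Prediction:
    """Full-resolution probability maps: segmentation and edge."""

    seg_prob: np.ndarray
    edge_prob: np.ndarray


class DualHeadNet:
    """Shared encoder, edge head, and edge-guided segmentation head."""

    def __init__(
        self,
        config: BackboneConfig = BackboneConfig(),
        seed: int = 0,
        dtype: np.dtype = np.float32,
    ) -> None:
        self.config = config
        self.dtype = np.dtype(dtype)
        rng = np.random.default_rng(seed)
        c = config.base_channels
        dt = self.dtype
        self.encoder = [Conv2d(1, c, 3, rng, dilation=1, dtype=dt)]
        for i in range(1, config.depth):
            self.encoder.append(Conv2d(c, c, 3, rng, dilation=min(2**i, 8), dtype=dt))
        self.edge_hidden = Conv2d(c, c, 3, rng, dtype=dt)
        # negative output-bias init: both heads predict rare foreground, so
        # starting near the foreground prior speeds early convergence
        self.edge_out = Conv2d(c, 1, 1, rng, relu=False, dtype=dt, bias_init=-2.0)
        self.seg_hidden = Conv2d(2 * c, c, 3, rng, dtype=dt)
        self.seg_out = Conv2d(c, 1, 1, rng, relu=False, dtype=dt, bias_init=-2.0)
        self.edge_frozen = False
        self._cache: dict[str, np.ndarray] = {}

    # ---- parameter bookkeeping -------------------------------------------------
    def layers(self) -> list[Conv2d]:
        return [*self.encoder, self.edge_hidden, self.edge_out, self.seg_hidden, self.seg_out]

    def edge_layers(self) -> list[Conv2d]:
        return [self.edge_hidden, self.edge_out]

    def trainable_layers(self) -> list[Conv2d]:
        frozen = set(map(id, self.edge_layers())) if self.edge_frozen else set()
        return [l for l in self.layers() if id(l) not in frozen]

    def zero_grad(self) -> None:
        for l in self.layers():
            l.zero_grad()

    def get_params(self) -> list[np.ndarray]:
        out = []
        for l in self.layers():
            out.extend([l.W.copy(), l.b.copy()])
        return out

    def set_params(self, params: list[np.ndarray]) -> None:
        it = iter(params)
        for l in self.layers():
            l.W[...] = next(it)
            l.b[...] = next(it)

    # ---- forward / backward ----------------------------------------------------
    def forward(self, image: np.ndarray) -> Prediction:
        img = np.asarray(image, dtype=self.dtype)
        if img.ndim != 2:
            raise ValueError(f"expected a 2D image, got shape {img.shape}")
        x = img[None]
        for l in self.encoder:
            x = l.forward(x)
        h_e = self.edge_hidden.forward(x)
        z_e = self.edge_out.forward(h_e)
        edge_prob = _sigmoid(z_e[0])
        h_s = self.seg_hidden.forward(np.concatenate([x, h_e], axis=0))
        z_s = self.seg_out.forward(h_s)
        seg_prob = _sigmoid(z_s[0])
        self._cache = {"seg_prob": seg_prob, "edge_prob": edge_prob}
        return Prediction(seg_prob=seg_prob, edge_prob=edge_prob)

    def backward(self, d_seg_prob: np.ndarray, d_edge_prob: np.ndarray | None = None) -> None:
        """Accumulate parameter gradients for the last forward pass.

        ``d_seg_prob`` / ``d_edge_prob`` are loss derivatives with respect
        to the output probability maps (the sigmoid is handled here).
        """
        seg_p = self._cache["seg_prob"]
        edge_p = self._cache["edge_prob"]
        dz_s = (d_seg_prob * seg_p * (1 - seg_p))[None]
        dh_s = self.seg_out.backward(dz_s)
        d_cat = self.seg_hidden.backward(dh_s)
        c = self.config.base_channels
        dx = d_cat[:c].copy()
        dh_e = d_cat[c:].copy()
        if d_edge_prob is not None:
            dz_e = (d_edge_prob * edge_p * (1 - edge_p))[None]
            dh_e += self.edge_out.backward(dz_e)
        dx += self.edge_hidden.backward(dh_e)
        for l in reversed(self.encoder):
            dx = l.backward(dx)

    def predict(self, image: np.ndarray) -> Prediction:
        return self.forward(image)

    # ---- checkpointing ---------------------------------------------------------
    def save(self, path: str) -> None:
        arrays = {}
        for i, l in enumerate(self.layers()):
            arrays[f"W{i}"] = l.W
            arrays[f"b{i}"] = l.b
        meta = json.dumps(
            {"version": CHECKPOINT_VERSION, "config": asdict(self.config), "dtype": self.dtype.name}
        )
        np.savez(path, meta=np.array(meta), **arrays)

    @classmethod
    def load(cls, path: str) -> "DualHeadNet":
        with np.load(path, allow_pickle=False) as data:
            meta = json.loads(str(data["meta"]))
            if meta["version"] != CHECKPOINT_VERSION:
                raise ValueError(f"unsupported checkpoint version {meta['version']}")
            net = cls(BackboneConfig(**meta["config"]), dtype=np.dtype(meta.get("dtype", "float32")))
            for i, l in enumerate(net.layers()):
                l.W[...] = data[f"W{i}"]
                l.b[...] = data[f"b{i}"]
        return net


class Adam:
    """Adam with decoupled L2 on convolution weights (not biases)."""

    def __init__(
        self,
        net: DualHeadNet,
        lr: float = 5e-4,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
        weight_decay: float = 1e-4,
    ) -> None:
        self.net = net
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self._m: dict[int, tuple[np.ndarray, np.ndarray]] = {}
        self._v: dict[int, tuple[np.ndarray, np.ndarray]] = {}
        for l in net.layers():
            self._m[id(l)] = (np.zeros_like(l.W), np.zeros_like(l.b))
            self._v[id(l)] = (np.zeros_like(l.W), np.zeros_like(l.b))

    def step(self) -> None:
        self.t += 1
        bc1 = 1 - self.beta1**self.t
        bc2 = 1 - self.beta2**self.t
        for l in self.net.trainable_layers():
            mW, mb = self._m[id(l)]
            vW, vb = self._v[id(l)]
            gW = l.dW + self.weight_decay * l.W
            gb = l.db
            mW[...] = self.beta1 * mW + (1 - self.beta1) * gW
            vW[...] = self.beta2 * vW + (1 - self.beta2) * gW**2
            mb[...] = self.beta1 * mb + (1 - self.beta1) * gb
            vb[...] = self.beta2 * vb + (1 - self.beta2) * gb**2
            l.W -= self.lr * (mW / bc1) / (np.sqrt(vW / bc2) + self.eps)
            l.b -= self.lr * (mb / bc1) / (np.sqrt(vb / bc2) + self.eps)
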