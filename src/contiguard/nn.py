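"""The residual convolutional network, implemented in numpy.

The detector maps a batch of per-position feature windows, shape
``(B, M, 14)``, to one misassembly probability per contig.  Topology: an
input batch-norm over the feature channels (whose moving statistics double
as the stored input-standardization constants), an initial convolution
(kernel 10, 16 filters), four residual groups of 2/5/5/2 blocks with
16/32/64/128 filters (the first convolution of groups 2-4 downsampling with
stride 2), masked global average pooling over the valid positions, and two
dense layers 128x50 (ReLU) and 50x1 (sigmoid).

All convolutions are *unpadded* (valid), so each residual block shortens its
input: the identity skip path is cropped by ``2*(K-1)`` positions, and a
downsampling block replaces it with a kernel-1 stride-2 convolution.
Because contigs in a batch are zero-padded to a common length, a per-sample
valid-length vector is threaded through every layer; positions computed from
padding are zeroed after each block, excluded from batch-norm statistics,
and excluded from the global average pool, which makes the final score
independent of how much padding a contig received.

No deep-learning framework is used: forward, backward (including mask-aware
batch norm) and the Adam update are explicit, which keeps the package
dependency-light and the arithmetic fully inspectable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = ["ModelConfig", "ResidualNet", "AdamOptimizer",
           "bce_with_logits", "clip_gradients"]

_EPS = 1e-3          # batch-norm epsilon
_BN_MOMENTUM = 0.9   # moving-statistics decay


@dataclass(frozen=True)
class ModelConfig:
    """Architecture specification.

    The defaults realize 562,573 parameters of which 559,441 are trainable.
    """

    in_channels: int = 14
    initial_filters: int = 16
    initial_kernel: int = 10
    group_blocks: tuple[int, ...] = (2, 5, 5, 2)
    group_filters: tuple[int, ...] = (16, 32, 64, 128)
    kernel_size: int = 5
    downsample_stride: int = 2
    dense_hidden: int = 50
    max_input_length: int = 20_000

    def __post_init__(self) -> None:
        if len(self.group_blocks) != len(self.group_filters):
            raise ValueError("group_blocks and group_filters length mismatch")
        if len(self.group_blocks) != 4:
            raise ValueError("architecture uses exactly 4 residual groups")
        for a, b in zip(self.group_filters, self.group_filters[1:]):
            if b != 2 * a:
                raise ValueError("filters must double between groups")
        if self.group_filters[0] != self.initial_filters:
            raise ValueError("first group must match the initial filters")
        if self.kernel_size < 2 or self.initial_kernel < 1:
            raise ValueError("invalid kernel sizes")

    def min_input_length(self) -> int:
        """Smallest input length yielding >= 1 valid output position."""
        lo, hi = 1, 4096
        while self._out_len(hi) < 1:
            hi *= 2
        while lo < hi:
            mid = (lo + hi) // 2
            if self._out_len(mid) >= 1:
                hi = mid
            else:
                lo = mid + 1
        return lo

    def _out_len(self, L: int) -> int:
        K, S = self.kernel_size, self.downsample_stride
        l = L - (self.initial_kernel - 1)
        for gi, nblocks in enumerate(self.group_blocks):
            for bi in range(nblocks):
                if gi > 0 and bi == 0:
                    if l < K:
                        return 0
                    l = (l - K) // S + 1 - (K - 1)
                else:
                    l = l - 2 * (K - 1)
                if l < 1:
                    return 0
        return l

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        d = dict(d)
        for k in ("group_blocks", "group_filters"):
            d[k] = tuple(d[k])
        return cls(**d)


# ---------------------------------------------------------------------------
# Layers
# ---------------------------------------------------------------------------

def _lengths_mask(lengths: np.ndarray, L: int) -> np.ndarray:
    return np.arange(L)[None, :] < lengths[:, None]


class _Conv1D:
    """Valid (unpadded) 1-D convolution with bias.

    Implemented as one dense GEMM ``(B*L, C) @ (C, K*F)`` followed by K
    shifted slice-accumulations — equivalent to im2col but without the
    large strided gather, which dominates runtime on long inputs.
    """

    def __init__(self, name, cin, cout, kernel, stride, rng):
        self.name = name
        self.cin, self.cout, self.K, self.S = cin, cout, kernel, stride
        scale = np.sqrt(2.0 / (kernel * cin))
        self.W = (rng.standard_normal((kernel, cin, cout)) * scale
                  ).astype(np.float32)
        self.b = np.zeros(cout, dtype=np.float32)
        self.gW = np.zeros_like(self.W)
        self.gb = np.zeros_like(self.b)
        self._x = None

    def params(self):
        yield f"{self.name}.W", self, "W", "gW", True
        yield f"{self.name}.b", self, "b", "gb", True

    def out_len(self, L: int) -> int:
        return (L - self.K) // self.S + 1 if L >= self.K else 0

    def _wall(self):
        # (C, K*F), block k holding the k-th tap
        return np.ascontiguousarray(
            self.W.transpose(1, 0, 2)).reshape(self.cin, self.K * self.cout)

    def forward(self, x, training):
        B, L, C = x.shape
        K, F, S = self.K, self.cout, self.S
        Lout = self.out_len(L)
        if Lout < 1:
            raise ValueError(
                f"{self.name}: input length {L} shorter than kernel {self.K}")
        z = (x.reshape(B * L, C) @ self._wall()).reshape(B, L, K, F)
        y = np.empty((B, Lout, F), dtype=z.dtype)
        y[:] = self.b
        span = S * (Lout - 1) + 1
        for k in range(K):
            y += z[:, k:k + span:S, k, :]
        if training:
            self._x = x
        return y

    def backward(self, dy):
        x = self._x
        B, L, C = x.shape
        K, F, S = self.K, self.cout, self.S
        Lout = dy.shape[1]
        dz = np.zeros((B, L, K, F), dtype=dy.dtype)
        span = S * (Lout - 1) + 1
        for k in range(K):
            dz[:, k:k + span:S, k, :] = dy
        dz2 = dz.reshape(B * L, K * F)
        x2 = x.reshape(B * L, C)
        gwall = x2.T @ dz2                      # (C, K*F)
        self.gW += gwall.reshape(C, K, F).transpose(1, 0, 2)
        self.gb += dy.sum(axis=(0, 1))
        dx = (dz2 @ self._wall().T).reshape(B, L, C)
        self._x = None
        return dx


class _BatchNorm:
    """Channel-wise batch norm; statistics over valid positions only."""

    def __init__(self, name, channels):
        self.name = name
        self.C = channels
        self.gamma = np.ones(channels, dtype=np.float32)
        self.beta = np.zeros(channels, dtype=np.float32)
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)
        self.ggamma = np.zeros_like(self.gamma)
        self.gbeta = np.zeros_like(self.beta)
        self._cache = None

    def params(self):
        yield f"{self.name}.gamma", self, "gamma", "ggamma", True
        yield f"{self.name}.beta", self, "beta", "gbeta", True
        yield f"{self.name}.running_mean", self, "running_mean", None, False
        yield f"{self.name}.running_var", self, "running_var", None, False

    def forward(self, x, mask, training):
        if training:
            m = mask[:, :, None].astype(x.dtype)
            n = float(mask.sum())
            mu = (x * m).sum(axis=(0, 1)) / n
            var = ((x - mu) ** 2 * m).sum(axis=(0, 1)) / n
            self.running_mean = (_BN_MOMENTUM * self.running_mean
                                 + (1 - _BN_MOMENTUM) * mu).astype(np.float32)
            self.running_var = (_BN_MOMENTUM * self.running_var
                                + (1 - _BN_MOMENTUM) * var).astype(np.float32)
        else:
            mu, var = self.running_mean, self.running_var
        ivar = 1.0 / np.sqrt(var + _EPS)
        xhat = (x - mu) * ivar
        if training:
            self._cache = (xhat, ivar, mask, float(mask.sum()))
        return self.gamma * xhat + self.beta

    def backward(self, dy):
        xhat, ivar, mask, n = self._cache
        m = mask[:, :, None].astype(dy.dtype)
        dy = dy * m
        self.ggamma += (dy * xhat).sum(axis=(0, 1))
        self.gbeta += dy.sum(axis=(0, 1))
        dgamma_x = (dy * xhat).sum(axis=(0, 1))
        dbeta_x = dy.sum(axis=(0, 1))
        dx = (self.gamma * ivar / n) * (n * dy - dbeta_x - xhat * dgamma_x)
        self._cache = None
        return dx * m


class _Dense:
    def __init__(self, name, nin, nout, rng):
        self.name = name
        scale = np.sqrt(2.0 / nin)
        self.W = (rng.standard_normal((nin, nout)) * scale).astype(np.float32)
        self.b = np.zeros(nout, dtype=np.float32)
        self.gW = np.zeros_like(self.W)
        self.gb = np.zeros_like(self.b)
        self._x = None

    def params(self):
        yield f"{self.name}.W", self, "W", "gW", True
        yield f"{self.name}.b", self, "b", "gb", True

    def forward(self, x, training):
        if training:
            self._x = x
        return x @ self.W + self.b

    def backward(self, dy):
        self.gW += self._x.T @ dy
        self.gb += dy.sum(axis=0)
        dx = dy @ self.W.T
        self._x = None
        return dx


class _ResidualBlock:
    """Two batch-normalized valid convolutions with a (possibly strided)
    skip connection; see the module docstring for the cropping rules."""

    def __init__(self, name, cin, cout, kernel, stride, rng):
        self.name = name
        self.K, self.S = kernel, stride
        self.downsample = stride != 1 or cin != cout
        self.conv1 = _Conv1D(f"{name}.conv1", cin, cout, kernel, stride, rng)
        self.bn1 = _BatchNorm(f"{name}.bn1", cout)
        self.conv2 = _Conv1D(f"{name}.conv2", cout, cout, kernel, 1, rng)
        self.bn2 = _BatchNorm(f"{name}.bn2", cout)
        if self.downsample:
            self.skip = _Conv1D(f"{name}.skip", cin, cout, 1, stride, rng)
        else:
            self.skip = None

    def params(self):
        for layer in (self.conv1, self.bn1, self.conv2, self.bn2, self.skip):
            if layer is not None:
                yield from layer.params()

    def out_lengths(self, lengths):
        if self.S == 1 and not self.downsample:
            return np.maximum(lengths - 2 * (self.K - 1), 0)
        l1 = np.where(lengths >= self.K, (lengths - self.K) // self.S + 1, 0)
        return np.maximum(l1 - (self.K - 1), 0)

    def forward(self, x, lengths, training):
        out_len_b = self.conv2.out_len(self.conv1.out_len(x.shape[1]))
        h = self.conv1.forward(x, training)
        new_lengths = self.out_lengths(lengths)
        mask_mid = _lengths_mask(
            np.where(lengths >= self.K,
                     (lengths - self.K) // self.S + 1, 0) if self.downsample
            else np.maximum(lengths - (self.K - 1), 0), h.shape[1])
        h = self.bn1.forward(h, mask_mid, training)
        h = np.maximum(h, 0.0)
        self._relu1 = h > 0 if training else None
        h = self.conv2.forward(h, training)
        h = self.bn2.forward(h, _lengths_mask(new_lengths, h.shape[1]),
                             training)
        if self.skip is not None:
            s = self.skip.forward(x, training)[:, :out_len_b]
        else:
            s = x[:, :out_len_b]
        y = np.maximum(h + s, 0.0)
        mask_out = _lengths_mask(new_lengths, y.shape[1])
        y = y * mask_out[:, :, None]
        if training:
            self._relu_out = y > 0
            self._in_shape = x.shape
        return y, new_lengths

    def backward(self, dy):
        dy = dy * self._relu_out
        ds = dy
        dh = self.bn2.backward(dy)
        dh = self.conv2.backward(dh)
        dh = dh * self._relu1
        dh = self.bn1.backward(dh)
        dx = self.conv1.backward(dh)
        if self.skip is not None:
            # skip conv consumed the full input; rebuild its padded grad
            n_out = self.skip.out_len(self._in_shape[1])
            tmp = np.zeros((dy.shape[0], n_out, dy.shape[2]), dtype=dy.dtype)
            tmp[:, :dy.shape[1]] = ds
            dx += self.skip.backward(tmp)
        else:
            dx[:, :dy.shape[1]] += ds
        self._relu1 = self._relu_out = None
        return dx


# ---------------------------------------------------------------------------
# The network
# ---------------------------------------------------------------------------

class ResidualNet:
    """The full detector network.

    Parameters
    ----------
    config : ModelConfig
    seed : int or numpy Generator
        Initialization randomness (He-normal weights).
    """

    #: floating dtype of the data path; float64 available for diagnostics
    dtype = np.float32

    def __init__(self, config: ModelConfig = ModelConfig(),
                 seed: int | np.random.Generator | None = 0):
        rng = np.random.default_rng(seed)
        self.config = config
        C = config.in_channels
        self.input_bn = _BatchNorm("input_bn", C)
        self.conv0 = _Conv1D("conv0", C, config.initial_filters,
                             config.initial_kernel, 1, rng)
        self.bn0 = _BatchNorm("bn0", config.initial_filters)
        self.blocks: list[_ResidualBlock] = []
        cin = config.initial_filters
        for gi, (nb, F) in enumerate(zip(config.group_blocks,
                                         config.group_filters)):
            for bi in range(nb):
                stride = (config.downsample_stride
                          if gi > 0 and bi == 0 else 1)
                self.blocks.append(_ResidualBlock(
                    f"rg{gi + 1}.b{bi + 1}", cin, F,
                    config.kernel_size, stride, rng))
                cin = F
        self.dense1 = _Dense("dense1", config.group_filters[-1],
                             config.dense_hidden, rng)
        self.dense2 = _Dense("dense2", config.dense_hidden, 1, rng)
        self._min_len = config.min_input_length()

    # -- parameter registry -------------------------------------------------

    def _layers(self):
        yield self.input_bn
        yield self.conv0
        yield self.bn0
        yield from self.blocks
        yield self.dense1
        yield self.dense2

    def parameters(self):
        """Yield (name, layer, attr, grad_attr, trainable) records."""
        for layer in self._layers():
            yield from layer.params()

    def count_parameters(self) -> tuple[int, int]:
        """Return (total, trainable) parameter counts."""
        total = trainable = 0
        for _, layer, attr, _, train in self.parameters():
            n = getattr(layer, attr).size
            total += n
            if train:
                trainable += n
        return total, trainable

    def zero_grad(self):
        for _, layer, _, gattr, train in self.parameters():
            if train:
                getattr(layer, gattr).fill(0.0)

    def gradients(self):
        for name, layer, _, gattr, train in self.parameters():
            if train:
                yield name, getattr(layer, gattr)

    # -- forward / backward -------------------------------------------------

    def forward_logits(self, x: np.ndarray, lengths: np.ndarray,
                       training: bool = False) -> np.ndarray:
        """Compute pre-sigmoid scores for a padded batch.

        ``x`` is (B, M, C) float32 with zeros beyond each sample's valid
        length; ``lengths`` gives those valid lengths.
        """
        x = np.asarray(x, dtype=self.dtype)
        lengths = np.asarray(lengths, dtype=np.int64)
        if x.ndim != 3 or x.shape[2] != self.config.in_channels:
            raise ValueError(
                f"expected (B, M, {self.config.in_channels}) input, "
                f"got {x.shape}")
        if (lengths < 1).any():
            raise ValueError("every sequence needs >= 1 valid position")
        lengths = np.minimum(lengths, x.shape[1])
        if (lengths < self._min_len).any():
            raise ValueError(
                f"valid length below the receptive minimum "
                f"{self._min_len}; zero-pad short contigs to at least that "
                f"length before batching")
        mask_in = _lengths_mask(lengths, x.shape[1])
        h = self.input_bn.forward(x, mask_in, training)
        h = h * mask_in[:, :, None]
        h = self.conv0.forward(h, training)
        lens = lengths - (self.config.initial_kernel - 1)
        m = _lengths_mask(lens, h.shape[1])
        h = self.bn0.forward(h, m, training)
        h = np.maximum(h, 0.0) * m[:, :, None]
        if training:
            self._relu0 = h > 0
            self._mask_in = mask_in
        for blk in self.blocks:
            h, lens = blk.forward(h, lens, training)
        if (lens < 1).any():
            raise ValueError("a sample lost all valid positions")
        m = _lengths_mask(lens, h.shape[1]).astype(h.dtype)
        pooled = (h * m[:, :, None]).sum(axis=1) / lens[:, None]
        if training:
            self._pool = (m, lens, h.shape)
        h2 = self.dense1.forward(pooled, training)
        h2r = np.maximum(h2, 0.0)
        if training:
            self._relu_d = h2 > 0
        logits = self.dense2.forward(h2r, training)
        return logits[:, 0]

    def predict_proba(self, x, lengths) -> np.ndarray:
        """Misassembly probabilities in (0, 1), inference mode."""
        z = self.forward_logits(x, lengths, training=False)
        return 1.0 / (1.0 + np.exp(-z))

    def backward(self, dlogits: np.ndarray) -> None:
        """Backpropagate d(loss)/d(logits); accumulates parameter grads."""
        dy = self.dense2.backward(dlogits[:, None].astype(self.dtype))
        dy = dy * self._relu_d
        dpool = self.dense1.backward(dy)
        m, lens, hshape = self._pool
        dh = (m[:, :, None] * (dpool[:, None, :] / lens[:, None, None])
              ).astype(np.float32)
        for blk in reversed(self.blocks):
            dh = blk.backward(dh)
        dh = dh * self._relu0
        dh = self.bn0.backward(dh)
        dh = self.conv0.backward(dh)
        dh = dh * self._mask_in[:, :, None]
        self.input_bn.backward(dh)
        self._relu0 = self._mask_in = self._pool = self._relu_d = None

    # -- checkpointing ------------------------------------------------------

    def state_dict(self) -> dict[str, np.ndarray]:
        return {name: getattr(layer, attr).copy()
                for name, layer, attr, _, _ in self.parameters()}

    def load_state_dict(self, state: dict) -> None:
        for name, layer, attr, _, _ in self.parameters():
            arr = np.asarray(state[name], dtype=np.float32)
            if arr.shape != getattr(layer, attr).shape:
                raise ValueError(f"shape mismatch for {name}")
            setattr(layer, attr, arr.copy())

    def save(self, path, extra: dict | None = None) -> None:
        """Single-file checkpoint: weights + config (+ catalog/stats JSON)."""
        meta = {"config": self.config.to_dict(), "format_version": 1}
        if extra:
            meta.update(extra)
        arrays = {f"param/{k}": v for k, v in self.state_dict().items()}
        np.savez_compressed(path, meta=np.frombuffer(
            json.dumps(meta).encode(), dtype=np.uint8), **arrays)

    @classmethod
    def load(cls, path) -> tuple["ResidualNet", dict]:
        with np.load(path) as z:
            meta = json.loads(bytes(z["meta"]).decode())
            state = {k[len("param/"):]: z[k] for k in z.files
                     if k.startswith("param/")}
        net = cls(ModelConfig.from_dict(meta["config"]), seed=0)
        net.load_state_dict(state)
        return net, meta


# ---------------------------------------------------------------------------
# Loss, clipping, optimizer
# ---------------------------------------------------------------------------

def bce_with_logits(logits: np.ndarray, targets: np.ndarray
                    ) -> tuple[float, np.ndarray]:
    """Mean binary cross-entropy and its gradient w.r.t. the logits."""
    z = np.asarray(logits, dtype=np.float64)
    y = np.asarray(targets, dtype=np.float64)
    loss = np.mean(np.maximum(z, 0) - z * y + np.log1p(np.exp(-np.abs(z))))
    p = 1.0 / (1.0 + np.exp(-z))
    grad = (p - y) / len(z)
    return float(loss), grad


def clip_gradients(grads: Sequence[np.ndarray], clip_value: float = 0.5,
                   clip_norm: float = 1.0) -> float:
    """Clip gradients element-wise to ``±clip_value`` then rescale so the
    global L2 norm is at most ``clip_norm``.  Returns the pre-clip norm."""
    for g in grads:
        np.clip(g, -clip_value, clip_value, out=g)
    norm = float(np.sqrt(sum(float((g ** 2).sum()) for g in grads)))
    if norm > clip_norm and norm > 0:
        scale = clip_norm / norm
        for g in grads:
            g *= scale
    return norm


class AdamOptimizer:
    """Adam with the usual bias correction."""

    def __init__(self, net: ResidualNet, lr: float = 1e-4,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.net = net
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = {name: np.zeros_like(getattr(layer, attr))
                  for name, layer, attr, _, tr in net.parameters() if tr}
        self.v = {name: np.zeros_like(x) for name, x in self.m.items()}

    def step(self, clip_value: float = 0.5, clip_norm: float = 1.0) -> float:
        records = [(name, layer, attr, gattr)
                   for name, layer, attr, gattr, tr in self.net.parameters()
                   if tr]
        grads = [getattr(layer, gattr) for _, layer, _, gattr in records]
        norm = clip_gradients(grads, clip_value, clip_norm)
        self.t += 1
        b1t = 1 - self.beta1 ** self.t
        b2t = 1 - self.beta2 ** self.t
        for (name, layer, attr, gattr), g in zip(records, grads):
            m = self.m[name]
            v = self.v[name]
            m *= self.beta1
            m += (1 - self.beta1) * g
            v *= self.beta2
            v += (1 - self.beta2) * g * g
            update = (self.lr * (m / b1t)
                      / (np.sqrt(v / b2t) + self.eps))
            arr = getattr(layer, attr)
            arr -= update.astype(arr.dtype)
        return norm
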