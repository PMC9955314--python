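"""Residual convolutional networks (depths 18 and 50) in plain numpy.

The architectures follow the standard residual-network design: a 7×7/2
stem with 3×3/2 max pooling, four stages of residual blocks (basic
two-convolution blocks for depth 18, 1-3-1 bottleneck blocks for depth 50),
global average pooling, and — replacing the stock classifier — a two-layer
fully connected head ending in a softmax-ready class layer. The pooled
penultimate vector is the "deep feature" tap: 512 dimensions at depth 18,
2048 at depth 50, independent of input resolution thanks to the global
pool.
"""

from __future__ import annotations

import numpy as np

from .layers import (
    BatchNorm2d,
    Chain,
    Conv2d,
    GlobalAvgPool,
    Linear,
    MaxPool2d,
    Module,
    ReLU,
)

__all__ = ["ResNet", "BasicBlock", "Bottleneck"]


def _conv_bn(in_ch, out_ch, kernel, stride, pad, rng, dtype):
    return [
        Conv2d(in_ch, out_ch, kernel, stride, pad, bias=False, rng=rng, dtype=dtype),
        BatchNorm2d(out_ch, dtype=dtype),
    ]


class _Residual(Module):
    """y = relu(branch(x) + shortcut(x)); shortcut=None means identity."""

    def __init__(self, branch: Chain, shortcut: Chain | None):
        self.branch = branch
        self.shortcut = shortcut
        self._mask = None

    def params(self):
        ps = self.branch.params()
        if self.shortcut is not None:
            ps = ps + self.shortcut.params()
        return ps

    def forward(self, x, train=False):
        y = self.branch.forward(x, train=train)
        sc = x if self.shortcut is None else self.shortcut.forward(x, train=train)
        out = y + sc
        if train:
            self._mask = out > 0
        return np.maximum(out, 0)

    def backward(self, dout):
        d = dout * self._mask
        self._mask = None
        dx = self.branch.backward(d)
        dsc = d if self.shortcut is None else self.shortcut.backward(d)
        return dx + dsc


def BasicBlock(in_ch, out_ch, stride, rng, dtype):
    """Two 3×3 convolutions; expansion 1."""
    branch = Chain(
        *_conv_bn(in_ch, out_ch, 3, stride, 1, rng, dtype),
        ReLU(),
        *_conv_bn(out_ch, out_ch, 3, 1, 1, rng, dtype),
    )
    shortcut = None
    if stride != 1 or in_ch != out_ch:
        shortcut = Chain(*_conv_bn(in_ch, out_ch, 1, stride, 0, rng, dtype))
    return _Residual(branch, shortcut)


def Bottleneck(in_ch, mid_ch, stride, rng, dtype):
    """1×1 reduce, 3×3, 1×1 expand (×4); expansion 4."""
    out_ch = mid_ch * 4
    branch = Chain(
        *_conv_bn(in_ch, mid_ch, 1, 1, 0, rng, dtype),
        ReLU(),
        *_conv_bn(mid_ch, mid_ch, 3, stride, 1, rng, dtype),
        ReLU(),
        *_conv_bn(mid_ch, out_ch, 1, 1, 0, rng, dtype),
    )
    shortcut = None
    if stride != 1 or in_ch != out_ch:
        shortcut = Chain(*_conv_bn(in_ch, out_ch, 1, stride, 0, rng, dtype))
    return _Residual(branch, shortcut)


_CONFIGS = {
    18: dict(block=BasicBlock, layers=(2, 2, 2, 2), expansion=1),
    50: dict(block=Bottleneck, layers=(3, 4, 6, 3), expansion=4),
}


class ResNet(Module):
    """Residual network with a penultimate feature tap.

    Parameters
    ----------
    depth : 18 or 50
    n_classes : int
        Output classes of the two-layer fully connected head.
    hidden : int
        Width of the first fully connected output layer (default 64).
    seed : int
        Weight-initialization seed (deterministic builds).
    dtype : numpy dtype
        float32 for speed; float64 for gradient checking.
    """

    def __init__(self, depth: int, n_classes: int = 2, hidden: int = 64,
                 seed: int = 0, dtype=np.float32):
        if depth not in _CONFIGS:
            raise ValueError(
                f"unsupported depth {depth}; supported: {sorted(_CONFIGS)}"
            )
        cfg = _CONFIGS[depth]
        rng = np.random.default_rng(seed)
        self.depth = depth
        self.feature_dim = 512 * cfg["expansion"]

        body: list[Module] = [
            *_conv_bn(3, 64, 7, 2, 3, rng, dtype),
            ReLU(),
            MaxPool2d(3, 2, 1),
        ]
        in_ch = 64
        for stage, n_blocks in enumerate(cfg["layers"]):
            ch = 64 * (2 ** stage)
            for b in range(n_blocks):
                stride = 2 if (stage > 0 and b == 0) else 1
                body.append(cfg["block"](in_ch, ch, stride, rng, dtype))
                in_ch = ch * cfg["expansion"]
        self.body = Chain(*body)
        self.pool = GlobalAvgPool()
        self.head = Chain(
            Linear(self.feature_dim, hidden, rng=rng, dtype=dtype),
            ReLU(),
            Linear(hidden, n_classes, rng=rng, dtype=dtype),
        )
        self.n_classes = n_classes
        self.hidden = hidden

    def params(self):
        return self.body.params() + self.head.params()

    def forward(self, x, train=False):
        feats = self.pool.forward(self.body.forward(x, train=train), train=train)
        return self.head.forward(feats, train=train)

    def forward_features(self, x) -> np.ndarray:
        """Penultimate pooled features (n, feature_dim), inference mode."""
        return self.pool.forward(self.body.forward(x, train=False))

    def backward(self, dlogits):
        d = self.head.backward(dlogits)
        d = self.pool.backward(d)
        return self.body.backward(d)

    # -- weight (de)serialization -------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        state = {}
        for i, p in enumerate(self.params()):
            state[f"p{i:04d}"] = p.data
        bns = [m for m in _walk_bn(self.body)]
        for i, bn in enumerate(bns):
            state[f"bn{i:04d}.mean"] = bn.running_mean
            state[f"bn{i:04d}.var"] = bn.running_var
        return state

    def load_state_dict(self, state: dict) -> None:
        for i, p in enumerate(self.params()):
            arr = np.asarray(state[f"p{i:04d}"])
            if arr.shape != p.data.shape:
                raise ValueError(
                    f"shape mismatch for parameter {i}: "
                    f"{arr.shape} vs {p.data.shape}"
                )
            p.data = arr.astype(p.data.dtype)
            p.grad = np.zeros_like(p.data)
            p.velocity = np.zeros_like(p.data)
        for i, bn in enumerate(_walk_bn(self.body)):
            bn.running_mean = np.asarray(state[f"bn{i:04d}.mean"]).astype(
                bn.running_mean.dtype
            )
            bn.running_var = np.asarray(state[f"bn{i:04d}.var"]).astype(
                bn.running_var.dtype
            )


def _walk_bn(module):
    if isinstance(module, BatchNorm2d):
        yield module
    elif isinstance(module, Chain):
        for m in module.modules:
            yield from _walk_bn(m)
    elif isinstance(module, _Residual):
        yield from _walk_bn(module.branch)
        if module.shortcut is not None:
            yield from _walk_bn(module.shortcut)
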