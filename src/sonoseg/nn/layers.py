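"""Neural-network building blocks for the trainable mask decoder.

Weight layout follows the (out_features, in_features) convention of the
reference released checkpoints so a name-by-name mapping is possible.
"""

from __future__ import annotations

import numpy as np

from .autograd import Tensor, concat, gelu, relu, softmax


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    """Tiny module system: parameters discovered by attribute walking."""

    def named_parameters(self, prefix: str = ""):
        for name, val in vars(self).items():
            key = f"{prefix}{name}"
            if isinstance(val, Parameter):
                yield key, val
            elif isinstance(val, Module):
                yield from val.named_parameters(f"{key}.")
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{key}.{i}.")
                    elif isinstance(item, Parameter):
                        yield f"{key}.{i}", item

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def num_parameters(self) -> int:
        return int(sum(p.size for p in self.parameters()))

    def state_dict(self) -> dict:
        return {k: p.data.copy() for k, p in self.named_parameters()}

    def load_state_dict(self, state: dict) -> None:
        params = dict(self.named_parameters())
        missing = set(params) - set(state)
        if missing:
            raise KeyError(f"state dict missing keys: {sorted(missing)[:5]} ...")
        for k, p in params.items():
            arr = np.asarray(state[k], dtype=np.float64)
            if arr.shape != p.data.shape:
                raise ValueError(f"shape mismatch for {k}: {arr.shape} vs {p.data.shape}")
            p.data = arr.copy()

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Identity(Module):
    def forward(self, x):
        return x


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator):
        bound = 1.0 / np.sqrt(in_features)
        self.weight = Parameter(rng.uniform(-bound, bound, size=(out_features, in_features)))
        self.bias = Parameter(rng.uniform(-bound, bound, size=(out_features,)))

    def forward(self, x: Tensor) -> Tensor:
        return x @ self.weight.T + self.bias


class LayerNorm(Module):
    """Normalization over the last axis with learned affine terms."""

    def __init__(self, dim: int, eps: float = 1e-6):
        self.weight = Parameter(np.ones(dim))
        self.bias = Parameter(np.zeros(dim))
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        return xc * ((var + self.eps) ** -0.5) * self.weight + self.bias


class LayerNorm2d(Module):
    """Channel-wise layer norm for (C, H, W) feature maps."""

    def __init__(self, channels: int, eps: float = 1e-6):
        self.weight = Parameter(np.ones(channels))
        self.bias = Parameter(np.zeros(channels))
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        axes = (1, 2, 0) if x.ndim == 3 else (0, 2, 3, 1)
        back = (2, 0, 1) if x.ndim == 3 else (0, 3, 1, 2)
        y = x.transpose(axes)  # channels last
        mu = y.mean(axis=-1, keepdims=True)
        yc = y - mu
        var = (yc * yc).mean(axis=-1, keepdims=True)
        y = yc * ((var + self.eps) ** -0.5) * self.weight + self.bias
        return y.transpose(back)


class MLPBlock(Module):
    """Two-layer point-wise feed-forward block, W2·GELU(W1 x + b1) + b2."""

    def __init__(self, dim: int, hidden: int, rng: np.random.Generator):
        self.lin1 = Linear(dim, hidden, rng)
        self.lin2 = Linear(hidden, dim, rng)

    def forward(self, x: Tensor) -> Tensor:
        return self.lin2(gelu(self.lin1(x)))


class MLP(Module):
    """Stack of linear layers with ReLU between (prediction heads)."""

    def __init__(self, in_dim: int, hidden: int, out_dim: int, depth: int,
                 rng: np.random.Generator):
        dims = [in_dim] + [hidden] * (depth - 1) + [out_dim]
        self.layers = [Linear(a, b, rng) for a, b in zip(dims[:-1], dims[1:])]

    def forward(self, x: Tensor) -> Tensor:
        for i, layer in enumerate(self.layers):
            x = layer(x)
            if i < len(self.layers) - 1:
                x = relu(x)
        return x


class Attention(Module):
    """Multi-head attention over un-batched (n_tokens, dim) streams.

    `downsample_rate` shrinks the internal head space, as in the reference
    decoder's cross-attention (256 -> 128).
    """

    def __init__(self, embedding_dim: int, num_heads: int, rng: np.random.Generator,
                 downsample_rate: int = 1):
        self.embedding_dim = embedding_dim
        self.num_heads = num_heads
        self.internal_dim = embedding_dim // downsample_rate
        if self.internal_dim % num_heads != 0:
            raise ValueError("internal dim must divide num_heads")
        self.q_proj = Linear(embedding_dim, self.internal_dim, rng)
        self.k_proj = Linear(embedding_dim, self.internal_dim, rng)
        self.v_proj = Linear(embedding_dim, self.internal_dim, rng)
        self.out_proj = Linear(self.internal_dim, embedding_dim, rng)

    def forward(self, q: Tensor, k: Tensor, v: Tensor) -> Tensor:
        """Accepts (n, dim) streams or batched (B, n, dim) streams."""
        batched = q.ndim == 3
        h = self.num_heads
        dh = self.internal_dim // h
        qp, kp, vp = self.q_proj(q), self.k_proj(k), self.v_proj(v)
        if batched:
            B, nq = qp.shape[0], qp.shape[1]
            split = lambda x: x.reshape(x.shape[0], x.shape[1], h, dh).transpose(0, 2, 1, 3)
        else:
            nq = qp.shape[0]
            split = lambda x: x.reshape(x.shape[0], h, dh).transpose(1, 0, 2)
        qh, kh, vh = split(qp), split(kp), split(vp)
        kt = kh.transpose(0, 1, 3, 2) if batched else kh.transpose(0, 2, 1)
        attn = softmax(qh @ kt * (1.0 / np.sqrt(dh)), axis=-1)
        out = attn @ vh
        if batched:
            out = out.transpose(0, 2, 1, 3).reshape(B, nq, self.internal_dim)
        else:
            out = out.transpose(1, 0, 2).reshape(nq, self.internal_dim)
        return self.out_proj(out)


class ConvTranspose2x2(Module):
    """Transposed convolution with kernel 2, stride 2 on (C, H, W) maps.

    With kernel == stride the operation is a per-pixel linear map into
    disjoint 2x2 output blocks, expressible with reshapes and one matmul.
    """

    def __init__(self, in_channels: int, out_channels: int, rng: np.random.Generator):
        bound = 1.0 / np.sqrt(in_channels * 4)
        self.weight = Parameter(
            rng.uniform(-bound, bound, size=(in_channels, out_channels, 2, 2))
        )
        self.bias = Parameter(rng.uniform(-bound, bound, size=(out_channels,)))
        self.in_channels = in_channels
        self.out_channels = out_channels

    def forward(self, x: Tensor) -> Tensor:
        cout = self.out_channels
        wmat = self.weight.reshape(self.in_channels, cout * 4)
        if x.ndim == 4:
            B, cin, h, w = x.shape
            y = x.transpose(0, 2, 3, 1).reshape(B * h * w, cin) @ wmat
            y = y.reshape(B, h, w, cout, 2, 2)
            y = y.transpose(0, 3, 1, 4, 2, 5).reshape(B, cout, 2 * h, 2 * w)
        else:
            cin, h, w = x.shape
            y = x.transpose(1, 2, 0).reshape(h * w, cin) @ wmat
            y = y.reshape(h, w, cout, 2, 2)
            y = y.transpose(2, 0, 3, 1, 4).reshape(cout, 2 * h, 2 * w)
        return y + self.bias.reshape(cout, 1, 1)


def bilinear_matrix(n_in: int, n_out: int) -> np.ndarray:
    """1-D bilinear interpolation matrix (half-pixel-center convention)."""
    A = np.zeros((n_out, n_in))
    scale = n_in / n_out
    for i in range(n_out):
        src = (i + 0.5) * scale - 0.5
        lo = int(np.floor(src))
        frac = src - lo
        lo_c = min(max(lo, 0), n_in - 1)
        hi_c = min(max(lo + 1, 0), n_in - 1)
        A[i, lo_c] += 1.0 - frac
        A[i, hi_c] += frac
    return A


def bilinear_resize(x: Tensor, out_hw: tuple[int, int]) -> Tensor:
    """Resize (C, H, W) -> (C, H', W') bilinearly; differentiable (two matmuls)."""
    _, h, w = x.shape
    A = Tensor(bilinear_matrix(h, out_hw[0]))
    B = Tensor(bilinear_matrix(w, out_hw[1]))
    return A @ x @ B.T


__all__ = [
    "Parameter", "Module", "Identity", "Linear", "LayerNorm", "LayerNorm2d",
    "MLPBlock", "MLP", "Attention", "ConvTranspose2x2",
    "bilinear_matrix", "bilinear_resize", "concat",
]
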