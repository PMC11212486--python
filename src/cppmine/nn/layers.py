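"""Neural-network layers built on the autograd core.

Layers hold :class:`~cppmine.nn.autograd.Tensor` parameters created from a
seeded ``numpy.random.Generator`` so that two models built with the same seed
are bit-identical.  The set implemented here is exactly what the peptide
classifier needs: dense layers, token embedding, layer normalisation,
multi-head self-attention with padding masks, a position-wise feed-forward
block, and a 1-D convolution + global-max-pool over fingerprint bit vectors.
"""

from __future__ import annotations

from typing import Iterable

import numpy as np

from .autograd import Tensor, concat, softmax


class Module:
    """Container base class; collects parameters from attributes recursively."""

    def parameters(self) -> Iterable[Tensor]:
        for value in self.__dict__.values():
            if isinstance(value, Tensor) and value.requires_grad:
                yield value
            elif isinstance(value, Module):
                yield from value.parameters()
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        yield from item.parameters()
                    elif isinstance(item, Tensor) and item.requires_grad:
                        yield item

    def state_arrays(self) -> list[np.ndarray]:
        return [p.data for p in self.parameters()]

    def load_state_arrays(self, arrays: list[np.ndarray]) -> None:
        params = list(self.parameters())
        if len(params) != len(arrays):
            raise ValueError(
                f"state mismatch: {len(params)} parameters, {len(arrays)} arrays")
        for p, a in zip(params, arrays):
            if p.data.shape != a.shape:
                raise ValueError(f"shape mismatch {p.data.shape} vs {a.shape}")
            p.data = np.asarray(a, dtype=np.float64).copy()


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int,
            shape: tuple[int, ...]) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class Linear(Module):
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator):
        self.weight = Tensor(_glorot(rng, in_dim, out_dim, (in_dim, out_dim)),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(out_dim), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class Embedding(Module):
    def __init__(self, vocab: int, dim: int, rng: np.random.Generator):
        self.table = Tensor(rng.normal(0.0, 0.02, size=(vocab, dim)),
                            requires_grad=True)

    def __call__(self, token_ids: np.ndarray) -> Tensor:
        return self.table.gather_rows(np.asarray(token_ids, dtype=np.int64))


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        self.gain = Tensor(np.ones(dim), requires_grad=True)
        self.bias = Tensor(np.zeros(dim), requires_grad=True)
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        centred = x - mu
        var = (centred * centred).mean(axis=-1, keepdims=True)
        return centred * (var + self.eps) ** -0.5 * self.gain + self.bias


class MultiHeadSelfAttention(Module):
    """Scaled dot-product self-attention over padded sequences.

    ``mask`` marks real positions (True); attention weights onto padding are
    forced to ~0 by adding a large negative constant to the logits.
    """

    def __init__(self, d_model: int, n_heads: int, rng: np.random.Generator):
        if d_model % n_heads:
            raise ValueError("d_model must be divisible by n_heads")
        self.n_heads = n_heads
        self.d_head = d_model // n_heads
        self.wq = Linear(d_model, d_model, rng)
        self.wk = Linear(d_model, d_model, rng)
        self.wv = Linear(d_model, d_model, rng)
        self.wo = Linear(d_model, d_model, rng)

    def __call__(self, x: Tensor, mask: np.ndarray) -> Tensor:
        B, L, D = x.shape
        H, dh = self.n_heads, self.d_head

        def split_heads(t: Tensor) -> Tensor:
            return t.reshape(B, L, H, dh).transpose((0, 2, 1, 3))

        q = split_heads(self.wq(x))
        k = split_heads(self.wk(x))
        v = split_heads(self.wv(x))
        scores = q @ k.transpose((0, 1, 3, 2)) * (1.0 / np.sqrt(dh))
        # disallow attending TO padding positions
        bias = np.where(mask[:, None, None, :], 0.0, -1e9)
        attn = softmax(scores + Tensor(bias), axis=-1)
        ctx = attn @ v
        ctx = ctx.transpose((0, 2, 1, 3)).reshape(B, L, D)
        return self.wo(ctx)


class FeedForward(Module):
    def __init__(self, d_model: int, hidden: int, rng: np.random.Generator):
        self.fc1 = Linear(d_model, hidden, rng)
        self.fc2 = Linear(hidden, d_model, rng)

    def __call__(self, x: Tensor) -> Tensor:
        return self.fc2(self.fc1(x).relu())


class TransformerEncoderLayer(Module):
    """Post-norm encoder block: x' = LN(x + MHA(x)); out = LN(x' + FFN(x'))."""

    def __init__(self, d_model: int, n_heads: int, ffn_dim: int,
                 rng: np.random.Generator):
        self.attn = MultiHeadSelfAttention(d_model, n_heads, rng)
        self.ffn = FeedForward(d_model, ffn_dim, rng)
        self.ln1 = LayerNorm(d_model)
        self.ln2 = LayerNorm(d_model)

    def __call__(self, x: Tensor, mask: np.ndarray) -> Tensor:
        x = self.ln1(x + self.attn(x, mask))
        return self.ln2(x + self.ffn(x))


def masked_mean_pool(x: Tensor, mask: np.ndarray) -> Tensor:
    """Mean over real (unpadded) positions; padding contributes nothing."""
    m = mask.astype(np.float64)[..., None]          # (B, L, 1)
    lengths = m.sum(axis=1)                          # (B, 1)
    return (x * Tensor(m)).sum(axis=1) * Tensor(1.0 / lengths)


class Conv1dMaxPool(Module):
    """1-D convolution over a bit vector, global max-pool over positions.

    The input is a fixed (non-trainable) 0/1 vector, so the convolution is a
    matmul of precomputed sliding windows against the kernel weights.
    """

    def __init__(self, kernel: int, channels: int, rng: np.random.Generator):
        self.kernel = kernel
        self.weight = Tensor(_glorot(rng, kernel, channels, (kernel, channels)),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(channels), requires_grad=True)

    def __call__(self, bits: np.ndarray) -> Tensor:
        # bits: (B, n_bits) -> windows (B, n_bits-kernel+1, kernel)
        windows = np.lib.stride_tricks.sliding_window_view(
            bits.astype(np.float64), self.kernel, axis=1)
        conv = Tensor(windows) @ self.weight + self.bias   # (B, W, C)
        return conv.relu().max(axis=1)                     # (B, C)


class MLP(Module):
    """Classifier head with access to the penultimate activation."""

    def __init__(self, in_dim: int, hidden: tuple[int, ...], n_out: int,
                 rng: np.random.Generator):
        if not hidden:
            raise ValueError("MLP needs at least one hidden layer "
                             "(the penultimate layer is exported)")
        dims = (in_dim, *hidden)
        self.layers = [Linear(a, b, rng) for a, b in zip(dims[:-1], dims[1:])]
        self.out = Linear(dims[-1], n_out, rng)

    def penultimate(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = layer(x).relu()
        return x

    def __call__(self, x: Tensor) -> Tensor:
        return self.out(self.penultimate(x))
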