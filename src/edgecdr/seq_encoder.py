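"""Transformer encoder over substructure token sequences.

A drug's token sequence is embedded as the sum of a learned token embedding
and a learned position embedding, passed through a stack of multi-head
scaled dot-product self-attention + position-wise feed-forward blocks (with
residual connections and layer normalization), and pooled by a masked mean
over real-token positions into a fixed-length drug embedding.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, concat
from .espf import SubstructureSequence
from .nn import Linear, Module, glorot, ones, zeros

__all__ = ["SeqEncoderConfig", "SeqEncoder", "embed", "attend", "ffn"]

_NEG = -1e9  # additive mask for padded positions


@dataclass(frozen=True)
class SeqEncoderConfig:
    vocab_size: int
    zeta: int = 64
    d_model: int = 128
    n_heads: int = 4
    n_layers: int = 2
    d_ff: int = 256
    d_seq: int = 100

    def __post_init__(self):
        if self.d_model % self.n_heads:
            raise ValueError("d_model must be divisible by n_heads")


class LayerNorm(Module):
    def __init__(self, d: int, eps: float = 1e-5):
        self.gamma = ones(d)
        self.beta = zeros(d)
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        centered = x - mu
        var = (centered ** 2).mean(axis=-1, keepdims=True)
        return centered * ((var + self.eps) ** -0.5) * self.gamma + self.beta


class AttentionParams(Module):
    def __init__(self, d_model: int, n_heads: int, rng: np.random.Generator):
        self.n_heads = n_heads
        self.d_model = d_model
        self.W_q = glorot(rng, d_model, d_model)
        self.W_k = glorot(rng, d_model, d_model)
        self.W_v = glorot(rng, d_model, d_model)
        self.W_o = glorot(rng, d_model, d_model)


class EncoderBlock(Module):
    def __init__(self, cfg: SeqEncoderConfig, rng: np.random.Generator):
        self.attn = AttentionParams(cfg.d_model, cfg.n_heads, rng)
        self.ln1 = LayerNorm(cfg.d_model)
        self.ff1 = Linear(cfg.d_model, cfg.d_ff, rng)
        self.ff2 = Linear(cfg.d_ff, cfg.d_model, rng)
        self.ln2 = LayerNorm(cfg.d_model)


def embed(seq: SubstructureSequence, W_c: Tensor, W_p: Tensor) -> Tensor:
    """Token + position embedding sum: row i = W_c[token_i] + W_p[i].

    Returns a (zeta, d) matrix; padded rows hold the bare position embedding
    and are masked out downstream.
    """
    zeta, d = W_p.shape
    if seq.max_len != zeta:
        raise ValueError(f"sequence max_len {seq.max_len} != position table {zeta}")
    ids = np.array(seq.token_ids, dtype=int)
    if ids.size and (ids.min() < 0 or ids.max() >= W_c.shape[0]):
        raise IndexError("token id outside vocabulary")
    rows = W_c[ids]                        # (l, d) gather
    if seq.length < zeta:
        pad = Tensor(np.zeros((zeta - seq.length, d)))
        rows = concat([rows, pad], axis=0)
    return rows + W_p


def attend(D: Tensor, params: AttentionParams, pad_mask: np.ndarray) -> Tensor:
    """Multi-head scaled dot-product self-attention over one sequence.

    Padded positions receive −1e9 scores before the softmax, so attention
    rows over real tokens sum to 1 and padding never leaks in.
    """
    zeta, d = D.shape
    h = params.n_heads
    dh = d // h
    q = (D @ params.W_q).reshape(zeta, h, dh).transpose(1, 0, 2)
    k = (D @ params.W_k).reshape(zeta, h, dh).transpose(1, 0, 2)
    v = (D @ params.W_v).reshape(zeta, h, dh).transpose(1, 0, 2)
    scores = (q @ k.transpose(0, 2, 1)) * (dh ** -0.5)          # (h, ζ, ζ)
    bias = np.where(pad_mask, 0.0, _NEG)[None, None, :]         # mask keys
    weights = (scores + Tensor(bias)).softmax(axis=-1)
    z = (weights @ v).transpose(1, 0, 2).reshape(zeta, d)
    return z @ params.W_o


def ffn(Z: Tensor, W_1: Tensor, b_1: Tensor, W_2: Tensor, b_2: Tensor) -> Tensor:
    """Position-wise feed-forward: max(0, Z W1 + b1) W2 + b2."""
    return (Z @ W_1 + b_1).relu() @ W_2 + b_2


class SeqEncoder(Module):
    """Embedding + n_layers of (attention, FFN) + masked mean pooling."""

    def __init__(self, config: SeqEncoderConfig, rng: np.random.Generator):
        cfg = config
        self.config = cfg
        self.W_c = glorot(rng, cfg.vocab_size, cfg.d_model)   # token table
        self.W_p = glorot(rng, cfg.zeta, cfg.d_model)         # position table
        self.blocks = [EncoderBlock(cfg, rng) for _ in range(cfg.n_layers)]
        self.out = Linear(cfg.d_model, cfg.d_seq, rng)

    def __call__(self, seq: SubstructureSequence) -> Tensor:
        return self.encode(seq)

    def encode(self, seq: SubstructureSequence) -> Tensor:
        """Drug sequence embedding, shape (1, d_seq)."""
        if seq.length == 0:
            raise ValueError("cannot encode an all-padding sequence")
        x = embed(seq, self.W_c, self.W_p)
        return self.encode_from_matrix(x, seq.pad_mask, seq.length)

    def encode_from_matrix(self, x: Tensor, pad_mask: np.ndarray,
                           length: int) -> Tensor:
        """Run the block stack and masked mean pooling on a prepared matrix."""
        for blk in self.blocks:
            x = blk.ln1(x + attend(x, blk.attn, pad_mask))
            x = blk.ln2(x + ffn(x, blk.ff1.W, blk.ff1.b, blk.ff2.W, blk.ff2.b))
        mask = pad_mask.astype(float)[:, None]
        pooled = (x * Tensor(mask)).sum(axis=0, keepdims=True) * (1.0 / length)
        return self.out(pooled)
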