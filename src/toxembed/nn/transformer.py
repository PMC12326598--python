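"""Bidirectional (BERT-style) transformer encoder for token sequences.

Pre-norm self-attention blocks over learned token + position embeddings.
The sentence-level summary ("pooled" vector) is, by default, the
first-position hidden state passed through a learned tanh pooling layer;
mean pooling over non-pad positions is available in the config.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from . import autograd as ag
from .autograd import Tensor
from .layers import Embedding, LayerNorm, Linear, Module


@dataclass
class EncoderConfig:
    """Encoder hyperparameters.

    The full-scale defaults follow the conventional BERT-base geometry
    (12 layers, 12 heads, 768 hidden); :meth:`tiny` gives a desk-test
    preset small enough to train on a laptop CPU in seconds.
    """

    vocab_size: int = 64
    n_layers: int = 12
    n_heads: int = 12
    hidden: int = 768
    ffn: int | None = None  # defaults to 4 * hidden
    max_length: int = 128
    dropout: float = 0.1
    pooling: str = "first"  # "first" (learned pooler) or "mean"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.hidden % self.n_heads != 0:
            raise ValueError("hidden size must be divisible by the head count")
        if self.ffn is None:
            self.ffn = 4 * self.hidden
        if self.pooling not in ("first", "mean"):
            raise ValueError("pooling must be 'first' or 'mean'")

    @classmethod
    def tiny(cls, vocab_size: int, **kw) -> "EncoderConfig":
        """Desk-test preset: 2 layers, 4 heads, 64 hidden."""
        defaults = dict(n_layers=2, n_heads=4, hidden=64, ffn=128, max_length=128)
        defaults.update(kw)
        return cls(vocab_size=vocab_size, **defaults)

    def to_dict(self) -> dict:
        return asdict(self)


class MultiHeadAttention(Module):
    def __init__(self, hidden: int, n_heads: int, rng: np.random.Generator):
        super().__init__()
        self.n_heads = n_heads
        self.head_dim = hidden // n_heads
        self.q = Linear(hidden, hidden, rng)
        self.k = Linear(hidden, hidden, rng)
        self.v = Linear(hidden, hidden, rng)
        self.out = Linear(hidden, hidden, rng)

    def __call__(self, x: Tensor, pad_mask: np.ndarray, drop_rate: float,
                 rng: np.random.Generator) -> Tensor:
        b, t, h = x.shape

        def split_heads(z: Tensor) -> Tensor:
            z = ag.reshape(z, (b, t, self.n_heads, self.head_dim))
            return ag.swapaxes(z, 1, 2)  # (B, nh, T, dh)

        q, k, v = split_heads(self.q(x)), split_heads(self.k(x)), split_heads(self.v(x))
        scores = ag.mul(ag.matmul(q, ag.swapaxes(k, -1, -2)), 1.0 / np.sqrt(self.head_dim))
        attn = ag.softmax(scores, mask=pad_mask[:, None, None, :])
        attn = ag.dropout(attn, drop_rate, rng, self.training)
        ctx = ag.matmul(attn, v)  # (B, nh, T, dh)
        ctx = ag.reshape(ag.swapaxes(ctx, 1, 2), (b, t, h))
        return self.out(ctx)


class EncoderLayer(Module):
    """Pre-norm block: x + MHA(LN(x)); x + FFN(LN(x))."""

    def __init__(self, hidden: int, n_heads: int, ffn: int, rng: np.random.Generator):
        super().__init__()
        self.ln1 = LayerNorm(hidden)
        self.attn = MultiHeadAttention(hidden, n_heads, rng)
        self.ln2 = LayerNorm(hidden)
        self.fc1 = Linear(hidden, ffn, rng)
        self.fc2 = Linear(ffn, hidden, rng)

    def __call__(self, x: Tensor, pad_mask: np.ndarray, drop_rate: float,
                 rng: np.random.Generator) -> Tensor:
        a = self.attn(self.ln1(x), pad_mask, drop_rate, rng)
        x = x + ag.dropout(a, drop_rate, rng, self.training)
        f = self.fc2(ag.gelu(self.fc1(self.ln2(x))))
        return x + ag.dropout(f, drop_rate, rng, self.training)


class TransformerEncoder(Module):
    def __init__(self, config: EncoderConfig):
        super().__init__()
        rng = np.random.default_rng(config.seed)
        self.config = config
        self.tok_emb = Embedding(config.vocab_size, config.hidden, rng)
        self.pos_emb = Embedding(config.max_length, config.hidden, rng)
        self.emb_ln = LayerNorm(config.hidden)
        self.blocks = [
            EncoderLayer(config.hidden, config.n_heads, config.ffn, rng)
            for _ in range(config.n_layers)
        ]
        self.final_ln = LayerNorm(config.hidden)
        self.pooler = Linear(config.hidden, config.hidden, rng)

    def __call__(self, token_ids: np.ndarray, pad_mask: np.ndarray,
                 rng: np.random.Generator | None = None) -> Tensor:
        """Hidden states (B, T, H) for padded int token ids (B, T).

        ``pad_mask`` is 1 for real tokens, 0 for padding.
        """
        if token_ids.shape[1] > self.config.max_length:
            raise ValueError(
                f"sequence length {token_ids.shape[1]} exceeds max_length "
                f"{self.config.max_length}"
            )
        rng = rng or np.random.default_rng()
        t = token_ids.shape[1]
        x = self.tok_emb(token_ids) + self.pos_emb(np.arange(t))
        x = ag.dropout(self.emb_ln(x), self.config.dropout, rng, self.training)
        for block in self.blocks:
            x = block(x, pad_mask, self.config.dropout, rng)
        return self.final_ln(x)

    def pooled(self, hidden: Tensor, pad_mask: np.ndarray) -> Tensor:
        """Sentence-level summary vector (B, H)."""
        if self.config.pooling == "mean":
            return ag.mean_over_mask(hidden, pad_mask)
        return ag.tanh(self.pooler(ag.take_position(hidden, 0)))
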