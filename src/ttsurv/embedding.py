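"""Column embedding and transformer encoder for categorical covariates.

Tabular rows have no sequential order, so positional encoding is replaced by
column embedding: every (feature, level) pair owns a learned vector, and a
per-column identifier vector is added so that the same level code in two
different columns embeds differently.  A handful of special tokens is
appended to the token sequence (reserved capacity; they are dropped before
pooling downstream).  Ordinal severity structure (stage I<II<III<IV,
Deauville 1..5) is left for the encoder's self-attention to discover — the
levels enter as plain categories.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._autodiff import Tensor, concat, layer_norm, relu, softmax

__all__ = [
    "EncoderConfig",
    "ColumnEmbeddingTable",
    "embed_categorical",
    "attention",
    "init_encoder_params",
    "encoder_forward",
]


@dataclass(frozen=True)
class EncoderConfig:
    """Transformer encoder hyperparameters.

    ``k_dim``/``v_dim`` default to ``d_embed // n_heads`` (concatenated-heads
    convention), which requires ``d_embed`` divisible by ``n_heads``.
    """

    d_embed: int = 16
    n_layers: int = 1
    n_heads: int = 4
    k_dim: int | None = None
    v_dim: int | None = None
    mlp_hidden: int = 32
    n_special_tokens: int = 1

    def __post_init__(self) -> None:
        for name in ("d_embed", "n_layers", "n_heads", "mlp_hidden"):
            if getattr(self, name) < (0 if name == "n_layers" else 1):
                raise ValueError(f"{name} must be positive")
        if self.k_dim is None and self.d_embed % self.n_heads != 0:
            raise ValueError("d_embed must be divisible by n_heads")

    @property
    def head_k(self) -> int:
        return self.k_dim if self.k_dim is not None else self.d_embed // self.n_heads

    @property
    def head_v(self) -> int:
        return self.v_dim if self.v_dim is not None else self.d_embed // self.n_heads


class ColumnEmbeddingTable:
    """Learned vectors for every (feature, level) pair plus special tokens.

    Total learned vector count = sum_i c_i + t + N: per-level vectors for each
    of the N categorical features (feature i has c_i levels), t special
    tokens, and N additive column identifiers.
    """

    def __init__(self, cardinalities: tuple[int, ...], d_embed: int,
                 n_special_tokens: int = 1, rng: np.random.Generator | None = None):
        if not cardinalities:
            raise ValueError("need at least one categorical feature")
        rng = rng if rng is not None else np.random.default_rng(0)
        self.cardinalities = tuple(int(c) for c in cardinalities)
        self.d_embed = int(d_embed)
        self.n_special_tokens = int(n_special_tokens)
        self.offsets = np.concatenate([[0], np.cumsum(self.cardinalities)[:-1]])
        total = sum(self.cardinalities)
        s = 1.0 / np.sqrt(d_embed)
        self.per_level = Tensor(rng.normal(0, s, (total, d_embed)), requires_grad=True)
        self.column_id = Tensor(
            rng.normal(0, s, (len(self.cardinalities), d_embed)), requires_grad=True)
        self.special = Tensor(
            rng.normal(0, s, (self.n_special_tokens, d_embed)), requires_grad=True)

    @property
    def n_features(self) -> int:
        return len(self.cardinalities)

    @property
    def n_vectors(self) -> int:
        return sum(self.cardinalities) + self.n_special_tokens + self.n_features

    def parameters(self) -> list[Tensor]:
        return [self.per_level, self.column_id, self.special]

    def embed(self, x_cat: np.ndarray, with_special: bool = True) -> Tensor:
        """Map an (B, N) code matrix to (B, m, d) token embeddings.

        m = N (+ t special tokens when ``with_special``).  Token i is the
        level vector of (feature i, code_i) plus column identifier i.
        """
        x_cat = np.asarray(x_cat, dtype=np.int64)
        if x_cat.ndim == 1:
            x_cat = x_cat[None, :]
        if x_cat.shape[1] != self.n_features:
            raise ValueError("code matrix width does not match feature count")
        for i, c in enumerate(self.cardinalities):
            col = x_cat[:, i]
            if col.size and (col.min() < 0 or col.max() >= c):
                raise ValueError(f"level code out of range for feature {i}")
        flat = x_cat + self.offsets  # (B, N) global row indices
        tokens = self.per_level.gather_rows(flat)  # (B, N, d)
        tokens = tokens + self.column_id.reshape(1, self.n_features, self.d_embed)
        if with_special and self.n_special_tokens:
            B = x_cat.shape[0]
            idx = np.zeros((B, self.n_special_tokens), dtype=np.intp)
            idx += np.arange(self.n_special_tokens)
            spec = self.special.gather_rows(idx)  # (B, t, d)
            tokens = concat([tokens, spec], axis=1)
        return tokens


def embed_categorical(x_cat_row: np.ndarray, table: ColumnEmbeddingTable) -> Tensor:
    """Embed one row of N level codes into N d-dimensional vectors."""
    out = table.embed(np.asarray(x_cat_row).reshape(1, -1), with_special=False)
    return out.reshape(table.n_features, table.d_embed)


def attention(Q, K, V) -> Tensor:
    """Scaled dot-product attention softmax(Q Kᵀ / sqrt(k)) · V.

    Accepts arrays or Tensors with optional leading batch axes; rows of the
    weight matrix sum to one by construction.
    """
    Q, K, V = Tensor._lift(Q), Tensor._lift(K), Tensor._lift(V)
    if Q.shape[-1] != K.shape[-1]:
        raise ValueError("query/key dimension mismatch")
    if K.shape[-2] != V.shape[-2]:
        raise ValueError("key/value row count mismatch")
    scale = 1.0 / np.sqrt(Q.shape[-1])
    scores = (Q @ K.transpose(*range(K.ndim - 2), K.ndim - 1, K.ndim - 2)) * scale
    return softmax(scores, axis=-1) @ V


def init_encoder_params(config: EncoderConfig,
                        rng: np.random.Generator) -> list[dict[str, Tensor]]:
    """Initialise per-layer parameters (post-norm transformer blocks)."""
    d, h = config.d_embed, config.n_heads
    k, v, mlp = config.head_k, config.head_v, config.mlp_hidden

    def lin(n_in: int, n_out: int) -> Tensor:
        return Tensor(rng.normal(0, 1.0 / np.sqrt(n_in), (n_in, n_out)),
                      requires_grad=True)

    layers = []
    for _ in range(config.n_layers):
        layers.append({
            "Wq": lin(d, h * k), "Wk": lin(d, h * k), "Wv": lin(d, h * v),
            "Wo": lin(h * v, d), "bo": Tensor(np.zeros(d), requires_grad=True),
            "ln1_g": Tensor(np.ones(d), requires_grad=True),
            "ln1_b": Tensor(np.zeros(d), requires_grad=True),
            "W1": lin(d, mlp), "b1": Tensor(np.zeros(mlp), requires_grad=True),
            "W2": lin(mlp, d), "b2": Tensor(np.zeros(d), requires_grad=True),
            "ln2_g": Tensor(np.ones(d), requires_grad=True),
            "ln2_b": Tensor(np.zeros(d), requires_grad=True),
        })
    return layers


def _split_heads(x: Tensor, n_heads: int, head_dim: int) -> Tensor:
    B, m = x.shape[0], x.shape[1]
    return x.reshape(B, m, n_heads, head_dim).transpose(0, 2, 1, 3)


def encoder_forward(tokens, config: EncoderConfig,
                    params: list[dict[str, Tensor]]) -> Tensor:
    """Run the post-norm encoder stack: x <- LN(x + MHA(x)); x <- LN(x + MLP(x)).

    ``tokens`` is (B, m, d) (a bare (m, d) sequence is promoted to B=1).
    Self-attention has no positional signal, so the map is permutation-
    equivariant over token positions.
    """
    x = Tensor._lift(tokens)
    squeeze = x.ndim == 2
    if squeeze:
        x = x.reshape(1, *x.shape)
    B, m, d = x.shape
    if m == 0:
        raise ValueError("empty token sequence")
    if d != config.d_embed:
        raise ValueError("token dimension does not match d_embed")
    h, k, v = config.n_heads, config.head_k, config.head_v
    for p in params[: config.n_layers]:
        Q = _split_heads(x @ p["Wq"], h, k)  # (B, h, m, k)
        K = _split_heads(x @ p["Wk"], h, k)
        V = _split_heads(x @ p["Wv"], h, v)
        heads = attention(Q, K, V)  # (B, h, m, v)
        merged = heads.transpose(0, 2, 1, 3).reshape(B, m, h * v)
        x = layer_norm(x + (merged @ p["Wo"] + p["bo"]), p["ln1_g"], p["ln1_b"])
        hidden = relu(x @ p["W1"] + p["b1"])
        x = layer_norm(x + (hidden @ p["W2"] + p["b2"]), p["ln2_g"], p["ln2_b"])
    return x.reshape(m, d) if squeeze else x
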