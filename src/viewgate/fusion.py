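"""View-token construction, gating, transformer fusion, and classification.

Each encoded view contributes one token ``e_i = v_i + PE_i`` where ``PE_i``
is a learnable view-specific positional vector (views are an unordered set of
named slots; the positional term carries *which view* a token is, not where
it sits in a sequence).  Gate values scale tokens elementwise (``z_i * e_i``)
and a token whose gate is exactly zero — or whose view is absent — is masked
out of attention entirely, so soft gating at z=0 and hard removal of the view
produce identical outputs.

Fusion is a standard transformer encoder block (multi-head self-attention,
8 heads by default, residual connections, a feed-forward expansion) followed
by mean-pooling over the active tokens; the pooled vector feeds a linear
softmax classifier.  With view identity attached to token content, the whole
map is invariant to token order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._autodiff import Tensor, softmax as _softmax_t

__all__ = [
    "FusionConfig",
    "PositionalTable",
    "TokenSet",
    "FusionModule",
    "make_tokens",
    "apply_gates",
    "fuse",
    "classify",
    "predict_topk",
]


@dataclass(frozen=True)
class FusionConfig:
    """Geometry of the fusion block and classifier."""

    n_heads: int = 8
    n_layers: int = 1
    embedding_dim: int = 32
    n_classes: int = 2
    ff_ratio: int = 4

    def __post_init__(self):
        if self.embedding_dim % self.n_heads != 0:
            raise ValueError(f"embedding_dim {self.embedding_dim} not divisible "
                             f"by n_heads {self.n_heads}")
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")


@dataclass
class PositionalTable:
    """Learnable view-slot positional vectors, one per view in the vocabulary."""

    pe: np.ndarray  # (N, D)

    def __post_init__(self):
        self.pe = np.asarray(self.pe, dtype=np.float64)
        if self.pe.ndim != 2:
            raise ValueError("PE table must be (n_views, D)")
        if not np.all(np.isfinite(self.pe)):
            raise ValueError("PE table must be finite")


@dataclass
class TokenSet:
    """The N view tokens of one specimen plus their active mask."""

    tokens: np.ndarray       # (N, D)
    active_mask: np.ndarray  # (N,) bool

    def __post_init__(self):
        self.tokens = np.asarray(self.tokens, dtype=np.float64)
        self.active_mask = np.asarray(self.active_mask, dtype=bool)
        if len(self.tokens) != len(self.active_mask):
            raise ValueError("token count != mask length")


def make_tokens(embeddings, table: PositionalTable) -> TokenSet:
    """Build e_i = v_i + PE_i; views not provided are marked inactive."""
    n, d = table.pe.shape
    tokens = np.zeros((n, d))
    active = np.zeros(n, dtype=bool)
    for emb in embeddings:
        i = emb.view_index
        if not 0 <= i < n:
            raise ValueError(f"view_index {i} outside [0, {n})")
        if active[i]:
            raise ValueError(f"duplicate view_index {i}")
        tokens[i] = emb.v + table.pe[i]
        active[i] = True
    return TokenSet(tokens=tokens, active_mask=active)


def apply_gates(tokens: TokenSet, z: np.ndarray) -> TokenSet:
    """Scale token i by gate value z_i; a zero gate deactivates the token."""
    z = np.asarray(z, dtype=np.float64)
    if z.shape != (len(tokens.tokens),):
        raise ValueError(f"gate vector length {z.shape} != token count "
                         f"{len(tokens.tokens)}")
    return TokenSet(tokens=tokens.tokens * z[:, None],
                    active_mask=tokens.active_mask & (z > 0))


class FusionModule:
    """Transformer-block fusion + linear softmax head, on the autodiff tape.

    ``forward(tokens, mask)`` takes (B, N, D) tokens and a (B, N) or (N,)
    boolean mask; inactive tokens are excluded from attention keys and from
    the mean pool, so they cannot influence the output.
    """

    def __init__(self, config: FusionConfig, rng: np.random.Generator):
        self.config = config
        D, H = config.embedding_dim, config.ff_ratio * config.embedding_dim

        def init(*shape, fan_in):
            t = Tensor(rng.standard_normal(shape) / np.sqrt(fan_in))
            t.requires_grad = True
            return t

        def zeros(*shape):
            t = Tensor(np.zeros(shape))
            t.requires_grad = True
            return t

        self.layers = []
        for _ in range(config.n_layers):
            layer = {
                "wq": init(D, D, fan_in=D), "wk": init(D, D, fan_in=D),
                "wv": init(D, D, fan_in=D), "wo": init(D, D, fan_in=D),
                "bo": zeros(D),
                "w1": init(D, H, fan_in=D), "b1": zeros(H),
                "w2": init(H, D, fan_in=H), "b2": zeros(D),
            }
            self.layers.append(layer)
        self.w_cls = init(D, config.n_classes, fan_in=D)
        self.b_cls = zeros(config.n_classes)

    def parameters(self) -> list[Tensor]:
        params = []
        for layer in self.layers:
            params += list(layer.values())
        return params + [self.w_cls, self.b_cls]

    # -- forward pieces ------------------------------------------------------

    def _attention(self, x: Tensor, layer, key_bias: np.ndarray) -> Tensor:
        B, N, D = x.shape
        h = self.config.n_heads
        dh = D // h

        def split(t):  # (B, N, D) -> (B, h, N, dh)
            return t.reshape(B, N, h, dh).transpose(0, 2, 1, 3)

        q, k, v = split(x @ layer["wq"]), split(x @ layer["wk"]), split(x @ layer["wv"])
        scores = (q @ k.transpose(0, 1, 3, 2)) / np.sqrt(dh)
        scores = scores + key_bias[:, None, None, :]   # mask inactive keys
        attn = _softmax_t(scores, axis=-1)
        out = (attn @ v).transpose(0, 2, 1, 3).reshape(B, N, D)
        return out @ layer["wo"] + layer["bo"]

    def fuse(self, tokens: Tensor, mask: np.ndarray) -> Tensor:
        """(B, N, D) tokens + (B, N) mask -> (B, D) pooled representation."""
        B, N, D = tokens.shape
        mask = np.broadcast_to(np.asarray(mask, dtype=bool), (B, N))
        counts = mask.sum(axis=1)
        if np.any(counts == 0):
            raise ValueError("at least one view must be active per specimen")
        key_bias = np.where(mask, 0.0, -1e9)
        x = tokens
        for layer in self.layers:
            x = x + self._attention(x, layer, key_bias)
            ff = ((x @ layer["w1"] + layer["b1"]).relu()) @ layer["w2"] + layer["b2"]
            x = x + ff
        pooled = (x * mask[:, :, None]).sum(axis=1) / counts[:, None]
        return pooled

    def logits(self, fused: Tensor) -> Tensor:
        return fused @ self.w_cls + self.b_cls

    def probabilities(self, fused: Tensor) -> Tensor:
        return _softmax_t(self.logits(fused), axis=-1)


def fuse(tokens: TokenSet, module: FusionModule) -> np.ndarray:
    """Fuse one specimen's token set into a single D-vector (eval path)."""
    if not tokens.active_mask.any():
        raise ValueError("no active views to fuse")
    x = Tensor(tokens.tokens[None])
    return module.fuse(x, tokens.active_mask[None]).data[0]


def classify(fused: np.ndarray, weights: np.ndarray, bias: np.ndarray) -> np.ndarray:
    """Linear softmax head: class probabilities from a fused vector."""
    fused = np.asarray(fused, dtype=np.float64)
    if not np.all(np.isfinite(fused)):
        raise ValueError("fused vector must be finite")
    logits = fused @ weights + bias
    logits -= logits.max()
    e = np.exp(logits)
    return e / e.sum()


def predict_topk(probabilities: np.ndarray, k: int = 3,
                 class_names: list[str] | None = None):
    """Top-k (label, confidence) pairs, descending; ties broken by class index."""
    probabilities = np.asarray(probabilities, dtype=np.float64)
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > probabilities.size:
        raise ValueError(f"k={k} exceeds the number of classes "
                         f"{probabilities.size}")
    order = np.argsort(-probabilities, kind="stable")[:k]
    if class_names is None:
        return [(int(i), float(probabilities[i])) for i in order]
    return [(class_names[i], float(probabilities[i])) for i in order]
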