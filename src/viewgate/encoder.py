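"""Per-view preprocessing, augmentation, and the shared-weight encoder.

One encoder — a single parameter set — embeds every anatomical view of a
specimen into a D-dimensional view-embedding vector.  The production design
this follows pairs a convolutional backbone with an attention head that uses
learnable queries to aggregate spatial features; here the encoder is a
registry so the test-scale backbone and any production backbone satisfy the
same contract:

* ``reference-tiny``  — a small strided conv stack + query pooling, random
  init, used by the image-mode tests.
* ``feature-mlp``     — a two-layer MLP over precomputed per-view feature
  vectors, used by feature-mode synthetic data.

Images are resized to ``input_size`` (224 x 224 by default, bilinear) and
scaled to [0, 1] before encoding; training-time augmentation applies random
flips, rotation within +/-60 degrees, colour jitter, and random erasing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from PIL import Image

from ._autodiff import Tensor, conv2d, softmax

__all__ = [
    "EncoderConfig",
    "AugmentConfig",
    "ViewImage",
    "ViewEmbedding",
    "preprocess",
    "augment",
    "encode_view",
    "QueryPool",
    "TinyConvEncoder",
    "FeatureMLPEncoder",
    "build_encoder",
    "ENCODER_REGISTRY",
]


@dataclass(frozen=True)
class EncoderConfig:
    """Backbone choice and embedding geometry.

    ``norm_mean``/``norm_std`` are per-channel normalisation constants applied
    after scaling to [0, 1]; the 0.5/0.5 defaults suit randomly initialised
    backbones (pretrained backbones would supply their own statistics).
    """

    backbone_name: str = "reference-tiny"
    embedding_dim: int = 32
    n_queries: int = 4
    input_size: tuple[int, int] = (224, 224)
    norm_mean: tuple[float, float, float] = (0.5, 0.5, 0.5)
    norm_std: tuple[float, float, float] = (0.5, 0.5, 0.5)

    def __post_init__(self):
        if self.embedding_dim < 2:
            raise ValueError("embedding_dim must be >= 2")
        if self.n_queries < 1:
            raise ValueError("n_queries must be >= 1")


@dataclass(frozen=True)
class AugmentConfig:
    """Probabilities and ranges of the training-time augmentations."""

    p_hflip: float = 0.5
    p_vflip: float = 0.0
    p_rotate: float = 0.5
    max_rotation_deg: float = 60.0
    p_jitter: float = 0.5
    jitter_strength: float = 0.2
    p_erase: float = 0.25
    erase_area: tuple[float, float] = (0.02, 0.2)


@dataclass
class ViewImage:
    """One preprocessed photograph of one anatomical view of a specimen."""

    pixels: np.ndarray  # (H, W, 3) floats in [0, 1]
    view_name: str = ""
    specimen_id: str = ""


@dataclass
class ViewEmbedding:
    """The encoder output v_i for one view."""

    v: np.ndarray
    view_index: int


def preprocess(image: np.ndarray, config: EncoderConfig,
               view_name: str = "", specimen_id: str = "") -> ViewImage:
    """Resize a raw RGB array to ``config.input_size`` and scale to [0, 1].

    Accepts uint8 (0..255) or float (already in [0, 1]) arrays of shape
    (H, W, 3).  Bilinear interpolation; deterministic.
    """
    arr = np.asarray(image)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError(f"expected an RGB (H, W, 3) array, got shape {arr.shape}")
    if arr.shape[0] < 1 or arr.shape[1] < 1:
        raise ValueError("image must contain at least one pixel")
    if arr.dtype == np.uint8:
        arr = arr.astype(np.float64) / 255.0
    else:
        arr = arr.astype(np.float64)
    h, w = config.input_size
    if arr.shape[:2] != (h, w):
        pil = Image.fromarray((np.clip(arr, 0, 1) * 255).astype(np.uint8))
        pil = pil.resize((w, h), resample=Image.BILINEAR)
        arr = np.asarray(pil, dtype=np.float64) / 255.0
    return ViewImage(pixels=np.clip(arr, 0.0, 1.0), view_name=view_name,
                     specimen_id=specimen_id)


def augment(image: ViewImage, rng: np.random.Generator,
            config: AugmentConfig = AugmentConfig()) -> ViewImage:
    """Apply the stochastic training augmentations; identity when all
    probabilities are zero; fully determined by the generator state."""
    arr = image.pixels.copy()
    if rng.random() < config.p_hflip:
        arr = arr[:, ::-1]
    if rng.random() < config.p_vflip:
        arr = arr[::-1]
    if rng.random() < config.p_rotate:
        angle = rng.uniform(-config.max_rotation_deg, config.max_rotation_deg)
        if angle != 0.0:
            from scipy import ndimage
            arr = ndimage.rotate(arr, angle, axes=(1, 0), reshape=False,
                                 order=1, mode="nearest")
    if rng.random() < config.p_jitter:
        s = config.jitter_strength
        brightness = rng.uniform(1 - s, 1 + s)
        contrast = rng.uniform(1 - s, 1 + s)
        saturation = rng.uniform(1 - s, 1 + s)
        arr = arr * brightness
        mean = arr.mean()
        arr = (arr - mean) * contrast + mean
        grey = arr.mean(axis=2, keepdims=True)
        arr = (arr - grey) * saturation + grey
    if rng.random() < config.p_erase:
        h, w = arr.shape[:2]
        frac = rng.uniform(*config.erase_area)
        eh = max(1, int(np.sqrt(frac) * h))
        ew = max(1, int(np.sqrt(frac) * w))
        top = rng.integers(0, h - eh + 1)
        left = rng.integers(0, w - ew + 1)
        arr[top:top + eh, left:left + ew] = rng.random(3)
    return ViewImage(pixels=np.clip(arr, 0.0, 1.0), view_name=image.view_name,
                     specimen_id=image.specimen_id)


# ---------------------------------------------------------------------------
# encoder backbones
# ---------------------------------------------------------------------------


def _init(rng: np.random.Generator, *shape, fan_in: int) -> Tensor:
    t = Tensor(rng.standard_normal(shape) / np.sqrt(fan_in))
    t.requires_grad = True
    return t


def _zeros(*shape) -> Tensor:
    t = Tensor(np.zeros(shape))
    t.requires_grad = True
    return t


class QueryPool:
    """Learnable-query cross-attention pooling of spatial features.

    ``n_queries`` learnable query vectors attend over the P spatial positions
    of a (B, P, d_in) feature map; the per-query outputs are concatenated and
    projected to the embedding dimension D.  With no positional terms the
    result is invariant to the order of spatial positions.
    """

    def __init__(self, d_in: int, d_out: int, n_queries: int,
                 rng: np.random.Generator, d_attn: int | None = None):
        d_attn = d_attn or d_in
        self.d_in, self.d_out, self.n_queries, self.d_attn = d_in, d_out, n_queries, d_attn
        self.queries = _init(rng, n_queries, d_attn, fan_in=d_attn)
        self.w_key = _init(rng, d_in, d_attn, fan_in=d_in)
        self.w_value = _init(rng, d_in, d_attn, fan_in=d_in)
        self.w_out = _init(rng, n_queries * d_attn, d_out, fan_in=n_queries * d_attn)
        self.b_out = _zeros(d_out)

    def parameters(self) -> list[Tensor]:
        return [self.queries, self.w_key, self.w_value, self.w_out, self.b_out]

    def __call__(self, features: Tensor) -> Tensor:
        B, P, _ = features.shape
        keys = features @ self.w_key          # (B, P, d_attn)
        values = features @ self.w_value      # (B, P, d_attn)
        scores = (self.queries @ keys.transpose(0, 2, 1)) / np.sqrt(self.d_attn)
        attn = softmax(scores, axis=-1)       # (B, nq, P)
        pooled = attn @ values                # (B, nq, d_attn)
        flat = pooled.reshape(B, self.n_queries * self.d_attn)
        return flat @ self.w_out + self.b_out

    def flops(self, n_positions: int) -> int:
        P, dq, nq = n_positions, self.d_attn, self.n_queries
        return 2 * (P * self.d_in * dq * 2        # key/value projections
                    + nq * P * dq * 2             # scores + weighted sum
                    + nq * dq * self.d_out)       # output projection


class TinyConvEncoder:
    """The built-in test-scale backbone: three strided convs + query pooling.

    Strides 4/2/2 reduce a (H, W) input to (H/16, W/16) positions with 64
    channels; :class:`QueryPool` then aggregates them into a D-vector.  All
    views share this single parameter set.
    """

    name = "reference-tiny"

    def __init__(self, config: EncoderConfig, rng: np.random.Generator):
        self.config = config
        self.channels = [(3, 16, 4, 4), (16, 32, 2, 2), (32, 64, 2, 2)]
        self.convs = []
        for c_in, c_out, k, _ in self.channels:
            w = _init(rng, c_out, c_in, k, k, fan_in=c_in * k * k)
            b = _zeros(c_out)
            self.convs.append((w, b))
        self.pool = QueryPool(64, config.embedding_dim, config.n_queries, rng)

    def parameters(self) -> list[Tensor]:
        params = []
        for w, b in self.convs:
            params += [w, b]
        return params + self.pool.parameters()

    def __call__(self, x: Tensor) -> Tensor:
        """x: (B, 3, H, W) normalised pixels -> (B, D) embeddings."""
        for (w, b), (_, _, _, stride) in zip(self.convs, self.channels):
            x = conv2d(x, w, b, stride=stride).relu()
        B, C, h, w = x.shape
        feats = x.reshape(B, C, h * w).transpose(0, 2, 1)  # (B, P, C)
        return self.pool(feats)

    def flops_per_view(self) -> int:
        h, w = self.config.input_size
        total = 0
        for c_in, c_out, k, stride in self.channels:
            h, w = (h - k) // stride + 1, (w - k) // stride + 1
            total += 2 * c_in * c_out * k * k * h * w
        return total + self.pool.flops(h * w)


class FeatureMLPEncoder:
    """Shared two-layer MLP over precomputed per-view feature vectors."""

    name = "feature-mlp"

    def __init__(self, config: EncoderConfig, rng: np.random.Generator,
                 input_dim: int = 16, hidden_dim: int = 64):
        self.config = config
        self.input_dim, self.hidden_dim = input_dim, hidden_dim
        self.w1 = _init(rng, input_dim, hidden_dim, fan_in=input_dim)
        self.b1 = _zeros(hidden_dim)
        self.w2 = _init(rng, hidden_dim, config.embedding_dim, fan_in=hidden_dim)
        self.b2 = _zeros(config.embedding_dim)

    def parameters(self) -> list[Tensor]:
        return [self.w1, self.b1, self.w2, self.b2]

    def __call__(self, x: Tensor) -> Tensor:
        """x: (B, input_dim) -> (B, D)."""
        h = (x @ self.w1 + self.b1).relu()
        return h @ self.w2 + self.b2

    def flops_per_view(self) -> int:
        return 2 * (self.input_dim * self.hidden_dim
                    + self.hidden_dim * self.config.embedding_dim)


ENCODER_REGISTRY = {
    "reference-tiny": TinyConvEncoder,
    "feature-mlp": FeatureMLPEncoder,
}


def build_encoder(config: EncoderConfig, rng: np.random.Generator, **kwargs):
    """Instantiate the backbone named in ``config`` from the registry."""
    try:
        cls = ENCODER_REGISTRY[config.backbone_name]
    except KeyError:
        raise ValueError(
            f"unknown backbone {config.backbone_name!r}; "
            f"available: {sorted(ENCODER_REGISTRY)}") from None
    return cls(config, rng, **kwargs)


def _normalise(pixels: np.ndarray, config: EncoderConfig) -> np.ndarray:
    mean = np.asarray(config.norm_mean)[:, None, None]
    std = np.asarray(config.norm_std)[:, None, None]
    chw = np.transpose(pixels, (2, 0, 1))
    return (chw - mean) / std


def encode_view(image: ViewImage, encoder, config: EncoderConfig,
                view_vocabulary: list[str] | None = None,
                view_index: int = 0) -> ViewEmbedding:
    """Embed one preprocessed view with the shared encoder (eval path)."""
    if view_vocabulary is not None and image.view_name not in view_vocabulary:
        raise ValueError(f"unknown view {image.view_name!r}; "
                         f"vocabulary: {view_vocabulary}")
    x = Tensor(_normalise(image.pixels, config)[None])
    v = encoder(x).data[0]
    return ViewEmbedding(v=v, view_index=view_index)
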