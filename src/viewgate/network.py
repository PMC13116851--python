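"""The assembled gated multi-view network.

One shared encoder embeds every view; learnable view-slot positional vectors
turn embeddings into tokens; Hard-Concrete gates scale (and, at zero, mask)
the tokens; a transformer block fuses the survivors; a linear softmax head
classifies the specimen.  A small projection head on the fused vector feeds
the supervised contrastive loss during training and is discarded at
inference.

Training uses stochastic gates sampled from the per-view logits ``alpha``;
evaluation uses the deterministic retention-probability mask with dropped
views never encoded at all (which is what makes the FLOPs of a reduced
configuration ``view_count x per-view cost``).
"""

from __future__ import annotations

import numpy as np

from ._autodiff import Tensor
from .encoder import EncoderConfig, build_encoder
from .fusion import FusionConfig, FusionModule
from .gates import GateConfig, GateState, deterministic_mask, sample_gates_tensor

__all__ = ["MultiViewNetwork"]


class MultiViewNetwork:
    """Encoder + positional table + gates + fusion + heads, as one model.

    Parameters
    ----------
    n_views, n_classes : int
        View vocabulary size and label count.
    encoder_config, fusion_config, gate_config :
        Component configurations (embedding dims must agree).
    input_dim : int, optional
        Per-view feature dimension (feature-mlp backbone only).
    alpha_init : float
        Initial value of every gate logit.
    proj_dim : int
        Output dimension of the contrastive projection head.
    rng : numpy Generator
        Parameter initialisation source.
    encoder : optional
        A pre-trained shared encoder to warm-start from (e.g. the output of
        the single-view stage); freshly initialised when omitted.
    """

    def __init__(self, n_views: int, n_classes: int,
                 encoder_config: EncoderConfig,
                 fusion_config: FusionConfig,
                 gate_config: GateConfig = GateConfig(),
                 input_dim: int | None = None,
                 alpha_init: float = 0.0,
                 proj_dim: int = 16,
                 rng: np.random.Generator | None = None,
                 encoder=None):
        if fusion_config.embedding_dim != encoder_config.embedding_dim:
            raise ValueError("encoder and fusion embedding dims differ")
        rng = rng if rng is not None else np.random.default_rng(0)
        self.n_views, self.n_classes = n_views, n_classes
        self.encoder_config, self.fusion_config = encoder_config, fusion_config
        self.gate_config = gate_config
        if encoder is not None:
            self.encoder = encoder
        else:
            kwargs = {}
            if encoder_config.backbone_name == "feature-mlp":
                kwargs["input_dim"] = int(input_dim)
            self.encoder = build_encoder(encoder_config, rng, **kwargs)
        D = encoder_config.embedding_dim
        self.pe = Tensor(0.02 * rng.standard_normal((n_views, D)))
        self.pe.requires_grad = True
        self.alpha = Tensor(np.full(n_views, float(alpha_init)))
        self.alpha.requires_grad = True
        self.fusion = FusionModule(fusion_config, rng)
        self.w_proj = Tensor(rng.standard_normal((D, proj_dim)) / np.sqrt(D))
        self.w_proj.requires_grad = True
        self.b_proj = Tensor(np.zeros(proj_dim))
        self.b_proj.requires_grad = True

    # -- parameter access ----------------------------------------------------

    def parameters(self) -> list[Tensor]:
        """All trainable tensors, gate logits included."""
        return self.model_parameters() + [self.alpha]

    def model_parameters(self) -> list[Tensor]:
        """Everything except the gate logits (which get their own lr)."""
        return (self.encoder.parameters() + [self.pe]
                + self.fusion.parameters() + [self.w_proj, self.b_proj])

    @property
    def gate_state(self) -> GateState:
        return GateState(alpha=self.alpha.data.copy(), beta=self._beta)

    _beta: float = GateConfig().beta_start

    # -- forward passes ------------------------------------------------------

    def _encode_views(self, X: np.ndarray, view_indices: np.ndarray) -> Tensor:
        """Encode a (B, k, ...) slab of views with the shared encoder.

        Returns (B, k, D) tokens including the positional vectors of the
        given view slots.
        """
        B, k = X.shape[:2]
        if self.encoder_config.backbone_name == "feature-mlp":
            flat = Tensor(X.reshape(B * k, -1))
        else:  # image backbone: (B, k, H, W, 3) -> (B*k, 3, H, W), normalised
            mean = np.asarray(self.encoder_config.norm_mean)
            std = np.asarray(self.encoder_config.norm_std)
            imgs = (X - mean) / std
            flat = Tensor(np.moveaxis(imgs, -1, 2).reshape(
                B * k, 3, X.shape[2], X.shape[3]))
        v = self.encoder(flat)
        D = self.encoder_config.embedding_dim
        tokens = v.reshape(B, k, D) + self.pe[view_indices]
        return tokens

    def forward_train(self, X: np.ndarray, beta: float,
                      rng: np.random.Generator, gated: bool = True,
                      fixed_mask: np.ndarray | None = None):
        """Stochastic training pass over all views.

        One uniform noise draw per view per forward pass (shared across the
        batch).  Returns (probs, projection, z) on the tape.  With
        ``gated=False`` the gates are pinned fully open (the ungated all-view
        fusion model); with ``fixed_mask`` the gates are frozen to that
        binary mask (the hard-selection fine-tuning phase).
        """
        self._beta = float(beta)
        if fixed_mask is not None:
            mask = np.asarray(fixed_mask, dtype=bool)
            if not mask.any():
                mask = mask.copy()
                mask[int(np.argmax(self.alpha.data))] = True
            z = Tensor(mask.astype(np.float64))
        elif gated:
            u = rng.uniform(1e-6, 1.0 - 1e-6, size=self.n_views)
            z = sample_gates_tensor(self.alpha, beta, self.gate_config, u)
        else:
            z = Tensor(np.ones(self.n_views))
        tokens = self._encode_views(X, np.arange(self.n_views))
        gated_tokens = tokens * z.reshape(1, self.n_views, 1)
        mask = z.data > 0
        if not mask.any():
            # all gates sampled shut: keep the least-suppressed view so the
            # fusion stays defined for this step
            mask = np.zeros(self.n_views, dtype=bool)
            mask[int(np.argmax(self.alpha.data))] = True
        fused = self.fusion.fuse(gated_tokens, mask[None, :])
        probs = self.fusion.probabilities(fused)
        proj = fused @ self.w_proj + self.b_proj
        return probs, proj, z

    def forward_eval(self, X: np.ndarray, mask: np.ndarray | None = None) -> np.ndarray:
        """Deterministic pass; only the masked-in views are encoded."""
        if mask is None:
            mask = self.selected_views()
        mask = np.asarray(mask, dtype=bool)
        idx = np.flatnonzero(mask)
        if idx.size == 0:
            raise ValueError("mask retains no views")
        tokens = self._encode_views(X[:, idx], idx)
        fused = self.fusion.fuse(tokens, np.ones(idx.size, dtype=bool)[None, :])
        return self.fusion.probabilities(fused).data

    def selected_views(self) -> np.ndarray:
        """Deterministic binary mask from the current gate state."""
        return deterministic_mask(self.gate_state, self.gate_config)

    def flops_per_view(self) -> float:
        return float(self.encoder.flops_per_view())

    # -- persistence ---------------------------------------------------------

    def state_arrays(self) -> dict[str, np.ndarray]:
        return {f"p{i}": p.data for i, p in enumerate(self.parameters())}

    def save(self, path) -> None:
        np.savez(path, **self.state_arrays(), _beta=np.array(self._beta))

    def load(self, path) -> None:
        blob = np.load(path)
        for i, p in enumerate(self.parameters()):
            arr = blob[f"p{i}"]
            if arr.shape != p.data.shape:
                raise ValueError(f"checkpoint shape mismatch for parameter {i}")
            p.data = arr.astype(np.float64)
        if "_beta" in blob:
            self._beta = float(blob["_beta"])
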