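"""Training orchestration: optimiser, schedules, the two stages, evaluation.

Stage 1 (``train_single_view``) benchmarks each anatomical view on its own:
the shared encoder plus one linear head per view, trained jointly, then
evaluated per view — the strongest view becomes the single-view baseline.
Stage 2 (``train_fusion``) trains the full gated multi-view network with the
compound objective (cross-entropy + supervised contrastive + expected-L0),
annealing the gate temperature each epoch and recording per-view retention
probabilities; the final evaluation uses the deterministic gate mask.

Optimisation is AdamW with a cosine-annealing-with-warm-restarts learning
rate schedule.  Gate logits form their own parameter group: they take a
larger learning rate and no weight decay (decay would drag every logit
toward the 50/50 point regardless of the data).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from ._autodiff import Tensor
from .encoder import EncoderConfig, build_encoder
from .fusion import FusionConfig
from .gates import GateConfig, GateState, anneal_beta, retention_probability
from .losses import (LossConfig, cross_entropy_tensor,
                     supervised_contrastive_tensor)
from .gates import expected_l0, expected_l0_tensor
from .network import MultiViewNetwork
from .synthdata import MultiViewDataset

logger = logging.getLogger(__name__)

__all__ = [
    "TrainConfig",
    "AdamW",
    "cosine_warm_restart_factor",
    "balanced_batches",
    "train_single_view",
    "train_fusion",
    "evaluate",
    "accuracy_pct",
    "round2",
]


def round2(x: float) -> float:
    """Round to 2 decimals, half away from zero (as the report tables do)."""
    return float(Decimal(repr(float(x))).quantize(Decimal("0.01"),
                                                  rounding=ROUND_HALF_UP))


def accuracy_pct(n_correct: int, n_total: int) -> float:
    """Top-1 accuracy as a percentage, 2 decimals."""
    if n_total < 1:
        raise ValueError("empty evaluation set")
    return round2(100.0 * n_correct / n_total)


@dataclass(frozen=True)
class TrainConfig:
    """Optimiser and schedule settings.

    The defaults (lr 1e-6, weight decay 5e-3, 300 fusion epochs, warm
    restarts every 10 epochs doubling each cycle) are the fine-tuning
    settings appropriate to a pretrained production backbone; the synthetic
    desk-scale runs override lr and epoch counts (see
    :mod:`viewgate.estimators`).
    """

    lr: float = 1e-6
    gate_lr: float = 0.05
    weight_decay: float = 5e-3
    epochs_fusion: int = 300
    epochs_single: int = 100
    restart_period: int = 10
    restart_mult: int = 2
    batch_size: int = 32
    input_noise_sd: float = 0.0
    freeze_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self):
        if not self.lr > 0:
            raise ValueError("lr must be positive")
        if self.epochs_fusion < 1 or self.epochs_single < 1:
            raise ValueError("epoch counts must be >= 1")


class AdamW:
    """AdamW over parameter groups (decoupled weight decay).

    A group may set ``adaptive: False`` to get plain SGD instead: the gate
    logits use this, because Adam's per-parameter normalisation would rescale
    the sparsity-penalty gradient to full step size regardless of the weight
    lambda, destroying the trade-off the lambda sweep is meant to trace.
    """

    def __init__(self, groups, betas=(0.9, 0.999), eps=1e-8):
        self.groups = []
        for g in groups:
            params = list(g["params"])
            self.groups.append({
                "params": params,
                "lr": g["lr"],
                "weight_decay": g.get("weight_decay", 0.0),
                "adaptive": g.get("adaptive", True),
                "m": [np.zeros_like(p.data) for p in params],
                "v": [np.zeros_like(p.data) for p in params],
            })
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0

    def zero_grad(self):
        for g in self.groups:
            for p in g["params"]:
                p.grad = None

    def step(self, lr_scale: float = 1.0):
        self.t += 1
        bc1 = 1 - self.b1 ** self.t
        bc2 = 1 - self.b2 ** self.t
        for g in self.groups:
            lr = g["lr"] * lr_scale
            for p, m, v in zip(g["params"], g["m"], g["v"]):
                if p.grad is None:
                    continue
                if not g["adaptive"]:
                    p.data -= lr * (p.grad + g["weight_decay"] * p.data)
                    continue
                m *= self.b1
                m += (1 - self.b1) * p.grad
                v *= self.b2
                v += (1 - self.b2) * p.grad ** 2
                update = (m / bc1) / (np.sqrt(v / bc2) + self.eps)
                p.data -= lr * (update + g["weight_decay"] * p.data)


def cosine_warm_restart_factor(epoch: int, period: int, mult: int = 2) -> float:
    """Cosine-annealing-with-warm-restarts multiplier in (0, 1]."""
    t, T = epoch, period
    while t >= T:
        t -= T
        T *= mult
    return 0.5 * (1.0 + np.cos(np.pi * t / T))


def balanced_batches(labels: np.ndarray, batch_size: int,
                     rng: np.random.Generator):
    """Yield index batches built from same-class pairs.

    Guarantees (class size permitting) at least two specimens of each sampled
    class per batch so the supervised contrastive loss has in-batch
    positives; leftover singletons are appended and simply skipped by the
    loss.
    """
    labels = np.asarray(labels)
    units: list[np.ndarray] = []
    for c in np.unique(labels):
        idx = np.flatnonzero(labels == c)
        rng.shuffle(idx)
        for s in range(0, len(idx) - 1, 2):
            units.append(idx[s:s + 2])
        if len(idx) % 2:
            units.append(idx[-1:])
    order = rng.permutation(len(units))
    per_batch = max(1, batch_size // 2)
    batch: list[np.ndarray] = []
    for k in order:
        batch.append(units[k])
        if len(batch) >= per_batch:
            yield np.concatenate(batch)
            batch = []
    if batch:
        yield np.concatenate(batch)


# ---------------------------------------------------------------------------
# stage 1: single-view benchmarking
# ---------------------------------------------------------------------------


def train_single_view(dataset: MultiViewDataset, config: TrainConfig,
                      encoder_config: EncoderConfig | None = None):
    """Train the shared encoder with one linear head per view; benchmark views.

    Returns ``(encoder, table)`` where ``table`` is a DataFrame with one row
    per view (columns ``view``, ``accuracy``, ``n_correct``, ``n``) on the
    validation split, plus the trained encoder.  The best row is the
    single-view baseline.
    """
    if encoder_config is None:
        encoder_config = EncoderConfig(backbone_name="feature-mlp")
    rng = np.random.default_rng(config.seed)
    V = dataset.n_views
    C = dataset.n_classes
    D = encoder_config.embedding_dim
    kwargs = {}
    if encoder_config.backbone_name == "feature-mlp":
        kwargs["input_dim"] = dataset.X_train.shape[-1]
    encoder = build_encoder(encoder_config, rng, **kwargs)
    heads = []
    for _ in range(V):
        w = Tensor(rng.standard_normal((D, C)) / np.sqrt(D))
        w.requires_grad = True
        b = Tensor(np.zeros(C))
        b.requires_grad = True
        heads.append((w, b))
    params = encoder.parameters() + [p for wb in heads for p in wb]
    opt = AdamW([{"params": params, "lr": config.lr,
                  "weight_decay": config.weight_decay}])
    X, y = dataset.X_train, dataset.y_train
    for epoch in range(config.epochs_single):
        scale = cosine_warm_restart_factor(epoch, config.restart_period,
                                           config.restart_mult)
        for batch in balanced_batches(y, config.batch_size, rng):
            opt.zero_grad()
            Xb = X[batch]
            if config.input_noise_sd > 0:
                Xb = Xb + config.input_noise_sd * rng.standard_normal(Xb.shape)
            emb = _encode_batch(encoder, encoder_config, Xb)  # (B, V, D)
            loss = None
            from ._autodiff import softmax as softmax_t
            for j, (w, b) in enumerate(heads):
                probs = softmax_t(emb[:, j, :] @ w + b, axis=-1)
                ce = cross_entropy_tensor(probs, y[batch])
                loss = ce if loss is None else loss + ce
            (loss / V).backward()
            opt.step(lr_scale=scale)
    rows = []
    emb = _encode_batch(encoder, encoder_config, dataset.X_val).data
    for j in range(V):
        w, b = heads[j]
        logits = emb[:, j, :] @ w.data + b.data
        pred = logits.argmax(axis=1)
        n_correct = int((pred == dataset.y_val).sum())
        rows.append({"view": dataset.view_names[j],
                     "accuracy": accuracy_pct(n_correct, len(dataset.y_val)),
                     "n_correct": n_correct, "n": len(dataset.y_val)})
    table = pd.DataFrame(rows)
    return encoder, table


def _encode_batch(encoder, encoder_config: EncoderConfig, X: np.ndarray) -> Tensor:
    B, V = X.shape[:2]
    if encoder_config.backbone_name == "feature-mlp":
        flat = Tensor(X.reshape(B * V, -1))
    else:
        mean = np.asarray(encoder_config.norm_mean)
        std = np.asarray(encoder_config.norm_std)
        imgs = (X - mean) / std
        flat = Tensor(np.moveaxis(imgs, -1, 2).reshape(B * V, 3,
                                                       X.shape[2], X.shape[3]))
    return encoder(flat).reshape(B, V, encoder_config.embedding_dim)


# ---------------------------------------------------------------------------
# stage 2: gated fusion training
# ---------------------------------------------------------------------------


def train_fusion(dataset: MultiViewDataset, network: MultiViewNetwork,
                 lambda_sparsity: float, config: TrainConfig,
                 loss_config: LossConfig | None = None,
                 gated: bool = True):
    """Train the gated multi-view network with the compound objective.

    Per epoch: anneal the gate temperature, sample gates each forward pass,
    minimise CE + lambda_contrast * SupCon + lambda_sparsity * E[L0], and
    record the loss breakdown plus per-view retention probabilities.  Over
    the last ``freeze_fraction`` of the epochs the gates are frozen to the
    deterministic mask and the surviving configuration is fine-tuned without
    sampling noise or sparsity pressure.  The final evaluation uses the
    deterministic mask with dropped views not encoded.  With ``gated=False``
    the gates stay pinned open throughout — the ungated all-view fusion
    model that serves as the sweep baseline.

    Returns ``(history, gate_state, accuracy)``: a DataFrame with one row per
    epoch, the final :class:`GateState`, and the deterministic-mask Top-1
    validation accuracy (%).
    """
    if loss_config is None:
        loss_config = LossConfig(lambda_sparsity=lambda_sparsity)
    else:
        loss_config = LossConfig(lambda_contrast=loss_config.lambda_contrast,
                                 lambda_sparsity=lambda_sparsity,
                                 tau=loss_config.tau)
    gcfg = network.gate_config
    rng = np.random.default_rng(config.seed)
    opt = AdamW([
        {"params": network.model_parameters(), "lr": config.lr,
         "weight_decay": config.weight_decay},
        {"params": [network.alpha], "lr": config.gate_lr, "weight_decay": 0.0,
         "adaptive": False},
    ])
    X, y = dataset.X_train, dataset.y_train
    records = []
    majority = int(np.bincount(y).argmax())
    epochs = config.epochs_fusion
    # temperature anneals over the sampling phase; the tail fine-tunes the
    # frozen deterministic selection
    n_sample = epochs if not gated else max(
        1, epochs - int(round(epochs * config.freeze_fraction)))
    for epoch in range(epochs):
        frozen = gated and epoch >= n_sample
        beta = anneal_beta(min(epoch, n_sample - 1), n_sample, gcfg)
        scale = cosine_warm_restart_factor(epoch, config.restart_period,
                                           config.restart_mult)
        fixed_mask = network.selected_views() if frozen else None
        sums = {"ce": 0.0, "contrast": 0.0, "l0": 0.0, "total": 0.0}
        n_batches = 0
        for batch in balanced_batches(y, config.batch_size, rng):
            opt.zero_grad()
            Xb = X[batch]
            if config.input_noise_sd > 0:
                # training-time jitter: the feature-space analogue of the
                # image augmentation pipeline
                Xb = Xb + config.input_noise_sd * rng.standard_normal(Xb.shape)
            probs, proj, _ = network.forward_train(Xb, beta, rng, gated=gated,
                                                   fixed_mask=fixed_mask)
            ce = cross_entropy_tensor(probs, y[batch])
            contrast = supervised_contrastive_tensor(proj, y[batch],
                                                     loss_config.tau)
            l0_value = expected_l0(network.gate_state, gcfg)
            loss = ce + loss_config.lambda_contrast * contrast
            if not frozen:
                # the penalty only acts while the gates are still learnable
                loss = loss + loss_config.lambda_sparsity * expected_l0_tensor(
                    network.alpha, beta, gcfg)
            total_value = (float(ce.data)
                           + loss_config.lambda_contrast * float(contrast.data)
                           + loss_config.lambda_sparsity * l0_value)
            if not np.isfinite(total_value):
                logger.error("divergent loss at epoch %d: %r", epoch, sums)
                raise RuntimeError(f"non-finite loss at epoch {epoch}")
            loss.backward()
            opt.step(lr_scale=scale)
            sums["ce"] += float(ce.data)
            sums["contrast"] += float(contrast.data)
            sums["l0"] += l0_value
            sums["total"] += total_value
            n_batches += 1
        probs_now = retention_probability(network.alpha.data, beta, gcfg)
        eval_mask = (network.selected_views() if gated
                     else np.ones(network.n_views, dtype=bool))
        rec = {"epoch": epoch, "beta": beta,
               "lambda_sparsity": loss_config.lambda_sparsity}
        rec.update({k: v / n_batches for k, v in sums.items()})
        rec["val_accuracy"] = evaluate(network, dataset.X_val, dataset.y_val,
                                       eval_mask, fallback_class=majority)
        for name, p in zip(dataset.view_names, probs_now):
            rec[f"retention_{name}"] = p
        records.append(rec)
    history = pd.DataFrame(records)
    state = network.gate_state
    final_mask = (network.selected_views() if gated
                  else np.ones(network.n_views, dtype=bool))
    final_acc = evaluate(network, dataset.X_val, dataset.y_val,
                         final_mask, fallback_class=majority)
    return history, state, final_acc


def evaluate(network: MultiViewNetwork, X: np.ndarray, y: np.ndarray,
             mask: np.ndarray, fallback_class: int | None = None) -> float:
    """Deterministic-mask Top-1 accuracy (%) on a validation set.

    With an all-zero mask there is nothing to fuse; if ``fallback_class`` is
    given, every specimen is assigned that class (the majority-class rate a
    fully suppressed model degenerates to), otherwise this is an error.
    """
    if len(y) == 0:
        raise ValueError("empty validation set")
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        if fallback_class is None:
            raise ValueError("mask retains no views")
        pred = np.full(len(y), fallback_class)
    else:
        probs = network.forward_eval(X, mask)
        pred = probs.argmax(axis=1)
    return accuracy_pct(int((pred == y).sum()), len(y))
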