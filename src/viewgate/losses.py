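"""The compound training objective.

    L_total = L_CE + lambda_contrast * L_contrast + lambda_sparsity * L_L0

``L_CE`` is standard cross-entropy on the class probabilities; ``L_contrast``
is the supervised contrastive loss (cosine similarities at temperature tau;
same-class pairs are positives, anchors with no in-batch positive are skipped)
computed on specimen-level representations to sharpen the separation of
sibling species; ``L_L0`` is the expected number of retained views under the
Hard-Concrete gates (see :mod:`viewgate.gates`), weighted by the sparsity
coefficient swept during Pareto analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from ._autodiff import Tensor, as_tensor

logger = logging.getLogger(__name__)

__all__ = [
    "LossConfig",
    "LossBreakdown",
    "cross_entropy",
    "cross_entropy_tensor",
    "supervised_contrastive",
    "supervised_contrastive_tensor",
    "total_loss",
]

_EPS = 1e-12


@dataclass(frozen=True)
class LossConfig:
    """Weights of the compound objective."""

    lambda_contrast: float = 0.2
    lambda_sparsity: float = 0.0
    tau: float = 0.1

    def __post_init__(self):
        if not self.tau > 0:
            raise ValueError("tau must be positive")
        if self.lambda_contrast < 0 or self.lambda_sparsity < 0:
            raise ValueError("loss weights must be non-negative")


@dataclass
class LossBreakdown:
    """The three component losses and their weighted total."""

    ce: float
    contrast: float
    l0: float
    total: float


def cross_entropy(probabilities: np.ndarray, labels: np.ndarray) -> float:
    """Mean negative log-probability of the true class.

    ``probabilities`` is (B, C) rows summing to 1; zero probabilities at the
    true class are clamped to a small epsilon (and logged) rather than
    producing infinities.
    """
    probs = np.asarray(probabilities, dtype=np.float64)
    labels = np.asarray(labels, dtype=int)
    if probs.ndim == 1:
        probs = probs[None]
        labels = np.atleast_1d(labels)
    true_p = probs[np.arange(len(labels)), labels]
    if np.any(true_p < _EPS):
        logger.warning("cross_entropy: clamping %d zero probabilities",
                       int(np.sum(true_p < _EPS)))
        true_p = np.clip(true_p, _EPS, 1.0)
    return float(-np.mean(np.log(true_p)))


def cross_entropy_tensor(probabilities: Tensor, labels: np.ndarray) -> Tensor:
    """Cross-entropy on the autodiff tape (training path)."""
    labels = np.asarray(labels, dtype=int)
    clipped = probabilities.clip(_EPS, 1.0)
    true_p = clipped[np.arange(len(labels)), labels]
    return -(true_p.log().mean())


def supervised_contrastive_tensor(representations: Tensor, labels: np.ndarray,
                                  tau: float = 0.1) -> Tensor:
    """Supervised contrastive loss on the tape.

    Representations are L2-normalised internally; for each anchor *i* with
    positive set P(i) (same label, not itself):

        -(1/|P(i)|) * sum_{p in P(i)} log( exp(s_ip / tau)
                                           / sum_{a != i} exp(s_ia / tau) )

    averaged over anchors with at least one positive.  Anchors without
    positives are excluded from the mean; if no anchor is eligible the loss
    is zero.
    """
    labels = np.asarray(labels, dtype=int)
    B = len(labels)
    if B < 2:
        raise ValueError("supervised contrastive loss needs a batch of >= 2")
    r = as_tensor(representations)
    norms = ((r * r).sum(axis=1, keepdims=True) + _EPS) ** 0.5
    rn = r / norms
    sims = (rn @ rn.transpose()) / tau                    # (B, B)
    eye = np.eye(B, dtype=bool)
    logits = sims + np.where(eye, -1e9, 0.0)              # exclude self
    shift = np.max(logits.data, axis=1, keepdims=True)    # detached, constant
    log_denom = ((logits - shift).exp().sum(axis=1, keepdims=True)).log() + shift
    log_prob = logits - log_denom
    pos = (labels[:, None] == labels[None, :]) & ~eye
    counts = pos.sum(axis=1)
    eligible = counts > 0
    if not eligible.any():
        return Tensor(0.0)
    safe = np.maximum(counts, 1).astype(float)
    per_anchor = (log_prob * pos.astype(float)).sum(axis=1) / safe
    return -((per_anchor * eligible.astype(float)).sum() / float(eligible.sum()))


def supervised_contrastive(representations: np.ndarray, labels: np.ndarray,
                           tau: float = 0.1) -> float:
    """Numpy-facing wrapper of :func:`supervised_contrastive_tensor`."""
    return float(supervised_contrastive_tensor(
        Tensor(np.asarray(representations, dtype=np.float64)), labels, tau).data)


def total_loss(ce: float, contrast: float, l0: float,
               config: LossConfig) -> LossBreakdown:
    """Combine the components per the compound objective."""
    for name, val in (("ce", ce), ("contrast", contrast), ("l0", l0)):
        if not np.isfinite(val):
            raise ValueError(f"non-finite component {name}={val}")
    total = ce + config.lambda_contrast * contrast + config.lambda_sparsity * l0
    return LossBreakdown(ce=float(ce), contrast=float(contrast), l0=float(l0),
                         total=float(total))
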