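"""Hard-Concrete stochastic gates over anatomical views.

Each view *i* owns a learnable logit ``alpha[i]``.  During training a gate
value ``z_i`` in [0, 1] is sampled from the stretched, clipped binary-concrete
("Hard-Concrete") distribution

    z_i = clip( sigmoid((logit(u) + alpha_i) / beta) * (zeta - gamma) + gamma,
                0, 1 ),        u ~ Uniform(0, 1)

whose stretch parameters ``gamma < 0 < 1 < zeta`` place positive probability
mass at exactly 0 and exactly 1, so views can be switched fully off or on
while the sampler stays differentiable in ``alpha``.  The expected number of
retained views (the relaxed L0 norm) has the closed form

    E[L0] = sum_i sigmoid(alpha_i - beta * log(-gamma / zeta))

which is the sparsity penalty added to the training objective.  The
temperature ``beta`` is annealed towards 0 so the relaxation sharpens as
training proceeds; at test time gates are replaced by a deterministic binary
mask thresholded on the retention probability P(z_i > 0).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._autodiff import Tensor, as_tensor

__all__ = [
    "GateConfig",
    "GateState",
    "GateSample",
    "sample_gates",
    "sample_gates_tensor",
    "retention_probability",
    "expected_l0",
    "expected_l0_tensor",
    "boundary_probabilities",
    "anneal_beta",
    "deterministic_mask",
]


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=np.float64)))


@dataclass(frozen=True)
class GateConfig:
    """Stretch, temperature and selection settings for Hard-Concrete gates.

    Parameters
    ----------
    zeta : float
        Upper stretch bound; must exceed 1 so the pre-clip value can reach 1.
    gamma : float
        Lower stretch bound; must be negative so the pre-clip value can
        reach 0.
    beta_start, beta_end : float
        Temperature annealing endpoints (start >= end > 0).
    selection_threshold : float
        Retention-probability cutoff used by :func:`deterministic_mask`.
    """

    zeta: float = 1.1
    gamma: float = -0.1
    beta_start: float = 0.67
    beta_end: float = 0.1
    selection_threshold: float = 0.5

    def __post_init__(self):
        if not self.gamma < 0:
            raise ValueError(f"gamma must be negative, got {self.gamma}")
        if not self.zeta > 1:
            raise ValueError(f"zeta must exceed 1, got {self.zeta}")
        if not 0 < self.beta_end <= self.beta_start:
            raise ValueError("need 0 < beta_end <= beta_start, got "
                             f"({self.beta_start}, {self.beta_end})")
        if not 0 < self.selection_threshold < 1:
            raise ValueError("selection_threshold must lie in (0, 1)")

    @property
    def log_ratio(self) -> float:
        """log(-gamma / zeta), the shift in the retention probability."""
        return float(np.log(-self.gamma / self.zeta))


@dataclass
class GateState:
    """Learnable per-view logits plus the current temperature."""

    alpha: np.ndarray
    beta: float

    def __post_init__(self):
        self.alpha = np.asarray(self.alpha, dtype=np.float64)
        if self.alpha.ndim != 1 or self.alpha.size < 1:
            raise ValueError("alpha must be a non-empty 1-D vector")
        if not self.beta > 0:
            raise ValueError("beta must be positive")

    @property
    def n_views(self) -> int:
        return int(self.alpha.size)


@dataclass
class GateSample:
    """One draw of the gates: the uniform noise and the gate values."""

    u: np.ndarray
    z: np.ndarray


def _check_noise(u: np.ndarray) -> np.ndarray:
    u = np.asarray(u, dtype=np.float64)
    if np.any(u <= 0.0) or np.any(u >= 1.0):
        raise ValueError("noise components must lie strictly in (0, 1)")
    return u


def sample_gates(state: GateState, config: GateConfig, u: np.ndarray) -> GateSample:
    """Draw gate values from the Hard-Concrete distribution.

    ``u`` supplies the uniform noise (strictly inside (0, 1), one component
    per view), so the draw is a deterministic function of the noise — the
    reparameterisation that lets gradients reach ``alpha``.
    """
    u = _check_noise(u)
    if u.shape != state.alpha.shape:
        raise ValueError(f"noise shape {u.shape} != alpha shape {state.alpha.shape}")
    pre = _sigmoid((np.log(u) - np.log1p(-u) + state.alpha) / state.beta)
    pre = pre * (config.zeta - config.gamma) + config.gamma
    return GateSample(u=u, z=np.clip(pre, 0.0, 1.0))


def sample_gates_tensor(alpha: Tensor, beta: float, config: GateConfig,
                        u: np.ndarray) -> Tensor:
    """Differentiable gate sample on the autodiff tape (training path)."""
    u = _check_noise(u)
    alpha = as_tensor(alpha)
    noise_logit = np.log(u) - np.log1p(-u)
    pre = ((alpha + noise_logit) / beta).sigmoid()
    pre = pre * (config.zeta - config.gamma) + config.gamma
    return pre.clip(0.0, 1.0)


def retention_probability(alpha, beta: float, config: GateConfig):
    """P(z > 0): the probability that a view survives the gate.

    Closed form ``sigmoid(alpha - beta * log(-gamma / zeta))``; strictly
    increasing in ``alpha``.  Accepts scalars or arrays.
    """
    return _sigmoid(np.asarray(alpha, dtype=np.float64) - beta * config.log_ratio)


def expected_l0(state: GateState, config: GateConfig) -> float:
    """Expected number of retained views: sum of retention probabilities."""
    return float(np.sum(retention_probability(state.alpha, state.beta, config)))


def expected_l0_tensor(alpha: Tensor, beta: float, config: GateConfig) -> Tensor:
    """Expected-L0 penalty on the autodiff tape (training path)."""
    return ((as_tensor(alpha) - beta * config.log_ratio).sigmoid()).sum()


def boundary_probabilities(alpha, beta: float, config: GateConfig):
    """(P(z = 0), P(z = 1)) — the point masses of the rectified distribution.

    With the default stretch (zeta=1.1, gamma=-0.1) both interior log-odds
    equal log(11), so at alpha = 0 the two masses coincide.
    """
    if not config.zeta > 1:
        raise ValueError("P(z = 1) undefined for zeta <= 1")
    alpha = np.asarray(alpha, dtype=np.float64)
    p_zero = _sigmoid(beta * config.log_ratio - alpha)
    log_one = float(np.log((1.0 - config.gamma) / (config.zeta - 1.0)))
    p_one = _sigmoid(alpha - beta * log_one)
    return p_zero, p_one


def anneal_beta(epoch: int, total_epochs: int, config: GateConfig) -> float:
    """Linear temperature schedule from beta_start (epoch 0) to beta_end."""
    if total_epochs < 1:
        raise ValueError("total_epochs must be >= 1")
    if not 0 <= epoch < total_epochs:
        raise ValueError(f"epoch {epoch} outside [0, {total_epochs})")
    if total_epochs == 1:
        return config.beta_end
    frac = epoch / (total_epochs - 1)
    return config.beta_start + frac * (config.beta_end - config.beta_start)


def deterministic_mask(state: GateState, config: GateConfig) -> np.ndarray:
    """Binary test-time mask: retain view i iff P(z_i > 0) > threshold."""
    probs = retention_probability(state.alpha, state.beta, config)
    return probs > config.selection_threshold
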