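"""Scikit-learn style estimators over the gated multi-view network.

Three estimators cover the workflow:

* :class:`GatedMultiViewClassifier` — the full model: shared encoder,
  view tokens, Hard-Concrete gates, transformer fusion, compound loss.
  ``X`` is a 3-D array (n_specimens, n_views, feature_dim) in feature mode
  or (n_specimens, n_views, H, W, 3) in image mode.
* :class:`SingleViewBenchmark` — per-view linear-probe accuracies over the
  shared encoder; its best row is the single-view baseline.
* :class:`SparsitySweep` — a GridSearchCV-like meta-estimator that retrains
  the classifier once per sparsity weight, assembles the accuracy-vs-FLOPs
  Pareto table, and selects the recommended minimal-view configuration.

All follow sklearn conventions (``get_params``/``set_params``, fitted
attributes with trailing underscores, ``clone``-ability), so they compose
with sklearn model selection where a 3-D ``X`` is acceptable.

The default optimisation settings here are the desk-scale ones used by the
synthetic studies; production fine-tuning settings live in
:class:`viewgate.training.TrainConfig`.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, clone

from .encoder import EncoderConfig
from .fusion import FusionConfig
from .gates import GateConfig, retention_probability
from .losses import LossConfig
from .network import MultiViewNetwork
from .pareto import pareto_frontier, run_sweep, select_recommended
from .synthdata import MultiViewDataset
from .training import TrainConfig, evaluate, train_fusion, train_single_view

__all__ = ["GatedMultiViewClassifier", "SingleViewBenchmark", "SparsitySweep"]


def _as_dataset(X, y, X_val, y_val, classes) -> MultiViewDataset:
    X = np.asarray(X, dtype=np.float64)
    if X.ndim not in (3, 5):
        raise ValueError("X must be (n, views, features) or (n, views, H, W, 3)")
    if X_val is None:
        X_val, y_val = X, y
    X_val = np.asarray(X_val, dtype=np.float64)
    view_names = [f"view_{j:02d}" for j in range(X.shape[1])]
    mode = "feature" if X.ndim == 3 else "image"
    return MultiViewDataset(
        X_train=X, y_train=np.asarray(y), X_val=X_val, y_val=np.asarray(y_val),
        view_names=view_names, class_names=[str(c) for c in classes],
        mode=mode, informative_views=())


class GatedMultiViewClassifier(ClassifierMixin, BaseEstimator):
    """Gated multi-view classifier with differentiable view selection.

    Parameters mirror the model description: ``lambda_sparsity`` weights the
    expected-L0 view penalty, ``lambda_contrast``/``tau`` the supervised
    contrastive term, ``beta_start``/``beta_end`` the gate temperature
    annealing, ``zeta``/``gamma`` the Hard-Concrete stretch, and
    ``selection_threshold`` the retention-probability cutoff for the
    deterministic test-time view mask.

    Fitted attributes include ``retention_probabilities_`` (per view),
    ``view_mask_`` (the deterministic selection), ``selected_views_``
    (indices), and ``history_`` (per-epoch loss breakdown, temperature and
    retention trajectories).
    """

    def __init__(self, *, embedding_dim=32, n_heads=8, n_layers=1,
                 proj_dim=16,
                 lambda_sparsity=0.0, lambda_contrast=0.2, tau=0.1,
                 epochs=200, batch_size=60, lr=5e-3, gate_lr=0.3,
                 weight_decay=1e-4, restart_period=200, restart_mult=2,
                 feature_noise=0.8, freeze_fraction=0.2,
                 beta_start=0.67, beta_end=0.1, zeta=1.1, gamma=-0.1,
                 selection_threshold=0.5, alpha_init=0.0,
                 gates_enabled=True, encoder=None,
                 backbone="feature-mlp", input_size=(64, 64),
                 random_state=0):
        self.embedding_dim = embedding_dim
        self.n_heads = n_heads
        self.n_layers = n_layers
        self.proj_dim = proj_dim
        self.lambda_sparsity = lambda_sparsity
        self.lambda_contrast = lambda_contrast
        self.tau = tau
        self.epochs = epochs
        self.batch_size = batch_size
        self.lr = lr
        self.gate_lr = gate_lr
        self.weight_decay = weight_decay
        self.restart_period = restart_period
        self.restart_mult = restart_mult
        self.feature_noise = feature_noise
        self.freeze_fraction = freeze_fraction
        self.beta_start = beta_start
        self.beta_end = beta_end
        self.zeta = zeta
        self.gamma = gamma
        self.selection_threshold = selection_threshold
        self.alpha_init = alpha_init
        self.gates_enabled = gates_enabled
        self.encoder = encoder
        self.backbone = backbone
        self.input_size = input_size
        self.random_state = random_state

    # -- config assembly -----------------------------------------------------

    def _gate_config(self) -> GateConfig:
        return GateConfig(zeta=self.zeta, gamma=self.gamma,
                          beta_start=self.beta_start, beta_end=self.beta_end,
                          selection_threshold=self.selection_threshold)

    def _train_config(self) -> TrainConfig:
        return TrainConfig(lr=self.lr, gate_lr=self.gate_lr,
                           weight_decay=self.weight_decay,
                           epochs_fusion=self.epochs,
                           epochs_single=self.epochs,
                           restart_period=self.restart_period,
                           restart_mult=self.restart_mult,
                           batch_size=self.batch_size,
                           input_noise_sd=self.feature_noise,
                           freeze_fraction=self.freeze_fraction,
                           seed=self.random_state)

    def _encoder_config(self) -> EncoderConfig:
        return EncoderConfig(backbone_name=self.backbone,
                             embedding_dim=self.embedding_dim,
                             input_size=tuple(self.input_size))

    # -- sklearn API ---------------------------------------------------------

    def fit(self, X, y, X_val=None, y_val=None):
        """Train on (X, y); optional (X_val, y_val) drive the per-epoch
        validation accuracies recorded in ``history_``."""
        y = np.asarray(y)
        self.classes_, y_enc = np.unique(y, return_inverse=True)
        if len(self.classes_) < 2:
            raise ValueError("need at least 2 classes")
        y_val_enc = None
        if y_val is not None:
            y_val_enc = np.searchsorted(self.classes_, np.asarray(y_val))
        dataset = _as_dataset(X, y_enc, X_val, y_val_enc, self.classes_)
        self.n_views_ = dataset.n_views
        rng = np.random.default_rng(self.random_state)
        fusion_cfg = FusionConfig(n_heads=self.n_heads, n_layers=self.n_layers,
                                  embedding_dim=self.embedding_dim,
                                  n_classes=len(self.classes_))
        input_dim = dataset.X_train.shape[-1] if dataset.mode == "feature" else None
        self.network_ = MultiViewNetwork(
            n_views=self.n_views_, n_classes=len(self.classes_),
            encoder_config=self._encoder_config(), fusion_config=fusion_cfg,
            gate_config=self._gate_config(), input_dim=input_dim,
            alpha_init=self.alpha_init, proj_dim=self.proj_dim, rng=rng,
            encoder=self.encoder)
        loss_cfg = LossConfig(lambda_contrast=self.lambda_contrast,
                              lambda_sparsity=self.lambda_sparsity,
                              tau=self.tau)
        self.history_, self.gate_state_, self.val_accuracy_ = train_fusion(
            dataset, self.network_, self.lambda_sparsity,
            self._train_config(), loss_cfg, gated=self.gates_enabled)
        self.retention_probabilities_ = retention_probability(
            self.gate_state_.alpha, self.gate_state_.beta, self._gate_config())
        self.view_mask_ = (self.network_.selected_views()
                           if self.gates_enabled
                           else np.ones(self.n_views_, dtype=bool))
        self.selected_views_ = np.flatnonzero(self.view_mask_)
        self.majority_class_ = int(np.bincount(y_enc).argmax())
        self.per_view_flops_ = self.network_.flops_per_view()
        return self

    def predict_proba(self, X):
        """Class probabilities using the deterministic view mask; a fully
        suppressed model degenerates to certainty on the majority class."""
        X = np.asarray(X, dtype=np.float64)
        if not hasattr(self, "network_"):
            raise RuntimeError("estimator is not fitted")
        if not self.view_mask_.any():
            probs = np.zeros((len(X), len(self.classes_)))
            probs[:, self.majority_class_] = 1.0
            return probs
        return self.network_.forward_eval(X, self.view_mask_)

    def predict(self, X):
        return self.classes_[self.predict_proba(X).argmax(axis=1)]

    def accuracy_pct(self, X, y) -> float:
        """Top-1 accuracy as a 2-decimal percentage (the reporting metric)."""
        y_enc = np.searchsorted(self.classes_, np.asarray(y))
        return evaluate(self.network_, np.asarray(X, dtype=np.float64),
                        y_enc, self.view_mask_,
                        fallback_class=self.majority_class_)


class SingleViewBenchmark(BaseEstimator):
    """Per-view linear-probe benchmark over the shared encoder.

    ``fit`` trains the shared encoder with one linear head per view and
    evaluates each view alone; ``per_view_accuracy_`` has one row per view
    and ``best_view_``/``best_accuracy_`` identify the single-view baseline.
    """

    def __init__(self, *, embedding_dim=32, epochs=150, batch_size=60,
                 lr=5e-3, weight_decay=1e-4, restart_period=150,
                 restart_mult=2, feature_noise=0.8,
                 backbone="feature-mlp", input_size=(64, 64),
                 random_state=0):
        self.embedding_dim = embedding_dim
        self.epochs = epochs
        self.batch_size = batch_size
        self.lr = lr
        self.weight_decay = weight_decay
        self.restart_period = restart_period
        self.restart_mult = restart_mult
        self.feature_noise = feature_noise
        self.backbone = backbone
        self.input_size = input_size
        self.random_state = random_state

    def fit(self, X, y, X_val=None, y_val=None):
        y = np.asarray(y)
        self.classes_, y_enc = np.unique(y, return_inverse=True)
        y_val_enc = None
        if y_val is not None:
            y_val_enc = np.searchsorted(self.classes_, np.asarray(y_val))
        dataset = _as_dataset(X, y_enc, X_val, y_val_enc, self.classes_)
        config = TrainConfig(lr=self.lr,
                             weight_decay=self.weight_decay,
                             epochs_fusion=1, epochs_single=self.epochs,
                             restart_period=self.restart_period,
                             restart_mult=self.restart_mult,
                             input_noise_sd=self.feature_noise,
                             batch_size=self.batch_size,
                             seed=self.random_state)
        enc_cfg = EncoderConfig(backbone_name=self.backbone,
                                embedding_dim=self.embedding_dim,
                                input_size=tuple(self.input_size))
        self.encoder_, self.per_view_accuracy_ = train_single_view(
            dataset, config, enc_cfg)
        best = self.per_view_accuracy_["accuracy"].idxmax()
        self.best_view_ = self.per_view_accuracy_.loc[best, "view"]
        self.best_accuracy_ = float(self.per_view_accuracy_.loc[best, "accuracy"])
        return self


class SparsitySweep(BaseEstimator):
    """Sweep the sparsity weight, build the Pareto table, pick the
    recommended configuration.

    One independent, freshly initialised training run per lambda in
    ``lambda_grid`` (plus the lambda = 0 all-view baseline), all under the
    same seed policy.  Fitted attributes: ``table_`` (the
    :class:`~viewgate.pareto.ParetoTable` with labels), ``dataframe_`` (the
    seven-column report table), ``recommended_``, and ``frontier_``.
    """

    def __init__(self, estimator=None, *,
                 lambda_grid=(0.1, 0.2, 0.3, 0.4, 0.5),
                 margin_pp=1.0, random_state=0):
        self.estimator = estimator
        self.lambda_grid = lambda_grid
        self.margin_pp = margin_pp
        self.random_state = random_state

    def fit(self, X, y, X_val=None, y_val=None):
        from .pareto import table_to_dataframe

        proto = (self.estimator if self.estimator is not None
                 else GatedMultiViewClassifier())
        X = np.asarray(X, dtype=np.float64)
        view_names = [f"view_{j:02d}" for j in range(X.shape[1])]
        if X_val is None:
            X_val, y_val = X, y
        self.estimators_ = {}

        def trainer(lam):
            est = clone(proto)
            # the lambda = 0 record is the all-view baseline: the ungated
            # fusion model, every view active in training and evaluation
            est.set_params(lambda_sparsity=lam, random_state=self.random_state,
                           gates_enabled=lam > 0.0)
            est.fit(X, y, X_val=X_val, y_val=y_val)
            self.estimators_[lam] = est
            acc = est.accuracy_pct(X_val, y_val)
            retained = tuple(view_names[j] for j in est.selected_views_)
            return acc, retained

        # per-view cost follows from the encoder geometry alone
        from .encoder import build_encoder

        enc_cfg = proto._encoder_config()
        kwargs = {"input_dim": X.shape[-1]} if X.ndim == 3 else {}
        probe_encoder = build_encoder(enc_cfg, np.random.default_rng(0), **kwargs)
        self.per_view_flops_ = float(probe_encoder.flops_per_view()) / 1e9  # G

        self.table_ = run_sweep(list(self.lambda_grid), trainer, view_names,
                                per_view_flops=self.per_view_flops_,
                                margin_pp=self.margin_pp)
        self.dataframe_ = table_to_dataframe(self.table_)
        self.recommended_ = select_recommended(self.table_, self.margin_pp)
        self.frontier_ = pareto_frontier(self.table_.ok_records())
        return self
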