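"""Training orchestration: schedules, batching, metrics, the two stages."""

import numpy as np
import pandas as pd
import pytest

from viewgate.encoder import EncoderConfig
from viewgate.estimators import GatedMultiViewClassifier
from viewgate.synthdata import SyntheticSpec, generate
from viewgate.training import (TrainConfig, accuracy_pct, balanced_batches,
                               cosine_warm_restart_factor, evaluate, round2,
                               train_fusion, train_single_view)


class TestMetrics:
    @pytest.mark.parametrize("correct,total,expected", [
        (108, 108, 100.00),
        (93, 108, 86.11),
        (90, 108, 83.33),
        (1, 3, 33.33),
    ])
    def test_accuracy_percentage_rounding(self, correct, total, expected):
        assert accuracy_pct(correct, total) == expected

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            accuracy_pct(0, 0)

    def test_round2_half_up(self):
        assert round2(7.06875) == 7.07
        assert round2(0.125) == 0.13
        assert round2(37.485) == 37.49


class TestSchedules:
    def test_cosine_restart_boundaries(self):
        assert cosine_warm_restart_factor(0, 10) == pytest.approx(1.0)
        # just before the first restart the factor is near its minimum
        assert cosine_warm_restart_factor(9, 10) < 0.05
        # the restart resets the factor to 1
        assert cosine_warm_restart_factor(10, 10) == pytest.approx(1.0)

    def test_cycle_lengths_double(self):
        # second cycle spans epochs 10..29 with multiplier 2
        assert cosine_warm_restart_factor(20, 10, 2) == pytest.approx(0.5)


class TestBalancedBatches:
    def test_batches_have_in_class_pairs(self, rng):
        labels = np.repeat(np.arange(5), 8)
        for batch in balanced_batches(labels, 20, rng):
            vals, counts = np.unique(labels[batch], return_counts=True)
            # every class present in a full batch comes at least twice
            if len(batch) >= 20:
                assert counts.min() >= 2

    def test_covers_every_sample_exactly_once(self, rng):
        labels = np.repeat(np.arange(4), 7)  # odd class sizes
        seen = np.concatenate(list(balanced_batches(labels, 12, rng)))
        assert sorted(seen.tolist()) == list(range(len(labels)))

    def test_config_validation(self):
        with pytest.raises(ValueError):
            TrainConfig(lr=0.0)
        with pytest.raises(ValueError):
            TrainConfig(epochs_fusion=0)


@pytest.fixture(scope="module")
def small_run():
    """One short fusion training shared by the reproducibility tests."""
    ds = generate(SyntheticSpec(n_classes=4, n_views=5,
                                informative_views=(1, 3), n_train=80,
                                n_val=24, seed=7))
    est = GatedMultiViewClassifier(epochs=25, random_state=11)
    est.fit(ds.X_train, ds.y_train, X_val=ds.X_val, y_val=ds.y_val)
    return ds, est


class TestTrainFusion:
    def test_history_one_row_per_epoch(self, small_run):
        _, est = small_run
        assert len(est.history_) == 25
        assert est.history_["epoch"].tolist() == list(range(25))

    def test_temperature_annealed_across_history(self, small_run):
        _, est = small_run
        beta = est.history_["beta"].to_numpy()
        assert beta[0] == pytest.approx(0.67)
        assert beta[-1] == pytest.approx(0.1)
        assert np.all(np.diff(beta) <= 0)

    def test_identical_seed_reproduces_history(self, small_run):
        ds, est = small_run
        est2 = GatedMultiViewClassifier(epochs=25, random_state=11)
        est2.fit(ds.X_train, ds.y_train, X_val=ds.X_val, y_val=ds.y_val)
        pd.testing.assert_frame_equal(est.history_, est2.history_)
        assert np.array_equal(est.gate_state_.alpha, est2.gate_state_.alpha)

    def test_no_sparsity_keeps_informative_views_open(self, small_run):
        ds, est = small_run
        # informative views must not collapse toward zero retention
        assert est.retention_probabilities_[[1, 3]].min() > 0.5

    def test_extreme_sparsity_suppresses_everything(self, small_run):
        ds, _ = small_run
        est = GatedMultiViewClassifier(epochs=25, lambda_sparsity=50.0,
                                       random_state=11)
        est.fit(ds.X_train, ds.y_train, X_val=ds.X_val, y_val=ds.y_val)
        assert est.view_mask_.sum() == 0
        # evaluation degenerates to the majority-class rate
        majority_rate = accuracy_pct(
            int(np.max(np.bincount(ds.y_val))), len(ds.y_val))
        assert est.val_accuracy_ == majority_rate


class TestEndToEndGradients:
    def test_one_backward_pass_reaches_every_parameter_group(self, rng):
        """Classification + contrastive + sparsity gradients flow to the gate
        logits, positional table, shared encoder and fusion block at once."""
        from viewgate.encoder import EncoderConfig
        from viewgate.fusion import FusionConfig
        from viewgate.gates import expected_l0_tensor
        from viewgate.losses import (cross_entropy_tensor,
                                     supervised_contrastive_tensor)
        from viewgate.network import MultiViewNetwork

        net = MultiViewNetwork(
            n_views=4, n_classes=3,
            encoder_config=EncoderConfig(backbone_name="feature-mlp"),
            fusion_config=FusionConfig(embedding_dim=32, n_classes=3),
            input_dim=6, rng=rng)
        X = rng.standard_normal((9, 4, 6))
        y = np.arange(9) % 3
        probs, proj, _ = net.forward_train(X, beta=0.67,
                                           rng=np.random.default_rng(0))
        loss = (cross_entropy_tensor(probs, y)
                + 0.2 * supervised_contrastive_tensor(proj, y, 0.1)
                + 0.3 * expected_l0_tensor(net.alpha, 0.67, net.gate_config))
        loss.backward()
        assert net.alpha.grad is not None and np.any(net.alpha.grad != 0)
        assert net.pe.grad is not None and np.any(net.pe.grad != 0)
        assert np.any(net.encoder.w1.grad != 0)
        assert np.any(net.fusion.layers[0]["wq"].grad != 0)
        assert np.any(net.fusion.w_cls.grad != 0)


class TestEvaluate:
    def test_empty_validation_rejected(self, small_run):
        ds, est = small_run
        with pytest.raises(ValueError):
            evaluate(est.network_, ds.X_val[:0], ds.y_val[:0], est.view_mask_)

    def test_empty_mask_without_fallback_rejected(self, small_run):
        ds, est = small_run
        with pytest.raises(ValueError):
            evaluate(est.network_, ds.X_val, ds.y_val,
                     np.zeros(5, dtype=bool))

    def test_accuracy_within_bounds(self, small_run):
        ds, est = small_run
        acc = evaluate(est.network_, ds.X_val, ds.y_val, est.view_mask_)
        assert 0.0 <= acc <= 100.0


class TestTrainSingleView:
    def test_single_informative_view_wins(self):
        spec = SyntheticSpec(n_classes=3, n_views=4, informative_views=(2,),
                             n_train=60, n_val=24, seed=5)
        ds = generate(spec)
        config = TrainConfig(lr=5e-3, epochs_single=40, batch_size=30,
                             weight_decay=1e-4, restart_period=40, seed=5)
        _, table = train_single_view(
            ds, config, EncoderConfig(backbone_name="feature-mlp"))
        assert len(table) == 4
        assert int(table["accuracy"].idxmax()) == 2

    def test_one_class_degenerates_to_perfect(self):
        # single-species survey: every view trivially scores 100
        ds = generate(SyntheticSpec(n_classes=2, n_views=3,
                                    informative_views=(0,), n_train=20,
                                    n_val=10, seed=1))
        ds.y_train[:] = 0
        ds.y_val[:] = 0
        config = TrainConfig(lr=5e-3, epochs_single=5, batch_size=10,
                             restart_period=10, seed=1)
        _, table = train_single_view(
            ds, config, EncoderConfig(backbone_name="feature-mlp"))
        assert (table["accuracy"] == 100.00).all()
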