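"""Hard-Concrete gate distribution: closed forms, sampling, annealing."""

import numpy as np
import pytest

from viewgate._autodiff import Tensor
from viewgate.gates import (GateConfig, GateState, anneal_beta,
                            boundary_probabilities, deterministic_mask,
                            expected_l0, expected_l0_tensor,
                            retention_probability, sample_gates,
                            sample_gates_tensor)

CFG = GateConfig()


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


class TestConfig:
    @pytest.mark.parametrize("kwargs", [
        {"gamma": 0.0}, {"gamma": 0.1}, {"zeta": 1.0}, {"zeta": 0.9},
        {"beta_end": 0.0}, {"beta_start": 0.05, "beta_end": 0.1},
        {"selection_threshold": 0.0}, {"selection_threshold": 1.0},
    ])
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            GateConfig(**kwargs)

    def test_state_validation(self):
        with pytest.raises(ValueError):
            GateState(alpha=np.zeros(0), beta=0.5)
        with pytest.raises(ValueError):
            GateState(alpha=np.zeros(3), beta=0.0)


class TestSampling:
    def test_symmetric_point_gives_half(self):
        # alpha=0, u=0.5: sigma(0)*1.2 - 0.1 = 0.5, no clipping
        s = sample_gates(GateState(alpha=np.zeros(1), beta=0.67), CFG,
                         np.array([0.5]))
        assert s.z[0] == pytest.approx(0.5)

    def test_strongly_negative_logit_clips_to_zero(self):
        s = sample_gates(GateState(alpha=np.array([-5.0]), beta=0.67), CFG,
                         np.array([0.5]))
        assert s.z[0] == 0.0

    def test_strongly_positive_logit_clips_to_one(self):
        s = sample_gates(GateState(alpha=np.array([10.0]), beta=0.67), CFG,
                         np.array([0.5]))
        assert s.z[0] == 1.0

    @pytest.mark.parametrize("bad", [0.0, 1.0])
    def test_boundary_noise_rejected(self, bad):
        with pytest.raises(ValueError):
            sample_gates(GateState(alpha=np.zeros(1), beta=0.5), CFG,
                         np.array([bad]))

    def test_samples_always_in_unit_interval(self, rng):
        st = GateState(alpha=rng.normal(size=50) * 3, beta=0.3)
        s = sample_gates(st, CFG, rng.uniform(1e-9, 1 - 1e-9, 50))
        assert np.all(s.z >= 0) and np.all(s.z <= 1)

    def test_near_degenerate_stretch_has_no_boundary_mass(self, rng):
        # gamma -> 0, zeta -> 1: a plain binary concrete, z strictly interior
        cfg = GateConfig(zeta=1 + 1e-12, gamma=-1e-12)
        st = GateState(alpha=np.zeros(1000), beta=0.67)
        s = sample_gates(st, cfg, rng.uniform(1e-6, 1 - 1e-6, 1000))
        assert np.all((s.z > 0) & (s.z < 1))

    def test_tensor_sampler_matches_numpy_and_is_differentiable(self, rng):
        alpha = rng.normal(size=6)
        u = rng.uniform(0.01, 0.99, 6)
        a = Tensor(alpha.copy())
        a.requires_grad = True
        z_t = sample_gates_tensor(a, 0.4, CFG, u)
        z_np = sample_gates(GateState(alpha=alpha, beta=0.4), CFG, u).z
        assert np.allclose(z_t.data, z_np)
        z_t.sum().backward()
        interior = (z_np > 0) & (z_np < 1)
        assert np.all(a.grad[interior] != 0)
        assert np.all(a.grad[~interior] == 0)


class TestClosedForms:
    def test_retention_at_origin(self):
        assert retention_probability(0.0, 0.67, CFG) == pytest.approx(
            _sigmoid(0.67 * np.log(11.0)), abs=1e-12)
        assert retention_probability(0.0, 0.67, CFG) == pytest.approx(0.8330,
                                                                      abs=5e-4)

    def test_retention_limits(self):
        assert retention_probability(-80.0, 0.67, CFG) == pytest.approx(0.0)
        assert retention_probability(80.0, 0.67, CFG) == pytest.approx(1.0)
        assert retention_probability(0.0, 0.0, CFG) == pytest.approx(0.5)

    def test_retention_monotone_in_alpha_and_beta(self):
        alphas = np.linspace(-4, 4, 41)
        p = retention_probability(alphas, 0.5, CFG)
        assert np.all(np.diff(p) > 0)
        # for alpha < 0, shrinking beta moves retention away from 0.5 downward,
        # i.e. retention increases with beta toward 0.5
        betas = np.linspace(0.05, 0.67, 20)
        p_neg = np.array([retention_probability(-2.0, b, CFG) for b in betas])
        assert np.all(np.diff(p_neg) > 0) and np.all(p_neg < 0.5)

    def test_expected_l0_is_sum_of_retentions(self, rng):
        st = GateState(alpha=rng.normal(size=8), beta=0.4)
        assert expected_l0(st, CFG) == pytest.approx(
            np.sum(retention_probability(st.alpha, st.beta, CFG)))

    def test_expected_l0_at_origin_default_temperature(self):
        st = GateState(alpha=np.zeros(8), beta=0.67)
        assert expected_l0(st, CFG) == pytest.approx(8 * 0.8330, abs=5e-3)

    def test_expected_l0_vanishes_for_suppressed_gates(self):
        st = GateState(alpha=np.full(1, -60.0), beta=0.3)
        assert expected_l0(st, CFG) == pytest.approx(0.0, abs=1e-12)

    def test_expected_l0_gradient_is_sigmoid_derivative(self):
        alpha = np.array([0.3, -1.2, 0.7])
        beta = 0.5
        a = Tensor(alpha.copy())
        a.requires_grad = True
        expected_l0_tensor(a, beta, CFG).backward()
        arg = alpha - beta * CFG.log_ratio
        expected = _sigmoid(arg) * (1 - _sigmoid(arg))
        assert np.allclose(a.grad, expected, atol=1e-10)

    def test_boundary_probabilities_at_origin_coincide(self):
        p0, p1 = boundary_probabilities(0.0, 0.67, CFG)
        assert p0 == pytest.approx(p1, abs=1e-12)
        assert p0 == pytest.approx(0.1670, abs=5e-4)

    def test_boundary_complement_identity(self, rng):
        alphas = rng.normal(size=20) * 3
        p0, _ = boundary_probabilities(alphas, 0.4, CFG)
        assert np.allclose(p0 + retention_probability(alphas, 0.4, CFG), 1.0)

    def test_large_alpha_boundary(self):
        p0, p1 = boundary_probabilities(10.0, 0.67, CFG)
        assert p0 == pytest.approx(0.0, abs=1e-4)
        assert p1 > 0.99

    def test_p_one_undefined_below_stretch(self):
        cfg = GateConfig(zeta=1.5, gamma=-0.1)
        object.__setattr__(cfg, "zeta", 0.99)  # corrupt past validation
        with pytest.raises(ValueError):
            boundary_probabilities(0.0, 0.5, cfg)


class TestMonteCarlo:
    @pytest.mark.parametrize("alpha", [-3.0, -1.0, 0.0, 1.0, 3.0])
    @pytest.mark.parametrize("beta", [0.67, 0.3, 0.1])
    def test_empirical_masses_match_closed_forms(self, alpha, beta):
        n = 100_000
        rng = np.random.default_rng(int(1000 * (alpha + 10) + 1e6 * beta))
        st = GateState(alpha=np.full(n, alpha), beta=beta)
        z = sample_gates(st, CFG, rng.uniform(1e-12, 1 - 1e-12, n)).z
        p0, p1 = boundary_probabilities(alpha, beta, CFG)
        p_pos = retention_probability(alpha, beta, CFG)
        for frac, p in ((np.mean(z == 0), p0), (np.mean(z == 1), p1),
                        (np.mean(z > 0), p_pos)):
            se = max(np.sqrt(p * (1 - p) / n), 1e-9)
            assert abs(frac - p) < 3 * se + 1e-6


class TestAnnealing:
    def test_endpoints(self):
        assert anneal_beta(0, 300, CFG) == pytest.approx(0.67)
        assert anneal_beta(299, 300, CFG) == pytest.approx(0.1)

    def test_linear_midpoint(self):
        assert anneal_beta(1, 3, CFG) == pytest.approx(0.385)

    def test_monotone_nonincreasing(self):
        vals = [anneal_beta(e, 50, CFG) for e in range(50)]
        assert np.all(np.diff(vals) <= 0)

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            anneal_beta(0, 0, CFG)
        with pytest.raises(ValueError):
            anneal_beta(5, 5, CFG)


class TestDeterministicMask:
    def test_all_suppressed_gives_empty_mask(self):
        st = GateState(alpha=np.full(6, -40.0), beta=0.1)
        assert deterministic_mask(st, CFG).sum() == 0

    def test_split_logits(self):
        st = GateState(alpha=np.array([5.0, -5.0]), beta=0.1)
        assert deterministic_mask(st, CFG).tolist() == [True, False]

    def test_origin_retained_at_default_threshold(self):
        st = GateState(alpha=np.zeros(3), beta=0.67)
        assert deterministic_mask(st, CFG).all()  # 0.8330 > 0.5
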