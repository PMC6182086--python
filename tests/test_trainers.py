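"""Learning rules: objectives, gradients, eligibility traces, constraints."""

import numpy as np
import pytest

from rnnplast.networks import (Architecture, InitSpec, default_architecture,
                               default_init, init_parameters, simulate_batch)
from rnnplast.presets import scaled_task_config, train_family
from rnnplast.tasks import make_batch
from rnnplast.trainers import (EligibilityState, HFLossSpec, PycogLossSpec,
                               PyrlSpec, RHebbConfig, backward_leaky, hf_loss,
                               project_dale, pycog_loss, pyrl_train,
                               rhebb_accumulate, rhebb_apply, sgd_train)
from rnnplast.trainers.sgd import _batch_targets
from rnnplast.trainers.pyrl import gru_forward, gru_backward


class TestRHebbRule:
    def test_single_entry_cubed(self):
        st = EligibilityState.zeros(2)
        st.x_bar[:] = 0.0
        cfg = RHebbConfig()
        rhebb_accumulate(st, np.array([1.0, 0.0]), np.array([2.0, 2.0]), cfg)
        assert st.e[0, 0] == 8.0  # (1 * 2)^3
        assert st.e[0, 1] == 0.0  # presynaptic rate 0 -> no change

    def test_zero_presynaptic_rate_leaves_trace(self):
        st = EligibilityState.zeros(3)
        e0 = st.e.copy()
        rhebb_accumulate(st, np.zeros(3), np.ones(3), RHebbConfig())
        assert np.array_equal(st.e, e0)

    def test_trace_matches_bruteforce_sum_of_cubes(self):
        # 20 random steps on a 5-unit network vs a per-synapse loop
        rng = np.random.default_rng(0)
        cfg = RHebbConfig()
        st = EligibilityState.zeros(5)
        expected = np.zeros((5, 5))
        for _ in range(20):
            r_prev = rng.normal(size=5)
            x = rng.normal(size=5)
            st.x_bar = rng.normal(size=5)
            for i in range(5):
                for j in range(5):
                    expected[i, j] += (r_prev[j] * (x[i] - st.x_bar[i])) ** 3
            rhebb_accumulate(st, r_prev, x, cfg)
        assert np.allclose(st.e, expected, atol=1e-10)

    def test_apply_arithmetic(self):
        from rnnplast.networks import NetworkParameters
        p = NetworkParameters(np.zeros((1, 1)), np.zeros((1, 4)), np.zeros(1))
        st = EligibilityState.zeros(1)
        st.e[0, 0] = 8.0
        cfg = RHebbConfig(eta=0.1, max_dw=None)
        rhebb_apply(p, st, R=0.0, config=cfg, condition=("c",))  # sets baseline
        st.R_bar[("c",)] = -0.5  # so R - Rbar = 0.5 next trial
        rhebb_apply(p, st, R=0.0, config=cfg, condition=("c",))
        assert np.isclose(p.W_rec[0, 0], 0.4)  # 0.1 * 8 * 0.5

    def test_reward_at_baseline_leaves_weights(self):
        from rnnplast.networks import NetworkParameters
        p = NetworkParameters(np.ones((2, 2)), np.zeros((2, 4)), np.zeros(2))
        st = EligibilityState.zeros(2)
        st.e[:] = 5.0
        cfg = RHebbConfig()
        rhebb_apply(p, st, R=-1.0, config=cfg, condition=("c",))
        rhebb_apply(p, st, R=-1.0, config=cfg, condition=("c",))  # R == Rbar
        assert np.array_equal(p.W_rec, np.ones((2, 2)))

    def test_negative_reward_error_flips_update_sign(self):
        from rnnplast.networks import NetworkParameters
        p = NetworkParameters(np.zeros((1, 1)), np.zeros((1, 4)), np.zeros(1))
        st = EligibilityState.zeros(1)
        st.e[0, 0] = 8.0
        cfg = RHebbConfig(eta=0.1, max_dw=None)
        st.R_bar[("c",)] = 0.0
        rhebb_apply(p, st, R=-1.0, config=cfg, condition=("c",))
        assert p.W_rec[0, 0] < 0  # e > 0 and R < Rbar

    def test_nonfinite_reward_rejected(self):
        from rnnplast.networks import NetworkParameters
        p = NetworkParameters(np.zeros((1, 1)), np.zeros((1, 4)), np.zeros(1))
        with pytest.raises(FloatingPointError):
            rhebb_apply(p, EligibilityState.zeros(1), float("nan"),
                        RHebbConfig())

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            RHebbConfig(eta=-1.0)
        with pytest.raises(ValueError):
            RHebbConfig(superlinear_exponent=2)

    def test_eta_zero_training_is_noop(self):
        from rnnplast.trainers import rhebb_train
        arch = default_architecture("rhebb", 12)
        p = init_parameters(arch, default_init("rhebb", arch),
                            np.random.default_rng(0))
        W0 = p.W_rec.copy()
        cfg = RHebbConfig(eta=0.0, n_trials=20, eval_every=20, n_validation=20)
        rec = rhebb_train(p, arch, scaled_task_config("rhebb", seed=0), cfg,
                          np.random.default_rng(0))
        assert np.array_equal(rec.W_last.W_rec, W0)

    def test_zero_exploration_rejected(self):
        from rnnplast.trainers import rhebb_train
        arch = default_architecture("rhebb", 8)
        arch = Architecture(**{**arch.__dict__, "noise_std_rec": 0.0})
        p = init_parameters(arch, default_init("rhebb", arch),
                            np.random.default_rng(0))
        cfg = RHebbConfig(n_trials=5, kick_probability=0.0)
        with pytest.raises(ValueError, match="noise"):
            rhebb_train(p, arch, scaled_task_config("rhebb", seed=0), cfg,
                        np.random.default_rng(0))


class TestObjectives:
    def test_hf_loss_zero_for_perfect_outputs(self, hf_setup):
        arch, p, cfg = hf_setup
        # zero-weight network outputs b_out = 0 everywhere; make targets 0
        p.W_rec[:] = 0; p.W_in[:] = 0; p.W_out[:] = 0
        p.b_x[:] = 0; p.b_out[:] = 0
        batch = make_batch(cfg, 4, "alternating", np.random.default_rng(0),
                           family="hf")
        for t in batch:
            t.target_outputs[:] = 0.0
        arch0 = Architecture(**{**arch.__dict__, "noise_std_rec": 0.0})
        assert hf_loss(p, arch0, batch, HFLossSpec()) == 0.0

    def test_hf_loss_half_squared_error(self, hf_setup):
        arch, p, cfg = hf_setup
        p.W_rec[:] = 0; p.W_in[:] = 0; p.W_out[:] = 0
        p.b_x[:] = 0; p.b_out[:] = 0
        arch0 = Architecture(**{**arch.__dict__, "noise_std_rec": 0.0})
        batch = make_batch(cfg, 1, "alternating", np.random.default_rng(3),
                           family="hf")
        # z == 0 always; target 1 at T, 0 at t=0 -> loss = 1/2
        batch.trials[0].target_outputs[-1, 0] = 1.0
        assert np.isclose(hf_loss(p, arch0, batch, HFLossSpec()), 0.5)

    def test_hf_loss_matches_bruteforce(self, hf_setup):
        arch, p, cfg = hf_setup
        arch0 = Architecture(**{**arch.__dict__, "noise_std_rec": 0.0})
        batch = make_batch(cfg, 3, "random", np.random.default_rng(4),
                           family="hf")
        _, _, zs = simulate_batch(p, arch0, batch.inputs_array(), None)
        expect = 0.0
        for n, t in enumerate(batch):
            for ti in (0, zs.shape[1] - 1):
                expect += (zs[n, ti, 0] - t.target_outputs[ti, 0]) ** 2
        expect /= 2 * 3
        assert np.isclose(hf_loss(p, arch0, batch, HFLossSpec()), expect)

    def test_hf_loss_requires_t0_target(self, hf_setup):
        arch, p, cfg = hf_setup
        batch = make_batch(cfg, 2, "alternating", np.random.default_rng(0),
                           family="hf")
        for t in batch:
            t.error_mask[0] = False
        with pytest.raises(ValueError, match="t = 0"):
            hf_loss(p, arch, batch, HFLossSpec())

    def test_pycog_loss_zero_when_perfect(self, pycog_setup):
        arch, p, cfg = pycog_setup
        p.W_rec[:] = 0; p.W_in[:] = 0; p.W_out[:] = 0
        p.b_x[:] = 0; p.b_out[:] = 0
        arch0 = Architecture(**{**arch.__dict__, "noise_std_rec": 0.0})
        batch = make_batch(cfg, 2, "alternating", np.random.default_rng(0),
                           family="pycog")
        for t in batch:
            t.target_outputs[:] = 0.0
        assert pycog_loss(p, arch0, batch,
                          PycogLossSpec(lambda_omega=0.0)) == 0.0

    def test_pycog_loss_matches_bruteforce(self, pycog_setup):
        arch, p, cfg = pycog_setup
        arch0 = Architecture(**{**arch.__dict__, "noise_std_rec": 0.0})
        batch = make_batch(cfg, 3, "random", np.random.default_rng(5),
                           family="pycog")
        _, _, zs = simulate_batch(p, arch0, batch.inputs_array(), None)
        B, T, No = zs.shape
        expect = 0.0
        for n, t in enumerate(batch):
            for ti in range(T):
                if t.error_mask[ti]:
                    for s in range(No):
                        expect += (zs[n, ti, s] -
                                   t.target_outputs[ti, s]) ** 2 / (No * T)
        expect /= B
        got = pycog_loss(p, arch0, batch, PycogLossSpec(lambda_omega=0.0))
        assert np.isclose(got, expect)

    def test_pycog_all_false_mask_rejected(self, pycog_setup):
        arch, p, cfg = pycog_setup
        batch = make_batch(cfg, 2, "alternating", np.random.default_rng(0),
                           family="pycog")
        for t in batch:
            t.error_mask[:] = False
        with pytest.raises(ValueError, match="mask"):
            pycog_loss(p, arch, batch, PycogLossSpec())


class TestBackpropOracles:
    def test_leaky_bptt_matches_finite_differences(self, hf_setup):
        arch, p, cfg = hf_setup
        arch0 = Architecture(**{**arch.__dict__, "noise_std_rec": 0.0})
        batch = make_batch(cfg, 2, "random", np.random.default_rng(6),
                           family="hf")
        inputs = batch.inputs_array()
        targets, masks = _batch_targets(batch, "hf")

        def loss():
            _, _, zs = simulate_batch(p, arch0, inputs, None)
            return float(np.sum(((zs - targets) ** 2) * masks[:, :, None])) / 4

        xs, _, zs = simulate_batch(p, arch0, inputs, None)
        dzs = (zs - targets) * masks[:, :, None] / 2
        grads = backward_leaky(p, arch0, inputs, xs, dzs)
        rng = np.random.default_rng(0)
        for name in ("W_rec", "W_in", "b_x", "W_out", "b_out"):
            A = getattr(p, name)
            flat_idx = rng.choice(A.size, size=min(5, A.size), replace=False)
            for fi in flat_idx:
                idx = np.unravel_index(fi, A.shape)
                old = A[idx]
                A[idx] = old + 1e-6
                lp = loss()
                A[idx] = old - 1e-6
                lm = loss()
                A[idx] = old
                num = (lp - lm) / 2e-6
                assert abs(num - grads[name][idx]) < 1e-5 * max(
                    1.0, abs(num)), name

    def test_gru_bptt_matches_finite_differences(self, pyrl_setup):
        arch, p, cfg = pyrl_setup
        arch0 = Architecture(**{**arch.__dict__, "noise_std_rec": 0.0})
        batch = make_batch(cfg, 2, "random", np.random.default_rng(7))
        inputs = batch.inputs_array()
        w = np.random.default_rng(1).normal(size=3)

        def loss():
            _, _, zs = gru_forward(p, arch0, inputs, None)
            return float(np.sum(zs[:, -1, :] ** 2) + np.sum(zs[:, 4, :] * w))

        cache, _, zs = gru_forward(p, arch0, inputs, None)
        dzs = np.zeros_like(zs)
        dzs[:, -1, :] = 2 * zs[:, -1, :]
        dzs[:, 4, :] = w
        grads = gru_backward(p, arch0, cache, dzs)
        rng = np.random.default_rng(2)
        for name in ("W_rec", "W_in", "b_x", "W_out", "b_out"):
            A = getattr(p, name)
            for fi in rng.choice(A.size, size=min(5, A.size), replace=False):
                idx = np.unravel_index(fi, A.shape)
                old = A[idx]
                A[idx] = old + 1e-6
                lp = loss()
                A[idx] = old - 1e-6
                lm = loss()
                A[idx] = old
                num = (lp - lm) / 2e-6
                assert abs(num - grads[name][idx]) < 1e-5 * max(
                    1.0, abs(num)), name


class TestSgdTrain:
    def test_zero_learning_rate_is_noop(self, hf_setup):
        arch, p, cfg = hf_setup
        W0 = p.W_rec.copy()
        spec = HFLossSpec(learning_rate=0.0, n_iterations=3, eval_every=3,
                          n_validation=20)
        rec = sgd_train(p, arch, cfg, spec, np.random.default_rng(0))
        assert np.array_equal(rec.W_last.W_rec, W0)
        assert np.array_equal(rec.W_init.W_rec, W0)

    def test_dale_constraint_preserved_through_training(self, pycog_setup):
        arch, p, cfg = pycog_setup
        spec = PycogLossSpec(n_iterations=30, eval_every=30, n_validation=20)
        rec = sgd_train(p, arch, cfg, spec, np.random.default_rng(0))
        exc = arch.dale_signs > 0
        assert np.all(rec.W_last.W_rec[:, exc] >= 0)
        assert np.all(rec.W_last.W_rec[:, ~exc] <= 0)

    def test_dale_projection_idempotent(self):
        rng = np.random.default_rng(0)
        W = rng.normal(size=(6, 6))
        signs = np.array([1, 1, 1, 1, -1, -1], dtype=float)
        once = project_dale(W.copy(), signs)
        twice = project_dale(once.copy(), signs)
        assert np.array_equal(once, twice)

    def test_training_reproducible_from_seed(self, hf_setup):
        arch, _, cfg = hf_setup
        outs = []
        for _ in range(2):
            p = init_parameters(arch, default_init("hf", arch),
                                np.random.default_rng(7))
            spec = HFLossSpec(n_iterations=10, eval_every=10, n_validation=20)
            rec = sgd_train(p, arch, cfg, spec, np.random.default_rng(42))
            outs.append(rec.W_last.W_rec)
        assert np.array_equal(outs[0], outs[1])


class TestPyrlTrain:
    def _setup(self, n=12, seed=11):
        arch = default_architecture("pyrl_policy", n, seed=seed)
        base = default_architecture("pyrl_baseline", n, seed=seed + 1)
        rng = np.random.default_rng(seed)
        p = init_parameters(arch, default_init("pyrl", arch), rng)
        bp = init_parameters(base, default_init("pyrl", base), rng)
        return arch, base, p, bp

    def test_frozen_synapses_exactly_unchanged(self):
        arch, base, p, bp = self._setup()
        cfg = scaled_task_config("pyrl", seed=11)
        spec = PyrlSpec(n_iterations=25, batch_size=8, eval_every=25,
                        n_validation=20)
        rec, brec = pyrl_train(p, bp, arch, base, cfg, spec,
                               np.random.default_rng(11))
        frozen = ~arch.plasticity_mask
        assert np.array_equal(rec.W_last.W_rec[frozen],
                              rec.W_init.W_rec[frozen])
        assert np.any(rec.W_last.W_rec[arch.plasticity_mask] !=
                      rec.W_init.W_rec[arch.plasticity_mask])
        bfrozen = ~base.plasticity_mask
        assert np.array_equal(brec.W_last.W_rec[bfrozen],
                              brec.W_init.W_rec[bfrozen])

    def test_baseline_squared_error_zero_for_perfect_predictor(self):
        # Eq-13-style residual: constant reward 1, prediction 1 -> 0
        v = np.ones((4, 10))
        rewards = np.ones(4)
        resid = ((rewards[:, None] - v) ** 2).mean()
        assert resid == 0.0

    def test_policy_improves_on_easy_discrimination(self):
        # high-coherence, low-noise trials: reward-gradient training should
        # raise accuracy well above chance within a few hundred updates
        arch, base, p, bp = self._setup(n=32, seed=5)
        from rnnplast.tasks import TaskConfig
        cfg = TaskConfig(coherence_levels_motion=(-0.04, 0.04),
                         coherence_levels_color=(-0.04, 0.04),
                         noise_std_motion=0.01, noise_std_color=0.01,
                         encoding_mode="separated_4channel", seed=5)
        spec = PyrlSpec(n_iterations=500, batch_size=16, eval_every=100,
                        n_validation=100, stop_accuracy=0.9)
        rec, _ = pyrl_train(p, bp, arch, base, cfg, spec,
                            np.random.default_rng(5))
        assert rec.performance_trace[:, 1].max() > 0.65

    def test_missing_mask_rejected(self):
        arch, base, p, bp = self._setup()
        arch_nomask = Architecture(**{**arch.__dict__, "plasticity_mask": None})
        with pytest.raises(ValueError, match="mask"):
            pyrl_train(p, bp, arch_nomask, base,
                       scaled_task_config("pyrl", seed=0), PyrlSpec(),
                       np.random.default_rng(0))
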