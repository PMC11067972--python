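import math

import numpy as np
import pandas as pd
import pytest

from csbp.chaos import ChaosConfig
from csbp.gradients import LossSpec, SurrogateSpec, backprop_bptt, bp_update
from csbp.lif import LIFParams, NetworkWeights, encode_constant
from csbp.trainer import (
    Batch,
    TrainState,
    combine_gradients,
    csbp_step,
    make_training_map,
    train,
)
from csbp.workbench import xor_batch


@pytest.fixture
def xor4(params):
    return xor_batch(params.T)


class TestCombineGradients:
    def test_degeneration_is_bitwise_copy(self, small_net, rng):
        g = [rng.standard_normal(w.shape) for w in small_net.weights]
        out = combine_gradients(g, None)
        for a, b in zip(out, g):
            np.testing.assert_array_equal(a, b)
            assert a is not b

    def test_masked_combination(self, rng):
        g = [np.zeros((1, 2))]
        c = [np.array([[-1.5, -0.75]])]
        out = combine_gradients(g, c)
        np.testing.assert_array_equal(out[0], c[0])

    def test_update_arithmetic_example(self):
        # grad_bp=0, z=10, I0=0.65, h=0.5, s=0.5, eta=0.1:
        # chaotic gradient -z*(I0-h)*s = -0.75, step moves weight by +0.075
        from csbp.chaos import chaotic_gradient

        g_chaos = chaotic_gradient(10.0, 0.65, 0.5, 0.5)
        combined = combine_gradients([np.zeros((1, 1))], [np.array([[g_chaos]])])
        w_new = 1.0 - 0.1 * combined[0][0, 0]
        assert w_new - 1.0 == pytest.approx(0.075)

    def test_layer_count_mismatch(self):
        with pytest.raises(ValueError):
            combine_gradients([np.zeros((1, 2))], [])

    def test_mask_leak_detected(self):
        mask = [np.array([False])]
        with pytest.raises(ValueError):
            combine_gradients([np.zeros((1, 2))], [np.ones((1, 2))], mask)


class TestCsbpStep:
    def test_z_zero_equals_bp_step_bitwise(self, params, xor4):
        for seed in range(5):
            net = NetworkWeights.init_uniform([2, 3, 2], rng=seed)
            sg = SurrogateSpec()
            state = TrainState(net, z=0.0, eta=0.1)
            chaos = ChaosConfig(z0=0.0)
            stepped = csbp_step(state, xor4, params, sg, chaos)
            grads = backprop_bptt(
                net, xor4.inputs, params,
                LossSpec("mse_rate", xor4.targets), sg,
            )
            baseline = bp_update(net, grads, 0.1)
            for a, b in zip(stepped.weights.weights, baseline.weights):
                np.testing.assert_array_equal(a, b)

    def test_determinism(self, params, xor4):
        net = NetworkWeights.init_uniform([2, 5, 2], rng=0)
        chaos = ChaosConfig()
        sg = SurrogateSpec()
        s1 = csbp_step(TrainState(net, z=20.0, eta=1.0), xor4, params, sg, chaos)
        s2 = csbp_step(TrainState(net, z=20.0, eta=1.0), xor4, params, sg, chaos)
        for a, b in zip(s1.weights.weights, s2.weights.weights):
            np.testing.assert_array_equal(a, b)
        assert s1.z == s2.z == 20.0 * chaos.beta
        assert s1.m == 1

    def test_scalar_map_oracle(self):
        # single neuron, silent input, zero task loss: only the bias
        # updates, following w' = w + eta*z*(I0 - sigmoid(w)) exactly
        T, eta, z0, beta = 8, 0.7, 5.0, 0.999
        params = LIFParams(T=T)
        batch = Batch(encode_constant(np.array([0.0]), T)[None], None)
        w0 = NetworkWeights((1, 1), [np.array([[0.3, 0.8]])])
        log = train(
            batch, (1, 1), params, ChaosConfig(z0=z0, beta=beta),
            SurrogateSpec(), epochs=60, eta=eta, loss_kind="zero",
            init_weights=w0, track=[(1, 1, 0)],
        )
        b, z = 0.3, z0
        for m in range(60):
            assert log.frame["w_1_1_0"].iloc[m] == pytest.approx(b, abs=1e-12)
            b = b + eta * z * (0.65 - 1.0 / (1.0 + math.exp(-b)))
            z = z0 * beta ** (m + 1)
        # the silent input's weight never moves (s_k = 0)
        assert log.final_weights.weights[0][0, 1] == 0.8

    def test_overflow_diagnostic(self, params, xor4):
        net = NetworkWeights.init_uniform([2, 3, 2], rng=0)
        state = TrainState(net, z=1e308, eta=1e10)
        with pytest.raises(FloatingPointError):
            csbp_step(state, xor4, params, SurrogateSpec(), ChaosConfig())


class TestTrain:
    def test_single_epoch_single_row(self, params):
        log = train(
            "xor", (2, 3, 2), params, ChaosConfig(), SurrogateSpec(),
            epochs=1, seed=0,
        )
        assert len(log.frame) == 1
        assert log.weights_history.shape[0] == 2

    def test_z_column_is_exact_geometric(self, params):
        chaos = ChaosConfig(z0=20.0, beta=0.9995)
        log = train(
            "xor", (2, 3, 2), params, chaos, SurrogateSpec(),
            epochs=300, seed=0, eta=1.0,
        )
        expect = np.array([20.0 * 0.9995**int(m) for m in log.frame["m"]])
        np.testing.assert_array_equal(log.frame["z"].to_numpy(), expect)
        np.testing.assert_allclose(
            log.frame["z"], 20.0 * 0.9995 ** log.frame["m"].to_numpy(),
            rtol=1e-12,
        )

    def test_z_nonincreasing_m_increasing(self, params):
        log = train(
            "xor", (2, 3, 2), params, ChaosConfig(), SurrogateSpec(),
            epochs=100, seed=0, eta=1.0,
        )
        assert np.all(np.diff(log.frame["z"]) < 0)
        assert np.all(np.diff(log.frame["m"]) == 1)

    def test_seed_reproducibility(self, params):
        kwargs = dict(epochs=50, seed=7, eta=1.0)
        a = train("xor", (2, 5, 2), params, ChaosConfig(), SurrogateSpec(), **kwargs)
        b = train("xor", (2, 5, 2), params, ChaosConfig(), SurrogateSpec(), **kwargs)
        pd.testing.assert_frame_equal(a.frame, b.frame)
        np.testing.assert_array_equal(a.weights_history, b.weights_history)

    def test_three_term_update_identity(self, params, xor4):
        # one step must equal: w - eta*grad_bp + eta*mean_b[z*(I0-h)*s]
        # with h, s recomputed independently per sample
        from csbp.chaos import hidden_activity, mean_presyn_activity
        from csbp.lif import simulate_forward

        net = NetworkWeights.init_uniform([2, 4, 2], rng=11)
        eta, z, I0 = 0.3, 6.0, 0.65
        sg = SurrogateSpec()
        chaos = ChaosConfig(z0=z, I0=I0)
        stepped = csbp_step(
            TrainState(net, z=z, eta=eta), xor4, params, sg, chaos
        )
        grad_bp = backprop_bptt(
            net, xor4.inputs, params, LossSpec("mse_rate", xor4.targets), sg
        )
        B = xor4.inputs.shape[0]
        for li, W in enumerate(net.weights):
            expect = W - eta * grad_bp[li]
            for b in range(B):
                rec = simulate_forward(net, xor4.inputs[b], params)
                s = mean_presyn_activity(rec, li + 1)
                for j in range(W.shape[0]):
                    h = hidden_activity(W[j], s)
                    expect[j] += eta * z * (I0 - h) * s / B
            np.testing.assert_allclose(
                stepped.weights.weights[li], expect, atol=1e-12
            )

    def test_tracked_weight_column(self, params):
        log = train(
            "xor", (2, 5, 2), params, ChaosConfig(), SurrogateSpec(),
            epochs=10, seed=0, track=[(2, 2, 0), (1, 1, 2)],
        )
        assert "w_2_2_0" in log.frame.columns
        assert "w_1_1_2" in log.frame.columns
        # the logged value at m=0 is the initial weight
        init = NetworkWeights.init_uniform(
            (2, 5, 2), rng=np.random.default_rng(0)
        )
        assert log.frame["w_2_2_0"].iloc[0] == init.weights[1][1, 0]

    def test_invalid_task(self, params):
        with pytest.raises(ValueError):
            train("parity", (2, 3, 2), params, ChaosConfig(), SurrogateSpec(),
                  epochs=1)

    def test_invalid_track(self, params):
        with pytest.raises(ValueError):
            train("xor", (2, 3, 2), params, ChaosConfig(), SurrogateSpec(),
                  epochs=1, track=[(3, 1, 0)])

    def test_regression_task_runs(self):
        params = LIFParams(T=8)
        log = train(
            "regression", (1, 4, 1), params, ChaosConfig(z0=2.0),
            SurrogateSpec(), epochs=5, seed=0, track=[(2, 1, 0)],
        )
        assert len(log.frame) == 5
        assert np.isfinite(log.frame["loss_bp"]).all()


class TestTrainingMap:
    def test_map_matches_step(self, params, xor4):
        net = NetworkWeights.init_uniform([2, 3, 2], rng=2)
        chaos = ChaosConfig()
        sg = SurrogateSpec()
        G = make_training_map(net, xor4, 4.0, 0.5, params, sg, chaos)
        out_vec = G(net.to_vector())
        stepped = csbp_step(
            TrainState(net, z=4.0, eta=0.5), xor4, params, sg, chaos
        )
        np.testing.assert_array_equal(out_vec, stepped.weights.to_vector())

    def test_map_is_deterministic(self, params, xor4):
        net = NetworkWeights.init_uniform([2, 3, 2], rng=2)
        G = make_training_map(
            net, xor4, 4.0, 0.5, params, SurrogateSpec(), ChaosConfig()
        )
        v = net.to_vector()
        np.testing.assert_array_equal(G(v), G(v))
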