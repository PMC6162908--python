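import math

import numpy as np
import pytest

from mibci.csp import FeatureSeries
from mibci.rnn import (
    RNNConfig,
    autoregressive_predict,
    cross_entropy,
    forward,
    forward_batch,
    init_model,
    loss_and_grads,
    make_signal_slices,
    predict_trial,
    sweep_depth,
    train,
    train_signal,
)
from mibci.sequential import TimeSlice

CELLS = ("vanilla", "lstm", "gru")
MODES = ("conventional_sigmoid", "relu_gates")


def toy_cfg(cell="gru", **kw):
    defaults = dict(cell=cell, unroll_len=4, hidden_width=3, dropout_rate=0.0,
                    init_sigma=0.3, seed=3, batch_size=8)
    defaults.update(kw)
    return RNNConfig(**defaults)


class TestInit:
    def test_same_seed_bit_identical(self):
        cfg = toy_cfg()
        a = init_model(cfg, 5, n_classes=2)
        b = init_model(cfg, 5, n_classes=2)
        for k in a.params:
            np.testing.assert_array_equal(a.params[k], b.params[k])

    def test_gaussian_spread_matches_sigma(self):
        cfg = toy_cfg(cell="lstm", hidden_width=64, init_sigma=0.2)
        m = init_model(cfg, 40, n_classes=4)
        weights = np.concatenate(
            [v.ravel() for k, v in m.params.items() if not k.startswith("b")]
        )
        assert weights.size > 10_000
        assert 0.19 < weights.std() < 0.21
        biases = np.concatenate(
            [v.ravel() for k, v in m.params.items() if k.startswith("b")]
        )
        np.testing.assert_array_equal(biases, 0.0)

    def test_unknown_cell_rejected(self):
        with pytest.raises(ValueError):
            RNNConfig(cell="elman")


class TestForward:
    def test_zero_model_gives_uniform_probabilities(self):
        cfg = toy_cfg()
        m = init_model(cfg, 2, n_classes=4)
        for k in m.params:
            m.params[k][...] = 0.0
        probs = forward(m, TimeSlice(np.ones((2, 4)), label=1))
        np.testing.assert_allclose(probs, 0.25, atol=1e-12)

    @pytest.mark.parametrize("cell", CELLS)
    def test_output_on_simplex(self, cell, rng):
        cfg = toy_cfg(cell=cell)
        m = init_model(cfg, 3, n_classes=3)
        probs = forward_batch(m, rng.normal(size=(10, 3, 4)))
        assert np.all(probs >= 0)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-9)

    def test_gru_hand_arithmetic_oracle(self):
        # 1 input, 1 unit, all weights 1, biases 0, sigmoid gates, two steps
        # on input [1, 1]; linear readout so the output is h_2 itself.
        cfg = RNNConfig(cell="gru", unroll_len=2, hidden_width=1,
                        dropout_rate=0.0, head="regression", seed=0)
        m = init_model(cfg, 1, n_classes=1)
        for k in m.params:
            m.params[k][...] = 0.0 if k.startswith("b") else 1.0
        sig = lambda v: 1.0 / (1.0 + math.exp(-v))
        # step 1: h0 = 0
        z1 = sig(1.0)
        r1 = sig(1.0)
        hh1 = math.tanh(1.0 + 1.0 * (r1 * 0.0))
        h1 = (1 - z1) * 0.0 + z1 * hh1
        # step 2
        z2 = sig(1.0 + h1)
        r2 = sig(1.0 + h1)
        hh2 = math.tanh(1.0 + r2 * h1)
        h2 = (1 - z2) * h1 + z2 * hh2
        out = forward_batch(m, np.ones((1, 1, 2)))[0, 0]
        assert out == pytest.approx(h2, abs=1e-12)

    def test_slice_length_mismatch_rejected(self):
        m = init_model(toy_cfg(), 2, n_classes=2)
        with pytest.raises(ValueError):
            forward(m, TimeSlice(np.ones((2, 7)), label=1))


class TestCrossEntropy:
    def test_perfect_prediction_zero_loss(self):
        assert cross_entropy([0.0, 1.0], 1) == pytest.approx(0.0, abs=1e-10)

    def test_binary_coin_flip_is_ln2(self):
        assert cross_entropy([0.5, 0.5], 0) == pytest.approx(math.log(2), abs=1e-12)

    def test_batch_average(self):
        a = cross_entropy([0.9, 0.1], 0)
        b = cross_entropy([0.3, 0.7], 1)
        both = cross_entropy([[0.9, 0.1], [0.3, 0.7]], [0, 1])
        assert both == pytest.approx((a + b) / 2, abs=1e-12)

    def test_clipping_keeps_loss_finite(self):
        assert np.isfinite(cross_entropy([1.0, 0.0], 1))


class TestGradients:
    @pytest.mark.parametrize("cell", CELLS)
    @pytest.mark.parametrize("mode", MODES)
    def test_bptt_matches_finite_differences(self, cell, mode):
        cfg = toy_cfg(cell=cell, gate_activation_mode=mode)
        rng = np.random.default_rng(1)
        m = init_model(cfg, 2, n_classes=3)
        x = rng.normal(size=(5, 2, 4))
        y = rng.integers(0, 3, 5)
        _, grads, _ = loss_and_grads(m, x, y)
        eps = 1e-5
        for k, v in m.params.items():
            flat = v.ravel()
            idx = rng.choice(flat.size, size=min(8, flat.size), replace=False)
            for i in idx:
                orig = flat[i]
                flat[i] = orig + eps
                lp, _, _ = loss_and_grads(m, x, y)
                flat[i] = orig - eps
                lm, _, _ = loss_and_grads(m, x, y)
                flat[i] = orig
                num = (lp - lm) / (2 * eps)
                ana = grads[k].ravel()[i]
                rel = abs(num - ana) / max(abs(num), abs(ana), 1e-4)
                assert rel < 1e-4, f"{cell}/{mode} param {k}[{i}]"

    def test_regression_head_gradients(self, rng):
        cfg = toy_cfg(head="regression")
        m = init_model(cfg, 2)
        x = rng.normal(size=(4, 2, 4))
        y = rng.normal(size=(4, 2))
        _, grads, _ = loss_and_grads(m, x, y)
        eps = 1e-5
        k = "Wh"
        for i in range(m.params[k].size):
            flat = m.params[k].ravel()
            orig = flat[i]
            flat[i] = orig + eps
            lp, _, _ = loss_and_grads(m, x, y)
            flat[i] = orig - eps
            lm, _, _ = loss_and_grads(m, x, y)
            flat[i] = orig
            num = (lp - lm) / (2 * eps)
            assert abs(num - grads[k].ravel()[i]) < 1e-6


def memorization_slices(n=8):
    rng = np.random.default_rng(0)
    return [TimeSlice(rng.normal(size=(3, 6)), label=i % 2) for i in range(n)]


class TestTrain:
    def test_trace_runs_exactly_max_iterations(self):
        cfg = toy_cfg(max_iterations=200, unroll_len=6)
        m = init_model(cfg, 3, n_classes=2)
        _, trace = train(m, memorization_slices(), None, cfg)
        assert len(trace) == 200
        assert all(l >= 0 for l in trace.train_loss)

    def test_gru_memorizes_small_slice_set(self):
        cfg = RNNConfig(cell="gru", unroll_len=6, hidden_width=8,
                        dropout_rate=0.0, max_iterations=500, seed=0,
                        batch_size=8)
        m = init_model(cfg, 3, n_classes=2)
        _, trace = train(m, memorization_slices(), None, cfg)
        assert trace.train_loss[-1] < 0.01

    def test_training_is_deterministic_given_seed(self):
        cfg = toy_cfg(max_iterations=20, unroll_len=6, dropout_rate=0.2)
        slices = memorization_slices()
        runs = []
        for _ in range(2):
            m = init_model(cfg, 3, n_classes=2)
            m, trace = train(m, slices, None, cfg)
            runs.append((m, trace))
        for k in runs[0][0].params:
            np.testing.assert_array_equal(runs[0][0].params[k], runs[1][0].params[k])
        assert runs[0][1].train_loss == runs[1][1].train_loss

    def test_empty_training_set_rejected(self):
        cfg = toy_cfg()
        m = init_model(cfg, 3, n_classes=2)
        with pytest.raises(ValueError):
            train(m, [], None, cfg)


class TestPredictTrial:
    def _model(self, rng):
        cfg = toy_cfg(unroll_len=5)
        m = init_model(cfg, 2, n_classes=2, class_order=[1, 2])
        return m

    def test_aggregate_invariants(self, rng):
        m = self._model(rng)
        z = FeatureSeries(rng.normal(size=(2, 30)), label=1)
        agg = predict_trial(m, z, tau=5)
        assert agg.slice_probs.shape == (25, 2)  # T - tau slices
        np.testing.assert_allclose(agg.mean_probs, agg.slice_probs.mean(axis=0))
        np.testing.assert_allclose(agg.slice_probs.sum(axis=1), 1.0, atol=1e-9)
        assert agg.final_label == [1, 2][int(np.argmax(agg.mean_probs))]

    def test_single_slice_is_its_own_argmax(self, rng):
        m = self._model(rng)
        z = FeatureSeries(rng.normal(size=(2, 6)), label=1)
        agg = predict_trial(m, z, tau=5)
        assert agg.slice_probs.shape[0] == 1
        assert agg.final_label == [1, 2][int(np.argmax(agg.slice_probs[0]))]

    def test_exact_tie_breaks_to_lowest_class(self, rng):
        m = self._model(rng)
        for k in m.params:
            m.params[k][...] = 0.0  # uniform probabilities -> exact tie
        z = FeatureSeries(rng.normal(size=(2, 30)), label=1)
        assert predict_trial(m, z, tau=5).final_label == 1

    def test_too_short_series_rejected(self, rng):
        m = self._model(rng)
        z = FeatureSeries(rng.normal(size=(2, 5)), label=1)
        with pytest.raises(ValueError):
            predict_trial(m, z, tau=5)


class TestAutoregressive:
    def _signal_model(self, **kw):
        cfg = RNNConfig(cell="gru", unroll_len=10, hidden_width=8,
                        dropout_rate=0.0, head="regression", seed=0,
                        max_iterations=5, **kw)
        return init_model(cfg, 1)

    def test_zero_steps_empty_output(self, rng):
        m = self._signal_model()
        out = autoregressive_predict(m, rng.normal(size=(1, 10)), 0)
        assert out.shape == (1, 0)

    def test_zero_model_predicts_zeros(self, rng):
        m = self._signal_model()
        for k in m.params:
            m.params[k][...] = 0.0
        out = autoregressive_predict(m, rng.normal(size=(1, 10)), 7)
        np.testing.assert_array_equal(out, 0.0)

    def test_classification_model_rejected(self, rng):
        m = init_model(toy_cfg(), 2, n_classes=2)
        with pytest.raises(ValueError):
            autoregressive_predict(m, rng.normal(size=(2, 4)), 3)

    def test_learned_sinusoid_keeps_its_frequency(self):
        # train one-step prediction on a pure 10 Hz tone at 250 Hz, then
        # free-run: the continuation's spectral peak must stay at 10 +/- 1 Hz
        t = np.arange(1000) / 250.0
        sig = np.sin(2 * np.pi * 10 * t)[None, :]
        cfg = RNNConfig(cell="gru", unroll_len=25, hidden_width=24,
                        dropout_rate=0.0, head="regression", seed=0,
                        max_iterations=60, batch_size=64, learning_rate=3e-3)
        x, y = make_signal_slices(sig, 25, stride=2)
        m = init_model(cfg, 1)
        m, losses = train_signal(m, x, y, cfg)
        assert losses[-1] < 1e-3
        pred = autoregressive_predict(m, sig[:, :250], 500)
        from scipy.signal import periodogram

        f, p = periodogram(pred[0], fs=250.0)
        assert abs(f[np.argmax(p)] - 10.0) <= 1.0


class TestSweepDepth:
    def _features(self, rng, n=16, t=30):
        out = []
        for i in range(n):
            lab = 1 + i % 2
            vals = rng.normal(size=(2, t)) * 0.3
            vals[lab - 1] += 1.0
            out.append(FeatureSeries(vals, label=lab))
        return out

    def test_singleton_grid_returns_it(self, rng):
        cfg = toy_cfg(max_iterations=3)
        feats = self._features(rng)
        tau, records = sweep_depth(feats[:12], feats[12:], [20], cfg)
        assert tau == 20
        assert set(records) == {20}

    def test_sweep_deterministic_across_reruns(self, rng):
        cfg = toy_cfg(max_iterations=3)
        feats = self._features(rng)
        a = sweep_depth(feats[:12], feats[12:], [3, 6], cfg)
        b = sweep_depth(feats[:12], feats[12:], [3, 6], cfg)
        assert a[0] == b[0]
        assert a[1] == b[1]

    def test_depth_matching_temporal_scale_beats_short_windows(self):
        # classes share amplitude statistics and differ only in oscillation
        # frequency, so a 2-sample window is nearly uninformative while a
        # window spanning the oscillation is not; majority vote over seeds
        def freq_features(seed, n=40, t=40):
            r = np.random.default_rng(seed)
            out = []
            for i in range(n):
                lab = 1 + i % 2
                freq = 0.3 if lab == 1 else 0.55  # rad/sample
                phase = r.uniform(0, 2 * np.pi)
                vals = r.normal(size=(2, t)) * 0.4
                vals[0] += np.sin(freq * np.arange(t) + phase)
                out.append(FeatureSeries(vals, label=lab))
            return out

        wins = 0
        for seed in range(5):
            feats = freq_features(seed)
            cfg = RNNConfig(cell="gru", hidden_width=12, dropout_rate=0.0,
                            max_iterations=25, seed=seed, batch_size=64)
            _, rec = sweep_depth(feats[:24], feats[24:], [2, 16], cfg,
                                 train_stride=2, eval_stride=2)
            wins += rec[16]["val_accuracy"] > rec[2]["val_accuracy"]
        assert wins >= 3

    def test_empty_grid_rejected(self, rng):
        with pytest.raises(ValueError):
            sweep_depth(self._features(rng), self._features(rng), [], toy_cfg())
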