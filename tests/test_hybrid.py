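"""Hybrid model: conv blocks, feature extraction, head, loss, training."""

import numpy as np
import pytest

from painq import hybrid, qsim
from painq.hybrid import (ConvBlockParams, LossWeights, TrainConfig,
                          conv_block_forward, conv2d)


def _identity_bn_block(weights, bias=None, stride=1):
    c_out = weights.shape[0]
    return ConvBlockParams(
        weights=weights,
        bias=np.zeros(c_out) if bias is None else bias,
        bn_gamma=np.ones(c_out), bn_beta=np.zeros(c_out),
        running_mean=np.zeros(c_out), running_var=np.ones(c_out),
        stride=stride)


class TestConvBlock:
    def test_bn_with_unit_stats_reduces_to_relu_conv(self, rng):
        w = rng.standard_normal((2, 1, 3, 3))
        p = _identity_bn_block(w)
        x = rng.standard_normal((1, 1, 8, 8))
        out = conv_block_forward(x, p, training=False)
        expected = np.maximum(conv2d(x, w, np.zeros(2)) /
                              np.sqrt(1 + p.eps), 0.0)
        assert np.allclose(out, expected, atol=1e-12)

    def test_all_negative_preactivations_give_zero(self):
        w = np.ones((1, 1, 3, 3))
        p = _identity_bn_block(w, bias=np.array([-100.0]))
        x = np.zeros((1, 1, 6, 6))
        assert np.all(conv_block_forward(x, p) == 0.0)

    def test_training_mode_normalizes_batch_statistics(self, rng):
        """Recompute per-channel stats of BN output before gamma/beta."""
        w = rng.standard_normal((3, 2, 3, 3))
        p = _identity_bn_block(w)
        x = rng.standard_normal((4, 2, 10, 10)) * 5 + 2
        z = conv2d(x, p.weights, p.bias)
        zn = (z - z.mean(axis=(0, 2, 3), keepdims=True)) / np.sqrt(
            z.var(axis=(0, 2, 3), keepdims=True) + p.eps)
        assert np.allclose(zn.mean(axis=(0, 2, 3)), 0.0, atol=1e-6)
        assert np.allclose(zn.var(axis=(0, 2, 3)), 1.0, atol=1e-4)
        out = conv_block_forward(x, p, training=True)
        assert np.allclose(out, np.maximum(zn, 0.0), atol=1e-10)

    def test_kernel_larger_than_input_rejected(self, rng):
        w = rng.standard_normal((1, 1, 5, 5))
        with pytest.raises(ValueError):
            conv2d(np.zeros((1, 1, 3, 3)), w, np.zeros(1))

    def test_conv2d_matches_scipy_oracle(self, rng):
        from scipy.signal import correlate2d

        x = rng.standard_normal((1, 1, 9, 9))
        w = rng.standard_normal((1, 1, 3, 3))
        out = conv2d(x, w, np.zeros(1))
        oracle = correlate2d(x[0, 0], w[0, 0], mode="valid")
        assert np.allclose(out[0, 0], oracle, atol=1e-12)


@pytest.fixture(scope="module")
def image():
    return np.random.default_rng(0).random((640, 640))


class TestExtractFeatures:

    def test_deterministic(self, image):
        backbone = hybrid.make_backbone("eq3_stack", seed=3)
        a = hybrid.extract_features(image, backbone)
        b = hybrid.extract_features(image.copy(), backbone)
        assert np.array_equal(a, b)

    @pytest.mark.parametrize("kind", ["eq3_stack", "resnet18_style"])
    def test_output_dimension_512(self, image, kind):
        backbone = hybrid.make_backbone(kind, seed=0)
        assert hybrid.extract_features(image, backbone).shape == (512,)

    def test_zero_image_gives_zero_features(self):
        backbone = hybrid.make_backbone("eq3_stack", seed=1)
        feats = hybrid.extract_features(np.zeros((640, 640)), backbone)
        assert np.allclose(feats, 0.0)

    def test_nonfinite_image_rejected(self):
        img = np.zeros((640, 640))
        img[0, 0] = np.nan
        with pytest.raises(ValueError):
            hybrid.extract_features(img)


class TestClassify:
    def test_zero_weights_uniform(self):
        p = hybrid.classify(np.ones(9), np.zeros((3, 9)), np.zeros(3))
        assert np.allclose(p, 1 / 3)

    def test_probabilities_sum_to_one(self, rng):
        w = rng.standard_normal((3, 9))
        p = hybrid.classify(rng.standard_normal((5, 9)), w,
                            rng.standard_normal(3))
        assert np.allclose(p.sum(axis=1), 1.0, atol=1e-12)
        assert np.all(p > 0)

    def test_shift_invariance_of_logits(self, rng):
        m = rng.standard_normal(9)
        w = rng.standard_normal((3, 9))
        b = rng.standard_normal(3)
        assert np.allclose(hybrid.classify(m, w, b),
                           hybrid.classify(m, w, b + 10.0), atol=1e-12)

    def test_dominant_logit_saturates(self):
        w = np.zeros((3, 1))
        b = np.array([50.0, 0.0, 0.0])
        p = hybrid.classify(np.zeros(1), w, b)
        assert p[0] > 1 - 1e-12


class TestHybridLoss:
    def test_perfect_prediction_zero_ce(self):
        lw = LossWeights(alpha=0.0, beta_reg=0.0)
        probs = np.eye(3)[[0, 1, 2]]
        probs = np.clip(probs, 1e-15, 1.0)
        probs /= probs.sum(axis=1, keepdims=True)
        loss = hybrid.hybrid_loss(probs, [0, 1, 2], [], 0.0, lw)
        assert loss.total == pytest.approx(0.0, abs=1e-9)

    def test_identical_states_penalty_b_squared(self):
        """B identical normalized states: sum |<i|j>|^2 = B^2."""
        lw = LossWeights(alpha=0.7, beta_reg=0.0, gamma_q=1.3)
        B = 5
        state = qsim.amplitude_encode(np.arange(1.0, 9.0), 3).amplitudes
        states = np.tile(state, (B, 1))
        probs = np.full((B, 3), 1 / 3)
        loss = hybrid.hybrid_loss(probs, [0] * B, [states], 0.0, lw)
        assert loss.quantum_penalty == pytest.approx(0.7 * 1.3 * B ** 2,
                                                     rel=1e-12)

    def test_orthogonal_states_penalty_b(self):
        """Mutually orthogonal states: only diagonal terms survive."""
        lw = LossWeights(alpha=1.0, beta_reg=0.0, gamma_q=1.0)
        B = 4
        states = np.eye(8, dtype=complex)[:B]
        probs = np.full((B, 3), 1 / 3)
        loss = hybrid.hybrid_loss(probs, [0] * B, [states], 0.0, lw)
        assert loss.quantum_penalty == pytest.approx(float(B), rel=1e-12)

    def test_penalty_matches_bruteforce_overlap_oracle(self, rng):
        states = rng.standard_normal((6, 16)) + 1j * rng.standard_normal(
            (6, 16))
        states /= np.linalg.norm(states, axis=1, keepdims=True)
        expected = sum(abs(np.vdot(states[i], states[j])) ** 2
                       for i in range(6) for j in range(6))
        assert hybrid.quantum_penalty([states]) == pytest.approx(
            expected, rel=1e-10)

    def test_penalty_invariant_under_circuit_parameters(self, rng):
        """Unitarity: batch overlaps after any layer equal input overlaps."""
        feats = rng.standard_normal((4, 512))
        base = hybrid.quantum_penalty(
            [qsim._encode_batch(feats, 9)])
        for seed in (1, 2):
            params = qsim.CircuitParameters.random(seed=seed)
            _, states = qsim.run_circuit_batch(feats, params,
                                               return_layer_states=True)
            for layer_states in states:
                assert hybrid.quantum_penalty([layer_states]) == \
                    pytest.approx(base, rel=1e-10)

    def test_clamped_probability_warns(self):
        lw = LossWeights(alpha=0.0, beta_reg=0.0)
        probs = np.array([[1.0, 0.0, 0.0]])
        with pytest.warns(UserWarning):
            loss = hybrid.hybrid_loss(probs, [2], [], 0.0, lw)
        assert np.isfinite(loss.total)


class TestSgdAndDiagnostics:
    def test_zero_learning_rate_no_change(self, rng):
        params = {"w": rng.standard_normal(5)}
        out = hybrid.sgd_step(params, {"w": rng.standard_normal(5)}, 0.0)
        assert np.array_equal(out["w"], params["w"])

    def test_quadratic_closed_form(self):
        out = hybrid.sgd_step({"t": np.array(1.0)}, {"t": np.array(1.0)},
                              0.1)
        assert out["t"] == pytest.approx(0.9)

    def test_nonfinite_gradient_aborts(self):
        with pytest.raises(FloatingPointError):
            hybrid.sgd_step({"w": np.ones(2)},
                            {"w": np.array([1.0, np.nan])}, 0.1)

    def test_monotone_descent_on_convex_toy(self):
        """Loss ||theta||^2/2 decreases over 50 steps at small eta."""
        theta = {"t": np.array([3.0, -2.0])}
        losses = []
        for _ in range(50):
            losses.append(0.5 * np.sum(theta["t"] ** 2))
            theta = hybrid.sgd_step(theta, {"t": theta["t"]}, 0.05)
        assert np.all(np.diff(losses) < 0)

    def test_convergence_bound_holds_on_convex_quadratic(self):
        """Gradient descent on ||t||^2/2 satisfies the 2(L0-L*)/(eta t) bound."""
        t = np.array([3.0, -2.0])
        eta = 0.05
        loss_hist, grad_hist = [], []
        for _ in range(100):
            loss_hist.append(0.5 * np.sum(t ** 2))
            grad_hist.append(np.linalg.norm(t))
            t = t - eta * t
        report = hybrid.convergence_diagnostic(loss_hist, grad_hist, eta)
        assert not report["violations"].any()

    def test_bound_halves_when_steps_double(self):
        loss = [4.0] + [1.0] * 99
        grad = [1.0] * 100
        report = hybrid.convergence_diagnostic(loss, grad, 0.1)
        assert report["bound"][39] == pytest.approx(2 * report["bound"][79],
                                                    rel=1e-12)

    def test_start_at_optimum_gives_zero_bound(self):
        report = hybrid.convergence_diagnostic([1.0, 1.0], [0.0, 0.0], 0.1)
        assert np.allclose(report["bound"], 0.0)
        assert not report["violations"].any()


class TestEvaluate:
    def test_perfect_predictions_all_ones(self):
        y = [0, 1, 2, 0, 1, 2]
        m = hybrid.evaluate(y, y)
        for key in ("accuracy", "sensitivity", "specificity", "f1"):
            assert m[key] == 1.0

    def test_symmetric_confusion_accuracy(self):
        y_true = sum(([c] * 10 for c in range(3)), [])
        y_pred = []
        for c in range(3):
            y_pred += [c] * 8 + [(c + 1) % 3, (c + 2) % 3]
        m = hybrid.evaluate(y_pred, y_true)
        assert m["accuracy"] == pytest.approx(0.8)
        cm = m["confusion_matrix"]
        assert np.trace(cm) == 24 and cm.sum() == 30

    def test_macro_metrics_match_sklearn(self, rng):
        """Cross-check macro averaging against scikit-learn."""
        from sklearn.metrics import f1_score, recall_score

        y_true = rng.integers(0, 3, 60)
        y_pred = rng.integers(0, 3, 60)
        m = hybrid.evaluate(y_pred, y_true)
        assert m["sensitivity"] == pytest.approx(
            recall_score(y_true, y_pred, average="macro"), abs=1e-12)
        assert m["f1"] == pytest.approx(
            f1_score(y_true, y_pred, average="macro"), abs=1e-12)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            hybrid.evaluate([], [])


class TestEndToEndGradient:
    def test_chain_matches_finite_differences_on_tiny_model(self, rng):
        """Full-pipeline finite differences vs the implemented chain
        (parameter shift for angles, analytic for the head)."""
        X, y = hybrid.make_separable_dataset(n_per_class=2, dim=8, seed=0,
                                             n_classes=3)
        tc = TrainConfig(learning_rate=0.01, epochs=1, batch_size=6,
                         seed=0, n_qubits=3, n_layers=2)
        lw = LossWeights(alpha=0.0, beta_reg=1e-3)
        trainer = hybrid.HybridTrainer(X, y, tc, lw)

        def total_loss(angles, head_w, head_b):
            params = qsim.CircuitParameters(angles=angles)
            m = qsim.run_circuit_batch(X, params)
            probs = hybrid.classify(m, head_w, head_b)
            p_true = probs[np.arange(len(y)), y]
            return (-np.mean(np.log(p_true))
                    + lw.beta_reg * np.sum(head_w ** 2))

        # implemented chain
        m, _, probs = trainer._forward(X)
        onehot = np.eye(3)[y]
        dlogits = (probs - onehot) / len(y)
        grad_w = dlogits.T @ m + 2 * lw.beta_reg * trainer.head_w
        dm = dlogits @ trainer.head_w
        jac = qsim.measurement_jacobian(X, trainer.circuit)
        grad_angles = np.einsum("bpj,bj->p", jac, dm).reshape(
            trainer.circuit.angles.shape)

        h = 1e-6
        a0 = trainer.circuit.angles
        for (l, q, k) in [(0, 0, 1), (1, 2, 0), (0, 1, 2)]:
            ap, am = a0.copy(), a0.copy()
            ap[l, q, k] += h
            am[l, q, k] -= h
            fd = (total_loss(ap, trainer.head_w, trainer.head_b)
                  - total_loss(am, trainer.head_w, trainer.head_b)) / (2 * h)
            rel = abs(grad_angles[l, q, k] - fd) / max(abs(fd), 1e-8)
            assert rel < 1e-4 or abs(grad_angles[l, q, k] - fd) < 1e-8
        for idx in [(0, 0), (2, 2)]:
            wp, wm = trainer.head_w.copy(), trainer.head_w.copy()
            wp[idx] += h
            wm[idx] -= h
            fd = (total_loss(a0, wp, trainer.head_b)
                  - total_loss(a0, wm, trainer.head_b)) / (2 * h)
            assert grad_w[idx] == pytest.approx(fd, rel=1e-4, abs=1e-8)


class TestTraining:
    def test_separable_task_reaches_high_accuracy(self):
        """>= 90% train accuracy within 200 epochs at eta = 0.001."""
        X, y = hybrid.make_separable_dataset(n_per_class=10, seed=0)
        tc = TrainConfig(learning_rate=0.001, epochs=0, batch_size=4, seed=1)
        trainer = hybrid.HybridTrainer(X, y, tc)
        acc = 0.0
        for _ in range(20):  # up to 200 epochs, stop once target reached
            trainer.run_epochs(10)
            acc = trainer.history[-1]["train_accuracy"]
            if acc >= 0.90:
                break
        assert acc >= 0.90
        assert len(trainer.history) <= 200

    def test_loss_components_nonnegative_and_loss_decreases(self):
        X, y = hybrid.make_separable_dataset(n_per_class=5, dim=32, seed=2,
                                             n_classes=3)
        tc = TrainConfig(learning_rate=0.05, epochs=10, batch_size=5, seed=3,
                         n_qubits=5, n_layers=2)
        trainer = hybrid.train_hybrid(X, y, tc)
        losses = [r["loss"] for r in trainer.history]
        assert np.mean(losses[-3:]) < np.mean(losses[:3])
        m, tracked, probs = trainer._forward(X)
        loss = hybrid.hybrid_loss(probs, y, tracked,
                                  float(np.sum(trainer.head_w ** 2)),
                                  trainer.lw)
        assert loss.cross_entropy >= 0
        assert loss.quantum_penalty >= 0
        assert loss.weight_decay >= 0

    def test_training_is_deterministic_under_seed(self):
        X, y = hybrid.make_separable_dataset(n_per_class=4, dim=16, seed=4,
                                             n_classes=3)
        tc = TrainConfig(learning_rate=0.005, epochs=3, batch_size=4,
                         seed=7, n_qubits=4, n_layers=2)
        a = hybrid.train_hybrid(X, y, tc)
        b = hybrid.train_hybrid(X, y, tc)
        assert np.array_equal(a.circuit.angles, b.circuit.angles)
        assert np.array_equal(a.head_w, b.head_w)
        assert a.history == b.history
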