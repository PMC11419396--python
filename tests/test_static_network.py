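"""Static classifier: activations, initialisation, gradients, training."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oscmux import (
    LabeledDataset,
    Placement,
    TrainConfig,
    build_training_set,
    evaluate,
    forward_static,
    make_image,
    shifted_sigmoid,
    softmax,
    train_network,
)
from oscmux.static_network import (
    SigmoidParams,
    _gradients,
    glorot_init,
    init_weights,
    layer1_input,
)


class TestShiftedSigmoid:
    def test_midpoint_value_and_reference_points(self):
        assert shifted_sigmoid(2.5) == pytest.approx(0.5)
        # sigma(1.7) = 1/(1+e^{2*0.8}) ~ 0.168
        assert shifted_sigmoid(1.7) == pytest.approx(0.17, abs=0.005)
        assert 1.0 - shifted_sigmoid(8.5) == pytest.approx(
            1.0 / (1.0 + np.exp(12.0)), rel=1e-6
        )
        assert 1.0 - shifted_sigmoid(8.5) < 1e-5

    @given(st.floats(-8, 13), st.floats(-8, 13))
    def test_strictly_increasing_where_not_saturated(self, z1, z2):
        # beyond |a (z - b)| ~ 36 the output saturates to 0/1 in double precision
        if abs(z1 - z2) < 1e-9:  # below the output's double-precision resolution
            return
        lo, hi = sorted((z1, z2))
        assert shifted_sigmoid(lo) < shifted_sigmoid(hi)

    def test_invalid_slope_rejected(self):
        with pytest.raises(ValueError):
            SigmoidParams(a=-1.0)


class TestSoftmax:
    def test_symmetry_and_normalisation(self):
        assert np.allclose(softmax(np.zeros(3)), 1 / 3)
        assert softmax(np.array([10.0, 0.0, 0.0]))[0] > 0.9999

    @given(st.lists(st.floats(-100, 100), min_size=3, max_size=3), st.floats(-50, 50))
    def test_shift_invariance_and_unit_sum(self, z, shift):
        z = np.array(z)
        p = softmax(z)
        assert p.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.allclose(p, softmax(z + shift), atol=1e-12)


class TestLayer1Input:
    def test_zero_image_gives_zero_drive(self):
        w = init_weights(0)
        img = np.zeros((56, 56))
        assert np.allclose(layer1_input(img, w.kernels1), 0.0)

    def test_quadrant_translation_invariance_noiseless(self):
        w = init_weights(0)
        imgs = [make_image([Placement("E", q)], 0.0, 0) for q in range(4)]
        z = [layer1_input(img, w.kernels1) for img in imgs]
        for other in z[1:]:
            assert np.allclose(z[0], other, atol=1e-12)

    def test_matches_naive_per_quadrant_oracle(self):
        rng = np.random.default_rng(5)
        w = init_weights(3)
        pixels = rng.random((56, 56))
        z = layer1_input(pixels, w.kernels1)
        oracle = np.zeros(64)
        for j in range(64):
            for qr in (0, 1):
                for qc in (0, 1):
                    quad = pixels[qr * 28 : (qr + 1) * 28, qc * 28 : (qc + 1) * 28]
                    oracle[j] += float(np.sum(w.kernels1[j] * quad))
        assert np.allclose(z, oracle, atol=1e-10)

    def test_wrong_shape_rejected(self):
        with pytest.raises(ValueError, match="56x56"):
            layer1_input(np.zeros((28, 28)), init_weights(0).kernels1)


class TestGlorotInit:
    def test_bounds_and_determinism(self):
        rng = np.random.default_rng(0)
        x = np.sqrt(6.0 / (784 + 64))
        block = glorot_init(784, 64, rng)
        assert np.all(np.abs(block) <= x)
        again = glorot_init(784, 64, np.random.default_rng(0))
        assert np.array_equal(block, again)

    def test_sample_mean_consistent_with_uniform_moments(self):
        rng = np.random.default_rng(1)
        n_in, n_out = 100, 100
        x = np.sqrt(6.0 / (n_in + n_out))
        block = glorot_init(n_in, n_out, rng)
        assert abs(block.mean()) < 3 * x / np.sqrt(12 * block.size)


class TestForward:
    def test_zero_image_hidden_activation_is_sigma_zero(self):
        rec = forward_static(np.zeros((56, 56)), init_weights(0))
        assert np.allclose(rec.h1, 1.0 / (1.0 + np.exp(5.0)))

    def test_probabilities_always_normalised(self, trained):
        weights, _ = trained
        for q in range(4):
            img = make_image([Placement("T", q)], 0.2, q)
            rec = forward_static(img, weights)
            assert rec.probs.sum() == pytest.approx(1.0, abs=1e-12)
            assert np.all(rec.probs > 0)

    def test_clean_letter_classified_with_high_confidence(self, trained):
        weights, _ = trained
        for i, letter in enumerate("AET"):
            img = make_image([Placement(letter, 0)], 0.0, 0)
            rec = forward_static(img, weights)
            assert np.argmax(rec.probs) == i
            assert rec.probs[i] > 0.99

    def test_non_finite_weights_rejected(self):
        w = init_weights(0)
        w.W2[0, 0] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            forward_static(np.zeros((56, 56)), w)


class TestGradients:
    def test_backprop_matches_central_finite_differences(self):
        """Analytic gradients agree with numeric differentiation to 1e-5."""
        weights = init_weights(11)
        img = make_image([Placement("A", 1)], 0.15, 3)
        label = 0
        _, grads, _ = _gradients(img, label, weights)
        rng = np.random.default_rng(0)
        eps = 1e-6
        for name in ("kernels1", "W2", "W3"):
            block = getattr(weights, name)
            for flat_idx in rng.choice(block.size, size=8, replace=False):
                idx = np.unravel_index(flat_idx, block.shape)
                orig = block[idx]
                block[idx] = orig + eps
                lp, _, _ = _gradients(img, label, weights)
                block[idx] = orig - eps
                lm, _, _ = _gradients(img, label, weights)
                block[idx] = orig
                numeric = (lp - lm) / (2 * eps)
                analytic = grads[name][idx]
                assert analytic == pytest.approx(numeric, rel=1e-5, abs=1e-8)


class TestTraining:
    def test_loss_decreases_and_training_set_is_learned(
        self, canonical_dataset, trained
    ):
        weights, trace = trained
        assert trace[-1] < trace[0]
        acc, _ = evaluate(weights, canonical_dataset)
        assert acc == 1.0

    def test_unseen_noise_generalisation(self, trained):
        weights, _ = trained
        test = build_training_set(seed=90210)
        acc, _ = evaluate(weights, test)
        assert acc == 1.0

    def test_hidden_activations_approximately_binary(self, canonical_dataset, trained):
        weights, _ = trained
        vals = []
        for img, _ in canonical_dataset.items:
            rec = forward_static(img, weights)
            vals.extend(rec.h1)
            vals.extend(rec.h2)
        vals = np.array(vals)
        assert np.mean((vals < 0.1) | (vals > 0.9)) >= 0.9

    def test_untrained_network_at_chance_over_seeds(self, canonical_dataset):
        small = LabeledDataset(items=canonical_dataset.items[::4])
        accs = [evaluate(init_weights(s), small)[0] for s in range(10)]
        assert np.mean(accs) == pytest.approx(1 / 3, abs=0.15)

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError):
            evaluate(init_weights(0), LabeledDataset())
        with pytest.raises(ValueError):
            train_network(LabeledDataset(), TrainConfig())

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            TrainConfig(epochs=0)
        with pytest.raises(ValueError):
            TrainConfig(batch_size=0)
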