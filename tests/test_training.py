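"""Loss, momentum-SGD recurrence, freezing and training-loop contracts."""

import math

import numpy as np
import pytest

import fmcnet as F
from fmcnet.training import (TrainingDivergedError, clone_model,
                             parameter_checksums)
from .conftest import make_split_tensors


class TestLogisticLoss:
    def test_maximum_entropy_is_ln2(self):
        p = np.full(8, 0.5)
        y = np.array([0, 1] * 4)
        assert F.logistic_loss(p, y) == pytest.approx(math.log(2))

    def test_perfect_fit_near_zero(self):
        y = np.array([1.0, 0.0, 1.0])
        assert F.logistic_loss(y, y) < 1e-6

    def test_hand_computed_two_sample_case(self):
        loss = F.logistic_loss(np.array([0.9, 0.2]), np.array([1, 0]))
        assert loss == pytest.approx(-0.5 * (math.log(0.9) + math.log(0.8)))

    def test_batch_permutation_invariant(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(0.01, 0.99, 50)
        y = rng.integers(0, 2, 50)
        perm = rng.permutation(50)
        assert F.logistic_loss(p, y) == pytest.approx(F.logistic_loss(p[perm], y[perm]))

    def test_extreme_predictions_clipped_finite(self):
        loss = F.logistic_loss(np.array([0.0, 1.0]), np.array([1, 0]))
        assert np.isfinite(loss)


class TestMomentumStep:
    def test_null_update_leaves_weights(self):
        state = F.OptimizerState(learning_rate=1e-4, momentum=0.95, weight_decay=0.0)
        w = np.array([1.0, -2.0])
        w2 = F.momentum_step(state, "w", w, np.zeros(2))
        assert np.array_equal(w2, w)

    def test_single_step_substitution(self):
        # v1 = mu*0 - lam*eps*w0 - eps*g = -(1e-6*1e-4*1 + 1e-4*0.5)
        state = F.OptimizerState(learning_rate=1e-4, momentum=0.95, weight_decay=1e-6)
        w = np.array([1.0])
        w1 = F.momentum_step(state, "w", w, np.array([0.5]))
        v1_expected = -(1e-6 * 1e-4 * 1.0 + 1e-4 * 0.5)
        assert state.velocities["w"][0] == pytest.approx(v1_expected, rel=1e-15)
        assert w1[0] == pytest.approx(1.0 + v1_expected, rel=1e-15)

    def test_unrolled_recurrence_matches_exactly(self):
        """k steps on a scalar equal direct evaluation of the recurrence."""
        eps, mu, lam, g = 0.01, 0.9, 0.001, 0.3
        state = F.OptimizerState(learning_rate=eps, momentum=mu, weight_decay=lam)
        w = np.array([2.0])
        v_ref, w_ref = 0.0, 2.0
        for _ in range(5):
            w = F.momentum_step(state, "w", w, np.array([g]))
            v_ref = mu * v_ref - lam * eps * w_ref - eps * g
            w_ref = w_ref + v_ref
            assert w[0] == w_ref  # identical floating-point sequence
            assert state.velocities["w"][0] == v_ref

    def test_shape_mismatch_rejected(self):
        state = F.OptimizerState()
        with pytest.raises(ValueError, match="shape"):
            F.momentum_step(state, "w", np.zeros(3), np.zeros(2))


class TestFreezeAndInit:
    def test_freeze_three_masks_exactly_conv123(self, tiny_spec):
        model = F.build_architecture(tiny_spec, rng=np.random.default_rng(0))
        mask = F.apply_freeze(model, 3)
        for name, trainable in mask.items():
            expect = not name.startswith(("conv1.", "conv2.", "conv3."))
            assert trainable == expect, name

    def test_freeze_zero_everything_trainable(self, tiny_spec):
        model = F.build_architecture(tiny_spec, rng=np.random.default_rng(0))
        assert all(F.apply_freeze(model, 0).values())

    def test_freeze_out_of_range_rejected(self, tiny_spec):
        model = F.build_architecture(tiny_spec, rng=np.random.default_rng(0))
        with pytest.raises(ValueError):
            F.apply_freeze(model, 6)

    def test_no_weights_file_reports_all_unmatched(self, tiny_spec):
        model = F.build_architecture(tiny_spec, rng=np.random.default_rng(0))
        report = F.load_initial_weights(model, None)
        assert report["matched"] == [] and len(report["unmatched"]) == len(model.params)

    def test_transfer_with_channel_slice_rule(self, tmp_path, tiny_spec):
        """Loading a plain-backbone checkpoint into FMC copies conv5's original
        input-channel slice and leaves only the widened slice scheme-initialized."""
        base = F.build_architecture(F.ArchitectureSpec(variant="base", size_profile="tiny"),
                                    rng=np.random.default_rng(1))
        F.save_checkpoint(base, tmp_path / "base.npz")
        fmc = F.build_architecture(tiny_spec, rng=np.random.default_rng(2))
        before = fmc.params["conv5.weight"].data.copy()
        report = F.load_initial_weights(fmc, tmp_path / "base.npz")
        assert "conv5.weight" in report["sliced"]
        assert "conv1.weight" in report["matched"]
        got = fmc.params["conv5.weight"].data
        assert np.array_equal(got[:, :, :48, :], base.params["conv5.weight"].data)
        assert np.array_equal(got[:, :, 48:, :], before[:, :, 48:, :])
        # base has no merged layer, so the projection stays scheme-initialized
        assert "merged.proj.weight" in report["unmatched"]


@pytest.fixture(scope="module")
def micro_splits():
    cfg = F.SyntheticConfig(n_samples=40, seed=13)
    images, labels, _, _ = F.generate_arrays(cfg)
    splits, _ = make_split_tensors(images, labels, seed=13)
    return splits


class TestTrainLoop:
    def test_zero_lr_zero_decay_leaves_weights_exact(self, tiny_spec, micro_splits):
        model = F.build_architecture(tiny_spec, rng=np.random.default_rng(3))
        before = model.state_dict()
        cfg = F.TrainConfig(epochs=1, batch_size=8, learning_rate=0.0,
                            momentum=0.95, weight_decay=0.0,
                            freeze_first_n_conv=0, seed=0)
        model, _ = F.train(model, micro_splits, cfg)
        after = model.state_dict()
        assert all(np.array_equal(before[k], after[k]) for k in before)

    def test_frozen_layers_bit_identical_after_training(self, tiny_spec, micro_splits):
        model = F.build_architecture(tiny_spec, rng=np.random.default_rng(4))
        before = parameter_checksums(model)
        cfg = F.TrainConfig(epochs=2, batch_size=16, learning_rate=1e-3,
                            momentum=0.9, weight_decay=1e-6,
                            freeze_first_n_conv=3, seed=1)
        model, _ = F.train(model, micro_splits, cfg)
        after = parameter_checksums(model)
        for name in before:
            if name.startswith(("conv1.", "conv2.", "conv3.")):
                assert after[name] == before[name], name

    def test_training_loss_decreases_on_separated_data(self, trained_tiny):
        hist = trained_tiny["history"]
        assert hist.train_loss[4] < hist.train_loss[0]
        assert min(hist.train_loss) == pytest.approx(hist.train_loss[-1], abs=0.5)

    def test_history_determinism(self, tiny_spec, micro_splits):
        runs = []
        for _ in range(2):
            model = F.build_architecture(tiny_spec, rng=np.random.default_rng(5))
            _, hist = F.train(model, micro_splits,
                              F.from_scratch_config(seed=5, epochs=2))
            runs.append(hist.to_frame())
        assert runs[0].equals(runs[1])

    def test_history_length_matches_epochs(self, trained_tiny):
        hist = trained_tiny["history"]
        assert len(hist.train_loss) == len(hist.train_acc) == len(hist.val_acc) == 20

    def test_divergence_detected(self, tiny_spec, micro_splits):
        model = F.build_architecture(tiny_spec, rng=np.random.default_rng(6))
        model.params["classifier.weight"].data[:] = np.inf
        with pytest.raises(TrainingDivergedError):
            F.train(model, micro_splits, F.from_scratch_config(seed=0, epochs=1))


class TestCheckpoints:
    def test_roundtrip_preserves_predictions(self, tmp_path, trained_tiny):
        model = trained_tiny["model"]
        x, _ = trained_tiny["splits"]["test"]
        F.save_checkpoint(model, tmp_path / "ckpt.npz")
        restored = F.load_checkpoint(tmp_path / "ckpt.npz")
        assert restored.spec == model.spec
        assert np.array_equal(restored.predict_proba(x[:8]), model.predict_proba(x[:8]))

    def test_corrupt_checkpoint_raises_clean_error(self, tmp_path):
        bad = tmp_path / "bad.npz"
        bad.write_bytes(b"not a checkpoint")
        with pytest.raises(OSError, match="checkpoint"):
            F.load_checkpoint(bad)

    def test_clone_is_independent(self, trained_tiny):
        model = trained_tiny["model"]
        clone = clone_model(model)
        clone.params["classifier.bias"].data += 1.0
        assert not np.array_equal(clone.params["classifier.bias"].data,
                                  model.params["classifier.bias"].data)
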