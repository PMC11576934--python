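import numpy as np
import pytest

from hypoparc.lut_io import HypoparcError, ParameterError, Volume
from hypoparc.network import NetworkConfig, build_fcnn
from hypoparc.train_engine import (
    AdamW,
    TrainConfig,
    augment_affine,
    augment_bias_field,
    combined_loss,
    external_scale_augment,
    median_frequency_weights,
    rng_streams,
    sample_modality_mode,
    softmax,
    train,
)

from conftest import make_volume


class TestMedianFrequencyWeights:
    def test_equal_counts_give_unit_weights(self):
        w = median_frequency_weights({0: 50, 1: 50, 2: 50})
        assert all(abs(v - 1.0) < 1e-12 for v in w.values())

    def test_hand_computed_example(self):
        w = median_frequency_weights({0: 900, 1: 90, 2: 10})
        assert w[0] == pytest.approx(0.1)
        assert w[1] == pytest.approx(1.0)
        assert w[2] == pytest.approx(9.0)

    def test_single_class_and_zero_count(self):
        w = median_frequency_weights({0: 100, 5: 0})
        assert w[0] == pytest.approx(1.0)
        assert w[5] == 0.0

    def test_empty_histogram_rejected(self):
        with pytest.raises(HypoparcError):
            median_frequency_weights({})


class TestCombinedLoss:
    def test_perfect_prediction_limit(self, rng):
        y = rng.integers(0, 3, size=(1, 6, 6))
        logits = np.full((1, 3, 6, 6), -40.0)
        for c in range(3):
            logits[0, c][y[0] == c] = 40.0
        loss, _, parts = combined_loss(logits, y)
        assert loss <= 1e-4

    def test_uniform_two_class_ce_is_ln2(self):
        logits = np.zeros((1, 2, 4, 4))
        y = np.zeros((1, 4, 4), dtype=int)
        _, _, parts = combined_loss(logits, y)
        assert parts["ce"] == pytest.approx(np.log(2), rel=1e-12)

    def test_dice_term_zero_on_self(self, rng):
        y = rng.integers(0, 3, size=(2, 5, 5))
        logits = np.where(
            np.arange(3)[None, :, None, None] == y[:, None], 60.0, -60.0
        )
        _, _, parts = combined_loss(logits, y)
        assert parts["dice"] == pytest.approx(0.0, abs=1e-9)

    def test_gradient_matches_finite_differences(self, rng):
        logits = rng.normal(size=(2, 3, 4, 4))
        y = rng.integers(0, 3, size=(2, 4, 4))
        w = np.array([0.5, 1.0, 2.0])
        loss, grad, _ = combined_loss(logits, y, w)
        eps = 1e-6
        for _ in range(10):
            idx = tuple(rng.integers(0, s) for s in logits.shape)
            lp = combined_loss(logits + eps * _one_at(logits.shape, idx), y, w)[0]
            lm = combined_loss(logits - eps * _one_at(logits.shape, idx), y, w)[0]
            assert grad[idx] == pytest.approx((lp - lm) / (2 * eps), rel=1e-4, abs=1e-9)

    def test_out_of_range_label_rejected(self):
        with pytest.raises(HypoparcError):
            combined_loss(np.zeros((1, 2, 3, 3)), np.full((1, 3, 3), 5))


def _one_at(shape, idx):
    e = np.zeros(shape)
    e[idx] = 1.0
    return e


class TestModalityDropout:
    def test_warmup_always_both(self):
        rng = np.random.default_rng(0)
        assert all(
            sample_modality_mode(5, rng, start_epoch=10) == "t1t2" for _ in range(200)
        )

    def test_deterministic_given_seed(self):
        seq1 = [sample_modality_mode(50, np.random.default_rng(9)) for _ in range(1)]
        a = np.random.default_rng(42)
        b = np.random.default_rng(42)
        s1 = [sample_modality_mode(20, a) for _ in range(100)]
        s2 = [sample_modality_mode(20, b) for _ in range(100)]
        assert s1 == s2

    def test_negative_epoch_rejected(self):
        with pytest.raises(ParameterError):
            sample_modality_mode(-1, np.random.default_rng(0))


class TestAugmentations:
    def test_identity_affine_ranges(self, rng):
        cfg = TrainConfig(
            affine_translation_mm=(0.0, 0.0),
            affine_rotation_deg=(0.0, 0.0),
            affine_scale=(1.0, 1.0),
        )
        vol = make_volume(rng.random((10, 10, 10)))
        out = augment_affine({"T1": vol}, rng, cfg)["T1"]
        np.testing.assert_allclose(out.data, vol.data, atol=1e-12)

    def test_affine_reproducible(self, rng):
        cfg = TrainConfig()
        vol = make_volume(rng.random((10, 10, 10)))
        a = augment_affine({"T1": vol}, np.random.default_rng(5), cfg)["T1"]
        b = augment_affine({"T1": vol}, np.random.default_rng(5), cfg)["T1"]
        np.testing.assert_array_equal(a.data, b.data)

    def test_rotation_moves_bright_voxel_to_predicted_place(self):
        # rotate a single bright voxel by a sampled small-angle transform and
        # verify it lands within one voxel of the analytic coordinate
        from hypoparc.train_engine import sample_affine, _rotation_matrix

        cfg = TrainConfig(affine_translation_mm=(0.0, 0.0))
        rng = np.random.default_rng(3)
        trans, rot, scale = sample_affine(np.random.default_rng(3), cfg)
        data = np.zeros((21, 21, 21))
        src = np.array([15, 10, 10])
        data[tuple(src)] = 100.0
        vol = make_volume(data)
        out = augment_affine({"T1": vol}, np.random.default_rng(3), cfg)["T1"]
        center = (np.asarray(vol.shape) - 1) / 2
        expected = center + _rotation_matrix(rot) * scale @ (src - center)
        peak = np.unravel_index(np.argmax(out.data), out.data.shape)
        assert np.linalg.norm(np.asarray(peak) - expected) <= np.sqrt(3.0)

    def test_bias_field_identity_positive_and_label_guard(self, rng):
        vol = make_volume(rng.random((8, 8, 8)) + 0.5)
        same = augment_bias_field(vol, np.random.default_rng(0), (0.0, 0.0))
        np.testing.assert_allclose(same.data, vol.data)
        biased = augment_bias_field(vol, np.random.default_rng(0), (-0.5, 0.5))
        assert biased.data.min() > 0
        lab = make_volume(np.zeros((8, 8, 8), dtype=np.int32), modality="LABEL")
        with pytest.raises(HypoparcError):
            augment_bias_field(lab, rng)

    def test_external_scale_resamples_grid_and_metadata(self, rng):
        vol = make_volume(rng.random((40, 40, 40)), (0.8, 0.8, 0.8))
        lab = make_volume(
            rng.integers(0, 3, size=(40, 40, 40)).astype(np.int32),
            (0.8, 0.8, 0.8),
            modality="LABEL",
        )
        out = external_scale_augment(
            {"T1": vol, "LABEL": lab}, np.random.default_rng(0), (1.0, 1.0)
        )
        assert out["T1"].shape == (32, 32, 32)
        assert out["T1"].voxel_size == (1.0, 1.0, 1.0)
        assert set(np.unique(out["LABEL"].data)) <= set(np.unique(lab.data))


class TestSchedule:
    def test_step_learning_rate(self):
        cfg = TrainConfig()  # full-scale defaults: 0.05 -> 0.005 after epoch 70
        assert cfg.lr_at(69) == 0.05
        assert cfg.lr_at(71) == 0.005

    def test_invalid_config_rejected(self):
        with pytest.raises(ParameterError):
            TrainConfig(lr_initial=0.01, lr_late=0.05)
        with pytest.raises(ParameterError):
            TrainConfig(epochs=10, lr_switch_epoch=20)


class TestTrainLoop:
    @staticmethod
    def _toy_stacks(n=8, seed=0):
        from hypoparc.lut_io import SliceStack

        rng = np.random.default_rng(seed)
        stacks = []
        for _ in range(n):
            lab = np.zeros((12, 12), dtype=np.int32)
            lab[3:9, 3:9] = 1
            t1 = np.where(lab > 0, 0.9, 0.1) + rng.normal(0, 0.05, (12, 12))
            t2 = np.where(lab > 0, 0.2, 0.8) + rng.normal(0, 0.05, (12, 12))
            stacks.append(
                SliceStack(
                    plane="coronal",
                    arrays={
                        "T1": np.repeat(t1[None], 3, axis=0),
                        "T2": np.repeat(t2[None], 3, axis=0),
                    },
                    in_plane_resolution=(0.8, 0.8),
                    center_index=0,
                    label=lab,
                )
            )
        return stacks

    @staticmethod
    def _tiny_cfg(epochs=2, seed=0):
        return TrainConfig(
            epochs=epochs,
            batch_size=4,
            lr_initial=0.01,
            lr_late=0.001,
            lr_switch_epoch=max(0, epochs - 1),
            modality_dropout_start_epoch=1,
            seed=seed,
        )

    @staticmethod
    def _tiny_net(seed=0):
        cfg = NetworkConfig(
            n_classes=2, inner_channels=6, outer_channels=4, stack_thickness=3, n_scales=3
        )
        return build_fcnn(cfg, "coronal", seed=seed)

    def test_loss_decreases_on_separable_toy_problem(self):
        history = train(self._tiny_net(), self._toy_stacks(), self._tiny_cfg())
        assert history["loss"][-1] < history["loss"][0]

    def test_bitwise_reproducible(self):
        h1 = train(self._tiny_net(1), self._toy_stacks(), self._tiny_cfg(seed=3))
        h2 = train(self._tiny_net(1), self._toy_stacks(), self._tiny_cfg(seed=3))
        assert h1["loss"] == h2["loss"]
        assert h1["mode_counts"] == h2["mode_counts"]

    def test_no_dropout_before_warmup(self):
        cfg = self._tiny_cfg(epochs=1)
        cfg.modality_dropout_start_epoch = 10
        h = train(self._tiny_net(), self._toy_stacks(), cfg)
        assert h["mode_counts"][0]["t1_only"] == 0
        assert h["mode_counts"][0]["t2_only"] == 0

    def test_empty_dataset_rejected(self):
        with pytest.raises(HypoparcError):
            train(self._tiny_net(), [], self._tiny_cfg())


def test_adamw_decays_only_flagged_params():
    from hypoparc.network.layers import Param

    decayed = Param(np.array([1.0]), decay=True)
    plain = Param(np.array([1.0]), decay=False)
    opt = AdamW([decayed, plain], lr=0.1, weight_decay=1.0)
    opt.step()  # zero gradients: only weight decay moves the decayed param
    assert decayed.value[0] < 1.0
    assert plain.value[0] == 1.0


def test_rng_streams_are_independent_and_deterministic():
    a = rng_streams(7, ["x", "y"])
    b = rng_streams(7, ["x", "y"])
    assert a["x"].random() == b["x"].random()
    assert a["x"].random() != a["y"].random()
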