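import numpy as np
import pytest

from volseg import (
    AugmentParams,
    LabelMap,
    ModelConfig,
    SegmentationModel,
    TrainConfig,
    Volume,
    augment,
    segmentation_loss,
    sliding_window_predict,
    split_dataset,
    train,
)
from volseg.metrics import evaluate
from volseg.nn import Tensor
from volseg.runtime import EarlyStopper

from conftest import micro_encoder_config, tiny_encoder_config


def micro_model(num_classes=2, seed=0, **enc_overrides) -> SegmentationModel:
    cfg = ModelConfig(encoder=micro_encoder_config(**enc_overrides),
                      in_channels=1, num_classes=num_classes, init_seed=seed)
    return SegmentationModel(cfg)


class TestSplitDataset:
    def test_30_items_at_080_gives_24_6(self):
        train_items, test_items = split_dataset(list(range(30)), 0.8, seed=1)
        assert (len(train_items), len(test_items)) == (24, 6)

    def test_disjoint_and_exhaustive(self):
        items = list(range(17))
        a, b = split_dataset(items, 0.8, seed=3)
        assert sorted(a + b) == items
        assert not set(a) & set(b)

    def test_single_item_warns_and_keeps_it_in_train(self):
        with pytest.warns(UserWarning):
            a, b = split_dataset([42], 0.8, seed=0)
        assert (a, b) == ([42], [])

    def test_same_seed_same_split(self):
        items = list(range(20))
        assert split_dataset(items, 0.8, 7) == split_dataset(items, 0.8, 7)
        assert split_dataset(items, 0.8, 7) != split_dataset(items, 0.8, 8)


class TestAugment:
    def _pair(self, rng):
        vol = Volume(data=rng.normal(size=(12, 12, 12, 2)).astype(np.float32))
        labels = LabelMap(labels=rng.integers(0, 3, size=(12, 12, 12)),
                          num_classes=3)
        return vol, labels

    def test_zero_magnitude_is_identity(self, rng):
        vol, labels = self._pair(rng)
        params = AugmentParams(rotation_deg=0.0, scale_range=(1.0, 1.0),
                               elastic_alpha=0.0)
        v2, l2 = augment(vol, labels, params, seed=0)
        np.testing.assert_array_equal(v2.data, vol.data)
        np.testing.assert_array_equal(l2.labels, labels.labels)

    def test_labels_stay_subset_of_original_values(self, rng):
        vol, labels = self._pair(rng)
        v2, l2 = augment(vol, labels, AugmentParams(), seed=5)
        assert set(np.unique(l2.labels)) <= set(np.unique(labels.labels))
        assert l2.labels.dtype.kind in "iu"

    def test_seed_determinism(self, rng):
        vol, labels = self._pair(rng)
        a = augment(vol, labels, AugmentParams(), seed=9)
        b = augment(vol, labels, AugmentParams(), seed=9)
        np.testing.assert_array_equal(a[0].data, b[0].data)
        np.testing.assert_array_equal(a[1].labels, b[1].labels)

    def test_pair_stays_aligned(self, rng):
        vol, labels = self._pair(rng)
        _, l2 = augment(vol, labels, AugmentParams(), seed=2)
        rep = evaluate(l2, l2)
        assert rep.mean_dice == 1.0

    def test_misaligned_pair_rejected(self, rng):
        vol = Volume(data=rng.normal(size=(8, 8, 8, 1)))
        labels = LabelMap(labels=np.zeros((9, 9, 9), dtype=int), num_classes=2)
        with pytest.raises(ValueError):
            augment(vol, labels, AugmentParams(), seed=0)


class TestLoss:
    def test_uniform_logits_ce_is_log_k(self):
        k = 5
        labels = np.random.default_rng(0).integers(0, k, size=(4, 4, 4))
        logits = Tensor(np.zeros((4, 4, 4, k)))
        loss = segmentation_loss(logits, labels, k,
                                 dice_weight=0.0, ce_weight=1.0)
        assert float(loss.data) == pytest.approx(np.log(k), abs=1e-12)

    def test_saturated_one_hot_prediction_near_zero_loss(self):
        k = 3
        labels = np.random.default_rng(1).integers(0, k, size=(4, 4, 4))
        onehot = (labels[..., None] == np.arange(k)).astype(float)
        logits = Tensor(20.0 * onehot)
        loss = segmentation_loss(logits, labels, k)
        assert float(loss.data) < 1e-3

    def test_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(2)
        labels = rng.integers(0, 3, size=(4, 4, 4))
        logits = Tensor(rng.normal(size=(4, 4, 4, 3)), requires_grad=True)

        def f():
            return segmentation_loss(logits, labels, 3)

        f().backward()
        grad = logits.grad
        eps = 1e-6
        rng2 = np.random.default_rng(3)
        for _ in range(20):  # spot-check random coordinates
            idx = tuple(rng2.integers(0, s) for s in logits.data.shape)
            orig = logits.data[idx]
            logits.data[idx] = orig + eps
            lp = float(f().data)
            logits.data[idx] = orig - eps
            lm = float(f().data)
            logits.data[idx] = orig
            num = (lp - lm) / (2 * eps)
            rel = abs(num - grad[idx]) / (abs(num) + abs(grad[idx]) + 1e-12)
            assert rel < 1e-4


class TestEarlyStopping:
    def test_stops_after_patience_without_improvement(self):
        stopper = EarlyStopper(patience=3)
        stops = [stopper.update(0.5, e) for e in range(10)]
        # epoch 0 improves; epochs 1-3 do not; stop signalled at epoch 3
        assert stops.index(True) == 3
        assert stopper.best_epoch == 0

    def test_constant_validation_metric_stops_at_epoch_four(self,
                                                            micro_phantoms):
        model = micro_model()
        # negligible learning rate: the monitored dice cannot improve
        tc = TrainConfig(learning_rate=1e-30, max_epochs=10,
                         early_stop_patience=3, batch_size=2, seed=0,
                         augment=None)
        _, history = train(model, micro_phantoms, tc)
        assert history.stop_reason == "early_stop"
        assert len(history.records) == 4

    def test_returned_parameters_are_from_best_epoch(self, micro_phantoms):
        model = micro_model()
        tc = TrainConfig(learning_rate=3e-3, max_epochs=4,
                         early_stop_patience=10, batch_size=2, seed=0,
                         augment=None)
        model, history = train(model, micro_phantoms, tc)
        assert history.best_epoch == int(np.argmax(history.val_dices))

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError):
            train(micro_model(), [], TrainConfig())


class TestTrainDeterminism:
    def test_identical_configs_identical_histories(self, micro_phantoms):
        tc = TrainConfig(learning_rate=3e-3, max_epochs=2,
                         early_stop_patience=10, batch_size=2, seed=0)
        _, h1 = train(micro_model(seed=0), micro_phantoms, tc)
        _, h2 = train(micro_model(seed=0), micro_phantoms, tc)
        assert h1.records == h2.records

    def test_loss_decreases_on_learnable_phantoms(self, micro_phantoms):
        tc = TrainConfig(learning_rate=3e-3, max_epochs=6,
                         early_stop_patience=10, batch_size=2, seed=0,
                         augment=None)
        _, history = train(micro_model(), micro_phantoms, tc)
        assert history.train_losses[-1] < history.train_losses[0]


class TestSlidingWindow:
    def test_single_window_is_bit_identical_to_direct_forward(self,
                                                              rng):
        model = micro_model()
        vol = Volume(data=rng.normal(size=(16, 16, 16, 1)).astype(np.float32))
        direct = model.predict(vol)
        windowed = sliding_window_predict(model, vol, window=(16, 16, 16),
                                          overlap=0.5)
        np.testing.assert_array_equal(windowed.probabilities,
                                      direct.probabilities)

    def test_blending_is_partition_of_unity(self, rng):
        """A constant-probability model must stay constant after tiling."""
        model = micro_model(num_classes=3)
        model.decoder.head.weight.data[:] = 0.0
        model.decoder.head.bias.data[:] = 0.0
        vol = Volume(data=rng.normal(size=(24, 20, 28, 1)).astype(np.float32))
        out = sliding_window_predict(model, vol, window=(16, 16, 16),
                                     overlap=0.5)
        np.testing.assert_allclose(out.probabilities, 1.0 / 3.0, atol=1e-6)
        np.testing.assert_allclose(out.probabilities.sum(axis=-1), 1.0,
                                   atol=1e-6)

    def test_windowed_close_to_whole_volume_forward(self, rng):
        model = micro_model(num_classes=2, base_input_shape=(32, 32, 32))
        vol = Volume(data=rng.normal(size=(48, 48, 48, 1)).astype(np.float32))
        whole = model.predict(vol).probabilities
        tiled = sliding_window_predict(model, vol, window=(32, 32, 32),
                                       overlap=0.5).probabilities
        assert np.abs(tiled - whole).mean() < 0.05

    def test_window_below_model_minimum_rejected(self, rng):
        model = micro_model()
        vol = Volume(data=rng.normal(size=(32, 32, 32, 1)).astype(np.float32))
        with pytest.raises(ValueError, match="minimum"):
            sliding_window_predict(model, vol, window=(8, 8, 8))

    def test_invalid_overlap_rejected(self, rng):
        model = micro_model()
        vol = Volume(data=rng.normal(size=(16, 16, 16, 1)).astype(np.float32))
        with pytest.raises(ValueError):
            sliding_window_predict(model, vol, window=(16, 16, 16),
                                   overlap=1.0)


class TestCheckpointRoundTrip:
    def test_save_load_reproduces_predictions(self, tmp_path, rng):
        from volseg import load_checkpoint, save_checkpoint
        model = micro_model()
        vol = rng.normal(size=(16, 16, 16, 1)).astype(np.float32)
        before = model.predict(vol).probabilities
        save_checkpoint(model, tmp_path / "best.ckpt")
        loaded = load_checkpoint(tmp_path / "best.ckpt")
        np.testing.assert_array_equal(loaded.predict(vol).probabilities,
                                      before)
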