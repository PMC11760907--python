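import dataclasses

import numpy as np
import pytest

from vesselseg import ensemble as ens
from vesselseg.errors import ConfigurationError, DimensionMismatchError
from vesselseg.metrics import roc_auc
from vesselseg.nn import autograd as ag
from vesselseg.training_pipeline import TrainConfig


def fast_cfg(**kw):
    kw.setdefault("learning_rate", 0.01)
    kw.setdefault("epochs", 2)
    kw.setdefault("batch_size", 4)
    kw.setdefault("seed", 3)
    kw.setdefault("auc_max_pixels", None)
    return TrainConfig(**kw)


class TestStackPredictions:
    def test_channels_are_lossless(self, rng):
        maps = [rng.random((16, 16)) for _ in range(4)]
        stacked = ens.stack_predictions(maps, ens.CANONICAL_ORDER)
        assert stacked.tensor.shape == (16, 16, 4)
        for k in range(4):
            np.testing.assert_array_equal(stacked.tensor[..., k], maps[k])

    def test_permutation_permutes_channels(self, rng):
        maps = [rng.random((8, 8)) for _ in range(4)]
        names = list(ens.CANONICAL_ORDER)
        perm = [2, 0, 3, 1]
        a = ens.stack_predictions(maps, names)
        b = ens.stack_predictions([maps[i] for i in perm],
                                  [names[i] for i in perm])
        for j, i in enumerate(perm):
            np.testing.assert_array_equal(b.tensor[..., j], a.tensor[..., i])
            assert b.model_order[j] == names[i]
        np.testing.assert_array_equal(b.channel("unet"), a.channel("unet"))

    def test_too_few_maps(self, rng):
        with pytest.raises(ValueError):
            ens.stack_predictions([rng.random((4, 4))])

    def test_shape_mismatch(self, rng):
        with pytest.raises(DimensionMismatchError):
            ens.stack_predictions([rng.random((4, 4)), rng.random((5, 5))])


class TestMetaModel:
    def test_parameter_count_k4_hidden64(self):
        meta = ens.build_meta_model(4, hidden_filters=64, seed=0)
        # 3x3x4x64 hidden weights + (64 weights + 1 bias) in the 1x1 head
        assert sum(p.data.size for p in meta.parameters()) == 2369

    def test_forward_contract(self, rng):
        meta = ens.build_meta_model(4, seed=1)
        out = meta.predict(rng.random((3, 64, 64, 4)))
        assert out.shape == (3, 64, 64, 1)
        assert 0 < out.min() and out.max() < 1

    def test_two_input_meta_builds(self, rng):
        meta = ens.build_meta_model(2, seed=0)
        assert meta.predict(rng.random((8, 8, 2))).shape == (8, 8, 1)

    def test_k_below_two_rejected(self):
        with pytest.raises(ValueError):
            ens.build_meta_model(1)

    def test_channel_count_validated(self, rng):
        meta = ens.build_meta_model(4, seed=0)
        with pytest.raises(ConfigurationError):
            meta.predict(rng.random((8, 8, 3)))


class TestTrainMetaModel:
    def test_bases_bit_identical_after_training(self, small_models,
                                                small_split):
        bases = list(small_models.values())
        before = [m.parameter_hash() for m in bases]
        ens.train_meta_model(bases, small_split, fast_cfg())
        assert [m.parameter_hash() for m in bases] == before

    def test_zero_epochs_is_noop(self, small_models, small_split):
        bases = list(small_models.values())
        meta, hist = ens.train_meta_model(bases, small_split,
                                          fast_cfg(epochs=0))
        fresh = ens.build_meta_model(len(bases), seed=fast_cfg().seed)
        assert meta.parameter_hash() == fresh.parameter_hash()
        assert hist.records == []

    def test_converges_on_perfect_bases(self, small_split):
        """Two bases that already output the truth: a constant averaging of
        perfect inputs achieves near-zero BCE, so 50 epochs of meta training
        on 4 images must reach at most 0.05."""
        from vesselseg.io_datasets import DatasetSplit

        size = small_split.train[0].mask.shape
        samples = small_split.train + small_split.test
        four = DatasetSplit(train=samples[:4], test=samples[4:6])

        class Perfect:
            def __init__(self):
                self.spec = dataclasses.make_dataclass(
                    "S", ["input_size"])(size)
                self._lookup = {s.image.tobytes(): s.mask for s in samples}

            def predict(self, batch):
                out = [np.clip(self._lookup[img.tobytes()].astype(float),
                               0.02, 0.98) for img in batch]
                return np.stack(out)[..., None]

        bases = [Perfect(), Perfect()]
        meta, hist = ens.train_meta_model(
            bases, four, fast_cfg(epochs=50, batch_size=1,
                                  learning_rate=0.03))
        assert hist.records[-1]["train_bce"] <= 0.05

    def test_size_mismatch_rejected(self, small_models, small_split):
        bases = list(small_models.values())

        class Odd:
            spec = dataclasses.make_dataclass("S", ["input_size"])((64, 64))

        with pytest.raises(ConfigurationError):
            ens.train_meta_model(bases + [Odd()], small_split, fast_cfg())


class TestPredictEnsemble:
    def test_deterministic_and_contract(self, small_models, small_split):
        bases = list(small_models.values())
        meta, _ = ens.train_meta_model(bases, small_split, fast_cfg())
        img = small_split.test[0].image
        a = ens.predict_ensemble(bases, meta, img)
        b = ens.predict_ensemble(bases, meta, img)
        np.testing.assert_array_equal(a, b)
        assert a.shape == (*img.shape[:2], 1)
        assert 0 < a.min() and a.max() < 1

    def test_model_count_mismatch(self, small_models):
        meta = ens.build_meta_model(3, seed=0)
        bases = list(small_models.values())  # 4 models
        with pytest.raises(ConfigurationError):
            ens.predict_ensemble(bases, meta, np.zeros((32, 32, 3)))

    def test_passthrough_meta_preserves_auc(self, rng):
        """A meta hand-set to pass channel 0 through is a monotone transform
        of base 0, so its AUC equals base 0's."""
        meta = ens.build_meta_model(2, hidden_filters=4, seed=0)
        meta.conv1.weight.data[:] = 0
        meta.conv1.weight.data[0, 0, 1, 1] = 1.0   # hidden filter 0 = p0
        meta.conv2.weight.data[:] = 0
        meta.conv2.weight.data[0, 0, 0, 0] = 5.0   # logit = 5*p0 + b
        meta.conv2.bias.data[:] = -2.5
        # quantise so float32 inference cannot merge distinct ranks
        p0 = np.round(rng.random((16, 16)), 3)
        p1 = np.round(rng.random((16, 16)), 3)
        truth = (rng.random((16, 16)) < 0.3).astype(int)
        stacked = ens.stack_predictions([p0, p1])
        fused = meta.predict(stacked.tensor)[..., 0]
        assert roc_auc(fused, truth) == pytest.approx(roc_auc(p0, truth),
                                                      abs=1e-12)


class TestAblation:
    def test_default_subsets_structure(self):
        assert len(ens.DEFAULT_SUBSETS) == 10
        sizes = sorted(len(s) for s in ens.DEFAULT_SUBSETS)
        assert sizes == [2] * 5 + [3] * 4 + [4]
        assert len({tuple(sorted(s)) for s in ens.DEFAULT_SUBSETS}) == 10

    def test_default_run_yields_ten_rows(self, small_models, small_split):
        table = ens.run_ablation(small_models, None, small_split,
                                 fast_cfg(epochs=1))
        assert len(table) == 10
        assert list(table.columns) == ["Meta-Model", "Loss", "Acc", "SN",
                                       "SP", "AUC", "F1-Score"]
        assert table["Meta-Model"].iloc[-1] == "All architectures"

    def test_duplicate_subsets_identical_rows(self, small_models,
                                              small_split):
        sub = [["unet", "ctu_net"], ["unet", "ctu_net"]]
        table = ens.run_ablation(small_models, sub, small_split,
                                 fast_cfg(epochs=1))
        assert table.iloc[0].equals(table.iloc[1])

    def test_unknown_model_name(self, small_models, small_split):
        with pytest.raises(ValueError):
            ens.run_ablation(small_models, [["unet", "nope"]], small_split,
                             fast_cfg(epochs=1))


def test_meta_checkpoint_roundtrip(tmp_path, rng, small_models, small_split):
    bases = list(small_models.values())
    meta, _ = ens.train_meta_model(bases, small_split, fast_cfg(),
                                   model_order=list(small_models))
    path = tmp_path / "meta.npz"
    ens.save_meta_checkpoint(meta, path)
    loaded = ens.load_meta_checkpoint(path)
    x = rng.random((8, 8, 4))
    np.testing.assert_array_equal(loaded.predict(x), meta.predict(x))
    assert loaded.model_order == tuple(small_models)
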