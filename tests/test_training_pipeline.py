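import numpy as np
import pandas as pd
import pytest
import yaml

from vesselseg.architectures import ArchitectureSpec, build_model
from vesselseg.errors import ConfigurationError, TrainingDivergedError
from vesselseg.metrics import evaluate_model
from vesselseg.training_pipeline import (TrainConfig, run_experiment,
                                         train_segmentation_model)


def tiny_model(seed=5):
    return build_model(ArchitectureSpec(name="unet", input_size=(32, 32),
                                        base_channels=4, depth=2, seed=seed))


def cfg(**kw):
    kw.setdefault("learning_rate", 1e-3)
    kw.setdefault("epochs", 3)
    kw.setdefault("batch_size", 4)
    kw.setdefault("seed", 2)
    kw.setdefault("auc_max_pixels", None)
    return TrainConfig(**kw)


class TestTrainConfig:
    def test_steps_per_epoch_clamps_to_one(self):
        assert TrainConfig(batch_size=32).steps_per_epoch(20) == 1

    def test_steps_per_epoch_floor(self):
        assert TrainConfig(batch_size=8).steps_per_epoch(40) == 5
        assert TrainConfig(batch_size=8).steps_per_epoch(47) == 5

    def test_total_step_accounting_identity(self):
        """Halving the epochs while doubling steps/epoch (half the batch
        size) keeps the optimizer-step budget constant."""
        a = TrainConfig(epochs=10, batch_size=8)
        b = TrainConfig(epochs=5, batch_size=4)
        assert a.epochs * a.steps_per_epoch(40) == \
            b.epochs * b.steps_per_epoch(40)

    def test_invalid_values(self):
        with pytest.raises(ConfigurationError):
            TrainConfig(learning_rate=0)
        with pytest.raises(ConfigurationError):
            TrainConfig(batch_size=0)
        with pytest.raises(ConfigurationError):
            TrainConfig(optimizer="sgd")

    def test_protocol_defaults(self):
        c = TrainConfig()
        assert (c.learning_rate, c.epochs, c.batch_size,
                c.checkpoint_metric) == (0.01, 500, 32, "val_loss")


class TestTrainSegmentationModel:
    def test_zero_epochs_noop(self, small_split):
        model = tiny_model()
        before = model.parameter_hash()
        out, hist = train_segmentation_model(model, small_split,
                                             cfg(epochs=0))
        assert out.parameter_hash() == before
        assert hist.records == []

    def test_empty_train_set_rejected(self, small_split):
        from vesselseg.io_datasets import DatasetSplit
        empty = DatasetSplit(train=[], test=small_split.test)
        with pytest.raises(ValueError):
            train_segmentation_model(tiny_model(), empty, cfg())

    def test_size_mismatch_rejected(self, small_split):
        model = build_model(ArchitectureSpec(name="unet",
                                             input_size=(64, 64),
                                             base_channels=4, seed=0))
        with pytest.raises(ConfigurationError):
            train_segmentation_model(model, small_split, cfg())

    @pytest.mark.filterwarnings("ignore::RuntimeWarning")
    def test_divergence_is_reported_with_location(self, small_split):
        model = tiny_model()
        model.net.head.weight.data[:] = np.inf
        with pytest.raises(TrainingDivergedError, match="epoch 0"):
            train_segmentation_model(model, small_split, cfg())

    def test_checkpoint_is_first_best_epoch(self, small_split):
        model, hist = train_segmentation_model(tiny_model(), small_split,
                                               cfg(epochs=4))
        val = [r["val_bce"] for r in hist.records]
        assert hist.best_val_loss == min(val)
        assert hist.best_epoch == val.index(min(val))

    def test_restored_checkpoint_reproduces_best_val_loss(self, small_split):
        c = cfg(epochs=4)
        model, hist = train_segmentation_model(tiny_model(), small_split, c)
        rep = evaluate_model(model, small_split.test,
                             auc_max_pixels=c.auc_max_pixels, seed=c.seed)
        assert rep.loss == pytest.approx(hist.best_val_loss, abs=1e-6)

    def test_seeded_reproducibility(self, small_split):
        a, _ = train_segmentation_model(tiny_model(), small_split, cfg())
        b, _ = train_segmentation_model(tiny_model(), small_split, cfg())
        assert a.parameter_hash() == b.parameter_hash()

    def test_history_columns(self, small_split):
        _, hist = train_segmentation_model(tiny_model(), small_split,
                                           cfg(epochs=2))
        frame = hist.to_dataframe()
        for col in ("epoch", "train_bce", "val_bce", "val_acc", "val_auc",
                    "val_f1"):
            assert col in frame.columns


EXPERIMENT_CONFIG = {
    "seed": 3,
    "data": {"source": "synthetic", "n": 8, "image_size": [32, 32],
             "n_train": 6},
    "architectures": [
        {"name": "unet", "base_channels": 4},
        {"name": "resnet50_seg", "base_channels": 4},
        {"name": "ctu_net", "base_channels": 4},
        {"name": "unet_resnet_backbone", "base_channels": 4},
    ],
    "training": {"learning_rate": 1e-3, "epochs": 2, "batch_size": 4,
                 "auc_max_pixels": None},
    "ensemble": {"hidden_filters": 16, "epochs": 2},
}


@pytest.fixture(scope="module")
def experiment_dirs(tmp_path_factory):
    root = tmp_path_factory.mktemp("exp")
    cfg_path = root / "cfg.yaml"
    cfg_path.write_text(yaml.safe_dump(EXPERIMENT_CONFIG))
    out1 = run_experiment(cfg_path, out_dir=root / "run1")
    out2 = run_experiment(cfg_path, out_dir=root / "run2")
    return out1, out2


class TestRunExperiment:
    def test_outputs_complete(self, experiment_dirs):
        out, _ = experiment_dirs
        for name in ("unet", "resnet50_seg", "ctu_net",
                     "unet_resnet_backbone", "meta"):
            assert (out / "checkpoints" / f"{name}.npz").exists()
            assert (out / "histories" / f"{name}.csv").exists()
        assert (out / "manifest.json").exists()
        assert (out / "split.csv").exists()
        assert list((out / "predictions").glob("*.png"))

    def test_report_schema_includes_meta_row(self, experiment_dirs):
        out, _ = experiment_dirs
        frame = pd.read_csv(out / "report.csv", index_col=0)
        assert list(frame.columns) == ["Loss", "Acc", "SN", "SP", "AUC",
                                       "F1-Score"]
        assert "Meta-model" in frame.index
        assert len(frame) == 5

    def test_rerun_is_byte_identical(self, experiment_dirs):
        out1, out2 = experiment_dirs
        assert (out1 / "report.csv").read_bytes() == \
            (out2 / "report.csv").read_bytes()

    def test_invalid_config_lists_missing_keys(self, tmp_path):
        p = tmp_path / "bad.yaml"
        p.write_text(yaml.safe_dump({"data": {"source": "synthetic"}}))
        with pytest.raises(ConfigurationError, match="architectures"):
            run_experiment(p)

    def test_real_source_requires_directories(self, tmp_path):
        bad = dict(EXPERIMENT_CONFIG, data={"source": "real"})
        p = tmp_path / "bad.yaml"
        p.write_text(yaml.safe_dump(bad))
        with pytest.raises(ConfigurationError, match="images_dir"):
            run_experiment(p)
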