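"""End-to-end model assembly, training loop, checkpointing, prediction."""

from dataclasses import replace

import numpy as np
import pytest

from dme_deeplab import (
    ModelConfig,
    TrainingConfig,
    build_model,
    load_checkpoint,
    save_checkpoint,
    train,
)
from dme_deeplab.train import predict, evaluate_dirs, list_pairs, _dataset_miou, _load_split

from conftest import compact_model_config


def tiny_train_config(**kw):
    defaults = dict(learning_rate=0.01, total_epochs=2, batch_size=4,
                    input_size=64, seed=5, model=compact_model_config())
    defaults.update(kw)
    return TrainingConfig(**defaults)


class TestBuildModel:
    def test_shape_contract_512(self, rng):
        model = build_model(compact_model_config())
        x = rng.random((1, 3, 64, 64)).astype(np.float32)
        assert model(x).shape == (1, 2, 64, 64)

    def test_same_seed_same_parameters(self):
        a = build_model(compact_model_config(seed=9))
        b = build_model(compact_model_config(seed=9))
        assert a.checksum() == b.checksum()
        c = build_model(compact_model_config(seed=10))
        assert a.checksum() != c.checksum()

    def test_non_multiple_of_16_rejected(self, rng):
        model = build_model(compact_model_config())
        with pytest.raises(ValueError, match="16"):
            model(rng.random((1, 3, 72, 72)))

    def test_lightweight_beats_dense_parallel_baseline(self):
        # full-width default vs the heavier ablation build (dense backbone,
        # classical parallel ASPP); the separable advantage needs realistic
        # widths, hence width 1.0 here
        light = build_model(ModelConfig())
        heavy = build_model(ModelConfig(
            backbone_variant="dense",
            aspp=replace(ModelConfig().aspp, mode="baseline_parallel",
                         rates=(1, 6, 12, 18))))
        assert light.num_parameters() < heavy.num_parameters()

    def test_bad_variant_names_offending_stage(self):
        with pytest.raises(ValueError, match="backbone"):
            build_model(replace(compact_model_config(), backbone_variant="vgg"))


class TestTrainingLoop:
    def test_loss_decreases_over_two_epochs(self, tiny_dataset):
        root, _ = tiny_dataset
        res = train(tiny_train_config(), root / "train")
        losses = [e["train_loss"] for e in res["log"]]
        assert losses[1] < losses[0]

    def test_zero_learning_rate_leaves_parameters_unchanged(self, tiny_dataset):
        root, _ = tiny_dataset
        model = build_model(compact_model_config(seed=5))
        before = model.checksum()
        cfg = tiny_train_config(learning_rate=0.0, total_epochs=1)
        train(cfg, root / "train", model=model)
        # parameters untouched; only batch-norm running stats may move
        after_params = [p.data.copy() for p in model.parameters()]
        model2 = build_model(compact_model_config(seed=5))
        for p, q in zip(after_params, model2.parameters()):
            np.testing.assert_array_equal(p, q.data)

    def test_identical_seeded_runs_have_identical_checksums(self, tiny_dataset):
        root, _ = tiny_dataset
        a = train(tiny_train_config(), root / "train")["model"].checksum()
        b = train(tiny_train_config(), root / "train")["model"].checksum()
        assert a == b

    def test_resume_reproduces_uninterrupted_run(self, tiny_dataset, tmp_path):
        root, _ = tiny_dataset
        cfg3 = tiny_train_config(total_epochs=3)
        full = train(cfg3, root / "train")
        cfg2 = tiny_train_config(total_epochs=2)
        train(cfg2, root / "train", out_dir=tmp_path)
        resumed = train(cfg3, root / "train", resume_from=tmp_path / "last.npz")
        assert resumed["log"][-1]["train_loss"] == full["log"][-1]["train_loss"]
        assert resumed["model"].checksum() == full["model"].checksum()

    def test_poly_schedule_decays_lr(self, tiny_dataset):
        root, _ = tiny_dataset
        res = train(tiny_train_config(lr_schedule="poly", total_epochs=2),
                    root / "train")
        lrs = [e["lr"] for e in res["log"]]
        assert lrs[1] < lrs[0] == 0.01

    def test_missing_mask_is_named(self, tmp_path):
        (tmp_path / "orphan.png").write_bytes(b"")
        with pytest.raises(FileNotFoundError, match="orphan"):
            list_pairs(tmp_path)


class TestCheckpointAndPredict:
    def test_checkpoint_roundtrip_preserves_outputs(self, tmp_path, rng):
        model = build_model(compact_model_config(seed=2))
        model.eval()
        x = rng.random((1, 3, 64, 64)).astype(np.float32)
        expected = model(x)
        save_checkpoint(model, tmp_path / "m.npz", extra={"note": "roundtrip"})
        loaded, extra = load_checkpoint(tmp_path / "m.npz")
        loaded.eval()
        np.testing.assert_array_equal(loaded(x), expected)
        assert extra["note"] == "roundtrip"

    def test_predict_writes_binary_pngs_and_fps(self, tiny_dataset, tmp_path):
        from PIL import Image

        root, manifest = tiny_dataset
        model = build_model(compact_model_config(seed=2))
        images = [root / e["image"] for e in manifest["splits"]["test"]]
        info = predict(model, images, tmp_path, input_size=64)
        assert info["fps"] > 0 and len(info["masks"]) == 2
        arr = np.asarray(Image.open(info["masks"][0]))
        assert set(np.unique(arr)) <= {0, 255}

    def test_evaluate_dirs_matches_direct_computation(self, tiny_dataset, tmp_path):
        root, manifest = tiny_dataset
        # use the ground-truth masks as "predictions" -> perfect scores
        import shutil

        pred_dir = tmp_path / "preds"
        pred_dir.mkdir()
        for e in manifest["splits"]["test"]:
            stem = (root / e["mask"]).stem.replace("_mask", "")
            shutil.copy(root / e["mask"], pred_dir / f"{stem}_pred.png")
        report = evaluate_dirs(pred_dir, root / "test", overlay_dir=tmp_path / "ov")
        assert report["micro"]["MIoU"] == pytest.approx(100.0)
        assert (tmp_path / "ov").exists()


class TestConvergenceSmoke:
    def test_short_training_learns_the_phantom_task(self, tiny_dataset):
        # 14 epochs on 8 tiny phantoms converge far enough that the model
        # beats MIoU 0.5 on its own training images and produces near-empty
        # masks on a lesion-free phantom.
        from dme_deeplab import PhantomSpec, generate_phantom

        root, _ = tiny_dataset
        cfg = tiny_train_config(total_epochs=14)
        res = train(cfg, root / "train")
        model = res["model"]
        xs, ys = _load_split(root / "train", 64)
        assert _dataset_miou(model, xs, ys) > 0.5
        blank_img, _ = generate_phantom(PhantomSpec(height=64, width=64,
                                                    n_lesions=0, seed=77))
        x = np.repeat(blank_img[None, None], 3, axis=1).astype(np.float32)
        blank_pred = model.predict_mask(x)
        assert blank_pred.mean() < 0.05
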