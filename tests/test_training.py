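import dataclasses

import numpy as np
import pytest

from efnet.data_io import EchoDataset, GrayVideo, VideoRecord
from efnet.training import (
    TrainConfig,
    clip_indices,
    fit,
    lr_at,
    make_splits,
    sample_clip,
)
from tests.conftest import TINY_MODEL

TINY_TRAIN = TrainConfig(epochs=2, batch_size=4, lr0=1e-3, clip_len=8, seed=9, augment=False)


def _stub_records(n):
    return [
        VideoRecord(
            video_id=f"v{i:05d}", ef=50.0, edv=100.0, esv=50.0, fps=50.0,
            n_frames=32, ed_frame=0, es_frame=8, split="TRAIN",
        )
        for i in range(n)
    ]


class TestLrSchedule:
    @pytest.mark.parametrize("epoch,expected", [(0, 1e-4), (15, 1e-4), (16, 1e-5), (31, 1e-5), (32, 1e-6), (44, 1e-6)])
    def test_step_decay(self, epoch, expected):
        assert lr_at(epoch, TrainConfig()) == pytest.approx(expected, rel=1e-9)

    def test_negative_epoch_rejected(self):
        with pytest.raises(ValueError):
            lr_at(-1, TrainConfig())


class TestSplits:
    def test_exact_fractions(self):
        assignment = make_splits(_stub_records(100), (0.8, 0.1, 0.1), seed=0)
        counts = {s: list(assignment.values()).count(s) for s in ("TRAIN", "VAL", "TEST")}
        assert counts == {"TRAIN": 80, "VAL": 10, "TEST": 10}

    def test_cohort_scale_floor_arithmetic(self):
        assignment = make_splits(_stub_records(10030), (0.8, 0.1, 0.1), seed=1)
        counts = {s: list(assignment.values()).count(s) for s in ("TRAIN", "VAL", "TEST")}
        assert counts == {"TRAIN": 8024, "VAL": 1003, "TEST": 1003}

    def test_remainders_go_to_train(self):
        assignment = make_splits(_stub_records(7), (0.8, 0.1, 0.1), seed=0)
        counts = {s: list(assignment.values()).count(s) for s in ("TRAIN", "VAL", "TEST")}
        assert counts == {"TRAIN": 7, "VAL": 0, "TEST": 0}

    def test_deterministic_and_seed_sensitive(self):
        records = _stub_records(50)
        assert make_splits(records, seed=5) == make_splits(records, seed=5)
        assert make_splits(records, seed=5) != make_splits(records, seed=6)

    def test_empty_input(self):
        assert make_splits([], seed=0) == {}

    def test_bad_fractions_rejected(self):
        with pytest.raises(ValueError):
            make_splits(_stub_records(5), (0.5, 0.2, 0.2), seed=0)


class TestClipSampling:
    def test_window_equal_to_clip_is_forced(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            idx = clip_indices(40, ed_frame=10, es_frame=17, clip_len=8, rng=rng)
            np.testing.assert_array_equal(idx, np.arange(10, 18))

    def test_short_video_repeats_last_frame(self):
        rng = np.random.default_rng(0)
        idx = clip_indices(4, ed_frame=0, es_frame=3, clip_len=16, rng=rng)
        np.testing.assert_array_equal(idx, [0, 1, 2, 3] + [3] * 12)

    def test_clip_stays_inside_long_window(self):
        rng = np.random.default_rng(7)
        for _ in range(1000):
            idx = clip_indices(200, ed_frame=150, es_frame=50, clip_len=16, rng=rng)
            assert idx.min() >= 50 and idx.max() <= 150
            np.testing.assert_array_equal(np.diff(idx), 1)

    def test_short_window_extends_into_video(self):
        rng = np.random.default_rng(0)
        idx = clip_indices(64, ed_frame=30, es_frame=33, clip_len=8, rng=rng)
        assert idx.size == 8
        assert set(range(30, 34)) <= set(idx.tolist())
        np.testing.assert_array_equal(np.diff(idx), 1)

    def test_invalid_clip_len(self):
        with pytest.raises(ValueError):
            clip_indices(10, 0, 5, 0, np.random.default_rng(0))

    def test_sampled_clip_is_normalized(self, small_phantom_dataset):
        rec = small_phantom_dataset.records[0]
        video = small_phantom_dataset.load_video(rec.video_id)
        clip = sample_clip(video, rec, 8, np.random.default_rng(0))
        assert clip.shape == (8, 1, 16, 16)
        assert clip.min() >= -1.0 and clip.max() <= 1.0


class TestFit:
    def test_two_video_overfit_drives_loss_down(self, tmp_path):
        from efnet.phantom import generate_phantom_dataset

        root = generate_phantom_dataset(
            2, seed=4, out_dir=tmp_path / "ds", image_size=16,
            cycle_frames=8, n_cycles=2, speckle_sigma=0.05,
        )
        cfg = TrainConfig(
            epochs=600, batch_size=2, lr0=1e-2, lr_step=400, clip_len=8,
            seed=2, augment=False,
        )
        _, logs = fit(root, TINY_MODEL, cfg)
        assert logs[-1].train_mse < 0.05 * logs[0].train_mse

    def test_identical_seeds_reproduce_epoch_zero(self, small_phantom_dataset):
        _, logs_a = fit(small_phantom_dataset, TINY_MODEL, dataclasses.replace(TINY_TRAIN, epochs=1))
        _, logs_b = fit(small_phantom_dataset, TINY_MODEL, dataclasses.replace(TINY_TRAIN, epochs=1))
        assert logs_a[0].train_mse == logs_b[0].train_mse
        assert logs_a[0].val_mae == logs_b[0].val_mae

    def test_logged_lr_follows_schedule(self, small_phantom_dataset):
        cfg = dataclasses.replace(TINY_TRAIN, epochs=3, lr_step=2)
        _, logs = fit(small_phantom_dataset, TINY_MODEL, cfg)
        for log in logs:
            assert log.lr == pytest.approx(lr_at(log.epoch, cfg))

    def test_test_split_is_never_read(self, small_phantom_root):
        class AuditingDataset(EchoDataset):
            def __init__(self, root):
                super().__init__(root)
                self.loaded = []

            def load_video(self, video_id):
                self.loaded.append(video_id)
                return super().load_video(video_id)

        dataset = AuditingDataset(small_phantom_root)
        fit(dataset, TINY_MODEL, dataclasses.replace(TINY_TRAIN, epochs=1))
        test_ids = {r.video_id for r in dataset.split_records("TEST")}
        assert test_ids  # the fixture does contain a TEST split
        assert not (set(dataset.loaded) & test_ids)

    def test_best_epoch_restore_and_checkpoint_agree_with_log(self, tmp_path, small_phantom_dataset):
        """The returned model, the on-disk checkpoint and the logged best
        validation MAE must all describe the same parameters AND the same
        batch-norm running statistics."""
        from efnet.evaluation import evaluate_split
        from efnet.model import load_checkpoint

        cfg = dataclasses.replace(TINY_TRAIN, epochs=3)
        model, logs = fit(small_phantom_dataset, TINY_MODEL, cfg, out_dir=tmp_path)
        best_logged = min(log.val_mae for log in logs)
        returned, _ = evaluate_split(small_phantom_dataset, model, split="VAL", clip_len=8)
        assert returned.mae == pytest.approx(best_logged, abs=1e-9)
        loaded = load_checkpoint(tmp_path / "best.npz")
        reloaded, _ = evaluate_split(small_phantom_dataset, loaded, split="VAL", clip_len=8)
        assert reloaded.mae == pytest.approx(returned.mae, abs=1e-9)

    def test_empty_train_split_rejected(self, tmp_path):
        from efnet.data_io import write_dataset

        rec = _stub_records(1)[0]
        rec = dataclasses.replace(rec, split="TEST")
        video = GrayVideo(np.zeros((32, 16, 16), dtype=np.uint8))
        write_dataset([rec], [video], tmp_path)
        with pytest.raises(ValueError, match="TRAIN"):
            fit(tmp_path, TINY_MODEL, TINY_TRAIN)
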