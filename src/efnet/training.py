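"""Clip sampling, split assignment and the MSE/Adam training loop.

Training clips are drawn from the ED-ES window of each video (the systolic
sweep that carries the EF signal); one clip per video per epoch.  The loss
is mean squared error on EF in percent units, optimized with Adam under a
step-decayed learning rate: lr(e) = lr0 * gamma^floor(e / step).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .augment import AugmentConfig, augment_clip
from .data_io import EchoDataset, GrayVideo, VideoRecord, normalize_frames
from .model import EFNet, ModelConfig, build_efnet, save_checkpoint
from .nn import Adam

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 45
    batch_size: int = 28
    lr0: float = 1e-4
    lr_gamma: float = 0.1
    lr_step: int = 16
    weight_decay: float = 1e-4
    clip_len: int = 16
    split_fractions: tuple[float, float, float] = (0.8, 0.1, 0.1)
    seed: int = 0
    augment: bool = True

    def __post_init__(self):
        if abs(sum(self.split_fractions) - 1.0) > 1e-9:
            raise ValueError(f"split fractions must sum to 1, got {self.split_fractions}")
        if self.clip_len < 1:
            raise ValueError(f"clip_len must be >= 1, got {self.clip_len}")
        for name in ("epochs", "batch_size"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        for name in ("lr0", "lr_gamma", "lr_step"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class EpochLog:
    epoch: int
    lr: float
    train_mse: float
    val_mse: float
    val_mae: float


def lr_at(epoch: int, config: TrainConfig) -> float:
    """Step decay: lr0 * gamma^floor(epoch / step)."""
    if epoch < 0:
        raise ValueError(f"epoch must be >= 0, got {epoch}")
    return config.lr0 * config.lr_gamma ** (epoch // config.lr_step)


def make_splits(
    records: list[VideoRecord],
    fractions: tuple[float, float, float] = (0.8, 0.1, 0.1),
    seed: int = 0,
) -> dict[str, str]:
    """Seeded shuffle, then contiguous TRAIN/VAL/TEST partition.

    Sizes are floor(n * f); leftover videos go to TRAIN.  A pure function of
    (ids, fractions, seed).
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError(f"fractions must sum to 1, got {fractions}")
    ids = [r.video_id for r in records]
    if not ids:
        return {}
    rng = np.random.default_rng(seed)
    order = [ids[i] for i in rng.permutation(len(ids))]
    n = len(ids)
    n_train = int(np.floor(n * fractions[0] + 1e-9))
    n_val = int(np.floor(n * fractions[1] + 1e-9))
    n_test = int(np.floor(n * fractions[2] + 1e-9))
    n_train += n - (n_train + n_val + n_test)
    assignment = {}
    for i, vid in enumerate(order):
        if i < n_train:
            assignment[vid] = "TRAIN"
        elif i < n_train + n_val:
            assignment[vid] = "VAL"
        else:
            assignment[vid] = "TEST"
    return assignment


def clip_indices(
    n_frames: int, ed_frame: int, es_frame: int, clip_len: int, rng: np.random.Generator
) -> np.ndarray:
    """Frame indices of one training clip within the ED-ES window.

    The start is uniform over positions that keep the clip inside the window;
    short windows are extended symmetrically into the video, and a video
    shorter than the clip is padded by repeating its last frame.
    """
    if clip_len < 1:
        raise ValueError(f"clip_len must be >= 1, got {clip_len}")
    lo, hi = sorted((ed_frame, es_frame))
    window = hi - lo + 1
    if window >= clip_len:
        start = int(rng.integers(lo, hi - clip_len + 2))
        return np.arange(start, start + clip_len)
    # extend the window symmetrically, clamped to the video
    need = clip_len - window
    lo = max(0, lo - need // 2)
    hi = min(n_frames - 1, lo + clip_len - 1)
    lo = max(0, hi - clip_len + 1)
    idx = np.arange(lo, min(hi, n_frames - 1) + 1)
    if idx.size < clip_len:  # video itself is too short: repeat the last frame
        idx = np.concatenate([idx, np.full(clip_len - idx.size, n_frames - 1)])
    return idx


def sample_clip(
    video: GrayVideo,
    record: VideoRecord,
    clip_len: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw one normalized clip (clip_len x 1 x H x W, values in [-1, 1])."""
    idx = clip_indices(video.n_frames, record.ed_frame, record.es_frame, clip_len, rng)
    return normalize_frames(video.pixels[idx])


def _batches(items: list, size: int):
    for i in range(0, len(items), size):
        yield items[i : i + size]


def fit(
    dataset: EchoDataset | str | Path,
    model_config: ModelConfig,
    train_config: TrainConfig,
    augment_config: AugmentConfig | None = None,
    out_dir: str | Path | None = None,
    resplit: bool = False,
) -> tuple[EFNet, list[EpochLog]]:
    """Train on the TRAIN split, validating per epoch with segment averaging.

    Returns the model restored to its best-validation-MAE parameters plus the
    per-epoch log.  With ``out_dir`` set, writes ``best.npz`` and ``log.csv``.
    Fully deterministic for a fixed seed.
    """
    from .evaluation import predict_patient  # circular at module level

    if not isinstance(dataset, EchoDataset):
        dataset = EchoDataset(dataset)
    records = dataset.records
    if resplit:
        assignment = make_splits(records, train_config.split_fractions, train_config.seed)
        records = [r.with_split(assignment[r.video_id]) for r in records]
    by_split = {s: [r for r in records if r.split == s] for s in ("TRAIN", "VAL")}
    if not by_split["TRAIN"]:
        raise ValueError("TRAIN split is empty")

    augment_config = augment_config or AugmentConfig()
    model = build_efnet(model_config)
    optimizer = Adam(
        model.parameters(), lr=train_config.lr0, weight_decay=train_config.weight_decay
    )
    rng = np.random.default_rng(train_config.seed)

    best_state = None
    best_val_mae = np.inf
    logs: list[EpochLog] = []
    for epoch in range(train_config.epochs):
        lr = lr_at(epoch, train_config)
        optimizer.lr = lr
        model.train()
        order = rng.permutation(len(by_split["TRAIN"]))
        train_records = [by_split["TRAIN"][i] for i in order]
        sq_errors = []
        for batch in _batches(train_records, train_config.batch_size):
            clips, targets = [], []
            for rec in batch:
                video = dataset.load_video(rec.video_id)
                clip = sample_clip(video, rec, train_config.clip_len, rng)
                if train_config.augment:
                    clip = augment_clip(clip, augment_config, rng)
                clips.append(clip)
                targets.append(rec.ef)
            x = np.stack(clips).transpose(0, 2, 1, 3, 4)  # B,1,T,H,W
            y = np.asarray(targets, dtype=np.float32).reshape(-1, 1)
            pred = model(x)
            err = pred - y
            loss = float(np.mean(err**2))
            if not np.isfinite(loss):
                raise RuntimeError(f"non-finite training loss at epoch {epoch}: {loss}")
            model.zero_grad()
            model.backward(2.0 * err.astype(np.float32) / err.size)
            optimizer.step()
            sq_errors.extend((err**2).ravel().tolist())
        train_mse = float(np.mean(sq_errors))

        model.eval()
        val_errs = []
        for rec in by_split["VAL"]:
            video = dataset.load_video(rec.video_id)
            pred = predict_patient(video, model, clip_len=train_config.clip_len)
            val_errs.append(pred - rec.ef)
        val_errs = np.asarray(val_errs) if val_errs else np.array([np.nan])
        val_mse = float(np.mean(val_errs**2))
        val_mae = float(np.mean(np.abs(val_errs)))
        logs.append(EpochLog(epoch, lr, train_mse, val_mse, val_mae))
        logger.info(
            "epoch %d lr %.2e train_mse %.3f val_mse %.3f val_mae %.3f",
            epoch, lr, train_mse, val_mse, val_mae,
        )
        if not by_split["VAL"] or val_mae <= best_val_mae or best_state is None:
            best_val_mae = val_mae if np.isfinite(val_mae) else best_val_mae
            best_state = _snapshot(model)

    _restore(model, best_state)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        save_checkpoint(out_dir / "best.npz", model)
        log_frame(logs).to_csv(out_dir / "log.csv", index=False)
    return model, logs


def log_frame(logs: list[EpochLog]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "epoch": [l.epoch for l in logs],
            "lr": [l.lr for l in logs],
            "train_mse": [l.train_mse for l in logs],
            "val_mse": [l.val_mse for l in logs],
            "val_mae": [l.val_mae for l in logs],
        }
    )


def _snapshot(model: EFNet):
    from .model import _named_bn

    state = model.state_dict()
    stats = {}
    scopes = [(model.stem, "stem.")] + [
        (s, f"stages.{i}.") for i, s in enumerate(model.stages)
    ]
    for scope, prefix in scopes:
        for name, bn in _named_bn(scope, prefix):
            stats[name] = (bn.running_mean.copy(), bn.running_var.copy())
    return state, stats


def _restore(model: EFNet, snapshot):
    from .model import _named_bn

    state, stats = snapshot
    model.load_state_dict(state)
    scopes = [(model.stem, "stem.")] + [
        (s, f"stages.{i}.") for i, s in enumerate(model.stages)
    ]
    for scope, prefix in scopes:
        for name, bn in _named_bn(scope, prefix):
            bn.running_mean[...] = stats[name][0]
            bn.running_var[...] = stats[name][1]
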