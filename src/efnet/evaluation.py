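"""Patient-level EF prediction and the regression metric suite.

Inference is segment-averaged: all frames of a video are split into
consecutive non-overlapping clip_len-frame segments (trailing remainder
dropped; a video shorter than one segment is repeat-padded), each segment is
forwarded independently, and the scalar outputs are averaged.  Metrics cover
MSE, RMSE, MAE, MAPE (as a fraction), R² and the F1 score of the clinically
relevant EF < 40% screen.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.metrics import (
    f1_score,
    mean_absolute_error,
    mean_absolute_percentage_error,
    mean_squared_error,
    r2_score,
)

from .data_io import EchoDataset, GrayVideo, normalize_frames

#: EF threshold (percent) below which systolic function counts as reduced
REDUCED_EF_THRESHOLD = 40.0


@dataclass(frozen=True)
class EvalResult:
    mse: float
    rmse: float
    mae: float
    mape: float
    r2: float
    f1_lt40: float

    def as_dict(self) -> dict[str, float]:
        return {
            "mse": self.mse,
            "rmse": self.rmse,
            "mae": self.mae,
            "mape": self.mape,
            "r2": self.r2,
            "f1_lt40": self.f1_lt40,
        }


def segment_clips(pixels: np.ndarray, clip_len: int) -> np.ndarray:
    """Partition T0 frames into floor(T0/clip_len) non-overlapping segments.

    Returns (S, clip_len, H, W).  A video shorter than clip_len becomes one
    segment padded by repeating the final frame.
    """
    t0 = pixels.shape[0]
    if t0 == 0:
        raise ValueError("video has zero frames")
    if t0 < clip_len:
        pad = np.repeat(pixels[-1:], clip_len - t0, axis=0)
        return np.concatenate([pixels, pad])[None]
    n_segments = t0 // clip_len
    return pixels[: n_segments * clip_len].reshape(n_segments, clip_len, *pixels.shape[1:])


def predict_patient(video: GrayVideo, model, clip_len: int = 16) -> float:
    """Segment-averaged EF prediction (percent) for one patient video."""
    segments = segment_clips(video.pixels, clip_len)
    preds = []
    for segment in segments:
        clip = normalize_frames(segment)  # T,1,H,W
        x = clip.transpose(1, 0, 2, 3)[None]  # 1,1,T,H,W
        preds.append(float(np.asarray(model(x)).reshape(-1)[0]))
    return float(np.mean(preds))


def compute_metrics(y_true, y_pred) -> EvalResult:
    """Regression metrics on EF percent values; MAPE is reported as a fraction."""
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.shape != y_pred.shape or y_true.ndim != 1:
        raise ValueError(f"shape mismatch: {y_true.shape} vs {y_pred.shape}")
    if y_true.size == 0:
        raise ValueError("empty inputs")
    if (y_true <= 0).any():
        raise ValueError("MAPE requires strictly positive true EF values")

    mse = mean_squared_error(y_true, y_pred)
    if np.allclose(y_true, y_true[0]):
        warnings.warn("zero-variance y_true: R² is undefined, reporting NaN")
        r2 = float("nan")
    else:
        r2 = r2_score(y_true, y_pred)
    true_pos = y_true < REDUCED_EF_THRESHOLD
    pred_pos = y_pred < REDUCED_EF_THRESHOLD
    if true_pos.any() or pred_pos.any():
        f1 = f1_score(true_pos, pred_pos, zero_division=0.0)
    else:
        f1 = float("nan")  # the binary task is vacuous without any positive
    return EvalResult(
        mse=float(mse),
        rmse=float(np.sqrt(mse)),
        mae=float(mean_absolute_error(y_true, y_pred)),
        mape=float(mean_absolute_percentage_error(y_true, y_pred)),
        r2=float(r2),
        f1_lt40=float(f1),
    )


def evaluate_split(
    dataset: EchoDataset | str | Path,
    model,
    split: str = "TEST",
    clip_len: int = 16,
) -> tuple[EvalResult, pd.DataFrame]:
    """Predict every video of a split; returns metrics + per-patient table."""
    if not isinstance(dataset, EchoDataset):
        dataset = EchoDataset(dataset)
    records = dataset.split_records(split)
    if not records:
        raise ValueError(f"split {split!r} is empty")
    if hasattr(model, "eval"):
        model.eval()
    rows = []
    for rec in records:
        video = dataset.load_video(rec.video_id)
        pred = predict_patient(video, model, clip_len=clip_len)
        rows.append({"video_id": rec.video_id, "ef_true": rec.ef, "ef_pred": pred})
    table = pd.DataFrame(rows, columns=["video_id", "ef_true", "ef_pred"])
    result = compute_metrics(table["ef_true"].to_numpy(), table["ef_pred"].to_numpy())
    return result, table
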