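"""Reading and writing echocardiogram datasets in the EchoNet-Dynamic layout.

A dataset root holds ``Videos/<id>.avi`` cine loops plus two CSV manifests:
``FileList.csv`` with per-video EF / volume / split metadata and an ED/ES
annotation CSV (``FileName,ED_Frame,ES_Frame``).  Pixel normalization maps
8-bit gray levels affinely onto [-1, 1] before a clip enters the network.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .avi import read_avi, write_avi

logger = logging.getLogger(__name__)

SPLITS = ("TRAIN", "VAL", "TEST")

FILELIST_COLUMNS = ["FileName", "EF", "ESV", "EDV", "FPS", "NumberOfFrames", "Split"]
TRACE_COLUMNS = ["FileName", "ED_Frame", "ES_Frame"]

#: largest representable gray level of 8-bit ultrasound video
MAX_PIXEL_VALUE = 255


@dataclass(frozen=True)
class GrayVideo:
    """Raw grayscale cine loop: T0 x H0 x W0 uint8 frames plus frame rate."""

    pixels: np.ndarray
    fps: float = 50.0

    def __post_init__(self):
        px = np.asarray(self.pixels)
        if px.ndim != 3:
            raise ValueError(f"pixels must be T x H x W, got shape {px.shape}")
        if px.shape[0] < 1:
            raise ValueError("video must contain at least one frame")

    @property
    def n_frames(self) -> int:
        return self.pixels.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.pixels.shape[1:]


@dataclass(frozen=True)
class VideoRecord:
    """Metadata for one patient video (labels, ED/ES annotation, split)."""

    video_id: str
    ef: float
    edv: float
    esv: float
    fps: float
    n_frames: int
    ed_frame: int
    es_frame: int
    split: str

    def validate(self) -> None:
        vid = self.video_id
        if not 0.0 <= self.ef <= 100.0:
            raise ValueError(f"{vid}: EF {self.ef} outside [0, 100]")
        if self.edv <= 0:
            raise ValueError(f"{vid}: EDV {self.edv} must be positive")
        if not 0.0 <= self.esv <= self.edv:
            raise ValueError(f"{vid}: ESV {self.esv} outside [0, EDV={self.edv}]")
        implied = compute_ef(self.edv, self.esv)
        if abs(self.ef - implied) > 0.5:
            raise ValueError(
                f"{vid}: EF {self.ef} inconsistent with volumes (implies {implied:.2f})"
            )
        for name, idx in (("ed_frame", self.ed_frame), ("es_frame", self.es_frame)):
            if not 0 <= idx < self.n_frames:
                raise ValueError(f"{vid}: {name}={idx} outside [0, {self.n_frames})")
        if self.ed_frame == self.es_frame:
            raise ValueError(f"{vid}: ED and ES frames coincide at {self.ed_frame}")
        if self.split not in SPLITS:
            raise ValueError(f"{vid}: split {self.split!r} not in {SPLITS}")

    def with_split(self, split: str) -> "VideoRecord":
        return replace(self, split=split)


def compute_ef(edv: float, esv: float) -> float:
    """Ejection fraction in percent: EF = (EDV - ESV) / EDV * 100."""
    if edv <= 0:
        raise ValueError(f"EDV must be positive, got {edv}")
    if not 0 <= esv <= edv:
        raise ValueError(f"ESV must lie in [0, EDV={edv}], got {esv}")
    return (edv - esv) / edv * 100.0


def read_video(path: str | Path) -> GrayVideo:
    """Load an AVI cine loop as grayscale; RGB content is reduced by ITU-R 601 luma."""
    frames, fps = read_avi(path)
    return GrayVideo(pixels=frames, fps=fps if fps > 0 else 50.0)


def normalize_frames(
    video: GrayVideo | np.ndarray,
    mean: float = 0.5,
    std: float = 0.5,
    max_pixel_value: int = MAX_PIXEL_VALUE,
) -> np.ndarray:
    """Map gray levels to (x - mean*max) / (std*max); inserts a channel axis.

    With mean = std = 0.5 the 8-bit range [0, 255] lands exactly on [-1, 1].
    Returns a float32 array of shape T x 1 x H x W.
    """
    if std <= 0:
        raise ValueError(f"std must be positive, got {std}")
    if max_pixel_value <= 0:
        raise ValueError(f"max_pixel_value must be positive, got {max_pixel_value}")
    pixels = video.pixels if isinstance(video, GrayVideo) else np.asarray(video)
    scaled = (pixels.astype(np.float32) - mean * max_pixel_value) / (std * max_pixel_value)
    return scaled[:, None, :, :]


def denormalize_frames(
    clip: np.ndarray,
    mean: float = 0.5,
    std: float = 0.5,
    max_pixel_value: int = MAX_PIXEL_VALUE,
) -> np.ndarray:
    """Inverse of :func:`normalize_frames` (drops the channel axis, keeps float)."""
    values = np.asarray(clip)
    if values.ndim == 4:
        values = values[:, 0]
    return values * (std * max_pixel_value) + mean * max_pixel_value


def _strip_avi(name: str) -> str:
    return name[:-4] if name.lower().endswith(".avi") else name


def read_manifest(filelist_path: str | Path, tracings_path: str | Path) -> list[VideoRecord]:
    """Join FileList and ED/ES annotation CSVs into validated records.

    Videos without an ED/ES annotation are dropped with a warning; invariant
    violations raise, naming the offending videos.
    """
    filelist = pd.read_csv(filelist_path)
    traces = pd.read_csv(tracings_path)
    for cols, path, df in (
        (FILELIST_COLUMNS, filelist_path, filelist),
        (TRACE_COLUMNS, tracings_path, traces),
    ):
        missing = [c for c in cols if c not in df.columns]
        if missing:
            raise ValueError(f"{path}: missing required columns {missing}")

    filelist = filelist.assign(FileName=filelist["FileName"].astype(str).map(_strip_avi))
    traces = traces.assign(FileName=traces["FileName"].astype(str).map(_strip_avi))
    merged = filelist.merge(traces[TRACE_COLUMNS], on="FileName", how="left")

    unannotated = merged["ED_Frame"].isna() | merged["ES_Frame"].isna()
    if unannotated.any():
        dropped = merged.loc[unannotated, "FileName"].tolist()
        logger.warning(
            "dropping %d video(s) without ED/ES annotation: %s",
            len(dropped), ", ".join(dropped[:5]) + ("..." if len(dropped) > 5 else ""),
        )
        merged = merged.loc[~unannotated]

    records, problems = [], []
    for row in merged.itertuples(index=False):
        rec = VideoRecord(
            video_id=row.FileName,
            ef=float(row.EF),
            edv=float(row.EDV),
            esv=float(row.ESV),
            fps=float(row.FPS),
            n_frames=int(row.NumberOfFrames),
            ed_frame=int(row.ED_Frame),
            es_frame=int(row.ES_Frame),
            split=str(row.Split).upper(),
        )
        try:
            rec.validate()
        except ValueError as exc:
            problems.append(str(exc))
            continue
        records.append(rec)
    if problems:
        raise ValueError("invalid manifest rows:\n  " + "\n  ".join(problems))
    return records


def video_path(root: str | Path, video_id: str) -> Path:
    return Path(root) / "Videos" / f"{video_id}.avi"


def write_dataset(
    records: list[VideoRecord],
    videos: list[GrayVideo],
    out_dir: str | Path,
) -> tuple[Path, Path]:
    """Write videos + manifests in the layout :func:`read_manifest` accepts.

    Returns (FileList.csv path, ED/ES annotation CSV path).  AVIs are
    uncompressed, so reading them back is pixel-identical.
    """
    if len(records) != len(videos):
        raise ValueError(f"{len(records)} records but {len(videos)} videos")
    out_dir = Path(out_dir)
    video_dir = out_dir / "Videos"
    video_dir.mkdir(parents=True, exist_ok=True)
    for rec, vid in zip(records, videos):
        if vid.n_frames != rec.n_frames:
            raise ValueError(
                f"{rec.video_id}: record says {rec.n_frames} frames, video has {vid.n_frames}"
            )
        write_avi(video_dir / f"{rec.video_id}.avi", vid.pixels, fps=rec.fps)

    filelist = pd.DataFrame(
        {
            "FileName": [r.video_id for r in records],
            "EF": [r.ef for r in records],
            "ESV": [r.esv for r in records],
            "EDV": [r.edv for r in records],
            "FPS": [r.fps for r in records],
            "NumberOfFrames": [r.n_frames for r in records],
            "Split": [r.split for r in records],
        },
        columns=FILELIST_COLUMNS,
    )
    traces = pd.DataFrame(
        {
            "FileName": [r.video_id for r in records],
            "ED_Frame": [r.ed_frame for r in records],
            "ES_Frame": [r.es_frame for r in records],
        },
        columns=TRACE_COLUMNS,
    )
    filelist_path = out_dir / "FileList.csv"
    traces_path = out_dir / "EDESFrames.csv"
    filelist.to_csv(filelist_path, index=False)
    traces.to_csv(traces_path, index=False)
    return filelist_path, traces_path


class EchoDataset:
    """A dataset root: records plus on-demand (cached) video loading."""

    def __init__(self, root: str | Path):
        self.root = Path(root)
        filelist = self.root / "FileList.csv"
        traces = self.root / "EDESFrames.csv"
        if not traces.exists():  # accept the upstream naming too
            alt = self.root / "VolumeTracings.csv"
            if alt.exists():
                traces = alt
        self.records = read_manifest(filelist, traces)
        self._by_id = {r.video_id: r for r in self.records}
        self._cache: dict[str, GrayVideo] = {}

    def __len__(self) -> int:
        return len(self.records)

    def record(self, video_id: str) -> VideoRecord:
        return self._by_id[video_id]

    def split_records(self, split: str) -> list[VideoRecord]:
        split = split.upper()
        return [r for r in self.records if r.split == split]

    def load_video(self, video_id: str) -> GrayVideo:
        if video_id not in self._cache:
            self._cache[video_id] = read_video(video_path(self.root, video_id))
        return self._cache[video_id]
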