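"""Synthetic echocardiogram phantoms with analytically known ejection fraction.

Each phantom is a cone-masked, speckled cine loop of a pulsating elliptical
blood pool inside a bright myocardial ring.  The per-frame pool volume follows
a raised-cosine cardiac cycle between EDV and ESV, so EF, ED frame and ES
frame are known exactly and the generator can emit a complete dataset in the
same on-disk layout real echocardiogram collections use.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .data_io import GrayVideo, VideoRecord, compute_ef, write_dataset

logger = logging.getLogger(__name__)

#: reference volume (mL) whose pool fills the nominal ellipse axes
_V_REF = 250.0
#: pool ellipse semi-axes at _V_REF, as fractions of image size
_SEMI_X, _SEMI_Y = 0.28, 0.18
#: myocardial ring outer radius relative to the pool radius
_RING_SCALE = 1.35
#: vertical pool-centre position as a fraction of image size
_CENTER_Y = 0.55
#: background tissue gray level inside the cone
_TISSUE_GRAY = 80


@dataclass(frozen=True)
class PhantomParams:
    """Generative parameters of one phantom cine loop."""

    target_ef: float  # percent, in (5, 85)
    edv: float  # mL
    cycle_frames: int = 16
    n_cycles: int = 2
    fps: float = 50.0
    image_size: int = 112
    cone_half_angle: float = 45.0  # degrees
    speckle_sigma: float = 0.15
    myocardium_brightness: int = 200
    pool_brightness: int = 30
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.target_ef < 100.0:
            raise ValueError(f"target_ef must lie in (0, 100), got {self.target_ef}")
        if self.edv <= 0:
            raise ValueError(f"edv must be positive, got {self.edv}")
        if self.cycle_frames < 8:
            raise ValueError(f"cycle_frames must be >= 8, got {self.cycle_frames}")
        if self.cycle_frames % 2:
            raise ValueError(
                "cycle_frames must be even so the cosine cycle attains ESV exactly"
            )
        if self.n_cycles < 1:
            raise ValueError(f"n_cycles must be >= 1, got {self.n_cycles}")
        if self.speckle_sigma < 0:
            raise ValueError(f"speckle_sigma must be >= 0, got {self.speckle_sigma}")

    @property
    def esv(self) -> float:
        return self.edv * (1.0 - self.target_ef / 100.0)

    @property
    def n_frames(self) -> int:
        return self.cycle_frames * self.n_cycles


@dataclass(frozen=True)
class VolumeTrace:
    """Per-frame left-ventricular volume (mL) of a phantom."""

    volumes: np.ndarray

    @property
    def edv(self) -> float:
        return float(self.volumes.max())

    @property
    def esv(self) -> float:
        return float(self.volumes.min())

    @property
    def ef(self) -> float:
        return compute_ef(self.edv, self.esv)


def make_volume_trace(params: PhantomParams) -> VolumeTrace:
    """Raised-cosine volume cycle: V(t) = ESV + (EDV-ESV) * (1+cos(2πt/C))/2.

    Frame 0 of every cycle attains EDV; frame C/2 attains ESV exactly.
    """
    t = np.arange(params.n_frames)
    phase = (1.0 + np.cos(2.0 * np.pi * t / params.cycle_frames)) / 2.0
    volumes = params.esv + (params.edv - params.esv) * phase
    return VolumeTrace(volumes=volumes)


def _cone_mask(size: int, half_angle_deg: float) -> np.ndarray:
    """Ultrasound sector: apex at top-centre, symmetric half-angle, range <= size."""
    y, x = np.mgrid[0:size, 0:size]
    dx = x - (size - 1) / 2.0
    dy = y.astype(float) + 1.0  # apex just above the top row
    tan_half = np.tan(np.deg2rad(half_angle_deg))
    inside_angle = np.abs(dx) <= dy * tan_half
    inside_range = np.hypot(dx, dy) <= size
    return inside_angle & inside_range


def render_frame(volume: float, params: PhantomParams, rng: np.random.Generator) -> np.ndarray:
    """Render one frame: dark pool + bright ring in a cone, multiplicative speckle.

    The pool's pixel area scales as volume^(2/3) — the cross-section of a
    3D volume — so appearance is strictly monotone in volume.
    """
    size = params.image_size
    scale = (volume / _V_REF) ** (1.0 / 3.0)
    a = _SEMI_X * size * scale  # pool semi-axis along x
    b = _SEMI_Y * size * scale  # pool semi-axis along y
    cx = (size - 1) / 2.0
    cy = _CENTER_Y * size

    y, x = np.mgrid[0:size, 0:size]
    r2 = ((x - cx) / a) ** 2 + ((y - cy) / b) ** 2
    img = np.full((size, size), float(_TISSUE_GRAY))
    img[r2 <= _RING_SCALE**2] = params.myocardium_brightness
    img[r2 <= 1.0] = params.pool_brightness
    img[~_cone_mask(size, params.cone_half_angle)] = 0.0

    if params.speckle_sigma > 0:
        g = rng.standard_normal(img.shape)
        img = img * (1.0 + params.speckle_sigma * g)
    return np.clip(np.rint(img), 0, 255).astype(np.uint8)


def render_phantom(params: PhantomParams) -> tuple[GrayVideo, VolumeTrace]:
    """Render a full cine loop from one parameter set (seeded, reproducible)."""
    trace = make_volume_trace(params)
    rng = np.random.default_rng(params.seed)
    frames = np.stack([render_frame(v, params, rng) for v in trace.volumes])
    return GrayVideo(pixels=frames, fps=params.fps), trace


def default_param_sampler(rng: np.random.Generator, **overrides) -> PhantomParams:
    """Cohort-style draw: EF ~ U(15, 80); EDV ~ N(91, 45.7) truncated to [40, 250]."""
    target_ef = rng.uniform(15.0, 80.0)
    edv = rng.normal(91.0, 45.7)
    while not 40.0 <= edv <= 250.0:
        edv = rng.normal(91.0, 45.7)
    seed = int(rng.integers(0, 2**31 - 1))
    return PhantomParams(target_ef=target_ef, edv=edv, seed=seed, **overrides)


def _ed_es_frames(trace: VolumeTrace, cycle_frames: int) -> tuple[int, int]:
    """ED = argmax of volume; ES = first argmin after ED within the first cycle."""
    first_cycle = trace.volumes[:cycle_frames]
    ed = int(np.argmax(first_cycle))
    after = first_cycle[ed + 1 :]
    es = ed + 1 + int(np.argmin(after))
    return ed, es


def generate_phantom_dataset(
    n_videos: int,
    seed: int,
    out_dir: str | Path,
    param_sampler=default_param_sampler,
    split_fractions: tuple[float, float, float] = (0.8, 0.1, 0.1),
    **param_overrides,
) -> Path:
    """Write ``n_videos`` phantoms plus manifests to ``out_dir``; returns the root.

    Splits are assigned 80/10/10 (TRAIN gets remainders) by a seeded shuffle.
    Everything downstream of (n_videos, sampler, seed) is deterministic.
    """
    if n_videos < 1:
        raise ValueError(f"n_videos must be >= 1, got {n_videos}")
    rng = np.random.default_rng(seed)

    records, videos = [], []
    for i in range(n_videos):
        params = param_sampler(rng, **param_overrides)
        video, trace = render_phantom(params)
        ed, es = _ed_es_frames(trace, params.cycle_frames)
        records.append(
            VideoRecord(
                video_id=f"phantom{i:05d}",
                ef=trace.ef,
                edv=trace.edv,
                esv=trace.esv,
                fps=params.fps,
                n_frames=video.n_frames,
                ed_frame=ed,
                es_frame=es,
                split="TRAIN",
            )
        )
        videos.append(video)

    if n_videos < len(split_fractions):
        warnings.warn(
            f"{n_videos} video(s) cannot fill {len(split_fractions)} splits; "
            "assigning everything to TRAIN"
        )
    else:
        from .training import make_splits  # deferred: training imports data_io too

        assignment = make_splits(records, split_fractions, seed)
        records = [r.with_split(assignment[r.video_id]) for r in records]

    for rec in records:
        rec.validate()
    write_dataset(records, videos, out_dir)
    return Path(out_dir)
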