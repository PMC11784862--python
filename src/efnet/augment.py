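"""Training-time clip augmentations.

One transform parameter set is drawn per clip and applied identically to
every frame, preserving the temporal coherence the motion signal depends on.
Clips are float arrays T x 1 x H x W in [-1, 1]; outputs are clipped back to
that range and keep the original frame size.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import numpy as np
from PIL import Image
from scipy import ndimage

from .data_io import denormalize_frames, normalize_frames

#: normalized gray level of the black background outside the ultrasound cone
_BLACK = -1.0


@dataclass(frozen=True)
class AugmentConfig:
    rotation_deg: tuple[float, float] = (-25.0, 25.0)
    p_hflip: float = 0.5
    p_blur: float = 0.5
    p_compress: float = 0.1
    brightness_delta: tuple[float, float] = (-0.2, 0.2)
    contrast_factor: tuple[float, float] = (0.8, 1.2)
    blur_sigma: tuple[float, float] = (0.3, 1.5)
    compress_quality: tuple[int, int] = (30, 90)

    def __post_init__(self):
        for name in ("p_hflip", "p_blur", "p_compress"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {p}")
        lo, hi = self.rotation_deg
        if abs(lo + hi) > 1e-9:
            raise ValueError(f"rotation range must be symmetric, got {self.rotation_deg}")

    @classmethod
    def identity(cls) -> "AugmentConfig":
        return cls(
            rotation_deg=(0.0, 0.0),
            p_hflip=0.0,
            p_blur=0.0,
            p_compress=0.0,
            brightness_delta=(0.0, 0.0),
            contrast_factor=(1.0, 1.0),
        )


def _jpeg_roundtrip(frames: np.ndarray, quality: int) -> np.ndarray:
    """Encode/decode each frame as JPEG at the same quality (blocking artifacts)."""
    out = np.empty_like(frames)
    for i, frame in enumerate(frames):
        buf = io.BytesIO()
        Image.fromarray(frame.astype(np.uint8), mode="L").save(
            buf, format="JPEG", quality=int(quality)
        )
        out[i] = np.asarray(Image.open(buf), dtype=frames.dtype)
    return out


def augment_clip(
    clip: np.ndarray, config: AugmentConfig, rng: np.random.Generator
) -> np.ndarray:
    """Apply rotation / flip / brightness-contrast / blur / compression to a clip."""
    frames = np.asarray(clip, dtype=np.float32)[:, 0]  # T x H x W

    angle = rng.uniform(*config.rotation_deg)
    do_flip = rng.random() < config.p_hflip
    delta = rng.uniform(*config.brightness_delta)
    contrast = rng.uniform(*config.contrast_factor)
    do_blur = rng.random() < config.p_blur
    sigma = rng.uniform(*config.blur_sigma)
    do_compress = rng.random() < config.p_compress
    quality = rng.integers(config.compress_quality[0], config.compress_quality[1] + 1)

    if angle != 0.0:
        frames = ndimage.rotate(
            frames, angle, axes=(1, 2), reshape=False, order=1,
            mode="constant", cval=_BLACK,
        )
    if do_flip:
        frames = frames[:, :, ::-1]

    if delta != 0.0 or contrast != 1.0:
        # brightness/contrast on the [0, 1] gray scale, pivoting about mid-gray
        gray = (frames + 1.0) / 2.0
        gray = (gray - 0.5) * contrast + 0.5 + delta
        frames = gray * 2.0 - 1.0

    if do_blur and sigma > 0:
        frames = ndimage.gaussian_filter1d(frames, sigma, axis=1)
        frames = ndimage.gaussian_filter1d(frames, sigma, axis=2)

    if do_compress:
        levels = np.clip(np.rint(denormalize_frames(frames[:, None])), 0, 255)
        levels = _jpeg_roundtrip(levels.astype(np.uint8), quality)
        frames = normalize_frames(levels)[:, 0]

    frames = np.clip(frames, -1.0, 1.0).astype(np.float32)
    return np.ascontiguousarray(frames[:, None])
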