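"""Minimal uncompressed AVI (RIFF) reader and writer.

Frames are stored as 24-bit bottom-up DIB ('DIB ' handler, BI_RGB), the
plain uncompressed layout every AVI player understands.  Grayscale frames
are replicated across B, G and R on write, so a write/read round trip is
bit-exact — the property the dataset fixtures rely on.
"""

from __future__ import annotations

import io
import struct
from pathlib import Path

import numpy as np

_AVIF_HASINDEX = 0x00000010
_AVIIF_KEYFRAME = 0x00000010


def _chunk(fourcc: bytes, payload: bytes) -> bytes:
    pad = b"\x00" if len(payload) % 2 else b""
    return fourcc + struct.pack("<I", len(payload)) + payload + pad


def _list_chunk(list_type: bytes, payload: bytes) -> bytes:
    return _chunk(b"LIST", list_type + payload)


def _frame_to_dib(frame: np.ndarray) -> bytes:
    """Pack one H x W grayscale frame as bottom-up BGR rows padded to 4 bytes."""
    h, w = frame.shape
    row_len = (w * 3 + 3) & ~3
    rows = np.zeros((h, row_len), dtype=np.uint8)
    bgr = np.repeat(frame[:, :, None], 3, axis=2)
    rows[:, : w * 3] = bgr.reshape(h, w * 3)
    return rows[::-1].tobytes()


def _dib_to_frame(data: bytes, width: int, height: int) -> np.ndarray:
    row_len = (width * 3 + 3) & ~3
    rows = np.frombuffer(data[: row_len * height], dtype=np.uint8)
    rows = rows.reshape(height, row_len)[::-1, : width * 3]
    bgr = rows.reshape(height, width, 3).astype(np.float64)
    # ITU-R 601 luma; exact for replicated-gray frames
    gray = 0.114 * bgr[:, :, 0] + 0.587 * bgr[:, :, 1] + 0.299 * bgr[:, :, 2]
    return np.clip(np.rint(gray), 0, 255).astype(np.uint8)


def write_avi(path: str | Path, frames: np.ndarray, fps: float = 50.0) -> None:
    """Write a T x H x W uint8 grayscale stack as an uncompressed AVI."""
    frames = np.asarray(frames)
    if frames.ndim != 3:
        raise ValueError(f"expected T x H x W grayscale stack, got shape {frames.shape}")
    if frames.dtype != np.uint8:
        if frames.min() < 0 or frames.max() > 255:
            raise ValueError("frame values must lie in [0, 255]")
        frames = frames.astype(np.uint8)
    n, h, w = frames.shape
    if n < 1:
        raise ValueError("cannot write an AVI with zero frames")
    frame_bytes = [_frame_to_dib(f) for f in frames]
    buf_size = max(len(b) for b in frame_bytes)

    rate = max(1, int(round(fps * 1000)))
    scale = 1000
    avih = struct.pack(
        "<14I",
        int(round(1e6 / fps)),  # dwMicroSecPerFrame
        buf_size * int(round(fps)),  # dwMaxBytesPerSec
        0,
        _AVIF_HASINDEX,
        n,
        0,
        1,  # dwStreams
        buf_size,
        w,
        h,
        0, 0, 0, 0,
    )
    strh = struct.pack(
        "<4s4sIHH8I4h",
        b"vids", b"DIB ",
        0, 0, 0,
        0,  # dwInitialFrames
        scale, rate,
        0, n, buf_size,
        0,  # dwQuality (driver default)
        0,  # dwSampleSize
        0, 0, w, h,
    )
    strf = struct.pack("<IiiHHIIiiII", 40, w, h, 1, 24, 0, len(frame_bytes[0]), 0, 0, 0, 0)
    hdrl = _list_chunk(
        b"hdrl",
        _chunk(b"avih", avih) + _list_chunk(b"strl", _chunk(b"strh", strh) + _chunk(b"strf", strf)),
    )

    movi_payload = io.BytesIO()
    offsets = []
    for fb in frame_bytes:
        offsets.append(movi_payload.tell() + 4)  # offset from the 'movi' fourcc
        movi_payload.write(_chunk(b"00db", fb))
    movi = _list_chunk(b"movi", movi_payload.getvalue())

    idx = b"".join(
        struct.pack("<4sIII", b"00db", _AVIIF_KEYFRAME, off, len(fb))
        for off, fb in zip(offsets, frame_bytes)
    )
    idx1 = _chunk(b"idx1", idx)

    riff_payload = b"AVI " + hdrl + movi + idx1
    with open(path, "wb") as fh:
        fh.write(b"RIFF" + struct.pack("<I", len(riff_payload)) + riff_payload)


def _iter_chunks(data: bytes, start: int, end: int):
    pos = start
    while pos + 8 <= end:
        fourcc = data[pos : pos + 4]
        (size,) = struct.unpack_from("<I", data, pos + 4)
        yield fourcc, pos + 8, size
        pos += 8 + size + (size % 2)


def read_avi(path: str | Path) -> tuple[np.ndarray, float]:
    """Read an uncompressed AVI; returns (T x H x W uint8 frames, fps)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    data = path.read_bytes()
    if len(data) < 12 or data[:4] != b"RIFF" or data[8:12] != b"AVI ":
        raise ValueError(f"{path} is not an AVI (RIFF) file")

    width = height = None
    fps = 0.0
    frames: list[np.ndarray] = []

    def walk(start: int, end: int) -> None:
        nonlocal width, height, fps
        for fourcc, payload_start, size in _iter_chunks(data, start, end):
            payload_end = payload_start + size
            if fourcc == b"LIST":
                walk(payload_start + 4, payload_end)
            elif fourcc == b"strh":
                fcc_type, _handler = struct.unpack_from("<4s4s", data, payload_start)
                if fcc_type == b"vids":
                    scale, rate = struct.unpack_from("<II", data, payload_start + 20)
                    if scale:
                        fps = rate / scale
            elif fourcc == b"strf" and width is None:
                _, w, h, _, bits, compression = struct.unpack_from(
                    "<IiiHHI", data, payload_start
                )
                if bits != 24 or compression != 0:
                    raise ValueError(
                        f"{path}: only uncompressed 24-bit DIB AVIs are supported "
                        f"(bits={bits}, compression={compression})"
                    )
                width, height = w, abs(h)
            elif fourcc in (b"00db", b"00dc"):
                if width is None:
                    raise ValueError(f"{path}: frame data before stream format header")
                frames.append(_dib_to_frame(data[payload_start:payload_end], width, height))

    walk(12, len(data))
    if not frames:
        raise ValueError(f"{path}: AVI container holds no video frames")
    return np.stack(frames), fps
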