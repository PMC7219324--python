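"""Uncompressed RGB AVI (RIFF) reader and writer.

Frames are stored as raw BI_RGB device-independent bitmaps ('00db'
chunks): bottom-up row order, BGR byte order, rows padded to 4-byte
boundaries.  The format is lossless, so a write/read round trip is the
identity on pixel content.  Any standard AVI player or ffmpeg can decode
the files; this module only decodes its own uncompressed layout.
"""

from __future__ import annotations

import struct
from pathlib import Path

import numpy as np

__all__ = ["write_avi", "read_avi"]

_AVIF_HASINDEX = 0x00000010


def _row_stride(width: int) -> int:
    return (width * 3 + 3) & ~3


def _frame_to_dib(frame: np.ndarray) -> bytes:
    h, w, _ = frame.shape
    stride = _row_stride(w)
    bgr = frame[::-1, :, ::-1]  # bottom-up, BGR
    if stride == w * 3:
        return bgr.tobytes()
    padded = np.zeros((h, stride), dtype=np.uint8)
    padded[:, : w * 3] = bgr.reshape(h, w * 3)
    return padded.tobytes()


def _dib_to_frame(data: bytes, width: int, height: int) -> np.ndarray:
    stride = _row_stride(width)
    rows = np.frombuffer(data, dtype=np.uint8, count=stride * height)
    rows = rows.reshape(height, stride)[:, : width * 3].reshape(height, width, 3)
    return rows[::-1, :, ::-1].copy()


def write_avi(path, frames: np.ndarray, fps: float) -> None:
    """Write ``frames`` of shape (T, H, W, 3), dtype uint8, to an AVI file."""
    frames = np.asarray(frames)
    if frames.ndim != 4 or frames.shape[-1] != 3 or frames.dtype != np.uint8:
        raise ValueError("frames must be uint8 with shape (T, H, W, 3)")
    if fps <= 0:
        raise ValueError("fps must be positive")
    n, h, w, _ = frames.shape
    frame_bytes = _row_stride(w) * h
    rate, scale = int(round(fps * 1000)), 1000

    avih = struct.pack(
        "<14I",
        int(round(1e6 / fps)),  # dwMicroSecPerFrame
        frame_bytes * int(fps + 1),  # dwMaxBytesPerSec (advisory)
        0,  # dwPaddingGranularity
        _AVIF_HASINDEX,
        n,  # dwTotalFrames
        0,  # dwInitialFrames
        1,  # dwStreams
        frame_bytes,  # dwSuggestedBufferSize
        w, h, 0, 0, 0, 0,
    )
    strh = struct.pack(
        "<4s4sIHHIIIIIIIIhhhh",
        b"vids", b"DIB ", 0, 0, 0, 0,
        scale, rate, 0, n, frame_bytes, 0xFFFFFFFF, 0,
        0, 0, w, h,
    )
    strf = struct.pack("<IiiHHIIiiII", 40, w, h, 1, 24, 0, frame_bytes, 0, 0, 0, 0)

    def chunk(tag: bytes, payload: bytes) -> bytes:
        pad = b"\x00" if len(payload) % 2 else b""
        return tag + struct.pack("<I", len(payload)) + payload + pad

    def list_chunk(kind: bytes, payload: bytes) -> bytes:
        return chunk(b"LIST", kind + payload)

    strl = list_chunk(b"strl", chunk(b"strh", strh) + chunk(b"strf", strf))
    hdrl = list_chunk(b"hdrl", chunk(b"avih", avih) + strl)

    movi_payload = b""
    offsets = []
    for f in frames:
        offsets.append(len(movi_payload) + 4)  # offset from 'movi' fourcc
        movi_payload += chunk(b"00db", _frame_to_dib(f))
    movi = list_chunk(b"movi", movi_payload)

    idx = b"".join(
        struct.pack("<4sIII", b"00db", 0x10, off, frame_bytes) for off in offsets
    )
    body = b"AVI " + hdrl + movi + chunk(b"idx1", idx)
    with open(path, "wb") as fh:
        fh.write(b"RIFF" + struct.pack("<I", len(body)) + body)


def read_avi(path) -> tuple[np.ndarray, float]:
    """Read an uncompressed DIB AVI; returns ``(frames, fps)``."""
    data = Path(path).read_bytes()
    if len(data) < 12 or data[:4] != b"RIFF" or data[8:12] != b"AVI ":
        raise ValueError(f"not a RIFF/AVI file: {path}")

    width = height = None
    fps = None
    frames: list[np.ndarray] = []

    def walk(buf: bytes, pos: int, end: int) -> None:
        nonlocal width, height, fps
        while pos + 8 <= end:
            tag = buf[pos : pos + 4]
            (size,) = struct.unpack_from("<I", buf, pos + 4)
            payload_start = pos + 8
            payload_end = payload_start + size
            if tag == b"LIST":
                walk(buf, payload_start + 4, payload_end)
            elif tag == b"strh":
                stream_type, handler = struct.unpack_from("<4s4s", buf, payload_start)
                if stream_type == b"vids":
                    scale, rate = struct.unpack_from("<II", buf, payload_start + 20)
                    if scale:
                        fps = rate / scale
                    if handler not in (b"DIB ", b"\x00\x00\x00\x00", b"RGB "):
                        raise ValueError(
                            f"unsupported AVI codec {handler!r}; only "
                            "uncompressed DIB streams are decodable"
                        )
            elif tag == b"strf":
                _, w, h = struct.unpack_from("<Iii", buf, payload_start)
                width, height = w, abs(h)
            elif tag in (b"00db", b"00dc"):
                if width is None:
                    raise ValueError("AVI stream format missing before frame data")
                frames.append(
                    _dib_to_frame(buf[payload_start:payload_end], width, height)
                )
            pos = payload_end + (size & 1)

    walk(data, 12, 8 + struct.unpack_from("<I", data, 4)[0])
    if not frames:
        raise ValueError(f"no decodable video frames in {path}")
    return np.stack(frames), float(fps if fps else 25.0)
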